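"""Mechanistic synthetic HIV-cohort generator.

No patient-level data from the study this package models are publicly
deposited, so testing needs a cohort with the same *mechanistic* structure:

* HIV infection duration drives SHBG upward (log-linear);
* in eugonadal and compensated men the pituitary defends a free-testosterone
  set point: latent free T is drawn near its set point, LH rises as a power
  law in SHBG, and total T follows by exact mass-action inversion — so TT
  is *high* when SHBG is high even though free T is unchanged;
* in overt hypogonadism the defence has failed: free T is drawn below the
  diagnostic cutoff and LH places the lesion (high = primary testicular
  failure, low = secondary/pituitary, in-range = normogonadotropic);
* compensated men have longer infection histories, hence higher SHBG, and
  their LH is elevated by construction.

This reproduces the observed correlation pattern — SHBG positively
correlated with TT, LH and infection duration, but *not* with calculated
free testosterone — as an emergent property rather than by direct
imposition.

Besides the stochastic generator, the module builds deterministic fixture
cohorts whose classification marginals match the published three-step
work-up exactly (Groups A, B and C), via stratified rejection sampling with
a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .classify import DEFAULT_LIMITS, GonadalClass, ReferenceLimits
from .hormones import (
    DEFAULT_CONSTANTS,
    BindingConstants,
    HormonePanel,
    PatientRecord,
    invert_free_to_total,
)

__all__ = [
    "SyntheticCohortConfig",
    "generate_cohort",
    "fixture_group_a",
    "fixture_group_b",
    "fixture_group_c",
    "GROUP_C_CLASS_COUNTS",
]

#: latent class order used by ``class_mix``
CLASS_ORDER = (
    GonadalClass.EUGONADAL,
    GonadalClass.COMPENSATED,
    GonadalClass.PRIMARY,
    GonadalClass.SECONDARY,
    GonadalClass.NORMOGONADOTROPIC,
)

#: the published Group C composition the default mix reproduces (n=94)
GROUP_C_CLASS_COUNTS = {
    GonadalClass.EUGONADAL: 62,
    GonadalClass.COMPENSATED: 13,
    GonadalClass.PRIMARY: 5,
    GonadalClass.SECONDARY: 2,
    GonadalClass.NORMOGONADOTROPIC: 12,
}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Distribution, set-point and class-mix parameters of the generator.

    Defaults are calibrated to the published Group C cohort: class mix
    (66.0% eugonadal, 13.8% compensated, 5.3% primary, 2.1% secondary,
    12.8% normogonadotropic), infection duration median ~11 y (compensated
    ~25.5 y), SHBG median ~63 nmol/l rising ~3%/year of infection, free-T
    set point centred at 100 pg/ml, overt free T centred at 52 pg/ml, and
    LH baseline 4.8 mUI/ml with a mild SHBG power law for eugonadal men and
    a steep one for compensated men.
    """

    n: int = 94
    seed: int = 0
    class_mix: tuple = (0.660, 0.138, 0.053, 0.021, 0.128)
    # lognormal (log-mean, log-sd), years
    duration_dist: tuple = (math.log(11.0), 0.60)
    duration_dist_compensated: tuple = (math.log(25.5), 0.30)
    # log-SHBG = intercept + slope * duration + N(0, sd); SHBG in nmol/l
    shbg_model: tuple = (3.78, 0.03, 0.33)
    # free-T set point (mean, sd) pg/ml, truncated above the cFT cutoff;
    # the compensated set point sits lower — the pituitary holds the free
    # level just inside the normal range, not at the eugonadal centre
    setpoint_ft: tuple = (100.0, 25.0)
    setpoint_ft_compensated: tuple = (90.0, 22.0)
    # overt free T (mean, sd) pg/ml, truncated at/below the cFT cutoff
    overt_ft_dist: tuple = (52.0, 12.0)
    # LH = baseline * (SHBG/shbg_ref)^gamma * exp(N(0, sd)); mUI/ml
    lh_model: tuple = (4.8, 0.4, 0.25)
    lh_gamma_compensated: float = 2.8
    # primary hypogonadism LH (testicular failure: high regardless of SHBG),
    # lognormal truncated above lh_upper
    primary_lh_dist: tuple = (math.log(13.0), 0.30)
    # secondary hypogonadism LH, lognormal truncated below lh_lower
    secondary_lh_dist: tuple = (math.log(0.9), 0.30)
    shbg_ref: float = 63.0
    # covariates (independent of hormones)
    age_dist: tuple = (53.0, 7.0)                  # normal, truncated > 18
    bmi_dist: tuple = (math.log(25.1), 0.14)       # lognormal
    cd4_nadir_dist: tuple = (math.log(132.0), 0.62)
    cd4_pct_dist: tuple = (math.log(14.6), 0.36)
    cart_lag_mean: float = 3.0                     # years, exponential
    albumin: float = 4.3                           # g/dl, fixed for all
    constants: BindingConstants = field(default_factory=BindingConstants)
    limits: ReferenceLimits = field(default_factory=ReferenceLimits)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("cohort size must be positive")
        if len(self.class_mix) != len(CLASS_ORDER):
            raise ValueError("class_mix must have five probabilities "
                             "(eugonadal, compensated, primary, secondary, "
                             "normogonadotropic)")
        mix = np.asarray(self.class_mix, dtype=float)
        if np.any(mix < 0) or not math.isclose(mix.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("class_mix must be non-negative and sum to 1")
        for name in ("duration_dist", "duration_dist_compensated",
                     "shbg_model", "setpoint_ft", "overt_ft_dist",
                     "lh_model", "secondary_lh_dist"):
            if getattr(self, name)[-1] < 0:
                raise ValueError(f"{name} spread must be >= 0")


def _rejection(rng: np.random.Generator, size: int,
               draw: Callable[[np.random.Generator, int], np.ndarray],
               ok: Callable[[np.ndarray], np.ndarray],
               max_iter: int = 10_000) -> np.ndarray:
    """Vectorised rejection sampling: redraw entries failing ``ok``."""
    out = np.empty(size, dtype=float)
    pending = np.arange(size)
    for _ in range(max_iter):
        cand = draw(rng, pending.size)
        good = ok(cand)
        out[pending[good]] = cand[good]
        pending = pending[~good]
        if pending.size == 0:
            return out
    raise RuntimeError("rejection sampling failed to converge; the "
                       "configured truncation region has negligible mass")


def _draw_shbg(rng, duration, cfg: SyntheticCohortConfig,
               lo: float = 0.0, hi: float = np.inf) -> np.ndarray:
    """SHBG conditional on infection duration, truncated to (lo, hi]."""
    icpt, slope, sd = cfg.shbg_model
    mu = icpt + slope * np.asarray(duration, dtype=float)
    return _trunc_lognormal(rng, mu, sd, lo, hi, mu.size)


def _trunc_lognormal(rng, log_med, sd: float, lo: float, hi: float,
                     size: int) -> np.ndarray:
    """Exact inverse-CDF draws from a lognormal truncated to [lo, hi].

    Stays accurate even when the truncation region sits far in a tail
    (compensated records with modest SHBG still need LH above the upper
    reference limit).
    """
    from scipy import stats as sps

    log_med = np.broadcast_to(np.asarray(log_med, dtype=float), (size,))
    if sd == 0:
        return np.exp(log_med.copy())
    u = rng.uniform(size=size)
    a = (math.log(lo) - log_med) / sd if lo > 0 else np.full(size, -np.inf)
    b = (math.log(hi) - log_med) / sd if np.isfinite(hi) else np.full(
        size, np.inf)
    if np.isfinite(hi):
        lo_cdf = sps.norm.cdf(a)
        z = sps.norm.ppf(lo_cdf + u * (sps.norm.cdf(b) - lo_cdf))
    else:
        # one-sided lower truncation: work on the survival scale for
        # precision deep in the upper tail
        z = sps.norm.isf(u * sps.norm.sf(a))
    return np.exp(log_med + sd * z)


def _draw_lh(rng, shbg, cfg: SyntheticCohortConfig, gamma: float,
             lo: float = 0.0, hi: float = np.inf) -> np.ndarray:
    """LH from the SHBG power law, optionally truncated to [lo, hi]."""
    base, _, sd = cfg.lh_model
    log_med = (math.log(base)
               + gamma * np.log(np.asarray(shbg, dtype=float) / cfg.shbg_ref))
    return _trunc_lognormal(rng, log_med, sd, lo, hi, log_med.size)


def _draw_covariates(rng, n: int, duration, cfg: SyntheticCohortConfig):
    age = _rejection(rng, n,
                     lambda r, k: r.normal(*cfg.age_dist, size=k),
                     lambda v: v > 18.5)
    bmi = np.exp(rng.normal(cfg.bmi_dist[0], cfg.bmi_dist[1], size=n))
    cd4 = np.exp(rng.normal(cfg.cd4_nadir_dist[0], cfg.cd4_nadir_dist[1],
                            size=n))
    cd4p = np.exp(rng.normal(cfg.cd4_pct_dist[0], cfg.cd4_pct_dist[1],
                             size=n))
    cd4p = np.minimum(cd4p, 60.0)
    lag = rng.exponential(cfg.cart_lag_mean, size=n)
    cart = np.maximum(np.asarray(duration) - lag, 0.0)
    return age, bmi, cd4, cd4p, cart


def generate_cohort(config: SyntheticCohortConfig,
                    return_latents: bool = False):
    """Draw a synthetic cohort of :class:`PatientRecord`.

    Each record gets a latent gonadal class from ``class_mix``; hormone
    values follow the mechanistic model described in the module docstring,
    with total testosterone produced by exact mass-action inversion of the
    latent free level (so the free-T solver recovers the latent exactly).

    With ``return_latents=True`` also returns a dict of latent arrays
    (``class_``, ``ft``) for parameter-recovery studies.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lim = cfg.limits
    n = cfg.n

    classes = rng.choice(len(CLASS_ORDER), size=n, p=np.asarray(cfg.class_mix))
    is_comp = classes == CLASS_ORDER.index(GonadalClass.COMPENSATED)
    is_overt = np.isin(classes, [CLASS_ORDER.index(c) for c in
                                 (GonadalClass.PRIMARY,
                                  GonadalClass.SECONDARY,
                                  GonadalClass.NORMOGONADOTROPIC)])

    # infection duration: compensated men have longer histories
    dur = np.where(
        is_comp,
        np.exp(rng.normal(*cfg.duration_dist_compensated, size=n)),
        np.exp(rng.normal(*cfg.duration_dist, size=n)),
    )
    shbg = _draw_shbg(rng, dur, cfg)

    # latent free testosterone: defended set point unless overt
    ft = np.empty(n)
    is_eug = ~(is_overt | is_comp)
    ft[is_eug] = _rejection(
        rng, int(is_eug.sum()),
        lambda r, k: r.normal(*cfg.setpoint_ft, size=k),
        lambda v: v > lim.cft_lower)
    ft[is_comp] = _rejection(
        rng, int(is_comp.sum()),
        lambda r, k: r.normal(*cfg.setpoint_ft_compensated, size=k),
        lambda v: v > lim.cft_lower)
    n_ov = int(is_overt.sum())
    ft[is_overt] = _rejection(
        rng, n_ov,
        lambda r, k: r.normal(*cfg.overt_ft_dist, size=k),
        lambda v: (v > 0) & (v <= lim.cft_lower))

    # LH by class
    lh = np.empty(n)
    for idx, cls in enumerate(CLASS_ORDER):
        mask = classes == idx
        if not mask.any():
            continue
        if cls is GonadalClass.EUGONADAL:
            lh[mask] = _draw_lh(rng, shbg[mask], cfg, cfg.lh_model[1])
        elif cls is GonadalClass.COMPENSATED:
            lh[mask] = _draw_lh(rng, shbg[mask], cfg,
                                cfg.lh_gamma_compensated,
                                lo=np.nextafter(lim.lh_upper, np.inf))
        elif cls is GonadalClass.PRIMARY:
            mu, sd = cfg.primary_lh_dist
            lh[mask] = _rejection(
                rng, int(mask.sum()),
                lambda r, k: np.exp(r.normal(mu, sd, size=k)),
                lambda v: v > lim.lh_upper)
        elif cls is GonadalClass.SECONDARY:
            mu, sd = cfg.secondary_lh_dist
            lh[mask] = _rejection(
                rng, int(mask.sum()),
                lambda r, k: np.exp(r.normal(mu, sd, size=k)),
                lambda v: v < lim.lh_lower)
        else:  # normogonadotropic: LH within the reference range
            lh[mask] = _draw_lh(rng, shbg[mask], cfg, cfg.lh_model[1],
                                lo=lim.lh_lower, hi=lim.lh_upper)

    tt = invert_free_to_total(ft, shbg, cfg.albumin, cfg.constants)
    age, bmi, cd4, cd4p, cart = _draw_covariates(rng, n, dur, cfg)

    order = rng.permutation(n)
    records = []
    for pos, i in enumerate(order):
        records.append(PatientRecord(
            id=f"S{pos:04d}",
            panel=HormonePanel(tt=float(tt[i]), shbg=float(shbg[i]),
                               lh=float(lh[i]), albumin=cfg.albumin),
            age=float(age[i]), bmi=float(bmi[i]),
            hiv_duration=float(dur[i]), cart_duration=float(cart[i]),
            cd4_nadir=float(cd4[i]), cd4_nadir_pct=float(cd4p[i]),
            symptomatic=True,
        ))
    if return_latents:
        latents = {
            "class_": [CLASS_ORDER[classes[i]] for i in order],
            "ft": ft[order],
        }
        return records, latents
    return records


# ---------------------------------------------------------------------------
# Deterministic fixtures reproducing the published three-step marginals
# ---------------------------------------------------------------------------

def _draw_one(rng, cfg: SyntheticCohortConfig, *,
              latent: GonadalClass,
              shbg_lo: float = 0.0, shbg_hi: float = np.inf,
              tt_lo: float = 0.0, tt_hi: float = np.inf,
              lh_lo: float = 0.0, lh_hi: float = np.inf,
              with_lh: bool = True,
              max_iter: int = 100_000) -> dict:
    """One record satisfying hard stratum constraints, by rejection."""
    lim = cfg.limits
    comp = latent is GonadalClass.COMPENSATED
    overt = latent in (GonadalClass.PRIMARY, GonadalClass.SECONDARY,
                       GonadalClass.NORMOGONADOTROPIC)
    for _ in range(max_iter):
        ddist = cfg.duration_dist_compensated if comp else cfg.duration_dist
        dur = float(np.exp(rng.normal(*ddist)))
        shbg = float(_draw_shbg(rng, np.array([dur]), cfg,
                                lo=shbg_lo, hi=shbg_hi)[0])
        if overt:
            ft = float(_rejection(
                rng, 1, lambda r, k: r.normal(*cfg.overt_ft_dist, size=k),
                lambda v: (v > 0) & (v <= lim.cft_lower))[0])
        else:
            sp = (cfg.setpoint_ft_compensated if comp else cfg.setpoint_ft)
            ft = float(_rejection(
                rng, 1, lambda r, k: r.normal(*sp, size=k),
                lambda v: v > lim.cft_lower)[0])
        tt = float(invert_free_to_total(ft, shbg, cfg.albumin, cfg.constants))
        if not (tt_lo <= tt < tt_hi):
            continue
        rec = {"duration": dur, "shbg": shbg, "ft": ft, "tt": tt,
               "latent": latent}
        if not with_lh:
            rec["lh"] = None
            return rec
        if latent is GonadalClass.SECONDARY:
            mu, sd = cfg.secondary_lh_dist
            lh = float(_rejection(
                rng, 1, lambda r, k: np.exp(r.normal(mu, sd, size=k)),
                lambda v: v < lim.lh_lower)[0])
        elif latent is GonadalClass.PRIMARY:
            mu, sd = cfg.primary_lh_dist
            lh = float(_rejection(
                rng, 1, lambda r, k: np.exp(r.normal(mu, sd, size=k)),
                lambda v: v > lim.lh_upper)[0])
        elif latent is GonadalClass.COMPENSATED:
            lh = float(_draw_lh(rng, np.array([shbg]), cfg,
                                cfg.lh_gamma_compensated,
                                lo=np.nextafter(lim.lh_upper, np.inf))[0])
        elif latent is GonadalClass.NORMOGONADOTROPIC:
            lh = float(_draw_lh(rng, np.array([shbg]), cfg, cfg.lh_model[1],
                                lo=lim.lh_lower, hi=lim.lh_upper)[0])
        else:  # eugonadal: LH constrained within range (and stratum bounds)
            lh = float(_draw_lh(rng, np.array([shbg]), cfg, cfg.lh_model[1],
                                lo=max(lh_lo, lim.lh_lower),
                                hi=min(lh_hi, lim.lh_upper))[0])
        rec["lh"] = lh
        return rec
    raise RuntimeError("fixture stratum constraints could not be satisfied")


def _assemble(rows: list[dict], rng, cfg: SyntheticCohortConfig,
              prefix: str) -> list[PatientRecord]:
    n = len(rows)
    dur = np.array([r["duration"] if r["duration"] is not None else
                    float(np.exp(rng.normal(*cfg.duration_dist)))
                    for r in rows])
    age, bmi, cd4, cd4p, cart = _draw_covariates(rng, n, dur, cfg)
    order = rng.permutation(n)
    out = []
    for pos, i in enumerate(order):
        r = rows[i]
        out.append(PatientRecord(
            id=f"{prefix}{pos:03d}",
            panel=HormonePanel(tt=r["tt"], shbg=r["shbg"], lh=r["lh"],
                               albumin=cfg.albumin if r["shbg"] is not None
                               else None),
            age=float(age[i]), bmi=float(bmi[i]), hiv_duration=float(dur[i]),
            cart_duration=float(cart[i]), cd4_nadir=float(cd4[i]),
            cd4_nadir_pct=float(cd4p[i]), symptomatic=True,
        ))
    return out


def fixture_group_c(seed: int = 0,
                    config: Optional[SyntheticCohortConfig] = None
                    ) -> list[PatientRecord]:
    """Deterministic 94-record full-profile cohort with exact marginals.

    Classified at step C the cohort yields exactly 62 eugonadal,
    13 compensated, 5 primary, 2 secondary and 12 normogonadotropic records
    (19 overt, 20.2%); exactly 10 records have TT below 3.46 ng/ml; exactly
    34 records have SHBG above 70 nmol/l, 18 of them eugonadal.  Built by
    stratified rejection sampling, so repeated calls with the same seed are
    identical.
    """
    cfg = config or SyntheticCohortConfig()
    lim = cfg.limits
    rng = np.random.default_rng(seed)
    eps_tt = lim.tt_lower  # strict boundary: [0, tt_lower) vs [tt_lower, inf)
    hi_shbg = np.nextafter(lim.shbg_upper, np.inf)

    strata = [
        # (count, latent, shbg_lo, shbg_hi, tt_lo, tt_hi)
        (18, GonadalClass.EUGONADAL, hi_shbg, np.inf, eps_tt, np.inf),
        (44, GonadalClass.EUGONADAL, 0.0, lim.shbg_upper, eps_tt, np.inf),
        (13, GonadalClass.COMPENSATED, hi_shbg, np.inf, eps_tt, np.inf),
        # overt meeting the TT criterion (10 in total)
        (3, GonadalClass.PRIMARY, 0.0, lim.shbg_upper, 0.0, eps_tt),
        (1, GonadalClass.SECONDARY, 0.0, lim.shbg_upper, 0.0, eps_tt),
        (6, GonadalClass.NORMOGONADOTROPIC, 0.0, lim.shbg_upper, 0.0, eps_tt),
        # overt by cFT only, normal SHBG (6)
        (1, GonadalClass.PRIMARY, 0.0, lim.shbg_upper, eps_tt, np.inf),
        (1, GonadalClass.SECONDARY, 0.0, lim.shbg_upper, eps_tt, np.inf),
        (4, GonadalClass.NORMOGONADOTROPIC, 0.0, lim.shbg_upper,
         eps_tt, np.inf),
        # overt by cFT only, high SHBG (3) -> 34 high-SHBG in total
        (1, GonadalClass.PRIMARY, hi_shbg, np.inf, eps_tt, np.inf),
        (2, GonadalClass.NORMOGONADOTROPIC, hi_shbg, np.inf, eps_tt, np.inf),
    ]
    rows = []
    for count, latent, slo, shi, tlo, thi in strata:
        for _ in range(count):
            rows.append(_draw_one(rng, cfg, latent=latent, shbg_lo=slo,
                                  shbg_hi=shi, tt_lo=tlo, tt_hi=thi))
    return _assemble(rows, rng, cfg, prefix="C")


def fixture_group_b(seed: int = 0,
                    config: Optional[SyntheticCohortConfig] = None
                    ) -> list[PatientRecord]:
    """Deterministic 118-record TT+SHBG+cFT cohort (no LH).

    Exactly 22 records are overt (18.6%): 10 meet the TT criterion and 12
    are caught only by low calculated free testosterone, so the
    full-profile to TT-alone diagnosis ratio is 22/10 = 2.2.
    """
    cfg = config or SyntheticCohortConfig()
    lim = cfg.limits
    rng = np.random.default_rng(seed)
    eps_tt = lim.tt_lower
    strata = [
        (96, GonadalClass.EUGONADAL, eps_tt, np.inf),
        (10, GonadalClass.NORMOGONADOTROPIC, 0.0, eps_tt),   # low TT
        (12, GonadalClass.NORMOGONADOTROPIC, eps_tt, np.inf),  # cFT only
    ]
    rows = []
    for count, latent, tlo, thi in strata:
        for _ in range(count):
            rows.append(_draw_one(rng, cfg, latent=latent, tt_lo=tlo,
                                  tt_hi=thi, with_lh=False))
    return _assemble(rows, rng, cfg, prefix="B")


def fixture_group_a(seed: int = 0,
                    config: Optional[SyntheticCohortConfig] = None
                    ) -> list[PatientRecord]:
    """Deterministic 169-record TT-only cohort: exactly 14 below the TT
    cutoff (8.3%)."""
    cfg = config or SyntheticCohortConfig()
    lim = cfg.limits
    rng = np.random.default_rng(seed)
    tts = np.concatenate([
        _rejection(rng, 155,
                   lambda r, k: np.exp(r.normal(math.log(6.8), 0.40, size=k)),
                   lambda v: v >= lim.tt_lower),
        _rejection(rng, 14,
                   lambda r, k: np.exp(r.normal(math.log(2.7), 0.25, size=k)),
                   lambda v: (v > 0) & (v < lim.tt_lower)),
    ])
    rows = [{"duration": None, "shbg": None, "ft": None, "tt": float(t),
             "lh": None, "latent": None} for t in tts]
    return _assemble(rows, rng, cfg, prefix="A")
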