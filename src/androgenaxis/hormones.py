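"""Domain types, unit conversions and the mass-action free-testosterone solver.

Circulating testosterone partitions between a free fraction, a high-affinity
SHBG-bound pool and a low-affinity albumin-bound pool. At equilibrium the
total concentration (all terms molar) satisfies

    TT = FT * (1 + Ka * Calb) + Kt * FT * SHBG / (1 + Kt * FT)

where ``Kt`` and ``Ka`` are the SHBG- and albumin-testosterone association
constants and ``Calb`` the molar albumin concentration.  Free testosterone is
the unique non-negative root of this mass balance — the quantity clinical
calculators report as *calculated free testosterone* (cFT).

All public I/O uses the clinical units (TT in ng/ml, SHBG in nmol/l, albumin
in g/dl, cFT in pg/ml); the equilibrium itself is solved in mol/l.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BindingConstants",
    "HormonePanel",
    "PatientRecord",
    "DEFAULT_CONSTANTS",
    "t_ngml_to_nmoll",
    "t_nmoll_to_ngml",
    "ft_pgml_to_moll",
    "ft_moll_to_pgml",
    "calc_free_testosterone",
    "invert_free_to_total",
]


@dataclass(frozen=True)
class BindingConstants:
    """Association constants and albumin parameters for the equilibrium.

    Defaults are the constants behind the widely used free-testosterone
    calculators: Kt = 1.0e9 L/mol for SHBG, Ka = 3.6e4 L/mol for albumin,
    with albumin defaulted to 4.3 g/dl when unmeasured.
    """

    k_shbg: float = 1.0e9
    k_albumin: float = 3.6e4
    albumin_default: float = 4.3
    mw_testosterone: float = 288.42
    mw_albumin: float = 69_000.0

    def __post_init__(self) -> None:
        for name in ("k_shbg", "k_albumin", "albumin_default",
                     "mw_testosterone", "mw_albumin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.k_shbg / self.k_albumin <= 1e3:
            raise ValueError("SHBG affinity must exceed albumin affinity "
                             "by more than 10^3 (k_shbg >> k_albumin)")


DEFAULT_CONSTANTS = BindingConstants()


def t_ngml_to_nmoll(x, mw: float = DEFAULT_CONSTANTS.mw_testosterone):
    """Convert a testosterone concentration from ng/ml to nmol/l."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration must be non-negative")
    out = x * 1000.0 / mw
    return float(out) if out.ndim == 0 else out


def t_nmoll_to_ngml(x, mw: float = DEFAULT_CONSTANTS.mw_testosterone):
    """Convert a testosterone concentration from nmol/l to ng/ml."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration must be non-negative")
    out = x * mw / 1000.0
    return float(out) if out.ndim == 0 else out


def ft_pgml_to_moll(x, mw: float = DEFAULT_CONSTANTS.mw_testosterone):
    """Convert free testosterone from pg/ml to mol/l."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration must be non-negative")
    out = x / (mw * 1e9)
    return float(out) if out.ndim == 0 else out


def ft_moll_to_pgml(x, mw: float = DEFAULT_CONSTANTS.mw_testosterone):
    """Convert free testosterone from mol/l to pg/ml."""
    x = np.asarray(x, dtype=float)
    out = x * mw * 1e9
    return float(out) if out.ndim == 0 else out


def _albumin_gdl_to_moll(albumin_gdl, mw_albumin: float):
    # g/dl * 10 = g/l ; divide by molar mass -> mol/l
    return np.asarray(albumin_gdl, dtype=float) * 10.0 / mw_albumin


def calc_free_testosterone(tt, shbg, albumin: Optional[float] = None,
                           constants: BindingConstants = DEFAULT_CONSTANTS):
    """Calculated free testosterone (pg/ml) from TT, SHBG and albumin.

    Parameters
    ----------
    tt : float or array
        Total testosterone, ng/ml.
    shbg : float or array
        SHBG, nmol/l.
    albumin : float or array, optional
        Albumin, g/dl.  When ``None`` the ``constants.albumin_default`` is
        used and a notice is logged (most laboratories do not report
        albumin alongside the gonadal panel).
    constants : BindingConstants
        Association constants and molecular weights.

    Returns
    -------
    float or ndarray
        Free testosterone in pg/ml: the unique non-negative root of the
        molar mass balance, evaluated in closed form with the numerically
        stable branch of the quadratic formula.
    """
    if albumin is None:
        logger.info("albumin not provided; using default %.2f g/dl",
                    constants.albumin_default)
        albumin = constants.albumin_default
    tt = np.asarray(tt, dtype=float)
    shbg = np.asarray(shbg, dtype=float)
    albumin = np.asarray(albumin, dtype=float)
    if np.any(tt < 0) or np.any(shbg < 0) or np.any(albumin < 0):
        raise ValueError("tt, shbg and albumin must all be non-negative")

    kt = constants.k_shbg
    ka = constants.k_albumin
    tt_m = tt * 1e-6 / constants.mw_testosterone      # ng/ml -> mol/l
    shbg_m = shbg * 1e-9                              # nmol/l -> mol/l
    calb = _albumin_gdl_to_moll(albumin, constants.mw_albumin)

    # A*Kt*FT^2 + B*FT - TT = 0 with A = 1 + Ka*Calb, B = A + Kt*(SHBG - TT).
    a = 1.0 + ka * calb
    b = a + kt * (shbg_m - tt_m)
    disc = np.sqrt(b * b + 4.0 * a * kt * tt_m)
    # Citardauq form when B >= 0 avoids cancellation between -B and sqrt(disc);
    # the classical form is the stable one when B < 0.
    with np.errstate(invalid="ignore", divide="ignore"):
        ft_m = np.where(
            b >= 0,
            np.divide(2.0 * tt_m, b + disc, out=np.zeros_like(disc),
                      where=(b + disc) > 0),
            (disc - b) / (2.0 * a * kt),
        )
    out = ft_moll_to_pgml(ft_m, constants.mw_testosterone)
    return float(out) if np.ndim(out) == 0 else out


def invert_free_to_total(ft, shbg, albumin: Optional[float] = None,
                         constants: BindingConstants = DEFAULT_CONSTANTS):
    """Total testosterone (ng/ml) implied by a free level — the exact inverse.

    Evaluates the mass balance forward: given free testosterone (pg/ml),
    SHBG (nmol/l) and albumin (g/dl), returns the total concentration in
    ng/ml.  ``calc_free_testosterone`` composed with this function is the
    identity to high relative precision; the synthetic cohort generator uses
    it to produce totals from latent free levels.
    """
    if albumin is None:
        albumin = constants.albumin_default
    ft = np.asarray(ft, dtype=float)
    shbg = np.asarray(shbg, dtype=float)
    albumin = np.asarray(albumin, dtype=float)
    if np.any(ft < 0) or np.any(shbg < 0) or np.any(albumin < 0):
        raise ValueError("ft, shbg and albumin must all be non-negative")

    kt = constants.k_shbg
    ka = constants.k_albumin
    ft_m = ft_pgml_to_moll(ft, constants.mw_testosterone)
    shbg_m = shbg * 1e-9
    calb = _albumin_gdl_to_moll(albumin, constants.mw_albumin)

    tt_m = ft_m * (1.0 + ka * calb) + kt * ft_m * shbg_m / (1.0 + kt * ft_m)
    out = tt_m * constants.mw_testosterone * 1e6  # mol/l -> ng/ml
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class HormonePanel:
    """One patient's hormone measurements.

    ``cft`` is always derived from TT/SHBG/albumin by the mass-action
    solver — direct free-testosterone immunoassay values are not accepted,
    because direct measurement is unreliable; use :meth:`with_cft`.
    """

    tt: float                       # total testosterone, ng/ml
    shbg: Optional[float] = None    # nmol/l
    lh: Optional[float] = None      # mUI/ml
    albumin: Optional[float] = None  # g/dl
    cft: Optional[float] = field(default=None, compare=True)  # pg/ml, derived

    def __post_init__(self) -> None:
        for name in ("tt", "shbg", "lh", "albumin", "cft"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_cft(self, constants: BindingConstants = DEFAULT_CONSTANTS
                 ) -> "HormonePanel":
        """Return a copy with cFT computed from TT, SHBG and albumin."""
        if self.shbg is None:
            raise ValueError("SHBG is required to calculate free testosterone")
        cft = calc_free_testosterone(self.tt, self.shbg, self.albumin,
                                     constants)
        return replace(self, cft=cft)

    def check_mass_balance(self, constants: BindingConstants = DEFAULT_CONSTANTS,
                           rtol: float = 1e-9) -> bool:
        """True when the stored cFT satisfies the mass balance for this panel."""
        if self.cft is None or self.shbg is None:
            return False
        expected = calc_free_testosterone(self.tt, self.shbg, self.albumin,
                                          constants)
        return math.isclose(self.cft, expected, rel_tol=rtol, abs_tol=1e-12)


@dataclass(frozen=True)
class PatientRecord:
    """A single analysis-eligible patient: clinical covariates plus hormones.

    Cohort inclusion requires adult age and the presence of sexual symptoms;
    classification refuses a clinical hypogonadism label for asymptomatic
    records.
    """

    id: str
    panel: HormonePanel
    age: Optional[float] = None            # years
    bmi: Optional[float] = None            # kg/m^2
    hiv_duration: Optional[float] = None   # years since HIV diagnosis
    cart_duration: Optional[float] = None  # years on cART
    cd4_nadir: Optional[float] = None      # cells/mm^3
    cd4_nadir_pct: Optional[float] = None  # percent
    symptomatic: bool = True

    def __post_init__(self) -> None:
        if self.age is not None and self.age <= 18:
            raise ValueError("inclusion requires age > 18 years")
        for name in ("hiv_duration", "cart_duration", "cd4_nadir",
                     "cd4_nadir_pct"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if (self.cart_duration is not None and self.hiv_duration is not None
                and self.cart_duration > self.hiv_duration + 1):
            raise ValueError("cART duration cannot exceed HIV duration "
                             "(+1 year rounding tolerance)")
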