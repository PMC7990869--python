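# Methods

## Free testosterone by mass-action equilibrium

Testosterone partitions between a free pool, SHBG (high affinity) and
albumin (low affinity, high capacity). With all concentrations molar, the
bound pools are `Kt·FT·SHBG/(1 + Kt·FT)` and `Ka·C_alb·FT`, giving the
mass balance

```
TT = FT·(1 + Ka·C_alb) + Kt·FT·SHBG/(1 + Kt·FT).
```

This is quadratic in FT with exactly one non-negative root. We evaluate
the root in closed form, choosing the branch of the quadratic formula
that avoids catastrophic cancellation (`2c/(B+√(B²+4AKt·c))` when the
linear coefficient `B ≥ 0`, the classical form otherwise). Correctness is
*defined* by the mass balance, not by the algebra: the test suite checks
the closed form against an independent bracketing root-finder
(`scipy.optimize.brentq`) to 1e-9 relative over the full clinical range
(TT 0.5–15 ng/ml, SHBG 5–200 nmol/l, albumin 3–5.5 g/dl), plus
monotonicity (cFT strictly ↓ in SHBG and albumin, ↑ in TT), boundedness
(0 ≤ cFT ≤ TT) and the no-binder limit cFT → TT.

Parameters (exposed in `BindingConstants`, overridable via config):

| parameter | value | unit | note |
|---|---|---|---|
| `k_shbg` (Kt) | 1.0×10⁹ | L/mol | SHBG–T association |
| `k_albumin` (Ka) | 3.6×10⁴ | L/mol | albumin–T association |
| `albumin_default` | 4.3 | g/dl | used when albumin unmeasured |
| MW testosterone | 288.42 | g/mol | unit conversions |
| MW albumin | 69 000 | g/mol | g/dl → mol/l |

These are the constants behind the widely used online free-testosterone
calculators. Laboratories rarely report albumin with the gonadal panel,
so the default path is assumed; a measured value can always be supplied.
Direct free-T immunoassay values are deliberately not accepted as input —
analog free-T assays are unreliable, and cFT is always recomputed from
TT/SHBG/albumin. Internal computation is in mol/l; all I/O uses clinical
units (ng/ml, nmol/l, pg/ml, g/dl).

Assay imprecision (interassay CV of a few percent) is not propagated into
cFT uncertainty; the package reports point values, as clinical
calculators do.

## Classification rules and boundary semantics

- TT hypogonadal when **strictly below** 3.46 ng/ml ("below" the limit).
- cFT low when **≤** 65 pg/ml (the "low if ≤" convention; boundary
  inclusive).
- LH normal on the **closed** interval [1.5, 9.4] mUI/ml; "high" means
  > 9.4, "low" means < 1.5.
- SHBG high when **strictly above** 70 nmol/l.

Overt = low TT and/or low cFT. Overt cases split by LH into primary
(high), secondary (low) and normogonadotropic (in range) — the standard
endocrine reading of "low to normal gonadotropins with a testicular
deficit". Non-overt with high LH is compensated. A normal-T patient with
isolated low LH receives no diagnostic class; the finding is surfaced as
an `isolated_low_lh` flag rather than inventing a category. Percentages
and ratios round half-up to one decimal, matching how such tables are
printed.

Classification functions operate on hormone values alone; the cohort
entry point (`classify_cohort`) enforces the clinical gate that only
symptomatic patients can receive a hypogonadism label, and excludes
asymptomatic rows with a logged count.

Missing LH downgrades a record to the step-B (TT+SHBG+cFT) call with an
`lh_missing` flag and a cohort-level warning; missing SHBG restricts it
to step A. The pipeline mirrors clinical nesting: every record with TT
enters step A, those with SHBG enter step B, those with LH as well enter
step C, and the report states n per step.

## Statistics

Hormone variables in such cohorts are not normal (screened with the
D'Agostino–Pearson omnibus K² test, which requires n ≥ 20), so all
comparisons are rank-based. Group contrasts use Kruskal–Wallis H with tie
correction (scipy), followed by Dunn's post-hoc test only when H is
significant. Dunn's test is implemented in-package (pooled-rank pairwise
z with the `Σ(t³−t)/(12(N−1))` tie term); it is validated in tests
against the two-group identity `z² = H` and a permutation oracle. Because
no standard correction is canonical here, both unadjusted and
Bonferroni-adjusted p-values are reported, with significance decided on
the adjusted ones. Associations use Spearman's rho on average ranks with
the t-approximation for p, pairwise-complete deletion, and an explicit
"undefined" result (rather than NaN) under zero variance. Quartiles use
linear interpolation between order statistics (the common
statistical-software default; configurable). Significance is declared at
p ≤ 0.05.

## The synthetic cohort generator

No patient-level data are available for this clinical setting, so the
package ships a *mechanistic* generator whose defaults are calibrated to
a published 94-patient full-profile cohort and which encodes the
pathophysiological reading of that cohort:

1. **Latent class** from `class_mix`, default (0.660, 0.138, 0.053,
   0.021, 0.128) for eugonadal / compensated / primary / secondary /
   normogonadotropic — the full-profile class proportions.
2. **Infection duration** lognormal, median 11 y (log-sd 0.60); the
   compensated class draws from an upshifted distribution (median 25.5 y,
   log-sd 0.30), matching the observed longer histories.
3. **SHBG** lognormal with log-mean `3.78 + 0.03·duration` (log-sd 0.33):
   SHBG rises ~3%/year of infection, giving an overall median ≈ 63 nmol/l
   and IQR close to the calibration cohort.
4. **Free-T set point**: eugonadal latents draw FT ~ N(100, 25) pg/ml
   truncated above the 65 pg/ml cutoff (eugonadal cFT median ≈ 106);
   compensated latents draw from N(90, 22) — their free level is held
   just inside the normal range (observed compensated median 89.1), not
   at the eugonadal centre. Overt latents draw N(52, 12) truncated at or
   below the cutoff (observed overt median 53.7).
5. **LH** follows a power law in SHBG, `4.8·(SHBG/63)^γ·lognoise`
   (log-sd 0.25): γ = 0.4 for eugonadal men, γ = 2.8 for compensated men
   (truncated above 9.4 — elevation is definitional). Primary latents
   draw high LH independently of SHBG (testicular failure), secondary
   latents low LH, normogonadotropic latents in-range LH. γ and the noise
   sd are calibration choices: the source tables give only class
   medians/IQRs, not a joint SHBG–LH distribution.
6. **Total testosterone** is produced by *exact mass-action inversion* of
   the latent free level given SHBG and albumin. This single choice makes
   the generator mechanistic rather than descriptive: TT is high when
   SHBG is high even though free T is unchanged, so the cohort-level
   correlation signature — SHBG positively correlated with duration, TT
   and LH, and *uncorrelated* with cFT — emerges from the model instead
   of being imposed. It also makes the solver testable by roundtrip on
   every generated record.
7. **Covariates** (age, BMI, CD4 nadir absolute and %) are drawn
   independently of the hormonal axis, matching the null associations in
   the calibration cohort; cART duration is infection duration minus an
   exponential lag.

Eugonadal LH is intentionally *not* truncated at 9.4, so a few percent of
eugonadal latents classify as compensated — the realistic boundary noise
the label-recovery tests budget for (recovery ≈ 98% at defaults,
asserted ≥ 95%). Truncated draws use exact inverse-CDF sampling on the
log scale (survival-function form deep in a tail), so generation is
deterministic per seed and robust even when a stratum's truncation region
is far from the distribution centre.

### Deterministic fixtures

`fixture_group_a/b/c` build 169-, 118- and 94-record cohorts by
stratified rejection sampling with hard per-stratum constraints
(latent class, SHBG side of 70 nmol/l, TT side of 3.46 ng/ml), so their
classified marginals are exact for any seed: Group C yields 62/13/5/2/12
across the five classes, exactly 10 records below the TT cutoff, and
exactly 34 high-SHBG records of which 18 are eugonadal; Group B yields
22 overt of which 10 meet the TT criterion; Group A yields 14 of 169
below the TT cutoff. Every printed prevalence, subtype split and
misdiagnosis ratio of the three-step work-up follows from these counts.

## What the synthetic data do and do not show

Passing tests demonstrate that the pipeline is internally correct: the
solver solves the stated equilibrium, the classifier implements the
stated cutoffs, the statistics match independent oracles, and a cohort
with the assumed mechanism yields the published marginals and correlation
pattern. They do not validate the mechanism itself against patients: real
cohorts have assay noise and batch drift, covariate–hormone entanglement
(age, BMI, hepatitis serostatus), per-patient albumin variation,
longitudinal progression (compensated → overt), and selection effects of
symptomatic referral — none of which the generator models. The fixtures
reproduce cohort *marginals* by construction; they are synthetic
stand-ins, not the study's data.

## Numerical and design notes

- Quadratic root: stable branch selection as above; at TT = 0 the root is
  0 by construction.
- Rounding: half-up (not banker's) at one decimal, via `decimal`, to
  match printed clinical tables.
- Input validation warns when a TT column's median exceeds 15 ng/ml — a
  cohort recorded in nmol/l sits ~3.5× too high (median ≈ 23), while
  plausible ng/ml medians (~5–9) never trigger it.
- Determinism: one `numpy.random.Generator` per entry point, seeded from
  config; reports contain no timestamps, so rerunning a pipeline yields
  byte-identical outputs (manifest aside, which records versions).
- Problem sizes in the test suite (e.g. 100 replicates of n = 500 for
  structure recovery, 2×10⁴–3×10⁴ permutations for the p-value oracles,
  1000 random panels for solver equivalence) were chosen so the whole
  suite runs in well under a minute while keeping Monte-Carlo error
  comfortably inside the asserted tolerances.

## Known limitations

- Bioavailable testosterone and free oestradiol are out of scope.
- No uncertainty propagation from assay CV into cFT or downstream calls.
- The secondary-vs-normogonadotropic split at LH < 1.5 is one defensible
  reading of standard nomenclature; cohorts using a different LH floor
  can configure `ReferenceLimits`.
- The generator's SHBG–LH joint behaviour (γ, noise) is calibrated to
  class medians only and should not be treated as an estimate of the
  true joint distribution.
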