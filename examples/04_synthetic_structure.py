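"""The mechanistic generator reproduces the cohort's correlation signature.

SHBG rises with HIV infection duration; the pituitary defends the free-T
set point by raising LH, which drags total testosterone up with SHBG while
the free level stays flat.  A cohort drawn from this mechanism should show
significant positive Spearman correlations of SHBG with duration, TT and
LH — and *no* correlation between SHBG and calculated free testosterone.
"""

from androgenaxis import classify_cohort, generate_cohort, spearman
from androgenaxis.synthetic import SyntheticCohortConfig

cohort = classify_cohort(
    generate_cohort(SyntheticCohortConfig(n=500, seed=42)))

shbg = [c.panel.shbg for c in cohort]
against = {
    "HIV duration": [c.record.hiv_duration for c in cohort],
    "total T":      [c.panel.tt for c in cohort],
    "LH":           [c.panel.lh for c in cohort],
    "free T (cFT)": [c.panel.cft for c in cohort],
}

print(f"Spearman correlations with SHBG (n={len(cohort)}):")
for name, vals in against.items():
    r = spearman(shbg, vals, names=("SHBG", name))
    verdict = "significant" if r.significant else "not significant"
    print(f"  SHBG vs {name:13s} rho = {r.rho:+.3f}   p = {r.p_value:.2g}"
          f"   ({verdict})")

print("\nThe free level is decoupled from SHBG by construction — the "
      "set-point defence —\nso its null correlation is the signature that "
      "TT's rise with SHBG is an artefact of binding, not of androgen "
      "status.")
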