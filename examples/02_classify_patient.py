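"""Three-step gonadal-status classification of individual patients.

Step A uses total testosterone alone (hypogonadal below 3.46 ng/ml);
step B adds SHBG and calculated free testosterone (overt when TT low
and/or cFT <= 65 pg/ml); step C adds LH (normal range 1.5-9.4 mUI/ml) to
split overt cases into primary / secondary / normogonadotropic and to
catch compensated hypogonadism (normal T maintained only by high LH).
"""

from androgenaxis import HormonePanel, classify_panel

patients = {
    # id: (tt ng/ml, shbg nmol/l, lh mUI/ml)
    "typical eugonadal":       (7.0, 55.0, 4.8),
    "high SHBG, masked overt": (4.2, 95.0, 5.8),   # TT normal, cFT low
    "compensated":             (8.2, 90.0, 13.0),
    "primary failure":         (2.1, 46.0, 15.0),
    "secondary failure":       (2.8, 40.0, 0.9),
}

for name, (tt, shbg, lh) in patients.items():
    panel = HormonePanel(tt=tt, shbg=shbg, lh=lh).with_cft()
    status = classify_panel(panel)
    flags = f"  flags={sorted(status.flags)}" if status.flags else ""
    print(f"{name:26s} TT {tt:4.1f}  SHBG {shbg:5.1f}  "
          f"cFT {panel.cft:6.1f}  LH {lh:4.1f}  ->  "
          f"{status.step_c.value}{flags}")

print("\nNote the masked patient: step A alone would call them eugonadal "
      "(TT 4.2 >= 3.46),\nbut the calculated free level exposes the "
      "deficit that high SHBG was hiding.")
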