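"""Classify glucose metabolism status from fasting and 2 h OGTT glucose.

Applies the WHO 2006 thresholds (fasting 6.1 / 7.0 mmol/l, 2 h 7.8 / 11.1
mmol/l) to a few representative glucose pairs, including boundary values.
"""

import ogttbcf as o

pairs = [
    (5.27, 5.65),   # typical normal glucose metabolism
    (6.00, 8.79),   # impaired glucose tolerance -> prediabetes
    (7.14, 12.3),   # newly diagnosed type 2 diabetes
    (6.95, 5.0),    # just under the fasting diabetic threshold
    (7.00, 5.0),    # exactly at it
    (5.0, 11.1),    # 2 h value exactly at the diabetic threshold
]
for fpg, g2h in pairs:
    print(f"fasting {fpg:5.2f} mmol/l, 2 h {g2h:5.2f} mmol/l -> "
          f"{o.classify_who2006(fpg, g2h)}")

print("\nDiabetic thresholds are inclusive (>=), so 7.00/11.1 classify as "
      "T2DM; the prediabetes ranges are half-open below them.")
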