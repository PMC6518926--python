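"""Compute beta-cell-function indices for a handful of OGTT records.

Uses the built-in six-subject worked cohort (two subjects per glucose
metabolism class, round-number concentrations) and prints a few indices
alongside the Matsuda insulin-sensitivity index.
"""

import pandas as pd

import ogttbcf as o

cohort = o.worked_fixture()
matrix = o.compute_index_matrix(cohort)
matsuda = o.matsuda_column(cohort.data)
matsuda.index = cohort.data["subject_id"]

show = ["igi_30", "cgi_30", "cir_30", "homa_b1", "auc_cp_g"]
table = matrix.values[show].copy()
table["matsuda"] = matsuda
table["di_cgi_30"] = table["cgi_30"] * table["matsuda"]

pd.set_option("display.width", 120)
print(table.round(2))
print()
print("igi_30 / cgi_30: early-phase insulinogenic and C-peptidogenic indices "
      "(0-30 min increment ratios);")
print("cir_30: corrected insulin response; homa_b1: fasting HOMA estimate of "
      "beta-cell function (%);")
print("di_cgi_30: disposition index = secretion adjusted for insulin "
      "sensitivity. All fall from NGM to T2DM.")
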