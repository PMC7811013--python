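"""Decompose longitudinal trait variance into inter- vs intra-patient parts.

Fits the generic model (trait ~ patient identifier + days since first scan)
per trait and measures each term's contribution by deletion of adjusted r2,
next to the clinical model (age + gender + disease duration + time).
"""

from msqmri import CohortConfig, simulate_cohort
from msqmri.longitudinal import longitudinal_report

patients, scans = simulate_cohort(CohortConfig(seed=3))
report = longitudinal_report(scans, patients)
cols = ["trait", "generic_adj_r2", "patient_share_pct", "time_share_pct",
        "clinical_adj_r2"]
print(report[cols].round(3).to_string(index=False))
print(f"\nBonferroni threshold (20 tests): {report['bonferroni_threshold'].iloc[0]}")
# The patient identifier claims almost all explained variance (share near
# 100%): who the patient is matters far more than time elapsed, and the
# clinical covariates recover only a small part of those differences.
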