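"""Repeat-scan reproducibility: generate paired replicate measurements with a
prescribed intraclass correlation and recover it with ICC(2,1)."""

import aircausal as ac
from aircausal.descriptives import icc_report

cohort = ac.generate_cohort(ac.default_config(n=5_000, seed=3))

for target in (0.99, 0.95):
    reps = ac.generate_repeat_scans(cohort, icc_target=target, seed=5)
    table = icc_report(reps)
    print(f"target ICC = {target}:")
    print(table.round(4).to_string(index=False), "\n")

print(
    "Reading: ICC(2,1) (two-way random effects, absolute agreement, single\n"
    "measurement) near 1 means the airway metrics are stable across repeat CT\n"
    "scans of the same participant — measurement noise is small relative to\n"
    "between-participant differences."
)
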