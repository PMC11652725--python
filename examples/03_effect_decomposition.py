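"""Decompose the effect of COPD severity on the log airway counts into the
direct pathway (airway narrowing/obliteration) and the wall-thickness-
mediated indirect pathway (wall thinning), with percentage declines."""

import aircausal as ac
from aircausal.simulate import learning_nodes

cohort = ac.apply_log_transforms(ac.generate_cohort(ac.default_config(n=20_000, seed=1)))

for outcome, label in (("log_tac", "TAC"), ("log_tac_p", "TACp")):
    pdag = ac.learn_pdag(
        cohort.data,
        alpha=0.05,
        constraints=ac.default_constraints(outcome),
        nodes=learning_nodes(outcome),
    )
    dec = ac.decompose(pdag, cohort, outcome=outcome)
    print(f"== {label} ==")
    print("single-door adjustment set:", dec.single_door)
    print("back-door adjustment set:  ", dec.back_door or "(empty)")
    print(dec.percent_declines().round(3).to_string(index=False))
    print("dominant pathway per group:", dec.dominant_pathway(), "\n")

print(
    "Reading: the direct coefficient a_g and indirect product b_g*d are log-scale\n"
    "effects vs the preserved-lung-function group; (1 - e^a)*100 converts them to\n"
    "percentage count declines. Wall thinning dominates in mild/moderate COPD,\n"
    "narrowing/obliteration of small airways dominates in severe COPD."
)
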