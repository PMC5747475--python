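"""Dynamic prediction: outcome probabilities given the state occupied later.

The Markov property makes 'given history through day s' equal to 'given the
state at day s', so a three-year outlook can be updated as a candidate's
CPRA or activity status changes.  This example contrasts a candidate who is
still active with CPRA 0% at day 60 against one who has become inactive with
CPRA 1-79% by then: inactivation lowers the transplant outlook and raises
the death outlook.
"""

import numpy as np

import waitlist_msm as wm

structure = wm.build_transition_structure(wm.build_state_space())
scenario = wm.validation_scenario(n_subjects=3000, seed=7, admin_horizon_day=1095)
fit = wm.fit_multistate(
    wm.prepare_transition_table(wm.simulate_cohort(scenario), structure), structure
)

space = structure.space
active_0 = space.index_of(1, wm.ActivityStatus.ACTIVE)  # CPRA 0%, active
inactive_low = space.index_of(2, wm.ActivityStatus.INACTIVE)  # CPRA 1-79%, inactive

print("probability of each outcome by year 3, given the state at day 60:\n")
for label, state in (("active CPRA 0%", active_0), ("inactive CPRA 1-79%", inactive_low)):
    pred = wm.dynamic_prediction(fit, state, s=60.0, horizon=1095.0)
    print(f"  occupying '{label}' at day 60:")
    for _, row in pred.iterrows():
        print(
            f"    {row['outcome']:28s} {row['estimate']:.3f}"
            f"  [{row['lower']:.3f}, {row['upper']:.3f}]"
        )
    print()

print("death curves by initial activity status (day-0 prediction):")
curves = wm.death_curves(fit, np.array([365.0, 1095.0]))
for cat in (1, 2):
    a = curves.query(f"initial_state == {2 * cat - 1} and time == 1095")["estimate"].item()
    i = curves.query(f"initial_state == {2 * cat} and time == 1095")["estimate"].item()
    lab = space.transient[2 * cat - 2].cpra.label
    print(f"  CPRA {lab:7s}: active {a:.3f} vs inactive {i:.3f} at year 3")
print("(the generating model inflates death intensity from inactive states,")
print(" and the estimates recover that ordering)")
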