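"""Simulate a waitlist cohort and recover its transition probabilities.

Draws 2,000 registrants from known piecewise-constant intensities, expands
their trajectories into the long-format counting-process table, estimates
Nelson-Aalen hazards and Aalen-Johansen transition probabilities, and
compares the one-year matrix with the exact matrix-exponential truth of the
generating model.  The sup-norm error shown is pure Monte-Carlo noise.
"""

import numpy as np

import waitlist_msm as wm

structure = wm.build_transition_structure(wm.build_state_space())
scenario = wm.validation_scenario(n_subjects=2000, seed=42)

records = wm.simulate_cohort(scenario)
table = wm.prepare_transition_table(records, structure)
print(f"simulated {len(records)} registrants")
print(f"long-format table: {len(table)} rows, {int(table['status'].sum())} events")

fit = wm.fit_multistate(table, structure)
traj = fit.transition_probabilities(s=0.0, times=np.array([365.0]))
P = traj.at(365.0)
truth = wm.true_transition_probability(scenario.intensities, 0, 365)

print("\nP(0, 365) row for state 1 (CPRA 0% active), estimate vs truth:")
space = structure.space
for j in (1, 2, 13, 14, 15, 16):
    print(
        f"  -> {space.state_label(j):28s} {P[0, j - 1]:.4f}  (truth {truth[0, j - 1]:.4f})"
    )
print(f"\nrow sums deviate from 1 by at most {np.abs(P.sum(axis=1) - 1).max():.2e}")
print(f"sup-norm error vs exp(365 Q): {np.abs(P - truth).max():.4f}")
print("(shrinks like 1/sqrt(n); each of the 12 starting states contributes"
      " about n/12 subjects of information to its row)")
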