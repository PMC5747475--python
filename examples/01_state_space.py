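"""Enumerate the 16-state waitlist model and its allowed transitions.

Prints the state inventory and transition counts: 12 transient CPRA-by-
activity states, 4 absorbing outcomes, and 174 allowed transitions (inactive
states cannot move straight to deceased-donor transplant).
"""

import waitlist_msm as wm

space = wm.build_state_space()
structure = wm.build_transition_structure(space)

print(f"{space.n_transient} transient states:")
for st in space.transient:
    print(f"  {st.index:2d}  {st.label}")
print(f"{len(space.absorbing)} absorbing states:")
for st in space.absorbing:
    print(f"  {st.index:2d}  {st.label}")

print(f"\nallowed transitions: {structure.n_transitions}")
for st in space.transient[:2] + space.transient[-2:]:
    dests = structure.destinations(st.index)
    print(f"  from {st.label:22s} -> {len(dests)} destinations")
print("(active states reach 15 destinations, inactive only 14:")
print(" deceased-donor transplant requires active status)")

print("\nCPRA categorization examples:")
for value in (0, 0.5, 45, 89.4, 90, 100):
    print(f"  CPRA {value:5}% -> category {wm.categorize_cpra(value).label}")
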