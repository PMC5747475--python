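"""Small reference inputs shipped with the package.

``KAS_ERA_DEMOGRAPHICS`` is the published demographic summary of US
kidney-waitlist registrants in two eras around the 2014-12-04 kidney
allocation system (KAS) change: a pre-KAS cohort (listed 2009-10-01 to
2013-12-04, n = 97,793) and a post-KAS cohort (listed 2014-12-04 to
2015-06-17, n = 13,113).  Counts are per category; percentages and
standardized differences are recomputed by :mod:`waitlist_msm.cohort_summary`
rather than stored.
"""

from __future__ import annotations

PRE_KAS_TOTAL = 97793
POST_KAS_TOTAL = 13113

#: variable -> list of (category, pre-KAS count, post-KAS count)
KAS_ERA_DEMOGRAPHICS: dict[str, list[tuple[str, int, int]]] = {
    "age_group": [
        ("18-39", 16139, 2295),
        ("40-64", 62804, 8289),
        (">=65", 18850, 2529),
    ],
    "gender": [
        ("Male", 59960, 8273),
        ("Female", 37833, 4840),
    ],
    "abo": [
        ("O", 47033, 6254),
        ("A", 32804, 4410),
        ("B", 14025, 1905),
        ("AB", 3931, 544),
    ],
    "race": [
        ("White", 43539, 5677),
        ("Black", 28304, 3657),
        ("Hispanic", 17649, 2564),
        ("Asian", 6275, 955),
        ("Other", 2026, 260),
    ],
    "esrd_diagnosis": [
        ("Diabetes", 35000, 4771),
        ("Glomerulonephritis", 10971, 1436),
        ("Graft Failure", 1950, 265),
        ("Hypertension", 22962, 2841),
        ("Other", 26910, 3800),
    ],
    "pra_category": [
        ("0-79%", 95925, 12884),
        ("80-89%", 575, 56),
        ("90-94%", 356, 45),
        ("95-98%", 443, 62),
        ("99-100%", 494, 66),
    ],
}
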