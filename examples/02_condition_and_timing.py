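"""Migratory condition and relative timing classes.

Condition = body mass minus the wing-chord-predicted fat-free mass (more
fat = better condition). Each year x sex x destination group's capture-date
range is split into equal thirds, so "early" and "late" are always relative
to conspecifics headed the same way in the same season.
"""

import pandas as pd

from warblerstop import assign_timing_classes, condition_index, fat_free_mass

print(f"fat-free mass at wing chord 60 mm: {fat_free_mass(60):.4f} g")
print(f"condition of a 3.0 g bird, wing 60 mm: {condition_index(3.0, 60):+.4f} g")
print(f"condition of a 2.0 g bird, wing 60 mm: {condition_index(2.0, 60):+.4f} g")
print()

birds = pd.DataFrame(
    {
        "bird_id": [f"b{i}" for i in range(6)],
        "day_of_year": [90, 95, 100, 110, 115, 120],
        "year": 2009,
        "sex": "M",
        "destination": "southeast",
    }
)
out = assign_timing_classes(birds)
print(out[["bird_id", "day_of_year", "timing"]].to_string(index=False))
print()
print(
    "The group's dates span 90-120, so the thirds cut at day 100 and 110;\n"
    "a bird exactly on a cut point falls into the later class."
)
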