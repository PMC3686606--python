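"""Published summary statistics from the motivating cohort study.

The original analysis was performed on restricted limited-access data from
a middle-aged U.S. biracial cohort (ARIC, baseline 1987-89, stroke
follow-up through 1999).  Its published summary tables — sex- and
side-specific medians, per-side geometry prevalences, and per-phenotype
subject and incident-stroke counts — are reproduced here as plain data:
they serve as calibration targets for the synthetic generator and as
inputs to worked examples that recompute the downstream diagnostic
statistics from counts alone.
"""

from __future__ import annotations

import pandas as pd

from .geometry import COMBINED_SETS, MedianTable

__all__ = [
    "PUBLISHED_MEDIANS",
    "PHENOTYPE_COUNTS",
    "TOTALS",
    "GEOMETRY_PREVALENCE_PCT",
    "phenotype_count_frame",
    "combined_counts",
]

#: Sex-specific medians (mm) of right/left CCA far-wall IMT and external diameter.
PUBLISHED_MEDIANS = MedianTable({
    ("M", "R", "IMT"): 0.663, ("M", "L", "IMT"): 0.676,
    ("M", "R", "DIA"): 8.092, ("M", "L", "DIA"): 7.997,
    ("F", "R", "IMT"): 0.609, ("F", "L", "IMT"): 0.603,
    ("F", "R", "DIA"): 7.303, ("F", "L", "DIA"): 7.199,
})

#: Per-phenotype (n subjects, incident strokes) by sex in the incidence sample.
PHENOTYPE_COUNTS: dict[str, dict[int, tuple[int, int]]] = {
    "F": {
        1: (852, 42), 2: (271, 4), 3: (448, 6), 4: (206, 1), 5: (322, 6),
        6: (106, 1), 7: (504, 1), 8: (269, 1), 9: (283, 2), 10: (753, 2),
    },
    "M": {
        1: (662, 51), 2: (229, 12), 3: (370, 19), 4: (172, 1), 5: (223, 10),
        6: (86, 0), 7: (417, 7), 8: (223, 5), 9: (270, 3), 10: (610, 7),
    },
}

#: Stratum totals (n subjects, incident strokes).
TOTALS: dict[str, tuple[int, int]] = {"F": (4014, 66), "M": (3262, 115)}

#: Per-side geometry prevalence (%) at baseline, sex x side x category.
GEOMETRY_PREVALENCE_PCT: dict[str, dict[str, dict[str, float]]] = {
    "M": {"R": {"BOTH": 32.1, "IMT_ONLY": 18.0, "DIA_ONLY": 18.0, "NEITHER": 32.0},
          "L": {"BOTH": 32.3, "IMT_ONLY": 18.2, "DIA_ONLY": 18.0, "NEITHER": 31.5}},
    "F": {"R": {"BOTH": 31.8, "IMT_ONLY": 18.3, "DIA_ONLY": 18.4, "NEITHER": 31.5},
          "L": {"BOTH": 33.9, "IMT_ONLY": 19.4, "DIA_ONLY": 16.3, "NEITHER": 30.5}},
}


def phenotype_count_frame() -> pd.DataFrame:
    """Long-format DataFrame of the published per-phenotype counts."""
    rows = [
        {"sex": sex, "phenotype_id": pid, "n": n, "n_events": ev}
        for sex, d in PHENOTYPE_COUNTS.items()
        for pid, (n, ev) in d.items()
    ]
    return pd.DataFrame(rows)


def combined_counts(sex: str, name: str) -> tuple[int, int]:
    """(n, events) for a combined phenotype, summed over its constituent ids."""
    ids = COMBINED_SETS[name]
    d = PHENOTYPE_COUNTS[sex]
    return sum(d[i][0] for i in ids), sum(d[i][1] for i in ids)
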