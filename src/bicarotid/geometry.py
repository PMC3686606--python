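"""Per-side carotid geometry classification and bilateral phenotypes.

Each common carotid artery (CCA) is classified into one of four geometric
patterns by dichotomizing far-wall intima-media thickness (IMT) and external
(interadventitial) diameter at sex- and side-specific medians: a measurement
is "large" when it is at or above the median.  The ordered (right, left) pair
of patterns — 16 combinations — is reduced under right/left symmetry to ten
non-overlapping bilateral phenotypes, ordered roughly by severity (id 1 =
both parameters large on both sides, id 10 = nothing large anywhere).  Six
named unions of phenotype ids ("combined phenotypes") serve as alternative
positivity definitions for risk screening.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeometryCategory",
    "MedianTable",
    "COMBINED_SETS",
    "PHENOTYPE_LABELS",
    "compute_medians",
    "classify_side",
    "classify_cohort",
    "bilateral_phenotype",
    "combined_membership",
    "tabulate_phenotypes",
]


class GeometryCategory(str, enum.Enum):
    """Four-level per-side pattern from the double median split."""

    BOTH = "BOTH"          # IMT and diameter both large
    IMT_ONLY = "IMT_ONLY"  # only IMT large
    DIA_ONLY = "DIA_ONLY"  # only diameter large
    NEITHER = "NEITHER"    # reference

    def __str__(self) -> str:  # CSV-friendly
        return self.value


#: Unordered (right, left) pattern pair -> bilateral phenotype id.
_C = GeometryCategory
_PAIR_TO_ID: dict[frozenset | tuple, int] = {
    frozenset({_C.BOTH}): 1,
    frozenset({_C.BOTH, _C.IMT_ONLY}): 2,
    frozenset({_C.BOTH, _C.DIA_ONLY}): 3,
    frozenset({_C.BOTH, _C.NEITHER}): 4,
    frozenset({_C.IMT_ONLY}): 5,
    frozenset({_C.IMT_ONLY, _C.DIA_ONLY}): 6,
    frozenset({_C.IMT_ONLY, _C.NEITHER}): 7,
    frozenset({_C.DIA_ONLY}): 8,
    frozenset({_C.DIA_ONLY, _C.NEITHER}): 9,
    frozenset({_C.NEITHER}): 10,
}

PHENOTYPE_LABELS: dict[int, str] = {
    1: "IMT and diameter both large bilaterally",
    2: "IMT and diameter large on one side and opposite IMT large (bilaterally large IMT)",
    3: "IMT and diameter large on one side and opposite diameter large (bilaterally large diameter)",
    4: "IMT and diameter large on one side and neither opposite IMT nor diameter large",
    5: "Bilaterally large IMT, no large diameter",
    6: "Unilaterally large IMT (R or L) and opposite diameter large",
    7: "Unilaterally large IMT (R or L) and no large diameter",
    8: "Bilaterally large diameter, no large IMT",
    9: "Unilaterally large diameter (R or L), no large IMT",
    10: "No IMT or diameter large",
}

#: Named combined phenotypes (unions of bilateral phenotype ids).
COMBINED_SETS: dict[str, frozenset[int]] = {
    "IMT_BILAT": frozenset({1, 2, 5}),
    "DIA_BILAT": frozenset({1, 3, 8}),
    "ANY_BILAT": frozenset({1, 2, 3, 5, 8}),
    "SAME_SIDE_BOTH": frozenset({1, 2, 3, 4}),
    "ANY_IMT": frozenset(range(1, 8)),
    "ANY_DIA": frozenset({1, 2, 3, 4, 6, 8, 9}),
}

COMBINED_LABELS: dict[str, str] = {
    "IMT_BILAT": "IMT large bilaterally, regardless of diameter",
    "DIA_BILAT": "Diameter large bilaterally, regardless of IMT",
    "ANY_BILAT": "Large IMT bilaterally and/or large diameter bilaterally",
    "SAME_SIDE_BOTH": "IMT and diameter both large on same side, unilaterally or bilaterally",
    "ANY_IMT": "Large IMT, unilaterally or bilaterally, regardless of diameter",
    "ANY_DIA": "Large diameter, unilaterally or bilaterally, regardless of IMT",
}

_MEASURE_COLS = {
    ("R", "IMT"): "r_imt_mm",
    ("L", "IMT"): "l_imt_mm",
    ("R", "DIA"): "r_dia_mm",
    ("L", "DIA"): "l_dia_mm",
}


@dataclass(frozen=True)
class MedianTable:
    """Sex-, side- and parameter-specific medians (mm).

    Keys are ``(sex, side, parameter)`` with sex in {"M", "F"}, side in
    {"R", "L"} and parameter in {"IMT", "DIA"}.  All eight cells must be
    present and positive.  A table may be supplied from published values or
    computed from an analysis cohort with :func:`MedianTable.from_cohort`.
    """

    values: Mapping[tuple[str, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, v in self.values.items():
            if not (v > 0):
                raise ValueError(f"median for {key} must be positive, got {v}")

    def get(self, sex: str, side: str, parameter: str) -> float:
        try:
            return self.values[(sex, side, parameter)]
        except KeyError:
            raise KeyError(f"no median for sex={sex!r}, side={side!r}, parameter={parameter!r}")

    def sexes(self) -> set[str]:
        return {k[0] for k in self.values}

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame) -> "MedianTable":
        """Compute all eight medians from a cohort table."""
        vals = {}
        for sex in sorted(cohort["sex"].unique()):
            for (side, param) in _MEASURE_COLS:
                vals[(sex, side, param)] = compute_medians(cohort, sex, side, param)
        return cls(vals)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sex": s, "side": sd, "parameter": p, "median_mm": v}
            for (s, sd, p), v in sorted(self.values.items())
        ]
        return pd.DataFrame(rows)


def compute_medians(cohort: pd.DataFrame, sex: str, side: str, parameter: str) -> float:
    """Sample median of one measurement stratum.

    For even n this is the mean of the two central order statistics.
    Raises ``ValueError`` on an empty stratum.
    """
    col = _MEASURE_COLS[(side, parameter)]
    vals = cohort.loc[cohort["sex"] == sex, col].dropna()
    if len(vals) == 0:
        raise ValueError(f"empty stratum: sex={sex!r}, side={side!r}, parameter={parameter!r}")
    return float(np.median(vals.to_numpy()))


def classify_side(imt: float, dia: float, imt_median: float, dia_median: float) -> GeometryCategory:
    """Classify one CCA side given its two measurements and the medians.

    "Large" is inclusive: a value exactly at the median counts as large.
    Missing (NaN) measurements are rejected — subjects with incomplete
    bilateral measures are excluded upstream.
    """
    if any(not np.isfinite(v) for v in (imt, dia, imt_median, dia_median)):
        raise ValueError("classify_side requires finite, non-missing measurements and medians")
    imt_large = imt >= imt_median
    dia_large = dia >= dia_median
    if imt_large and dia_large:
        return GeometryCategory.BOTH
    if imt_large:
        return GeometryCategory.IMT_ONLY
    if dia_large:
        return GeometryCategory.DIA_ONLY
    return GeometryCategory.NEITHER


def bilateral_phenotype(right: GeometryCategory, left: GeometryCategory) -> int:
    """Map an ordered (right, left) pattern pair to its phenotype id (1-10).

    Symmetric in its arguments: the ten ids are defined on unordered pairs.
    """
    return _PAIR_TO_ID[frozenset({GeometryCategory(right), GeometryCategory(left)})]


def combined_membership(phenotype_id: int) -> set[str]:
    """Names of the combined phenotype sets containing ``phenotype_id``."""
    if phenotype_id not in PHENOTYPE_LABELS:
        raise ValueError(f"phenotype id must be in 1..10, got {phenotype_id}")
    return {name for name, ids in COMBINED_SETS.items() if phenotype_id in ids}


def classify_cohort(cohort: pd.DataFrame, medians: MedianTable) -> pd.DataFrame:
    """Append ``r_geometry``, ``l_geometry`` and ``phenotype_id`` columns.

    Vectorized over the cohort; the ``>= median`` rule is applied per sex
    and side.  Returns a copy.
    """
    out = cohort.copy()
    n = len(out)
    cats = {side: np.empty(n, dtype=object) for side in ("R", "L")}
    pheno = np.zeros(n, dtype=int)
    for sex in out["sex"].unique():
        mask = (out["sex"] == sex).to_numpy()
        for side, prefix in (("R", "r"), ("L", "l")):
            imt = out.loc[mask, f"{prefix}_imt_mm"].to_numpy(dtype=float)
            dia = out.loc[mask, f"{prefix}_dia_mm"].to_numpy(dtype=float)
            if np.isnan(imt).any() or np.isnan(dia).any():
                raise ValueError(
                    f"missing {side}CCA measurements for sex={sex!r}; apply exclusions first"
                )
            imt_l = imt >= medians.get(sex, side, "IMT")
            dia_l = dia >= medians.get(sex, side, "DIA")
            c = np.where(
                imt_l & dia_l, "BOTH",
                np.where(imt_l, "IMT_ONLY", np.where(dia_l, "DIA_ONLY", "NEITHER")),
            )
            cats[side][mask] = c
    pair_ids = {
        (a.value, b.value): _PAIR_TO_ID[frozenset({a, b})]
        for a in GeometryCategory for b in GeometryCategory
    }
    for i in range(n):
        pheno[i] = pair_ids[(cats["R"][i], cats["L"][i])]
    out["r_geometry"] = cats["R"]
    out["l_geometry"] = cats["L"]
    out["phenotype_id"] = pheno
    return out


def tabulate_phenotypes(classified: pd.DataFrame, medians: MedianTable | None = None) -> pd.DataFrame:
    """Per-sex phenotype table: n, incident events and cumulative incidence.

    Rows cover the ten phenotype ids (counts partition each sex stratum)
    followed by the six combined phenotypes, whose counts are sums over
    their constituent ids.  Incidence is ``100 * n_events / n`` rounded to
    one decimal.
    """
    if "phenotype_id" not in classified.columns:
        if medians is None:
            raise ValueError("cohort is unclassified and no medians were supplied")
        classified = classify_cohort(classified, medians)
    if medians is not None:
        missing = set(classified["sex"].unique()) - medians.sexes()
        if missing:
            raise ValueError(f"median table lacks sexes: {sorted(missing)}")
    rows = []
    for sex, grp in classified.groupby("sex"):
        counts = grp.groupby("phenotype_id").agg(
            n=("phenotype_id", "size"), n_events=("event", "sum")
        )
        by_id = {
            pid: (
                int(counts["n"].get(pid, 0)),
                int(counts["n_events"].get(pid, 0)),
            )
            for pid in range(1, 11)
        }
        for pid in range(1, 11):
            n, ev = by_id[pid]
            rows.append({
                "sex": sex, "phenotype": str(pid), "label": PHENOTYPE_LABELS[pid],
                "n": n, "n_events": ev,
                "incidence_pct": round(100.0 * ev / n, 1) if n else float("nan"),
            })
        for name, ids in COMBINED_SETS.items():
            n = sum(by_id[i][0] for i in ids)
            ev = sum(by_id[i][1] for i in ids)
            rows.append({
                "sex": sex, "phenotype": name, "label": COMBINED_LABELS[name],
                "n": n, "n_events": ev,
                "incidence_pct": round(100.0 * ev / n, 1) if n else float("nan"),
            })
    return pd.DataFrame(rows)
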