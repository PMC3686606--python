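"""Diagnostic-accuracy and incidence statistics for phenotype positivity.

A bilateral phenotype set defines a binary "test" (subject positive iff
their phenotype id is in the set); crossing it with incident stroke gives a
2x2 table from which sensitivity, specificity, positive and negative
likelihood ratios (with log-method delta CIs), cumulative incidence and
unadjusted relative risk are computed.

The likelihood-ratio CI uses the delta method on the log of a ratio of two
binomial proportions (Simel et al.):

    SE(ln LR+) = sqrt((1 - sens)/tp + spec/fp)
    SE(ln LR-) = sqrt(sens/fn + (1 - spec)/tn)

with 95% bounds ``LR * exp(+-1.96 SE)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .geometry import COMBINED_LABELS, COMBINED_SETS, PHENOTYPE_LABELS

__all__ = [
    "TwoByTwoTable",
    "DiagnosticResult",
    "two_by_two",
    "diagnostic_metrics",
    "cumulative_incidence",
    "relative_risk",
    "diagnostics_report",
]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts crossing test positivity with incident events.

    tp: event and positive; fp: no event and positive;
    fn: event and negative; tn: no event and negative.
    """

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("2x2 cell counts must be non-negative")

    @property
    def n_events(self) -> float:
        return self.tp + self.fn

    @property
    def n_nonevents(self) -> float:
        return self.fp + self.tn

    @property
    def n(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_counts(cls, pos_events: int, pos_n: int, total_events: int, total_n: int) -> "TwoByTwoTable":
        """Build from (events, n) in the positive group and overall totals."""
        tp = pos_events
        fp = pos_n - pos_events
        fn = total_events - tp
        tn = (total_n - total_events) - fp
        return cls(tp=tp, fp=fp, fn=fn, tn=tn)


def two_by_two(classified: pd.DataFrame, positive_set: set[int], sex: str) -> TwoByTwoTable:
    """2x2 table for one sex stratum and one phenotype positivity set."""
    bad = set(positive_set) - set(range(1, 11))
    if bad:
        raise ValueError(f"positive_set contains invalid phenotype ids: {sorted(bad)}")
    df = classified[classified["sex"] == sex]
    if len(df) == 0:
        raise ValueError(f"no subjects with sex={sex!r}")
    pos = df["phenotype_id"].isin(positive_set)
    ev = df["event"].astype(bool)
    return TwoByTwoTable(
        tp=int((pos & ev).sum()), fp=int((pos & ~ev).sum()),
        fn=int((~pos & ev).sum()), tn=int((~pos & ~ev).sum()),
    )


@dataclass(frozen=True)
class DiagnosticResult:
    sensitivity: float
    specificity: float
    plr: float
    plr_ci: tuple[float, float]
    nlr: float
    nlr_ci: tuple[float, float]
    corrected: bool = False  # True when the 0.5 continuity correction was applied

    def rounded(self) -> dict:
        """Display precision: two decimals for proportions and ratios."""
        return {
            "sensitivity": round(self.sensitivity, 2),
            "specificity": round(self.specificity, 2),
            "plr": round(self.plr, 2),
            "plr_lo": round(self.plr_ci[0], 2), "plr_hi": round(self.plr_ci[1], 2),
            "nlr": round(self.nlr, 2),
            "nlr_lo": round(self.nlr_ci[0], 2), "nlr_hi": round(self.nlr_ci[1], 2),
        }


def diagnostic_metrics(t: TwoByTwoTable) -> DiagnosticResult:
    """Sensitivity, specificity and likelihood ratios with log-method CIs.

    If any cell is zero, 0.5 is added to all four cells (flagged in the
    result) so every statistic and CI is finite; otherwise raw counts are
    used throughout, keeping plr*(1-specificity) == sensitivity exactly.
    """
    if t.n_events <= 0 or t.n_nonevents <= 0:
        raise ValueError("2x2 table needs at least one event and one non-event")
    corrected = min(t.tp, t.fp, t.fn, t.tn) == 0
    if corrected:
        t = TwoByTwoTable(t.tp + 0.5, t.fp + 0.5, t.fn + 0.5, t.tn + 0.5)
    sens = t.tp / t.n_events
    spec = t.tn / t.n_nonevents
    plr = sens / (1.0 - spec)
    nlr = (1.0 - sens) / spec
    se_p = math.sqrt((1.0 - sens) / t.tp + spec / t.fp)
    se_n = math.sqrt(sens / t.fn + (1.0 - spec) / t.tn)
    return DiagnosticResult(
        sensitivity=sens, specificity=spec,
        plr=plr, plr_ci=(plr * math.exp(-1.96 * se_p), plr * math.exp(1.96 * se_p)),
        nlr=nlr, nlr_ci=(nlr * math.exp(-1.96 * se_n), nlr * math.exp(1.96 * se_n)),
        corrected=corrected,
    )


def cumulative_incidence(n_events: int, n: int) -> float:
    """Cumulative incidence over follow-up, percent (100 * events / n)."""
    if n <= 0:
        raise ValueError("cumulative incidence needs n > 0")
    return 100.0 * n_events / n


def relative_risk(
    exposed: tuple[int, int], reference: tuple[int, int]
) -> tuple[float, tuple[float, float]]:
    """Unadjusted relative risk of the exposed vs reference group, with 95% CI.

    Arguments are (events, n) pairs.  The CI is the log-delta method:
    SE(ln RR) = sqrt(1/e1 - 1/n1 + 1/e0 - 1/n0).  Zero reference events give
    an infinite RR; a one-sided lower bound is then computed with 0.5 added
    to the zero cell.
    """
    e1, n1 = exposed
    e0, n0 = reference
    if n1 <= 0 or n0 <= 0:
        raise ValueError("both groups need n > 0")
    if e0 == 0:
        if e1 == 0:
            raise ValueError("relative risk undefined with zero events in both groups")
        rr_lo = ((e1 / n1) / (0.5 / n0)) * math.exp(
            -1.96 * math.sqrt(1 / e1 - 1 / n1 + 1 / 0.5 - 1 / n0)
        )
        return math.inf, (rr_lo, math.inf)
    rr = (e1 / n1) / (e0 / n0)
    if e1 == 0:
        return 0.0, (0.0, ((0.5 / n1) / (e0 / n0)) * math.exp(
            1.96 * math.sqrt(1 / 0.5 - 1 / n1 + 1 / e0 - 1 / n0)))
    se = math.sqrt(1 / e1 - 1 / n1 + 1 / e0 - 1 / n0)
    return rr, (rr * math.exp(-1.96 * se), rr * math.exp(1.96 * se))


#: Positivity sets reported in the screening summary: the most severe single
#: phenotype plus the six combined phenotypes.
REPORT_SETS: dict[str, frozenset[int]] = {
    "PHENO_1": frozenset({1}),
    **{name: ids for name, ids in COMBINED_SETS.items()},
}

_REPORT_LABELS = {"PHENO_1": PHENOTYPE_LABELS[1], **COMBINED_LABELS}


def diagnostics_report(classified: pd.DataFrame, sexes: tuple[str, ...] = ("M", "F")) -> pd.DataFrame:
    """Screening summary: one row per (positivity set, sex).

    Columns: phenotype_label, sex, n_events, sensitivity, specificity, plr,
    plr_lo, plr_hi, nlr, nlr_lo, nlr_hi (ratios and proportions at display
    precision).
    """
    rows = []
    for name, ids in REPORT_SETS.items():
        for sex in sexes:
            t = two_by_two(classified, set(ids), sex)
            m = diagnostic_metrics(t).rounded()
            rows.append({
                "phenotype_label": _REPORT_LABELS[name], "sex": sex,
                "n_events": int(t.tp), **m,
            })
    return pd.DataFrame(rows)
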