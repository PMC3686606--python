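"""Right-left agreement of carotid geometry categories.

The same subject's right and left CCA often fall in different geometry
categories; this module quantifies that with a 4x4 cross-classification
table, Cohen's unweighted kappa (chance-corrected overall agreement, with
the Fleiss-Cohen-Everitt large-sample variance), and category-specific
positive agreement 2*n_cc / (row_c + col_c) with a subject-level bootstrap
confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import GeometryCategory

__all__ = [
    "CATEGORY_ORDER",
    "build_agreement_table",
    "cohens_kappa",
    "category_specific_agreement",
    "concordance_report",
]

CATEGORY_ORDER = [
    GeometryCategory.BOTH,
    GeometryCategory.IMT_ONLY,
    GeometryCategory.DIA_ONLY,
    GeometryCategory.NEITHER,
]
_IDX = {c.value: i for i, c in enumerate(CATEGORY_ORDER)}


def build_agreement_table(classified: pd.DataFrame, sex: str | None = None) -> np.ndarray:
    """4x4 count matrix; rows = right category, columns = left category."""
    df = classified if sex is None else classified[classified["sex"] == sex]
    table = np.zeros((4, 4), dtype=int)
    if len(df) == 0:
        return table
    r = df["r_geometry"].map(_IDX).to_numpy()
    l = df["l_geometry"].map(_IDX).to_numpy()
    np.add.at(table, (r, l), 1)
    return table


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    defined: bool = True


def cohens_kappa(table: np.ndarray) -> KappaResult:
    """Unweighted Cohen's kappa with a 95% large-sample CI.

    Expected agreement comes from the product of row and column marginals.
    If expected agreement is 1 (degenerate marginals) kappa is undefined and
    the result is flagged rather than raised.
    """
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n < 2:
        raise ValueError("kappa requires a table with at least 2 subjects")
    p = table / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = np.trace(p)
    pe = float(row @ col)
    if pe >= 1.0 - 1e-12:
        return KappaResult(float("nan"), float("nan"), float("nan"), float("nan"), defined=False)
    kappa = (po - pe) / (1.0 - pe)
    # Fleiss, Cohen & Everitt large-sample variance
    diag = np.diag(p)
    a = float(np.sum(diag * (1.0 - (row + col) * (1.0 - kappa)) ** 2))
    b = 0.0
    k = table.shape[0]
    for i in range(k):
        for j in range(k):
            if i != j:
                b += p[i, j] * (col[i] + row[j]) ** 2
    b *= (1.0 - kappa) ** 2
    c = (kappa - pe * (1.0 - kappa)) ** 2
    var = (a + b - c) / (n * (1.0 - pe) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    return KappaResult(float(kappa), se, float(kappa - 1.96 * se), float(kappa + 1.96 * se))


@dataclass(frozen=True)
class AgreementResult:
    percent: float
    ci_low: float
    ci_high: float
    defined: bool = True


def _specific_agreement(table: np.ndarray, idx: int) -> float:
    n_cc = table[idx, idx]
    margin = table[idx, :].sum() + table[:, idx].sum()
    if margin == 0:
        return float("nan")
    return 200.0 * n_cc / margin


def category_specific_agreement(
    table: np.ndarray,
    category: GeometryCategory | str,
    n_boot: int = 2000,
    seed: int = 0,
) -> AgreementResult:
    """Category-specific (positive) agreement, percent, with bootstrap CI.

    Point estimate ``2 * n_cc / (row_c + col_c) * 100``: of all right- or
    left-side classifications into the category, the share whose opposite
    side agrees.  The CI resamples subjects (multinomial over the 16 cells,
    percentile method, seeded).  A zero combined margin leaves the statistic
    undefined, flagged in the result.
    """
    table = np.asarray(table, dtype=int)
    idx = _IDX[GeometryCategory(category).value]
    point = _specific_agreement(table, idx)
    if np.isnan(point):
        return AgreementResult(float("nan"), float("nan"), float("nan"), defined=False)
    n = int(table.sum())
    rng = np.random.Generator(np.random.Philox(seed))
    probs = (table / n).ravel()
    draws = rng.multinomial(n, probs, size=n_boot).reshape(n_boot, 4, 4)
    stats = np.array([_specific_agreement(d, idx) for d in draws])
    stats = stats[~np.isnan(stats)]
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return AgreementResult(float(point), float(lo), float(hi))


def concordance_report(
    classified: pd.DataFrame, sex: str | None = None, n_boot: int = 2000, seed: int = 0
) -> pd.DataFrame:
    """Per-category prevalence and right-left agreement for one stratum.

    Columns: category, n_right, pct_right, n_left, pct_left, agreement_pct,
    ci_low, ci_high.
    """
    table = build_agreement_table(classified, sex)
    n = table.sum()
    rows = []
    for i, cat in enumerate(CATEGORY_ORDER):
        res = category_specific_agreement(table, cat, n_boot=n_boot, seed=seed + i)
        n_r = int(table[i, :].sum())
        n_l = int(table[:, i].sum())
        rows.append({
            "category": cat.value,
            "n_right": n_r, "pct_right": round(100.0 * n_r / n, 1) if n else float("nan"),
            "n_left": n_l, "pct_left": round(100.0 * n_l / n, 1) if n else float("nan"),
            "agreement_pct": round(res.percent, 1),
            "ci_low": round(res.ci_low, 1), "ci_high": round(res.ci_high, 1),
        })
    return pd.DataFrame(rows)
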