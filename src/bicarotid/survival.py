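"""Cox proportional-hazards estimation by partial-likelihood maximization.

A from-scratch Newton-Raphson fitter for right-censored survival data with
Breslow (default) or Efron handling of tied event times, Wald inference
from the inverse observed information, and the epidemiological
covariate-retention procedure: backward elimination keeping the exposure
indicators and base adjustment terms forced in, dropping candidates that
are non-significant unless their removal shifts an exposure coefficient by
more than a change-in-estimate threshold.

The design matrix is a pandas DataFrame with named columns; geometry
exposures are the three indicator columns (both large / IMT only /
diameter only, versus the neither-large reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxFit",
    "ConvergenceError",
    "SeparationError",
    "fit_cox",
    "wald_interval",
    "select_covariates",
    "cox_log_likelihood",
    "geometry_design",
]


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge."""


class SeparationError(ConvergenceError):
    """Monotone partial likelihood: a coefficient diverges to +-infinity."""


@dataclass
class CoxFit:
    """Result of a converged partial-likelihood maximization."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    iterations: int
    gradient_norm: float
    ties: str
    covariance: np.ndarray

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    def p_values(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def coef_of(self, term: str) -> float:
        return float(self.coef[self.terms.index(term)])

    def summary(self) -> pd.DataFrame:
        with np.errstate(over="ignore"):  # near-separated terms: CI bound -> inf
            lo, hi = self.hr * np.exp(-1.96 * self.se), self.hr * np.exp(1.96 * self.se)
        return pd.DataFrame({
            "term": self.terms, "coefficient": self.coef, "se": self.se,
            "hr": self.hr, "ci_low": lo, "ci_high": hi, "p_value": self.p_values(),
        })


def _prepare(time, event, X):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if isinstance(X, pd.DataFrame):
        terms = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        terms = [f"x{j}" for j in range(X.shape[1])]
    if np.any(time <= 0):
        raise ValueError("all follow-up times must be positive")
    if event.sum() < 1:
        raise ValueError("at least one event is required")
    if np.isnan(X).any():
        raise ValueError("design matrix contains missing values")
    order = np.argsort(time, kind="stable")
    return time[order], event[order], X[order], terms


def _check_rank(X: np.ndarray, terms: list[str]) -> None:
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    if s.size and s[-1] < 1e-10 * max(s[0], 1.0):
        # identify an offending term by dropping columns one at a time
        for j, t in enumerate(terms):
            sub = np.delete(Xc, j, axis=1)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(Xc):
                raise np.linalg.LinAlgError(
                    f"design matrix is rank deficient; term {t!r} is collinear with the rest"
                )
        raise np.linalg.LinAlgError("design matrix is rank deficient")


def _loglik_grad_hess(beta, time, event, X, ties):
    """Log partial likelihood, gradient and Hessian (sorted inputs)."""
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # guard overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = np.einsum("i,ij,ik->ijk", w, X, X)
    # risk-set aggregates: suffix sums over time-sorted subjects
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        deaths = np.arange(i, j)[event[i:j] == 1]
        d = deaths.size
        if d > 0:
            ll += eta[deaths].sum()
            grad += X[deaths].sum(axis=0)
            S0, S1, S2 = s0[i], s1[i], s2[i]
            if ties == "breslow" or d == 1:
                ll -= d * np.log(S0)
                grad -= d * S1 / S0
                hess -= d * (S2 / S0 - np.outer(S1, S1) / S0**2)
            else:  # efron
                dw = w[deaths].sum()
                dw1 = wx[deaths].sum(axis=0)
                dw2 = wxx[deaths].sum(axis=0)
                for r in range(d):
                    f = r / d
                    S0r = S0 - f * dw
                    S1r = S1 - f * dw1
                    S2r = S2 - f * dw2
                    ll -= np.log(S0r)
                    grad -= S1r / S0r
                    hess -= S2r / S0r - np.outer(S1r, S1r) / S0r**2
        i = j
    return ll, grad, hess


def cox_log_likelihood(beta, time, event, X, ties: str = "breslow") -> float:
    """Log partial likelihood at ``beta`` (public, for oracles and tests)."""
    time, event, X, _ = _prepare(time, event, X)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    ll, _, _ = _loglik_grad_hess(beta, time, event, X, ties)
    return float(ll)


def fit_cox(
    time,
    event,
    X,
    ties: str = "breslow",
    tol_grad: float = 1e-8,
    tol_ll: float = 1e-10,
    max_iter: int = 100,
    coef_bound: float = 20.0,
) -> CoxFit:
    """Maximize the Cox log partial likelihood by Newton-Raphson.

    Converges when the max absolute gradient falls below ``tol_grad`` or the
    relative log-likelihood change falls below ``tol_ll``.  Coefficients
    exceeding ``coef_bound`` in absolute value indicate a monotone
    likelihood (separation) and raise :class:`SeparationError`; a rank-
    deficient design raises ``numpy.linalg.LinAlgError`` naming a collinear
    term.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"ties must be 'breslow' or 'efron', got {ties!r}")
    time, event, X, terms = _prepare(time, event, X)
    _check_rank(X, terms)
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _loglik_grad_hess(beta, time, event, X, ties)
    ll_null = ll
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            raise ConvergenceError("singular information matrix during Newton step")
        # step-halving keeps the likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            beta_new = beta + scale * step
            ll_new, grad_new, hess_new = _loglik_grad_hess(beta_new, time, event, X, ties)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        else:
            raise ConvergenceError("step-halving failed to improve the likelihood")
        rel = abs(ll_new - ll) / max(abs(ll), 1e-8)
        beta, ll_prev, ll, grad, hess = beta_new, ll, ll_new, grad_new, hess_new
        if np.any(np.abs(beta) > coef_bound):
            raise SeparationError(
                "monotone partial likelihood: coefficient magnitude exceeds "
                f"{coef_bound}; data are separated for at least one term"
            )
        if np.max(np.abs(grad)) < tol_grad or rel < tol_ll:
            break
    else:
        raise ConvergenceError(f"no convergence in {max_iter} Newton iterations")
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    return CoxFit(
        terms=terms, coef=beta, se=se, loglik=float(ll), loglik_null=float(ll_null),
        iterations=it, gradient_norm=float(np.max(np.abs(grad))), ties=ties,
        covariance=cov,
    )


def wald_interval(fit: CoxFit, term: str) -> tuple[float, float, float]:
    """Hazard ratio and 95% Wald interval exp(beta +- 1.96 se) for one term."""
    if term not in fit.terms:
        raise KeyError(f"term {term!r} not in fit (has {fit.terms})")
    j = fit.terms.index(term)
    b, s = fit.coef[j], fit.se[j]
    return float(np.exp(b)), float(np.exp(b - 1.96 * s)), float(np.exp(b + 1.96 * s))


@dataclass
class SelectionStep:
    term: str
    p_value: float
    action: str           # "dropped" or "kept"
    reason: str
    max_exposure_shift: float


@dataclass
class SelectionResult:
    fit: CoxFit
    retained: list[str]
    audit: list[SelectionStep] = field(default_factory=list)

    def audit_text(self) -> str:
        lines = [
            f"{s.action.upper():7s} {s.term:24s} p={s.p_value:.4f} "
            f"max_exposure_shift={s.max_exposure_shift:.4f}  {s.reason}"
            for s in self.audit
        ]
        return "\n".join(lines)


def select_covariates(
    time,
    event,
    X: pd.DataFrame,
    exposure_terms: list[str],
    base_terms: list[str] | None = None,
    candidate_terms: list[str] | None = None,
    alpha: float = 0.05,
    delta: float = 0.10,
    change_scale: str = "coef",
    ties: str = "breslow",
) -> SelectionResult:
    """Backward elimination with a change-in-estimate confounding guard.

    Exposure indicators and base adjustment terms are always forced in.
    Iteratively, the least significant candidate with p >= ``alpha`` is
    removed unless dropping it changes any exposure estimate by more than
    ``delta`` (relative), in which case it is retained as a confounder.
    ``change_scale`` measures the shift on the log-hazard coefficient scale
    ("coef", default) or on the hazard-ratio scale ("hr"); for coefficients
    near zero an absolute shift is used.  Ties in p-value break by term
    name.  Returns the final fit plus an ordered audit trail.
    """
    base_terms = list(base_terms or [])
    candidates = list(candidate_terms or [])
    if change_scale not in ("coef", "hr"):
        raise ValueError("change_scale must be 'coef' or 'hr'")
    forced = list(exposure_terms) + base_terms
    current = forced + sorted(candidates)
    audit: list[SelectionStep] = []
    fit = fit_cox(time, event, X[current], ties=ties)
    kept_as_confounder: set[str] = set()
    while True:
        pvals = dict(zip(fit.terms, fit.p_values()))
        droppable = [
            t for t in current
            if t not in forced and t not in kept_as_confounder and pvals[t] >= alpha
        ]
        if not droppable:
            break
        # drop highest p first; ties broken by name for determinism
        t = max(droppable, key=lambda u: (pvals[u], u))
        trial_terms = [u for u in current if u != t]
        trial = fit_cox(time, event, X[trial_terms], ties=ties)
        shifts = []
        for e in exposure_terms:
            b0, b1 = fit.coef_of(e), trial.coef_of(e)
            if change_scale == "hr":
                b0, b1 = np.exp(b0), np.exp(b1)
            shifts.append(abs(b1 - b0) / abs(b0) if abs(b0) > 1e-6 else abs(b1 - b0))
        shift = float(max(shifts))
        if shift > delta:
            kept_as_confounder.add(t)
            audit.append(SelectionStep(
                t, float(pvals[t]), "kept",
                f"removal shifts an exposure estimate by {100 * shift:.1f}% > {100 * delta:.0f}%",
                shift,
            ))
        else:
            current = trial_terms
            fit = trial
            audit.append(SelectionStep(
                t, float(pvals[t]), "dropped",
                f"p >= {alpha} and exposure shift {100 * shift:.1f}% <= {100 * delta:.0f}%",
                shift,
            ))
    return SelectionResult(fit=fit, retained=current, audit=audit)


def geometry_design(
    classified: pd.DataFrame,
    side: str,
    extra_terms: list[str] | None = None,
) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """(time, event, X) for a side-specific geometry hazard model.

    X holds the three geometry indicators for the requested side (neither
    large = reference) plus age, black-race indicator and height, and any
    ``extra_terms`` columns copied from the cohort table.
    """
    prefix = side.lower()
    if prefix not in ("r", "l"):
        raise ValueError("side must be 'R' or 'L'")
    g = classified[f"{prefix}_geometry"]
    X = pd.DataFrame({
        "geom_both": (g == "BOTH").astype(float),
        "geom_imt_only": (g == "IMT_ONLY").astype(float),
        "geom_dia_only": (g == "DIA_ONLY").astype(float),
        "age": classified["age"].astype(float),
        "race_black": (classified["race"] == "black").astype(float),
        "height_cm": classified["height_cm"].astype(float),
    }, index=classified.index)
    for t in extra_terms or []:
        X[t] = classified[t].astype(float)
    return classified["time_years"], classified["event"], X
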