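"""Binomial logistic regression by IRLS and forward stepwise selection.

The fit maximizes the binomial log-likelihood by iteratively reweighted
least squares, declaring convergence when the largest absolute
coefficient change drops below ``tol`` (default 1e-8) within
``max_iter`` (default 50) iterations.  Quasi-complete separation makes
the coefficients diverge; that surfaces as ``converged=False`` on the
returned fit rather than an exception, so selection loops can continue
over the remaining candidates.

Forward stepwise selection adds, at each step, the candidate with the
smallest likelihood-ratio-test p-value against the current model, as
long as that p-value is below the entry threshold (0.05 by default);
ties break deterministically by candidate order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

_ETA_CLIP = 30.0  # |linear predictor| cap; keeps exp() finite under separation


@dataclass
class LogisticFit:
    term_names: list[str]
    coefficients: np.ndarray  # aligned with term_names
    intercept: float
    log_likelihood: float
    ll_null: float
    converged: bool
    n_iterations: int

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.term_names.index(term)])


@dataclass
class StepwiseResult:
    selected: list[str]
    fit: LogisticFit
    path: list[tuple[str, float]] = field(default_factory=list)  # (term, LR p at entry)


def _as_matrix(design) -> tuple[np.ndarray, list[str]]:
    if isinstance(design, pd.DataFrame):
        return design.to_numpy(dtype=float), [str(c) for c in design.columns]
    arr = np.asarray(design, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # stable: log(1+exp(eta)) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(design, outcome, *, tol: float = 1e-8, max_iter: int = 50) -> LogisticFit:
    """IRLS fit of a logistic model (intercept added internally).

    Parameters
    ----------
    design
        Subject x term indicator matrix (DataFrame or array), without
        an intercept column.
    outcome
        Binary 0/1 (or case/control boolean) outcome vector.
    """
    X, names = _as_matrix(design)
    y = np.asarray(outcome, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("design and outcome lengths differ")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more subjects than terms")
    const = np.ptp(X, axis=0) == 0
    if const.any():
        raise ValueError(f"term {names[int(np.argmax(const))]!r} is constant across subjects")

    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    ll_null = _ll_intercept_only(y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(Xd @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        # Newton step via weighted normal equations
        XtW = Xd.T * w
        try:
            delta = np.linalg.solve(XtW @ Xd, Xd.T @ (y - mu))
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(XtW @ Xd, Xd.T @ (y - mu), rcond=None)[0]
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    eta = np.clip(Xd @ beta, -_ETA_CLIP, _ETA_CLIP)
    return LogisticFit(
        term_names=names,
        coefficients=beta[1:].copy(),
        intercept=float(beta[0]),
        log_likelihood=_log_likelihood(y, eta),
        ll_null=ll_null,
        converged=converged,
        n_iterations=it,
    )


def _ll_intercept_only(y: np.ndarray) -> float:
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    n = len(y)
    k = y.sum()
    return float(k * np.log(p) + (n - k) * np.log(1 - p))


def likelihood_ratio_p(ll_full: float, ll_reduced: float, df: int = 1) -> float:
    lr = max(0.0, 2.0 * (ll_full - ll_reduced))
    return float(stats.chi2.sf(lr, df))


def forward_stepwise(design, outcome, p_enter: float = 0.05) -> StepwiseResult:
    """Forward stepwise logistic selection with likelihood-ratio entry.

    ``design`` holds all candidate indicator columns.  Returns the
    selection order with per-step entry p-values and the final fit (an
    intercept-only placeholder fit when nothing enters).
    """
    X, names = _as_matrix(design)
    if X.shape[1] == 0:
        raise ValueError("candidate set is empty")
    y = np.asarray(outcome, dtype=float).ravel()

    selected: list[int] = []
    path: list[tuple[str, float]] = []
    current_ll = _ll_intercept_only(y)
    current_fit: LogisticFit | None = None
    while len(selected) < X.shape[1]:
        best: tuple[float, int, LogisticFit] | None = None
        for j in range(X.shape[1]):
            if j in selected:
                continue
            cols = selected + [j]
            try:
                fit = fit_logistic(X[:, cols], y)
            except ValueError:
                continue
            p = likelihood_ratio_p(fit.log_likelihood, current_ll)
            if best is None or p < best[0]:
                best = (p, j, fit)
        if best is None or best[0] >= p_enter:
            break
        p, j, fit = best
        selected.append(j)
        path.append((names[j], p))
        current_ll = fit.log_likelihood
        current_fit = fit
    if current_fit is None:
        current_fit = LogisticFit(
            term_names=[],
            coefficients=np.empty(0),
            intercept=float(_null_intercept(y)),
            log_likelihood=current_ll,
            ll_null=current_ll,
            converged=True,
            n_iterations=0,
        )
    else:
        current_fit.term_names = [names[j] for j in selected]
    return StepwiseResult(selected=[names[j] for j in selected], fit=current_fit, path=path)


def _null_intercept(y: np.ndarray) -> float:
    p = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    return float(np.log(p / (1 - p)))
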