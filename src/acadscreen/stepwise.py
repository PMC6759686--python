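"""Stepwise multivariate logistic marker selection.

The selector follows the classic forward-selection-with-backward-removal
protocol: at each step the candidate whose Rao score entry test (evaluated
at the current fit) has the smallest p-value enters if p <= ``entry_p``;
after every entry, included variables whose removal likelihood-ratio
p-value exceeds ``removal_p`` are dropped.  Ties are broken by canonical
feature order, so the procedure is deterministic given the input column
order and configuration.

Candidate feature sets in this domain (hundreds of channel ratios, a
handful of disease cases) are far wider than the event count, so an
optional univariate score-test prescreen admits only the top-K candidates
to the stepwise search (``prescreen_k=None`` disables it and searches the
full set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import ValidationError
from .firth import LogisticFit, fit_logistic


@dataclass
class StepRecord:
    step: int
    action: str  # "add" | "remove"
    feature: str
    p_value: float
    loglik: float


@dataclass
class SelectionConfig:
    """Configuration of the subgroup-consensus selection protocol.

    Defaults mirror a 200,000-newborn model-building cohort split into
    20 subgroups of 10,000 with LR entry at p<=0.05, removal at p>0.10 and
    a two-subgroup consensus requirement; all sizes scale down for tests.
    """

    n_model: int = 200_000
    n_subgroups: int = 20
    subgroup_size: int | None = 10_000
    entry_p: float = 0.05
    removal_p: float = 0.10
    max_steps: int = 20
    consensus_min: int = 2
    outcome: str = "any"  # "any" | "per-condition"
    penalty: str = "firth"  # "firth" | "none"
    prescreen_k: int | None = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.entry_p <= self.removal_p < 1):
            raise ValidationError("require 0 < entry_p <= removal_p < 1")
        if self.consensus_min < 1:
            raise ValidationError("consensus_min must be >= 1")
        if self.subgroup_size is not None and self.n_subgroups * self.subgroup_size > self.n_model:
            raise ValidationError("n_subgroups * subgroup_size must be <= n_model")


def score_test_statistics(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized univariate score-test statistics against a null model.

    For logistic regression with intercept only, the score statistic for
    adding column x is ``U^2 / V`` with ``U = sum (y_i - ybar) x_i`` and
    ``V = ybar (1 - ybar) sum (x_i - xbar)^2``; it is chi-square(1) under
    the null.  Zero-variance columns get statistic 0.
    """
    y = np.asarray(y, dtype=float)
    ybar = y.mean()
    w = y - ybar
    U = w @ X
    centered_ss = np.einsum("ij,ij->j", X, X) - X.shape[0] * (X.mean(axis=0) ** 2)
    V = ybar * (1.0 - ybar) * centered_ss
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(V > 0, U * U / V, 0.0)
    return stat


class StepwiseLogisticSelector(BaseEstimator):
    """Forward/backward stepwise logistic regression feature selector.

    Parameters
    ----------
    entry_p, removal_p : float
        LR-test entry (p <= entry_p) and removal (p > removal_p) levels.
    max_steps : int
        Cap on forward entries.
    penalty : {"firth", "none"}
        Likelihood used throughout; Firth keeps separated fits finite.
    prescreen_k : int or None
        Univariate score-test prescreen size; None searches all columns.

    Attributes
    ----------
    selected_features_ : list of str
        Names of retained features, in entry order after removals.
    fit_ : LogisticFit
        Final model over the retained features (intercept-only if none).
    step_trace_ : list of StepRecord
    degenerate_ : bool
        True when the outcome had no cases or no controls (empty selection).
    """

    def __init__(self, entry_p: float = 0.05, removal_p: float = 0.10,
                 max_steps: int = 20, penalty: str = "firth",
                 prescreen_k: int | None = 50):
        self.entry_p = entry_p
        self.removal_p = removal_p
        self.max_steps = max_steps
        self.penalty = penalty
        self.prescreen_k = prescreen_k

    # ------------------------------------------------------------------
    def fit(self, X, y):
        if not (0 < self.entry_p <= self.removal_p < 1):
            raise ValidationError("require 0 < entry_p <= removal_p < 1")
        X_arr, names = _as_matrix(X)
        y = np.asarray(y)
        if set(np.unique(y)) - {0, 1, True, False}:
            raise ValidationError("outcome must be binary")
        y = y.astype(int)
        self.feature_names_in_ = names
        self.n_features_in_ = X_arr.shape[1]

        if y.sum() == 0 or y.sum() == len(y):
            self.degenerate_ = True
            self.selected_features_ = []
            self.selected_idx_ = []
            self.step_trace_ = []
            self.fit_ = fit_logistic(None, y) if 0 < y.sum() < len(y) else None
            return self
        self.degenerate_ = False

        candidates = self._prescreen(X_arr, y)
        included: list[int] = []
        trace: list[StepRecord] = []
        current = fit_logistic(None, y, penalty=self.penalty)
        step = 0
        seen = {frozenset()}
        while step < self.max_steps:
            entry = self._best_entry(X_arr, y, included, candidates, current)
            if entry is None:
                break
            idx, p_val, new_fit = entry
            if p_val > self.entry_p:
                break
            step += 1
            included.append(idx)
            current = new_fit
            trace.append(StepRecord(step, "add", names[idx], p_val, current.loglik))
            current, removed = self._backward(X_arr, y, included, current, trace, step)
            if idx in removed:  # immediate undo of this entry: stop
                break
            state = frozenset(included)
            if state in seen:  # add/remove cycle: stop
                break
            seen.add(state)
        self.selected_idx_ = list(included)
        self.selected_features_ = [names[i] for i in included]
        self.step_trace_ = trace
        self.fit_ = current
        return self

    # ------------------------------------------------------------------
    def _prescreen(self, X: np.ndarray, y: np.ndarray) -> list[int]:
        k = self.prescreen_k
        if k is None or k >= X.shape[1]:
            return list(range(X.shape[1]))
        stat = score_test_statistics(X, y)
        # stable sort keeps canonical order among ties
        order = np.argsort(-stat, kind="stable")[:k]
        return sorted(order.tolist())

    def _best_entry(self, X, y, included, candidates, current):
        """Pick the entry candidate by Rao score test at the current fit.

        The score statistic for adding column x to the fitted model is
        ``U^2 / V`` with ``U = x'(y - p)`` and ``V = x'Wx - x'WX (X'WX)^-1
        X'Wx`` (W the current fit's weight matrix), the classic stepwise
        entry statistic; it is computed for all candidates in one
        vectorized pass, and only the winner is actually refitted.
        """
        cand = np.array([i for i in candidates if i not in included], dtype=int)
        if cand.size == 0:
            return None
        n = X.shape[0]
        Xd = np.column_stack([np.ones(n)] + [X[:, i] for i in included])
        eta = Xd @ current.params
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = p * (1.0 - p)
        resid = y - p
        Xc = X[:, cand]
        WXd = Xd * w[:, None]
        info = Xd.T @ WXd
        M = Xc.T @ WXd                      # K x k cross-information
        try:
            sol = np.linalg.solve(info, M.T)
        except np.linalg.LinAlgError:
            sol = np.linalg.pinv(info) @ M.T
        # efficient score: project out the fitted design so a non-zero
        # residual score of the current (penalized) fit cannot leak into U
        s0 = Xd.T @ resid
        U = resid @ Xc - sol.T @ s0
        V = w @ (Xc * Xc) - np.einsum("kj,jk->k", M, sol)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(V > 1e-12, U * U / V, 0.0)
        pvals = stats.chi2.sf(stat, df=1)
        pos = int(np.argmin(pvals))         # ties -> smallest canonical index
        idx = int(cand[pos])
        p_val = float(pvals[pos])
        if p_val > self.entry_p:
            return idx, p_val, current
        fit = fit_logistic(X[:, included + [idx]], y, penalty=self.penalty)
        return idx, p_val, fit

    def _backward(self, X, y, included, current, trace, step):
        removed: list[int] = []
        while len(included) > 1:
            ll_full = current.loglik
            worst = None
            for pos, idx in enumerate(included):
                reduced_cols = included[:pos] + included[pos + 1:]
                reduced = fit_logistic(X[:, reduced_cols], y, penalty=self.penalty)
                lr = max(0.0, 2.0 * (ll_full - reduced.loglik))
                p = float(stats.chi2.sf(lr, df=1))
                if worst is None or p > worst[1] + 1e-15:
                    worst = (pos, p, reduced)
            if worst is None or worst[1] <= self.removal_p:
                break
            pos, p, reduced = worst
            idx = included.pop(pos)
            removed.append(idx)
            current = reduced
            trace.append(StepRecord(step, "remove",
                                    self.feature_names_in_[idx], p,
                                    current.loglik))
        return current, removed

    # ------------------------------------------------------------------
    def transform(self, X):
        X_arr, _ = _as_matrix(X)
        return X_arr[:, self.selected_idx_]

    def predict_proba(self, X):
        if self.fit_ is None:
            raise ValidationError("selector fitted on a degenerate outcome")
        X_arr, _ = _as_matrix(X)
        eta = self.fit_.intercept_ + X_arr[:, self.selected_idx_] @ self.fit_.coef_
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("X must be 2-dimensional")
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def fit_stepwise_logistic(features, outcome, config: SelectionConfig):
    """Functional wrapper: run the stepwise engine on a feature table.

    ``features`` may be a FeatureMatrix, DataFrame or ndarray.  Returns the
    fitted :class:`StepwiseLogisticSelector`.
    """
    values = getattr(features, "values", features)
    if not isinstance(values, (pd.DataFrame, np.ndarray)):
        values = np.asarray(values)
    sel = StepwiseLogisticSelector(
        entry_p=config.entry_p, removal_p=config.removal_p,
        max_steps=config.max_steps, penalty=config.penalty,
        prescreen_k=config.prescreen_k,
    )
    return sel.fit(values, outcome)
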