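"""Logistic regression back-end for rare-event marker selection.

Screening cohorts have case:control ratios of order 1:10,000 and candidate
markers that often separate the classes perfectly, where plain
maximum-likelihood logistic regression diverges.  The default engine is
therefore Firth's bias-reduced logistic regression — maximum penalized
likelihood with the Jeffreys-prior penalty ``0.5 * log det I(beta)`` —
whose estimates stay finite under complete separation.  Likelihood-ratio
tests between nested models use penalized log-likelihood differences, the
standard practice for this estimator.

Plain maximum likelihood (via statsmodels) is retained as an option; fits
that separate are flagged rather than silently reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import ValidationError

Penalty = str  # "firth" | "none"


@dataclass
class LogisticFit:
    """Result of a (possibly penalized) logistic fit with intercept.

    ``params``/``bse`` are ordered intercept-first; ``loglik`` is the
    penalized log-likelihood for Firth fits and the ordinary one otherwise.
    """

    params: np.ndarray
    bse: np.ndarray
    loglik: float
    converged: bool
    separation: bool
    method: str
    n_iter: int

    @property
    def coef_(self) -> np.ndarray:
        return self.params[1:]

    @property
    def intercept_(self) -> float:
        return float(self.params[0])


def _design(X: np.ndarray | None, n: int) -> np.ndarray:
    if X is None or X.shape[1] == 0:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), X])


def _detect_separation(eta: np.ndarray, y: np.ndarray) -> bool:
    """Complete separation: every case scores above every control."""
    if y.all() or not y.any():
        return False
    return float(eta[y == 1].min()) > float(eta[y == 0].max())


def fit_firth(X: np.ndarray | None, y: np.ndarray, max_iter: int = 50,
              tol: float = 1e-6) -> LogisticFit:
    """Firth-penalized logistic regression via modified-score Newton steps.

    The score is adjusted by the hat-diagonal term
    ``U*_j = sum_i (y_i - p_i + h_i (1/2 - p_i)) x_ij`` and iterations use
    step-halving on the penalized log-likelihood.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    Xd = _design(np.asarray(X, dtype=float) if X is not None else None, n)
    k = Xd.shape[1]
    beta = np.zeros(k)
    ll = _penalized_loglik(Xd, y, beta)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        eta = Xd @ beta
        p = _sigmoid(eta)
        w = p * (1.0 - p)
        XtW = Xd.T * w
        info = XtW @ Xd
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        # hat diagonal of W^1/2 X (X'WX)^-1 X' W^1/2
        h = w * np.einsum("ij,jk,ik->i", Xd, info_inv, Xd)
        score = Xd.T @ (y - p + h * (0.5 - p))
        delta = info_inv @ score
        # step-halving: accept the largest step that improves penalized ll
        step = 1.0
        for _ in range(12):
            cand = beta + step * delta
            ll_new = _penalized_loglik(Xd, y, cand)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:
            cand, ll_new = beta, ll
        beta, ll = cand, ll_new
        if np.max(np.abs(score)) < tol or np.max(np.abs(step * delta)) < tol:
            converged = True
            break

    eta = Xd @ beta
    p = _sigmoid(eta)
    w = p * (1.0 - p)
    info = (Xd.T * w) @ Xd
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return LogisticFit(
        params=beta, bse=bse, loglik=float(ll), converged=converged,
        separation=_detect_separation(eta, y.astype(int)), method="firth",
        n_iter=n_iter,
    )


def fit_ml(X: np.ndarray | None, y: np.ndarray, max_iter: int = 100) -> LogisticFit:
    """Ordinary maximum-likelihood logistic fit (statsmodels Logit)."""
    y = np.asarray(y, dtype=float)
    Xd = _design(np.asarray(X, dtype=float) if X is not None else None, y.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xd).fit(disp=0, maxiter=max_iter,
                                      warn_convergence=False)
            params = np.asarray(res.params, dtype=float)
            bse = np.asarray(res.bse, dtype=float)
            ll = float(res.llf)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            # Perfect separation or singular design: fall back to Firth so the
            # caller still gets finite numbers, flagged as separated.
            fit = fit_firth(X, y)
            return LogisticFit(
                params=fit.params, bse=fit.bse, loglik=fit.loglik,
                converged=False, separation=True, method="ml-separated",
                n_iter=fit.n_iter,
            )
    eta = Xd @ params
    sep = _detect_separation(eta, y.astype(int)) or np.max(np.abs(params)) > 15
    return LogisticFit(params=params, bse=bse, loglik=ll, converged=converged,
                       separation=bool(sep), method="ml", n_iter=max_iter)


def fit_logistic(X: np.ndarray | None, y: np.ndarray,
                 penalty: Penalty = "firth") -> LogisticFit:
    """Fit a logistic model with intercept under the requested penalty."""
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("outcome must be binary 0/1")
    if penalty == "firth":
        return fit_firth(X, y)
    if penalty == "none":
        return fit_ml(X, y)
    raise ValidationError(f"unknown penalty {penalty!r}")


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ex = np.exp(eta[~pos])
    out[~pos] = ex / (1.0 + ex)
    return np.clip(out, 1e-12, 1.0 - 1e-12)


def _penalized_loglik(Xd: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    p = _sigmoid(Xd @ beta)
    ll = float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    w = p * (1.0 - p)
    info = (Xd.T * w) @ Xd
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * float(logdet)
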