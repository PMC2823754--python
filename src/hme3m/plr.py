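"""Ridge-penalized logistic regression experts (damped reweighted ridge steps).

Each expert maximizes a weighted log-likelihood penalized by (lambda/2)|beta|^2
(intercept excluded).  The update is a damped Newton step — ``alpha`` times the
iterative reweighted ridge regression step — where the observation weights
combine the usual IRLS weights p(1-p) with the per-observation responsibilities
h_i supplied by the mixture-of-experts architecture.  A backtracking halving of
the step guards the ascent property the surrounding EM relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

logger = logging.getLogger("hme3m")

__all__ = ["PLRExpert", "fit_plr", "predict_proba_plr"]

_PCLIP = 1e-10  # probability clipping where ratios of p are formed


@dataclass
class PLRExpert:
    """A fitted ridge logistic expert: beta[0] is the intercept, beta[1:] per edge."""

    beta: np.ndarray
    lam: float = 1.0
    alpha: float = 0.5
    max_iter: int = 50
    tol: float = 1e-6
    n_iter_: int = field(default=0, compare=False)
    converged_: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")
        _validate_hyperparams(self.lam, self.alpha)


def _validate_hyperparams(lam: float, alpha: float) -> None:
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if lam > 2:
        logger.warning("lambda=%g outside the usual [0, 2] range; accepted", lam)
    if not 0 < alpha <= 1:
        raise ValueError("alpha (learning rate) must lie in (0, 1]")


def _design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.hstack([np.ones((X.shape[0], 1)), X])


def _penalized_loglik_eta(eta: np.ndarray, y: np.ndarray, h: np.ndarray,
                          lam: float, beta: np.ndarray) -> float:
    # sum_i h_i [y_i eta_i - log(1 + e^eta_i)] - lam/2 |beta_1:|^2
    ll = float(h @ (y * eta - np.logaddexp(0.0, eta)))
    return ll - 0.5 * lam * float(beta[1:] @ beta[1:])


def fit_plr(
    X: np.ndarray,
    y: np.ndarray,
    h: np.ndarray | None = None,
    lam: float = 1.0,
    alpha: float = 0.5,
    max_iter: int = 50,
    tol: float = 1e-6,
    beta0: np.ndarray | None = None,
    _design_matrix: np.ndarray | None = None,
) -> PLRExpert:
    """Fit a weighted ridge logistic regression by damped Newton (ridge IRLS) steps.

    Parameters
    ----------
    X : (N, P) binary design (an intercept column is prepended internally).
    y : (N,) binary response.
    h : (N,) nonnegative observation weights (responsibilities); ones if None.
    lam : ridge penalty on the non-intercept coefficients.
    alpha : learning rate damping the Newton step.
    beta0 : optional warm start (length P + 1).

    Each iteration solves the penalized normal equations
    ``(X'WX + Lambda) d = X'h(y - p) - Lambda beta`` with W_ii = h_i p_i (1-p_i)
    and takes ``beta += alpha * d`` — exactly alpha times the step of iterative
    reweighted ridge regression — halving the step if it would decrease the
    penalized weighted log-likelihood.  Stops when the step's max-norm falls
    below ``tol``.
    """
    _validate_hyperparams(lam, alpha)
    Xd = _design(X) if _design_matrix is None else _design_matrix
    y = np.asarray(y, dtype=float)
    n, p1 = Xd.shape
    if h is None:
        h = np.ones(n)
    else:
        h = np.asarray(h, dtype=float)
        if np.any(h < 0):
            raise ValueError("weights h must be nonnegative")
        if not np.any(h > 0):
            raise ValueError("weights h must not all be zero")
    Lam = np.full(p1, lam)
    Lam[0] = 0.0  # the intercept is not penalized
    beta = np.zeros(p1) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    diag = np.arange(p1)

    eta = Xd @ beta
    obj = _penalized_loglik_eta(eta, y, h, lam, beta)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # clip p where weights are formed so saturated experts (p -> 0 or 1)
        # keep a positive-definite system
        p = np.clip(expit(eta), _PCLIP, 1 - _PCLIP)
        w = h * p * (1 - p)
        A = (Xd * w[:, None]).T @ Xd
        A[diag, diag] += Lam
        g = Xd.T @ (h * (y - p)) - Lam * beta
        try:
            step = np.linalg.solve(A, g)
            if not np.all(np.isfinite(step)):
                raise np.linalg.LinAlgError("non-finite step")
        except np.linalg.LinAlgError as exc:
            if lam == 0:
                raise np.linalg.LinAlgError(
                    "singular penalized normal equations; use lambda > 0 to regularize"
                ) from exc
            # ill-conditioned despite the ridge (e.g. fully saturated fit):
            # a least-squares step is still an ascent direction under backtracking
            step = np.linalg.lstsq(A, g, rcond=None)[0]
            if not np.all(np.isfinite(step)):
                converged = True
                break
        # damped step with backtracking to preserve ascent
        step_eta = Xd @ step
        scale = alpha
        for _ in range(40):
            cand = beta + scale * step
            cand_eta = eta + scale * step_eta
            cand_obj = _penalized_loglik_eta(cand_eta, y, h, lam, cand)
            if cand_obj >= obj - 1e-12:
                break
            scale *= 0.5
        else:
            converged = True  # no improving step left
            break
        beta, eta, obj = cand, cand_eta, cand_obj
        if scale * np.max(np.abs(step)) < tol:
            converged = True
            break
    return PLRExpert(beta=beta, lam=lam, alpha=alpha, max_iter=max_iter, tol=tol,
                     n_iter_=n_iter, converged_=converged)


def predict_proba_plr(expert: PLRExpert, X: np.ndarray) -> np.ndarray:
    """Per-row probability of y = 1 under the expert (sigmoid of the linear predictor)."""
    Xd = _design(X)
    return np.clip(expit(Xd @ expert.beta), _PCLIP, 1 - _PCLIP)
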