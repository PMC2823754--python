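"""Mixture of first-order Markov chains over start->end paths (the gate model).

Each mixture component m is a Markov chain on the network: for every compound
the out-edge transition probabilities theta_tm sum to one, and the probability
of a complete path is the product of theta over its traversed edges (the start
state has probability 1, there being a single start compound).  Fitting the
mixture by EM clusters observed paths around dominant routes; inside the
supervised model the same machinery provides the gating weights.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .network import GeneNetwork

logger = logging.getLogger("hme3m")

__all__ = [
    "MarkovMixtureParams",
    "component_path_probability",
    "mixture_path_probability",
    "posterior_component_probability",
    "mixture_m_step",
    "fit_markov_mixture",
]

#: pseudocount added to weighted edge counts before per-node normalization so
#: no observed path is ever assigned probability exactly 0 mid-fit
THETA_SMOOTHING = 1e-6


@dataclass
class MarkovMixtureParams:
    """Component priors pi (length M) and transition probabilities theta (M x P)."""

    pi: np.ndarray
    theta: np.ndarray
    network: GeneNetwork = field(repr=False)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2 or self.theta.shape[0] != self.pi.shape[0]:
            raise ValueError("theta must be M x P with M = len(pi)")
        if self.theta.shape[1] != self.network.n_edges:
            raise ValueError("theta column count must equal the network edge count")

    @property
    def n_components(self) -> int:
        return len(self.pi)

    def validate(self, atol: float = 1e-10) -> None:
        """Check the simplex invariants: pi sums to 1; per-source-node theta sums to 1."""
        if np.any(self.pi < -atol) or abs(self.pi.sum() - 1.0) > atol:
            raise ValueError("pi is not a probability vector")
        if np.any(self.theta < -atol):
            raise ValueError("theta has negative entries")
        for group in self.network.source_node_groups():
            s = self.theta[:, group].sum(axis=1)
            if np.any(np.abs(s - 1.0) > atol):
                raise ValueError(
                    f"theta out-edge probabilities for node {self.network.edges[group[0]][0]!r} "
                    f"do not sum to 1: {s}"
                )

    # ----- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "theta": self.theta.tolist(),
            "edges": [list(e) for e in self.network.edges],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict, network: GeneNetwork) -> "MarkovMixtureParams":
        return cls(pi=np.array(d["pi"]), theta=np.array(d["theta"]), network=network)


def component_path_probability(theta_m: np.ndarray, x: np.ndarray) -> float:
    """Probability of path ``x`` under one chain: product of theta over traversed edges."""
    theta_m = np.asarray(theta_m, dtype=float)
    x = np.asarray(x)
    return float(np.prod(theta_m[x == 1]))


def log_path_probabilities(params: MarkovMixtureParams, X: np.ndarray) -> np.ndarray:
    """N x M matrix of log p(x_i | theta_m); vectorized as X @ log(theta)^T."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    with np.errstate(divide="ignore"):
        logt = np.log(params.theta)
    logp = X @ logt.T
    logp[np.isnan(logp)] = -np.inf  # 0 * -inf from untraversed zero-prob edges
    return logp


def mixture_path_probability(params: MarkovMixtureParams, x: np.ndarray) -> float:
    """sum_m pi_m p(x | theta_m)."""
    logp = log_path_probabilities(params, x)[0]
    with np.errstate(divide="ignore"):
        logpi = np.log(params.pi)
    return float(np.exp(logsumexp(logpi + logp)))


def posterior_component_probability(
    params: MarkovMixtureParams, x: np.ndarray
) -> np.ndarray:
    """Posterior component memberships pi_m p(x|theta_m) / sum_k pi_k p(x|theta_k)."""
    return _responsibilities(params, np.atleast_2d(x))[0]


def _responsibilities(params: MarkovMixtureParams, X: np.ndarray,
                      extra_log: np.ndarray | None = None) -> np.ndarray:
    """Row-normalized posteriors; optional extra per-(i,m) log factors (expert terms)."""
    with np.errstate(divide="ignore"):
        logw = np.log(params.pi) + log_path_probabilities(params, X)
    if extra_log is not None:
        logw = logw + extra_log
    norm = logsumexp(logw, axis=1, keepdims=True)
    degenerate = ~np.isfinite(norm[:, 0])
    if degenerate.any():
        logger.warning(
            "%d observation(s) with zero probability under every component; "
            "uniform posterior fallback", int(degenerate.sum()),
        )
    H = np.full(logw.shape, 1.0 / params.n_components)
    ok = ~degenerate
    H[ok] = np.exp(logw[ok] - norm[ok])
    return H


def mixture_m_step(
    X: np.ndarray,
    H: np.ndarray,
    network: GeneNetwork,
    smoothing: float = THETA_SMOOTHING,
) -> MarkovMixtureParams:
    """Maximize the mixture part of the expected complete-data log-likelihood.

    pi_m is the mean responsibility; theta_tm is the responsibility-weighted
    count of traversals of edge t, normalized over the edges sharing t's
    source compound (so each compound's out-edge probabilities sum to one).
    A pseudocount keeps every transition strictly positive; a compound with no
    weighted traversals at all gets a uniform distribution over its out-edges.
    """
    X = np.asarray(X, dtype=float)
    H = np.asarray(H, dtype=float)
    n, m = H.shape
    pi = H.sum(axis=0) / n
    pi = pi / pi.sum()
    counts = H.T @ X  # M x P weighted traversal counts
    theta = np.zeros_like(counts)
    for group in network.source_node_groups():
        block = counts[:, group] + smoothing
        totals = block.sum(axis=1, keepdims=True)
        zero = totals[:, 0] == 0  # node never traversed and no pseudocount
        totals[zero] = 1.0
        theta[:, group] = block / totals
        theta[np.ix_(zero, group)] = 1.0 / len(group)
    return MarkovMixtureParams(pi=pi, theta=theta, network=network)


def fit_markov_mixture(
    X: np.ndarray,
    network: GeneNetwork,
    n_components: int,
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    n_restarts: int = 1,
) -> tuple[MarkovMixtureParams, list[float]]:
    """Unsupervised EM for the path mixture; returns (params, log-likelihood trace).

    Initialization draws per-row responsibilities from a flat Dirichlet and
    applies an M-step first.  The trace is the observed-data log-likelihood
    after each M-step and is non-decreasing.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= n_components <= n:
        raise ValueError("need 1 <= n_components <= number of observations")
    rng = np.random.default_rng(seed)
    best: tuple[float, MarkovMixtureParams, list[float]] | None = None
    for _ in range(n_restarts):
        H = rng.dirichlet(np.ones(n_components), size=n)
        params = mixture_m_step(X, H, network)
        history: list[float] = [_loglik(params, X)]
        for _it in range(max_iter):
            H = _responsibilities(params, X)
            params = mixture_m_step(X, H, network)
            history.append(_loglik(params, X))
            if abs(history[-1] - history[-2]) < tol * (1 + abs(history[-2])):
                break
        if best is None or history[-1] > best[0]:
            best = (history[-1], params, history)
    assert best is not None
    return best[1], best[2]


def _loglik(params: MarkovMixtureParams, X: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        logw = np.log(params.pi) + log_path_probabilities(params, X)
    return float(logsumexp(logw, axis=1).sum())
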