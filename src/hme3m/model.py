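"""The supervised model: Markov-mixture gates with penalized logistic experts.

The model is a two-layer mixture of experts for binary classification of
network paths.  The gate is the path mixture of first-order Markov chains:
component m has prior pi_m and transition probabilities theta_m, so a path
x is soft-assigned to components by its similarity to each dominant route.
The expert attached to component m is a ridge logistic regression beta_m on
the binary edge vector.  The likelihood of an observation (x, y) is

    sum_m pi_m p(x | theta_m) p(y | x, beta_m)

and the parameters are fitted by EM: the E-step computes responsibilities
h_im proportional to the summand above; the M-step re-estimates (pi, theta)
from responsibility-weighted traversal counts and takes damped ridge-Newton
steps on each expert weighted by its responsibilities (a generalized EM).
Fitting maximizes the ridge-penalized likelihood; the recorded history is
that penalized objective, which the EM never decreases.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .network import ConfigurationError, GeneNetwork
from .markov import (
    MarkovMixtureParams,
    _responsibilities,
    log_path_probabilities,
    mixture_m_step,
)
from .plr import PLRExpert, _design as _plr_design, fit_plr, predict_proba_plr, _PCLIP

logger = logging.getLogger("hme3m")

__all__ = [
    "HME3MModel",
    "e_step",
    "fit_hme3m",
    "predict_proba",
    "predict",
    "component_scores",
    "dominant_path_report",
    "export_graphml",
    "export_dot",
]

_COLLAPSE_TOL = 1e-8  # pi below this freezes the component


@dataclass
class HME3MModel:
    mixture: MarkovMixtureParams
    experts: list[PLRExpert]
    config: dict
    history: list[float] = field(default_factory=list)
    loglik_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.experts) != self.mixture.n_components:
            raise ValueError("number of experts must match mixture components")
        p1 = self.mixture.theta.shape[1] + 1
        for ex in self.experts:
            if len(ex.beta) != p1:
                raise ValueError("expert dimension must be edge count + 1 (intercept)")

    @property
    def n_components(self) -> int:
        return self.mixture.n_components

    @property
    def network(self) -> GeneNetwork:
        return self.mixture.network

    # ----- serialization (lossless text round trip) ----------------------
    def to_json(self, path) -> None:
        doc = {
            "config": self.config,
            "history": self.history,
            "loglik_history": self.loglik_history,
            "pi": self.mixture.pi.tolist(),
            "theta": self.mixture.theta.tolist(),
            "experts": [
                {"beta": ex.beta.tolist(), "lam": ex.lam, "alpha": ex.alpha,
                 "max_iter": ex.max_iter, "tol": ex.tol}
                for ex in self.experts
            ],
            "network": {
                "nodes": list(self.network.nodes),
                "edges": [list(e) for e in self.network.edges],
                "start": self.network.start,
                "end": self.network.end,
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "HME3MModel":
        with open(path) as fh:
            doc = json.load(fh)
        net = GeneNetwork(
            nodes=tuple(doc["network"]["nodes"]),
            edges=tuple(tuple(e) for e in doc["network"]["edges"]),
            start=doc["network"]["start"],
            end=doc["network"]["end"],
        )
        mix = MarkovMixtureParams(pi=np.array(doc["pi"]), theta=np.array(doc["theta"]),
                                  network=net)
        experts = [
            PLRExpert(beta=np.array(e["beta"]), lam=e["lam"], alpha=e["alpha"],
                      max_iter=e["max_iter"], tol=e["tol"])
            for e in doc["experts"]
        ]
        return cls(mixture=mix, experts=experts, config=doc["config"],
                   history=doc["history"], loglik_history=doc["loglik_history"])


# ---------------------------------------------------------------------------
# E-step / likelihood
# ---------------------------------------------------------------------------

def _expert_log_py(model_experts: list[PLRExpert], X: np.ndarray,
                   y: np.ndarray, design: np.ndarray | None = None) -> np.ndarray:
    """N x M matrix of log p(y_i | x_i, beta_m)."""
    y = np.asarray(y, dtype=float)
    Xd = _plr_design(X) if design is None else design
    B = np.column_stack([ex.beta for ex in model_experts])
    eta = Xd @ B  # N x M linear predictors
    # log p(y|eta) = y*eta - log(1 + e^eta), stable for both labels
    return y[:, None] * eta - np.logaddexp(0.0, eta)


def e_step(model: HME3MModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Responsibilities h_im ∝ pi_m p(x_i|theta_m) p(y_i|x_i, beta_m); rows sum to 1."""
    return _responsibilities(model.mixture, np.asarray(X, dtype=float),
                             extra_log=_expert_log_py(model.experts, X, y))


def _observed_loglik(mixture: MarkovMixtureParams, experts: list[PLRExpert],
                     X: np.ndarray, y: np.ndarray,
                     design: np.ndarray | None = None) -> float:
    with np.errstate(divide="ignore"):
        logw = (np.log(mixture.pi) + log_path_probabilities(mixture, X)
                + _expert_log_py(experts, X, y, design=design))
    return float(logsumexp(logw, axis=1).sum())


def _penalty(experts: list[PLRExpert], lam: float) -> float:
    return 0.5 * lam * sum(float(ex.beta[1:] @ ex.beta[1:]) for ex in experts)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_hme3m(
    X: np.ndarray,
    y: np.ndarray,
    network: GeneNetwork,
    n_components: int,
    lam: float = 1.0,
    alpha: float = 0.5,
    max_em_iter: int = 100,
    em_tol: float = 1e-6,
    seed: int | None = None,
    n_restarts: int = 3,
    warm_start: bool = True,
    plr_max_iter: int = 50,
    plr_tol: float = 1e-6,
) -> HME3MModel:
    """Fit the model by EM; the best of ``n_restarts`` random initializations wins.

    Each restart draws row responsibilities from a flat Dirichlet, applies an
    M-step, then alternates E- and M-steps until the relative change of the
    penalized observed-data objective falls below ``em_tol`` or ``max_em_iter``
    is reached.  Experts are warm-started across EM iterations by default.
    Fully reproducible given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if not 1 <= n_components <= n:
        raise ConfigurationError("need 1 <= n_components <= number of observations")
    rng = np.random.default_rng(seed)
    Xd = _plr_design(X)

    best: HME3MModel | None = None
    for _restart in range(max(1, n_restarts)):
        H = rng.dirichlet(np.ones(n_components), size=n)
        mixture = mixture_m_step(X, H, network)
        experts = [
            fit_plr(X, y, h=H[:, m], lam=lam, alpha=alpha,
                    max_iter=plr_max_iter, tol=plr_tol, _design_matrix=Xd)
            for m in range(n_components)
        ]
        ll = _observed_loglik(mixture, experts, X, y, design=Xd)
        history = [ll - _penalty(experts, lam)]
        loglik_history = [ll]
        for _it in range(max_em_iter):
            H = _responsibilities(mixture, X,
                                  extra_log=_expert_log_py(experts, X, y, design=Xd))
            mixture = mixture_m_step(X, H, network)
            collapsed = mixture.pi < _COLLAPSE_TOL
            if collapsed.any():
                logger.warning("component(s) %s collapsed (pi < %g); frozen",
                               np.where(collapsed)[0].tolist(), _COLLAPSE_TOL)
            new_experts = []
            for m in range(n_components):
                if collapsed[m] or H[:, m].sum() <= 0:
                    new_experts.append(experts[m])  # frozen
                    continue
                beta0 = experts[m].beta if warm_start else None
                new_experts.append(
                    fit_plr(X, y, h=H[:, m], lam=lam, alpha=alpha,
                            max_iter=plr_max_iter, tol=plr_tol, beta0=beta0,
                            _design_matrix=Xd)
                )
            experts = new_experts
            ll = _observed_loglik(mixture, experts, X, y, design=Xd)
            history.append(ll - _penalty(experts, lam))
            loglik_history.append(ll)
            if abs(history[-1] - history[-2]) < em_tol * (1 + abs(history[-2])):
                break
        fitted = HME3MModel(
            mixture=mixture, experts=experts,
            config={"M": n_components, "lambda": lam, "alpha": alpha,
                    "max_em_iter": max_em_iter, "em_tol": em_tol, "seed": seed,
                    "n_restarts": n_restarts, "warm_start": warm_start},
            history=history, loglik_history=loglik_history,
        )
        if best is None or fitted.history[-1] > best.history[-1]:
            best = fitted
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Prediction and diagnostics
# ---------------------------------------------------------------------------

def predict_proba(model: HME3MModel, X: np.ndarray) -> np.ndarray:
    """P(y=1 | x) = sum_m p(m | x, theta) p(y=1 | x, beta_m) with the 3M gate posterior."""
    X = np.asarray(X, dtype=float)
    gate = _responsibilities(model.mixture, X)  # p(m | x, theta)
    expert_p = np.column_stack([predict_proba_plr(ex, X) for ex in model.experts])
    return np.clip((gate * expert_p).sum(axis=1), _PCLIP, 1 - _PCLIP)


def predict(model: HME3MModel, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Class labels: 1 iff the predicted probability exceeds ``threshold``."""
    return (predict_proba(model, X) > threshold).astype(int)


def component_scores(model: HME3MModel, X: np.ndarray, m: int,
                     gate_weighted: bool = False) -> np.ndarray:
    """Ranking scores for component m's ROC: the raw expert probability p(y=1|x, beta_m).

    With ``gate_weighted=True`` the expert probability is multiplied by the
    gate posterior p(m | x, theta) instead.
    """
    if not 0 <= m < model.n_components:
        raise IndexError(f"component index {m} out of range for M={model.n_components}")
    X = np.asarray(X, dtype=float)
    scores = predict_proba_plr(model.experts[m], X)
    if gate_weighted:
        scores = scores * _responsibilities(model.mixture, X)[:, m]
    return scores


def dominant_path_report(model: HME3MModel, m: int,
                         threshold: float = 0.5) -> pd.DataFrame:
    """Edges with theta_tm >= threshold, grouped by source compound.

    Columns: source, target, gene, edge (1-based coordinate, matching
    human-readable path numbering), theta.
    """
    if not 0 <= m < model.n_components:
        raise IndexError(f"component index {m} out of range for M={model.n_components}")
    net = model.network
    theta = model.mixture.theta[m]
    rows = []
    for group in net.source_node_groups():
        for t in group:
            if theta[t] >= threshold:
                u, v, gene = net.edges[t]
                rows.append({"source": u, "target": v, "gene": gene,
                             "edge": t + 1, "theta": theta[t]})
    return pd.DataFrame(rows, columns=["source", "target", "gene", "edge", "theta"])


# ---------------------------------------------------------------------------
# Graph exports (transition probabilities as edge attributes)
# ---------------------------------------------------------------------------

def export_graphml(model: HME3MModel, path) -> None:
    import networkx as nx

    g = model.network.to_multigraph()
    for _u, _v, k, data in g.edges(keys=True, data=True):
        for m in range(model.n_components):
            data[f"theta_{m + 1}"] = float(model.mixture.theta[m, k])
    nx.write_graphml(g, path)


def export_dot(model: HME3MModel, path, m: int = 0) -> None:
    """Plain DOT text with gene labels and component-m transition probabilities."""
    net = model.network
    theta = model.mixture.theta[m]
    lines = ["digraph pathway {"]
    for t, (u, v, gene) in enumerate(net.edges):
        lines.append(f'  "{u}" -> "{v}" [label="{gene} ({theta[t]:.3f})"];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
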