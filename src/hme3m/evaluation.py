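"""Cross-validation protocols, metrics, significance tests, and baselines.

Reproduces the benchmark protocol: 10 runs of stratified 10-fold
cross-validation reporting the median and range of the per-fold correct
classification rate (CCR, in percent), paired t-tests between models run on
identical fold assignments, inverse k-fold cross-validation (train on one
group, test on the other k-1), and per-component ROC/AUC diagnostics.
Baselines are a standalone ridge logistic regression and support vector
machines with linear, polynomial (degree 3) and radial kernels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .network import GeneNetwork, PathwayDataset
from .model import fit_hme3m, predict as hme3m_predict, predict_proba as hme3m_predict_proba
from .plr import fit_plr, predict_proba_plr
from .simulate import SimulationConfig, simulate_pathways

logger = logging.getLogger("hme3m")

__all__ = [
    "EvaluationResult",
    "ccr",
    "cross_validate",
    "inverse_cross_validate",
    "paired_t_test",
    "roc_auc",
    "run_baselines",
    "simulation_grid",
    "HME3MClassifier",
    "PLRClassifier",
    "make_estimator",
]


# ---------------------------------------------------------------------------
# Estimator wrappers (uniform fit/predict interface for the CV driver)
# ---------------------------------------------------------------------------

class HME3MClassifier:
    """sklearn-style wrapper around the mixture-of-experts fit."""

    def __init__(self, network: GeneNetwork, n_components: int = 2, lam: float = 1.0,
                 alpha: float = 0.5, seed: int | None = None, n_restarts: int = 3,
                 max_em_iter: int = 100, em_tol: float = 1e-6):
        self.network = network
        self.n_components = n_components
        self.lam = lam
        self.alpha = alpha
        self.seed = seed
        self.n_restarts = n_restarts
        self.max_em_iter = max_em_iter
        self.em_tol = em_tol
        self.model_ = None

    def fit(self, X, y):
        self.model_ = fit_hme3m(
            X, y, self.network, self.n_components, lam=self.lam, alpha=self.alpha,
            seed=self.seed, n_restarts=self.n_restarts,
            max_em_iter=self.max_em_iter, em_tol=self.em_tol,
        )
        return self

    def predict(self, X):
        return hme3m_predict(self.model_, X)

    def predict_proba(self, X):
        return hme3m_predict_proba(self.model_, X)


class PLRClassifier:
    """Standalone ridge logistic regression (the expert model with h = 1)."""

    def __init__(self, lam: float = 1.0, alpha: float = 0.5, max_iter: int = 50,
                 tol: float = 1e-6, seed: int | None = None):
        self.lam = lam
        self.alpha = alpha
        self.max_iter = max_iter
        self.tol = tol
        self.expert_ = None

    def fit(self, X, y):
        self.expert_ = fit_plr(X, y, h=None, lam=self.lam, alpha=self.alpha,
                               max_iter=self.max_iter, tol=self.tol)
        return self

    def predict(self, X):
        return (self.predict_proba(X) > 0.5).astype(int)

    def predict_proba(self, X):
        return predict_proba_plr(self.expert_, X)


def make_estimator(name: str, network: GeneNetwork | None = None,
                   seed: int | None = None, **kw):
    """Build an estimator by name: hme3m, plr, svm_linear, svm_poly, svm_radial.

    SVM hyperparameters stay at library defaults (cost 1; radial gamma 1/P,
    polynomial degree 3), mirroring the referenced implementation's defaults.
    """
    if name == "hme3m":
        return HME3MClassifier(network=network, seed=seed, **kw)
    if name == "plr":
        return PLRClassifier(seed=seed, **kw)
    if name == "svm_linear":
        return SVC(kernel="linear", C=1.0)
    if name == "svm_poly":
        return SVC(kernel="poly", degree=3, C=1.0, gamma="auto")
    if name == "svm_radial":
        return SVC(kernel="rbf", C=1.0, gamma="auto")
    raise ValueError(f"unknown estimator {name!r}")


# ---------------------------------------------------------------------------
# Metrics and tests
# ---------------------------------------------------------------------------

def ccr(y_true, y_pred) -> float:
    """Correct classification rate in percent: 100 * (#correct) / N."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    return 100.0 * float(np.mean(y_true == y_pred))


@dataclass
class TTestResult:
    statistic: float
    pvalue: float
    zero_variance: bool = False

    @property
    def significant(self) -> bool:
        return self.pvalue < 0.05


def paired_t_test(ccr_a, ccr_b) -> TTestResult:
    """Two-sided paired t-test of per-fold CCRs (paired by fold assignment).

    Zero-variance differences (including identical vectors) are reported as
    t = 0, p = 1 and flagged, since the test statistic is undefined there.
    """
    a = np.asarray(ccr_a, dtype=float).ravel()
    b = np.asarray(ccr_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired CCR vectors must have equal length")
    d = a - b
    if np.allclose(d.std(ddof=1) if len(d) > 1 else 0.0, 0.0):
        return TTestResult(statistic=0.0, pvalue=1.0, zero_variance=True)
    t, p = stats.ttest_rel(a, b)
    return TTestResult(statistic=float(t), pvalue=float(p))


def roc_auc(y_true, scores) -> tuple[float, np.ndarray, np.ndarray]:
    """Rank-based AUC (ties averaged) plus the ROC curve points (fpr, tpr)."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC is undefined for single-class y_true")
    fpr, tpr, _ = roc_curve(y_true, np.asarray(scores, dtype=float))
    return float(_sk_auc(fpr, tpr)), fpr, tpr


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    model: str
    ccrs: np.ndarray  # runs x folds test CCRs (%)
    fold_assignments: list[np.ndarray] = field(repr=False, default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def median(self) -> float:
        return float(np.median(self.ccrs))

    @property
    def range(self) -> float:
        return float(np.max(self.ccrs) - np.min(self.ccrs))


def make_folds(y, folds: int = 10, runs: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Per-run fold labels (stratified); identical assignments let models be paired."""
    y = np.asarray(y)
    assignments = []
    ss = np.random.SeedSequence(seed)
    for run_seed in ss.generate_state(runs):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(run_seed % (2**31)))
        lab = np.empty(len(y), dtype=int)
        for k, (_tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
            lab[te] = k
        assignments.append(lab)
    return assignments


def _check_folds(y, lab, folds):
    for k in range(folds):
        tr = y[lab != k]
        if len(np.unique(tr)) < 2:
            return False
    return True


def cross_validate(
    estimator_factory,
    X,
    y,
    folds: int = 10,
    runs: int = 10,
    seed: int = 0,
    fold_assignments: list[np.ndarray] | None = None,
    name: str = "model",
) -> EvaluationResult:
    """Repeated stratified k-fold CV; returns per-run-fold test CCRs.

    ``estimator_factory(fit_seed)`` must return a fresh estimator with
    fit/predict; ``fit_seed`` varies deterministically with (seed, run, fold)
    so stochastic fits are reproducible.  Pass ``fold_assignments`` (from
    :func:`make_folds`) to evaluate several models on identical folds.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if len(y) < folds:
        raise ValueError("need at least as many observations as folds")
    if fold_assignments is None:
        fold_assignments = make_folds(y, folds, runs, seed)
    ccrs = np.empty((runs, folds))
    ss = np.random.SeedSequence(seed + 1)
    fit_seeds = ss.generate_state(runs * folds)
    for r, lab in enumerate(fold_assignments[:runs]):
        if not _check_folds(y, lab, folds):
            logger.warning("run %d folds leave a single-class training set; re-stratifying", r)
            lab = make_folds(y, folds, 1, seed + 7919 * (r + 1))[0]
            fold_assignments[r] = lab
        for k in range(folds):
            tr, te = lab != k, lab == k
            est = estimator_factory(int(fit_seeds[r * folds + k] % (2**31)))
            est.fit(X[tr], y[tr])
            ccrs[r, k] = ccr(y[te], est.predict(X[te]))
    return EvaluationResult(model=name, ccrs=ccrs, fold_assignments=fold_assignments,
                            config={"folds": folds, "runs": runs, "seed": seed})


def inverse_cross_validate(
    estimator_factory,
    X,
    y,
    folds: int = 20,
    seed: int = 0,
    name: str = "model",
) -> EvaluationResult:
    """Inverse k-fold CV: train on one group (~N/k rows), test on the other k-1."""
    X = np.asarray(X)
    y = np.asarray(y)
    lab = make_folds(y, folds, 1, seed)[0]
    ss = np.random.SeedSequence(seed + 1)
    fit_seeds = ss.generate_state(folds)
    ccrs = np.empty((1, folds))
    for k in range(folds):
        tr, te = lab == k, lab != k
        if len(np.unique(y[tr])) < 2:
            logger.warning("inverse-CV group %d single-class; re-stratifying", k)
            lab = make_folds(y, folds, 1, seed + 7919)[0]
            tr, te = lab == k, lab != k
        est = estimator_factory(int(fit_seeds[k] % (2**31)))
        est.fit(X[tr], y[tr])
        ccrs[0, k] = ccr(y[te], est.predict(X[te]))
    return EvaluationResult(model=name, ccrs=ccrs, fold_assignments=[lab],
                            config={"folds": folds, "runs": 1, "seed": seed,
                                    "inverse": True})


# ---------------------------------------------------------------------------
# Baselines and the simulation grid
# ---------------------------------------------------------------------------

BASELINE_NAMES = ("plr", "svm_linear", "svm_poly", "svm_radial")


def run_baselines(
    dataset: PathwayDataset,
    folds: int = 10,
    runs: int = 10,
    seed: int = 0,
    models: tuple[str, ...] = BASELINE_NAMES,
    fold_assignments: list[np.ndarray] | None = None,
    lam: float = 1.0,
    alpha: float = 0.5,
) -> dict[str, EvaluationResult]:
    """Evaluate the comparison models on identical fold assignments.

    Every model sees the same binary path matrix X, so the network information
    supplied is the same for all of them; only the inductive bias differs.
    """
    if fold_assignments is None:
        fold_assignments = make_folds(dataset.y, folds, runs, seed)
    out = {}
    for nm in models:
        if nm == "plr":
            factory = lambda s: make_estimator("plr", lam=lam, alpha=alpha)  # noqa: E731
        else:
            factory = lambda s, _nm=nm: make_estimator(_nm)  # noqa: E731
        out[nm] = cross_validate(factory, dataset.X, dataset.y, folds, runs, seed,
                                 fold_assignments=fold_assignments, name=nm)
    return out


def evaluate_cell(
    size: str,
    noise: float,
    n_components: int,
    seed: int = 0,
    runs: int = 10,
    folds: int = 10,
    lam: float = 1.0,
    alpha: float = 0.5,
    models: tuple[str, ...] = ("hme3m",),
    n_restarts: int = 3,
) -> dict[str, EvaluationResult]:
    """One simulation-grid cell: generate the dataset, CV every requested model."""
    sim = simulate_pathways(SimulationConfig(network_size=size, noise_fraction=noise,
                                             seed=seed))
    fold_assignments = make_folds(sim.dataset.y, folds, runs, seed)
    out: dict[str, EvaluationResult] = {}
    for nm in models:
        if nm == "hme3m":
            factory = lambda s: HME3MClassifier(  # noqa: E731
                network=sim.network, n_components=n_components, lam=lam,
                alpha=alpha, seed=s, n_restarts=n_restarts)
        elif nm == "plr":
            factory = lambda s: make_estimator("plr", lam=lam, alpha=alpha)  # noqa: E731
        else:
            factory = lambda s, _nm=nm: make_estimator(_nm)  # noqa: E731
        out[nm] = cross_validate(factory, sim.dataset.X, sim.dataset.y, folds, runs,
                                 seed, fold_assignments=fold_assignments, name=nm)
    return out


def simulation_grid(
    sizes=("small", "medium", "large"),
    noises=(0.1, 0.2, 0.3, 0.4, 0.5),
    Ms=(2, 3),
    models=("hme3m",) + BASELINE_NAMES,
    runs: int = 10,
    folds: int = 10,
    seed: int = 0,
    lam: float = 1.0,
    alpha: float = 0.5,
    n_restarts: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The full benchmark grid (graph size x noise x M) with paired baselines.

    Returns a long-format table (graph, model, M, noise, run, fold, ccr) and a
    summary (median, range, and a significance star where the paired t-test
    against the same-cell mixture-of-experts model has p < 0.05).
    """
    long_rows = []
    summary_rows = []
    for size in sizes:
        for noise in noises:
            cell_seed = abs(hash((size, round(noise * 100)))) % (2**31 - 1) ^ seed
            for M in Ms:
                res = evaluate_cell(size, noise, M, seed=cell_seed, runs=runs,
                                    folds=folds, lam=lam, alpha=alpha,
                                    models=models, n_restarts=n_restarts)
                ref = res.get("hme3m")
                for nm, r in res.items():
                    for run_i in range(r.ccrs.shape[0]):
                        for fold_i in range(r.ccrs.shape[1]):
                            long_rows.append(dict(graph=size, model=nm, M=M,
                                                  noise=noise, run=run_i,
                                                  fold=fold_i,
                                                  ccr=r.ccrs[run_i, fold_i]))
                    star = ""
                    if ref is not None and nm != "hme3m":
                        tt = paired_t_test(ref.ccrs, r.ccrs)
                        star = "*" if tt.significant else ""
                    summary_rows.append(dict(graph=size, model=nm, M=M, noise=noise,
                                             median=r.median, range=r.range,
                                             significant=star))
    return pd.DataFrame(long_rows), pd.DataFrame(summary_rows)
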