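"""Simulation benchmark: layered networks with planted dominant paths + noise.

The generator emulates the benchmark design used to validate the classifier:
a layered DAG from one start to one end compound, two planted dominant paths
per response class (equal expression), and "noise" observations drawn
uniformly from the remaining valid start->end paths.  Class labels are
balanced by construction (``n_per_class`` rows each); as the noise fraction
grows the dominant paths' relative expression shrinks and classification gets
harder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ConfigurationError, GeneNetwork, PathwayDataset, enumerate_paths

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "make_network",
    "plant_dominant_paths",
    "simulate_pathways",
    "LAYER_SPECS",
]

#: intermediate-layer widths for the three benchmark complexities; layers are
#: fully connected, so the path counts are 8, 27 and 64
LAYER_SPECS: dict[str, tuple[int, ...]] = {
    "small": (2, 2, 2),
    "medium": (3, 3, 3),
    "large": (4, 4, 4),
}


@dataclass(frozen=True)
class SimulationConfig:
    network_size: str | tuple[int, ...] = "small"
    n_per_class: int = 200
    noise_fraction: float = 0.1
    dominant_paths_per_class: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.noise_fraction < 1:
            raise ConfigurationError("noise_fraction must lie in [0, 1)")
        if self.n_per_class < 1 or self.dominant_paths_per_class < 1:
            raise ConfigurationError("n_per_class and dominant_paths_per_class must be >= 1")

    @property
    def layers(self) -> tuple[int, ...]:
        if isinstance(self.network_size, str):
            try:
                return LAYER_SPECS[self.network_size]
            except KeyError:
                raise ConfigurationError(
                    f"unknown network size {self.network_size!r}; "
                    f"expected one of {sorted(LAYER_SPECS)} or an explicit layer tuple"
                ) from None
        return tuple(self.network_size)


@dataclass
class SimulationResult:
    network: GeneNetwork
    dataset: PathwayDataset
    dominant_paths: dict[int, list[np.ndarray]]  # class label -> path vectors
    config: SimulationConfig = field(repr=False)


def make_network(size_spec: str | tuple[int, ...] = "small",
                 seed: int | None = None) -> GeneNetwork:
    """A layered DAG: start -> L1 -> ... -> Lk -> end, fully connected layer to layer.

    ``size_spec`` is one of 'small'/'medium'/'large' or an explicit tuple of
    intermediate-layer widths.  Gene labels g1, g2, ... follow the edge order.
    The topology is deterministic; ``seed`` is accepted for interface symmetry.
    """
    layers = LAYER_SPECS[size_spec] if isinstance(size_spec, str) else tuple(size_spec)
    if any(k < 1 for k in layers) or not layers:
        raise ConfigurationError("every layer must have at least one node")
    n_paths = int(np.prod(layers))
    if n_paths < 4:
        raise ConfigurationError(
            f"layer spec {layers} yields only {n_paths} start->end paths; "
            "at least 4 are required to plant the dominant paths"
        )
    node_layers: list[list[str]] = [["start"]]
    for li, width in enumerate(layers):
        node_layers.append([f"n{li + 1}_{j + 1}" for j in range(width)])
    node_layers.append(["end"])
    edges: list[tuple[str, str, str]] = []
    for a, b in zip(node_layers[:-1], node_layers[1:]):
        for u in a:
            for v in b:
                edges.append((u, v, f"g{len(edges) + 1}"))
    nodes = tuple(n for layer in node_layers for n in layer)
    return GeneNetwork(nodes=nodes, edges=tuple(edges), start="start", end="end")


def plant_dominant_paths(network: GeneNetwork, per_class: int = 2,
                         seed: int | None = None) -> dict[int, list[np.ndarray]]:
    """Sample 2*per_class mutually distinct paths uniformly, per_class per label."""
    paths = enumerate_paths(network)
    need = 2 * per_class
    if len(paths) < need:
        raise ConfigurationError(
            f"network has {len(paths)} paths but {need} dominant paths are required"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(paths), size=need, replace=False)
    return {0: [paths[i] for i in chosen[:per_class]],
            1: [paths[i] for i in chosen[per_class:]]}


def simulate_pathways(config: SimulationConfig) -> SimulationResult:
    """Generate the labeled path dataset for one simulation condition.

    Per class: ``round(n_per_class * (1 - noise_fraction))`` rows are split as
    evenly as possible across that class's dominant paths; the remaining rows
    are noise, drawn uniformly (with replacement) from the valid paths that
    are not dominant for either class.  Rows are shuffled; everything is a
    deterministic function of the config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    network = make_network(config.layers)
    dominant = plant_dominant_paths(network, config.dominant_paths_per_class,
                                    seed=rng.integers(2**31))
    all_paths = enumerate_paths(network)
    dom_keys = {p.tobytes() for paths in dominant.values() for p in paths}
    noise_pool = [p for p in all_paths if p.tobytes() not in dom_keys]

    rows: list[np.ndarray] = []
    labels: list[int] = []
    for cls in (0, 1):
        n_dom = round(config.n_per_class * (1 - config.noise_fraction))
        n_noise = config.n_per_class - n_dom
        if n_noise > 0 and not noise_pool:
            raise ConfigurationError(
                "noise_fraction > 0 but the network has no non-dominant path"
            )
        share = np.full(config.dominant_paths_per_class,
                        n_dom // config.dominant_paths_per_class)
        share[: n_dom % config.dominant_paths_per_class] += 1
        for path, k in zip(dominant[cls], share):
            rows.extend([path] * int(k))
        for i in rng.integers(len(noise_pool), size=n_noise) if n_noise else []:
            rows.append(noise_pool[i])
        labels.extend([cls] * config.n_per_class)

    X = np.array(rows, dtype=np.int8)
    y = np.array(labels, dtype=np.int8)
    perm = rng.permutation(len(y))
    dataset = PathwayDataset(X=X[perm], y=y[perm], network=network)
    return SimulationResult(network=network, dataset=dataset,
                            dominant_paths=dominant, config=config)
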