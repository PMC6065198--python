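"""Generators for inputs with the statistical structure each stage assumes.

Every analysis stage of the toolkit can be exercised without any download:

* :func:`simulate_wing_dataset` draws landmark data whose log-size variance
  decomposes into exactly the components the FA10 ANOVA estimates
  (individual, side, individual x side, measurement error);
* :func:`simulate_gene_universe` plants an exact overlap between two gene
  sets drawn from a common universe, for the hypergeometric test;
* :func:`simulate_scored_network` plants a connected high-scoring module in
  an Erdos-Renyi background, for the active-module search;
* :func:`simulate_qpcr_table` draws Cq values with a known fold change, for
  the Pfaffl quantification.

All generators take an explicit integer seed and are bit-reproducible; none
touches global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError
from .morphometry import LEFT, RIGHT, LandmarkRecord

# 15 wing-like landmarks (arbitrary length units, ~2-unit wing span):
# hinge at the origin, margin landmarks along the top and bottom, vein
# intersections in the blade.  Only the geometry's scale matters to the
# size traits; the layout keeps interlandmark distances realistic.
DEFAULT_MEAN_SHAPE: np.ndarray = np.array(
    [
        (0.00, 0.45), (0.25, 0.70), (0.60, 0.85), (1.05, 0.90),
        (1.50, 0.82), (1.85, 0.62), (2.00, 0.40), (1.82, 0.18),
        (1.45, 0.05), (1.00, 0.00), (0.55, 0.05), (0.22, 0.18),
        (0.70, 0.45), (1.15, 0.50), (1.55, 0.42),
    ],
    dtype=float,
)


@dataclass(frozen=True)
class WingSimParams:
    """Generative counterparts of the FA10 variance components.

    Size acts multiplicatively: wing (i, s) has true scale
    ``exp(ind_i + da*[s=right] + fa_is)`` applied to ``mean_shape``, so log
    centroid size inherits the additive variance structure.  Each session
    re-digitizes the wing with i.i.d. Gaussian coordinate noise of variance
    ``sigma2_me`` (length units squared).
    """

    n_individuals: int = 30
    n_sessions: int = 2
    sigma2_ind: float = 0.01     # individual log-size variance
    da: float = 0.005            # right-side log-size offset (directional asymmetry)
    sigma2_fa: float = 0.002     # per-wing log-size developmental noise
    sigma2_me: float = 0.0025    # per-coordinate digitization error variance
    seed: int = 0
    mean_shape: np.ndarray = field(default_factory=lambda: DEFAULT_MEAN_SHAPE.copy())
    genotype: str = "sim"

    def __post_init__(self) -> None:
        for name in ("sigma2_ind", "sigma2_fa", "sigma2_me"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.n_individuals < 2:
            raise ParameterError("n_individuals must be >= 2")
        if self.n_sessions < 1:
            raise ParameterError("n_sessions must be >= 1")
        shape = np.asarray(self.mean_shape, dtype=float)
        if shape.ndim != 2 or shape.shape[1] != 2 or shape.shape[0] < 3:
            raise ParameterError("mean_shape must be (k>=3, 2)")
        # collinearity check via the rank of the centred configuration
        if np.linalg.matrix_rank(shape - shape.mean(axis=0), tol=1e-12) < 2:
            raise ParameterError("mean_shape points must not be collinear")
        object.__setattr__(self, "mean_shape", shape)


def _simulate_coords(params: WingSimParams, rng: np.random.Generator) -> np.ndarray:
    """Coordinate array of shape (n, 2 sides, M, k, 2); side 0 = left."""
    n, m = params.n_individuals, params.n_sessions
    k = params.mean_shape.shape[0]
    ind = rng.normal(0.0, np.sqrt(params.sigma2_ind), size=n)
    fa = rng.normal(0.0, np.sqrt(params.sigma2_fa), size=(n, 2))
    log_scale = ind[:, None] + fa + params.da * np.array([0.0, 1.0])
    true = np.exp(log_scale)[:, :, None, None, None] * params.mean_shape
    noise = rng.normal(
        0.0, np.sqrt(params.sigma2_me), size=(n, 2, m, k, 2)
    )
    return np.broadcast_to(true, (n, 2, m, k, 2)) + noise


def simulate_wing_dataset(params: WingSimParams) -> list[LandmarkRecord]:
    """Draw a balanced landmark dataset: n individuals x 2 sides x M sessions."""
    rng = np.random.default_rng(params.seed)
    coords = _simulate_coords(params, rng)
    records = []
    for i in range(params.n_individuals):
        for s, side in enumerate((LEFT, RIGHT)):
            for sess in range(params.n_sessions):
                records.append(
                    LandmarkRecord(
                        individual_id=f"ind{i + 1:04d}",
                        genotype=params.genotype,
                        side=side,
                        session=sess + 1,
                        landmarks=coords[i, s, sess].copy(),
                    )
                )
    return records


def simulate_log_centroid_sizes(params: WingSimParams) -> np.ndarray:
    """Log centroid sizes, shape (n, 2 sides, M).

    Fast path for Monte-Carlo studies; bit-identical to computing
    log centroid size on :func:`simulate_wing_dataset` with the same seed.
    """
    rng = np.random.default_rng(params.seed)
    coords = _simulate_coords(params, rng)
    centred = coords - coords.mean(axis=3, keepdims=True)
    cs = np.sqrt((centred ** 2).sum(axis=(3, 4)))
    return np.log(cs)


def simulate_gene_universe(
    N: int, K: int, n: int, planted_overlap: int, seed: int = 0
) -> tuple[list[str], set[str], set[str]]:
    """Universe of N gene ids plus sets A (|A|=K) and B (|B|=n) with
    ``|A & B|`` exactly ``planted_overlap``."""
    if not (0 <= planted_overlap <= min(K, n) <= N):
        raise ParameterError(
            f"need planted_overlap <= min(K, n) <= N, got "
            f"N={N}, K={K}, n={n}, overlap={planted_overlap}"
        )
    if K + n - planted_overlap > N:
        raise ParameterError("K + n - planted_overlap exceeds the universe")
    rng = np.random.default_rng(seed)
    universe = [f"gene{i + 1:05d}" for i in range(N)]
    order = rng.permutation(N)
    shared = [universe[i] for i in order[:planted_overlap]]
    a_only = [universe[i] for i in order[planted_overlap:K]]
    b_only = [
        universe[i] for i in order[K:K + (n - planted_overlap)]
    ]
    return universe, set(shared) | set(a_only), set(shared) | set(b_only)


@dataclass(frozen=True)
class NetworkSimParams:
    """Erdos-Renyi background with a connected planted module.

    Planted nodes get z-scores ~ N(planted_z_mean, 1), background nodes
    ~ N(0, 1); p-values derive from z through the inverse of the scoring
    transform (p = 1 - Phi(z)), so the module search sees exactly the
    significance structure it assumes.
    """

    n_nodes: int = 200
    edge_prob: float = 0.005
    planted_module_size: int = 15
    planted_z_mean: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.edge_prob <= 1:
            raise ParameterError("edge_prob must be in (0, 1]")
        if not 0 <= self.planted_module_size <= self.n_nodes:
            raise ParameterError("planted_module_size must be <= n_nodes")
        if self.n_nodes < 1:
            raise ParameterError("n_nodes must be >= 1")


def simulate_scored_network(
    params: NetworkSimParams,
) -> tuple[nx.Graph, pd.DataFrame, list[str]]:
    """Return (graph, node-score table, planted node ids).

    The planted module is made connected by construction: a random spanning
    tree over the planted nodes is added on top of the background
    Erdos-Renyi edges.  The score table has columns node, p_value, z.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(params.seed)
    n = params.n_nodes
    names = [f"g{i + 1:04d}" for i in range(n)]
    g = nx.gnp_random_graph(
        n, params.edge_prob, seed=int(rng.integers(2 ** 31))
    )
    g = nx.relabel_nodes(g, dict(enumerate(names)))

    planted_idx = rng.choice(n, size=params.planted_module_size, replace=False)
    planted = [names[i] for i in sorted(planted_idx)]
    # random spanning tree: connect each planted node to a random earlier one
    shuffled = list(planted)
    rng.shuffle(shuffled)
    for pos in range(1, len(shuffled)):
        anchor = shuffled[rng.integers(pos)]
        g.add_edge(shuffled[pos], anchor)

    z = rng.normal(0.0, 1.0, size=n)
    z[sorted(planted_idx)] += params.planted_z_mean
    p = norm.sf(z)
    scores = pd.DataFrame({"node": names, "p_value": p, "z": z})
    return g, scores, planted


def simulate_qpcr_table(
    fold_change: float = 2.0,
    target: str = "CycG",
    references: Sequence[str] = ("Lam", "rin"),
    n_bio: int = 2,
    n_tech: int = 3,
    efficiency: float = 2.0,
    cq_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cq and efficiency tables for a known treated-vs-control fold change.

    The target's treated Cq is shifted by -log_E(fold_change) relative to
    control; reference genes do not shift.  Returns (cq_table, efficiency
    table) in the CSV schemas consumed by the qPCR module.
    """
    if fold_change <= 0:
        raise ParameterError("fold_change must be positive")
    rng = np.random.default_rng(seed)
    genes = [target, *references]
    base_cq = {g: 20.0 + 2.0 * i for i, g in enumerate(genes)}
    rows = []
    for gene in genes:
        for condition in ("control", "treated"):
            shift = 0.0
            if gene == target and condition == "treated":
                shift = -np.log(fold_change) / np.log(efficiency)
            for b in range(1, n_bio + 1):
                bio_offset = rng.normal(0.0, cq_sd)
                for t in range(1, n_tech + 1):
                    rows.append(
                        {
                            "gene": gene,
                            "condition": condition,
                            "bio_rep": b,
                            "tech_rep": t,
                            "Cq": base_cq[gene] + shift + bio_offset
                            + rng.normal(0.0, cq_sd / 2),
                        }
                    )
    eff = pd.DataFrame({"gene": genes, "E": [efficiency] * len(genes)})
    return pd.DataFrame(rows), eff
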