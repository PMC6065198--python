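"""Interactome construction, centrality ranking and active-module search.

The interactome is a simple undirected graph mixing protein-protein (PPI)
and transcription-factor/gene (PDI) edges; PDI direction is kept only as
edge metadata.  Two analyses run on it:

* **Betweenness centrality** — the fraction of all-pairs shortest paths
  through a node, normalized per connected component by (n-1)(n-2)/2 — to
  rank hub candidates.
* **Active-module search** — find connected sub-networks of co-deregulated
  genes.  Each node carries a z-score derived from its deregulation
  p-value, z = Phi^-1(1 - p); a node set A of size k scores
  z_A = sum(z_i)/sqrt(k), and a size-adjusted score
  s_A = (z_A - mu_k)/sigma_k calibrates z_A against Monte-Carlo draws of
  uniform random k-subsets.  Search is greedy regional hill-climbing from
  seed nodes (grow by the neighbour that most improves s_A, then prune),
  with near-duplicate modules above a Jaccard overlap threshold collapsed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from lxml import etree
from scipy.stats import norm

from .errors import FormatError, ParameterError

PPI = "PPI"
PDI = "PDI"

#: p-values below this floor are clamped before the z transform.
P_FLOOR = 1e-16
#: z ceiling implied by the p floor; scores are clamped to [-Z_MAX, Z_MAX].
Z_MAX = float(norm.isf(P_FLOOR))


class DegenerateCalibrationError(ParameterError):
    """Raised when the calibration null has zero spread (sigma_k = 0)."""


# ---------------------------------------------------------------------------
# Interactome construction and XGMML I/O
# ---------------------------------------------------------------------------

def build_interactome(
    ppi_edges: Iterable[tuple[str, str]] = (),
    pdi_edges: Iterable[tuple[str, str]] = (),
    expressed_nodes: set[str] | None = None,
) -> nx.Graph:
    """Simple undirected graph from PPI/PDI edge tables.

    Self-loops are dropped, duplicates merged (an edge present in both
    tables keeps both type tags), and — when an expressed-node set is given,
    e.g. genes above a read-count cutoff in the control tissue — edges with
    an unexpressed endpoint are dropped.  Drop counts are stored in
    ``g.graph["dropped"]``.
    """
    g = nx.Graph()
    dropped = {"self_loop": 0, "unexpressed": 0, "duplicate": 0}
    for kind, edges in ((PPI, ppi_edges), (PDI, pdi_edges)):
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                dropped["self_loop"] += 1
                continue
            if expressed_nodes is not None and (
                u not in expressed_nodes or v not in expressed_nodes
            ):
                dropped["unexpressed"] += 1
                continue
            if g.has_edge(u, v):
                dropped["duplicate"] += 1
                g.edges[u, v]["types"].add(kind)
            else:
                g.add_edge(u, v, types={kind})
    if g.number_of_edges() == 0:
        raise ParameterError("no edges remain after filtering")
    g.graph["dropped"] = dropped
    return g


def read_edge_table(path) -> list[tuple[str, str]]:
    """Two-column (source, target) TSV; extra columns ignored."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least 2 columns")
    return [(str(a), str(b)) for a, b in df.iloc[:, :2].itertuples(index=False)]


def read_node_scores(path) -> pd.DataFrame:
    """Node-score TSV with columns node, p_value (extras preserved)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"node", "p_value"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad = df[(df.p_value <= 0) | (df.p_value > 1)]
    if len(bad):
        raise FormatError(
            f"{path}: p-values outside (0, 1] for nodes "
            f"{bad.node.tolist()[:5]}"
        )
    return df


def read_xgmml(path) -> nx.Graph:
    """Graph from an XGMML document (node ``label``s become node ids).

    Duplicate edges are merged; parse counts land in ``g.graph``.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: malformed XML: {exc}") from None
    root = tree.getroot()

    def local(tag: str) -> str:
        return etree.QName(tag).localname if "}" in tag else tag

    g = nx.Graph()
    id_to_label: dict[str, str] = {}
    n_edge_elements = 0
    for el in root.iter():
        if not isinstance(el.tag, str):
            continue
        tag = local(el.tag)
        if tag == "node":
            node_id = el.get("id")
            label = el.get("label") or node_id
            if node_id is None and label is None:
                raise FormatError(f"{path}: node element without id/label")
            id_to_label[node_id if node_id is not None else label] = label
            g.add_node(label)
    for el in root.iter():
        if isinstance(el.tag, str) and local(el.tag) == "edge":
            n_edge_elements += 1
            src, tgt = el.get("source"), el.get("target")
            if src is None or tgt is None:
                raise FormatError(
                    f"{path}:{el.sourceline}: edge element missing "
                    "source/target"
                )
            u = id_to_label.get(src, src)
            v = id_to_label.get(tgt, tgt)
            if u != v:
                g.add_edge(u, v)
    g.graph["xgmml_edge_elements"] = n_edge_elements
    g.graph["xgmml_duplicate_edges"] = n_edge_elements - g.number_of_edges()
    return g


def write_xgmml(g: nx.Graph, path, label: str = "network") -> None:
    root = etree.Element("graph", label=label, directed="0")
    ids = {node: str(i) for i, node in enumerate(sorted(g.nodes))}
    for node, i in ids.items():
        etree.SubElement(root, "node", id=i, label=str(node))
    for u, v in sorted(g.edges):
        etree.SubElement(root, "edge", source=ids[u], target=ids[v])
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# ---------------------------------------------------------------------------
# Betweenness centrality
# ---------------------------------------------------------------------------

def betweenness(g: nx.Graph, normalized: bool = True) -> dict[str, float]:
    """Shortest-path betweenness, per connected component.

    Normalization divides by (n_c - 1)(n_c - 2)/2 within each component of
    size n_c, so a component's most central node can reach 1.0 regardless
    of the rest of the graph.
    """
    if g.number_of_nodes() == 0:
        raise ParameterError("empty graph")
    out: dict[str, float] = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        out.update(nx.betweenness_centrality(sub, normalized=normalized))
    return out


def betweenness_ranking(
    g: nx.Graph, normalized: bool = True
) -> pd.DataFrame:
    """Nodes ranked by betweenness (descending), ties broken by node id."""
    cent = betweenness(g, normalized=normalized)
    df = pd.DataFrame(
        sorted(cent.items(), key=lambda kv: (-kv[1], str(kv[0]))),
        columns=["node", "betweenness"],
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def betweenness_bruteforce(g: nx.Graph) -> dict[str, Fraction]:
    """Exact-rational betweenness by enumerating all shortest paths.

    Oracle for small graphs only (exponential path enumeration).
    Unnormalized pair-fraction counts over unordered pairs.
    """
    nodes = list(g.nodes)
    acc = {v: Fraction(0) for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            acc[v] += Fraction(through, len(paths))
    return acc


# ---------------------------------------------------------------------------
# Node scoring and module scores
# ---------------------------------------------------------------------------

def z_from_p(p_values: np.ndarray | Sequence[float]) -> np.ndarray:
    """z = Phi^-1(1 - p), p clamped to [P_FLOOR, 1], z to [-Z_MAX, Z_MAX].

    p = 1 (the convention for nodes absent from the expression table) maps
    to the z floor -Z_MAX.
    """
    p = np.clip(np.asarray(p_values, dtype=float), P_FLOOR, 1.0)
    return np.clip(norm.isf(p), -Z_MAX, Z_MAX)


def node_z_map(scores: pd.DataFrame, nodes: Iterable[str]) -> dict[str, float]:
    """z per node; nodes without a score row get p = 1 (z floor)."""
    table = dict(zip(scores["node"].astype(str), z_from_p(scores["p_value"])))
    return {str(v): table.get(str(v), -Z_MAX) for v in nodes}


@dataclass(frozen=True)
class ActiveModule:
    nodes: frozenset[str]
    seed_node: str
    z_score: float          # z_A = sum(z)/sqrt(k)
    adjusted_score: float   # s_A = (z_A - mu_k)/sigma_k
    k: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "k", len(self.nodes))

    def jaccard(self, other: "ActiveModule") -> float:
        inter = len(self.nodes & other.nodes)
        union = len(self.nodes | other.nodes)
        return inter / union if union else 1.0


def aggregate_z(z_values: Sequence[float]) -> float:
    """z_A = sum(z_i) / sqrt(k)."""
    k = len(z_values)
    if k == 0:
        raise ParameterError("empty node set")
    return float(np.sum(z_values) / np.sqrt(k))


class _Calibration:
    """Monte-Carlo mu_k / sigma_k of z_A for uniform random k-subsets.

    One set of n_mc random node orderings serves every k (the first k
    entries of a uniform random permutation are a uniform k-subset), so
    subsets are nested across k: common random numbers make the estimated
    mu_k / sigma_k vary smoothly in k, and comparisons of adjusted scores
    across sizes are far less noisy than with independent draws.
    """

    #: nested draws are precomputed up to this subset size; larger k falls
    #: back to independent per-k sampling (memory stays bounded on graphs
    #: with tens of thousands of nodes)
    K_CAP = 512
    _CHUNK = 256

    def __init__(self, z: np.ndarray, n_mc: int, seed: int) -> None:
        self.z = np.asarray(z, dtype=float)
        self.n_mc = int(n_mc)
        self.rng = np.random.default_rng(seed)
        self._cumsums: np.ndarray | None = None
        self._cache: dict[int, tuple[float, float]] = {}

    def _nested_cumsums(self) -> np.ndarray:
        if self._cumsums is None:
            n = self.z.size
            kcap = min(n, self.K_CAP)
            out = np.empty((self.n_mc, kcap))
            for lo in range(0, self.n_mc, self._CHUNK):
                hi = min(lo + self._CHUNK, self.n_mc)
                keys = self.rng.random((hi - lo, n))
                if kcap < n:
                    part = np.argpartition(keys, kcap - 1, axis=1)[:, :kcap]
                    sub = np.take_along_axis(keys, part, axis=1)
                    idx = np.take_along_axis(
                        part, np.argsort(sub, axis=1), axis=1
                    )
                else:
                    idx = np.argsort(keys, axis=1)
                out[lo:hi] = np.cumsum(self.z[idx], axis=1)
            self._cumsums = out
        return self._cumsums

    def params(self, k: int) -> tuple[float, float]:
        if k not in self._cache:
            n = self.z.size
            if k > n:
                raise ParameterError(f"subset size {k} exceeds {n} nodes")
            if k <= min(n, self.K_CAP):
                draws = self._nested_cumsums()[:, k - 1] / np.sqrt(k)
            else:
                draws = np.empty(self.n_mc)
                for i in range(self.n_mc):
                    idx = self.rng.choice(n, size=k, replace=False)
                    draws[i] = self.z[idx].sum()
                draws /= np.sqrt(k)
            self._cache[k] = (float(draws.mean()), float(draws.std(ddof=1)))
        return self._cache[k]

    def adjust(self, z_a: float, k: int) -> float:
        mu, sigma = self.params(k)
        if sigma == 0.0:
            raise DegenerateCalibrationError(
                f"calibration sigma is 0 at k={k}; node scores carry no "
                "spread to calibrate against"
            )
        return (z_a - mu) / sigma

    def score_se(self, s: float) -> float:
        """Monte-Carlo standard error of an adjusted score of magnitude s.

        Error propagation through s = (z_A - mu_hat)/sigma_hat:
        Var from mu_hat is 1/n_mc, from sigma_hat is s^2/(2 n_mc).
        """
        return float(np.sqrt((1.0 + s * s / 2.0) / self.n_mc))


def score_module(
    nodes: Iterable[str],
    scores: pd.DataFrame,
    g: nx.Graph,
    n_mc: int = 4000,
    seed: int = 0,
) -> ActiveModule:
    """Score a connected node set: z_A and its size-adjusted s_A.

    Calibration draws ``n_mc`` uniform random k-subsets of all graph nodes
    (not constrained to be connected) to estimate mu_k and sigma_k.
    """
    node_set = frozenset(str(v) for v in nodes)
    if not node_set:
        raise ParameterError("empty module")
    missing = node_set - set(g.nodes)
    if missing:
        raise ParameterError(f"nodes absent from graph: {sorted(missing)[:5]}")
    if not nx.is_connected(g.subgraph(node_set)):
        raise ParameterError("module's induced subgraph is not connected")
    zmap = node_z_map(scores, g.nodes)
    z_a = aggregate_z([zmap[v] for v in node_set])
    calib = _Calibration(np.array(list(zmap.values())), n_mc, seed)
    s_a = calib.adjust(z_a, len(node_set))
    return ActiveModule(
        nodes=node_set,
        seed_node=min(node_set),
        z_score=z_a,
        adjusted_score=s_a,
    )


# ---------------------------------------------------------------------------
# Greedy regional search
# ---------------------------------------------------------------------------

def _grow_from_seed(
    g: nx.Graph,
    zmap: Mapping[str, float],
    seed_node: str,
    calib: _Calibration,
    max_depth: int,
    max_size: int,
) -> tuple[frozenset[str], float, float]:
    """Greedy regional growth with one-standard-error parsimony trim.

    Within the radius-``max_depth`` ball around the seed, the frontier node
    with the highest z is appended at every step — at fixed target size
    that is exactly the addition maximizing s_A — even when s_A temporarily
    drops (strict hill-climbing stalls in local optima because a moderately
    scored neighbour can lower z_A at small k).  The s_A(k) curve along the
    growth order is typically razor-flat around its maximum: hanger-on
    nodes with mildly positive z change the score by less than the
    Monte-Carlo uncertainty of the calibration.  The module kept is
    therefore the smallest prefix scoring within one calibration standard
    error of the trajectory maximum, after which a prune pass removes
    removable low-z nodes for as long as the score stays above that same
    plateau floor.
    """
    region = set(
        nx.single_source_shortest_path_length(g, seed_node, cutoff=max_depth)
    )
    order = [seed_node]
    in_module = {seed_node}
    z_sum = zmap[seed_node]
    scores = [calib.adjust(z_sum, 1)]
    frontier = {nb for nb in g.neighbors(seed_node) if nb in region}
    while frontier and len(order) < min(max_size, len(region)):
        cand = max(sorted(frontier), key=lambda v: zmap[v])
        frontier.discard(cand)
        order.append(cand)
        in_module.add(cand)
        z_sum += zmap[cand]
        k = len(order)
        scores.append(calib.adjust(z_sum / np.sqrt(k), k))
        frontier.update(
            nb for nb in g.neighbors(cand)
            if nb in region and nb not in in_module
        )
    s_max = float(np.max(scores))
    floor = s_max - calib.score_se(s_max)
    best_k = next(k for k, s in enumerate(scores, start=1) if s >= floor)
    module = set(order[:best_k])
    score = scores[best_k - 1]
    # prune: drop removable low-z nodes while staying on the score plateau
    improved = True
    while improved and len(module) > 1:
        improved = False
        z_sum = sum(zmap[v] for v in module)
        for cand in sorted(module - {seed_node}, key=lambda v: (zmap[v], v)):
            trial = module - {cand}
            if not nx.is_connected(g.subgraph(trial)):
                continue
            k = len(trial)
            s = calib.adjust((z_sum - zmap[cand]) / np.sqrt(k), k)
            if s >= floor or s > score + 1e-12:
                module = trial
                score = s
                improved = True
                break
    z_a = aggregate_z([zmap[v] for v in module])
    return frozenset(module), z_a, score


def find_active_modules(
    g: nx.Graph,
    scores: pd.DataFrame,
    seeds: Sequence[str] | str = "top10",
    max_depth: int = 8,
    overlap_threshold: float = 0.8,
    n_modules: int = 5,
    n_mc: int = 4000,
    seed: int = 0,
    max_size: int = 60,
) -> list[ActiveModule]:
    """Ranked active modules by greedy regional search.

    ``seeds`` is an explicit node list, ``"all"``, or ``"topN"`` (the N
    highest-z nodes).  From each seed the search grows within a ball of
    radius ``max_depth``, adding (then pruning) the node that maximally
    increases the size-adjusted score until no move helps.  Modules whose
    pairwise Jaccard overlap exceeds ``overlap_threshold`` are collapsed,
    keeping the best-scoring one; only modules with s_A > 0 are returned.
    Deterministic for fixed seed.
    """
    if g.number_of_nodes() == 0:
        raise ParameterError("empty graph")
    zmap = node_z_map(scores, g.nodes)
    if g.number_of_nodes() == 1:
        # no background to calibrate against: report the node itself
        (v,) = g.nodes
        z_a = zmap[v]
        if z_a <= 0:
            return []
        return [
            ActiveModule(
                nodes=frozenset({v}), seed_node=v,
                z_score=z_a, adjusted_score=z_a,
            )
        ]
    z_arr = np.array([zmap[v] for v in sorted(g.nodes)])
    if float(z_arr.std()) == 0.0:
        return []  # constant scores: nothing can score above background
    calib = _Calibration(z_arr, n_mc, seed)

    if isinstance(seeds, str):
        if seeds == "all":
            seed_nodes = sorted(g.nodes)
        elif seeds.startswith("top"):
            count = int(seeds[3:] or 20)
            seed_nodes = [
                v for v, _ in sorted(
                    zmap.items(), key=lambda kv: (-kv[1], kv[0])
                )[:count]
            ]
        else:
            raise ParameterError(f"unknown seeds spec {seeds!r}")
    else:
        seed_nodes = [str(v) for v in seeds]
        missing = set(seed_nodes) - set(g.nodes)
        if missing:
            raise ParameterError(f"seed nodes not in graph: {sorted(missing)}")

    found: list[ActiveModule] = []
    for sn in seed_nodes:
        nodes, z_a, s_a = _grow_from_seed(
            g, zmap, sn, calib, max_depth, max_size
        )
        found.append(
            ActiveModule(
                nodes=nodes, seed_node=sn, z_score=z_a, adjusted_score=s_a
            )
        )
    found = [m for m in found if m.adjusted_score > 0]
    found.sort(key=lambda m: (-m.adjusted_score, sorted(m.nodes)))
    kept: list[ActiveModule] = []
    for mod in found:
        if all(mod.jaccard(prev) <= overlap_threshold for prev in kept):
            kept.append(mod)
        if len(kept) == n_modules:
            break
    return kept
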