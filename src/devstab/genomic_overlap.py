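"""Genomic association statistics.

Four questions recur when relating a ChIP peak set to other genomic
annotations:

* Is the overlap between two **gene sets** larger than random sampling from
  the annotated genome would produce?  Under the null the overlap count
  follows a hypergeometric law X ~ HY(K, N, n); significance is the upper
  tail P(X >= k) (:func:`gene_overlap_test`).
* Is the **base-pair overlap** between two interval sets larger (or
  smaller) than expected when the query segments are placed at random in
  the mappable genome?  A GAT-style randomization answers with an empirical
  two-tailed p (:func:`interval_randomization`).
* Which genes does a peak set **bind**?  A gene is bound iff its span
  intersects at least one peak, half-open semantics
  (:func:`assign_peaks_to_genes`).
* Where does the signal sit?  Peaks ranked by height into deciles and
  annotated by feature type (:func:`rank_peaks_deciles`), and metagene
  aggregation profiles over scaled gene bodies with flanks
  (:func:`aggregation_profile`).

All intervals are 0-based half-open (BED convention) internally; GFF input
(1-based closed) is converted at the reading boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import FormatError, ParameterError

TSS_FEATURE = "TSS"
BODY_FEATURE = "gene_body"
INTERGENIC_FEATURE = "intergenic"
DEFAULT_TSS_WINDOW = 500  # bp either side of the TSS

# Relative tolerance of the uniform-signal exclusion rule: a gene is
# dropped when the summed absolute successive differences of its body
# signal do not exceed this fraction of its mean signal.
UNIFORM_SIGNAL_RTOL = 1e-9


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic segment, optionally scored by peak height."""

    chrom: str
    start: int
    end: int
    height: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ParameterError(
                f"need 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """Gene span with strand-aware TSS (0-based half-open span)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ParameterError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ParameterError(
                f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class OverlapTest:
    N: int
    K: int
    n: int
    k: int
    p_value: float


@dataclass(frozen=True)
class RandomizationResult:
    observed_bp: float
    expected_bp: float
    fold: float
    p_two_tailed: float
    n_samples: int
    seed: int
    null_sd: float


# ---------------------------------------------------------------------------
# Interval / gene I/O
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """BED3+ reader; column 4 is kept as the name, column 5 as the height."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{line_no}: fewer than 3 BED columns")
            try:
                iv = GenomicInterval(
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    name=parts[3] if len(parts) > 3 else None,
                    height=float(parts[4]) if len(parts) > 4 else None,
                )
            except (ValueError, ParameterError) as exc:
                raise FormatError(f"{path}:{line_no}: {exc}") from None
            out.append(iv)
    return out


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda v: (v.chrom, v.start, v.end)):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.height is not None:
                cols.append(iv.name or ".")
            if iv.height is not None:
                cols.append(f"{iv.height:g}")
            fh.write("\t".join(cols) + "\n")


def read_gene_models(path) -> list[GeneModel]:
    """Gene models from 6-column TSV (gene_id, chrom, start, end, strand,
    optional biotype; 0-based half-open) or GFF3 ``gene`` features
    (1-based closed, converted here)."""
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("##gff") or head.count("\t") == 8:
        return _read_gff3_genes(path)
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"gene TSV missing columns {sorted(missing)}")
    return [
        GeneModel(
            gene_id=str(r.gene_id), chrom=str(r.chrom),
            start=int(r.start), end=int(r.end), strand=str(r.strand),
            biotype=str(r.biotype) if "biotype" in df.columns else None,
        )
        for r in df.itertuples(index=False)
    ]


def _read_gff3_genes(path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{line_no}: expected 9 GFF columns")
            if parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("gene_id") or f"gene_l{line_no}"
            genes.append(
                GeneModel(
                    gene_id=gene_id, chrom=parts[0],
                    start=int(parts[3]) - 1,  # GFF is 1-based closed
                    end=int(parts[4]),
                    strand=parts[6],
                )
            )
    return genes


# ---------------------------------------------------------------------------
# Hypergeometric gene-set overlap
# ---------------------------------------------------------------------------

def gene_overlap_test(N: int, K: int, n: int, k: int) -> OverlapTest:
    """Upper-tail hypergeometric overlap test, P(X >= k), X ~ HY(K, N, n).

    N: universe size (all annotated genes); K: genes in set A (e.g. bound
    genes); n: genes in set B (e.g. deregulated genes); k: observed overlap.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ParameterError(f"{name} must be a non-negative integer")
    if not (k <= min(K, n) <= N and K <= N and n <= N):
        raise ParameterError(
            f"inconsistent counts: need k <= min(K, n) <= N, got "
            f"N={N}, K={K}, n={n}, k={k}"
        )
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapTest(N=N, K=K, n=n, k=k, p_value=min(p, 1.0))


def gene_set_overlap_test(
    universe: Iterable[str], set_a: Iterable[str], set_b: Iterable[str]
) -> OverlapTest:
    """Convenience wrapper: counts taken from explicit gene-id sets."""
    uni = set(universe)
    a, b = set(set_a) & uni, set(set_b) & uni
    return gene_overlap_test(len(uni), len(a), len(b), len(a & b))


# ---------------------------------------------------------------------------
# Interval-randomization overlap (GAT-style, simplified)
# ---------------------------------------------------------------------------

def _merge(intervals: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    """Merge overlapping intervals; {chrom: array (m, 2) of [start, end)}."""
    by_chrom: dict[str, list[list[int]]] = {}
    for iv in sorted(intervals, key=lambda v: (v.chrom, v.start, v.end)):
        segs = by_chrom.setdefault(iv.chrom, [])
        if segs and iv.start <= segs[-1][1]:
            segs[-1][1] = max(segs[-1][1], iv.end)
        else:
            segs.append([iv.start, iv.end])
    return {c: np.array(s, dtype=np.int64) for c, s in by_chrom.items()}


def total_bp(intervals: Sequence[GenomicInterval]) -> int:
    return int(sum((segs[:, 1] - segs[:, 0]).sum() for segs in _merge(intervals).values()))


class _CoverageIndex:
    """Cumulative-coverage lookup over merged intervals of one chromosome."""

    def __init__(self, segs: np.ndarray) -> None:
        self.starts = segs[:, 0]
        self.ends = segs[:, 1]
        self.cum = np.concatenate([[0], np.cumsum(self.ends - self.starts)])

    def coverage_before(self, pos: np.ndarray) -> np.ndarray:
        """Covered bp in [0, pos) for each position (vectorized)."""
        i = np.searchsorted(self.starts, pos, side="right") - 1
        base = self.cum[np.maximum(i + 1, 0)]
        inside = np.clip(
            pos - np.where(i >= 0, self.ends[np.maximum(i, 0)], 0), None, 0
        )
        # base counts segments fully left of pos plus the one containing it;
        # subtract the part of the containing segment to the right of pos.
        return base + np.where(i >= 0, inside, 0)

    def overlap(self, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        return self.coverage_before(end) - self.coverage_before(start)


def _overlap_bp(
    segments: Mapping[str, np.ndarray], annotation: Mapping[str, np.ndarray]
) -> int:
    total = 0
    for chrom, segs in segments.items():
        if chrom not in annotation:
            continue
        idx = _CoverageIndex(annotation[chrom])
        total += int(idx.overlap(segs[:, 0], segs[:, 1]).sum())
    return total


def _clip_to_workspace(
    intervals: Sequence[GenomicInterval],
    workspace: Mapping[str, np.ndarray],
    label: str,
) -> list[GenomicInterval]:
    clipped: list[GenomicInterval] = []
    trimmed = 0
    for iv in intervals:
        segs = workspace.get(iv.chrom)
        if segs is None:
            trimmed += 1
            continue
        lo = np.maximum(segs[:, 0], iv.start)
        hi = np.minimum(segs[:, 1], iv.end)
        pieces = [(int(a), int(b)) for a, b in zip(lo, hi) if a < b]
        if [(iv.start, iv.end)] != pieces:
            trimmed += 1
        clipped.extend(
            replace(iv, start=a, end=b) for a, b in pieces
        )
    if trimmed:
        warnings.warn(
            f"{trimmed} {label} interval(s) extended outside the workspace "
            "and were clipped",
            stacklevel=3,
        )
    return clipped


def interval_randomization(
    query: Sequence[GenomicInterval],
    annotation: Sequence[GenomicInterval],
    workspace: Sequence[GenomicInterval],
    n_samples: int = 10_000,
    seed: int = 0,
) -> RandomizationResult:
    """Empirical significance of query/annotation base-pair overlap.

    Null model: each query segment is independently re-placed uniformly over
    all integer start positions at which it fits wholly inside one workspace
    (mappable-genome) segment, preserving its length.  Two-tailed p uses the
    add-one rule 2 * min((r+1)/(m+1) over both tails), capped at 1.
    """
    if n_samples < 100:
        raise ParameterError("n_samples must be >= 100")
    ws = _merge(workspace)
    if not ws:
        raise ParameterError("empty workspace")
    if not annotation:
        raise ParameterError("empty annotation: fold is undefined")
    query = _clip_to_workspace(query, ws, "query")
    annotation = _clip_to_workspace(annotation, ws, "annotation")
    ann = _merge(annotation)
    qsegs = _merge(query)
    observed = _overlap_bp(qsegs, ann)

    # flatten workspace segments; each query length gets its own
    # fit-weighted segment distribution
    ws_chroms, ws_bounds = [], []
    for chrom, segs in ws.items():
        for a, b in segs:
            ws_chroms.append(chrom)
            ws_bounds.append((int(a), int(b)))
    ws_len = np.array([b - a for a, b in ws_bounds], dtype=np.int64)
    ann_idx = {c: _CoverageIndex(s) for c, s in ann.items()}

    rng = np.random.default_rng(seed)
    lengths = [int(iv.end - iv.start) for iv in query]
    null = np.zeros(n_samples, dtype=np.int64)
    for L in lengths:
        counts = np.maximum(ws_len - L + 1, 0)
        if counts.sum() == 0:
            raise ParameterError(
                f"query segment of length {L} fits in no workspace segment"
            )
        seg_choice = rng.choice(
            len(ws_bounds), size=n_samples, p=counts / counts.sum()
        )
        offset = rng.integers(0, counts[seg_choice])  # high exclusive
        starts = np.array([ws_bounds[s][0] for s in seg_choice]) + offset
        ends = starts + L
        for chrom in set(ws_chroms):
            mask = np.array([ws_chroms[s] == chrom for s in seg_choice])
            if not mask.any():
                continue
            idx = ann_idx.get(chrom)
            if idx is not None:
                null[mask] += idx.overlap(starts[mask], ends[mask])

    expected = float(null.mean())
    greater = (int((null >= observed).sum()) + 1) / (n_samples + 1)
    less = (int((null <= observed).sum()) + 1) / (n_samples + 1)
    return RandomizationResult(
        observed_bp=float(observed),
        expected_bp=expected,
        fold=observed / expected if expected > 0 else float("inf"),
        p_two_tailed=min(1.0, 2.0 * min(greater, less)),
        n_samples=n_samples,
        seed=seed,
        null_sd=float(null.std(ddof=1)),
    )


# ---------------------------------------------------------------------------
# Peak -> gene assignment
# ---------------------------------------------------------------------------

def assign_peaks_to_genes(
    peaks: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> tuple[set[str], dict[str, list[str]]]:
    """Bound genes (span intersects >= 1 peak, half-open) and, per peak,
    the list of genes it overlaps.

    Peaks are keyed by name when present, else by ``chrom:start-end``.
    A disjoint chromosome naming between the two inputs triggers a warning.
    """
    peak_chroms = {p.chrom for p in peaks}
    gene_chroms = {g.chrom for g in genes}
    if peaks and genes and not (peak_chroms & gene_chroms):
        warnings.warn(
            f"no shared chromosome names: peaks use {sorted(peak_chroms)}, "
            f"genes use {sorted(gene_chroms)}",
            stacklevel=2,
        )
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
    bound: set[str] = set()
    per_peak: dict[str, list[str]] = {}
    for p in peaks:
        key = p.name or f"{p.chrom}:{p.start}-{p.end}"
        tree = trees.get(p.chrom)
        hits = sorted(h.data for h in tree.overlap(p.start, p.end)) if tree else []
        per_peak[key] = hits
        bound.update(hits)
    return bound, per_peak


# ---------------------------------------------------------------------------
# Decile ranking + feature annotation
# ---------------------------------------------------------------------------

def _largest_remainder_sizes(total: int, bins: int) -> list[int]:
    base, rem = divmod(total, bins)
    return [base + 1] * rem + [base] * (bins - rem)


def classify_peak(
    peak: GenomicInterval,
    genes: Sequence[GeneModel],
    tss_window: int = DEFAULT_TSS_WINDOW,
) -> str:
    """Feature type with precedence TSS window > gene body > intergenic."""
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        lo, hi = g.tss - tss_window, g.tss + tss_window + 1
        if peak.start < hi and lo < peak.end:
            return TSS_FEATURE
    for g in genes:
        if g.chrom == peak.chrom and peak.start < g.end and g.start < peak.end:
            return BODY_FEATURE
    return INTERGENIC_FEATURE


def rank_peaks_deciles(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel] = (),
    n_bins: int = 10,
    tss_window: int = DEFAULT_TSS_WINDOW,
) -> pd.DataFrame:
    """Rank peaks by height (descending) into near-equal deciles.

    Bin sizes follow largest-remainder allocation so they differ by at most
    one; ties in height break deterministically by (chrom, start, end).
    Each peak is annotated with its feature type when gene models are given.
    Decile 1 holds the tallest peaks.
    """
    if not peaks:
        raise ParameterError("no peaks to rank")
    if any(p.height is None for p in peaks):
        raise ParameterError("every peak needs a height for decile ranking")
    ordered = sorted(
        peaks, key=lambda p: (-p.height, p.chrom, p.start, p.end)
    )
    sizes = _largest_remainder_sizes(len(ordered), n_bins)
    deciles = np.repeat(np.arange(1, n_bins + 1), sizes)
    rows = []
    for rank, (p, d) in enumerate(zip(ordered, deciles), start=1):
        rows.append(
            {
                "chrom": p.chrom, "start": p.start, "end": p.end,
                "name": p.name or f"{p.chrom}:{p.start}-{p.end}",
                "height": p.height, "rank": rank, "decile": int(d),
                "feature": classify_peak(p, genes, tss_window) if genes else None,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Metagene aggregation profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AggregationProfile:
    positions: np.ndarray    # bin centres: flank (-bp), body (0..1), flank (+bp)
    mean: np.ndarray
    sem: np.ndarray
    n_genes: int
    excluded_genes: list[str]
    n_body_bins: int
    flank_bp: int
    n_flank_bins: int


def read_bedgraph(path) -> dict[str, np.ndarray]:
    """Per-base signal arrays from a bedGraph file (uncovered bases = 0)."""
    spans: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{line_no}: expected 4 bedGraph columns")
            spans.setdefault(parts[0], []).append(
                (int(parts[1]), int(parts[2]), float(parts[3]))
            )
    out: dict[str, np.ndarray] = {}
    for chrom, rows in spans.items():
        arr = np.zeros(max(e for _, e, _ in rows))
        for s, e, v in rows:
            arr[s:e] = v
        out[chrom] = arr
    return out


def _rebin(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean signal in n_bins near-equal contiguous chunks."""
    edges = np.linspace(0, values.size, n_bins + 1).round().astype(int)
    return np.array(
        [values[a:b].mean() if b > a else 0.0 for a, b in zip(edges, edges[1:])]
    )


def _gene_window(
    signal: Mapping[str, np.ndarray], gene: GeneModel, flank_bp: int
) -> np.ndarray:
    track = signal.get(gene.chrom)
    lo, hi = gene.start - flank_bp, gene.end + flank_bp
    window = np.zeros(hi - lo)
    if track is not None:
        a, b = max(lo, 0), min(hi, track.size)
        if b > a:
            window[a - lo:b - lo] = track[a:b]
    if gene.strand == "-":
        window = window[::-1]
    return window


def aggregation_profile(
    signal: Mapping[str, np.ndarray],
    genes: Sequence[GeneModel],
    flank_bp: int = 500,
    n_body_bins: int = 40,
    n_flank_bins: int = 10,
) -> AggregationProfile:
    """Mean +/- SEM signal over scaled gene bodies with fixed-bp flanks.

    Every gene body is rescaled to ``n_body_bins`` bins (minus-strand genes
    reversed so bins run TSS -> TES); each flank is split into
    ``n_flank_bins`` fixed-width bins.  Genes shorter than ``n_body_bins``
    bases are skipped with a warning; genes whose body signal is uniform
    (summed absolute successive differences <= 1e-9 x mean signal) are
    excluded and listed — these are the spurious flat-signal genes the
    exclusion rule targets.
    """
    if n_body_bins < 1 or flank_bp < 0 or n_flank_bins < 1:
        raise ParameterError("invalid binning parameters")
    profiles, excluded, skipped = [], [], []
    for gene in genes:
        if gene.end - gene.start < n_body_bins:
            skipped.append(gene.gene_id)
            continue
        window = _gene_window(signal, gene, flank_bp)
        body = window[flank_bp:window.size - flank_bp]
        roughness = float(np.abs(np.diff(body)).sum())
        if roughness <= UNIFORM_SIGNAL_RTOL * abs(float(body.mean())):
            excluded.append(gene.gene_id)
            continue
        up = _rebin(window[:flank_bp], n_flank_bins) if flank_bp else np.empty(0)
        down = (
            _rebin(window[window.size - flank_bp:], n_flank_bins)
            if flank_bp else np.empty(0)
        )
        profiles.append(np.concatenate([up, _rebin(body, n_body_bins), down]))
    if skipped:
        warnings.warn(
            f"{len(skipped)} gene(s) shorter than {n_body_bins} bp skipped: "
            f"{skipped[:5]}...",
            stacklevel=2,
        )
    if not profiles:
        raise ParameterError("no gene survives the profile filters")
    mat = np.vstack(profiles)
    nfb = n_flank_bins if flank_bp else 0
    positions = np.concatenate(
        [
            -flank_bp + (np.arange(nfb) + 0.5) * (flank_bp / max(nfb, 1)),
            (np.arange(n_body_bins) + 0.5) / n_body_bins,
            1.0 + (np.arange(nfb) + 0.5) * (flank_bp / max(nfb, 1)),
        ]
    )
    return AggregationProfile(
        positions=positions,
        mean=mat.mean(axis=0),
        sem=mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
        if mat.shape[0] > 1 else np.zeros(mat.shape[1]),
        n_genes=mat.shape[0],
        excluded_genes=excluded,
        n_body_bins=n_body_bins,
        flank_bp=flank_bp,
        n_flank_bins=nfb,
    )
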