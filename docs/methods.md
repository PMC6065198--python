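# Methods

This note records the models behind each stage, the defaults that matter,
what the synthetic generators do and do not emulate, and the numerical
decisions taken where the design was open.

## Wing size and the FA10 index

A wing measurement is an ordered set of planar landmarks (15 in the full
design) per (individual, side, session). Two size traits are supported:
centroid size (√ of summed squared distances from the landmark centroid;
translation- and rotation-invariant, linear under scaling) and wing length
(Euclidean distance between two 1-based landmark indices, 3 and 13 by
default). Landmark indices are 1-based in all user-facing I/O; side labels
are normalized case-insensitively from {L, left, side1, 1} and
{R, right, side2, 2}. Coordinates carry no intrinsic unit; FA comparisons
are scale-dependent, so mixing units across genotypes is the caller's
responsibility.

The sides ANOVA is the classical balanced two-way mixed decomposition
(side fixed with s = 2 levels, individual random with n levels, M replicate
digitization sessions per cell):

    SS_side = nM Σ_s (ȳ_s − ȳ)²            df = s − 1
    SS_ind  = sM Σ_i (ȳ_i − ȳ)²            df = n − 1
    SS_int  = M Σ_is (ȳ_is − ȳ_i − ȳ_s + ȳ)²   df = (n−1)(s−1)
    SS_err  = Σ (y − ȳ_is)²                df = ns(M − 1)

FA10 is the interaction variance component (MS_int − MS_err)/M, floored at
zero for reporting with the raw (possibly negative) value retained for
diagnostics. An optional `convention="difference-variance"` doubles it,
matching the expected variance of the left-minus-right difference; the
component convention is the default because it is the cited index-10
definition. Two F-tests accompany each estimate: interaction vs error (is
FA real?) on ((n−1)(s−1), ns(M−1)) df, and side vs interaction
(directional asymmetry) on (s−1, (n−1)(s−1)) df.

Genotypes are compared by F = FA10_a / FA10_b on the two interaction df,
two-tailed by doubling the smaller tail (no direction is privileged).
This treats each FA10 as a variance estimate on its interaction df, which
is exact only when measurement error is negligible; no Satterthwaite
correction is applied, and the simulated type-I error is mildly
anticonservative (≈ 6–7% at nominal 5% under the default study conditions,
rising as ME/FA grows). No multiplicity correction is applied across a
genotype panel by default (a Bonferroni option exists), mirroring
per-comparison reporting with significance stars at 0.05/0.01/0.001.

M = 1 designs are rejected: without replicate digitization, measurement
error cannot be separated from FA. Unbalanced designs are rejected with the
offending individuals named (a non-strict reader mode reports instead).

## Wing simulator

Size acts multiplicatively: wing (i, s) has true scale
exp(ind_i + da·[s = right] + fa_is) applied to a fixed 15-landmark mean
shape (~2 length units across, centroid size 2.65), with
ind_i ~ N(0, σ²_ind), fa_is ~ N(0, σ²_fa), and a constant log-scale
directional offset `da` on the right side. Each session adds i.i.d.
N(0, σ²_me) noise to every coordinate. Log centroid size therefore carries
the additive decomposition the ANOVA assumes: the FA component appears
with exactly variance σ²_fa, and coordinate noise propagates to
≈ σ²_me / CS² ≈ σ²_me/7 on the log scale.

Defaults (chosen once as a realistic wing study): n = 30 flies, M = 2
sessions, σ²_ind = 0.01, da = 0.005, σ²_fa = 0.002, σ²_me = 0.0025
(coordinate units²). Under these the interaction F-test is well powered at
the n = 30, M = 2 design (F ≈ 14), and FA is an order of magnitude below
individual size variation, as in real wings. The generator emulates the
variance structure only: no shape variation, no digitization bias, no
missing wings, no antisymmetry — so passing tests certify the estimators,
not robustness to those artefacts.

Monte-Carlo checks: mean FA10 over 200 simulated datasets (n = 300,
σ²_fa = 0.01, σ²_me = 0.0025) recovers 0.010 within ±0.001; empirical
variance components of simulated log centroid size converge to their
generative values.

## Gene-set and interval overlap

`gene_overlap_test` is the exact hypergeometric upper tail
P(X ≥ k) = `scipy.stats.hypergeom.sf(k−1, N, K, n)`, stable at genome
scale; it agrees with direct pmf summation over the entire consistent grid
N ≤ 12 to 1e-16.

`interval_randomization` tests nucleotide overlap between query and
annotation intervals within a mappable workspace. All intervals are merged
0-based half-open; queries and annotations extending outside the workspace
are clipped with a warning. The null re-places each query segment
independently and uniformly over all integer start positions at which the
segment fits wholly inside one workspace segment (segment lengths
preserved, inter-segment gaps not), choosing workspace segments with
probability proportional to their valid-start counts. The two-tailed
empirical p is 2·min((r+1)/(m+1) over both tails), capped at 1 — never
exactly zero. On the enumerable toy (length-10 query, annotation [0,50) in
workspace [0,100)) the sampled expectation converges to the exact 455/91 =
5.0 bp. Overlap arithmetic uses a cumulative-coverage index over merged
annotation intervals, so each placement is O(log m).

Peak→gene assignment declares a gene bound iff its span intersects at
least one peak under half-open semantics (touching intervals do not
overlap); an interval tree gives the per-peak gene lists. Decile ranking
sorts peaks by height descending with deterministic (chrom, start, end)
tie-breaks and allocates bins by largest remainder, so bin sizes differ by
at most one. Peak feature classification uses precedence TSS window >
gene body > intergenic, with a ±500 bp default window around the
strand-aware TSS (the window size is a configurable default, not a
measured quantity).

Aggregation profiles rescale each gene body to a fixed number of bins
(mean signal per near-equal chunk) plus fixed-bp flanks split into their
own bins; minus-strand genes are reversed so bins run TSS→TES. Genes whose
body signal is uniform — summed absolute successive differences ≤ 1e-9 ×
mean signal, a numerical stand-in for "zero cumulative derivative" — are
excluded and listed; genes shorter than one bin per base are skipped with
a warning. The profile reports per-bin mean and standard error across the
surviving genes.

## Interactome and active modules

The interactome is a simple undirected graph built from PPI and PDI edge
tables: self-loops dropped, duplicates merged (keeping both type tags),
and, when an expressed-gene set is supplied, edges with an unexpressed
endpoint removed; drop counts are kept as graph metadata. The XGMML
reader accepts namespaced or plain documents, resolves node ids to labels,
and merges duplicate edges, recording parse statistics. PDI direction is
discarded for topology (undirected centrality and search) and retained as
metadata.

Betweenness is shortest-path betweenness computed per connected component,
normalized by (n_c − 1)(n_c − 2)/2 within each component; ranking ties
break by node id. It matches an exact-rational brute-force path
enumeration on random small graphs and the path/cycle/star closed forms.

Node scores: z = Φ⁻¹(1 − p) with p floored at 1e-16 and z clamped to
±8.21; nodes missing from the score table get p = 1 (z at the negative
floor), so unscored nodes actively repel module growth. A module A of
size k scores z_A = Σz/√k; the size adjustment s_A = (z_A − μ_k)/σ_k uses
Monte-Carlo estimates of μ_k, σ_k over uniform random k-subsets of all
nodes (not connectivity-constrained — a conservative choice). The default
n_mc = 4000 puts the calibration standard error near 1% of typical module
scores. Draws are nested across k (the first k entries of random
permutations), so μ_k/σ_k vary smoothly in k and cross-size score
comparisons share their Monte-Carlo noise; draws are precomputed to
k ≤ 512 and fall back to independent sampling beyond. A σ_k of exactly
zero (all scores equal) raises a degenerate-calibration error from
`score_module`; the search instead returns an empty result for constant
scores, since nothing can score above background.

Search is greedy and regional. From each seed node (default: the 10
highest-z nodes) the candidate region is the radius-8 ball. Growth appends
the highest-z frontier node at every step — at fixed target size exactly
the addition that maximizes s_A — continuing through temporary score dips
up to 60 nodes, because strict hill-climbing stalls when a moderately
scored connector must be crossed. The s_A(k) curve along this trajectory
is typically razor-flat around its maximum: hanger-on nodes with mildly
positive z move the score by less than the calibration uncertainty. The
module kept is therefore the smallest prefix within one calibration
standard error of the trajectory maximum (a one-standard-error parsimony
rule), followed by a prune pass that removes low-z, connectivity-preserving
nodes while the score stays on that plateau. Modules from all seeds are
ranked by s_A and near-duplicates above a Jaccard overlap threshold
(default 0.8) collapse to the best-scoring one. Everything is
deterministic for a fixed seed.

Known limitation: the Σz/√k statistic genuinely rewards absorbing any
neighbour whose z exceeds ≈ z_A(√(k+1) − √k) ≈ 1.4 for a 15-node module
at z̄ ≈ 3, and it cannot distinguish a marginal true member (z ≈ 1.6) from
a background neighbour at the same score. On the planted-module benchmark
below, the top module matches the planted set at Jaccard ≥ 0.8 in ≈ 85%
of networks (batch range 0.72–0.92 over 50-network batches); the residual
errors are ± 2–4 boundary nodes that the score provably cannot classify.

## Network simulator

Background: Erdős–Rényi G(n, p) with n = 200 nodes and edge probability
0.005 (mean background degree ≈ 1 — a sparse background against which a
planted module is the dominant connected high-score structure; at mean
degree ≥ 4 the score's true optimum becomes a sprawling superset of any
planted module and recovery is impossible by construction). The planted
module (default 15 nodes) is made connected by adding a random spanning
tree over its members on top of the background edges. Planted node
z-scores are N(planted_z_mean, 1) (default mean 3), background N(0, 1);
p-values are the exact inverse of the scoring transform, p = Φ̄(z). The
generator emulates score structure and connectivity only — not degree
heterogeneity, edge-type mixtures, or correlated expression noise of real
interactomes.

## Pfaffl quantification

Technical replicates are averaged within biological replicates before any
Cq difference is formed. ΔCq = mean Cq(control) − mean Cq(treated) per
gene; the ratio is E_t^ΔCq_t normalized by the geometric mean of
E_r^ΔCq_r over the reference genes. Amplification efficiency is the
per-cycle factor (2.0 = perfect doubling), accepted as a factor in
(1, 2.2], a percent string ("95%" → 1.95), or a bare percent in [50, 120];
anything else is rejected rather than silently misread, since the two
conventions differ by ~2× in log space. Per-treated-biological-replicate
ratios (against the control condition mean) feed a one-sample t-test of
log₂-ratio = 0, the dispersion unit matching a 2-biological ×
3-technical design; the t-test is skipped (reported as None) with fewer
than two biological replicates or zero spread.

## Pipeline runner

`devstab run config.cfg` executes stages in dependency order from an
INI-style config (one section per stage, key = value options, an optional
`args` key for positional inputs). Validation happens before any
computation: unknown stages, missing inputs (unless produced by an earlier
stage of the same run), and — in strict mode — stochastic stages without
an explicit seed are configuration errors. The JSON manifest records the
tool version, config digest, input digests (sha256), per-stage parameters
and outputs with digests, and wall-clock times; identical configs and
seeds reproduce deterministic stage outputs bit-for-bit.

## Problem sizes used in verification

The shipped test suite and `scripts/acceptance.py` use: 200 simulated
datasets of 300 flies for FA10 recovery; 1000 null genotype pairs of 30
flies for the F-test's type-I error; exhaustive hypergeometric enumeration
to N = 12; 10,000 randomization samples on the enumerable interval toy;
100 random graphs of ≤ 7 nodes against the exact betweenness oracle; and
50 simulated 200-node networks for planted-module recovery. These sizes
make the whole verification run in well under a minute on one CPU while
keeping Monte-Carlo standard errors a factor of ~3 below the tolerances
they are checked against.
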