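# Methods

`statepath` infers multi-branching developmental trajectories from
single-cell expression data using a landmark-and-transitional-cell model,
and annotates the result with signature scoring and differential
expression along pseudotime. This note records the model, its parameters,
the numerical conventions, and what the synthetic benchmark does and does
not establish.

## Model

Cellular differentiation is treated as a continuum: cells populate not
only discrete states but also the transitions between adjacent states. The
method exploits this in four steps.

**1. Landmark designation.** Cells are clustered hierarchically in
Euclidean gene space (Ward minimum-variance criterion — equivalently Ward
on squared Euclidean distances) on the log2 expression matrix, typically
restricted to a set of informative genes (lineage signature genes or ANOVA
hits). The dendrogram is cut at increasing depth k; at each cut, a cluster
is designated a *landmark* if it is both pure and large:

- purity: Shannon diversity of its group labels (FACS gates or time
  points), H = −Σ_g p_g ln p_g, must not exceed the diversity cut
  (default 0.6, natural log, unnormalized; a 50/50 two-group cluster has
  H = ln 2 ≈ 0.693 and fails). A normalized variant H / ln(#groups) is
  available.
- size: at least `size_cut` (default 5%) of all cells.

Both cutoffs are inclusive at the boundary. The landmark count as a
function of k rises, plateaus, then falls as clusters shrink below the
size cut; the chosen cut is the smallest k attaining the maximum of this
curve (the start of the plateau). A user-supplied k overrides the rule,
which is how the robustness re-runs at plateau+1/plateau+2 are done. Each
landmark is summarised by its centroid (per-gene mean over members) and
named `<majority group>_<letter>`, letters assigned in cluster-index order
within each majority group; the suffix is always present so names are
deterministic.

**2. Neighborhood network.** Every cell (landmark members included) is
assigned to its two nearest landmark centroids by Euclidean distance
(ties broken by landmark name order). Each unordered landmark pair becomes
an edge weighted by w(e) = the number of cells assigned to it, so edge
weights always sum to the number of cells. Cell count — not centroid
distance — measures the evidence for a state transition: two
transcriptionally similar end states that no cells actually bridge get a
light edge, which is precisely what distinguishes this construction from
a centroid-distance MST (`evaluate.centroid_mst` implements the latter as
a comparison baseline).

**3. Trimming.** The state-transition network is the spanning tree of
maximum total weight, i.e. the minimum spanning tree under distance
−w(e). It is computed by greedy edge insertion with union–find over the
*complete* landmark graph, absent pairs at weight 0, so a tree always
exists even when the observed neighborhood graph is disconnected; any
retained zero-weight edge triggers a warning. Determinism: edges are
processed by weight descending, then lexicographic endpoint names.

**4. Cell ordering.** Given an ordered landmark path (a, b, c, …) whose
consecutive pairs are tree edges, cells whose nearest pair is a path edge
are orthogonally projected onto the line spanned by that edge's centroids:
t = ((x−a)·(b−a))/‖b−a‖². Within each edge cells are sorted by t (ties by
cell id) and the per-edge orderings concatenated. On interior edges t is
clamped to [0, 1]; on the first and last edges t < 0 / t > 1 are kept, so
cells before the first or after the last landmark sit on the terminal
edge extensions. The pseudotime coordinate is the Euclidean arc length
through the centroids (offset of completed segments + t·segment length).
The original formulation defines only an ordering; arc length is this
package's numeric convention, chosen because it is comparable across
branches. A rank column (0..n−1) is also emitted and is what the DE
module uses. An opt-in `rescue` mode attaches cells whose nearest pair is
not a path edge — but whose single nearest landmark is on the path — to
the incident path edge with the smallest perpendicular residual.

## Annotation layers

**Connectivity scoring.** A cell's genes are ranked by descending
expression (ties by gene name). For a gene set of size s at ranked
positions V(1..s) among n genes, the KS-style enrichment is
a = max_j(j/s − V(j)/n), b = max_j(V(j)/n − (j−1)/s), ks = a if a > b
else −b. The raw score is ks_up − ks_down when the two statistics have
opposite signs, else 0. Permutation p-values use random up/down gene-set
pairs of matched sizes drawn from the matrix's genes, one draw shared by
all cells per permutation (default 1,000 permutations), with the add-one
estimator p = (1 + #{|null| ≥ |raw|})/(1 + n_perm), so p ≥ 1/(n_perm+1)
and never 0. Scores are scaled to [−1, 1] by the maximum |raw| over the
scored population (population-relative, documented as such). A cell is
labelled committed when p < α (default 0.05) and its raw score is
non-zero, with the sign giving the lineage; otherwise uncommitted.

**Landmark differential expression.** Per-gene one-way ANOVA across
landmarks (or any grouping), BH adjustment across genes, Tukey HSD
pairwise p-values computed only for genes passing the BH threshold, and
log2 fold changes as differences of group means on the log2 scale.
Constant genes are defined to have F = 0, p = 1. Marker overlays are
per-landmark medians min-max scaled to [0, 1]; a constant marker maps to
all zeros with a warning.

**Pseudotime DE and wave clustering.** Each gene is regressed on a
cubic-spline basis of the pseudotime *rank* (Gaussian errors on log2
expression) against an intercept-only null, with the likelihood-ratio
statistic n·ln(RSS0/RSS1) referred to χ² with df degrees of freedom
(default df = 3). The rank covariate makes the test invariant to
monotone re-scalings of pseudotime and robust to uneven cell density; an
arc-length mode exists. The default basis is an unconstrained cubic
B-spline: at df = 3 it spans exactly the cubic polynomials, so noise-free
polynomial trends of degree ≤ 3 are reproduced to numerical precision — a
property used as a correctness check. A natural cubic basis (`cr`) is
available but is linear beyond its boundary knots and cannot represent
even quadratics, which is why it is not the default. The χ² reference is
asymptotic; at n = 100 its true size at nominal 0.05 is ≈ 0.057, inside
the binomial 99% band checked by the test suite. Significant genes
(BH-adjusted p < α) are grouped into k waves by Ward clustering of their
z-scored fitted profiles (genes processed in sorted-name order, so the
result is independent of input order); k is user-supplied — published
analyses of this kind report 5–7 waves without an automatic rule — and
per-wave trends are lowess smooths (span 0.75) of member-mean profiles.

## Synthetic data

The generator places cells on the segments of a small rooted state tree.
Each state owns a block of `block_size` (default 20) signature genes
elevated by δ (default 4) over a baseline of 1.0, all in log2 units; a
cell at position u ~ U(0, 1) on segment (s1, s2) has mean
(1−u)·μ(s1) + u·μ(s2) plus i.i.d. N(0, noise_sd) noise (default 0.5), and
the linear-scale value is 2^y − 1 clipped at 0, the exact inverse of the
log2(v+1) transform. Group labels mimic FACS gates: each cell is labelled
with its nearer segment endpoint. The canonical benchmark is the Y
topology A→B, B→C, B→D with 100 cells per segment and 100 genes.

What this emulates: a branching continuum with block-structured lineage
signatures, label noise at segment midpoints, and magnitudes comparable
to log2 TPM. What it does not emulate: dropout/zero inflation, count
noise, library-size variation, batch effects, or correlated gene modules
beyond the signature blocks. Passing the recovery benchmark therefore
shows the geometry and combinatorics of the method are right under its
own model assumptions — not that the method is robust to the technical
noise of real single-cell protocols. Clipping at 0 on the linear scale
slightly truncates the lower noise tail (about 2% of baseline draws at
noise 0.5); with noise 0 the log2 structure is recovered exactly.

Benchmark sizes were chosen to keep the full suite fast (≈45 s) while
leaving the statistical checks well-powered: 20 simulation seeds for
recovery rates, 1,000 genes for calibration checks, 200 random graphs
(≤ 6 nodes) for the exhaustive spanning-tree oracle, 50 random instances
for the nearest-pair oracle.

## Degenerate inputs and tie-breaks

- Duplicate gene/cell ids, negative linear values and ragged files are
  rejected at load; double log-transform raises.
- Low-expression filter: a gene is dropped only when the fraction of
  cells below `min_value` strictly exceeds `max_low_fraction` in *every*
  group.
- Coincident landmark centroids make projection undefined and raise.
- Nearest-landmark ties, equal-weight tree edges, equal projection
  scalars and expression ties in rankings all break by name order, making
  every stage deterministic and invariant to input order.
- A strictly rising landmark curve (no plateau inside the scanned range)
  returns the largest k with a warning.

## Known limitations

- Landmark designation needs a priori group labels; fully unsupervised
  data has no purity signal (the original method shares this assumption).
- The plateau rule picks the smallest k at the curve's global maximum;
  with a noisy curve, a user-fixed k is the recommended override.
- Pseudotime is defined per user-selected path; root selection is the
  user's biological call.
- The permutation scheme and score scaling are documented conventions;
  other implementations of connectivity scoring may differ numerically.
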