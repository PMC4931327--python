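# statepath

Landmark-based inference of multi-branching single-cell developmental
trajectories, with pseudotime ordering and downstream annotation.

## The problem

Single-cell RNA-seq of a differentiating system (e.g. dendritic-cell
progenitors progressing MDP → CDP → preDC, or myoblasts differentiating
after a medium switch) captures a continuum: discrete cell states plus
the transitional cells moving between them. Reconstructing *which* states
are adjacent — especially when a lineage branches into two fates that are
transcriptionally similar — is hard for methods that rely on pairwise
distances alone. `statepath` is for computational biologists who have a
genes × cells expression matrix (TPM/RPKM/FPKM), per-cell group labels
(FACS gates or time points), and optionally up/down lineage gene
signatures, and who want a state-transition tree plus per-branch
pseudotime.

## The method

1. **Landmarks.** Hierarchical clustering (Euclidean, Ward) of cells on
   the log2 matrix; the dendrogram is cut at increasing depth k and a
   cluster is a *landmark* if its Shannon label diversity
   H = −Σ p_g ln p_g ≤ 0.6 and it holds ≥ 5% of cells. The chosen k is
   where the landmark count plateaus. Landmarks are named after their
   majority group and summarised by centroids.
2. **Neighborhood network.** Each cell is assigned to its two nearest
   landmark centroids; each landmark pair becomes an edge weighted by
   w(e) = number of cells assigned to it (weights sum to the cell count).
3. **Trimming.** The state-transition network is the maximum-weight
   spanning tree (equivalently, MST under distance −w(e)): the tree that
   connects all landmarks through the transitions supported by the most
   cells. Cell count, not centroid distance, is the evidence — which is
   what lets two similar terminal states end up on separate branches.
4. **Ordering.** Along a user-chosen landmark path, each cell is
   orthogonally projected onto its edge's centroid line
   (t = ((x−a)·(b−a))/‖b−a‖²) and cells are sorted edge by edge;
   pseudotime is arc length through the centroids, with extensions past
   the terminal landmarks.

Annotation layers: per-cell connectivity (cMAP-style KS) scores against
up/down signatures with permutation p-values and commitment labels;
per-landmark ANOVA (+BH, Tukey HSD) differential expression and marker
overlays; spline likelihood-ratio tests for genes changing along
pseudotime, clustered into expression "waves".

## Worked example

Simulate a Y-shaped lineage (A→B, then B→C and B→D; 100 cells per
segment, 20 signature genes per state at log2 effect 4, noise 0.5), infer
the trajectory, and order cells along the branch to C:

```python
import statepath as sp
from statepath.evaluate import branch_landmark_path, ordering_accuracy

ds = sp.simulate_branching(sp.y_topology(), n_genes=100, noise_sd=0.5, seed=11)
m = sp.log_transform(ds.expression)
ls, nn, stn = sp.infer_trajectory(m, ds.annotation)
print("chosen k:", ls.k)
print("landmarks:", ", ".join(ls.names))
print("tree edges:", stn.edges)

path = branch_landmark_path(stn, ls, ds.annotation, "A", "C")
po = sp.order_cells_along_path(m, ls, stn, path)
print("path:", " -> ".join(path))
print("ordered cells:", len(po.cell_ids))
print("Spearman vs truth: %.3f" % ordering_accuracy(po, ds, "C"))
```

Output:

```
chosen k: 12
landmarks: A_a, A_b, B_a, B_b, C_a, C_b, B_c, D_a, B_d, D_b
tree edges: [('A_a', 'A_b'), ('A_a', 'B_b'), ('B_a', 'B_b'), ('B_a', 'B_c'), ('B_a', 'B_d'), ('B_c', 'C_b'), ('B_d', 'D_a'), ('C_a', 'C_b'), ('D_a', 'D_b')]
path: A_b -> A_a -> B_b -> B_a -> B_c -> C_b -> C_a
ordered cells: 210
Spearman vs truth: 0.997
```

The plateau rule picked 12 clusters, 10 of which pass the purity/size
cutoffs; several landmarks per generative state is expected (early/late
sub-states along each segment). Collapsing landmarks by majority label,
the tree is exactly A–B, B–C, B–D: the branch point at B is recovered,
and the 210 cells assigned to the A→C branch are ordered almost perfectly
(rank correlation 0.997 against the generative positions).

The same pipeline runs from the shell:

```sh
statepath simulate --seed 11 --out-expression expr.tsv \
    --out-annotation ann.tsv --out-truth truth.tsv
statepath preprocess --expression expr.tsv --annotation ann.tsv --out log2.tsv
statepath landmarks --expression log2.tsv --annotation ann.tsv \
    --out-membership mem.tsv --out-centroids cen.tsv
statepath network --expression log2.tsv --membership mem.tsv \
    --centroids cen.tsv --out-edges edges.tsv
statepath order --expression log2.tsv --membership mem.tsv --centroids cen.tsv \
    --edges edges.tsv --path A_b,A_a,B_b,B_a,B_c,C_b,C_a --out ordering.tsv
```

or end-to-end from a TOML config with `statepath run --config config.toml`,
which writes every stage's output plus a JSON manifest of parameters and
seeds.

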