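# vizclust

How much of the cluster structure in 2-D maps of bulk transcriptomic data
is real, and how much is an artifact of the value transformation and the
embedding method? `vizclust` implements that comparison end to end for
FPKM-like expression tables: three transforms (unprocessed, log10 with
the exact-zero rule, log10+1) × two dimension-reduction stages (a
parameterized t-SNE and a from-scratch **adapted UMAP**), downstream
clustering (k-means with elbow selection, Leiden), a scale-dependent
kNN-overlap similarity between maps, association statistics against
sample labels, and figures that always carry a **UTMC** provenance legend
(Unit | Transformation | Method | Clustering). A synthetic FPKM generator
with planted subgroups, expression-independent site labels and an
optional primary↔metastatic gradient makes every stage testable offline.

It is written for computational biologists who use t-SNE/UMAP maps of
bulk RNA-seq cohorts and want the transform/method sensitivity of their
visual clusters to be measurable rather than anecdotal.

## The core method

The adapted UMAP builds, from squared pairwise Euclidean distances
between samples, per-sample local scales: ρᵢ is the distance to the
nearest neighbor, and σᵢ solves

    Σ_{j ∈ kNN(i, 15)} exp(−max(0, D_ij − ρᵢ)/σᵢ) = log₂ 15

by binary search. Affinities p_{j|i} = exp(−max(0, D_ij − ρᵢ)/σᵢ) over
each sample's 50 nearest neighbors (25 for cohorts under 50 samples) are
symmetrized by the half-sum P = (p + pᵀ)/2, and the map Y minimizes the
proper cross-entropy

    C(Y) = −Σ_{i≠j} P̂_ij log(Q_ij + ε),   Q = W/ΣW,
    W_ij = 1/(1 + a‖y_i − y_j‖^{2b}),

with (a, b) least-squares fitted to the min_dist = 0.25 target curve and
P̂ = P/ΣP, by full-batch gradient descent with Adam step scaling. The
analytic gradient is verified against finite differences — that check is
the module's central correctness oracle. The t-SNE stage runs on 50
principal components at perplexity 27 and learning rate 300.

Map agreement is quantified as the mean kNN overlap
|NN_A(i, k_a) ∩ NN_B(i, k_b)| / min(k_a, k_b) over a grid of scales:
small k probes local neighborhoods, large k global arrangement.

## Worked example

```
vizclust synth --genes 2000 --samples 300 --subgroups 3 --effect 2 \
    --zero-frac 0.3 --seed 1 --out data/
vizclust run --matrix data/matrix.tsv --annotations data/annotations.tsv \
    --seed 1 --out grid/
```

or, as a scripted study (the numbered drivers under `analysis/` run the
same library code and write their tables to `results/`):

```
$ python analysis/03_recovery_and_site_null.py --seed 1
5 replicate cohorts, full grid each
t-SNE  log10+1  + k-means(3): mean ARI 1.000
UMAP   log10+1  + k-means(3): mean ARI 1.000
UMAP   raw FPKM + k-means(3): mean ARI 0.377
UMAP   log10+1  + Leiden(15, res 1): mean ARI 0.588  (resolution 1 oversplits ~100-sample clusters)
raw < log10+1 recovery in 5/5 seeds
median ARI(site, clusters) over 210 grid cells: -0.0014  (site labels are null)
```

Reading: with three planted subgroups (log2 effect 2, 30% zeros), both
methods recover the truth perfectly from log10+1-transformed values
(ARI 1.0), while the adapted UMAP on raw FPKM collapses to ARI 0.38 —
the transformation, not the biology, decides what the map shows. The
site labels, drawn independently of expression, never drive clustering
(median ARI ≈ 0 across all 210 method × transform × clustering cells).
The Leiden resolution-1 line illustrates a clustering-side artifact:
modularity at that resolution splits ~100-sample clusters even in
perfect maps, so its ARI saturates near 0.6.

```
$ python analysis/04_map_similarity.py --seed 1
      method transform_a transform_b  mean_local  mean_global
        tsne unprocessed       log10      0.0691       0.7699
        tsne unprocessed     log10p1      0.0593       0.7727
        tsne       log10     log10p1      0.2266       0.7862
umap_adapted unprocessed       log10      0.0611       0.5899
umap_adapted unprocessed     log10p1      0.0471       0.5957
umap_adapted       log10     log10p1      0.2550       0.8162
```

Changing the transform shuffles local neighborhoods almost completely
(overlap ≈ 0.05 at k ≤ 10, near the 0.03–0.1 random baseline) while the
global arrangement largely survives (≈ 0.6–0.8 at k ≥ 50).

Every figure the pipeline writes embeds its UTMC line, e.g.
`U: FPKM | T: log10 + 1 | M: UMAP (adapted) | C: leiden(resolution=0.05, n_neighbors=15)`.

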