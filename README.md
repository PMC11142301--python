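# modpres

Weighted co-expression module detection and **preservation analysis** for
grouped single-cell RNA-seq data.

Tumors sampled at different stages (or sites) differ not only in which genes
are expressed but in how genes are *wired together*.  `modpres` asks that
question directly: detect gene modules in a reference condition (say, early
stage), measure how well each module's co-expression density and connectivity
pattern recur in a test condition (late stages), flag the modules that are
not preserved, and characterize exactly how their sub-networks changed.  It
is written for computational biologists who want the full comparative
workflow — QC, normalization, stratified down-sampling, network construction,
preservation statistics, sub-network comparison — as a tested, seedable
Python library, with a synthetic-data generator that plants known modules so
every stage can be validated against ground truth.

## The method in brief

Co-expression is soft-thresholded Pearson correlation, `a_ij = |cor(x_i,
x_j)|^β`, with β chosen so the weighted degree distribution approximates a
scale-free law (signed R² ≥ 0.8).  Modules are branches of an
average-linkage dendrogram of `1 − TOM`, where

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

accepted by core-scatter/gap criteria and merged when their eigengenes
(first PC of the module's standardized expression) correlate above
`1 − merge_height`.  Preservation of a reference module in the test network
is summarized by permutation Z-scores (`Zsummary = (Zdensity +
Zconnectivity)/2`) and by median preservation ranks; a module is flagged
non-preserved when its median rank is ≥ 10 and its size ≤ 100 genes.  For a
flagged module, per-condition sub-networks over the module-dominated cells
yield node connectivities `k_i = Σ_j a_ij`, compared across conditions by
Spearman's

    ρ = 1 − 6 Σ d_i² / (n(n² − 1)),

top-decile unique edges, and per-gene two-sample z-scores
`z = (x̄_test − x̄_ref)/√(s²_t/n_t + s²_r/n_r)` that color the circle-plot
nodes from blue (≤ −2) through white (0) to red (≥ +2).  Groups of unequal
size are first equalized to the smallest group's total by largest-remainder
quotas per cell type with farthest-point (space-filling) sampling inside
each stratum.  Details and conventions: [docs/methods.md](docs/methods.md).

## A worked example

```python
from modpres import generate_dataset, preservation_report, \
    adjacency, topological_overlap, detect_modules
from modpres.coexpression import NetworkParams
from modpres.evaluate import lognorm_frames
from modpres.syndata import default_config

datasets, truth = generate_dataset(default_config(seed=0))
frames = lognorm_frames(datasets)
ref, test = frames["reference"], frames["test"]

params = NetworkParams(power=6.0)
partition = detect_modules(topological_overlap(adjacency(ref, params)),
                           params, expr=ref)
report = preservation_report(ref, test, partition, n_perm=50, seed=0, beta=6.0)
print(report.ranks[["medianRank_pres"]].join(report.flags).sort_values("medianRank_pres"))
```

prints (seed 0, abridged):

```
        medianRank_pres  median_rank  size  flagged
module
E7                  2.0          2.0    51    False
E9                  2.5          2.5    59    False
...
E5                  9.0          9.0    46    False
E1                 10.0         10.0    28     True
E3                 11.0         11.0    35     True
```

The two flagged modules (worst median ranks, sizes ≤ 100) are exactly the
two planted non-preserved modules (E1 matches planted module M01 at Jaccard
0.93, E3 matches M02 at 1.0) — the generator destroyed their latent
co-expression factor in the test condition while leaving everything else
shared.  `examples/` walks through each capability separately (simulation,
QC/clustering, down-sampling, detection, preservation, sub-network
comparison, the full pipeline); each script prints its numbers with a line
on what they mean.  A thin CLI mirrors the stages
(`modpres simulate|preprocess|downsample|modules|preserve|compare|run-all`).

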