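"""Equalize group sizes by stratified, diversity-preserving down-sampling.

Every non-base group is reduced to the base group's total; within a group,
per-type quotas follow largest-remainder apportionment (exact totals, at most
one cell from exact proportionality per stratum) and cells are picked by
farthest-point sampling on PCA coordinates so rare subpopulations survive.
"""

import anndata as ad
import pandas as pd

from modpres import (
    compute_quotas,
    generate_dataset,
    log_normalize,
    run_pca,
    scale_genes,
    select_variable_genes,
    stratified_downsample,
)
from modpres.syndata import default_config

datasets, truth = generate_dataset(default_config(seed=0))
combined = ad.concat(datasets, label="condition", index_unique=None, merge="same")

table = pd.crosstab(combined.obs["group"].astype(str),
                    combined.obs["cell_type"].astype(str))
print("cells per group x type before down-sampling:")
print(table.to_string())

quotas = compute_quotas(table, base_group="pT1")
combined = log_normalize(combined)
hvg = select_variable_genes(combined, fraction=0.2)
combined.obsm["X_pca"] = run_pca(scale_genes(combined, genes=hvg), seed=0).scores

sub = stratified_downsample(combined, quotas, strategy="space_filling", seed=0,
                            base_group="pT1")
after = sub.obs.groupby("group", observed=True).size()
print("\ntotals after down-sampling (all equal to pT1):")
print(after.to_string())
# each non-base group now matches pT1's total while keeping its own
# cell-type mix; the space-filling sampler spreads picks across PC space
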