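import numpy as np
import pandas as pd
import pytest

from modpres.coexpression import (
    ModulePartition,
    NetworkParams,
    adjacency,
    detect_modules,
    topological_overlap,
)
from modpres.evaluate import lognorm_frames
from modpres.syndata import default_config, generate_dataset, small_config


@pytest.fixture(scope="session")
def canonical_dataset():
    """The canonical planted scenario (4 stage groups, 1500 genes, 12 modules)."""
    return generate_dataset(default_config(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """Down-scaled two-condition dataset with 3 planted modules (one non-preserved)."""
    datasets, truth = generate_dataset(small_config(seed=7))
    return datasets, truth


@pytest.fixture(scope="session")
def small_frames(small_dataset):
    datasets, truth = small_dataset
    frames = lognorm_frames(datasets)
    return frames, truth


@pytest.fixture(scope="session")
def small_partition(small_frames):
    """Detected reference-network partition of the small scenario."""
    frames, truth = small_frames
    params = NetworkParams(power=4.0)
    tom = topological_overlap(adjacency(frames["reference"], params))
    return detect_modules(tom, params, expr=frames["reference"]), params


@pytest.fixture(scope="session")
def truth_partition(small_frames):
    """Planted partition over the analyzed gene universe of the small scenario."""
    frames, truth = small_frames
    cols = frames["reference"].columns
    labels = truth.module_labels.reindex(cols).fillna("grey")
    return ModulePartition(labels=labels)


def block_expression(rng, n_cells, blocks, noise=1.0, block_strength=1.0, n_noise=0):
    """Expression with planted correlated blocks: shared factor + iid noise."""
    cols = []
    names = []
    for b, size in enumerate(blocks):
        f = rng.standard_normal(n_cells)
        for g in range(size):
            cols.append(block_strength * f + noise * rng.standard_normal(n_cells))
            names.append(f"B{b}_{g}")
    for g in range(n_noise):
        cols.append(noise * rng.standard_normal(n_cells))
        names.append(f"N_{g}")
    return pd.DataFrame(np.column_stack(cols), columns=names)
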