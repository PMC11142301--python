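"""Synthetic grouped single-cell counts with planted cell types and co-expression modules.

The generator emulates the structure of a multi-group tumor single-cell atlas:
several patient groups of unequal size, seven major cell types, negative-
binomial counts with lognormal library sizes, a name-flagged mitochondrial gene
subset, and latent-factor-driven co-expression modules whose factor structure
is either preserved or destroyed between two conditions (reference vs test).

Count model
-----------
For cell ``c`` of type ``t`` and gene ``g`` the expected count is

    mu_gc = libsize_c * p_gc,   p_gc ∝ baseline_g * type_effect_tg * f_gc

where ``f_gc = exp(lambda_m * l_g * a_mc)`` for genes of planted module ``m``
when cell ``c`` belongs to one of the module's target cell types (``a_mc``
standard normal per cell and module; per-gene loadings ``l_g`` are lognormal
around 1, giving each module hub genes, and are shared between conditions for
preserved modules while rewired modules redraw them), and 1 otherwise.  Relative rates are renormalized per cell so library sizes
are governed by the lognormal draw alone.  Counts are Gamma–Poisson
(negative binomial) with a dispersion shared across genes.

Both conditions share all structural draws (baselines, type effects, marker
placement, mitochondrial flags); they differ only in the factor strength and
loadings of non-preserved modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "ConfigError",
    "GroupSpec",
    "PlantedModuleSpec",
    "SynthConfig",
    "GroundTruth",
    "generate_dataset",
    "default_config",
    "small_config",
    "DEFAULT_CELL_TYPES",
]

#: The seven major cell types of a colorectal tumor atlas.
DEFAULT_CELL_TYPES = (
    "T_NK_ILC",
    "B",
    "plasma",
    "mast",
    "myeloid",
    "stroma_endothelial",
    "epithelial",
)


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass
class GroupSpec:
    """One patient group: a label, per-type cell counts and the condition it feeds."""

    label: str
    cells_per_type: dict[str, int]
    condition: str = "test"  # "reference" or "test"

    @property
    def n_cells(self) -> int:
        return int(sum(self.cells_per_type.values()))


@dataclass
class PlantedModuleSpec:
    """A planted co-expression module driven by a per-cell latent factor.

    ``preserved=True`` means the test condition uses the same factor strength
    and loadings as the reference.  Otherwise the factor is removed
    (``mode="removed"``, the default: ``lambda_test = 0``) or rewired
    (``mode="rewired"``: fresh independent per-gene loadings in the test
    condition, same strength).
    """

    n_module_genes: int
    target_cell_types: tuple[str, ...]
    factor_strength_ref: float = 1.0
    factor_strength_test: float | None = None
    preserved: bool = True
    mode: str = "removed"

    def resolved_test_strength(self) -> float:
        if self.preserved:
            return self.factor_strength_ref
        if self.factor_strength_test is not None:
            return self.factor_strength_test
        return self.factor_strength_ref if self.mode == "rewired" else 0.0


@dataclass
class SynthConfig:
    """Full generator configuration; defaults define the canonical study-like scenario."""

    n_genes: int = 1500
    groups: list[GroupSpec] = field(default_factory=list)
    frac_mito: float = 0.03
    libsize_logmean: float = float(np.log(5000.0))
    libsize_logsd: float = 0.35
    nb_dispersion: float = 2.0
    modules: list[PlantedModuleSpec] = field(default_factory=list)
    seed: int = 0
    # structural knobs (calibrated once; see docs/methods.md)
    baseline_logsd: float = 1.2
    type_effect_sd: float = 0.2
    marker_genes_per_type: int = 8
    marker_effect: float = 6.0
    module_baseline_boost: float = 2.0
    module_target_effect: float = 1.8
    loading_logsd: float = 0.35  # spread of per-gene factor loadings (hubs)
    mito_baseline_boost: float = 3.0
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if len(self.groups) < 2:
            raise ConfigError("at least 2 groups are required")
        if not (0.0 <= self.frac_mito < 0.5):
            raise ConfigError("frac_mito must lie in [0, 0.5)")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        for g in self.groups:
            if g.condition not in ("reference", "test"):
                raise ConfigError(f"group {g.label!r}: unknown condition {g.condition!r}")
            if any(n < 0 for n in g.cells_per_type.values()):
                raise ConfigError(f"group {g.label!r}: negative cell count")
            unknown = set(g.cells_per_type) - set(self.cell_types)
            if unknown:
                raise ConfigError(f"group {g.label!r}: unknown cell types {sorted(unknown)}")
        if not any(g.condition == "reference" for g in self.groups):
            raise ConfigError("no group assigned to the reference condition")
        for m in self.modules:
            if m.n_module_genes < 5:
                raise ConfigError("modules need at least 5 genes")
            if m.factor_strength_ref < 0:
                raise ConfigError("factor strengths must be nonnegative")
            if m.mode not in ("removed", "rewired"):
                raise ConfigError(f"unknown non-preservation mode {m.mode!r}")
            if not set(m.target_cell_types) <= set(self.cell_types):
                raise ConfigError("module target types must be known cell types")
        n_planted = sum(m.n_module_genes for m in self.modules)
        n_marker = self.marker_genes_per_type * len(self.cell_types)
        n_mito = int(round(self.frac_mito * self.n_genes))
        if n_planted + n_marker + n_mito > self.n_genes:
            raise ConfigError(
                f"module/marker/mito genes ({n_planted}+{n_marker}+{n_mito}) "
                f"exceed n_genes ({self.n_genes})"
            )


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset.

    ``module_labels`` maps every gene to its planted module label, with
    ``"grey"`` for background genes; ``preserved`` maps module label to the
    planted preservation flag; ``markers`` is the (gene, cell_type) marker
    table suitable for :func:`modpres.preprocess.assign_cell_types`.
    Per-cell type and group labels live in each condition's ``obs``.
    """

    module_labels: pd.Series
    preserved: dict[str, bool]
    markers: pd.DataFrame

    def module_genes(self, label: str) -> list[str]:
        return list(self.module_labels.index[self.module_labels == label])

    @property
    def module_sizes(self) -> pd.Series:
        lab = self.module_labels[self.module_labels != "grey"]
        return lab.value_counts().sort_index()


def _gene_layout(config: SynthConfig, rng: np.random.Generator):
    """Assign gene names and roles: planted modules, markers, mitochondrial, background."""
    n = config.n_genes
    labels = np.array(["grey"] * n, dtype=object)
    pos = 0
    module_names = []
    for i, m in enumerate(config.modules):
        name = f"M{i + 1:02d}"
        module_names.append(name)
        labels[pos : pos + m.n_module_genes] = name
        pos += m.n_module_genes
    marker_idx: dict[str, np.ndarray] = {}
    for t in config.cell_types:
        marker_idx[t] = np.arange(pos, pos + config.marker_genes_per_type)
        pos += config.marker_genes_per_type
    n_mito = int(round(config.frac_mito * n))
    mito_idx = np.arange(pos, pos + n_mito)
    names = np.array([f"G{i + 1:05d}" for i in range(n)], dtype=object)
    for j, i in enumerate(mito_idx):
        names[i] = f"MT-{j + 1}"
    return names, labels, marker_idx, mito_idx, module_names


def generate_dataset(config: SynthConfig):
    """Generate the two-condition dataset.

    Returns
    -------
    datasets : dict with keys ``"reference"`` and ``"test"``
        Each an :class:`~anndata.AnnData` of sparse integer counts
        (cells x genes) with ``obs['group']``, ``obs['cell_type']`` and
        ``var['mt']``.
    truth : GroundTruth
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    names, labels, marker_idx, mito_idx, module_names = _gene_layout(config, rng)
    n_genes = config.n_genes
    n_types = len(config.cell_types)
    type_of = {t: i for i, t in enumerate(config.cell_types)}

    # structural draws (shared by both conditions)
    baseline = rng.lognormal(0.0, config.baseline_logsd, n_genes)
    for mname in module_names:
        baseline[labels == mname] *= config.module_baseline_boost
    baseline[mito_idx] *= config.mito_baseline_boost
    type_effect = rng.lognormal(0.0, config.type_effect_sd, (n_types, n_genes))
    for t, idx in marker_idx.items():
        type_effect[:, idx] = 1.0
        type_effect[type_of[t], idx] = config.marker_effect
    # per-gene loadings give each module hub genes; preserved modules share
    # them across conditions, rewired modules redraw them for the test side
    ref_loadings = {}
    test_loadings = {}
    for mname, m in zip(module_names, config.modules):
        n_mod = int((labels == mname).sum())
        ref_loadings[mname] = rng.lognormal(0.0, config.loading_logsd, n_mod)
        if not m.preserved and m.mode == "rewired":
            test_loadings[mname] = rng.standard_normal(n_mod)

    theta = config.nb_dispersion
    datasets = {}
    for condition in ("reference", "test"):
        blocks, obs_group, obs_type, barcodes = [], [], [], []
        cell_no = 0
        for g in config.groups:
            if g.condition != condition:
                continue
            types = np.concatenate(
                [np.full(n, type_of[t], dtype=int) for t, n in g.cells_per_type.items()]
            ) if g.n_cells else np.empty(0, dtype=int)
            nc = len(types)
            lib = rng.lognormal(config.libsize_logmean, config.libsize_logsd, nc)
            rates = baseline[None, :] * type_effect[types, :]
            for mname, m in zip(module_names, config.modules):
                lam = m.factor_strength_ref if condition == "reference" else m.resolved_test_strength()
                a = rng.standard_normal(nc)  # drawn regardless of lam for seed stability
                gidx = np.flatnonzero(labels == mname)
                tmask = np.isin(types, [type_of[t] for t in m.target_cell_types])
                # module genes are elevated in target cells in both conditions:
                # the module "captures" those cell types; only the shared
                # co-expression factor differs between conditions
                rates[np.ix_(tmask, gidx)] *= config.module_target_effect
                if lam == 0.0:
                    continue
                loads = ref_loadings[mname]
                if condition == "test" and mname in test_loadings:
                    loads = test_loadings[mname]
                fac = np.zeros((nc, 1))
                fac[tmask, 0] = lam * a[tmask]
                rates[:, gidx] = rates[:, gidx] * np.exp(fac * loads[None, :])
            rates /= rates.sum(axis=1, keepdims=True)
            mu = rates * lib[:, None]
            counts = rng.poisson(rng.gamma(theta, mu / theta))
            blocks.append(sp.csr_matrix(counts))
            obs_group.extend([g.label] * nc)
            obs_type.extend([config.cell_types[t] for t in types])
            barcodes.extend(f"{condition[:3]}_{cell_no + i:06d}" for i in range(nc))
            cell_no += nc
        X = sp.vstack(blocks, format="csr") if blocks else sp.csr_matrix((0, n_genes), dtype=int)
        obs = pd.DataFrame(
            {"group": pd.Categorical(obs_group), "cell_type": pd.Categorical(obs_type)},
            index=pd.Index(barcodes, name="barcode"),
        )
        var = pd.DataFrame(
            {"mt": np.array([nm.startswith("MT-") for nm in names])},
            index=pd.Index(names, name="gene"),
        )
        datasets[condition] = AnnData(X=X, obs=obs, var=var)

    markers = pd.DataFrame(
        [(names[i], t) for t, idx in marker_idx.items() for i in idx],
        columns=["gene", "cell_type"],
    )
    truth = GroundTruth(
        module_labels=pd.Series(labels, index=pd.Index(names, name="gene")),
        preserved={nm: m.preserved for nm, m in zip(module_names, config.modules)},
        markers=markers,
    )
    return datasets, truth


def _scaled_types(total: int, props: dict[str, float]) -> dict[str, int]:
    raw = {t: total * p for t, p in props.items()}
    out = {t: int(np.floor(v)) for t, v in raw.items()}
    rem = total - sum(out.values())
    order = sorted(props, key=lambda t: raw[t] - np.floor(raw[t]), reverse=True)
    for t in order[:rem]:
        out[t] += 1
    return out


#: realistic-ish major-type composition of a tumor sample
_TYPE_PROPS = {
    "T_NK_ILC": 0.25,
    "B": 0.10,
    "plasma": 0.08,
    "mast": 0.05,
    "myeloid": 0.12,
    "stroma_endothelial": 0.10,
    "epithelial": 0.30,
}

#: planted module sizes (ascending) and target types; the two smallest modules
#: are the non-preserved ones, mirroring a myeloid- and an epithelial-linked
#: module losing their co-expression program in the test condition.
_MODULE_PLAN = [
    (30, ("myeloid", "epithelial", "B"), False),
    (35, ("epithelial", "plasma", "T_NK_ILC"), False),
    (40, ("T_NK_ILC", "B", "plasma"), True),
    (45, ("mast", "myeloid", "epithelial"), True),
    (50, ("epithelial", "stroma_endothelial", "myeloid"), True),
    (55, ("B", "T_NK_ILC", "mast"), True),
    (60, ("T_NK_ILC", "epithelial", "stroma_endothelial"), True),
    (65, ("myeloid", "T_NK_ILC", "B"), True),
    (70, ("epithelial", "mast", "plasma"), True),
    (75, ("stroma_endothelial", "B", "T_NK_ILC"), True),
    (85, ("myeloid", "epithelial", "plasma"), True),
    (90, ("T_NK_ILC", "stroma_endothelial", "plasma"), True),
]


def default_config(seed: int = 0) -> SynthConfig:
    """Canonical scenario: 4 unequal tumor-stage groups, 7 cell types, 1500 genes,
    12 planted modules (sizes 30-90) of which the 2 smallest are non-preserved."""
    groups = [
        GroupSpec("pT1", _scaled_types(2000, _TYPE_PROPS), "reference"),
        GroupSpec("pT2", _scaled_types(2600, _TYPE_PROPS), "test"),
        GroupSpec("pT3", _scaled_types(3400, _TYPE_PROPS), "test"),
        GroupSpec("pT4", _scaled_types(2400, _TYPE_PROPS), "test"),
    ]
    modules = [
        PlantedModuleSpec(n, targets, factor_strength_ref=1.0, preserved=pres)
        for n, targets, pres in _MODULE_PLAN
    ]
    return SynthConfig(n_genes=1500, groups=groups, modules=modules, seed=seed)


def small_config(seed: int = 0) -> SynthConfig:
    """Down-scaled scenario for quick tests: 2 groups, 400 genes, 3 modules."""
    groups = [
        GroupSpec("pT1", _scaled_types(400, _TYPE_PROPS), "reference"),
        GroupSpec("pT2", _scaled_types(600, _TYPE_PROPS), "test"),
    ]
    modules = [
        PlantedModuleSpec(30, ("myeloid", "epithelial", "B"), preserved=False),
        PlantedModuleSpec(35, ("T_NK_ILC", "B", "plasma"), preserved=True),
        PlantedModuleSpec(40, ("epithelial", "mast", "plasma"), preserved=True),
    ]
    return SynthConfig(n_genes=400, groups=groups, modules=modules, seed=seed)
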