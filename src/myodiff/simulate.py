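"""Negative-binomial count simulator with planted group effects and latent
immune-infiltration / muscle-regeneration factors.

Counts for gene g in sample j are drawn NB with mean

    mu_gj = L_j * 2 ** (b_g + delta_gj + lambda_g * u_j + rho_g * v_j)

where L_j is a log-normal library factor, b_g the baseline log2 mean,
delta_gj the planted group log2 fold change, u_j / v_j per-sample latent
infiltration and regeneration values (standard normal around group-specific
shifts), and lambda_g / rho_g the per-gene loadings. Variance is
mu + phi_g * mu^2 via gamma-Poisson mixing.

``make_table1_scenario`` builds a study-shaped configuration: published
group sizes (optionally scaled down), a type-1 module planted in IBM, a
distinct type-1-plus-interferon-beta module in DM, small modules in Jo1 and
PM/Scl, a near-empty IMNM module, background-only groups, and a control
group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .panels import MARKER_SETS
from .types import (
    CountMatrix,
    GroupHierarchy,
    DEFAULT_HIERARCHY,
    OTHER_SUBGROUP,
    SampleAnnotation,
    ValidationError,
)

#: Published sample sizes at leaf granularity (subgroup or remainder).
TABLE1_LEAF_SIZES: dict[str, int] = {
    "Mi2": 22, "MDA5": 11, "NXP2": 21, "TIF1": 28, "DM_other": 23,
    "HMGCR": 60, "SRP": 20,
    "Jo1": 37, "ASyS_other": 28,
    "IBM": 53,
    "PM/Scl": 19,
    "OTHER_INFLAMMATORY": 239, "GENETIC": 71, "NT": 37,
}


@dataclass(frozen=True)
class PlantedEffect:
    gene: str
    groups: tuple[str, ...]
    log2fc: float


@dataclass
class SimulationConfig:
    seed: int
    group_sizes: dict[str, int]
    n_genes: int = 600
    genes: Optional[list[str]] = None
    baseline_log2_loc: float = 5.0
    baseline_log2_scale: float = 1.5
    dispersion_log_mean: float = float(np.log(0.15))
    dispersion_log_sd: float = 0.4
    library_size_log_sd: float = 0.3
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    infiltration_loadings: dict[str, float] = field(default_factory=dict)
    regeneration_loadings: dict[str, float] = field(default_factory=dict)
    infiltration_group_shift: dict[str, float] = field(default_factory=dict)
    regeneration_group_shift: dict[str, float] = field(default_factory=dict)

    def gene_names(self) -> list[str]:
        names = list(self.genes) if self.genes else []
        referenced = [e.gene for e in self.planted_effects]
        referenced += list(self.infiltration_loadings) + list(self.regeneration_loadings)
        for g in referenced:
            if g not in names:
                names.append(g)
        if len(names) > self.n_genes:
            raise ValidationError(
                f"{len(names)} named genes exceed n_genes={self.n_genes}"
            )
        names += [f"FILLER_{i:04d}" for i in range(1, self.n_genes - len(names) + 1)]
        return names

    def validate(self, hierarchy: GroupHierarchy = DEFAULT_HIERARCHY) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be positive")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValidationError(f"group {g!r} has size {n}; all sizes must be >= 2")
        if self.dispersion_log_sd < 0 or self.library_size_log_sd < 0:
            raise ValidationError("scale parameters must be nonnegative")
        reachable = set(self.group_sizes)
        for leaf in self.group_sizes:
            clinical, sub = _leaf_labels(leaf, hierarchy)
            reachable.add(clinical)
            if sub is not None:
                reachable.add(sub)
        for eff in self.planted_effects:
            if eff.log2fc == 0:
                raise ValidationError(f"planted effect on {eff.gene!r} has zero log2fc")
            for grp in eff.groups:
                if grp not in reachable:
                    raise ValidationError(
                        f"planted effect targets unknown group {grp!r}"
                    )
        self.gene_names()  # raises if over capacity


@dataclass
class SimulationTruth:
    planted: dict[str, dict[str, float]]      # group -> {gene: log2fc}
    infiltration: pd.Series                   # per sample u_j
    regeneration: pd.Series                   # per sample v_j
    baseline_log2: pd.Series                  # per gene b_g
    dispersion: pd.Series                     # per gene phi_g
    library_factor: pd.Series                 # per sample L_j

    def planted_genes(self, group: str) -> set[str]:
        return set(self.planted.get(group, {}))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group": grp, "gene": gene, "log2fc": lfc}
            for grp, genes in self.planted.items()
            for gene, lfc in genes.items()
        ]
        return pd.DataFrame(rows, columns=["group", "gene", "log2fc"])


def _leaf_labels(
    leaf: str, hierarchy: GroupHierarchy
) -> tuple[str, Optional[str]]:
    """Map a size-table leaf label to (clinical_group, subgroup)."""
    if leaf in hierarchy.parent_of:
        return hierarchy.parent_of[leaf], leaf
    if leaf.endswith("_other") and leaf[: -len("_other")] in hierarchy.clinical_groups:
        return leaf[: -len("_other")], OTHER_SUBGROUP
    return leaf, None


def _sample_in_group(ann: SampleAnnotation, group: str) -> bool:
    return ann.clinical_group == group or ann.autoantibody_subgroup == group


def simulate_counts(
    config: SimulationConfig,
    hierarchy: GroupHierarchy = DEFAULT_HIERARCHY,
) -> tuple[CountMatrix, list[SampleAnnotation], SimulationTruth]:
    """Draw a count matrix, its annotations, and the ground truth."""
    config.validate(hierarchy)
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    n_genes = len(genes)

    annotations: list[SampleAnnotation] = []
    counter = 0
    for leaf in config.group_sizes:  # insertion order: deterministic
        clinical, sub = _leaf_labels(leaf, hierarchy)
        for _ in range(config.group_sizes[leaf]):
            counter += 1
            annotations.append(
                SampleAnnotation(
                    sample_id=f"S{counter:04d}",
                    clinical_group=clinical,
                    autoantibody_subgroup=sub,
                )
            )
    n_samples = len(annotations)

    baseline = rng.normal(config.baseline_log2_loc, config.baseline_log2_scale, n_genes)
    dispersion = np.exp(
        rng.normal(config.dispersion_log_mean, config.dispersion_log_sd, n_genes)
    )
    lib = np.exp(rng.normal(0.0, config.library_size_log_sd, n_samples))

    u_shift = np.array(
        [
            max(
                (
                    config.infiltration_group_shift.get(k, 0.0)
                    for k in (a.clinical_group, a.autoantibody_subgroup)
                    if k is not None
                ),
                default=0.0,
                key=abs,
            )
            for a in annotations
        ]
    )
    v_shift = np.array(
        [
            max(
                (
                    config.regeneration_group_shift.get(k, 0.0)
                    for k in (a.clinical_group, a.autoantibody_subgroup)
                    if k is not None
                ),
                default=0.0,
                key=abs,
            )
            for a in annotations
        ]
    )
    u = rng.normal(0.0, 1.0, n_samples) + u_shift
    v = rng.normal(0.0, 1.0, n_samples) + v_shift

    gene_idx = {g: i for i, g in enumerate(genes)}
    lam = np.zeros(n_genes)
    rho = np.zeros(n_genes)
    for g, w in config.infiltration_loadings.items():
        lam[gene_idx[g]] = w
    for g, w in config.regeneration_loadings.items():
        rho[gene_idx[g]] = w

    delta = np.zeros((n_genes, n_samples))
    planted: dict[str, dict[str, float]] = {}
    for eff in config.planted_effects:
        gi = gene_idx[eff.gene]
        for grp in eff.groups:
            planted.setdefault(grp, {})[eff.gene] = eff.log2fc
            for j, ann in enumerate(annotations):
                if _sample_in_group(ann, grp):
                    # overlapping plantings take the largest magnitude, not a sum
                    if abs(eff.log2fc) > abs(delta[gi, j]):
                        delta[gi, j] = eff.log2fc

    log2_mu = (
        baseline[:, None]
        + delta
        + lam[:, None] * u[None, :]
        + rho[:, None] * v[None, :]
    )
    mu = lib[None, :] * np.exp2(log2_mu)
    # gamma-Poisson: shape 1/phi, scale mu*phi -> var = mu + phi mu^2
    shape = 1.0 / dispersion[:, None]
    lam_mix = rng.gamma(np.broadcast_to(shape, mu.shape), mu * dispersion[:, None])
    counts = rng.poisson(lam_mix)

    sample_ids = [a.sample_id for a in annotations]
    cm = CountMatrix(gene_ids=genes, sample_ids=sample_ids, counts=counts)
    truth = SimulationTruth(
        planted=planted,
        infiltration=pd.Series(u, index=sample_ids),
        regeneration=pd.Series(v, index=sample_ids),
        baseline_log2=pd.Series(baseline, index=genes),
        dispersion=pd.Series(dispersion, index=genes),
        library_factor=pd.Series(lib, index=sample_ids),
    )
    return cm, annotations, truth


# --- study-shaped default scenario ---------------------------------------

_IBM_MODULE = {
    "CCL5": 3.0, "CCR5": 2.5, "CXCR3": 2.5, "IFNG": 2.0, "CD27": 2.0, "XCL1": 2.0,
}
_DM_MODULE = {
    "TNFSF10": 2.5, "GDF15": 2.5, "IL1RN": 2.0, "IFNB1": 3.0, "TNFSF18": 2.0,
}
_JO1_MODULE = {"CXCL8": 2.5, "CCL20": 2.0, "CCL3L3": 2.0}
_PMSCL_MODULE = {"TNFRSF25": 2.0, "TNFRSF4": 2.0, "LTB": 1.5}
_IMNM_MODULE = {"SPP1": 1.5}
_SHARED_TYPE1 = {"CXCL9": ("IBM", "Jo1", "PM/Scl"), "CXCL10": ("IBM", "Jo1")}

_LEUKOCYTE_MARKERS = (
    "CD3E", "CD4", "CD8A", "CD14", "CD68", "CD19", "MS4A1", "CD1C", "CD1E",
    "TBX21", "STAT1",
)


def make_table1_scenario(
    scale: float = 1.0,
    seed: int = 0,
    n_genes: int = 600,
    infiltration_loading: float = 0.8,
) -> SimulationConfig:
    """Study-patterned simulation config with sizes = round(scale * published)."""
    if not 0.0 < scale <= 1.0:
        raise ValidationError(f"scale must be in (0, 1], got {scale}")
    sizes = {g: round(scale * n) for g, n in TABLE1_LEAF_SIZES.items()}
    too_small = {g: n for g, n in sizes.items() if n < 2}
    if too_small:
        raise ValidationError(f"scale {scale} gives group sizes < 2: {too_small}")

    effects: list[PlantedEffect] = []
    for module, grp in (
        (_IBM_MODULE, "IBM"),
        (_DM_MODULE, "DM"),
        (_JO1_MODULE, "Jo1"),
        (_PMSCL_MODULE, "PM/Scl"),
        (_IMNM_MODULE, "IMNM"),
    ):
        effects += [PlantedEffect(g, (grp,), lfc) for g, lfc in module.items()]
    effects += [
        PlantedEffect(g, grps, 2.0) for g, grps in _SHARED_TYPE1.items()
    ]

    planted_cytokines = sorted({e.gene for e in effects})
    infiltration = {g: infiltration_loading for g in _LEUKOCYTE_MARKERS}
    infiltration.update({g: infiltration_loading for g in planted_cytokines})
    regeneration = {g: 0.8 for g in MARKER_SETS["regeneration"]}
    regeneration.update({g: 0.4 for g in planted_cytokines})
    regeneration.update({g: -0.8 for g in MARKER_SETS["mature_muscle"]})
    regeneration.update({g: -0.8 for g in MARKER_SETS["mitochondrial"]})

    marker_genes = [g for genes in MARKER_SETS.values() for g in genes]
    named = list(dict.fromkeys(planted_cytokines + marker_genes))

    return SimulationConfig(
        seed=seed,
        group_sizes=sizes,
        n_genes=n_genes,
        genes=named,
        planted_effects=effects,
        infiltration_loadings=infiltration,
        regeneration_loadings=regeneration,
        infiltration_group_shift={
            "IBM": 1.5, "DM": 0.5, "ASyS": 0.5, "PM/Scl": 1.0,
            "IMNM": 0.3, "NT": -0.5,
        },
        regeneration_group_shift={
            "IBM": 0.5, "DM": 0.8, "ASyS": 0.5, "PM/Scl": 0.3,
            "IMNM": 0.8, "NT": -1.0,
        },
    )


def null_config(
    seed: int,
    group_sizes: Optional[Mapping[str, int]] = None,
    n_genes: int = 600,
) -> SimulationConfig:
    """No planted effects, no latent structure: null calibration scenario."""
    sizes = dict(group_sizes) if group_sizes else {"GROUP_A": 30, "GROUP_B": 30}
    return SimulationConfig(seed=seed, group_sizes=sizes, n_genes=n_genes)
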