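"""Synthetic cross-system scRNA-seq generator with known ground truth.

The generator emulates the statistical structure that makes cross-system
integration hard: two (or more) systems with strong nonlinear batch shifts,
samples nested inside systems with weaker shifts, shared cell types with
unbalanced (possibly zero) proportions across systems, binary condition
effects, and continuous within-cell-type gene-program gradients.

Counts are negative binomial. Per cell, the expected expression profile is

    mu = library_size * softmax(base_type + system_shift + sample_shift
                                + gradient_score * loading + condition_effect)

so all effects act on the log-mean scale and are nonlinear in count space —
the regime conditional VAEs are designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import ExpressionDataset, ProcessingState

__all__ = [
    "CellTypeSpec",
    "GradientProgram",
    "ConditionEffect",
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "generate",
    "preset",
]


@dataclass
class CellTypeSpec:
    name: str
    mean_profile_seed: int
    proportion_per_system: list[float]  # one entry per system; zeros allowed


@dataclass
class GradientProgram:
    genes: list[int]
    cell_type: str
    amplitude: float


@dataclass
class ConditionEffect:
    cell_type: str
    systems: list[int]  # system indices carrying a diseased condition
    genes: list[int]
    amplitude: float


@dataclass
class SyntheticConfig:
    n_systems: int = 2
    n_samples_per_system: list[int] = field(default_factory=lambda: [4, 4])
    cell_types: list[CellTypeSpec] = field(default_factory=list)
    n_genes: int = 500
    type_separation: float = 0.6  # scale of type-specific deltas around the shared backbone
    system_shift_scale: float = 1.0
    # cell types diverge between systems to different degrees (cross-species
    # divergence is cell-type-specific); scale of the type x system shift
    system_type_interaction_scale: float = 0.5
    sample_shift_scale: float = 0.25
    gradient_programs: list[GradientProgram] = field(default_factory=list)
    condition_effects: list[ConditionEffect] = field(default_factory=list)
    library_size_lognormal: tuple[float, float] = (8.5, 0.35)
    dispersion: float = 2.0
    n_cells_total: int = 4000
    seed: int = 0

    def __post_init__(self):
        if len(self.n_samples_per_system) != self.n_systems:
            raise ValueError("n_samples_per_system length must equal n_systems")
        for ct in self.cell_types:
            if len(ct.proportion_per_system) != self.n_systems:
                raise ValueError(f"cell type {ct.name}: need one proportion per system")
        for s in range(self.n_systems):
            tot = sum(ct.proportion_per_system[s] for ct in self.cell_types)
            if self.cell_types and not np.isclose(tot, 1.0):
                raise ValueError(f"proportions for system {s} sum to {tot}, expected 1")
        if min(self.system_shift_scale, self.sample_shift_scale, 0.0) < 0:
            raise ValueError("shift scales must be non-negative")


@dataclass
class SyntheticGroundTruth:
    """Generating parameters, for parameter-recovery tests."""

    type_means: dict[str, np.ndarray]  # log-scale base profile per cell type
    system_shifts: np.ndarray  # n_systems x n_genes
    sample_shifts: dict[str, np.ndarray]  # per sample name
    gradient_scores: np.ndarray  # per cell; NaN for cells without a program
    gradient_programs: list[GradientProgram]
    condition: np.ndarray  # per cell: "healthy" | "diseased"
    system_type_shifts: np.ndarray | None = None  # n_systems x n_types x n_genes


def generate(config: SyntheticConfig) -> tuple[ExpressionDataset, SyntheticGroundTruth]:
    """Draw a dataset and its ground truth; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    if not config.cell_types:
        raise ValueError("config must declare at least one cell type")

    # cell types share a transcriptome backbone and differ by smaller deltas,
    # as real cell types do; `type_separation` sets how distinct they are
    backbone = rng.normal(0.0, 1.0, n_genes)
    type_means = {
        ct.name: backbone
        + np.random.default_rng(ct.mean_profile_seed).normal(
            0.0, config.type_separation, n_genes
        )
        for ct in config.cell_types
    }
    system_shifts = rng.normal(0.0, config.system_shift_scale, (config.n_systems, n_genes))
    interaction = rng.normal(
        0.0,
        config.system_type_interaction_scale,
        (config.n_systems, len(config.cell_types), n_genes),
    )
    type_index = {ct.name: i for i, ct in enumerate(config.cell_types)}
    sample_names: list[str] = []
    sample_system: dict[str, int] = {}
    sample_shifts: dict[str, np.ndarray] = {}
    for s in range(config.n_systems):
        for j in range(config.n_samples_per_system[s]):
            name = f"sys{s}_smp{j}"
            sample_names.append(name)
            sample_system[name] = s
            sample_shifts[name] = rng.normal(0.0, config.sample_shift_scale, n_genes)

    # assign cells: system (uniform over systems), type (per-system proportions),
    # sample (uniform within system)
    n = config.n_cells_total
    cell_system = rng.integers(0, config.n_systems, size=n)
    type_names = [ct.name for ct in config.cell_types]
    props = np.array([ct.proportion_per_system for ct in config.cell_types])  # T x S
    cell_type = np.empty(n, dtype=object)
    for s in range(config.n_systems):
        mask = cell_system == s
        cell_type[mask] = rng.choice(type_names, size=mask.sum(), p=props[:, s])
    cell_sample = np.empty(n, dtype=object)
    for s in range(config.n_systems):
        mask = cell_system == s
        names_s = [nm for nm in sample_names if sample_system[nm] == s]
        cell_sample[mask] = rng.choice(names_s, size=mask.sum())

    grad_by_type = {}
    for prog in config.gradient_programs:
        grad_by_type.setdefault(prog.cell_type, []).append(prog)
    gradient_scores = np.full(n, np.nan)
    has_prog = np.isin(cell_type.astype(str), list(grad_by_type))
    gradient_scores[has_prog] = rng.uniform(0.0, 1.0, has_prog.sum())

    condition = np.full(n, "healthy", dtype=object)
    diseased_pool = np.zeros(n, dtype=bool)
    for eff in config.condition_effects:
        diseased_pool |= (cell_type.astype(str) == eff.cell_type) & np.isin(
            cell_system, eff.systems
        )
    condition[diseased_pool & (rng.uniform(size=n) < 0.5)] = "diseased"

    # compose per-cell log-mean
    logit = np.empty((n, n_genes))
    for t in type_names:
        mask = cell_type == t
        logit[mask] = type_means[t]
    logit += system_shifts[cell_system]
    type_codes = np.array([type_index[t] for t in cell_type])
    logit += interaction[cell_system, type_codes]
    for nm in sample_names:
        mask = cell_sample == nm
        logit[mask] += sample_shifts[nm]
    for prog in config.gradient_programs:
        mask = cell_type == prog.cell_type
        logit[np.ix_(mask, prog.genes)] += (
            prog.amplitude * gradient_scores[mask][:, None]
        )
    for eff in config.condition_effects:
        mask = (cell_type == eff.cell_type) & (condition == "diseased")
        logit[np.ix_(mask, eff.genes)] += eff.amplitude

    # softmax per cell -> expected fraction of the library per gene
    logit -= logit.max(axis=1, keepdims=True)
    frac = np.exp(logit)
    frac /= frac.sum(axis=1, keepdims=True)
    mu0, sigma0 = config.library_size_lognormal
    library = rng.lognormal(mu0, sigma0, n)
    mu = frac * library[:, None]

    # NB via gamma-Poisson: var = mu + mu^2 / dispersion
    lam = rng.gamma(shape=config.dispersion, scale=mu / config.dispersion)
    counts = rng.poisson(lam).astype(np.float64)

    ds = ExpressionDataset(
        matrix=counts,
        gene_ids=[f"g{i}" for i in range(n_genes)],
        cell_ids=[f"c{i}" for i in range(n)],
        system=np.array([f"sys{s}" for s in cell_system]),
        sample=cell_sample.astype(str),
        cell_type=cell_type.astype(str),
        condition=condition.astype(str),
        state=ProcessingState.RAW_COUNTS,
        obs_extra=pd.DataFrame({"gradient_score": gradient_scores}),
    )
    truth = SyntheticGroundTruth(
        type_means=type_means,
        system_shifts=system_shifts,
        sample_shifts=sample_shifts,
        gradient_scores=gradient_scores,
        gradient_programs=list(config.gradient_programs),
        condition=condition.astype(str),
        system_type_shifts=interaction,
    )
    return ds, truth


def _default_types(props_a, props_b, n_types):
    names = [f"type{i}" for i in range(n_types)]
    return [
        CellTypeSpec(name=nm, mean_profile_seed=100 + i,
                     proportion_per_system=[props_a[i], props_b[i]])
        for i, nm in enumerate(names)
    ]


def preset(name: str, **overrides) -> SyntheticConfig:
    """Documented study configurations.

    ``balanced_two_system``
        Five cell types with equal proportions in both systems; strong
        system shift. The baseline integration scenario.
    ``unbalanced_missing_type``
        One cell type entirely absent from the second system and another
        strongly depleted — the regime where distribution-matching
        (adversarial) integration mixes unrelated populations.
    ``condition_shift``
        A healthy/diseased condition effect on one cell type, present in
        both systems, for condition-mixing evaluation.
    ``gradient_rich``
        Three within-cell-type gene-program gradients on top of the
        balanced design, for fine-variation (Moran's I) evaluation.
    """
    if name == "balanced_two_system":
        cfg = SyntheticConfig(
            cell_types=_default_types([0.2] * 5, [0.2] * 5, 5),
        )
    elif name == "unbalanced_missing_type":
        cfg = SyntheticConfig(
            cell_types=_default_types(
                [0.25, 0.25, 0.2, 0.15, 0.15], [0.4, 0.35, 0.22, 0.03, 0.0], 5
            ),
        )
    elif name == "condition_shift":
        base = _default_types([0.25] * 4, [0.25] * 4, 4)
        cfg = SyntheticConfig(
            cell_types=base,
            condition_effects=[
                ConditionEffect(
                    cell_type="type0", systems=[0, 1],
                    genes=list(range(0, 40)), amplitude=2.0,
                )
            ],
        )
    elif name == "gradient_rich":
        base = _default_types([0.25] * 4, [0.25] * 4, 4)
        cfg = SyntheticConfig(
            cell_types=base,
            gradient_programs=[
                GradientProgram(genes=list(range(50, 70)), cell_type="type0", amplitude=2.0),
                GradientProgram(genes=list(range(70, 90)), cell_type="type1", amplitude=2.0),
                GradientProgram(genes=list(range(90, 110)), cell_type="type2", amplitude=2.0),
            ],
        )
    else:
        raise ValueError(
            f"unknown preset {name!r}; choose from balanced_two_system, "
            "unbalanced_missing_type, condition_shift, gradient_rich"
        )
    return replace(cfg, **overrides) if overrides else cfg
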