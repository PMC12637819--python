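"""Synthetic study generation with known ground truth.

Every downstream stage of the pipeline (deconvolution, interaction-QTL
mapping, classification, colocalization) can be exercised on data produced
here. The generative model for bulk methylation is the mixture the
interaction analysis implicitly assumes: for sample *i* and CpG *j*,

    beta_ij = sum_k pi_ik * (m_jk + b_jk * g_i) + eps_ij

where ``pi`` are cell-type proportions on the simplex, ``m_jk`` are
per-cell-type baseline methylomes, ``b_jk`` is a planted cell-type-specific
allelic effect on the beta scale (nonzero only for configured effects, with
``g_i`` the dosage of the planted variant), and ``eps`` is Gaussian
measurement noise. Values are clipped away from {0, 1} so that the logit
(M-value) transform stays finite.

A single integer seed fans out deterministically to per-operation child
seeds, so individual generators can be re-run in isolation while a full
study remains bit-reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MethylationMatrix

logger = logging.getLogger(__name__)

DEFAULT_CELL_TYPES = ("epithelial", "fibroblast", "endothelial", "immune")


def child_rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic per-operation generator derived from one global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class PlantedEffect:
    """A cell-type-specific allelic effect on one CpG.

    ``beta`` is the per-dosage shift of the cell type's methylome on the
    beta scale; positive beta in cell type k yields a positive fitted
    genotype-by-proportion interaction coefficient downstream.
    """

    cpg_index: int
    variant_index: int
    cell_type: str
    beta: float


@dataclass
class SimulationConfig:
    n_samples: int = 200
    n_variants: int = 50
    n_cpgs: int = 20
    maf_range: tuple[float, float] = (0.1, 0.5)
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES
    dirichlet_alpha: Sequence[float] = (1.0, 1.0, 1.0, 1.0)
    effect_table: list[PlantedEffect] = field(default_factory=list)
    noise_sd: float = 0.05
    # Spread (SD) of per-cell-type deviations around each CpG's shared
    # baseline; nonzero by default because distinct cell-type methylomes are
    # the premise of deconvolution.
    celltype_baseline_sd: float = 0.1
    baseline_range: tuple[float, float] = (0.1, 0.9)
    beta_clip_eps: float = 1e-3
    # Optional linear confounding of methylation by covariates (beta scale
    # per year / per unit sex); zero keeps covariates pure plumbing.
    age_effect: float = 0.0
    sex_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.cell_types = list(self.cell_types)
        self.dirichlet_alpha = tuple(float(a) for a in self.dirichlet_alpha)
        if len(self.dirichlet_alpha) != len(self.cell_types):
            raise ValueError("dirichlet_alpha length must match cell_types")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("all dirichlet_alpha entries must be > 0")
        if len(self.cell_types) < 2:
            raise ValueError("need at least 2 cell types")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.beta_clip_eps < 0.5:
            raise ValueError("beta_clip_eps must lie in (0, 0.5)")
        for eff in self.effect_table:
            if not 0 <= eff.cpg_index < self.n_cpgs:
                raise ValueError(f"planted cpg_index {eff.cpg_index} out of bounds")
            if not 0 <= eff.variant_index < self.n_variants:
                raise ValueError(f"planted variant_index {eff.variant_index} out of bounds")
            if eff.cell_type not in self.cell_types:
                raise ValueError(f"planted cell type {eff.cell_type!r} unknown")


@dataclass
class SimulatedStudy:
    genotypes: GenotypeMatrix
    true_proportions: pd.DataFrame
    bulk: MethylationMatrix
    baselines: pd.DataFrame  # cpg x cell type mean beta m_jk
    covariates: pd.DataFrame  # age, sex
    truth: pd.DataFrame  # copy of the planted effect table
    config: SimulationConfig | None = None


def _validate_maf_range(maf_range) -> tuple[float, float]:
    try:
        lo, hi = float(maf_range[0]), float(maf_range[1])
    except (TypeError, ValueError, IndexError) as exc:
        raise ValueError("maf_range must be a (low, high) pair") from exc
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    return lo, hi


def simulate_genotypes(
    n_samples: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.1, 0.5),
    positions: np.ndarray | None = None,
    chrom: str = "1",
    seed: int = 0,
) -> GenotypeMatrix:
    """HWE genotypes: dosage ~ Binomial(2, maf) per variant.

    Positions are strictly increasing along ``chrom``; by default variants
    are spread at random gaps averaging 5 kb.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if n_variants < 1:
        raise ValueError("need at least 1 variant")
    lo, hi = _validate_maf_range(maf_range)
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_variants)
    dos = rng.binomial(2, mafs, size=(n_samples, n_variants)).astype(float)
    if positions is None:
        positions = np.cumsum(rng.integers(1, 10_000, size=n_variants)) + 1
    else:
        positions = np.asarray(positions, dtype=np.int64)
        if len(positions) != n_variants:
            raise ValueError("positions length must equal n_variants")
        if np.any(np.diff(positions) <= 0):
            raise ValueError("positions must be strictly increasing")
    ids = [f"chr{chrom}_{p}_A_G" for p in positions]
    samples = [f"S{i:04d}" for i in range(n_samples)]
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "G", "true_maf": mafs},
        index=pd.Index(ids, name="variant_id"),
    )
    dosages = pd.DataFrame(dos, index=pd.Index(samples, name="sample_id"), columns=variants.index)
    return GenotypeMatrix(dosages, variants)


def simulate_proportions(
    n_samples: int,
    dirichlet_alpha: Sequence[float],
    cell_types: Sequence[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Dirichlet cell-type proportions; each row sums to one.

    The concentration vector controls both the mean (alpha_k / sum alpha)
    and, through the total concentration, the inter-individual variance —
    the knob the power analyses turn.
    """
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if alpha.ndim != 1 or len(alpha) < 2:
        raise ValueError("need at least 2 cell types")
    if np.any(alpha <= 0):
        raise ValueError("all dirichlet_alpha entries must be > 0")
    if cell_types is None:
        cell_types = [f"cell{k}" for k in range(len(alpha))]
    if len(cell_types) != len(alpha):
        raise ValueError("cell_types length must match alpha")
    rng = np.random.default_rng(seed)
    props = rng.dirichlet(alpha, size=n_samples)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    return pd.DataFrame(props, index=pd.Index(samples, name="sample_id"), columns=list(cell_types))


def simulate_covariates(n_samples: int, seed: int = 0) -> pd.DataFrame:
    """Age ~ N(50, 10) and sex ~ Bernoulli(0.5)."""
    rng = np.random.default_rng(seed)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    return pd.DataFrame(
        {
            "age": rng.normal(50.0, 10.0, size=n_samples),
            "sex": rng.integers(0, 2, size=n_samples).astype(float),
        },
        index=pd.Index(samples, name="sample_id"),
    )


def _default_cpg_positions(variant_pos: np.ndarray, n_cpgs: int) -> np.ndarray:
    """Spread CpGs over the variant span so every CpG has cis variants."""
    lo, hi = int(variant_pos.min()), int(variant_pos.max())
    pos = np.linspace(lo, max(hi, lo + n_cpgs), n_cpgs)
    pos = np.round(pos).astype(np.int64)
    # enforce strict increase for degenerate spans
    pos += np.arange(n_cpgs)
    return pos


def simulate_bulk_methylation(
    genotypes: GenotypeMatrix,
    proportions: pd.DataFrame,
    config: SimulationConfig,
    covariates: pd.DataFrame | None = None,
    baselines: pd.DataFrame | None = None,
    cpg_positions: np.ndarray | None = None,
    seed: int | None = None,
) -> SimulatedStudy:
    """Proportion-weighted mixture of per-cell-type methylomes.

    Planted effects shift the target cell type's methylome by
    ``beta * dosage``; everything is summed with the sample's proportions,
    Gaussian noise added, and the result clipped to
    [eps, 1 - eps].
    """
    if genotypes.n_samples != len(proportions):
        raise ValueError("genotypes and proportions disagree on sample count")
    if not np.allclose(proportions.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("proportion rows must sum to 1")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n, j, k = genotypes.n_samples, config.n_cpgs, len(config.cell_types)
    cell_types = list(config.cell_types)
    pi = proportions[cell_types].to_numpy(float)

    cpg_ids = pd.Index([f"cg{i:07d}" for i in range(j)], name="cpg_id")
    if baselines is None:
        base = rng.uniform(*config.baseline_range, size=j)
        dev = rng.normal(0.0, config.celltype_baseline_sd, size=(j, k))
        m = np.clip(base[:, None] + dev, 0.05, 0.95)
        baselines = pd.DataFrame(m, index=cpg_ids, columns=cell_types)
    else:
        baselines = baselines.copy()
        baselines.index = cpg_ids
        m = baselines[cell_types].to_numpy(float)

    # mixture mean: (n, j)
    bulk = pi @ m.T

    dose = genotypes.dosages.to_numpy(float)
    for eff in config.effect_table:
        ki = cell_types.index(eff.cell_type)
        g = dose[:, eff.variant_index]
        shift = pi[:, ki] * eff.beta * g
        col = bulk[:, eff.cpg_index] + shift
        overshoot = max(col.max() - 1.0, -col.min(), 0.0)
        if overshoot > 0.5:
            warnings.warn(
                f"planted effect at cpg {eff.cpg_index} pushes mean beta "
                f"{overshoot:.2f} outside (0,1) before clipping",
                stacklevel=2,
            )
        bulk[:, eff.cpg_index] = col

    if config.noise_sd > 0:
        bulk = bulk + rng.normal(0.0, config.noise_sd, size=bulk.shape)
    eps = config.beta_clip_eps

    if covariates is None:
        covariates = simulate_covariates(n, seed=seed + 1 if seed is not None else 1)
    covariates = covariates.copy()
    covariates.index = proportions.index
    if config.age_effect or config.sex_effect:
        adj = (
            config.age_effect * (covariates["age"].to_numpy() - 50.0)
            + config.sex_effect * covariates["sex"].to_numpy()
        )
        bulk = bulk + adj[:, None]
    bulk = np.clip(bulk, eps, 1.0 - eps)

    if cpg_positions is None:
        cpg_positions = _default_cpg_positions(genotypes.variants["pos"].to_numpy(), j)
    positions = pd.DataFrame(
        {"chrom": genotypes.variants["chrom"].iloc[0], "pos": np.asarray(cpg_positions, dtype=np.int64)},
        index=cpg_ids,
    )
    values = pd.DataFrame(bulk.T, index=cpg_ids, columns=proportions.index)
    truth = pd.DataFrame(
        [
            {
                "cpg_id": cpg_ids[e.cpg_index],
                "variant_id": genotypes.variants.index[e.variant_index],
                "cell_type": e.cell_type,
                "beta": e.beta,
            }
            for e in config.effect_table
        ],
        columns=["cpg_id", "variant_id", "cell_type", "beta"],
    )
    return SimulatedStudy(
        genotypes=genotypes,
        true_proportions=proportions,
        bulk=MethylationMatrix(values, positions, scale="beta"),
        baselines=baselines,
        covariates=covariates,
        truth=truth,
        config=config,
    )


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run the full generator chain from a single config and seed."""
    geno = simulate_genotypes(
        config.n_samples,
        config.n_variants,
        config.maf_range,
        seed=_spawn(config.seed, 0),
    )
    props = simulate_proportions(
        config.n_samples,
        config.dirichlet_alpha,
        cell_types=config.cell_types,
        seed=_spawn(config.seed, 1),
    )
    covars = simulate_covariates(config.n_samples, seed=_spawn(config.seed, 2))
    return simulate_bulk_methylation(
        geno, props, config, covariates=covars, seed=_spawn(config.seed, 3)
    )


def _spawn(seed: int, stream: int) -> int:
    """Derive a 31-bit child seed from (seed, stream)."""
    return int(child_rng(seed, stream).integers(0, 2**31 - 1))


@dataclass
class PlantedDMC:
    """A CpG hypomethylated in one target cell type by ``delta`` beta."""

    cpg_index: int
    target_type: str
    delta: float


def simulate_sorted_reference(
    cell_types: Sequence[str],
    n_per_type: int,
    n_cpgs: int,
    planted_dmcs: Sequence[PlantedDMC],
    seed: int = 0,
    noise_sd: float = 0.02,
    clip_eps: float = 1e-3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Sorted-cell beta matrix (CpG x sample) plus cell-type labels.

    Planted DMCs sit at ``(1 - delta)/2`` in the target type and
    ``(1 + delta)/2`` in every other type, so the group-mean difference is
    exactly ``delta``; all other CpGs share a common mean across types.
    """
    cell_types = list(cell_types)
    if n_per_type < 2:
        raise ValueError("need at least 2 samples per cell type")
    for dmc in planted_dmcs:
        if not 0 < dmc.delta <= 1:
            raise ValueError("planted delta must lie in (0, 1]")
        if not 0 <= dmc.cpg_index < n_cpgs:
            raise ValueError("planted cpg_index out of bounds")
        if dmc.target_type not in cell_types:
            raise ValueError(f"unknown target type {dmc.target_type!r}")
    rng = np.random.default_rng(seed)
    n_total = n_per_type * len(cell_types)
    base = rng.uniform(0.2, 0.8, size=n_cpgs)
    mat = np.tile(base[:, None], (1, n_total))
    labels = np.repeat(cell_types, n_per_type)
    for dmc in planted_dmcs:
        lo, hi = (1 - dmc.delta) / 2, (1 + dmc.delta) / 2
        row = np.where(labels == dmc.target_type, lo, hi)
        mat[dmc.cpg_index] = row
    mat = mat + rng.normal(0.0, noise_sd, size=mat.shape)
    mat = np.clip(mat, clip_eps, 1 - clip_eps)
    cpg_ids = pd.Index([f"cg{i:07d}" for i in range(n_cpgs)], name="cpg_id")
    sample_ids = pd.Index([f"ref{i:04d}" for i in range(n_total)], name="sample_id")
    values = pd.DataFrame(mat, index=cpg_ids, columns=sample_ids)
    return values, pd.Series(labels, index=sample_ids, name="cell_type")


def marginal_summary_stats(
    g: np.ndarray, y: np.ndarray, positions: np.ndarray, chrom: str = "1"
) -> pd.DataFrame:
    """Per-variant simple-regression effect and SE of trait ``y`` on each
    column of the dosage matrix ``g`` (the summary-statistic track format
    consumed by colocalization)."""
    n = len(y)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    ss_g = (gc**2).sum(axis=0)
    ss_g = np.where(ss_g == 0, np.nan, ss_g)
    beta = gc.T @ yc / ss_g
    resid_ss = (yc**2).sum() - beta**2 * ss_g
    se = np.sqrt(resid_ss / (n - 2) / ss_g)
    positions = np.asarray(positions, dtype=np.int64)
    return pd.DataFrame(
        {
            "variant_id": [f"chr{chrom}_{p}_A_G" for p in positions],
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "G",
            "beta": beta,
            "se": se,
            "n": n,
        }
    )


def simulate_summary_pair(
    n_variants: int,
    causal_config: str,
    n1: int,
    n2: int,
    seed: int = 0,
    maf: float = 0.3,
    causal_z: float = 8.0,
    ld_r: float = 0.0,
    chrom: str = "1",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two per-variant summary-statistic tracks over a shared variant grid.

    ``causal_config`` is one of ``none`` (no causal variant in either
    trait), ``shared`` (the same causal variant drives both) or
    ``distinct`` (each trait has its own causal variant). Effect sizes are
    scaled so that the causal variant's expected marginal z-statistic is
    ``causal_z``. Optional first-order LD copies neighbouring haplotypes
    with probability ``ld_r``.
    """
    if causal_config not in {"none", "shared", "distinct"}:
        raise ValueError("causal_config must be none|shared|distinct")
    if causal_config == "distinct" and n_variants < 2:
        raise ValueError("distinct causal variants need at least 2 variants")
    rng = np.random.default_rng(seed)

    def draw_genotypes(n: int) -> np.ndarray:
        haps = np.empty((2, n, n_variants))
        for h in range(2):
            haps[h, :, 0] = rng.binomial(1, maf, size=n)
            for v in range(1, n_variants):
                copy = rng.random(n) < ld_r
                fresh = rng.binomial(1, maf, size=n)
                haps[h, :, v] = np.where(copy, haps[h, :, v - 1], fresh)
        return haps.sum(axis=0)

    mid = n_variants // 2
    if causal_config == "none":
        causal1 = causal2 = None
    elif causal_config == "shared":
        causal1 = causal2 = mid
    else:
        causal1, causal2 = max(0, mid - 2), min(n_variants - 1, mid + 2)

    sd_g = np.sqrt(2 * maf * (1 - maf))
    positions = np.arange(1, n_variants + 1) * 1000

    def one_track(n: int, causal: int | None) -> pd.DataFrame:
        g = draw_genotypes(n)
        y = rng.normal(0.0, 1.0, size=n)
        if causal is not None:
            b = causal_z / (sd_g * np.sqrt(n))
            y = y + b * g[:, causal]
        return marginal_summary_stats(g, y, positions, chrom=chrom)

    t1 = one_track(n1, causal1)
    t2 = one_track(n2, causal2)
    truth = {"causal_config": causal_config, "causal1": causal1, "causal2": causal2}
    return t1, t2, truth
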