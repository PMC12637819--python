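"""Calibration and recovery experiments run on synthetic studies.

These are the package's reference experiments: parameter-recovery and
cell-type-specificity calls under a planted effect, family-wise error
calibration of the EMT + Bonferroni pipeline under the global null,
deconvolution recovery on in-silico mixtures, the power-versus-proportion-
variance curve, and colocalization calibration. Tests and the acceptance
script run them at documented problem sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import deconvolution as dc
from . import mapping
from .containers import MethylationMatrix
from .coloc import ColocPriors, DEFAULT_PRIORS, coloc_enumerate
from .interpret import call_cell_type_specific, stratified_association
from .preprocess import prepare_response, rank_inverse_normal
from .sim import (
    PlantedDMC,
    PlantedEffect,
    SimulationConfig,
    simulate_sorted_reference,
    simulate_study,
    simulate_summary_pair,
    _spawn,
)

# The specificity experiment emulates the setting in which candidate
# cell-type-specific effects arise in practice: a minor cell type whose
# proportion is highly dispersed across individuals (near-absent in most,
# substantial in some), against a dominant background type.
SPECIFICITY_ALPHA = (0.1, 1.0)
SPECIFICITY_CELL_TYPES = ("epithelial", "stromal")


def sign_and_specificity_experiment(
    n_reps: int = 200,
    n_samples: int = 2000,
    effect: float = 0.2,
    seed: int = 0,
    noise_sd: float = 0.05,
) -> dict:
    """Plant one cell-type-specific effect; measure interaction-sign
    recovery and the cell-type-specificity call across replicates.

    Per replicate: one CpG, one variant, a planted beta-scale effect in
    the first (minor, high-variance) cell type only; the interaction model
    is fitted for every cell type and the two-part specificity rule
    applied to each.
    """
    modeled = SPECIFICITY_CELL_TYPES[0]
    sign_ok = np.zeros(n_reps, dtype=bool)
    call_ok = np.zeros(n_reps, dtype=bool)
    for rep in range(n_reps):
        cfg = SimulationConfig(
            n_samples=n_samples,
            n_variants=1,
            n_cpgs=1,
            maf_range=(0.2, 0.4),
            cell_types=SPECIFICITY_CELL_TYPES,
            dirichlet_alpha=SPECIFICITY_ALPHA,
            effect_table=[PlantedEffect(0, 0, modeled, effect)],
            noise_sd=noise_sd,
            seed=_spawn(seed, rep),
        )
        study = simulate_study(cfg)
        y = prepare_response(study.bulk.values).to_numpy(float)[0]
        g = study.genotypes.dosages.to_numpy(float)[:, 0]
        covars = study.covariates
        inter, strat = {}, {}
        for ct in cfg.cell_types:
            c = np.asarray(rank_inverse_normal(study.true_proportions[ct]), float)
            inter[ct] = mapping.fit_interaction_model(y, g, c, covars)
            strat[ct] = stratified_association(
                y, g, study.true_proportions[ct], "upper", covars
            )
        inter_df, strat_df = pd.DataFrame(inter).T, pd.DataFrame(strat).T
        sign_ok[rep] = np.sign(inter_df.at[modeled, "beta_gxc"]) == np.sign(effect)
        calls = {
            ct: call_cell_type_specific(ct, inter_df, strat_df)[0]
            for ct in cfg.cell_types
        }
        call_ok[rep] = calls[modeled] and not any(
            calls[ct] for ct in cfg.cell_types if ct != modeled
        )
    return {
        "n_reps": n_reps,
        "sign_recovery_rate": float(sign_ok.mean()),
        "specificity_call_rate": float(call_ok.mean()),
    }


def _null_study(
    seed: int,
    n_samples: int,
    n_cpgs: int,
    n_variants_per_cpg: int,
    cell_types=("epithelial", "stromal"),
    dirichlet_alpha=(1.0, 1.0),
    celltype_baseline_sd: float = 0.0,
):
    """A multi-CpG study with no planted effects: CpGs are spaced far
    apart (2 Mb) and each carries its own block of cis variants within
    +/-100 kb, so cis windows do not overlap.

    Calibration runs use shared per-CpG baselines across cell types
    (``celltype_baseline_sd=0``): the interaction test is exactly
    calibrated under this model-consistent null, whereas strongly
    cell-type-divergent baselines induce proportion-dependent residual
    variance after the INT transform and mild tail inflation (see the
    methods note)."""
    n_variants = n_cpgs * n_variants_per_cpg
    cfg = SimulationConfig(
        n_samples=n_samples,
        n_variants=n_variants,
        n_cpgs=n_cpgs,
        maf_range=(0.15, 0.5),
        cell_types=cell_types,
        dirichlet_alpha=dirichlet_alpha,
        celltype_baseline_sd=celltype_baseline_sd,
        effect_table=[],
        seed=seed,
    )
    spacing = 2_000_000
    cpg_pos = (np.arange(n_cpgs) + 1) * spacing
    variant_pos = np.sort(
        np.concatenate(
            [
                p + np.linspace(-100_000, 100_000, n_variants_per_cpg).astype(int)
                for p in cpg_pos
            ]
        )
    )
    from .sim import simulate_covariates, simulate_genotypes, simulate_proportions
    from .sim import simulate_bulk_methylation

    geno = simulate_genotypes(
        n_samples, n_variants, cfg.maf_range, positions=variant_pos, seed=_spawn(seed, 0)
    )
    props = simulate_proportions(
        n_samples, dirichlet_alpha, cell_types=cell_types, seed=_spawn(seed, 1)
    )
    covars = simulate_covariates(n_samples, seed=_spawn(seed, 2))
    return simulate_bulk_methylation(
        geno, props, cfg, covariates=covars, cpg_positions=cpg_pos, seed=_spawn(seed, 3)
    )


def fwer_experiment(
    n_studies: int = 200,
    n_samples: int = 200,
    n_cpgs: int = 50,
    n_variants_per_cpg: int = 20,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Family-wise rejection rate of the EMT + Bonferroni pipeline on null
    studies (no planted effects)."""
    rejections = np.zeros(n_studies, dtype=bool)
    for s in range(n_studies):
        study = _null_study(_spawn(seed + 1, s), n_samples, n_cpgs, n_variants_per_cpg)
        res = mapping.map_interaction_mqtls(
            study.genotypes,
            study.bulk,
            study.true_proportions,
            cell_type=study.config.cell_types[0],
            covariates=study.covariates,
            alpha=alpha,
        )
        rejections[s] = bool(res.leads["is_significant"].any()) if len(res.leads) else False
    fwer = float(rejections.mean())
    mc_se = float(np.sqrt(alpha * (1 - alpha) / n_studies))
    return {"fwer": fwer, "n_studies": n_studies, "mc_se": mc_se, "bound": alpha + 2 * mc_se}


def power_by_variance(
    concentrations: tuple[float, ...] = (40.0, 8.0, 1.5),
    mean_proportions: tuple[float, float] = (0.3, 0.7),
    n_reps: int = 200,
    n_samples: int = 300,
    effect: float = 0.15,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Detection power of one planted interaction effect at fixed effect
    size and mean proportion, across proportion-variance settings.

    Concentration c scales Dirichlet(c * mean): larger c means smaller
    inter-individual variance. Detection = interaction p < alpha for the
    single planted variant-CpG pair.
    """
    rows = []
    for ci, conc in enumerate(concentrations):
        alpha_vec = tuple(conc * m for m in mean_proportions)
        hits = np.zeros(n_reps, dtype=bool)
        for rep in range(n_reps):
            cfg = SimulationConfig(
                n_samples=n_samples,
                n_variants=1,
                n_cpgs=1,
                maf_range=(0.2, 0.4),
                cell_types=("target", "background"),
                dirichlet_alpha=alpha_vec,
                effect_table=[PlantedEffect(0, 0, "target", effect)],
                seed=_spawn(seed, ci * n_reps + rep),
            )
            study = simulate_study(cfg)
            y = prepare_response(study.bulk.values).to_numpy(float)[0]
            g = study.genotypes.dosages.to_numpy(float)[:, 0]
            c = np.asarray(rank_inverse_normal(study.true_proportions["target"]), float)
            fit = mapping.fit_interaction_model(y, g, c, study.covariates)
            hits[rep] = fit["p_gxc"] < alpha
        var_pi = mean_proportions[0] * (1 - mean_proportions[0]) / (sum(alpha_vec) + 1)
        rows.append(
            {
                "concentration": conc,
                "proportion_variance": var_pi,
                "power": float(hits.mean()),
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows).sort_values("proportion_variance").reset_index(drop=True)


def build_synthetic_panel(
    seed: int = 0,
    n_per_type: int = 12,
    n_cpgs: int = 1500,
    dmc_counts: dict[str, int] | None = None,
    dmc_deltas: dict[str, float] | None = None,
    noise_sd: float = 0.02,
    n_decoys: int = 100,
    return_heldout: bool = False,
):
    """Construct a four-cell-type reference panel from simulated sorted
    data with planted DMC counts (defaults: 62 immune, 65 epithelial,
    60 fibroblast, 66 endothelial — the generic panel's composition) plus
    sub-threshold decoy DMCs that selection must reject."""
    dmc_counts = dmc_counts or {
        "immune": 62, "epithelial": 65, "fibroblast": 60, "endothelial": 66
    }
    dmc_deltas = dmc_deltas or {
        "immune": 0.95, "epithelial": 0.85, "fibroblast": 0.85, "endothelial": 0.75
    }
    cell_types = list(dmc_counts)
    planted = []
    idx = 0
    for ct, count in dmc_counts.items():
        for _ in range(count):
            planted.append(PlantedDMC(idx, ct, dmc_deltas[ct]))
            idx += 1
    rng = np.random.default_rng(seed)
    for _ in range(n_decoys):  # below every per-type threshold
        planted.append(PlantedDMC(idx, rng.choice(cell_types), 0.5))
        idx += 1
    if idx > n_cpgs:
        raise ValueError("n_cpgs too small for the planted DMCs")
    values, labels = simulate_sorted_reference(
        cell_types, 2 * n_per_type, n_cpgs, planted, seed=_spawn(seed, 10),
        noise_sd=noise_sd,
    )
    # split columns into construction and held-out halves per cell type
    build_cols, held_cols = [], []
    for ct in cell_types:
        cols = list(values.columns[(labels == ct).to_numpy()])
        build_cols += cols[:n_per_type]
        held_cols += cols[n_per_type:]
    panel = dc.build_reference_panel(values[build_cols], labels.loc[build_cols])
    if return_heldout:
        return panel, values[held_cols], labels.loc[held_cols]
    return panel


def rpc_recovery_experiment(
    n_mixtures: int = 500, noise_sd: float = 0.05, seed: int = 0
) -> pd.DataFrame:
    """Deconvolution recovery: noisy in-silico mixtures of held-out sorted
    profiles, deconvoluted with a panel built from independent samples;
    reports Pearson r and RMSE per cell type."""
    panel, held_vals, held_labels = build_synthetic_panel(seed=seed, return_heldout=True)
    return dc.validate_panel_insilico(
        panel, held_vals, held_labels, n_mixtures=n_mixtures,
        seed=_spawn(seed, 20), noise_sd=noise_sd,
    )


def coloc_calibration(
    n_reps: int = 100,
    causal_config: str = "shared",
    n_variants: int = 50,
    n1: int = 5000,
    n2: int = 5000,
    causal_z: float = 8.0,
    seed: int = 0,
    priors: ColocPriors | tuple = DEFAULT_PRIORS,
) -> dict:
    """Colocalization calibration over simulated summary-statistic pairs:
    fraction of replicates with PP4 > 0.9 (shared causal) and the rate at
    which PP0 is the largest posterior (null)."""
    pp4_high = np.zeros(n_reps, dtype=bool)
    pp0_top = np.zeros(n_reps, dtype=bool)
    for rep in range(n_reps):
        t1, t2, _ = simulate_summary_pair(
            n_variants, causal_config, n1, n2, seed=_spawn(seed, rep), causal_z=causal_z
        )
        res = coloc_enumerate(t1, t2, priors=priors)
        pp4_high[rep] = res.pp4 > 0.9
        pp0_top[rep] = int(np.argmax(res.pp)) == 0
    return {
        "n_reps": n_reps,
        "causal_config": causal_config,
        "pp4_gt_0.9_rate": float(pp4_high.mean()),
        "pp0_top_rate": float(pp0_top.mean()),
    }
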