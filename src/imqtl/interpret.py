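"""Post-mapping analytics for interaction mQTLs.

Covers the imQTL class taxonomy (directional consistency between the
interaction term and the marginal bulk-tissue effect), calling candidate
cell-type-specific imQTLs from the two-part sign / stratified-significance
rule, cross-cell-type effect sharing, and replication in an independent
study.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .containers import GenotypeMatrix, MethylationMatrix
from .mapping import fit_marginal_model
from .preprocess import prepare_response

logger = logging.getLogger(__name__)

MARGINAL_P_THRESHOLD = 1e-5
NOMINAL_P = 0.05


# ---------------------------------------------------------------------------
# directional consistency taxonomy


def classify_directional_consistency(
    imqtls: pd.DataFrame,
    marginal: pd.DataFrame,
    marginal_p_threshold: float = MARGINAL_P_THRESHOLD,
) -> pd.DataFrame:
    """Classify each imQTL as consistent / inconsistent / unknown.

    ``unknown`` when the marginal-effect p-value exceeds the threshold (or
    no marginal record exists); otherwise ``consistent`` iff the marginal
    effect and the interaction term share a sign. Every imQTL receives
    exactly one class.
    """
    marg = marginal.set_index(["variant_id", "cpg_id"])[["beta_main", "p_main"]]
    marg.columns = ["beta_marginal", "p_marginal"]
    out = imqtls.join(marg, on=["variant_id", "cpg_id"])
    missing = out["beta_marginal"].isna()
    if missing.any():
        logger.info("%d imQTLs lack a marginal record; classed unknown", missing.sum())
    unknown = missing | (out["p_marginal"] > marginal_p_threshold)
    same_sign = np.sign(out["beta_marginal"]) == np.sign(out["beta_gxc"])
    out["class"] = np.where(unknown, "unknown", np.where(same_sign, "consistent", "inconsistent"))
    return out


def consistency_summary(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-cell-type counts and percent consistent (of all imQTLs)."""
    rows = []
    for ct, sub in classified.groupby("cell_type"):
        counts = sub["class"].value_counts()
        n = len(sub)
        rows.append(
            {
                "cell_type": ct,
                "n_imqtls": n,
                "n_consistent": int(counts.get("consistent", 0)),
                "n_inconsistent": int(counts.get("inconsistent", 0)),
                "n_unknown": int(counts.get("unknown", 0)),
                "pct_consistent": percent_consistent(int(counts.get("consistent", 0)), n),
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")


def percent_consistent(n_consistent: int, n_total: int) -> float:
    """Directional-consistency percentage, rounded to one decimal."""
    if n_total <= 0:
        raise ValueError("need at least one imQTL")
    return round(100.0 * n_consistent / n_total, 1)


# ---------------------------------------------------------------------------
# stratified associations and cell-type specificity


def stratified_association(
    y: np.ndarray,
    g: np.ndarray,
    proportions: pd.Series,
    half: str,
    covariates: pd.DataFrame | None = None,
) -> pd.Series:
    """Genotype-methylation OLS within one proportion half.

    Samples at the median go to the lower half (same split as the
    stratified MAF filter). Returns slope/se/p for the genotype term, or
    an untestable record when the genotype is monomorphic in the half.
    """
    if half not in {"upper", "lower"}:
        raise ValueError("half must be 'upper' or 'lower'")
    prop = np.asarray(proportions, float)
    sel = prop <= np.median(prop) if half == "lower" else prop > np.median(prop)
    if sel.sum() < 10:
        raise ValueError("need at least 10 samples in the half")
    y_h, g_h = np.asarray(y, float)[sel], np.asarray(g, float)[sel]
    if np.std(g_h) == 0:
        return pd.Series(
            {"slope": np.nan, "se": np.nan, "p": np.nan, "n": int(sel.sum()), "testable": False}
        )
    cov_h = covariates.loc[sel] if covariates is not None else None
    fit = fit_marginal_model(y_h, g_h, cov_h)
    return pd.Series(
        {
            "slope": fit["beta_main"], "se": fit["se_main"], "p": fit["p_main"],
            "n": int(sel.sum()), "testable": True,
        }
    )


def call_cell_type_specific(
    target_cell_type: str,
    interaction_fits: pd.DataFrame,
    stratified_fits: pd.DataFrame,
    nominal_p: float = NOMINAL_P,
) -> tuple[bool, pd.Series]:
    """Two-part rule for a candidate cell-type-specific imQTL.

    ``interaction_fits``: one row per cell type (index) with ``beta_gxc``
    and ``p_gxc`` for the same variant-CpG pair. ``stratified_fits``: one
    row per cell type with the genotype-methylation ``slope`` and ``p``
    in that cell type's own upper-50% proportion subset.

    Criterion 1: the modeled type's interaction has the opposite sign to
    every other type's, OR no other type is nominally significant.
    Criterion 2: the modeled type's upper-half association is nominally
    significant, and every other type's upper-half association is either
    not significant or runs in the opposite direction.
    """
    if len(interaction_fits) < 2:
        raise ValueError("need interaction fits for at least 2 cell types")
    others = [ct for ct in interaction_fits.index if ct != target_cell_type]
    sign_t = np.sign(interaction_fits.at[target_cell_type, "beta_gxc"])
    opposite_all = all(
        np.sign(interaction_fits.at[ct, "beta_gxc"]) != sign_t for ct in others
    )
    none_significant = all(
        interaction_fits.at[ct, "p_gxc"] >= nominal_p for ct in others
    )
    criterion1 = opposite_all or none_significant

    strat_t = stratified_fits.loc[target_cell_type]
    criterion2 = bool(strat_t.get("testable", True)) and strat_t["p"] < nominal_p
    slope_sign = np.sign(strat_t["slope"])
    if criterion2:
        for ct in others:
            if ct not in stratified_fits.index:
                continue
            row = stratified_fits.loc[ct]
            if not bool(row.get("testable", True)):
                continue
            if row["p"] < nominal_p and np.sign(row["slope"]) == slope_sign:
                criterion2 = False
                break
    evidence = pd.Series(
        {
            "cell_type": target_cell_type,
            "criterion1_opposite_sign": opposite_all,
            "criterion1_no_other_significant": none_significant,
            "criterion1": criterion1,
            "criterion2": criterion2,
            "specific": bool(criterion1 and criterion2),
        }
    )
    return bool(criterion1 and criterion2), evidence


# ---------------------------------------------------------------------------
# effect sharing


def effect_sharing_matrix(
    fits: pd.DataFrame, nominal_p: float = NOMINAL_P
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise sharing of interaction effects across cell types.

    ``fits`` holds, for every imQTL (lead variant-CpG pair discovered in
    any cell type of the tissue) and every cell type, the interaction
    estimate: columns ``pair_id``, ``cell_type``, ``beta_gxc``, ``p_gxc``.

    Entry (a, b) — rows are the reference cell type a — is the fraction of
    the tissue's imQTLs for which cell type b's interaction has the same
    sign as a's AND b's p < 0.05, over imQTLs testable in both; the
    diagonal is 1 by convention. The matrix need not be symmetric.
    Display order comes from average-linkage clustering of 1 - sharing.
    """
    wide_b = fits.pivot(index="pair_id", columns="cell_type", values="beta_gxc")
    wide_p = fits.pivot(index="pair_id", columns="cell_type", values="p_gxc")
    cell_types = list(wide_b.columns)
    if len(cell_types) < 2:
        raise ValueError("need at least 2 cell types")
    if wide_b.empty:
        raise ValueError("no imQTLs provided")
    k = len(cell_types)
    share = pd.DataFrame(np.eye(k), index=cell_types, columns=cell_types)
    for a in cell_types:
        for b in cell_types:
            if a == b:
                continue
            ok = wide_b[a].notna() & wide_b[b].notna()
            n_ok = int(ok.sum())
            if n_ok < len(wide_b):
                logger.info(
                    "sharing (%s, %s): %d imQTLs untestable excluded",
                    a, b, len(wide_b) - n_ok,
                )
            if n_ok == 0:
                share.loc[a, b] = np.nan
                continue
            same = np.sign(wide_b[a][ok]) == np.sign(wide_b[b][ok])
            sig = wide_p[b][ok] < nominal_p
            share.loc[a, b] = float((same & sig).mean())
    sym = 1.0 - (share.to_numpy() + share.to_numpy().T) / 2.0
    np.fill_diagonal(sym, 0.0)
    sym = np.nan_to_num(sym, nan=1.0)
    order = leaves_list(average(squareform(sym, checks=False)))
    return share, [cell_types[i] for i in order]


# ---------------------------------------------------------------------------
# replication


def harmonize_alleles(
    discovery_variants: pd.DataFrame, replication_variants: pd.DataFrame
) -> pd.Series:
    """Sign multiplier per shared variant id after allele harmonization.

    Match on (chrom, pos); +1 when ref/alt agree, -1 when swapped; strand
    flips and other mismatches raise.
    """
    merged = discovery_variants.merge(
        replication_variants,
        on=["chrom", "pos"],
        suffixes=("_d", "_r"),
    )
    same = (merged["ref_d"] == merged["ref_r"]) & (merged["alt_d"] == merged["alt_r"])
    swapped = (merged["ref_d"] == merged["alt_r"]) & (merged["alt_d"] == merged["ref_r"])
    bad = ~(same | swapped)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} variants cannot be harmonized (possible strand flips)"
        )
    flip = pd.Series(np.where(same, 1.0, -1.0), index=merged["variant_id_d"].to_numpy())
    return flip


def replicate_imqtls(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    sign_flip: pd.Series | None = None,
    nominal_p: float = NOMINAL_P,
) -> dict:
    """Validate discovery imQTLs in an independent study.

    A discovery imQTL validates iff its replication interaction p < 0.05
    with a matching (harmonized) sign. Pairs untestable in replication are
    excluded from the denominator and counted separately. Returns per-
    cell-type validated fractions, the overall fraction, and the r^2
    between discovery and replication interaction estimates.
    """
    keys = ["variant_id", "cpg_id", "cell_type"]
    rep = replication.set_index(keys)[["beta_gxc", "p_gxc"]]
    rep.columns = ["beta_rep", "p_rep"]
    merged = discovery.join(rep, on=keys)
    if sign_flip is not None:
        mult = merged["variant_id"].map(sign_flip).fillna(1.0)
        merged["beta_rep"] = merged["beta_rep"] * mult
    untestable = merged["beta_rep"].isna()
    tested = merged[~untestable].copy()
    tested["validated"] = (tested["p_rep"] < nominal_p) & (
        np.sign(tested["beta_rep"]) == np.sign(tested["beta_gxc"])
    )
    per_cell = tested.groupby("cell_type")["validated"].agg(["mean", "sum", "count"])
    per_cell.columns = ["fraction_validated", "n_validated", "n_tested"]
    if len(tested) >= 2 and tested["beta_rep"].std() > 0:
        r = np.corrcoef(tested["beta_gxc"], tested["beta_rep"])[0, 1]
        r2 = float(r * r)
    else:
        r2 = np.nan
    return {
        "per_cell_type": per_cell,
        "overall_fraction": float(tested["validated"].mean()) if len(tested) else np.nan,
        "n_untestable": int(untestable.sum()),
        "r_squared": r2,
        "table": tested,
    }


# ---------------------------------------------------------------------------
# convenience: fits of one pair across all retained cell types


def pair_fits_across_cell_types(
    genotypes: GenotypeMatrix,
    methylation: MethylationMatrix,
    proportions: pd.DataFrame,
    variant_id: str,
    cpg_id: str,
    cell_types: list[str] | None = None,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Interaction fits and upper-half stratified fits of one variant-CpG
    pair for every retained cell type (inputs to the specificity call)."""
    from .mapping import fit_interaction_model
    from .preprocess import rank_inverse_normal

    cell_types = cell_types or list(proportions.columns)
    response = (
        prepare_response(methylation.values)
        if methylation.scale == "beta"
        else methylation.values
    )
    y = response.loc[cpg_id].to_numpy(float)
    g = genotypes.dosages[variant_id].to_numpy(float)
    inter_rows, strat_rows = {}, {}
    for ct in cell_types:
        c = np.asarray(rank_inverse_normal(proportions[ct].loc[genotypes.samples]), float)
        inter_rows[ct] = fit_interaction_model(y, g, c, covariates)
        strat_rows[ct] = stratified_association(
            y, g, proportions[ct].loc[genotypes.samples], "upper", covariates
        )
    return pd.DataFrame(inter_rows).T, pd.DataFrame(strat_rows).T
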