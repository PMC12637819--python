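"""Cell-type EWAS, annotation enrichment, and cross-tissue meta-analysis.

Enrichment of QTL features (lead variants or target CpGs) in genomic
annotations is a two-sided Fisher exact test of a 2x2 table — inside /
outside the annotation by target / background-minus-target — with log
odds ratios (Haldane-Anscombe 0.5 correction when any cell is empty) and
Woolf standard errors. Per-tissue log odds ratios are pooled by a
DerSimonian-Laird random-effects meta-analysis.

Interval membership is 0-based half-open: a feature at ``start`` is
inside, at ``end`` outside. Variant and CpG positions arrive 1-based
(VCF / array-manifest convention) and are converted before comparison.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.meta_analysis import combine_effects
from statsmodels.stats.multitest import multipletests

from .mapping import _batched_ols, _design_base, _pvalues

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# annotation containers


class AnnotationSet:
    """Named collections of genomic intervals (0-based half-open)."""

    def __init__(self, collections: dict[str, pd.DataFrame]):
        self._merged: dict[str, dict[str, np.ndarray]] = {}
        self.labels = list(collections)
        for label, df in collections.items():
            if (df["start"] >= df["end"]).any():
                raise ValueError(f"annotation {label!r} has start >= end")
            self._merged[label] = {
                chrom: _merge_intervals(sub[["start", "end"]].to_numpy(np.int64))
                for chrom, sub in df.groupby("chrom")
            }

    def contains(self, label: str, chrom: np.ndarray, pos0: np.ndarray) -> np.ndarray:
        """Membership of 0-based positions in the (merged) intervals."""
        chrom = np.asarray(chrom)
        pos0 = np.asarray(pos0, dtype=np.int64)
        out = np.zeros(len(pos0), dtype=bool)
        for ch in np.unique(chrom):
            merged = self._merged[label].get(ch)
            if merged is None:
                continue
            sel = chrom == ch
            starts, ends = merged[:, 0], merged[:, 1]
            idx = np.searchsorted(starts, pos0[sel], side="right") - 1
            inside = (idx >= 0) & (pos0[sel] < ends[np.clip(idx, 0, None)])
            out[np.flatnonzero(sel)] = inside
        return out


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Merge overlapping/abutting half-open intervals (sorted output)."""
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    merged = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def read_bed(path, default_label: str | None = None) -> AnnotationSet:
    """Read a BED file (3+ columns, optional label in column 4).

    Rows with a 4th column are grouped by label; otherwise everything goes
    into a single collection named ``default_label`` (or the file stem).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError("BED needs at least 3 columns")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    df["chrom"] = df["chrom"].astype(str)
    if df.shape[1] >= 4:
        df = df.rename(columns={3: "label"})
        groups = {str(lab): sub for lab, sub in df.groupby("label")}
    else:
        from pathlib import Path

        name = default_label or Path(path).stem
        groups = {name: df}
    return AnnotationSet(groups)


# ---------------------------------------------------------------------------
# cell-type EWAS


def ewas_cell_proportion_dms(
    response: pd.DataFrame,
    proportions: pd.DataFrame,
    cell_type: str,
    covariates: pd.DataFrame | None = None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-CpG association of transformed methylation with a cell type's
    proportion (plus covariates); DMS are CpGs passing BH-FDR.

    ``response`` is CpG x sample on a transformed scale (M-value / INT).
    """
    prop = proportions[cell_type].loc[response.columns].to_numpy(float)
    if np.std(prop) == 0:
        raise ValueError("constant proportion vector")
    n = len(prop)
    z, _ = _design_base(None, covariates, n)
    rows = []
    y_all = response.to_numpy(float)
    for j in range(y_all.shape[0]):
        coef, se, df, ok = _batched_ols(y_all[j], z, [prop[:, None]])
        p = _pvalues(coef, se, df)
        rows.append((coef[0, -1], se[0, -1], p[0, -1]))
    out = pd.DataFrame(rows, index=response.index, columns=["beta", "se", "p"])
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["is_dms"] = out["fdr"] < fdr_threshold
    return out


def proportion_in_dms(
    target_cpgs, dms_cpgs, background_cpgs, comparison_cpgs=None
) -> dict:
    """Fraction of each CpG set intersecting the union of cell-type DMS."""
    dms = set(dms_cpgs)
    background = set(background_cpgs)
    if not background:
        raise ValueError("background CpG set is empty")

    def frac(cpgs) -> float:
        cpgs = set(cpgs)
        return len(cpgs & dms) / len(cpgs) if cpgs else 0.0

    out = {"target": frac(target_cpgs), "background": frac(background)}
    if comparison_cpgs is not None:
        out["comparison"] = frac(comparison_cpgs)
    return out


# ---------------------------------------------------------------------------
# Fisher enrichment


def fisher_enrichment(
    target: pd.DataFrame,
    background: pd.DataFrame,
    annotations: AnnotationSet,
    tissue: str | None = None,
) -> pd.DataFrame:
    """Annotation enrichment of target features against a background.

    ``target`` and ``background`` are feature tables with columns
    ``feature_id``, ``chrom``, ``pos`` (1-based); target must be a proper
    subset of background. Per annotation, the 2x2 table is
    (in/out annotation) x (target / background-minus-target); the p-value
    is the two-sided Fisher exact test; the log odds ratio applies the
    Haldane-Anscombe 0.5 correction when any cell is zero, with a Woolf
    standard error on the corrected table.
    """
    t_ids = set(target["feature_id"])
    b_ids = set(background["feature_id"])
    if not t_ids <= b_ids:
        raise ValueError("target features must be a subset of the background")
    if t_ids == b_ids:
        raise ValueError("target equals background; enrichment undefined")
    rest = background[~background["feature_id"].isin(t_ids)]

    rows = []
    for label in annotations.labels:
        a = int(annotations.contains(label, target["chrom"].to_numpy(), target["pos"].to_numpy() - 1).sum())
        b = len(target) - a
        c = int(annotations.contains(label, rest["chrom"].to_numpy(), rest["pos"].to_numpy() - 1).sum())
        d = len(rest) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            if b == 0 and d == 0:
                logger.warning("annotation %s covers every feature", label)
        else:
            aa, bb, cc, dd = a, b, c, d
        log_or = float(np.log((aa * dd) / (bb * cc)))
        se = float(np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd))
        rows.append(
            {
                "annotation": label, "tissue": tissue,
                "a": a, "b": b, "c": c, "d": d,
                "log_or": log_or, "se_log_or": se, "p": float(p),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# random-effects meta-analysis


def re_meta_analysis(log_ors: np.ndarray, ses: np.ndarray) -> dict:
    """DerSimonian-Laird random-effects pooling of per-tissue log odds
    ratios. Returns pooled estimate, SE, Wald p, and tau^2.

    tau^2 = max(0, (Q - df) / C) with fixed-effect weights w = 1/SE^2,
    Q the weighted heterogeneity statistic and C = sum w - sum w^2 / sum w;
    the pooled estimate uses weights 1 / (SE^2 + tau^2).
    """
    eff = np.asarray(log_ors, float)
    se = np.asarray(ses, float)
    if len(eff) < 2:
        raise ValueError("need at least 2 tissues")
    if np.any(~np.isfinite(eff)) or np.any(~np.isfinite(se)):
        raise ValueError("estimates and SEs must be finite")
    if np.any(se <= 0):
        raise ValueError("all SEs must be positive")
    w = 1.0 / se**2
    mu_fe = np.sum(w * eff) / np.sum(w)
    q = float(np.sum(w * (eff - mu_fe) ** 2))
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (len(eff) - 1)) / c)
    w_re = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_re * eff) / np.sum(w_re))
    pooled_se = float(np.sqrt(1.0 / np.sum(w_re)))
    z = pooled / pooled_se
    return {
        "pooled_log_or": pooled,
        "se": pooled_se,
        "p": float(2 * stats.norm.sf(abs(z))),
        "tau2": tau2,
    }
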