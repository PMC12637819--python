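"""Transformations, covariate construction, and variant QC before mapping.

The response used for QTL mapping is the rank-based inverse normal
transform (INT) of M-values; cell-type proportions are likewise INT'd
before entering the interaction model. Variant QC drops missing, Hardy-
Weinberg-violating (exact test p < 1e-6) and low-frequency (MAF <= 0.1)
variants. Genetic PCs are computed on LD-pruned (r^2 <= 0.2 in 500 kb
windows), standardized dosages; methylation PCs are chosen by a
distance-to-line elbow on the scree curve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import KNNImputer

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# scale transforms


def beta_to_mvalue(beta):
    """M = log2(beta / (1 - beta)), elementwise.

    Raises on values at 0 or 1 (clip upstream, e.g. with the generator's
    ``beta_clip_eps``) so M-values stay finite.
    """
    arr = np.asarray(beta, dtype=float) if not isinstance(beta, (pd.DataFrame, pd.Series)) else beta
    vals = arr.to_numpy() if hasattr(arr, "to_numpy") else arr
    if np.any(vals <= 0) or np.any(vals >= 1):
        raise ValueError("beta values must lie strictly in (0, 1); clip upstream")
    return np.log2(arr / (1 - arr))


def mvalue_to_beta(m):
    return 2.0**m / (1.0 + 2.0**m)


def rank_inverse_normal(values, offset: float = 0.5):
    """Rank-based INT: x -> Phi^-1((rank - offset) / n), average ranks on ties.

    The default offset of 0.5 is the plain quantile midpoint customary in
    QTL pipelines; Blom-style offsets can be passed instead.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("rank_inverse_normal expects a 1-D vector")
    n = len(arr)
    if n < 2:
        raise ValueError("need at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    if np.all(arr == arr[0]):
        raise ValueError("constant vector: ranks undefined for QTL use")
    ranks = stats.rankdata(arr, method="average")
    out = stats.norm.ppf((ranks - offset) / n)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def int_rows(df: pd.DataFrame, offset: float = 0.5) -> pd.DataFrame:
    """Apply the rank-based INT to every row (CpG) of a matrix."""
    out = np.empty(df.shape)
    vals = df.to_numpy(float)
    n = df.shape[1]
    for i in range(df.shape[0]):
        ranks = stats.rankdata(vals[i], method="average")
        out[i] = stats.norm.ppf((ranks - offset) / n)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def prepare_response(beta_df: pd.DataFrame) -> pd.DataFrame:
    """Mapping response: rank-INT of M-values, per CpG row."""
    return int_rows(beta_to_mvalue(beta_df))


# ---------------------------------------------------------------------------
# missing-data imputation


def impute_knn(df: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """kNN imputation over CpG rows (neighbouring probes).

    A missing entry is replaced by the unweighted mean of the k nearest
    complete rows under (nan-)Euclidean distance on shared observed
    columns. Rows entirely missing are rejected.
    """
    vals = df.to_numpy(float)
    if np.all(np.isfinite(vals)):
        return df.copy()
    all_missing = np.all(np.isnan(vals), axis=1)
    if all_missing.any():
        bad = list(df.index[all_missing])
        raise ValueError(f"rows entirely missing cannot be imputed: {bad[:5]}")
    n_complete = int(np.sum(~np.isnan(vals).any(axis=1)))
    if n_complete < k:
        raise ValueError(f"need >= {k} complete neighbour rows, have {n_complete}")
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    out = imputer.fit_transform(vals)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Standard exact enumeration of the conditional distribution of the
    heterozygote count given allele counts (no mid-p correction). Returns
    the sum of probabilities of configurations no more probable than the
    observed one.
    """
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # probabilities over all possible het counts with same parity as rare
    het_values = np.arange(rare % 2, rare + 1, 2)
    log_probs = np.empty(len(het_values), dtype=float)
    from scipy.special import gammaln

    for i, h in enumerate(het_values):
        r_hom = (rare - h) // 2
        c_hom = n - h - r_hom
        log_probs[i] = (
            h * np.log(2.0)
            + gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(r_hom + 1)
            - gammaln(c_hom + 1)
            - (gammaln(2 * n + 1) - gammaln(rare + 1) - gammaln(2 * n - rare + 1))
        )
    probs = np.exp(log_probs - log_probs.max())
    probs /= probs.sum()
    obs = np.searchsorted(het_values, n_het)
    p = probs[probs <= probs[obs] * (1 + 1e-12)].sum()
    return float(min(1.0, p))


def filter_variants(
    gm: GenotypeMatrix,
    maf_min: float = 0.1,
    hwe_p: float = 1e-6,
) -> tuple[GenotypeMatrix, dict]:
    """Drop variants with missingness, HWE exact p < ``hwe_p``, or MAF <= ``maf_min``.

    Reasons are assessed in that priority order for the report; the kept
    set is independent of variant ordering.
    """
    dos = gm.dosages.to_numpy(float)
    n_var = gm.n_variants
    missing = np.isnan(dos).any(axis=0)
    hwe_fail = np.zeros(n_var, dtype=bool)
    maf_fail = np.zeros(n_var, dtype=bool)
    for v in range(n_var):
        if missing[v]:
            continue
        col = dos[:, v]
        n_hom1 = int(np.sum(col == 0))
        n_het = int(np.sum(col == 1))
        n_hom2 = int(np.sum(col == 2))
        if hwe_exact_pvalue(n_het, n_hom1, n_hom2) < hwe_p:
            hwe_fail[v] = True
            continue
        p = col.mean() / 2.0
        if min(p, 1 - p) <= maf_min:
            maf_fail[v] = True
    keep = ~(missing | hwe_fail | maf_fail)
    report = {
        "n_input": n_var,
        "n_missing": int(missing.sum()),
        "n_hwe": int(hwe_fail.sum()),
        "n_maf": int(maf_fail.sum()),
        "n_kept": int(keep.sum()),
    }
    if report["n_kept"] == 0:
        warnings.warn("variant QC removed every variant", stacklevel=2)
    kept_ids = gm.variants.index[keep]
    return gm.subset_variants(kept_ids), report


# ---------------------------------------------------------------------------
# principal components


def ld_prune(gm: GenotypeMatrix, r2_threshold: float = 0.2, window_bp: int = 500_000) -> pd.Index:
    """Greedy LD pruning: walk variants in position order and keep a variant
    only if its r^2 with every already-kept variant within ``window_bp``
    stays at or below the threshold."""
    variants = gm.variants.sort_values(["chrom", "pos"])
    dos = gm.dosages
    kept: list[str] = []
    kept_pos: list[tuple[str, int]] = []
    for vid, row in variants.iterrows():
        g = dos[vid].to_numpy(float)
        if np.var(g) == 0:
            continue
        ok = True
        for kid, (kchrom, kpos) in zip(reversed(kept), reversed(kept_pos)):
            if kchrom != row["chrom"] or row["pos"] - kpos > window_bp:
                break
            r = np.corrcoef(g, dos[kid].to_numpy(float))[0, 1]
            if r * r > r2_threshold:
                ok = False
                break
        if ok:
            kept.append(vid)
            kept_pos.append((row["chrom"], int(row["pos"])))
    return pd.Index(kept)


def _pca_scores(x: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """SVD-based PCA of a centered observation x feature matrix.

    Sign convention: each component's largest-magnitude loading is made
    positive, so scores are reproducible across runs and sample orderings.
    """
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    for c in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            vt[c] *= -1
            scores[:, c] *= -1
    return scores[:, :n_components], (s**2)


def compute_genetic_pcs(
    gm: GenotypeMatrix,
    n_pcs: int = 5,
    r2_threshold: float = 0.2,
    window_bp: int = 500_000,
) -> pd.DataFrame:
    """Top genetic PC scores from pruned, variance-standardized dosages."""
    if gm.n_samples < 6:
        raise ValueError("need at least 6 samples for genetic PCs")
    kept = ld_prune(gm, r2_threshold=r2_threshold, window_bp=window_bp)
    if len(kept) < n_pcs:
        raise ValueError(
            f"only {len(kept)} of {gm.n_variants} variants survive LD pruning; "
            f"need >= {n_pcs}"
        )
    x = gm.dosages[kept].to_numpy(float)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    x = x[:, sd > 0] / sd[sd > 0]
    scores, _ = _pca_scores(x, n_pcs)
    cols = [f"pc{i + 1}" for i in range(n_pcs)]
    return pd.DataFrame(scores, index=gm.samples, columns=cols)


def _scree_elbow(eigenvalues: np.ndarray, method: str = "gap", dominance: float = 10.0) -> int:
    """Elbow of a descending scree curve (1-based component count).

    ``gap`` (default): the component count is the position of the largest
    eigenvalue gap, provided that gap dominates the spectrum (at least
    ``dominance`` times the median gap); otherwise the scree is treated
    as structureless and a single component is kept. This keeps the
    selected count at the signal/noise boundary and is robust to the
    smooth bulk-eigenvalue decay of pure-noise matrices.

    ``distance``: classic chord rule — the point of maximum perpendicular
    distance to the line joining the first and last scree points (axes
    rescaled to [0, 1]). Kept for comparison; on noise-dominated data it
    lands deep inside the eigenvalue bulk.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if len(lam) < 2 or np.allclose(lam, lam[0]):
        warnings.warn("degenerate scree; selecting a single component", stacklevel=2)
        return 1
    if method == "distance":
        x = np.linspace(0.0, 1.0, len(lam))
        y = (lam - lam[-1]) / (lam[0] - lam[-1])
        dist = np.abs((y[-1] - y[0]) * x - y + y[0])
        return int(np.argmax(dist)) + 1
    if method != "gap":
        raise ValueError("method must be 'gap' or 'distance'")
    gaps = lam[:-1] - lam[1:]
    med = np.median(gaps)
    if med > 0 and gaps.max() < dominance * med:
        return 1
    return int(np.argmax(gaps)) + 1


def select_methylation_pcs(
    m_values: pd.DataFrame,
    max_components: int | None = None,
    method: str = "gap",
) -> tuple[pd.DataFrame, int]:
    """PCA across samples of a CpG x sample M-value matrix; number of
    components L chosen by the scree-curve elbow (see ``_scree_elbow``).
    Returns the L score columns (samples x L) and L."""
    if m_values.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = m_values.to_numpy(float).T  # samples x cpgs
    x = x - x.mean(axis=0)
    scores, eig = _pca_scores(x, x.shape[0])
    n_avail = min(x.shape[0] - 1, x.shape[1])
    eig = eig[:n_avail]
    if max_components is not None:
        eig = eig[:max_components]
    tol = eig[0] * 1e-12 if len(eig) else 0.0
    nonzero = eig > tol
    if nonzero.sum() <= 1:
        ell = 1
    else:
        ell = _scree_elbow(eig[nonzero], method=method)
    cols = [f"mpc{i + 1}" for i in range(ell)]
    return pd.DataFrame(scores[:, :ell], index=m_values.columns, columns=cols), ell


# ---------------------------------------------------------------------------
# covariates


@dataclass
class CovariateSet:
    """Per-sample covariates entering the mapping model: age, sex, top
    genetic PCs and L methylation PCs. Zero-variance columns are removed;
    missing values are rejected."""

    table: pd.DataFrame

    @property
    def columns(self) -> list[str]:
        return list(self.table.columns)


def assemble_covariates(
    base: pd.DataFrame,
    genetic_pcs: pd.DataFrame | None = None,
    methylation_pcs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join age/sex with PC scores, dropping zero-variance columns."""
    parts = [base]
    if genetic_pcs is not None:
        parts.append(genetic_pcs)
    if methylation_pcs is not None:
        parts.append(methylation_pcs)
    table = pd.concat(parts, axis=1)
    if table.isna().any().any():
        bad = list(table.columns[table.isna().any()])
        raise ValueError(f"covariates contain missing values: {bad}")
    keep = table.std(axis=0, ddof=0) > 0
    dropped = list(table.columns[~keep])
    if dropped:
        logger.info("dropping zero-variance covariates: %s", dropped)
    return table.loc[:, keep]
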