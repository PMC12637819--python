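"""Enumeration-based colocalization of two summary-statistic tracks.

Each variant's evidence for association with a trait is a Wakefield
approximate Bayes factor computed from the effect estimate and its
standard error under a N(0, W) effect prior. Assuming at most one causal
variant per trait, the five hypotheses — H0 neither trait associated, H1
trait 1 only, H2 trait 2 only, H3 both but distinct causal variants, H4
one shared causal variant — have unnormalized weights

    H0 = 1
    H1 = p1 * sum_i ABF1_i
    H2 = p2 * sum_j ABF2_j
    H3 = p1 * p2 * (sum_i ABF1_i * sum_j ABF2_j - sum_i ABF1_i * ABF2_i)
    H4 = p12 * sum_i ABF1_i * ABF2_i

with per-variant priors (p1, p2, p12). Posteriors PP0..PP4 are these
weights normalized. All arithmetic is in log space (ABFs overflow the
double range beyond |z| ~ 40).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)
PRIOR_SD_QUANT = 0.15
PRIOR_SD_CC = 0.2


@dataclass(frozen=True)
class ColocPriors:
    p1: float
    p2: float
    p12: float

    def __post_init__(self) -> None:
        if min(self.p1, self.p2, self.p12) <= 0:
            raise ValueError("priors must be > 0")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")


def derive_priors(
    n_total_variants: float,
    n_trait1_variants: float,
    n_trait2_variants: float,
    n_shared: float,
) -> ColocPriors:
    """Biologically informed per-variant priors from genome-wide counts.

    With N variants genome-wide of which n1 regulate trait 1, n2 regulate
    trait 2 and s regulate both: p1 = (n1 - s)/N, p2 = (n2 - s)/N,
    p12 = s/N.
    """
    if n_shared > min(n_trait1_variants, n_trait2_variants):
        raise ValueError("n_shared cannot exceed either trait's variant count")
    if n_total_variants <= n_trait1_variants + n_trait2_variants:
        raise ValueError("n_total must exceed the sum of trait variant counts")
    return ColocPriors(
        p1=(n_trait1_variants - n_shared) / n_total_variants,
        p2=(n_trait2_variants - n_shared) / n_total_variants,
        p12=n_shared / n_total_variants,
    )


def wakefield_log_abf(effect, se, prior_sd: float = PRIOR_SD_QUANT):
    """Log approximate Bayes factor for one association.

    With z = effect/se and V = se^2:
    log ABF = 0.5 * log(V / (V + W)) + 0.5 * z^2 * W / (V + W), W = prior_sd^2.
    """
    effect = np.asarray(effect, float)
    se = np.asarray(se, float)
    if np.any(~np.isfinite(effect)) or np.any(~np.isfinite(se)):
        raise ValueError("effect and se must be finite")
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be > 0")
    v = se**2
    w = prior_sd**2
    z = effect / se
    r = w / (v + w)
    return 0.5 * np.log(v / (v + w)) + 0.5 * z**2 * r


def se_from_pvalue(p, maf, n, trait_type: str = "quant"):
    """Reconstruct effect SE from p, MAF and N for ABF computation.

    Uses the asymptotic identity Var(beta_hat) ~ 1 / (2 * maf * (1-maf) * n)
    for a standardized quantitative trait; the z-score then sets the
    implied |effect| = |z| * se.
    """
    from scipy import stats

    p = np.asarray(p, float)
    maf = np.asarray(maf, float)
    n = np.asarray(n, float)
    se = np.sqrt(1.0 / (2.0 * maf * (1.0 - maf) * n))
    z = stats.norm.isf(p / 2.0)
    return z * se, se


@dataclass
class ColocResult:
    pp: np.ndarray  # PP0..PP4
    n_variants: int
    priors: ColocPriors

    def __post_init__(self) -> None:
        if not np.isclose(self.pp.sum(), 1.0, atol=1e-9):
            raise ValueError("posterior probabilities must sum to 1")

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    def as_series(self) -> pd.Series:
        return pd.Series(self.pp, index=[f"PP{i}" for i in range(5)])


def harmonize_tracks(
    stats1: pd.DataFrame, stats2: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align two tracks on (chrom, pos), flipping track-2 signs when
    ref/alt are swapped; unresolvable allele pairs are dropped with a
    logged count."""
    merged = stats1.merge(stats2, on=["chrom", "pos"], suffixes=("_1", "_2"))
    same = (merged["ref_1"] == merged["ref_2"]) & (merged["alt_1"] == merged["alt_2"])
    swapped = (merged["ref_1"] == merged["alt_2"]) & (merged["alt_1"] == merged["ref_2"])
    keep = same | swapped
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d variants with unresolvable alleles", n_dropped)
    merged = merged[keep].copy()
    merged.loc[swapped[keep], "beta_2"] *= -1.0
    t1 = merged[["chrom", "pos", "beta_1", "se_1"]].rename(
        columns={"beta_1": "beta", "se_1": "se"}
    )
    t2 = merged[["chrom", "pos", "beta_2", "se_2"]].rename(
        columns={"beta_2": "beta", "se_2": "se"}
    )
    return t1, t2


def coloc_enumerate(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    priors: ColocPriors | tuple = DEFAULT_PRIORS,
    prior_sd1: float = PRIOR_SD_QUANT,
    prior_sd2: float = PRIOR_SD_QUANT,
    harmonize: bool = True,
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    ``stats1`` / ``stats2`` need columns ``beta`` and ``se`` (plus
    ``chrom``/``pos``/``ref``/``alt`` when ``harmonize``).
    """
    if not isinstance(priors, ColocPriors):
        priors = ColocPriors(*priors)
    if harmonize:
        stats1, stats2 = harmonize_tracks(stats1, stats2)
    if len(stats1) == 0:
        raise ValueError("zero shared variants after harmonization")
    if len(stats1) != len(stats2):
        raise ValueError("tracks must cover the same variants")
    l1 = wakefield_log_abf(stats1["beta"].to_numpy(), stats1["se"].to_numpy(), prior_sd1)
    l2 = wakefield_log_abf(stats2["beta"].to_numpy(), stats2["se"].to_numpy(), prior_sd2)
    return posterior_from_log_abfs(l1, l2, priors)


def posterior_from_log_abfs(
    l1: np.ndarray, l2: np.ndarray, priors: ColocPriors | tuple = DEFAULT_PRIORS
) -> ColocResult:
    """Hypothesis posteriors from per-variant log ABFs of the two traits."""
    if not isinstance(priors, ColocPriors):
        priors = ColocPriors(*priors)
    l1 = np.asarray(l1, float)
    l2 = np.asarray(l2, float)
    if len(l1) != len(l2) or len(l1) == 0:
        raise ValueError("need matching, nonempty ABF vectors")
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(priors.p1) + s1
    lh[2] = np.log(priors.p2) + s2
    if len(l1) > 1:
        # log(exp(s1 + s2) - exp(s12)), clipped at -inf for the 1-variant case
        big, small = s1 + s2, s12
        diff = -np.inf if small >= big else big + np.log1p(-np.exp(small - big))
        lh[3] = np.log(priors.p1) + np.log(priors.p2) + diff
    else:
        lh[3] = -np.inf
    lh[4] = np.log(priors.p12) + s12
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(pp=pp, n_variants=len(l1), priors=priors)


def classify_colocalized(
    results: pd.DataFrame, threshold: float = 0.5
) -> pd.DataFrame:
    """Flag colocalized locus pairs (strict PP4 > threshold) and mark, per
    CpG, the partner with the highest PP4 as the top colocalization.

    ``results`` needs columns ``cpg_id``, ``partner_id``, ``PP4``.
    """
    out = results.copy()
    out["colocalized"] = out["PP4"] > threshold
    out["is_top"] = False
    for _, sub in out.groupby("cpg_id"):
        best = sub["PP4"].idxmax()
        out.loc[best, "is_top"] = True
    return out


def coloc_cross_tabulation(
    eqtl_calls: pd.DataFrame, gwas_calls: pd.DataFrame
) -> pd.Series:
    """Cross-tabulate imQTLs by whether they colocalize with an eQTL, a
    GWAS trait, both, or neither (any colocalized partner counts)."""
    e = eqtl_calls.groupby("cpg_id")["colocalized"].any()
    g = gwas_calls.groupby("cpg_id")["colocalized"].any()
    ids = e.index.union(g.index)
    e = e.reindex(ids, fill_value=False)
    g = g.reindex(ids, fill_value=False)
    return pd.Series(
        {
            "eqtl_only": int((e & ~g).sum()),
            "gwas_only": int((~e & g).sum()),
            "both": int((e & g).sum()),
            "neither": int((~e & ~g).sum()),
        }
    )
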