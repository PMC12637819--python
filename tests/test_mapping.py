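"""Interaction/marginal scans, filters, EMT arithmetic, secondary signals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import statsmodels.api as sm

from imqtl import mapping
from imqtl.containers import GenotypeMatrix, MethylationMatrix
from imqtl.mapping import (
    conditional_secondary_scan,
    emt_estimate,
    fit_interaction_model,
    map_interaction_mqtls,
    pleiotropy_count,
    stratified_maf_filter,
)
from imqtl.preprocess import rank_inverse_normal
from imqtl.sim import (
    PlantedEffect,
    SimulationConfig,
    simulate_genotypes,
    simulate_study,
)
from conftest import make_proportions


def _gm_from_dosages(dos: np.ndarray, positions=None, ids=None) -> GenotypeMatrix:
    n, m = dos.shape
    ids = ids or [f"v{i}" for i in range(m)]
    positions = positions if positions is not None else (np.arange(m) + 1) * 1000
    variants = pd.DataFrame(
        {"chrom": "1", "pos": positions, "ref": "A", "alt": "G"},
        index=pd.Index(ids, name="variant_id"),
    )
    samples = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")
    return GenotypeMatrix(pd.DataFrame(dos.astype(float), index=samples, columns=ids), variants)


class TestStratifiedMAF:
    def test_minor_allele_confined_to_lower_half_removed(self):
        n = 100
        prop = np.linspace(0, 1, n)
        dos = np.zeros((n, 1))
        dos[:20, 0] = 1.0  # carriers only among low-proportion samples
        gm = _gm_from_dosages(dos)
        props = pd.Series(prop, index=gm.samples)
        mask = stratified_maf_filter(gm, props)
        assert not mask.iloc[0]

    def test_common_variant_kept(self, rng):
        n = 200
        dos = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        gm = _gm_from_dosages(dos)
        props = pd.Series(rng.random(n), index=gm.samples)
        assert stratified_maf_filter(gm, props).iloc[0]

    def test_matches_brute_force_recount(self, rng):
        n, m = 150, 40
        dos = rng.binomial(2, rng.uniform(0.05, 0.5, m), size=(n, m)).astype(float)
        gm = _gm_from_dosages(dos)
        prop = pd.Series(rng.random(n), index=gm.samples)
        mask = stratified_maf_filter(gm, prop)
        med = np.median(prop)
        lower = prop.to_numpy() <= med
        for v in range(m):
            mafs = []
            for half in (lower, ~lower):
                p = dos[half, v].mean() / 2
                mafs.append(min(p, 1 - p))
            assert mask.iloc[v] == (min(mafs) > 0.1)

    def test_too_few_samples_rejected(self):
        gm = _gm_from_dosages(np.zeros((3, 1)))
        with pytest.raises(ValueError):
            stratified_maf_filter(gm, pd.Series([0.1, 0.2, 0.3], index=gm.samples))


class TestInteractionFit:
    def test_matches_statsmodels_ols(self, rng):
        n = 120
        g = rng.binomial(2, 0.3, n).astype(float)
        c = rank_inverse_normal(rng.random(n))
        covars = pd.DataFrame({"age": rng.normal(50, 10, n), "sex": rng.integers(0, 2, n)})
        y = 0.1 * g + 0.2 * c + 0.3 * g * c + rng.normal(size=n)
        fit = fit_interaction_model(y, g, c, covars)
        X = sm.add_constant(
            np.column_stack([c, covars["age"], covars["sex"], g, g * c])
        )
        ref = sm.OLS(y, X).fit()
        assert fit["beta_gxc"] == pytest.approx(ref.params[-1], rel=1e-10)
        assert fit["se_gxc"] == pytest.approx(ref.bse[-1], rel=1e-10)
        assert fit["p_gxc"] == pytest.approx(ref.pvalues[-1], rel=1e-8)
        assert fit["beta_main"] == pytest.approx(ref.params[-2], rel=1e-10)
        assert fit["beta_cell"] == pytest.approx(ref.params[1], rel=1e-10)

    def test_null_interaction_pvalues_uniform(self):
        # clean null: shared baselines; 5 studies x 1,000 pair fits
        ps = []
        for s in range(5):
            cfg = SimulationConfig(
                n_samples=150, n_variants=200, n_cpgs=10,
                cell_types=("a", "b"), dirichlet_alpha=(1.0, 1.0),
                celltype_baseline_sd=0.0, maf_range=(0.15, 0.5), seed=100 + s,
            )
            study = simulate_study(cfg)
            res = map_interaction_mqtls(
                study.genotypes, study.bulk, study.true_proportions, "a",
                covariates=study.covariates, cis_window=10**9,
            )
            ps.append(res.records["p_gxc"].to_numpy())
        allp = np.concatenate(ps)
        assert len(allp) >= 5000
        assert stats.kstest(allp, "uniform").pvalue > 0.01


class TestEMT:
    def test_identical_columns_collapse_to_one(self, rng):
        g = rng.binomial(2, 0.4, size=(80, 1)).astype(float)
        assert emt_estimate(np.tile(g, (1, 7))) == 1

    def test_independent_variants_close_to_m(self, rng):
        m = 30
        g = rng.binomial(2, 0.4, size=(3000, m)).astype(float)
        m_eff = emt_estimate(g)
        assert abs(m_eff - m) <= 0.1 * m

    def test_constant_column_excluded_with_warning(self, rng):
        g = np.column_stack([np.ones(50), rng.binomial(2, 0.4, 50)]).astype(float)
        with pytest.warns(UserWarning, match="constant"):
            assert emt_estimate(g) == 1

    def test_bounds(self, rng):
        g = rng.binomial(2, 0.3, size=(100, 12)).astype(float)
        m_eff = emt_estimate(g)
        assert 1 <= m_eff <= 12


class TestScanArithmetic:
    def _one_pair_study(self, seed=0):
        cfg = SimulationConfig(
            n_samples=120, n_variants=1, n_cpgs=1,
            cell_types=("a", "b"), dirichlet_alpha=(1.0, 1.0), seed=seed,
        )
        return simulate_study(cfg)

    def test_single_variant_single_cpg_pfinal_is_raw(self):
        study = self._one_pair_study()
        res = map_interaction_mqtls(
            study.genotypes, study.bulk, study.true_proportions, "a",
            covariates=study.covariates,
        )
        lead = res.leads.iloc[0]
        assert lead["m_eff"] == 1
        assert lead["p_emt"] == pytest.approx(lead["p_gxc"])
        assert lead["p_bonf"] == pytest.approx(lead["p_gxc"])

    def test_perfectly_correlated_variants_no_penalty(self):
        study = self._one_pair_study(seed=1)
        g = study.genotypes.dosages.iloc[:, 0].to_numpy()
        dup = _gm_from_dosages(
            np.tile(g[:, None], (1, 5)),
            positions=study.genotypes.variants["pos"].iloc[0] + np.arange(5),
        )
        res = map_interaction_mqtls(
            dup, study.bulk, study.true_proportions, "a",
            covariates=study.covariates,
        )
        lead = res.leads.iloc[0]
        assert lead["m_eff"] == 1
        assert lead["p_emt"] == pytest.approx(res.records["p_gxc"].min())

    def test_adjustment_monotonicity(self, small_study):
        res = map_interaction_mqtls(
            small_study.genotypes, small_study.bulk,
            small_study.true_proportions, "epithelial",
            covariates=small_study.covariates,
        )
        for _, lead in res.leads.iterrows():
            p_min = res.records.loc[
                res.records["cpg_id"] == lead["cpg_id"], "p_gxc"
            ].min()
            assert lead["p_emt"] >= p_min - 1e-15
            assert lead["p_bonf"] >= lead["p_emt"] - 1e-15

    def test_lead_tiebreak_prefers_proximity_then_id(self):
        study = self._one_pair_study(seed=2)
        g = study.genotypes.dosages.iloc[:, 0].to_numpy()
        cpg_pos = int(study.bulk.positions["pos"].iloc[0])
        # identical genotypes -> identical p; distances 5000 and 100
        dup = _gm_from_dosages(
            np.tile(g[:, None], (1, 2)),
            positions=[cpg_pos - 5000, cpg_pos + 100],
            ids=["far_variant", "near_variant"],
        )
        res = map_interaction_mqtls(
            dup, study.bulk, study.true_proportions, "a",
            covariates=study.covariates,
        )
        assert res.leads.iloc[0]["variant_id"] == "near_variant"

    def test_planted_effect_found_and_significant(self, small_study):
        res = map_interaction_mqtls(
            small_study.genotypes, small_study.bulk,
            small_study.true_proportions, "epithelial",
            covariates=small_study.covariates,
        )
        truth = small_study.truth.iloc[0]
        lead = res.leads.set_index("cpg_id").loc[truth["cpg_id"]]
        assert lead["variant_id"] == truth["variant_id"]
        assert lead["is_significant"]
        assert np.sign(lead["beta_gxc"]) == np.sign(truth["beta"])

    def test_cpg_without_cis_variants_reported_skipped(self):
        study = self._one_pair_study(seed=3)
        far = study.bulk.positions.copy()
        far["pos"] = far["pos"] + 10_000  # move the CpG outside the window
        bulk = MethylationMatrix(study.bulk.values, far)
        res = map_interaction_mqtls(
            study.genotypes, bulk, study.true_proportions, "a",
            covariates=study.covariates, cis_window=100,
        )
        assert res.skipped_cpgs == list(bulk.cpgs)
        assert res.n_cpgs_tested == 0


class TestVectorizedEquivalence:
    def test_scan_matches_per_pair_lstsq(self, small_study):
        """Fast-path records equal an independent per-pair least-squares
        oracle to 1e-8 relative error."""
        from imqtl.preprocess import prepare_response

        res = map_interaction_mqtls(
            small_study.genotypes, small_study.bulk,
            small_study.true_proportions, "epithelial",
            covariates=small_study.covariates,
        )
        response = prepare_response(small_study.bulk.values)
        c = np.asarray(
            rank_inverse_normal(small_study.true_proportions["epithelial"]), float
        )
        cov = small_study.covariates
        rng = np.random.default_rng(1)
        sample = res.records.sample(min(len(res.records), 200), random_state=1)
        for _, row in sample.iterrows():
            y = response.loc[row["cpg_id"]].to_numpy()
            g = small_study.genotypes.dosages[row["variant_id"]].to_numpy()
            X = np.column_stack(
                [np.ones(len(y)), c, cov["age"], cov["sex"], g, g * c]
            )
            b = np.linalg.lstsq(X, y, rcond=None)[0]
            resid = y - X @ b
            s2 = resid @ resid / (len(y) - X.shape[1])
            se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
            assert row["beta_gxc"] == pytest.approx(b[-1], rel=1e-8)
            assert row["se_gxc"] == pytest.approx(se[-1], rel=1e-8)
            assert row["beta_main"] == pytest.approx(b[-2], rel=1e-8)
            assert row["beta_cell"] == pytest.approx(b[1], rel=1e-8)


class TestSecondarySignals:
    def _two_signal_study(self, seed=0):
        cfg = SimulationConfig(
            n_samples=800, n_variants=20, n_cpgs=1,
            cell_types=("a", "b"), dirichlet_alpha=(1.0, 1.0),
            effect_table=[
                PlantedEffect(0, 4, "a", 0.4),
                PlantedEffect(0, 15, "a", 0.4),
            ],
            seed=seed,
        )
        return simulate_study(cfg)

    def test_second_planted_signal_recovered(self):
        study = self._two_signal_study(seed=5)
        res = map_interaction_mqtls(
            study.genotypes, study.bulk, study.true_proportions, "a",
            covariates=study.covariates,
        )
        lead = res.leads.iloc[0]
        cands = conditional_secondary_scan(
            lead, study.genotypes, study.bulk, study.true_proportions,
            covariates=study.covariates,
        )
        planted = set(study.truth["variant_id"])
        other = planted - {lead["variant_id"]}
        assert other <= set(cands["variant_id"])

    def test_single_signal_yields_no_secondaries(self):
        clean = 0
        for s in range(10):
            cfg = SimulationConfig(
                n_samples=500, n_variants=15, n_cpgs=1,
                cell_types=("a", "b"), dirichlet_alpha=(1.0, 1.0),
                effect_table=[PlantedEffect(0, 7, "a", 0.4)],
                seed=200 + s,
            )
            study = simulate_study(cfg)
            res = map_interaction_mqtls(
                study.genotypes, study.bulk, study.true_proportions, "a",
                covariates=study.covariates,
            )
            cands = conditional_secondary_scan(
                res.leads.iloc[0], study.genotypes, study.bulk,
                study.true_proportions, covariates=study.covariates,
            )
            clean += int(len(cands) == 0)
        assert clean >= 9

    def test_candidate_identical_to_lead_skipped(self):
        study = self._two_signal_study(seed=6)
        g = study.genotypes.dosages.to_numpy()
        dup = np.column_stack([g, g[:, 4]])
        pos = np.append(
            study.genotypes.variants["pos"].to_numpy(),
            study.genotypes.variants["pos"].iloc[4] + 1,
        )
        order = np.argsort(pos)
        gm = _gm_from_dosages(dup[:, order], positions=pos[order])
        res = map_interaction_mqtls(
            gm, study.bulk, study.true_proportions, "a",
            covariates=study.covariates,
        )
        lead = res.leads.iloc[0]
        cands = conditional_secondary_scan(
            lead, gm, study.bulk, study.true_proportions,
            covariates=study.covariates,
        )
        # the duplicate of the lead must never appear as a candidate
        lead_g = gm.dosages[lead["variant_id"]].to_numpy()
        for vid in cands["variant_id"]:
            r = np.corrcoef(gm.dosages[vid].to_numpy(), lead_g)[0, 1]
            assert r**2 < 1 - 1e-10


class TestPleiotropy:
    def test_planted_multi_cpg_variant_counted(self):
        cfg = SimulationConfig(
            n_samples=600, n_variants=10, n_cpgs=6,
            cell_types=("a", "b"), dirichlet_alpha=(1.0, 1.0),
            effect_table=[PlantedEffect(j, 3, "a", 0.4) for j in range(3)],
            seed=9,
        )
        study = simulate_study(cfg)
        res = map_interaction_mqtls(
            study.genotypes, study.bulk, study.true_proportions, "a",
            covariates=study.covariates, cis_window=10**9,
        )
        vid = study.genotypes.variants.index[3]
        count = pleiotropy_count(vid, res.records)
        assert count == 3

    def test_matches_brute_force_recount(self, small_study):
        res = map_interaction_mqtls(
            small_study.genotypes, small_study.bulk,
            small_study.true_proportions, "epithelial",
            covariates=small_study.covariates,
        )
        for vid in res.records["variant_id"].unique()[:5]:
            brute = len(
                {
                    c
                    for _, r in res.records.iterrows()
                    if r["variant_id"] == vid and r["p_gxc"] < 1e-4
                    for c in [r["cpg_id"]]
                }
            )
            assert pleiotropy_count(vid, res.records) == brute

    def test_variant_without_hits_counts_zero(self):
        records = pd.DataFrame(
            {"variant_id": ["v1"], "cpg_id": ["cg1"], "p_gxc": [0.5]}
        )
        assert pleiotropy_count("v1", records) == 0
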