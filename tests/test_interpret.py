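"""imQTL classification, cell-type specificity, sharing, replication."""

import numpy as np
import pandas as pd
import pytest

from imqtl.interpret import (
    call_cell_type_specific,
    classify_directional_consistency,
    consistency_summary,
    effect_sharing_matrix,
    harmonize_alleles,
    pair_fits_across_cell_types,
    percent_consistent,
    replicate_imqtls,
    stratified_association,
)
from imqtl.mapping import map_interaction_mqtls
from imqtl.sim import PlantedEffect, SimulationConfig, simulate_study
from conftest import make_proportions


def _imqtl_row(beta_gxc, variant="v1", cpg="cg1", cell_type="a"):
    return {
        "variant_id": variant, "cpg_id": cpg, "cell_type": cell_type,
        "beta_gxc": beta_gxc, "p_gxc": 1e-8,
    }


def _marginal_row(beta, p, variant="v1", cpg="cg1"):
    return {"variant_id": variant, "cpg_id": cpg, "beta_main": beta, "p_main": p}


class TestClassification:
    @pytest.mark.parametrize(
        "beta_marg,p_marg,beta_gxc,expected",
        [
            (0.5, 1e-10, 0.3, "consistent"),
            (0.5, 0.5, 0.3, "unknown"),  # marginal p above 1e-5
            (-0.5, 1e-10, 0.3, "inconsistent"),
        ],
    )
    def test_taxonomy_rules(self, beta_marg, p_marg, beta_gxc, expected):
        out = classify_directional_consistency(
            pd.DataFrame([_imqtl_row(beta_gxc)]),
            pd.DataFrame([_marginal_row(beta_marg, p_marg)]),
        )
        assert out["class"].iloc[0] == expected

    def test_missing_marginal_record_is_unknown(self):
        out = classify_directional_consistency(
            pd.DataFrame([_imqtl_row(0.3)]),
            pd.DataFrame([_marginal_row(0.5, 1e-10, variant="other")]),
        )
        assert out["class"].iloc[0] == "unknown"

    def test_every_imqtl_gets_exactly_one_class(self, rng):
        imqtls = pd.DataFrame(
            [
                _imqtl_row(rng.normal(), variant=f"v{i}", cpg=f"cg{i}")
                for i in range(30)
            ]
        )
        marginal = pd.DataFrame(
            [
                _marginal_row(rng.normal(), 10 ** rng.uniform(-12, 0),
                              variant=f"v{i}", cpg=f"cg{i}")
                for i in range(25)
            ]
        )
        out = classify_directional_consistency(imqtls, marginal)
        assert out["class"].isin(["consistent", "inconsistent", "unknown"]).all()
        assert len(out) == 30

    def test_percentage_from_printed_counts(self):
        assert percent_consistent(505, 587) == 86.0

    def test_summary_counts(self):
        imqtls = pd.DataFrame(
            [_imqtl_row(0.3, variant=f"v{i}", cpg=f"cg{i}") for i in range(4)]
        )
        marginal = pd.DataFrame(
            [
                _marginal_row(0.5, 1e-10, variant="v0", cpg="cg0"),
                _marginal_row(-0.5, 1e-10, variant="v1", cpg="cg1"),
                _marginal_row(0.5, 1e-10, variant="v2", cpg="cg2"),
                _marginal_row(0.5, 0.9, variant="v3", cpg="cg3"),
            ]
        )
        summary = consistency_summary(classify_directional_consistency(imqtls, marginal))
        row = summary.loc["a"]
        assert (row["n_consistent"], row["n_inconsistent"], row["n_unknown"]) == (2, 1, 1)
        assert row["pct_consistent"] == 50.0


class TestSpecificityRule:
    def _fits(self, betas, ps):
        return pd.DataFrame(
            {"beta_gxc": betas, "p_gxc": ps}, index=["a", "b", "c"]
        )

    def _strat(self, slopes, ps, testable=None):
        df = pd.DataFrame({"slope": slopes, "p": ps}, index=["a", "b", "c"])
        df["testable"] = testable if testable is not None else True
        return df

    def test_opposite_signs_and_clean_strata_is_specific(self):
        called, ev = call_cell_type_specific(
            "a",
            self._fits([0.5, -0.2, -0.1], [1e-8, 0.01, 0.2]),
            self._strat([0.4, 0.0, 0.01], [1e-4, 0.8, 0.6]),
        )
        assert called and ev["criterion1"] and ev["criterion2"]

    def test_same_sign_significant_other_fails_criterion1(self):
        called, ev = call_cell_type_specific(
            "a",
            self._fits([0.5, 0.4, -0.1], [1e-8, 0.01, 0.2]),
            self._strat([0.4, 0.0, 0.0], [1e-4, 0.8, 0.9]),
        )
        assert not called and not ev["criterion1"]

    def test_no_other_significant_passes_criterion1_despite_same_sign(self):
        called, _ = call_cell_type_specific(
            "a",
            self._fits([0.5, 0.4, 0.1], [1e-8, 0.3, 0.2]),
            self._strat([0.4, 0.0, 0.0], [1e-4, 0.8, 0.9]),
        )
        assert called

    def test_same_direction_significant_stratum_fails_criterion2(self):
        called, ev = call_cell_type_specific(
            "a",
            self._fits([0.5, -0.2, -0.1], [1e-8, 0.01, 0.2]),
            self._strat([0.4, 0.39, 0.0], [1e-4, 1e-3, 0.9]),
        )
        assert not called and not ev["criterion2"]

    def test_opposite_direction_significant_stratum_allowed(self):
        called, _ = call_cell_type_specific(
            "a",
            self._fits([0.5, -0.2, -0.1], [1e-8, 0.01, 0.2]),
            self._strat([0.4, -0.39, 0.0], [1e-4, 1e-3, 0.9]),
        )
        assert called

    def test_fewer_than_two_cell_types_rejected(self):
        with pytest.raises(ValueError):
            call_cell_type_specific(
                "a",
                pd.DataFrame({"beta_gxc": [0.5], "p_gxc": [1e-8]}, index=["a"]),
                pd.DataFrame({"slope": [0.4], "p": [1e-4]}, index=["a"]),
            )


class TestStratifiedAssociation:
    def test_halves_partition_samples(self, rng):
        n = 60
        y = rng.normal(size=n)
        g = rng.binomial(2, 0.4, n).astype(float)
        prop = pd.Series(rng.random(n))
        up = stratified_association(y, g, prop, "upper")
        lo = stratified_association(y, g, prop, "lower")
        assert up["n"] + lo["n"] == n

    def test_degenerate_proportions_recover_planted_slope(self):
        cfg = SimulationConfig(
            n_samples=600, n_variants=1, n_cpgs=1, noise_sd=0.01,
            cell_types=("a", "b"), dirichlet_alpha=(1.0, 1.0),
            celltype_baseline_sd=0.0, baseline_range=(0.4, 0.6),
            effect_table=[PlantedEffect(0, 0, "a", 0.2)], seed=3,
        )
        from imqtl.sim import simulate_bulk_methylation, simulate_genotypes

        geno = simulate_genotypes(600, 1, seed=3)
        # upper half has pi_a = 1: the planted beta-scale slope is fully exposed
        pi_a = np.concatenate([np.zeros(300), np.ones(300)])
        props = make_proportions(np.column_stack([pi_a, 1 - pi_a]), ("a", "b"))
        study = simulate_bulk_methylation(geno, props, cfg)
        y = study.bulk.values.iloc[0].to_numpy()  # beta scale, untransformed
        g = geno.dosages.iloc[:, 0].to_numpy()
        res = stratified_association(y, g, props["a"], "upper")
        assert res["slope"] == pytest.approx(0.2, abs=0.01)

    def test_monomorphic_genotype_untestable(self, rng):
        n = 40
        res = stratified_association(
            rng.normal(size=n), np.zeros(n), pd.Series(rng.random(n)), "upper"
        )
        assert not res["testable"]

    def test_small_half_rejected(self, rng):
        with pytest.raises(ValueError):
            stratified_association(
                rng.normal(size=10), rng.binomial(2, 0.5, 10).astype(float),
                pd.Series(rng.random(10)), "upper",
            )


class TestEffectSharing:
    def _fits_frame(self, table):
        rows = []
        for pair, cells in table.items():
            for ct, (b, p) in cells.items():
                rows.append(
                    {"pair_id": pair, "cell_type": ct, "beta_gxc": b, "p_gxc": p}
                )
        return pd.DataFrame(rows)

    def test_diagonal_is_one(self):
        fits = self._fits_frame({"p1": {"a": (0.5, 1e-4), "b": (-0.2, 0.2)}})
        share, _ = effect_sharing_matrix(fits)
        assert share.loc["a", "a"] == 1.0 and share.loc["b", "b"] == 1.0

    def test_identical_fitted_tables_share_fully(self):
        fits = self._fits_frame(
            {
                "p1": {"a": (0.5, 1e-4), "b": (0.5, 1e-4)},
                "p2": {"a": (-0.3, 1e-3), "b": (-0.3, 1e-3)},
            }
        )
        share, _ = effect_sharing_matrix(fits)
        assert share.loc["a", "b"] == 1.0 and share.loc["b", "a"] == 1.0

    def test_lineages_cluster_together(self, rng):
        # two lineages (a1,a2) and (b1,b2): effects shared within, not between
        table = {}
        for i in range(40):
            s = rng.choice([-1.0, 1.0])
            table[f"p{i}"] = {
                "a1": (s * 0.5, 1e-5), "a2": (s * 0.4, 1e-4),
                "b1": (-s * 0.5, 1e-5), "b2": (-s * 0.4, 1e-4),
            }
        share, order = effect_sharing_matrix(self._fits_frame(table))
        assert share.loc["a1", "a2"] > share.loc["a1", "b1"]
        assert share.loc["b1", "b2"] > share.loc["b2", "a2"]
        pos = {ct: i for i, ct in enumerate(order)}
        assert abs(pos["a1"] - pos["a2"]) == 1
        assert abs(pos["b1"] - pos["b2"]) == 1

    def test_zero_imqtls_rejected(self):
        empty = pd.DataFrame(columns=["pair_id", "cell_type", "beta_gxc", "p_gxc"])
        with pytest.raises(ValueError):
            effect_sharing_matrix(empty)


class TestReplication:
    def _discovery(self):
        return pd.DataFrame(
            [
                {"variant_id": "v1", "cpg_id": "cg1", "cell_type": "a",
                 "beta_gxc": 0.5, "p_gxc": 1e-8},
                {"variant_id": "v2", "cpg_id": "cg2", "cell_type": "a",
                 "beta_gxc": -0.4, "p_gxc": 1e-7},
            ]
        )

    def test_identical_replication_validates_everything(self):
        disc = self._discovery()
        out = replicate_imqtls(disc, disc)
        assert out["overall_fraction"] == 1.0
        assert out["r_squared"] == pytest.approx(1.0)

    def test_flipped_alleles_harmonized(self):
        disc = self._discovery()
        rep = disc.copy()
        rep["beta_gxc"] = -rep["beta_gxc"]  # replication coded on the other allele
        flip = pd.Series({"v1": -1.0, "v2": -1.0})
        out = replicate_imqtls(disc, rep, sign_flip=flip)
        assert out["overall_fraction"] == 1.0

    def test_untestable_pairs_excluded_from_denominator(self):
        disc = self._discovery()
        rep = disc.iloc[[0]]
        out = replicate_imqtls(disc, rep)
        assert out["n_untestable"] == 1
        assert out["per_cell_type"].loc["a", "n_tested"] == 1

    def test_harmonize_alleles_flags_strand_flips(self):
        d = pd.DataFrame(
            {"variant_id": ["v1"], "chrom": ["1"], "pos": [100],
             "ref": ["A"], "alt": ["G"]}
        )
        r_ok = d.copy()
        r_ok["ref"], r_ok["alt"] = "G", "A"
        assert harmonize_alleles(d, r_ok).loc["v1"] == -1.0
        r_bad = d.copy()
        r_bad["ref"], r_bad["alt"] = "T", "C"
        with pytest.raises(ValueError, match="harmonized"):
            harmonize_alleles(d, r_bad)

    def test_independent_simulations_validate_strong_effects(self):
        from imqtl.sim import simulate_genotypes, simulate_proportions, simulate_bulk_methylation

        frames = []
        positions = (np.arange(5) + 1) * 3000  # shared variant grid
        for seed in (31, 32):
            cfg = SimulationConfig(
                n_samples=1000, n_variants=5, n_cpgs=2,
                cell_types=("a", "b"), dirichlet_alpha=(1.0, 1.0),
                effect_table=[PlantedEffect(0, 2, "a", 0.35)], seed=seed,
            )
            geno = simulate_genotypes(1000, 5, positions=positions, seed=seed)
            props = simulate_proportions(1000, (1.0, 1.0), cell_types=("a", "b"), seed=seed + 50)
            study = simulate_bulk_methylation(geno, props, cfg, seed=seed + 100)
            res = map_interaction_mqtls(
                study.genotypes, study.bulk, study.true_proportions, "a",
                covariates=study.covariates,
            )
            frames.append(res.records)
        # same generative truth, independent samples: the planted pair validates
        disc = frames[0][frames[0]["p_gxc"] < 1e-4]
        out = replicate_imqtls(disc, frames[1])
        assert out["overall_fraction"] > 0.5


def test_pair_fits_convenience_runs(small_study):
    truth = small_study.truth.iloc[0]
    inter, strat = pair_fits_across_cell_types(
        small_study.genotypes, small_study.bulk, small_study.true_proportions,
        truth["variant_id"], truth["cpg_id"], covariates=small_study.covariates,
    )
    assert set(inter.index) == {"epithelial", "stromal"}
    assert np.sign(inter.loc["epithelial", "beta_gxc"]) == np.sign(truth["beta"])
    assert strat.loc["epithelial", "p"] < 0.05
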