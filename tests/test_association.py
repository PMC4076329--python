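"""Phenotype transform, single-SNP association and conditional screening."""

import numpy as np
import pytest
from scipy import stats

from transfinemap import synthetic_data as sd
from transfinemap.association import (
    AssocResult,
    bonferroni_alpha,
    direction_significance,
    exclusion_screen,
    inverse_normal_transform,
    linear_assoc,
    logistic_assoc,
    pairwise_conditional,
)
from transfinemap.errors import DegenerateError, InputError, TransformError

from .conftest import make_panel, make_pheno


class TestInverseNormalTransform:
    def test_three_distinct_values_map_to_symmetric_blom_scores(self):
        out = inverse_normal_transform([5.0, 1.0, 3.0])
        expected = stats.norm.ppf((np.array([3, 1, 2]) - 0.375) / 3.25)
        assert out == pytest.approx(expected)
        assert out[2] == pytest.approx(0.0, abs=1e-12)
        assert out[0] == pytest.approx(-out[1])

    def test_rank_invariance_under_monotone_transform(self, rng):
        x = rng.normal(size=50)
        assert inverse_normal_transform(np.exp(x)) == pytest.approx(
            inverse_normal_transform(x)
        )

    def test_groups_processed_independently(self, rng):
        x = rng.normal(size=40)
        labels = np.repeat([1, 2], 20)
        joint = inverse_normal_transform(x, labels)
        assert joint[:20] == pytest.approx(inverse_normal_transform(x[:20]))
        assert joint[20:] == pytest.approx(inverse_normal_transform(x[20:]))

    def test_mean_near_zero_and_missing_preserved(self, rng):
        x = rng.normal(size=101)
        x[7] = np.nan
        out = inverse_normal_transform(x)
        assert np.isnan(out[7])
        assert abs(np.nansum(out)) < 1e-8 * 101

    def test_small_or_constant_group_raises(self):
        with pytest.raises(TransformError):
            inverse_normal_transform([1.0])
        with pytest.raises(TransformError):
            inverse_normal_transform([2.0, 2.0, 2.0])


class TestLinearAssoc:
    def test_noiseless_planted_effect_recovered_exactly(self):
        eff = sd.EffectConfig(noise_sd=0.0, age_lin=0.0, age_quad=0.0)
        panel, pheno, _ = sd.simulate_clustered_panel(
            400, 1, beta=0.07, eff_cfg=eff, seed=11
        )
        r = linear_assoc("clu1", panel, pheno, transform="none")
        assert r.beta == pytest.approx(0.07, abs=1e-10)

    def test_planted_beta_recovered_within_2se(self):
        panel, pheno, _ = sd.simulate_clustered_panel(
            10_000, 1, beta=0.07, mafs=0.2, seed=13
        )
        r = linear_assoc("clu1", panel, pheno)
        assert abs(r.beta - 0.07) < 2 * r.se

    def test_null_p_uniform_under_permutation(self, rng):
        """Permuting the phenotype yields uniform p over 200 replicates."""
        panel, pheno, _ = sd.simulate_clustered_panel(800, 1, beta=0.0, seed=17)
        ps = []
        for _ in range(200):
            df = pheno.data.copy()
            df["bmi"] = rng.permutation(df["bmi"].values)
            ps.append(linear_assoc("clu1", panel, type(pheno)(df)).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_effect_allele_flip_negates_beta(self):
        panel, pheno, _ = sd.simulate_clustered_panel(500, 1, beta=0.2, seed=19)
        r = linear_assoc("clu1", panel, pheno)
        panel.set_effect_allele("clu1", panel.variant("clu1").other_allele)
        r_flip = linear_assoc("clu1", panel, pheno)
        assert r_flip.beta == pytest.approx(-r.beta)
        assert r_flip.p == pytest.approx(r.p)
        assert r_flip.eaf == pytest.approx(1 - r.eaf)

    def test_degenerate_and_small_inputs_raise(self):
        panel = make_panel(np.ones((20, 1), dtype=int))
        pheno = make_pheno(panel.samples, bmi=np.arange(20.0))
        with pytest.raises(DegenerateError):
            linear_assoc("snp1", panel, pheno)
        small = make_panel([[0], [1], [2]])
        with pytest.raises(InputError):
            linear_assoc(
                "snp1", small, make_pheno(small.samples, bmi=[20.0, 21.0, 22.0])
            )


class TestLogisticAssoc:
    def test_planted_log_or_recovered_within_2se(self):
        panel, pheno, _ = sd.simulate_clustered_panel(
            20_000, 1, beta=0.0, log_or=float(np.log(1.22)), seed=23
        )
        r = logistic_assoc("clu1", panel, pheno)
        assert abs(r.beta - np.log(1.22)) < 2 * r.se

    def test_null_genotype_gives_small_beta(self):
        panel, pheno, _ = sd.simulate_clustered_panel(
            5_000, 1, beta=0.0, log_or=0.0, seed=29
        )
        r = logistic_assoc("clu1", panel, pheno)
        assert abs(r.beta) < 2 * r.se

    def test_matches_closed_form_allelic_or_under_hwe(self):
        """With HWE genotype counts in both strata, the additive logistic
        MLE equals the allelic odds ratio."""
        g = np.concatenate(
            [np.repeat([2, 1, 0], [180, 240, 80]), np.repeat([2, 1, 0], [80, 240, 180])]
        )
        panel = make_panel(g.reshape(-1, 1))
        pheno = make_pheno(
            panel.samples, t2d=["case"] * 500 + ["control"] * 500
        )
        r = logistic_assoc("snp1", panel, pheno, covariates=())
        allelic_or = (0.6 / 0.4) / (0.4 / 0.6)
        assert r.beta == pytest.approx(np.log(allelic_or), abs=1e-8)


class TestDirectionSignificance:
    @pytest.fixture
    def result(self):
        def build(p, beta, effect="A"):
            return AssocResult(
                snp_id="rs1", trait="bmi", effect_allele=effect,
                other_allele="G" if effect == "A" else "A",
                eaf=0.3, beta=beta, se=0.02, p=p, n=1000,
            )
        return build

    def test_significant_when_risk_on_reference(self, result):
        assert direction_significance(result(0.003, 0.05), "A") == "significant"

    def test_not_significant_when_direction_flips(self, result):
        assert direction_significance(result(0.003, 0.05), "G") == "not_significant"
        assert direction_significance(result(0.003, -0.05), "A") == "not_significant"
        assert direction_significance(result(0.003, -0.05), "G") == "significant"

    def test_large_p_never_significant(self, result):
        assert direction_significance(result(0.412, 0.05), "A") == "not_significant"


class TestConditional:
    def test_self_pair_is_indistinguishable(self):
        panel, pheno, _ = sd.simulate_clustered_panel(200, 1, seed=31)
        res = pairwise_conditional("clu1", "clu1", panel, pheno)
        assert res.indistinguishable

    def test_perfect_proxy_pair_is_indistinguishable(self):
        panel, pheno, _ = sd.simulate_clustered_panel(500, 1, 1, proxy_r2=1.0, seed=37)
        res = pairwise_conditional("clu1", "clu1_px1", panel, pheno)
        assert res.indistinguishable

    def test_conditioning_on_independent_partner_equals_marginal(self):
        panel, pheno, _ = sd.simulate_clustered_panel(
            2_000, 2, beta=0.15, seed=41
        )
        marg = linear_assoc("clu1", panel, pheno)
        cond = pairwise_conditional("clu1", "clu2", panel, pheno)
        # same complete-case subset, r^2 ~ 0: conditional ~ marginal
        assert cond.beta_a_given_b == pytest.approx(marg.beta, abs=5e-3)
        assert np.log10(cond.p_a_given_b) == pytest.approx(np.log10(marg.p), abs=0.5)

    def test_two_independent_causal_snps_both_stay_significant(self):
        panel, pheno, _ = sd.simulate_clustered_panel(
            5_000, 2, beta=0.15, causal_cluster=[0, 1], seed=43
        )
        res = pairwise_conditional("clu1", "clu2", panel, pheno)
        assert res.p_a_given_b < 0.05 and res.p_b_given_a < 0.05

    def test_causal_beats_proxy_in_most_replicates(self):
        """Planted causal + r^2=0.6 proxy at n=20,000: the causal stays
        significant given the proxy while the proxy drops, in >= 90% of
        100 seeded replicates."""
        wins = 0
        for seed in range(100):
            panel, pheno, _ = sd.simulate_clustered_panel(
                20_000, 1, 1, proxy_r2=0.6, mafs=0.3, beta=0.15, seed=1000 + seed
            )
            res = pairwise_conditional("clu1", "clu1_px1", panel, pheno)
            if res.p_a_given_b < 0.0056 and res.p_b_given_a > 0.05:
                wins += 1
        assert wins >= 90


class TestExclusionScreen:
    def _make_results(self, pvals):
        """ConditionalResult set from {(a, b): (p_a_given_b, p_b_given_a)}."""
        from transfinemap.association import ConditionalResult

        out = []
        for (a, b), (pab, pba) in pvals.items():
            ind = np.isnan(pab)
            out.append(
                ConditionalResult(a, b, pab, pba, 0.1, 0.1, 100, 0.5, indistinguishable=ind)
            )
        return out

    def test_alpha_default_recomputed_from_input(self):
        assert round(bonferroni_alpha(9), 4) == 0.0056

    def test_universally_dominated_snp_is_excluded(self):
        res = self._make_results(
            {("a", "b"): (0.5, 1e-5), ("a", "c"): (0.6, 1e-4), ("b", "c"): (0.01, 0.02)}
        )
        assert exclusion_screen(res, alpha_adj=0.017) == ["a"]

    def test_mutually_perfect_proxies_exclude_nothing(self):
        res = self._make_results(
            {(a, b): (np.nan, np.nan) for a, b in [("a", "b"), ("a", "c"), ("b", "c")]}
        )
        assert exclusion_screen(res) == []

    def test_incomplete_pair_coverage_raises(self):
        res = self._make_results({("a", "b"): (0.5, 0.001), ("a", "c"): (0.5, 0.001)})
        with pytest.raises(InputError, match="missing"):
            exclusion_screen(res)

    def test_weakest_proxy_excluded_on_planted_panels(self):
        """Causal + two complete proxies + one weak proxy: only the weak
        proxy loses against every (distinguishable) partner."""
        hits = 0
        for seed in range(20):
            panel, pheno, _ = sd.simulate_clustered_panel(
                20_000, 1, 3, proxy_r2=[1.0, 1.0, 0.4], mafs=0.3, beta=0.15,
                seed=2000 + seed,
            )
            snps = ["clu1", "clu1_px1", "clu1_px2", "clu1_px3"]
            res = [
                pairwise_conditional(a, b, panel, pheno)
                for i, a in enumerate(snps)
                for b in snps[i + 1 :]
            ]
            if exclusion_screen(res) == ["clu1_px3"]:
                hits += 1
        assert hits >= 18
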