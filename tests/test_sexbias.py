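import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from dosagecomp import normalization as norm, sexbias, simulate as sim

from conftest import empty_df_intervals, two_group_design


class TestEstimateDispersion:
    def test_poisson_like_floors_at_zero(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(100, (200, 3)).astype(float)
        b = rng.poisson(100, (200, 3)).astype(float)
        alpha = sexbias.estimate_dispersion(a, b)
        assert (alpha >= 0).all()
        assert np.median(alpha) < 0.01

    def test_hand_computed_moment_formula(self):
        # groups (80,100,120) twice: pooled var 400, pooled mean 100
        a = np.array([[80.0, 100.0, 120.0]])
        b = np.array([[80.0, 100.0, 120.0]])
        alpha = sexbias.estimate_dispersion(a, b)
        assert alpha[0] == pytest.approx((400 - 100) / 100**2)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            sexbias.estimate_dispersion(np.array([[5.0]]), np.array([[4.0, 6.0]]))

    def test_pooled_dispersion_recovers_truth(self):
        rng = np.random.default_rng(1)
        mu = rng.lognormal(4, 1, 3000)[:, None]
        n = 1 / 0.05
        a = rng.negative_binomial(n, n / (n + mu), (3000, 3)).astype(float)
        b = rng.negative_binomial(n, n / (n + mu), (3000, 3)).astype(float)
        assert sexbias.pooled_dispersion(a, b) == pytest.approx(0.05, rel=0.25)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        got = sexbias.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(got, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert sexbias.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        assert np.allclose(sexbias.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sexbias.bh_adjust([0.5, 1.5])

    def test_nan_passthrough(self):
        got = sexbias.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(got[1])
        # the two tested p-values are adjusted with m=2
        assert np.allclose(got[[0, 2]], multipletests([0.01, 0.04], method="fdr_bh")[1])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=500))
    @settings(max_examples=50, deadline=None)
    def test_matches_statsmodels_oracle(self, ps):
        got = sexbias.bh_adjust(ps)
        expected = multipletests(ps, method="fdr_bh")[1]
        assert np.allclose(got, expected)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 1000)
        assert (sexbias.bh_adjust(p) >= p - 1e-12).all()


class TestWaldTest:
    def _counts(self, seed=0, n_genes=400, delta_log2=0.0, alpha=0.02, mean=100.0):
        rng = np.random.default_rng(seed)
        mu_a = np.full((n_genes, 3), mean)
        mu_b = np.full((n_genes, 3), mean * 2**delta_log2)
        n = 1 / alpha
        counts = np.hstack(
            [rng.negative_binomial(n, n / (n + mu_a)), rng.negative_binomial(n, n / (n + mu_b))]
        )
        df = pd.DataFrame(counts, columns=[f"s{i}" for i in range(6)])
        return df, pd.Series(1.0, index=df.columns)

    def test_identical_groups_give_zero_logfc_and_large_p(self):
        counts = pd.DataFrame({f"s{i}": [10, 20, 30] for i in range(6)})
        sf = pd.Series(1.0, index=counts.columns)
        res = sexbias.nb_wald_test(counts, sf, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["pvalue"] > 0.99).all()

    def test_label_swap_negates_logfc_and_keeps_p(self):
        counts, sf = self._counts(seed=4, delta_log2=1.0)
        ab = sexbias.nb_wald_test(counts, sf, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        ba = sexbias.nb_wald_test(counts, sf, ["s3", "s4", "s5"], ["s0", "s1", "s2"])
        assert np.allclose(ab["log2fc"], -ba["log2fc"])
        assert np.allclose(ab["pvalue"], ba["pvalue"])

    def test_zero_group_mean_left_untested(self):
        counts = pd.DataFrame(
            {"s0": [0], "s1": [0], "s2": [0], "s3": [5], "s4": [6], "s5": [7]}
        )
        sf = pd.Series(1.0, index=counts.columns)
        res = sexbias.nb_wald_test(counts, sf, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert np.isnan(res["pvalue"].iloc[0])

    def test_strong_bias_detected_with_high_power(self):
        """4-fold bias at mean 200, dispersion 0.05, n=3: near-complete detection at FDR 5%."""
        powers = []
        for seed in range(20):
            rng = np.random.default_rng(3000 + seed)
            n_null, n_true = 900, 100
            mu = np.full(n_null + n_true, 200.0)
            fc = np.ones(n_null + n_true)
            fc[n_null:] = 4.0
            n = 1 / 0.05
            ca = rng.negative_binomial(n, n / (n + mu[:, None] * np.ones(3)))
            cb = rng.negative_binomial(n, n / (n + (mu * fc)[:, None] * np.ones(3)))
            counts = pd.DataFrame(np.hstack([ca, cb]), columns=[f"s{i}" for i in range(6)])
            sf = pd.Series(1.0, index=counts.columns)
            res = sexbias.nb_wald_test(counts, sf, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
            padj = sexbias.bh_adjust(res["pvalue"].to_numpy())
            powers.append((padj[n_null:] < 0.05).mean())
        assert np.mean(powers) > 0.9

    def test_null_rejection_rate_is_sane(self):
        counts, sf = self._counts(seed=6, n_genes=2000)
        res = sexbias.nb_wald_test(counts, sf, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        rate = (res["pvalue"] < 0.05).mean()
        assert 0.02 < rate < 0.09


class TestClassification:
    def _result(self, log2fc, padj):
        return pd.DataFrame({"log2fc": log2fc, "padj": padj})

    def test_counts_split_by_sign(self):
        res = self._result([-1, -2, 0.5, 1, 2], [0.01, 0.01, 0.5, 0.01, 0.01])
        # A-biased = higher in A = negative log2fc (B over A orientation)
        assert sexbias.classify_sex_bias(res) == (2, 2)

    def test_nothing_significant(self):
        res = self._result([1, -1], [0.5, 0.9])
        assert sexbias.classify_sex_bias(res) == (0, 0)

    def test_alpha_one_counts_all_tested(self):
        res = self._result([1, -1, 2], [0.99, 0.5, 0.7])
        assert sexbias.classify_sex_bias(res, alpha=1.01) == (1, 2)


class TestStudyLevel:
    def test_tra2_transformation_removes_downstream_bias(self):
        """XX-vs-XY calls collapse in tra2-transformed XX vs XY comparisons,
        except for karyotype-linked (roX-like) genes."""
        study = sim.simulate_study(seed=21, n_genes_per_arm=500)
        sf = norm.compute_size_factors(
            study.counts, feature_classes=study.annotation["feature_class"]
        )
        wt = sexbias.sex_bias_table(
            study.counts, study.design, sf,
            group_a={"genotype": "w1118", "karyotype": "XX", "tra2": False},
            group_b={"genotype": "w1118", "karyotype": "XY", "tra2": False},
            label_a="XX", label_b="XY",
        )
        tr = sexbias.sex_bias_table(
            study.counts, study.design, sf,
            group_a={"genotype": "w1118", "karyotype": "XX", "tra2": True},
            group_b={"genotype": "w1118", "karyotype": "XY", "tra2": True},
            label_a="XX", label_b="XY",
        )
        n_wt = sum(sexbias.classify_sex_bias(wt))
        n_tr = sum(sexbias.classify_sex_bias(tr))
        assert n_wt > 20
        assert n_tr < 0.3 * n_wt
        # roX-like upstream genes stay XY-biased after transformation
        # (all but possibly the weakly expressed ones, which fall below the cutoff)
        upstream = study.truth.genes.index[~study.truth.genes["tra2_downstream"]]
        expressed = tr.loc[upstream, "call"] != "untested"
        assert expressed.sum() >= 3
        assert (tr.loc[upstream, "call"][expressed] == "XY-biased").all()
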