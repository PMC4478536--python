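import math

import numpy as np
import pandas as pd
import pytest

from dosagecomp import dosage, normalization as norm, simulate as sim
from dosagecomp.io import ANNOTATION_COLUMNS


def tiny_annotation():
    rows = [
        ("gA", "X", 10, 20, "+", 10, "gene"),
        ("gB", "X", 90, 110, "+", 20, "gene"),   # straddles Df boundary at 100
        ("gC", "3L", 500, 600, "+", 100, "gene"),
        ("gD", "X", 300, 400, "+", 100, "gene"),
    ]
    ann = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    return ann.set_index("feature_id", drop=False).rename_axis(None)


def tiny_dfs():
    dfs = pd.DataFrame(
        [{"df_id": "DfX", "chrom": "X", "start": 0, "end": 100}]
    )
    dfs["extent_bp"] = dfs["end"] - dfs["start"]
    return dfs.set_index("df_id", drop=False).rename_axis(None)


def tiny_design():
    return pd.DataFrame(
        [
            {"sample_id": "df1", "genotype": "DfX/+", "df_id": "DfX", "karyotype": "XX", "tra2": False, "replicate": 1},
            {"sample_id": "wt1", "genotype": "w", "df_id": None, "karyotype": "XX", "tra2": False, "replicate": 1},
            {"sample_id": "m1", "genotype": "w", "df_id": None, "karyotype": "XY", "tra2": False, "replicate": 1},
        ]
    )


class TestAssignDosage:
    def test_containment_straddle_and_male_x(self):
        dose = dosage.assign_dosage(tiny_annotation(), tiny_dfs(), tiny_design())
        assert dose.loc["gA", "df1"] == dosage.DOSE_ONE_DF       # fully inside
        assert (dose.loc["gB"] == dosage.EXCLUDED_STRADDLE).all()  # straddles boundary
        assert dose.loc["gC", "m1"] == dosage.DOSE_TWO           # autosomal gene, XY sample
        assert dose.loc["gA", "wt1"] == dosage.DOSE_TWO
        assert dose.loc["gD", "m1"] == dosage.DOSE_ONE_MALE_X    # X gene in male
        assert dose.loc["gD", "df1"] == dosage.DOSE_TWO          # X gene outside the Df

    def test_unknown_df_chromosome_rejected(self):
        dfs = tiny_dfs()
        dfs.loc["DfX", "chrom"] = "4"
        with pytest.raises(ValueError, match="absent"):
            dosage.assign_dosage(tiny_annotation(), dfs, tiny_design())


class TestBoxStats:
    def test_hand_computed_notch(self):
        bs = dosage.box_stats(np.arange(1, 9))
        assert bs.median == pytest.approx(4.5)
        assert bs.iqr == pytest.approx(3.5)
        assert bs.notch == pytest.approx(1.57 * 3.5 / math.sqrt(8))

    def test_constant_vector(self):
        bs = dosage.box_stats([7, 7, 7])
        assert bs.iqr == 0 and bs.notch == 0 and bs.median == 7

    def test_single_value(self):
        bs = dosage.box_stats([3.5])
        assert bs.median == 3.5 and bs.notch == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dosage.box_stats([])


class TestBootstrapReference:
    def test_constant_values_give_degenerate_ci(self):
        ref, (lo, hi) = dosage.bootstrap_reference(np.full(10, 10.0), seed=0)
        assert (ref, lo, hi) == (10.0, 10.0, 10.0)

    def test_same_seed_reproduces_ci(self):
        rng = np.random.default_rng(1)
        v = rng.lognormal(3, 0.3, 30)
        a = dosage.bootstrap_reference(v, seed=42)
        b = dosage.bootstrap_reference(v, seed=42)
        assert a == b

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            dosage.bootstrap_reference([1.0, 2.0, 3.0])

    def test_ci_covers_generator_median(self):
        """Percentile bootstrap CI contains the true median for >=93% of genes.

        Pool size 100 matches the reference pools of the full design (the
        percentile bootstrap of a median undercovers at much smaller n).
        """
        rng = np.random.default_rng(7)
        n_genes, n_samples = 200, 100
        true_median = 50.0  # lognormal(log 50, 0.4) has median 50
        hits = 0
        for g in range(n_genes):
            v = np.exp(rng.normal(np.log(true_median), 0.4, n_samples))
            _, (lo, hi) = dosage.bootstrap_reference(v, n_boot=2000, seed=g)
            hits += lo <= true_median <= hi
        assert hits / n_genes >= 0.93


class TestGeneCompensation:
    @pytest.mark.parametrize(
        "scale,expected_c", [(0.5, 1.0), (1.0, 2.0), (0.55, 1.1)]
    )
    def test_ratio_and_fold(self, scale, expected_c):
        one_dose = np.full(3, 10.0) * scale
        r, c = dosage.gene_compensation(one_dose, 10.0)
        assert c == pytest.approx(expected_c)
        assert c == pytest.approx(2 * r)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            dosage.gene_compensation([1.0], 0.0)


class TestCompareArms:
    def test_identical_constants_give_p_one(self):
        out = dosage.compare_arms([2.0, 2.0, 2.0], [2.0, 2.0])
        assert out.p_value == 1.0

    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(0)
        hits = 0
        for rep in range(20):
            a = rng.normal(1.1, 0.3, 100)
            b = rng.normal(1.6, 0.3, 100)
            if dosage.compare_arms(a, b).p_value < 0.01:
                hits += 1
        assert hits >= 19

    def test_welch_option(self):
        rng = np.random.default_rng(1)
        a, b = rng.lognormal(0, 0.2, 50), rng.lognormal(0.5, 0.2, 50)
        out = dosage.compare_arms(a, b, method="welch")
        assert out.p_value < 0.01 and out.method == "welch"


class TestExtentCorrelation:
    def _dfs(self, extents):
        dfs = pd.DataFrame(
            {
                "df_id": [f"d{i}" for i in range(len(extents))],
                "chrom": "X",
                "start": 0,
                "end": extents,
                "extent_bp": extents,
            }
        )
        return dfs.set_index("df_id", drop=False).rename_axis(None)

    def test_monotone_relation_gives_rho_one(self):
        extents = [100, 200, 300, 400, 500]
        comp = pd.Series([1.0, 1.1, 1.2, 1.3, 1.4], index=[f"d{i}" for i in range(5)])
        rho, p = dosage.df_extent_correlation(comp, self._dfs(extents))
        assert rho == pytest.approx(1.0)

    def test_reversed_monotone_gives_minus_one(self):
        extents = [100, 200, 300, 400, 500]
        comp = pd.Series([1.4, 1.3, 1.2, 1.1, 1.0], index=[f"d{i}" for i in range(5)])
        rho, _ = dosage.df_extent_correlation(comp, self._dfs(extents))
        assert rho == pytest.approx(-1.0)

    def test_tied_extents_reported_missing(self):
        comp = pd.Series(np.linspace(1, 2, 5), index=[f"d{i}" for i in range(5)])
        rho, p = dosage.df_extent_correlation(comp, self._dfs([100] * 5))
        assert math.isnan(rho) and math.isnan(p)


@pytest.fixture(scope="module")
def table(normalized_study):
    study, sf, expr = normalized_study
    return study, dosage.compensation_table(
        expr, study.design, study.annotation, study.df_intervals,
        count_cutoff=6.0, n_boot=300, seed=0,
    )


class TestStudyLevelCompensation:
    def test_fold_is_twice_ratio_everywhere(self, table):
        _, t = table
        ok = t["ratio"].notna()
        assert np.allclose(t.loc[ok, "compensation"], 2 * t.loc[ok, "ratio"])

    def test_recovers_true_compensation(self, table):
        study, t = table
        hemi = t[(t["kind"] == "hemizygous") & t["passes_cutoff"]]
        assert len(hemi) >= 300
        assert abs(hemi["compensation"].median() - study.config.true_compensation) < 0.05

    def test_controls_center_on_two(self, table):
        _, t = table
        ctrl = t[(t["kind"] == "control") & t["passes_cutoff"]]
        bs = dosage.box_stats(ctrl["compensation"])
        assert abs(bs.median - 2.0) <= bs.notch + 0.02

    def test_control_sets_match_hemizygous_sizes(self, table):
        _, t = table
        hemi = t[(t["kind"] == "hemizygous") & t["passes_cutoff"]]
        ctrl = t[t["kind"] == "control"]
        h = hemi.groupby(["df_id", "class"]).size()
        c = ctrl.groupby(["df_id", "class"]).size()
        common = h.index.intersection(c.index)
        assert len(common) > 20
        assert (h.loc[common] == c.loc[common]).all()

    def test_male_x_is_fully_compensated(self, table):
        study, t = table
        mx = t[(t["kind"] == "male_x") & t["passes_cutoff"]]
        assert abs(mx["compensation"].median() - study.config.male_x_compensation) < 0.07

    def test_arms_indistinguishable_under_equal_truth(self, table):
        _, t = table
        hemi = t[(t["kind"] == "hemizygous") & t["passes_cutoff"]]
        out = dosage.compare_arms(
            hemi.loc[hemi["arm"] == "X", "compensation"],
            hemi.loc[hemi["arm"] == "3L", "compensation"],
        )
        assert out.p_value > 0.001
        assert out.notch_overlap

    def test_no_extent_correlation_under_constant_truth(self, table):
        study, t = table
        per_df = dosage.per_df_median_compensation(t)
        rho, p = dosage.df_extent_correlation(per_df, study.df_intervals)
        assert abs(rho) < 0.5


class TestDfValidationScan:
    def test_true_df_confirmed_and_absent_df_flagged(self):
        study = sim.simulate_study(
            seed=13, absent_df_ids=(sim.ABSENT_DF_DEFAULT,), n_genes_per_arm=300
        )
        sf = norm.compute_size_factors(
            study.counts, feature_classes=study.annotation["feature_class"]
        )
        expr = norm.normalize(study.counts, sf)
        scan = dosage.df_validation_scan(
            expr, study.design, study.annotation, study.df_intervals, count_cutoff=6.0
        )
        assert scan.loc[sim.ABSENT_DF_DEFAULT, "verdict"] == "df_absent"
        others = scan[scan["df_id"] != sim.ABSENT_DF_DEFAULT]
        determinate = others[others["verdict"] != "indeterminate"]
        assert len(determinate) >= 30
        assert (determinate["verdict"] == "df_confirmed").all()

    def test_sparse_df_is_indeterminate(self):
        ann = tiny_annotation()
        dfs = tiny_dfs()
        design = pd.DataFrame(
            [
                {"sample_id": s, "genotype": g, "df_id": d, "karyotype": "XX", "tra2": False, "replicate": r}
                for s, g, d, r in [
                    ("df1", "DfX/+", "DfX", 1), ("df2", "DfX/+", "DfX", 2),
                    ("wt1", "w", None, 1), ("wt2", "w", None, 2),
                ]
            ]
        )
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.poisson(50, (4, 4)).astype(float), index=ann.index, columns=design["sample_id"]
        )
        scan = dosage.df_validation_scan(expr, design, ann, dfs, count_cutoff=6.0)
        assert scan.loc["DfX", "verdict"] == "indeterminate"  # only gA inside
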