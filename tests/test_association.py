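"""Replicate QC, ANOVA, Fisher's LSD and the association pipeline."""

import itertools

import numpy as np
import pytest
from scipy import stats

from delbin.association import (
    PhenotypeRecord,
    associate,
    fisher_lsd,
    one_way_anova,
    parse_phenotype_table,
    qc_mean,
    replicate_cv,
)
from delbin.synthetic_data import PhenotypeConfig, gen_variety_panel


def record(*reps, variety="v", region="R"):
    return PhenotypeRecord(variety=variety, region=region, replicates=tuple(reps))


class TestReplicateCV:
    @pytest.mark.parametrize(
        "values, expected",
        [((100, 100), 0.0), ((100, 110), 6.7343), ((100, 150), 28.2843)],
    )
    def test_known_values(self, values, expected):
        assert replicate_cv(values) == pytest.approx(expected, abs=1e-3)

    def test_needs_positive_mean(self):
        with pytest.raises(ValueError):
            replicate_cv((-5, 5))

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            replicate_cv((100,))


class TestQCMean:
    def test_low_cv_duplicate_passes(self):
        rs = qc_mean(record(100, 105))
        assert rs.qc_status == "pass" and rs.accepted_mean == pytest.approx(102.5)

    def test_retested_record_uses_closest_pair(self):
        rs = qc_mean(record(100, 150, 148))
        assert rs.qc_status == "retested"
        assert rs.accepted_mean == pytest.approx(149.0)

    def test_high_cv_duplicate_fails(self):
        rs = qc_mean(record(100, 150))
        assert rs.qc_status == "fail" and rs.accepted_mean is None

    def test_permutation_invariance(self):
        for reps in itertools.permutations((100.0, 150.0, 148.0)):
            rs = qc_mean(record(*reps))
            assert rs.qc_status == "retested"
            assert rs.accepted_mean == pytest.approx(149.0)

    def test_record_validation(self):
        with pytest.raises(ValueError):
            record(100)
        with pytest.raises(ValueError):
            record(100, -5)


class TestAnova:
    def test_hand_computed_example(self):
        """Groups {1,2,3} and {2,3,4}: SSB 1.5, SSW 4, F = 1.5 on (1, 4) df."""
        res = one_way_anova([[1, 2, 3], [2, 3, 4]])
        assert res.f_statistic == pytest.approx(1.5)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_identical_groups_f_zero(self):
        res = one_way_anova([[5, 5], [5, 5]])
        assert res.f_statistic == 0.0 and res.p_value == 1.0

    def test_zero_within_variance_unequal_means(self):
        res = one_way_anova([[5, 5], [7, 7]])
        assert np.isinf(res.f_statistic) and res.p_value == 0.0

    def test_matches_scipy_f_oneway(self, rng):
        """Cross-check against the independent reference implementation."""
        for _ in range(20):
            groups = [
                rng.normal(700, 80, size=int(rng.integers(3, 40)))
                for _ in range(int(rng.integers(2, 5)))
            ]
            res = one_way_anova(groups)
            ref = stats.f_oneway(*groups)
            assert res.f_statistic == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_two_group_f_equals_t_squared(self, rng):
        """F on two groups equals the pooled-variance t statistic squared."""
        for _ in range(20):
            a = rng.normal(676, 80, size=int(rng.integers(5, 120)))
            b = rng.normal(708, 80, size=int(rng.integers(5, 120)))
            res = one_way_anova([a, b])
            t = stats.ttest_ind(a, b, equal_var=True)
            assert res.f_statistic == pytest.approx(t.statistic**2)
            assert res.p_value == pytest.approx(t.pvalue)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            one_way_anova([[1, 2]])
        with pytest.raises(ValueError):
            one_way_anova([[1], [2, 3]])


class TestFisherLSD:
    def test_close_means_share_letter(self, rng):
        a = rng.normal(700, 80, 50)
        b = a + 1.0
        out = fisher_lsd([a, b], alpha=0.05, labels=["x", "y"])
        assert out["letters"] == {"x": "a", "y": "a"}

    def test_separated_means_get_distinct_letters(self, rng):
        a = rng.normal(600, 10, 50)
        b = rng.normal(700, 10, 50)
        out = fisher_lsd([a, b], alpha=0.05, labels=["lo", "hi"])
        assert out["letters"] == {"lo": "b", "hi": "a"}

    def test_three_groups_two_equal_one_apart(self, rng):
        g1 = rng.normal(600, 15, 200)
        g2 = rng.normal(600, 15, 200)
        g3 = rng.normal(700, 15, 200)
        out = fisher_lsd([g1, g2, g3], alpha=0.05, labels=["a1", "a2", "b1"])
        letters = out["letters"]
        assert letters["a1"] == letters["a2"]
        assert letters["b1"] != letters["a1"]

    def test_single_group_single_letter(self):
        assert fisher_lsd([[1, 2, 3]], labels=["only"])["letters"] == {"only": "a"}

    def test_lsd_threshold_formula(self, rng):
        a = rng.normal(700, 80, 30)
        b = rng.normal(700, 80, 45)
        out = fisher_lsd([a, b], alpha=0.05, labels=["x", "y"])
        anova = out["anova"]
        expected = stats.t.ppf(0.975, anova.df_within) * np.sqrt(
            anova.ms_within * (1 / 30 + 1 / 45)
        )
        assert out["lsd"][("x", "y")] == pytest.approx(expected)


class TestAssociate:
    def test_panel_bookkeeping(self):
        """Default panel: 224 varieties, combined groups 115 and 109."""
        calls, records, _ = gen_variety_panel(seed=5)
        assert len(records) == 224
        result = associate(calls, records)
        combined = {s.allele: s.n for s in result.summaries if s.region == "combined"}
        assert combined == {"TaPod-D1b": 115, "TaPod-D1a": 109}
        assert sum(combined.values()) + result.n_excluded == 224

    def test_group_sizes_sum_in_every_scope(self):
        calls, records, _ = gen_variety_panel(seed=8)
        result = associate(calls, records)
        for region, n_expected in (("YHRVWWR", 147), ("NWWR", 77)):
            ns = [s.n for s in result.summaries if s.region == region]
            assert sum(ns) == n_expected

    def test_planted_effect_recovered(self):
        """The estimated allele effect is unbiased: averaged over panels it
        sits within 2 standard errors of the planted 32 U min^-1 g^-1."""
        cfg = PhenotypeConfig()
        cfg.group_means = {k: (676.0 if "D1a" in k[1] else 708.0) for k in cfg.group_sizes}
        n_panels = 15
        diffs = []
        for seed in range(n_panels):
            calls, records, _ = gen_variety_panel(cfg, seed=seed)
            result = associate(calls, records)
            means = {s.allele: s.mean for s in result.summaries if s.region == "combined"}
            diffs.append(means["TaPod-D1b"] - means["TaPod-D1a"])
        se = 80.0 * np.sqrt(1 / 115 + 1 / 109) / np.sqrt(n_panels)
        assert np.mean(diffs) == pytest.approx(32.0, abs=2 * se)

    def test_ambiguous_and_null_excluded(self):
        calls, records, _ = gen_variety_panel(seed=2)
        names = list(calls)
        calls[names[0]] = "ambiguous"
        calls[names[1]] = "null"
        result = associate(calls, records)
        assert result.n_excluded == 2
        combined = [s for s in result.summaries if s.region == "combined"]
        assert sum(s.n for s in combined) == 222

    def test_missing_genotype_raises(self):
        calls, records, _ = gen_variety_panel(seed=2)
        del calls[records[0].variety]
        with pytest.raises(ValueError, match="no genotype"):
            associate(calls, records)

    def test_single_class_region_skips_test_with_note(self):
        cfg = PhenotypeConfig(
            group_sizes={("R1", "TaPod-D1a"): 10},
            group_means={("R1", "TaPod-D1a"): 700.0},
        )
        calls, records, _ = gen_variety_panel(cfg, seed=3)
        result = associate(calls, records)
        assert result.anova["R1"] is None
        assert any("one allele class" in n for n in result.notes)

    def test_phenotype_table_round_trip(self, tmp_path):
        calls, records, _ = gen_variety_panel(seed=4)
        path = tmp_path / "pheno.csv"
        with open(path, "w") as fh:
            fh.write("variety,region,rep1,rep2,rep3\n")
            for r in records:
                reps = list(r.replicates) + [""] * (3 - len(r.replicates))
                fh.write(f"{r.variety},{r.region},{reps[0]},{reps[1]},{reps[2]}\n")
        again = parse_phenotype_table(path)
        assert len(again) == len(records)
        assert all(
            x.replicates == pytest.approx(y.replicates) for x, y in zip(again, records)
        )


class TestCalibration:
    def test_type_i_error_near_alpha(self):
        """Null panels reject at about the nominal 5% rate (200 seeds)."""
        cfg = PhenotypeConfig()
        cfg.group_means = {k: 700.0 for k in cfg.group_sizes}
        alpha, n_runs = 0.05, 200
        rejections = 0
        for seed in range(n_runs):
            calls, records, _ = gen_variety_panel(cfg, seed=seed)
            result = associate(calls, records)
            if result.anova["combined"].p_value < alpha:
                rejections += 1
        rate = rejections / n_runs
        margin = 3 * np.sqrt(alpha * (1 - alpha) / n_runs)  # ~0.046
        assert abs(rate - alpha) < margin

    def test_planted_effect_detected_at_panel_scale(self):
        """A 32 U min^-1 g^-1 effect at n=115/109 and SD 80 is detected at
        a rate consistent with the closed-form power of the two-sample test."""
        cfg = PhenotypeConfig()
        cfg.group_means = {k: (676.0 if "D1a" in k[1] else 708.0) for k in cfg.group_sizes}
        alpha, n_runs = 0.01, 120
        rejections = 0
        for seed in range(n_runs):
            calls, records, _ = gen_variety_panel(cfg, seed=1000 + seed)
            if associate(calls, records).anova["combined"].p_value < alpha:
                rejections += 1
        rate = rejections / n_runs
        # power of the corresponding z/t test (replicate noise inflates the
        # per-variety SD slightly beyond the between-variety SD of 80)
        se = 80.0 * np.sqrt(1 / 115 + 1 / 109)
        zcrit = stats.norm.ppf(1 - alpha / 2)
        power = stats.norm.sf(zcrit - 32.0 / se)
        margin = 3 * np.sqrt(power * (1 - power) / n_runs) + 0.05
        assert abs(rate - power) < margin
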