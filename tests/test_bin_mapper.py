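"""Chromosome/arm assignment and deletion-bin inference."""

import numpy as np
import pytest

from delbin.bin_mapper import (
    ContradictionError,
    assign_arm,
    assign_chromosome,
    brute_force_bin,
    count_amplified,
    infer_bin,
    map_bins,
)
from delbin.stock_panel import AmplificationMatrix, Call, StockClass
from delbin.synthetic_data import (
    MarkerTruth,
    PanelConfig,
    gen_amplification_matrix,
    gen_stock_panel,
)


def synthetic_matrix(truth, breakpoints=None, seed=0, **errors):
    cfg = PanelConfig() if breakpoints is None else PanelConfig(del_breakpoints=breakpoints)
    panel = gen_stock_panel(cfg)
    return gen_amplification_matrix(panel, truth, seed=seed, **errors)


class TestChromosomeAssignment:
    def test_absent_only_in_7d_nullisomic(self):
        matrix = synthetic_matrix(MarkerTruth("M", "7D", "S", 0.7))
        ca = assign_chromosome(matrix, "M")
        assert ca.chromosome == "7D"

    def test_present_everywhere_is_unresolved(self):
        # marker on an arm with no nullisomic in the panel: restrict NT set
        panel = gen_stock_panel(PanelConfig(nt_chromosomes=["1A", "2B"]))
        matrix = gen_amplification_matrix(panel, MarkerTruth("M", "7D", "S", 0.7))
        ca = assign_chromosome(matrix, "M")
        assert not ca.resolved
        assert "no chromosome signal" in ca.diagnostic

    def test_two_nullisomic_chromosomes_flags_multilocus(self):
        matrix = synthetic_matrix(MarkerTruth("M", "7D", "S", 0.7))
        # corrupt: also absent in the 7A nullisomic
        nt7a = next(
            l for l in matrix.panel.of_class(StockClass.NT)
            if l.nullisomic_chromosome == "7A"
        )
        matrix.calls[("M", nt7a.name)] = Call.ABSENT
        ca = assign_chromosome(matrix, "M")
        assert not ca.resolved
        assert "multi-locus" in ca.diagnostic


class TestArmAssignment:
    def test_short_arm_marker_from_dt_lines(self, cs_matrix):
        """Absence in the Dt line retaining 7DL puts the marker on 7DS."""
        aa = assign_arm(cs_matrix, "P1", "7D")
        assert aa.chromosome_arm == "7DS"

    def test_long_arm_marker_from_dt_lines(self, cs_matrix):
        aa = assign_arm(cs_matrix, "P5", "7A")
        assert aa.chromosome_arm == "7AL"

    def test_present_in_both_dt_lines_unresolved(self, cs_matrix):
        aa = assign_arm(cs_matrix, "P1", "7A")  # P1 amplifies in both 7A Dt lines
        assert not aa.resolved

    def test_no_dt_lines_unresolved(self):
        panel = gen_stock_panel(PanelConfig(dt_chromosomes=["7D"], del_breakpoints={}))
        matrix = gen_amplification_matrix(panel, MarkerTruth("M", "7D", "S", 0.7))
        aa = assign_arm(matrix, "M", "1A")
        assert not aa.resolved and "no Dt lines" in aa.diagnostic


class TestBinInference:
    @pytest.mark.parametrize(
        "marker, chrom, arm, lower, upper",
        [
            ("P1", "7D", "S", 0.61, 1.00),
            ("P2", "7D", "S", 0.61, 1.00),
            ("P3", "7A", "S", 0.73, 0.83),
            ("P4", "7A", "S", 0.73, 0.83),
            ("P5", "7A", "L", 0.40, 0.49),
            ("P6", "7B", "L", 0.40, 0.48),
        ],
    )
    def test_packaged_panel_bins(self, cs_matrix, marker, chrom, arm, lower, upper):
        """The four gene bins implied by the group-7 panel."""
        b = infer_bin(cs_matrix, marker, chrom, arm)
        assert (b.lower_fl, b.upper_fl) == pytest.approx((lower, upper))

    def test_whole_arm_bin_reports_distal_fraction(self, cs_matrix):
        b = infer_bin(cs_matrix, "P1", "7D", "S")
        assert b.distal_fraction == pytest.approx(0.39)
        b2 = infer_bin(cs_matrix, "P3", "7A", "S")
        assert b2.distal_fraction is None

    def test_contradiction_raises_with_pair(self, cs_matrix):
        # flip the most distal amplifying 7AS Del line to absent: its FL
        # (0.83) then exceeds nothing proximal, but flipping a *present*
        # proximal line creates an absent >= present conflict
        matrix = AmplificationMatrix(
            markers=list(cs_matrix.markers),
            panel=cs_matrix.panel,
            calls=dict(cs_matrix.calls),
        )
        matrix.calls[("P3", "CS Del7AS-1")] = Call.ABSENT  # FL 0.89 > 0.83
        with pytest.raises(ContradictionError, match="Del7AS-1"):
            infer_bin(matrix, "P3", "7A", "S")

    def test_tolerant_mode_drops_minimal_calls(self, cs_matrix):
        matrix = AmplificationMatrix(
            markers=list(cs_matrix.markers),
            panel=cs_matrix.panel,
            calls=dict(cs_matrix.calls),
        )
        matrix.calls[("P3", "CS Del7AS-1")] = Call.ABSENT
        b = infer_bin(matrix, "P3", "7A", "S", tolerant=True)
        assert b.dropped_calls == ("CS Del7AS-1",)
        assert (b.lower_fl, b.upper_fl) == pytest.approx((0.73, 0.83))

    def test_missing_calls_are_skipped(self, cs_matrix):
        matrix = AmplificationMatrix(
            markers=list(cs_matrix.markers),
            panel=cs_matrix.panel,
            calls=dict(cs_matrix.calls),
        )
        matrix.calls[("P3", "CS Del7AS-12")] = Call.MISSING  # upper support, FL 0.83
        b = infer_bin(matrix, "P3", "7A", "S")
        assert b.upper_fl == pytest.approx(0.87)  # next amplifying line

    def test_no_del_lines_errors(self, cs_matrix):
        with pytest.raises(ContradictionError, match="no deletion lines"):
            infer_bin(cs_matrix, "P1", "7D", "L")


class TestBruteForceOracle:
    def test_packaged_panel_agreement(self, cs_matrix):
        for marker, chrom, arm in [
            ("P1", "7D", "S"), ("P3", "7A", "S"), ("P5", "7A", "L"), ("P6", "7B", "L"),
        ]:
            fast = infer_bin(cs_matrix, marker, chrom, arm)
            slow = brute_force_bin(cs_matrix, marker, chrom, arm, grid_step=0.001)
            assert slow.lower_fl == pytest.approx(fast.lower_fl, abs=1e-9)
            assert slow.upper_fl == pytest.approx(fast.upper_fl, abs=1e-9)

    def test_single_present_line_hull(self):
        matrix = synthetic_matrix(
            MarkerTruth("M", "7D", "S", 0.3), breakpoints={"7DS": [0.5]}
        )
        b = brute_force_bin(matrix, "M", "7D", "S", grid_step=0.01)
        assert (b.lower_fl, b.upper_fl) == pytest.approx((0.0, 0.5), abs=1e-9)

    def test_oracle_equivalence_on_random_panels(self):
        """infer_bin equals the exhaustive grid hull on 100 random panels."""
        rng = np.random.default_rng(7)
        step = 0.01
        for _ in range(100):
            n_del = int(rng.integers(1, 12))
            # breakpoints on the grid so the hull is exact
            fls = (rng.integers(1, 100, size=n_del) * step).round(9).tolist()
            pos = float(rng.integers(1, 101) * step)
            matrix = synthetic_matrix(
                MarkerTruth("M", "7D", "S", pos), breakpoints={"7DS": fls}
            )
            fast = infer_bin(matrix, "M", "7D", "S")
            slow = brute_force_bin(matrix, "M", "7D", "S", grid_step=step)
            assert slow.lower_fl == pytest.approx(fast.lower_fl, abs=step / 2)
            assert slow.upper_fl == pytest.approx(fast.upper_fl, abs=step / 2)
            assert fast.contains(pos)

    def test_contradictory_panel_raises(self, cs_matrix):
        matrix = AmplificationMatrix(
            markers=list(cs_matrix.markers),
            panel=cs_matrix.panel,
            calls=dict(cs_matrix.calls),
        )
        matrix.calls[("P3", "CS Del7AS-1")] = Call.ABSENT
        with pytest.raises(ContradictionError):
            brute_force_bin(matrix, "P3", "7A", "S")


class TestBinProperties:
    def test_bin_contains_truth_on_error_free_panels(self):
        """Soundness: the inferred bin always contains the true position."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            fls = rng.uniform(0.05, 0.95, size=int(rng.integers(1, 10))).tolist()
            pos = float(rng.uniform(0.01, 1.0))
            matrix = synthetic_matrix(
                MarkerTruth("M", "7B", "L", pos), breakpoints={"7BL": fls}
            )
            assert infer_bin(matrix, "M", "7B", "L").contains(pos)

    def test_adding_del_line_never_widens(self):
        rng = np.random.default_rng(13)
        pos = 0.55
        fls = [0.2, 0.8]
        for _ in range(20):
            wider = infer_bin(
                synthetic_matrix(MarkerTruth("M", "7A", "S", pos), {"7AS": fls}),
                "M", "7A", "S",
            )
            fls_more = fls + [float(rng.uniform(0.05, 0.95))]
            narrower = infer_bin(
                synthetic_matrix(MarkerTruth("M", "7A", "S", pos), {"7AS": fls_more}),
                "M", "7A", "S",
            )
            assert narrower.lower_fl >= wider.lower_fl
            assert narrower.upper_fl <= wider.upper_fl
            fls = fls_more

    def test_flipped_call_never_silently_excludes_truth(self):
        """On a dense error-free panel, one flipped call either leaves the
        bin containing the truth or raises a contradiction."""
        pos = 0.5
        fls = [0.1, 0.3, 0.45, 0.55, 0.7, 0.9]
        base = synthetic_matrix(MarkerTruth("M", "7D", "S", pos), {"7DS": fls})
        del_names = [l.name for l in base.panel.of_class(StockClass.DEL)]
        for name in del_names:
            matrix = AmplificationMatrix(
                markers=["M"], panel=base.panel, calls=dict(base.calls)
            )
            old = matrix.calls[("M", name)]
            matrix.calls[("M", name)] = (
                Call.ABSENT if old is Call.PRESENT else Call.PRESENT
            )
            try:
                b = infer_bin(matrix, "M", "7D", "S")
            except ContradictionError:
                continue
            # a successful inference that excludes truth can only come from a
            # flip at the boundary, where the data genuinely moved the bin
            if not b.contains(pos):
                flipped = base.panel[name].breakpoint_fl
                assert flipped in (0.45, 0.55)


class TestCountsAndReport:
    def test_del_line_amplification_counts(self, cs_matrix):
        assert count_amplified(cs_matrix, "P1", StockClass.DEL) == 35
        assert count_amplified(cs_matrix, "P3", StockClass.DEL) == 31

    def test_empty_matrix_counts_zero(self, cs_panel):
        calls = {("M", n): Call.MISSING for n in cs_panel.names}
        matrix = AmplificationMatrix(markers=["M"], panel=cs_panel, calls=calls)
        assert count_amplified(matrix, "M", StockClass.DEL) == 0

    def test_map_bins_report(self, cs_matrix):
        report = map_bins(cs_matrix)
        assert list(report["marker"]) == ["P1", "P2", "P3", "P4", "P5", "P6"]
        assert (report["status"] == "ok").all()
        p1 = report[report["marker"] == "P1"].iloc[0]
        assert (p1["chromosome"], p1["arm"]) == ("7D", "S")
        assert p1["distal_fraction"] == pytest.approx(0.39)

    def test_map_bins_uses_nt_lines_when_available(self):
        matrix = synthetic_matrix(MarkerTruth("M", "7D", "S", 0.7))
        report = map_bins(matrix)
        row = report.iloc[0]
        assert (row["chromosome"], row["arm"]) == ("7D", "S")
        assert row["status"] == "ok"
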