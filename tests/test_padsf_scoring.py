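from decimal import ROUND_HALF_UP, Decimal
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fluoroscreen as fs
from fluoroscreen.padsf_scoring import find_subtraction_control

from conftest import make_curve


class TestSubtractControl:
    def test_zero_control_is_identity(self, flat_control):
        sample = make_curve(np.linspace(0, 3000, 71))
        out = fs.subtract_control(sample, flat_control)
        np.testing.assert_allclose(out.rfu, sample.rfu)

    def test_constant_control_shifts_down(self):
        sample = make_curve(np.linspace(500, 2500, 71))
        control = make_curve(400.0)
        out = fs.subtract_control(sample, control)
        np.testing.assert_allclose(out.rfu, sample.rfu - 400.0)

    def test_grid_mismatch_raises(self):
        sample = make_curve(np.linspace(0, 1, 71))
        short = fs.MeltCurve(np.arange(25.0, 95.0), np.zeros(70), sample.channel)
        with pytest.raises(fs.ValidationError, match="grid mismatch"):
            fs.subtract_control(sample, short)


class TestSummarizeCurve:
    def test_linear_rise(self, flat_control):
        sample = make_curve(np.linspace(0, 3000, 71))
        s = fs.summarize_curve(sample, flat_control)
        assert (s.f_max, s.f_min, s.t_at_max, s.delta_f) == (3000, 0, 95, 3000)

    def test_constant_curve_has_zero_delta(self):
        s = fs.summarize_curve(make_curve(500.0), make_curve(500.0))
        assert s.delta_f == 0.0
        assert s.f_max == s.f_min == 500.0

    def test_tied_maximum_resolves_to_lowest_temperature(self, flat_control):
        rfu = np.zeros(71)
        rfu[15] = rfu[35] = 1000.0  # 40 and 60 degC
        s = fs.summarize_curve(make_curve(rfu), flat_control)
        assert s.t_at_max == 40.0

    def test_non_finite_value_names_temperature(self, flat_control):
        rfu = np.zeros(71)
        rfu[10] = np.nan
        with pytest.raises(fs.ValidationError, match="35"):
            fs.summarize_curve(make_curve(rfu), flat_control)

    def test_delta_from_subtracted_not_raw(self):
        # raw range is 2900 but the subtracted curve is flat at 100
        sample = make_curve(np.linspace(100, 3000, 71))
        control = make_curve(np.linspace(0, 2900, 71))
        s = fs.summarize_curve(sample, control)
        assert s.delta_f == pytest.approx(0.0, abs=1e-9)
        assert s.f_max == 3000.0


class TestScoreSummary:
    @pytest.mark.parametrize(
        "summary, expected",
        [
            # one worked example per printed rule, plus the catch-all zero
            (fs.CurveSummary(3200, 100, 42, 2800), 10),
            (fs.CurveSummary(3200, 100, 42, 2000), 8),
            (fs.CurveSummary(1500, 100, 42, 1200), 5),
            (fs.CurveSummary(3000, 100, 62, 2900), 3),
            (fs.CurveSummary(3000, 100, 80, 2900), 1),
            (fs.CurveSummary(200, 50, 40, 150), 0),
        ],
    )
    def test_rule_table_worked_examples(self, summary, expected):
        assert fs.score_summary(summary) == expected

    @pytest.mark.parametrize(
        "summary, expected",
        [
            # delta_f band edges are half-open: lower bound in, upper bound out
            (fs.CurveSummary(3200, 100, 42, 2500), 8),
            (fs.CurveSummary(3200, 100, 42, 1500), 8),
            (fs.CurveSummary(3200, 100, 42, 1499.999), 5),
            (fs.CurveSummary(3200, 100, 42, 1000), 5),
            (fs.CurveSummary(3200, 100, 42, 999.999), 0),
            # temperature bands: 55 leaves the early rules, 70 stays with rule 3
            (fs.CurveSummary(3200, 100, 55, 2800), 3),
            (fs.CurveSummary(3200, 100, 70, 2800), 3),
            (fs.CurveSummary(3200, 100, 70.001, 2800), 1),
            # f_min gates: -1000 fails the 10-rule but passes the 8-band
            (fs.CurveSummary(3200, -1500, 42, 2600), 0),
            (fs.CurveSummary(3200, -1500, 42, 2400), 8),
        ],
    )
    def test_rule_boundaries(self, summary, expected):
        assert fs.score_summary(summary) == expected

    def test_totality_and_partition_fuzz(self):
        rng = np.random.default_rng(2024)
        for _ in range(10_000):
            f_min = rng.uniform(-5000, 5000)
            f_max = f_min + rng.uniform(0, 10_000)
            s = fs.CurveSummary(f_max, f_min, rng.uniform(25, 95), rng.uniform(-1000, 6000))
            assert fs.score_summary(s) in fs.SCORE_VALUES

    def test_monotone_in_delta_f(self):
        scores = [
            fs.score_summary(fs.CurveSummary(d, 0, 40, d))
            for d in (900, 1200, 2000, 2600)
        ]
        assert scores == [0, 5, 8, 10]
        assert scores == sorted(scores)

    @given(
        f_max=st.floats(1000.001, 50_000),
        f_min=st.floats(-999.999, 1000),
        t=st.floats(25, 54.999),
        delta=st.floats(2500.001, 50_000),
    )
    @settings(max_examples=300, derandomize=True)
    def test_top_rule_precedence(self, f_max, f_min, t, delta):
        """A summary meeting the score-10 conditions never scores lower."""
        assert fs.score_summary(fs.CurveSummary(f_max, min(f_min, f_max), t, delta)) == 10


class TestScoreWell:
    def test_well_score_is_max_over_channels(self, noise_free_screen):
        run, controls = noise_free_screen.runs[0], noise_free_screen.controls[0]
        table = fs.score_run(run, controls)
        for key, ws in table.entries.items():
            assert ws.well_score == max(ws.channel_scores.values())
            assert ws.channel_scores[ws.best_channel] == ws.well_score

    def test_all_zero_channels_give_zero_well(self, flat_control):
        well = fs.Well("D001", "monomer_WT", "monomer",
                       {"FAM": make_curve(200.0)}, protein_variant="WT")
        controls = fs.ScreenRun("c", 1, [
            fs.Well("D001", "dye_alone", "no_protein", {"FAM": make_curve(200.0)})
        ])
        ws = fs.score_well(well, controls)
        assert ws.well_score == 0

    def test_missing_control_names_the_well(self):
        well = fs.Well("D001", "WT_ind07", "fibril", {"FAM": make_curve(200.0)},
                       protein_variant="WT", inducer_id=7)
        empty_controls = fs.ScreenRun("c", 1, [])
        with pytest.raises(fs.ValidationError, match="D001"):
            fs.score_well(well, empty_controls)

    def test_fibril_pairs_with_matching_polyanion_control(self, noise_free_screen):
        run, controls = noise_free_screen.runs[0], noise_free_screen.controls[0]
        well = next(w for w in run.wells if w.sample_type == "fibril")
        curve = find_subtraction_control(well, controls, "FAM")
        assert curve.channel.name == "FAM"


class TestAggregateAndTriage:
    @staticmethod
    def _table(rep, scores):
        t = fs.ScoreTable(rep)
        for (dye, sample), v in scores.items():
            t.entries[(dye, sample)] = fs.WellScore(dye, sample, {"FAM": v}, v, "FAM")
        return t

    def test_two_top_scores_sum_to_twenty(self):
        r1 = self._table(1, {("D001", "WT_ind07"): 10})
        r2 = self._table(2, {("D001", "WT_ind07"): 10})
        assert fs.aggregate_replicates(r1, r2).entries[("D001", "WT_ind07")] == 20

    def test_aggregation_is_symmetric(self):
        rng = np.random.default_rng(5)
        keys = [(f"D{i:03d}", "WT_ind07") for i in range(20)]
        s1 = {k: int(rng.choice(fs.SCORE_VALUES)) for k in keys}
        s2 = {k: int(rng.choice(fs.SCORE_VALUES)) for k in keys}
        a12 = fs.aggregate_replicates(self._table(1, s1), self._table(2, s2))
        a21 = fs.aggregate_replicates(self._table(2, s2), self._table(1, s1))
        assert a12.entries == a21.entries

    def test_asymmetric_keys_rejected(self):
        r1 = self._table(1, {("D001", "WT_ind07"): 10})
        r2 = self._table(2, {("D002", "WT_ind07"): 10})
        with pytest.raises(fs.ValidationError, match="keys"):
            fs.aggregate_replicates(r1, r2)

    def test_triage_hit_exclusion_and_cutoff(self):
        additive = fs.AdditiveScoreTable({
            ("D001", "WT_ind07"): 20,   # clean hit
            ("D002", "WT_ind07"): 20,   # monomer-reactive
            ("D003", "WT_ind07"): 18,   # below cutoff
        })
        monomer = self._table(1, {
            ("D001", "monomer_WT"): 0,
            ("D002", "monomer_WT"): 10,
            ("D003", "monomer_WT"): 0,
        })
        result = fs.triage_hits(additive, monomer)
        assert [h.dye_id for h in result.hits] == ["D001"]
        assert [h.dye_id for h in result.excluded] == ["D002"]
        assert result.excluded[0].monomer_flag
        assert all(not h.monomer_flag for h in result.hits)

    def test_curated_additions_pass_monomer_filter(self):
        additive = fs.AdditiveScoreTable({
            ("D003", "WT_ind07"): 18, ("D004", "WT_ind07"): 18,
        })
        monomer = self._table(1, {
            ("D003", "monomer_WT"): 0, ("D004", "monomer_WT"): 10,
        })
        result = fs.triage_hits(additive, monomer, curated_additions=["D003", "D004"])
        assert [h.dye_id for h in result.hits] == ["D003"]
        assert result.hits[0].curated
        assert [h.dye_id for h in result.excluded] == ["D004"]

    def test_missing_monomer_dye_raises(self):
        additive = fs.AdditiveScoreTable({("D001", "WT_ind07"): 20})
        with pytest.raises(fs.ValidationError, match="D001"):
            fs.triage_hits(additive, self._table(1, {("D009", "monomer_WT"): 0}))


class TestHitRate:
    @pytest.mark.parametrize("n, total, expected", [
        (30, 306, 9.8),
        (5, 306, 1.6),
        (80, 306, 26.1),
        (148, 306, 48.4),
        (28, 306, 9.2),
        (0, 306, 0.0),
        (306, 306, 100.0),
        (1, 800, 0.1),   # 0.125 -> half-up -> 0.1
        (1, 400, 0.3),   # 0.25  -> half-up -> 0.3
    ])
    def test_printed_and_boundary_rates(self, n, total, expected):
        assert fs.hit_rate(n, total) == expected

    def test_exhaustive_against_decimal_oracle(self):
        """Agreement with an independent Decimal half-up computation."""
        for total in range(1, 1001, 7):  # stride keeps the sweep quick but broad
            for n in range(0, total + 1):
                oracle = float(
                    (Decimal(100 * n) / Decimal(total)).quantize(
                        Decimal("0.1"), rounding=ROUND_HALF_UP
                    )
                )
                assert fs.hit_rate(n, total) == oracle

    def test_domain_errors(self):
        with pytest.raises(fs.ValidationError):
            fs.hit_rate(1, 0)
        with pytest.raises(fs.ValidationError):
            fs.hit_rate(5, 4)


class TestSdActivityCall:
    def test_boundary_is_inclusive(self):
        monomer = [90, 100, 110]  # mean 100, sd 10
        assert fs.sd_activity_call([130, 130], monomer, k=3)

    def test_just_below_threshold_inactive(self):
        monomer = [90, 100, 110]
        assert not fs.sd_activity_call([129.9, 129.9], monomer, k=3)

    def test_degenerate_k_zero_equal_means(self):
        assert fs.sd_activity_call([100, 100], [90, 100, 110], k=0)

    def test_zero_monomer_variance_demands_tolerance(self):
        with pytest.raises(fs.ValidationError, match="tolerance"):
            fs.sd_activity_call([200], [100, 100, 100])


class TestClusterOrder:
    def test_identical_rows_are_adjacent(self):
        additive = fs.AdditiveScoreTable({
            ("A", "s1"): 10, ("A", "s2"): 0,
            ("B", "s1"): 10, ("B", "s2"): 0,
            ("C", "s1"): 0, ("C", "s2"): 20,
        })
        rows, _cols = fs.cluster_order(additive)
        assert abs(rows.index("A") - rows.index("B")) == 1

    def test_single_cell_table_is_identity(self):
        rows, cols = fs.cluster_order(fs.AdditiveScoreTable({("A", "s1"): 20}))
        assert rows == ["A"] and cols == ["s1"]

    def test_distant_row_is_at_an_edge(self):
        """Brute-force check: with two equal rows and one row 100 away in every
        cell, average-linkage merges the equal pair first, so every valid leaf
        ordering keeps the pair adjacent and the distant row at an edge."""
        additive = fs.AdditiveScoreTable({})
        values = {"A": 0, "B": 0, "C": 100}
        for dye, v in values.items():
            for sample in ("s1", "s2", "s3"):
                additive.entries[(dye, sample)] = v
        rows, _ = fs.cluster_order(additive)
        assert rows.index("C") in (0, 2)
        valid = {p for p in permutations("ABC") if abs(p.index("A") - p.index("B")) == 1}
        assert tuple(rows) in valid

    def test_empty_table_raises(self):
        with pytest.raises(fs.ValidationError):
            fs.cluster_order(fs.AdditiveScoreTable({}))


def test_bright_dye_flagging(noise_free_screen):
    controls = noise_free_screen.controls[0]
    flagged = fs.flag_bright_wells(controls)
    assert flagged == sorted(noise_free_screen.truth.bright_artifacts)
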