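import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_matrix
from sdig import preprocess as pp
from sdig.containers import SPOT_COLUMNS
from sdig.errors import ConfigError, DegenerateInputError
from sdig.diversity import sdig
from sdig.synthetic import SimulationConfig, simulate_two_channel_table


def spots(rows):
    """rows: (gene, ch1i, ch1b, ch2i, ch2b, flag)."""
    return pd.DataFrame(
        [
            {"spot_id": f"s{i}", "gene_id": g, "ch1i_mean": a, "ch1b_median": b,
             "ch2i_mean": c, "ch2b_median": d, "flag": f}
            for i, (g, a, b, c, d, f) in enumerate(rows)
        ]
    )[SPOT_COLUMNS]


class TestBackgroundCorrect:
    @pytest.mark.parametrize(
        "ch1i,ch1b,expected",
        [(100.0, 20.0, 80.0), (20.0, 20.0, 0.0), (10.0, 20.0, -10.0)],
    )
    def test_subtracts_background_median(self, ch1i, ch1b, expected):
        table = spots([("g1", ch1i, ch1b, 50.0, 10.0, 0)])
        out = pp.background_correct(table)
        assert out.loc[0, "ch1d_mean"] == expected
        assert out.loc[0, "ch2d_mean"] == 40.0
        assert len(out) == 1  # negatives retained, no filtering here

    @given(c=st.floats(min_value=0.01, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_linearity_under_common_rescaling(self, c):
        base = spots([("g1", 100.0, 20.0, 60.0, 30.0, 0),
                      ("g2", 7.0, 9.0, 5.0, 1.0, 0)])
        scaled = base.copy()
        for col in ["ch1i_mean", "ch1b_median", "ch2i_mean", "ch2b_median"]:
            scaled[col] *= c
        np.testing.assert_allclose(
            pp.background_correct(scaled)[["ch1d_mean", "ch2d_mean"]],
            pp.background_correct(base)[["ch1d_mean", "ch2d_mean"]] * c,
            rtol=1e-12,
        )


class TestFlagAndWellMeasured:
    def test_only_unflagged_spots_survive(self):
        table = spots([("g1", 9, 1, 9, 1, 0), ("g2", 9, 1, 9, 1, -50),
                       ("g3", 9, 1, 9, 1, -100), ("g4", 9, 1, 9, 1, 0)])
        kept = pp.flag_filter(table)
        assert list(kept["gene_id"]) == ["g1", "g4"]

    def test_all_good_flags_is_identity(self):
        table = spots([("g1", 9, 1, 9, 1, 0), ("g2", 9, 1, 9, 1, 0)])
        pd.testing.assert_frame_equal(pp.flag_filter(table), table)

    def test_all_flagged_gives_empty_table(self):
        table = spots([("g1", 9, 1, 9, 1, -100)])
        assert len(pp.flag_filter(table)) == 0

    @pytest.mark.parametrize(
        "ch1i,ch1b,ch2i,ch2b,kept",
        [
            (100, 20, 60, 30, True),   # 100>30 and 60>45
            (25, 20, 100, 20, False),  # 25 < 30: channel 1 fails
            (30, 20, 100, 20, False),  # exactly 1.5x: strict boundary
        ],
    )
    def test_intensity_must_beat_1p5x_background_in_both_channels(
        self, ch1i, ch1b, ch2i, ch2b, kept
    ):
        table = spots([("g1", ch1i, ch1b, ch2i, ch2b, 0)])
        assert (len(pp.well_measured_filter(table)) == 1) is kept

    def test_boundary_kept_when_not_strict(self):
        table = spots([("g1", 30, 20, 100, 20, 0)])
        assert len(pp.well_measured_filter(table, strict=False)) == 1

    def test_survivor_set_matches_per_spot_rule_on_synthetic_table(self):
        table, truth = simulate_two_channel_table(SimulationConfig(S=500, seed=42))
        kept = pp.well_measured_filter(pp.flag_filter(table))
        assert set(kept["spot_id"]) == set(table.loc[truth, "spot_id"])


class TestExpressionFromChannels:
    def test_ratio_is_sample_over_reference(self):
        corrected = pp.background_correct(
            spots([("g1", 50, 10, 90, 10, 0), ("g2", 60, 10, 60, 10, 0)])
        )
        values = pp.ratio_expression(corrected, reference_channel=1)
        assert values["g1"] == pytest.approx(2.0)  # 80 / 40
        assert values["g2"] == pytest.approx(1.0)

    def test_nonpositive_reference_drops_spot(self):
        corrected = pp.background_correct(
            spots([("g1", 10, 10, 90, 10, 0), ("g2", 60, 10, 60, 10, 0)])
        )
        values = pp.ratio_expression(corrected, reference_channel=1)
        assert "g1" not in values.index and "g2" in values.index

    def test_all_spots_dropped_is_an_error(self):
        corrected = pp.background_correct(spots([("g1", 10, 10, 90, 10, 0)]))
        with pytest.raises(DegenerateInputError):
            pp.ratio_expression(corrected, reference_channel=1)

    def test_channel_assignment_maps_groups(self):
        corrected = pp.background_correct(spots([("g1", 90, 10, 50, 10, 0)]))
        out = pp.channel_expression(corrected, {1: "tumor", 2: "normal"})
        assert out.loc["g1", "tumor"] == 80.0
        assert out.loc["g1", "normal"] == 40.0

    def test_negative_corrected_value_becomes_missing(self):
        corrected = pp.background_correct(spots([("g1", 5, 10, 50, 10, 0)]))
        out = pp.channel_expression(corrected, {1: "tumor", 2: "normal"})
        assert np.isnan(out.loc["g1", "tumor"])
        assert out.loc["g1", "normal"] == 40.0

    def test_missing_channel_assignment_is_config_error(self):
        corrected = pp.background_correct(spots([("g1", 90, 10, 50, 10, 0)]))
        with pytest.raises(ConfigError):
            pp.channel_expression(corrected, {1: "tumor"})

    def test_duplicate_spots_per_gene_are_averaged(self):
        corrected = pp.background_correct(
            spots([("g1", 90, 10, 50, 10, 0), ("g1", 50, 10, 30, 10, 0)])
        )
        out = pp.channel_expression(corrected, {1: "tumor", 2: "normal"})
        assert out.loc["g1", "tumor"] == pytest.approx(60.0)  # mean(80, 40)


class TestMatrixStages:
    def test_replicate_filter_keeps_two_drops_one_and_zero(self):
        nan = np.nan
        m = make_matrix(
            [[1, 2, nan], [1, nan, nan], [nan, nan, nan], [1, 2, 3]],
            ["tumor", "tumor", "normal"],
        )
        out = pp.replicate_filter(m, min_replicates=2)
        assert list(out.gene_ids) == ["g1", "g4"]

    def test_replicate_filter_is_idempotent(self):
        m = make_matrix([[1, 2, np.nan], [1, 2, 3]], ["tumor", "tumor", "normal"])
        once = pp.replicate_filter(m)
        twice = pp.replicate_filter(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_impute_uses_within_group_mean(self):
        m = make_matrix([[10, np.nan, 20, 7]],
                        ["tumor", "tumor", "tumor", "normal"])
        out = pp.impute_missing(m)
        assert out.values.loc["g1", "s2"] == pytest.approx(15.0)

    def test_impute_falls_back_to_overall_mean_when_group_unobserved(self):
        # gene observed only in normals; the tumor cell gets the overall mean
        m = make_matrix([[np.nan, 10, 20], [1, 1, 1]],
                        ["tumor", "normal", "normal"])
        out = pp.impute_missing(m)
        assert out.values.loc["g1", "s1"] == pytest.approx(15.0)

    def test_impute_is_idempotent_and_identity_without_missing(self, small_matrix):
        same = pp.impute_missing(small_matrix)
        pd.testing.assert_frame_equal(same.values, small_matrix.values)
        m = make_matrix([[10, np.nan, 20]], ["tumor", "tumor", "tumor"])
        once = pp.impute_missing(m)
        twice = pp.impute_missing(once)
        pd.testing.assert_frame_equal(once.values, twice.values)
        assert not once.has_missing()

    @pytest.mark.parametrize("value,expected", [(0.0, 1.0), (3.0, 8.0)])
    def test_inverse_log_transform_exponentiates(self, value, expected):
        m = make_matrix([[value, 1.0]], ["tumor", "normal"])
        out = pp.inverse_log_transform(m, base=2)
        assert out.values.loc["g1", "s1"] == pytest.approx(expected)

    def test_inverse_log_transform_changes_diversity(self):
        # the transform is not diversity-preserving: [1,3] -> [2,8] skews
        # the proportions (0.25,0.75) to (0.2,0.8)
        assert sdig([2.0, 8.0]) == pytest.approx(0.32, abs=1e-12)
        assert sdig([1.0, 3.0]) == pytest.approx(0.375, abs=1e-12)
        m = make_matrix([[1.0], [3.0]], ["tumor"])
        out = pp.inverse_log_transform(m, base=2)
        np.testing.assert_allclose(out.values["s1"], [2.0, 8.0])


class TestComposition:
    def test_composed_pipeline_equals_sequential_stages(self):
        table, _ = simulate_two_channel_table(SimulationConfig(S=300, seed=7))
        staged = pp.background_correct(
            pp.well_measured_filter(pp.flag_filter(table))
        )
        composed = pp.background_correct(pp.well_measured_filter(pp.flag_filter(table)))
        pd.testing.assert_frame_equal(staged, composed)
        out = pp.channel_expression(staged, {1: "tumor", 2: "normal"})
        assert len(out) == len(staged["gene_id"].unique())
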