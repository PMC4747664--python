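import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdig.errors import ValidationError
from sdig.pair_stats import (
    PairSummary,
    count_positive_pairs,
    pppn,
    pps,
    round_half_up,
    summarize_dataset,
)


def count_bruteforce(tumor, normal):
    return sum(1 for t in tumor for n in normal if t > n)


class TestCountPositivePairs:
    @pytest.mark.parametrize(
        "tumor,normal,q",
        [
            ([0.9, 0.8], [0.7, 0.6], 4),   # complete dominance
            ([0.5], [0.5], 0),             # tie is not positive
            ([0.9, 0.6], [0.7, 0.5], 3),
        ],
    )
    def test_known_counts(self, tumor, normal, q):
        assert count_positive_pairs(tumor, normal) == q

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValidationError):
            count_positive_pairs([], [0.5])

    @given(
        tumor=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12),
        normal=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_definitional_double_loop(self, tumor, normal):
        assert count_positive_pairs(tumor, normal) == count_bruteforce(tumor, normal)

    def test_monotonicity_in_either_group(self):
        rng = np.random.default_rng(5)
        tumor, normal = rng.random(8), rng.random(6)
        q0 = count_positive_pairs(tumor, normal)
        bumped = tumor.copy()
        bumped[3] += 0.5
        assert count_positive_pairs(bumped, normal) >= q0
        raised_normal = normal.copy()
        raised_normal[2] += 0.5
        assert count_positive_pairs(tumor, raised_normal) <= q0


class TestPppn:
    @pytest.mark.parametrize(
        "q,m,n,t",
        [(238, 50, 5, 95.2), (343, 20, 20, 85.75), (0, 7, 3, 0.0)],
    )
    def test_full_precision_values(self, q, m, n, t):
        assert pppn(q, m, n) == pytest.approx(t)

    def test_display_rounding_half_up(self):
        assert round_half_up(85.75, 0) == 86
        assert round_half_up(pppn(146, 14, 14), 1) == 74.5
        assert round_half_up(72.45, 0) == 72

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            pppn(1, 0, 5)
        with pytest.raises(ValidationError):
            pppn(26, 5, 5)

    @given(
        m=st.integers(1, 20), n=st.integers(1, 20),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_t_plus_pnpn_is_exactly_100(self, m, n, data):
        q = data.draw(st.integers(0, m * n))
        t = pppn(q, m, n)
        assert t + (100.0 - t) == 100.0
        assert 0.0 <= t <= 100.0


class TestPps:
    def test_twelve_of_fourteen_pairs(self):
        idx = [f"p{i}" for i in range(14)]
        normal = pd.Series(0.5, index=idx)
        tumor = pd.Series([0.6] * 12 + [0.4, 0.5], index=idx)
        assert pps(tumor, normal) == pytest.approx(100 * 12 / 14)
        assert round_half_up(pps(tumor, normal), 1) == 85.7

    def test_all_greater_and_all_ties(self):
        idx = ["a", "b", "c"]
        normal = pd.Series([0.1, 0.2, 0.3], index=idx)
        assert pps(normal + 0.1, normal) == 100.0
        assert pps(normal.copy(), normal) == 0.0  # strict inequality

    def test_mismatched_pair_ids_rejected(self):
        with pytest.raises(ValidationError):
            pps(pd.Series([1.0], index=["a"]), pd.Series([1.0], index=["b"]))


def diversity_frame(tumor, normal, pair_ids=None):
    rows = []
    for i, d in enumerate(tumor):
        rows.append({"sample_id": f"t{i}", "group": "tumor", "D": d,
                     "pair_id": None if pair_ids is None else pair_ids[i]})
    for i, d in enumerate(normal):
        rows.append({"sample_id": f"n{i}", "group": "normal", "D": d,
                     "pair_id": None if pair_ids is None else pair_ids[i]})
    return pd.DataFrame(rows)


class TestSummarizeDataset:
    def test_paired_complete_dominance(self):
        div = diversity_frame([0.9, 0.8], [0.7, 0.6], pair_ids=["p1", "p2"])
        s = summarize_dataset(div, paired=True)
        assert s == PairSummary(M=2, N=2, Q=4, T=100.0, PNPN=0.0, PPS=100.0)

    def test_unpaired_reports_pps_not_available(self):
        div = diversity_frame([0.9, 0.8], [0.7, 0.6])
        s = summarize_dataset(div, paired=False)
        assert s.PPS is None and s.Q == 4

    def test_cross_product_shape_recovers_published_style_t(self):
        # 50 tumor vs 5 normal with exactly 238 dominating pairs
        normal = np.linspace(0.90, 0.94, 5)          # thresholds
        tumor = np.concatenate([
            np.full(38, 0.99),   # beat all 5 normals       -> 190 pairs
            np.full(12, 0.935),  # beat the lowest 4        ->  48 pairs
        ])
        assert count_bruteforce(tumor, normal) == 238
        s = summarize_dataset(diversity_frame(tumor, normal), paired=False)
        assert s.Q == 238
        assert round_half_up(s.T, 1) == 95.2

    def test_single_group_is_an_error(self):
        div = diversity_frame([0.9], [])
        with pytest.raises(ValidationError):
            summarize_dataset(div, paired=False)

    def test_pps_uses_only_matched_pairs_not_cross_product(self):
        # tumor beats every normal except its own partner: PPS=0, T high
        div = diversity_frame([0.5, 0.6], [0.7, 0.8], pair_ids=["p1", "p2"])
        div.loc[div["sample_id"] == "t0", "D"] = 0.75  # beats n1(0.7)? index p1->0.7
        s = summarize_dataset(div, paired=True)
        assert s.PPS == pytest.approx(100 * 1 / 2)
        assert s.Q == count_bruteforce(
            div.loc[div["group"] == "tumor", "D"],
            div.loc[div["group"] == "normal", "D"],
        )
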