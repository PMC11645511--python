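"""Weighted kappa, straight-lining rules, mean root of pairs, and Winsorized
burden -- each checked against an independently coded oracle or hand values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelqc import careless
from panelqc.codebook import Battery
from .conftest import make_responses


def kappa_oracle(table, cats):
    """Independent direct-summation evaluation: kappa = (po_w - pe_w)/(1 - pe_w)
    with agreement weights 1 - (i-j)^2/(max-min)^2."""
    table = np.asarray(table, float)
    n = table.sum()
    k = len(cats)
    span = (cats[-1] - cats[0]) ** 2
    po = pe = 0.0
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    for i in range(k):
        for j in range(k):
            w = 1.0 - (cats[i] - cats[j]) ** 2 / span
            po += w * table[i, j] / n
            pe += w * row[i] * col[j]
    return (po - pe) / (1 - pe)


def expand(table, cats):
    """Vectors x, y realizing a contingency table of counts."""
    xs, ys = [], []
    for i, ci in enumerate(cats):
        for j, cj in enumerate(cats):
            xs += [ci] * int(table[i][j])
            ys += [cj] * int(table[i][j])
    return np.array(xs, float), np.array(ys, float)


class TestWeightedKappa:
    def test_perfect_agreement(self):
        x = np.array([1, 2, 3, 4, 5, 2, 3])
        assert careless.weighted_kappa(x, x) == pytest.approx(1.0)

    def test_frozen_3x3_table_matches_oracle(self):
        table = [[2, 1, 0], [1, 2, 1], [0, 1, 2]]
        cats = [1, 2, 3]
        x, y = expand(table, cats)
        k = careless.weighted_kappa(x, y, categories=cats)
        assert k == pytest.approx(2 / 3)  # hand evaluation of the formula
        assert k == pytest.approx(kappa_oracle(table, cats))

    def test_random_tables_match_oracle_and_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        cats = [1, 2, 3, 4, 5]
        for _ in range(100):
            table = rng.integers(0, 6, size=(5, 5))
            if table.sum() < 2:
                continue
            x, y = expand(table, cats)
            if np.unique(np.concatenate([x, y])).size < 2:
                continue
            ours = careless.weighted_kappa(x, y, categories=cats)
            assert ours == pytest.approx(kappa_oracle(table, cats), abs=1e-12)
            assert ours == pytest.approx(
                cohen_kappa_score(x, y, weights="quadratic", labels=cats), abs=1e-10
            )

    def test_chance_agreement_limit(self, rng):
        x = rng.integers(1, 6, size=30000).astype(float)
        y = rng.permutation(x)
        assert abs(careless.weighted_kappa(x, y)) < 0.02

    def test_symmetry_and_order_preserving_relabel(self, rng):
        x = rng.integers(1, 6, size=200).astype(float)
        y = rng.integers(1, 6, size=200).astype(float)
        k_xy = careless.weighted_kappa(x, y)
        assert careless.weighted_kappa(y, x) == pytest.approx(k_xy)
        # common affine relabeling of the declared range leaves kappa unchanged
        cats2 = [2 * c + 3 for c in range(1, 6)]
        assert careless.weighted_kappa(
            2 * x + 3, 2 * y + 3, categories=cats2
        ) == pytest.approx(k_xy)

    def test_pairwise_complete_cases(self):
        x = np.array([1, 2, np.nan, 4])
        y = np.array([1, np.nan, 3, 4])
        assert careless.weighted_kappa(x, y) == pytest.approx(1.0)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="pairwise-complete"):
            careless.weighted_kappa([1, np.nan], [np.nan, 2])
        with pytest.raises(ValueError, match="equal length"):
            careless.weighted_kappa([1, 2], [1, 2, 3])
        # constant joint distribution: chance disagreement zero -> undefined
        assert np.isnan(careless.weighted_kappa([3, 3, 3], [3, 3, 3]))


class TestInterpretKappa:
    @pytest.mark.parametrize(
        "value, label",
        [
            (0.83, "almost perfect"),
            (0.46, "moderate"),
            (0.205, "fair"),  # half-up rounding decides the band
            (0.72, "substantial"),
            (0.15, "slight"),
            (-0.2, "poor"),
            (0.0, "slight"),
            (1.0, "almost perfect"),
        ],
    )
    def test_bands(self, value, label):
        assert careless.interpret_kappa(value) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            careless.interpret_kappa(1.2)


ITEMS = ["a1", "a2", "a3", "b1", "b2", "b3"]
BATTERIES = [Battery("A", ("a1", "a2", "a3")), Battery("B", ("b1", "b2", "b3"))]


class TestStraightlineAllSets:
    def test_same_constant_everywhere_flags(self):
        resp = make_responses([[4] * 6], items=ITEMS)
        assert careless.straightline_all_sets(resp, BATTERIES).iloc[0]

    def test_different_constants_per_set_still_flag(self):
        resp = make_responses([[2, 2, 2, 5, 5, 5]], items=ITEMS)
        assert careless.straightline_all_sets(resp, BATTERIES).iloc[0]

    def test_one_varying_set_does_not_flag(self):
        resp = make_responses([[2, 2, 2, 5, 5, 4]], items=ITEMS)
        assert not careless.straightline_all_sets(resp, BATTERIES).iloc[0]

    def test_unanswered_set_excludes_from_flag(self):
        resp = make_responses([[2, 2, 2, np.nan, np.nan, np.nan]], items=ITEMS)
        assert not careless.straightline_all_sets(resp, BATTERIES).iloc[0]

    def test_answered_subset_is_what_counts(self):
        resp = make_responses([[2, np.nan, 2, 5, 5, np.nan]], items=ITEMS)
        assert careless.straightline_all_sets(resp, BATTERIES).iloc[0]

    def test_empty_battery_list_rejected(self):
        with pytest.raises(ValueError):
            careless.straightline_all_sets(make_responses([[1]], items=["a1"]), [])


class TestStraightlineBattery:
    PF = Battery("pf", ("a1", "a2", "a3", "b1", "b2", "b3"), allowed_category=5)
    SLEEP = Battery("sleep", ("a1", "a2", "a3"), allowed_category=3)

    def test_allowed_category_not_flagged(self):
        resp = make_responses([[5] * 6, [2] * 6], items=ITEMS)
        flags = careless.straightline_battery(resp, self.PF)
        assert flags.tolist() == [False, True]

    def test_sleep_allowance(self):
        resp = make_responses([[3, 3, 3, 1, 1, 1], [4, 4, 4, 1, 1, 1]], items=ITEMS)
        flags = careless.straightline_battery(resp, self.SLEEP)
        assert flags.tolist() == [False, True]

    def test_incomplete_battery_never_flagged(self):
        resp = make_responses([[2, 2, np.nan, 1, 1, 1]], items=ITEMS)
        assert not careless.straightline_battery(resp, self.SLEEP).iloc[0]


class TestMeanRootOfPairs:
    def test_hand_cases(self):
        resp = make_responses([[3, 3, 3], [1, 5, 1]], items=["a", "b", "c"])
        rp = careless.mean_root_of_pairs(resp, ["a", "b", "c"], (1, 5))
        assert rp.iloc[0] == pytest.approx(1.0)
        # pairs sqrt(4), sqrt(4), sqrt(0): mean 4/3, /2 -> 2/3, rp = 1/3
        assert rp.iloc[1] == pytest.approx(1 / 3)

    def test_extreme_pair_is_zero(self):
        resp = make_responses([[1, 5]], items=["a", "b"])
        assert careless.mean_root_of_pairs(resp, ["a", "b"], (1, 5)).iloc[0] == 0.0

    def test_fewer_than_two_answers_undefined(self):
        resp = make_responses([[2, np.nan, np.nan]], items=["a", "b", "c"])
        assert np.isnan(careless.mean_root_of_pairs(resp, ["a", "b", "c"]).iloc[0])

    def test_monotone_in_spread(self):
        rows = [[3, 3, 3], [3, 3, 4], [3, 4, 5], [1, 3, 5]]
        resp = make_responses(rows, items=["a", "b", "c"])
        rp = careless.mean_root_of_pairs(resp, ["a", "b", "c"]).to_numpy()
        assert np.all(np.diff(rp) < 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 5), min_size=2, max_size=8))
    def test_bounded_between_zero_and_one(self, values):
        resp = make_responses([values], items=[f"i{j}" for j in range(len(values))])
        rp = careless.mean_root_of_pairs(resp, list(resp.columns)).iloc[0]
        assert -1e-12 <= rp <= 1 + 1e-12

    def test_planted_straightliners_score_higher(self, convenience_cohort, codebook):
        c = convenience_cohort
        bat = codebook.special_batteries["sleep_set_1"]
        rp = careless.mean_root_of_pairs(c.responses, bat)
        planted = c.truth.persona == "straightliner"
        assert planted.sum() >= 10 and (~planted).sum() >= 500
        assert rp[planted].mean() > rp[~planted].mean()

    def test_removing_fake_endorsers_reduces_straightlining(self, codebook):
        from panelqc.synthetic_cohort import PersonaConfig, generate_cohort

        cfg = PersonaConfig(
            n_respondents=2000,
            persona_mix={"attentive": 0.8, "misrepresenter": 0.2},
            misrepresenter_straightline_frac=0.4,
            seed=17,
        )
        c = generate_cohort(cfg, codebook)
        fake = c.endorsements[list(codebook.fake_conditions)].sum(axis=1) > 0
        rule3 = careless.straightline_battery(
            c.responses, codebook.special_batteries["sleep_set_1"]
        ) | careless.straightline_battery(
            c.responses, codebook.special_batteries["sleep_set_2"]
        )
        assert rule3[~fake].mean() < rule3.mean()


class TestWinsorizedBurden:
    def test_constant_durations(self):
        b = careless.winsorized_burden([600.0] * 10)
        assert b.mean == b.median == 10.0

    def test_cap_matches_percentile_oracle(self):
        values = np.array(list(range(1, 40)) + [1000], float)

        # independent linear-interpolation percentile
        def pct(sorted_vals, q):
            h = (len(sorted_vals) - 1) * q
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])

        expected_cap = pct(np.sort(values), 0.975)
        b = careless.winsorized_burden(values)
        assert b.cap_seconds == pytest.approx(expected_cap)
        assert b.max == pytest.approx(expected_cap / 60)

    def test_capping_is_idempotent(self, rng):
        # n chosen so the 97.5th percentile lands on an order statistic,
        # making the cap an exact fixed point under linear interpolation
        d = rng.lognormal(6.5, 0.6, size=401)
        first = careless.winsorized_burden(d)
        capped = np.minimum(d, first.cap_seconds)
        second = careless.winsorized_burden(capped)
        assert second.mean == pytest.approx(first.mean)
        assert second.max == pytest.approx(first.max)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            careless.winsorized_burden([])
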