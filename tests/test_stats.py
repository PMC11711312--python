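import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from folliclemap import (
    binomial_two_sided,
    crossing_index,
    gradient_analysis,
    group_test,
    polarization_scan,
)
from folliclemap.frames import signed_angle_diff


def enumeration_binomial_p(k: int, n: int) -> float:
    """Independent oracle: exact integer enumeration of outcome masses."""
    ck = math.comb(n, k)
    total = sum(math.comb(n, m) for m in range(n + 1) if math.comb(n, m) <= ck)
    return total / 2**n


class TestBinomialTwoSided:
    @pytest.mark.parametrize("k, n, expected", [(2, 4, 1.0), (7, 10, 0.34375)])
    def test_known_values(self, k, n, expected):
        assert binomial_two_sided(k, n) == pytest.approx(expected, abs=1e-12)

    def test_extreme_tail_closed_form(self):
        assert binomial_two_sided(58, 58) == pytest.approx(2 * 0.5**58, rel=1e-9)

    def test_matches_enumeration_oracle_and_scipy(self):
        for n in range(1, 13):
            for k in range(n + 1):
                p = binomial_two_sided(k, n)
                assert p == pytest.approx(enumeration_binomial_p(k, n), abs=1e-12)
                assert p == pytest.approx(
                    sps.binomtest(k, n, 0.5).pvalue, abs=1e-10)

    def test_symmetry_under_complement(self):
        for n in (5, 12, 31):
            for k in range(n + 1):
                assert binomial_two_sided(k, n) == pytest.approx(
                    binomial_two_sided(n - k, n), abs=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            binomial_two_sided(5, 4)
        with pytest.raises(ValueError):
            binomial_two_sided(0, 0)


class TestPolarizationScan:
    def test_all_angles_in_one_semicircle(self):
        scan = polarization_scan({"m": np.full(20, 180.0)})
        row = scan[(scan["cut_deg"] == 100.0) & (scan["class"] == "m")].iloc[0]
        assert row["k"] == 20 and row["n"] == 20
        assert row["p_value"] == pytest.approx(2 * 0.5**20, rel=1e-9)

    def test_alternating_angles_are_never_polarized(self):
        angles = np.tile([0.0, 180.0], 10)
        scan = polarization_scan({"m": angles})
        sub = scan[scan["class"] == "m"]
        assert (sub["k"] == 10).all()
        np.testing.assert_allclose(sub["p_value"], 1.0, rtol=1e-12)

    def test_antipodal_cuts_share_p(self):
        rng = np.random.default_rng(2)
        scan = polarization_scan({"m": rng.uniform(0, 360, 101)})
        sub = scan[scan["class"] == "m"].set_index("cut_deg")
        for cut in np.arange(0, 180, 20.0):
            assert sub.loc[cut, "p_value"] == pytest.approx(
                sub.loc[cut + 180.0, "p_value"])

    def test_rotating_angles_shifts_minimum_p_cut(self):
        rng = np.random.default_rng(3)
        angles = np.degrees(rng.vonmises(np.pi, 3.0, 500)) % 360
        delta = 60.0

        def min_cut(a):
            scan = polarization_scan({"m": a})
            sub = scan[scan["class"] == "m"]
            return sub.loc[sub["p_value"].idxmin(), "cut_deg"]

        c0, c1 = min_cut(angles), min_cut((angles + delta) % 360)
        d = abs(signed_angle_diff(c1, c0 + delta))
        assert min(d, abs(d - 180.0)) <= 20.0  # grid resolution

    def test_pooled_class_present(self):
        scan = polarization_scan({"a": [10.0, 20.0], "b": [200.0]})
        total = scan[scan["class"] == "total"]
        assert (total["n"] == 3).all()


def brute_force_crossings(ref, term, arms):
    """Independent tally via complex-argument sign comparison per pair."""
    n = len(ref)
    intra = np.zeros(n, int)
    inter = np.zeros(n, int)
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        dr = np.angle(np.exp(1j * np.deg2rad(ref[i] - ref[j])), deg=True)
        dt = np.angle(np.exp(1j * np.deg2rad(term[i] - term[j])), deg=True)
        if dr in (0.0, 180.0, -180.0) or dt in (0.0, 180.0, -180.0):
            continue
        if (dr > 0) != (dt > 0):
            pairs += 1
            tgt = intra if arms[i] == arms[j] else inter
            tgt[i] += 1
            tgt[j] += 1
    return intra, inter, pairs


class TestCrossingIndex:
    def test_formula_values(self):
        # three axons engineered so axon 0 crosses 1 (same arm) but not 2
        ref = np.array([10.0, 20.0, 50.0])
        term = np.array([25.0, 15.0, 60.0])
        res = crossing_index(ref, term, arm_ids=[0, 0, 1])
        assert res.loc[0, "n_intra"] == 1 and res.loc[0, "n_inter"] == 0
        assert res.loc[0, "crossing_index"] == pytest.approx(1.0)
        assert res.loc[2, "crossing_index"] == 0.0  # no crossings at all

    def test_mixed_counts_match_brute_force(self):
        ref = [0.0, 10.0, 20.0, 30.0, 40.0]
        term = [35.0, 5.0, 15.0, 25.0, 33.0]
        out = crossing_index(ref, term, arm_ids=[0, 0, 1, 1, 1])
        i_brute, n_brute, _ = brute_force_crossings(
            np.array(ref), np.array(term), np.array([0, 0, 1, 1, 1]))
        np.testing.assert_array_equal(out["n_intra"], i_brute)
        np.testing.assert_array_equal(out["n_inter"], n_brute)

    def test_parallel_axons_have_zero_index(self):
        res = crossing_index([0.0, 90.0], [10.0, 100.0], arm_ids=[0, 1])
        assert (res["crossing_index"] == 0.0).all()

    def test_symmetric_tally_identity(self, small_follicle):
        _, _, features, _ = small_follicle
        deep = features[~features["superficial"]]
        res = crossing_index(
            deep["angle_ref"].to_numpy(), deep["terminal_angle"].to_numpy(),
            deep["arm_id"].to_numpy())
        i_b, n_b, pairs = brute_force_crossings(
            deep["angle_ref"].to_numpy(), deep["terminal_angle"].to_numpy(),
            deep["arm_id"].to_numpy())
        assert res["n_total"].sum() == 2 * pairs
        np.testing.assert_array_equal(res["n_intra"], i_b)
        assert res["crossing_index"].between(-1, 1).all()

    def test_missing_angle_named(self):
        with pytest.raises(ValueError, match="ax1"):
            crossing_index([0.0, np.nan], [1.0, 2.0], [0, 1],
                           axon_ids=["ax0", "ax1"])


class TestGradientAnalysis:
    def test_noiseless_affine_data_recovered_exactly(self):
        h = np.linspace(100, 1200, 50)
        area = 2.0 + 0.04 * h
        v = 6.0 * 2 * np.sqrt(area / np.pi)
        res = gradient_analysis(h, area, v)
        assert res.area_fit["r"] == pytest.approx(1.0, abs=1e-12)
        assert res.area_fit["slope"] == pytest.approx(0.04, rel=1e-9)

    def test_split_group_medians(self):
        h = np.array([100.0, 200.0, 900.0, 1000.0])
        area = np.pi * np.array([1.0, 1.0, 4.0, 4.0])  # radii 1 and 2
        v = np.ones(4)
        res = gradient_analysis(h, area, v, split=850.0)
        assert res.median_diameter_below == pytest.approx(2.0)
        assert res.median_diameter_above == pytest.approx(4.0)

    def test_shuffled_heights_decorrelate(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            h = rng.uniform(100, 1200, 174)
            v = 0.03 * h + rng.normal(0, 5, 174)
            res = gradient_analysis(rng.permutation(h), np.abs(v) + 1, v)
            hits += abs(res.velocity_fit["r"]) < 0.2
        assert hits >= 95

    def test_zero_variance_heights_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            gradient_analysis([1.0, 1.0, 1.0], [1, 2, 3], [1, 2, 3])


class TestGroupTest:
    def test_identical_groups_show_nothing(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        res = group_test(g)
        assert res.H == pytest.approx(0.0, abs=1e-12)
        assert (res.pairwise["p_adjusted"] == 1.0).all()

    def test_h_matches_rank_arithmetic_oracle(self):
        # groups (1,2,3), (10,11,12), (20,21,22): ranks 1..9, mean ranks 2,5,8
        # H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2 = 12/90 * 3*18 = 7.2
        res = group_test({"a": [1, 2, 3], "b": [10, 11, 12], "c": [20, 21, 22]})
        assert res.H == pytest.approx(7.2, rel=1e-12)

    def test_planted_shift_detected_with_power(self):
        detected = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            groups = {
                "a": rng.normal(0, 1, 25),
                "b": rng.normal(0, 1, 25),
                "c": rng.normal(3, 1, 25),  # 3 SD shift
                "d": rng.normal(0, 1, 25),
            }
            res = group_test(groups)
            row = res.pairwise[
                (res.pairwise["group_a"] == "b") & (res.pairwise["group_b"] == "c")
            ].iloc[0]
            detected += row["p_adjusted"] < 0.05
        assert detected >= 95

    def test_bonferroni_is_capped_scaled_raw(self):
        rng = np.random.default_rng(1)
        res = group_test({k: rng.normal(size=10) for k in "abcd"})
        assert len(res.pairwise) == 6
        for _, row in res.pairwise.iterrows():
            assert row["p_adjusted"] == pytest.approx(min(1.0, 6 * row["p_raw"]))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            group_test({"a": [1.0], "b": []})
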