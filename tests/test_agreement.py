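"""DTW distance, warp paths, Lin's CCC and Fleiss grading."""

import numpy as np
import pytest

from handkin import (
    compare_subject,
    dtw_bruteforce,
    dtw_distance,
    grade_agreement,
    lins_ccc,
)
from handkin.agreement import AgreementError, WarpPath


class TestDtw:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 2, 3], [1, 2, 2, 3], 0.0),
            ([0, 0], [1, 1], 2.0),
            ([0], [5], 5.0),
            ([3], [3], 0.0),
        ],
    )
    def test_worked_examples(self, a, b, expected):
        dist, _ = dtw_distance(a, b)
        assert dist == expected
        assert dtw_bruteforce(a, b) == expected

    def test_self_distance_zero_diagonal_path(self, rng):
        for _ in range(20):
            a = rng.normal(0, 10, rng.integers(2, 30))
            dist, path = dtw_distance(a, a)
            assert dist == 0.0
            assert path.pairs == tuple((i, i) for i in range(1, len(a) + 1))

    def test_symmetry(self, rng):
        for _ in range(50):
            a = rng.normal(0, 5, rng.integers(1, 15))
            b = rng.normal(0, 5, rng.integers(1, 15))
            assert dtw_distance(a, b)[0] == pytest.approx(dtw_distance(b, a)[0], abs=1e-12)

    def test_dp_equals_bruteforce_on_random_integer_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            a = rng.integers(0, 10, rng.integers(1, 7)).astype(float)
            b = rng.integers(0, 10, rng.integers(1, 7)).astype(float)
            dp, _ = dtw_distance(a, b)
            assert dp == pytest.approx(dtw_bruteforce(a, b), abs=1e-12)

    def test_monotone_under_cost_inflation(self, rng):
        a = rng.normal(0, 5, 10)
        b = rng.normal(0, 5, 12)
        base, _ = dtw_distance(a, b)
        # inflating one element's mismatch cannot decrease the optimum
        b2 = b.copy()
        b2[5] += 100 * np.sign(b2[5] - a.mean() + 1e-9)
        inflated, _ = dtw_distance(a, b2)
        assert inflated >= base - 1e-12

    def test_path_invariants(self, rng):
        a = rng.normal(0, 5, 8)
        b = rng.normal(0, 5, 13)
        _, path = dtw_distance(a, b)
        assert path.pairs[0] == (1, 1)
        assert path.pairs[-1] == (8, 13)
        # WarpPath validates step structure on construction
        WarpPath(path.pairs)

    def test_path_cost_attains_distance(self, rng):
        a = rng.normal(0, 5, 9)
        b = rng.normal(0, 5, 7)
        dist, path = dtw_distance(a, b)
        cost = sum(abs(a[m - 1] - b[n - 1]) for m, n in path.pairs)
        assert cost == pytest.approx(dist, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(AgreementError):
            dtw_distance([], [1.0])

    def test_bruteforce_size_limit(self):
        with pytest.raises(AgreementError):
            dtw_bruteforce(np.zeros(9), np.zeros(9))


class TestWarpPath:
    def test_bad_start_rejected(self):
        with pytest.raises(AgreementError):
            WarpPath(((2, 1), (3, 2)))

    def test_bad_step_rejected(self):
        with pytest.raises(AgreementError):
            WarpPath(((1, 1), (3, 1)))


class TestLinsCcc:
    def test_closed_form_example(self):
        ccc, pearson, c_b = lins_ccc([1, 2, 3], [2, 3, 4])
        assert ccc == pytest.approx(4.0 / 7.0, abs=1e-12)
        assert pearson == pytest.approx(1.0, abs=1e-12)
        assert c_b == pytest.approx(4.0 / 7.0, abs=1e-12)

    def test_perfect_concordance(self, rng):
        x = rng.normal(0, 3, 50)
        ccc, _, c_b = lins_ccc(x, x)
        assert ccc == pytest.approx(1.0, abs=1e-12)
        assert c_b == pytest.approx(1.0, abs=1e-12)

    def test_matches_covariance_matrix_oracle(self, rng):
        for _ in range(50):
            x = rng.normal(0, 5, 30)
            y = 0.5 * x + rng.normal(2, 3, 30)
            ccc, pearson, _ = lins_ccc(x, y)
            cov = np.cov(x, y, ddof=0)
            oracle = 2 * cov[0, 1] / (cov[0, 0] + cov[1, 1] + (x.mean() - y.mean()) ** 2)
            assert ccc == pytest.approx(oracle, abs=1e-12)
            assert abs(ccc) <= abs(pearson) + 1e-12

    def test_offset_decreases_ccc_not_pearson(self, rng):
        x = rng.normal(50, 10, 100)
        y = x + rng.normal(0, 1, 100)
        ccc0, r0, _ = lins_ccc(x, y)
        ccc1, r1, _ = lins_ccc(x, y + 20.0)
        assert ccc1 < ccc0
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_cb_bounded(self, rng):
        for _ in range(50):
            x = rng.normal(0, 5, 25)
            y = rng.normal(1, 4, 25)
            _, _, c_b = lins_ccc(x, y)
            assert 0 < abs(c_b) <= 1 + 1e-12

    def test_constant_input_rejected(self):
        with pytest.raises(AgreementError):
            lins_ccc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGrading:
    @pytest.mark.parametrize(
        "ccc,grade",
        [
            (0.95, "very good"),
            (0.60, "moderate"),
            (0.20, "no agreement"),
            (0.75, "acceptable"),
            (0.40, "poor"),
            (1.0, "very good"),
            (-0.5, "no agreement"),
        ],
    )
    def test_band_probes(self, ccc, grade):
        assert grade_agreement(ccc) == grade

    def test_monotone_step_function(self):
        probes = np.linspace(-1, 1, 201)
        order = {"no agreement": 0, "poor": 1, "moderate": 2, "acceptable": 3, "very good": 4}
        ranks = [order[grade_agreement(c)] for c in probes]
        assert all(b >= a for a, b in zip(ranks, ranks[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(AgreementError):
            grade_agreement(1.5)


class TestCompareSubject:
    def test_identical_series(self, series_factory):
        t = np.arange(300) / 30.0
        s = series_factory(50 + 40 * np.sin(2 * np.pi * t))
        result = compare_subject(s, s)
        assert result.dtw_distance == 0.0
        assert result.ccc == pytest.approx(1.0, abs=1e-12)
        assert result.grade == "very good"

    def test_offset_penalised_by_both_measures(self, series_factory):
        t = np.arange(300) / 30.0
        base = 50 + 30 * np.sin(2 * np.pi * t)
        a = series_factory(base)
        b = series_factory(base + 20.0)
        result = compare_subject(a, b)
        assert result.dtw_distance > 0.0
        assert result.ccc < 1.0
        assert result.pearson_r == pytest.approx(1.0, abs=1e-9)
        # closed-form CCC under a pure location shift d with equal variances:
        # ccc = 2 s^2 / (2 s^2 + d^2)
        s2 = np.var(base)
        assert result.ccc == pytest.approx(2 * s2 / (2 * s2 + 400.0), rel=1e-6)

    def test_finger_mismatch_rejected(self, series_factory):
        a = series_factory(np.arange(100.0), finger="index")
        b = series_factory(np.arange(100.0), finger="ring")
        with pytest.raises(AgreementError):
            compare_subject(a, b)

    def test_warp_pairing_option(self, series_factory):
        rng = np.random.default_rng(0)
        t = np.arange(300) / 30.0
        a = series_factory(50 + 40 * np.sin(2 * np.pi * t) + rng.normal(0, 1, 300))
        b = series_factory(50 + 40 * np.sin(2 * np.pi * (t - 0.05)) + rng.normal(0, 1, 300))
        res_resample = compare_subject(a, b, ccc_pairing="resample")
        res_warp = compare_subject(a, b, ccc_pairing="warp")
        # DTW pairing aligns the phase shift away, so concordance cannot drop
        assert res_warp.ccc >= res_resample.ccc - 0.05

    def test_unequal_rates_resampled(self, series_factory):
        t60 = np.arange(600) / 60.0
        t30 = np.arange(300) / 30.0
        a = series_factory(50 + 40 * np.sin(2 * np.pi * t30), fps=30.0)
        b = series_factory(50 + 40 * np.sin(2 * np.pi * t60), fps=60.0)
        result = compare_subject(a, b)
        assert result.ccc > 0.999
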