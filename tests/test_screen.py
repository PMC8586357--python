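import numpy as np
import pytest

from bekinet import (
    ReducedParams,
    find_peak,
    pt_pb_reduced,
    screen_candidates,
    selectivity_scan,
    sensitivity_scan,
)
from bekinet.errors import ValidationError
from bekinet.screen import DEFAULT_GRID


def brute_force_peak(params, lo, hi, step=1e-5):
    xs = np.arange(lo, hi + step / 2, step)
    best_x, best_s = lo, -np.inf
    for x in xs:
        pt, pb = pt_pb_reduced(params.replace(ddEm=float(x)))
        if pt - pb > best_s:
            best_x, best_s = float(x), pt - pb
    return best_x, best_s


class TestSelectivityScan:
    def test_values_match_pointwise_closed_form(self, calib_params):
        grid = np.arange(-2.0, 12.0001, 0.5)
        curve = selectivity_scan(calib_params, grid)
        for i, x in enumerate(grid):
            pt, pb = pt_pb_reduced(calib_params.replace(ddEm=float(x)))
            assert curve.p_t[i] == pt and curve.p_b[i] == pb
            assert curve.s[i] == pt - pb

    def test_single_interior_maximum_in_4_6(self, calib_params):
        curve = selectivity_scan(calib_params, np.arange(-2.0, 12.0001, 0.05))
        i_max = int(np.argmax(curve.s))
        assert 0 < i_max < curve.s.size - 1
        assert 4.0 <= curve.ddEm[i_max] <= 6.0
        # exactly one interior maximum: S rises then falls
        ds = np.sign(np.diff(curve.s))
        assert np.all(ds[:i_max] >= 0) and np.all(ds[i_max:] <= 0)

    def test_zero_dde0_gives_zero_selectivity(self, calib_params):
        curve = selectivity_scan(calib_params.replace(ddE0=0.0), np.arange(-3.0, 3.1, 0.5))
        assert np.allclose(curve.s, 0.0, atol=0)

    def test_selectivity_vanishes_at_extremes(self, calib_params):
        curve = selectivity_scan(calib_params, np.array([-30.0, 30.0]))
        assert np.all(np.abs(curve.s) < 1e-6)

    def test_selectivity_bounded(self, calib_params):
        curve = selectivity_scan(calib_params)
        assert np.all(curve.s >= -1.0) and np.all(curve.s <= 1.0)

    def test_decreasing_grid_rejected(self, calib_params):
        with pytest.raises(ValidationError):
            selectivity_scan(calib_params, np.array([1.0, 0.5]))


class TestFindPeak:
    def test_peak_matches_dense_brute_force(self, calib_params):
        curve = selectivity_scan(calib_params, np.arange(-2.0, 12.0001, 0.05))
        peak = find_peak(curve)
        x_star, s_star = brute_force_peak(calib_params, 4.0, 7.0)
        assert peak.ddEm_peak == pytest.approx(x_star, abs=1e-3)
        assert peak.s_max == pytest.approx(s_star, abs=1e-8)

    def test_peak_randomized_against_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            p = ReducedParams(
                gamma1=10 ** rng.uniform(-1, 1),
                gamma2=10 ** rng.uniform(0, 1.5),
                gamma3=10 ** rng.uniform(-5, -2),
                m=float(rng.uniform(0, 1)),
                ddE0=float(rng.uniform(2, 8)),
            )
            curve = selectivity_scan(p, np.arange(-5.0, 15.0001, 0.05))
            peak = find_peak(curve)
            x_star, _ = brute_force_peak(p, peak.ddEm_peak - 0.2, peak.ddEm_peak + 0.2)
            assert peak.ddEm_peak == pytest.approx(x_star, abs=1e-3)

    def test_window_contains_peak_and_respects_fraction(self, calib_params):
        curve = selectivity_scan(calib_params, np.arange(-2.0, 12.0001, 0.05))
        peak = find_peak(curve, fraction=0.9)
        lo, hi = peak.window
        assert lo <= peak.ddEm_peak <= hi
        for x in (lo + 1e-3, hi - 1e-3):
            pt, pb = pt_pb_reduced(calib_params.replace(ddEm=x))
            assert pt - pb >= 0.9 * peak.s_max - 1e-6
        # just outside the window, S drops below the threshold
        pt, pb = pt_pb_reduced(calib_params.replace(ddEm=lo - 0.05))
        assert pt - pb < 0.9 * peak.s_max

    def test_fraction_one_collapses_window(self, calib_params):
        curve = selectivity_scan(calib_params, np.arange(-2.0, 12.0001, 0.05))
        peak = find_peak(curve, fraction=1.0)
        lo, hi = peak.window
        assert hi - lo <= 2e-3

    def test_degenerate_flat_curve(self, calib_params):
        curve = selectivity_scan(calib_params.replace(ddE0=0.0), np.arange(-2.0, 2.1, 0.5))
        peak = find_peak(curve)
        assert peak.degenerate

    def test_bad_fraction_rejected(self, calib_params):
        curve = selectivity_scan(calib_params, np.arange(0.0, 1.1, 0.5))
        with pytest.raises(ValidationError):
            find_peak(curve, fraction=0.0)


class TestScreenCandidates:
    def test_peak_and_overshoot(self, calib_params):
        curve = selectivity_scan(calib_params)
        peak = find_peak(curve)
        ranked = screen_candidates(
            calib_params,
            [("at_peak", peak.ddEm_peak), ("overshoot", peak.ddEm_peak + 8.0)],
        )
        by_name = {c.name: c for c in ranked}
        assert by_name["at_peak"].in_window
        assert not by_name["overshoot"].in_window
        assert by_name["at_peak"].rank == 1

    def test_identical_ddem_tie_broken_by_name(self, calib_params):
        ranked = screen_candidates(calib_params, [("b_mut", 3.0), ("a_mut", 3.0)])
        assert [c.name for c in ranked] == ["a_mut", "b_mut"]
        assert [c.rank for c in ranked] == [1, 2]

    def test_ranking_matches_brute_force_sort(self, calib_params):
        cands = [(f"c{i}", float(x)) for i, x in enumerate(np.linspace(-2, 10, 13))]
        ranked = screen_candidates(calib_params, cands)
        s_direct = {
            name: (lambda pq: pq[0] - pq[1])(pt_pb_reduced(calib_params.replace(ddEm=x)))
            for name, x in cands
        }
        expected = sorted(s_direct, key=lambda n: (-s_direct[n], n))
        assert [c.name for c in ranked] == expected

    def test_input_order_invariance(self, calib_params):
        cands = [(f"c{i}", float(x)) for i, x in enumerate([5.0, 1.0, 3.0, 8.0])]
        a = screen_candidates(calib_params, cands)
        b = screen_candidates(calib_params, list(reversed(cands)))
        assert [(c.name, c.rank) for c in a] == [(c.name, c.rank) for c in b]

    def test_empty_candidates_rejected(self, calib_params):
        with pytest.raises(ValidationError):
            screen_candidates(calib_params, [])


class TestSensitivityScan:
    def test_gamma1_divided_by_five(self, calib_params):
        grid = np.arange(-2.0, 12.0001, 0.05)
        base = selectivity_scan(calib_params, grid)
        varied = sensitivity_scan(calib_params, "gamma1", [0.2], grid)[0.2]
        i0 = int(np.argmin(np.abs(grid)))
        # S at ddEm=0 changes little in absolute terms while the peak
        # selectivity increases substantially.
        assert abs(varied.s[i0] - base.s[i0]) < 0.05
        assert varied.s.max() > base.s.max() + 0.1

    def test_gamma3_divided_by_five(self, calib_params):
        grid = np.arange(-2.0, 14.0001, 0.05)
        base = find_peak(selectivity_scan(calib_params, grid))
        varied = find_peak(sensitivity_scan(calib_params, "gamma3", [0.2], grid)[0.2])
        assert varied.ddEm_peak > base.ddEm_peak + 0.5  # right shift
        assert abs(varied.s_max - base.s_max) < 0.01  # max unchanged

    def test_m_insensitivity(self, calib_params):
        grid = np.arange(-2.0, 12.0001, 0.1)
        curves = sensitivity_scan(calib_params, "m", [0.0, 1.0], grid)
        assert np.max(np.abs(curves[0.0].p_t - curves[1.0].p_t)) < 0.05

    def test_unknown_parameter_rejected(self, calib_params):
        with pytest.raises(ValidationError):
            sensitivity_scan(calib_params, "gamma2", [0.5])

    def test_nonpositive_factor_rejected(self, calib_params):
        with pytest.raises(ValidationError):
            sensitivity_scan(calib_params, "gamma1", [0.0])
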