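import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucleoflux.correction import correct_plate
from nucleoflux.errors import KineticsError
from nucleoflux.kinetics import (fit_lsq_cubic_spline, promoter_activity,
                                 schoenberg_whitney_ok, select_knots,
                                 synthesis_rate)
from tests.conftest import make_expression


# ---------------------------------------------------------------------------
# Discrete promoter activity d(F/OD)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fod, expected_raw", [
    ([800.0] * 4, [0.0, 0.0, 0.0]),          # constant -> zero activity
    ([100.0, 160.0], [60.0]),                # rising
    ([160.0, 100.0], [-60.0]),               # falling -> negative raw
])
def test_discrete_activity_differences(fod, expected_raw):
    prof = promoter_activity(make_expression(np.arange(len(fod)) * 10.0, fod))
    np.testing.assert_allclose(prof.d_fod_raw, expected_raw)
    np.testing.assert_allclose(prof.d_fod_clipped,
                               np.maximum(expected_raw, 0.0))


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=40),
       st.floats(-1e3, 1e3))
def test_activity_telescopes_and_is_shift_invariant(fod, shift):
    t = np.arange(len(fod)) * 10.0
    prof = promoter_activity(make_expression(t, fod))
    # telescoping: sum of raw differences == last - first
    assert np.nansum(prof.d_fod_raw) == pytest.approx(fod[-1] - fod[0],
                                                      abs=1e-6)
    shifted = promoter_activity(make_expression(t, np.asarray(fod) + shift))
    np.testing.assert_allclose(shifted.d_fod_raw, prof.d_fod_raw, atol=1e-9)
    # clipped profile is nonnegative and equals max(raw, 0)
    assert np.all(prof.d_fod_clipped[prof.mask] >= 0)
    np.testing.assert_array_equal(prof.d_fod_clipped[prof.mask],
                                  np.maximum(prof.d_fod_raw[prof.mask], 0.0))


def test_masked_points_invalidate_adjacent_differences():
    fod = np.array([100.0, np.nan, 120.0, 130.0])
    prof = promoter_activity(make_expression(np.arange(4) * 10.0, fod))
    np.testing.assert_array_equal(prof.mask, [False, False, True])
    assert prof.d_fod_raw[2] == pytest.approx(10.0)


def test_all_masked_series_yields_empty_profile_with_warning():
    fod = np.full(5, np.nan)
    with pytest.warns(UserWarning, match="empty activity"):
        prof = promoter_activity(make_expression(np.arange(5) * 10.0, fod))
    assert len(prof) == 0


# ---------------------------------------------------------------------------
# Knot selection and least-squares spline
# ---------------------------------------------------------------------------

def test_zero_interior_knots_is_global_cubic():
    t = np.linspace(0, 100, 20)
    knots = select_knots(t, 0)
    assert knots.size == 8  # boundary knots only, repeated degree+1 times
    spl = fit_lsq_cubic_spline(t, 3 * t ** 2 + 1, knots)
    np.testing.assert_allclose(spl(t), 3 * t ** 2 + 1, rtol=1e-9)


def test_uniform_grid_knots_admissible_and_quantile_spaced():
    t = np.arange(139) * 10.0  # 23 h at 10 min
    knots = select_knots(t, 10)
    interior = knots[4:-4]
    assert interior.size == 10
    assert schoenberg_whitney_ok(t, knots)
    # roughly 1/11 quantile spacing on a uniform grid
    expected = np.quantile(t, np.arange(1, 11) / 11.0)
    assert np.abs(interior - expected).max() < 2 * 10.0


def test_clustered_sampling_gives_denser_early_knots():
    rng = np.random.default_rng(5)
    t = np.sort(np.concatenate([rng.uniform(0, 100, 80),
                                rng.uniform(100, 1000, 20)]))
    knots = select_knots(t, 8)
    interior = knots[4:-4]
    assert schoenberg_whitney_ok(t, knots)
    assert (interior < 100).sum() > (interior >= 100).sum()


@pytest.mark.parametrize("pattern", range(200))
def test_selected_knots_always_admissible(pattern):
    rng = np.random.default_rng(pattern)
    n = int(rng.integers(12, 200))
    kind = pattern % 3
    if kind == 0:
        t = np.sort(rng.uniform(0, 1000, n))
    elif kind == 1:  # clustered
        t = np.sort(np.concatenate([rng.uniform(0, 50, n // 2),
                                    rng.uniform(900, 1000, n - n // 2)]))
    else:  # uniform grid with jitter
        t = np.arange(n) * 10.0 + rng.uniform(0, 2, n)
    t = np.unique(t)
    n_int = int(rng.integers(0, max(1, t.size // 4 - 3)))
    if t.size < n_int + 4:
        n_int = t.size - 4
    knots = select_knots(t, n_int)
    assert schoenberg_whitney_ok(t, knots)
    # and the fit is actually solvable
    fit_lsq_cubic_spline(t, np.sin(t / 100.0), knots)


def test_too_few_points_raises_with_minimum():
    with pytest.raises(KineticsError, match="at least"):
        select_knots(np.arange(5.0), 4)


def test_spline_reproduces_cubic_polynomials():
    t = np.linspace(0, 200, 60)
    knots = select_knots(t, 5)
    lin = fit_lsq_cubic_spline(t, 2 * t + 1, knots)
    np.testing.assert_allclose(lin(t), 2 * t + 1, rtol=1e-9, atol=1e-9)
    cub = fit_lsq_cubic_spline(t, t ** 3, knots)
    resid = np.linalg.norm(cub(t) - t ** 3) / np.linalg.norm(t ** 3)
    assert resid < 1e-8


def test_inadmissible_knots_rejected():
    t = np.linspace(0, 10, 12)
    # interior knots piled up outside the data support of one basis
    bad = np.concatenate([[0.0] * 4, [5.0, 5.001, 5.002, 5.003, 5.004],
                          [10.0] * 4])
    assert not schoenberg_whitney_ok(t, bad)
    with pytest.raises(KineticsError, match="Schoenberg"):
        fit_lsq_cubic_spline(t, t, bad)


def test_residual_matches_known_noise_level():
    rng = np.random.default_rng(42)
    t = np.arange(139) * 10.0
    sd = 5.0
    y_true = 1000.0 / (1 + np.exp(-(t - 600) / 80.0))  # logistic fluorescence
    y = y_true + rng.normal(0, sd, t.size)
    spl = fit_lsq_cubic_spline(t, y, select_knots(t, 10))
    rms = np.sqrt(np.mean((spl(t) - y) ** 2))
    assert 0.7 * sd < rms < 1.3 * sd


def test_residual_nonincreasing_in_knot_count(noiseless_constitutive_plate):
    wells, layout, _ = noiseless_constitutive_plate
    e = correct_plate(wells, layout)["B1"]
    t, y = e.time_min[e.mask], e.f_corr[e.mask]
    resids = []
    for n_int in (4, 8, 12, 16):
        spl = fit_lsq_cubic_spline(t, y, select_knots(t, n_int))
        resids.append(np.linalg.norm(spl(t) - y))
    assert all(b <= a * (1 + 1e-9) for a, b in zip(resids, resids[1:]))


# ---------------------------------------------------------------------------
# Synthesis rate q(t) = F'(t) / OD(t)
# ---------------------------------------------------------------------------

def test_linear_f_constant_od_gives_constant_rate():
    t = np.arange(60) * 10.0
    s, c = 4.0, 0.25
    expr = make_expression(t, (s * t + 7.0) / c, od=c)
    prof = synthesis_rate(expr, n_interior=5)
    np.testing.assert_allclose(prof.q, s / c, rtol=1e-6)
    # margin excluded at both ends
    assert prof.eval_times[0] >= t[0] + 30.0
    assert prof.eval_times[-1] <= t[-1] - 30.0


def test_plateau_recovery_on_noiseless_piecewise_activity(
        noiseless_piecewise_plate):
    """q(t) recovers piecewise-constant per-biomass activity within 5%."""
    wells, layout, truth = noiseless_piecewise_plate
    e = correct_plate(wells, layout)["B1"]
    prof = synthesis_rate(e)
    t = prof.eval_times
    for lo, hi, a_true in [(None, 350.0, 40.0), (450.0, 750.0, 80.0),
                           (850.0, None, 20.0)]:
        sel = np.ones_like(t, dtype=bool)
        if lo is not None:
            sel &= t >= lo
        if hi is not None:
            sel &= t <= hi
        assert sel.sum() > 50
        assert np.abs(prof.q[sel] / a_true - 1).max() < 0.05


def test_rate_agrees_with_finite_difference_oracle(
        noiseless_constitutive_plate):
    """Spline derivative vs central finite differences on noiseless data."""
    wells, layout, _ = noiseless_constitutive_plate
    e = correct_plate(wells, layout)["B1"]
    prof = synthesis_rate(e)
    t, f, od = e.time_min[e.mask], e.f_corr[e.mask], e.od_corr[e.mask]
    q_fd = (f[2:] - f[:-2]) / (t[2:] - t[:-2]) / od[1:-1]
    oracle = np.interp(prof.eval_times, t[1:-1], q_fd)
    assert np.abs(prof.q / oracle - 1).max() < 0.01


def test_too_few_unmasked_points_raises():
    expr = make_expression(np.arange(5) * 10.0, np.full(5, 100.0))
    with pytest.raises(KineticsError, match="10 unmasked"):
        synthesis_rate(expr)
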