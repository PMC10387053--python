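"""LOESS smoother and depth-profile extrapolation/binning/weighting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootflux.loess import Loess, fit_loess, tricube
from rootflux.profiles import (
    PREDICTION_DEPTH_TOPS_CM,
    DepthMeansProfile,
    bin_profile,
    depth_means_from_observations,
    depth_weighted_mean,
    midpoint_partition_weights,
    predict_grid,
)
from rootflux.tables import measured_depth_means

MIDS = np.array([1.25, 7.25, 17.25, 37.25, 72.25])


def _profile(eco: str) -> DepthMeansProfile:
    means_tbl = measured_depth_means()
    return DepthMeansProfile.from_table(means_tbl[means_tbl["ecosystem"] == eco], label=eco)


@pytest.mark.parametrize("degree", [0, 1, 2])
def test_loess_reproduces_constants(degree):
    sm = fit_loess(MIDS, np.full(5, 3.3), span=1.0, degree=degree)
    np.testing.assert_allclose(sm.predict(np.linspace(0, 100, 23)), 3.3, rtol=1e-9)


@pytest.mark.parametrize("span", [0.8, 1.0, 1.5])
def test_local_linear_exact_on_linear_data(span):
    y = 2.0 - 0.01 * MIDS
    sm = fit_loess(MIDS, y, span=span, degree=1)
    x_new = np.linspace(0.0, 98.75, 17)
    np.testing.assert_allclose(sm.predict(x_new), 2.0 - 0.01 * x_new, atol=1e-10)


def test_loess_matches_closed_form_tricube_solve():
    """Degree 1, span 1: every prediction equals the direct weighted solve."""
    y = np.array([18.82, 9.66, 0.21, 4.26, 1.57])
    sm = fit_loess(MIDS, y, span=1.0, degree=1)
    for x0 in [1.25, 10.0, 40.0, 72.25, 95.0]:
        d = np.abs(MIDS - x0)
        w = tricube(d / d.max())
        W = np.diag(w)
        A = np.column_stack([np.ones(5), MIDS - x0])
        coef = np.linalg.solve(A.T @ W @ A, A.T @ W @ y)
        assert sm.predict(x0)[0] == pytest.approx(coef[0], rel=1e-10)


def test_loess_agrees_with_statsmodels_lowess_at_training_points():
    from statsmodels.nonparametric.smoothers_lowess import lowess

    y = np.array([18.82, 9.66, 0.21, 4.26, 1.57])
    ours = fit_loess(MIDS, y, span=1.0, degree=1).predict(MIDS)
    theirs = lowess(y, MIDS, frac=1.0, it=0, return_sorted=False)
    np.testing.assert_allclose(ours, theirs, rtol=1e-8)


def test_span_too_small_reports_minimum():
    with pytest.raises(ValueError, match="span"):
        fit_loess(MIDS, np.ones(5), span=0.3, degree=1)


@given(shift=st.floats(min_value=-50, max_value=50, allow_nan=False))
@settings(max_examples=25, derandomize=True, deadline=None)
def test_loess_shift_invariance_before_clamping(shift):
    y = np.array([18.82, 9.66, 0.21, 4.26, 1.57])
    grid = np.linspace(0, 100, 11)
    base = fit_loess(MIDS, y, span=1.0, degree=1).predict(grid)
    shifted = fit_loess(MIDS, y + shift, span=1.0, degree=1).predict(grid)
    np.testing.assert_allclose(shifted, base + shift, atol=1e-8)


def test_predict_grid_has_40_clamped_windows():
    prof = _profile("terra_firme")
    sm_mean, sm_se = prof.smoothers()
    dp = predict_grid(sm_mean, sm_se, label=prof.label)
    assert tuple(dp.table["depth_top_cm"]) == PREDICTION_DEPTH_TOPS_CM
    assert (dp.table["frp_mean"] >= 0).all() and (dp.table["frp_se"] >= 0).all()
    assert (dp.table["frp_mean"] <= max(prof.means)).all()


def test_hardwood_deep_windows_near_zero():
    """The extrapolated hardwood profile vanishes below 70 cm, matching the
    published 0.00 carbon entries there."""
    prof = _profile("hardwood_peat")
    sm_mean, _ = prof.smoothers()
    dp = predict_grid(sm_mean, label=prof.label)
    deep = dp.table[dp.table["depth_top_cm"] >= 77.5]["frp_mean"]
    assert (deep < 0.2).all()


def test_monotone_inputs_never_exceed_surface_mean():
    y = np.array([20.0, 12.0, 6.0, 2.0, 0.5])
    sm = fit_loess(MIDS, y, span=1.0, degree=1)
    grid = np.asarray(PREDICTION_DEPTH_TOPS_CM) + 1.25
    assert (sm.predict(grid) <= 20.0 + 1e-9).all()


def test_bin_profile_constant_and_arithmetic():
    prof = _profile("palm_peat")
    sm_mean, sm_se = prof.smoothers()
    dp = predict_grid(sm_mean, sm_se, label="x")
    # constant profile
    const = dp.table.copy()
    const["frp_mean"] = 4.0
    from rootflux.profiles import DepthProfile

    binned = bin_profile(DepthProfile(label="c", table=const))
    np.testing.assert_allclose(binned.table["frp_mean"], 4.0)
    # explicit arithmetic in the first bin
    custom = dp.table.copy()
    custom.loc[custom.index[:4], "frp_mean"] = [8.0, 6.0, 4.0, 2.0]
    binned = bin_profile(DepthProfile(label="a", table=custom))
    assert binned.table["frp_mean"].iloc[0] == pytest.approx(5.0)


def test_binning_conserves_grid_average():
    prof = _profile("terra_firme")
    sm_mean, sm_se = prof.smoothers()
    dp = predict_grid(sm_mean, sm_se, label="tf")
    binned = bin_profile(dp)
    assert binned.table["frp_mean"].mean() == pytest.approx(
        dp.table["frp_mean"].mean(), rel=1e-12
    )


def test_midpoint_partition_weights():
    w = midpoint_partition_weights()
    np.testing.assert_allclose(w * 75.0, [4.25, 8.0, 15.0, 27.5, 20.25])
    assert w.sum() == pytest.approx(1.0)
    with pytest.raises(ValueError, match="max_depth"):
        midpoint_partition_weights(max_depth_cm=50.0)


def test_depth_weighted_means_reproduce_published_values():
    assert round(depth_weighted_mean(_profile("terra_firme")), 1) == 4.1
    hw = depth_weighted_mean(_profile("hardwood_peat"))
    assert 4.6 <= hw <= 4.7
    const = DepthMeansProfile(
        label="c", midpoints_cm=tuple(MIDS), means=(2.0,) * 5, ses=(0.1,) * 5
    )
    assert depth_weighted_mean(const) == pytest.approx(2.0)


def test_depth_means_from_observations_structure(default_obs):
    profs = depth_means_from_observations(default_obs)
    assert [p.label for p in profs] == ["terra_firme", "hardwood_peat", "palm_peat"]
    by_season = depth_means_from_observations(default_obs, by_season=True)
    assert len(by_season) == 9
    for p in profs:
        assert all(s >= 0 for s in p.ses)


def test_depth_means_profile_validation():
    with pytest.raises(ValueError, match="midpoints"):
        DepthMeansProfile("x", (1.0, 2.0, 3.0, 4.0, 5.0), (1,) * 5, (0,) * 5)
    with pytest.raises(ValueError, match="non-negative"):
        DepthMeansProfile("x", tuple(MIDS), (1, 1, 1, 1, -1), (0,) * 5)
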