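"""Tweedie regression: likelihood, Type-III tests, marginal means, Tukey, AICc."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from rootflux.data import ECOSYSTEMS, MEASURED_DEPTH_TOPS_CM, SEASONS
from rootflux.model import (
    FitError,
    ModelSpec,
    aicc_compare,
    build_design,
    fit,
    marginal_means,
    pairwise_tukey,
    type3_anova,
)
from rootflux.simulate import default_generator_spec, generate_study
from rootflux.tables import measured_depth_means
from rootflux.tweedie import tweedie_loglike


def _constant_frame(c: float, n_tubes: int = 2) -> pd.DataFrame:
    rows = list(
        itertools.product(ECOSYSTEMS, range(1, n_tubes + 1), SEASONS, MEASURED_DEPTH_TOPS_CM)
    )
    df = pd.DataFrame(rows, columns=["ecosystem", "tube_id", "season", "depth_top_cm"])
    df["frp_length"] = c
    return df


def test_intercept_only_on_constant_data_is_log_mean():
    df = _constant_frame(3.7)
    fx = fit(df, ModelSpec(fixed_terms=(), power_grid=(1.5,)))
    assert fx.beta_hat.iloc[0] == pytest.approx(np.log(3.7), abs=1e-8)


def test_fit_is_deterministic(small_obs):
    spec = ModelSpec(power_grid=(1.5, 1.6, 1.7))
    a = fit(small_obs, spec)
    b = fit(small_obs, spec)
    np.testing.assert_allclose(a.beta_hat.values, b.beta_hat.values, rtol=1e-12)
    assert a.power_hat == b.power_hat and a.phi_hat == b.phi_hat


def test_all_zero_response_is_fit_error():
    df = _constant_frame(0.0)
    with pytest.raises(FitError, match="zero"):
        fit(df, ModelSpec(power_grid=(1.6,)))


def test_profile_likelihood_selects_generating_power(default_obs):
    fx = fit(default_obs, ModelSpec(power_grid=(1.2, 1.4, 1.6, 1.8)))
    assert fx.power_hat == pytest.approx(1.6, abs=0.2001)
    # the profile is evaluated at every grid point
    assert len(fx.profile) == 4
    assert fx.loglik == fx.profile["loglik"].max()


def test_likelihood_beats_brute_force_grid():
    """On a small sample the fitted (β₀, φ) dominates a coarse grid search."""
    rng = np.random.default_rng(3)
    y = np.round(rng.gamma(1.2, 2.0, size=18), 3)
    y[rng.random(18) < 0.4] = 0.0
    df = _constant_frame(1.0, n_tubes=1).iloc[: len(y)].copy()
    df["frp_length"] = y
    fx = fit(df, ModelSpec(fixed_terms=(), power_grid=(1.5,)))
    best_grid = max(
        tweedie_loglike(y, np.full_like(y, np.exp(b0)), 1.5, phi)
        for b0 in np.linspace(-1.0, 2.0, 31)
        for phi in np.linspace(0.2, 6.0, 30)
    )
    assert fx.loglik >= best_grid - 1e-6


def test_anova_df_structure(default_obs):
    fx = fit(default_obs, ModelSpec(power_grid=(1.6,)))
    an = type3_anova(fx).table.set_index("term")
    expected = {
        "ecosystem": 2,
        "season": 2,
        "depth": 4,
        "ecosystem:season": 4,
        "ecosystem:depth": 8,
        "season:depth": 8,
    }
    for term, df_t in expected.items():
        assert an.loc[term, "df"] == df_t
    assert ((an["p_value"] >= 0) & (an["p_value"] <= 1)).all()


def test_collapsed_factor_dropped_from_anova(small_obs):
    one_depth = small_obs.subset(depth_top_cm=0.0)
    fx = fit(one_depth, ModelSpec(power_grid=(1.6,)))
    terms = set(type3_anova(fx).table["term"])
    assert not any("depth" in t for t in terms)
    assert "ecosystem" in terms


def test_anova_invariant_to_level_reordering(small_obs):
    df = small_obs.to_frame()
    base = type3_anova(fit(df, ModelSpec(power_grid=(1.6,)))).table.set_index("term")
    df2 = df.copy()
    df2["ecosystem"] = df2["ecosystem"].cat.reorder_categories(
        ["palm_peat", "terra_firme", "hardwood_peat"]
    )
    df2["season"] = df2["season"].cat.reorder_categories(
        ["long_dry", "short_wet", "long_wet"]
    )
    reord = type3_anova(fit(df2, ModelSpec(power_grid=(1.6,)))).table.set_index("term")
    for term in base.index:
        assert base.loc[term, "chi_square"] == pytest.approx(
            reord.loc[term, "chi_square"], rel=1e-6
        ), term


def test_marginal_means_invariant_on_constant_data():
    df = _constant_frame(5.0)
    fx = fit(df, ModelSpec(power_grid=(1.6,)))
    for by in [(), ("depth",), ("ecosystem", "season")]:
        mm = marginal_means(fx, by)
        np.testing.assert_allclose(mm.table["mean"], 5.0, rtol=1e-6)


def test_marginal_means_over_all_factors_reproduce_cell_means(small_obs):
    fx = fit(small_obs, ModelSpec(power_grid=(1.6,)))
    mm = marginal_means(fx, ("ecosystem", "season", "depth"))
    grid = mm.table[["ecosystem", "season", "depth_top_cm"]].copy()
    eta = fx.predict_eta(grid)
    np.testing.assert_allclose(mm.table["mean"], np.exp(eta), rtol=1e-10)
    assert len(mm) == 45


def test_marginal_mean_unknown_factor_rejected(small_obs):
    fx = fit(small_obs, ModelSpec(power_grid=(1.6,)))
    with pytest.raises(ValueError, match="unknown factor"):
        marginal_means(fx, ("plot",))


def test_depth_marginal_means_recover_generating_emmeans():
    """Near-noiseless data at the published cell means ⇒ depth emmeans at the
    link-scale cell-mean averages of the generating model.

    Marginal means average on the log scale (the emmeans convention), so
    the depth-level estimand is the geometric mean of the cells, not the
    arithmetic row average — which is reproduced by the raw-averages path.
    """
    from rootflux.simulate import _default_cell_log_means

    spec = dataclasses.replace(
        default_generator_spec(seed=5, n_tubes=16), tube_sd=0.0, phi=0.05
    )
    obs = generate_study(spec)
    fx = fit(obs, ModelSpec(power_grid=(1.6,)))
    mm = marginal_means(fx, ("depth",)).table.set_index("depth_top_cm")
    truth = np.exp(_default_cell_log_means().groupby("depth_top_cm").mean())
    for d in truth.index:
        assert mm.loc[d, "mean"] == pytest.approx(truth.loc[d], rel=0.05), d


def test_marginal_mean_se_shrinks_like_sqrt_n():
    ses = {}
    for n_tubes in (16, 64):
        spec = dataclasses.replace(
            default_generator_spec(seed=2, n_tubes=n_tubes), tube_sd=0.0
        )
        fx = fit(generate_study(spec), ModelSpec(power_grid=(1.6,)))
        ses[n_tubes] = marginal_means(fx, ("depth",)).table["se_eta"].mean()
    ratio = ses[16] / ses[64]
    assert ratio == pytest.approx(2.0, rel=0.35)


def test_tukey_row_count_and_identical_levels(small_obs):
    fx = fit(small_obs, ModelSpec(power_grid=(1.6,)))
    for by, k in [(("ecosystem",), 3), (("depth",), 5), (("ecosystem", "season"), 9)]:
        tk = pairwise_tukey(marginal_means(fx, by))
        assert len(tk) == k * (k - 1) // 2
        assert ((tk["p_adj"] >= 0) & (tk["p_adj"] <= 1)).all()


def test_tukey_identical_means_give_p_one():
    df = _constant_frame(2.0)
    fx = fit(df, ModelSpec(power_grid=(1.6,)))
    tk = pairwise_tukey(marginal_means(fx, ("ecosystem",)))
    np.testing.assert_allclose(tk["estimate"], 0.0, atol=1e-8)
    np.testing.assert_allclose(tk["p_adj"], 1.0, atol=1e-6)


def test_tukey_single_level_empty(small_obs):
    one = small_obs.subset(ecosystem="terra_firme")
    fx = fit(one, ModelSpec(power_grid=(1.6,)))
    mm = marginal_means(fx, ("ecosystem",))
    assert len(pairwise_tukey(mm)) == 0


def test_aicc_identical_fits_tie(small_obs):
    a = fit(small_obs, ModelSpec(power_grid=(1.6,)))
    b = fit(small_obs, ModelSpec(power_grid=(1.6,)))
    cmp = aicc_compare([a, b])
    assert cmp["delta_aicc"].iloc[1] == pytest.approx(0.0, abs=1e-9)


def test_aicc_requires_identical_n(small_obs):
    a = fit(small_obs, ModelSpec(power_grid=(1.6,)))
    b = fit(small_obs.subset(season="long_dry"), ModelSpec(power_grid=(1.6,)))
    with pytest.raises(ValueError, match="sample sizes"):
        aicc_compare([a, b])


def test_aicc_correction_divergence_flagged():
    from rootflux.model import _aicc

    assert np.isinf(_aicc(-10.0, k=9, n=10))
    assert np.isfinite(_aicc(-10.0, k=8, n=10))


def test_rank_deficient_design_names_problem():
    df = _constant_frame(1.0)
    df = df[df["season"] == "long_dry"]  # single season level retained below
    X, info, _ = build_design(df, ("ecosystem",))
    # duplicating a column makes the design singular
    import patsy

    mat = np.hstack([X, X[:, -1:]])
    from rootflux.model import _check_design

    with pytest.raises(FitError, match="rank-deficient"):
        _check_design(mat, list(info.column_names) + ["dup"])


def test_random_intercept_fit_improves_marginal_likelihood():
    spec = dataclasses.replace(
        default_generator_spec(seed=3, n_tubes=4), tube_sd=0.8
    )
    obs = generate_study(spec)
    fixed = fit(obs, ModelSpec(fixed_terms=("depth",), power_grid=(1.6,)))
    mixed = fit(
        obs,
        ModelSpec(fixed_terms=("depth",), power_grid=(1.6,), include_tube_intercept=True),
    )
    assert mixed.tube_sigma is not None and mixed.tube_sigma > 0
    assert mixed.loglik >= fixed.loglik - 1e-6
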