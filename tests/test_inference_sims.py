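"""Repeated-simulation validation of the estimator and its inference.

These simulations run in an information-adequate regime: the factorial
design and Table-shaped mean structure of the study, but dispersion φ = 2
(≈16% exact zeros) so that maximum-likelihood regularity holds and the
classical sampling properties (unbiasedness to O(1/n), nominal Wald
coverage and test size) are the correct yardstick.  The behaviour of the
same estimator under the study's own extreme zero inflation (≈75% zeros)
is measured separately in the acceptance suite and discussed in the
methods note.
"""

import dataclasses

import numpy as np
import pytest

from rootflux.model import ModelSpec, fit, marginal_means, pairwise_tukey, type3_anova
from rootflux.simulate import (
    _default_cell_log_means,
    beta_from_cell_means,
    default_generator_spec,
    generate_study,
)

N_REP = 200
MODERATE_PHI = 2.0


def _moderate_spec(seed=0):
    return dataclasses.replace(
        default_generator_spec(seed=seed), tube_sd=0.0, phi=MODERATE_PHI
    )


def _ecosystem_null_spec(seed=0):
    """Depth and season effects as calibrated; every ecosystem effect zero."""
    lm = _default_cell_log_means()
    null = lm.groupby(["season", "depth_top_cm"], observed=True).transform("mean")
    null.index = lm.index
    return dataclasses.replace(_moderate_spec(seed), beta=beta_from_cell_means(null))


@pytest.fixture(scope="module")
def recovery_fits():
    spec0 = _moderate_spec()
    est, se = [], []
    for r in range(N_REP):
        obs = generate_study(dataclasses.replace(spec0, seed=30_000 + r))
        fx = fit(obs, ModelSpec(power_grid=(1.6,)))
        est.append(fx.beta_hat.values)
        se.append(np.sqrt(np.diag(fx.cov_beta.values)))
    return spec0, np.array(est), np.array(se)


def test_depth_contrast_bias_small(recovery_fits):
    spec0, est, _ = recovery_fits
    depth_cols = [
        i for i, n in enumerate(spec0.beta.index) if "depth" in n and ":" not in n
    ]
    bias = est.mean(axis=0) - spec0.beta.values
    assert np.abs(bias[depth_cols]).max() < 0.1
    # the implicit fifth (sum-to-zero) depth contrast
    assert abs(bias[depth_cols].sum()) < 0.1


def test_wald_coverage_near_nominal(recovery_fits):
    spec0, est, se = recovery_fits
    cover = np.abs(est - spec0.beta.values) <= 1.96 * se
    # binomial 95% bounds for a 0.95 proportion over 200 replicates
    assert 0.9198 <= cover.mean() <= 0.9802


def test_type3_power_and_size():
    """Strong depth effect detected essentially always; ecosystem test holds
    its nominal 5% level under the ecosystem-null generator."""
    spec = _ecosystem_null_spec()
    p_depth, p_eco = [], []
    for r in range(N_REP):
        obs = generate_study(dataclasses.replace(spec, seed=40_000 + r))
        an = type3_anova(fit(obs, ModelSpec(power_grid=(1.6,)))).table.set_index("term")
        p_depth.append(an.loc["depth", "p_value"])
        p_eco.append(an.loc["ecosystem", "p_value"])
    assert np.mean(np.array(p_depth) < 0.05) >= 0.80
    assert 0.0198 <= np.mean(np.array(p_eco) < 0.05) <= 0.0802


def test_tukey_familywise_error_near_nominal():
    """Under the ecosystem null, any significant pairwise ecosystem contrast
    counts as a family error; the rate should sit at the Tukey 5% level."""
    spec = _ecosystem_null_spec()
    hits = []
    for r in range(N_REP):
        obs = generate_study(dataclasses.replace(spec, seed=50_000 + r))
        fx = fit(obs, ModelSpec(power_grid=(1.6,)))
        tk = pairwise_tukey(marginal_means(fx, ("ecosystem",)))
        hits.append((tk["p_adj"] < 0.05).any())
    assert 0.0198 <= np.mean(hits) <= 0.0802 + 0.02  # small upward allowance:
    # the three contrasts share one estimated dispersion


def test_aicc_prefers_simpler_model_on_null_term():
    """A spurious season term on season-null data loses the AICc ranking in
    the clear majority of replicates (theory: P(χ²₂ < 2·2+ε) ≈ 0.86)."""
    from rootflux.model import aicc_compare

    lm = _default_cell_log_means()
    no_season = lm.groupby(
        [lm.index.get_level_values("ecosystem"), lm.index.get_level_values("depth_top_cm")],
        observed=True,
    ).transform("mean")
    no_season.index = lm.index
    spec = dataclasses.replace(
        _moderate_spec(),
        beta=beta_from_cell_means(no_season),
        n_tubes=4,
    )
    wins = 0
    for r in range(N_REP):
        obs = generate_study(dataclasses.replace(spec, seed=60_000 + r))
        simple = fit(obs, ModelSpec(fixed_terms=("ecosystem", "depth", "ecosystem:depth"),
                                    power_grid=(1.6,)))
        spurious = fit(
            obs,
            ModelSpec(
                fixed_terms=("ecosystem", "season", "depth", "ecosystem:depth"),
                power_grid=(1.6,),
            ),
        )
        ranking = aicc_compare([simple, spurious])
        wins += ranking["model"].iloc[0] == 0
    assert wins / N_REP > 0.6
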