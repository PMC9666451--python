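"""Sampler behaviour, convergence diagnostics, HDIs, and predictions."""

import numpy as np
import pytest

from karstocc.design import TransformSpec
from karstocc.inference import (
    ChainSet,
    McmcConfig,
    bayesian_p_value,
    compute_hdi,
    compute_rhat,
    fit,
    gelman_rubin,
    predict_occurrence,
    summarize,
)
from karstocc.exceptions import ConfigError
from karstocc.model import (
    PARAM_NAMES,
    ModelCoefficients,
    PriorSpec,
    ozark_coefficients,
)
from karstocc.simulate import Scenario, generate_study
from karstocc.design import transform_covariates

from conftest import intercept_only_designs


def _independent_psrf(x):
    """Second, deliberately naive implementation of the B/W formula."""
    m, n = x.shape
    chain_means = [sum(row) / n for row in x]
    grand = sum(chain_means) / m
    b_over_n = sum((cm - grand) ** 2 for cm in chain_means) / (m - 1)
    w = sum(
        sum((v - cm) ** 2 for v in row) / (n - 1) for row, cm in zip(x, chain_means)
    ) / m
    return ((n - 1) / n * w + b_over_n) ** 0.5 / w ** 0.5


def test_rhat_near_one_for_identically_distributed_chains():
    rng = np.random.default_rng(0)
    chains = rng.standard_normal((2, 10000))
    r = gelman_rubin(chains)
    assert 0.99 <= r <= 1.01
    assert r == pytest.approx(_independent_psrf(chains), rel=1e-10)


def test_rhat_flags_separated_chains():
    rng = np.random.default_rng(1)
    chains = np.vstack(
        [rng.normal(0, 1, size=2000), rng.normal(5, 1, size=2000)]
    )
    r = gelman_rubin(chains)
    assert r > 1.1
    assert r == pytest.approx(_independent_psrf(chains), rel=1e-10)


def test_rhat_nan_for_constant_chains():
    with pytest.warns(UserWarning, match="constant"):
        assert np.isnan(gelman_rubin(np.full((2, 100), 3.0)))


def test_hdi_shortest_window_with_first_tie_winner():
    samples = np.arange(1, 101, dtype=float)
    # all 6 windows of 95 consecutive integers have width 94; first wins
    assert compute_hdi(samples, 0.95) == (1.0, 95.0)


def test_hdi_matches_normal_quantiles():
    rng = np.random.default_rng(2)
    low, high = compute_hdi(rng.standard_normal(200_000), 0.95)
    assert low == pytest.approx(-1.96, abs=0.05)
    assert high == pytest.approx(1.96, abs=0.05)


def test_hdi_agrees_with_arviz_on_skewed_samples():
    az = pytest.importorskip("arviz")
    rng = np.random.default_rng(3)
    samples = rng.gamma(2.0, 1.0, size=100_000)
    ours = compute_hdi(samples, 0.95)
    theirs = az.hdi(samples, hdi_prob=0.95)
    assert ours[0] == pytest.approx(theirs[0], abs=0.05)
    assert ours[1] == pytest.approx(theirs[1], abs=0.05)


def test_hdi_degenerate_and_input_checks():
    assert compute_hdi(np.full(25, 4.2)) == (4.2, 4.2)
    with pytest.raises(ValueError):
        compute_hdi(np.arange(10))
    with pytest.raises(ValueError):
        compute_hdi(np.arange(100), mass=1.2)


def _small_fit(seed=0, **kwargs):
    rng = np.random.default_rng(42)
    y = rng.integers(0, 2, size=(2, 30)).astype(np.int8)
    det, occ = intercept_only_designs(y, n_units=10)
    config = McmcConfig(n_iterations=600, n_burnin=100, seed=seed)
    return det, occ, fit(det, occ, config=config, **kwargs)


def test_fit_is_deterministic_under_fixed_seed():
    _, _, first = _small_fit(seed=5)
    _, _, second = _small_fit(seed=5)
    np.testing.assert_array_equal(first.draws, second.draws)
    np.testing.assert_array_equal(first.z_draws, second.z_draws)
    _, _, third = _small_fit(seed=6)
    assert not np.array_equal(first.draws, third.draws)


def test_detected_units_always_occupied_in_every_draw():
    det, occ, chains = _small_fit(seed=1)
    any_det = det.any_detection
    for i in range(2):
        detected = np.where(any_det[i])[0]
        assert np.all(chains.z_draws[:, :, i, detected] == 1)


def test_perfect_detection_recovers_naive_occupancy():
    """With p pinned near 1, mean posterior psi equals the detected fraction."""
    rng = np.random.default_rng(7)
    n_units, k = 100, 2
    z = (rng.random(n_units) < 0.6).astype(np.int8)
    y = np.vstack([np.repeat(z, k), np.repeat(z, k)]).astype(np.int8)
    det, occ = intercept_only_designs(y, n_units=n_units)
    lower = np.full(len(PARAM_NAMES), -10.0)
    upper = np.full(len(PARAM_NAMES), 10.0)
    for name in ("cave_crayfish_det_intercept", "cavefish_det_intercept"):
        lower[PARAM_NAMES.index(name)] = 9.5  # pins p = logit^-1(~9.75) ~ 1
    prior = PriorSpec(lower=lower, upper=upper)
    config = McmcConfig(n_iterations=2000, n_burnin=500, seed=11)
    chains = fit(det, occ, prior, config)
    frac = z.mean()
    from scipy.special import expit

    for name in ("cave_crayfish_occ_intercept", "cavefish_occ_intercept"):
        psi_mean = expit(chains.pooled(name)).mean()
        assert psi_mean == pytest.approx(frac, abs=0.05)


def test_config_invariants_enforced():
    with pytest.raises(ConfigError):
        McmcConfig(n_iterations=100, n_burnin=100)
    with pytest.raises(ConfigError):
        McmcConfig(n_chains=1)
    with pytest.raises(ConfigError):
        McmcConfig(thin=0)
    assert McmcConfig(n_iterations=55_000, n_burnin=5_000).n_retained == 50_000


def _constant_chainset(theta, n=30, z=None):
    draws = np.tile(theta, (2, n, 1))
    z_draws = None if z is None else np.tile(z.astype(np.int8), (2, n, 1, 1))
    return ChainSet(
        draws=draws,
        param_names=PARAM_NAMES,
        acceptance=np.zeros((2, len(PARAM_NAMES))),
        config=McmcConfig(n_iterations=n + 1, n_burnin=0),
        z_draws=z_draws,
    )


def test_summarize_degenerate_chains():
    theta = ozark_coefficients().to_vector()
    summary = summarize(_constant_chainset(theta))
    assert summary["mean"].to_numpy() == pytest.approx(theta)
    assert summary["sd"].to_numpy() == pytest.approx(0.0, abs=1e-12)
    assert summary["hdi_low"].to_numpy() == pytest.approx(theta)
    assert summary["rhat"].isna().all()


def test_summarize_recovers_known_moments():
    rng = np.random.default_rng(9)
    draws = rng.normal(2.83, 1.20, size=(2, 20000, 1))
    chainset = ChainSet(
        draws=draws, param_names=("lithology_effect",),
        acceptance=np.zeros((2, 1)),
        config=McmcConfig(n_iterations=20001, n_burnin=0),
    )
    row = summarize(chainset).iloc[0]
    assert row["mean"] == pytest.approx(2.83, abs=0.03)
    assert row["sd"] == pytest.approx(1.20, abs=0.03)
    assert row["rhat"] == pytest.approx(1.0, abs=0.01)


def _tspec():
    return TransformSpec(
        log_transformed=frozenset({"volume", "disturbance"}),
        standardization={"disturbance": (0.5, 0.6), "volume": (3.0, 1.3)},
    )


def test_predict_flat_when_disturbance_slope_is_zero():
    values = {name: 0.0 for name in PARAM_NAMES}
    values["cave_crayfish_occ_intercept"] = -1.0
    values["cave_crayfish_occ_lithology"] = 0.5
    theta = ModelCoefficients.from_dict(values).to_vector()
    chains = _constant_chainset(theta)
    from scipy.special import expit

    grid = np.linspace(1.0, 8.67, 9)
    dolo = predict_occurrence(chains, _tspec(), grid, "dolostone", "cave_crayfish")
    assert dolo["mean"].to_numpy() == pytest.approx(expit(-1.0))
    lime = predict_occurrence(chains, _tspec(), grid, "limestone", "cave_crayfish")
    assert lime["mean"].to_numpy() == pytest.approx(expit(-0.5))


def test_predict_monotone_decreasing_for_negative_slope_and_lithology_offset():
    values = {name: 0.0 for name in PARAM_NAMES}
    values["cave_crayfish_occ_intercept"] = -0.5
    values["cave_crayfish_occ_disturbance"] = -2.0
    values["cave_crayfish_occ_lithology"] = 2.83
    theta = ModelCoefficients.from_dict(values).to_vector()
    chains = _constant_chainset(theta)
    grid = np.linspace(1.0, 8.67, 12)
    dolo = predict_occurrence(chains, _tspec(), grid, "dolostone", "cave_crayfish")
    assert np.all(np.diff(dolo["mean"].to_numpy()) < 0)
    lime = predict_occurrence(chains, _tspec(), grid, "limestone", "cave_crayfish")
    logit = lambda p: np.log(p / (1 - p))  # noqa: E731
    offset = logit(lime["mean"].to_numpy()) - logit(dolo["mean"].to_numpy())
    assert offset == pytest.approx(2.83, abs=1e-9)


def test_predict_warns_outside_index_range():
    chains = _constant_chainset(np.zeros(len(PARAM_NAMES)))
    with pytest.warns(UserWarning, match="extrapolat"):
        predict_occurrence(chains, _tspec(), [0.5, 2.0], "dolostone", "cavefish")


def test_bayesian_p_value_single_draw_is_binary():
    study, truth = generate_study(Scenario(n_units=15), seed=21)
    det, occ, _ = transform_covariates(study)
    chains = _constant_chainset(
        truth.coefficients.to_vector(), n=1, z=truth.realized_z
    )
    value = bayesian_p_value(
        chains, det, occ, statistic="freeman_tukey", n_draws=1, seed=0
    )
    assert value in (0.0, 1.0)


def test_bayesian_p_value_detects_gross_misspecification():
    """Data generated with detection suppressed far below the evaluated
    coefficients push the predictive p-value out of the adequacy band."""
    truth = ozark_coefficients()
    weak = truth.to_dict()
    weak["cave_crayfish_det_intercept"] -= 3.0
    weak["cavefish_det_intercept"] -= 3.0
    study, gen_truth = generate_study(
        Scenario(n_units=61), seed=5,
        coefficients=ModelCoefficients.from_dict(weak),
    )
    det, occ, _ = transform_covariates(study)
    chains = _constant_chainset(truth.to_vector(), n=300, z=gen_truth.realized_z)
    value = bayesian_p_value(chains, det, occ, n_draws=300, seed=1)
    assert value < 0.10 or value > 0.90


def test_compute_rhat_dispatches_on_chainset():
    _, _, chains = _small_fit(seed=2)
    name = "cave_crayfish_occ_intercept"
    direct = gelman_rubin(chains.chains_of(name))
    assert compute_rhat(chains, name) == direct
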