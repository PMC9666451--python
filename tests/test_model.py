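"""Likelihood machinery: link functions, joint density, unit marginals."""

import itertools
import math

import numpy as np
import pytest

from karstocc.design import DetectionDesign, OccurrenceDesign
from karstocc.model import (
    ModelCoefficients,
    N_PARAMS,
    PriorSpec,
    detection_probability,
    joint_log_density,
    marginal_log_likelihood,
    marginal_unit_likelihood,
    occurrence_probability,
    ozark_coefficients,
    posterior_predictive_discrepancy,
)

from conftest import intercept_only_designs


def _coefs(occ0=0.0, det0=0.0):
    det = np.zeros((2, 8))
    occ = np.zeros((2, 3))
    det[:, 0] = det0
    occ[:, 0] = occ0
    return ModelCoefficients(det=det, occ=occ)


def _inv_logit(x):  # independent of scipy.special.expit
    return 1.0 / (1.0 + math.exp(-x))


def test_occurrence_probability_examples():
    coefs = _coefs()
    assert occurrence_probability(coefs, [1, 0, 0], "cave_crayfish") == 0.5
    coefs = _coefs(occ0=-2.45)
    p = occurrence_probability(coefs, [1, 0, 0], "cave_crayfish")
    assert p == pytest.approx(_inv_logit(-2.45), abs=1e-12)
    assert p == pytest.approx(0.0794, abs=5e-4)
    # limestone effect: logit^-1(-2.45 + 2.83) ~ 0.594
    occ = np.zeros((2, 3))
    occ[0] = [-2.45, 0.0, 2.83]
    coefs = ModelCoefficients(det=np.zeros((2, 8)), occ=occ)
    p_lime = occurrence_probability(coefs, [1, 0, 1], 0)
    assert p_lime == pytest.approx(_inv_logit(0.38), abs=1e-12)
    assert p_lime == pytest.approx(0.594, abs=1e-3)


def test_detection_probability_examples_and_monotonicity():
    assert detection_probability(_coefs(), [1, 0, 0, 0, 0, 0, 0, 0], 0) == 0.5
    p = detection_probability(_coefs(det0=-0.17), [1, 0, 0, 0, 0, 0, 0, 0], 0)
    assert p == pytest.approx(_inv_logit(-0.17), abs=1e-12)
    assert p == pytest.approx(0.4576, abs=5e-4)
    row = [1, 1, 0, 0, 1, 0.3, 0, 0]
    values = [
        detection_probability(_coefs(det0=a), row, 1) for a in (-1.0, 0.0, 1.0, 2.0)
    ]
    assert values == sorted(values)


def test_marginal_unit_likelihood_worked_values():
    assert marginal_unit_likelihood(0.5, [0.5, 0.5], [0, 0]) == pytest.approx(0.625)
    assert marginal_unit_likelihood(1.0, [0.8, 0.4], [1, 0]) == pytest.approx(0.48)
    assert marginal_unit_likelihood(0.0, [0.3, 0.9], [0, 0]) == pytest.approx(1.0)


def test_marginal_unit_likelihood_perfect_detection_limits():
    psi = 0.37
    assert marginal_unit_likelihood(psi, [1.0, 1.0], [0, 0]) == pytest.approx(1 - psi)
    assert marginal_unit_likelihood(psi, [1.0, 1.0], [1, 1]) == pytest.approx(psi)
    assert marginal_unit_likelihood(psi, [1.0, 1.0], [1, 0]) == pytest.approx(0.0)


@pytest.mark.parametrize("n_units,n_surveys", list(itertools.product([1, 2, 3], [1, 2, 3])))
def test_marginal_matches_brute_force_enumeration(n_units, n_surveys):
    """z-marginalized unit likelihood == explicit sum over latent states."""
    rng = np.random.default_rng(100 * n_units + n_surveys)
    for _ in range(5):
        psi = rng.uniform(0.05, 0.95)
        p = rng.uniform(0.05, 0.95, size=n_surveys)
        y = rng.integers(0, 2, size=n_surveys)
        brute = 0.0
        for z in (0, 1):
            term = psi if z else 1 - psi
            for pk, yk in zip(p, y):
                q = z * pk
                term *= q if yk else 1 - q
            brute += term
        ours = marginal_unit_likelihood(psi, p, y)
        assert ours == pytest.approx(brute, rel=1e-12)


def _random_instance(rng, n_units, k):
    det = DetectionDesign(
        matrix=np.column_stack(
            [np.ones(n_units * k), rng.normal(size=(n_units * k, 7))]
        ),
        unit_index=np.repeat(np.arange(n_units), k),
        y=rng.integers(0, 2, size=(2, n_units * k)).astype(np.int8),
        n_units=n_units,
        survey_keys=[("U", s, "eDNA") for s in range(n_units * k)],
    )
    occ = OccurrenceDesign(
        matrix=np.column_stack([np.ones(n_units), rng.normal(size=(n_units, 2))]),
        unit_ids=[f"U{j}" for j in range(n_units)],
        site_ids=[f"S{j}" for j in range(n_units)],
    )
    det_c = rng.uniform(-2, 2, size=(2, 8))
    det_c[1, 1] = det_c[0, 1]
    det_c[1, 3] = det_c[0, 3]
    coefs = ModelCoefficients(det=det_c, occ=rng.uniform(-2, 2, size=(2, 3)))
    return det, occ, coefs


@pytest.mark.parametrize("n_units,k", list(itertools.product([1, 2, 3], [1, 3])))
def test_joint_density_sums_to_marginal_times_prior(n_units, k):
    """Sum over all 2^(2J) latent configurations of exp(joint log density)
    equals the prior mass times the product of unit marginals."""
    rng = np.random.default_rng(7 * n_units + k)
    det, occ, coefs = _random_instance(rng, n_units, k)
    prior = PriorSpec()
    total = 0.0
    for flat in itertools.product((0, 1), repeat=2 * n_units):
        z = np.array(flat).reshape(2, n_units)
        ld = joint_log_density(coefs, z, det, occ, prior)
        if np.isfinite(ld):
            total += math.exp(ld)
    expected = math.exp(prior.log_density(coefs.to_vector()))
    for i in range(2):
        psi_all = 1 / (1 + np.exp(-(occ.matrix @ coefs.occ[i])))
        p_all = 1 / (1 + np.exp(-(det.matrix @ coefs.det[i])))
        for j in range(n_units):
            mask = det.unit_index == j
            expected *= marginal_unit_likelihood(
                psi_all[j], p_all[mask], det.y[i, mask]
            )
    assert total == pytest.approx(expected, rel=1e-10)
    # and the closed-form marginal log likelihood agrees too
    assert marginal_log_likelihood(coefs, det, occ) == pytest.approx(
        math.log(expected) - prior.log_density(coefs.to_vector()), rel=1e-10
    )


def test_joint_density_is_minus_inf_for_impossible_states():
    rng = np.random.default_rng(3)
    det, occ, coefs = _random_instance(rng, 2, 2)
    det.y[:] = 0
    det.y[0, 0] = 1  # taxon 0 detected at unit 0
    z = np.ones((2, 2))
    z[0, 0] = 0  # ... but declared absent
    assert joint_log_density(coefs, z, det, occ) == -np.inf


def test_joint_density_is_minus_inf_outside_prior_support():
    rng = np.random.default_rng(4)
    det, occ, coefs = _random_instance(rng, 1, 1)
    det.y[:] = 0
    narrow = PriorSpec(lower=-0.1, upper=0.1)
    z = np.zeros((2, 1))
    assert joint_log_density(coefs, z, det, occ, narrow) == -np.inf


def test_likelihood_invariant_under_survey_reordering():
    rng = np.random.default_rng(8)
    det, occ, coefs = _random_instance(rng, 3, 3)
    base = marginal_log_likelihood(coefs, det, occ)
    perm = rng.permutation(det.n_surveys)
    shuffled = DetectionDesign(
        matrix=det.matrix[perm],
        unit_index=det.unit_index[perm],
        y=det.y[:, perm],
        n_units=det.n_units,
        survey_keys=[det.survey_keys[p] for p in perm],
    )
    assert marginal_log_likelihood(coefs, shuffled, occ) == pytest.approx(base, rel=1e-12)


def test_unoccupied_unit_contributes_one_minus_psi():
    y = np.zeros((2, 2), dtype=np.int8)
    det, occ = intercept_only_designs(y, n_units=1)
    coefs = _coefs(occ0=0.7, det0=0.4)
    z = np.zeros((2, 1))
    prior = PriorSpec()
    ld = joint_log_density(coefs, z, det, occ, prior)
    psi = _inv_logit(0.7)
    expected = prior.log_density(coefs.to_vector()) + 2 * math.log(1 - psi)
    assert ld == pytest.approx(expected, rel=1e-12)


def test_discrepancy_requires_surveys():
    det = DetectionDesign(
        matrix=np.empty((0, 8)), unit_index=np.empty(0, dtype=int),
        y=np.empty((2, 0), dtype=np.int8), n_units=0, survey_keys=[],
    )
    with pytest.raises(ValueError):
        posterior_predictive_discrepancy(
            ozark_coefficients(), np.empty((2, 0)), det, np.random.default_rng(0)
        )


def test_coefficient_vector_round_trip():
    coefs = ozark_coefficients()
    theta = coefs.to_vector()
    assert theta.shape == (N_PARAMS,)
    back = ModelCoefficients.from_vector(theta)
    np.testing.assert_array_equal(back.det, coefs.det)
    np.testing.assert_array_equal(back.occ, coefs.occ)
    with pytest.raises(ValueError):
        bad = coefs.det.copy()
        bad[0, 1] += 1.0  # shared velocity term must match across taxa
        ModelCoefficients(det=bad, occ=coefs.occ)
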