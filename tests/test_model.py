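"""Detection function, linear predictor, priors, complete-data likelihood."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lionscr.model import (CaptureData, LatentState, ModelSpec, Parameters,
                           Priors, complete_data_loglik, detection_prob,
                           distance_term, linear_predictor, log_prior)


SPEC1 = ModelSpec.from_model_number(1)
TABLE_PARAMS = Parameters()   # defaults are the fitted posterior means


class TestDistanceTerm:
    @pytest.mark.parametrize("sigma,theta", [(0.5, 1.0), (2.0, 1.0), (1.0, 0.7)])
    def test_zero_distance(self, sigma, theta):
        assert distance_term(0.0, sigma, theta) == 0.0

    def test_algebraic_identity(self):
        assert distance_term(2.0 * math.sqrt(2) / 2 * 2, 2.0, 1.0) == pytest.approx(1.0)
        assert distance_term(1.82, 1.82, 1.0) == pytest.approx(0.5)

    def test_halving_sigma_quadruples_term(self):
        d = 1.82
        assert distance_term(d, 0.91, 1.0) == pytest.approx(
            4.0 * distance_term(d, 1.82, 1.0))

    def test_monotone_in_distance(self):
        d = np.linspace(0, 10, 50)
        f = distance_term(d, 1.5, 1.0)
        assert np.all(np.diff(f) > 0)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            distance_term(1.0, 0.0)


class TestLinearPredictor:
    def test_baseline_female_at_center(self):
        eta = linear_predictor(TABLE_PARAMS, sex=0, search_km=1.0, playback=0,
                               d=0.0, spec=SPEC1)
        assert eta == pytest.approx(math.log(0.003), abs=1e-9)
        assert eta == pytest.approx(-5.809, abs=1e-3)

    def test_playback_adds_its_coefficient(self):
        base = linear_predictor(TABLE_PARAMS, 0, 1.0, 0, 0.0, SPEC1)
        with_pb = linear_predictor(TABLE_PARAMS, 0, 1.0, 1, 0.0, SPEC1)
        assert with_pb - base == pytest.approx(0.28)

    def test_male_offset_is_beta_sex(self):
        shared = Parameters(sigma_f=1.9, sigma_m=1.9)
        f = linear_predictor(shared, 0, 1.0, 0, 0.0, SPEC1)
        m = linear_predictor(shared, 1, 1.0, 0, 0.0, SPEC1)
        assert m - f == pytest.approx(-0.33)

    def test_inactive_cell_occasion_rejected(self):
        with pytest.raises(ValueError, match="inactive"):
            linear_predictor(TABLE_PARAMS, 0, 0.0, 0, 1.0, SPEC1)

    def test_playback_only_cell_has_no_effort_term(self):
        eta = linear_predictor(TABLE_PARAMS, 0, 0.0, 1, 0.0, SPEC1)
        assert eta == pytest.approx(math.log(0.003) + 0.28)

    @settings(max_examples=40, deadline=None)
    @given(st.floats(0.05, 10.0), st.floats(0.05, 10.0), st.floats(0.0, 12.0))
    def test_detection_monotone_in_effort_and_distance(self, e1, e2, d):
        lo, hi = sorted([e1, e2])
        p_lo = detection_prob(linear_predictor(TABLE_PARAMS, 0, lo, 0, d, SPEC1))
        p_hi = detection_prob(linear_predictor(TABLE_PARAMS, 0, hi, 0, d, SPEC1))
        assert p_hi >= p_lo
        p_far = detection_prob(linear_predictor(TABLE_PARAMS, 0, hi, 0, d + 1.0, SPEC1))
        assert p_far <= p_hi


class TestDetectionProb:
    def test_small_rate_approximates_rate(self):
        assert detection_prob(math.log(0.003)) == pytest.approx(1 - math.exp(-0.003))
        assert detection_prob(math.log(0.003)) == pytest.approx(0.0029955, abs=1e-6)

    def test_closed_forms(self):
        assert detection_prob(0.0) == pytest.approx(1 - math.exp(-1))
        assert detection_prob(-np.inf) == 0.0

    def test_strictly_increasing(self):
        eta = np.linspace(-8, 3, 100)
        assert np.all(np.diff(detection_prob(eta)) > 0)


class TestLogPrior:
    def test_uniform_psi_contributes_zero(self):
        spec = ModelSpec.from_model_number(3, include_playback=False)
        pr = Priors(sigma_upper=15.0)
        p1 = Parameters(psi=0.5, beta_eff=0.0)
        p2 = Parameters(psi=0.9, beta_eff=0.0)
        assert log_prior(p1, spec, pr) == pytest.approx(log_prior(p2, spec, pr))

    def test_out_of_support(self):
        spec = ModelSpec.from_model_number(1)
        bad = Parameters(sigma_f=20.0)   # above the Uniform(0, 15) support
        assert log_prior(bad, spec, Priors(sigma_upper=15.0)) == -math.inf

    def test_normal_beta_density(self):
        spec = ModelSpec.from_model_number(3, include_playback=False)
        pr = Priors(sigma_upper=15.0)
        base = log_prior(Parameters(beta_eff=0.0), spec, pr)
        shifted = log_prior(Parameters(beta_eff=10.0), spec, pr)
        assert base - shifted == pytest.approx(0.5)  # (10/10)^2 / 2


class TestCompleteDataLoglik:
    def test_single_detection_is_log_pi(self, tiny_instance):
        ss, traps, effort, data, spec, params = tiny_instance
        lat = LatentState(z=np.array([1, 0, 0]), s=np.array([0, 0, 0]),
                          sex=np.array([0, 0, 0]))
        ll = complete_data_loglik(params, lat, data, spec, ss)
        # reproduce by hand: one hit occasion 1, one miss occasion 2
        d = data.dist[np.asarray(ss.habitat)][0, 0]
        eta = linear_predictor(params, 0, effort.search_km[0, 0], 0, d, spec)
        pi = detection_prob(eta)
        expected = (math.log(pi) + math.log(1 - pi)              # hit + miss
                    + math.log(params.psi) + 2 * math.log(1 - params.psi)
                    + math.log(1 - params.psi_sex) + math.log(1 / 3))
        assert ll == pytest.approx(expected)

    def test_all_zero_included_individual_pays_miss_mass(self, tiny_instance):
        ss, traps, effort, data, spec, params = tiny_instance
        base = LatentState(z=np.array([1, 0, 0]), s=np.array([0, 0, 0]),
                           sex=np.array([0, 0, 0]))
        incl = LatentState(z=np.array([1, 1, 0]), s=np.array([0, 0, 0]),
                           sex=np.array([0, 0, 0]))
        d = data.dist[np.asarray(ss.habitat)][0, 0]
        eta = linear_predictor(params, 0, effort.search_km[0, 0], 0, d, spec)
        pi = detection_prob(eta)
        diff = complete_data_loglik(params, incl, data, spec, ss) \
            - complete_data_loglik(params, base, data, spec, ss)
        expected = (2 * math.log(1 - pi)            # two missed occasions
                    + math.log(params.psi) - math.log(1 - params.psi)
                    + math.log(1 - params.psi_sex) + math.log(1 / 3))
        assert diff == pytest.approx(expected)

    def test_invariant_to_relabeling_augmented(self, tiny_instance):
        ss, traps, effort, data, spec, params = tiny_instance
        a = LatentState(z=np.array([1, 1, 0]), s=np.array([0, 2, 1]),
                        sex=np.array([0, 1, 0]))
        b = LatentState(z=np.array([1, 0, 1]), s=np.array([0, 1, 2]),
                        sex=np.array([0, 0, 1]))
        assert complete_data_loglik(params, a, data, spec, ss) == pytest.approx(
            complete_data_loglik(params, b, data, spec, ss))

    def test_observed_must_be_included(self, tiny_instance):
        ss, traps, effort, data, spec, params = tiny_instance
        lat = LatentState(z=np.array([0, 0, 0]), s=np.zeros(3, int),
                          sex=np.zeros(3, int))
        with pytest.raises(ValueError):
            complete_data_loglik(params, lat, data, spec, ss)


class TestModelSpec:
    def test_four_models(self):
        combos = {ModelSpec.from_model_number(k): k for k in (1, 2, 3, 4)}
        structures = {(s.lambda0_sex_specific, s.sigma_sex_specific)
                      for s in combos}
        assert structures == {(True, True), (False, True), (False, False),
                              (True, False)}

    def test_param_names_follow_structure(self):
        assert "sigma" in ModelSpec.from_model_number(3).param_names()
        assert "sigma_f" in ModelSpec.from_model_number(2).param_names()
        assert "beta_sex" not in ModelSpec.from_model_number(2).param_names()
        assert "beta_sex" in ModelSpec.from_model_number(4).param_names()

    def test_capture_without_effort_rejected(self, tiny_instance):
        ss, traps, effort, data, spec, params = tiny_instance
        # force a detection into an inactive cell-occasion
        eff2 = type(effort)(search_km=np.array([[0.6, 0.0]]),
                            playback=np.zeros((1, 2), dtype=np.int8),
                            n_occasions=2)
        bad = CaptureData(y=np.array([[[0, 1]]], dtype=np.uint8),
                          sex_obs=data.sex_obs, effort=eff2,
                          dist=data.dist, trap_grid=traps)
        with pytest.raises(ValueError, match="effort"):
            bad.validate()
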