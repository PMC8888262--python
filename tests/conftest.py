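"""Shared fixtures: a tiny enumerable instance and a small fitted survey."""

import numpy as np
import pytest
from shapely.geometry import box

from lionscr.mcmc import ChainConfig, run
from lionscr.model import CaptureData, ModelSpec, Parameters
from lionscr.simulate import SimulationConfig, generate_dataset
from lionscr.state_space import build_state_space, distance_matrix, rasterize_effort


@pytest.fixture(scope="session")
def tiny_instance():
    """3 habitat pixels in a row, 1 trap cell, 2 occasions, M = 3.

    Small enough that the posterior over (z, s, sex) can be enumerated
    exhaustively; one observed individual with a single detection.
    """
    ss = build_state_space(box(0, 0, 3, 1), buffer_km=0.0, pixel_area_km2=1.0)
    seg = np.array([[0.2, 0.5], [0.8, 0.5]])
    tracks = [(seg, 1), (seg, 2)]
    traps, effort = rasterize_effort(tracks, [], 1.0, n_occasions=2)
    dist = distance_matrix(ss, traps)
    y = np.zeros((1, traps.n_traps, 2), dtype=np.uint8)
    y[0, 0, 0] = 1
    data = CaptureData(y=y, sex_obs=np.array([-1], dtype=np.int8),
                       effort=effort, dist=dist, trap_grid=traps)
    spec = ModelSpec(lambda0_sex_specific=True, sigma_sex_specific=True, M=3)
    params = Parameters(lambda0=0.5, sigma_f=0.8, sigma_m=1.5, beta_eff=1.0,
                        beta_eff2=0.0, beta_sex=0.4, psi=0.6, psi_sex=0.5)
    return ss, traps, effort, data, spec, params


@pytest.fixture(scope="session")
def oracle_posterior(tiny_instance):
    """Latent-only sampler run on the tiny instance, sized for the
    enumeration comparison.

    Eight independent chains give a chain-level standard error with enough
    degrees of freedom that the Monte-Carlo error bound is itself reliable;
    activity-center draws are strongly autocorrelated, so per-draw SEs
    would be far too optimistic.
    """
    ss, traps, effort, data, spec, params = tiny_instance
    cc = ChainConfig(seed=17, n_chains=8, n_iter=31000, burn_in=1000,
                     latent_stride=1, s_window=2)
    return run(spec, data, ss, cc, fix_params=params)


@pytest.fixture(scope="session")
def small_config():
    """A fast, small synthetic survey: 64 km^2, 12 occasions, M = 60."""
    spec = ModelSpec(lambda0_sex_specific=False, sigma_sex_specific=False, M=60)
    truth = Parameters(lambda0=0.02, sigma_f=1.5, sigma_m=1.5, beta_eff=2.0,
                       beta_eff2=0.3, beta_sex=0.0, psi=0.5, psi_sex=0.4)
    return SimulationConfig(seed=42, survey_area_km2=64.0, n_occasions=12,
                            km_per_occasion=20.0, n_playbacks=3, buffer_km=6.0,
                            M=60, truth=truth, spec=spec)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_fit(small_bundle, small_config):
    """A short but converged-enough fit of the small survey."""
    cc = ChainConfig(seed=9, n_chains=2, n_iter=1200, burn_in=200,
                     latent_stride=5)
    return run(small_config.spec, small_bundle.capture,
               small_bundle.state_space, cc)
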