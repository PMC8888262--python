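"""Observation and state model for unstructured spatial capture-recapture.

The population is embedded in an augmented super-population of ``M``
pseudo-individuals.  Each individual carries an inclusion indicator
``z ~ Bernoulli(psi)``, a sex ``~ Bernoulli(psi_sex)`` (1 = male) and a
latent activity center ``s`` uniform over habitat pixels.  Detection of an
included individual in trap cell ``j`` on occasion ``k`` is Bernoulli with
a complementary log-log linear predictor

    cloglog(pi_ijk) = log(lambda0) + beta_eff * log(effort_jk)
                      + beta_eff2 * playback_jk + beta_sex * sex_i
                      - (d_ij^2 / (2 sigma_sex^2))^theta

where ``d_ij`` is the distance (km) between the activity center and the
trap-cell centroid.  With ``theta = 1`` the distance term is the exponent
of a half-normal detection function; ``sigma`` is the spatial scale of
movement/detection.  Only cell-occasions with effort (search km > 0 or a
playback) enter the likelihood: a trap exists only where effort was
invested, so there can be no detection without effort.

Four candidate model structures are supported, differing in whether the
basal encounter rate (via the male cloglog offset ``beta_sex``) and/or
``sigma`` are sex-specific:

    1. both sex-specific    2. sigma only    3. neither    4. encounter rate only
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ModelSpec",
    "Parameters",
    "Priors",
    "LatentState",
    "CaptureData",
    "distance_term",
    "linear_predictor",
    "detection_prob",
    "complete_data_loglik",
    "log_prior",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Which of the four candidate model structures to fit.

    ``lambda0_sex_specific`` makes the basal encounter rate sex-specific
    through the male offset ``beta_sex`` on the cloglog scale (so the male
    basal rate is ``lambda0 * exp(beta_sex)``); ``sigma_sex_specific``
    splits the movement scale into female/male values.
    """

    lambda0_sex_specific: bool = True
    sigma_sex_specific: bool = True
    theta: float = 1.0
    M: int = 250
    include_playback: bool = True
    include_sex_beta: bool | None = None

    @property
    def sex_beta(self) -> bool:
        if self.include_sex_beta is None:
            return self.lambda0_sex_specific
        return self.include_sex_beta

    @property
    def sex_dependent_detection(self) -> bool:
        return self.sex_beta or self.sigma_sex_specific

    @classmethod
    def from_model_number(cls, number: int, **kw) -> "ModelSpec":
        table = {1: (True, True), 2: (False, True), 3: (False, False), 4: (True, False)}
        if number not in table:
            raise ValueError("model number must be 1-4")
        lam, sig = table[number]
        return cls(lambda0_sex_specific=lam, sigma_sex_specific=sig, **kw)

    def param_names(self) -> list[str]:
        names = []
        if self.sigma_sex_specific:
            names += ["sigma_f", "sigma_m"]
        else:
            names += ["sigma"]
        if self.sex_beta:
            names += ["beta_sex"]
        names += ["beta_eff"]
        if self.include_playback:
            names += ["beta_eff2"]
        names += ["lambda0", "psi", "psi_sex"]
        return names


@dataclass
class Parameters:
    """Model parameter vector.

    ``lambda0`` is the female basal encounter rate per occasion for an
    activity center at a trap-cell centroid with 1 km of search effort;
    ``sigma_f``/``sigma_m`` are movement scales in km (kept equal when the
    model shares sigma); ``psi`` is the augmentation inclusion probability
    and ``psi_sex`` the probability an individual is male.
    """

    lambda0: float = 0.003
    sigma_f: float = 1.82
    sigma_m: float = 2.00
    beta_eff: float = 3.65
    beta_eff2: float = 0.28
    beta_sex: float = -0.33
    psi: float = 0.47
    psi_sex: float = 0.32

    def __post_init__(self) -> None:
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be > 0")
        if self.sigma_f <= 0 or self.sigma_m <= 0:
            raise ValueError("sigma must be > 0")
        if not (0.0 <= self.psi <= 1.0 and 0.0 <= self.psi_sex <= 1.0):
            raise ValueError("psi and psi_sex must lie in [0, 1]")

    @property
    def lambda0_male(self) -> float:
        """Male basal encounter rate implied by the cloglog offset."""
        return self.lambda0 * math.exp(self.beta_sex)

    def sigma(self, sex, spec: ModelSpec):
        """sigma for sex 0 (female) / 1 (male), honouring the model structure."""
        sex = np.asarray(sex)
        if not spec.sigma_sex_specific:
            return np.broadcast_to(np.float64(self.sigma_f), sex.shape)
        return np.where(sex == 1, self.sigma_m, self.sigma_f)

    def tied(self, spec: ModelSpec) -> "Parameters":
        """Copy with structurally absent parameters tied/zeroed."""
        p = replace(self)
        if not spec.sigma_sex_specific:
            p = replace(p, sigma_m=p.sigma_f)
        if not spec.sex_beta:
            p = replace(p, beta_sex=0.0)
        if not spec.include_playback:
            p = replace(p, beta_eff2=0.0)
        return p

    def as_dict(self, spec: ModelSpec) -> dict[str, float]:
        out = {}
        for name in spec.param_names():
            out[name] = getattr(self, "sigma_f" if name == "sigma" else name)
        return out


@dataclass
class Priors:
    """Weakly-informative default priors (all configurable).

    psi, psi_sex ~ Uniform(0, 1); log(lambda0) ~ Uniform(-20, 5);
    sigma ~ Uniform(0, sigma_upper) with the upper bound defaulting to the
    state-space buffer width; regression coefficients ~ Normal(0, beta_sd).
    """

    log_lambda0_bounds: tuple[float, float] = (-20.0, 5.0)
    sigma_upper: float = 15.0
    beta_sd: float = 10.0

    def _normal(self, x: float) -> float:
        return -_LOG_SQRT_2PI - math.log(self.beta_sd) - 0.5 * (x / self.beta_sd) ** 2


def log_prior(params: Parameters, spec: ModelSpec, priors: Priors | None = None) -> float:
    """Sum of independent log prior densities; -inf outside support."""
    pr = priors or Priors()
    lo, hi = pr.log_lambda0_bounds
    ll = math.log(params.lambda0)
    if not (lo <= ll <= hi):
        return -math.inf
    total = -math.log(hi - lo)
    sigmas = [params.sigma_f, params.sigma_m] if spec.sigma_sex_specific else [params.sigma_f]
    for s in sigmas:
        if not (0.0 < s < pr.sigma_upper):
            return -math.inf
        total += -math.log(pr.sigma_upper)
    if not (0.0 <= params.psi <= 1.0 and 0.0 <= params.psi_sex <= 1.0):
        return -math.inf
    total += pr._normal(params.beta_eff)
    if spec.include_playback:
        total += pr._normal(params.beta_eff2)
    if spec.sex_beta:
        total += pr._normal(params.beta_sex)
    return total


# ---------------------------------------------------------------------------
# Detection function


def distance_term(d, sigma, theta: float = 1.0):
    """Distance component of the cloglog predictor: (d^2 / (2 sigma^2))^theta.

    With ``theta = 1`` this is the half-normal exponent; it is subtracted
    from the linear predictor, so detection decays with distance.
    """
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be > 0")
    base = np.square(d) / (2.0 * np.square(sigma))
    if theta == 1.0:
        return base
    return np.power(base, theta)


def linear_predictor(params: Parameters, sex, search_km, playback, d,
                     spec: ModelSpec):
    """cloglog-scale predictor for an *active* cell-occasion.

    ``search_km`` enters on the log scale; a playback-only cell-occasion
    (search_km = 0, playback = 1) contributes no log-effort term.  Raises
    for inactive cell-occasions, which are structurally outside the model.
    """
    search_km = np.asarray(search_km, dtype=float)
    playback = np.asarray(playback)
    if np.any((search_km <= 0) & (playback == 0)):
        raise ValueError("inactive cell-occasion: search_km = 0 and playback = 0")
    sex = np.asarray(sex)
    with np.errstate(divide="ignore"):
        log_eff = np.where(search_km > 0, np.log(np.where(search_km > 0, search_km, 1.0)), 0.0)
    eta = math.log(params.lambda0) + params.beta_eff * log_eff
    if spec.include_playback:
        eta = eta + params.beta_eff2 * playback
    if spec.sex_beta:
        eta = eta + params.beta_sex * sex
    sig = params.sigma(sex, spec)
    return eta - distance_term(d, sig, spec.theta)


def detection_prob(eta):
    """pi = 1 - exp(-exp(eta)): inverse complementary log-log link."""
    return -np.expm1(-np.exp(eta))


# ---------------------------------------------------------------------------
# Latent state and data containers


@dataclass
class LatentState:
    """Latent state of the augmented population.

    ``s`` indexes habitat pixels of the state-space; the first
    ``n_observed`` individuals correspond to the rows of the capture data
    and have ``z = 1`` always.
    """

    z: np.ndarray    # (M,) 0/1
    s: np.ndarray    # (M,) habitat pixel index
    sex: np.ndarray  # (M,) 0 female / 1 male


@dataclass
class CaptureData:
    """Binary capture histories with their effort and distance context.

    ``y[i, j, k]`` is 1 when observed individual ``i`` was detected in trap
    cell ``j`` on occasion ``k``.  ``sex_obs`` is 0/1 with -1 for unknown.
    ``dist`` is the full pixel x trap distance matrix (km).
    """

    y: np.ndarray          # (n, J, K) uint8
    sex_obs: np.ndarray    # (n,) int8
    effort: "EffortArray"  # noqa: F821 (state_space.EffortArray)
    dist: np.ndarray       # (P, J) km
    trap_grid: object = None

    @property
    def n_observed(self) -> int:
        return self.y.shape[0]

    def validate(self) -> None:
        active = self.effort.active
        if np.any(self.y[:, ~active]):
            raise ValueError(
                "capture history records a detection in a cell-occasion with no "
                "effort; detections require search or playback effort"
            )
        per_ind = self.y.reshape(self.n_observed, -1).sum(axis=1)
        if np.any(per_ind < 1):
            raise ValueError("every observed individual needs >= 1 detection")


def _log_pi_and_miss(eta):
    """(log pi, log(1 - pi)) computed stably from the cloglog predictor."""
    r = np.exp(eta)
    with np.errstate(divide="ignore"):
        log_pi = np.log(-np.expm1(-r))
    return log_pi, -r


def complete_data_loglik(params: Parameters, latent: LatentState,
                         data: CaptureData, spec: ModelSpec,
                         state_space) -> float:
    """Reference complete-data log-likelihood.

    Detection terms over active cell-occasions for included individuals,
    plus Bernoulli(psi) mass of z for all M, and -- for included
    individuals only -- Bernoulli(psi_sex) mass of sex and uniform mass of
    s over habitat pixels.  Excluded individuals contribute only the z
    term.  Written for clarity, not speed; the sampler keeps an equivalent
    incremental version that is tested against this one.
    """
    M = latent.z.shape[0]
    n = data.n_observed
    if np.any(latent.z[:n] != 1):
        raise ValueError("observed individuals must have z = 1")
    eff = data.effort
    active = eff.active
    aj, ak = np.nonzero(active)
    with np.errstate(divide="ignore"):
        x1 = np.where(eff.search_km[aj, ak] > 0, np.log(eff.search_km[aj, ak]), 0.0)
    x2 = eff.playback[aj, ak].astype(float)
    dist_hab = data.dist[np.asarray(state_space.habitat)]
    nh = dist_hab.shape[0]

    total = 0.0
    psi = params.psi
    total += float(np.sum(np.where(latent.z == 1,
                                   math.log(psi) if psi > 0 else -math.inf,
                                   math.log1p(-psi) if psi < 1 else -math.inf)))
    for i in range(M):
        if latent.z[i] != 1:
            continue
        sex = int(latent.sex[i])
        p_sex = params.psi_sex if sex == 1 else 1.0 - params.psi_sex
        total += math.log(p_sex) if p_sex > 0 else -math.inf
        total += -math.log(nh)
        d = dist_hab[latent.s[i], aj]
        eta = math.log(params.lambda0) + params.beta_eff * x1
        if spec.include_playback:
            eta = eta + params.beta_eff2 * x2
        if spec.sex_beta:
            eta = eta + params.beta_sex * sex
        eta = eta - distance_term(d, float(params.sigma(sex, spec)), spec.theta)
        log_pi, log_miss = _log_pi_and_miss(eta)
        if i < n:
            yi = data.y[i, aj, ak].astype(bool)
            total += float(np.sum(np.where(yi, log_pi, log_miss)))
        else:
            total += float(np.sum(log_miss))
    return total
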