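"""Metropolis-within-Gibbs sampler for the augmented SCR model.

Latent structure (per augmented individual): inclusion ``z``, activity
center pixel ``s``, and sex.  ``z`` and the conjugate probabilities
``psi``/``psi_sex`` get closed-form Gibbs draws; activity centers move by a
discretized symmetric random walk on the habitat lattice; the remaining
parameters use Gaussian random-walk Metropolis on transformed scales (log
for ``lambda0`` and ``sigma``, identity for the betas), with optional
proposal-scale adaptation restricted to burn-in.

The per-individual detection likelihood factorizes as

    ll_i = -Lambda_i + sum over detections of h(eta)

where ``Lambda_i = lambda0 * exp(beta_sex * sex_i) * sum_j K_ij * E_j`` is
the expected number of encounters summed over active cell-occasions,
``K_ij = exp(-f(d_ij))`` the distance kernel and
``E_j = sum_k exp(beta_eff * log effort_jk + beta_eff2 * playback_jk)``
the per-trap effort total, and ``h(eta) = log(exp(exp(eta)) - 1)`` the
Bernoulli correction at observed detections.  The sampler maintains
``K``, ``E`` and ``Lambda`` incrementally; the stored complete-data
log-likelihood is unit-tested against the reference implementation in
:mod:`lionscr.model`.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import xlogy

from .model import CaptureData, ModelSpec, Parameters, Priors

logger = logging.getLogger(__name__)

__all__ = [
    "ChainConfig",
    "PosteriorSamples",
    "Sampler",
    "run",
    "inclusion_probability",
]


def inclusion_probability(psi, p0):
    """Conditional inclusion probability for an all-zero augmented individual.

    ``p0`` is the probability of an all-zero capture history if the
    individual were present (product of misses over active cell-occasions);
    the Gibbs draw for ``z`` is Bernoulli(psi * p0 / (psi * p0 + 1 - psi)).
    """
    psi = np.asarray(psi, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    num = psi * p0
    return num / (num + 1.0 - psi)


@dataclass
class ChainConfig:
    """MCMC run configuration (defaults follow the survey analysis setup)."""

    seed: int
    n_chains: int = 4
    n_iter: int = 51000
    burn_in: int = 1000
    thin: int = 1
    latent_stride: int = 10
    adapt: bool = True
    s_window: int = 5
    proposal_scales: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.proposal_scales:
            for k, v in self.proposal_scales.items():
                if v == 0:
                    logger.warning(
                        "proposal scale for %s is 0: that block can never move", k
                    )


_DEFAULT_SCALES = {
    "lambda0": 0.25,
    "sigma_f": 0.12,
    "sigma_m": 0.12,
    "beta_eff": 0.15,
    "beta_eff2": 0.5,
    "beta_sex": 0.3,
}


@dataclass
class PosteriorSamples:
    """Multi-chain posterior draws plus thinned latent-state snapshots."""

    spec: ModelSpec
    config: ChainConfig
    names: list[str]
    draws: dict[str, np.ndarray]       # each (n_chains, n_stored)
    n_super: np.ndarray                # (n_chains, n_stored)
    loglik: np.ndarray                 # (n_chains, n_stored)
    latent_z: np.ndarray               # (n_chains, L, M)
    latent_s: np.ndarray               # (n_chains, L, M)
    latent_sex: np.ndarray             # (n_chains, L, M)
    latent_iters: np.ndarray           # (L,) stored-iteration index
    acceptance: dict[str, np.ndarray]  # block -> (n_chains,)

    @property
    def n_chains(self) -> int:
        return self.loglik.shape[0]

    @property
    def n_stored(self) -> int:
        return self.loglik.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        if name == "n_super":
            return self.n_super.ravel()
        return self.draws[name].ravel()

    def chains(self, name: str) -> np.ndarray:
        if name == "n_super":
            return self.n_super
        return self.draws[name]

    def to_dataframe(self, chain: int):
        import pandas as pd

        cols = {"iteration": np.arange(self.n_stored)}
        for name in self.names:
            cols[name] = self.draws[name][chain]
        cols["n_super"] = self.n_super[chain]
        cols["loglik"] = self.loglik[chain]
        return pd.DataFrame(cols)

    def parameters_at(self, chain: int, stored_iter: int) -> Parameters:
        """Reconstruct a Parameters object from one stored draw."""
        kw = {}
        for name in self.names:
            v = float(self.draws[name][chain][stored_iter])
            if name == "sigma":
                kw["sigma_f"] = v
                kw["sigma_m"] = v
            else:
                kw[name] = v
        p = Parameters(**{k: v for k, v in kw.items() if k in Parameters.__dataclass_fields__})
        return p.tied(self.spec)


def _h(eta: np.ndarray) -> np.ndarray:
    """log(exp(exp(eta)) - 1): log-odds-like Bernoulli hit correction.

    Equals log(pi) - log(1 - pi) for the cloglog link; stable for very
    negative eta (-> eta) and large eta (-> exp(eta)).
    """
    r = np.exp(eta)
    out = np.empty_like(r)
    big = r > 20.0
    out[big] = r[big]
    with np.errstate(divide="ignore"):
        out[~big] = np.log(np.expm1(r[~big]))
    return out


class Sampler:
    """One-dataset sampler; use :func:`run` for the multi-chain interface."""

    def __init__(self, spec: ModelSpec, data: CaptureData, state_space,
                 config: ChainConfig, priors: Priors | None = None,
                 fix_params: Parameters | None = None):
        data.validate()
        self.spec = spec
        self.data = data
        self.ss = state_space
        self.config = config
        self.priors = priors or Priors(sigma_upper=max(state_space.buffer_km, 1.0))
        self.fix_params = fix_params
        self.M = spec.M
        self.n = data.n_observed
        if self.M < self.n:
            raise ValueError("M must be at least the number of observed individuals")
        self.theta = spec.theta

        hab = np.asarray(state_space.habitat)
        self.D2h = np.ascontiguousarray(data.dist[hab] ** 2)   # (nh, J)
        self.nh = self.D2h.shape[0]
        self.J = self.D2h.shape[1]
        self.lattice = state_space.habitat_lattice()
        self.hab_ij = state_space.habitat_ij()

        eff = data.effort
        active = eff.active
        self.act_j, self.act_k = np.nonzero(active)
        sk = eff.search_km[self.act_j, self.act_k]
        self.act_x1 = np.where(sk > 0, np.log(np.where(sk > 0, sk, 1.0)), 0.0)
        self.act_x2 = eff.playback[self.act_j, self.act_k].astype(float)
        if not spec.include_playback:
            self.act_x2 = np.zeros_like(self.act_x2)

        yi, yj, yk = np.nonzero(data.y)
        order = np.argsort(yi, kind="stable")
        self.det_owner = yi[order].astype(np.int64)
        self.det_j = yj[order].astype(np.int64)
        det_k = yk[order]
        dsk = eff.search_km[self.det_j, det_k]
        self.det_x1 = np.where(dsk > 0, np.log(np.where(dsk > 0, dsk, 1.0)), 0.0)
        self.det_x2 = eff.playback[self.det_j, det_k].astype(float)
        if not spec.include_playback:
            self.det_x2 = np.zeros_like(self.det_x2)
        self.n_det = self.det_owner.size

        self.obs = np.zeros(self.M, dtype=bool)
        self.obs[: self.n] = True
        self.sex_known = np.zeros(self.M, dtype=bool)
        self.sex_known[: self.n] = data.sex_obs >= 0

        self.scales = dict(_DEFAULT_SCALES)
        if config.proposal_scales:
            self.scales.update(config.proposal_scales)
        self._blocks_tried: dict[str, int] = {}
        self._blocks_acc: dict[str, int] = {}

    # -- small helpers ------------------------------------------------------

    def _inv2s2(self, sex: np.ndarray) -> np.ndarray:
        p = self.params
        if self.spec.sigma_sex_specific:
            s = np.where(sex == 1, p.sigma_m, p.sigma_f)
        else:
            s = np.full(np.shape(sex), p.sigma_f, dtype=float)
        return 1.0 / (2.0 * s * s)

    def _kernel(self, d2rows: np.ndarray, sex: np.ndarray) -> np.ndarray:
        f = d2rows * self._inv2s2(sex)[:, None]
        if self.theta != 1.0:
            f = f ** self.theta
        return np.exp(-f)

    def _compute_E(self, beta_eff: float, beta_eff2: float) -> np.ndarray:
        w = np.exp(beta_eff * self.act_x1 + beta_eff2 * self.act_x2)
        return np.bincount(self.act_j, weights=w, minlength=self.J)

    def _mult(self, sex: np.ndarray) -> np.ndarray:
        p = self.params
        if self.spec.sex_beta:
            return p.lambda0 * np.exp(p.beta_sex * np.asarray(sex, dtype=float))
        return np.full(np.shape(sex), p.lambda0, dtype=float)

    def _det_eta(self, lambda0=None, beta_eff=None, beta_eff2=None,
                 beta_sex=None, sigma_f=None, sigma_m=None) -> np.ndarray:
        """Cloglog predictor at every observed detection, with overrides."""
        p = self.params
        lambda0 = p.lambda0 if lambda0 is None else lambda0
        beta_eff = p.beta_eff if beta_eff is None else beta_eff
        beta_eff2 = p.beta_eff2 if beta_eff2 is None else beta_eff2
        beta_sex = p.beta_sex if beta_sex is None else beta_sex
        sigma_f = p.sigma_f if sigma_f is None else sigma_f
        sigma_m = p.sigma_m if sigma_m is None else sigma_m
        sex = self.sex[self.det_owner]
        eta = math.log(lambda0) + beta_eff * self.det_x1 + beta_eff2 * self.det_x2
        if self.spec.sex_beta:
            eta = eta + beta_sex * sex
        if self.spec.sigma_sex_specific:
            s = np.where(sex == 1, sigma_m, sigma_f)
        else:
            s = sigma_f
        f = self.det_d2 / (2.0 * s * s)
        if self.theta != 1.0:
            f = f ** self.theta
        return eta - f

    def _refresh(self, idx: np.ndarray) -> None:
        """Recompute kernel rows, effort sums and Lambda for individuals idx."""
        if idx.size == 0:
            return
        self.K[idx] = self._kernel(self.D2h[self.s[idx]], self.sex[idx])
        self.S[idx] = self.K[idx] @ self.E
        self.mult[idx] = self._mult(self.sex[idx])
        self.Lam[idx] = self.mult[idx] * self.S[idx]

    def _refresh_det_d2(self, owner_mask: np.ndarray | None = None) -> None:
        m = slice(None) if owner_mask is None else owner_mask
        self.det_d2[m] = self.D2h[self.s[self.det_owner[m]], self.det_j[m]]

    # -- initialization -----------------------------------------------------

    def init_state(self, rng: np.random.Generator) -> None:
        spec, data = self.spec, self.data
        for attempt in range(20):
            if self.fix_params is not None:
                self.params = replace(self.fix_params).tied(spec)
            else:
                lo = min(-7.0, self.priors.log_lambda0_bounds[1] - 1.0)
                sig_hi = min(5.0, 0.9 * self.priors.sigma_upper)
                p = Parameters(
                    lambda0=math.exp(rng.uniform(lo, lo + 2.5)),
                    sigma_f=rng.uniform(0.3 * sig_hi, sig_hi),
                    sigma_m=rng.uniform(0.3 * sig_hi, sig_hi),
                    beta_eff=rng.normal(2.0, 1.0),
                    beta_eff2=rng.normal(0.0, 0.5),
                    beta_sex=rng.normal(0.0, 0.5),
                    psi=rng.uniform(0.2, 0.8),
                    psi_sex=rng.uniform(0.2, 0.8),
                )
                self.params = p.tied(spec)

            self.z = np.zeros(self.M, dtype=np.int8)
            self.z[: self.n] = 1
            self.z[self.n:] = rng.random(self.M - self.n) < self.params.psi
            self.sex = np.where(rng.random(self.M) < self.params.psi_sex, 1, 0).astype(np.int8)
            if self.n:
                known = data.sex_obs >= 0
                self.sex[: self.n][known] = data.sex_obs[known]

            # observed individuals start at the habitat pixel nearest the
            # mean location of their detections
            self.s = rng.integers(0, self.nh, size=self.M)
            if self.n:
                tc = data.trap_grid.cell_centroids if data.trap_grid is not None else None
                hc = self.ss.habitat_centroids
                for i in range(self.n):
                    ji = self.det_j[self.det_owner == i]
                    if tc is None or ji.size == 0:
                        continue
                    center = tc[ji].mean(axis=0)
                    self.s[i] = int(np.argmin(((hc - center) ** 2).sum(axis=1)))

            self.E = self._compute_E(self.params.beta_eff, self.params.beta_eff2)
            self.K = np.zeros((self.M, self.J))
            self.S = np.zeros(self.M)
            self.mult = np.zeros(self.M)
            self.Lam = np.zeros(self.M)
            self._refresh(np.arange(self.M))
            self.det_d2 = np.zeros(self.n_det)
            self._refresh_det_d2()
            if np.isfinite(self.loglik()):
                return
        raise RuntimeError(
            "could not find initial values with finite likelihood after 20 tries; "
            "check the capture data against the effort arrays"
        )

    # -- update blocks ------------------------------------------------------

    def update_activity_centers(self, rng: np.random.Generator) -> None:
        """Lattice random-walk Metropolis on s for included individuals."""
        mov = np.flatnonzero(self.z == 1)
        if mov.size == 0:
            return
        w = self.config.s_window
        off = rng.integers(-w, w + 1, size=(mov.size, 2))
        logu = np.log(rng.random(mov.size))
        ij = self.hab_ij[self.s[mov]] + off
        ny, nx = self.ss.shape
        ok = (ij[:, 0] >= 0) & (ij[:, 0] < nx) & (ij[:, 1] >= 0) & (ij[:, 1] < ny)
        pnew = np.full(mov.size, -1, dtype=np.int64)
        pnew[ok] = self.lattice[ij[ok, 1], ij[ok, 0]]
        ok &= pnew >= 0          # proposals into non-habitat are rejected
        cand = mov[ok]
        if cand.size == 0:
            self._try_s = getattr(self, "_try_s", 0) + mov.size
            return
        pn = pnew[ok]
        Kn = self._kernel(self.D2h[pn], self.sex[cand])
        Sn = Kn @ self.E
        Ln = self.mult[cand] * Sn
        dll = self.Lam[cand] - Ln

        moved = np.zeros(self.M, dtype=bool)
        moved[cand] = True
        rmask = moved[self.det_owner]
        if rmask.any():
            snew = self.s.copy()
            snew[cand] = pn
            ro = self.det_owner[rmask]
            d2n = self.D2h[snew[ro], self.det_j[rmask]]
            eta_all = self._det_eta()
            d2_save = self.det_d2
            self.det_d2 = d2_save.copy()
            self.det_d2[rmask] = d2n
            eta_new = self._det_eta()
            self.det_d2 = d2_save
            delta = _h(eta_new[rmask]) - _h(eta_all[rmask])
            dll = dll + np.bincount(ro, weights=delta, minlength=self.M)[cand]

        accept = logu[ok] < dll
        acc = cand[accept]
        self.s[acc] = pn[accept]
        self.K[acc] = Kn[accept]
        self.S[acc] = Sn[accept]
        self.Lam[acc] = Ln[accept]
        if acc.size and self.n_det:
            am = np.zeros(self.M, dtype=bool)
            am[acc] = True
            ram = am[self.det_owner]
            if ram.any():
                self._refresh_det_d2(ram)
        self._acc_s = getattr(self, "_acc_s", 0) + int(accept.sum())
        self._try_s = getattr(self, "_try_s", 0) + mov.size

    def update_free_centers(self, rng: np.random.Generator) -> None:
        """Prior (Gibbs) draw of s and sex for currently excluded individuals."""
        z0 = np.flatnonzero(self.z == 0)
        if z0.size == 0:
            return
        self.s[z0] = rng.integers(0, self.nh, size=z0.size)
        self.sex[z0] = (rng.random(z0.size) < self.params.psi_sex).astype(np.int8)
        self._refresh(z0)

    def update_inclusion(self, rng: np.random.Generator) -> None:
        """Gibbs draw of z for augmented (all-zero history) individuals."""
        idx = np.flatnonzero(~self.obs)
        if idx.size == 0:
            return
        p0 = np.exp(-self.Lam[idx])
        pstar = inclusion_probability(self.params.psi, p0)
        self.z[idx] = (rng.random(idx.size) < pstar).astype(np.int8)

    def update_sex(self, rng: np.random.Generator) -> None:
        """Gibbs draw of sex for included individuals without an observed sex."""
        t = np.flatnonzero((self.z == 1) & (~self.sex_known))
        if t.size == 0:
            return
        psx = self.params.psi_sex
        if not self.spec.sex_dependent_detection:
            self.sex[t] = (rng.random(t.size) < psx).astype(np.int8)
            return
        alt = (1 - self.sex[t]).astype(np.int8)
        Ka = self._kernel(self.D2h[self.s[t]], alt)
        Sa = Ka @ self.E
        sex_save = self.sex
        self.sex = self.sex.copy()
        self.sex[t] = alt
        mult_a = self._mult(self.sex[t])
        La = mult_a * Sa
        log_cur = xlogy(sex_save[t], psx) + xlogy(1 - sex_save[t], 1 - psx) - self.Lam[t]
        log_alt = xlogy(alt, psx) + xlogy(1 - alt, 1 - psx) - La
        tset = np.zeros(self.M, dtype=bool)
        tset[t] = True
        rmask = tset[self.det_owner]
        if rmask.any():
            # observed individuals of unknown sex: add detection terms
            self.sex, alt_sex_full = sex_save, self.sex
            eta_cur = self._det_eta()
            self.sex = alt_sex_full
            eta_alt = self._det_eta()
            dcur = np.bincount(self.det_owner[rmask], weights=_h(eta_cur[rmask]), minlength=self.M)
            dalt = np.bincount(self.det_owner[rmask], weights=_h(eta_alt[rmask]), minlength=self.M)
            log_cur = log_cur + dcur[t]
            log_alt = log_alt + dalt[t]
        self.sex = sex_save
        with np.errstate(over="ignore"):
            p_switch = 1.0 / (1.0 + np.exp(log_cur - log_alt))
        switch = rng.random(t.size) < p_switch
        ids = t[switch]
        self.sex[ids] = alt[switch]
        self.K[ids] = Ka[switch]
        self.S[ids] = Sa[switch]
        self.mult[ids] = mult_a[switch]
        self.Lam[ids] = La[switch]

    # -- parameter blocks ---------------------------------------------------

    def _det_ll(self, Lsum: float, hsum: float) -> float:
        return -Lsum + hsum

    def _bump(self, name: str, accepted: bool) -> None:
        self._blocks_tried[name] = self._blocks_tried.get(name, 0) + 1
        if accepted:
            self._blocks_acc[name] = self._blocks_acc.get(name, 0) + int(accepted)

    def update_parameters(self, rng: np.random.Generator) -> None:
        if self.fix_params is not None:
            return
        p = self.params
        spec = self.spec
        z1 = np.flatnonzero(self.z == 1)
        nz = z1.size

        # conjugate Gibbs draws under the Uniform(0,1) priors
        a = int(self.z.sum())
        p.psi = float(rng.beta(1 + a, 1 + self.M - a))
        m = int(self.sex[z1].sum())
        p.psi_sex = float(rng.beta(1 + m, 1 + nz - m))

        Lsum = float(self.Lam[z1].sum())
        hsum = float(_h(self._det_eta()).sum())
        pr = self.priors

        # lambda0: random walk on the log scale, Uniform prior on log lambda0
        d = rng.normal(0.0, self.scales["lambda0"])
        u = math.log(rng.random())
        lo, hi = pr.log_lambda0_bounds
        new_ll0 = math.log(p.lambda0) + d
        if lo <= new_ll0 <= hi:
            hn = float(_h(self._det_eta(lambda0=math.exp(new_ll0))).sum())
            Ln = Lsum * math.exp(d)
            acc = u < self._det_ll(Ln, hn) - self._det_ll(Lsum, hsum)
            if acc:
                p.lambda0 = math.exp(new_ll0)
                self.mult *= math.exp(d)
                self.Lam *= math.exp(d)
                Lsum, hsum = Ln, hn
        else:
            acc = False
        self._bump("lambda0", acc)

        # beta_sex
        if spec.sex_beta:
            d = rng.normal(0.0, self.scales["beta_sex"])
            u = math.log(rng.random())
            bs = p.beta_sex + d
            fac = np.exp(d * self.sex[z1])
            Ln = float((self.Lam[z1] * fac).sum())
            hn = float(_h(self._det_eta(beta_sex=bs)).sum())
            dprior = (bs ** 2 - p.beta_sex ** 2) / (-2.0 * pr.beta_sd ** 2)
            acc = u < self._det_ll(Ln, hn) - self._det_ll(Lsum, hsum) + dprior
            if acc:
                p.beta_sex = bs
                self.mult = self._mult(self.sex)
                self.Lam = self.mult * self.S
                Lsum, hsum = Ln, hn
            self._bump("beta_sex", acc)

        # beta_eff / beta_eff2: effort totals E change
        for name, x in (("beta_eff", "x1"), ("beta_eff2", "x2")):
            if name == "beta_eff2" and not spec.include_playback:
                continue
            d = rng.normal(0.0, self.scales[name])
            u = math.log(rng.random())
            be = p.beta_eff + d if name == "beta_eff" else p.beta_eff
            be2 = p.beta_eff2 + d if name == "beta_eff2" else p.beta_eff2
            En = self._compute_E(be, be2)
            Sn = self.K[z1] @ En
            Ln = float((self.mult[z1] * Sn).sum())
            hn = float(_h(self._det_eta(beta_eff=be, beta_eff2=be2)).sum())
            old = p.beta_eff if name == "beta_eff" else p.beta_eff2
            dprior = ((old + d) ** 2 - old ** 2) / (-2.0 * pr.beta_sd ** 2)
            acc = u < self._det_ll(Ln, hn) - self._det_ll(Lsum, hsum) + dprior
            if acc:
                if name == "beta_eff":
                    p.beta_eff = be
                else:
                    p.beta_eff2 = be2
                self.E = En
                self.S[z1] = Sn
                self.Lam[z1] = self.mult[z1] * Sn
                Lsum, hsum = Ln, hn
            self._bump(name, acc)

        # sigma blocks: random walk on log sigma, Uniform(0, upper) prior
        sig_blocks = (
            [("sigma_f", 0), ("sigma_m", 1)] if spec.sigma_sex_specific
            else [("sigma_f", None)]
        )
        for name, sex_code in sig_blocks:
            d = rng.normal(0.0, self.scales[name])
            u = math.log(rng.random())
            cur = p.sigma_f if name == "sigma_f" else p.sigma_m
            new = cur * math.exp(d)
            if not (0.0 < new < pr.sigma_upper):
                self._bump(name, False)
                continue
            if sex_code is None:
                idx = z1
            else:
                idx = z1[self.sex[z1] == sex_code]
            sf = new if name == "sigma_f" else p.sigma_f
            sm = new if name == "sigma_m" else p.sigma_m
            inv = 1.0 / (2.0 * new * new)
            f = self.D2h[self.s[idx]] * inv
            if self.theta != 1.0:
                f = f ** self.theta
            Kn = np.exp(-f)
            Sn = Kn @ self.E
            Ln_part = self.mult[idx] * Sn
            Ln = Lsum - float(self.Lam[idx].sum()) + float(Ln_part.sum())
            hn = float(_h(self._det_eta(sigma_f=sf, sigma_m=sm)).sum())
            # Jacobian of the log-scale walk: |d new / d log| = new
            djac = math.log(new) - math.log(cur)
            acc = u < self._det_ll(Ln, hn) - self._det_ll(Lsum, hsum) + djac
            if acc:
                if name == "sigma_f":
                    p.sigma_f = new
                    if not spec.sigma_sex_specific:
                        p.sigma_m = new
                else:
                    p.sigma_m = new
                self.K[idx] = Kn
                self.S[idx] = Sn
                self.Lam[idx] = Ln_part
                Lsum, hsum = Ln, hn
            self._bump(name, acc)

    def _adapt(self) -> None:
        for name in list(self._blocks_tried):
            tried = self._blocks_tried[name]
            if tried < 50:
                continue
            rate = self._blocks_acc.get(name, 0) / tried
            if rate < 0.2:
                self.scales[name] *= 0.7
            elif rate > 0.5:
                self.scales[name] *= 1.4
            self._blocks_tried[name] = 0
            self._blocks_acc[name] = 0

    # -- likelihood bookkeeping --------------------------------------------

    def loglik(self) -> float:
        """Complete-data log-likelihood of the current state."""
        z1 = self.z == 1
        nz = int(z1.sum())
        det = -float(self.Lam[z1].sum())
        if self.n_det:
            det += float(_h(self._det_eta()).sum())
        a = int(self.z.sum())
        p = self.params
        zmass = float(xlogy(a, p.psi) + xlogy(self.M - a, 1.0 - p.psi))
        msex = int(self.sex[z1].sum())
        sexmass = float(xlogy(msex, p.psi_sex) + xlogy(nz - msex, 1.0 - p.psi_sex))
        smass = -nz * math.log(self.nh)
        return det + zmass + sexmass + smass

    def iterate(self, rng: np.random.Generator, adapt: bool = False) -> None:
        self.update_activity_centers(rng)
        self.update_free_centers(rng)
        self.update_inclusion(rng)
        self.update_sex(rng)
        self.update_parameters(rng)
        if adapt:
            self._adapt()

    def acceptance_rates(self) -> dict[str, float]:
        out = {}
        if getattr(self, "_try_s", 0):
            out["s"] = self._acc_s / self._try_s
        for name, tried in self._cum_tried.items():
            out[name] = self._cum_acc.get(name, 0) / tried if tried else 0.0
        return out

    # -- single chain -------------------------------------------------------

    def run_chain(self, rng: np.random.Generator):
        cfg = self.config
        names = self.spec.param_names()
        n_stored = (cfg.n_iter - cfg.burn_in) // cfg.thin
        draws = {name: np.empty(n_stored) for name in names}
        n_super = np.empty(n_stored, dtype=np.int64)
        loglik = np.empty(n_stored)
        lat_iters = np.arange(0, n_stored, cfg.latent_stride)
        Lz = np.empty((lat_iters.size, self.M), dtype=np.int8)
        Ls = np.empty((lat_iters.size, self.M), dtype=np.int32)
        Lsex = np.empty((lat_iters.size, self.M), dtype=np.int8)

        self.init_state(rng)
        self._acc_s = self._try_s = 0
        self._blocks_tried = {}
        self._blocks_acc = {}
        self._cum_tried: dict[str, int] = {}
        self._cum_acc: dict[str, int] = {}

        stored = 0
        lat = 0
        for it in range(cfg.n_iter):
            in_burn = it < cfg.burn_in
            before_t = dict(self._blocks_tried)
            before_a = dict(self._blocks_acc)
            self.iterate(rng, adapt=cfg.adapt and in_burn)
            if not in_burn:
                for k in self._blocks_tried:
                    self._cum_tried[k] = self._cum_tried.get(k, 0) + (
                        self._blocks_tried[k] - before_t.get(k, 0))
                for k in self._blocks_acc:
                    self._cum_acc[k] = self._cum_acc.get(k, 0) + (
                        self._blocks_acc[k] - before_a.get(k, 0))
                post = it - cfg.burn_in
                if post % cfg.thin == 0:
                    for name in names:
                        attr = "sigma_f" if name == "sigma" else name
                        draws[name][stored] = getattr(self.params, attr)
                    n_super[stored] = int(self.z.sum())
                    loglik[stored] = self.loglik()
                    if lat < lat_iters.size and stored == lat_iters[lat]:
                        Lz[lat] = self.z
                        Ls[lat] = self.s
                        Lsex[lat] = self.sex
                        lat += 1
                    stored += 1
        return draws, n_super, loglik, Lz, Ls, Lsex, lat_iters, self.acceptance_rates()


def run(spec: ModelSpec, data: CaptureData, state_space,
        config: ChainConfig, priors: Priors | None = None,
        fix_params: Parameters | None = None) -> PosteriorSamples:
    """Fit the model: independent chains from over-dispersed initial values.

    All randomness derives from ``config.seed`` through per-chain
    sub-streams, so an identical seed + config + data reproduces the output
    exactly.  ``fix_params`` freezes the parameter vector (latent-state
    updates only), which is how the sampler is validated against exhaustive
    enumeration on tiny instances.
    """
    ss_seq = np.random.SeedSequence(config.seed)
    child_seqs = ss_seq.spawn(config.n_chains)
    names = spec.param_names()
    all_draws = []
    acc: dict[str, list[float]] = {}
    for c in range(config.n_chains):
        sampler = Sampler(spec, data, state_space, config, priors=priors,
                          fix_params=fix_params)
        rng = np.random.Generator(np.random.PCG64(child_seqs[c]))
        t0 = time.perf_counter()
        all_draws.append(sampler.run_chain(rng))
        rates = all_draws[-1][7]
        logger.info("chain %d/%d: %d iterations in %.1f s (seed %s); "
                    "acceptance %s", c + 1, config.n_chains, config.n_iter,
                    time.perf_counter() - t0, config.seed,
                    {k: round(v, 3) for k, v in rates.items()})
        for k, v in rates.items():
            acc.setdefault(k, []).append(v)

    draws = {name: np.stack([d[0][name] for d in all_draws]) for name in names}
    return PosteriorSamples(
        spec=spec,
        config=config,
        names=names,
        draws=draws,
        n_super=np.stack([d[1] for d in all_draws]),
        loglik=np.stack([d[2] for d in all_draws]),
        latent_z=np.stack([d[3] for d in all_draws]),
        latent_s=np.stack([d[4] for d in all_draws]),
        latent_sex=np.stack([d[5] for d in all_draws]),
        latent_iters=all_draws[0][6],
        acceptance={k: np.array(v) for k, v in acc.items()},
    )
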