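"""Convergence assessment, model choice, and posterior summarization.

Implements the battery used to vet each candidate model fit: the
Gelman-Rubin potential scale reduction factor (convergence declared at
R-hat <= 1.05), shortest-interval 95% HPDs, a posterior predictive
Bayesian p-value with a Freeman-Tukey discrepancy on individual encounter
frequencies, the harmonic-mean estimator of the log marginal likelihood
(MLHM) for ranking candidate models, and pairwise parameter correlations
for spotting redundancy involving the density-linked parameters.
"""

from __future__ import annotations

import math
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .mcmc import PosteriorSamples

__all__ = [
    "gelman_rubin",
    "hpd_interval",
    "bayesian_p_value",
    "mlhm",
    "pairwise_correlations",
    "summarize",
    "detection_frequency_table",
    "RHAT_THRESHOLD",
]

RHAT_THRESHOLD = 1.05


def gelman_rubin(chains: np.ndarray, split: bool = False) -> float:
    """Potential scale reduction factor from (n_chains, n_samples) draws.

    Classic between/within form: with chain variance W and between-chain
    variance B, R-hat = sqrt(((n-1)/n W + B/n) / W).  Identical chains give
    R-hat ~ 1; chains stuck in different regions give R-hat >> 1.05.
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    if split:
        half = chains.shape[1] // 2
        chains = np.vstack([chains[:, :half], chains[:, half:2 * half]])
    m, n = chains.shape
    if m < 2:
        raise ValueError(
            "Gelman-Rubin needs >= 2 chains; pass split=True to split a single "
            "chain into halves"
        )
    if n < 2:
        raise ValueError("chains too short")
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(math.sqrt(var_plus / W))


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` samples.

    Deterministic: ties in width go to the earliest (lowest) window of the
    sorted draws.
    """
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    need = math.ceil(1.0 / (1.0 - mass))
    if n < need:
        raise ValueError(f"need >= {need} samples for mass {mass}")
    m = math.ceil(mass * n)
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def mlhm(loglik: np.ndarray) -> float:
    """Harmonic-mean estimate of the log marginal likelihood.

    log ML ~ -(logsumexp(-l_t) - log T), computed in log space.  Larger
    values indicate more support; used to rank the four candidate models.
    """
    l = np.asarray(loglik, dtype=float).ravel()
    if l.size == 0 or not np.all(np.isfinite(l)):
        raise ValueError("mlhm requires finite log-likelihood draws")
    return float(-(logsumexp(-l) - math.log(l.size)))


def _freeman_tukey(obs: np.ndarray, exp: np.ndarray) -> float:
    return float(np.sum((np.sqrt(obs) - np.sqrt(exp)) ** 2))


def bayesian_p_value(samples: PosteriorSamples, data, state_space,
                     max_draws: int = 200, seed: int = 0) -> float:
    """Posterior predictive check of model fit.

    At each stored latent draw, the expected encounter frequency of every
    included individual is computed under the current parameters and latent
    state; replicate frequencies are simulated from the same Bernoulli
    model.  The discrepancy is Freeman-Tukey,
    T = sum_i (sqrt(count_i) - sqrt(expected_i))^2, over included
    individuals (augmented ones count as zeros in the observed data).  The
    p-value is the fraction of draws with T(replicate) >= T(observed);
    values inside roughly (0.15, 0.85) indicate adequate fit.
    """
    spec = samples.spec
    if samples.latent_z.size == 0:
        raise ValueError("no stored latent draws: rerun with latent_stride set")
    rng = np.random.default_rng(seed)
    eff = data.effort
    act_j, act_k = np.nonzero(eff.active)
    sk = eff.search_km[act_j, act_k]
    x1 = np.where(sk > 0, np.log(np.where(sk > 0, sk, 1.0)), 0.0)
    x2 = eff.playback[act_j, act_k].astype(float)
    hab = np.asarray(state_space.habitat)
    D2 = data.dist[hab] ** 2
    n = data.n_observed
    y_counts = data.y.reshape(n, -1).sum(axis=1)

    C, L = samples.latent_z.shape[:2]
    pairs = [(c, l) for c in range(C) for l in range(L)]
    if len(pairs) > max_draws:
        idx = rng.choice(len(pairs), size=max_draws, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]

    n_extreme = 0
    for c, l in pairs:
        it = int(samples.latent_iters[l])
        p = samples.parameters_at(c, it)
        z = samples.latent_z[c, l]
        s = samples.latent_s[c, l]
        sex = samples.latent_sex[c, l]
        inc = np.flatnonzero(z == 1)
        sig = np.where(sex[inc] == 1, p.sigma_m, p.sigma_f) if spec.sigma_sex_specific \
            else np.full(inc.size, p.sigma_f)
        g = math.log(p.lambda0) - D2[s[inc]][:, act_j] / (2.0 * sig[:, None] ** 2)
        if spec.theta != 1.0:
            g = math.log(p.lambda0) - (D2[s[inc]][:, act_j] / (2.0 * sig[:, None] ** 2)) ** spec.theta
        if spec.sex_beta:
            g = g + p.beta_sex * sex[inc][:, None]
        eta = g + p.beta_eff * x1 + (p.beta_eff2 * x2 if spec.include_playback else 0.0)
        pi = -np.expm1(-np.exp(eta))
        expected = pi.sum(axis=1)
        obs_counts = np.zeros(inc.size)
        obs_mask = inc < n
        obs_counts[obs_mask] = y_counts[inc[obs_mask]]
        rep_counts = (rng.random(pi.shape) < pi).sum(axis=1)
        t_obs = _freeman_tukey(obs_counts, expected)
        t_rep = _freeman_tukey(rep_counts, expected)
        if t_rep >= t_obs:
            n_extreme += 1
    return n_extreme / len(pairs)


def pairwise_correlations(samples: PosteriorSamples, threshold: float = 0.9,
                          density_params: tuple[str, ...] = ("psi", "n_super")):
    """Pooled-chain Pearson correlations between parameters.

    Returns ``(table, flags)`` where ``flags`` lists pairs with
    ``|r| > threshold`` (parameter redundancy); pairs involving the
    density-linked parameters are listed first.  Constant columns yield NaN
    and are reported as undefined rather than raising.
    """
    cols = {name: samples.pooled(name) for name in samples.names}
    cols["n_super"] = samples.pooled("n_super").astype(float)
    df = pd.DataFrame(cols)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = df.corr()
    flags = []
    names = list(corr.columns)
    for a_i, a in enumerate(names):
        for b in names[a_i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) > threshold:
                flags.append((a, b, float(r)))
    flags.sort(key=lambda t: (not (t[0] in density_params or t[1] in density_params),
                              -abs(t[2])))
    return corr, flags


def plot_pairwise(samples: PosteriorSamples, path, max_points: int = 2000) -> None:
    """Export a pairwise scatter-matrix of the posterior draws."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(samples.names) + ["n_super"]
    k = len(names)
    pooled = {n: samples.pooled(n) for n in names}
    total = pooled[names[0]].size
    sel = np.linspace(0, total - 1, min(max_points, total)).astype(int)
    fig, axes = plt.subplots(k, k, figsize=(2 * k, 2 * k))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            ax = axes[i, j]
            if i == j:
                ax.hist(pooled[a], bins=30)
            else:
                ax.plot(pooled[b][sel], pooled[a][sel], ".", ms=1, alpha=0.4)
            if i == k - 1:
                ax.set_xlabel(b, fontsize=7)
            if j == 0:
                ax.set_ylabel(a, fontsize=7)
            ax.tick_params(labelsize=5)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def summarize(samples: PosteriorSamples, derived: dict[str, np.ndarray] | None = None,
              mass: float = 0.95) -> pd.DataFrame:
    """Posterior mean, PSD, HPD bounds, and R-hat per parameter.

    ``derived`` adds rows for derived quantities given as (n_chains, T)
    draw arrays (e.g. region abundance or density draws).
    """
    rows = {}
    items = [(n, samples.chains(n)) for n in list(samples.names) + ["n_super"]]
    for name, arr in items + list((derived or {}).items()):
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        pooled = arr.ravel()
        if pooled.std() == 0:
            lo = hi = float(pooled[0])
            rhat = np.nan
        else:
            lo, hi = hpd_interval(pooled, mass)
            rhat = gelman_rubin(arr) if arr.shape[0] > 1 else np.nan
        rows[name] = {
            "mean": float(pooled.mean()),
            "psd": float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
            "hpd_lower": lo,
            "hpd_upper": hi,
            "rhat": rhat,
        }
    table = pd.DataFrame(rows).T
    table.index.name = "parameter"
    return table


def detection_frequency_table(y: np.ndarray) -> pd.DataFrame:
    """Distribution of per-individual detection counts.

    ``y`` is the (n, J, K) capture array (or a CaptureData).  Returns a
    table of (detections, n_individuals) rows; the totals line gives the
    number of individuals and the total detection count.
    """
    if hasattr(y, "y"):
        y = y.y
    counts = np.asarray(y).reshape(y.shape[0], -1).sum(axis=1).astype(int)
    vals, freq = np.unique(counts, return_counts=True)
    tab = pd.DataFrame({"detections": vals, "n_individuals": freq})
    tab.attrs["n_individuals"] = int(counts.size)
    tab.attrs["n_detections"] = int(counts.sum())
    return tab
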