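"""Derived density and abundance quantities from posterior latent draws.

Turns stored draws of the latent activity centers into the reported
quantities: a per-pixel posterior density surface, abundance within
arbitrary regions (with PSD and 95% HPD), density per 100 km^2, the
weighted-mean-sigma buffer region around the trap array, and the sex
ratio implied by ``psi_sex``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely

from .diagnostics import gelman_rubin, hpd_interval
from .mcmc import PosteriorSamples
from .state_space import StateSpace, TrapGrid

__all__ = [
    "DensitySurface",
    "RegionAbundance",
    "pixel_density_surface",
    "abundance_in_region",
    "density_per_100km2",
    "weighted_sigma_buffer",
    "BufferRegion",
    "sex_ratio",
    "format_sex_ratio",
]


@dataclass
class DensitySurface:
    """Posterior mean activity-center count per habitat pixel.

    ``values[p]`` is the expected number of included individuals whose
    activity center falls in habitat pixel ``p``; the surface sums to the
    posterior mean of N_super.
    """

    values: np.ndarray          # (n_habitat,)
    state_space: StateSpace

    @property
    def pixel_area(self) -> float:
        return self.state_space.pixel_area

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def per_100km2(self) -> np.ndarray:
        """Convert per-pixel counts to individuals per 100 km^2."""
        return self.values / self.pixel_area * 100.0

    def to_grid(self, fill: float = np.nan) -> np.ndarray:
        """Full-lattice (ny, nx) array, NaN outside habitat."""
        ny, nx = self.state_space.shape
        grid = np.full((ny, nx), fill)
        ij = self.state_space.habitat_ij()
        grid[ij[:, 1], ij[:, 0]] = self.values
        return grid


@dataclass
class RegionAbundance:
    """Draw-wise abundance of included individuals inside a region."""

    draws: np.ndarray        # (n_chains, L) integer counts
    area_km2: float

    @property
    def pooled(self) -> np.ndarray:
        return self.draws.ravel()

    @property
    def mean(self) -> float:
        return float(self.pooled.mean())

    @property
    def psd(self) -> float:
        return float(self.pooled.std(ddof=1))

    def hpd(self, mass: float = 0.95) -> tuple[float, float]:
        return hpd_interval(self.pooled, mass)

    def density_per_100km2(self) -> "RegionAbundance":
        return density_per_100km2(self.pooled, self.area_km2)

    def summary(self) -> dict[str, float]:
        lo, hi = self.hpd()
        out = {"mean": self.mean, "psd": self.psd, "hpd_lower": lo, "hpd_upper": hi}
        if self.draws.shape[0] > 1 and self.pooled.std() > 0:
            out["rhat"] = gelman_rubin(self.draws.astype(float))
        return out


def pixel_density_surface(samples: PosteriorSamples,
                          state_space: StateSpace) -> DensitySurface:
    """Per-pixel posterior mean count of included activity centers."""
    if samples.latent_z.size == 0:
        raise ValueError("no stored latent draws")
    nh = state_space.n_habitat
    z = samples.latent_z.reshape(-1, samples.latent_z.shape[-1])
    s = samples.latent_s.reshape(z.shape)
    n_draws = z.shape[0]
    inc = z == 1
    counts = np.bincount(s[inc], minlength=nh).astype(float)
    return DensitySurface(values=counts / n_draws, state_space=state_space)


def _region_mask(region, state_space: StateSpace) -> np.ndarray:
    """Boolean mask over habitat pixels from a polygon or an explicit mask."""
    if isinstance(region, np.ndarray) and region.dtype == bool:
        if region.size != state_space.n_habitat:
            raise ValueError("boolean region mask must cover the habitat pixels")
        return region
    hc = state_space.habitat_centroids
    return shapely.intersects_xy(region, hc[:, 0], hc[:, 1])


def abundance_in_region(samples: PosteriorSamples, region,
                        state_space: StateSpace,
                        area_km2: float | None = None) -> RegionAbundance:
    """Draw-wise count of included individuals with activity center in region.

    ``region`` is a shapely polygon or a boolean mask over habitat pixels.
    Abundance is evaluated at the stored latent draws; with the full
    state-space as region the draws equal N_super exactly.
    """
    mask = _region_mask(region, state_space)
    if not mask.any():
        raise ValueError("empty region: no habitat pixel falls inside")
    if area_km2 is None:
        area_km2 = float(mask.sum()) * state_space.pixel_area
    C, L, M = samples.latent_z.shape
    draws = np.empty((C, L), dtype=np.int64)
    for c in range(C):
        inside = mask[samples.latent_s[c]]           # (L, M)
        draws[c] = ((samples.latent_z[c] == 1) & inside).sum(axis=1)
    return RegionAbundance(draws=draws, area_km2=area_km2)


def density_per_100km2(n, area_km2: float):
    """D = N / area * 100 (individuals per 100 km^2); works on draws too."""
    if area_km2 <= 0:
        raise ValueError("area must be > 0")
    return np.asarray(n, dtype=float) / area_km2 * 100.0


@dataclass
class BufferRegion:
    """Habitat pixels within the weighted-mean sigma of any trap cell."""

    mask: np.ndarray         # bool over habitat pixels
    sigma_bar: float         # km
    area_km2: float


def weighted_sigma_buffer(sigma_f: float, sigma_m: float, psi_sex: float,
                          trap_grid: TrapGrid,
                          state_space: StateSpace) -> BufferRegion:
    """Region within the sex-weighted mean movement scale of the trap array.

    sigma_bar = psi_sex * sigma_m + (1 - psi_sex) * sigma_f; the region is
    the union of discs of radius sigma_bar around trap-cell centroids,
    discretized to habitat pixels.  Weighting by the posterior sex
    proportion is the default; pass detected-sex proportions for the
    count-weighted variant.
    """
    if sigma_f <= 0 or sigma_m <= 0:
        raise ValueError("sigma values must be > 0")
    if not (0.0 <= psi_sex <= 1.0):
        raise ValueError("psi_sex must lie in [0, 1]")
    if trap_grid.n_traps == 0:
        raise ValueError("empty trap grid")
    sigma_bar = psi_sex * sigma_m + (1.0 - psi_sex) * sigma_f
    hc = state_space.habitat_centroids
    dmin = np.full(hc.shape[0], np.inf)
    for c in trap_grid.cell_centroids:
        d = np.hypot(hc[:, 0] - c[0], hc[:, 1] - c[1])
        np.minimum(dmin, d, out=dmin)
    mask = dmin <= sigma_bar
    return BufferRegion(mask=mask, sigma_bar=float(sigma_bar),
                        area_km2=float(mask.sum()) * state_space.pixel_area)


def sex_ratio(psi_sex: float) -> float:
    """Females per male implied by psi_sex: (1 - psi_sex) / psi_sex."""
    if not (0.0 < psi_sex < 1.0):
        raise ValueError("psi_sex must lie strictly in (0, 1)")
    return (1.0 - psi_sex) / psi_sex


def format_sex_ratio(psi_sex: float) -> str:
    """Sex ratio as the conventional 'r♀:1♂' string, one decimal."""
    r = sex_ratio(psi_sex)
    return f"{math.floor(r * 10 + 0.5) / 10:.1f}♀:1♂"
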