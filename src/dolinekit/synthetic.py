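"""Synthetic inputs with known ground truth for every analysis module.

The blink generator emulates the statistical structure of a dSTORM
localization table: clustered blinks (Gaussian around cluster centres)
plus uniform background blinks, spread uniformly over ~9,000 frames, with
intensity / uncertainty / PSF-width marginals chosen to sit inside the
quality-filter window (lognormal intensity with median ~1000 photons,
gamma-distributed uncertainty with mean 15 nm, normal PSF width
150 +/- 20 nm).  A configurable fraction of deliberately out-of-window
records exercises the filter.  These are synthetic conventions, not
measured marginals.

The force-curve generator produces deflection-displacement data exactly
consistent with the spherical Hertz contact model (solving the implicit
cantilever/indentation balance per sample) plus additive Gaussian noise;
the GP generator inverts the Laurdan generalized-polarization formula.

All generators are pure functions of (params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .smlm import COLUMNS, LocalizationTable

__all__ = [
    "BlinkParams",
    "BlinkGroundTruth",
    "gen_blinks",
    "gen_force_curve",
    "gen_gp_frames",
]


@dataclass(frozen=True)
class BlinkParams:
    """Parameters of the synthetic blink-table generator."""

    n_clusters: int = 10
    blinks_per_cluster: tuple[int, ...] | int = 100
    cluster_sd: tuple[float, ...] | float = 8.0     # nm
    roi_side: float = 2000.0                        # nm (square ROI)
    border_margin: float = 200.0                    # nm, keeps clusters inside
    min_separation: float = 150.0                   # nm between centres
    n_frames: int = 9000
    noise_fraction: float = 0.05       # uniform background per cluster blink
    outlier_fraction: float = 0.02     # extra records failing the filters
    intensity_median: float = 1000.0
    intensity_sigma_log: float = 0.5
    uncertainty_mean: float = 15.0     # nm
    sigma_psf_mean: float = 150.0      # nm
    sigma_psf_sd: float = 20.0         # nm

    def counts(self) -> np.ndarray:
        c = self.blinks_per_cluster
        arr = (np.full(self.n_clusters, c) if np.isscalar(c)
               else np.asarray(c, dtype=int))
        if len(arr) != self.n_clusters or (arr < 0).any():
            raise ValueError("blinks_per_cluster must give one non-negative "
                             "count per cluster")
        return arr.astype(int)

    def spreads(self) -> np.ndarray:
        s = self.cluster_sd
        arr = (np.full(self.n_clusters, s) if np.isscalar(s)
               else np.asarray(s, dtype=float))
        if len(arr) != self.n_clusters or (arr <= 0).any():
            raise ValueError("cluster_sd must give one positive sd per cluster")
        return arr

    def __post_init__(self) -> None:
        if self.n_clusters < 0 or self.n_frames < 1:
            raise ValueError("infeasible blink parameters")
        if not 0 <= self.noise_fraction:
            raise ValueError("noise_fraction must be non-negative")
        self.counts()
        self.spreads()


@dataclass
class BlinkGroundTruth:
    """What the generator actually placed (per-cluster truth plus noise)."""

    centers: np.ndarray          # (K, 2) nm
    sds: np.ndarray              # (K,) nm
    counts: np.ndarray           # (K,) blinks per cluster
    n_noise: int
    n_outliers: int
    roi_area: float
    seed: int

    @property
    def true_densities(self) -> np.ndarray:
        """Nominal blink density per cluster ~ count / (pi (2 sd)^2)."""
        return self.counts / (math.pi * (2.0 * self.sds) ** 2)


def _draw_centers(rng: np.random.Generator, p: BlinkParams) -> np.ndarray:
    lo, hi = p.border_margin, p.roi_side - p.border_margin
    if hi <= lo:
        raise ValueError("border_margin too large for roi_side")
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < p.n_clusters:
        c = rng.uniform(lo, hi, size=2)
        if all(np.hypot(*(c - o)) >= p.min_separation for o in centers):
            centers.append(c)
        attempts += 1
        if attempts > 10000 * max(p.n_clusters, 1):
            raise ValueError("cannot place cluster centres with the "
                             "requested separation")
    return np.array(centers) if centers else np.empty((0, 2))


def _attributes(rng: np.random.Generator, p: BlinkParams, n: int) -> dict:
    intensity = rng.lognormal(math.log(p.intensity_median),
                              p.intensity_sigma_log, n)
    # keep the in-window marginal actually inside the strict filter window
    intensity = np.clip(intensity, 301.0, 4999.0)
    shape_k = 4.0
    uncertainty = np.clip(rng.gamma(shape_k, p.uncertainty_mean / shape_k, n),
                          0.0, 34.9)
    sigma = np.clip(rng.normal(p.sigma_psf_mean, p.sigma_psf_sd, n),
                    1.0, 299.0)
    return {"sigma": sigma, "intensity": intensity, "uncertainty": uncertainty}


def gen_blinks(params: BlinkParams = BlinkParams(), seed: int = 0
               ) -> tuple[LocalizationTable, BlinkGroundTruth]:
    """Generate a blink table with known cluster ground truth."""
    rng = np.random.default_rng(seed)
    p = params
    centers = _draw_centers(rng, p)
    counts = p.counts()
    sds = p.spreads()

    xs, ys = [], []
    for (cx, cy), cnt, sd in zip(centers, counts, sds):
        xs.append(rng.normal(cx, sd, cnt))
        ys.append(rng.normal(cy, sd, cnt))
    n_cluster_blinks = int(counts.sum())
    n_noise = int(round(p.noise_fraction * n_cluster_blinks))
    xs.append(rng.uniform(0.0, p.roi_side, n_noise))
    ys.append(rng.uniform(0.0, p.roi_side, n_noise))
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    n = len(x)

    frames = rng.integers(1, p.n_frames + 1, n)
    attrs = _attributes(rng, p, n)

    # extra out-of-window records to exercise the quality filter
    n_out = int(round(p.outlier_fraction * n))
    if n_out:
        xo = rng.uniform(0.0, p.roi_side, n_out)
        yo = rng.uniform(0.0, p.roi_side, n_out)
        fo = rng.integers(1, p.n_frames + 1, n_out)
        ao = _attributes(rng, p, n_out)
        kind = rng.integers(0, 4, n_out)
        ao["intensity"][kind == 0] = 100.0    # too dim
        ao["intensity"][kind == 1] = 8000.0   # too bright
        ao["uncertainty"][kind == 2] = 60.0   # too imprecise
        ao["sigma"][kind == 3] = 400.0        # too wide
        x = np.concatenate([x, xo]); y = np.concatenate([y, yo])
        frames = np.concatenate([frames, fo])
        for k in attrs:
            attrs[k] = np.concatenate([attrs[k], ao[k]])

    df = pd.DataFrame({"frame": frames.astype(int), "x": x, "y": y, **attrs})
    df = df.sort_values("frame", kind="stable").reset_index(drop=True)
    df = df[list(COLUMNS)]

    s = p.roi_side
    table = LocalizationTable(
        df, roi_area=s * s,
        roi_polygon=[(0.0, 0.0), (s, 0.0), (s, s), (0.0, s)])
    truth = BlinkGroundTruth(centers=centers, sds=sds, counts=counts,
                             n_noise=n_noise, n_outliers=n_out,
                             roi_area=s * s, seed=seed)
    return table, truth


def gen_force_curve(E_true: float, R_bead: float, k_cant: float,
                    z_c: float = 0.5e-6, d_0: float = 0.0,
                    noise_sd: float = 0.0, seed: int = 0,
                    z_max: float = 3e-6, n_samples: int = 400):
    """Synthesize an AFM approach curve obeying the spherical Hertz model.

    For each cantilever displacement z past the contact point the
    deflection d satisfies the force balance
    k (d - d_0) = 4 E sqrt(R) / (3 (1 - mu^2)) * delta^{3/2} with
    delta = (z - z_c) - (d - d_0); the implicit equation is solved per
    sample, then Gaussian noise of sd ``noise_sd`` is added to d.

    Returns a :class:`dolinekit.biophys.ForceCurve` (SI units).
    """
    from .biophys import ForceCurve, hertz_force

    if E_true <= 0 or R_bead <= 0 or k_cant <= 0:
        raise ValueError("E_true, R_bead, k_cant must be positive")
    if z_c < 0 or z_c >= z_max:
        raise ValueError("contact point must lie inside the ramp")
    rng = np.random.default_rng(seed)
    z = np.linspace(0.0, z_max, n_samples)
    d = np.full_like(z, d_0)
    for i, zi in enumerate(z):
        travel = zi - z_c
        if travel <= 0:
            continue
        g = lambda delta: (k_cant * (travel - delta)
                           - hertz_force(E_true, R_bead, delta))
        d[i] = d_0 + (travel - brentq(g, 0.0, travel, xtol=1e-18, rtol=1e-14))
    if noise_sd > 0:
        d = d + rng.normal(0.0, noise_sd, len(d))
    return ForceCurve(z=z, d=d, k_cant=k_cant)


def gen_gp_frames(gp_true_map, G: float = 1.0, noise: float = 0.0,
                  seed: int = 0, i490_scale: float = 1000.0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Paired (I440, I490) intensity arrays whose noiseless GP equals
    ``gp_true_map`` under G-factor ``G`` (inverse of the GP formula)."""
    gp = np.asarray(gp_true_map, dtype=float)
    if np.any(gp <= -1.0) or np.any(gp >= 1.0):
        raise ValueError("gp_true must lie strictly inside (-1, 1)")
    rng = np.random.default_rng(seed)
    i490 = np.full_like(gp, float(i490_scale))
    i440 = G * i490 * (1.0 + gp) / (1.0 - gp)
    if noise > 0:
        i440 = i440 + rng.normal(0.0, noise, gp.shape)
        i490 = i490 + rng.normal(0.0, noise, gp.shape)
    return i440, i490
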