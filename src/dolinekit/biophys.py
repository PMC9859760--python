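"""Membrane-biophysics measurement formulas.

Spherical Hertz contact fitting for bead-AFM force curves (Young's
modulus with joint contact-point estimation), Laurdan generalized
polarization with G-factor calibration, and optical-stretcher axial
strain.  SI units internally (m, N, Pa).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ForceCurve",
    "HertzFit",
    "hertz_force",
    "fit_hertz",
    "laurdan_gp",
    "calibrate_g",
    "os_strain",
    "HertzModel",
    "HertzResults",
]


@dataclass(frozen=True)
class ForceCurve:
    """Cantilever displacement / deflection samples [m] and spring constant
    k_cant [N/m]; force is F = k_cant * d."""

    z: np.ndarray
    d: np.ndarray
    k_cant: float

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "d", d)
        if len(z) != len(d) or len(z) < 10:
            raise ValueError("z and d must have equal length >= 10")
        if self.k_cant <= 0:
            raise ValueError("k_cant must be positive")

    @property
    def force(self) -> np.ndarray:
        return self.k_cant * self.d


@dataclass(frozen=True)
class HertzFit:
    """Result of a spherical-Hertz fit."""

    E: float          # Young's modulus [Pa]
    z_c: float        # contact displacement [m]
    d_0: float        # deflection offset [m]
    mu: float         # Poisson ratio
    R_bead: float     # bead radius [m]
    rss: float        # residual sum of squares [N^2]
    n_contact: int    # post-contact samples used

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not 0.0 <= self.mu <= 0.5:
            raise ValueError("mu must lie in [0, 0.5]")


def hertz_force(E: float, R: float, delta, mu: float = 0.5):
    """Spherical Hertz contact force F = 4 E R^{1/2} / (3 (1 - mu^2)) delta^{3/2}.

    ``delta`` may be scalar or array; negative indentation raises.
    """
    if E <= 0 or R <= 0:
        raise ValueError("E and R must be positive")
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("delta must be non-negative")
    F = 4.0 * E * np.sqrt(R) / (3.0 * (1.0 - mu**2)) * delta**1.5
    return float(F) if F.ndim == 0 else F


def _indentation(z, d, z_c, d_0):
    return (z - z_c) - (d - d_0)


def fit_hertz(curve: ForceCurve, R_bead: float, mu: float = 0.5) -> HertzFit:
    """Jointly estimate (E, z_c, d_0) by nonlinear least squares.

    The model predicts force k*(d - d_0) = Hertz(E, delta) on the
    delta >= 0 branch and zero before contact, with indentation
    delta = (z - z_c) - (d - d_0).  The deflection offset is initialized
    from the pre-contact (first fifth) residual baseline and the contact
    point from where the baseline-subtracted force first rises above its
    noise floor.  Deterministic given the data.
    """
    if R_bead <= 0:
        raise ValueError("R_bead must be positive")
    z, d, k = curve.z, curve.d, curve.k_cant
    n = len(z)
    n_pre = max(n // 5, 5)
    d0_init = float(np.median(d[:n_pre]))
    f = k * (d - d0_init)
    noise = float(np.std(f[:n_pre]))
    thresh = max(5.0 * noise, 0.02 * float(np.max(f)))
    above = np.flatnonzero(f > thresh)
    zc_init = float(z[above[0]]) if len(above) else float(z[n // 2])

    def pack_resid(x):
        E, z_c, d_0 = x
        delta = np.clip(_indentation(z, d, z_c, d_0), 0.0, None)
        return k * (d - d_0) - hertz_force(abs(E), R_bead, delta, mu)

    delta_end = max(_indentation(z[-1], d[-1], zc_init, d0_init), 1e-9)
    E_init = max(k * (d[-1] - d0_init)
                 / (4.0 * np.sqrt(R_bead) / (3.0 * (1.0 - mu**2))
                    * delta_end**1.5), 1.0)

    res = least_squares(pack_resid, x0=[E_init, zc_init, d0_init],
                        x_scale=[max(E_init, 1.0), max(zc_init, 1e-8), 1e-9],
                        method="lm" if n >= 3 else "trf", xtol=1e-15,
                        ftol=1e-15, gtol=1e-15, max_nfev=5000)
    if not res.success:
        raise RuntimeError(f"Hertz fit did not converge: {res.message}")
    E, z_c, d_0 = float(abs(res.x[0])), float(res.x[1]), float(res.x[2])
    n_contact = int(np.sum(_indentation(z, d, z_c, d_0) > 0))
    if n_contact < 5:
        raise ValueError("insufficient post-contact samples for a Hertz fit")
    return HertzFit(E=E, z_c=z_c, d_0=d_0, mu=mu, R_bead=R_bead,
                    rss=float(np.sum(res.fun**2)), n_contact=n_contact)


def laurdan_gp(I440, I490, G: float = 1.0):
    """Laurdan generalized polarization GP = (I440 - G I490)/(I440 + G I490).

    Elements with a non-positive denominator are returned as NaN (flagged,
    not fatal).  With G = 1 and non-negative intensities GP lies in
    [-1, 1].
    """
    I440 = np.asarray(I440, dtype=float)
    I490 = np.asarray(I490, dtype=float)
    denom = I440 + G * I490
    with np.errstate(divide="ignore", invalid="ignore"):
        gp = np.where(denom > 0, (I440 - G * I490) / denom, np.nan)
    return float(gp) if gp.ndim == 0 else gp


def calibrate_g(I440_ref: float, I490_ref: float, gp_known: float) -> float:
    """G-factor from a reference of known GP (e.g. Laurdan in DMSO):

    G = (I440_ref / I490_ref) * (1 - gp_known) / (1 + gp_known),
    so that laurdan_gp(I440_ref, I490_ref, G) == gp_known exactly.
    """
    if I440_ref <= 0 or I490_ref <= 0:
        raise ValueError("reference intensities must be positive")
    if not -1.0 < gp_known < 1.0:
        raise ValueError("gp_known must lie strictly inside (-1, 1)")
    return (I440_ref / I490_ref) * (1.0 - gp_known) / (1.0 + gp_known)


def os_strain(r_t, r0: float, percent: bool = False):
    """Optical-stretcher axial strain Strain(t) = (r(t) - r0) / r0."""
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    strain = (np.asarray(r_t, dtype=float) - r0) / r0
    if percent:
        strain = strain * 100.0
    return float(strain) if strain.ndim == 0 else strain


class HertzModel:
    """Model wrapper for :func:`fit_hertz` (statsmodels-style).

    >>> from dolinekit.synthetic import gen_force_curve
    >>> curve = gen_force_curve(1000.0, 2.25e-6, 0.03)
    >>> res = HertzModel(curve, R_bead=2.25e-6).fit()
    >>> round(res.fit.E)
    1000
    """

    def __init__(self, curve: ForceCurve, R_bead: float, mu: float = 0.5):
        self.curve = curve
        self.R_bead = R_bead
        self.mu = mu

    def fit(self) -> "HertzResults":
        return HertzResults(self, fit_hertz(self.curve, self.R_bead, self.mu))


class HertzResults:
    def __init__(self, model: HertzModel, fit: HertzFit):
        self.model = model
        self.fit = fit

    def summary(self) -> str:
        f = self.fit
        buf = io.StringIO()
        buf.write("Spherical Hertz contact fit\n")
        buf.write("===========================\n")
        buf.write(f"Young's modulus E : {f.E:.6g} Pa\n")
        buf.write(f"contact point z_c : {f.z_c * 1e6:.4g} um\n")
        buf.write(f"deflection offset : {f.d_0 * 1e9:.4g} nm\n")
        buf.write(f"Poisson ratio mu  : {f.mu}\n")
        buf.write(f"bead radius       : {f.R_bead * 1e6:.4g} um\n")
        buf.write(f"RSS               : {f.rss:.4g} N^2 "
                  f"({f.n_contact} contact samples)\n")
        return buf.getvalue()
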