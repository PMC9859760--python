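"""Thermodynamic ensemble of protein-coated membrane domains.

Many identical spherical-cap domains (number density ``n`` per nm^2 of
projected membrane, coat area ``A_d``, depth ``u``) coexist with a
dispersed pool of coat proteins at fixed average protein area fraction
``phi_bar`` and tension ``sigma``.  The model is monodisperse and assumes
a close-packed coat (protein fraction 1 inside domains), so protein
bookkeeping is exact: n * A_d + phi_disp = phi_bar.

Free-energy density [kBT / nm^2], with kBT = 1 internally:

    f = n [ E_mech(A_d, u; sigma) + (A_d / a_p) delta ]
        + (phi_disp / a_p) e_f
        + n ( ln(n a_p) - 1 )

where E_mech includes bending, tension-on-excess-area and the rim line
energy, e_f = 2 kappa_c a_p c0^2 is the flat-frustration energy of a
dispersed coat protein, and the last term is the translational entropy of
the domains with reference area a_p.

Minimizing f over (n, A_d, u) at each tension yields the equilibrium
density, size and shape of the domains, and hence the projected diameter,
domain density and projected areal strain curves as tension is swept.
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import spearmanr

from .cap_geometry import (CapShape, CoatParams, TensionProtocol, cap_from,
                           coat_preset, convert_tension, mech_energy_u)

__all__ = [
    "EnsembleState",
    "EnsembleSweep",
    "free_energy_density",
    "minimize_state",
    "sweep_tension",
    "regime_report",
    "EnsembleModel",
    "EnsembleResults",
    "DEFAULT_COVERAGES",
    "A_D_BOUNDS",
]

A_D_BOUNDS = (1e3, 1e6)           # nm^2
DEFAULT_COVERAGES = (0.01, 0.03, 0.06)
_Q_FLOOR = 1e-12                  # smallest condensed fraction considered


@dataclass(frozen=True)
class EnsembleState:
    """One equilibrium point of the ensemble model."""

    n: float                  # domain number density [nm^-2]
    shape: CapShape
    phi_bar: float
    phi_disp: float           # dispersed protein fraction, = phi_bar - n A_d
    f: float                  # free-energy density [kBT/nm^2]
    sigma: float
    converged: bool = True
    n_starts: int = 1

    @property
    def s_stored(self) -> float:
        """Stored (excess) area per unit projected area, n * dA_excess."""
        return self.n * self.shape.dA_excess

    @property
    def condensed_fraction(self) -> float:
        """Protein enrichment readout: fraction of protein in domains."""
        return self.n * self.shape.A_d / self.phi_bar if self.phi_bar else 0.0


def free_energy_density(n: float, A_d: float, u: float, coat: CoatParams,
                        sigma: float, phi_bar: float) -> float:
    """Evaluate f [kBT/nm^2]; raises on protein-conservation violation."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0.0 <= u <= 2.0:
        raise ValueError("u must lie in [0, 2]")
    if n * A_d > phi_bar * (1 + 1e-12):
        raise ValueError("constraint violation: n * A_d > phi_bar")
    phi_disp = max(phi_bar - n * A_d, 0.0)
    e_f = coat.flat_frustration_per_protein
    disp = (phi_disp / coat.a_p) * e_f
    if n == 0.0:
        return disp
    E = float(mech_energy_u(A_d, u, coat, sigma))
    dom = n * (E + (A_d / coat.a_p) * coat.delta_assembly)
    entropy = n * (math.log(n * coat.a_p) - 1.0)
    return dom + disp + entropy


def _objective(x: np.ndarray, coat: CoatParams, sigma: float,
               phi_bar: float) -> float:
    q, lnA, u = x
    A_d = math.exp(lnA)
    n = q * phi_bar / A_d
    return free_energy_density(n, A_d, u, coat, sigma, phi_bar)


def _state_from_x(x, coat, sigma, phi_bar, f, converged, n_starts) -> EnsembleState:
    q, lnA, u = x
    A_d = float(math.exp(lnA))
    n = float(q) * phi_bar / A_d
    shape = cap_from(A_d, float(np.clip(u, 0.0, 2.0)))
    return EnsembleState(n=n, shape=shape, phi_bar=phi_bar,
                         phi_disp=max(phi_bar - n * A_d, 0.0), f=float(f),
                         sigma=sigma, converged=converged, n_starts=n_starts)


def _start_lattice() -> list[np.ndarray]:
    """Deterministic 5x5x5 lattice over (q, ln A_d, u)."""
    qs = np.geomspace(1e-4, 1.0, 5)
    lnAs = np.linspace(math.log(A_D_BOUNDS[0]), math.log(A_D_BOUNDS[1]), 5)
    us = np.linspace(0.05, 1.95, 5)
    return [np.array(x) for x in itertools.product(qs, lnAs, us)]


def minimize_state(coat: CoatParams, sigma: float, phi_bar: float,
                   init: EnsembleState | None = None) -> EnsembleState:
    """Bounded local minimization of f over (condensed fraction, ln A_d, u).

    With ``init`` None, a deterministic 5x5x5 multi-start lattice is used
    and the lowest-f candidate returned (ties within 1e-10 broken toward
    smaller u, then smaller A_d).  With ``init`` given, a single local
    minimization warm-starts from it (the continuation step used by
    :func:`sweep_tension`).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if not 0.0 < phi_bar < 1.0:
        raise ValueError("phi_bar must lie in (0, 1)")
    bounds = [(_Q_FLOOR, 1.0),
              (math.log(A_D_BOUNDS[0]), math.log(A_D_BOUNDS[1])),
              (0.0, 2.0)]
    if init is not None:
        q0 = min(max(init.n * init.shape.A_d / phi_bar, _Q_FLOOR), 1.0)
        starts = [np.array([q0, math.log(init.shape.A_d), init.shape.u])]
    else:
        starts = _start_lattice()

    def _run(start_list):
        best: tuple[float, np.ndarray] | None = None
        ok = False
        for x0 in start_list:
            res = minimize(_objective, x0, args=(coat, sigma, phi_bar),
                           method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": 200, "ftol": 1e-15,
                                    "gtol": 1e-12})
            f = float(res.fun)
            if not math.isfinite(f):
                continue
            x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
            ok = ok or bool(res.success)
            if best is None or f < best[0] - 1e-10:
                best = (f, x)
            elif abs(f - best[0]) <= 1e-10:
                # tie: prefer smaller u, then smaller A_d
                if (x[2], x[1]) < (best[1][2], best[1][1]):
                    best = (min(f, best[0]), x)
        return best, ok

    best, ok = _run(starts)
    if init is not None and (best is None or not ok):
        # warm start failed its line search: retry from the full lattice
        lat_best, lat_ok = _run(_start_lattice())
        if lat_best is not None and (best is None or lat_best[0] < best[0]):
            best, ok = lat_best, lat_ok or ok
    if best is None:
        raise RuntimeError(
            f"ensemble minimization found no finite state at sigma={sigma:g}, "
            f"phi_bar={phi_bar:g}")
    return _state_from_x(best[1], coat, sigma, phi_bar, best[0], ok, len(starts))


@dataclass
class EnsembleSweep:
    """Equilibrium states along one tension protocol at fixed coverage."""

    coat: CoatParams
    phi_bar: float
    protocol: TensionProtocol
    states: list[EnsembleState]
    legs: list[str]            # "up"/"down" per state

    @property
    def sigma(self) -> np.ndarray:
        return np.array([s.sigma for s in self.states])

    @property
    def n(self) -> np.ndarray:
        return np.array([s.n for s in self.states])

    @property
    def A_d(self) -> np.ndarray:
        return np.array([s.shape.A_d for s in self.states])

    @property
    def u(self) -> np.ndarray:
        return np.array([s.shape.u for s in self.states])

    @property
    def D_proj(self) -> np.ndarray:
        return np.array([s.shape.D_proj for s in self.states])

    @property
    def s_stored(self) -> np.ndarray:
        return np.array([s.s_stored for s in self.states])

    @property
    def areal_strain(self) -> np.ndarray:
        """Projected areal strain: stored area released relative to the
        lowest tension of the sweep, s(sigma_min) - s(sigma)."""
        s = self.s_stored
        sig = self.sigma
        return s[np.argmin(sig)] - s

    def leg_mask(self, leg: str) -> np.ndarray:
        return np.asarray(self.legs) == leg

    def to_frame(self) -> pd.DataFrame:
        T = self.coat.temperature_K
        return pd.DataFrame({
            "preset": self.coat.name,
            "phi_bar": self.phi_bar,
            "leg": self.legs,
            "sigma_kBT_nm2": self.sigma,
            "sigma_mN_m": [convert_tension(s, "kBT_per_nm2", "mN_per_m", T)
                           for s in self.sigma],
            "n_per_um2": self.n * 1e6,
            "A_d_nm2": self.A_d,
            "u": self.u,
            "psi_deg": [st.shape.psi_deg for st in self.states],
            "D_proj_nm": self.D_proj,
            "areal_strain": self.areal_strain,
            "f": [st.f for st in self.states],
        })


def sweep_tension(coat: CoatParams, protocol: TensionProtocol,
                  phi_bar_list=DEFAULT_COVERAGES) -> list[EnsembleSweep]:
    """Sweep the protocol at each coverage with warm-start continuation.

    The first tension of each sweep uses the full multi-start lattice;
    every subsequent point warm-starts from the previous minimizer
    (direction-dependent, so cycle protocols can exhibit continuation
    hysteresis between metastable branches).
    """
    sweeps = []
    for phi_bar in phi_bar_list:
        states: list[EnsembleState] = []
        legs: list[str] = []
        prev: EnsembleState | None = None
        for direction, grid in protocol.legs():
            for s in grid:
                st = minimize_state(coat, s, phi_bar, init=prev)
                states.append(st)
                legs.append(direction)
                prev = st
        sweeps.append(EnsembleSweep(coat=coat, phi_bar=phi_bar,
                                    protocol=protocol, states=states,
                                    legs=legs))
    return sweeps


def _upper_half_variation(x: np.ndarray) -> float:
    """Relative variation (max-min)/mean over the upper half of a curve."""
    h = x[len(x) // 2:]
    m = np.mean(np.abs(h))
    if m == 0:
        return 0.0
    return float((np.max(h) - np.min(h)) / m)


def _trend_label(sweep: EnsembleSweep) -> dict:
    """Trend diagnostics and regime label for one up-leg sweep."""
    mask = sweep.leg_mask("up")
    sig, n, A, u = (sweep.sigma[mask], sweep.n[mask],
                    sweep.A_d[mask], sweep.u[mask])
    R = np.where(u > 0, np.sqrt(A / (2 * np.pi * np.clip(u, 1e-300, None))),
                 np.inf)
    rho_n = spearmanr(sig, n).statistic if len(set(n)) > 1 else 0.0
    rho_A = spearmanr(sig, A).statistic if len(set(A)) > 1 else 0.0
    half = len(sig) // 2
    n_hi = n[half:]
    n_drop = 1.0 - (n_hi[-1] / n_hi[0]) if n_hi[0] > 0 else 0.0
    var_R = _upper_half_variation(np.where(np.isfinite(R), R, 0.0))
    var_u = _upper_half_variation(u)
    if rho_n > 0.8 and rho_A < -0.8:
        label = "splitting"
    elif n_drop > 0.5 and max(var_R, var_u) < 0.10:
        label = "number_reduction"
    else:
        label = "indeterminate"
    i0 = int(np.argmin(sig))
    return {
        "label": label,
        "spearman_n_sigma": float(rho_n),
        "spearman_A_sigma": float(rho_A),
        "n_drop_upper_half": float(n_drop),
        "shape_variation_upper_half": {"R": var_R, "u": var_u},
        "psi_deg_at_sigma_min": float(np.degrees(np.arccos(1 - u[i0]))),
        "u_at_sigma_min": float(u[i0]),
    }


def _decile_strain(sweep: EnsembleSweep) -> tuple[float, float]:
    """(strain released over the lowest tension decile,
        strain released over the highest decile), up leg."""
    mask = sweep.leg_mask("up")
    strain = sweep.areal_strain[mask]
    k = max(1, len(strain) // 10)
    low = strain[k - 1] - strain[0]
    high = strain[-1] - strain[-k]
    return float(low), float(high)


def _coverage_dependence(values: list[float]) -> float:
    arr = np.abs(np.asarray(values, dtype=float))
    m = arr.mean()
    return float((arr.max() - arr.min()) / m) if m > 0 else 0.0


def regime_report(sweeps_by_preset: dict[str, list[EnsembleSweep]]) -> dict:
    """Structured summary of the tension-response regimes of each coat.

    ``sweeps_by_preset`` maps preset name -> list of sweeps (one per
    coverage, same protocol).  Reports trend labels (splitting vs number
    reduction), contact angles at the lowest tension, strain released over
    the lowest/highest tension deciles and its coverage dependence.
    """
    report: dict = {}
    for preset, sweeps in sweeps_by_preset.items():
        per_cov = {}
        lows, highs = [], []
        for sw in sweeps:
            t = _trend_label(sw)
            lo, hi = _decile_strain(sw)
            t["strain_low_decile"] = lo
            t["strain_high_decile"] = hi
            lows.append(lo)
            highs.append(hi)
            per_cov[sw.phi_bar] = t
        report[preset] = {
            "per_coverage": per_cov,
            "coverage_dependence_low": _coverage_dependence(lows),
            "coverage_dependence_high": _coverage_dependence(highs),
            "mean_strain_low_decile": float(np.mean(lows)),
            "mean_strain_high_decile": float(np.mean(highs)),
        }
    return report


class EnsembleModel:
    """Ensemble free-energy model for one coat over a tension protocol.

    Examples
    --------
    >>> model = EnsembleModel.from_preset("cav1")
    >>> res = model.fit()
    >>> print(res.summary())          # doctest: +SKIP
    """

    def __init__(self, coat: CoatParams, protocol: TensionProtocol | None = None,
                 coverages=DEFAULT_COVERAGES):
        self.coat = coat
        self.protocol = protocol or TensionProtocol.log_spaced()
        self.coverages = tuple(coverages)

    @classmethod
    def from_preset(cls, preset: str, protocol: TensionProtocol | None = None,
                    coverages=DEFAULT_COVERAGES, **coat_overrides):
        return cls(coat_preset(preset, **coat_overrides), protocol, coverages)

    def fit(self) -> "EnsembleResults":
        sweeps = sweep_tension(self.coat, self.protocol, self.coverages)
        return EnsembleResults(self, sweeps)


class EnsembleResults:
    def __init__(self, model: EnsembleModel, sweeps: list[EnsembleSweep]):
        self.model = model
        self.sweeps = sweeps

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([sw.to_frame() for sw in self.sweeps],
                         ignore_index=True)

    def report(self) -> dict:
        return regime_report({self.model.coat.name: self.sweeps})

    def summary(self) -> str:
        rep = self.report()[self.model.coat.name]
        buf = io.StringIO()
        w = buf.write
        w("Ensemble tension sweep\n")
        w("======================\n")
        w(f"coat preset  : {self.model.coat.name}\n")
        w(f"coverages    : {self.model.coverages}\n")
        grid = self.model.protocol.sigma_grid
        w(f"sigma grid   : {min(grid):g} .. {max(grid):g} kBT/nm^2 "
          f"({len(grid)} pts, {self.model.protocol.direction})\n")
        for phi, t in rep["per_coverage"].items():
            w(f"phi_bar={phi:g}: label={t['label']}, "
              f"psi(sigma_min)={t['psi_deg_at_sigma_min']:.1f} deg, "
              f"rho(n)={t['spearman_n_sigma']:+.2f}, "
              f"rho(A)={t['spearman_A_sigma']:+.2f}\n")
        w(f"coverage dependence of released strain: "
          f"low decile {rep['coverage_dependence_low']:.2f}, "
          f"high decile {rep['coverage_dependence_high']:.2f}\n")
        return buf.getvalue()
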