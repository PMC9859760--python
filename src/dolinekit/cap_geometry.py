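"""Exact geometry and mechanics of a spherical-cap membrane domain.

A protein-coated domain of fixed coat area ``A_d`` deforms as a spherical
cap.  Its shape is parameterized by the single dimensionless variable

    u = 1 - cos(psi),   u in [0, 2],

where ``psi`` is the contact angle of the cap: u = 0 is a flat disc,
u = 1 a hemisphere, u = 2 a fully budded sphere with a closed neck.  All
derived quantities (sphere radius, projected area, stored excess area,
projected diameter, rim perimeter) are closed-form in (A_d, u), which is
what makes this module usable as the analytic oracle for the domain and
ensemble models built on top of it.

Mechanical energy follows a minimal Helfrich-type form: uniform-curvature
bending of the coat against its spontaneous curvature c0, membrane tension
charged on the stored (excess) area, and an optional rim line energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "KB_PN_NM_PER_K",
    "CoatParams",
    "CapShape",
    "TensionProtocol",
    "cap_from",
    "mech_energy",
    "optimal_angle_closed_form",
    "convert_tension",
    "coat_preset",
    "coat_from_config",
    "PRESETS",
]

#: Boltzmann constant in pN nm / K (1.380649e-23 J/K * 1e21 pN nm / J).
KB_PN_NM_PER_K = 1.380649e-2


@dataclass(frozen=True)
class CoatParams:
    """Material constants of one protein-coat model.

    Parameters
    ----------
    name : str
        Label; the built-in presets are ``"cav1"`` (doline-forming coat,
        c0 = 1/200 nm^-1) and ``"ptrf"`` (full caveolar coat,
        c0 = 1/50 nm^-1).
    kappa_c : float
        Coat bending rigidity [kBT].
    c0 : float
        Coat spontaneous curvature [nm^-1]; c0 > 0 bends toward the cell
        interior, so a sphere of radius 1/c0 has zero bending energy.
    lambda_rim : float
        Rim line tension [kBT/nm].
    a_p : float
        Protein footprint area [nm^2].
    delta_assembly : float
        Net non-curvature assembly penalty per protein [kBT].
    barrier : float
        Metastability allowance Delta F_b [kBT] separating the assembled
        and dispersed branches of the quasi-static two-state model.
    temperature_K : float
        Absolute temperature [K].
    """

    name: str
    kappa_c: float
    c0: float
    lambda_rim: float = 0.02
    a_p: float = 25.0
    delta_assembly: float = 0.0
    barrier: float = 10.0
    temperature_K: float = 298.15

    def __post_init__(self) -> None:
        if self.kappa_c <= 0:
            raise ValueError("kappa_c must be positive")
        if self.c0 < 0:
            raise ValueError("c0 must be non-negative")
        if self.lambda_rim < 0:
            raise ValueError("lambda_rim must be non-negative")
        if self.a_p <= 0:
            raise ValueError("a_p must be positive")
        if self.barrier < 0:
            raise ValueError("barrier must be non-negative")
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be positive")

    @property
    def flat_frustration_per_protein(self) -> float:
        """Bending energy e_f = 2 kappa_c a_p c0^2 [kBT] paid by a coat
        protein forced flat (the curvature-mediated assembly drive)."""
        return 2.0 * self.kappa_c * self.a_p * self.c0**2

    def with_(self, **kw) -> "CoatParams":
        """Copy with selected fields replaced."""
        return replace(self, **kw)


def _preset_cav1() -> CoatParams:
    # delta_assembly calibrated so the Cav1 domain disassembles only after
    # unfolding has brought u* well below 0.3 (continuous regime).
    return CoatParams(name="cav1", kappa_c=20.0, c0=1.0 / 200.0,
                      lambda_rim=0.02, a_p=25.0, delta_assembly=0.01,
                      barrier=10.0)


def _preset_ptrf() -> CoatParams:
    # delta_assembly = 0.875 * e_f: domain remains super-hemispherical at
    # the up-transition, producing the snap (e_f = 2*20*25/50^2 = 0.4 kBT).
    coat = CoatParams(name="ptrf", kappa_c=20.0, c0=1.0 / 50.0,
                      lambda_rim=0.02, a_p=25.0, barrier=10.0)
    return coat.with_(delta_assembly=0.875 * coat.flat_frustration_per_protein)


PRESETS = {"cav1": _preset_cav1, "ptrf": _preset_ptrf}


def coat_preset(name: str, **overrides) -> CoatParams:
    """Return a built-in coat preset, optionally overriding fields."""
    try:
        coat = PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return coat.with_(**overrides) if overrides else coat


def coat_from_config(path) -> CoatParams:
    """Load coat parameters from a YAML file.

    The file either names a preset with optional overrides
    (``preset: cav1`` plus any CoatParams field) or gives the full field
    set for a custom coat.
    """
    import yaml
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "preset" in data:
        name = data.pop("preset")
        return coat_preset(name, **data)
    return CoatParams(**data)


@dataclass(frozen=True)
class CapShape:
    """Spherical-cap geometry derived from (A_d, u); build via :func:`cap_from`."""

    A_d: float            # coat area [nm^2]
    u: float              # 1 - cos(psi), in [0, 2]
    psi: float            # contact angle [rad]
    R: float              # sphere radius [nm]; inf at the flat limit u = 0
    A_p: float            # projected (footprint) area [nm^2]
    dA_excess: float      # stored excess area A_d - A_p [nm^2]
    D_proj: float         # projected diameter [nm]
    rim_len: float        # rim perimeter [nm]

    @property
    def psi_deg(self) -> float:
        return math.degrees(self.psi)

    @property
    def mean_curvature(self) -> float:
        """1/R, with the analytic flat limit 0 at u = 0."""
        return 0.0 if self.u == 0.0 else 1.0 / self.R


def cap_from(A_d: float, u: float) -> CapShape:
    """Construct the spherical-cap shape for coat area ``A_d`` and depth ``u``.

    Closed forms (exact):
      A_p   = A_d (2 - u) / 2
      dA    = A_d u / 2
      R     = sqrt(A_d / (2 pi u))        (u > 0; flat limit R = inf)
      D     = 2 sqrt(A_d (2 - u) / (2 pi))
      rim   = sqrt(2 pi A_d (2 - u)) = pi D
    """
    if not A_d > 0:
        raise ValueError(f"A_d must be positive, got {A_d}")
    if not 0.0 <= u <= 2.0:
        raise ValueError(f"u must lie in [0, 2], got {u}")
    A_p = A_d * (2.0 - u) / 2.0
    dA = A_d * u / 2.0
    R = math.inf if u == 0.0 else math.sqrt(A_d / (2.0 * math.pi * u))
    D = 2.0 * math.sqrt(A_d * (2.0 - u) / (2.0 * math.pi))
    rim = math.sqrt(2.0 * math.pi * A_d * (2.0 - u))
    psi = math.acos(max(-1.0, min(1.0, 1.0 - u)))
    return CapShape(A_d=A_d, u=u, psi=psi, R=R, A_p=A_p,
                    dA_excess=dA, D_proj=D, rim_len=rim)


def mech_energy(shape: CapShape, coat: CoatParams, sigma: float) -> float:
    """Mechanical energy [kBT] of one cap at tension ``sigma`` [kBT/nm^2].

    E = 2 kappa_c A_d (1/R - c0)^2 + sigma * dA_excess + lambda_rim * rim_len

    The flat limit uses 1/R -> 0 at u = 0; E is finite and continuous in u
    on [0, 2].
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    H = shape.mean_curvature
    bend = 2.0 * coat.kappa_c * shape.A_d * (H - coat.c0) ** 2
    return bend + sigma * shape.dA_excess + coat.lambda_rim * shape.rim_len


def mech_energy_u(A_d: float, u, coat: CoatParams, sigma: float):
    """Vectorized mech_energy as a function of u at fixed A_d (helper for
    minimizers); accepts scalar or ndarray u."""
    u = np.asarray(u, dtype=float)
    H = np.where(u > 0, np.sqrt(2.0 * np.pi * np.clip(u, 1e-300, None) / A_d), 0.0)
    bend = 2.0 * coat.kappa_c * A_d * (H - coat.c0) ** 2
    dA = A_d * u / 2.0
    rim = np.sqrt(2.0 * np.pi * A_d * np.clip(2.0 - u, 0.0, None))
    return bend + sigma * dA + coat.lambda_rim * rim


def optimal_angle_closed_form(A_d: float, coat: CoatParams,
                              sigma: float) -> tuple[float, float]:
    """Global minimizer of mech_energy over u for a rimless coat (lambda = 0).

    With lambda_rim = 0 the energy is E(u) = a u - b sqrt(u) + 2 kappa A_d c0^2
    with a = 4 pi kappa + sigma A_d / 2 and b = 4 kappa c0 sqrt(2 pi A_d),
    minimized at u* = min(b^2 / (4 a^2), 2).

    Returns
    -------
    (u_star, E_star)
    """
    if coat.lambda_rim != 0.0:
        raise ValueError("closed form requires lambda_rim == 0")
    if not A_d > 0:
        raise ValueError("A_d must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    a = 4.0 * math.pi * coat.kappa_c + sigma * A_d / 2.0
    b = 4.0 * coat.kappa_c * coat.c0 * math.sqrt(2.0 * math.pi * A_d)
    u_star = min(b * b / (4.0 * a * a), 2.0)
    const = 2.0 * coat.kappa_c * A_d * coat.c0**2
    E_star = a * u_star - b * math.sqrt(u_star) + const
    return u_star, E_star


_TENSION_UNITS = ("kBT_per_nm2", "mN_per_m", "pN_per_nm")


def convert_tension(value: float, from_units: str, to_units: str,
                    temperature_K: float = 298.15) -> float:
    """Convert membrane tension between kBT/nm^2, mN/m and pN/nm.

    1 kBT/nm^2 equals (k_B T in pN nm) pN/nm, and 1 mN/m = 1 pN/nm.
    """
    for u in (from_units, to_units):
        if u not in _TENSION_UNITS:
            raise ValueError(f"unknown tension unit {u!r}; use one of {_TENSION_UNITS}")
    kbt = KB_PN_NM_PER_K * temperature_K  # pN nm
    # normalize to pN/nm (== mN/m)
    in_pn_per_nm = value * kbt if from_units == "kBT_per_nm2" else float(value)
    if to_units == "kBT_per_nm2":
        return in_pn_per_nm / kbt
    return in_pn_per_nm


@dataclass(frozen=True)
class TensionProtocol:
    """An ordered tension protocol [kBT/nm^2].

    ``direction``: "up" (loading), "down" (unloading) or "cycle"
    (loading leg followed by the reversed grid).
    """

    sigma_grid: tuple[float, ...]
    direction: str = "up"
    sigma_units_io: str = "kBT_per_nm2"

    def __post_init__(self) -> None:
        grid = tuple(float(s) for s in self.sigma_grid)
        object.__setattr__(self, "sigma_grid", grid)
        if self.direction not in ("up", "down", "cycle"):
            raise ValueError("direction must be 'up', 'down' or 'cycle'")
        if any(s < 0 for s in grid):
            raise ValueError("all tensions must be non-negative")
        diffs = np.diff(grid)
        if len(grid) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("sigma_grid must be strictly monotone")

    @classmethod
    def log_spaced(cls, sigma_min: float = 1e-4, sigma_max: float = 1.0,
                   n: int = 60, direction: str = "up") -> "TensionProtocol":
        """Default protocol: ``n`` log-spaced tensions (ascending)."""
        grid = np.logspace(math.log10(sigma_min), math.log10(sigma_max), n)
        return cls(sigma_grid=tuple(grid), direction=direction)

    def legs(self) -> list[tuple[str, tuple[float, ...]]]:
        """Expand into ("up"/"down", grid) legs honoring ``direction``."""
        asc = tuple(sorted(self.sigma_grid))
        if self.direction == "up":
            return [("up", asc)]
        if self.direction == "down":
            return [("down", asc[::-1])]
        return [("up", asc), ("down", asc[::-1])]
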