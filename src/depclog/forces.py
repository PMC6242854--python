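"""Cell-wall adhesion (DLVO) forces, DEP repulsion, and their balance.

A cell at distance ``h`` from a flat channel wall feels a van der Waals
attraction ``F_v = A d / (12 h^2)`` and an electrostatic double-layer
interaction

    F_EDL = 32 pi eps_m eps_0 kappa d gamma_p gamma_w exp(-kappa h) (kB T / e)^2

with ``gamma = tanh(z e zeta / (4 kB T))`` for each surface.  Their sum is
the long-range adhesive force responsible for initial cell attachment and
hence channel clogging.  The anti-clogging countermeasure is negative
dielectrophoresis from coplanar interdigitated electrodes under the channel
floor: ``F_DEP = 2 pi r^3 eps_m eps_0 Re(f_CM) grad(E_rms^2)``, repulsive
for Re(f_CM) < 0.  This module computes the individual forces, the
height-resolved balance between them (crossover distance, protection flag)
and the smallest particle diameter the repulsion can protect.

The electrode field-gradient model is pluggable.  The default,
``"coplanar_idt"``, is a characteristic-scale law for a periodic coplanar
array with gap ``g`` and pitch ``p``::

    |grad(E_rms^2)|(h) = (V_rms / g)^2 * (4 pi / p) * exp(-4 pi h / p)

capturing the correct voltage-squared scaling and the exponential decay of
a periodic electrode field with height.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .constants import BOLTZMANN, ELEMENTARY_CHARGE, VACUUM_PERMITTIVITY
from .errors import DomainError, ThresholdOutOfRangeError, UsageError

__all__ = [
    "AdhesionParams",
    "FieldModel",
    "ForceBalanceResult",
    "gamma_factor",
    "van_der_waals_force",
    "edl_force",
    "adhesive_force",
    "field_gradient",
    "dep_force",
    "force_balance",
    "protected_diameter_threshold",
    "GRADIENT_MODELS",
]


@dataclass(frozen=True)
class AdhesionParams:
    """Parameters of the DLVO adhesion model (SI units).

    Defaults are the reference values for an RBC against a PDMS wall in
    PBS-diluted plasma: Hamaker constant 5 zJ, Debye parameter
    0.159 nm^-1, T = 296.15 K, monovalent electrolyte, zeta potentials
    -10.8 mV (RBC) and -13.825 mV (PDMS), medium relative permittivity 78.
    """

    hamaker_A: float = 5e-21
    debye_kappa: float = 1.59e8
    temperature_T: float = 296.15
    valency_z: int = 1
    zeta_particle: float = -10.8e-3
    zeta_wall: float = -13.825e-3
    eps_medium: float = 78.0

    def __post_init__(self):
        if not self.hamaker_A > 0:
            raise DomainError("hamaker_A must be > 0")
        if not self.debye_kappa > 0:
            raise DomainError("debye_kappa must be > 0")
        if not self.temperature_T > 0:
            raise DomainError("temperature_T must be > 0")
        if self.valency_z < 1:
            raise DomainError("valency_z must be >= 1")


def _coplanar_idt_gradient(field_model: "FieldModel", h: float) -> float:
    v_rms = field_model.voltage_amplitude / math.sqrt(2.0)
    g = field_model.electrode_gap_g
    p = field_model.electrode_pitch_p
    return (v_rms / g) ** 2 * (4.0 * math.pi / p) * math.exp(-4.0 * math.pi * h / p)


#: Registry of named |grad(E_rms^2)| models; each maps (field, h) -> V^2/m^3.
GRADIENT_MODELS: Dict[str, Callable[["FieldModel", float], float]] = {
    "coplanar_idt": _coplanar_idt_gradient,
}


@dataclass(frozen=True)
class FieldModel:
    """Electrode drive and geometry.

    ``voltage_amplitude`` is the sinusoid peak in volts (the rms value used
    in the force law is ``V/sqrt(2)``).  Gap and pitch describe the
    interdigitated array; defaults (4 um gap, 30 um pitch) are sized so
    that at 20 V the repulsion protects particles down to about 1 um.
    """

    voltage_amplitude: float = 20.0
    frequency: float = 1e3
    electrode_gap_g: float = 4e-6
    electrode_pitch_p: float = 30e-6
    gradient_scale_model: str = "coplanar_idt"

    def __post_init__(self):
        if self.voltage_amplitude < 0:
            raise DomainError("voltage_amplitude must be >= 0")
        if not (self.electrode_gap_g > 0 and self.electrode_pitch_p > 0):
            raise DomainError("electrode dimensions must be > 0")
        if self.gradient_scale_model not in GRADIENT_MODELS:
            raise UsageError(
                f"unknown gradient model {self.gradient_scale_model!r}; "
                f"known: {sorted(GRADIENT_MODELS)}"
            )


def gamma_factor(zeta: float, valency_z: int = 1, temperature_T: float = 296.15) -> float:
    """Reduced surface potential ``tanh(z e zeta / (4 kB T))``.

    Odd in ``zeta`` and bounded in (-1, 1).
    """
    if not temperature_T > 0:
        raise DomainError("temperature_T must be > 0")
    return math.tanh(
        valency_z * ELEMENTARY_CHARGE * zeta / (4.0 * BOLTZMANN * temperature_T)
    )


def van_der_waals_force(diameter_d: float, distance_h: float, hamaker_A: float = 5e-21) -> float:
    """Sphere-plate van der Waals attraction ``A d / (12 h^2)`` in N."""
    if not diameter_d > 0:
        raise DomainError("diameter_d must be > 0")
    if not distance_h > 0:
        raise DomainError("distance_h must be > 0 (force is singular at contact)")
    return hamaker_A * diameter_d / (12.0 * distance_h**2)


def edl_force(diameter_d: float, distance_h: float, params: AdhesionParams) -> float:
    """Electrostatic double-layer force magnitude in N.

    ``32 pi eps_m eps_0 kappa d gamma_p gamma_w exp(-kappa h) (kB T / e)^2``;
    decays exponentially with decay constant ``kappa``.  With like-signed
    zeta potentials the returned value is positive.
    """
    if not diameter_d > 0:
        raise DomainError("diameter_d must be > 0")
    if distance_h < 0:
        raise DomainError("distance_h must be >= 0")
    g_p = gamma_factor(params.zeta_particle, params.valency_z, params.temperature_T)
    g_w = gamma_factor(params.zeta_wall, params.valency_z, params.temperature_T)
    kt_over_e = BOLTZMANN * params.temperature_T / ELEMENTARY_CHARGE
    return (
        32.0
        * math.pi
        * params.eps_medium
        * VACUUM_PERMITTIVITY
        * params.debye_kappa
        * diameter_d
        * g_p
        * g_w
        * math.exp(-params.debye_kappa * distance_h)
        * kt_over_e**2
    )


def adhesive_force(
    diameter_d: float,
    distance_h: float,
    params: Optional[AdhesionParams] = None,
    convention: str = "literal-sum",
) -> float:
    """Total adhesive force ``F_adh`` on a cell at height ``h``.

    ``convention="literal-sum"`` (default) returns ``F_v + F_EDL``;
    ``convention="signed"`` returns ``F_v - F_EDL``, treating the
    double-layer term as a repulsion opposing the van der Waals attraction.
    """
    params = params or AdhesionParams()
    f_v = van_der_waals_force(diameter_d, distance_h, params.hamaker_A)
    f_edl = edl_force(diameter_d, distance_h, params)
    if convention == "literal-sum":
        return f_v + f_edl
    if convention == "signed":
        return f_v - f_edl
    raise UsageError(f"unknown convention {convention!r}")


def field_gradient(field_model: FieldModel, height_h: float) -> float:
    """|grad(E_rms^2)| at height ``h`` above the electrode plane, V^2/m^3."""
    if height_h < 0:
        raise DomainError("height_h must be >= 0")
    return GRADIENT_MODELS[field_model.gradient_scale_model](field_model, height_h)


def dep_force(
    radius_r: float,
    re_fcm: float,
    grad_e2: float,
    eps_medium_rel: float = 78.0,
) -> float:
    """Time-averaged DEP force ``2 pi r^3 eps_m eps_0 Re(f_CM) grad(E_rms^2)``.

    Signed: negative for nDEP (repulsion from the high-field electrode
    plane), positive for pDEP.
    """
    if not radius_r > 0:
        raise DomainError("radius_r must be > 0")
    return (
        2.0
        * math.pi
        * radius_r**3
        * eps_medium_rel
        * VACUUM_PERMITTIVITY
        * re_fcm
        * grad_e2
    )


@dataclass
class ForceBalanceResult:
    """Height-resolved balance of adhesion vs DEP repulsion.

    ``crossover_h`` is the wall distance at which the two magnitudes are
    equal (adhesion dominates below it), or ``None`` when the curves never
    cross on the sampled grid.  ``protected`` means the DEP magnitude
    exceeds adhesion at every sampled height above ``h_floor``.
    """

    h_grid: np.ndarray
    f_adh_curve: np.ndarray
    f_dep_curve: np.ndarray
    crossover_h: Optional[float]
    protected: bool
    h_floor: float = field(default=0.5e-9)


def _dep_magnitude_at(diameter_d, field_model, re_fcm, eps_medium, h):
    return abs(
        dep_force(diameter_d / 2.0, re_fcm, field_gradient(field_model, h), eps_medium)
    )


def force_balance(
    diameter_d: float,
    field_model: FieldModel,
    adhesion: AdhesionParams,
    re_fcm: float,
    h_grid: Sequence[float],
    h_floor: float = 0.5e-9,
    convention: str = "literal-sum",
    xtol: float = 1e-12,
) -> ForceBalanceResult:
    """Sample ``F_adh`` and ``|F_DEP|`` over ``h_grid`` and locate their
    crossing by bisection (absolute tolerance ``xtol`` metres).

    ``protected`` is True when ``|F_DEP| > F_adh`` at every grid height
    >= ``h_floor`` (default 0.5 nm).
    """
    grid = np.asarray(h_grid, dtype=float)
    if grid.size == 0:
        raise UsageError("h_grid must be non-empty")
    if not (np.all(grid > 0) and np.all(np.diff(grid) > 0)):
        raise UsageError("h_grid must be ascending and strictly positive")

    f_adh = np.array([adhesive_force(diameter_d, h, adhesion, convention) for h in grid])
    f_dep = np.array(
        [_dep_magnitude_at(diameter_d, field_model, re_fcm, adhesion.eps_medium, h) for h in grid]
    )

    def diff(h: float) -> float:
        return adhesive_force(diameter_d, h, adhesion, convention) - _dep_magnitude_at(
            diameter_d, field_model, re_fcm, adhesion.eps_medium, h
        )

    crossover: Optional[float] = None
    d = f_adh - f_dep
    flips = np.flatnonzero(np.sign(d[:-1]) * np.sign(d[1:]) < 0)
    zero_hits = np.flatnonzero(d == 0.0)
    if zero_hits.size:
        crossover = float(grid[zero_hits[0]])
    elif flips.size:
        i = flips[0]
        crossover = float(brentq(diff, grid[i], grid[i + 1], xtol=xtol))

    above = grid >= h_floor
    protected = bool(above.any() and np.all(f_dep[above] > f_adh[above]))
    return ForceBalanceResult(
        h_grid=grid,
        f_adh_curve=f_adh,
        f_dep_curve=f_dep,
        crossover_h=crossover,
        protected=protected,
        h_floor=h_floor,
    )


def protected_diameter_threshold(
    field_model: FieldModel,
    adhesion: AdhesionParams,
    re_fcm: float,
    h_eval: float,
    d_range: tuple = (0.05e-6, 100e-6),
    convention: str = "literal-sum",
    xtol: float = 1e-9,
) -> float:
    """Smallest diameter at which ``|F_DEP| >= F_adh`` at height ``h_eval``.

    Adhesion is linear and DEP cubic in diameter, so the threshold is the
    unique root of their difference; located by bisection over ``d_range``
    to absolute tolerance ``xtol`` metres.

    Raises
    ------
    ThresholdOutOfRangeError
        If the difference does not change sign over ``d_range`` (e.g. zero
        voltage or Re(f_CM) = 0: never protected).
    """
    if not h_eval > 0:
        raise DomainError("h_eval must be > 0")

    def diff(d: float) -> float:
        return _dep_magnitude_at(d, field_model, re_fcm, adhesion.eps_medium, h_eval) - adhesive_force(
            d, h_eval, adhesion, convention
        )

    lo, hi = d_range
    f_lo, f_hi = diff(lo), diff(hi)
    if f_lo == 0.0:
        return float(lo)
    if f_lo > 0:
        raise ThresholdOutOfRangeError(
            "already protected at the lower end of d_range; threshold below range"
        )
    if f_hi < 0:
        raise ThresholdOutOfRangeError(
            "not protected anywhere in d_range (weak field or Re(f_CM) ~ 0)"
        )
    return float(brentq(diff, lo, hi, xtol=xtol))
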