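"""Dielectric spectra and the Clausius-Mossotti (CM) factor.

A particle in an AC field polarises relative to its suspending medium; the
complex CM factor

    f_CM = (eps*_p - eps*_m) / (eps*_p + 2 eps*_m)

with complex permittivities ``eps* = eps_r*eps_0 - j*sigma/omega`` sets both
the magnitude and the sign of the time-averaged dielectrophoretic force.
For passive materials Re(f_CM) is bounded in [-0.5, 1.0]: negative values
(nDEP) push particles toward low field regions, positive values (pDEP)
toward high field regions.

Blood cells in plasma are strongly conductivity-contrasted (plasma
~60 mS/m, intact cells ~1 uS/m behind the insulating membrane), so below
~10 kHz Re(f_CM) sits at the nDEP floor of about -0.5 — the operating
regime the anti-clogging method exploits at its 1 kHz drive.

Cells are not homogeneous spheres; a single-shell (membrane + cytoplasm)
model is supported through :class:`ShelledParticleModel` and the standard
core-shell mixing formula.  The homogeneous model with the printed bulk
parameters is the default because no membrane parameter set is part of the
reference characterisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq

from .constants import VACUUM_PERMITTIVITY
from .errors import DegenerateInputError, DomainError, UsageError

__all__ = [
    "DielectricMaterial",
    "ShelledParticleModel",
    "CMSpectrum",
    "PLASMA",
    "BLOOD_CELL",
    "complex_permittivity",
    "clausius_mossotti",
    "effective_shell_permittivity",
    "particle_permittivity",
    "cm_spectrum",
]


@dataclass(frozen=True)
class DielectricMaterial:
    """A homogeneous phase characterised by relative permittivity and
    conductivity.

    Parameters
    ----------
    epsilon_r
        Relative permittivity (dimensionless, multiplies ``eps_0``); > 0.
    sigma
        Electrical conductivity in S/m; >= 0.
    """

    epsilon_r: float
    sigma: float

    def __post_init__(self):
        if not self.epsilon_r > 0:
            raise DomainError(f"epsilon_r must be > 0, got {self.epsilon_r}")
        if self.sigma < 0:
            raise DomainError(f"sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class ShelledParticleModel:
    """Single-shell particle: a core of radius ``r_inner`` wrapped in a
    shell extending to ``r_outer`` (membrane + cytoplasm for a cell)."""

    r_inner: float
    r_outer: float
    core: DielectricMaterial
    shell: DielectricMaterial

    def __post_init__(self):
        if not (0 < self.r_inner < self.r_outer):
            raise DomainError(
                f"require 0 < r_inner < r_outer, got {self.r_inner}, {self.r_outer}"
            )


#: Blood plasma bulk parameters (relative permittivity 78, 60 mS/m).
PLASMA = DielectricMaterial(78.0, 60e-3)

#: Homogeneous blood-cell bulk parameters (relative permittivity 63, 1.0 uS/m).
BLOOD_CELL = DielectricMaterial(63.0, 1.0e-6)


def complex_permittivity(material: DielectricMaterial, frequency: float) -> complex:
    """Complex permittivity ``eps_r*eps_0 - j*sigma/omega`` in F/m at the
    given frequency (Hz); ``omega = 2*pi*frequency``.

    Raises
    ------
    DomainError
        If ``frequency`` is not strictly positive.
    """
    if not frequency > 0:
        raise DomainError(f"frequency must be > 0, got {frequency}")
    omega = 2.0 * math.pi * frequency
    return complex(material.epsilon_r * VACUUM_PERMITTIVITY, -material.sigma / omega)


def clausius_mossotti(eps_particle: complex, eps_medium: complex) -> complex:
    """Complex CM factor ``(eps*_p - eps*_m) / (eps*_p + 2 eps*_m)``.

    Raises
    ------
    DegenerateInputError
        If the denominator vanishes.
    """
    denom = eps_particle + 2.0 * eps_medium
    if denom == 0:
        raise DegenerateInputError("eps_particle + 2*eps_medium is zero")
    return (eps_particle - eps_medium) / denom


def effective_shell_permittivity(model: ShelledParticleModel, frequency: float) -> complex:
    """Effective complex permittivity of a core-shell particle.

    Uses the standard single-shell mixing rule with the radius ratio
    ``q = (r_outer/r_inner)**3``::

        eps*_eff = eps*_shell * (q + 2 K) / (q - K),
        K = (eps*_core - eps*_shell) / (eps*_core + 2 eps*_shell)

    which collapses to the core permittivity when the shell vanishes and to
    the shell permittivity when the core vanishes.
    """
    q = (model.r_outer / model.r_inner) ** 3
    eps_in = complex_permittivity(model.core, frequency)
    eps_out = complex_permittivity(model.shell, frequency)
    k = clausius_mossotti(eps_in, eps_out)
    return eps_out * (q + 2.0 * k) / (q - k)


Particle = Union[DielectricMaterial, ShelledParticleModel]


def particle_permittivity(particle: Particle, frequency: float) -> complex:
    """Complex permittivity of either a homogeneous material or a
    core-shell particle model at ``frequency``."""
    if isinstance(particle, ShelledParticleModel):
        return effective_shell_permittivity(particle, frequency)
    return complex_permittivity(particle, frequency)


@dataclass
class CMSpectrum:
    """Re(f_CM) sampled over an ascending frequency grid.

    ``sign_crossover`` is the frequency at which Re(f_CM) changes sign,
    refined by bisection between the bracketing grid points, or ``None``
    if the real part keeps one sign over the grid.
    """

    frequencies: np.ndarray
    re_fcm: np.ndarray
    sign_crossover: Optional[float] = field(default=None)


def cm_spectrum(
    particle: Particle,
    medium: DielectricMaterial,
    frequencies: Sequence[float],
    crossover_rtol: float = 1e-6,
) -> CMSpectrum:
    """Evaluate Re(f_CM) over a frequency grid and locate any sign change.

    Parameters
    ----------
    particle
        Homogeneous :class:`DielectricMaterial` or :class:`ShelledParticleModel`.
    medium
        Suspending medium.
    frequencies
        Non-empty, strictly ascending, positive frequencies in Hz.
    crossover_rtol
        Relative frequency tolerance of the bisection refinement.
    """
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.size == 0:
        raise UsageError("frequency list must be non-empty")
    if freqs.size > 1 and not np.all(np.diff(freqs) > 0):
        raise UsageError("frequencies must be strictly ascending")

    def re_at(f: float) -> float:
        return clausius_mossotti(
            particle_permittivity(particle, f), complex_permittivity(medium, f)
        ).real

    re = np.array([re_at(f) for f in freqs])

    crossover: Optional[float] = None
    zero_hits = np.flatnonzero(re == 0.0)
    if zero_hits.size:
        # exact zero at a grid point: report that grid frequency
        crossover = float(freqs[zero_hits[0]])
    else:
        signs = np.sign(re)
        flips = np.flatnonzero(signs[:-1] * signs[1:] < 0)
        if flips.size:
            i = flips[0]
            crossover = float(
                brentq(re_at, freqs[i], freqs[i + 1], rtol=crossover_rtol)
            )
    return CMSpectrum(frequencies=freqs, re_fcm=re, sign_crossover=crossover)
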