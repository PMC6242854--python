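"""Synthetic blood populations and emulated counting experiments.

The generator draws a population of cell "parcels" matching a target
haematocrit: RBC diameters 7-8 um, WBC 10-15 um, PLT 2-3 um (uniform
within each range), with number concentrations in physiological ratio
(RBC : PLT : WBC = 5e6 : 3e5 : 7e3 per ul in whole blood).  The RBC
concentration is set from the haematocrit target using the spherical
equivalent volume of the drawn diameter distribution, so diluting 45 %
whole blood to 25 % scales every species by 25/45.

Because a microlitre of blood holds millions of cells, populations above
``max_cells`` are represented by equally weighted parcels: each simulated
cell stands for ``weight`` physical cells, and concentrations are recovered
by multiplying parcel counts by the weight.

``emulate_count_experiment`` overlays multiplicative lognormal counting
noise (mean-preserving, given CV) on a count table, mimicking replicate
haemocytometer counts reported as mean +/- SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dielectric import BLOOD_CELL, DielectricMaterial
from .errors import ConfigError, DomainError
from .metrics import CountTable

__all__ = [
    "CellSpeciesSpec",
    "CellPopulation",
    "DEFAULT_SPECIES",
    "generate_population",
    "emulate_count_experiment",
]


@dataclass(frozen=True)
class CellSpeciesSpec:
    """One blood-cell species: diameter range (m), reference whole-blood
    concentration (cells/ul at haematocrit 45 %), zeta potential (V) and
    the dielectric model used for its CM factor."""

    name: str
    d_min: float
    d_max: float
    ref_concentration: float
    zeta: float = -10.8e-3
    dielectric: DielectricMaterial = BLOOD_CELL

    def __post_init__(self):
        if not (0 < self.d_min <= self.d_max):
            raise DomainError(f"{self.name}: diameter range must be positive and ordered")

    def mean_sphere_volume(self) -> float:
        """E[pi/6 d^3] for d ~ U(d_min, d_max), in m^3."""
        a, b = self.d_min, self.d_max
        if a == b:
            ed3 = a**3
        else:
            ed3 = (b**4 - a**4) / (4.0 * (b - a))
        return math.pi / 6.0 * ed3


#: RBC/WBC/PLT defaults: printed diameter ranges, physiological ratios.
DEFAULT_SPECIES: Tuple[CellSpeciesSpec, ...] = (
    CellSpeciesSpec("RBC", 7e-6, 8e-6, 5e6, zeta=-10.8e-3),
    CellSpeciesSpec("PLT", 2e-6, 3e-6, 3e5, zeta=-10.8e-3),
    CellSpeciesSpec("WBC", 10e-6, 15e-6, 7e3, zeta=-10.8e-3),
)

#: Reference whole-blood haematocrit (%) the ref_concentrations refer to.
REFERENCE_HCT = 45.0


@dataclass
class CellPopulation:
    """A (possibly parcel-weighted) cell population.

    ``cells`` has columns ``species``, ``diameter_m``, ``near_wall``.
    ``concentration`` maps species to physical cells/ul; ``parcel_weight``
    maps species to physical cells represented per parcel.
    """

    cells: pd.DataFrame
    haematocrit_pct: float
    volume_ul: float
    concentration: Dict[str, float]
    parcel_weight: Dict[str, float]
    species_specs: Dict[str, CellSpeciesSpec] = field(default_factory=dict)

    def realized_haematocrit(self) -> float:
        """Haematocrit implied by the drawn RBC parcels (volume %)."""
        rbc = self.cells[self.cells["species"] == "RBC"]
        if rbc.empty:
            return 0.0
        w = self.parcel_weight.get("RBC", 1.0)
        vol_m3 = math.pi / 6.0 * float((rbc["diameter_m"] ** 3).sum()) * w
        return 100.0 * vol_m3 / (self.volume_ul * 1e-9)

    def __len__(self) -> int:
        return len(self.cells)


def generate_population(
    haematocrit_target: float,
    volume_ul: float,
    species_specs: Optional[Sequence[CellSpeciesSpec]] = None,
    seed: Optional[int] = None,
    max_cells: int = 10_000,
    near_wall_occupancy: float = 0.35,
) -> CellPopulation:
    """Draw a synthetic blood population at the requested haematocrit.

    The RBC concentration is solved from ``haematocrit_target`` and the
    mean spherical RBC volume; the other species keep their physiological
    ratio to RBC.  Lateral position is reduced to a two-class state: each
    cell is near-wall with probability ``near_wall_occupancy``, otherwise
    in the cell-rich core.

    Raises
    ------
    ConfigError
        If the haematocrit target is outside (0, 85] (not reachable with
        quasi-spherical cells) or no RBC species is present.
    """
    specs = tuple(species_specs) if species_specs is not None else DEFAULT_SPECIES
    if not (0 < haematocrit_target <= 85):
        raise ConfigError([f"haematocrit_target {haematocrit_target} not in (0, 85]"])
    if not volume_ul > 0:
        raise DomainError("volume_ul must be > 0")
    by_name = {s.name: s for s in specs}
    if "RBC" not in by_name:
        raise ConfigError(["species_specs must include an RBC entry"])

    rng = np.random.default_rng(seed)
    rbc = by_name["RBC"]
    # cells/ul that realise the target haematocrit with spherical volumes
    conc_rbc = (haematocrit_target / 100.0) * 1e-9 / rbc.mean_sphere_volume()
    scale = conc_rbc / rbc.ref_concentration
    concentration = {s.name: s.ref_concentration * scale for s in specs}

    n_phys = {name: conc * volume_ul for name, conc in concentration.items()}
    total_phys = sum(n_phys.values())
    n_total = int(min(max_cells, round(total_phys)))
    if n_total < 1:
        raise ConfigError(["population is empty: volume too small for any cell"])

    frames = []
    parcel_weight = {}
    for spec in specs:
        n_p = int(round(n_phys[spec.name] / total_phys * n_total))
        if n_phys[spec.name] > 0 and n_p == 0:
            n_p = 1
        if n_p == 0:
            continue
        parcel_weight[spec.name] = n_phys[spec.name] / n_p
        d = rng.uniform(spec.d_min, spec.d_max, size=n_p)
        nw = rng.random(n_p) < near_wall_occupancy
        frames.append(
            pd.DataFrame({"species": spec.name, "diameter_m": d, "near_wall": nw})
        )
    cells = pd.concat(frames, ignore_index=True)
    # shuffle so arrival order mixes species
    cells = cells.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(
        drop=True
    )
    return CellPopulation(
        cells=cells,
        haematocrit_pct=haematocrit_target,
        volume_ul=volume_ul,
        concentration=concentration,
        parcel_weight=parcel_weight,
        species_specs=dict(by_name),
    )


def _noisy_table(table: CountTable, cv: float, rng: np.random.Generator) -> CountTable:
    if cv == 0:
        factor = lambda: 1.0  # noqa: E731
    else:
        sigma = math.sqrt(math.log1p(cv * cv))
        mu = -0.5 * sigma * sigma  # mean-preserving lognormal
        factor = lambda: float(rng.lognormal(mu, sigma))  # noqa: E731
    scale = lambda d: {k: v * factor() for k, v in d.items()}  # noqa: E731
    return CountTable(
        c_in=scale(table.c_in),
        c_blood_out=scale(table.c_blood_out),
        c_plasma_out=scale(table.c_plasma_out),
        h_in=min(100.0, table.h_in * factor()),
        h_blood_out=min(100.0, table.h_blood_out * factor()),
        h_plasma_out=min(100.0, table.h_plasma_out * factor()),
    )


def emulate_count_experiment(
    table: CountTable,
    cv_noise: float = 0.10,
    replicates: int = 3,
    seed: Optional[int] = None,
) -> Tuple[List[CountTable], pd.DataFrame]:
    """Emulate replicate haemocytometer counts of a separation outcome.

    Applies independent multiplicative lognormal noise (coefficient of
    variation ``cv_noise``, mean-preserving, never negative) to every
    concentration and haematocrit, ``replicates`` times.

    Returns the replicate tables and a tidy summary frame with columns
    ``species``, ``column``, ``mean``, ``sd``.
    """
    if cv_noise < 0:
        raise DomainError("cv_noise must be >= 0")
    if replicates < 1:
        raise DomainError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    reps = [_noisy_table(table, cv_noise, rng) for _ in range(replicates)]

    records = []
    for sp in table.species:
        for col in ("c_in", "c_blood_out", "c_plasma_out"):
            vals = np.array([getattr(r, col)[sp] for r in reps])
            records.append(
                {"species": sp, "column": col, "mean": vals.mean(), "sd": vals.std(ddof=1) if replicates > 1 else 0.0}
            )
    for col in ("h_in", "h_blood_out", "h_plasma_out"):
        vals = np.array([getattr(r, col) for r in reps])
        records.append(
            {"species": "", "column": col, "mean": vals.mean(), "sd": vals.std(ddof=1) if replicates > 1 else 0.0}
        )
    return reps, pd.DataFrame.from_records(records)
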