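"""Separation performance statistics: cell loss, purity efficiency, plasma yield.

Given inlet/outlet cell concentrations ``C_i, C_o, C_p`` (cells/ul at the
inlet, blood outlet and plasma outlet) and haematocrits ``H_i, H_o, H_p``
(volume %), the three conventional indexes are

    cell loss          eta_L = (1 - (C_o + C_p) / C_i) * 100 %
    purity efficiency  E_p   = (1 - C_p / C_i) * 100 %
    plasma yield       eta   = 100 * (100 - H_p)(H_o - H_i)
                                  / [(100 - H_i)(H_o - H_p)] %

Cell loss near zero means no cells are unaccounted for (no wall adhesion or
lysis); purity near 100 % means the extracted plasma is nearly cell-free;
plasma yield is the fraction of inlet plasma volume recovered at the plasma
outlet, inferred from the haematocrit balance.

Counting noise can make ``C_o + C_p`` exceed ``C_i``; out-of-range values
are reported as-is with a data-quality warning rather than clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd

from .errors import DegenerateInputError, DomainError

__all__ = [
    "CountTable",
    "PerformanceReport",
    "cell_loss",
    "purity_efficiency",
    "plasma_yield",
    "evaluate",
]

AGGREGATE = "all"


@dataclass
class CountTable:
    """Per-species inlet/outlet concentrations (cells/ul) plus haematocrits (%).

    Keys of the three concentration dicts must match.  Haematocrits are on
    the 0-100 scale.
    """

    c_in: Dict[str, float]
    c_blood_out: Dict[str, float]
    c_plasma_out: Dict[str, float]
    h_in: float
    h_blood_out: float
    h_plasma_out: float

    def __post_init__(self):
        keys = set(self.c_in)
        if set(self.c_blood_out) != keys or set(self.c_plasma_out) != keys:
            raise DomainError("species keys differ between concentration columns")
        for d in (self.c_in, self.c_blood_out, self.c_plasma_out):
            for sp, v in d.items():
                if v < 0:
                    raise DomainError(f"negative concentration for {sp!r}: {v}")
        for name, h in (
            ("h_in", self.h_in),
            ("h_blood_out", self.h_blood_out),
            ("h_plasma_out", self.h_plasma_out),
        ):
            if not (0 <= h <= 100):
                raise DomainError(f"{name} must be in [0, 100], got {h}")

    @property
    def species(self) -> List[str]:
        return list(self.c_in)


def cell_loss(c_in: float, c_blood_out: float, c_plasma_out: float) -> float:
    """Cell loss ``(1 - (C_o + C_p)/C_i) * 100`` in percent."""
    if not c_in > 0:
        raise DomainError("c_in must be > 0")
    return (1.0 - (c_blood_out + c_plasma_out) / c_in) * 100.0


def purity_efficiency(c_in: float, c_plasma_out: float) -> float:
    """Purity efficiency ``(1 - C_p/C_i) * 100`` in percent."""
    if not c_in > 0:
        raise DomainError("c_in must be > 0")
    return (1.0 - c_plasma_out / c_in) * 100.0


def plasma_yield(h_in: float, h_blood_out: float, h_plasma_out: float) -> float:
    """Plasma yield from the haematocrit balance, in percent.

    ``100 * (100 - H_p)(H_o - H_i) / [(100 - H_i)(H_o - H_p)]``.

    Raises
    ------
    DegenerateInputError
        If ``H_o == H_p`` (no separation between the outlets).
    DomainError
        If ``H_i >= 100``.
    """
    if not h_in < 100:
        raise DomainError("h_in must be < 100")
    if h_blood_out == h_plasma_out:
        raise DegenerateInputError("h_blood_out == h_plasma_out: no separation")
    return (
        100.0
        * (100.0 - h_plasma_out)
        * (h_blood_out - h_in)
        / ((100.0 - h_in) * (h_blood_out - h_plasma_out))
    )


@dataclass
class PerformanceReport:
    """Per-species and aggregate statistics for one count table.

    ``table`` has one row per species plus an ``"all"`` aggregate row
    (summed concentrations) with columns ``cell_loss_pct`` and
    ``purity_efficiency_pct``; ``plasma_yield_pct`` is a single scalar
    (haematocrit-based, species-independent).  ``warnings`` flags values
    outside [0, 100], which noisy counts can legitimately produce.
    """

    table: pd.DataFrame
    plasma_yield_pct: Optional[float]
    warnings: List[str] = field(default_factory=list)


def evaluate(counts: CountTable, flow_weighted: bool = False,
             flow_split: Optional[float] = None) -> PerformanceReport:
    """Compute all three statistics from a :class:`CountTable`.

    By default concentrations enter the formulas exactly as printed.  With
    ``flow_weighted=True`` the outlet concentrations are weighted by the
    outlet volume split ``flow_split`` (plasma-outlet fraction of the inlet
    volume) before the cell-loss ratio is formed, so that counts rather
    than concentrations are conserved.
    """
    warnings: List[str] = []
    rows = {}
    species = counts.species
    if flow_weighted:
        if flow_split is None or not (0 < flow_split < 1):
            raise DomainError("flow_weighted=True requires flow_split in (0, 1)")
        w_p, w_o = flow_split, 1.0 - flow_split
    else:
        w_p = w_o = 1.0

    def one(ci, co, cp, label):
        loss = cell_loss(ci, w_o * co, w_p * cp)
        pur = purity_efficiency(ci, cp)
        if not (0 <= loss <= 100):
            warnings.append(f"cell_loss_pct out of [0, 100] for {label!r}: {loss:.3f}")
        return {"cell_loss_pct": loss, "purity_efficiency_pct": pur}

    for sp in species:
        if counts.c_in[sp] > 0:
            rows[sp] = one(counts.c_in[sp], counts.c_blood_out[sp], counts.c_plasma_out[sp], sp)
    tot_i = sum(counts.c_in.values())
    tot_o = sum(counts.c_blood_out.values())
    tot_p = sum(counts.c_plasma_out.values())
    if tot_i > 0:
        rows[AGGREGATE] = one(tot_i, tot_o, tot_p, AGGREGATE)

    try:
        eta = plasma_yield(counts.h_in, counts.h_blood_out, counts.h_plasma_out)
        if not (0 <= eta <= 100):
            warnings.append(f"plasma_yield_pct out of [0, 100]: {eta:.3f}")
    except DegenerateInputError:
        eta = None
        warnings.append("plasma yield undefined: equal outlet haematocrits")

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "species"
    return PerformanceReport(table=table, plasma_yield_pct=eta, warnings=warnings)
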