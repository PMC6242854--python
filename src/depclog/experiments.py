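"""Frozen in-silico study conditions and the experiments built on them.

The wet-lab characterisation of the separator runs for minutes to hours at
1 ul/min; the desk-scale simulator compresses that into a few simulated
minutes by tracking ~333 cell parcels per second (20,000 per 60 s).  The
conditions here are the package's reference experiments — the analysis
scripts, the test suite and the acceptance script all run exactly these.

* ``run_condition`` — one separation run at a given voltage.
* ``voltage_sweep`` — cell loss / purity / yield across 0-30 V,
  replicated over seeds (the U-shaped loss curve with its minimum at the
  20 V lysis threshold).
* ``clogging_contrast`` — the lifespan experiment: an unprotected (0 V)
  device runs to full clogging within the 240 s scaled horizon, while the
  20 V device stays open for three times that horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .metrics import evaluate, plasma_yield
from .synthetic import generate_population
from .transport import ChannelNetwork, SeparationOutcome, simulate_separation

__all__ = [
    "PARCELS_PER_SECOND",
    "SWEEP_DURATION_S",
    "CLOG_HORIZON_S",
    "DILUTED_HCT",
    "WHOLE_BLOOD_HCT",
    "DRIVE_FREQUENCY_HZ",
    "run_condition",
    "voltage_sweep",
    "clogging_contrast",
]

#: Scaled parcel arrival rate (parcels per simulated second).
PARCELS_PER_SECOND = 20_000 / 60.0

#: Horizon of one voltage-sweep run, s.
SWEEP_DURATION_S = 60.0

#: Horizon of the unprotected (0 V) clogging run, s; the protected run is
#: observed for three times this.
CLOG_HORIZON_S = 240.0

DILUTED_HCT = 25.0
WHOLE_BLOOD_HCT = 45.0
DRIVE_FREQUENCY_HZ = 1e3


def run_condition(
    voltage: float,
    seed: int,
    duration: float = SWEEP_DURATION_S,
    haematocrit: float = DILUTED_HCT,
    network: Optional[ChannelNetwork] = None,
    frequency: float = DRIVE_FREQUENCY_HZ,
) -> SeparationOutcome:
    """One separation run at the frozen study conditions.

    The population seed and the transport seed are both derived from
    ``seed`` so a single integer reproduces the whole run.
    """
    network = network or ChannelNetwork()
    pop = generate_population(
        haematocrit,
        volume_ul=network.inlet_flow * duration * 1e9,
        seed=seed,
        max_cells=int(round(PARCELS_PER_SECOND * duration)),
    )
    return simulate_separation(
        pop,
        network,
        voltage,
        frequency=frequency,
        duration=duration,
        dt=duration / 20.0,
        seed=seed + 10_000,
    )


def _summarise(outcome: SeparationOutcome) -> dict:
    rep = evaluate(outcome.count_table)
    try:
        eta = plasma_yield(
            outcome.count_table.h_in,
            outcome.count_table.h_blood_out,
            outcome.count_table.h_plasma_out,
        )
    except DegenerateInputError:
        eta = float("nan")
    return {
        "cell_loss_count_pct": outcome.simulated_cell_loss_pct,
        "purity_efficiency_pct": float(rep.table.loc["all", "purity_efficiency_pct"]),
        "plasma_yield_pct": eta,
        "plasma_fraction": outcome.plasma_fraction_avg,
        "captured": int(outcome.counts["captured"].sum()),
        "lysed": int(outcome.counts.drop(index="debris", errors="ignore")["lysed"].sum()),
        "all_clogged": outcome.all_clogged,
        "conserved": outcome.conservation_ok(),
    }


def voltage_sweep(
    voltages: Sequence[float] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0),
    seeds: Sequence[int] = tuple(range(1, 11)),
    duration: float = SWEEP_DURATION_S,
    haematocrit: float = DILUTED_HCT,
) -> pd.DataFrame:
    """Replicated voltage sweep; one row per (voltage, seed)."""
    rows = []
    for v in voltages:
        for s in seeds:
            out = run_condition(v, int(s), duration=duration, haematocrit=haematocrit)
            rows.append({"voltage_v": v, "seed": int(s), **_summarise(out)})
    return pd.DataFrame(rows)


@dataclass
class CloggingContrast:
    """Result of the paired lifespan experiment at one seed."""

    seed: int
    unprotected: SeparationOutcome   # 0 V over CLOG_HORIZON_S
    protected: SeparationOutcome     # 20 V over 3 x CLOG_HORIZON_S

    @property
    def unprotected_clog_time(self) -> Optional[float]:
        times = [b.clog_time for b in self.unprotected.branch_states if b.clog_time is not None]
        return max(times) if len(times) == len(self.unprotected.branch_states) else None


def clogging_contrast(seed: int, horizon: float = CLOG_HORIZON_S) -> CloggingContrast:
    """Run the 0 V vs 20 V lifespan contrast at one seed."""
    return CloggingContrast(
        seed=seed,
        unprotected=run_condition(0.0, seed, duration=horizon),
        protected=run_condition(20.0, seed, duration=3.0 * horizon),
    )
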