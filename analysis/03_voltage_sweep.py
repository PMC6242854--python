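#!/usr/bin/env python
"""Separation performance across drive voltage (0-30 V).

Runs the stochastic separator at the frozen scaled study conditions over
a replicated 0-30 V sweep and summarises count-based cell loss, plasma
purity and plasma yield.  Findings this reproduces: cell loss falls as
the drive rises (stronger nDEP protection), is minimal at the 20 V lysis
threshold, and rises again above it as electroporation destroys cells;
purity improves strongly with the drive; plasma yield sits near 40 % at
the 20 V / 1 ul/min operating point.

Writes results/voltage_sweep.csv and results/voltage_sweep_summary.csv.
"""

from pathlib import Path

from depclog.experiments import voltage_sweep

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    df = voltage_sweep(seeds=range(1, 6))
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "voltage_sweep.csv", index=False)
    summary = (
        df.groupby("voltage_v")[
            ["cell_loss_count_pct", "purity_efficiency_pct", "plasma_yield_pct"]
        ]
        .agg(["mean", "std"])
        .round(3)
    )
    summary.to_csv(OUT / "voltage_sweep_summary.csv")
    print(summary.to_string())
    mean_loss = df.groupby("voltage_v")["cell_loss_count_pct"].mean()
    print(
        f"\nCell loss is U-shaped with its minimum at {mean_loss.idxmin():.0f} V; "
        "above 20 V lysis drives the loss back up."
    )
    print(f"Wrote {OUT / 'voltage_sweep.csv'}")


if __name__ == "__main__":
    main()
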