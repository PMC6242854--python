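"""CSV readers/writers and run-report assembly.

Count tables are plain UTF-8 CSV with a header row: one row per species
with columns ``species, c_in, c_blood_out, c_plasma_out`` (cells/ul) and a
final row with ``species = "haematocrit_pct"`` carrying the inlet, blood
outlet and plasma outlet haematocrits in the same three columns.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Union

import pandas as pd

from .errors import UsageError
from .metrics import CountTable, PerformanceReport

__all__ = ["write_count_table", "read_count_table", "write_report"]

HCT_ROW = "haematocrit_pct"


def write_count_table(table: CountTable, path: Union[str, Path]) -> None:
    rows = [
        {
            "species": sp,
            "c_in": table.c_in[sp],
            "c_blood_out": table.c_blood_out[sp],
            "c_plasma_out": table.c_plasma_out[sp],
        }
        for sp in table.species
    ]
    rows.append(
        {
            "species": HCT_ROW,
            "c_in": table.h_in,
            "c_blood_out": table.h_blood_out,
            "c_plasma_out": table.h_plasma_out,
        }
    )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_count_table(path: Union[str, Path]) -> CountTable:
    df = pd.read_csv(path)
    required = {"species", "c_in", "c_blood_out", "c_plasma_out"}
    if not required.issubset(df.columns):
        raise UsageError(f"count table must have columns {sorted(required)}")
    hct = df[df["species"] == HCT_ROW]
    if len(hct) != 1:
        raise UsageError(f"count table must contain exactly one {HCT_ROW!r} row")
    cells = df[df["species"] != HCT_ROW]
    return CountTable(
        c_in=dict(zip(cells["species"], cells["c_in"].astype(float))),
        c_blood_out=dict(zip(cells["species"], cells["c_blood_out"].astype(float))),
        c_plasma_out=dict(zip(cells["species"], cells["c_plasma_out"].astype(float))),
        h_in=float(hct["c_in"].iloc[0]),
        h_blood_out=float(hct["c_blood_out"].iloc[0]),
        h_plasma_out=float(hct["c_plasma_out"].iloc[0]),
    )


def write_report(
    outdir: Union[str, Path],
    *,
    seed: int,
    config_hash: str,
    count_table: Optional[CountTable] = None,
    performance: Optional[PerformanceReport] = None,
    extra_tables: Optional[Dict[str, pd.DataFrame]] = None,
    notes: Optional[Dict[str, str]] = None,
) -> Path:
    """Write all tabular results plus a human-readable run summary.

    Returns the output directory.  Empty inputs still produce valid
    (header-only) files so downstream tooling never crashes on a quiet run.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    if count_table is not None:
        write_count_table(count_table, out / "count_table.csv")
    if performance is not None:
        performance.table.to_csv(out / "performance.csv")
    for name, df in (extra_tables or {}).items():
        df.to_csv(out / f"{name}.csv", index=False)

    from . import __version__

    lines = [
        "depclog run summary",
        "===================",
        f"package version : {__version__}",
        f"seed            : {seed}",
        f"config hash     : {config_hash}",
    ]
    if performance is not None:
        if performance.plasma_yield_pct is not None:
            lines.append(f"plasma yield    : {performance.plasma_yield_pct:.2f} %")
        for sp, row in performance.table.iterrows():
            lines.append(
                f"{sp:>8}: cell loss {row['cell_loss_pct']:.2f} %, "
                f"purity {row['purity_efficiency_pct']:.2f} %"
            )
        for w in performance.warnings:
            lines.append(f"warning: {w}")
    for k, v in (notes or {}).items():
        lines.append(f"{k}: {v}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return out
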