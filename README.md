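# depclog

Biophysical analysis of a dielectrophoretic (DEP) anti-clogging method
for microfluidic blood-plasma separators.

On-chip plasma separators skim the cell-free layer of flowing blood
through narrow branch channels; they usually die within hours because
cells adhere to the branch walls (DLVO forces), aggregate and clog the
channels.  Driving coplanar interdigitated electrodes under the branch
entrances at 1 kHz generates negative dielectrophoresis that repels
blood cells from the walls and the branch mouths, extending the device
lifespan while improving plasma purity and yield.  `depclog` implements
the full analysis chain a designer of such a device needs:

* **`depclog.dielectric`** — complex permittivities
  (ε* = ε_r ε₀ − jσ/ω), the Clausius–Mossotti factor
  f_CM = (ε*_p − ε*_m)/(ε*_p + 2ε*_m), single-shell (membrane +
  cytoplasm) mixing, and frequency spectra with sign-crossover search.
* **`depclog.forces`** — DLVO adhesion (van der Waals
  F_v = A·d/12h², double-layer
  F_EDL = 32π ε_m ε₀ κ d γ_p γ_w e^{−κh}(k_BT/e)²), the DEP force
  F_DEP = 2π r³ ε_m ε₀ Re(f_CM) ∇E²_rms with a pluggable electrode
  field-gradient model, force-balance crossovers and the smallest
  protected particle diameter.
* **`depclog.metrics`** — the three standard performance statistics:
  cell loss η_L, purity efficiency E_p, plasma yield η.
* **`depclog.transport`** — a stochastic Lagrangian simulator of the
  50-branch network: lumped hydraulic-resistance flow split, bifurcation
  entry rule with margination, near-wall capture, clog-narrowing
  feedback with aggregation, and voltage-dependent lysis above 20 V.
* **`depclog.synthetic`** — synthetic blood populations (RBC 7–8 µm,
  PLT 2–3 µm, WBC 10–15 µm; haematocrit-targeted) and emulated
  replicate counting with lognormal noise.
* **`depclog.config` / `depclog.cli`** — unit-aware YAML configs
  ("5 zJ", "0.159 nm^-1", "1 ul/min") and a CLI
  (`cm-spectrum`, `force-balance`, `operating-map`, `simulate`,
  `metrics`, `generate`).

The model and its defaults are documented in [docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from depclog import (PLASMA, BLOOD_CELL, AdhesionParams, FieldModel,
                     cm_spectrum, force_balance, protected_diameter_threshold,
                     evaluate)
from depclog.experiments import run_condition

# 1) Why 1 kHz? Blood cells sit at the nDEP floor below ~10 kHz.
spec = cm_spectrum(BLOOD_CELL, PLASMA, np.logspace(1, 8, 200))
print(spec.re_fcm[0])                  # -0.49999  (strong nDEP)

# 2) Does 20 V protect an RBC?  Smallest protected diameter?
field = FieldModel(voltage_amplitude=20.0)
fb = force_balance(7e-6, field, AdhesionParams(), -0.5, np.logspace(-12, -7, 200))
print(fb.protected)                    # True  (DEP > adhesion above 0.5 nm)
thr = protected_diameter_threshold(field, AdhesionParams(), -0.5, 0.5e-9)
print(round(thr * 1e6, 2))             # 1.11  (µm -> sub-micron debris unprotected)

# 3) Simulate a separation at the 20 V / 1 µl/min operating point.
out = run_condition(voltage=20.0, seed=1)
rep = evaluate(out.count_table)
print(round(rep.table.loc["all", "purity_efficiency_pct"], 1))  # 98.7
print(round(rep.plasma_yield_pct, 1))                           # 39.6
print(out.all_clogged)                                          # False
```

Interpretation: at the 20 V drive the repulsion exceeds adhesion for
every blood-cell size (threshold ≈ 1.1 µm), so the simulated separator
keeps all 50 branches open, delivers nearly cell-free plasma
(purity ≈ 99 %) and recovers ≈ 40 % of the inlet plasma.  The same run
at 0 V clogs every branch within the scaled horizon and its purity drops
below 60 % — the lifespan/performance contrast the anti-clogging method
exists to fix.

## Analysis scripts

The numbered drivers under `analysis/` rerun the characterisation and
write their tables to `results/`:

```sh
python analysis/01_cm_spectra.py        # CM spectra of RBC/WBC/PLT
python analysis/02_force_balance.py     # force crossovers, operating map
python analysis/03_voltage_sweep.py     # loss/purity/yield over 0-30 V
python analysis/04_longterm_clogging.py # 0 V vs 20 V lifespan contrast
```

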