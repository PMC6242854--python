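# Methods

This note documents the models behind `depclog`, the assumptions they
make, the parameters that matter, and what the synthetic experiments can
and cannot say about a real device.

## Physical setting

A hydrodynamic blood-plasma separator consists of a main microchannel
tapped by 50 narrow branch channels (15 µm wide, 80 µm deep, 25 per
side).  Margination concentrates cells along the channel axis, leaving a
cell-free layer near the walls; the branch channels skim this layer, and
the bifurcation (Zweifach–Fung) preference keeps most cells in the
higher-flow main channel.  The failure mode is clogging: a cell that
approaches a branch wall closer than a few nanometres is captured by
DLVO adhesion, the deposit narrows the branch, aggregation accelerates,
and the branch dies.  The countermeasure is negative dielectrophoresis
(nDEP) from coplanar interdigitated electrodes under the branch
entrances, driven at 1 kHz, which repels polarisable cells from the
high-field wall region.

## Dielectric model

Complex permittivities follow `ε* = ε_r ε₀ − j σ/ω`; the DEP sign and
magnitude follow the Clausius–Mossotti factor
`f_CM = (ε*_p − ε*_m)/(ε*_p + 2 ε*_m)`, whose real part is bounded in
[−0.5, 1.0] for passive materials.  Default bulk parameters: plasma
(78, 60 mS/m), homogeneous blood cell (63, 1.0 µS/m).  Because the
intact membrane insulates the cytoplasm, cells are strongly
conductivity-contrasted against plasma and Re(f_CM) ≈ −0.5 below
~10 kHz — the nDEP floor the 1 kHz drive exploits.  A single-shell
(membrane + cytoplasm) mixing model is implemented for users who have
membrane parameters; the homogeneous model is the default because the
reference characterisation provides none.  Numerical note: the
vanishing-shell limit of the mixing rule converges linearly in shell
thickness with a prefactor of order |ε*_core/ε*_shell|, so limit tests
use a moderate-contrast shell.

## Adhesion and repulsion

Sphere–plate DLVO forces at wall distance `h` for a cell of diameter `d`:

* van der Waals attraction `F_v = A d / (12 h²)`, Hamaker constant
  A = 5 zJ;
* electrostatic double-layer force
  `F_EDL = 32π ε_m ε₀ κ d γ_p γ_w e^{−κh} (k_B T/e)²` with
  `γ = tanh(z e ζ / 4 k_B T)`, Debye parameter κ = 0.159 nm⁻¹,
  ζ(RBC) = −10.8 mV, ζ(PDMS wall) = −13.825 mV, T = 296.15 K, z = 1
  (PBS is dominated by monovalent ions).

The total adhesive force defaults to the literal sum `F_v + F_EDL`; a
`signed` convention treating the double-layer term as a repulsion is
available, since like-signed zeta potentials physically repel while the
conventional one-line model adds the magnitudes.

The time-averaged DEP force is `F_DEP = 2π r³ ε_m ε₀ Re(f_CM) ∇E_rms²`.
The electrode field gradient is a pluggable model; the default is a
characteristic-scale law for a periodic coplanar array with gap `g` and
pitch `p`:

    |∇E_rms²|(h) = (V_rms/g)² (4π/p) exp(−4πh/p),  V_rms = V_peak/√2.

This carries the correct voltage-squared scaling and the exponential
height decay of a periodic electrode field, but it is a one-parameter
caricature of the true fringing field.  The geometry defaults (gap 4 µm,
pitch 30 µm) were sized so that at 20 V the protection threshold —
the smallest diameter at which |F_DEP| ≥ F_adh at h = 0.5 nm — lands
near 1 µm, the effectiveness limit quoted for this device class.  With
that anchoring the computed threshold at 20 V is 1.11 µm, and the
adhesion-dominance region for a 7 µm RBC lies below ~0.08 nm.  A single
exponential scale cannot simultaneously place the threshold at 1 µm and
the RBC force crossover at 0.5 nm; the threshold anchor was chosen
because it controls which species are protected, which is what the
separation outcome depends on.  Crossovers are located by `brentq`
bisection (1 pm absolute tolerance for distances, 1 nm for the diameter
threshold); oracle tests compare against dense-grid minimisation.

## Performance statistics

With inlet/outlet concentrations `C_i, C_o, C_p` and haematocrits
`H_i, H_o, H_p`:

* cell loss `η_L = (1 − (C_o + C_p)/C_i)·100 %`
* purity efficiency `E_p = (1 − C_p/C_i)·100 %`
* plasma yield `η = 100 (100−H_p)(H_o−H_i) / [(100−H_i)(H_o−H_p)] %`

The cell-loss formula is concentration-based as conventionally printed.
Note that applied to exactly conserved counts with unequal outlet
volumes it is negative (the blood outlet is more concentrated than the
inlet); a flow-weighted variant is available behind a flag, and the
simulator's qualitative loss analyses use the count-based loss
(captured + lysed over inlet).  Out-of-range values, which counting
noise legitimately produces, are reported with a warning, never clipped.

## Transport and clogging simulator

Flow: every channel segment is a rectangular duct with hydraulic
resistance `R = 12 μ L / (w h³ (1 − 0.63 h/w))` (smaller dimension
cubed), assembled into a ladder network (inlet flow source, both outlets
at equal pressure) and solved exactly; volume is conserved to solver
round-off.  The unprinted branch length (4 mm) was set by a one-off
design calculation so the clean-device plasma flow fraction is ≈ 0.30,
the operating point implied by the reported ≈ 39 % plasma yield at 25 %
haematocrit.  Main-channel width (100 µm), station spacing (200 µm) and
outlet stub (1 mm) are design values of the hydraulic model.

Cells are Lagrangian parcels resolved in arrival order.  At each
junction a cell enters a branch with probability

    (clean-geometry branch flow fraction) × (margination factor)
        × (1 − DEP deflection probability).

* Margination is a two-class state: cells are near-wall with probability
  0.35 (entry factor 1) or core (entry factor 0.5), both multiplied by a
  size factor `10 µm/(10 µm + d)` so larger cells marginate harder;
  plasma tracers carry factor 1.
* The nDEP junction barrier is a soft competition `R/(1+R)` between the
  DEP force at a 1 µm gate height and the Stokes drag pulling the cell
  into the branch, scaled so the 50 % point at 20 V sits near 1 µm;
  its `d²` scaling makes the barrier ineffective on sub-micron debris.
* Delivery uses the clean-geometry flow fraction deliberately: the mouth
  spans the full wall segment and the growing aggregate protrudes into
  the main stream, so narrowing must not shield the mouth from further
  arrivals.  (Using the narrowed-width hydraulic fraction lets the `w³`
  resistance growth choke delivery and clogs never complete.)  The
  hydraulic solve, which does feel the narrowing, still governs outlet
  volumes, yields and transit times.

Capture: a delivered cell wider than the remaining effective width is
captured outright (sieving).  Otherwise it makes one near-wall approach
at a height drawn uniformly in (0, 10·h_capture) with h_capture = 10 nm,
and is captured iff the approach is inside the capture window and
`F_adh(h) > |F_DEP(h)|` there.  Each capture narrows the branch by 0.8 of
the captured diameter and shrinks the next approach-height range by the
aggregation factor 3 (equivalently, multiplies the capture probability
by 3), standing in for cell-to-cell aggregation.  A branch is clogged
when no simulated cell fits through; clogged branches carry no flow and
receive no cells.

Lysis: at drive amplitudes above 20 V each cell lyses with probability
`1 − exp(−λ (V − 20) t)` (λ = 0.002 V⁻¹s⁻¹, `t` the transit time, so
slower flow means more lysis).  A lysed cell counts as lost and re-enters
transport as a 0.5 µm debris particle, which the DEP barrier does not
deflect and which adhesion can capture — the mechanism by which
over-driving re-introduces clogging and depresses plasma yield.

Randomness: one `numpy.random.Generator` seeded from the run seed and
consumed in deterministic arrival order; identical seed + configuration
gives a bitwise-identical outcome.  Draw counts are kept independent of
branch state so trajectories diverge only through physics.

## Synthetic populations and counting noise

Diameters are uniform within the quoted ranges (RBC 7–8 µm, PLT 2–3 µm,
WBC 10–15 µm).  The RBC number concentration is solved from the target
haematocrit using the spherical-equivalent cell volume; PLT and WBC keep
physiological ratios to RBC (5×10⁶ : 3×10⁵ : 7×10³ per µl), so diluting
45 % whole blood to 25 % scales all species by 25/45.  Populations above
`max_cells` are represented by equally weighted parcels.  Counting noise
is multiplicative lognormal, mean-preserving, with CV 0.10 by default —
chosen to give replicate SDs of the same order as typical
haemocytometer counts; it is a free parameter.

## Scaled study conditions

A wet device runs for hours at 1 µl/min (~10⁹ cells); the simulator
compresses this to desk scale.  Frozen reference conditions: parcel
arrival rate ≈ 333 s⁻¹ (20,000 parcels per 60 s), voltage-sweep horizon
60 s, unprotected-clogging horizon 240 s with the protected run observed
for 3× that (the compression lives jointly in the parcel weighting and
the per-capture deposit fraction).  Under these conditions the 0 V
device reaches full clogging in 50–150 simulated seconds in every tested
seed, while the 20 V device stays fully open.

What passing these experiments shows: the implemented force balance,
junction rules and clog feedback jointly reproduce the *directions* and
*orderings* observed in the laboratory — purity and lifespan gains under
nDEP, the U-shaped loss curve with its minimum at the lysis threshold,
yield near 40 % at the design point.  What it does not show: absolute
wet-lab percentages (cell loss levels in particular depend on
concentration-based counting and on near-wall statistics the model
parameterises crudely), non-Newtonian rheology, cell deformability,
biochemical adhesion maturation, or electrode-scale field detail.

## Known limitations

* The field-gradient law is a single-scale surrogate; quantitative force
  magnitudes inherit its calibration.
* Margination and near-wall approach statistics are config-exposed
  guesses, not fitted to data.
* The hydraulic model is quasi-static and laminar; clog growth is
  geometric (width loss per capture), not a deposition PDE.
* Whole-blood (45 %) runs use the same dilute-suspension transport rules;
  crowding effects beyond concentration scaling are absent.
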