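# Methods

This note documents the model implemented in `hemosim`, the choices made
where the design was genuinely open, the defaults of every tunable
parameter class, what the synthetic-data generator does and does not
emulate, and the numerical conventions.

## Model structure

### Cell compartments

All compartment sizes are dimensionless, normalised so that 1 is the
homeostatic value; clinical units are attached only at output (ANC =
4000 cells/µl × C_GRA, lymphocytes 3000 cells/µl, HB, RET and serum
concentrations by configurable normals).  Each non-stem compartment obeys

    dC/dt = A_in·C_in − C/T − Ψ·C.

`hemosim` maps the regulated overall amplification onto the influx as

    A_in·C_in = amp_rel(t) · efflux_rel(t) / T_nor,

where `amp_rel` is the amplification regulator normalised to 1 at steady
state, `efflux_rel` the upstream efflux relative to its homeostatic value,
and `T_nor` the homeostatic transition time.  This guarantees the all-ones
state is an exact fixed point for *any* admissible regulator settings —
`build_steady_state` additionally verifies the full right-hand side
residual is below 1e−8 and reports the offending equations otherwise
(e.g. an amplification regulator whose normal value is not exactly 1).

The erythroid chain is BE → CE → PEB → MEB → RET → ERY; BE, CE and PEB are
proliferative (EPO-regulated amplification), MEB post-mitotic with
EPO-shortened maturation, RET transit constant by default (an optional
regulator slot exists in the parameter file: replace the constant RET
transition regulator with a decreasing one), and ERY a long-lived
(120-day) first-order pool.  The granulopoietic chain is
CG → PGB → MGB → GRA, with G-CSF-regulated amplification in CG and PGB,
G-CSF-shortened post-mitotic maturation in MGB (the "release" mechanism)
and a 0.4-day granulocyte blood residence.

### Stem cells

Stem cells cycle with proliferative fraction `a_S` every `τ_S` days and
self-renew with probability

    p = p_δ·tanh(−ϑ_S(C_S^rel−1) − ϑ_E(C_E^rel−1) − ϑ_G(C_G^rel−1)) + ½,

ϑ_E = −2, ϑ_G = −8, ϑ_S = 2·(C_S^rel)^0.6 for C_S^rel ≤ 1 and 2 above
(continuous at 1).  The committed efflux 2(1−p)·C_S·a_S/τ_S splits
α_E = 0.15 / α_G = 0.8 into the lineages (5% unsimulated thrombopoiesis);
in the relative formulation the α are dummies, as only ratios to the
homeostatic efflux enter.

The marrow aggregates C_E^rel and C_G^rel mirror ratios of absolute pool
sums, so the normalised compartments are combined with homeostatic
weights (defaults BE 0.05, CE 0.10, PEB 0.45, MEB 0.40; CG 0.05, PGB
0.35, MGB 0.60 — post-mitotic pools dominate marrow cellularity).  This
weighting is load-bearing: with equal weights, sustained G-CSF inflates
the small progenitor pools enough to lock the self-renewal feedback at
its ceiling and the stem pool grows without bound, whereas the
absolute-pool weighting lets the drained MGB stage offset the inflated
CG/PGB stages, and all sustained-stimulation scenarios reach finite new
equilibria.

### Proliferative fraction

For X ∈ {S, BE, CG}, the marrow-content measure

    x = ω_E·ln C_E^rel + ω_G·ln C_G^rel + ω_S·(ln C_S^rel  if C_S^rel ≤ 1, else C_S^rel−1)

(ω_E = 0.3, ω_G = 0.4, ω_S placeholder 1.0) feeds a tanh-type sigmoid
anchored so that a(0) = a_nor and a(−ln 2) = a_int, saturating at a_max
(empty marrow) and a_min (crowded marrow).  In S the fraction multiplies
the cycling rate; in BE and CG it multiplies the amplification relative
to its normal value.

### G-CSF effect on the erythroid progenitors

The CE transition time is multiplied by

    F_T(t) = w_P·Z_T_Peg(c_peg) + (1−w_P)·Z_T_Fil(c_fil),

with the fitted regulator values (Filgrastim/endogenous: min 0.9995,
nor 1, max 98.37, b 0.930; Pegfilgrastim: min 1, nor 1.037, max 2.787,
b 0.5660).  The companion amplification factor is the constant 1 (the
fitting of the source model found a negligible amplification effect).
The receptor-competition weight has no published closed form; it is
implemented as the Pegfilgrastim share w_P = c_peg/(c_peg + c_fil)
(0 when both vanish) and is a replaceable strategy.  The same
superposition pattern is applied to the G-CSF regulators of CG, PGB and
MGB, whose Pegfilgrastim parameter sets default to the Filgrastim shapes
but are independently configurable.

Note the Filgrastim factor's log-rate constant is ≈ 5×10⁻⁶, so the factor
is ≈ 1 at concentrations up to ~100× normal and approaches its 98.37
asymptote only around 10⁷–10⁸× normal; erythroid suppression by G-CSF
therefore becomes visible only under strong sustained exposure, which is
the behaviour reported for this interaction.

### Pharmacokinetics

Two G-CSF species are tracked: endogenous G-CSF pooled with Filgrastim
(identical PK/PD), and Pegfilgrastim.  Each has a two-sub-compartment
subcutaneous depot (first-order transits, saturable Michaelis–Menten
bioavailability loss in the first stage — so the *fraction* lost falls
with dose), two-way central/peripheral exchange, first-order renal
elimination and granulocyte-mediated Michaelis–Menten elimination
proportional to the relative granulocyte count.  Endogenous production is
a decreasing sigmoid of the weighted mean of MGB and GRA.

Two EPO species are tracked: endogenous EPO pooled with the
first-generation derivatives Alfa/Beta/Delta (shared PK constants,
site-group-specific subcutaneous absorption), and Darbepoetin Alfa with
its own constants.  Central EPO binds free receptors (both species compete
for one pool), the complex dissociates or is internalised, and the shared
internalised pool — the argument of every erythroid regulator — decays
first order.  Receptor-mediated clearance saturates, so high doses decay
slower, and aplasia slows G-CSF clearance; both classic features emerge
from the structure.  Subcutaneous EPO splits into a direct and a
lymphatic route, each a two-stage first-order delay chain with losses at
the injection site and in the lymphatic route; nine site groups (thigh,
shoulder, forearm, abdomen variants per derivative) carry their own
absorption parameters.  The chain length is structurally fixed at two
stages per route; mean delays are tuned via the stage rates.

Doses are accepted in µg (G-CSF, Darbepoetin) or IU and IU/kg (EPO)
with a body-weight configuration (default 70 kg) and per-species
dose-to-relative-concentration factors.  One site group per EPO species
per scenario is enforced (the state vector holds one chain per species).

### Chemotherapy

Each drug carries per-compartment depletion intensities k_X (1/day) for
X ∈ {S, CG, PGB, MGB, BE, CE, PEB, MEB, RET, LY} — circulating
erythrocytes are exempt — applied as a rectangular pulse on
[day + delay, day + delay + duration) after each administration (defaults:
delay 0, duration 1 day).  Drugs damage independently, so Ψ vectors add.
The first therapy cycle is scaled by ffc ≥ 1 (default 1.2); the ≥ 60 age
group by elderly_factor (default 1.3).  Dose dependence enters through
parameter-set selection, not a continuous dose–response.  The lymphocyte
count is 3000·exp(−Λ_LY) with Λ_LY = ∫Ψ_LY dτ integrated as an ODE state;
no lymphocyte recovery term is added (the most literal reading; a
recovery mechanism is a known open question).  A regimen library encodes
CHOP-14/21, CHOEP-14/21, BEACOPP-21, EC-T and E-T-C day patterns with
their G-CSF support schedules; the sequential protocols (EC-T, E-T-C) are
encoded as single macro-cycles with an `ffc_window` marking the first
block.

## Numerical methods

Scenarios integrate with `scipy.integrate.solve_ivp` (LSODA,
rtol 1e−8 / atol 1e−10 by default) piecewise between forcing
discontinuities — injection times, toxicity-window edges, infusion
switches — with bolus state jumps applied at segment starts (same-day
events in schedule order).  Output is sampled on a configurable grid
(default 0.25 days) plus the event times.  States are floored at zero;
an undershoot beyond 1e−9 aborts with a diagnostic.  Runs are
deterministic given scenario, parameters and solver options; refining the
tolerance tenfold moves observables by far less than 0.1%.

Oscillation analysis lightly smooths the absolute deviation from baseline
(5-point moving average), locates local maxima above an amplitude floor
and reports successive amplitude ratios (< 1 damped, ≈ 1 sustained) and a
period estimate of twice the mean extremum spacing; it reproduces the
closed-form decay exp(−π/(ωτ)) of a decaying sinusoid to a few percent.

The fitness functional ∫|log f_model − log f_data| dt uses trapezoidal
quadrature on the union of the simulation grid and the observation times,
with the data medians linearly interpolated; it is zero iff the curves
agree on the window at grid resolution and is invariant under common
rescaling.  Outcomes and scenarios add unweighted; an optional weight per
outcome exists.

The optimiser is an elitist (1+3) evolutionary strategy.  A single
dimensionless mutation strength is self-adapted by the log-normal rule
with learning rate τ = 1/√(2√n); coordinate mutations scale with the
bound spans and reflect at the bounds.  A scalar step size was chosen over
per-coordinate step-size vectors because, with only three offspring per
generation, per-coordinate adaptation is noise-dominated and stalls
(observed directly on the sphere benchmark), while the scalar rule reaches
1e−12 or better on a 5-dimensional sphere within 500 generations across
seeds.  The run stops at the generation budget, or early once the step
size has collapsed below 1e−9 with no improvement for 100 generations.

Sensitivity analysis perturbs each selected parameter by ±2.5% and
reports the fitness deterioration; at a generating-parameter optimum all
deteriorations are non-negative and unused parameters give exactly zero.

## Parameter provenance and defaults

Every parameter lives in a flat, dotted-name `ParameterSet` with a value,
unit and mandatory provenance tag and round-trips through YAML.  Values
printed in the source model's main description are tagged `paper` (the
ϑ and ω weights, the lineage split, the Table of CE regulators, the
4000/3000 cells/µl normals).  Everything whose published value exists
only in unavailable supplementary tables is tagged `placeholder`:
transition times (stem cycle 2.5 d; BE/CE 3 d, PEB 4 d, MEB 3.5 d, RET
1.5 d, ERY 120 d, CG 3 d, PGB 5 d, MGB 6.4 d, GRA 0.4 d — standard
human kinetic ranges), regulator extrema (erythroid amplification maxima
2–4, granulopoietic 2.5–3, MGB maturation 6.4 → 1 d under maximal
G-CSF), p_δ = 0.25, the a-curve anchors, PK rate constants placed to give
half-lives of ≈ 4 h (Filgrastim), days (Pegfilgrastim, via a slow
peripheral exchange that also produces its smooth non-oscillatory
return), ≈ 8 h (EPO) and longer for Darbepoetin, dose conversions (300 µg
G-CSF ≈ 4000× normal endogenous concentration; 150 IU/kg EPO ≈ 350×),
and the per-drug toxicity tables (intensities concentrated on
proliferating stages; S and post-mitotic stages less sensitive).  These
defaults were fixed once to reproduce the documented qualitative regimes
and are the knobs a user fits to data; they are not measurements.

`steepened_stem_feedback_overrides()` returns the parameter set in which
the stem-cell feedback responds intensively enough (ω_S = 6, steepened
a-curves of S/BE/CG, p_δ = 0.49) that the homeostatic fixed point
undergoes a Hopf-type destabilisation: a single chemotherapy pulse then
settles into a stable ≈ 0.9–1.3× limit cycle with a period of roughly two
to three weeks instead of damped relaxation — the regime classically
invoked for cyclic neutropenia.  In this parameterisation raising p_δ
alone does not destabilise the fixed point (checked by Jacobian
eigenvalues); the proliferative-fraction response is the binding lever.

## Synthetic cohorts

`generate_fixture` simulates a scenario under known "truth" parameters,
samples the chosen outcomes on given days, multiplies by per-patient
log-normal noise (median-unbiased), and emits per-day median and
quartiles — the same summary statistics clinical fitting data come as.
It is deterministic given its seed, and with zero noise its medians equal
the simulated truth, making it the ground truth for parameter-recovery
studies.  It emulates *sampling* variability only: no patient-level
parameter heterogeneity, dropout, transfusion censoring, assay detection
limits or irregular visit schedules.  Recovery results on these fixtures
therefore demonstrate identifiability of parameters under the model, not
robustness to real-cohort artefacts.

## Known limitations

* Thrombopoiesis is not simulated; 5% of the stem efflux is unrouted.
* Lymphocytes are a closed-form exponential, not a modelled lineage, so
  WBC recovery between late cycles is driven by granulocytes only.
* All placeholder-tagged constants are calibration targets, not
  measurements; quantitative agreement with any specific clinical data
  set requires fitting them.
* Toxicity is per (drug, dose-level) parameter set; interpolating between
  dose levels is out of scope.
* One subcutaneous site group per species per scenario.
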