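# hemosim

Combined ordinary-differential-equation model of human **erythropoiesis**
and **granulopoiesis** under cytotoxic chemotherapy, G-CSF and EPO
treatment — a simulator library with a thin command-line interface.

Cancer chemotherapy depletes the bone marrow; clinicians counter the
resulting neutropenia and anaemia with growth-factor derivatives
(Filgrastim, Pegfilgrastim, EPO Alfa/Beta/Delta, Darbepoetin Alfa) whose
pharmacokinetics differ widely.  Because chemotherapy toxicity and
growth-factor stimulation interact through shared stem cells and cytokine
feedback, schedule design is non-trivial.  `hemosim` implements a
mechanistic compartment model of both blood-cell lineages for exactly this
question: simulate a treatment schedule, read off the clinical time
courses (WBC, ANC, HB, reticulocytes, serum EPO/G-CSF), and fit unknown
parameters to cohort medians.

## The model

Eleven cell compartments — stem cells S; the erythroid chain
BE → CE → PEB → MEB → RET → ERY; the granulopoietic chain
CG → PGB → MGB → GRA — evolve by balance equations

    dC/dt = A_in · C_in − C/T − Ψ(t)·C

where amplification `A` and transition time `T` are regulated between a
minimum and maximum by the sigmoid

    Z(c) = Y_max − (Y_max − Y_min) · exp(−ln((Y_max−Y_min)/(Y_max−Y_nor)) · c^b),

driven by internalised EPO (erythroid chain) or central G-CSF
(granulopoietic chain).  Stem cells self-renew with probability

    p = p_δ · tanh(−ϑ_S(C_S−1) − ϑ_E(C_E−1) − ϑ_G(C_G−1)) + 1/2,

ϑ_E = −2, ϑ_G = −8, and a marrow-content-dependent proliferative fraction
`a`; their committed efflux splits 15% / 80% / 5% into the erythroid,
granulopoietic and (unsimulated) thrombopoietic lineages.  G-CSF delays
the CE transition time by a factor combining Filgrastim and Pegfilgrastim
regulators under receptor competition (the fitted factors: normal value
1.037 and maximum 2.787 for Pegfilgrastim, maximum 98.37 for
Filgrastim/endogenous G-CSF).  Chemotherapy acts as first-order depletion
Ψ_X(t) on the marrow stages, additive across drugs, with a first-cycle
factor and an elderly (≥ 60) parameter set; lymphocytes follow
`3000·exp(−∫Ψ_LY)` so that WBC = lymphocytes + 4000·C_GRA.

Pharmacokinetics: G-CSF species have a two-stage subcutaneous depot with
saturable bioavailability loss, central/peripheral exchange, renal and
granulocyte-mediated (Michaelis–Menten) elimination; EPO species bind,
dissociate and internalise on a shared receptor pool — internalised EPO
drives all erythroid regulators — with direct and lymphatic subcutaneous
absorption routes per injection-site group.

Parameter estimation minimises the area between the log of the simulated
curve and the log of the interpolated data medians, summed over outcomes
and scenarios, with an elitist (1+3) evolutionary strategy with
self-adaptive mutation step size.

## A worked example

```python
import hemosim as hs

scenario = hs.TreatmentScenario(
    injections=[hs.InjectionEvent(0.0, "filgrastim", 300.0, "ug", "sc",
                                  site="gcsf_default")],
    horizon=160.0,
)
result = hs.simulate(scenario)
anc = result.observable("ANC")
print(f"ANC peak {anc.max():.0f} /ul at day {result.t[anc.argmax()]:.1f}; "
      f"minimum {anc.min():.0f} /ul")
metrics = hs.oscillation_metrics(result.t, result.state("GRA"), min_amplitude=0.02)
print("amplitude ratios:", metrics.ratios.round(2))
```

prints

```
ANC peak 15696 /ul at day 0.8; minimum 3696 /ul
amplitude ratios: [0.11 0.09]
```

— a single 300 µg Filgrastim injection releases marrow reserves (ANC
nearly quadruples within a day), after which the count returns through a
mild undershoot in a damped oscillation (each extremum roughly a tenth of
the previous one).  The `examples/` directory contains narrative scripts
for the steady state, growth-factor boluses, multi-cycle chemotherapy,
the cyclic-neutropenia regime, toxicity-parameter fitting and the
sensitivity scan; `hemosim --help` lists the equivalent shell commands
(`simulate`, `steady-state`, `fit`, `fixtures`, `scenarios list`).

## Scope

The package simulates relative compartment sizes scaled to clinical units
at output; absolute marrow cell bookkeeping, thrombopoiesis, stochastic
lineage commitment and refits of proprietary patient data sets are out of
scope.  Parameters whose published values are not printed in the main
model description ship as physiologically plausible defaults tagged
`placeholder` and are meant to be overridden from parameter
files (see `docs/methods.md`).
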