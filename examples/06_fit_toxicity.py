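"""Recover a chemotherapy toxicity parameter from a synthetic WBC curve.

A cohort time series is generated by simulating the model with known
parameters (the "truth"); the cyclophosphamide toxicity on the CG
progenitor compartment is then re-estimated from the leukocyte medians
with the (1+3) evolutionary strategy, minimising the area between the
log-curves.
"""

from dataclasses import replace

import numpy as np

import hemosim as hs
from hemosim.chemo import regimen_library

base = hs.default_parameters()
truth_name = "chemo.cyclophosphamide.k.CG"
print(f"truth: {truth_name} = {base[truth_name]:.3f} /day")

regimen = replace(regimen_library()["CHOP-21"], n_cycles=1, support=())
scenario = hs.TreatmentScenario(chemo=regimen, horizon=42.0, grid_dt=0.5, name="chop1")
series = hs.generate_fixture(hs.FixtureSpec(
    scenario=scenario, sampling_days=np.arange(0.0, 36.0, 1.0),
    outcomes=("WBC",), n_patients=1, seed=3,
))

problem = hs.FitProblem(
    free={truth_name: (0.3, 8.0)}, scenarios=[(scenario, series)], base=base
)
report = hs.recover_parameters(problem, seed=7, generations=60,
                               truth={truth_name: base[truth_name]})
print(f"recovered: {report.recovered[0]:.4f} /day "
      f"(relative error {100 * report.relative_error[0]:.2f}%)")
print(f"fitness (log-area) at the optimum: {report.best_fitness:.4f}")
print(f"objective evaluations: {report.n_evaluations}")
# A relative error well under 5% from a noise-free single-cycle curve shows
# one toxicity intensity is identifiable from leukocyte medians alone.
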