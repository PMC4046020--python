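"""Sustained oscillations under intensified stem-cell feedback.

With the default parameters every disturbance decays (all feedback loops
are negative and well damped).  If the stem-cell self-renewal and the
proliferative-fraction regulation are allowed to respond more intensively
to marrow content, the homeostatic fixed point destabilises and a single
chemotherapy pulse settles into stable cycling of all lineages — the
regime classically used to explain cyclic neutropenia.
"""

from dataclasses import replace

import numpy as np

import hemosim as hs
from hemosim.chemo import regimen_library
from hemosim.params import steepened_stem_feedback_overrides

pulse = replace(regimen_library()["CHOP-21"], n_cycles=1, support=())
scenario = hs.TreatmentScenario(chemo=pulse, horizon=400.0, grid_dt=0.5)

for label, pset in (
    ("default feedback", hs.default_parameters()),
    ("steepened feedback", hs.default_parameters().with_values(
        steepened_stem_feedback_overrides())),
):
    r = hs.simulate(scenario, hs.build_model_params(pset))
    gra_late = r.state("GRA")[r.t > 300.0]
    m = hs.oscillation_metrics(r.t[r.t > 100.0], r.state("GRA")[r.t > 100.0],
                               min_amplitude=1e-3)
    print(f"{label}:")
    print(f"  granulocytes on days 300-400: {gra_late.min():.2f} .. {gra_late.max():.2f}")
    print(f"  mean successive amplitude ratio: "
          f"{m.damping_ratio if m.damping_ratio is None else round(m.damping_ratio, 2)}")
    if m.period:
        print(f"  oscillation period estimate: {m.period:.1f} days")
# A ratio < 1 with a flat late trajectory is damped relaxation; a ratio
# >= 1 with persistent swings (here roughly 0.9 to 1.3 of baseline) is a
# stable limit cycle.
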