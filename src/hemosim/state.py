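"""Layout of the full ODE state vector.

Eleven relative cell compartments, two G-CSF species (endogenous/Filgrastim
pooled, Pegfilgrastim separate), two EPO species (first-generation pool,
Darbepoetin) with subcutaneous delay chains and receptor binding, the shared
internalised-EPO pool, and the accumulated lymphocyte toxicity integral.
"""

from __future__ import annotations

from .params import COMPARTMENTS

_PK_NAMES = (
    "FIL_SC1", "FIL_SC2", "FIL_CENT", "FIL_PERI",
    "PEG_SC1", "PEG_SC2", "PEG_CENT", "PEG_PERI",
    "EPO_D1", "EPO_D2", "EPO_L1", "EPO_L2", "EPO_CENT", "EPO_PERI", "EPO_RB",
    "DAR_D1", "DAR_D2", "DAR_L1", "DAR_L2", "DAR_CENT", "DAR_PERI", "DAR_RB",
    "EPO_INT",
    "LAM_LY",
)

STATE_NAMES: tuple[str, ...] = COMPARTMENTS + _PK_NAMES
IDX: dict[str, int] = {name: i for i, name in enumerate(STATE_NAMES)}
N_STATES: int = len(STATE_NAMES)
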