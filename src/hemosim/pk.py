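"""Pharmacokinetics of G-CSF and EPO species and injection handling.

G-CSF (endogenous + Filgrastim pooled; Pegfilgrastim separate) follows a
subcutaneous two-sub-compartment chain with a saturable bioavailability
loss, a central compartment with two-way exchange to a peripheral
(protein-bound) compartment, first-order renal elimination and a
granulocyte-mediated Michaelis–Menten degradation.

EPO (endogenous + first-generation derivatives pooled; Darbepoetin
separate) has central/peripheral exchange, unspecific first-order
elimination and receptor kinetics: binding to free receptors, dissociation,
and internalisation, the internalised pool driving all EPO regulators.
Subcutaneous EPO doses split into a direct and a lymphatic absorption
route, each a two-stage first-order delay chain with route-specific losses.

Concentrations are expressed relative to the normal endogenous central
concentration of the respective cytokine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import EpoPkParams, GcsfPkParams, ModelParams, ScAbsorptionParams
from .regulation import RegulationParams, sigmoid_regulator
from .state import IDX

__all__ = [
    "GcsfPkState",
    "EpoPkState",
    "InjectionEvent",
    "gcsf_pk_rhs",
    "gcsf_production",
    "epo_pk_rhs",
    "epo_production",
    "sc_absorption_rhs",
    "apply_injection",
    "GCSF_SPECIES",
    "EPO_SPECIES",
]

# derivative identifier -> PK species
GCSF_SPECIES = {"filgrastim": "FIL", "pegfilgrastim": "PEG"}
EPO_SPECIES = {
    "epo_alfa": "EPO",
    "epo_beta": "EPO",
    "epo_delta": "EPO",
    "darbepoetin_alfa": "DAR",
}
KNOWN_DERIVATIVES = sorted(GCSF_SPECIES) + sorted(EPO_SPECIES)


class ConfigurationError(ValueError):
    """Unknown derivative, missing site group, or invalid dose."""


@dataclass
class GcsfPkState:
    """Sub-compartment amounts of one G-CSF species."""

    sc1: float = 0.0
    sc2: float = 0.0
    cent: float = 0.0
    peri: float = 0.0


@dataclass
class EpoPkState:
    """PK state of one EPO species (sc delay chains, central, peripheral,
    receptor-bound); the shared internalised pool is tracked separately."""

    d1: float = 0.0
    d2: float = 0.0
    l1: float = 0.0
    l2: float = 0.0
    cent: float = 0.0
    peri: float = 0.0
    rb: float = 0.0


@dataclass(frozen=True)
class InjectionEvent:
    """One growth-factor administration."""

    time: float  # days
    drug: str  # derivative identifier, e.g. "filgrastim"
    dose: float
    unit: str = "ug"  # ug | ug/kg for G-CSF, IU/kg | IU | ug for EPO
    route: str = "sc"  # "iv" | "sc"
    site: str | None = None  # site group, required for s.c. EPO

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ConfigurationError(f"dose must be > 0, got {self.dose}")
        if self.drug not in GCSF_SPECIES and self.drug not in EPO_SPECIES:
            raise ConfigurationError(f"unknown derivative {self.drug!r}")
        if self.route not in ("iv", "sc"):
            raise ConfigurationError(f"route must be 'iv' or 'sc', got {self.route!r}")
        if self.route == "sc" and self.drug in EPO_SPECIES and self.site is None:
            raise ConfigurationError("s.c. EPO injection requires a site group")


def gcsf_pk_rhs(
    state: GcsfPkState,
    gra_rel: float,
    production: float,
    params: GcsfPkParams,
) -> GcsfPkState:
    """Derivatives of one G-CSF species.

    sc1 transits first order to sc2 and loses to a saturable
    (Michaelis–Menten) sink modelling dose-dependent bioavailability; sc2
    transits to central; central exchanges with peripheral two-way first
    order and is eliminated renally (first order) plus by the
    granulocyte-mediated Michaelis–Menten route proportional to gra_rel.
    """
    for name in ("k_sc12", "k_sc2c", "vmax_sc", "k_cp", "k_pc", "k_ren", "vmax_gra"):
        if getattr(params, name) < 0:
            raise ValueError(f"rate constant {name} must be >= 0")
    loss_sc1 = params.vmax_sc * state.sc1 / (params.km_sc + state.sc1) if state.sc1 > 0 else 0.0
    gra_sink = gra_rel * params.vmax_gra * state.cent / (params.km_gra + state.cent) if state.cent > 0 else 0.0
    d_sc1 = -params.k_sc12 * state.sc1 - loss_sc1
    d_sc2 = params.k_sc12 * state.sc1 - params.k_sc2c * state.sc2
    d_cent = (
        params.k_sc2c * state.sc2
        + production
        - params.k_ren * state.cent
        - gra_sink
        - params.k_cp * state.cent
        + params.k_pc * state.peri
    )
    d_peri = params.k_cp * state.cent - params.k_pc * state.peri
    return GcsfPkState(d_sc1, d_sc2, d_cent, d_peri)


def gcsf_production(
    mgb_rel: float,
    gra_rel: float,
    reg_params: RegulationParams,
    w_mgb: float = 0.5,
    p_nor: float = 1.0,
) -> float:
    """Endogenous G-CSF production, driven by the demand for granulocytes.

    A decreasing sigmoid of the weighted mean of the final bone-marrow
    compartment and circulating granulocytes; equals p_nor at (1, 1) and
    saturates at its maximum when both vanish.
    """
    if mgb_rel < 0 or gra_rel < 0:
        raise ValueError("relative sizes must be >= 0")
    c = w_mgb * mgb_rel + (1.0 - w_mgb) * gra_rel
    return p_nor * sigmoid_regulator(c, reg_params)


def epo_production(ery_rel: float, reg_params: RegulationParams, p_nor: float = 1.0) -> float:
    """Endogenous EPO production: decreasing sigmoid of the relative
    erythrocyte count (renal oxygen sensing), normal rate at 1."""
    if ery_rel < 0:
        raise ValueError("ery_rel must be >= 0")
    return p_nor * sigmoid_regulator(ery_rel, reg_params)


def sc_absorption_rhs(
    d1: float, d2: float, l1: float, l2: float, site: ScAbsorptionParams
) -> tuple[float, float, float, float, float]:
    """Derivatives of the subcutaneous delay chains of an EPO site group.

    Returns (dd1, dd2, dl1, dl2, efflux_to_central).  The injected dose is
    split at injection time into the first stages of the direct and
    lymphatic routes; both are linear chains of two first-order stages, with
    loss at the injection site (first direct stage) and in the lymphatic
    route (first lymphatic stage) reducing bioavailability.
    """
    if not 0.0 <= site.f_direct <= 1.0:
        raise ValueError("direct-route fraction must lie in [0, 1]")
    dd1 = -(site.k_direct + site.loss_site) * d1
    dd2 = site.k_direct * d1 - site.k_direct * d2
    dl1 = -(site.k_lymph + site.loss_lymph) * l1
    dl2 = site.k_lymph * l1 - site.k_lymph * l2
    efflux = site.k_direct * d2 + site.k_lymph * l2
    return dd1, dd2, dl1, dl2, efflux


def epo_pk_rhs(
    state: EpoPkState,
    production: float,
    r_free: float,
    params: EpoPkParams,
    site: ScAbsorptionParams,
) -> tuple[EpoPkState, float]:
    """Derivatives of one EPO species and its internalisation flux.

    Central EPO binds free receptors (k_on * cent * r_free), the complex
    dissociates (k_off) or is internalised (k_int), feeding the shared
    internalised pool; unspecific elimination is first order; central and
    peripheral exchange two-way first order.  ``r_free`` is supplied by the
    caller so that two species can compete for one receptor pool.
    """
    for name in ("k_el", "k_on", "k_off", "k_int", "k_cp", "k_pc"):
        if getattr(params, name) < 0:
            raise ValueError(f"rate constant {name} must be >= 0")
    dd1, dd2, dl1, dl2, sc_efflux = sc_absorption_rhs(
        state.d1, state.d2, state.l1, state.l2, site
    )
    binding = params.k_on * state.cent * max(r_free, 0.0)
    d_cent = (
        sc_efflux
        + production
        - params.k_el * state.cent
        - binding
        + params.k_off * state.rb
        - params.k_cp * state.cent
        + params.k_pc * state.peri
    )
    d_peri = params.k_cp * state.cent - params.k_pc * state.peri
    d_rb = binding - (params.k_off + params.k_int) * state.rb
    internalisation = params.k_int * state.rb
    return EpoPkState(dd1, dd2, dl1, dl2, d_cent, d_peri, d_rb), internalisation


# ---------------------------------------------------------------------------
# injections


def _epo_dose_rel(event: InjectionEvent, params: ModelParams, pk: EpoPkParams) -> float:
    if event.unit == "IU/kg":
        iu_per_kg = event.dose
    elif event.unit == "IU":
        iu_per_kg = event.dose / params.body_weight_kg
    elif event.unit == "ug":
        iu_per_kg = event.dose * params.darbe_iu_per_ug / params.body_weight_kg
    else:
        raise ConfigurationError(f"unsupported EPO dose unit {event.unit!r}")
    return iu_per_kg * pk.dose_to_conc


def _gcsf_dose_rel(event: InjectionEvent, params: ModelParams, pk: GcsfPkParams) -> float:
    if event.unit == "ug":
        ug = event.dose
    elif event.unit == "ug/kg":
        ug = event.dose * params.body_weight_kg
    else:
        raise ConfigurationError(f"unsupported G-CSF dose unit {event.unit!r}")
    return ug * pk.dose_to_conc


def apply_injection(y: np.ndarray, event: InjectionEvent, params: ModelParams) -> np.ndarray:
    """Apply a bolus injection to the state vector (returns a copy).

    i.v. doses are added to the central compartment of the species; s.c.
    G-CSF doses enter the first subcutaneous sub-compartment, s.c. EPO doses
    split between the direct and lymphatic chains of the event's site group.
    """
    y = y.copy()
    if event.drug in GCSF_SPECIES:
        species = GCSF_SPECIES[event.drug]
        pk = params.pk_fil if species == "FIL" else params.pk_peg
        amount = _gcsf_dose_rel(event, params, pk)
        if event.route == "iv":
            y[IDX[f"{species}_CENT"]] += amount
        else:
            y[IDX[f"{species}_SC1"]] += amount
    else:
        species = EPO_SPECIES[event.drug]
        pk = params.pk_epo if species == "EPO" else params.pk_darbe
        amount = _epo_dose_rel(event, params, pk)
        if event.route == "iv":
            y[IDX[f"{species}_CENT"]] += amount
        else:
            if event.site not in params.sc_sites:
                raise ConfigurationError(f"unknown site group {event.site!r}")
            site = params.sc_sites[event.site]
            y[IDX[f"{species}_D1"]] += site.f_direct * amount
            y[IDX[f"{species}_L1"]] += (1.0 - site.f_direct) * amount
    return y
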