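"""Model parameters: flat provenance-tagged sets and the structured view.

Two representations are used.  :class:`ParameterSet` is a flat mapping of
dotted names to scalar values with units and a provenance tag; it is what
parameter files load into and what the fitting machinery overrides.
:class:`ModelParams` is the structured, validated view the ODE right-hand
sides consume, built once per simulation from a :class:`ParameterSet`.

Provenance tags:

* ``published`` — established value of the underlying model (the fitted
  CE regulators, the stem-feedback weights, the lineage split, the normal
  blood counts).
* ``placeholder`` — the original value is not publicly available; the
  default here is a physiologically plausible stand-in chosen once (see
  docs/methods.md) and meant to be overridden.
* ``fitted`` / ``user`` — produced by a fitting run or supplied by a user.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

from .regulation import (
    GcsfOnCeParams,
    ProliferativeFractionParams,
    RegulationParams,
    StemRegulationParams,
)

__all__ = [
    "Param",
    "ParameterSet",
    "ModelParams",
    "CompartmentKinetics",
    "GcsfRegulatorPair",
    "GcsfPkParams",
    "EpoPkParams",
    "ScAbsorptionParams",
    "DrugToxicity",
    "default_parameters",
    "ERYTHROID_MARROW",
    "GRANULO_MARROW",
    "COMPARTMENTS",
    "TOXICITY_TARGETS",
]

PUBLISHED = "published"
PLACEHOLDER = "placeholder"

COMPARTMENTS = ("S", "BE", "CE", "PEB", "MEB", "RET", "ERY", "CG", "PGB", "MGB", "GRA")
ERYTHROID_MARROW = ("BE", "CE", "PEB", "MEB")
GRANULO_MARROW = ("CG", "PGB", "MGB")
# chemotherapy depletes these stages; circulating erythrocytes are exempt
TOXICITY_TARGETS = ("S", "CG", "PGB", "MGB", "BE", "CE", "PEB", "MEB", "RET", "LY")


@dataclass(frozen=True)
class Param:
    value: float
    unit: str = ""
    provenance: str = PLACEHOLDER


class ParameterSet:
    """Flat mapping of dotted parameter names to provenance-tagged values."""

    def __init__(self, entries: Mapping[str, Param] | None = None):
        self._entries: dict[str, Param] = dict(entries or {})

    def __getitem__(self, name: str) -> float:
        return self._entries[name].value

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def entry(self, name: str) -> Param:
        return self._entries[name]

    def names(self) -> list[str]:
        return sorted(self._entries)

    def with_values(self, overrides: Mapping[str, float], provenance: str = "user") -> "ParameterSet":
        """Return a copy with the given scalar values replaced."""
        entries = dict(self._entries)
        for name, value in overrides.items():
            if name not in entries:
                raise KeyError(f"unknown parameter {name!r}")
            entries[name] = replace(entries[name], value=float(value), provenance=provenance)
        return ParameterSet(entries)

    def to_nested(self) -> dict:
        """Nested dict form (for YAML round-trips), one leaf per parameter."""
        root: dict = {}
        for name in self.names():
            p = self._entries[name]
            node = root
            parts = name.split(".")
            for part in parts[:-1]:
                node = node.setdefault(part, {})
            node[parts[-1]] = {"value": p.value, "unit": p.unit, "provenance": p.provenance}
        return root

    @classmethod
    def from_nested(cls, nested: Mapping) -> "ParameterSet":
        entries: dict[str, Param] = {}

        def walk(node: Mapping, prefix: str) -> None:
            if set(node) >= {"value", "provenance"}:
                entries[prefix] = Param(
                    value=float(node["value"]),
                    unit=str(node.get("unit", "")),
                    provenance=str(node["provenance"]),
                )
                return
            for key, child in node.items():
                if not isinstance(child, Mapping):
                    raise ValueError(f"malformed parameter entry at {prefix}.{key}")
                walk(child, f"{prefix}.{key}" if prefix else str(key))

        walk(nested, "")
        return cls(entries)

    def content_hash(self) -> str:
        payload = json.dumps(
            {k: self._entries[k].value for k in self.names()}, sort_keys=True
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# structured view


@dataclass(frozen=True)
class CompartmentKinetics:
    """Kinetic description of one non-stem cell compartment.

    ``t_reg`` returns the transition time in days (y_nor is the normal
    residence time); ``amp_reg`` returns the amplification relative to its
    steady-state value (y_nor = 1), so the constructed fixed point balances
    regardless of the absolute amplification convention.
    """

    name: str
    t_reg: RegulationParams
    amp_reg: RegulationParams | None = None

    @property
    def t_nor(self) -> float:
        return self.t_reg.y_nor


@dataclass(frozen=True)
class GcsfRegulatorPair:
    """Filgrastim/endogenous and Pegfilgrastim regulators for one quantity,
    superimposed with the receptor-competition weight w_P."""

    fil: RegulationParams
    peg: RegulationParams

    def value(self, c_fil_rel: float, c_peg_rel: float, w_p: float) -> float:
        return w_p * self.peg(c_peg_rel) + (1.0 - w_p) * self.fil(c_fil_rel)


@dataclass(frozen=True)
class GcsfPkParams:
    """PK constants of one G-CSF species (rates in 1/day, concentrations in
    units of the normal endogenous central concentration)."""

    k_sc12: float  # sc1 -> sc2 transit
    k_sc2c: float  # sc2 -> central transit
    vmax_sc: float  # saturable (bioavailability) loss in sc1
    km_sc: float
    k_cp: float  # central -> peripheral
    k_pc: float  # peripheral -> central
    k_ren: float  # unspecific renal elimination
    vmax_gra: float  # granulocyte-mediated Michaelis-Menten elimination
    km_gra: float
    dose_to_conc: float  # relative concentration units per microgram injected


@dataclass(frozen=True)
class EpoPkParams:
    """PK constants of one EPO species (receptor binding/internalisation)."""

    k_el: float  # unspecific first-order elimination of central
    k_on: float  # receptor binding (per concentration unit per day)
    k_off: float  # complex dissociation
    k_int: float  # internalisation of bound EPO
    k_cp: float
    k_pc: float
    dose_to_conc: float  # relative concentration units per IU/kg injected


@dataclass(frozen=True)
class ScAbsorptionParams:
    """Subcutaneous absorption chain of an EPO site group: a direct and a
    lymphatic route, each a chain of two first-order sub-compartments, with
    first-order losses at the injection site and in the lymphatic route."""

    f_direct: float  # dose fraction entering the direct route
    k_direct: float  # per-stage transit rate, direct chain (1/day)
    k_lymph: float  # per-stage transit rate, lymphatic chain (1/day)
    loss_site: float  # loss rate in the first direct sub-compartment
    loss_lymph: float  # loss rate in the first lymphatic sub-compartment


@dataclass(frozen=True)
class DrugToxicity:
    """Per-drug bone-marrow toxicity: first-order depletion intensities k_X
    (1/day) applied on [delay, delay+duration) after each administration,
    scaled by ffc in the first cycle and by elderly_factor for age >= 60."""

    name: str
    k: Mapping[str, float]
    delay: float = 0.0
    duration: float = 1.0
    ffc: float = 1.0
    elderly_factor: float = 1.0


@dataclass(frozen=True)
class ModelParams:
    """Structured parameters of the full combined model."""

    # stem cell
    stem: StemRegulationParams
    tau_s: float
    prolif_s: ProliferativeFractionParams
    prolif_be: ProliferativeFractionParams
    prolif_cg: ProliferativeFractionParams
    alpha_e: float
    alpha_g: float
    # homeostatic weights of the bone-marrow aggregates (sum to 1 per lineage)
    w_marrow_e: Mapping[str, float]
    w_marrow_g: Mapping[str, float]
    # lineage compartments, chain order
    erythroid: tuple[CompartmentKinetics, ...]  # BE, CE, PEB, MEB, RET, ERY
    granulo_cg: CompartmentKinetics
    granulo_pgb: CompartmentKinetics
    granulo_mgb: CompartmentKinetics
    t_gra: float  # granulocyte first-order blood residence (days)
    # G-CSF regulation pairs (fil/peg) for granulopoiesis
    cg_amp: GcsfRegulatorPair
    pgb_amp: GcsfRegulatorPair
    mgb_t: GcsfRegulatorPair
    # G-CSF effect on CE
    gcsf_on_ce: GcsfOnCeParams
    # PK
    pk_fil: GcsfPkParams
    pk_peg: GcsfPkParams
    pk_epo: EpoPkParams
    pk_darbe: EpoPkParams
    r_tot: float
    k_deg_int: float
    sc_sites: Mapping[str, ScAbsorptionParams]
    # endogenous production regulators
    gcsf_prod_reg: RegulationParams
    gcsf_prod_w_mgb: float
    epo_prod_reg: RegulationParams
    # chemotherapy
    toxicity: Mapping[str, DrugToxicity]
    # observables / units
    c_gra: float  # normal granulocytes per microlitre
    c_ly: float  # normal lymphocytes per microlitre
    hb_nor: float  # g/dl
    ret_nor: float  # reticulocytes per microlitre
    epo_serum_nor: float  # mU/ml
    gcsf_serum_nor: float  # pg/ml
    body_weight_kg: float
    darbe_iu_per_ug: float = 200.0

    @property
    def a_s_nor(self) -> float:
        return self.prolif_s.a_nor

    @property
    def stem_efflux_nor(self) -> float:
        # homeostatic stem efflux: 2(1-p_nor)*C_S*a_S/tau_S with
        # p_nor = 1/2 and C_S = 1 gives a_S_nor / tau_S.
        return self.a_s_nor / self.tau_s


# ---------------------------------------------------------------------------
# defaults


def _reg_entries(prefix: str, reg: RegulationParams, unit: str, prov: str) -> dict[str, Param]:
    return {
        f"{prefix}.min": Param(reg.y_min, unit, prov),
        f"{prefix}.nor": Param(reg.y_nor, unit, prov),
        f"{prefix}.max": Param(reg.y_max, unit, prov),
        f"{prefix}.b": Param(reg.b, "", prov),
    }


def _prolif_entries(prefix: str, a: tuple[float, float, float, float], prov: str) -> dict[str, Param]:
    names = ("a_min", "a_nor", "a_int", "a_max")
    return {f"{prefix}.{n}": Param(v, "", prov) for n, v in zip(names, a)}


def default_parameters() -> ParameterSet:
    """Default parameter set of the combined model.

    Established values of the underlying model carry provenance
    "published"; all other numerics are flagged "placeholder" and were
    fixed once from standard haematology and growth-factor PK literature
    ranges (rationale and units in docs/methods.md).
    """
    e: dict[str, Param] = {}

    # --- stem cell feedback
    e["stem.p_delta"] = Param(0.25, "", PLACEHOLDER)
    e["stem.theta_e"] = Param(-2.0, "", PUBLISHED)
    e["stem.theta_g"] = Param(-8.0, "", PUBLISHED)
    e["stem.tau_s"] = Param(2.5, "day", PLACEHOLDER)
    e["stem.alpha_e"] = Param(0.15, "", PUBLISHED)
    e["stem.alpha_g"] = Param(0.80, "", PUBLISHED)
    e["prolif.omega_e"] = Param(0.3, "", PUBLISHED)
    e["prolif.omega_g"] = Param(0.4, "", PUBLISHED)
    e["prolif.omega_s"] = Param(1.0, "", PLACEHOLDER)
    e.update(_prolif_entries("prolif.S", (0.05, 0.25, 0.4, 0.9), PLACEHOLDER))
    e.update(_prolif_entries("prolif.BE", (0.2, 0.5, 0.7, 0.95), PLACEHOLDER))
    e.update(_prolif_entries("prolif.CG", (0.2, 0.5, 0.7, 0.95), PLACEHOLDER))

    # homeostatic weights of the marrow aggregates C_E^rel and C_G^rel
    # (relative absolute pool sizes; post-mitotic stages dominate)
    for comp, w in (("BE", 0.05), ("CE", 0.10), ("PEB", 0.45), ("MEB", 0.40),
                    ("CG", 0.05), ("PGB", 0.35), ("MGB", 0.60)):
        e[f"marrow_weight.{comp}"] = Param(w, "", PLACEHOLDER)

    # --- erythroid chain: transition times (days) and relative amplification
    # regulators driven by internalised EPO (nor = 1 by construction)
    day = "day"
    e.update(_reg_entries("erythroid.BE.t", RegulationParams(3.0, 3.0, 3.0), day, PLACEHOLDER))
    e.update(_reg_entries("erythroid.BE.amp", RegulationParams(0.3, 1.0, 2.0, 0.9), "", PLACEHOLDER))
    e.update(_reg_entries("erythroid.CE.t", RegulationParams(4.5, 3.0, 1.2, 1.0), day, PLACEHOLDER))
    e.update(_reg_entries("erythroid.CE.amp", RegulationParams(0.05, 1.0, 4.0, 1.0), "", PLACEHOLDER))
    e.update(_reg_entries("erythroid.PEB.t", RegulationParams(6.0, 4.0, 1.5, 1.0), day, PLACEHOLDER))
    e.update(_reg_entries("erythroid.PEB.amp", RegulationParams(0.5, 1.0, 1.8, 1.0), "", PLACEHOLDER))
    e.update(_reg_entries("erythroid.MEB.t", RegulationParams(4.5, 3.5, 2.2, 1.0), day, PLACEHOLDER))
    # reticulocyte transit is not EPO-regulated by default (constant regulator)
    e.update(_reg_entries("erythroid.RET.t", RegulationParams(1.5, 1.5, 1.5), day, PLACEHOLDER))
    e.update(_reg_entries("erythroid.ERY.t", RegulationParams(120.0, 120.0, 120.0), day, PLACEHOLDER))

    # --- granulopoietic chain, regulators driven by relative central G-CSF
    e.update(_reg_entries("granulo.CG.t", RegulationParams(3.0, 3.0, 3.0), day, PLACEHOLDER))
    e.update(_reg_entries("granulo.CG.amp.fil", RegulationParams(0.4, 1.0, 2.5, 0.9), "", PLACEHOLDER))
    e.update(_reg_entries("granulo.CG.amp.peg", RegulationParams(0.4, 1.0, 2.5, 0.9), "", PLACEHOLDER))
    e.update(_reg_entries("granulo.PGB.t", RegulationParams(5.0, 5.0, 5.0), day, PLACEHOLDER))
    e.update(_reg_entries("granulo.PGB.amp.fil", RegulationParams(0.4, 1.0, 3.0, 0.9), "", PLACEHOLDER))
    e.update(_reg_entries("granulo.PGB.amp.peg", RegulationParams(0.4, 1.0, 3.0, 0.9), "", PLACEHOLDER))
    e.update(_reg_entries("granulo.MGB.t.fil", RegulationParams(7.5, 6.4, 1.0, 1.0), day, PLACEHOLDER))
    e.update(_reg_entries("granulo.MGB.t.peg", RegulationParams(7.5, 6.4, 1.0, 1.0), day, PLACEHOLDER))
    e["granulo.GRA.t"] = Param(0.4, "day", PLACEHOLDER)

    # --- G-CSF effect on CE transition time (printed, fitted values)
    e.update(_reg_entries("gcsf_on_ce.fil", RegulationParams(0.9995, 1.0, 98.37, 0.930), "", PUBLISHED))
    e.update(_reg_entries("gcsf_on_ce.peg", RegulationParams(1.0, 1.037, 2.787, 0.5660), "", PUBLISHED))

    # --- G-CSF pharmacokinetics (relative concentration units)
    per_day = "1/day"
    for name, vals in {
        "pk.fil": dict(k_sc12=6.0, k_sc2c=6.0, vmax_sc=3.0, km_sc=500.0,
                       k_cp=1.0, k_pc=5.0, k_ren=2.0, vmax_gra=50.0, km_gra=20.0,
                       dose_to_conc=13.3),
        "pk.peg": dict(k_sc12=0.8, k_sc2c=0.8, vmax_sc=2.0, km_sc=500.0,
                       k_cp=3.0, k_pc=0.15, k_ren=0.12, vmax_gra=30.0, km_gra=20.0,
                       dose_to_conc=10.0),
    }.items():
        for key, val in vals.items():
            unit = "rel/ug" if key == "dose_to_conc" else ("rel" if key.startswith("km") else per_day)
            e[f"{name}.{key}"] = Param(val, unit, PLACEHOLDER)

    # --- EPO pharmacokinetics
    for name, vals in {
        "pk.epo": dict(k_el=1.2, k_on=1.0, k_off=5.0, k_int=5.0, k_cp=0.5, k_pc=2.5,
                       dose_to_conc=2.33),
        "pk.darbe": dict(k_el=0.3, k_on=0.5, k_off=5.0, k_int=5.0, k_cp=0.5, k_pc=2.5,
                         dose_to_conc=2.33),
    }.items():
        for key, val in vals.items():
            unit = "rel/(IU/kg)" if key == "dose_to_conc" else per_day
            e[f"{name}.{key}"] = Param(val, unit, PLACEHOLDER)
    e["pk.epo_receptor.r_tot"] = Param(2.0, "rel", PLACEHOLDER)
    e["pk.epo_receptor.k_deg_int"] = Param(2.0, per_day, PLACEHOLDER)

    # --- subcutaneous site groups (EPO derivatives; Darbepoetin separate)
    site_defaults = dict(f_direct=0.6, k_direct=1.5, k_lymph=0.8, loss_site=0.3, loss_lymph=0.2)
    sites = {
        "epo_alfa_thigh": site_defaults,
        "epo_alfa_shoulder": dict(site_defaults, k_lymph=0.9),
        "epo_alfa_forearm": dict(site_defaults, k_lymph=0.7),
        "epo_alfa_abdomen": dict(site_defaults, f_direct=0.65),
        "epo_beta_forearm": dict(site_defaults, k_lymph=0.7),
        "epo_beta_abdomen": dict(site_defaults, f_direct=0.65),
        "epo_beta_thigh": site_defaults,
        "epo_delta": site_defaults,
        "darbepoetin_alfa": dict(site_defaults, k_direct=0.9, k_lymph=0.5),
        "gcsf_default": site_defaults,  # G-CSF uses its own two-compartment chain
    }
    for site, vals in sites.items():
        for key, val in vals.items():
            unit = "" if key == "f_direct" else per_day
            e[f"sc_site.{site}.{key}"] = Param(val, unit, PLACEHOLDER)

    # --- endogenous production regulators (relative production rates)
    e.update(_reg_entries("production.gcsf", RegulationParams(15.0, 1.0, 0.1, 1.5), "", PLACEHOLDER))
    e["production.gcsf_w_mgb"] = Param(0.5, "", PLACEHOLDER)
    e.update(_reg_entries("production.epo", RegulationParams(50.0, 1.0, 0.1, 3.0), "", PLACEHOLDER))

    # --- chemotherapy toxicity (placeholder intensities)
    # intensities concentrate on the proliferating stages (CG, PGB, BE, CE,
    # PEB); stem cells and post-mitotic stages are less sensitive
    tox = {
        "cyclophosphamide": dict(S=0.15, CG=3.0, PGB=2.5, MGB=0.4, BE=1.0, CE=1.0,
                                 PEB=0.6, MEB=0.15, RET=0.05, LY=0.10),
        "doxorubicin": dict(S=0.12, CG=2.4, PGB=2.0, MGB=0.32, BE=0.8, CE=0.8,
                            PEB=0.48, MEB=0.12, RET=0.04, LY=0.08),
        "epirubicine": dict(S=0.12, CG=2.4, PGB=2.0, MGB=0.32, BE=0.8, CE=0.8,
                            PEB=0.48, MEB=0.12, RET=0.04, LY=0.08),
        "vincristine": dict(S=0.03, CG=0.7, PGB=0.6, MGB=0.10, BE=0.25, CE=0.25,
                            PEB=0.15, MEB=0.04, RET=0.01, LY=0.05),
        "etoposide": dict(S=0.13, CG=2.5, PGB=2.1, MGB=0.34, BE=0.85, CE=0.85,
                          PEB=0.5, MEB=0.13, RET=0.04, LY=0.08),
        "paclitaxel": dict(S=0.08, CG=1.8, PGB=1.5, MGB=0.24, BE=0.6, CE=0.6,
                           PEB=0.36, MEB=0.09, RET=0.03, LY=0.06),
        "prednisone": dict(S=0.0, CG=0.0, PGB=0.0, MGB=0.0, BE=0.0, CE=0.0,
                           PEB=0.0, MEB=0.0, RET=0.0, LY=0.02),
        "procarbazine": dict(S=0.10, CG=1.8, PGB=1.5, MGB=0.24, BE=0.6, CE=0.6,
                             PEB=0.36, MEB=0.09, RET=0.03, LY=0.08),
        "bleomycin": dict(S=0.02, CG=0.36, PGB=0.3, MGB=0.05, BE=0.12, CE=0.12,
                          PEB=0.07, MEB=0.02, RET=0.01, LY=0.03),
    }
    for drug, ks in tox.items():
        for comp, k in ks.items():
            e[f"chemo.{drug}.k.{comp}"] = Param(k, per_day, PLACEHOLDER)
        e[f"chemo.{drug}.delay"] = Param(0.0, "day", PLACEHOLDER)
        e[f"chemo.{drug}.duration"] = Param(1.0, "day", PLACEHOLDER)
        e[f"chemo.{drug}.ffc"] = Param(1.2, "", PLACEHOLDER)
        e[f"chemo.{drug}.elderly_factor"] = Param(1.3, "", PLACEHOLDER)

    # --- observables and units
    e["observables.c_gra"] = Param(4000.0, "cells/ul", PUBLISHED)
    e["observables.c_ly"] = Param(3000.0, "cells/ul", PUBLISHED)
    e["observables.hb_nor"] = Param(14.0, "g/dl", PLACEHOLDER)
    e["observables.ret_nor"] = Param(50000.0, "cells/ul", PLACEHOLDER)
    e["observables.epo_serum_nor"] = Param(10.0, "mU/ml", PLACEHOLDER)
    e["observables.gcsf_serum_nor"] = Param(25.0, "pg/ml", PLACEHOLDER)
    e["dosing.body_weight_kg"] = Param(70.0, "kg", PLACEHOLDER)
    e["dosing.darbe_iu_per_ug"] = Param(200.0, "IU/ug", PLACEHOLDER)

    return ParameterSet(e)


def steepened_stem_feedback_overrides() -> dict[str, float]:
    """Parameter overrides that let the stem-cell feedback respond more
    intensively to marrow content, destabilising the homeostatic fixed point.

    With these values a single disturbance (e.g. one chemotherapy pulse)
    settles into sustained oscillations of all lineages rather than damped
    relaxation — the regime used to explain cyclic neutropenia.  The stem
    weight omega_S is raised and the proliferative-fraction curves of S, BE
    and CG are steepened (a_int close to a_max), together with a near-maximal
    self-renewal half-range p_delta.
    """
    over: dict[str, float] = {"prolif.omega_s": 6.0, "stem.p_delta": 0.49}
    for comp, levels in {
        "S": (0.05, 0.25, 0.85, 0.9),
        "BE": (0.2, 0.5, 0.93, 0.95),
        "CG": (0.2, 0.5, 0.93, 0.95),
    }.items():
        for name, v in zip(("a_min", "a_nor", "a_int", "a_max"), levels):
            over[f"prolif.{comp}.{name}"] = v
    return over


def _reg(p: ParameterSet, prefix: str) -> RegulationParams:
    return RegulationParams(
        y_min=p[f"{prefix}.min"], y_nor=p[f"{prefix}.nor"],
        y_max=p[f"{prefix}.max"], b=p[f"{prefix}.b"],
    )


def _prolif(p: ParameterSet, prefix: str) -> ProliferativeFractionParams:
    return ProliferativeFractionParams(
        a_min=p[f"{prefix}.a_min"], a_nor=p[f"{prefix}.a_nor"],
        a_int=p[f"{prefix}.a_int"], a_max=p[f"{prefix}.a_max"],
        omega_e=p["prolif.omega_e"], omega_g=p["prolif.omega_g"],
        omega_s=p["prolif.omega_s"],
    )


def _gcsf_pk(p: ParameterSet, prefix: str) -> GcsfPkParams:
    keys = ("k_sc12", "k_sc2c", "vmax_sc", "km_sc", "k_cp", "k_pc",
            "k_ren", "vmax_gra", "km_gra", "dose_to_conc")
    return GcsfPkParams(**{k: p[f"{prefix}.{k}"] for k in keys})


def _epo_pk(p: ParameterSet, prefix: str) -> EpoPkParams:
    keys = ("k_el", "k_on", "k_off", "k_int", "k_cp", "k_pc", "dose_to_conc")
    return EpoPkParams(**{k: p[f"{prefix}.{k}"] for k in keys})


def _sites(p: ParameterSet) -> dict[str, ScAbsorptionParams]:
    names = {n.split(".")[1] for n in p if n.startswith("sc_site.")}
    out = {}
    for site in sorted(names):
        out[site] = ScAbsorptionParams(
            f_direct=p[f"sc_site.{site}.f_direct"],
            k_direct=p[f"sc_site.{site}.k_direct"],
            k_lymph=p[f"sc_site.{site}.k_lymph"],
            loss_site=p[f"sc_site.{site}.loss_site"],
            loss_lymph=p[f"sc_site.{site}.loss_lymph"],
        )
    return out


def _toxicity(p: ParameterSet) -> dict[str, DrugToxicity]:
    drugs = {n.split(".")[1] for n in p if n.startswith("chemo.")}
    out = {}
    for drug in sorted(drugs):
        k = {c: p[f"chemo.{drug}.k.{c}"] for c in TOXICITY_TARGETS
             if f"chemo.{drug}.k.{c}" in p}
        out[drug] = DrugToxicity(
            name=drug, k=k,
            delay=p[f"chemo.{drug}.delay"],
            duration=p[f"chemo.{drug}.duration"],
            ffc=p[f"chemo.{drug}.ffc"],
            elderly_factor=p[f"chemo.{drug}.elderly_factor"],
        )
    return out


def _normalised_weights(p: ParameterSet, comps: tuple[str, ...]) -> dict[str, float]:
    raw = {c: p[f"marrow_weight.{c}"] for c in comps}
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("marrow weights must have positive sum")
    return {c: w / total for c, w in raw.items()}


def build_model_params(pset: ParameterSet | None = None) -> ModelParams:
    """Construct the structured, validated parameter view."""
    p = pset if pset is not None else default_parameters()
    erythroid = tuple(
        CompartmentKinetics(
            name=name,
            t_reg=_reg(p, f"erythroid.{name}.t"),
            amp_reg=_reg(p, f"erythroid.{name}.amp") if f"erythroid.{name}.amp.nor" in p else None,
        )
        for name in ("BE", "CE", "PEB", "MEB", "RET", "ERY")
    )
    return ModelParams(
        stem=StemRegulationParams(
            p_delta=p["stem.p_delta"], theta_e=p["stem.theta_e"], theta_g=p["stem.theta_g"],
        ),
        tau_s=p["stem.tau_s"],
        prolif_s=_prolif(p, "prolif.S"),
        prolif_be=_prolif(p, "prolif.BE"),
        prolif_cg=_prolif(p, "prolif.CG"),
        alpha_e=p["stem.alpha_e"],
        alpha_g=p["stem.alpha_g"],
        w_marrow_e=_normalised_weights(p, ERYTHROID_MARROW),
        w_marrow_g=_normalised_weights(p, GRANULO_MARROW),
        erythroid=erythroid,
        granulo_cg=CompartmentKinetics("CG", t_reg=_reg(p, "granulo.CG.t")),
        granulo_pgb=CompartmentKinetics("PGB", t_reg=_reg(p, "granulo.PGB.t")),
        granulo_mgb=CompartmentKinetics("MGB", t_reg=_reg(p, "granulo.MGB.t.fil")),
        t_gra=p["granulo.GRA.t"],
        cg_amp=GcsfRegulatorPair(_reg(p, "granulo.CG.amp.fil"), _reg(p, "granulo.CG.amp.peg")),
        pgb_amp=GcsfRegulatorPair(_reg(p, "granulo.PGB.amp.fil"), _reg(p, "granulo.PGB.amp.peg")),
        mgb_t=GcsfRegulatorPair(_reg(p, "granulo.MGB.t.fil"), _reg(p, "granulo.MGB.t.peg")),
        gcsf_on_ce=GcsfOnCeParams(
            filgrastim=_reg(p, "gcsf_on_ce.fil"),
            pegfilgrastim=_reg(p, "gcsf_on_ce.peg"),
        ),
        pk_fil=_gcsf_pk(p, "pk.fil"),
        pk_peg=_gcsf_pk(p, "pk.peg"),
        pk_epo=_epo_pk(p, "pk.epo"),
        pk_darbe=_epo_pk(p, "pk.darbe"),
        r_tot=p["pk.epo_receptor.r_tot"],
        k_deg_int=p["pk.epo_receptor.k_deg_int"],
        sc_sites=_sites(p),
        gcsf_prod_reg=_reg(p, "production.gcsf"),
        gcsf_prod_w_mgb=p["production.gcsf_w_mgb"],
        epo_prod_reg=_reg(p, "production.epo"),
        toxicity=_toxicity(p),
        c_gra=p["observables.c_gra"],
        c_ly=p["observables.c_ly"],
        hb_nor=p["observables.hb_nor"],
        ret_nor=p["observables.ret_nor"],
        epo_serum_nor=p["observables.epo_serum_nor"],
        gcsf_serum_nor=p["observables.gcsf_serum_nor"],
        body_weight_kg=p["dosing.body_weight_kg"],
        darbe_iu_per_ug=p["dosing.darbe_iu_per_ug"],
    )
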