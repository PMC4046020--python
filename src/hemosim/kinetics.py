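"""Cell-compartment kinetics: stem cells, erythroid and granulopoietic chains.

Compartment sizes are dimensionless and normalised to their homeostatic
values, so 1 means steady state everywhere.  Each non-stem compartment
follows the balance

    dC/dt = A_in * C_in - C / T - Psi * C

where ``A_in * C_in`` is written here as ``amp_rel * efflux_rel / T_nor``:
the regulated amplification relative to its steady-state value, times the
upstream efflux relative to its steady-state value, times the homeostatic
throughput 1/T_nor.  This mapping of the overall amplification onto the
influx guarantees that the all-ones state is an exact fixed point for any
admissible regulator settings, independent of the absolute amplification
convention.  The stem-cell compartment instead self-renews with probability
p and cycles a fraction a_S of its cells every tau_S days.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import regulation as reg
from .params import ERYTHROID_MARROW, GRANULO_MARROW, ModelParams

__all__ = [
    "CompartmentState",
    "compartment_flux",
    "stem_cell_rhs",
    "lineage_split",
    "erythroid_rhs",
    "granulo_rhs",
    "observables",
]

_ERYTHROID_CHAIN = ("BE", "CE", "PEB", "MEB", "RET", "ERY")


@dataclass
class CompartmentState:
    """Relative sizes of the 11 cell compartments (1 = steady state)."""

    s: float = 1.0
    be: float = 1.0
    ce: float = 1.0
    peb: float = 1.0
    meb: float = 1.0
    ret: float = 1.0
    ery: float = 1.0
    cg: float = 1.0
    pgb: float = 1.0
    mgb: float = 1.0
    gra: float = 1.0

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if value < 0:
                raise ValueError(f"compartment {name} must be >= 0, got {value}")

    def as_dict(self) -> dict[str, float]:
        return {
            "S": self.s, "BE": self.be, "CE": self.ce, "PEB": self.peb,
            "MEB": self.meb, "RET": self.ret, "ERY": self.ery,
            "CG": self.cg, "PGB": self.pgb, "MGB": self.mgb, "GRA": self.gra,
        }

    def erythroid_marrow_rel(self, weights: dict[str, float] | None = None) -> float:
        """Relative size of the erythroid bone marrow (BE+CE+PEB+MEB).

        The aggregate mirrors the ratio of absolute pool sums, so each
        normalised compartment is weighted by its homeostatic share of the
        lineage's marrow; equal weights if none are given.
        """
        d = self.as_dict()
        if weights is None:
            return sum(d[c] for c in ERYTHROID_MARROW) / len(ERYTHROID_MARROW)
        return sum(weights[c] * d[c] for c in ERYTHROID_MARROW)

    def granulo_marrow_rel(self, weights: dict[str, float] | None = None) -> float:
        """Relative size of the granulopoietic bone marrow (CG+PGB+MGB)."""
        d = self.as_dict()
        if weights is None:
            return sum(d[c] for c in GRANULO_MARROW) / len(GRANULO_MARROW)
        return sum(weights[c] * d[c] for c in GRANULO_MARROW)


def compartment_flux(
    c: float, c_in: float, a_in: float, t_transit: float, psi: float = 0.0
) -> float:
    """Time derivative of one transit compartment.

    ``a_in * c_in`` is the amplified influx, ``c / t_transit`` the efflux to
    the next stage, and ``psi * c`` the chemotherapy depletion.
    """
    if t_transit <= 0:
        raise ValueError(f"transition time must be > 0, got {t_transit}")
    if psi < 0:
        raise ValueError(f"toxicity rate must be >= 0, got {psi}")
    return a_in * c_in - c / t_transit - psi * c


def stem_cell_rhs(
    cs: float, p: float, a_s: float, tau_s: float, psi_s: float = 0.0
) -> tuple[float, float]:
    """Stem-cell derivative and efflux.

    A fraction a_s of the pool cycles every tau_s days; each division keeps
    the daughters with probability p (self-renewal) or commits them.  Hence
    d(C_S)/dt = (2p - 1) C_S a_s / tau_s and the committed efflux is
    2 (1 - p) C_S a_s / tau_s.
    """
    if not 0.0 < p < 1.0:
        if p in (0.0, 1.0):  # closed boundary allowed as a limit
            pass
        else:
            raise ValueError(f"self-renewal probability must lie in (0, 1), got {p}")
    if tau_s <= 0:
        raise ValueError("tau_s must be > 0")
    turnover = cs * a_s / tau_s
    derivative = (2.0 * p - 1.0) * turnover - psi_s * cs
    efflux = 2.0 * (1.0 - p) * turnover
    return derivative, efflux


def lineage_split(cs_out: float, alpha_e: float = 0.15, alpha_g: float = 0.80) -> tuple[float, float]:
    """Split the committed stem efflux into the erythroid and granulopoietic
    lineages (the remaining 5% commit to thrombopoiesis, not simulated)."""
    if cs_out < 0:
        raise ValueError("stem efflux must be >= 0")
    return alpha_e * cs_out, alpha_g * cs_out


def erythroid_rhs(
    state: CompartmentState,
    stem_efflux_rel: float,
    epo_int_rel: float,
    f_t_gcsf: float,
    psi: dict[str, float],
    params: ModelParams,
) -> dict[str, float]:
    """Derivatives of the erythroid chain BE -> CE -> PEB -> MEB -> RET -> ERY.

    Amplifications and transition times are regulated by internalised EPO;
    the CE transition time is additionally delayed by the G-CSF factor
    ``f_t_gcsf`` while CE amplification keeps the constant G-CSF factor 1.
    BE amplification also scales with the marrow-driven proliferative
    fraction.  RET and ERY are post-mitotic; circulating erythrocytes are
    exempt from chemotherapy depletion.
    """
    if f_t_gcsf < 0:
        raise ValueError("G-CSF transition factor must be >= 0")
    sizes = state.as_dict()
    ce_rel = state.erythroid_marrow_rel(dict(params.w_marrow_e))
    cg_rel = state.granulo_marrow_rel(dict(params.w_marrow_g))
    a_be = reg.proliferative_fraction(
        max(state.s, 1e-12), max(ce_rel, 1e-12), max(cg_rel, 1e-12), params.prolif_be
    )
    deriv: dict[str, float] = {}
    efflux_rel = stem_efflux_rel  # relative influx feed of the first stage
    for kin in params.erythroid:
        name = kin.name
        amp_rel = kin.amp_reg(epo_int_rel) if kin.amp_reg is not None else 1.0
        if name == "BE":
            amp_rel *= a_be / params.prolif_be.a_nor
        if name == "CE":
            amp_rel *= reg.gcsf_erythroid_amplification_factor()
        t = kin.t_reg(epo_int_rel)
        if name == "CE":
            t *= f_t_gcsf
        c = sizes[name]
        # circulating erythrocytes are exempt from chemotherapy depletion
        psi_x = 0.0 if name == "ERY" else psi.get(name, 0.0)
        deriv[name] = compartment_flux(
            c, c_in=efflux_rel, a_in=amp_rel / kin.t_nor,
            t_transit=t, psi=psi_x,
        )
        efflux_rel = (c / t) * kin.t_nor  # relative efflux feeding the next stage
    return deriv


def granulo_rhs(
    state: CompartmentState,
    stem_efflux_rel: float,
    c_fil_rel: float,
    c_peg_rel: float,
    psi: dict[str, float],
    params: ModelParams,
) -> dict[str, float]:
    """Derivatives of the granulopoietic chain CG -> PGB -> MGB -> GRA.

    CG and PGB amplification and the MGB (post-mitotic maturation) transition
    time are G-CSF-regulated, with Filgrastim/endogenous and Pegfilgrastim
    contributions superimposed via the receptor-competition weight.
    Circulating granulocytes are eliminated first order.
    """
    w_p = reg.receptor_competition_weight(c_fil_rel, c_peg_rel)
    ce_rel = state.erythroid_marrow_rel(dict(params.w_marrow_e))
    cg_rel = state.granulo_marrow_rel(dict(params.w_marrow_g))
    a_cg = reg.proliferative_fraction(
        max(state.s, 1e-12), max(ce_rel, 1e-12), max(cg_rel, 1e-12), params.prolif_cg
    )
    deriv: dict[str, float] = {}

    amp_cg = params.cg_amp.value(c_fil_rel, c_peg_rel, w_p) * (a_cg / params.prolif_cg.a_nor)
    t_cg = params.granulo_cg.t_nor
    deriv["CG"] = compartment_flux(
        state.cg, c_in=stem_efflux_rel, a_in=amp_cg / t_cg,
        t_transit=t_cg, psi=psi.get("CG", 0.0),
    )
    efflux_cg = state.cg  # t = t_nor, so relative efflux is just the size

    amp_pgb = params.pgb_amp.value(c_fil_rel, c_peg_rel, w_p)
    t_pgb = params.granulo_pgb.t_nor
    deriv["PGB"] = compartment_flux(
        state.pgb, c_in=efflux_cg, a_in=amp_pgb / t_pgb,
        t_transit=t_pgb, psi=psi.get("PGB", 0.0),
    )
    efflux_pgb = state.pgb

    t_mgb = params.mgb_t.value(c_fil_rel, c_peg_rel, w_p)
    t_mgb_nor = params.mgb_t.fil.y_nor
    deriv["MGB"] = compartment_flux(
        state.mgb, c_in=efflux_pgb, a_in=1.0 / t_mgb_nor,
        t_transit=t_mgb, psi=psi.get("MGB", 0.0),
    )
    efflux_mgb = (state.mgb / t_mgb) * t_mgb_nor

    deriv["GRA"] = compartment_flux(
        state.gra, c_in=efflux_mgb, a_in=1.0 / params.t_gra,
        t_transit=params.t_gra, psi=0.0,
    )
    return deriv


def observables(
    state: CompartmentState,
    cumulative_lymphotoxicity: float,
    params: ModelParams,
) -> dict[str, float]:
    """Clinical observables from the relative state.

    WBC approximates leukocytes as chemotherapy-depleted lymphocytes plus
    granulocytes: WBC = c_LY * exp(-Lambda_LY) + c_GRA * gra_rel, with the
    printed normals c_LY = 3000/ul and c_GRA = 4000/ul.  HB and RET scale
    the relative erythrocyte and reticulocyte compartments by their normal
    absolute values.
    """
    if cumulative_lymphotoxicity < 0:
        raise ValueError("cumulative lymphotoxicity must be >= 0")
    import math

    anc = params.c_gra * state.gra
    wbc = params.c_ly * math.exp(-cumulative_lymphotoxicity) + anc
    return {
        "WBC": wbc,
        "ANC": anc,
        "HB": params.hb_nor * state.ery,
        "RET": params.ret_nor * state.ret,
        "ERY_rel": state.ery,
    }
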