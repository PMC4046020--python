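"""Algebraic regulatory kernels of the haematopoiesis model.

All feedback in the model is mediated by a small set of closed-form
functions: a sigmoidal regulator mapping a relative cytokine concentration
to an amplification or transition-time value, the stem-cell self-renewal
probability, the proliferative fraction of the cycling compartments, and
the G-CSF-mediated modulation of the erythroid progenitor compartment CE.
These are pure functions of their arguments and carry no ODE state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "RegulationParams",
    "StemRegulationParams",
    "ProliferativeFractionParams",
    "GcsfOnCeParams",
    "sigmoid_regulator",
    "self_renewal_probability",
    "proliferative_fraction",
    "bone_marrow_log_content",
    "gcsf_erythroid_transition_factor",
    "gcsf_erythroid_amplification_factor",
    "receptor_competition_weight",
    "FILGRASTIM_CE_TRANSITION",
    "PEGFILGRASTIM_CE_TRANSITION",
]


class ParameterError(ValueError):
    """Raised when a regulator parameter set violates its invariants."""


@dataclass(frozen=True)
class RegulationParams:
    """Quadruple (y_min, y_nor, y_max, b) of one sigmoidal regulator.

    ``y_nor`` is the steady-state value attained at relative concentration 1;
    ``y_min`` is the value at zero stimulation and ``y_max`` the asymptote at
    infinite stimulation.  A decreasing regulator has ``y_max < y_nor < y_min``.
    ``b`` is the dimensionless sensitivity exponent.
    """

    y_min: float
    y_nor: float
    y_max: float
    b: float = 1.0

    def __post_init__(self) -> None:
        increasing = self.y_min < self.y_nor < self.y_max
        decreasing = self.y_max < self.y_nor < self.y_min
        constant = self.y_min == self.y_nor == self.y_max
        if not (increasing or decreasing or constant):
            raise ParameterError(
                f"levels must be strictly ordered either way or all equal, "
                f"got (min={self.y_min}, nor={self.y_nor}, max={self.y_max})"
            )
        if self.b <= 0:
            raise ParameterError(f"sensitivity b must be > 0, got {self.b}")

    @property
    def is_constant(self) -> bool:
        return self.y_min == self.y_max

    def __call__(self, c_rel: float) -> float:
        return sigmoid_regulator(c_rel, self)


def sigmoid_regulator(c_rel: float, params: RegulationParams) -> float:
    """Evaluate the regulatory function Z at relative concentration ``c_rel``.

    Z(c) = y_max - (y_max - y_min) * exp(-ln((y_max-y_min)/(y_max-y_nor)) * c**b)

    which satisfies Z(0) = y_min, Z(1) = y_nor and Z(inf) = y_max for either
    orientation of the levels.  The constant branch (all levels equal) returns
    y_nor exactly.
    """
    if c_rel < 0:
        raise ValueError(f"relative concentration must be >= 0, got {c_rel}")
    if params.is_constant:
        return params.y_nor
    span = params.y_max - params.y_min
    rate = math.log(span / (params.y_max - params.y_nor))
    return params.y_max - span * math.exp(-rate * c_rel ** params.b)


@dataclass(frozen=True)
class StemRegulationParams:
    """Parameters of the stem-cell self-renewal feedback.

    At homeostasis half of the dividing stem cells self-renew (p_nor = 0.5);
    the probability moves within [0.5 - p_delta, 0.5 + p_delta] in response to
    the relative bone-marrow contents, weighted by theta_E (erythroid) and
    theta_G (granulopoietic).  The stem-cell weight theta_S depends on the
    stem pool itself: 2 * cs_rel**0.6 below normal, constant 2 above.
    """

    p_delta: float = 0.25  # placeholder default; not a published value
    theta_e: float = -2.0
    theta_g: float = -8.0
    p_nor: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.p_delta < 0.5:
            raise ParameterError(f"p_delta must lie in (0, 0.5), got {self.p_delta}")
        if self.p_nor != 0.5:
            raise ParameterError("p_nor is 0.5 at homeostasis by construction")


def _theta_s(cs_rel: float) -> float:
    # continuous at cs_rel = 1 (both branches give 2)
    return 2.0 * cs_rel ** 0.6 if cs_rel <= 1.0 else 2.0


def self_renewal_probability(
    cs_rel: float,
    ce_rel: float,
    cg_rel: float,
    params: StemRegulationParams,
) -> float:
    """Self-renewal probability p of the stem-cell compartment.

    p = p_delta * tanh(-theta_S(cs)*(cs-1) - theta_E*(ce-1) - theta_G*(cg-1)) + 1/2

    with cs/ce/cg the relative sizes of the stem, erythroid and granulopoietic
    bone-marrow compartments.  A depleted marrow raises p above 1/2 (expansion),
    a crowded marrow lowers it (net differentiation).
    """
    if cs_rel <= 0 or ce_rel <= 0 or cg_rel <= 0:
        raise ValueError("relative compartment sizes must be > 0")
    arg = (
        -_theta_s(cs_rel) * (cs_rel - 1.0)
        - params.theta_e * (ce_rel - 1.0)
        - params.theta_g * (cg_rel - 1.0)
    )
    return params.p_delta * math.tanh(arg) + params.p_nor


@dataclass(frozen=True)
class ProliferativeFractionParams:
    """Anchors and weights of the proliferative-fraction regulator a_X.

    The fraction of cells in cycle ranges over [a_min, a_max]; a_nor is
    attained at normal marrow content (x = 0) and a_int at x = -ln 2, which
    pins the slope of the sigmoid.  omega_E/G/S weight the log marrow
    contents in x.
    """

    a_min: float
    a_nor: float
    a_int: float
    a_max: float
    omega_e: float = 0.3
    omega_g: float = 0.4
    omega_s: float = 1.0  # placeholder default; not a published value

    def __post_init__(self) -> None:
        ordered = self.a_min < self.a_nor < self.a_int < self.a_max
        constant = self.a_min == self.a_nor == self.a_int == self.a_max
        if not (ordered or constant):
            raise ParameterError(
                "a-levels must satisfy a_min < a_nor < a_int < a_max or all equal"
            )

    @property
    def is_constant(self) -> bool:
        return self.a_min == self.a_max


def bone_marrow_log_content(
    cs_rel: float,
    ce_rel: float,
    cg_rel: float,
    params: ProliferativeFractionParams,
) -> float:
    """Weighted log measure x of total bone-marrow content.

    x = omega_E*ln(ce) + omega_G*ln(cg) + omega_S*(ln(cs) if cs<=1 else cs-1).
    x = 0 at normal marrow; x -> -inf as any lineage empties.
    """
    if cs_rel <= 0 or ce_rel <= 0 or cg_rel <= 0:
        raise ValueError("relative compartment sizes must be > 0")
    stem_term = math.log(cs_rel) if cs_rel <= 1.0 else cs_rel - 1.0
    return (
        params.omega_e * math.log(ce_rel)
        + params.omega_g * math.log(cg_rel)
        + params.omega_s * stem_term
    )


def proliferative_fraction(
    cs_rel: float,
    ce_rel: float,
    cg_rel: float,
    params: ProliferativeFractionParams,
) -> float:
    """Proliferative fraction a_X of a cycling compartment.

    Maps the marrow-content measure x through a tanh-type sigmoid anchored
    so that a(x=0) = a_nor and a(x=-ln 2) = a_int; monotonically decreasing
    in x, saturating at a_max for empty marrow and a_min for crowded marrow.
    """
    if params.is_constant:
        # still validate the inputs so the two branches agree on the domain
        bone_marrow_log_content(cs_rel, ce_rel, cg_rel, params)
        return params.a_nor
    x = bone_marrow_log_content(cs_rel, ce_rel, cg_rel, params)
    return proliferative_fraction_from_x(x, params)


def proliferative_fraction_from_x(x: float, params: ProliferativeFractionParams) -> float:
    """Proliferative fraction as a function of the marrow measure x directly."""
    if params.is_constant:
        return params.a_nor
    # log-odds anchors: ratios of distances to the asymptotes
    l_nor = math.log((params.a_max - params.a_nor) / (params.a_nor - params.a_min))
    l_int = math.log((params.a_max - params.a_int) / (params.a_int - params.a_min))
    slope = -(l_int - l_nor) / (2.0 * math.log(2.0))
    y = slope * x + 0.5 * l_nor
    # a = (a_max e^-y + a_min e^y) / (e^-y + e^y), numerically as a logistic
    t = math.exp(-2.0 * y)  # e^-y / e^y
    return (params.a_max * t + params.a_min) / (t + 1.0)


@dataclass(frozen=True)
class GcsfOnCeParams:
    """Transition-time regulators for the G-CSF effect on compartment CE.

    One regulator for endogenous G-CSF/Filgrastim and one for Pegfilgrastim;
    their outputs are superimposed with the receptor-competition weight w_P.
    The companion amplification factor is identically 1: fitting showed a
    negligible G-CSF influence on CE amplification, so only the transition
    time is delayed.
    """

    filgrastim: RegulationParams
    pegfilgrastim: RegulationParams


# Fitted/set parameter values for the CE transition-time delay factors.
FILGRASTIM_CE_TRANSITION = RegulationParams(y_min=0.9995, y_nor=1.0, y_max=98.37, b=0.930)
PEGFILGRASTIM_CE_TRANSITION = RegulationParams(y_min=1.0, y_nor=1.037, y_max=2.787, b=0.5660)

DEFAULT_GCSF_ON_CE = GcsfOnCeParams(
    filgrastim=FILGRASTIM_CE_TRANSITION,
    pegfilgrastim=PEGFILGRASTIM_CE_TRANSITION,
)


def receptor_competition_weight(c_fil_rel: float, c_peg_rel: float) -> float:
    """Weight w_P of the Pegfilgrastim regulator under receptor competition.

    Modelled as the Pegfilgrastim share of total G-CSF, w_P = peg/(peg+fil),
    with w_P = 0 when both concentrations vanish.
    """
    if c_fil_rel < 0 or c_peg_rel < 0:
        raise ValueError("concentrations must be >= 0")
    total = c_fil_rel + c_peg_rel
    if total == 0.0:
        return 0.0
    return c_peg_rel / total


def gcsf_erythroid_transition_factor(
    c_fil_rel: float,
    c_peg_rel: float,
    w_p: float,
    params: GcsfOnCeParams = DEFAULT_GCSF_ON_CE,
) -> float:
    """Combined delay factor F_T on the CE transition time.

    F_T = w_P * Z_T_Peg(c_peg) + (1 - w_P) * Z_T_Fil(c_fil).
    """
    if not 0.0 <= w_p <= 1.0:
        raise ValueError(f"w_p must lie in [0, 1], got {w_p}")
    return w_p * sigmoid_regulator(c_peg_rel, params.pegfilgrastim) + (
        1.0 - w_p
    ) * sigmoid_regulator(c_fil_rel, params.filgrastim)


def gcsf_erythroid_amplification_factor(*_args, **_kwargs) -> float:
    """Amplification counterpart F_A of the G-CSF effect on CE; fixed at 1."""
    return 1.0
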