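"""Full-model assembly and scenario integration.

The complete ODE system couples the stem-cell compartment, the erythroid
and granulopoietic chains, the G-CSF and EPO pharmacokinetics and the
chemotherapy forcing.  Treatment scenarios are integrated piecewise with a
stiff-capable variable-step solver, restarting at every discontinuity
(injection boluses, toxicity-window edges, infusion switches) so the smooth
pieces are solved to tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from . import kinetics, pk, regulation
from .chemo import ChemoRegimen, toxicity_at, toxicity_breakpoints
from .kinetics import CompartmentState
from .params import ModelParams, ParameterSet, build_model_params
from .pk import EpoPkState, GcsfPkState, InjectionEvent
from .state import IDX, N_STATES, STATE_NAMES

__all__ = [
    "ConstantInfusion",
    "TreatmentScenario",
    "SimulationResult",
    "SteadyStateError",
    "Homeostasis",
    "build_steady_state",
    "simulate",
    "oscillation_metrics",
    "OscillationMetrics",
    "sensitivity_scan",
]

_COMP_SLICE = slice(0, 11)
_EPS = 1e-12  # regulator-domain floor for near-empty compartments


class SteadyStateError(RuntimeError):
    """No consistent fixed point under the given parameters."""


@dataclass(frozen=True)
class ConstantInfusion:
    """Constant influx into the central compartment of a cytokine species,
    used to hold serum concentrations at an elevated level."""

    species: str  # FIL | PEG | EPO | DAR
    rate: float  # relative concentration units per day
    start: float = 0.0
    end: float = math.inf

    def __post_init__(self) -> None:
        if self.species not in ("FIL", "PEG", "EPO", "DAR"):
            raise ValueError(f"unknown species {self.species!r}")
        if self.rate < 0:
            raise ValueError("infusion rate must be >= 0")


@dataclass
class TreatmentScenario:
    """A treatment schedule: growth-factor injections, an optional
    chemotherapy regimen and optional constant infusions, over a horizon."""

    injections: list[InjectionEvent] = field(default_factory=list)
    chemo: ChemoRegimen | None = None
    infusions: list[ConstantInfusion] = field(default_factory=list)
    horizon: float | None = None  # days; default regimen length + 60
    grid_dt: float = 0.25  # output grid spacing, days
    name: str = "scenario"

    def resolved_horizon(self) -> float:
        if self.horizon is not None:
            return self.horizon
        if self.chemo is not None:
            return self.chemo.duration + 60.0
        last = max((e.time for e in self.injections), default=0.0)
        return last + 60.0

    def all_injections(self) -> list[InjectionEvent]:
        """Scenario injections plus the regimen's growth-factor support,
        expanded to absolute days, in schedule order."""
        events = list(self.injections)
        if self.chemo is not None:
            for support in self.chemo.support:
                for cycle in range(self.chemo.n_cycles):
                    offset = cycle * self.chemo.cycle_length
                    for day in support.days:
                        events.append(
                            InjectionEvent(
                                time=offset + day, drug=support.drug,
                                dose=support.dose, unit=support.unit,
                                route=support.route, site=support.site,
                            )
                        )
        # stable sort keeps same-day events in schedule order
        events.sort(key=lambda e: e.time)
        horizon = self.resolved_horizon()
        for e in events:
            if not 0.0 <= e.time <= horizon:
                raise ValueError(f"injection at day {e.time} outside horizon {horizon}")
        return events


@dataclass(frozen=True)
class Homeostasis:
    """Derived homeostatic quantities fixed at steady-state construction."""

    gcsf_prod_nor: float  # endogenous G-CSF production balancing cent = 1
    epo_prod_nor: float  # endogenous EPO production balancing cent = 1
    rb_nor: float  # receptor-bound EPO at steady state
    int_nor: float  # internalised EPO pool at steady state
    stem_efflux_nor: float


def _derive_homeostasis(params: ModelParams) -> Homeostasis:
    g = params.pk_fil
    gcsf_prod_nor = g.k_ren + g.vmax_gra / (g.km_gra + 1.0)
    e = params.pk_epo
    # k_on * (R - rb) = (k_off + k_int) * rb  at cent = 1
    rb_nor = e.k_on * params.r_tot / (e.k_on + e.k_off + e.k_int)
    int_nor = e.k_int * rb_nor / params.k_deg_int
    epo_prod_nor = e.k_el + e.k_int * rb_nor
    return Homeostasis(
        gcsf_prod_nor=gcsf_prod_nor,
        epo_prod_nor=epo_prod_nor,
        rb_nor=rb_nor,
        int_nor=int_nor,
        stem_efflux_nor=params.stem_efflux_nor,
    )


def build_steady_state(params: ModelParams | None = None) -> tuple[np.ndarray, Homeostasis]:
    """Construct the homeostatic initial state and verify it is a fixed point.

    All relative cell compartments are 1; the PK states sit at their
    endogenous fixed points derived analytically from the rate constants.
    The residual of the full right-hand side is verified to be below 1e-8;
    otherwise a :class:`SteadyStateError` reports the offending equations
    (e.g. an amplification regulator whose normal value is not 1).
    """
    params = params if params is not None else build_model_params()
    home = _derive_homeostasis(params)
    y0 = np.zeros(N_STATES)
    y0[_COMP_SLICE] = 1.0
    y0[IDX["FIL_CENT"]] = 1.0
    y0[IDX["FIL_PERI"]] = params.pk_fil.k_cp / params.pk_fil.k_pc
    y0[IDX["EPO_CENT"]] = 1.0
    y0[IDX["EPO_PERI"]] = params.pk_epo.k_cp / params.pk_epo.k_pc
    y0[IDX["EPO_RB"]] = home.rb_nor
    y0[IDX["EPO_INT"]] = home.int_nor
    rhs = _make_rhs(params, home, psi=dict.fromkeys(tuple(), 0.0), infusion_rates={})
    residual = rhs(0.0, y0)
    worst = float(np.max(np.abs(residual)))
    if worst >= 1e-8:
        report = "; ".join(
            f"{STATE_NAMES[i]}: {residual[i]:+.3e}"
            for i in np.argsort(-np.abs(residual))[:5]
        )
        raise SteadyStateError(
            f"constructed state is not a fixed point (max residual {worst:.3e}): {report}"
        )
    return y0, home


def _epo_site(params: ModelParams, events: Sequence[InjectionEvent], species: str) -> str:
    """Site group of the s.c. absorption chain of an EPO species; a scenario
    may use at most one site group per species."""
    sites = {
        e.site for e in events
        if e.route == "sc" and pk.EPO_SPECIES.get(e.drug) == species and e.site
    }
    if len(sites) > 1:
        raise pk.ConfigurationError(
            f"multiple s.c. site groups for species {species}: {sorted(sites)}"
        )
    if sites:
        return sites.pop()
    return "darbepoetin_alfa" if species == "DAR" else "epo_alfa_thigh"


def _make_rhs(
    params: ModelParams,
    home: Homeostasis,
    psi: Mapping[str, float],
    infusion_rates: Mapping[str, float],
    epo_site: str = "epo_alfa_thigh",
    dar_site: str = "darbepoetin_alfa",
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Right-hand side with frozen (piecewise-constant) forcing."""
    site_epo = params.sc_sites[epo_site]
    site_dar = params.sc_sites[dar_site]
    inf_fil = infusion_rates.get("FIL", 0.0)
    inf_peg = infusion_rates.get("PEG", 0.0)
    inf_epo = infusion_rates.get("EPO", 0.0)
    inf_dar = infusion_rates.get("DAR", 0.0)
    psi_ly = psi.get("LY", 0.0)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        comp = CompartmentState(*(max(v, 0.0) for v in y[_COMP_SLICE]))
        cs = max(comp.s, _EPS)
        ce_rel = max(comp.erythroid_marrow_rel(dict(params.w_marrow_e)), _EPS)
        cg_rel = max(comp.granulo_marrow_rel(dict(params.w_marrow_g)), _EPS)

        # cytokine drives
        c_fil = max(y[IDX["FIL_CENT"]], 0.0)
        c_peg = max(y[IDX["PEG_CENT"]], 0.0)
        epo_int_rel = max(y[IDX["EPO_INT"]], 0.0) / home.int_nor
        w_p = regulation.receptor_competition_weight(c_fil, c_peg)
        f_t = regulation.gcsf_erythroid_transition_factor(
            c_fil, c_peg, w_p, params.gcsf_on_ce
        )

        # stem cell
        p = regulation.self_renewal_probability(cs, ce_rel, cg_rel, params.stem)
        a_s = regulation.proliferative_fraction(cs, ce_rel, cg_rel, params.prolif_s)
        d_s, efflux = kinetics.stem_cell_rhs(
            comp.s, p, a_s, params.tau_s, psi.get("S", 0.0)
        )
        dy[IDX["S"]] = d_s
        efflux_rel = efflux / home.stem_efflux_nor

        ery_d = kinetics.erythroid_rhs(comp, efflux_rel, epo_int_rel, f_t, psi, params)
        for name, value in ery_d.items():
            dy[IDX[name]] = value
        gran_d = kinetics.granulo_rhs(comp, efflux_rel, c_fil, c_peg, psi, params)
        for name, value in gran_d.items():
            dy[IDX[name]] = value

        # G-CSF PK: endogenous production feeds the Filgrastim-pooled species
        prod_fil = pk.gcsf_production(
            comp.mgb, comp.gra, params.gcsf_prod_reg,
            params.gcsf_prod_w_mgb, home.gcsf_prod_nor,
        ) + inf_fil
        fil = GcsfPkState(*(y[IDX["FIL_SC1"]:IDX["FIL_PERI"] + 1]))
        d_fil = pk.gcsf_pk_rhs(fil, comp.gra, prod_fil, params.pk_fil)
        dy[IDX["FIL_SC1"]:IDX["FIL_PERI"] + 1] = (d_fil.sc1, d_fil.sc2, d_fil.cent, d_fil.peri)

        peg = GcsfPkState(*(y[IDX["PEG_SC1"]:IDX["PEG_PERI"] + 1]))
        d_peg = pk.gcsf_pk_rhs(peg, comp.gra, inf_peg, params.pk_peg)
        dy[IDX["PEG_SC1"]:IDX["PEG_PERI"] + 1] = (d_peg.sc1, d_peg.sc2, d_peg.cent, d_peg.peri)

        # EPO PK: two species compete for one receptor pool
        r_free = params.r_tot - y[IDX["EPO_RB"]] - y[IDX["DAR_RB"]]
        prod_epo = pk.epo_production(comp.ery, params.epo_prod_reg, home.epo_prod_nor) + inf_epo
        epo = EpoPkState(*(y[IDX["EPO_D1"]:IDX["EPO_RB"] + 1]))
        d_epo, internalised = pk.epo_pk_rhs(epo, prod_epo, r_free, params.pk_epo, site_epo)
        dy[IDX["EPO_D1"]:IDX["EPO_RB"] + 1] = (
            d_epo.d1, d_epo.d2, d_epo.l1, d_epo.l2, d_epo.cent, d_epo.peri, d_epo.rb
        )
        dar = EpoPkState(*(y[IDX["DAR_D1"]:IDX["DAR_RB"] + 1]))
        d_dar, internalised_dar = pk.epo_pk_rhs(dar, inf_dar, r_free, params.pk_darbe, site_dar)
        dy[IDX["DAR_D1"]:IDX["DAR_RB"] + 1] = (
            d_dar.d1, d_dar.d2, d_dar.l1, d_dar.l2, d_dar.cent, d_dar.peri, d_dar.rb
        )
        dy[IDX["EPO_INT"]] = (
            internalised + internalised_dar - params.k_deg_int * y[IDX["EPO_INT"]]
        )
        dy[IDX["LAM_LY"]] = psi_ly
        return dy

    return rhs


@dataclass
class SimulationResult:
    """Time-indexed trajectories of all states and clinical observables."""

    t: np.ndarray
    y: np.ndarray  # shape (len(t), N_STATES)
    params: ModelParams
    scenario: TreatmentScenario
    events: list[InjectionEvent]

    def state(self, name: str) -> np.ndarray:
        """Trajectory of one state variable (relative units)."""
        return self.y[:, IDX[name]]

    def observable(self, name: str) -> np.ndarray:
        return self.observables()[name].to_numpy()

    def observables(self) -> pd.DataFrame:
        """Clinical observables on the output grid."""
        p = self.params
        gra = self.y[:, IDX["GRA"]]
        anc = p.c_gra * gra
        wbc = p.c_ly * np.exp(-self.y[:, IDX["LAM_LY"]]) + anc
        frame = pd.DataFrame(
            {
                "time": self.t,
                "WBC": wbc,
                "ANC": anc,
                "HB": p.hb_nor * self.y[:, IDX["ERY"]],
                "RET": p.ret_nor * self.y[:, IDX["RET"]],
                "EPO": p.epo_serum_nor
                * (self.y[:, IDX["EPO_CENT"]] + self.y[:, IDX["DAR_CENT"]]),
                "GCSF": p.gcsf_serum_nor
                * (self.y[:, IDX["FIL_CENT"]] + self.y[:, IDX["PEG_CENT"]]),
            }
        )
        return frame

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, variable, value) table of all states and observables."""
        states = pd.DataFrame(self.y, columns=list(STATE_NAMES))
        states.insert(0, "time", self.t)
        tidy = states.melt(id_vars="time", var_name="variable", value_name="value")
        obs = self.observables().melt(id_vars="time", var_name="variable", value_name="value")
        return pd.concat([tidy, obs], ignore_index=True)


def simulate(
    scenario: TreatmentScenario,
    params: ModelParams | ParameterSet | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate a treatment scenario from the constructed steady state.

    The time axis is partitioned at every discontinuity of the forcing
    (injection times, toxicity-window edges, infusion switches); each smooth
    piece is integrated with a variable-step solver and sampled on the output
    grid.  Bolus injections are applied as state jumps at their event time,
    same-day events in schedule order.  The run is deterministic given the
    scenario, parameters and solver options.
    """
    if isinstance(params, ParameterSet):
        params = build_model_params(params)
    params = params if params is not None else build_model_params()
    horizon = scenario.resolved_horizon()
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    events = scenario.all_injections()
    epo_site = _epo_site(params, events, "EPO")
    dar_site = _epo_site(params, events, "DAR")

    cuts = {0.0, horizon}
    cuts.update(e.time for e in events)
    cuts.update(b for b in toxicity_breakpoints(scenario.chemo, params.toxicity) if b < horizon)
    for inf in scenario.infusions:
        cuts.add(max(inf.start, 0.0))
        if inf.end < horizon:
            cuts.add(inf.end)
    cut_times = sorted(c for c in cuts if 0.0 <= c <= horizon)

    grid = np.round(np.arange(0.0, horizon + 0.5 * scenario.grid_dt, scenario.grid_dt), 12)
    grid = grid[grid <= horizon]

    y, home = build_steady_state(params)
    ts: list[float] = []
    ys: list[np.ndarray] = []

    for t0, t1 in zip(cut_times[:-1], cut_times[1:]):
        for event in (e for e in events if e.time == t0):
            y = pk.apply_injection(y, event, params)
        mid = 0.5 * (t0 + t1)
        psi = toxicity_at(mid, scenario.chemo, params.toxicity)
        infusion_rates: dict[str, float] = {}
        for inf in scenario.infusions:
            if inf.start <= mid < inf.end:
                infusion_rates[inf.species] = infusion_rates.get(inf.species, 0.0) + inf.rate
        rhs = _make_rhs(params, home, psi, infusion_rates, epo_site, dar_site)
        inner = grid[(grid > t0) & (grid < t1)]
        t_eval = np.concatenate(([t0], inner, [t1]))
        sol = solve_ivp(
            rhs, (t0, t1), y, method=method, rtol=rtol, atol=atol, t_eval=t_eval,
        )
        if not sol.success:
            raise RuntimeError(
                f"solver failed in [{t0}, {t1}]: {sol.message}; last state recorded"
            )
        y = sol.y[:, -1]
        undershoot = y[y < 0.0]
        if len(undershoot) and undershoot.min() < -1e-9:
            raise RuntimeError(f"state went negative beyond tolerance: {undershoot.min():.3e}")
        y = np.maximum(y, 0.0)
        ts.extend(sol.t[:-1].tolist())
        ys.extend(sol.y.T[:-1])

    ts.append(horizon)
    ys.append(y)
    t_arr = np.asarray(ts)
    y_arr = np.vstack(ys)
    # de-duplicate grid points repeated at segment boundaries (keep post-event)
    keep = np.ones(len(t_arr), dtype=bool)
    keep[:-1] = np.diff(t_arr) > 0
    return SimulationResult(
        t=t_arr[keep], y=np.maximum(y_arr[keep], 0.0), params=params,
        scenario=scenario, events=events,
    )


# ---------------------------------------------------------------------------
# analysis operations


@dataclass(frozen=True)
class OscillationMetrics:
    """Extrema of a trajectory's deviation from baseline and their decay."""

    times: np.ndarray
    values: np.ndarray
    amplitudes: np.ndarray  # |value - baseline| at the extrema
    ratios: np.ndarray  # successive amplitude ratios
    period: float | None  # 2 x mean extremum spacing (full-period estimate)

    @property
    def damping_ratio(self) -> float | None:
        """Mean successive amplitude ratio; < 1 damped, about 1 sustained."""
        if len(self.ratios) == 0:
            return None
        return float(np.mean(self.ratios))

    @property
    def n_extrema(self) -> int:
        return len(self.times)


def oscillation_metrics(
    t: np.ndarray,
    series: np.ndarray,
    baseline: float = 1.0,
    min_amplitude: float = 1e-4,
    smooth_window: int = 5,
) -> OscillationMetrics:
    """Detect oscillation extrema of a trajectory around ``baseline``.

    The absolute deviation is lightly smoothed with a moving average, local
    maxima above ``min_amplitude`` are located, and successive amplitude
    ratios are returned: ratios below 1 indicate damping, near 1 sustained
    oscillation.  For a decaying sinusoid e^(-t/tau) sin(w t) the extrema
    lie half a period apart with ratio exp(-pi/(w tau)).
    """
    t = np.asarray(t, dtype=float)
    series = np.asarray(series, dtype=float)
    if len(t) < 8 or len(t) != len(series):
        raise ValueError("series too short for oscillation analysis")
    dev = np.abs(series - baseline)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        dev = np.convolve(dev, kernel, mode="same")
    peaks, _ = find_peaks(dev, height=min_amplitude)
    times = t[peaks]
    values = series[peaks]
    amplitudes = np.abs(values - baseline)
    ratios = amplitudes[1:] / amplitudes[:-1] if len(amplitudes) > 1 else np.array([])
    period = 2.0 * float(np.mean(np.diff(times))) if len(times) > 1 else None
    return OscillationMetrics(times, values, amplitudes, ratios, period)


def sensitivity_scan(
    pset: ParameterSet,
    objective: Callable[[ParameterSet], float],
    names: Sequence[str],
    perturbation: float = 0.025,
) -> pd.DataFrame:
    """Fitness deterioration under symmetric relative parameter perturbations.

    Each named parameter is varied by +/- ``perturbation`` (default 2.5%)
    with all others fixed; the deterioration is objective(perturbed) minus
    objective(base).  Deterministic: repeated scans give identical tables.
    """
    base = objective(pset)
    rows = []
    for name in names:
        value = pset[name]
        out = {"parameter": name, "value": value}
        for label, sign in (("minus", -1.0), ("plus", +1.0)):
            perturbed = pset.with_values({name: value * (1.0 + sign * perturbation)})
            out[label] = objective(perturbed) - base
        rows.append(out)
    return pd.DataFrame(rows, columns=["parameter", "value", "minus", "plus"])
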