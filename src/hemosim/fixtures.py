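"""Synthetic "clinical" series: simulate known truth, add patient noise.

Clinical fitting data are medians (and quartiles) of patient cohorts.  The
fixture generator stands in for such data: it simulates the model with a
known truth parameter set, draws per-patient multiplicative log-normal
noise per outcome and sampling day, and emits the per-day median and
quartiles.  With zero noise the medians equal the simulated truth exactly,
which makes the generator the ground-truth source for parameter-recovery
studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fitting import ObservedSeries
from .params import ParameterSet, build_model_params, default_parameters
from .simulate import TreatmentScenario, simulate

__all__ = ["FixtureSpec", "generate_fixture"]


@dataclass
class FixtureSpec:
    """Specification of one synthetic-cohort fixture."""

    scenario: TreatmentScenario
    sampling_days: Sequence[float]
    outcomes: Sequence[str] = ("WBC", "HB")
    truth: Mapping[str, float] = field(default_factory=dict)  # parameter overrides
    noise_sd: Mapping[str, float] = field(default_factory=dict)  # log-sd per outcome
    n_patients: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise sd must be >= 0")
        days = list(self.sampling_days)
        if len(days) < 2 or any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("sampling days must be strictly increasing, >= 2 points")


def generate_fixture(
    spec: FixtureSpec, base: ParameterSet | None = None
) -> list[ObservedSeries]:
    """Simulate the truth and emit noisy cohort medians per outcome.

    Deterministic given ``spec.seed``; with ``noise_sd == 0`` (or an outcome
    missing from ``noise_sd``) the medians equal the simulated truth.
    """
    base = base if base is not None else default_parameters()
    pset = base.with_values(spec.truth, provenance="user") if spec.truth else base
    sim = simulate(spec.scenario, build_model_params(pset))
    rng = np.random.default_rng(spec.seed)
    days = np.asarray(list(spec.sampling_days), dtype=float)
    series: list[ObservedSeries] = []
    for outcome in spec.outcomes:
        truth_values = np.interp(days, sim.t, sim.observable(outcome))
        sd = spec.noise_sd.get(outcome, 0.0)
        # per-patient multiplicative log-normal noise, one draw per day
        noise = np.exp(rng.normal(0.0, sd, size=(spec.n_patients, len(days))))
        samples = truth_values[None, :] * noise
        q25, med, q75 = np.percentile(samples, [25, 50, 75], axis=0)
        series.append(
            ObservedSeries(
                outcome=outcome,
                times=tuple(days),
                medians=tuple(med),
                q25=tuple(q25),
                q75=tuple(q75),
                scenario=spec.scenario.name,
            )
        )
    return series
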