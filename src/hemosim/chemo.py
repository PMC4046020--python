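"""Chemotherapy toxicity forcing and the bundled regimen library.

Each cytotoxic drug depletes the bone-marrow stages S, CG, PGB, MGB, BE,
CE, PEB, MEB and RET (circulating erythrocytes are exempt) with a
first-order rate Psi_X active on a rectangular window after each
administration.  Drugs act independently, so the toxicity functions of a
combination simply add.  The first cycle carries a factor ffc >= 1, and
patients aged 60 or older get a uniformly scaled parameter set.  The
depleted lymphocyte count is described by exp(-integral of Psi_LY).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .params import DrugToxicity, TOXICITY_TARGETS

__all__ = [
    "ChemoAdministration",
    "GrowthFactorSupport",
    "ChemoRegimen",
    "toxicity_at",
    "toxicity_breakpoints",
    "lymphocyte_factor",
    "regimen_library",
]

AGE_GROUPS = ("<60", ">=60")


@dataclass(frozen=True)
class ChemoAdministration:
    """One drug administration at a day within the cycle."""

    day: float
    drug: str
    dose_mg_m2: float | None = None  # informational; toxicity is per parameter set


@dataclass(frozen=True)
class GrowthFactorSupport:
    """Per-cycle growth-factor support schedule (e.g. Filgrastim day 4-13)."""

    drug: str
    dose: float
    unit: str = "ug"
    route: str = "sc"
    site: str | None = "gcsf_default"
    days: tuple[float, ...] = ()


@dataclass(frozen=True)
class ChemoRegimen:
    """A multi-cycle chemotherapy regimen."""

    name: str
    administrations: tuple[ChemoAdministration, ...]  # days within one cycle
    cycle_length: float  # days
    n_cycles: int
    age_group: str = "<60"
    support: tuple[GrowthFactorSupport, ...] = ()
    # administrations before this absolute day count as first-cycle (ffc);
    # defaults to one cycle length.  Sequential protocols encoded as a single
    # long macro-cycle set this to the span of their first block.
    ffc_window: float | None = None

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("number of cycles must be >= 1")
        if self.cycle_length <= 0:
            raise ValueError("cycle length must be > 0")
        days = [a.day for a in self.administrations]
        if any(d < 0 for d in days) or days != sorted(days):
            raise ValueError("administration days must be non-negative and sorted")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"age group must be one of {AGE_GROUPS}")

    @property
    def duration(self) -> float:
        return self.cycle_length * self.n_cycles

    @property
    def first_cycle_end(self) -> float:
        return self.ffc_window if self.ffc_window is not None else self.cycle_length

    def expanded(self) -> list[tuple[float, str, int]]:
        """All (absolute day, drug, cycle index) administrations."""
        out = []
        for cycle in range(self.n_cycles):
            offset = cycle * self.cycle_length
            for admin in self.administrations:
                out.append((offset + admin.day, admin.drug, cycle))
        return out


def _drug_params(regimen: ChemoRegimen, drug: str, toxicity: Mapping[str, DrugToxicity]) -> DrugToxicity:
    try:
        return toxicity[drug]
    except KeyError:
        raise KeyError(f"no toxicity parameters for drug {drug!r}") from None


def toxicity_at(
    t: float,
    regimen: ChemoRegimen | None,
    toxicity: Mapping[str, DrugToxicity],
) -> dict[str, float]:
    """Summed depletion rates Psi_X (1/day) over all compartments at time t.

    Each administration contributes its per-compartment intensity on the
    window [day + delay, day + delay + duration), multiplied by ffc in the
    first cycle and by the elderly factor for the >= 60 age group;
    contributions of all drugs and administrations add.
    """
    if t < 0:
        raise ValueError("time must be >= 0")
    psi = {c: 0.0 for c in TOXICITY_TARGETS}
    if regimen is None:
        return psi
    elderly = regimen.age_group == ">=60"
    for day, drug, _cycle in regimen.expanded():
        par = _drug_params(regimen, drug, toxicity)
        start = day + par.delay
        if start <= t < start + par.duration:
            first = day < regimen.first_cycle_end
            scale = (par.ffc if first else 1.0) * (par.elderly_factor if elderly else 1.0)
            for comp, k in par.k.items():
                psi[comp] += scale * k
    return psi


def toxicity_breakpoints(
    regimen: ChemoRegimen | None, toxicity: Mapping[str, DrugToxicity]
) -> list[float]:
    """Window edges where the (piecewise-constant) Psi vector jumps."""
    if regimen is None:
        return []
    edges = set()
    for day, drug, _cycle in regimen.expanded():
        par = _drug_params(regimen, drug, toxicity)
        edges.add(day + par.delay)
        edges.add(day + par.delay + par.duration)
    return sorted(edges)


def lymphocyte_factor(
    t: float,
    regimen: ChemoRegimen | None,
    toxicity: Mapping[str, DrugToxicity],
) -> float:
    """Lymphocyte depletion multiplier exp(-Lambda_LY(t)) in (0, 1].

    Lambda_LY(t) is the running integral of the (rectangular-pulse)
    lymphocyte toxicity; with rectangular windows the integral has closed
    form, evaluated exactly here.
    """
    if t < 0:
        raise ValueError("time must be >= 0")
    if regimen is None:
        return 1.0
    lam = 0.0
    elderly = regimen.age_group == ">=60"
    for day, drug, _cycle in regimen.expanded():
        par = _drug_params(regimen, drug, toxicity)
        k_ly = par.k.get("LY", 0.0)
        if k_ly == 0.0:
            continue
        first = day < regimen.first_cycle_end
        scale = (par.ffc if first else 1.0) * (par.elderly_factor if elderly else 1.0)
        start = day + par.delay
        overlap = min(t, start + par.duration) - start
        if overlap > 0:
            lam += scale * k_ly * overlap
    return math.exp(-lam)


# ---------------------------------------------------------------------------
# regimen library


def _chop_admins() -> tuple[ChemoAdministration, ...]:
    return (
        ChemoAdministration(0.0, "cyclophosphamide", 750.0),
        ChemoAdministration(0.0, "doxorubicin", 50.0),
        ChemoAdministration(0.0, "vincristine", 1.4),
        ChemoAdministration(0.0, "prednisone", 100.0),
    )


def _choep_admins() -> tuple[ChemoAdministration, ...]:
    return _chop_admins() + (
        ChemoAdministration(0.0, "etoposide", 100.0),
        ChemoAdministration(1.0, "etoposide", 100.0),
        ChemoAdministration(2.0, "etoposide", 100.0),
    )


def regimen_library() -> dict[str, ChemoRegimen]:
    """Bundled regimens with day patterns of the standard protocols.

    CHOP/CHOEP variants for aggressive non-Hodgkin lymphoma (14- or 21-day
    cycles, Filgrastim support on days 4-13 or 6-12 of the 14-day variants),
    BEACOPP for Hodgkin lymphoma, and the breast-cancer EC-T and E-T-C
    sequences.
    """
    fil_4_13 = GrowthFactorSupport("filgrastim", 480.0, days=tuple(float(d) for d in range(4, 14)))
    fil_6_12 = GrowthFactorSupport("filgrastim", 480.0, days=tuple(float(d) for d in range(6, 13)))
    fil_8_15 = GrowthFactorSupport("filgrastim", 480.0, days=tuple(float(d) for d in range(8, 16)))
    peg_day4 = GrowthFactorSupport("pegfilgrastim", 6000.0, days=(4.0,))

    beacopp = tuple(
        sorted(
            (
                ChemoAdministration(0.0, "cyclophosphamide", 650.0),
                ChemoAdministration(0.0, "doxorubicin", 25.0),
                ChemoAdministration(0.0, "etoposide", 100.0),
                ChemoAdministration(1.0, "etoposide", 100.0),
                ChemoAdministration(2.0, "etoposide", 100.0),
                ChemoAdministration(0.0, "procarbazine", 100.0),
                ChemoAdministration(0.0, "prednisone", 40.0),
                ChemoAdministration(7.0, "vincristine", 1.4),
                ChemoAdministration(7.0, "bleomycin", 10.0),
            ),
            key=lambda a: a.day,
        )
    )

    regimens = {
        "CHOP-21": ChemoRegimen("CHOP-21", _chop_admins(), 21.0, 6),
        "CHOP-14": ChemoRegimen("CHOP-14", _chop_admins(), 14.0, 6, support=(fil_4_13,)),
        "CHOP-14-8cy": ChemoRegimen("CHOP-14-8cy", _chop_admins(), 14.0, 8, support=(fil_6_12,)),
        "CHOP-14-peg": ChemoRegimen("CHOP-14-peg", _chop_admins(), 14.0, 6, support=(peg_day4,)),
        "CHOEP-21": ChemoRegimen("CHOEP-21", _choep_admins(), 21.0, 6),
        "CHOEP-14": ChemoRegimen("CHOEP-14", _choep_admins(), 14.0, 6, support=(fil_4_13,)),
        "BEACOPP-21": ChemoRegimen("BEACOPP-21", beacopp, 21.0, 8, support=(fil_8_15,)),
        # sequential protocols as single macro-cycles (drug changes per block)
        "EC-T": ChemoRegimen(
            "EC-T",
            tuple(
                ChemoAdministration(float(d), drug, dose)
                for d, drug, dose in sorted(
                    [(21 * i, "epirubicine", 90.0) for i in range(4)]
                    + [(21 * i, "cyclophosphamide", 600.0) for i in range(4)]
                    + [(84 + 21 * i, "paclitaxel", 175.0) for i in range(4)]
                )
            ),
            168.0, 1, ffc_window=21.0,
        ),
        "E-T-C": ChemoRegimen(
            "E-T-C",
            tuple(
                ChemoAdministration(float(d), drug, dose)
                for d, drug, dose in sorted(
                    [(14 * i, "epirubicine", 150.0) for i in range(3)]
                    + [(42 + 14 * i, "paclitaxel", 225.0) for i in range(3)]
                    + [(84 + 14 * i, "cyclophosphamide", 2500.0) for i in range(3)]
                )
            ),
            126.0, 1, ffc_window=14.0,
            support=(
                GrowthFactorSupport(
                    "filgrastim", 480.0,
                    days=tuple(float(b + d) for b in range(0, 126, 14) for d in range(3, 11)),
                ),
            ),
        ),
    }
    return regimens
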