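"""Configuration and data I/O: scenario files, parameter files, series tables.

Scenarios and parameters are human-editable YAML with explicit units in key
names; observed series are plain CSV tables with columns
(scenario, outcome, day, median, q25, q75).  Schema violations are reported
with the path of the offending key, and every loader round-trips with its
saver.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .chemo import ChemoAdministration, ChemoRegimen, GrowthFactorSupport, regimen_library
from .fitting import ObservedSeries
from .params import ParameterSet
from .pk import InjectionEvent
from .simulate import ConstantInfusion, TreatmentScenario

__all__ = [
    "SchemaError",
    "load_scenario",
    "save_scenario",
    "scenario_from_dict",
    "scenario_to_dict",
    "load_parameters",
    "save_parameters",
    "load_series",
    "save_series",
    "bundled_scenarios",
    "load_bundled_scenario",
]


class SchemaError(ValueError):
    """A configuration file violates the expected schema."""


def _check_keys(mapping: Mapping[str, Any], allowed: set[str], path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise SchemaError(f"unknown key(s) {sorted(unknown)} at {path or '<root>'}")


_INJECTION_KEYS = {"day", "drug", "dose", "unit", "route", "site"}
_SCENARIO_KEYS = {"name", "horizon_days", "grid_dt_days", "injections", "chemo", "infusions"}
_CHEMO_KEYS = {
    "regimen", "name", "cycles", "cycle_length_days", "age_group",
    "administrations", "support", "ffc_window_days",
}
_SUPPORT_KEYS = {"drug", "dose", "unit", "route", "site", "days"}
_INFUSION_KEYS = {"species", "rate", "start_day", "end_day"}


def _injection_from_dict(d: Mapping[str, Any], path: str) -> InjectionEvent:
    _check_keys(d, _INJECTION_KEYS, path)
    try:
        return InjectionEvent(
            time=float(d["day"]), drug=str(d["drug"]), dose=float(d["dose"]),
            unit=str(d.get("unit", "ug")), route=str(d.get("route", "sc")),
            site=d.get("site"),
        )
    except (KeyError, ValueError) as exc:
        raise SchemaError(f"invalid injection at {path}: {exc}") from exc


def _chemo_from_dict(d: Mapping[str, Any], path: str) -> ChemoRegimen:
    _check_keys(d, _CHEMO_KEYS, path)
    if "regimen" in d:
        library = regimen_library()
        name = str(d["regimen"])
        if name not in library:
            raise SchemaError(f"unknown regimen {name!r} at {path}")
        regimen = library[name]
        if "age_group" in d:
            from dataclasses import replace

            regimen = replace(regimen, age_group=str(d["age_group"]))
        return regimen
    try:
        support = tuple(
            GrowthFactorSupport(
                drug=str(s["drug"]), dose=float(s["dose"]),
                unit=str(s.get("unit", "ug")), route=str(s.get("route", "sc")),
                site=s.get("site", "gcsf_default"),
                days=tuple(float(x) for x in s.get("days", [])),
            )
            for s in d.get("support", [])
        )
        return ChemoRegimen(
            name=str(d["name"]),
            administrations=tuple(
                ChemoAdministration(
                    day=float(a["day"]), drug=str(a["drug"]),
                    dose_mg_m2=a.get("dose_mg_m2"),
                )
                for a in d["administrations"]
            ),
            cycle_length=float(d["cycle_length_days"]),
            n_cycles=int(d["cycles"]),
            age_group=str(d.get("age_group", "<60")),
            support=support,
            ffc_window=float(d["ffc_window_days"]) if "ffc_window_days" in d else None,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"invalid chemo block at {path}: {exc}") from exc


def scenario_from_dict(d: Mapping[str, Any]) -> TreatmentScenario:
    _check_keys(d, _SCENARIO_KEYS, "")
    injections = [
        _injection_from_dict(inj, f"injections[{i}]")
        for i, inj in enumerate(d.get("injections", []))
    ]
    chemo = _chemo_from_dict(d["chemo"], "chemo") if d.get("chemo") else None
    infusions = []
    for i, inf in enumerate(d.get("infusions", [])):
        _check_keys(inf, _INFUSION_KEYS, f"infusions[{i}]")
        infusions.append(
            ConstantInfusion(
                species=str(inf["species"]), rate=float(inf["rate"]),
                start=float(inf.get("start_day", 0.0)),
                end=float(inf.get("end_day", float("inf"))),
            )
        )
    return TreatmentScenario(
        injections=injections, chemo=chemo, infusions=infusions,
        horizon=float(d["horizon_days"]) if d.get("horizon_days") is not None else None,
        grid_dt=float(d.get("grid_dt_days", 0.25)),
        name=str(d.get("name", "scenario")),
    )


def scenario_to_dict(scenario: TreatmentScenario) -> dict:
    d: dict[str, Any] = {"name": scenario.name}
    if scenario.horizon is not None:
        d["horizon_days"] = scenario.horizon
    d["grid_dt_days"] = scenario.grid_dt
    d["injections"] = [
        {
            "day": e.time, "drug": e.drug, "dose": e.dose, "unit": e.unit,
            "route": e.route, **({"site": e.site} if e.site else {}),
        }
        for e in scenario.injections
    ]
    if scenario.chemo is not None:
        c = scenario.chemo
        d["chemo"] = {
            "name": c.name, "cycles": c.n_cycles, "cycle_length_days": c.cycle_length,
            "age_group": c.age_group,
            "administrations": [
                {"day": a.day, "drug": a.drug,
                 **({"dose_mg_m2": a.dose_mg_m2} if a.dose_mg_m2 is not None else {})}
                for a in c.administrations
            ],
            **({"ffc_window_days": c.ffc_window} if c.ffc_window is not None else {}),
            **(
                {"support": [
                    {"drug": s.drug, "dose": s.dose, "unit": s.unit, "route": s.route,
                     "site": s.site, "days": list(s.days)}
                    for s in c.support
                ]} if c.support else {}
            ),
        }
    if scenario.infusions:
        d["infusions"] = [
            {"species": i.species, "rate": i.rate, "start_day": i.start,
             **({"end_day": i.end} if i.end != float("inf") else {})}
            for i in scenario.infusions
        ]
    return d


def load_scenario(path: str | Path) -> TreatmentScenario:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise SchemaError(f"{path}: scenario file must be a mapping")
    return scenario_from_dict(data)


def save_scenario(scenario: TreatmentScenario, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=False)


def load_parameters(path: str | Path) -> ParameterSet:
    with open(path) as fh:
        nested = yaml.safe_load(fh)
    if not isinstance(nested, Mapping):
        raise SchemaError(f"{path}: parameter file must be a mapping")
    return ParameterSet.from_nested(nested)


def save_parameters(pset: ParameterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(pset.to_nested(), fh, sort_keys=True)


_SERIES_COLUMNS = ["scenario", "outcome", "day", "median", "q25", "q75"]


def save_series(series: list[ObservedSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for i, day in enumerate(s.times):
            rows.append(
                {
                    "scenario": s.scenario, "outcome": s.outcome, "day": day,
                    "median": s.medians[i],
                    "q25": s.q25[i] if s.q25 else "",
                    "q75": s.q75[i] if s.q75 else "",
                }
            )
    pd.DataFrame(rows, columns=_SERIES_COLUMNS).to_csv(path, index=False)


def load_series(path: str | Path) -> list[ObservedSeries]:
    frame = pd.read_csv(path)
    missing = set(_SERIES_COLUMNS[:4]) - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for (scen, outcome), grp in frame.groupby(["scenario", "outcome"], sort=False):
        grp = grp.sort_values("day")
        has_q = "q25" in grp and grp["q25"].notna().all()
        out.append(
            ObservedSeries(
                outcome=str(outcome),
                times=tuple(grp["day"].astype(float)),
                medians=tuple(grp["median"].astype(float)),
                q25=tuple(grp["q25"].astype(float)) if has_q else None,
                q75=tuple(grp["q75"].astype(float)) if has_q else None,
                scenario=str(scen),
            )
        )
    return out


def bundled_scenarios() -> list[str]:
    """Names of the scenario files shipped with the package."""
    root = importlib.resources.files("hemosim") / "data"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_bundled_scenario(name: str) -> TreatmentScenario:
    root = importlib.resources.files("hemosim") / "data"
    path = root / f"{name}.yaml"
    if not path.is_file():
        raise FileNotFoundError(
            f"no bundled scenario {name!r}; available: {bundled_scenarios()}"
        )
    return scenario_from_dict(yaml.safe_load(path.read_text()))
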