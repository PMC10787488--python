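"""Domain types and configuration handling for the EP patient-flow model.

The simulator is configured entirely through a :class:`ModelConfig`:
resource counts (ward beds, EP labs, on-duty electrophysiologists), the
working calendar, negative-binomial daily-arrival moments for the three
patient classes (TEP: target EP patients treated in the EP labs; CLEP:
catheter-lab EP patients; NEP: non-EP cardiology patients), and
per-procedure-type duration summaries (operative time, lab clean-up,
length of stay, pre-operative stay) given as mean/SD/min/max.

Configurations round-trip through YAML (:func:`load_config` /
:func:`write_config`); :func:`default_config` returns the packaged
configuration of a large Chinese tertiary cardiology department: 87 ward
beds, two EP labs open 08:00-22:00 on workdays, two electrophysiologists
on duty per workday, and eleven EP procedure types.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "WEEKDAYS",
    "PATIENT_CLASSES",
    "ConfigError",
    "ValidationError",
    "DurationSpec",
    "ArrivalSpec",
    "ProcedureClass",
    "WeekdayAllocation",
    "Calendar",
    "Horizon",
    "ResourceSet",
    "ModelConfig",
    "load_config",
    "write_config",
    "default_config",
    "parse_time_of_day",
    "format_time_of_day",
]

WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
PATIENT_CLASSES = ("TEP", "CLEP", "NEP")

#: Seed used when a configuration file omits ``seed``.
DEFAULT_SEED = 20220501


class ConfigError(Exception):
    """A configuration file could not be read or parsed."""


class ValidationError(ConfigError):
    """A configuration value violates a model invariant."""


def parse_time_of_day(value: str) -> int:
    """Parse a 24-hour ``"HH:MM"`` string into minutes after midnight."""
    try:
        hh, mm = value.split(":")
        hh_i, mm_i = int(hh), int(mm)
    except (ValueError, AttributeError) as exc:
        raise ValidationError(f"not a valid HH:MM time of day: {value!r}") from exc
    if not (0 <= hh_i < 24 and 0 <= mm_i < 60):
        raise ValidationError(f"time of day out of range: {value!r}")
    return 60 * hh_i + mm_i


def format_time_of_day(minutes: int) -> str:
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


@dataclass(frozen=True)
class DurationSpec:
    """Four-number summary (mean, SD, min, max) of a positive duration.

    ``units`` is ``"days"`` for stays and ``"minutes"`` for operative and
    clean-up times.  ``sd == 0`` denotes a constant duration, in which case
    ``min == mean == max`` is required.
    """

    mean: float
    sd: float
    min: float
    max: float
    units: str = "days"

    def __post_init__(self) -> None:
        if self.units not in ("days", "minutes"):
            raise ValidationError(f"unknown duration units: {self.units!r}")
        if self.sd < 0:
            raise ValidationError(f"duration SD must be >= 0, got {self.sd}")
        if self.min < 0:
            raise ValidationError(f"duration min must be >= 0, got {self.min}")
        if not (self.min <= self.mean <= self.max):
            raise ValidationError(
                f"duration mean {self.mean} outside [{self.min}, {self.max}]"
            )
        if self.sd == 0 and not (self.min == self.mean == self.max):
            raise ValidationError(
                f"constant duration (sd=0) requires min == mean == max, "
                f"got ({self.min}, {self.mean}, {self.max})"
            )

    @property
    def is_constant(self) -> bool:
        return self.sd == 0


@dataclass(frozen=True)
class ArrivalSpec:
    """Daily-arrival moments for one patient class.

    ``regime`` distinguishes the empirical negative-binomial arrival stream
    from the synthetic bed-saturating stream used in capacity scenarios;
    saturation only ever applies to TEP patients.
    """

    patient_class: str
    mean: float
    sd: float
    regime: str = "empirical"

    def __post_init__(self) -> None:
        if self.patient_class not in PATIENT_CLASSES:
            raise ValidationError(f"unknown patient class: {self.patient_class!r}")
        if self.mean <= 0:
            raise ValidationError(f"arrival mean must be > 0, got {self.mean}")
        if self.sd < 0:
            raise ValidationError(f"arrival SD must be >= 0, got {self.sd}")
        if self.regime not in ("empirical", "saturating"):
            raise ValidationError(f"unknown arrival regime: {self.regime!r}")
        if self.regime == "saturating" and self.patient_class != "TEP":
            raise ValidationError("saturating arrivals apply only to TEP patients")


@dataclass(frozen=True)
class ProcedureClass:
    """One EP procedure type: its admission-mix share and duration summaries."""

    name: str
    proportion: float
    operative_time: DurationSpec
    cleanup: DurationSpec
    length_of_stay: DurationSpec
    preop_stay: DurationSpec

    def __post_init__(self) -> None:
        if not (0 < self.proportion <= 1):
            raise ValidationError(
                f"proportion for {self.name!r} must be in (0, 1], got {self.proportion}"
            )
        for spec, units in (
            (self.operative_time, "minutes"),
            (self.cleanup, "minutes"),
            (self.length_of_stay, "days"),
            (self.preop_stay, "days"),
        ):
            if spec.units != units:
                raise ValidationError(
                    f"{self.name!r}: expected {units} units, got {spec.units!r}"
                )
        if self.preop_stay.min > self.length_of_stay.max:
            raise ValidationError(
                f"{self.name!r}: pre-op minimum {self.preop_stay.min} exceeds "
                f"length-of-stay maximum {self.length_of_stay.max}"
            )


@dataclass(frozen=True)
class WeekdayAllocation:
    """Share of the day's procedures assigned to each on-duty physician slot."""

    weekday: str
    p_first: float
    p_second: float

    def __post_init__(self) -> None:
        if self.weekday not in WEEKDAYS:
            raise ValidationError(f"unknown weekday: {self.weekday!r}")
        for p in (self.p_first, self.p_second):
            if not (0 <= p <= 1):
                raise ValidationError(f"allocation probability {p} outside [0, 1]")
        if abs(self.p_first + self.p_second - 1.0) > 1e-9:
            raise ValidationError(
                f"{self.weekday} allocation {self.p_first}+{self.p_second} != 1"
            )


@dataclass(frozen=True)
class Calendar:
    """Working calendar: workdays, lab opening hours, daily arrival instant."""

    workdays: tuple[str, ...] = ("Mon", "Tue", "Wed", "Thu", "Fri")
    lab_open: str = "08:00"
    lab_close: str = "22:00"
    arrival_time: str = "07:00"
    start_weekday: str = "Sun"

    def __post_init__(self) -> None:
        for wd in self.workdays:
            if wd not in WEEKDAYS:
                raise ValidationError(f"unknown workday: {wd!r}")
        if not self.workdays:
            raise ValidationError("calendar needs at least one workday")
        if self.start_weekday not in WEEKDAYS:
            raise ValidationError(f"unknown start weekday: {self.start_weekday!r}")
        if self.lab_open_min >= self.lab_close_min:
            raise ValidationError(
                f"lab_open {self.lab_open!r} must precede lab_close {self.lab_close!r}"
            )
        if self.arrival_min >= self.lab_open_min:
            raise ValidationError(
                f"arrival_time {self.arrival_time!r} must precede lab_open "
                f"{self.lab_open!r}"
            )

    @property
    def lab_open_min(self) -> int:
        return parse_time_of_day(self.lab_open)

    @property
    def lab_close_min(self) -> int:
        return parse_time_of_day(self.lab_close)

    @property
    def arrival_min(self) -> int:
        return parse_time_of_day(self.arrival_time)

    def weekday_of(self, day: int) -> str:
        """Weekday name of 1-based simulation day ``day``."""
        start = WEEKDAYS.index(self.start_weekday)
        return WEEKDAYS[(start + day - 1) % 7]

    def is_workday(self, day: int) -> bool:
        return self.weekday_of(day) in self.workdays

    def next_workday(self, day: int) -> int:
        """Smallest workday >= ``day``."""
        while not self.is_workday(day):
            day += 1
        return day


@dataclass(frozen=True)
class Horizon:
    """Simulation horizon: warm-up days, observation days, replications."""

    warmup_days: int = 10
    observation_days: int = 61
    replications: int = 1000

    def __post_init__(self) -> None:
        for name in ("warmup_days", "observation_days", "replications"):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ValidationError(f"{name} must be a positive integer, got {v!r}")


@dataclass(frozen=True)
class ResourceSet:
    beds: int
    labs: int
    physicians_on_duty: int = 2

    def __post_init__(self) -> None:
        for name in ("beds", "labs", "physicians_on_duty"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValidationError(f"{name} must be an integer >= 1, got {v!r}")


@dataclass(frozen=True)
class ModelConfig:
    """A complete, validated set of model inputs.

    ``bed_policy`` controls what an arrival finding every ward bed occupied
    does: ``"queue"`` (default) joins a FIFO waiting list and is admitted at
    a later morning turnover; ``"balk"`` leaves the model unserved.
    """

    calendar: Calendar
    horizon: Horizon
    resources: ResourceSet
    arrivals: Mapping[str, ArrivalSpec]
    procedure_classes: tuple[ProcedureClass, ...]
    weekday_allocations: Mapping[str, WeekdayAllocation]
    clep_los: DurationSpec
    nep_los: DurationSpec
    seed: int = DEFAULT_SEED
    bed_policy: str = "queue"

    def __post_init__(self) -> None:
        if self.bed_policy not in ("queue", "balk"):
            raise ValidationError(f"unknown bed policy: {self.bed_policy!r}")
        for cls in PATIENT_CLASSES:
            if cls not in self.arrivals:
                raise ValidationError(f"missing arrival spec for class {cls}")
            if self.arrivals[cls].patient_class != cls:
                raise ValidationError(f"arrival spec mismatch for class {cls}")
        if not self.procedure_classes:
            raise ValidationError("at least one procedure class is required")
        total = sum(pc.proportion for pc in self.procedure_classes)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"procedure-class proportions sum to {total}, expected 1 "
                "(normalize before constructing ModelConfig)"
            )
        names = [pc.name for pc in self.procedure_classes]
        if len(set(names)) != len(names):
            raise ValidationError("procedure-class names must be unique")
        for wd in self.calendar.workdays:
            if wd not in self.weekday_allocations:
                raise ValidationError(f"missing weekday allocation for {wd}")
        for spec in (self.clep_los, self.nep_los):
            if spec.units != "days":
                raise ValidationError("CLEP/NEP length of stay must be in days")

    def procedure_class(self, name: str) -> ProcedureClass:
        for pc in self.procedure_classes:
            if pc.name == name:
                return pc
        raise KeyError(name)


# ---------------------------------------------------------------------------
# YAML (de)serialization


def _require(mapping: Mapping, key: str, context: str):
    if key not in mapping:
        raise ConfigError(f"missing required key {key!r} in {context}")
    return mapping[key]


def _duration_from_dict(d: Mapping, units: str, context: str,
                        default_bounds: bool = False) -> DurationSpec:
    if not isinstance(d, Mapping):
        raise ConfigError(f"expected a mapping for {context}, got {d!r}")
    mean = float(_require(d, "mean", context))
    sd = float(_require(d, "sd", context))
    if default_bounds:
        # CLEP/NEP stays: only moments are given; bound at 1 day and a
        # 6-sigma ceiling to keep the lognormal tail realistic.
        lo = float(d.get("min", 1.0))
        hi = float(d.get("max", mean + 6.0 * sd))
    else:
        lo = float(_require(d, "min", context))
        hi = float(_require(d, "max", context))
    return DurationSpec(mean=mean, sd=sd, min=lo, max=hi, units=units)


def config_from_dict(raw: Mapping) -> ModelConfig:
    """Build and validate a :class:`ModelConfig` from a parsed YAML mapping.

    Optional sections fall back to the documented defaults; procedure-class
    proportions are normalized to sum to one.
    """
    if not isinstance(raw, Mapping):
        raise ConfigError("configuration root must be a mapping")

    cal_d = raw.get("calendar", {}) or {}
    calendar = Calendar(
        workdays=tuple(cal_d.get("workdays", ("Mon", "Tue", "Wed", "Thu", "Fri"))),
        lab_open=str(cal_d.get("lab_open", "08:00")),
        lab_close=str(cal_d.get("lab_close", "22:00")),
        arrival_time=str(cal_d.get("arrival_time", "07:00")),
        start_weekday=str(cal_d.get("start_weekday", "Sun")),
    )
    hor_d = raw.get("horizon", {}) or {}
    horizon = Horizon(
        warmup_days=int(hor_d.get("warmup_days", 10)),
        observation_days=int(hor_d.get("observation_days", 61)),
        replications=int(hor_d.get("replications", 1000)),
    )
    res_d = _require(raw, "resources", "configuration")
    resources_ = ResourceSet(
        beds=int(_require(res_d, "beds", "resources")),
        labs=int(_require(res_d, "labs", "resources")),
        physicians_on_duty=int(res_d.get("physicians_on_duty", 2)),
    )
    arr_d = _require(raw, "arrivals", "configuration")
    arrivals = {}
    for cls in PATIENT_CLASSES:
        spec_d = _require(arr_d, cls, "arrivals")
        arrivals[cls] = ArrivalSpec(
            patient_class=cls,
            mean=float(_require(spec_d, "mean", f"arrivals.{cls}")),
            sd=float(_require(spec_d, "sd", f"arrivals.{cls}")),
        )

    pcs_raw = _require(raw, "procedure_classes", "configuration")
    if not pcs_raw:
        raise ConfigError("procedure_classes must be a non-empty list")
    raw_props = [float(_require(d, "proportion", "procedure_classes")) for d in pcs_raw]
    prop_total = sum(raw_props)
    if prop_total <= 0:
        raise ConfigError("procedure-class proportions must sum to a positive value")
    pcs = []
    for d, prop in zip(pcs_raw, raw_props):
        name = str(_require(d, "name", "procedure_classes"))
        pcs.append(
            ProcedureClass(
                name=name,
                proportion=prop / prop_total,
                operative_time=_duration_from_dict(
                    _require(d, "operative_time", name), "minutes", f"{name}.operative_time"
                ),
                cleanup=_duration_from_dict(
                    _require(d, "cleanup", name), "minutes", f"{name}.cleanup"
                ),
                length_of_stay=_duration_from_dict(
                    _require(d, "length_of_stay", name), "days", f"{name}.length_of_stay"
                ),
                preop_stay=_duration_from_dict(
                    _require(d, "preop_stay", name), "days", f"{name}.preop_stay"
                ),
            )
        )

    alloc_d = _require(raw, "weekday_allocations", "configuration")
    allocations = {}
    for wd, pair in alloc_d.items():
        if not isinstance(pair, Sequence) or len(pair) != 2:
            raise ConfigError(f"weekday_allocations.{wd} must be a [p_first, p_second] pair")
        allocations[wd] = WeekdayAllocation(
            weekday=wd, p_first=float(pair[0]), p_second=float(pair[1])
        )

    clep_los = _duration_from_dict(
        _require(raw, "clep_los", "configuration"), "days", "clep_los", default_bounds=True
    )
    nep_los = _duration_from_dict(
        _require(raw, "nep_los", "configuration"), "days", "nep_los", default_bounds=True
    )

    return ModelConfig(
        calendar=calendar,
        horizon=horizon,
        resources=resources_,
        arrivals=arrivals,
        procedure_classes=tuple(pcs),
        weekday_allocations=allocations,
        clep_los=clep_los,
        nep_los=nep_los,
        seed=int(raw.get("seed", DEFAULT_SEED)),
        bed_policy=str(raw.get("bed_policy", "queue")),
    )


def config_to_dict(config: ModelConfig) -> dict:
    """Inverse of :func:`config_from_dict` (field-exact round trip)."""

    def dur(d: DurationSpec) -> dict:
        return {"mean": d.mean, "sd": d.sd, "min": d.min, "max": d.max}

    return {
        "calendar": {
            "workdays": list(config.calendar.workdays),
            "lab_open": config.calendar.lab_open,
            "lab_close": config.calendar.lab_close,
            "arrival_time": config.calendar.arrival_time,
            "start_weekday": config.calendar.start_weekday,
        },
        "horizon": {
            "warmup_days": config.horizon.warmup_days,
            "observation_days": config.horizon.observation_days,
            "replications": config.horizon.replications,
        },
        "resources": {
            "beds": config.resources.beds,
            "labs": config.resources.labs,
            "physicians_on_duty": config.resources.physicians_on_duty,
        },
        "arrivals": {
            cls: {"mean": spec.mean, "sd": spec.sd}
            for cls, spec in config.arrivals.items()
        },
        "procedure_classes": [
            {
                "name": pc.name,
                "proportion": pc.proportion,
                "operative_time": dur(pc.operative_time),
                "cleanup": dur(pc.cleanup),
                "length_of_stay": dur(pc.length_of_stay),
                "preop_stay": dur(pc.preop_stay),
            }
            for pc in config.procedure_classes
        ],
        "weekday_allocations": {
            wd: [alloc.p_first, alloc.p_second]
            for wd, alloc in config.weekday_allocations.items()
        },
        "clep_los": dur(config.clep_los),
        "nep_los": dur(config.nep_los),
        "seed": config.seed,
        "bed_policy": config.bed_policy,
    }


def load_config(path: str | Path) -> ModelConfig:
    """Read, validate and default-fill a YAML model configuration."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read configuration file {path}: {exc}") from exc
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    return config_from_dict(raw)


def write_config(config: ModelConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=False, allow_unicode=True)
    )


def default_config() -> ModelConfig:
    """The packaged department configuration (87 beds, 2 EP labs, 11 types)."""
    with resources.as_file(
        resources.files("eplabsim").joinpath("data/default_config.yaml")
    ) as p:
        return load_config(p)
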