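"""Estimate a model configuration from a raw patient-log table.

The calibration path mirrors how the packaged inputs would be rebuilt from
a department's admission log: one row per patient with class, admission
and discharge dates, and -- for EP-lab (TEP) patients -- procedure type,
date, start/end clock times and the performing physician.  From such a log
the estimator derives daily-arrival moments per class, per-procedure-type
duration summaries, CLEP/NEP length-of-stay moments, and the weekday
splits between the two busiest physicians.  Clean-up times do not appear
in admission logs and are taken from a template configuration instead.

``generate_synthetic_log`` draws a well-formed log from a configuration's
own distributions; composing it with ``estimate_config`` gives the
parameter-recovery round trip used to test the estimator.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import distributions as dists
from .input_model import (
    ArrivalSpec,
    Calendar,
    DurationSpec,
    ModelConfig,
    ProcedureClass,
    WeekdayAllocation,
    default_config,
)

__all__ = [
    "LOG_COLUMNS",
    "PatientLogRow",
    "CalibrationError",
    "read_log",
    "write_log",
    "generate_synthetic_log",
    "estimate_config",
]

LOG_COLUMNS = (
    "patient_id",
    "patient_class",
    "admission_date",
    "discharge_date",
    "procedure_class",
    "procedure_date",
    "procedure_start",
    "procedure_end",
    "physician_id",
)

_WD = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


class CalibrationError(ValueError):
    """The patient log cannot support the requested estimation."""


@dataclass(frozen=True)
class PatientLogRow:
    """One admission record; EP-lab fields are None for CLEP/NEP patients."""

    patient_id: str
    patient_class: str
    admission_date: dt.date
    discharge_date: dt.date
    procedure_class: str | None = None
    procedure_date: dt.date | None = None
    procedure_start: str | None = None  # "HH:MM"
    procedure_end: str | None = None
    physician_id: str | None = None

    def __post_init__(self) -> None:
        if self.admission_date > self.discharge_date:
            raise CalibrationError(
                f"{self.patient_id}: admission after discharge"
            )
        if self.patient_class == "TEP":
            if self.procedure_date is None:
                raise CalibrationError(f"{self.patient_id}: TEP row lacks procedure date")
            if not (self.admission_date <= self.procedure_date <= self.discharge_date):
                raise CalibrationError(
                    f"{self.patient_id}: procedure date outside the stay"
                )


def read_log(path: str | Path) -> pd.DataFrame:
    """Read a CSV patient log, enforcing the exact documented header."""
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise CalibrationError(f"empty patient log: {path}") from exc
    if tuple(df.columns) != LOG_COLUMNS:
        raise CalibrationError(
            f"unexpected log header {tuple(df.columns)}; expected {LOG_COLUMNS}"
        )
    for col in ("admission_date", "discharge_date", "procedure_date"):
        df[col] = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
    return df


def write_log(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in ("admission_date", "discharge_date", "procedure_date"):
        if np.issubdtype(out[col].dtype, np.datetime64):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, columns=list(LOG_COLUMNS))


def _minutes(hhmm: str) -> int:
    h, m = hhmm.split(":")
    return 60 * int(h) + int(m)


def _hhmm(minutes: int) -> str:
    minutes = int(minutes) % 1440
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


def generate_synthetic_log(
    config: ModelConfig,
    n_days: int,
    seed: int,
    start_date: dt.date = dt.date(2022, 5, 1),
) -> pd.DataFrame:
    """Draw a synthetic admission log from a configuration's distributions.

    Each day's arrivals per class come from the fitted negative binomial;
    every admitted patient receives sampled stays (and, for TEP, procedure
    type, operative window and physician).  Procedure dates are placed
    exactly ``preop`` days after admission -- the generator emulates the
    log's marginal distributions, not the engine's queueing -- so the
    estimator round trip is unbiased.  Deterministic given ``seed``.
    """
    if n_days < 1:
        raise CalibrationError(f"n_days must be >= 1, got {n_days}")
    compiled_nb = {
        cls: dists.fit_negative_binomial(spec.mean, spec.sd)
        for cls, spec in config.arrivals.items()
    }
    classes = list(config.procedure_classes)
    # same mean-calibrated fits as the simulation engine, so the generated
    # log's realized means agree with the configuration's summaries
    op_p = [dists.fit_mean_calibrated(pc.operative_time) for pc in classes]
    los_p = [dists.fit_mean_calibrated(pc.length_of_stay) for pc in classes]
    pre_p = [dists.fit_mean_calibrated(pc.preop_stay) for pc in classes]
    clep_p = dists.fit_mean_calibrated(config.clep_los)
    nep_p = dists.fit_mean_calibrated(config.nep_los)
    cum = np.cumsum([pc.proportion for pc in classes])
    open_min = config.calendar.lab_open_min
    close_min = config.calendar.lab_close_min

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows: list[dict] = []
    pid = 0
    for day in range(n_days):
        adm = start_date + dt.timedelta(days=day)
        for cls, los_params in (("CLEP", clep_p), ("NEP", nep_p)):
            for _ in range(dists.sample_daily_arrivals(compiled_nb[cls], rng)):
                los = dists.sample_integer_days(los_params, rng)
                rows.append(
                    {
                        "patient_id": f"P{pid:05d}",
                        "patient_class": cls,
                        "admission_date": adm,
                        "discharge_date": adm + dt.timedelta(days=los),
                        "procedure_class": "",
                        "procedure_date": "",
                        "procedure_start": "",
                        "procedure_end": "",
                        "physician_id": "",
                    }
                )
                pid += 1
        for _ in range(dists.sample_daily_arrivals(compiled_nb["TEP"], rng)):
            u = rng.random() * cum[-1]
            k = min(int(np.searchsorted(cum, u, side="right")), len(classes) - 1)
            los = dists.sample_integer_days(los_p[k], rng)
            preop = dists.sample_preop_given_los(pre_p[k], los, rng)
            op_minutes = max(1, round(dists.sample_truncated(op_p[k], rng)))
            proc_date = adm + dt.timedelta(days=preop)
            latest_start = max(open_min + 1, close_min - op_minutes)
            start = int(rng.integers(open_min, latest_start))
            weekday = _WD[proc_date.weekday()]
            alloc = config.weekday_allocations.get(weekday)
            p_first = alloc.p_first if alloc is not None else 0.5
            rows.append(
                {
                    "patient_id": f"P{pid:05d}",
                    "patient_class": "TEP",
                    "admission_date": adm,
                    "discharge_date": adm + dt.timedelta(days=los),
                    "procedure_class": classes[k].name,
                    "procedure_date": proc_date,
                    "procedure_start": _hhmm(start),
                    "procedure_end": _hhmm(start + op_minutes),
                    "physician_id": "EP1" if rng.random() < p_first else "EP2",
                }
            )
            pid += 1
    df = pd.DataFrame(rows, columns=list(LOG_COLUMNS))
    for col in ("admission_date", "discharge_date", "procedure_date"):
        df[col] = pd.to_datetime(df[col], errors="coerce")
    return df


def _moments(values: np.ndarray, context: str) -> tuple[float, float, float, float]:
    if len(values) < 2:
        raise CalibrationError(
            f"{context}: need at least 2 complete records to estimate an SD "
            "(collect more data or merge this category)"
        )
    return (
        float(np.mean(values)),
        float(np.std(values, ddof=1)),
        float(np.min(values)),
        float(np.max(values)),
    )


def _daily_arrival_spec(df: pd.DataFrame, cls: str, span: pd.DatetimeIndex) -> ArrivalSpec:
    sub = df[df["patient_class"] == cls]
    counts = (
        sub.groupby("admission_date").size().reindex(span, fill_value=0).to_numpy()
    )
    mean, sd, _, _ = _moments(counts, f"daily {cls} arrivals")
    return ArrivalSpec(patient_class=cls, mean=mean, sd=sd)


def estimate_config(
    log: pd.DataFrame,
    calendar: Calendar | None = None,
    template: ModelConfig | None = None,
) -> ModelConfig:
    """Estimate every learnable model input from a patient log.

    Arrival moments are computed over all calendar days spanned by the
    log's admissions (zero-arrival days included).  Durations use whole-day
    date differences (a same-day discharge counts as a 1-day stay) and
    operative minutes from the recorded clock times.  Weekday physician
    splits come from the two most frequent physician ids per weekday;
    procedures by any other physician are folded into the closer slot with
    a warning.  Resources, horizon, calendar and clean-up times are taken
    from ``template`` (default: the packaged configuration).
    """
    template = template or default_config()
    calendar = calendar or template.calendar

    df = log.copy()
    complete = df["admission_date"].notna() & df["discharge_date"].notna()
    tep_mask = df["patient_class"] == "TEP"
    complete &= ~tep_mask | df["procedure_date"].notna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} incomplete log rows", stacklevel=2)
        df = df[complete]
    for cls in ("TEP", "CLEP", "NEP"):
        if not (df["patient_class"] == cls).any():
            raise CalibrationError(f"patient log contains no {cls} rows")

    span = pd.date_range(df["admission_date"].min(), df["admission_date"].max(), freq="D")
    arrivals = {cls: _daily_arrival_spec(df, cls, span) for cls in ("TEP", "CLEP", "NEP")}

    def los_days(sub: pd.DataFrame) -> np.ndarray:
        days = (sub["discharge_date"] - sub["admission_date"]).dt.days.to_numpy()
        return np.maximum(days, 1)

    def day_spec(values: np.ndarray, context: str) -> DurationSpec:
        mean, sd, lo, hi = _moments(values, context)
        if sd == 0:
            lo = hi = mean
        return DurationSpec(mean=mean, sd=sd, min=lo, max=hi, units="days")

    tep = df[df["patient_class"] == "TEP"]
    template_cleanup = {pc.name: pc.cleanup for pc in template.procedure_classes}
    fallback_cleanup = DurationSpec(mean=7.0, sd=3.0, min=1.0, max=30.0, units="minutes")
    pcs: list[ProcedureClass] = []
    for name, sub in tep.groupby("procedure_class", sort=True):
        op_minutes = (
            sub["procedure_end"].map(_minutes) - sub["procedure_start"].map(_minutes)
        ).to_numpy(dtype=float)
        op_minutes = np.where(op_minutes <= 0, op_minutes + 1440, op_minutes)  # overnight
        m, s, lo, hi = _moments(op_minutes, f"{name} operative time")
        if s == 0:
            lo = hi = m
        preop = (sub["procedure_date"] - sub["admission_date"]).dt.days.to_numpy()
        pre_m, pre_s, pre_lo, pre_hi = _moments(preop, f"{name} pre-operative stay")
        if pre_s == 0:
            pre_lo = pre_hi = pre_m
        pcs.append(
            ProcedureClass(
                name=str(name),
                proportion=len(sub) / len(tep),
                operative_time=DurationSpec(m, s, lo, hi, units="minutes"),
                cleanup=template_cleanup.get(str(name), fallback_cleanup),
                length_of_stay=day_spec(los_days(sub), f"{name} length of stay"),
                preop_stay=DurationSpec(pre_m, pre_s, pre_lo, pre_hi, units="days"),
            )
        )

    allocations: dict[str, WeekdayAllocation] = {}
    tep_weekdays = tep["procedure_date"].dt.weekday.map(lambda i: _WD[i])
    for wd in calendar.workdays:
        phys = tep.loc[tep_weekdays == wd, "physician_id"].value_counts()
        if len(phys) == 0:
            warnings.warn(f"no {wd} procedures in log; defaulting to a 50/50 split",
                          stacklevel=2)
            allocations[wd] = WeekdayAllocation(weekday=wd, p_first=0.5, p_second=0.5)
            continue
        top = phys.iloc[:2]
        n_first = int(top.iloc[0])
        n_second = int(top.iloc[1]) if len(top) > 1 else 0
        extras = phys.iloc[2:]
        if len(extras):
            warnings.warn(
                f"{wd}: folding {int(extras.sum())} procedures by "
                f"{len(extras)} additional physician(s) into the two slots",
                stacklevel=2,
            )
            for count in extras:
                # fold into the slot currently closer in volume
                if abs(n_first - count) <= abs(n_second - count):
                    n_first += int(count)
                else:
                    n_second += int(count)
        total = n_first + n_second
        allocations[wd] = WeekdayAllocation(
            weekday=wd, p_first=n_first / total, p_second=n_second / total
        )

    def moments_only_spec(values: np.ndarray, context: str) -> DurationSpec:
        mean, sd, _, _ = _moments(values, context)
        if sd == 0:
            return DurationSpec(mean=mean, sd=0.0, min=mean, max=mean, units="days")
        return DurationSpec(mean=mean, sd=sd, min=min(1.0, mean),
                            max=mean + 6.0 * sd, units="days")

    clep = df[df["patient_class"] == "CLEP"]
    nep = df[df["patient_class"] == "NEP"]
    return ModelConfig(
        calendar=calendar,
        horizon=template.horizon,
        resources=template.resources,
        arrivals=arrivals,
        procedure_classes=tuple(pcs),
        weekday_allocations=allocations,
        clep_los=moments_only_spec(los_days(clep), "CLEP length of stay"),
        nep_los=moments_only_spec(los_days(nep), "NEP length of stay"),
        seed=template.seed,
    )
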