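"""Day-structured discrete-event core of the inpatient EP model.

Each simulated day unfolds in a fixed order at the morning turnover
instant: (1) patients whose stay ends today are discharged and their beds
freed; (2) admissions: first the FIFO waiting list from earlier days, then
the day's arrivals while free beds last (in a random interleaved order of
the three classes under the empirical regime; CLEP/NEP first and then
bed-saturating TEP demand under the saturating regime).  Arrivals who find
no free bed join the waiting list under the default ``queue`` bed policy,
or leave the model unserved under the ``balk`` policy; (3) on
workdays the EP labs run: each on-duty physician slot serves its queue
FIFO, a procedure may start at any instant in [lab_open, lab_close) at
which both the assigned physician and some lab are free, runs to
completion even past closing, releases the physician at once and the lab
after clean-up.  Patients not started by closing roll to the next workday
and re-draw their physician slot from that day's allocation.

TEP patients are admitted with a sampled length of stay, pre-operative
stay (capped at the LOS), operative time and clean-up time; their
procedure is planned ``preop`` days after admission (advanced to the next
workday if needed) and they are discharged ``LOS - preop`` days after the
realized procedure day.  CLEP and NEP patients only occupy beds for their
sampled stay.  Time is integer days plus continuous minutes within a day.

Randomness is organized as named substreams (arrivals, patient durations,
admission order, physician assignment) spawned from a single seed, so runs
are reproducible and scenarios can share common random numbers.
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass, field

import numpy as np

from . import distributions as dists
from . import scenarios as _scenarios
from .input_model import Calendar, ModelConfig

__all__ = [
    "Patient",
    "ReplicationResult",
    "CompiledInputs",
    "plan_procedure_day",
    "interleave_admissions",
    "schedule_lab_day",
    "run_replication",
]

MINUTES_PER_DAY = 1440


@dataclass
class Patient:
    """One simulated inpatient and its realized event times."""

    id: int
    patient_class: str
    arrival_day: int
    los_days: int
    procedure_class: str | None = None
    preop_days: int | None = None
    operative_minutes: float | None = None
    cleanup_minutes: float | None = None
    planned_day: int | None = None      # first planned procedure day (FIFO key)
    scheduled_day: int | None = None    # current queue day (= planned_day unless rolled)
    physician_slot: str | None = None
    procedure_day: int | None = None
    procedure_start: float | None = None  # minute of day
    procedure_end: float | None = None    # may exceed lab closing
    discharge_day: int | None = None

    def fifo_key(self) -> tuple[int, int, int]:
        return (self.planned_day, self.arrival_day, self.id)


@dataclass
class ReplicationResult:
    """Outputs of one replication.

    ``daily_discharges`` covers the observation window only (length
    ``observation_days``); ``total_tep_discharges`` is its sum.
    ``occupancy[d]`` is the number of occupied beds just after day ``d+1``'s
    admissions (whole horizon, warm-up included).  ``balked`` is nonzero
    only under the ``balk`` bed policy; ``queued`` counts arrivals that had
    to wait at least one day for a bed under the ``queue`` policy.
    """

    total_tep_discharges: int
    daily_discharges: np.ndarray
    balked: dict[str, int]
    occupancy: np.ndarray
    queued: dict[str, int] | None = None
    patients: list[Patient] | None = None
    trace: list[tuple] | None = None


class CompiledInputs:
    """Distribution parameters fitted once per (resolved) configuration.

    ``fit_mode`` selects how duration summaries become lognormals:
    ``"calibrated"`` (default) shifts the location so the *truncated* mean
    reproduces the tabulated mean; ``"plain"`` is the raw moment fit;
    ``"refit"`` solves for both truncated moments (may be infeasible for
    some summaries).
    """

    def __init__(self, config: ModelConfig, fit_mode: str = "calibrated"):
        if fit_mode == "calibrated":
            fit = dists.fit_mean_calibrated
        elif fit_mode == "plain":
            fit = dists.fit_truncated_lognormal
        elif fit_mode == "refit":
            fit = lambda spec: dists.fit_truncated_lognormal(spec, refit=True)
        else:
            raise ValueError(f"unknown fit_mode {fit_mode!r}")
        self.config = config
        self.calendar = config.calendar
        self.arrival_nb = {
            cls: dists.fit_negative_binomial(spec.mean, spec.sd)
            for cls, spec in config.arrivals.items()
        }
        self.classes = list(config.procedure_classes)
        self.cum_props = np.cumsum([pc.proportion for pc in self.classes])
        self.op_params = [fit(pc.operative_time) for pc in self.classes]
        self.cleanup_params = [fit(pc.cleanup) for pc in self.classes]
        self.los_params = [fit(pc.length_of_stay) for pc in self.classes]
        self.preop_params = [fit(pc.preop_stay) for pc in self.classes]
        self.clep_los = fit(config.clep_los)
        self.nep_los = fit(config.nep_los)
        self.p_first = {
            wd: alloc.p_first for wd, alloc in config.weekday_allocations.items()
        }

    def draw_class_index(self, rng: np.random.Generator) -> int:
        u = rng.random() * self.cum_props[-1]
        return min(int(np.searchsorted(self.cum_props, u, side="right")),
                   len(self.classes) - 1)


def plan_procedure_day(arrival_day: int, preop_days: int, calendar: Calendar) -> int:
    """Earliest candidate procedure day: ``arrival_day + preop_days``,
    advanced to the next workday if the labs are closed on that day."""
    return calendar.next_workday(arrival_day + preop_days)


def interleave_admissions(
    counts: dict[str, int], free_beds: int, rng: np.random.Generator
) -> tuple[dict[str, int], dict[str, int]]:
    """Admit arrivals of several classes in a random interleaved order.

    Returns (admitted, balked) counts per class; the first ``free_beds``
    patients of the shuffled arrival sequence are admitted, the rest balk.
    """
    labels: list[str] = []
    for cls, n in counts.items():
        labels.extend([cls] * n)
    rng.shuffle(labels)
    admitted = {cls: 0 for cls in counts}
    balked = {cls: 0 for cls in counts}
    for i, cls in enumerate(labels):
        if i < free_beds:
            admitted[cls] += 1
        else:
            balked[cls] += 1
    return admitted, balked


def schedule_lab_day(
    slot_queues: dict[str, deque],
    lab_free_abs: list[float],
    day: int,
    calendar: Calendar,
) -> tuple[list[tuple[Patient, float, float, int]], list[Patient]]:
    """Run one workday of EP-lab activity.

    ``slot_queues`` maps physician-slot names to FIFO deques of patients;
    ``lab_free_abs`` holds each lab's next-free time in absolute minutes
    (mutated in place, clean-up included).  A procedure starts at the
    earliest instant >= lab_open at which its slot's physician and any lab
    are free, provided that instant is strictly before lab_close; ties
    between slots go to the patient first in FIFO order.  Returns the
    started procedures as (patient, start_abs, end_abs, lab_index) and the
    patients rolled to the next workday.
    """
    open_abs = day * MINUTES_PER_DAY + calendar.lab_open_min
    close_abs = day * MINUTES_PER_DAY + calendar.lab_close_min
    phys_free = {slot: float(open_abs) for slot in slot_queues}
    started: list[tuple[Patient, float, float, int]] = []

    while True:
        best = None
        for slot, queue in slot_queues.items():
            if not queue:
                continue
            lab_idx = min(range(len(lab_free_abs)),
                          key=lambda i: (max(lab_free_abs[i], open_abs), i))
            cand = max(phys_free[slot], lab_free_abs[lab_idx], open_abs)
            key = (cand, *queue[0].fifo_key())
            if best is None or key < best[0]:
                best = (key, slot, lab_idx, cand)
        if best is None:
            rolled: list[Patient] = []
            break
        _, slot, lab_idx, cand = best
        if cand >= close_abs:
            # nothing can start before closing: roll every remaining patient
            rolled = [p for q in slot_queues.values() for p in q]
            rolled.sort(key=Patient.fifo_key)
            for q in slot_queues.values():
                q.clear()
            break
        patient = slot_queues[slot].popleft()
        end = cand + patient.operative_minutes
        phys_free[slot] = end  # physician released at completion
        lab_free_abs[lab_idx] = end + patient.cleanup_minutes
        started.append((patient, cand, end, lab_idx))
    return started, rolled


def run_replication(
    config: ModelConfig,
    scenario: _scenarios.ScenarioSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
    trace: bool = False,
    compiled: CompiledInputs | None = None,
) -> ReplicationResult:
    """Simulate one full horizon (warm-up + observation window).

    CLEP/NEP flows run from day 1; TEP flows start on day ``warmup + 1``.
    Only TEP discharges whose discharge day falls inside the observation
    window are counted.  Deterministic given (config, scenario, seed).
    ``compiled`` may carry pre-fitted distributions for the *resolved*
    configuration to avoid refitting per replication.
    """
    scenario = scenario or _scenarios.validation_scenario()
    if compiled is None:
        compiled = CompiledInputs(_scenarios.resolve_config(config, scenario))
    cfg = compiled.config
    cal = compiled.calendar
    saturating = scenario.tep_regime == "saturating"

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_arrivals, rng_patients, rng_admission, rng_phys = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    warmup = cfg.horizon.warmup_days
    horizon = warmup + cfg.horizon.observation_days
    beds = cfg.resources.beds
    slots = [chr(ord("A") + i) for i in range(cfg.resources.physicians_on_duty)]

    free_beds = beds
    queue_policy = cfg.bed_policy == "queue"
    bed_queue: deque[str] = deque()  # class labels waiting for a bed (FIFO)
    bed_releases: dict[int, int] = defaultdict(int)
    pending: dict[int, list[Patient]] = defaultdict(list)
    lab_free_abs = [0.0] * cfg.resources.labs
    daily = np.zeros(cfg.horizon.observation_days, dtype=np.int64)
    occupancy = np.zeros(horizon, dtype=np.int64)
    balked = {cls: 0 for cls in ("TEP", "CLEP", "NEP")}
    queued = {cls: 0 for cls in ("TEP", "CLEP", "NEP")}
    events: list[tuple] | None = [] if trace else None
    tep_patients: list[Patient] | None = [] if trace else None
    next_id = 0

    def admit_ward_patient(cls: str, day: int, los: int) -> None:
        # CLEP/NEP: bed occupant only; bed freed at the discharge-day turnover
        bed_releases[day + los] += 1
        if events is not None:
            events.append(("admit", cls, day))

    def admit_tep_patient(day: int) -> None:
        nonlocal next_id
        k = compiled.draw_class_index(rng_patients)
        los = dists.sample_integer_days(compiled.los_params[k], rng_patients)
        preop = dists.sample_preop_given_los(compiled.preop_params[k], los, rng_patients)
        patient = Patient(
            id=next_id,
            patient_class="TEP",
            arrival_day=day,
            los_days=los,
            procedure_class=compiled.classes[k].name,
            preop_days=preop,
            operative_minutes=dists.sample_truncated(compiled.op_params[k], rng_patients),
            cleanup_minutes=dists.sample_truncated(compiled.cleanup_params[k], rng_patients),
        )
        next_id += 1
        patient.planned_day = plan_procedure_day(day, preop, cal)
        patient.scheduled_day = patient.planned_day
        pending[patient.planned_day].append(patient)
        if tep_patients is not None:
            tep_patients.append(patient)
        if events is not None:
            events.append(("admit", "TEP", day))

    def admit(cls: str, day: int) -> None:
        if cls == "TEP":
            admit_tep_patient(day)
        else:
            los_params = compiled.clep_los if cls == "CLEP" else compiled.nep_los
            admit_ward_patient(cls, day, dists.sample_integer_days(los_params, rng_patients))

    def overflow(cls: str, n: int) -> None:
        if n <= 0:
            return
        if queue_policy:
            queued[cls] += n
            bed_queue.extend([cls] * n)
        else:
            balked[cls] += n

    for day in range(1, horizon + 1):
        # --- morning turnover: discharges free beds before admissions
        free_beds += bed_releases.pop(day, 0)

        # --- admissions: waiting list first, then today's arrivals
        while bed_queue and free_beds > 0:
            admit(bed_queue.popleft(), day)
            free_beds -= 1

        n_clep = dists.sample_daily_arrivals(compiled.arrival_nb["CLEP"], rng_arrivals)
        n_nep = dists.sample_daily_arrivals(compiled.arrival_nb["NEP"], rng_arrivals)
        tep_day = day > warmup
        if saturating:
            # CLEP and NEP admitted first; TEP then fills every free bed
            for cls, n in (("CLEP", n_clep), ("NEP", n_nep)):
                n_adm = min(n, free_beds)
                overflow(cls, n - n_adm)
                for _ in range(n_adm):
                    admit(cls, day)
                free_beds -= n_adm
            if tep_day:
                for _ in range(free_beds):
                    admit_tep_patient(day)
                free_beds = 0
        else:
            n_tep = (
                dists.sample_daily_arrivals(compiled.arrival_nb["TEP"], rng_arrivals)
                if tep_day
                else 0
            )
            admitted, excess = interleave_admissions(
                {"CLEP": n_clep, "NEP": n_nep, "TEP": n_tep}, free_beds, rng_admission
            )
            for cls, n in excess.items():
                overflow(cls, n)
            for cls, n_adm in admitted.items():
                for _ in range(n_adm):
                    admit(cls, day)
            free_beds -= sum(admitted.values())
        occupancy[day - 1] = beds - free_beds

        # --- EP-lab day
        if cal.is_workday(day) and pending.get(day):
            queue = sorted(pending.pop(day), key=Patient.fifo_key)
            weekday = cal.weekday_of(day)
            p_first = compiled.p_first[weekday]
            slot_queues: dict[str, deque] = {slot: deque() for slot in slots}
            for patient in queue:
                if len(slots) == 2:
                    patient.physician_slot = "A" if rng_phys.random() < p_first else "B"
                else:
                    patient.physician_slot = slots[int(rng_phys.random() * len(slots))]
                slot_queues[patient.physician_slot].append(patient)
            started, rolled = schedule_lab_day(slot_queues, lab_free_abs, day, cal)
            for patient, start_abs, end_abs, lab_idx in started:
                patient.procedure_day = day
                patient.procedure_start = start_abs - day * MINUTES_PER_DAY
                patient.procedure_end = end_abs - day * MINUTES_PER_DAY
                postop = patient.los_days - patient.preop_days
                patient.discharge_day = day + postop
                # a same-day discharge keeps its bed until the next turnover
                bed_releases[patient.discharge_day if postop > 0 else day + 1] += 1
                if warmup < patient.discharge_day <= horizon:
                    daily[patient.discharge_day - warmup - 1] += 1
                if events is not None:
                    events.append(
                        ("procedure", patient.id, day, patient.procedure_start,
                         patient.procedure_end, lab_idx, patient.physician_slot)
                    )
            for patient in rolled:
                nxt = cal.next_workday(day + 1)
                patient.scheduled_day = nxt
                pending[nxt].append(patient)

    return ReplicationResult(
        total_tep_discharges=int(daily.sum()),
        daily_discharges=daily,
        balked=balked,
        occupancy=occupancy,
        queued=queued,
        patients=tep_patients,
        trace=events,
    )
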