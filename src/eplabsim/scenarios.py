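"""Capacity-limiting scenarios and process-improvement modifications.

Two base regimes bracket the department's bottlenecks:

* ``cls_wards_base`` -- fully occupied ward beds: the empirical resource
  counts are kept but TEP demand is saturated, i.e. after CLEP and NEP
  admissions every remaining free bed receives a TEP patient.
* ``cls_eplabs_base`` -- fully occupied EP labs: beds are raised to 110 and
  the labs cut to one, again with saturating TEP demand, so lab time rather
  than beds constrains throughput.

On top of a base regime, a :class:`DurationModification` shortens one phase
of the AF-ablation pathway.  For stay phases the reduction is expressed as
a percentage of the class's mean length of stay: that expected number of
days is removed from the pre-operative mean (floored at 1 day), the
post-operative side (by shrinking the LOS mean with the pre-op spec
untouched), or both proportionally.  Operative-time reductions scale the
whole operative-time distribution multiplicatively.  SDs are held fixed;
distributions are refit from the modified summaries at simulation time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .input_model import (
    DurationSpec,
    ModelConfig,
    ProcedureClass,
    ResourceSet,
    ValidationError,
)

__all__ = [
    "AF_ABLATION_CLASSES",
    "PHASES",
    "DurationModification",
    "ScenarioSpec",
    "validation_scenario",
    "cls_wards_base",
    "cls_eplabs_base",
    "apply_reduction",
    "resolve_config",
    "scenario_grid",
]

AF_ABLATION_CLASSES = ("Paroxysmal AF ablation", "Persistent AF ablation")
PHASES = ("preop", "postop", "both", "operative")


@dataclass(frozen=True)
class DurationModification:
    """Reduce one phase of selected procedure classes by ``reduction_pct``%.

    For ``preop``/``postop``/``both`` the percentage applies to the class's
    mean length of stay; for ``operative`` it scales the operative-time
    distribution directly.
    """

    phase: str
    reduction_pct: float
    target_classes: tuple[str, ...] = AF_ABLATION_CLASSES

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        if not (0 < self.reduction_pct < 100):
            raise ValidationError(
                f"reduction_pct must be in (0, 100), got {self.reduction_pct}"
            )
        if not self.target_classes:
            raise ValidationError("modification needs at least one target class")


@dataclass(frozen=True)
class ScenarioSpec:
    """A runnable experiment: resource overrides, arrival regime, modifications."""

    name: str
    tep_regime: str = "empirical"
    bed_override: int | None = None
    lab_override: int | None = None
    modifications: tuple[DurationModification, ...] = ()

    def __post_init__(self) -> None:
        if self.tep_regime not in ("empirical", "saturating"):
            raise ValidationError(f"unknown TEP regime {self.tep_regime!r}")
        for override in (self.bed_override, self.lab_override):
            if override is not None and override < 1:
                raise ValidationError(f"resource override must be >= 1, got {override}")


def validation_scenario() -> ScenarioSpec:
    """Empirical arrivals, unmodified resources: the validation run."""
    return ScenarioSpec(name="validation", tep_regime="empirical")


def cls_wards_base() -> ScenarioSpec:
    """Fully occupied ward beds: saturating TEP demand, resources unchanged."""
    return ScenarioSpec(name="wards/base", tep_regime="saturating")


def cls_eplabs_base() -> ScenarioSpec:
    """Fully occupied EP labs: 110 beds, one lab, saturating TEP demand."""
    return ScenarioSpec(
        name="eplabs/base", tep_regime="saturating", bed_override=110, lab_override=1
    )


def _reduced_los(los: DurationSpec, delta: float, preop_min: float,
                 context: str) -> DurationSpec:
    """Shift the LOS mean down by ``delta`` days, SD and bounds held fixed.

    When the reduced mean undercuts the truncation minimum, the minimum is
    relaxed to floor(new mean) -- never below the pre-op lower bound or
    1 day -- so that aggressive reductions of already-short stays remain
    expressible.  If even that cannot restore min <= mean, the modification
    is rejected.
    """
    new_mean = los.mean - delta
    lo = los.min
    if new_mean < lo:
        lo = max(1.0, float(math.ceil(preop_min)), float(math.floor(new_mean)))
        if new_mean < lo:
            raise ValidationError(
                f"{context}: reduced LOS mean {new_mean:.3f} falls below the "
                f"feasible minimum {lo}"
            )
    return replace(los, mean=new_mean, min=lo)


def _modify_class(pc: ProcedureClass, mod: DurationModification) -> ProcedureClass:
    frac = mod.reduction_pct / 100.0
    if mod.phase == "operative":
        op = pc.operative_time
        scale = 1.0 - frac
        return replace(
            pc,
            operative_time=replace(
                op, mean=op.mean * scale, sd=op.sd * scale,
                min=op.min * scale, max=op.max * scale,
            ),
        )

    los, pre = pc.length_of_stay, pc.preop_stay
    delta = frac * los.mean  # expected days removed from the total stay
    context = f"{pc.name}/{mod.phase}"
    if mod.phase == "preop":
        new_pre_min = max(pre.min, 1.0)
        new_pre_mean = max(pre.mean - delta, 1.0, new_pre_min)
        achieved = pre.mean - new_pre_mean  # unachievable remainder is dropped
        new_pre = replace(pre, mean=new_pre_mean, min=new_pre_min)
        new_los = _reduced_los(los, achieved, new_pre_min, context)
    elif mod.phase == "postop":
        new_pre = pre
        new_los = _reduced_los(los, delta, pre.min, context)
    else:  # both: split in proportion to the phase shares of the LOS mean
        share_pre = pre.mean / los.mean
        new_pre_min = max(pre.min, 1.0)
        new_pre_mean = max(pre.mean - delta * share_pre, 1.0, new_pre_min)
        new_pre = replace(pre, mean=new_pre_mean, min=new_pre_min)
        # the pre-op shortfall lands on the post-op side automatically:
        # the full delta comes off the LOS mean while pre-op keeps its floor
        new_los = _reduced_los(los, delta, new_pre_min, context)
    return replace(pc, length_of_stay=new_los, preop_stay=new_pre)


def apply_reduction(config: ModelConfig, mod: DurationModification) -> ModelConfig:
    """Return a new config with ``mod`` applied to its target classes."""
    known = {pc.name for pc in config.procedure_classes}
    missing = set(mod.target_classes) - known
    if missing:
        raise ValidationError(f"unknown target procedure classes: {sorted(missing)}")
    new_classes = tuple(
        _modify_class(pc, mod) if pc.name in mod.target_classes else pc
        for pc in config.procedure_classes
    )
    return replace(config, procedure_classes=new_classes)


def resolve_config(config: ModelConfig, scenario: ScenarioSpec) -> ModelConfig:
    """Apply a scenario's resource overrides and duration modifications."""
    cfg = config
    for mod in scenario.modifications:
        cfg = apply_reduction(cfg, mod)
    res = cfg.resources
    if scenario.bed_override is not None or scenario.lab_override is not None:
        res = ResourceSet(
            beds=scenario.bed_override or res.beds,
            labs=scenario.lab_override or res.labs,
            physicians_on_duty=res.physicians_on_duty,
        )
        cfg = replace(cfg, resources=res)
    return cfg


def scenario_grid() -> list[ScenarioSpec]:
    """Every cell of the scenario analysis: 2 base cases + 2 x 4 phases x 3 levels."""
    grid: list[ScenarioSpec] = []
    for base in (cls_wards_base(), cls_eplabs_base()):
        grid.append(base)
        cls_name = base.name.split("/")[0]
        for phase in PHASES:
            for pct in (10, 20, 30):
                grid.append(
                    replace(
                        base,
                        name=f"{cls_name}/{phase}/{pct}",
                        modifications=(DurationModification(phase=phase, reduction_pct=pct),),
                    )
                )
    return grid
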