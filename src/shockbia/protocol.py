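"""Three-phase hemorrhage-resuscitation experiment protocol.

Encodes the experimental design consumed by both the simulator and the
analysis: a 180-min protocol split into controlled hemorrhage (1 L bled
over 60 min as ten 100-ml withdrawals) followed by two sequential 60-min
resuscitation phases of 1 L fluid each, with the fluid composition set by
the treatment group.  Bioimpedance is measured every 3 min (61 timepoints
including baseline) and vitals every minute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "FluidKind",
    "Group",
    "Phase",
    "FluidDose",
    "ExperimentProtocol",
    "ProtocolError",
    "UnknownGroupError",
    "standard_protocol",
    "PHASE_BOUNDS",
]


class ProtocolError(ValueError):
    """Invalid protocol definition or query."""


class UnknownGroupError(ProtocolError):
    """Treatment group is not one of the three defined groups."""


class Group(str, Enum):
    CRYSTALLOID = "crystalloid"
    CRYSTALLOID_DEXTROSE = "crystalloid_dextrose"
    CRYSTALLOID_ALBUMIN = "crystalloid_albumin"


class FluidKind(str, Enum):
    BALANCED_CRYSTALLOID = "balanced_crystalloid"
    DEXTROSE5 = "dextrose5"
    ALBUMIN20 = "albumin20"
    WHOLE_BLOOD = "whole_blood"


class Phase(str, Enum):
    HEMORRHAGE = "hemorrhage"
    RESUS1 = "resus1"
    RESUS2 = "resus2"


#: Phase boundaries in minutes; phases are half-open [0,60), [60,120), [120,180].
PHASE_BOUNDS: tuple[float, float, float, float] = (0.0, 60.0, 120.0, 180.0)

_RESUS_WINDOWS = {
    Phase.RESUS1: (PHASE_BOUNDS[1], PHASE_BOUNDS[2]),
    Phase.RESUS2: (PHASE_BOUNDS[2], PHASE_BOUNDS[3]),
}

#: Per-resuscitation-phase fluid composition (ml) for each treatment group.
GROUP_PHASE_FLUIDS: dict[Group, dict[FluidKind, float]] = {
    Group.CRYSTALLOID: {FluidKind.BALANCED_CRYSTALLOID: 1000.0},
    Group.CRYSTALLOID_DEXTROSE: {
        FluidKind.BALANCED_CRYSTALLOID: 500.0,
        FluidKind.DEXTROSE5: 500.0,
    },
    Group.CRYSTALLOID_ALBUMIN: {
        FluidKind.BALANCED_CRYSTALLOID: 800.0,
        FluidKind.ALBUMIN20: 200.0,
    },
}


@dataclass(frozen=True)
class FluidDose:
    """One fluid administration (or withdrawal) assigned to a phase."""

    fluid_kind: FluidKind
    volume_ml: float
    phase: Phase

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ProtocolError(f"dose volume must be positive, got {self.volume_ml}")
        if self.fluid_kind is FluidKind.WHOLE_BLOOD:
            if self.phase is not Phase.HEMORRHAGE:
                raise ProtocolError("whole blood appears only in the hemorrhage phase")
        elif self.phase is Phase.HEMORRHAGE:
            raise ProtocolError("resuscitation fluids appear only in resus phases")


@dataclass(frozen=True)
class ExperimentProtocol:
    """Queryable schedule of bleeding, infusion and measurement events."""

    group: Group
    bleed_events: tuple[tuple[float, float], ...]  # (time min, volume ml)
    phase_fluids: Mapping[Phase, Mapping[FluidKind, float]]
    bia_interval_min: float = 3.0
    vitals_interval_min: float = 1.0
    baseline_replicates: int = 3

    def __post_init__(self) -> None:
        if self.bia_interval_min <= 0 or 180.0 % self.bia_interval_min != 0:
            raise ProtocolError(
                f"bia_interval_min must divide 180, got {self.bia_interval_min}"
            )
        if any(v <= 0 for _, v in self.bleed_events):
            raise ProtocolError("bleed volumes must be positive")

    # -- schedules ---------------------------------------------------------

    @property
    def duration_min(self) -> float:
        return PHASE_BOUNDS[-1]

    def measurement_schedule(self) -> np.ndarray:
        """Impedance measurement times: baseline 0 plus every bia_interval up to 180."""
        n = int(round(self.duration_min / self.bia_interval_min))
        return np.linspace(0.0, self.duration_min, n + 1)

    def vitals_schedule(self) -> np.ndarray:
        n = int(round(self.duration_min / self.vitals_interval_min))
        return np.linspace(0.0, self.duration_min, n + 1)

    # -- volume bookkeeping ------------------------------------------------

    def _check_time(self, t: float) -> None:
        if not 0.0 <= t <= self.duration_min:
            raise ProtocolError(f"time {t} min outside [0, {self.duration_min}]")

    def cumulative_bled_volume(self, t: float) -> float:
        """Blood withdrawn (ml) by time t; right-continuous step function."""
        self._check_time(t)
        return float(sum(v for et, v in self.bleed_events if et <= t))

    def cumulative_infused(self, t: float) -> dict[FluidKind, float]:
        """Per-fluid volume (ml) delivered by time t at constant within-phase rates."""
        self._check_time(t)
        out: dict[FluidKind, float] = {}
        for phase, fluids in self.phase_fluids.items():
            if phase is Phase.HEMORRHAGE:
                continue
            start, end = _RESUS_WINDOWS[phase]
            frac = min(max((t - start) / (end - start), 0.0), 1.0)
            for kind, vol in fluids.items():
                out[kind] = out.get(kind, 0.0) + vol * frac
        return out

    def infusion_rates(self, t: float) -> dict[FluidKind, float]:
        """Instantaneous infusion rates (ml/min) at time t (phases half-open)."""
        self._check_time(t)
        for phase, (start, end) in _RESUS_WINDOWS.items():
            if start <= t < end:
                return {
                    kind: vol / (end - start)
                    for kind, vol in self.phase_fluids.get(phase, {}).items()
                }
        return {}

    def phase_of(self, t: float) -> Phase:
        self._check_time(t)
        if t < PHASE_BOUNDS[1]:
            return Phase.HEMORRHAGE
        if t < PHASE_BOUNDS[2]:
            return Phase.RESUS1
        return Phase.RESUS2

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        phase_names = {
            Phase.HEMORRHAGE: ("hemorrhage", PHASE_BOUNDS[0], PHASE_BOUNDS[1]),
            Phase.RESUS1: ("resus1", *_RESUS_WINDOWS[Phase.RESUS1]),
            Phase.RESUS2: ("resus2", *_RESUS_WINDOWS[Phase.RESUS2]),
        }
        phases = []
        for phase, (name, start, end) in phase_names.items():
            fluids = [
                {"kind": kind.value, "volume_ml": vol}
                for kind, vol in self.phase_fluids.get(phase, {}).items()
            ]
            phases.append(
                {"name": name, "start_min": start, "end_min": end, "fluids": fluids}
            )
        return {
            "group": self.group.value,
            "bleed_events": [
                {"time_min": t, "volume_ml": v} for t, v in self.bleed_events
            ],
            "phases": phases,
            "bia_interval_min": self.bia_interval_min,
            "vitals_interval_min": self.vitals_interval_min,
            "baseline_replicates": self.baseline_replicates,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentProtocol":
        phase_fluids: dict[Phase, dict[FluidKind, float]] = {}
        for ph in d.get("phases", []):
            if not ph["fluids"]:
                continue
            phase = Phase(ph["name"])
            phase_fluids[phase] = {
                FluidKind(f["kind"]): float(f["volume_ml"]) for f in ph["fluids"]
            }
        return cls(
            group=Group(d["group"]),
            bleed_events=tuple(
                (float(e["time_min"]), float(e["volume_ml"]))
                for e in d["bleed_events"]
            ),
            phase_fluids=phase_fluids,
            bia_interval_min=float(d.get("bia_interval_min", 3.0)),
            vitals_interval_min=float(d.get("vitals_interval_min", 1.0)),
            baseline_replicates=int(d.get("baseline_replicates", 3)),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_file(cls, path) -> "ExperimentProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_bia_interval(self, interval: float) -> "ExperimentProtocol":
        return replace(self, bia_interval_min=interval)


def standard_protocol(group: Group | str) -> ExperimentProtocol:
    """Standard protocol for one of the three treatment groups.

    Ten 100-ml bleeds at minutes 6, 12, ..., 60; each resuscitation phase
    delivers 1000 ml with the group's fluid composition as a continuous
    infusion over its 60 minutes.
    """
    try:
        group = Group(group)
    except ValueError:
        raise UnknownGroupError(f"unknown treatment group: {group!r}") from None
    bleeds = tuple((6.0 * k, 100.0) for k in range(1, 11))
    fluids = GROUP_PHASE_FLUIDS[group]
    return ExperimentProtocol(
        group=group,
        bleed_events=bleeds,
        phase_fluids={Phase.RESUS1: dict(fluids), Phase.RESUS2: dict(fluids)},
    )
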