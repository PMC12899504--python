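"""Core time-series containers for synchronized force-plate / IMU trials.

All channels in a trial share one clock: the time of sample ``k`` of a
:class:`UniformSignal` is ``t0 + k / rate`` seconds.  Sample indexing is
0-based throughout, and every detected event carries both its sample index
(on the detecting signal's clock) and its time in seconds on the shared
trial clock, so that events from a 1000 Hz force plate and a 60 Hz IMU can
be compared directly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import FormatError


class Task(str, enum.Enum):
    """Movement task: 90-degree change of direction or sprint-deceleration."""

    COD = "COD"
    DEC = "DEC"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Leg(str, enum.Enum):
    DOMINANT = "dominant"
    NONDOMINANT = "nondominant"


class Algorithm(str, enum.Enum):
    """Which detector produced a result."""

    PVV = "PVV"
    RFA = "RFA"
    HYBRID = "HYBRID"


class EventType(str, enum.Enum):
    IC = "IC"
    TO = "TO"


@dataclass(frozen=True)
class UniformSignal:
    """One uniformly sampled channel.

    Parameters
    ----------
    values : array-like
        Samples in channel units (N, m/s, m/s^2 ...).
    rate : float
        Sampling rate in Hz.  Must be positive.
    t0 : float
        Time of sample 0 on the shared trial clock, in seconds.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise FormatError("signal must be a non-empty 1-D array")
        if not np.all(np.isfinite(vals)):
            bad = int(np.flatnonzero(~np.isfinite(vals))[0])
            raise FormatError(f"non-finite sample at index {bad}")
        if not (self.rate > 0):
            raise FormatError(f"rate must be positive, got {self.rate}")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Span from the first to the last sample, in seconds."""
        return (len(self) - 1) / self.rate

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        """Time stamps of all samples on the shared trial clock."""
        return self.t0 + np.arange(len(self)) / self.rate

    def time_at(self, index: int) -> float:
        return self.t0 + index / self.rate

    def replace_values(self, values: np.ndarray) -> "UniformSignal":
        """Same clock, new samples (used by filters)."""
        return UniformSignal(values=values, rate=self.rate, t0=self.t0)


@dataclass(frozen=True)
class TriaxialSignal:
    """Three clock-aligned channels, e.g. foot linear acceleration x/y/z."""

    x: UniformSignal
    y: UniformSignal
    z: UniformSignal

    def __post_init__(self) -> None:
        for axis in (self.y, self.z):
            if (
                axis.rate != self.x.rate
                or axis.t0 != self.x.t0
                or len(axis) != len(self.x)
            ):
                raise FormatError("triaxial channels must share rate, t0 and length")

    @property
    def rate(self) -> float:
        return self.x.rate

    @property
    def t0(self) -> float:
        return self.x.t0

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class TrialMeta:
    trial_id: str
    participant_id: str
    task: Task
    sex: Sex
    leg: Leg

    def __post_init__(self) -> None:
        object.__setattr__(self, "task", Task(self.task))
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "leg", Leg(self.leg))


@dataclass(frozen=True)
class Trial:
    """Synchronized signal bundle for one movement repetition.

    ``vgrf`` (vertical ground reaction force, N, nominally 1000 Hz) is
    optional: field recordings away from the force plate have only the IMU
    channels.  ``pelvis_vz`` (m/s) and ``foot_acc`` (m/s^2) are the 60 Hz
    IMU channels and must share rate and clock.
    """

    meta: TrialMeta
    pelvis_vz: UniformSignal
    foot_acc: TriaxialSignal
    vgrf: Optional[UniformSignal] = None

    def __post_init__(self) -> None:
        if self.pelvis_vz.rate != self.foot_acc.rate:
            raise FormatError("pelvis_vz and foot_acc must share the sampling rate")
        if self.pelvis_vz.t0 != self.foot_acc.t0:
            raise FormatError("pelvis_vz and foot_acc must share t0")

    @property
    def imu_rate(self) -> float:
        return self.pelvis_vz.rate


@dataclass(frozen=True)
class ContactEvent:
    """An (initial contact, toe off) pair.

    Indices live on the clock of the signal that produced the event; times
    are seconds on the shared trial clock, so events detected at different
    rates remain comparable.
    """

    ic_index: int
    to_index: int
    ic_time: float
    to_time: float

    def __post_init__(self) -> None:
        if not self.to_time > self.ic_time:
            raise FormatError(
                f"toe-off ({self.to_time}) must follow initial contact ({self.ic_time})"
            )

    @property
    def duration(self) -> float:
        """Stance duration in seconds."""
        return self.to_time - self.ic_time

    @classmethod
    def from_indices(
        cls, ic_index: int, to_index: int, rate: float, t0: float = 0.0
    ) -> "ContactEvent":
        return cls(
            ic_index=ic_index,
            to_index=to_index,
            ic_time=t0 + ic_index / rate,
            to_time=t0 + to_index / rate,
        )
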