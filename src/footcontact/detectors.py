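"""IMU-based foot contact detectors.

Three detectors identify the (initial contact, toe-off) window of a
high-dynamic movement — a sidestep cut or a sprint-deceleration — from
wearable inertial sensors, without a force plate:

* **PVV** works on pelvis vertical velocity: initial contact is a local
  minimum, toe-off the following local maximum, and the pair is accepted
  only if a descent (velocity derivative below -0.1 m/s^2) follows the
  maximum and the maximum is the highest peak before that descent.
* **RFA** works on the resultant (Euclidean norm) foot acceleration: both
  events are impact-like local maxima, the toe-off peak must reach
  30 m/s^2, and the two peaks must enclose a "U shape" (a deep valley).
* **Hybrid** relies on RFA for both events, falls back to PVV when RFA
  finds no valid window, and substitutes PVV's initial contact when the
  foot acceleration at contact is below 60 m/s^2 — the regime where
  impact peaks become unreliable.

Each detector returns every acceptable candidate pair; the pair with the
longest duration is selected as the foot contact of interest (the task's
main plant step), with ties broken by the earlier initial contact.
Detection failure is encoded in the result, never raised.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import ParameterError, SelectionError
from .preprocessing import FilterSpec, derivative, lowpass, resultant
from .signals import Algorithm, ContactEvent, TriaxialSignal, UniformSignal


class Provenance(str, enum.Enum):
    """Which detector(s) produced a hybrid result."""

    RFA_BOTH = "RFA_BOTH"
    PVV_BOTH = "PVV_BOTH"
    PVV_IC_RFA_TO = "PVV_IC_RFA_TO"


@dataclass(frozen=True)
class DetectorParams:
    """All detection thresholds and filter constants in one record.

    Attributes
    ----------
    filter : FilterSpec
        Low-pass filter applied to the pelvis-velocity and resultant-
        acceleration signals before peak search (20 Hz, order 3).
    pvv_descent_threshold : float
        Velocity-derivative threshold (m/s^2, negative) marking the
        post-toe-off descent in the pelvis velocity pattern.
    rfa_to_threshold : float
        Minimum resultant foot acceleration (m/s^2) for an eligible
        toe-off peak.
    hybrid_ic_gate : float
        Foot acceleration at initial contact (m/s^2) below which the
        hybrid detector replaces RFA's contact with PVV's.
    min_prominence_frac : float
        Candidate-peak prominence floor as a fraction of the filtered
        signal's range; suppresses noise-born micro-extrema.
    u_shape_factor : float
        The inter-peak valley must drop below this fraction of the lower
        of the two peak heights for the pair to count as a "U shape".
    """

    filter: FilterSpec = field(default_factory=FilterSpec)
    pvv_descent_threshold: float = -0.1
    rfa_to_threshold: float = 30.0
    hybrid_ic_gate: float = 60.0
    min_prominence_frac: float = 0.05
    u_shape_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.pvv_descent_threshold >= 0:
            raise ParameterError("pvv_descent_threshold must be negative")
        if self.rfa_to_threshold <= 0:
            raise ParameterError("rfa_to_threshold must be positive")
        if self.hybrid_ic_gate <= 0:
            raise ParameterError("hybrid_ic_gate must be positive")
        if not (0 <= self.min_prominence_frac < 1):
            raise ParameterError("min_prominence_frac must be in [0, 1)")
        if not (0 < self.u_shape_factor <= 1):
            raise ParameterError("u_shape_factor must be in (0, 1]")


@dataclass(frozen=True)
class DetectionResult:
    algorithm: Algorithm
    contact: Optional[ContactEvent]
    failed: bool
    candidates: tuple[ContactEvent, ...] = ()
    rfa_at_ic: Optional[float] = None
    provenance: Optional[Provenance] = None

    def __post_init__(self) -> None:
        if self.failed == (self.contact is not None):
            raise ParameterError("failed must be the negation of contact presence")


def _candidate_extrema(
    values: np.ndarray, frac: float
) -> tuple[np.ndarray, np.ndarray]:
    """Local minima and maxima with a prominence floor of frac * range."""
    rng = float(values.max() - values.min())
    prom = frac * rng if (frac > 0 and rng > 0) else None
    kwargs = {} if prom is None else {"prominence": prom}
    maxima, _ = find_peaks(values, **kwargs)
    minima, _ = find_peaks(-values, **kwargs)
    return minima, maxima


def select_longest(candidates: Sequence[ContactEvent]) -> ContactEvent:
    """The valid step: longest-duration contact, earliest on ties.

    Durations within 1 ns count as tied, so windows of equal sample count
    are not separated by floating-point rounding of their times.
    """
    if not candidates:
        raise SelectionError("no candidate contacts to select from")
    longest = max(e.duration for e in candidates)
    tied = [e for e in candidates if e.duration >= longest - 1e-9]
    return min(tied, key=lambda e: e.ic_time)


def detect_pvv(
    pelvis_vz: UniformSignal, params: DetectorParams = DetectorParams()
) -> DetectionResult:
    """Pelvis-vertical-velocity detector.

    After low-pass filtering, local minima are candidate initial contacts
    and local maxima candidate toe-offs.  For each contact candidate, toe-
    off candidates are scanned in order; the first satisfying both pattern
    conditions is paired with it:

    1. a descent follows the toe-off — the derivative of the filtered
       velocity drops below ``pvv_descent_threshold`` at some sample after
       the toe-off and before the next candidate toe-off, and
    2. the toe-off is the highest candidate maximum between the contact
       and that descent onset.
    """
    filtered = lowpass(pelvis_vz, params.filter)
    v = filtered.values
    minima, maxima = _candidate_extrema(v, params.min_prominence_frac)
    deriv = derivative(filtered).values

    candidates: list[ContactEvent] = []
    for ic in minima:
        tos = maxima[maxima > ic]
        for k, to in enumerate(tos):
            next_to = int(tos[k + 1]) if k + 1 < len(tos) else len(v)
            window = deriv[to + 1 : next_to]
            below = np.flatnonzero(window < params.pvv_descent_threshold)
            if below.size == 0:
                continue
            onset = int(to) + 1 + int(below[0])
            comparison = maxima[(maxima > ic) & (maxima <= onset)]
            peak_pool = v[comparison] if comparison.size else np.array([v[to]])
            if v[to] >= peak_pool.max():
                candidates.append(
                    ContactEvent.from_indices(
                        int(ic), int(to), rate=filtered.rate, t0=filtered.t0
                    )
                )
                break

    if not candidates:
        return DetectionResult(Algorithm.PVV, contact=None, failed=True)
    return DetectionResult(
        Algorithm.PVV,
        contact=select_longest(candidates),
        failed=False,
        candidates=tuple(candidates),
    )


def detect_rfa(
    foot_acc: TriaxialSignal, params: DetectorParams = DetectorParams()
) -> DetectionResult:
    """Resultant-foot-acceleration detector.

    The resultant acceleration is low-pass filtered; every prominent local
    maximum is a candidate for either event.  For each candidate initial-
    contact peak, subsequent peaks are scanned in order: peaks below
    ``rfa_to_threshold`` are discarded, and the first peak that both
    reaches the threshold and encloses a U-shaped valley with the contact
    peak (inter-peak minimum below ``u_shape_factor`` times the lower peak)
    becomes the toe-off.

    ``rfa_at_ic`` in the result is the filtered resultant acceleration at
    the selected contact — the quantity the hybrid detector gates on.
    """
    rfa = lowpass(resultant(foot_acc), params.filter)
    a = rfa.values
    _, peaks = _candidate_extrema(a, params.min_prominence_frac)

    candidates: list[ContactEvent] = []
    for i, ic in enumerate(peaks):
        for to in peaks[i + 1 :]:
            if a[to] < params.rfa_to_threshold:
                continue
            if to - ic < 2:
                continue
            valley = float(a[ic + 1 : to].min())
            if valley < params.u_shape_factor * min(a[ic], a[to]):
                candidates.append(
                    ContactEvent.from_indices(
                        int(ic), int(to), rate=rfa.rate, t0=rfa.t0
                    )
                )
                break

    if not candidates:
        return DetectionResult(Algorithm.RFA, contact=None, failed=True)
    contact = select_longest(candidates)
    return DetectionResult(
        Algorithm.RFA,
        contact=contact,
        failed=False,
        candidates=tuple(candidates),
        rfa_at_ic=float(a[contact.ic_index]),
    )


def detect_hybrid(
    pelvis_vz: UniformSignal,
    foot_acc: TriaxialSignal,
    params: DetectorParams = DetectorParams(),
) -> DetectionResult:
    """Hybrid detector combining RFA's precision with PVV's robustness.

    Decision logic:

    * RFA succeeds with foot acceleration at contact >= ``hybrid_ic_gate``
      -> RFA's window as-is (provenance ``RFA_BOTH``).
    * RFA succeeds below the gate and PVV's contact precedes RFA's toe-off
      -> PVV contact + RFA toe-off (``PVV_IC_RFA_TO``).
    * RFA succeeds below the gate but PVV failed or its contact does not
      precede RFA's toe-off -> keep RFA's window (``RFA_BOTH``).
    * RFA fails, PVV succeeds -> PVV's window (``PVV_BOTH``).
    * Both fail -> failure.
    """
    rfa_res = detect_rfa(foot_acc, params)
    pvv_res = detect_pvv(pelvis_vz, params)

    if rfa_res.failed:
        if pvv_res.failed:
            return DetectionResult(Algorithm.HYBRID, contact=None, failed=True)
        return DetectionResult(
            Algorithm.HYBRID,
            contact=pvv_res.contact,
            failed=False,
            candidates=pvv_res.candidates,
            provenance=Provenance.PVV_BOTH,
        )

    assert rfa_res.contact is not None and rfa_res.rfa_at_ic is not None
    if rfa_res.rfa_at_ic >= params.hybrid_ic_gate:
        return DetectionResult(
            Algorithm.HYBRID,
            contact=rfa_res.contact,
            failed=False,
            candidates=rfa_res.candidates,
            rfa_at_ic=rfa_res.rfa_at_ic,
            provenance=Provenance.RFA_BOTH,
        )

    if (
        not pvv_res.failed
        and pvv_res.contact is not None
        and pvv_res.contact.ic_time < rfa_res.contact.to_time
    ):
        combined = ContactEvent(
            ic_index=pvv_res.contact.ic_index,
            to_index=rfa_res.contact.to_index,
            ic_time=pvv_res.contact.ic_time,
            to_time=rfa_res.contact.to_time,
        )
        return DetectionResult(
            Algorithm.HYBRID,
            contact=combined,
            failed=False,
            candidates=(combined,),
            rfa_at_ic=rfa_res.rfa_at_ic,
            provenance=Provenance.PVV_IC_RFA_TO,
        )

    # substitution impossible: keep RFA's own window
    return DetectionResult(
        Algorithm.HYBRID,
        contact=rfa_res.contact,
        failed=False,
        candidates=rfa_res.candidates,
        rfa_at_ic=rfa_res.rfa_at_ic,
        provenance=Provenance.RFA_BOTH,
    )
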