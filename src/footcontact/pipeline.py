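"""Glue between simulation, detection and validation.

These helpers run the detectors over whole cohorts and pair their events
with the force-plate reference, producing the offset records the agreement
statistics consume.  Both the command-line interface and reproduction
scripts are thin wrappers around this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .agreement import OffsetRecord, compute_offset
from .detectors import (
    DetectionResult,
    DetectorParams,
    detect_hybrid,
    detect_pvv,
    detect_rfa,
)
from .errors import FootContactError
from .ground_truth import GrfParams, detect_grf_contact
from .signals import Algorithm, ContactEvent, EventType, Trial, TrialMeta


@dataclass(frozen=True)
class TrialEvaluation:
    """Reference event and per-algorithm detections for one trial."""

    meta: TrialMeta
    reference: ContactEvent
    results: dict[Algorithm, DetectionResult]


def detect_all(
    trial: Trial,
    params: DetectorParams = DetectorParams(),
    algorithms: Sequence[Algorithm] = tuple(Algorithm),
) -> dict[Algorithm, DetectionResult]:
    """Run the selected detectors on one trial."""
    out: dict[Algorithm, DetectionResult] = {}
    for alg in algorithms:
        alg = Algorithm(alg)
        if alg is Algorithm.PVV:
            out[alg] = detect_pvv(trial.pelvis_vz, params)
        elif alg is Algorithm.RFA:
            out[alg] = detect_rfa(trial.foot_acc, params)
        else:
            out[alg] = detect_hybrid(trial.pelvis_vz, trial.foot_acc, params)
    return out


def evaluate_trials(
    trials: Iterable[tuple[Trial, Optional[ContactEvent]]],
    detector_params: DetectorParams = DetectorParams(),
    grf_params: GrfParams = GrfParams(),
    algorithms: Sequence[Algorithm] = tuple(Algorithm),
) -> list[TrialEvaluation]:
    """Evaluate detectors against the reference on each trial.

    Each item is ``(trial, reference)``; when ``reference`` is None it is
    extracted from the trial's force channel with the 50 N rule.  Trials
    with neither a reference nor a force channel are skipped.
    """
    evaluations: list[TrialEvaluation] = []
    for trial, reference in trials:
        if reference is None:
            if trial.vgrf is None:
                continue
            try:
                reference = detect_grf_contact(trial.vgrf, grf_params)
            except FootContactError:
                continue
        evaluations.append(
            TrialEvaluation(
                meta=trial.meta,
                reference=reference,
                results=detect_all(trial, detector_params, algorithms),
            )
        )
    return evaluations


def collect_offsets(
    evaluations: Sequence[TrialEvaluation],
    algorithm: Algorithm,
    event: EventType,
) -> tuple[list[OffsetRecord], int]:
    """Offset records for one algorithm x event; failures counted apart.

    Failed detections carry no event time, so they cannot enter the offset
    distribution; they are reported as a separate count.
    """
    algorithm = Algorithm(algorithm)
    event = EventType(event)
    offsets: list[OffsetRecord] = []
    failures = 0
    for ev in evaluations:
        res = ev.results.get(algorithm)
        if res is None:
            continue
        if res.failed or res.contact is None:
            failures += 1
            continue
        offsets.append(
            compute_offset(ev.reference, res.contact, event, ev.meta, algorithm)
        )
    return offsets, failures
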