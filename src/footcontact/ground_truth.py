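"""Reference foot-contact window from the force platform.

Initial contact is the first sample where the vertical ground reaction
force (vGRF) strictly exceeds a 50 N threshold; toe-off is the first
subsequent sample strictly below it.  The inequalities are strict on both
sides, so a sample exactly at the threshold triggers neither event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoContactError, ParameterError, TruncatedContactError
from .signals import ContactEvent, UniformSignal
from .preprocessing import map_time_to_index


@dataclass(frozen=True)
class GrfParams:
    """Force-plate thresholding parameters.

    Attributes
    ----------
    threshold_n : float
        Contact threshold in newtons (default 50).
    min_contact_s : float
        Debounce: supra-threshold windows shorter than this are treated as
        plate ringing and skipped (default 0.05 s; set 0 to keep every
        crossing as a candidate window).
    """

    threshold_n: float = 50.0
    min_contact_s: float = 0.05

    def __post_init__(self) -> None:
        if self.threshold_n <= 0:
            raise ParameterError(f"threshold must be positive, got {self.threshold_n}")
        if self.min_contact_s < 0:
            raise ParameterError(
                f"debounce must be non-negative, got {self.min_contact_s}"
            )


def detect_grf_contact(
    vgrf: UniformSignal, params: GrfParams = GrfParams()
) -> ContactEvent:
    """Threshold-crossing contact window on the force-plate clock.

    Scans for windows where vGRF > threshold; windows shorter than the
    debounce are skipped and the scan continues.  If several windows
    survive, the longest is returned (earliest on ties), mirroring the
    longest-contact rule used by the IMU detectors.

    Raises
    ------
    NoContactError
        If no sample exceeds the threshold.
    TruncatedContactError
        If the only contact found is still above threshold at signal end.
    """
    v = vgrf.values
    above = v > params.threshold_n
    if not above.any():
        raise NoContactError(
            f"vGRF never exceeds {params.threshold_n} N (max {v.max():.1f} N)"
        )

    windows: list[tuple[int, int]] = []
    truncated = False
    i = 0
    n = len(v)
    while i < n:
        if not above[i]:
            i += 1
            continue
        ic = i
        while i < n and not (v[i] < params.threshold_n):
            i += 1
        if i == n:
            truncated = True
            break
        to = i
        if (to - ic) / vgrf.rate >= params.min_contact_s:
            windows.append((ic, to))

    if not windows:
        if truncated:
            raise TruncatedContactError(
                "contact still above threshold at end of signal"
            )
        raise NoContactError(
            f"no supra-threshold window survives the "
            f"{params.min_contact_s * 1000:.0f} ms debounce"
        )
    ic, to = max(windows, key=lambda w: (w[1] - w[0], -w[0]))
    return ContactEvent.from_indices(ic, to, rate=vgrf.rate, t0=vgrf.t0)


def grf_event_on_imu_clock(
    event: ContactEvent, imu_rate: float, imu_t0: float = 0.0, imu_len: int | None = None
) -> ContactEvent:
    """Re-express a force-plate event's indices on the IMU sampling grid.

    Times are unchanged (the clocks are synchronized); only the indices are
    remapped to the nearest IMU sample so force-plate and IMU events can be
    compared frame-by-frame.
    """
    n = imu_len if imu_len is not None else int(np.ceil(
        (event.to_time - imu_t0) * imu_rate
    )) + 2
    grid = UniformSignal(values=np.zeros(max(n, 2)), rate=imu_rate, t0=imu_t0)
    return ContactEvent(
        ic_index=map_time_to_index(event.ic_time, grid),
        to_index=map_time_to_index(event.to_time, grid),
        ic_time=event.ic_time,
        to_time=event.to_time,
    )
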