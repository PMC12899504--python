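import numpy as np
import pytest

from footcontact import (
    CohortSpec,
    DetectorParams,
    Leg,
    Sex,
    Task,
    Trial,
    TrialMeta,
    TriaxialSignal,
    UniformSignal,
)

IMU_RATE = 60.0


@pytest.fixture
def meta():
    return TrialMeta(
        trial_id="T01",
        participant_id="P01",
        task=Task.COD,
        sex=Sex.FEMALE,
        leg=Leg.DOMINANT,
    )


@pytest.fixture
def small_cohort_spec():
    """A 10-participant cohort, quick enough for unit-level checks."""
    return CohortSpec(n_participants=10, trials_per_participant=4, seed=11)


def gauss_bump(t, center, width):
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def make_trial(
    meta,
    ic=1.2,
    to=1.7,
    h_ic=95.0,
    h_to=45.0,
    duration=3.0,
    pvv_depth=0.55,
    pvv_height=0.6,
):
    """Hand-built trial with the canonical landmark geometry: a velocity
    dip/peak pair and twin acceleration impact peaks at (ic, to)."""
    t = np.arange(int(duration * IMU_RATE)) / IMU_RATE
    d = to - ic
    pvv = (
        0.05
        - pvv_depth * gauss_bump(t, ic, max(0.03, d / 6))
        + pvv_height * gauss_bump(t, to, max(0.04, d / 5))
    )
    rfa = 2.0 + h_ic * gauss_bump(t, ic, 0.025) + h_to * gauss_bump(t, to, 0.025)
    direction = np.array([0.5, 0.3, np.sqrt(1 - 0.34)])
    foot = TriaxialSignal(
        UniformSignal(rfa * direction[0], IMU_RATE),
        UniformSignal(rfa * direction[1], IMU_RATE),
        UniformSignal(rfa * direction[2], IMU_RATE),
    )
    tg = np.arange(int(duration * 1000)) / 1000.0
    vgrf = np.zeros_like(tg)
    stance = (tg >= ic) & (tg <= to)
    vgrf[stance] = 50.0 + 1450.0 * np.sin(np.pi * (tg[stance] - ic) / d)
    return Trial(
        meta=meta,
        pelvis_vz=UniformSignal(pvv, IMU_RATE),
        foot_acc=foot,
        vgrf=UniformSignal(vgrf, 1000.0),
    )
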