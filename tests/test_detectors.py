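import numpy as np
import pytest

from footcontact import (
    Algorithm,
    ContactEvent,
    DetectorParams,
    FilterSpec,
    Provenance,
    TriaxialSignal,
    UniformSignal,
    detect_hybrid,
    detect_pvv,
    detect_rfa,
    select_longest,
)
from footcontact.errors import SelectionError
from footcontact.preprocessing import derivative, lowpass, resultant

from conftest import IMU_RATE, gauss_bump, make_trial
from oracles import brute_pvv_pairs, brute_rfa_pairs


def pvv_signal(patterns, duration=4.0, baseline=0.05):
    """Pelvis velocity with one dip/peak pattern per (ic, to) pair."""
    t = np.arange(int(duration * IMU_RATE)) / IMU_RATE
    v = np.full_like(t, baseline)
    for ic, to in patterns:
        d = to - ic
        v += -0.55 * gauss_bump(t, ic, max(0.03, d / 6))
        v += 0.60 * gauss_bump(t, to, max(0.04, d / 5))
    return UniformSignal(v, IMU_RATE)


def rfa_signal(peaks, duration=4.0, baseline=2.0):
    """Resultant-style acceleration as a triaxial bundle."""
    t = np.arange(int(duration * IMU_RATE)) / IMU_RATE
    a = np.full_like(t, baseline)
    for center, height in peaks:
        a += height * gauss_bump(t, center, 0.025)
    direction = np.array([0.5, 0.3, np.sqrt(1 - 0.34)])
    return TriaxialSignal(*(UniformSignal(a * c, IMU_RATE) for c in direction))


def nearest(t):
    return int(round(t * IMU_RATE))


class TestPvv:
    def test_recovers_planted_pattern(self):
        res = detect_pvv(pvv_signal([(1.2, 1.7)]))
        assert not res.failed
        assert abs(res.contact.ic_index - nearest(1.2)) <= 1
        assert abs(res.contact.to_index - nearest(1.7)) <= 1

    def test_monotone_signal_fails(self):
        sig = UniformSignal(np.linspace(-1, 1, 200), IMU_RATE)
        res = detect_pvv(sig)
        assert res.failed and res.contact is None and not res.candidates

    def test_longest_of_two_stances_selected(self):
        short, long_ = (1.0, 1.2), (2.2, 2.65)
        res = detect_pvv(pvv_signal([short, long_]))
        assert len(res.candidates) == 2
        assert abs(res.contact.ic_index - nearest(long_[0])) <= 1
        assert abs(res.contact.to_index - nearest(long_[1])) <= 1


class TestRfa:
    def test_recovers_twin_peaks(self):
        res = detect_rfa(rfa_signal([(1.2, 95.0), (1.7, 80.0)]))
        assert not res.failed
        assert abs(res.contact.ic_index - nearest(1.2)) <= 1
        assert abs(res.contact.to_index - nearest(1.7)) <= 1
        assert res.rfa_at_ic == pytest.approx(95.0, rel=0.10)

    def test_all_peaks_below_toeoff_threshold_fails(self):
        res = detect_rfa(rfa_signal([(1.2, 25.0), (1.7, 20.0)]))
        assert res.failed

    def test_distractor_step_shorter_duration(self):
        # a following shorter step: every candidate pair it spawns
        # (including cross pairs) is shorter than the main stance
        res = detect_rfa(
            rfa_signal([(1.2, 95.0), (2.0, 80.0), (2.3, 70.0), (2.6, 40.0)])
        )
        assert abs(res.contact.ic_index - nearest(1.2)) <= 1
        assert abs(res.contact.to_index - nearest(2.0)) <= 1
        assert len(res.candidates) >= 2


class TestSelectLongest:
    def events(self, spans):
        return [ContactEvent.from_indices(a, b, rate=1000.0) for a, b in spans]

    def test_longest_duration_wins(self):
        evs = self.events([(0, 200), (300, 750), (800, 1100)])
        assert select_longest(evs) is evs[1]

    def test_single_and_empty(self):
        evs = self.events([(0, 100)])
        assert select_longest(evs) is evs[0]
        with pytest.raises(SelectionError):
            select_longest([])

    def test_tie_broken_by_earlier_contact(self):
        evs = self.events([(600, 900), (200, 500)])
        assert select_longest(evs) is evs[1]


class TestHybrid:
    def test_gate_monotonicity(self):
        """Raising the substitution gate never decreases the number of
        velocity-substituted contacts."""
        trials = [
            make_trial(None, h_ic=h)
            for h in (35.0, 55.0, 65.0, 80.0, 95.0, 110.0)
        ]
        counts = []
        for gate in (30.0, 60.0, 90.0, 120.0):
            params = DetectorParams(hybrid_ic_gate=gate)
            counts.append(
                sum(
                    detect_hybrid(t.pelvis_vz, t.foot_acc, params).provenance
                    is Provenance.PVV_IC_RFA_TO
                    for t in trials
                )
            )
        assert counts == sorted(counts)

    def test_determinism(self):
        trial = make_trial(None, h_ic=50.0)
        r1 = detect_hybrid(trial.pelvis_vz, trial.foot_acc)
        r2 = detect_hybrid(trial.pelvis_vz, trial.foot_acc)
        assert r1 == r2


def random_pvv(rng, n):
    # smooth low-frequency wander: realistic extremum density
    from scipy.signal import butter, filtfilt

    b, a = butter(3, 4.0, fs=IMU_RATE)
    return UniformSignal(filtfilt(b, a, rng.normal(0, 1.0, n)), IMU_RATE)


def test_pvv_candidates_match_bruteforce_sample():
    """Spot check of the exhaustive-enumeration equivalence (the full
    sweep runs in the acceptance suite)."""
    params = DetectorParams(min_prominence_frac=0.0)
    rng = np.random.default_rng(3)
    for _ in range(20):
        sig = random_pvv(rng, int(rng.integers(60, 400)))
        filtered = lowpass(sig, params.filter)
        pairs = brute_pvv_pairs(
            filtered.values, derivative(filtered).values, params.pvv_descent_threshold
        )
        res = detect_pvv(sig, params)
        got = [(c.ic_index, c.to_index) for c in res.candidates]
        assert got == pairs


def test_every_contact_well_ordered():
    rng = np.random.default_rng(9)
    for _ in range(30):
        sig = random_pvv(rng, 300)
        res = detect_pvv(sig, DetectorParams(min_prominence_frac=0.0))
        for c in res.candidates:
            assert c.to_time > c.ic_time
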