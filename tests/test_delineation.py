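"""T/P detection windows, the five decision rules, and pipeline invariants."""

import numpy as np
import pytest

from pwavedet.delineation import (
    ALL_RULES,
    DelineationConfig,
    PCandidate,
    apply_rules,
    delineate_record,
    detect_p_candidate,
    detect_t,
    dissociated_search,
    refine_peak,
)
from pwavedet.evaluation import match
from pwavedet.qrs_detection import BeatSet
from pwavedet.synthetic_ecg import (
    RhythmScript,
    WaveParams,
    generate_record,
    make_beat,
)


FS = 1000.0  # 1 kHz in the synthetic unit tests: samples == milliseconds


def gauss(n, centre, sigma, amp):
    t = np.arange(n, dtype=float)
    return amp * np.exp(-((t - centre) ** 2) / (2 * sigma**2))


class TestWindows:
    def test_t_window_arithmetic(self):
        """RR(i+1) = 1000 ms -> T searched in [R+160 ms, R+570 ms]."""
        n = 4000
        smooth = gauss(n, 1000 + 150, 40.0, 0.3)  # just inside the lower edge
        beats = BeatSet(r_samples=np.array([1000, 2000, 3000]))
        t = detect_t(None, beats, smooth=smooth)
        assert t[0] is None or t[0] >= 1160  # nothing before R+160 is reachable
        smooth2 = gauss(n, 1300, 40.0, 0.3)
        t2 = detect_t(None, beats, smooth=smooth2)
        assert t2[0] == 1300

    def test_t_last_beat_uses_rr_surrogate(self):
        n = 4000
        smooth = gauss(n, 3000 + 300, 40.0, 0.3)
        beats = BeatSet(r_samples=np.array([1000, 2000, 3000]))
        t = detect_t(None, beats, smooth=smooth)
        assert t[2] == 3300  # window [R+160, R+570] from RR(i) = 1000

    def test_p_window_arithmetic(self):
        """RR(i) = 1000 ms -> P searched in [R-700 ms, R-70 ms]."""
        smooth = gauss(3000, 2000 - 300, 25.0, 0.15)
        cand = detect_p_candidate(smooth, FS, 2000, 1000)
        assert cand is not None and abs(cand.sample - 1700) <= 2
        # a wave just outside the window is not reachable
        outside = gauss(3000, 2000 - 30, 25.0, 0.15)
        cand2 = detect_p_candidate(outside, FS, 2000, 1000)
        assert cand2 is None or cand2.sample <= 1930

    def test_boundary_maximum_is_not_a_candidate(self):
        """A truncated falling flank at the window edge is not a P."""
        t = np.arange(3000, dtype=float)
        smooth = 0.3 * np.exp(-np.maximum(t - 1250, 0.0) / 150.0)
        cand = detect_p_candidate(smooth, FS, 2000, 1000)
        assert cand is None

    def test_window_collapse_returns_none(self):
        cand = detect_p_candidate(np.zeros(3000), FS, 50, 10)
        assert cand is None

    def test_dissociated_window_empty(self):
        """T at 0 ms, R at 400 ms: [200, 100] is empty -> no candidate."""
        assert dissociated_search(np.zeros(1000), FS, 0, 400) is None

    def test_dissociated_window_finds_blocked_p(self):
        smooth = gauss(3000, 1500, 25.0, 0.15)
        cand = dissociated_search(smooth, FS, 500, 2400)
        assert cand is not None and abs(cand.sample - 1500) <= 2
        assert cand.p_type == "dissociated"


class TestRefinePeak:
    def test_symmetric_gaussian_refines_to_peak(self):
        voltage = gauss(1000, 500, 25.0, 0.2)
        assert refine_peak(voltage, FS, 500) == 500

    def test_offset_candidate_recovered(self):
        voltage = gauss(1000, 500, 25.0, 0.2)
        assert refine_peak(voltage, FS, 510) == 500  # 10 ms off, within +-20

    def test_negative_p_refines_to_trough(self):
        voltage = -gauss(1000, 500, 25.0, 0.2)
        assert refine_peak(voltage, FS, 507) == 500


def make_rule_fixture(rr=(1000, 1000, 1000)):
    """Four-beat scaffold with controllable RR sequence at 1 kHz.

    Returns (beats, t_samples, voltage, smooth); QRS spikes of 1 mV at each
    R, T bumps 300 ms after each R, P bumps 160 ms before each R.
    """
    r = np.cumsum((1000,) + tuple(rr))
    n = int(r[-1] + 1500)
    voltage = np.zeros(n)
    smooth = np.zeros(n)
    for rs in r:
        voltage += gauss(n, rs, 10.0, 1.0)
        smooth += gauss(n, rs, 12.0, 0.8)
        voltage += gauss(n, rs + 300, 50.0, 0.3)
        smooth += gauss(n, rs + 300, 50.0, 0.28)
        voltage += gauss(n, rs - 160, 25.0, 0.15)
        smooth += gauss(n, rs - 160, 25.0, 0.14)
    beats = BeatSet(r_samples=r)
    t_samples = [int(rs + 300) for rs in r]
    return beats, t_samples, voltage, smooth


def run_rules(beats, t_samples, voltage, smooth, labels=None, candidates=None,
              rules=ALL_RULES):
    labels = labels or ["other"] * len(beats)
    if candidates is None:
        candidates = {
            i: detect_p_candidate(smooth, FS, int(beats.r_samples[i]), beats.rr(i))
            for i in range(1, len(beats))
        }
    return apply_rules(
        candidates, beats, t_samples, labels, voltage, smooth, FS, rules=rules
    )


class TestDecisionRules:
    def test_rule_a_deletes_p_before_pvc(self):
        beats, t_samples, voltage, smooth = make_rule_fixture()
        labels = ["other", "other", "PVC", "other"]
        entries, audit = run_rules(beats, t_samples, voltage, smooth, labels)
        deleted = [a for a in audit if a["event"] == "rule_pvc"]
        assert len(deleted) == 1 and deleted[0]["beat"] == 2
        # no accepted P belongs to the PVC beat's window
        r_pvc = beats.r_samples[2]
        assert all(not (r_pvc - 700 <= s <= r_pvc) for s, _ in entries)

    def test_rule_a_skips_remaining_rules(self):
        beats, t_samples, voltage, smooth = make_rule_fixture()
        labels = ["other", "other", "PVC", "other"]
        _, audit = run_rules(beats, t_samples, voltage, smooth, labels)
        pvc_events = [a["event"] for a in audit if a["beat"] == 2]
        assert pvc_events == ["rule_pvc"]

    def test_rule_b_deletes_candidate_at_previous_t(self):
        beats, t_samples, voltage, smooth = make_rule_fixture()
        cand = {2: PCandidate(sample=t_samples[1] + 10, phase_value=1.0,
                              p_type="normal")}
        entries, audit = run_rules(
            beats, t_samples, voltage, smooth, candidates=cand
        )
        assert [a["event"] for a in audit if a["beat"] == 2] == ["rule_after_t"]

    def test_rule_c_triggers_dissociated_search(self):
        """RR(i)=1000 > 1.6 x RR(i-1)=600 and previous beat not PVC."""
        beats, t_samples, voltage, smooth = make_rule_fixture(rr=(600, 600, 1000))
        _, audit = run_rules(beats, t_samples, voltage, smooth)
        searches = [a for a in audit if a["event"] == "dissociated_search"]
        assert [a["beat"] for a in searches] == [3]

    def test_rule_c_suppressed_when_previous_is_pvc(self):
        beats, t_samples, voltage, smooth = make_rule_fixture(rr=(600, 600, 1000))
        labels = ["other", "other", "PVC", "other"]
        _, audit = run_rules(beats, t_samples, voltage, smooth, labels)
        assert not [a for a in audit if a["event"] == "dissociated_search"]

    def test_rule_d_sves_suppresses_dissociated_search(self):
        """RR(i-1)=500 < 0.85 x RR(i-2)=527 -> SVES assumed, no search."""
        beats, t_samples, voltage, smooth = make_rule_fixture(rr=(620, 500, 1000))
        _, audit = run_rules(beats, t_samples, voltage, smooth)
        assert [a["event"] for a in audit if a["beat"] == 3 and
                a["event"] in ("rule_sves", "dissociated_search")] == ["rule_sves"]

    def test_rule_d_inactive_when_ratio_not_met(self):
        """RR(i-1)=560 >= 0.85 x RR(i-2)=527 -> search proceeds."""
        beats, t_samples, voltage, smooth = make_rule_fixture(rr=(620, 560, 1000))
        _, audit = run_rules(beats, t_samples, voltage, smooth)
        assert [a for a in audit if a["event"] == "dissociated_search"]

    def test_rule_e_amplitude_floor(self):
        """U_P = 0.05 mV against U_QRS = 1.0 mV is deleted (0.05 <= 0.1)."""
        beats, t_samples, voltage, smooth = make_rule_fixture()
        weak = 1000 + 1000 - 400  # between T(0)+guard and R(1)
        voltage[weak - 60 : weak + 61] = 0.0
        voltage += gauss(voltage.size, weak, 20.0, 0.05)
        cand = {1: PCandidate(sample=weak, phase_value=0.5, p_type="normal")}
        entries, audit = run_rules(
            beats, t_samples, voltage, smooth, candidates=cand
        )
        events = [a["event"] for a in audit if a["beat"] == 1]
        assert events == ["rule_amplitude"]
        assert not any(abs(s - weak) < 50 for s, _ in entries)

    def test_rules_off_accepts_everything(self):
        beats, t_samples, voltage, smooth = make_rule_fixture()
        labels = ["other", "other", "PVC", "other"]
        entries_off, audit_off = run_rules(
            beats, t_samples, voltage, smooth, labels, rules=None
        )
        entries_on, _ = run_rules(beats, t_samples, voltage, smooth, labels)
        assert len(entries_off) >= len(entries_on)
        assert all(a["event"] == "accepted" for a in audit_off)


class TestEndToEnd:
    def test_sinus_t_and_p_found(self, sinus):
        rec, truth = sinus
        beats, _ = delineate_record(rec)
        t_det = [t for t in beats.t_samples if t is not None]
        assert match(t_det, truth.t_samples, 60.0, rec.fs).se == 100.0
        rep = match(beats.p_samples(), truth.p_samples, 60.0, rec.fs)
        assert rep.se == 100.0 and rep.pp == 100.0

    def test_avb2_blocked_p_typed_dissociated(self, avb2):
        rec, truth = avb2
        beats, audit = delineate_record(rec)
        true_dis = truth.p_samples[
            [i for i, t in enumerate(truth.p_types) if t == "dissociated"]
        ]
        det_dis = np.sort(beats.p_samples("dissociated"))
        rep = match(det_dis, true_dis, 60.0, rec.fs)
        assert rep.se == 100.0  # every blocked-cycle P found and typed
        assert [a for a in audit if a["event"] == "dissociated_search"]

    def test_dissociated_entries_inside_gap_bounds(self, avb2):
        rec, _ = avb2
        beats, _ = delineate_record(rec)
        fs = rec.fs
        t_by_sample = [t for t in beats.t_samples if t is not None]
        for s, kind in beats.p_entries:
            if kind != "dissociated":
                continue
            r_next = beats.r_samples[np.searchsorted(beats.r_samples, s)]
            t_prev = max(t for t in t_by_sample if t < s)
            assert t_prev + 0.2 * fs <= s <= r_next - 0.3 * fs + 25

    def test_no_p_attached_to_pvc(self, bigeminy):
        rec, truth = bigeminy
        beats, _ = delineate_record(rec)
        pvc_r = truth.r_samples[np.array(truth.beat_labels) == "PVC"]
        for s, _ in beats.p_entries:
            # no accepted P inside any PVC's pre-QRS neighbourhood
            assert not np.any((s > pvc_r - int(0.35 * rec.fs)) & (s <= pvc_r))

    def test_no_accepted_p_before_previous_t(self, sinus):
        rec, _ = sinus
        beats, _ = delineate_record(rec)
        t_det = np.array([t for t in beats.t_samples if t is not None])
        for s, _ in beats.p_entries:
            prev_t = t_det[t_det < s]
            if prev_t.size:
                assert s > prev_t.max()

    def test_rules_never_increase_false_positives(self, bigeminy):
        rec, truth = bigeminy
        on, _ = delineate_record(rec)
        off, _ = delineate_record(rec, rules=None)
        rep_on = match(on.p_samples(), truth.p_samples, 60.0, rec.fs)
        rep_off = match(off.p_samples(), truth.p_samples, 60.0, rec.fs)
        assert rep_on.fp <= rep_off.fp
        assert rep_on.pp >= rep_off.pp

    def test_rule_c_only_adds_true_positives_on_avb2(self, avb2):
        rec, truth = avb2
        with_c, _ = delineate_record(rec)
        without_c, _ = delineate_record(rec, rules=("a", "b", "d", "e"))
        rep_with = match(with_c.p_samples(), truth.p_samples, 60.0, rec.fs)
        rep_without = match(without_c.p_samples(), truth.p_samples, 60.0, rec.fs)
        assert rep_with.tp >= rep_without.tp

    def test_zero_amplitude_t_does_not_crash(self):
        beats_spec = [
            make_beat("normal", 0.5 + 0.8 * i, t=WaveParams(1e-9, 50.0, 250.0))
            for i in range(12)
        ]
        script = RhythmScript(fs=360.0, duration=11.0, beats=beats_spec)
        rec, _ = generate_record(script)
        beats, _ = delineate_record(rec)
        assert len(beats) == 12

    def test_negative_p_detected(self):
        p = WaveParams(-0.15, 25.0, -160.0)
        beats_spec = [make_beat("normal", 0.4 + i * 0.857, p=p) for i in range(40)]
        script = RhythmScript(fs=360.0, duration=35.0, beats=beats_spec)
        rec, truth = generate_record(script)
        beats, _ = delineate_record(rec)
        rep = match(beats.p_samples(), truth.p_samples, 60.0, rec.fs)
        assert rep.se == 100.0 and rep.pp == 100.0


def test_config_validation():
    with pytest.raises(ValueError):
        DelineationConfig(t_win=(0.5, 0.2)).validate()
    with pytest.raises(ValueError):
        DelineationConfig(p_win=(0.07, 0.70)).validate()
    with pytest.raises(ValueError):
        DelineationConfig(amp_ratio=-0.1).validate()
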