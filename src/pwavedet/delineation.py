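"""T wave and P wave detection with knowledge-based decision rules.

Detection runs on two isoelectric-referenced signals prepared once per
record (:func:`prepare_signals`): the baseline-removed ECG and its 40 ms
median-smoothed version, both minus a 600 ms rolling-median estimate of the
isoelectric line.  (A zero-DC high-passed ECG keeps its inter-beat baseline
slightly below zero; re-referencing to the isoelectric level is what lets
the sign-symmetric |arctan| phase rank wave deflections rather than the
baseline offset.)

Search windows are demarcated relative to the detected R peaks:

* T wave of beat i: phase maximum (phasor R_V = 0.1) in
  [R(i) + 0.16 x RR(i+1), R(i) + 0.57 x RR(i+1)]; the last beat substitutes
  RR(i) for the missing RR(i+1).
* P candidate of beat i: highest *interior* phase peak (R_V = 0.05) in
  [R(i) - 0.70 x RR(i), R(i) - 0.07 x RR(i)]; a maximum attained at the
  window boundary is the truncated flank of the neighbouring T wave, not a
  P.  The first beat substitutes RR(1) for its undefined RR.

Five decision rules then accept, delete or re-route each candidate:

a. the current beat is a PVC -> no P exists before it; delete the candidate
   and skip the remaining rules;
b. the candidate does not lie (clearly) after the previous beat's T wave ->
   the T was caught instead of a P; delete and skip the remaining rules;
c. RR(i) > 1.6 x RR(i-1) and the previous beat is not a PVC -> a blocked
   (dissociated) P may hide in the long interval; search the segment from
   200 ms after the previous T to 300 ms before R(i) with the normal P
   settings;
d. RR(i-1) < 0.85 x RR(i-2) -> the prolonged RR(i) is the pause after a
   supraventricular extrasystole, not an AV block; suppress the dissociated
   search;
e. a surviving candidate (normal or dissociated) is a real P wave only if
   U_P(i) > 0.1 x U_QRS(i), both measured on the isoelectric-referenced
   baseline-removed signal.

Accepted peaks are refined to the extremum of |signal| within +-20 ms of
the phase maximum, which honours negative and biphasic P waves.

When the pre-QRS candidate of the beat that ends a long RR gap coincides
with an accepted dissociated P (both searches latched onto the blocked P),
the pre-QRS search is repeated with that neighbourhood masked so the
conducted P is still found.

Every deletion, suppression and search is recorded in an audit log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .io_formats import EcgRecord
from .phasor import phasor_transform
from .preprocess import (
    FilterSpec,
    median_smooth,
    ms_to_samples,
    remove_baseline,
    rolling_median,
)
from .qrs_detection import BeatSet, QrsConfig, detect_qrs

__all__ = [
    "DelineationConfig",
    "PCandidate",
    "prepare_signals",
    "detect_t",
    "detect_p_candidate",
    "dissociated_search",
    "refine_peak",
    "apply_rules",
    "delineate_record",
    "ALL_RULES",
]

ALL_RULES = ("a", "b", "c", "d", "e")


@dataclass(frozen=True)
class DelineationConfig:
    """Constants of the T/P detection stage.

    The window fractions are of the neighbouring RR interval; ms quantities
    are converted per record via round(ms*fs/1000).
    """

    t_rv: float = 0.1
    t_win: tuple[float, float] = (0.16, 0.57)
    p_rv: float = 0.05
    p_win: tuple[float, float] = (0.70, 0.07)  # before R: [R-0.70RR, R-0.07RR]
    avb_ratio: float = 1.6
    dissoc_start_ms: float = 200.0  # after the previous T
    dissoc_end_ms: float = 300.0  # before the current R
    sves_ratio: float = 0.85
    amp_ratio: float = 0.1
    refine_halfwidth_ms: float = 20.0
    t_guard_ms: float = 80.0  # candidates within T +- guard count as "not after T"
    iso_window_ms: float = 600.0  # rolling-median isoelectric estimate
    coincide_ms: float = 40.0  # dissociated/pre-QRS candidates deemed identical
    mask_halfwidth_ms: float = 100.0  # masked neighbourhood on re-search

    def validate(self) -> None:
        ratios = (self.avb_ratio, self.sves_ratio, self.amp_ratio)
        if any(v <= 0 for v in ratios):
            raise ValueError("ratios must be positive")
        if not (0 < self.t_win[0] < self.t_win[1]):
            raise ValueError("t_win fractions must be increasing and positive")
        if not (0 < self.p_win[1] < self.p_win[0]):
            raise ValueError("p_win fractions must satisfy 0 < end < start")


@dataclass
class PCandidate:
    """A potential P wave and its fate under the decision rules."""

    sample: int  # phase-maximum sample
    phase_value: float
    p_type: str  # "normal" | "dissociated"
    status: str = "candidate"  # "candidate" | "accepted" | "deleted"
    reason: str | None = None  # rule_pvc | rule_after_t | rule_amplitude | ...
    refined_sample: int | None = None

    def delete(self, reason: str) -> None:
        self.status = "deleted"
        self.reason = reason


def prepare_signals(
    record: EcgRecord,
    filter_spec: FilterSpec | None = None,
    cfg: DelineationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Isoelectric-referenced signals for P/T detection.

    Returns ``(voltage, smooth)``: the baseline-removed ECG and its median-
    smoothed version, both re-referenced by subtracting the rolling-median
    isoelectric estimate of the smoothed signal.
    """
    spec = filter_spec or FilterSpec()
    cfg = cfg or DelineationConfig()
    hp = remove_baseline(record, spec)
    sm = median_smooth(hp, record.fs, spec.median_window)
    iso = rolling_median(sm, record.fs, cfg.iso_window_ms)
    return hp - iso, sm - iso


def _interior_peak_argmax(phase: np.ndarray) -> int | None:
    """Highest interior local maximum of a phase segment, or None."""
    peaks, _ = find_peaks(phase)
    if peaks.size == 0:
        return None
    return int(peaks[np.argmax(phase[peaks])])


def detect_t(
    record: EcgRecord | None,
    beats: BeatSet,
    cfg: DelineationConfig | None = None,
    filter_spec: FilterSpec | None = None,
    smooth: np.ndarray | None = None,
) -> list[int | None]:
    """Detect the T peak of every beat (None where the window collapses).

    ``smooth`` may carry the precomputed detection signal from
    :func:`prepare_signals`; otherwise it is derived from ``record``.
    """
    cfg = cfg or DelineationConfig()
    cfg.validate()
    if len(beats) < 2:
        raise ValueError("T detection needs at least 2 beats")
    if smooth is None:
        if record is None:
            raise ValueError("either record or smooth is required")
        _, smooth = prepare_signals(record, filter_spec, cfg)
    out: list[int | None] = []
    r = beats.r_samples
    for i in range(len(beats)):
        rr_next = r[i + 1] - r[i] if i + 1 < len(beats) else beats.rr(i)
        lo = max(r[i] + int(round(cfg.t_win[0] * rr_next)), 0)
        hi = min(r[i] + int(round(cfg.t_win[1] * rr_next)) + 1, smooth.size)
        if hi - lo < 3:
            warnings.warn(f"beat {i}: T window collapsed", stacklevel=2)
            out.append(None)
            continue
        phase = phasor_transform(smooth[lo:hi], cfg.t_rv).phase
        out.append(lo + int(np.argmax(phase)))
    return out


def detect_p_candidate(
    smooth: np.ndarray,
    fs: float,
    r_i: int,
    rr_i: int,
    cfg: DelineationConfig | None = None,
    mask: tuple[int, int] | None = None,
) -> PCandidate | None:
    """Pre-QRS P candidate: interior phase peak in [R - 0.70 RR, R - 0.07 RR].

    ``smooth`` is the isoelectric-referenced smoothed signal from
    :func:`prepare_signals`.  ``mask`` excludes a half-open sample range
    from the search (used by the masked re-search after a coinciding
    dissociated P).
    """
    cfg = cfg or DelineationConfig()
    lo = max(r_i - int(round(cfg.p_win[0] * rr_i)), 0)
    hi = min(r_i - int(round(cfg.p_win[1] * rr_i)) + 1, smooth.size)
    if hi - lo < 3:
        return None
    seg = smooth[lo:hi].copy()
    if mask is not None:
        mlo, mhi = max(mask[0] - lo, 0), min(mask[1] - lo, hi - lo)
        if mhi > mlo:
            seg[mlo:mhi] = 0.0
    phase = phasor_transform(seg, cfg.p_rv).phase
    k = _interior_peak_argmax(phase)
    if k is None:
        return None
    return PCandidate(sample=lo + k, phase_value=float(phase[k]), p_type="normal")


def dissociated_search(
    smooth: np.ndarray,
    fs: float,
    t_prev: int,
    r_i: int,
    cfg: DelineationConfig | None = None,
) -> PCandidate | None:
    """Search a long RR gap for a dissociated P wave.

    Window: [previous T + 200 ms, R(i) - 300 ms], with the same phasor
    settings as the normal P search; None when the window is empty or holds
    no interior phase peak.
    """
    cfg = cfg or DelineationConfig()
    lo = max(t_prev + ms_to_samples(cfg.dissoc_start_ms, fs), 0)
    hi = min(r_i - ms_to_samples(cfg.dissoc_end_ms, fs) + 1, smooth.size)
    if hi - lo < 3:
        return None
    phase = phasor_transform(smooth[lo:hi], cfg.p_rv).phase
    k = _interior_peak_argmax(phase)
    if k is None:
        return None
    return PCandidate(
        sample=lo + k, phase_value=float(phase[k]), p_type="dissociated"
    )


def refine_peak(
    voltage: np.ndarray,
    fs: float,
    sample: int,
    cfg: DelineationConfig | None = None,
) -> int:
    """Refine a phase maximum to the wave extremum in the voltage signal.

    Final sample = argmax of |isoelectric-referenced voltage| within
    +-20 ms of the phase maximum; the absolute value honours negative and
    biphasic P waves.
    """
    cfg = cfg or DelineationConfig()
    w = ms_to_samples(cfg.refine_halfwidth_ms, fs)
    lo, hi = max(sample - w, 0), min(sample + w + 1, voltage.size)
    return lo + int(np.argmax(np.abs(voltage[lo:hi])))


def _u_qrs(voltage: np.ndarray, r: int, fs: float) -> float:
    """QRS altitude U_QRS(i): max |voltage| over R +- 50 ms."""
    half = ms_to_samples(50.0, fs)
    lo, hi = max(r - half, 0), min(r + half + 1, voltage.size)
    return float(np.max(np.abs(voltage[lo:hi])))


def apply_rules(
    candidates: dict[int, PCandidate | None],
    beats: BeatSet,
    t_samples: list[int | None],
    labels: list[str],
    voltage: np.ndarray,
    smooth: np.ndarray,
    fs: float,
    cfg: DelineationConfig | None = None,
    rules: tuple[str, ...] | None = ALL_RULES,
) -> tuple[list[tuple[int, str]], list[dict]]:
    """Run the decision rules over all pre-QRS candidates.

    Parameters
    ----------
    candidates : beat index -> PCandidate (or None where no window existed).
    voltage, smooth : the two signals from :func:`prepare_signals`.
    rules : subset of ``("a", "b", "c", "d", "e")``; ``None`` or empty
        disables all rules (every candidate is refined and accepted) —
        used for ablation studies.

    Returns
    -------
    (p_entries, audit) : accepted (refined_sample, p_type) pairs in
        ascending order, and the per-beat audit log of rule firings.
    """
    cfg = cfg or DelineationConfig()
    cfg.validate()
    active = frozenset(rules or ())
    t_guard = ms_to_samples(cfg.t_guard_ms, fs)
    audit: list[dict] = []
    entries: list[tuple[int, str]] = []

    def log(beat: int, event: str, **extra) -> None:
        audit.append({"beat": int(beat), "event": event, **extra})

    def accept(beat: int, cand: PCandidate) -> None:
        cand.status = "accepted"
        entries.append((int(cand.refined_sample), cand.p_type))
        log(beat, "accepted", sample=int(cand.refined_sample), p_type=cand.p_type)

    def rule_e(beat: int, cand: PCandidate, u_qrs_i: float) -> bool:
        cand.refined_sample = refine_peak(voltage, fs, cand.sample, cfg)
        if "e" not in active:
            return True
        u_p = float(np.abs(voltage[cand.refined_sample]))
        if u_p > cfg.amp_ratio * u_qrs_i:
            return True
        cand.delete("rule_amplitude")
        log(
            beat,
            "rule_amplitude",
            sample=int(cand.refined_sample),
            u_p=u_p,
            u_qrs=u_qrs_i,
            p_type=cand.p_type,
        )
        return False

    def fails_rule_b(cand: PCandidate, t_prev: int | None) -> bool:
        return t_prev is not None and cand.sample <= t_prev + t_guard

    n = len(beats)
    r = beats.r_samples
    for i in range(0, n):
        cand = candidates.get(i)
        u_qrs_i = _u_qrs(voltage, int(r[i]), fs)

        # rule a: no P wave exists before a PVC
        if "a" in active and labels[i] == "PVC":
            if cand is not None:
                cand.delete("rule_pvc")
                log(i, "rule_pvc", sample=int(cand.sample))
            continue  # rules b-e skipped

        # rule b: the previous T was caught instead of a P
        t_prev = (
            t_samples[i - 1] if 0 < i and i - 1 < len(t_samples) else None
        )
        if "b" in active and cand is not None and fails_rule_b(cand, t_prev):
            cand.delete("rule_after_t")
            log(i, "rule_after_t", sample=int(cand.sample), t_prev=int(t_prev))
            continue  # rules c-e skipped

        # rules c and d: dissociated P search in a prolonged RR interval
        dis: PCandidate | None = None
        if "c" in active and i >= 2:
            rr_i, rr_prev = beats.rr(i), beats.rr(i - 1)
            if rr_i > cfg.avb_ratio * rr_prev and labels[i - 1] != "PVC":
                sves = (
                    "d" in active
                    and i >= 3
                    and rr_prev < cfg.sves_ratio * beats.rr(i - 2)
                )
                if sves:
                    log(i, "rule_sves", rr_prev=rr_prev, rr_prev2=beats.rr(i - 2))
                elif t_prev is not None:
                    dis = dissociated_search(smooth, fs, int(t_prev), int(r[i]), cfg)
                    log(
                        i,
                        "dissociated_search",
                        found=dis is not None,
                        sample=None if dis is None else int(dis.sample),
                    )

        # rule e on the dissociated candidate first
        if dis is not None and rule_e(i, dis, u_qrs_i):
            accept(i, dis)

        if cand is None:
            continue
        cand.refined_sample = refine_peak(voltage, fs, cand.sample, cfg)

        # both searches latched onto the same (blocked) P: re-search the
        # pre-QRS window with that neighbourhood masked
        if (
            dis is not None
            and dis.status == "accepted"
            and abs(cand.refined_sample - dis.refined_sample)
            <= ms_to_samples(cfg.coincide_ms, fs)
        ):
            half = ms_to_samples(cfg.mask_halfwidth_ms, fs)
            masked = detect_p_candidate(
                smooth,
                fs,
                int(r[i]),
                beats.rr(i),
                cfg,
                mask=(dis.refined_sample - half, dis.refined_sample + half + 1),
            )
            log(
                i,
                "masked_research",
                found=masked is not None,
                sample=None if masked is None else int(masked.sample),
            )
            cand.delete("rule_duplicate_dissociated")
            if masked is None:
                continue
            cand = masked
            if "b" in active and fails_rule_b(cand, t_prev):
                cand.delete("rule_after_t")
                log(i, "rule_after_t", sample=int(cand.sample), t_prev=int(t_prev))
                continue

        if rule_e(i, cand, u_qrs_i):
            accept(i, cand)

    entries.sort()
    return entries, audit


_default_model = None


def _get_default_model():
    global _default_model
    if _default_model is None:
        from .pvc_classifier import train_default_classifier

        _default_model = train_default_classifier()
    return _default_model


def delineate_record(
    record: EcgRecord,
    qrs_cfg: QrsConfig | None = None,
    cfg: DelineationConfig | None = None,
    filter_spec: FilterSpec | None = None,
    classifier=None,
    rules: tuple[str, ...] | None = ALL_RULES,
    enable_backward_search: bool = True,
) -> tuple[BeatSet, list[dict]]:
    """Run the full pipeline: QRS -> T -> features -> PVC labels -> rules -> P.

    Returns the completed :class:`BeatSet` (R, labels, T, accepted P entries)
    and the decision-rule audit log.  ``classifier=None`` uses a cached
    default 1-NN model trained on synthetic presets.
    """
    from .pvc_classifier import extract_features

    spec = filter_spec or FilterSpec()
    cfg = cfg or DelineationConfig()
    beats = detect_qrs(
        record, qrs_cfg, spec, enable_backward_search=enable_backward_search
    )
    n = len(beats)
    if n < 3:
        beats.t_samples = [None] * n
        return beats, [{"beat": -1, "event": "too_few_beats", "n": n}]

    fs = record.fs
    voltage, smooth = prepare_signals(record, spec, cfg)
    t_samples = detect_t(record, beats, cfg, spec, smooth=smooth)

    labels = ["other"] * n
    X, idx = extract_features(record, beats, spec)
    if X.size:
        model = classifier or _get_default_model()
        for k, label in zip(idx, model.predict(X)):
            labels[k] = str(label)
    beats.labels = labels

    candidates = {
        i: detect_p_candidate(smooth, fs, int(beats.r_samples[i]), beats.rr(i), cfg)
        for i in range(1, n)
    }
    # boundary beat: RR(0) is undefined; search with the following interval
    # as a surrogate (mirrors the last beat's T-window surrogate)
    candidates[0] = detect_p_candidate(
        smooth, fs, int(beats.r_samples[0]), beats.rr(1), cfg
    )
    entries, audit = apply_rules(
        candidates, beats, t_samples, labels, voltage, smooth, fs, cfg, rules
    )
    beats.t_samples = t_samples
    beats.p_entries = entries
    return beats, audit
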