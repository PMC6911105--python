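"""QRS detection on the phase signal with adaptive threshold and backward search.

The detector runs the QRS-band signal (12-19 Hz bandpass) through the phasor
transform with R_V = 0.001 and chains 300 ms maximum-search windows along the
phase signal: each window begins at the previously discovered maximum, so at
most one candidate arises per 300 ms (the physiological upper bound on heart
rate).  A candidate is kept when its phase exceeds an adaptive threshold —
twice the standard deviation of the phase over a centred 2 s window.  A
200 ms refractory rule resolves near-coincident acceptances in favour of the
larger phase value.

Units: the bandpassed millivolt signal is rescaled to volts before the
phasor, so that R_V = 0.001 is commensurate with a typical QRS deflection
(~3e-4 V after bandpassing a 1 mV R wave).  On that scale the arctangent has
dynamic range — attenuated beats genuinely fall below the adaptive threshold
instead of saturating at pi/2 — which is what gives the backward search
something to do.

Backward search: whenever RR(i) >= 1.75 x RR(i-1) a beat was probably missed
inside the long interval.  The magnitude signal M(n) is searched inside the
gap (excluding a 200 ms guard around the flanking beats) and the maximum is
added as a beat if its deflection amplitude sqrt(M^2 - R_V^2) = |x| exceeds
0.3 x the deflection of the previously detected R wave.  The pass iterates
until no gap qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import EcgRecord
from .phasor import phasor_transform
from .preprocess import FilterSpec, bandpass_qrs, ms_to_samples

__all__ = ["QrsConfig", "BeatSet", "detect_qrs", "adaptive_threshold", "backward_search"]

_MV_TO_V = 1e-3


@dataclass(frozen=True)
class QrsConfig:
    """Constants of the QRS detector.

    rv : phasor constant for the QRS stage (volt scale).
    search_window_ms : length of the chained maximum-search window.
    threshold_window_ms : window of the rolling-std adaptive threshold.
    threshold_mult : threshold = mult x rolling std.
    missed_ratio : RR(i) >= ratio x RR(i-1) triggers backward search.
    backward_mult : amplitude floor of backward search, x previous R.
    refractory_ms : minimum spacing between accepted beats.
    """

    rv: float = 0.001
    search_window_ms: float = 300.0
    threshold_window_ms: float = 2000.0
    threshold_mult: float = 2.0
    missed_ratio: float = 1.75
    backward_mult: float = 0.3
    refractory_ms: float = 200.0
    r_refine_ms: float = 60.0
    # absolute phase floor (rad): a candidate must also represent a physical
    # deflection (~0.01 mV after bandpassing), not numerical filter ripple in
    # an otherwise silent stretch where the rolling std collapses
    min_phase: float = 0.01

    def validate(self) -> None:
        vals = (
            self.rv,
            self.search_window_ms,
            self.threshold_window_ms,
            self.threshold_mult,
            self.missed_ratio,
            self.backward_mult,
            self.refractory_ms,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all QrsConfig fields must be positive")
        if self.missed_ratio <= 1:
            raise ValueError("missed_ratio must exceed 1")


@dataclass
class BeatSet:
    """Per-beat fiducials of one record.

    ``r_samples`` are strictly ascending 0-based R-peak indices;
    ``labels`` ("PVC"/"other") align with them.  ``t_samples`` (T peak or
    None per beat) and ``p_entries`` ((sample, p_type) pairs) are filled by
    the delineation stage.
    """

    r_samples: np.ndarray
    labels: list[str] = field(default_factory=list)
    t_samples: list[int | None] = field(default_factory=list)
    p_entries: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r_samples = np.asarray(self.r_samples, dtype=int)
        if np.any(np.diff(self.r_samples) <= 0):
            raise ValueError("r_samples must be strictly ascending")
        if not self.labels:
            self.labels = ["other"] * self.r_samples.size

    def __len__(self) -> int:
        return int(self.r_samples.size)

    def rr(self, i: int) -> int:
        """RR(i) = R(i) - R(i-1), in samples (i >= 1)."""
        return int(self.r_samples[i] - self.r_samples[i - 1])

    def p_samples(self, p_type: str | None = None) -> np.ndarray:
        return np.array(
            [s for s, k in self.p_entries if p_type is None or k == p_type],
            dtype=int,
        )

    def to_annotations(self) -> "AnnotationSet":
        """Flatten to an AnnotationSet (R, PVC labels, T, typed P entries)."""
        from .io_formats import AnnEntry, AnnotationSet

        entries = []
        for r, label in zip(self.r_samples, self.labels):
            entries.append(AnnEntry(int(r), "R"))
            if label == "PVC":
                entries.append(AnnEntry(int(r), "PVC"))
        for t in self.t_samples:
            if t is not None:
                entries.append(AnnEntry(int(t), "T"))
        for s, p_type in self.p_entries:
            entries.append(AnnEntry(int(s), "P", p_type))
        return AnnotationSet(entries)


def adaptive_threshold(
    phase: np.ndarray, fs: float, cfg: QrsConfig | None = None
) -> np.ndarray:
    """Rolling adaptive threshold: ``threshold_mult`` x std over a centred window.

    The window (default 2 s) shrinks symmetrically at the record edges.
    A constant phase yields a zero threshold everywhere; scaling the phase
    scales the threshold by the same factor.
    """
    cfg = cfg or QrsConfig()
    phase = np.asarray(phase, dtype=float)
    w = ms_to_samples(cfg.threshold_window_ms, fs)
    if phase.size < w:
        raise ValueError("phase shorter than the threshold window")
    half = w // 2
    n = phase.size
    # centre on the global mean before the cumulative sums: the rolling
    # variance is shift-invariant, and this avoids catastrophic cancellation
    # for a (near-)constant phase
    p0 = phase - phase.mean()
    c1 = np.concatenate(([0.0], np.cumsum(p0)))
    c2 = np.concatenate(([0.0], np.cumsum(p0**2)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    cnt = hi - lo
    s1 = c1[hi] - c1[lo]
    s2 = c2[hi] - c2[lo]
    var = np.maximum(s2 / cnt - (s1 / cnt) ** 2, 0.0)
    return cfg.threshold_mult * np.sqrt(var)


def _chain_candidates(phase: np.ndarray, window: int) -> list[int]:
    """Chained max search: each window begins at the previous maximum."""
    n = phase.size
    if n == 0:
        return []
    first = int(np.argmax(phase[: min(window, n)]))  # ties -> earlier sample
    cand = [first]
    pos = first
    while pos + 1 < n:
        seg = phase[pos + 1 : pos + 1 + window]
        m = pos + 1 + int(np.argmax(seg))
        cand.append(m)
        pos = m
    return cand


def _apply_refractory(
    candidates: list[int], phase: np.ndarray, refractory: int
) -> list[int]:
    accepted: list[int] = []
    for c in candidates:
        if accepted and c - accepted[-1] < refractory:
            # keep the stronger of the two near-coincident detections
            if phase[c] > phase[accepted[-1]]:
                accepted[-1] = c
        else:
            accepted.append(c)
    return accepted


def backward_search(
    r_list: np.ndarray | list[int],
    magnitude: np.ndarray,
    fs: float,
    cfg: QrsConfig | None = None,
) -> np.ndarray:
    """Recover missed beats inside prolonged RR intervals.

    For every interval with RR(i) >= ``missed_ratio`` x RR(i-1), the maximum
    of the magnitude signal M(n) inside the gap (excluding a refractory
    guard around the flanking beats) is added as a beat iff its deflection
    amplitude sqrt(M^2 - R_V^2) exceeds ``backward_mult`` x the deflection of
    the preceding detected R wave.  Repeats until no gap qualifies; never
    removes existing beats.
    """
    cfg = cfg or QrsConfig()
    r = sorted(int(v) for v in r_list)
    if len(r) < 2:
        return np.asarray(r, dtype=int)
    guard = ms_to_samples(cfg.refractory_ms, fs)
    deflection = np.sqrt(np.maximum(magnitude**2 - cfg.rv**2, 0.0))
    changed = True
    while changed:
        changed = False
        for i in range(2, len(r)):
            rr_i = r[i] - r[i - 1]
            rr_prev = r[i - 1] - r[i - 2]
            if rr_i < cfg.missed_ratio * rr_prev:
                continue
            lo, hi = r[i - 1] + guard, r[i] - guard
            if hi - lo < 1:
                continue
            m = lo + int(np.argmax(magnitude[lo:hi]))
            if deflection[m] > cfg.backward_mult * deflection[r[i - 1]]:
                r.insert(i, m)
                changed = True
                break
    return np.asarray(r, dtype=int)


def detect_qrs(
    record: EcgRecord,
    cfg: QrsConfig | None = None,
    filter_spec: FilterSpec | None = None,
    enable_backward_search: bool = True,
) -> BeatSet:
    """Detect R peaks in a record.

    Pipeline: QRS bandpass -> phasor transform (R_V = 0.001, volt scale) ->
    chained 300 ms maximum search -> adaptive threshold -> refractory ->
    backward search.  Returned indices are on the original sampling grid
    (the filters are delay-compensated).
    """
    cfg = cfg or QrsConfig()
    cfg.validate()
    if record.duration * 1000.0 < 2 * cfg.threshold_window_ms:
        raise ValueError(
            "record must be at least twice the threshold window "
            f"({2 * cfg.threshold_window_ms / 1000:.0f} s)"
        )
    fs = record.fs
    bp = bandpass_qrs(record, filter_spec)
    pt = phasor_transform(bp * _MV_TO_V, cfg.rv)
    phase = pt.phase

    window = ms_to_samples(cfg.search_window_ms, fs)
    refractory = ms_to_samples(cfg.refractory_ms, fs)
    thresh = adaptive_threshold(phase, fs, cfg)

    floor = np.maximum(thresh, cfg.min_phase)
    cand = [c for c in _chain_candidates(phase, window) if phase[c] > floor[c]]
    accepted = _apply_refractory(cand, phase, refractory)
    r = np.asarray(accepted, dtype=int)
    if enable_backward_search and r.size >= 2:
        r = backward_search(r, pt.magnitude, fs, cfg)
    if r.size:
        r = _refine_r(r, record, fs, cfg, filter_spec)
    return BeatSet(r_samples=r)


def _refine_r(
    r: np.ndarray,
    record: EcgRecord,
    fs: float,
    cfg: QrsConfig,
    filter_spec: FilterSpec | None,
) -> np.ndarray:
    """Move each detection to the dominant QRS deflection.

    The phase maximum of the bandpassed signal sits on the *sharpest* QRS
    component (often a narrow S wave), not necessarily the largest one;
    each beat is relocated to the extremum of the isoelectric-referenced,
    baseline-removed voltage within +-60 ms.
    """
    from .preprocess import remove_baseline, rolling_median

    hp = remove_baseline(record, filter_spec)
    hp = hp - rolling_median(hp, fs, 600.0)
    w = ms_to_samples(cfg.r_refine_ms, fs)
    out = []
    for c in r:
        lo, hi = max(c - w, 0), min(c + w + 1, hp.size)
        out.append(lo + int(np.argmax(np.abs(hp[lo:hi]))))
    return np.unique(np.asarray(out, dtype=int))
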