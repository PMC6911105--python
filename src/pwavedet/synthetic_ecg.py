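"""Scripted synthetic ECG with exact ground-truth fiducials.

Every downstream stage of the delineation pipeline is exercised against
records produced here, so the generator favours *controllability* over
physiological realism: each wave is a Gaussian kernel (a QRS complex is a
Q/R/S triplet of three Gaussians), beats are scheduled explicitly, and the
scheduled wave-peak samples are returned as ground truth.  Additive white
Gaussian noise and a sinusoidal baseline wander emulate the disturbances the
0.67 Hz high-pass and the median smoother are designed to absorb.

Beat types
----------
``normal``
    P-QRS-T in the usual order.
``pvc``
    Premature ventricular contraction: wide QRS (R sigma at least 1.5x the
    normal preset), no P wave, inverted T.
``blocked_p``
    A P wave whose conduction is blocked (second-degree AV block): P present,
    QRS and T absent.
``nodal``
    Junctional beat: QRS and T present, P absent (or hidden).
``sves``
    Supraventricular extrasystole: normal morphology, scheduled early.

Rhythm presets (:func:`preset`) assemble these into normal sinus rhythm,
second-degree AV block (``avb2``), ventricular bigeminy/trigeminy, nodal
rhythm and a sinus-with-SVES mix, with defaults chosen as typical MLII
magnitudes: P 0.15 mV / sigma 25 ms at -160 ms before R, R 1.0 mV /
sigma 12 ms, T 0.3 mV / sigma 50 ms at +250 ms; PVC R 1.3 mV / sigma 30 ms
with an inverted T and no P.

All indices are 0-based samples; regeneration with the same script (same
seed) is bit-identical.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .io_formats import EcgRecord

__all__ = [
    "WaveParams",
    "BeatSpec",
    "RhythmScript",
    "GroundTruth",
    "render_beat",
    "generate_record",
    "preset",
    "PRESET_NAMES",
    "NORMAL_MORPHOLOGY",
    "PVC_MORPHOLOGY",
]

_MIN_BEAT_SPACING_S = 0.250
_NORMAL_R_SIGMA_MS = 12.0


@dataclass(frozen=True)
class WaveParams:
    """One rendered wave: a Gaussian (or biphasic Gaussian pair) kernel.

    Attributes
    ----------
    amplitude : float
        Peak voltage in mV; negative for negative waves.
    width : float
        Gaussian sigma in ms (> 0).
    offset : float
        Signed delay of the wave peak from the beat anchor, in ms.
    shape : {"gaussian", "biphasic-pair"}
        ``biphasic-pair`` renders two opposite-sign Gaussians centred
        ``width`` ms either side of ``offset`` (positive lobe first).
    """

    amplitude: float
    width: float
    offset: float = 0.0
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("wave width must be positive")
        if self.shape not in ("gaussian", "biphasic-pair"):
            raise ValueError(f"unknown wave shape {self.shape!r}")


# Typical MLII morphology; Q and S are small narrow negative deflections
# flanking R.
NORMAL_MORPHOLOGY = {
    "p": WaveParams(0.15, 25.0, -160.0),
    "qrs": (
        WaveParams(-0.10, 6.0, -26.0),
        WaveParams(1.00, _NORMAL_R_SIGMA_MS, 0.0),
        WaveParams(-0.20, 7.0, 26.0),
    ),
    "t": WaveParams(0.30, 50.0, 250.0),
}

# A PVC is wide and slurred (R sigma 30 ms) but still carries the sharp,
# deep terminal deflection every real ventricular beat shows; without that
# fast S component the beat would have no QRS-band (12-19 Hz) energy at all,
# which no real PVC lacks.
PVC_MORPHOLOGY = {
    "p": None,
    "qrs": (
        WaveParams(-0.20, 12.0, -60.0),
        WaveParams(1.30, 30.0, 0.0),
        WaveParams(-0.90, 10.0, 50.0),
    ),
    "t": WaveParams(-0.35, 60.0, 300.0),  # discordant (inverted) T
}

BEAT_TYPES = ("normal", "pvc", "blocked_p", "nodal", "sves")


@dataclass(frozen=True)
class BeatSpec:
    """One scheduled beat: anchor time plus optional P, QRS triplet and T.

    ``onset`` is the anchor in seconds from record start (the R peak for
    beats with a QRS; for ``blocked_p`` it is where the R would have been,
    with the P at its usual offset before it).
    """

    beat_type: str
    onset: float
    p: WaveParams | None = None
    qrs: tuple[WaveParams, WaveParams, WaveParams] | None = None
    t: WaveParams | None = None

    def __post_init__(self) -> None:
        if self.beat_type not in BEAT_TYPES:
            raise ValueError(f"unknown beat type {self.beat_type!r}")
        if self.beat_type == "pvc":
            if self.p is not None:
                raise ValueError("PVC beats carry no P wave")
            if self.qrs is None or self.qrs[1].width < 1.5 * _NORMAL_R_SIGMA_MS:
                raise ValueError(
                    "PVC requires a QRS with R width >= 1.5x the normal preset"
                )
        if self.beat_type == "blocked_p":
            if self.qrs is not None or self.t is not None:
                raise ValueError("blocked_p beats have no QRS or T")
            if self.p is None:
                raise ValueError("blocked_p beats must carry a P wave")
        if self.beat_type == "nodal" and self.p is not None:
            raise ValueError("nodal beats carry no P wave")

    @property
    def r_offset_ms(self) -> float:
        return self.qrs[1].offset if self.qrs else 0.0


def _default_waves(beat_type: str) -> dict:
    morph = PVC_MORPHOLOGY if beat_type == "pvc" else NORMAL_MORPHOLOGY
    morph = copy.deepcopy(morph)
    if beat_type == "blocked_p":
        morph["qrs"] = None
        morph["t"] = None
    if beat_type in ("nodal", "pvc"):
        morph["p"] = None
    return morph


def make_beat(beat_type: str, onset: float, **overrides) -> BeatSpec:
    """Build a BeatSpec of the given type with the preset morphology."""
    waves = _default_waves(beat_type)
    waves.update(overrides)
    return BeatSpec(beat_type=beat_type, onset=onset, **waves)


@dataclass
class RhythmScript:
    """Declarative description of a synthetic record.

    ``noise_rms`` is the standard deviation of the additive white Gaussian
    noise in mV; ``baseline_wander`` is an (amplitude mV, frequency Hz)
    sinusoid.  Beat onsets must be strictly increasing and at least 250 ms
    apart; ``fs`` must be at least 250 Hz.
    """

    fs: float
    duration: float
    beats: list[BeatSpec] = field(default_factory=list)
    noise_rms: float = 0.0
    baseline_wander: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def validate(self) -> None:
        if self.fs < 250:
            raise ValueError("fs must be at least 250 Hz")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        onsets = [b.onset for b in self.beats]
        for a, b in zip(onsets, onsets[1:]):
            if b - a < _MIN_BEAT_SPACING_S:
                raise ValueError(
                    f"beats at {a:.3f}s and {b:.3f}s overlap "
                    f"(closer than {_MIN_BEAT_SPACING_S * 1000:.0f} ms)"
                )

    def to_json(self) -> str:
        """Serialise the script (documented schema, reversible)."""
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RhythmScript":
        raw = json.loads(text)

        def wave(d):
            return None if d is None else WaveParams(**d)

        beats = [
            BeatSpec(
                beat_type=b["beat_type"],
                onset=b["onset"],
                p=wave(b.get("p")),
                qrs=None
                if b.get("qrs") is None
                else tuple(wave(w) for w in b["qrs"]),
                t=wave(b.get("t")),
            )
            for b in raw.pop("beats")
        ]
        raw["baseline_wander"] = tuple(raw.get("baseline_wander", (0.0, 0.0)))
        return cls(beats=beats, **raw)


@dataclass
class GroundTruth:
    """Scheduled wave-peak samples and per-beat labels.

    ``r_samples``/``beat_labels`` cover beats with a QRS (label ``"PVC"`` or
    ``"other"``); ``p_samples``/``p_types`` cover every scheduled P wave
    (``"dissociated"`` for blocked beats, else ``"normal"``); ``t_samples``
    every scheduled T.
    """

    r_samples: np.ndarray
    p_samples: np.ndarray
    t_samples: np.ndarray
    beat_labels: list[str]
    p_types: list[str]

    def to_annotations(self):
        """Flatten to an io_formats.AnnotationSet (R, PVC, T, typed P)."""
        from .io_formats import AnnEntry, AnnotationSet

        entries = []
        for r, label in zip(self.r_samples, self.beat_labels):
            entries.append(AnnEntry(int(r), "R"))
            if label == "PVC":
                entries.append(AnnEntry(int(r), "PVC"))
        for t in self.t_samples:
            entries.append(AnnEntry(int(t), "T"))
        for p, p_type in zip(self.p_samples, self.p_types):
            entries.append(AnnEntry(int(p), "P", p_type))
        return AnnotationSet(entries)


def _add_wave(t: np.ndarray, out: np.ndarray, wave: WaveParams, anchor_s: float):
    centre = anchor_s + wave.offset / 1000.0
    sigma = wave.width / 1000.0
    if wave.shape == "gaussian":
        out += wave.amplitude * np.exp(-((t - centre) ** 2) / (2 * sigma**2))
    else:  # biphasic-pair: positive lobe then negative lobe
        for sign, shift in ((1.0, -sigma), (-1.0, sigma)):
            out += (
                sign
                * wave.amplitude
                * np.exp(-((t - centre - shift) ** 2) / (2 * sigma**2))
            )


def render_beat(spec: BeatSpec, fs: float, duration: float | None = None) -> np.ndarray:
    """Render one beat on its own time axis (anchor at ``duration/2``).

    Returns the sum of the Gaussian kernels of the waves present; absent
    waves contribute zero.  Mainly a building block for tests and fixtures —
    :func:`generate_record` renders whole scripts.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    duration = duration if duration is not None else 1.2
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    out = np.zeros(n)
    anchor = duration / 2.0
    waves = [spec.p, spec.t] + (list(spec.qrs) if spec.qrs else [])
    for wave in waves:
        if wave is not None:
            _add_wave(t, out, wave, anchor)
    return out


def generate_record(script: RhythmScript) -> tuple[EcgRecord, GroundTruth]:
    """Render a script into an ECG record plus exact ground truth.

    The record has ``round(duration*fs)`` samples; noise and baseline wander
    are drawn from ``numpy.random.default_rng(script.seed)``, so the same
    script regenerates bit-identically.  Ground-truth indices are the
    scheduled wave-peak samples (``round(time*fs)``).
    """
    script.validate()
    fs = script.fs
    n = int(round(script.duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)

    r_samples, t_samples, p_samples = [], [], []
    beat_labels, p_types = [], []
    for beat in script.beats:
        for wave in ([beat.p, beat.t] + (list(beat.qrs) if beat.qrs else [])):
            if wave is not None:
                _add_wave(t, x, wave, beat.onset)
        if beat.qrs is not None:
            r_samples.append(
                int(round((beat.onset + beat.qrs[1].offset / 1000.0) * fs))
            )
            beat_labels.append("PVC" if beat.beat_type == "pvc" else "other")
        if beat.t is not None:
            t_samples.append(
                int(round((beat.onset + beat.t.offset / 1000.0) * fs))
            )
        if beat.p is not None:
            p_samples.append(
                int(round((beat.onset + beat.p.offset / 1000.0) * fs))
            )
            p_types.append(
                "dissociated" if beat.beat_type == "blocked_p" else "normal"
            )

    rng = np.random.default_rng(script.seed)
    amp, freq = script.baseline_wander
    if amp != 0.0 and freq != 0.0:
        phase = rng.uniform(0, 2 * np.pi)
        x = x + amp * np.sin(2 * np.pi * freq * t + phase)
    if script.noise_rms > 0:
        x = x + rng.normal(0.0, script.noise_rms, size=n)

    for arr in (r_samples, t_samples, p_samples):
        if arr and (arr[0] < 0 or arr[-1] >= n):
            raise ValueError("scheduled wave peak outside the record")

    truth = GroundTruth(
        r_samples=np.array(r_samples, dtype=int),
        p_samples=np.array(p_samples, dtype=int),
        t_samples=np.array(t_samples, dtype=int),
        beat_labels=beat_labels,
        p_types=p_types,
    )
    return EcgRecord(samples=x, fs=fs, lead="synthetic"), truth


# ---------------------------------------------------------------------------
# rhythm presets

PRESET_NAMES = (
    "normal_sinus",
    "avb2",
    "bigeminy",
    "trigeminy",
    "nodal",
    "sves_mix",
)

# Realistic default disturbances; pass noise_rms=0 / baseline_wander=(0, 0)
# for the noise-free variants used in controlled experiments.
_DEFAULT_NOISE_RMS = 0.02
_DEFAULT_WANDER = (0.10, 0.30)


def preset(
    name: str,
    duration: float = 60.0,
    fs: float = 360.0,
    seed: int = 0,
    heart_rate: float = 70.0,
    noise_rms: float = _DEFAULT_NOISE_RMS,
    baseline_wander: tuple[float, float] = _DEFAULT_WANDER,
) -> RhythmScript:
    """Build a RhythmScript for a named rhythm.

    ``heart_rate`` (bpm) sets the base cycle length: the sinus RR for
    ``normal_sinus``/``nodal``/``sves_mix``, the atrial P-P interval for
    ``avb2``, and the underlying sinus interval for bigeminy/trigeminy.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    rr = 60.0 / heart_rate
    margin = 0.40  # keep first P and last T inside the record
    beats: list[BeatSpec] = []

    if name == "normal_sinus":
        t0 = margin
        while t0 < duration - margin:
            beats.append(make_beat("normal", t0))
            t0 += rr
    elif name == "nodal":
        t0 = margin
        while t0 < duration - margin:
            beats.append(make_beat("nodal", t0))
            t0 += rr
    elif name == "avb2":
        # Regular atrial clock; every 4th P blocked (4:3 conduction).
        k, i = 4, 0
        t0 = margin
        while t0 < duration - margin:
            kind = "blocked_p" if (i % k) == k - 1 else "normal"
            beats.append(make_beat(kind, t0))
            i += 1
            t0 += rr
    elif name == "bigeminy":
        # two-beat sinus run-in (ectopy onsets from sinus rhythm), then
        # normal / PVC pairs; PVC coupled early, full compensatory pause
        couple = max(0.45, 0.55 * rr)
        beats.append(make_beat("normal", margin))
        beats.append(make_beat("normal", margin + rr))
        t0 = margin + 2 * rr
        while t0 + couple < duration - margin:
            beats.append(make_beat("normal", t0))
            beats.append(make_beat("pvc", t0 + couple))
            t0 += 2 * rr
    elif name == "trigeminy":
        couple = max(0.45, 0.55 * rr)
        t0 = margin
        while t0 + rr + couple < duration - margin:
            beats.append(make_beat("normal", t0))
            beats.append(make_beat("normal", t0 + rr))
            beats.append(make_beat("pvc", t0 + rr + couple))
            t0 += 3 * rr
    elif name == "sves_mix":
        # every 5th beat arrives early (at 0.65 RR after its predecessor)
        # and the following sinus beat stays on the grid, so the SVES is
        # followed by a compensatory-like prolonged interval
        t0 = margin
        i = 0
        while t0 < duration - margin:
            if i % 5 == 3:
                beats.append(make_beat("sves", t0 - 0.35 * rr))
            else:
                beats.append(make_beat("normal", t0))
            i += 1
            t0 += rr

    return RhythmScript(
        fs=fs,
        duration=duration,
        beats=beats,
        noise_rms=noise_rms,
        baseline_wander=baseline_wander,
        seed=seed,
    )
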