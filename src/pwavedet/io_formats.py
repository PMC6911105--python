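"""Reading and writing ECG records and fiducial annotations.

Two record formats are supported:

* plain CSV — one voltage sample (mV) per line; the sampling frequency must
  be supplied by the caller;
* WFDB — the PhysioNet header/signal pair (``.hea`` + ``.dat``), signal
  format 16 (16-bit little-endian integers).  Gain and baseline from the
  header are applied so that samples come out in millivolts.  The codec is a
  deliberately small subset of the WFDB specification, sufficient for
  single/multi-channel format-16 records such as the arrhythmia-database
  recordings (360 Hz, MLII first channel).

Annotations travel either as a CSV dialect with the exact header
``sample,kind,subtype`` (comma separated, LF line endings, sorted — bit-exact
round trips) or as MIT-format binary annotation files.  The WFDB annotation
code mapping used is::

    kind  code  meaning
    R        1  normal beat (QRS fiducial)
    PVC      5  premature ventricular contraction (beat label)
    P       24  P wave peak
    T       27  T wave peak

The ``dissociated`` subtype of P entries is carried in the MIT ``subtyp``
field (0 = normal, 1 = dissociated).  Unknown annotation codes are preserved
with kind ``"unknown:<code>"`` so no information is silently dropped.

All sample indices are 0-based throughout the package; WFDB command-line
tools that print 1-based sample times require a +1 shift.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EcgRecord",
    "AnnEntry",
    "AnnotationSet",
    "read_record",
    "write_record",
    "read_annotations",
    "write_annotations",
]

_KIND_TO_CODE = {"R": 1, "PVC": 5, "P": 24, "T": 27}
_CODE_TO_KIND = {v: k for k, v in _KIND_TO_CODE.items()}
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63
_WFDB_GAIN = 200.0  # ADC units per mV used when writing


@dataclass
class EcgRecord:
    """A uniformly sampled single-lead voltage series.

    Attributes
    ----------
    samples : ndarray
        Voltage in millivolts.
    fs : float
        Sampling frequency in Hz.
    lead : str
        Lead label (e.g. ``"MLII"``).
    """

    samples: np.ndarray
    fs: float
    lead: str = "ECG"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("record contains non-finite samples")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs


@dataclass(frozen=True, order=True)
class AnnEntry:
    """One fiducial annotation: 0-based sample index, kind, optional subtype."""

    sample: int
    kind: str
    subtype: str | None = None


@dataclass
class AnnotationSet:
    """An ordered collection of fiducial annotations."""

    entries: list[AnnEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries)
        if any(e.sample < 0 for e in self.entries):
            raise ValueError("annotation sample indices must be non-negative")

    def samples_of(self, kind: str) -> np.ndarray:
        """Sample indices of all entries of the given kind, ascending."""
        return np.array(
            [e.sample for e in self.entries if e.kind == kind], dtype=int
        )

    def validate_against(self, record: EcgRecord) -> None:
        if self.entries and self.entries[-1].sample >= record.samples.size:
            raise ValueError("annotation index beyond record length")

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, AnnotationSet) and self.entries == other.entries


# ---------------------------------------------------------------------------
# records


def read_record(
    path: str | os.PathLike,
    format: str = "csv",
    fs: float | None = None,
    channel: int = 0,
) -> EcgRecord:
    """Read an ECG record.

    Parameters
    ----------
    path : path
        For ``csv``, the file itself; for ``wfdb``, the ``.hea`` file or the
        record base name (extension optional).
    format : {"csv", "wfdb"}
    fs : float, optional
        Required for CSV input (the file carries no rate).
    channel : int
        Channel to extract from a multi-channel WFDB record.
    """
    path = Path(path)
    if format == "csv":
        if fs is None:
            raise ValueError("fs is required for csv records")
        samples = np.loadtxt(path, dtype=float, ndmin=1)
        return EcgRecord(samples=samples, fs=fs, lead="ECG")
    if format == "wfdb":
        return _read_wfdb_record(path, channel)
    raise ValueError(f"unknown record format {format!r}")


def write_record(
    record: EcgRecord, path: str | os.PathLike, format: str = "csv"
) -> None:
    """Write an ECG record as CSV (6-decimal mV) or a WFDB .hea/.dat pair.

    WFDB output quantises to 16-bit ADC units at 200 adu/mV; CSV round trips
    are exact to 6 decimals.
    """
    path = Path(path)
    if format == "csv":
        np.savetxt(path, record.samples, fmt="%.6f", newline="\n")
        return
    if format == "wfdb":
        _write_wfdb_record(record, path)
        return
    raise ValueError(f"unknown record format {format!r}")


def _wfdb_base(path: Path) -> Path:
    return path.with_suffix("") if path.suffix in {".hea", ".dat"} else path


def _read_wfdb_record(path: Path, channel: int) -> EcgRecord:
    base = _wfdb_base(path)
    hea = base.with_suffix(".hea")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    nsig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    if not 0 <= channel < nsig:
        raise ValueError(f"channel {channel} out of range for {nsig} signals")
    sig = lines[1 + channel].split()
    fname, fmt = sig[0], sig[1].split("x")[0]
    if fmt not in ("16", "212"):
        raise ValueError(
            f"unsupported WFDB signal format {fmt!r} (16 and 212 supported)"
        )
    gain_tok = sig[2] if len(sig) > 2 else "200"
    gain_part = gain_tok.split("/")[0]
    if "(" in gain_part:
        gain_s, base_s = gain_part.split("(")
        baseline = int(base_s.rstrip(")"))
    else:
        gain_s, baseline = gain_part, 0
    gain = float(gain_s) if float(gain_s) != 0 else _WFDB_GAIN
    lead = " ".join(sig[8:]) if len(sig) > 8 else f"ch{channel}"
    if fmt == "16":
        raw = np.fromfile(base.parent / fname, dtype="<i2")
        raw = raw.reshape(-1, nsig)[:, channel]
    else:  # 212: two 12-bit two's-complement samples packed into 3 bytes
        b = np.fromfile(base.parent / fname, dtype=np.uint8)
        b = b[: (b.size // 3) * 3].reshape(-1, 3).astype(np.int32)
        s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        flat = np.empty(2 * b.shape[0], dtype=np.int32)
        flat[0::2], flat[1::2] = s0, s1
        flat[flat > 2047] -= 4096
        raw = flat[: (flat.size // nsig) * nsig].reshape(-1, nsig)[:, channel]
    return EcgRecord(samples=(raw - baseline) / gain, fs=fs, lead=lead)


def _write_wfdb_record(record: EcgRecord, path: Path) -> None:
    base = _wfdb_base(path)
    adc = np.clip(
        np.round(record.samples * _WFDB_GAIN), -32768, 32767
    ).astype("<i2")
    dat = base.with_suffix(".dat")
    adc.tofile(dat)
    first = int(adc[0]) if adc.size else 0
    fs = record.fs
    fs_s = f"{fs:g}"
    hea = base.with_suffix(".hea")
    hea.write_text(
        f"{base.name} 1 {fs_s} {adc.size}\n"
        f"{dat.name} 16 {_WFDB_GAIN:g}(0)/mV 16 0 {first} 0 0 {record.lead}\n"
    )


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str | os.PathLike, format: str = "csv") -> AnnotationSet:
    """Read annotations from the CSV dialect or a MIT-format binary file."""
    path = Path(path)
    if format == "csv":
        return _read_ann_csv(path)
    if format == "wfdb_ann":
        return _read_ann_mit(path)
    raise ValueError(f"unknown annotation format {format!r}")


def write_annotations(
    annotations: AnnotationSet, path: str | os.PathLike, format: str = "csv"
) -> None:
    """Write annotations; output bytes are deterministic for a given set."""
    path = Path(path)
    if format == "csv":
        _write_ann_csv(annotations, path)
        return
    if format == "wfdb_ann":
        _write_ann_mit(annotations, path)
        return
    raise ValueError(f"unknown annotation format {format!r}")


def _read_ann_csv(path: Path) -> AnnotationSet:
    entries = []
    with open(path, newline="") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return AnnotationSet()
    if lines[0] != "sample,kind,subtype":
        raise ValueError(
            f"{path}: expected header 'sample,kind,subtype', got {lines[0]!r}"
        )
    for ln in lines[1:]:
        parts = ln.split(",")
        if len(parts) != 3:
            raise ValueError(f"{path}: malformed row {ln!r}")
        sample, kind, sub = parts
        entries.append(AnnEntry(int(sample), kind, sub or None))
    return AnnotationSet(entries)


def _write_ann_csv(annotations: AnnotationSet, path: Path) -> None:
    rows = ["sample,kind,subtype"]
    for e in sorted(annotations.entries):
        rows.append(f"{e.sample},{e.kind},{e.subtype or ''}")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(rows) + "\n")


def _read_ann_mit(path: Path) -> AnnotationSet:
    data = path.read_bytes()
    entries: list[AnnEntry] = []
    t = 0
    i = 0
    while i + 1 < len(data):
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code, interval = word >> 10, word & 0x3FF
        if word == 0:  # EOF
            break
        if code == _SKIP:
            hi = data[i] | (data[i + 1] << 8)
            lo = data[i + 2] | (data[i + 3] << 8)
            i += 4
            t += np.int32((hi << 16) | lo)
        elif code == _SUB:
            sub = interval if interval < 512 else interval - 1024
            if entries and entries[-1].kind == "P":
                entries[-1] = AnnEntry(
                    entries[-1].sample,
                    "P",
                    "dissociated" if sub == 1 else "normal",
                )
        elif code in (_NUM, _CHN, _AUX):
            if code == _AUX:  # aux string: length byte + text, even padded
                n = interval
                i += n + (n & 1)
        else:
            t += interval
            kind = _CODE_TO_KIND.get(code, f"unknown:{code}")
            sub = "normal" if kind == "P" else None
            entries.append(AnnEntry(int(t), kind, sub))
    return AnnotationSet(entries)


def _write_ann_mit(annotations: AnnotationSet, path: Path) -> None:
    out = bytearray()

    def word(code: int, interval: int) -> None:
        w = ((code & 0x3F) << 10) | (interval & 0x3FF)
        out.extend(struct.pack("<H", w))

    t = 0
    for e in sorted(annotations.entries):
        code = _KIND_TO_CODE.get(e.kind)
        if code is None:
            raise ValueError(f"kind {e.kind!r} has no WFDB annotation code")
        delta = e.sample - t
        if delta > 1023:
            word(_SKIP, 0)
            out += struct.pack("<H", (delta >> 16) & 0xFFFF)
            out += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        word(code, delta)
        t = e.sample
        if e.kind == "P" and e.subtype == "dissociated":
            word(_SUB, 1)
    word(0, 0)  # EOF
    path.write_bytes(bytes(out))
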