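"""Tolerance-based fiducial matching and sensitivity / positive predictivity.

A detected peak matches a reference peak when they lie within the tolerance
(default +-100 ms for P/T, +-50 ms for R — the tolerance is always an
explicit argument).  Matching is one-to-one and optimal: among all pairings
it maximises the number of matched pairs and, among those, minimises the
total absolute distance.  For points on a line with an interval constraint an
optimal matching always exists without crossings, so a two-index dynamic
program over the sorted lists finds it in O(n*m).

Se = 100 x TP / (TP + FN), PP = 100 x TP / (TP + FP).  When nothing was
detected PP is defined as 0 (100 when the reference is empty too).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MatchReport", "match", "per_rhythm_report", "DEFAULT_TOLERANCE_MS"]

DEFAULT_TOLERANCE_MS = {"R": 50.0, "P": 100.0, "T": 100.0}


@dataclass(frozen=True)
class MatchReport:
    """Outcome of matching a detected against a reference fiducial list."""

    tp: int
    fp: int
    fn: int
    se: float
    pp: float
    tolerance_ms: float
    pairs: tuple[tuple[int, int], ...]  # (detected_index, reference_index)


def _check_ascending(name: str, arr: np.ndarray) -> None:
    if np.any(np.diff(arr) < 0):
        raise ValueError(f"{name} list must be ascending")


def match(
    detected, reference, tolerance_ms: float, fs: float
) -> MatchReport:
    """Optimally match detected to reference samples within a tolerance.

    Parameters
    ----------
    detected, reference : ascending sequences of 0-based sample indices.
    tolerance_ms : maximum |detected - reference| distance, in ms.
    fs : sampling frequency used to convert the tolerance to samples.
    """
    d = np.asarray(list(detected), dtype=float)
    r = np.asarray(list(reference), dtype=float)
    _check_ascending("detected", d)
    _check_ascending("reference", r)
    tol = tolerance_ms * fs / 1000.0

    n, m = d.size, r.size

    def pref(t):  # maximise pairs, then minimise total distance
        return (t[0], -t[1])

    # backward DP over (i, j): best (pairs, total_distance) for the suffixes
    best = [[(0, 0.0)] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        row, nxt = best[i], best[i + 1]
        for j in range(m - 1, -1, -1):
            cand = max(nxt[j], row[j + 1], key=pref)
            dist = abs(d[i] - r[j])
            if dist <= tol:
                p, c = nxt[j + 1]
                cand = max(cand, (p + 1, c + dist), key=pref)
            row[j] = cand
    # reconstruct the pairing
    pairs = []
    i = j = 0
    while i < n and j < m:
        here = best[i][j]
        dist = abs(d[i] - r[j])
        if (
            dist <= tol
            and here[0] == best[i + 1][j + 1][0] + 1
            and here[1] == best[i + 1][j + 1][1] + dist
        ):
            pairs.append((i, j))
            i += 1
            j += 1
        elif pref(best[i + 1][j]) >= pref(best[i][j + 1]):
            i += 1
        else:
            j += 1

    tp = len(pairs)
    fp = n - tp
    fn = m - tp
    se = 100.0 * tp / (tp + fn) if (tp + fn) else 100.0
    pp = 100.0 * tp / (tp + fp) if (tp + fp) else (100.0 if m == 0 else 0.0)
    return MatchReport(
        tp=tp,
        fp=fp,
        fn=fn,
        se=se,
        pp=pp,
        tolerance_ms=tolerance_ms,
        pairs=tuple(pairs),
    )


def per_rhythm_report(
    reports: dict[str, MatchReport | tuple[float, float]],
    grouping: dict[str, list[str]],
) -> pd.DataFrame:
    """Aggregate per-record Se/PP into per-rhythm means.

    ``reports`` maps record name to a :class:`MatchReport` (or a bare
    ``(se, pp)`` pair); ``grouping`` maps rhythm-group name to the record
    names it contains.  Group values are unweighted means across records.
    """
    rows = {}
    for group, names in grouping.items():
        if not names:
            raise ValueError(f"group {group!r} is empty")
        se, pp = [], []
        for name in names:
            rep = reports[name]
            if isinstance(rep, MatchReport):
                se.append(rep.se)
                pp.append(rep.pp)
            else:
                se.append(float(rep[0]))
                pp.append(float(rep[1]))
        rows[group] = {
            "se": float(np.mean(se)),
            "pp": float(np.mean(pp)),
            "n_records": len(names),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
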