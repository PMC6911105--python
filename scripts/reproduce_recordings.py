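"""Optional: score P wave detection on user-downloaded real recordings.

This script is separate from the self-contained synthetic pipeline in
``scripts/acceptance.py``: it requires WFDB recordings (format 16 or 212)
and P-peak reference annotations that YOU download yourself — for example
half-hour arrhythmia-database records at 360 Hz together with the publicly
available expert P wave annotations.  Nothing here is fetched
automatically, and results depend on the matching tolerance chosen (the
reference methodology for the comparable published tables does not state
one), so figures should be read as approximate reproductions.

Usage:

    python scripts/reproduce_recordings.py \
        --record path/to/231.hea --p-ann path/to/231.pwave \
        --record path/to/106.hea --p-ann path/to/106.pwave \
        --ann-format wfdb_ann --tolerance-ms 100 --out report.csv

Each --record is paired positionally with one --p-ann file (reference P
peak positions as a WFDB annotation file or the package's annotation CSV).
Prints per-record and mean Se/PP for P wave detection.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np

from pwavedet.delineation import delineate_record
from pwavedet.evaluation import match, per_rhythm_report
from pwavedet.io_formats import read_annotations, read_record


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--record", action="append", required=True,
                    help="WFDB .hea path (repeatable)")
    ap.add_argument("--p-ann", action="append", required=True,
                    help="reference P annotations, one per --record")
    ap.add_argument("--ann-format", choices=["wfdb_ann", "csv"],
                    default="wfdb_ann")
    ap.add_argument("--channel", type=int, default=0)
    ap.add_argument("--tolerance-ms", type=float, default=100.0)
    ap.add_argument("--out", type=Path, default=None,
                    help="optional CSV report path")
    args = ap.parse_args()
    if len(args.record) != len(args.p_ann):
        ap.error("need exactly one --p-ann per --record")

    reports = {}
    for rec_path, ann_path in zip(args.record, args.p_ann):
        record = read_record(rec_path, "wfdb", channel=args.channel)
        reference = read_annotations(ann_path, args.ann_format).samples_of("P")
        beats, _ = delineate_record(record)
        rep = match(
            np.sort(beats.p_samples()), reference, args.tolerance_ms, record.fs
        )
        name = Path(rec_path).stem
        reports[name] = rep
        print(f"{name}: Se={rep.se:6.2f}%  PP={rep.pp:6.2f}%  "
              f"(TP={rep.tp} FP={rep.fp} FN={rep.fn})")

    table = per_rhythm_report(reports, {"mean": list(reports)})
    print(f"mean: Se={table.loc['mean', 'se']:6.2f}%  "
          f"PP={table.loc['mean', 'pp']:6.2f}%")
    if args.out:
        table.to_csv(args.out)


if __name__ == "__main__":
    main()
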