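"""Tabular readers/writers for calls, boundaries, truth sets and summaries.

The primary call table uses 1-based inclusive coordinates (SAM-style); BED
export is 0-based half-open. Internally everything is 0-based half-open.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .benchmark import BenchmarkSummary
from .boundaries import BoundaryPoint
from .caller import ScnaCall
from .simulate import SimulatedEvent

CALL_COLUMNS = [
    "Chromosome name",
    "SCNA start",
    "SCNA end",
    "cumulative log_2_ratio",
    "t-statistic",
    "P-value",
]


def write_calls(calls: list[ScnaCall], path: str | Path, refined_column: bool = False) -> None:
    rows = []
    for c in calls:
        row = {
            CALL_COLUMNS[0]: c.chrom,
            CALL_COLUMNS[1]: c.start + 1,  # 1-based inclusive
            CALL_COLUMNS[2]: c.end,
            CALL_COLUMNS[3]: c.clr,
            CALL_COLUMNS[4]: c.z,
            CALL_COLUMNS[5]: c.p,
            "kind": c.kind,
        }
        if refined_column:
            row["refined"] = int(c.refined)
        rows.append(row)
    cols = CALL_COLUMNS + ["kind"] + (["refined"] if refined_column else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> list[ScnaCall]:
    df = pd.read_csv(path, sep="\t")
    calls = []
    for _, r in df.iterrows():
        calls.append(
            ScnaCall(
                chrom=str(r[CALL_COLUMNS[0]]),
                start=int(r[CALL_COLUMNS[1]]) - 1,
                end=int(r[CALL_COLUMNS[2]]),
                clr=float(r[CALL_COLUMNS[3]]),
                z=float(r[CALL_COLUMNS[4]]),
                p=float(r[CALL_COLUMNS[5]]),
                kind=str(r["kind"]),
                refined=bool(r.get("refined", False)),
            )
        )
    return calls


def write_calls_bed(calls: list[ScnaCall], path: str | Path) -> None:
    """BED6: name = kind, score = -10*log10(p) capped at 1000."""
    lines = []
    for c in calls:
        score = 1000 if c.p <= 0 else min(1000, int(round(-10 * math.log10(c.p))))
        lines.append(f"{c.chrom}\t{c.start}\t{c.end}\t{c.kind}\t{score}\t.")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_boundaries(bounds: list[BoundaryPoint], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "chrom": b.chrom,
                "pos": b.pos,
                "category": b.category,
                "ratio": b.ratio,
                "copy_state": b.copy_state,
            }
            for b in bounds
        ],
        columns=["chrom", "pos", "category", "ratio", "copy_state"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_boundaries(path: str | Path) -> list[BoundaryPoint]:
    df = pd.read_csv(path, sep="\t")
    return [
        BoundaryPoint(
            chrom=str(r.chrom),
            pos=int(r.pos),
            category=str(r.category),
            ratio=float(r.ratio),
            copy_state=int(r.copy_state),
        )
        for r in df.itertuples()
    ]


def write_truth(events: list[SimulatedEvent], path: str | Path) -> None:
    """BED-like TSV truth set: chrom, start, end, kind, copy_number."""
    df = pd.DataFrame(
        [
            {
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "kind": e.kind,
                "copy_number": e.copy_number,
            }
            for e in events
        ],
        columns=["chrom", "start", "end", "kind", "copy_number"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> list[SimulatedEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        SimulatedEvent(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            kind=str(r.kind),
            copy_number=int(r.copy_number),
        )
        for r in df.itertuples()
    ]


def write_summary(summary: BenchmarkSummary, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sensitivity_pct": summary.sensitivity_pct,
                "false_positive_pct": summary.false_positive_pct,
                "mean_size_deviation_pct": summary.mean_size_deviation_pct,
            }
        ]
    ).to_csv(path, sep="\t", index=False)
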