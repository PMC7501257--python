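"""Collapse overlapping structural-variant calls within each individual.

Merging is single-linkage over intervals sharing at least one base, within
(sample, sv_type, contig) strata only — calls of different types or from
different individuals are never merged, and abutting intervals (end ==
start) stay separate. Translocations merge only on identical breakpoint
pairs (optionally within a window).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

INTERVAL_TYPES = {"DEL", "DUP", "INV", "INS"}
SV_TYPES = INTERVAL_TYPES | {"TRA"}


@dataclass(frozen=True)
class SVCall:
    sample: str
    sv_type: str
    contig: str
    start: int  # 0-based half-open; INS: end = start + 1
    end: int
    mate_contig: Optional[str] = None  # TRA only
    mate_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r} ({self})")
        if self.sv_type in INTERVAL_TYPES and not self.start < self.end:
            raise ValueError(
                f"malformed interval start={self.start} end={self.end} ({self})"
            )


@dataclass(frozen=True)
class CollapsedSV:
    sample: str
    sv_type: str
    contig: str
    start: int
    end: int
    n_source_calls: int
    mate_contig: Optional[str] = None
    mate_pos: Optional[int] = None


def collapse_overlapping(
    calls: Iterable[SVCall], tra_window: int = 0
) -> list[CollapsedSV]:
    """Single-linkage merge of >=1 bp-overlapping calls per stratum.

    Output intervals are disjoint within each stratum and sorted by
    (sample, sv_type, contig, start). Idempotent and invariant to input
    order.
    """
    strata: dict[tuple, list[SVCall]] = {}
    for call in calls:
        strata.setdefault((call.sample, call.sv_type, call.contig), []).append(
            call
        )

    out: list[CollapsedSV] = []
    for (sample, sv_type, contig), members in sorted(strata.items()):
        if sv_type == "TRA":
            out.extend(_collapse_tra(sample, contig, members, tra_window))
            continue
        members = sorted(members, key=lambda c: (c.start, c.end))
        cur_start, cur_end, n = members[0].start, members[0].end, 1
        for call in members[1:]:
            if call.start < cur_end:  # >=1 bp overlap; abutting does not merge
                cur_end = max(cur_end, call.end)
                n += 1
            else:
                out.append(
                    CollapsedSV(sample, sv_type, contig, cur_start, cur_end, n)
                )
                cur_start, cur_end, n = call.start, call.end, 1
        out.append(CollapsedSV(sample, sv_type, contig, cur_start, cur_end, n))
    out.sort(key=lambda c: (c.sample, c.sv_type, c.contig, c.start, c.end))
    return out


def _collapse_tra(
    sample: str, contig: str, members: list[SVCall], window: int
) -> list[CollapsedSV]:
    groups: dict[tuple, list[SVCall]] = {}
    for call in sorted(
        members, key=lambda c: (c.start, c.mate_contig or "", c.mate_pos or 0)
    ):
        placed = False
        for key, grp in groups.items():
            rep = grp[0]
            if (
                rep.mate_contig == call.mate_contig
                and abs(rep.start - call.start) <= window
                and abs((rep.mate_pos or 0) - (call.mate_pos or 0)) <= window
            ):
                grp.append(call)
                placed = True
                break
        if not placed:
            groups[(call.start, call.mate_contig, call.mate_pos)] = [call]
    out = []
    for grp in groups.values():
        rep = grp[0]
        out.append(
            CollapsedSV(
                sample, "TRA", contig, rep.start, rep.end, len(grp),
                mate_contig=rep.mate_contig, mate_pos=rep.mate_pos,
            )
        )
    return out


def sv_summary(collapsed: Iterable[CollapsedSV]) -> pd.DataFrame:
    """Per-sample counts by type plus totals; cohort mean in ``attrs``.

    ``df.attrs["cohort_mean"]`` is the mean total per individual rounded
    to the unit; ``df.attrs["cohort_mean_exact"]`` keeps the exact value.
    """
    rows = [(c.sample, c.sv_type) for c in collapsed]
    if not rows:
        df = pd.DataFrame(columns=["sample", "total"])
        df.attrs["cohort_mean"] = 0
        df.attrs["cohort_mean_exact"] = 0.0
        return df
    raw = pd.DataFrame(rows, columns=["sample", "sv_type"])
    counts = (
        raw.groupby(["sample", "sv_type"]).size().unstack(fill_value=0)
    )
    counts["total"] = counts.sum(axis=1)
    counts = counts.reset_index()
    mean = float(counts["total"].mean())
    counts.attrs["cohort_mean_exact"] = mean
    counts.attrs["cohort_mean"] = int(round(mean))
    return counts


def calls_from_frame(df: pd.DataFrame) -> list[SVCall]:
    """Build SVCall records from a TSV-derived frame (sample, sv_type,
    contig, start, end[, mate_contig, mate_pos])."""
    has_mate = {"mate_contig", "mate_pos"} <= set(df.columns)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SVCall(
                sample=str(row.sample),
                sv_type=str(row.sv_type),
                contig=str(row.contig),
                start=int(row.start),
                end=int(row.end),
                mate_contig=(
                    str(row.mate_contig)
                    if has_mate and pd.notna(row.mate_contig)
                    else None
                ),
                mate_pos=(
                    int(row.mate_pos)
                    if has_mate and pd.notna(row.mate_pos)
                    else None
                ),
            )
        )
    return out
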