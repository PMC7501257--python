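"""Meta-assembly complementation and base-level QV.

Gap detection takes the complement of base-assembly alignment coverage on
the reference; patch selection keeps gaps strictly longer than a length
cutoff that do not touch centromeres; patch sequences come from an
alternative assembly through supplied alignment blocks. QV is
-10*log10(weighted homozygous differences / effective genome size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class GapRegion:
    contig: str
    start: int  # 0-based half-open
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PatchRegion:
    gap: GapRegion
    alt_contig: Optional[str]
    alt_start: Optional[int]
    alt_end: Optional[int]
    strand: Optional[str]
    sequence: Optional[str]
    patchable: bool
    reason: str = ""


@dataclass(frozen=True)
class QVReport:
    weighted_diff_count: float
    effective_genome_size: int
    qv: float
    is_lower_bound: bool  # True when no differences were observed


def _validate_coverage(
    coverage: Mapping[str, Sequence[tuple[int, int]]],
    contig_lengths: Mapping[str, int],
) -> None:
    for contig, intervals in coverage.items():
        if contig not in contig_lengths:
            raise ValueError(f"coverage on unknown contig {contig!r}")
        length = contig_lengths[contig]
        prev_end = -1
        for s, e in sorted(intervals):
            if not (0 <= s < e <= length):
                raise ValueError(
                    f"coverage interval {contig}:{s}-{e} exceeds contig "
                    f"bounds [0, {length})"
                )
            if s < prev_end:
                raise ValueError(
                    f"overlapping coverage intervals on {contig} at {s}"
                )
            prev_end = e


def uncovered_gaps(
    coverage: Mapping[str, Sequence[tuple[int, int]]],
    contig_lengths: Mapping[str, int],
) -> list[GapRegion]:
    """Maximal reference intervals not covered by base-assembly alignments.

    Gaps and coverage tile each contig exactly. Contigs absent from
    ``coverage`` are entirely uncovered.
    """
    _validate_coverage(coverage, contig_lengths)
    gaps: list[GapRegion] = []
    for contig, length in contig_lengths.items():
        prev = 0
        for s, e in sorted(coverage.get(contig, [])):
            if s > prev:
                gaps.append(GapRegion(contig, prev, s))
            prev = max(prev, e)
        if prev < length:
            gaps.append(GapRegion(contig, prev, length))
    return gaps


def select_patch_regions(
    gaps: Sequence[GapRegion],
    centromeres: Sequence[tuple[str, int, int]] = (),
    min_len: int = 800_000,
    max_centromere_overlap: int = 0,
) -> list[GapRegion]:
    """Gaps strictly longer than ``min_len`` whose centromere overlap does
    not exceed ``max_centromere_overlap`` bp (default: any overlap excludes)."""
    kept = []
    for gap in gaps:
        if gap.length <= min_len:
            continue
        overlap = 0
        for contig, cs, ce in centromeres:
            if contig == gap.contig:
                overlap += max(0, min(gap.end, ce) - max(gap.start, cs))
        if overlap > max_centromere_overlap:
            continue
        kept.append(gap)
    return sorted(kept, key=lambda g: (g.contig, g.start))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_patches(
    regions: Sequence[GapRegion],
    alt_alignment: pd.DataFrame,
    alt_fasta,
) -> list[PatchRegion]:
    """Pull patch sequences from the alternative assembly.

    ``alt_alignment`` maps reference intervals to alternative-assembly
    intervals (columns ref_contig, ref_start, ref_end, alt_contig,
    alt_start, alt_end, strand). A gap must fall within exactly one block;
    gaps spanning zero or multiple blocks are reported unpatchable, never
    guessed. Minus-strand blocks yield the reverse complement.

    ``alt_fasta`` is any mapping from contig name to an indexable sequence
    (e.g. ``pyfaidx.Fasta`` or a plain dict of strings).
    """
    patches: list[PatchRegion] = []
    for gap in regions:
        hits = alt_alignment[
            (alt_alignment["ref_contig"] == gap.contig)
            & (alt_alignment["ref_start"] <= gap.start)
            & (alt_alignment["ref_end"] >= gap.end)
        ]
        overlapping = alt_alignment[
            (alt_alignment["ref_contig"] == gap.contig)
            & (alt_alignment["ref_start"] < gap.end)
            & (alt_alignment["ref_end"] > gap.start)
        ]
        if len(hits) == 0:
            reason = (
                "gap spans multiple alignment blocks"
                if len(overlapping) > 1
                else "gap not covered by any alignment block"
            )
            patches.append(
                PatchRegion(gap, None, None, None, None, None, False, reason)
            )
            continue
        if len(hits) > 1 or len(overlapping) > 1:
            patches.append(
                PatchRegion(
                    gap, None, None, None, None, None, False,
                    "gap ambiguous across alignment blocks",
                )
            )
            continue
        block = hits.iloc[0]
        offset = gap.start - int(block["ref_start"])
        alt_s = int(block["alt_start"]) + offset
        alt_e = alt_s + gap.length
        strand = str(block["strand"])
        seq = str(alt_fasta[str(block["alt_contig"])][alt_s:alt_e])
        if strand == "-":
            seq = reverse_complement(seq)
        patches.append(
            PatchRegion(
                gap, str(block["alt_contig"]), alt_s, alt_e, strand, seq, True
            )
        )
    return patches


def count_homozygous_differences(
    diffs: pd.DataFrame, qual_min: float = 10.0
) -> float:
    """Weighted bp count of assembly-vs-read differences.

    ``diffs`` columns: ref, alt, quality, zygosity ("hom"/"het"). Keeps
    homozygous records with quality >= ``qual_min``; an SNV contributes 1,
    an indel the absolute length difference of its alleles.
    """
    kept = diffs[
        (diffs["zygosity"] == "hom") & (diffs["quality"] >= qual_min)
    ]
    if len(kept) == 0:
        return 0.0
    weights = (kept["ref"].str.len() - kept["alt"].str.len()).abs()
    weights = weights.where(weights > 0, 1)  # SNV / same-length substitution
    return float(weights.sum())


def assembly_qv(weighted_count: float, effective_size: int) -> QVReport:
    """QV = -10*log10(weighted_count / effective_size).

    With zero observed differences the error rate is below 1/size, so the
    report carries the ceiling ``-10*log10(1/size)`` flagged as a lower
    bound.
    """
    if effective_size <= 0:
        raise ValueError(f"effective genome size must be > 0, got {effective_size}")
    if weighted_count < 0:
        raise ValueError("weighted difference count must be >= 0")
    if weighted_count == 0:
        ceiling = -10.0 * math.log10(1.0 / effective_size)
        return QVReport(0.0, effective_size, ceiling, True)
    qv = -10.0 * math.log10(weighted_count / effective_size)
    return QVReport(weighted_count, effective_size, qv, False)


def effective_size_from_depth(depth: np.ndarray, depth_min: int = 1) -> int:
    """Bases with read coverage at least ``depth_min`` in a depth track."""
    return int((np.asarray(depth) >= depth_min).sum())
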