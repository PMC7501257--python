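"""Non-reference insertion-region calling from per-base multi-sample depth.

A region is called when a maximal run of consecutive bases each has enough
samples above the depth threshold, and the run is long enough. Sample
identity is deliberately not tracked across bases: the per-base criterion
only counts qualifying samples, so the qualifying set may differ from base
to base (the per-region support figure is the conservative minimum over
bases).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DepthMatrix:
    """Dense per-base depth for one contig, rows = samples."""

    contig: str
    start: int  # 0-based offset of column 0
    depths: np.ndarray  # (n_samples, n_bases), non-negative ints
    samples: list[str]

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.ndim != 2:
            raise ValueError("depth matrix must be 2-D (samples x bases)")
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")
        if len(self.samples) != self.depths.shape[0]:
            raise ValueError("sample list does not match matrix rows")


@dataclass(frozen=True)
class InsertionRegion:
    contig: str
    start: int  # 0-based half-open
    end: int
    n_supporting_samples: int

    @property
    def length(self) -> int:
        return self.end - self.start


def samples_passing(
    depth: DepthMatrix, depth_min: int = 5, strict: bool = True
) -> np.ndarray:
    """Per-base count of samples whose depth exceeds (strict) or reaches
    (inclusive) ``depth_min``."""
    if strict:
        return (depth.depths > depth_min).sum(axis=0)
    return (depth.depths >= depth_min).sum(axis=0)


def call_insertion_regions(
    depth: DepthMatrix,
    min_len: int = 500,
    depth_min: int = 5,
    min_samples: int = 10,
    strict: bool = True,
) -> list[InsertionRegion]:
    """Maximal runs of bases with >= ``min_samples`` qualifying samples,
    kept iff at least ``min_len`` bp long.

    Default semantics are depth strictly greater than ``depth_min``
    (``strict=False`` switches to >=). Runs separated by even a single
    failing base are never merged.
    """
    if min_len <= 0 or depth_min <= 0 or min_samples <= 0:
        raise ValueError("thresholds must be positive")
    counts = samples_passing(depth, depth_min, strict)
    qualifying = counts >= min_samples
    regions: list[InsertionRegion] = []
    padded = np.concatenate(([False], qualifying, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for run_start, run_end in zip(edges[0::2], edges[1::2]):
        if run_end - run_start >= min_len:
            support = int(counts[run_start:run_end].min())
            regions.append(
                InsertionRegion(
                    contig=depth.contig,
                    start=depth.start + int(run_start),
                    end=depth.start + int(run_end),
                    n_supporting_samples=support,
                )
            )
    regions.sort(key=lambda r: (r.contig, r.start))
    return regions


def summarize_insertions(regions: list[InsertionRegion]) -> pd.DataFrame:
    """Per-region table sorted by (contig, start); attach totals via attrs.

    ``df.attrs["n_regions"]`` and ``df.attrs["total_length"]`` carry the
    headline numbers.
    """
    ordered = sorted(regions, key=lambda r: (r.contig, r.start))
    df = pd.DataFrame(
        [
            (r.contig, r.start, r.end, r.length, r.n_supporting_samples)
            for r in ordered
        ],
        columns=["contig", "start", "end", "length", "n_supporting_samples"],
    )
    df.attrs["n_regions"] = len(ordered)
    df.attrs["total_length"] = int(sum(r.length for r in ordered))
    return df


def matrix_from_tracks(
    tracks: dict[str, dict[str, np.ndarray]], contig: str
) -> DepthMatrix:
    """Stack per-sample track dicts (as from the simulator or BedGraph
    reading) into one DepthMatrix for a contig."""
    samples = sorted(tracks)
    rows = [tracks[s][contig] for s in samples]
    return DepthMatrix(
        contig=contig, start=0, depths=np.vstack(rows), samples=samples
    )
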