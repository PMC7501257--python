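"""Phasing completeness, gene-level phase-block integrity, and long-ROH
totals per individual."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

DEFAULT_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))


@dataclass(frozen=True)
class PhasedFraction:
    n_phased: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_phased / self.n_total

    @property
    def percentage(self) -> float:
        """Percentage rounded to one decimal for reporting."""
        return round(100.0 * self.fraction, 1)


def phased_fraction(
    variants: pd.DataFrame,
    autosomes_only: bool = True,
    autosomes: Sequence[str] = DEFAULT_AUTOSOMES,
    het_denominator: bool = False,
) -> PhasedFraction:
    """Fraction of variants assigned to a phase block.

    ``variants`` columns: contig, pos, zygosity ("het"/"hom"),
    phase_block_id (missing/empty = unphased). With ``het_denominator``
    the denominator is restricted to heterozygous variants (phase is only
    meaningful there); the default denominator counts all variants. Both
    are exposed because reported phasing rates do not always state which
    denominator was used.
    """
    if len(variants) == 0:
        raise ValueError("phased fraction undefined for an empty variant set")
    df = variants
    if autosomes_only:
        df = df[df["contig"].isin(set(autosomes))]
    if het_denominator:
        df = df[df["zygosity"] == "het"]
    if len(df) == 0:
        raise ValueError("no variants left after filtering; fraction undefined")
    phased = df["phase_block_id"].notna() & (
        df["phase_block_id"].astype(str) != ""
    )
    return PhasedFraction(n_phased=int(phased.sum()), n_total=int(len(df)))


def phased_counts(n_phased: int, n_total: int) -> PhasedFraction:
    """Build the report directly from already-tallied counts."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_phased <= n_total:
        raise ValueError("n_phased must lie in [0, n_total]")
    return PhasedFraction(n_phased=n_phased, n_total=n_total)


def genes_single_block(
    genes: pd.DataFrame,
    variants: pd.DataFrame,
    max_len: int = 100_000,
    min_het: int = 2,
) -> tuple[int, int, Optional[float]]:
    """Fraction of eligible genes whose het variants share one phase block.

    ``genes`` columns: gene_id, contig, start, end (1-based inclusive).
    Eligible genes have length strictly below ``max_len`` and at least
    ``min_het`` heterozygous variants within their span. A gene counts as
    single-block iff every such het variant is phased and all share one
    phase_block_id. Returns (n_single_block, n_eligible, fraction), the
    fraction ``None`` when no gene is eligible.
    """
    het = variants[variants["zygosity"] == "het"]
    n_single = 0
    n_eligible = 0
    for gene in genes.itertuples(index=False):
        length = int(gene.end) - int(gene.start) + 1
        if length >= max_len:
            continue
        inside = het[
            (het["contig"] == gene.contig)
            & (het["pos"] >= gene.start)
            & (het["pos"] <= gene.end)
        ]
        if len(inside) < min_het:
            continue
        n_eligible += 1
        blocks = inside["phase_block_id"]
        if blocks.isna().any() or (blocks.astype(str) == "").any():
            continue
        if blocks.nunique() == 1:
            n_single += 1
    frac = (n_single / n_eligible) if n_eligible else None
    return n_single, n_eligible, frac


def total_long_roh(
    segments: pd.DataFrame, min_len: int = 5_000_000
) -> pd.Series:
    """Per-sample sum of ROH segment lengths strictly greater than ``min_len``.

    ``segments`` columns: sample, contig, start, end (0-based half-open).
    Samples present in the input but with no qualifying segment report 0.
    """
    if len(segments) == 0:
        return pd.Series(dtype="int64", name="total_long_roh_bp")
    lengths = segments["end"] - segments["start"]
    if (lengths <= 0).any():
        bad = segments[lengths <= 0].iloc[0]
        raise ValueError(
            f"non-positive ROH segment at {bad['contig']}:{bad['start']}-{bad['end']}"
        )
    long = segments[lengths > min_len]
    totals = (long["end"] - long["start"]).groupby(long["sample"]).sum()
    all_samples = pd.Index(sorted(segments["sample"].unique()), name="sample")
    return (
        totals.reindex(all_samples, fill_value=0)
        .astype("int64")
        .rename("total_long_roh_bp")
    )
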