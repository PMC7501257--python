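"""Synthetic inputs with the statistical structure the analyses assume.

The genotype simulator realizes block-wise linkage disequilibrium with a
founder-pool copying model: within an LD block every haplotype copies one
of a small pool of founder haplotypes, and founder choice recombines at
block boundaries. This gives high r-squared within blocks, near-zero
across blocks, and an exactly known per-site allele frequency (the mean
founder allele), without any coalescent machinery.

Every generator is deterministic given ``SimConfig.seed`` (independent
named sub-streams per stage) and returns a machine-readable truth object
alongside the fixture so recovery tests can assert exact values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import spawn_rng
from .io import (
    MISSING,
    GenotypeTable,
    write_bed,
    write_bedgraph,
    write_tsv,
    write_vcf,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class InsertionPlan:
    """One planted non-reference region in the depth tracks."""

    contig: str
    start: int
    end: int
    n_carrier_samples: int
    carrier_depth: int


@dataclass
class SimConfig:
    seed: int = 0
    n_samples: int = 110
    n_sites: int = 1000
    contig_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000}
    )
    af_range: tuple[float, float] = (0.05, 0.95)
    ld_block_length: int = 50_000
    recomb_between_blocks: float = 1.0
    missing_rate: float = 0.0
    depth_mean: float = 3.0
    insertion_plan: list[InsertionPlan] = field(default_factory=list)
    n_founders: int = 8

    def __post_init__(self) -> None:
        for name, p in [
            ("recomb_between_blocks", self.recomb_between_blocks),
            ("missing_rate", self.missing_rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} not a probability")
        lo, hi = self.af_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"af_range {self.af_range} invalid")
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        for plan in self.insertion_plan:
            length = self.contig_lengths.get(plan.contig)
            if length is None:
                raise ValueError(f"insertion plan on unknown contig {plan.contig}")
            if not (0 <= plan.start < plan.end <= length):
                raise ValueError(
                    f"planted interval {plan.contig}:{plan.start}-{plan.end} "
                    f"outside contig bounds [0, {length})"
                )
            if plan.n_carrier_samples > self.n_samples:
                raise ValueError(
                    f"{plan.n_carrier_samples} carriers > {self.n_samples} samples"
                )


def _site_positions(config: SimConfig) -> pd.DataFrame:
    """Place sites on a regular grid, apportioned over contigs by length."""
    total = sum(config.contig_lengths.values())
    rows = []
    remaining = config.n_sites
    items = list(config.contig_lengths.items())
    for idx, (contig, length) in enumerate(items):
        if idx == len(items) - 1:
            n_c = remaining
        else:
            n_c = int(round(config.n_sites * length / total))
            n_c = min(n_c, remaining)
        remaining -= n_c
        if n_c == 0:
            continue
        step = length / (n_c + 1)
        for j in range(n_c):
            pos = int((j + 1) * step)  # 1-based VCF position
            rows.append((contig, max(pos, 1)))
    return pd.DataFrame(rows, columns=["contig", "pos"])


def _founder_alleles(
    rng: np.random.Generator, n_sites: int, n_founders: int, af_range
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = af_range
    target_af = rng.uniform(lo, hi, size=n_sites)
    founders = (rng.random((n_founders, n_sites)) < target_af).astype(np.int8)
    return founders, target_af


def _copy_haplotypes(
    rng: np.random.Generator,
    founders: np.ndarray,
    block_of_site: np.ndarray,
    n_haplotypes: int,
    recomb: float,
) -> np.ndarray:
    """Per haplotype, pick a founder per block (Markov over block order)."""
    n_founders = founders.shape[0]
    blocks = np.unique(block_of_site)
    n_blocks = blocks.size
    choice = np.empty((n_haplotypes, n_blocks), dtype=np.int64)
    choice[:, 0] = rng.integers(0, n_founders, size=n_haplotypes)
    for b in range(1, n_blocks):
        redraw = rng.random(n_haplotypes) < recomb
        fresh = rng.integers(0, n_founders, size=n_haplotypes)
        choice[:, b] = np.where(redraw, fresh, choice[:, b - 1])
    block_index = np.searchsorted(blocks, block_of_site)
    founder_of_site = choice[:, block_index]  # (n_hap, n_sites)
    return founders[founder_of_site, np.arange(founders.shape[1])]


def simulate_cohort(
    config: SimConfig,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Simulate a diploid cohort with block-wise LD.

    Returns the genotype table and a truth frame with columns
    contig, pos, ref, alt, true_af where ``true_af`` is the exact marginal
    alternative-allele probability of a random haplotype (the founder-pool
    mean at the site).
    """
    if config.n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if config.n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    for contig, length in config.contig_lengths.items():
        if length < config.ld_block_length:
            raise ValueError(
                f"contig {contig} ({length} bp) shorter than one LD block "
                f"({config.ld_block_length} bp)"
            )

    rng = spawn_rng(config.seed, "cohort")
    sites = _site_positions(config)
    n_sites = len(sites)

    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_shift = rng.integers(1, 4, size=n_sites)
    sites["ref"] = _BASES[ref_idx]
    sites["alt"] = _BASES[(ref_idx + alt_shift) % 4]
    sites["rsid"] = None

    founders, _ = _founder_alleles(
        rng, n_sites, config.n_founders, config.af_range
    )
    true_af = founders.mean(axis=0)

    n_hap = 2 * config.n_samples
    hap = np.empty((n_hap, n_sites), dtype=np.int8)
    for contig in dict.fromkeys(sites["contig"]):
        mask = (sites["contig"] == contig).to_numpy()
        block = (sites.loc[mask, "pos"].to_numpy() - 1) // config.ld_block_length
        hap[:, mask] = _copy_haplotypes(
            rng, founders[:, mask], block, n_hap, config.recomb_between_blocks
        )

    dosages = (hap[0::2] + hap[1::2]).T.astype(np.int16)  # sites x samples
    if config.missing_rate > 0:
        drop = rng.random(dosages.shape) < config.missing_rate
        dosages[drop] = MISSING

    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    truth = sites[["contig", "pos", "ref", "alt"]].copy()
    truth["true_af"] = true_af
    return GenotypeTable(sites=sites, samples=samples, dosages=dosages), truth


def simulate_two_populations(
    config_a: SimConfig,
    config_b: SimConfig,
    shared_founders: bool = True,
) -> tuple[GenotypeTable, GenotypeTable, pd.DataFrame]:
    """Two cohorts on identical sites, differing (typically) in LD block length.

    With ``shared_founders`` both populations draw haplotypes from the same
    founder pool, so site frequencies match in expectation while LD range
    differs. The population with the shorter block length has, in
    expectation, fewer high-r-squared proxies per site.
    """
    if config_a.n_sites != config_b.n_sites:
        raise ValueError("configs must share n_sites")
    if config_a.contig_lengths != config_b.contig_lengths:
        raise ValueError("configs must share contig_lengths (site positions)")

    gt_a, truth_a = simulate_cohort(config_a)
    if shared_founders:
        config_b = SimConfig(
            **{
                **config_b.__dict__,
                "seed": config_b.seed,
                "af_range": config_a.af_range,
                "n_founders": config_a.n_founders,
            }
        )
        # regenerate population b from config_a's founder pool
        rng_a = spawn_rng(config_a.seed, "cohort")
        sites = _site_positions(config_a)
        n_sites = len(sites)
        rng_a.integers(0, 4, size=n_sites)  # consume ref draws
        rng_a.integers(1, 4, size=n_sites)
        founders, _ = _founder_alleles(
            rng_a, n_sites, config_a.n_founders, config_a.af_range
        )
        rng_b = spawn_rng(config_b.seed, "cohort-b")
        n_hap = 2 * config_b.n_samples
        hap = np.empty((n_hap, n_sites), dtype=np.int8)
        for contig in dict.fromkeys(sites["contig"]):
            mask = (sites["contig"] == contig).to_numpy()
            block = (
                sites.loc[mask, "pos"].to_numpy() - 1
            ) // config_b.ld_block_length
            hap[:, mask] = _copy_haplotypes(
                rng_b,
                founders[:, mask],
                block,
                n_hap,
                config_b.recomb_between_blocks,
            )
        dosages = (hap[0::2] + hap[1::2]).T.astype(np.int16)
        if config_b.missing_rate > 0:
            drop = rng_b.random(dosages.shape) < config_b.missing_rate
            dosages[drop] = MISSING
        sites_b = gt_a.sites.copy()
        gt_b = GenotypeTable(
            sites=sites_b,
            samples=[f"T{i:04d}" for i in range(config_b.n_samples)],
            dosages=dosages,
        )
    else:
        gt_b, _ = simulate_cohort(config_b)
        gt_b.samples = [f"T{i:04d}" for i in range(config_b.n_samples)]
    return gt_a, gt_b, truth_a


# ---------------------------------------------------------------------------
# Depth tracks


def plant_depth_tracks(
    config: SimConfig,
) -> tuple[dict[str, dict[str, np.ndarray]], pd.DataFrame]:
    """Per-sample per-base depth with planted carrier regions.

    Background depth is Poisson(``depth_mean``); inside each planted
    interval exactly ``n_carrier_samples`` samples (a seeded random subset)
    have depth exactly ``carrier_depth``. Returns
    ``{sample: {contig: depth array}}`` and the plan as a truth frame.
    """
    rng = spawn_rng(config.seed, "depth")
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    tracks: dict[str, dict[str, np.ndarray]] = {
        s: {
            c: rng.poisson(config.depth_mean, size=length).astype(np.int64)
            for c, length in config.contig_lengths.items()
        }
        for s in samples
    }
    rows = []
    for plan in config.insertion_plan:
        carriers = rng.choice(
            config.n_samples, size=plan.n_carrier_samples, replace=False
        )
        for ci in carriers:
            tracks[samples[ci]][plan.contig][plan.start : plan.end] = (
                plan.carrier_depth
            )
        rows.append(
            (
                plan.contig,
                plan.start,
                plan.end,
                plan.end - plan.start,
                plan.n_carrier_samples,
                plan.carrier_depth,
            )
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "contig", "start", "end", "length",
            "n_carrier_samples", "carrier_depth",
        ],
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# SV calls


def _union_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sweep-line union; overlap means sharing >= 1 bp (abutting stays split)."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s < out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def simulate_sv_calls(
    config: SimConfig,
    n_calls_per_sample: int = 30,
    sv_types: Sequence[str] = ("DEL", "DUP", "INV"),
    mean_length: int = 5_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random per-sample SV calls plus the true collapsed set.

    The truth is computed by an in-place interval-union sweep per
    (sample, type, contig) stratum, independent of the collapsing module.
    """
    rng = spawn_rng(config.seed, "sv")
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    contigs = list(config.contig_lengths)
    rows = []
    for sample in samples:
        for _ in range(n_calls_per_sample):
            contig = contigs[rng.integers(len(contigs))]
            length = max(50, int(rng.exponential(mean_length)))
            length = min(length, config.contig_lengths[contig] - 1)
            start = int(rng.integers(0, config.contig_lengths[contig] - length))
            rows.append(
                (sample, str(rng.choice(sv_types)), contig, start, start + length)
            )
    calls = pd.DataFrame(
        rows, columns=["sample", "sv_type", "contig", "start", "end"]
    )
    truth_rows = []
    if len(calls):
        for (sample, sv_type, contig), grp in calls.groupby(
            ["sample", "sv_type", "contig"], sort=True
        ):
            merged = _union_intervals(
                list(zip(grp["start"], grp["end"]))
            )
            for s, e in merged:
                truth_rows.append((sample, sv_type, contig, s, e))
    truth = pd.DataFrame(
        truth_rows, columns=["sample", "sv_type", "contig", "start", "end"]
    )
    return calls, truth


# ---------------------------------------------------------------------------
# Assembly alignment coverage with planted gaps


def simulate_alignment_coverage(
    config: SimConfig,
    gap_plan: Sequence[tuple[str, int, int]] = (),
    centromeres: Sequence[tuple[str, int, int]] = (),
    min_gap_len: int = 800_000,
) -> tuple[dict[str, list[tuple[int, int]]], pd.DataFrame]:
    """Coverage intervals = contig minus planted gaps; truth = patchable gaps.

    A planted gap enters the truth iff it is strictly longer than
    ``min_gap_len`` and overlaps no centromere interval — pure arithmetic
    on the plan.
    """
    by_contig: dict[str, list[tuple[int, int]]] = {
        c: [] for c in config.contig_lengths
    }
    for contig, start, end in gap_plan:
        length = config.contig_lengths.get(contig)
        if length is None or not (0 <= start < end <= length):
            raise ValueError(f"gap {contig}:{start}-{end} out of bounds")
        by_contig[contig].append((start, end))

    coverage: dict[str, list[tuple[int, int]]] = {}
    for contig, length in config.contig_lengths.items():
        gaps = _union_intervals(by_contig[contig])
        ivs = []
        prev = 0
        for s, e in gaps:
            if s > prev:
                ivs.append((prev, s))
            prev = max(prev, e)
        if prev < length:
            ivs.append((prev, length))
        coverage[contig] = ivs

    truth_rows = []
    for contig, start, end in gap_plan:
        if end - start <= min_gap_len:
            continue
        hits_cen = any(
            c == contig and start < ce and cs < end
            for c, cs, ce in centromeres
        )
        if not hits_cen:
            truth_rows.append((contig, start, end, end - start))
    truth = pd.DataFrame(
        truth_rows, columns=["contig", "start", "end", "length"]
    ).sort_values(["contig", "start"], ignore_index=True)
    return coverage, truth


# ---------------------------------------------------------------------------
# Phase annotations


def simulate_phase_annotations(
    config: SimConfig,
    het_rate: float = 0.6,
    phased_rate: float = 0.95,
    block_span: int = 100_000,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-variant zygosity and phase-set labels plus true summary fractions.

    Het variants are phased with probability ``phased_rate``; phased
    variants within the same ``block_span`` window share a phase-set id.
    Truth fractions are direct counts over the generated rows.
    """
    rng = spawn_rng(config.seed, "phase")
    sites = _site_positions(config)
    n = len(sites)
    is_het = rng.random(n) < het_rate
    phased = is_het & (rng.random(n) < phased_rate)
    block_ids: list[str | None] = []
    for i in range(n):
        if phased[i]:
            window = sites["pos"].iloc[i] // block_span
            block_ids.append(f"PS_{sites['contig'].iloc[i]}_{window}")
        else:
            block_ids.append(None)
    df = sites.copy()
    df["zygosity"] = np.where(is_het, "het", "hom")
    df["phase_block_id"] = block_ids
    n_total = n
    n_phased = int(phased.sum())
    n_het = int(is_het.sum())
    truth = {
        "n_total": float(n_total),
        "n_het": float(n_het),
        "n_phased": float(n_phased),
        "phased_fraction_all": n_phased / n_total if n_total else float("nan"),
        "phased_fraction_het": n_phased / n_het if n_het else float("nan"),
    }
    return df, truth


# ---------------------------------------------------------------------------
# ROH segments


def simulate_roh(
    config: SimConfig,
    segments_per_sample: int = 8,
    length_scale: int = 2_000_000,
    min_sum_len: int = 5_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random per-sample ROH segments plus true long-ROH totals.

    Truth: per sample, the sum of planted segment lengths strictly greater
    than ``min_sum_len``.
    """
    rng = spawn_rng(config.seed, "roh")
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    contigs = list(config.contig_lengths)
    rows = []
    for sample in samples:
        for _ in range(segments_per_sample):
            contig = contigs[rng.integers(len(contigs))]
            clen = config.contig_lengths[contig]
            length = max(100_000, int(rng.exponential(length_scale)))
            length = min(length, clen - 1)
            start = int(rng.integers(0, clen - length))
            rows.append((sample, contig, start, start + length, length))
    segments = pd.DataFrame(
        rows, columns=["sample", "contig", "start", "end", "length"]
    )
    totals = (
        segments[segments["length"] > min_sum_len]
        .groupby("sample")["length"]
        .sum()
    )
    truth = pd.DataFrame(
        {
            "sample": samples,
            "total_long_roh_bp": [int(totals.get(s, 0)) for s in samples],
        }
    )
    return segments, truth


# ---------------------------------------------------------------------------
# One-shot fixture writer (CLI `simulate`)


def generate_all(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write every fixture plus its truth sidecar into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    gt, af_truth = simulate_cohort(config)
    p = outdir / "cohort.vcf"
    write_vcf(gt, p, config.contig_lengths)
    written["cohort_vcf"] = p
    p = outdir / "cohort.truth_af.tsv"
    write_tsv(af_truth, p)
    written["cohort_truth"] = p

    tracks, depth_truth = plant_depth_tracks(config)
    depth_dir = outdir / "depth"
    depth_dir.mkdir(exist_ok=True)
    for sample, per_contig in tracks.items():
        write_bedgraph(per_contig, depth_dir / f"{sample}.bedgraph")
    written["depth_dir"] = depth_dir
    p = outdir / "depth.truth_regions.tsv"
    write_tsv(depth_truth, p)
    written["depth_truth"] = p

    calls, sv_truth = simulate_sv_calls(config)
    p = outdir / "sv_calls.tsv"
    write_tsv(calls, p)
    written["sv_calls"] = p
    p = outdir / "sv.truth_collapsed.tsv"
    write_tsv(sv_truth, p)
    written["sv_truth"] = p

    phase, phase_truth = simulate_phase_annotations(config)
    p = outdir / "phase_annotations.tsv"
    write_tsv(phase, p)
    written["phase"] = p
    p = outdir / "phase.truth.tsv"
    write_tsv(pd.DataFrame([phase_truth]), p)
    written["phase_truth"] = p

    roh, roh_truth = simulate_roh(config)
    p = outdir / "roh_segments.tsv"
    write_tsv(roh, p)
    written["roh"] = p
    p = outdir / "roh.truth.tsv"
    write_tsv(roh_truth, p)
    written["roh_truth"] = p

    contig_bed = [
        (c, 0, length) for c, length in config.contig_lengths.items()
    ]
    write_bed(contig_bed, outdir / "contigs.bed")
    written["contigs"] = outdir / "contigs.bed"
    return written
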