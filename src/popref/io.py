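"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions
-----------
* VCF positions are 1-based (the format's own convention); BED and BedGraph
  intervals are 0-based half-open.
* Genotypes are held in memory as dosage matrices (``n_sites x n_samples``,
  values 0/1/2, missing = -1); multi-allelic VCF records are split into one
  biallelic row per alternative allele on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

SITE_COLUMNS = ["contig", "pos", "ref", "alt", "rsid"]


class PloidyError(ValueError):
    """A genotype record is not diploid."""


@dataclass
class GenotypeTable:
    """Multi-sample biallelic genotype dosages plus site metadata.

    ``sites`` has columns contig, pos (1-based), ref, alt, rsid (may be
    None); ``dosages`` is int16 with shape ``(len(sites), len(samples))``.
    """

    sites: pd.DataFrame
    samples: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        if self.dosages.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_keys(self) -> pd.Index:
        s = self.sites
        return pd.Index(zip(s["contig"], s["pos"], s["ref"], s["alt"]))


def write_vcf(
    table: GenotypeTable,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a GT-only multi-sample VCF 4.2 file (uncompressed)."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in dict.fromkeys(table.sites["contig"]):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        sites = table.sites
        for i in range(len(sites)):
            row = sites.iloc[i]
            rsid = row["rsid"] if row["rsid"] not in (None, "", np.nan) else "."
            gts = "\t".join(gt_strings[int(d)] for d in table.dosages[i])
            fh.write(
                f"{row['contig']}\t{row['pos']}\t{rsid}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> GenotypeTable:
    """Read a multi-sample VCF into dosages, splitting multi-allelic records.

    Each alternative allele becomes its own biallelic row whose dosage is
    the per-sample count of that allele. Raises :class:`PloidyError` for
    non-diploid genotype records.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[tuple] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        genos = var.genotypes  # [[a0, a1, phased], ...]
        for g in genos:
            if len(g) - 1 != 2:
                raise PloidyError(
                    f"non-diploid genotype at {var.CHROM}:{var.POS}"
                )
        alleles = np.array([[g[0], g[1]] for g in genos], dtype=np.int16)
        missing = (alleles < 0).any(axis=1)
        for alt_idx, alt in enumerate(var.ALT, start=1):
            dos = (alleles == alt_idx).sum(axis=1).astype(np.int16)
            dos[missing] = MISSING
            records.append(
                (var.CHROM, var.POS, var.REF, alt, var.ID or None)
            )
            rows.append(dos)
    vcf.close()
    sites = pd.DataFrame(records, columns=SITE_COLUMNS)
    dosages = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int16)
    )
    return GenotypeTable(sites=sites, samples=samples, dosages=dosages)


# ---------------------------------------------------------------------------
# BED / BedGraph


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write (contig, start, end[, extra...]) tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_bedgraph(
    depths: Mapping[str, np.ndarray], path: str | Path
) -> None:
    """Write per-base depths (one array per contig, offset 0) as BedGraph.

    Consecutive equal-depth bases are run-length collapsed; zero-depth runs
    are written too so the coordinate span is explicit.
    """
    with open(path, "w") as fh:
        for contig, arr in depths.items():
            arr = np.asarray(arr)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{contig}\t{s}\t{e}\t{int(arr[s])}\n")


def read_bedgraph(
    path: str | Path, contig_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Expand a BedGraph into dense per-base integer depth arrays.

    Bases not covered by any record get depth 0.
    """
    out = {
        c: np.zeros(length, dtype=np.int64)
        for c, length in contig_lengths.items()
    }
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            contig, start, end, value = line.split("\t")[:4]
            if contig not in out:
                raise ValueError(f"unknown contig {contig!r} in {path}")
            s, e = int(start), int(end)
            if e > out[contig].size:
                raise ValueError(
                    f"interval {contig}:{s}-{e} exceeds contig length"
                )
            out[contig][s:e] = int(float(value))
    return out


# ---------------------------------------------------------------------------
# Generic TSV helpers


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_panel_table(path: str | Path) -> pd.DataFrame:
    """Panel allele frequencies: columns contig, pos, ref, alt, panel, af."""
    df = read_tsv(path)
    required = {"contig", "pos", "ref", "alt", "panel", "af"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel table missing columns: {sorted(missing)}")
    return df


def read_paf_like(path: str | Path) -> pd.DataFrame:
    """Alignment blocks between a reference and an alternative assembly.

    Columns: ref_contig, ref_start, ref_end, alt_contig, alt_start,
    alt_end, strand (+/-). Coordinates 0-based half-open.
    """
    df = read_tsv(path)
    required = {
        "ref_contig", "ref_start", "ref_end",
        "alt_contig", "alt_start", "alt_end", "strand",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"alignment table missing columns: {sorted(missing)}")
    return df


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
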