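"""Cohort allele statistics, common/population-specific/novel variant sets,
and the major-allele rule used to build a population reference."""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeTable

KEY_COLUMNS = ["contig", "pos", "ref", "alt"]


def compute_allele_stats(table: GenotypeTable) -> pd.DataFrame:
    """Per-site allele statistics from a dosage table.

    Returns a frame with the site key columns plus:

    ``n_genotyped``
        individuals with a non-missing genotype,
    ``alt_af``
        alternative-allele count / (2 * n_genotyped), NaN when nobody is
        genotyped (such sites are flagged via ``n_genotyped == 0``, never
        dropped),
    ``maf``
        min(alt_af, 1 - alt_af).
    """
    dosages = table.dosages
    observed = dosages != MISSING
    n_genotyped = observed.sum(axis=1)
    alt_count = np.where(observed, dosages, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_af = np.where(
            n_genotyped > 0, alt_count / (2.0 * n_genotyped), np.nan
        )
    stats = table.sites[KEY_COLUMNS + ["rsid"]].copy()
    stats["n_genotyped"] = n_genotyped
    stats["alt_af"] = alt_af
    stats["maf"] = np.minimum(alt_af, 1.0 - alt_af)
    return stats


def select_common(
    stats: pd.DataFrame,
    maf_min: float = 0.05,
    min_genotyped: int = 100,
    frequency: str = "maf",
) -> pd.DataFrame:
    """Common variants: frequency strictly above ``maf_min`` and genotypes in
    at least ``min_genotyped`` individuals.

    ``frequency`` selects the filtered column: ``"maf"`` (default) or
    ``"alt_af"``.
    """
    if frequency not in ("maf", "alt_af"):
        raise ValueError(f"frequency must be 'maf' or 'alt_af', got {frequency!r}")
    keep = (stats[frequency] > maf_min) & (stats["n_genotyped"] >= min_genotyped)
    return stats[keep.fillna(False)].reset_index(drop=True)


def select_population_specific(
    common: pd.DataFrame,
    panels: pd.DataFrame,
    rare_max: float = 0.01,
) -> pd.DataFrame:
    """Common variants that are rare (< ``rare_max``) or absent in every panel.

    ``panels`` has columns contig, pos, ref, alt, panel, af; a site key
    absent from the table counts as "not detected". Allele-mismatched
    panel entries do not match the key and therefore also count as not
    detected.
    """
    if len(common) == 0:
        return common.copy()
    panel_keyed = panels.set_index(KEY_COLUMNS) if len(panels) else None
    keep = []
    keys = list(common[KEY_COLUMNS].itertuples(index=False, name=None))
    for key in keys:
        if panel_keyed is None or key not in panel_keyed.index:
            keep.append(True)
            continue
        afs = panel_keyed.loc[[key], "af"]
        keep.append(bool((afs < rare_max).all()))
    return common[np.array(keep)].reset_index(drop=True)


def flag_novel(
    variants: pd.DataFrame, rsid_index: Iterable[str]
) -> pd.DataFrame:
    """Variants lacking any identifier: rsid unset and site key not indexed.

    ``rsid_index`` is a collection of known identifiers keyed as
    ``contig:pos:ref:alt`` strings (may be empty).
    """
    index = set(rsid_index)
    has_rsid = variants["rsid"].notna() & (variants["rsid"] != "")
    keys = (
        variants["contig"].astype(str)
        + ":" + variants["pos"].astype(str)
        + ":" + variants["ref"] + ":" + variants["alt"]
    )
    keep = ~has_rsid & ~keys.isin(index)
    return variants[keep].reset_index(drop=True)


def major_allele_at(stats: pd.DataFrame) -> pd.Series:
    """The allele with the highest cohort AF at each site (ref wins ties).

    Raises for any site with ``n_genotyped == 0`` — the major allele is
    undefined there.
    """
    ungenotyped = stats[stats["n_genotyped"] == 0]
    if len(ungenotyped):
        first = ungenotyped.iloc[0]
        raise ValueError(
            f"major allele undefined at {len(ungenotyped)} ungenotyped "
            f"site(s), first: {first['contig']}:{first['pos']}"
        )
    return pd.Series(
        np.where(stats["alt_af"] > 0.5, stats["alt"], stats["ref"]),
        index=stats.index,
        name="major_allele",
    )
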