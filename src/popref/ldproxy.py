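"""GWAS tag-SNP selection, LD proxy discovery, and cross-population proxy
comparison.

r-squared is the squared Pearson correlation of genotype dosages (composite
LD) — phase is not assumed available for either cohort. Haplotype-based
r-squared via EM would be a drop-in extension but is deliberately not
implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._util import round_half_away
from .io import MISSING, GenotypeTable

SiteKey = tuple  # (contig, pos, ref, alt)


class MonomorphicError(ValueError):
    """r-squared is undefined for a monomorphic dosage vector."""


def r_squared(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation of two dosage vectors (0/1/2 scale).

    Missing entries (coded ``-1``) are removed pairwise-complete. Raises
    :class:`MonomorphicError` when either vector is constant over the
    complete pairs, and ``ValueError`` for fewer than two complete pairs —
    undefined is signalled, never silently reported as 0.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    complete = (a != MISSING) & (b != MISSING)
    a, b = a[complete], b[complete]
    if a.size < 2:
        raise ValueError(
            f"need >= 2 complete dosage pairs, have {a.size}"
        )
    va = a.var()
    vb = b.var()
    if va == 0.0 or vb == 0.0:
        raise MonomorphicError("monomorphic vector: r-squared undefined")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    # guard against float error pushing a perfect correlation past 1
    return float(min(cov * cov / (va * vb), 1.0))


# ---------------------------------------------------------------------------
# Tag SNP selection


@dataclass(frozen=True)
class TagSNP:
    trait_term: str
    contig: str
    pos: int
    ref: str
    alt: str
    strength: float
    n_supporting_associations: int
    n_studies: int
    locus_start: int
    locus_end: int

    @property
    def key(self) -> SiteKey:
        return (self.contig, self.pos, self.ref, self.alt)


def select_tag_snps(
    associations: pd.DataFrame,
    window_bp: int = 1_000_000,
    min_studies: int = 2,
    contig_lengths: Optional[dict[str, int]] = None,
) -> list[TagSNP]:
    """Greedy per-trait locus clustering: strongest association first.

    ``associations`` columns: trait_term, contig, pos, ref, alt, strength
    (smaller is stronger, e.g. a p-value), study_id. Per trait the
    strongest remaining association seeds a locus; every association on
    the same contig within ``window_bp`` joins it; the locus is retained
    iff it draws on at least ``min_studies`` distinct study_ids, in which
    case its seed becomes the TagSNP. Ties on strength break by lower
    (contig, pos), so the result is invariant under input permutation.
    """
    required = {"trait_term", "contig", "pos", "ref", "alt", "strength", "study_id"}
    missing = required - set(associations.columns)
    if missing:
        raise ValueError(f"association table missing columns: {sorted(missing)}")
    if (associations["strength"] <= 0).any():
        raise ValueError("association strength must be > 0")

    tags: list[TagSNP] = []
    for trait in sorted(associations["trait_term"].unique()):
        pool = (
            associations[associations["trait_term"] == trait]
            .sort_values(["strength", "contig", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )
        while len(pool):
            seed = pool.iloc[0]
            in_locus = (pool["contig"] == seed["contig"]) & (
                (pool["pos"] - seed["pos"]).abs() <= window_bp
            )
            locus = pool[in_locus]
            n_studies = locus["study_id"].nunique()
            if n_studies >= min_studies:
                lo = max(1, int(seed["pos"]) - window_bp)
                hi = int(seed["pos"]) + window_bp
                if contig_lengths and seed["contig"] in contig_lengths:
                    hi = min(hi, contig_lengths[seed["contig"]])
                tags.append(
                    TagSNP(
                        trait_term=trait,
                        contig=str(seed["contig"]),
                        pos=int(seed["pos"]),
                        ref=str(seed["ref"]),
                        alt=str(seed["alt"]),
                        strength=float(seed["strength"]),
                        n_supporting_associations=int(len(locus)),
                        n_studies=int(n_studies),
                        locus_start=lo,
                        locus_end=hi,
                    )
                )
            pool = pool[~in_locus].reset_index(drop=True)
    return tags


# ---------------------------------------------------------------------------
# Proxy discovery


@dataclass
class ProxySet:
    tag_key: SiteKey
    population: str
    proxies: dict[SiteKey, float] = field(default_factory=dict)
    assessable: bool = True
    reason: str = ""
    not_assessable_sites: list[SiteKey] = field(default_factory=list)

    @property
    def n_proxies(self) -> int:
        return len(self.proxies)


def find_proxies(
    tag_key: SiteKey,
    table: GenotypeTable,
    r2_min: float = 0.8,
    window_bp: int = 1_000_000,
    min_complete: int = 10,
    population: str = "",
) -> ProxySet:
    """Sites within ``window_bp`` of the tag with r-squared strictly above
    ``r2_min``; the tag itself is excluded.

    A tag absent from the table or monomorphic in it yields an
    unassessable ProxySet (``assessable=False``). Candidate pairs with
    fewer than ``min_complete`` complete observations are recorded in
    ``not_assessable_sites`` rather than given an r-squared.
    """
    contig, pos, ref, alt = tag_key
    keys = table.site_keys()
    try:
        tag_idx = keys.get_loc(tag_key)
    except KeyError:
        return ProxySet(
            tag_key, population, assessable=False, reason="tag not present"
        )
    if isinstance(tag_idx, (slice, np.ndarray)):  # duplicated key
        tag_idx = np.flatnonzero(keys == tag_key)[0]
    tag_dos = table.dosages[tag_idx].astype(float)
    tag_obs = tag_dos != MISSING
    if tag_obs.sum() < 2 or tag_dos[tag_obs].var() == 0.0:
        return ProxySet(
            tag_key, population, assessable=False,
            reason="tag monomorphic or insufficiently genotyped",
        )

    sites = table.sites
    in_window = (
        (sites["contig"] == contig)
        & ((sites["pos"] - pos).abs() <= window_bp)
    ).to_numpy()
    in_window[tag_idx] = False

    result = ProxySet(tag_key, population)
    cand_idx = np.flatnonzero(in_window)
    if cand_idx.size == 0:
        return result

    cand = table.dosages[cand_idx].astype(float)
    cand_obs = cand != MISSING
    fully_observed = cand_obs.all(axis=1)

    if tag_obs.all() and fully_observed.any():
        # vectorized path for fully observed candidates
        sub = cand[fully_observed]
        n = sub.shape[1]
        if n >= min_complete:
            var = sub.var(axis=1)
            poly = var > 0.0
            centered = sub - sub.mean(axis=1, keepdims=True)
            tag_centered = tag_dos - tag_dos.mean()
            cov = centered @ tag_centered / n
            tv = tag_dos.var()
            with np.errstate(invalid="ignore", divide="ignore"):
                r2 = np.where(poly, np.minimum(cov * cov / (var * tv), 1.0), np.nan)
            for local_i, global_i in enumerate(cand_idx[fully_observed]):
                if poly[local_i] and r2[local_i] > r2_min:
                    row = sites.iloc[global_i]
                    result.proxies[
                        (row["contig"], row["pos"], row["ref"], row["alt"])
                    ] = float(r2[local_i])
        remaining = cand_idx[~fully_observed]
    else:
        remaining = cand_idx

    for global_i in remaining:
        row = sites.iloc[global_i]
        key = (row["contig"], row["pos"], row["ref"], row["alt"])
        other = table.dosages[global_i].astype(float)
        complete = tag_obs & (other != MISSING)
        if complete.sum() < min_complete:
            result.not_assessable_sites.append(key)
            continue
        try:
            r2 = r_squared(tag_dos[complete], other[complete])
        except MonomorphicError:
            continue
        if r2 > r2_min:
            result.proxies[key] = r2
    return result


# ---------------------------------------------------------------------------
# Proxy comparison


@dataclass
class ProxyComparison:
    tag_key: SiteKey
    n_a: int
    n_b: int
    n_shared: int
    frac_a_shared: Optional[float]
    frac_b_shared: Optional[float]

    @property
    def frac_a_only(self) -> Optional[float]:
        return None if self.frac_a_shared is None else 1.0 - self.frac_a_shared

    @property
    def frac_b_only(self) -> Optional[float]:
        return None if self.frac_b_shared is None else 1.0 - self.frac_b_shared

    def _pct(self, frac: Optional[float]) -> Optional[int]:
        return None if frac is None else int(round_half_away(100.0 * frac))

    @property
    def pct_a_shared(self) -> Optional[int]:
        return self._pct(self.frac_a_shared)

    @property
    def pct_a_only(self) -> Optional[int]:
        return self._pct(self.frac_a_only)

    @property
    def pct_b_shared(self) -> Optional[int]:
        return self._pct(self.frac_b_shared)

    @property
    def pct_b_only(self) -> Optional[int]:
        return self._pct(self.frac_b_only)


def compare_proxy_sets(set_a: ProxySet, set_b: ProxySet) -> ProxyComparison:
    """Shared/only proxy fractions between two populations for one tag.

    Percentages are rounded half-away-from-zero to the nearest integer;
    the exact fractions are retained alongside. An empty proxy set leaves
    its percentages undefined (``None``) rather than 0 or 100.
    """
    if set_a.tag_key != set_b.tag_key:
        raise ValueError(
            f"proxy sets are for different tags: {set_a.tag_key} vs {set_b.tag_key}"
        )
    shared = set(set_a.proxies) & set(set_b.proxies)
    n_a, n_b, n_shared = len(set_a.proxies), len(set_b.proxies), len(shared)
    return ProxyComparison(
        tag_key=set_a.tag_key,
        n_a=n_a,
        n_b=n_b,
        n_shared=n_shared,
        frac_a_shared=(n_shared / n_a) if n_a else None,
        frac_b_shared=(n_shared / n_b) if n_b else None,
    )


# ---------------------------------------------------------------------------
# AF contrast


def af_contrast(
    tag_sites: pd.DataFrame,
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    common_cut: float = 0.05,
) -> pd.DataFrame:
    """Per-tag alternative-AF difference between two cohorts, with a class
    label in {common-both, common-a-rare-b, common-b-rare-a, rare-both,
    absent-in-a, absent-in-b}.

    "Common" means AF strictly above ``common_cut``. Tags absent (or
    ungenotyped) in one cohort are labelled absent and count toward the
    not-assessable tally; ``delta`` is NaN there.
    """
    key_cols = ["contig", "pos", "ref", "alt"]

    def _lookup(stats: pd.DataFrame) -> pd.Series:
        if len(stats) == 0:
            return pd.Series(dtype=float)
        usable = stats[stats["n_genotyped"] > 0]
        return usable.set_index(key_cols)["alt_af"]

    af_a_map = _lookup(stats_a)
    af_b_map = _lookup(stats_b)
    rows = []
    for key in tag_sites[key_cols].itertuples(index=False, name=None):
        af_a = af_a_map.get(key, np.nan)
        af_b = af_b_map.get(key, np.nan)
        if np.isnan(af_a):
            label = "absent-in-a"
        elif np.isnan(af_b):
            label = "absent-in-b"
        else:
            common_a = af_a > common_cut
            common_b = af_b > common_cut
            label = {
                (True, True): "common-both",
                (True, False): "common-a-rare-b",
                (False, True): "common-b-rare-a",
                (False, False): "rare-both",
            }[(common_a, common_b)]
        rows.append((*key, af_a, af_b, af_a - af_b, label))
    return pd.DataFrame(
        rows, columns=key_cols + ["af_a", "af_b", "delta", "label"]
    )
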