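"""r-squared, tag-SNP clustering, proxy discovery and comparison."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_table
from popref.io import MISSING
from popref.ldproxy import (
    MonomorphicError,
    ProxySet,
    af_contrast,
    compare_proxy_sets,
    find_proxies,
    r_squared,
    select_tag_snps,
)


def brute_force_r2(a, b):
    """Textbook Pearson correlation squared, math only — the oracle."""
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / n
    va = sum((x - ma) ** 2 for x in a) / n
    vb = sum((y - mb) ** 2 for y in b) / n
    return (cov * cov) / (va * vb)


class TestRSquared:
    def test_identical_vectors(self):
        assert r_squared([0, 1, 2, 0], [0, 1, 2, 0]) == pytest.approx(1.0)

    def test_orthogonal_by_construction(self):
        assert r_squared([0, 0, 2, 2], [0, 2, 0, 2]) == pytest.approx(0.0)

    def test_hand_pearson(self):
        a, b = [0, 1, 2, 0, 1, 2], [0, 1, 1, 0, 1, 2]
        assert r_squared(a, b) == pytest.approx(brute_force_r2(a, b))

    def test_monomorphic_signalled_not_zero(self):
        with pytest.raises(MonomorphicError):
            r_squared([1, 1, 1, 1], [0, 1, 2, 0])

    def test_too_short(self):
        with pytest.raises(ValueError, match="complete"):
            r_squared([1], [2])

    def test_pairwise_complete_deletion(self):
        a = [0, 1, 2, 0, MISSING, 2]
        b = [0, 1, 1, MISSING, 1, 2]
        expect = brute_force_r2([0, 1, 2, 2], [0, 1, 1, 2])
        assert r_squared(a, b) == pytest.approx(expect)

    def test_exhaustive_short_vectors(self):
        # every polymorphic dosage-vector pair of length 3 and 4
        for n in (3, 4):
            for a in itertools.product((0, 1, 2), repeat=n):
                if len(set(a)) == 1:
                    continue
                for b in itertools.product((0, 1, 2), repeat=n):
                    if len(set(b)) == 1:
                        continue
                    assert r_squared(a, b) == pytest.approx(
                        brute_force_r2(a, b), abs=1e-12
                    )

    @given(
        st.integers(2, 8).flatmap(
            lambda n: st.tuples(
                st.lists(st.sampled_from([0, 1, 2]), min_size=n, max_size=n),
                st.lists(st.sampled_from([0, 1, 2]), min_size=n, max_size=n),
            )
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_length_le_8(self, pair):
        a, b = pair
        if len(set(a)) == 1 or len(set(b)) == 1:
            with pytest.raises(MonomorphicError):
                r_squared(a, b)
            return
        got = r_squared(a, b)
        assert got == pytest.approx(brute_force_r2(a, b), abs=1e-12)
        assert 0.0 <= got <= 1.0 + 1e-12

    @given(
        st.integers(2, 8).flatmap(
            lambda n: st.tuples(
                st.lists(st.sampled_from([0, 1, 2]), min_size=n, max_size=n),
                st.lists(st.sampled_from([0, 1, 2]), min_size=n, max_size=n),
            )
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_relabel_invariant(self, pair):
        a, b = pair
        if len(set(a)) == 1 or len(set(b)) == 1:
            return
        r = r_squared(a, b)
        assert r_squared(b, a) == pytest.approx(r)
        assert r_squared([2 - x for x in a], b) == pytest.approx(r)
        assert r_squared(a, [2 - y for y in b]) == pytest.approx(r)


def assoc_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["trait_term", "contig", "pos", "ref", "alt", "strength", "study_id"],
    )


def brute_force_tags(df, window=1_000_000, min_studies=2):
    """Independent clustering oracle: repeatedly pop the global strongest."""
    tags = []
    for trait in sorted(df["trait_term"].unique()):
        pool = df[df["trait_term"] == trait].to_dict("records")
        while pool:
            seed = min(pool, key=lambda r: (r["strength"], r["contig"], r["pos"]))
            locus = [
                r for r in pool
                if r["contig"] == seed["contig"]
                and abs(r["pos"] - seed["pos"]) <= window
            ]
            if len({r["study_id"] for r in locus}) >= min_studies:
                tags.append((trait, seed["contig"], seed["pos"]))
            pool = [r for r in pool if r not in locus]
    return tags


class TestSelectTagSnps:
    def test_unreplicated_locus_dropped(self):
        df = assoc_frame([("t", "chr1", 1000, "A", "C", 1e-8, "s1")])
        assert select_tag_snps(df) == []

    def test_two_variants_one_locus(self):
        df = assoc_frame(
            [
                ("t", "chr1", 1_000_000, "A", "C", 1e-9, "s1"),
                ("t", "chr1", 1_500_000, "G", "T", 1e-8, "s2"),
            ]
        )
        tags = select_tag_snps(df)
        assert len(tags) == 1
        assert tags[0].pos == 1_000_000
        assert tags[0].n_supporting_associations == 2
        assert [(t.trait_term, t.contig, t.pos) for t in tags] == brute_force_tags(df)

    def test_disjoint_windows_two_tags(self):
        df = assoc_frame(
            [
                ("t", "chr1", 1_000_000, "A", "C", 1e-9, "s1"),
                ("t", "chr1", 1_000_100, "A", "G", 1e-7, "s2"),
                ("t", "chr1", 4_000_000, "G", "T", 1e-8, "s3"),
                ("t", "chr1", 4_000_200, "G", "A", 1e-6, "s4"),
            ]
        )
        tags = select_tag_snps(df)
        assert [t.pos for t in tags] == [1_000_000, 4_000_000]

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(2, 30))
            df = assoc_frame(
                [
                    (
                        f"t{rng.integers(2)}",
                        f"chr{rng.integers(1, 3)}",
                        int(rng.integers(1, 10_000_000)),
                        "A", "C",
                        float(rng.uniform(1e-12, 1e-4)),
                        f"s{rng.integers(5)}",
                    )
                    for _ in range(n)
                ]
            )
            got = [(t.trait_term, t.contig, t.pos) for t in select_tag_snps(df)]
            assert got == brute_force_tags(df)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        df = assoc_frame(
            [
                ("t", "chr1", int(p), "A", "C", float(s), f"s{i % 3}")
                for i, (p, s) in enumerate(
                    zip(
                        rng.integers(1, 20_000_000, 25),
                        rng.uniform(1e-12, 1e-5, 25),
                    )
                )
            ]
        )
        base = select_tag_snps(df)
        for seed in range(3):
            shuffled = df.sample(frac=1, random_state=seed).reset_index(drop=True)
            assert select_tag_snps(shuffled) == base

    def test_output_loci_pairwise_apart(self):
        rng = np.random.default_rng(2)
        df = assoc_frame(
            [
                ("t", "chr1", int(p), "A", "C", float(s), f"s{i % 2}")
                for i, (p, s) in enumerate(
                    zip(
                        rng.integers(1, 30_000_000, 40),
                        rng.uniform(1e-12, 1e-5, 40),
                    )
                )
            ]
        )
        tags = select_tag_snps(df)
        pos = sorted(t.pos for t in tags)
        assert all(b - a > 1_000_000 for a, b in zip(pos, pos[1:]))

    def test_empty_input(self):
        assert select_tag_snps(assoc_frame([])) == []


class TestFindProxies:
    def table_with_tag(self):
        # site 0 = tag; site 1 duplicates it; site 2 orthogonal; site 3 far away
        dos = np.array(
            [
                [0, 0, 1, 1, 2, 2, 0, 1, 2, 0],
                [0, 0, 1, 1, 2, 2, 0, 1, 2, 0],
                [0, 2, 0, 2, 0, 2, 0, 2, 0, 2],
                [0, 0, 1, 1, 2, 2, 0, 1, 2, 0],
            ]
        )
        table = make_table(dos, spacing=100)
        table.sites.loc[3, "pos"] = 5_000_000  # outside the window
        return table

    def tag_key(self, table):
        row = table.sites.iloc[0]
        return (row["contig"], row["pos"], row["ref"], row["alt"])

    def test_duplicate_dosages_is_proxy_with_r2_1(self):
        table = self.table_with_tag()
        ps = find_proxies(self.tag_key(table), table, min_complete=5)
        assert ps.assessable
        keys = {k[1] for k in ps.proxies}
        assert 200 in keys
        assert ps.proxies[("chr1", 200, "A", "C")] == pytest.approx(1.0)

    def test_tag_excluded_from_own_proxies(self):
        table = self.table_with_tag()
        ps = find_proxies(self.tag_key(table), table, min_complete=5)
        assert self.tag_key(table) not in ps.proxies

    def test_window_excludes_far_site(self):
        table = self.table_with_tag()
        ps = find_proxies(self.tag_key(table), table, min_complete=5)
        assert 5_000_000 not in {k[1] for k in ps.proxies}

    def test_boundary_r2_excluded(self):
        # construct r2 exactly at the threshold: r2_min equal to actual r2
        table = self.table_with_tag()
        tag = self.tag_key(table)
        r2 = 1.0
        ps = find_proxies(tag, table, r2_min=r2, min_complete=5)
        assert ("chr1", 200, "A", "C") not in ps.proxies  # strict >

    def test_absent_tag_not_assessable(self):
        table = self.table_with_tag()
        ps = find_proxies(("chr9", 1, "A", "C"), table)
        assert not ps.assessable and "not present" in ps.reason

    def test_monomorphic_tag_not_assessable(self):
        dos = np.array([[1, 1, 1, 1], [0, 1, 2, 0]])
        table = make_table(dos)
        row = table.sites.iloc[0]
        ps = find_proxies((row["contig"], row["pos"], row["ref"], row["alt"]), table)
        assert not ps.assessable

    def test_no_polymorphic_sites_in_window_empty(self):
        dos = np.array([[0, 1, 2, 0], [1, 1, 1, 1]])
        table = make_table(dos)
        row = table.sites.iloc[0]
        ps = find_proxies(
            (row["contig"], row["pos"], row["ref"], row["alt"]),
            table, min_complete=2,
        )
        assert ps.assessable and ps.n_proxies == 0

    def test_too_few_complete_pairs_not_assessable(self):
        dos = np.array(
            [
                [0, 1, 2, 0, 1, 2, 0, 1, 2, 0, 1, 2],
                [0, 1, 2, 0, 1] + [MISSING] * 7,
            ]
        )
        table = make_table(dos)
        row = table.sites.iloc[0]
        ps = find_proxies(
            (row["contig"], row["pos"], row["ref"], row["alt"]),
            table, min_complete=10,
        )
        assert ("chr1", 200, "A", "C") in ps.not_assessable_sites
        assert ("chr1", 200, "A", "C") not in ps.proxies

    def test_monotone_in_r2_min_and_window(self, small_cohort):
        gt, _ = small_cohort
        keys = list(gt.site_keys())
        tag = keys[len(keys) // 2]
        base = find_proxies(tag, gt, r2_min=0.2, window_bp=100_000, min_complete=5)
        if not base.assessable:
            pytest.skip("seeded tag happens to be monomorphic")
        tighter = find_proxies(tag, gt, r2_min=0.8, window_bp=100_000, min_complete=5)
        narrower = find_proxies(tag, gt, r2_min=0.2, window_bp=10_000, min_complete=5)
        assert set(tighter.proxies) <= set(base.proxies)
        assert set(narrower.proxies) <= set(base.proxies)

    def test_vectorized_path_matches_pairwise(self, small_cohort):
        gt, _ = small_cohort
        keys = list(gt.site_keys())
        tag = keys[10]
        fast = find_proxies(tag, gt, r2_min=0.5, min_complete=5)
        if not fast.assessable:
            pytest.skip("seeded tag happens to be monomorphic")
        tag_dos = gt.dosages[10]
        slow = {}
        for i, key in enumerate(keys):
            if i == 10:
                continue
            try:
                r2 = r_squared(tag_dos, gt.dosages[i])
            except ValueError:
                continue
            if r2 > 0.5:
                slow[key] = r2
        assert set(fast.proxies) == set(slow)
        for k in slow:
            assert fast.proxies[k] == pytest.approx(slow[k])


class TestCompareProxySets:
    def mk(self, keys, tag=("chr1", 500, "A", "C"), pop="x"):
        return ProxySet(tag, pop, proxies={k: 0.9 for k in keys})

    def key(self, i):
        return ("chr1", 1000 + i, "A", "C")

    def test_worked_example_7_3_2(self):
        set_a = self.mk([self.key(i) for i in range(7)], pop="a")
        set_b = self.mk(
            [self.key(0), self.key(1), self.key(100)], pop="b"
        )
        cmp_ = compare_proxy_sets(set_a, set_b)
        assert (cmp_.n_a, cmp_.n_b, cmp_.n_shared) == (7, 3, 2)
        assert cmp_.pct_a_shared == 29
        assert cmp_.pct_a_only == 71
        assert cmp_.pct_b_shared == 67
        assert cmp_.pct_b_only == 33
        assert cmp_.frac_a_shared == pytest.approx(2 / 7)

    def test_identical_sets(self):
        keys = [self.key(i) for i in range(4)]
        cmp_ = compare_proxy_sets(self.mk(keys, pop="a"), self.mk(keys, pop="b"))
        assert cmp_.pct_a_shared == 100 and cmp_.pct_a_only == 0
        assert cmp_.pct_b_shared == 100 and cmp_.pct_b_only == 0

    def test_empty_side_undefined(self):
        cmp_ = compare_proxy_sets(
            self.mk([], pop="a"), self.mk([self.key(1)], pop="b")
        )
        assert cmp_.n_shared == 0
        assert cmp_.pct_a_shared is None and cmp_.pct_a_only is None
        assert cmp_.pct_b_shared == 0

    def test_mismatched_tags_rejected(self):
        a = self.mk([], tag=("chr1", 500, "A", "C"))
        b = self.mk([], tag=("chr2", 500, "A", "C"))
        with pytest.raises(ValueError, match="different tags"):
            compare_proxy_sets(a, b)

    def test_shared_plus_only_is_100(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            na, nb = rng.integers(1, 10, 2)
            shared = int(rng.integers(0, min(na, nb) + 1))
            a_keys = [self.key(i) for i in range(na)]
            b_keys = [self.key(i) for i in range(shared)] + [
                self.key(1000 + i) for i in range(nb - shared)
            ]
            cmp_ = compare_proxy_sets(self.mk(a_keys, pop="a"), self.mk(b_keys, pop="b"))
            assert cmp_.frac_a_shared + cmp_.frac_a_only == pytest.approx(1.0)
            assert cmp_.frac_b_shared + cmp_.frac_b_only == pytest.approx(1.0)


class TestAfContrast:
    def stats(self, af_by_pos, n=110):
        rows = []
        for pos, af in af_by_pos.items():
            rows.append(
                dict(contig="chr1", pos=pos, ref="A", alt="C", rsid=None,
                     n_genotyped=n, alt_af=af, maf=min(af, 1 - af))
            )
        return pd.DataFrame(rows)

    def sites(self, pos_list):
        return pd.DataFrame(
            [dict(contig="chr1", pos=p, ref="A", alt="C") for p in pos_list]
        )

    def test_common_both_zero_delta(self):
        out = af_contrast(
            self.sites([100]), self.stats({100: 0.30}), self.stats({100: 0.30})
        )
        assert out.loc[0, "label"] == "common-both"
        assert out.loc[0, "delta"] == pytest.approx(0.0)

    def test_straddles_cut(self):
        out = af_contrast(
            self.sites([100]), self.stats({100: 0.06}), self.stats({100: 0.04})
        )
        assert out.loc[0, "label"] == "common-a-rare-b"

    def test_absent_in_b(self):
        out = af_contrast(self.sites([100]), self.stats({100: 0.3}), self.stats({}))
        assert out.loc[0, "label"] == "absent-in-b"
        assert np.isnan(out.loc[0, "delta"])
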