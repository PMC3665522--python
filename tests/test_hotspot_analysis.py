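"""De-redundification, representative-domain selection, cross-species
linking, Fisher enrichment, relatability classes, co-occurrence tests."""

import math
from fractions import Fraction

import numpy as np
import pytest

import domainhotspots as dh


def _dom(acc, root=False, feats=False, L=100, sfam="s1"):
    return dh.DomainModel(accession=acc, source="synthetic", length=L,
                          is_hierarchy_root=root, superfamily_key=sfam,
                          has_feature_annotation=feats)


def _call(acc, pos, key, kind="position", thr=1.6, species=("yeast",),
          feature=None, score=2.0):
    return dh.HotspotCall(domain_accession=acc, position=pos, score=score,
                          kind=kind, threshold=thr, mutation_set_key=tuple(key),
                          species_set=frozenset(species), feature_name=feature)


def exact_right_fisher(a, b, c, d) -> Fraction:
    """Right-sided Fisher p by exhaustive hypergeometric enumeration."""
    N, m1, r1 = a + b + c + d, a + c, a + b
    lo, hi = max(0, r1 + m1 - N), min(r1, m1)
    num = sum(math.comb(r1, k) * math.comb(N - r1, m1 - k)
              for k in range(max(a, lo), hi + 1))
    return Fraction(num, math.comb(N, m1))


class TestRepresentativeDomain:
    def test_root_preferred_over_alphanumeric_order(self):
        doms = [_dom("pfam00071"), _dom("smart00175"), _dom("cd00882", root=True)]
        assert dh.select_representative_domain(doms) == "cd00882"
        # root wins even when it sorts last
        doms = [_dom("aaa"), _dom("zzz", root=True)]
        assert dh.select_representative_domain(doms) == "zzz"

    def test_feature_annotation_is_the_fallback(self):
        doms = [_dom("aaa"), _dom("bbb", feats=True)]
        assert dh.select_representative_domain(doms) == "bbb"

    def test_first_overall_when_no_root_or_features(self):
        doms = [_dom("bbb"), _dom("aaa")]
        assert dh.select_representative_domain(doms) == "aaa"

    def test_single_domain(self):
        assert dh.select_representative_domain([_dom("x")]) == "x"

    def test_ordering_is_case_insensitive(self):
        doms = [_dom("PFAM1", root=True), _dom("cd9", root=True)]
        assert dh.select_representative_domain(doms) == "cd9"


class TestDeduplicate:
    def test_redundant_copies_collapse_to_one_group(self):
        doms = [_dom(f"d{i:03d}", root=(i == 0)) for i in range(120)]
        calls = [_call(d.accession, 17, ("m1", "m2", "m3")) for d in doms]
        groups = dh.deduplicate(calls, doms)
        assert len(groups) == 1
        assert groups[0].representative_domain == "d000"
        assert len(groups[0].member_calls) == 120

    def test_disjoint_mutation_sets_stay_separate(self):
        doms = [_dom("d1"), _dom("d2")]
        calls = [_call("d1", 5, ("m1",)), _call("d2", 9, ("m2",))]
        assert len(dh.deduplicate(calls, doms)) == 2

    def test_idempotent_and_member_conserving(self):
        doms = [_dom(f"d{i}") for i in range(6)]
        calls = [_call(f"d{i}", 3, ("mA", "mB")) for i in range(4)] + \
                [_call("d4", 8, ("mC",)), _call("d5", 1, ("mC",))]
        groups = dh.deduplicate(calls, doms)
        assert sum(len(g.member_calls) for g in groups) == len(calls)
        again = dh.deduplicate([c for g in groups for c in g.member_calls], doms)
        assert {g.mutation_set_key for g in again} == {g.mutation_set_key for g in groups}

    def test_mixed_kinds_rejected(self):
        doms = [_dom("d1")]
        calls = [_call("d1", 1, ("m1",), kind="position"),
                 _call("d1", 2, ("m1",), kind="feature")]
        with pytest.raises(ValueError):
            dh.deduplicate(calls, doms)


class TestLinkHotspots:
    def _tables(self, yeast_counts, human_counts, L=20, acc="d1"):
        t = dh.DomainMutationTable(domain_accession=acc, length=L)
        t.counts_by_species["yeast"] = np.array(yeast_counts)
        t.counts_by_species["human"] = np.array(human_counts)
        return {acc: t}

    def test_position_group_links_on_same_column(self):
        yeast = [0] * 20
        yeast[16] = 3
        human = [0] * 20
        human[16] = 2
        tables = self._tables(yeast, human)
        g = dh.HotspotGroup(("m1",), [_call("d1", 17, ("m1",))], "d1")
        linked, frac = dh.link_hotspots([g], tables, "human")
        assert linked == [True] and frac == 1.0

    def test_feature_group_links_via_other_feature_column(self):
        yeast = [0] * 20
        yeast[4] = 3
        human = [0] * 20
        human[9] = 1  # different column, same feature
        tables = self._tables(yeast, human)
        feats = [dh.FeatureAnnotation("d1", "site", frozenset({5, 10}))]
        g = dh.HotspotGroup(
            ("m1",), [_call("d1", 5, ("m1",), kind="feature", feature="site")], "d1")
        linked, frac = dh.link_hotspots([g], tables, "human", feats)
        assert linked == [True]
        # a position-kind group at the same column does NOT link
        g2 = dh.HotspotGroup(("m1",), [_call("d1", 5, ("m1",))], "d1")
        linked2, _ = dh.link_hotspots([g2], tables, "human", feats)
        assert linked2 == [False]

    def test_no_other_species_mutations_links_nothing(self):
        tables = self._tables([3] + [0] * 19, [0] * 20)
        g = dh.HotspotGroup(("m1",), [_call("d1", 1, ("m1",))], "d1")
        linked, frac = dh.link_hotspots([g], tables, "human")
        assert frac == 0.0


class TestEnrichmentTest:
    @pytest.mark.parametrize("cells,expected", [
        ((5, 0, 0, 5), Fraction(1, 252)),
        ((1, 1, 1, 1), Fraction(5, 6)),
        ((0, 5, 5, 0), Fraction(1, 1)),
    ])
    def test_known_tables(self, cells, expected):
        p = dh.enrichment_test(dh.ContingencyTable2x2(*cells))
        assert p == pytest.approx(float(expected), rel=1e-12)

    def test_all_zero_table_gives_one(self):
        assert dh.enrichment_test(dh.ContingencyTable2x2(0, 0, 0, 0)) == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            dh.ContingencyTable2x2(-1, 0, 0, 0)

    def test_agrees_with_enumeration_small_tables(self):
        for a in range(0, 6):
            for b in range(0, 6):
                for c in range(0, 6):
                    for d in range(0, 6):
                        got = dh.enrichment_test(dh.ContingencyTable2x2(a, b, c, d))
                        want = float(exact_right_fisher(a, b, c, d)) \
                            if a + b + c + d else 1.0
                        assert got == pytest.approx(want, abs=1e-12, rel=1e-12)


class TestRelatability:
    def test_four_classes(self):
        hit = dh.DomainHit("p1", "d1", 1e-9,
                           tuple((i + 1, i + 1) for i in range(10)))
        hits_by = {"p1": [hit]}
        m_in = dh.MutationRecord("m1", "yeast", "p1", "g1", 5, "A", "V", "x")
        m_out = dh.MutationRecord("m2", "yeast", "p1", "g1", 50, "A", "V", "x")
        shared = {"d1"}
        assert dh.classify_relatability(m_in, set(), hits_by, shared) == "domain_only"
        assert dh.classify_relatability(m_in, {"g1"}, hits_by, shared) == "both"
        assert dh.classify_relatability(m_out, {"g1"}, hits_by, shared) == "ortholog_only"
        assert dh.classify_relatability(m_out, set(), hits_by, shared) == "neither"
        # mutation inside a non-shared domain is not domain-relatable
        assert dh.classify_relatability(m_in, set(), hits_by, set()) == "neither"

    def test_partition_on_synthetic_data(self, small_dataset):
        dataset, _ = small_dataset
        kept = dh.filter_hits(dataset.hits)
        prot_species = {p.protein_id: p.species for p in dataset.proteins}
        by_sp = {}
        for h in kept:
            by_sp.setdefault(prot_species[h.protein_id], set()).add(h.domain_accession)
        shared = by_sp.get("human", set()) & by_sp.get("yeast", set())
        summary = dh.relatability_summary(dataset.mutations, dataset.orthologs,
                                          kept, shared)
        n_by_species = {}
        for m in dataset.mutations:
            n_by_species[m.species] = n_by_species.get(m.species, 0) + 1
        for s, counts in summary.items():
            assert sum(counts.values()) == n_by_species[s]


class TestCooccurrence:
    def _tables_with_pairs(self, pairs, start_col=1, acc="d1", L=120):
        """pairs: list of (human_label, yeast_label); one column per pair,
        one human + one yeast mutation each."""
        t = dh.DomainMutationTable(domain_accession=acc, length=L)
        t.counts_by_species = {"human": np.zeros(L, int), "yeast": np.zeros(L, int)}
        mutations = []
        for i, (hl, yl) in enumerate(pairs):
            col = start_col + i
            hm = dh.MutationRecord(f"hm{i}", "human", f"hp{i}", f"hg{i}", 1,
                                   "A", "V", hl)
            ym = dh.MutationRecord(f"ym{i}", "yeast", f"yp{i}", f"yg{i}", 1,
                                   "A", "V", yl)
            mutations += [hm, ym]
            t.counts_by_species["human"][col - 1] = 1
            t.counts_by_species["yeast"][col - 1] = 1
            t.mutation_index[("human", col)] = {hm.mutation_id}
            t.mutation_index[("yeast", col)] = {ym.mutation_id}
        return {acc: t}, mutations

    def test_planted_corner_p_value(self):
        """6 planted (H, Y) overlaps among 60 total, margins 6 and 6:
        p = 1 / C(60, 6)."""
        pairs = [("H", "Y")] * 6 + [(f"h{i}", f"y{i}") for i in range(54)]
        tables, muts = self._tables_with_pairs(pairs)
        results = dh.cooccurrence_tests(tables, muts)
        top = results[0]
        assert (top.human_label, top.yeast_label) == ("H", "Y")
        assert (top.a, top.b, top.c, top.d) == (6, 0, 0, 54)
        assert top.p_value == pytest.approx(1 / math.comb(60, 6), rel=1e-9)

    def test_never_cooccurring_pair_has_p_one(self):
        pairs = [("H", "y1"), ("h1", "Y"), ("h2", "y2")]
        tables, muts = self._tables_with_pairs(pairs)
        results = {(r.human_label, r.yeast_label): r
                   for r in dh.cooccurrence_tests(tables, muts)}
        # (H, y1) observed; the a=0 combination (H, Y) is not enumerated,
        # but any observed pair at its margin minimum has the right tail from 0
        r = results[("H", "y1")]
        assert r.a == 1

    def test_redundant_domain_copies_count_once(self):
        pairs = [("H", "Y")]
        tables, muts = self._tables_with_pairs(pairs)
        # clone the table as a redundant copy
        import copy
        t2 = copy.deepcopy(tables["d1"])
        t2.domain_accession = "d2"
        tables["d2"] = t2
        results = dh.cooccurrence_tests(tables, muts)
        (r,) = results
        assert r.a == 1 and r.a + r.b + r.c + r.d == 1

    def test_no_overlaps_gives_empty_result(self):
        t = dh.DomainMutationTable(domain_accession="d1", length=10)
        t.counts_by_species = {"human": np.zeros(10, int),
                               "yeast": np.zeros(10, int)}
        assert dh.cooccurrence_tests({"d1": t}, []) == []


class TestMultispeciesNovelty:
    def test_novel_iff_no_single_species_call_at_same_site(self):
        doms = [_dom("d1"), _dom("d2")]
        multi = dh.deduplicate(
            [_call("d1", 5, ("m1", "m2"), kind="multispecies_position"),
             _call("d2", 9, ("m3",), kind="multispecies_position")], doms)
        single = {"yeast": [_call("d1", 5, ("m1",))], "human": []}
        novel = dh.multispecies_novel_groups(multi, single, threshold=1.6)
        assert [g.mutation_set_key for g in novel] == [("m3",)]
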