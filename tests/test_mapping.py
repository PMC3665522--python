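"""Hit filtering, protein-to-domain coordinate mapping (gap rule), and
count-table construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import domainhotspots as dh


def _hit(column_map, pid="p1", acc="d1", e=1e-6):
    return dh.DomainHit(protein_id=pid, domain_accession=acc, e_value=e,
                        column_map=tuple(column_map))


class TestFilterHits:
    def test_boundary_inclusive(self):
        hits = [_hit([(1, 1)], e=1e-5), _hit([(1, 1)], e=0.001),
                _hit([(1, 1)], e=0.01)]
        kept = dh.filter_hits(hits, 0.001)
        assert kept == hits[:2]

    def test_empty_and_infinite(self):
        assert dh.filter_hits([], 0.001) == []
        hits = [_hit([(1, 1)], e=5.0)]
        assert dh.filter_hits(hits, float("inf")) == hits

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            dh.filter_hits([], 0.0)


class TestMapPosition:
    def test_direct_alignment(self):
        assert dh.map_position(_hit([(10, 1), (11, 2), (12, 3)]), 11) == 2

    def test_insertion_maps_to_last_column_before_gap(self):
        h = _hit([(10, 1), (11, None), (12, None), (13, 2)])
        assert dh.map_position(h, 12) == 1
        assert dh.map_position(h, 11) == 1

    def test_outside_span_is_unmapped(self):
        h = _hit([(10, 1), (11, 2)])
        assert dh.map_position(h, 50) is None
        assert dh.map_position(h, 9) is None

    def test_insertion_before_first_match_column_is_unmapped(self):
        h = _hit([(10, None), (11, 1), (12, 2)])
        assert dh.map_position(h, 10) is None

    @given(st.integers(5, 40), st.data())
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_identity_without_insertions(self, L, data):
        """column(p) <= column(q) for p < q; with no insertions the map is
        the identity on the column map."""
        start = data.draw(st.integers(1, 100))
        ins_after = data.draw(st.sets(st.integers(1, L - 1), max_size=5))
        tokens, p = [], start
        for col in range(1, L + 1):
            tokens.append((p, col))
            p += 1
            if col in ins_after:
                tokens.append((p, None))
                p += 1
        h = _hit(tokens)
        mapped = [(q, dh.map_position(h, q)) for q in range(start, p)]
        cols = [c for _, c in mapped if c is not None]
        assert cols == sorted(cols)
        if not ins_after:
            assert all(c == q - start + 1 for q, c in mapped)


class TestBuildTables:
    def _domains(self, n=2, L=10):
        return [dh.DomainModel(f"d{i}", "synthetic", L, i == 0, "s1")
                for i in range(n)]

    def _mut(self, mid, pos, gene="g1", pid="p1", species="yeast", label="slow_growth"):
        return dh.MutationRecord(mid, species, pid, gene, pos, "A", "V", label)

    def test_redundant_hits_propagate_one_mutation_to_each_domain(self):
        domains = self._domains(2)
        cmap = [(i + 1, i + 1) for i in range(10)]
        hits = [_hit(cmap, acc="d0"), _hit(cmap, acc="d1")]
        reps = {("yeast", "g1"): "p1"}
        tables = dh.build_tables([self._mut("m1", 5)], hits, reps, domains)
        by = {t.domain_accession: t for t in tables}
        assert by["d0"].counts()[4] == 1 and by["d1"].counts()[4] == 1
        assert by["d0"].n_total() == 1

    def test_pooling_across_genes_at_one_column(self):
        domains = self._domains(1)
        cmap = [(i + 1, i + 1) for i in range(10)]
        hits = [_hit(cmap, pid=f"p{i}", acc="d0") for i in range(3)]
        reps = {("yeast", f"g{i}"): f"p{i}" for i in range(3)}
        muts = [self._mut(f"m{i}", 5, gene=f"g{i}", pid=f"p{i}") for i in range(3)]
        (table,) = dh.build_tables(muts, hits, reps, domains)
        assert table.counts()[4] == 3
        assert table.mutation_ids_at(5) == {"m0", "m1", "m2"}

    def test_non_representative_mutations_ignored(self):
        domains = self._domains(1)
        cmap = [(i + 1, i + 1) for i in range(10)]
        hits = [_hit(cmap, pid="p1", acc="d0"), _hit(cmap, pid="p2", acc="d0")]
        reps = {("yeast", "g1"): "p1"}
        muts = [self._mut("m1", 5, pid="p2")]  # p2 is not the representative
        (table,) = dh.build_tables(muts, hits, reps, domains)
        assert table.n_total() == 0

    def test_same_domain_twice_counts_once_per_column(self):
        """Two identical hits of one accession: the mutation occupies that
        column once; two *offset* hits (repeat domain) occupy two columns."""
        domains = self._domains(1)
        cmap = [(i + 1, i + 1) for i in range(10)]
        hits = [_hit(cmap, acc="d0"), _hit(cmap, acc="d0")]
        reps = {("yeast", "g1"): "p1"}
        (table,) = dh.build_tables([self._mut("m1", 5)], hits, reps, domains)
        assert table.counts()[4] == 1 and table.n_total() == 1

        offset = [(i + 11, i + 1) for i in range(10)]  # repeat at 11..20
        hits = [_hit(cmap, acc="d0"), _hit(offset, acc="d0")]
        (table,) = dh.build_tables([self._mut("m1", 15)], hits, reps, domains)
        # position 15 is outside the first hit, column 5 of the repeat
        assert table.counts()[4] == 1

    def test_zero_mutations_gives_zero_tables(self):
        domains = self._domains(2)
        tables = dh.build_tables([], [], {}, domains)
        assert all(t.n_total() == 0 for t in tables)

    def test_position_beyond_protein_length_is_hard_error(self):
        domains = self._domains(1)
        proteins = [dh.ProteinRecord("p1", "g1", "yeast", 20, "sgd")]
        cmap = [(i + 1, i + 1) for i in range(10)]
        hits = [_hit(cmap, acc="d0")]
        reps = {("yeast", "g1"): "p1"}
        with pytest.raises(ValueError, match="exceeds"):
            dh.build_tables([self._mut("m1", 25)], hits, reps, domains,
                            proteins=proteins)

    def test_counts_match_brute_force_recount(self, small_dataset, small_tables):
        """Sum of each species' count vector equals an independent recount of
        (mutation, hit) mappings, and the mutation index is consistent."""
        dataset, _ = small_dataset
        reps = dh.select_representative_proteins(dataset.proteins)
        kept = dh.filter_hits(dataset.hits)
        expected = {}
        for m in dataset.mutations:
            if reps.get((m.species, m.gene_id)) != m.protein_id:
                continue
            seen = set()
            for h in kept:
                if h.protein_id != m.protein_id:
                    continue
                col = dh.map_position(h, m.position)
                if col is not None and (h.domain_accession, col) not in seen:
                    seen.add((h.domain_accession, col))
                    key = (h.domain_accession, m.species)
                    expected[key] = expected.get(key, 0) + 1
        for t in small_tables.values():
            for s, vec in t.counts_by_species.items():
                assert int(vec.sum()) == expected.get((t.domain_accession, s), 0)
                index_total = sum(len(t.mutation_index[(sp, col)])
                                  for (sp, col) in t.mutation_index if sp == s)
                assert index_total == int(vec.sum())


class TestSiteClasses:
    def test_feature_and_conserved_fractions(self):
        domains = [dh.DomainModel("d0", "synthetic", 10, True, "s1")]
        cmap = [(i + 1, i + 1) for i in range(10)]
        hits = [_hit(cmap, acc="d0")]
        reps = {("yeast", "g1"): "p1"}
        muts = [dh.MutationRecord(f"m{i}", "yeast", "p1", "g1", pos, "A", "V", "x")
                for i, pos in enumerate([1, 1, 2, 2, 3, 3, 4, 5, 6, 7])]
        tables = dh.build_tables(muts, hits, reps, domains)
        feats = [dh.FeatureAnnotation("d0", "Active_site", frozenset({1, 2}))]
        tally = dh.tally_site_classes(tables, feats, {"d0": set(range(1, 11))},
                                      muts, hits, reps)["yeast"]
        assert tally.domain_mutations == 10
        assert tally.at_feature_sites == 4 and tally.feature_fraction == 0.4
        assert tally.conserved_fraction == 1.0
        assert tally.in_domain_fraction == 1.0
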