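"""Project protein point mutations into domain-model coordinates.

Each mutation on a representative protein is distributed to *every* domain
alignment (hit) that covers its position and passed the E-value filter —
including redundant copies of the same domain from different sources or
hierarchy levels.  Counts are aggregated per (domain, column, species) into
:class:`DomainMutationTable` objects, the input of the DS-Score stage.

A mutation that falls in an insertion relative to the domain model is assigned
to the last match column before the insertion; an insertion before the first
match column leaves the mutation unmapped (logged).
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .domain_data import (DomainHit, DomainModel, FeatureAnnotation,
                          MutationRecord, write_results)

logger = logging.getLogger("domainhotspots")

DEFAULT_E_VALUE_MAX = 0.001


@dataclass
class DomainMutationTable:
    """Per-domain, per-column, per-species mutation counts.

    ``counts_by_species[s]`` is a length-``L`` integer vector (index 0 is
    domain column 1); ``mutation_index[(s, col)]`` records which mutation ids
    produced each count.
    """

    domain_accession: str
    length: int
    counts_by_species: Dict[str, np.ndarray] = field(default_factory=dict)
    mutation_index: Dict[Tuple[str, int], Set[str]] = field(default_factory=dict)

    def counts(self, species_subset: Optional[Iterable[str]] = None) -> np.ndarray:
        """Counts pooled over a species subset (all species by default)."""
        pooled = np.zeros(self.length, dtype=int)
        keys = self.counts_by_species if species_subset is None else [
            s for s in species_subset if s in self.counts_by_species]
        for s in keys:
            pooled += self.counts_by_species[s]
        return pooled

    def n_total(self, species_subset: Optional[Iterable[str]] = None) -> int:
        return int(self.counts(species_subset).sum())

    def species_present(self) -> frozenset:
        return frozenset(s for s, v in self.counts_by_species.items() if v.sum() > 0)

    def mutation_ids_at(self, column: int,
                        species_subset: Optional[Iterable[str]] = None) -> Set[str]:
        keys = self.counts_by_species if species_subset is None else species_subset
        out: Set[str] = set()
        for s in keys:
            out |= self.mutation_index.get((s, column), set())
        return out


def filter_hits(hits: Sequence[DomainHit], e_max: float = DEFAULT_E_VALUE_MAX) -> list:
    """Keep hits with E-value <= ``e_max`` (boundary inclusive), order preserved."""
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    return [h for h in hits if h.e_value <= e_max]


def map_position(hit: DomainHit, protein_position: int) -> Optional[int]:
    """Map a protein residue to a 1-based domain column through one hit.

    Residues aligned to a match column map directly; residues in an insertion
    map to the last match column before the insertion; residues outside the
    aligned span (or in an insertion preceding any match column) map to None.
    """
    positions = [p for p, _ in hit.column_map]
    i = bisect.bisect_right(positions, protein_position) - 1
    if i < 0 or positions[i] != protein_position:
        # outside the aligned span (the span is contiguous in protein coords)
        if i < 0 or protein_position > positions[-1]:
            return None
        return None
    col = hit.column_map[i][1]
    if col is not None:
        return col
    # insertion: walk back to the last match column
    for j in range(i - 1, -1, -1):
        col = hit.column_map[j][1]
        if col is not None:
            return col
    logger.debug("map_position: insertion before first match column in hit "
                 "%s/%s at %d", hit.protein_id, hit.domain_accession, protein_position)
    return None


def build_tables(mutations: Sequence[MutationRecord],
                 hits: Sequence[DomainHit],
                 representatives: Mapping[tuple, str],
                 domains: Sequence[DomainModel],
                 proteins=None) -> list:
    """Aggregate mutations into per-domain count tables.

    ``representatives`` maps (species, gene_id) -> protein_id; mutations on
    non-representative proteins are ignored.  Every filtered hit overlapping a
    mutation's position receives it — redundant domain copies included by
    design — but a mutation contributes at most once per (domain, column):
    two hits of the same accession can map a mutation to two different columns
    (repeat domains), never twice to the same one.

    Returns one :class:`DomainMutationTable` per domain model (all-zero tables
    for unmutated domains included).
    """
    lengths = {d.accession: d.length for d in domains}
    protein_lengths = {p.protein_id: p.length for p in proteins} \
        if proteins is not None else None
    hits_by_protein: Dict[str, list] = {}
    for h in hits:
        if h.domain_accession not in lengths:
            raise ValueError(f"hit references unknown domain {h.domain_accession}")
        hits_by_protein.setdefault(h.protein_id, []).append(h)

    tables = {acc: DomainMutationTable(domain_accession=acc, length=L,
                                       counts_by_species={})
              for acc, L in lengths.items()}
    rep_ids = set(representatives.values())
    n_skipped = 0
    for m in mutations:
        if representatives.get((m.species, m.gene_id)) != m.protein_id:
            n_skipped += 1
            continue
        if protein_lengths is not None and m.protein_id in protein_lengths \
                and m.position > protein_lengths[m.protein_id]:
            raise ValueError(
                f"mutation {m.mutation_id}: position {m.position} exceeds "
                f"protein {m.protein_id} length {protein_lengths[m.protein_id]}")
        # columns this mutation occupies, per domain accession
        cols_by_domain: Dict[str, Set[int]] = {}
        for h in hits_by_protein.get(m.protein_id, ()):
            col = map_position(h, m.position)
            if col is not None:
                cols_by_domain.setdefault(h.domain_accession, set()).add(col)
        for acc, cols in cols_by_domain.items():
            t = tables[acc]
            if m.species not in t.counts_by_species:
                t.counts_by_species[m.species] = np.zeros(t.length, dtype=int)
            for col in cols:
                t.counts_by_species[m.species][col - 1] += 1
                t.mutation_index.setdefault((m.species, col), set()).add(m.mutation_id)
    if n_skipped:
        logger.info("build_tables: %d mutations on non-representative proteins ignored",
                    n_skipped)
    return list(tables.values())


@dataclass(frozen=True)
class SiteClassTally:
    """Per-species breakdown of domain mutations by site class."""

    species: str
    protein_mutations: int
    protein_mutations_in_domains: int
    domain_mutations: int
    at_feature_sites: int
    at_conserved_sites: int

    @property
    def in_domain_fraction(self) -> float:
        if self.protein_mutations == 0:
            return 0.0
        return self.protein_mutations_in_domains / self.protein_mutations

    @property
    def feature_fraction(self) -> float:
        return self.at_feature_sites / self.domain_mutations if self.domain_mutations else 0.0

    @property
    def conserved_fraction(self) -> float:
        return self.at_conserved_sites / self.domain_mutations if self.domain_mutations else 0.0


def tally_site_classes(tables: Sequence[DomainMutationTable],
                       features: Sequence[FeatureAnnotation],
                       conserved_columns: Mapping[str, Set[int]],
                       mutations: Optional[Sequence[MutationRecord]] = None,
                       hits: Optional[Sequence[DomainHit]] = None,
                       representatives: Optional[Mapping[tuple, str]] = None) -> dict:
    """Count, per species: total domain mutations, domain mutations at
    annotated feature columns, at conserved columns, and (when the mutation
    and hit lists are supplied) the fraction of protein mutations that fall
    inside any domain region.

    ``conserved_columns`` maps domain accession -> set of conserved columns
    (from the entropy stage).  Returns ``{species: SiteClassTally}``.
    """
    feature_cols: Dict[str, Set[int]] = {}
    for f in features:
        feature_cols.setdefault(f.domain_accession, set()).update(f.positions)

    totals: Dict[str, int] = {}
    at_feat: Dict[str, int] = {}
    at_cons: Dict[str, int] = {}
    for t in tables:
        fcols = feature_cols.get(t.domain_accession, set())
        ccols = conserved_columns.get(t.domain_accession, set())
        for s, vec in t.counts_by_species.items():
            totals[s] = totals.get(s, 0) + int(vec.sum())
            for col in np.nonzero(vec)[0] + 1:
                c = int(vec[col - 1])
                if col in fcols:
                    at_feat[s] = at_feat.get(s, 0) + c
                if col in ccols:
                    at_cons[s] = at_cons.get(s, 0) + c

    n_prot: Dict[str, int] = {}
    n_in_dom: Dict[str, int] = {}
    if mutations is not None and hits is not None and representatives is not None:
        hits_by_protein: Dict[str, list] = {}
        for h in hits:
            hits_by_protein.setdefault(h.protein_id, []).append(h)
        for m in mutations:
            if representatives.get((m.species, m.gene_id)) != m.protein_id:
                continue
            n_prot[m.species] = n_prot.get(m.species, 0) + 1
            if any(map_position(h, m.position) is not None
                   for h in hits_by_protein.get(m.protein_id, ())):
                n_in_dom[m.species] = n_in_dom.get(m.species, 0) + 1

    species = set(totals) | set(n_prot)
    return {
        s: SiteClassTally(species=s,
                          protein_mutations=n_prot.get(s, 0),
                          protein_mutations_in_domains=n_in_dom.get(s, 0),
                          domain_mutations=totals.get(s, 0),
                          at_feature_sites=at_feat.get(s, 0),
                          at_conserved_sites=at_cons.get(s, 0))
        for s in sorted(species)
    }


def write_domain_counts(tables: Sequence[DomainMutationTable], path,
                        header_lines=()) -> None:
    rows = []
    for t in sorted(tables, key=lambda t: t.domain_accession):
        for s in sorted(t.counts_by_species):
            vec = t.counts_by_species[s]
            for col in np.nonzero(vec)[0] + 1:
                ids = ";".join(sorted(t.mutation_index.get((s, int(col)), ())))
                rows.append((t.domain_accession, s, int(col), int(vec[col - 1]), ids))
    df = pd.DataFrame(rows, columns=["domain_accession", "species", "position",
                                     "count", "mutation_ids"])
    write_results(df, path, header_lines)
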