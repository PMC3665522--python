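"""Downstream analysis of hotspot calls.

Domain databases are redundant: superfamily hierarchies and duplicate models
from different sources mean one cluster of mutations can surface as a hotspot
on dozens of domain copies.  This module collapses such calls into groups
keyed by their underlying mutation set, picks a representative domain per
group (alphanumeric order with preference for hierarchy roots, then for
annotated domains), links one species' hotspots to the other species'
mutations, classifies how each mutation can be related across species
(shared domain vs. orthologous gene), and runs the right-sided Fisher exact
tests for site-class enrichment and disease-phenotype co-occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .domain_data import (DomainHit, DomainModel, FeatureAnnotation,
                          MutationRecord, OrthologPair, write_results)
from .dsscore import HotspotCall
from .mutation_mapping import DomainMutationTable, map_position


# ---------------------------------------------------------------------------
# de-redundification
# ---------------------------------------------------------------------------

def select_representative_domain(domains: Sequence[DomainModel]) -> str:
    """Representative of a redundant domain group.

    Accessions are ordered alphanumerically (case-insensitive) from lowest to
    highest; the first hierarchy-root domain wins, else the first domain with
    functional feature annotation, else the first overall.
    """
    if not domains:
        raise ValueError("empty domain list")
    ordered = sorted(domains, key=lambda d: (d.accession.lower(), d.accession))
    for d in ordered:
        if d.is_hierarchy_root:
            return d.accession
    for d in ordered:
        if d.has_feature_annotation:
            return d.accession
    return ordered[0].accession


@dataclass
class HotspotGroup:
    """Hotspot calls across redundant domain copies that originate from one
    identical set of mutations."""

    mutation_set_key: tuple
    member_calls: list
    representative_domain: str

    @property
    def member_domains(self) -> frozenset:
        return frozenset(c.domain_accession for c in self.member_calls)


def deduplicate(calls: Sequence[HotspotCall],
                domains: Sequence[DomainModel]) -> list:
    """Collapse calls sharing an identical mutation set into one group each.

    The group count is the non-redundant hotspot count.  Calls must share one
    threshold and kind (groups across kinds would conflate different
    statistics).
    """
    if calls:
        kinds = {(c.kind, c.threshold) for c in calls}
        if len(kinds) > 1:
            raise ValueError(f"calls mix kinds/thresholds: {sorted(kinds)}")
    by_acc = {d.accession: d for d in domains}
    grouped: Dict[tuple, list] = {}
    for c in calls:
        grouped.setdefault(c.mutation_set_key, []).append(c)
    groups = []
    for key in sorted(grouped):
        members = grouped[key]
        member_domains = [by_acc[c.domain_accession] for c in members
                          if c.domain_accession in by_acc]
        if not member_domains:
            raise ValueError("no domain metadata for group members")
        rep = select_representative_domain(member_domains)
        groups.append(HotspotGroup(mutation_set_key=key, member_calls=members,
                                   representative_domain=rep))
    return groups


# ---------------------------------------------------------------------------
# cross-species linking
# ---------------------------------------------------------------------------

def link_hotspots(groups: Sequence[HotspotGroup],
                  tables: Mapping[str, DomainMutationTable],
                  species_b: str,
                  features: Sequence[FeatureAnnotation] = ()) -> Tuple[list, float]:
    """Which species-A hotspot groups hit at least one species-B mutation.

    A position-kind group links iff any member (domain, position) carries a
    species-B count; a feature-kind group links iff any column of the same
    named feature in a member domain does — the feature-based comparison
    tolerates different columns within one functional site.

    Returns (per-group booleans, linked fraction).
    """
    feat_cols: Dict[Tuple[str, str], Set[int]] = {}
    for f in features:
        feat_cols.setdefault((f.domain_accession, f.feature_name), set()) \
            .update(f.positions)
    linked: list = []
    for g in groups:
        hit = False
        for call in g.member_calls:
            t = tables.get(call.domain_accession)
            if t is None or species_b not in t.counts_by_species:
                continue
            vec = t.counts_by_species[species_b]
            if call.feature_name is None:
                cols = {call.position}
            else:
                cols = feat_cols.get((call.domain_accession, call.feature_name),
                                     {call.position})
            if any(1 <= c <= t.length and vec[c - 1] > 0 for c in cols):
                hit = True
                break
        linked.append(hit)
    fraction = float(np.mean(linked)) if linked else 0.0
    return linked, fraction


def link_enrichment(calls: Sequence[HotspotCall],
                    tables: Mapping[str, DomainMutationTable],
                    species_a: str, species_b: str) -> "ContingencyTable2x2":
    """2x2 table for hotspot/species-B-mutation association.

    Rows: species-A mutated (domain, position) sites that are / are not
    hotspot positions; columns: the site carries / lacks >= 1 species-B
    mutation.  Feeds :func:`enrichment_test`.
    """
    hotspot_sites = {(c.domain_accession, c.position) for c in calls}
    a = b = c_ = d = 0
    for acc, t in tables.items():
        vec_a = t.counts_by_species.get(species_a)
        if vec_a is None:
            continue
        vec_b = t.counts_by_species.get(species_b)
        for col in np.nonzero(vec_a)[0] + 1:
            col = int(col)
            has_b = vec_b is not None and vec_b[col - 1] > 0
            is_hot = (acc, col) in hotspot_sites
            if is_hot and has_b:
                a += 1
            elif is_hot:
                b += 1
            elif has_b:
                c_ += 1
            else:
                d += 1
    return ContingencyTable2x2(a, b, c_, d)


# ---------------------------------------------------------------------------
# Fisher exact machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """row1 = in-class (yes, no); row2 = out-of-class (yes, no)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")


def enrichment_test(table: ContingencyTable2x2) -> float:
    """Right-sided Fisher exact p-value: the hypergeometric tail
    P(X >= a) given the table's margins.  An all-zero table gives 1."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n_total = a + b + c + d
    if n_total == 0:
        return 1.0
    return float(hypergeom.sf(a - 1, n_total, a + b, a + c))


# ---------------------------------------------------------------------------
# relatability classes
# ---------------------------------------------------------------------------

RELATABILITY_CLASSES = ("both", "domain_only", "ortholog_only", "neither")


def classify_relatability(mutation: MutationRecord,
                          ortholog_genes: Set[str],
                          hits_by_protein: Mapping[str, Sequence[DomainHit]],
                          shared_domains: Set[str]) -> str:
    """How a mutation can be related to the other species.

    domain-relatable: the mutation maps inside a hit to a domain present in
    both species' proteomes.  ortholog-relatable: its gene has a cross-species
    ortholog.  The four combinations partition all mutations.
    """
    dom = any(h.domain_accession in shared_domains
              and map_position(h, mutation.position) is not None
              for h in hits_by_protein.get(mutation.protein_id, ()))
    orth = mutation.gene_id in ortholog_genes
    if dom and orth:
        return "both"
    if dom:
        return "domain_only"
    if orth:
        return "ortholog_only"
    return "neither"


def relatability_summary(mutations: Sequence[MutationRecord],
                         orthologs: Sequence[OrthologPair],
                         hits: Sequence[DomainHit],
                         shared_domains: Set[str]) -> Dict[str, Dict[str, int]]:
    """Per-species counts over the four relatability classes."""
    hits_by_protein: Dict[str, list] = {}
    for h in hits:
        hits_by_protein.setdefault(h.protein_id, []).append(h)
    genes_with_orth: Dict[str, Set[str]] = {}
    for p in orthologs:
        genes_with_orth.setdefault(p.species_a, set()).add(p.gene_id_a)
        genes_with_orth.setdefault(p.species_b, set()).add(p.gene_id_b)
    out: Dict[str, Dict[str, int]] = {}
    for m in mutations:
        cls = classify_relatability(m, genes_with_orth.get(m.species, set()),
                                    hits_by_protein, shared_domains)
        out.setdefault(m.species, {k: 0 for k in RELATABILITY_CLASSES})[cls] += 1
    return out


# ---------------------------------------------------------------------------
# disease-phenotype co-occurrence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CooccurrenceResult:
    human_label: str
    yeast_label: str
    a: int
    b: int
    c: int
    d: int
    p_value: float


def _overlap_events(tables: Mapping[str, DomainMutationTable],
                    mutations: Sequence[MutationRecord],
                    species_a: str = "human",
                    species_b: str = "yeast") -> list:
    """Deduplicated cross-species overlap events.

    An overlap is a (species-A mutation, species-B mutation) pair localized at
    the same column of an identical domain.  Redundant domain copies would
    replicate each pair, so events are deduplicated such that no protein
    mutation is counted more than once as overlapping a given other-species
    label: an event is kept only if neither (mutation-A, label-B) nor
    (mutation-B, label-A) has already been used.  Candidate pairs are visited
    in sorted order, so the result is deterministic.
    """
    labels = {m.mutation_id: m.label for m in mutations}
    pairs: Set[Tuple[str, str]] = set()
    for acc in sorted(tables):
        t = tables[acc]
        va = t.counts_by_species.get(species_a)
        vb = t.counts_by_species.get(species_b)
        if va is None or vb is None:
            continue
        for col in np.nonzero((va > 0) & (vb > 0))[0] + 1:
            col = int(col)
            for ma in t.mutation_index.get((species_a, col), ()):
                for mb in t.mutation_index.get((species_b, col), ()):
                    pairs.add((ma, mb))
    used_a: Set[Tuple[str, str]] = set()
    used_b: Set[Tuple[str, str]] = set()
    events = []
    for ma, mb in sorted(pairs):
        la, lb = labels[ma], labels[mb]
        if (ma, lb) in used_a or (mb, la) in used_b:
            continue
        used_a.add((ma, lb))
        used_b.add((mb, la))
        events.append((la, lb))
    return events


def cooccurrence_tests(tables: Mapping[str, DomainMutationTable],
                       mutations: Sequence[MutationRecord],
                       species_a: str = "human",
                       species_b: str = "yeast") -> list:
    """Right-sided Fisher test per (species-A label, species-B label) pair.

    For each pair (H, Y): a = overlaps of H with Y, b = overlaps of H with a
    species-B label other than Y, c = overlaps of Y with a species-A label
    other than H, d = all remaining overlaps.  Results are sorted by p-value
    ascending.  No overlaps at all gives an empty result.
    """
    events = _overlap_events(tables, mutations, species_a, species_b)
    if not events:
        return []
    total = len(events)
    count: Dict[Tuple[str, str], int] = {}
    margin_a: Dict[str, int] = {}
    margin_b: Dict[str, int] = {}
    for la, lb in events:
        count[(la, lb)] = count.get((la, lb), 0) + 1
        margin_a[la] = margin_a.get(la, 0) + 1
        margin_b[lb] = margin_b.get(lb, 0) + 1
    results = []
    for (la, lb), a in sorted(count.items()):
        b = margin_a[la] - a
        c = margin_b[lb] - a
        d = total - a - b - c
        p = enrichment_test(ContingencyTable2x2(a, b, c, d))
        results.append(CooccurrenceResult(human_label=la, yeast_label=lb,
                                          a=a, b=b, c=c, d=d, p_value=p))
    results.sort(key=lambda r: (r.p_value, r.human_label, r.yeast_label))
    return results


# ---------------------------------------------------------------------------
# multi-species novelty
# ---------------------------------------------------------------------------

def multispecies_novel_groups(multi_groups: Sequence[HotspotGroup],
                              single_calls_by_species: Mapping[str, Sequence[HotspotCall]],
                              threshold: float) -> list:
    """Multi-species groups not already found in either species alone.

    A group is novel if no member (domain, position) of it was called at the
    same threshold from any single species' mutations by itself.
    """
    single_sites = {
        (c.domain_accession, c.position)
        for calls in single_calls_by_species.values() for c in calls
        if c.threshold == threshold
    }
    return [g for g in multi_groups
            if not any((c.domain_accession, c.position) in single_sites
                       for c in g.member_calls)]


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_hotspot_groups(groups: Sequence[HotspotGroup], path, header_lines=()) -> None:
    rows = [(g.representative_domain,
             ";".join(sorted(g.member_domains)),
             len(g.member_calls),
             g.member_calls[0].kind, g.member_calls[0].threshold,
             ";".join(g.mutation_set_key))
            for g in groups]
    df = pd.DataFrame(rows, columns=["representative_domain", "member_domains",
                                     "n_member_calls", "kind", "threshold",
                                     "mutation_set_key"])
    write_results(df, path, header_lines)


def write_links(groups: Sequence[HotspotGroup], linked: Sequence[bool], path,
                header_lines=()) -> None:
    rows = [(g.representative_domain, g.member_calls[0].kind,
             g.member_calls[0].threshold, int(flag),
             ";".join(g.mutation_set_key))
            for g, flag in zip(groups, linked)]
    df = pd.DataFrame(rows, columns=["representative_domain", "kind", "threshold",
                                     "linked", "mutation_set_key"])
    write_results(df, path, header_lines)


def write_relatability(summary: Mapping[str, Mapping[str, int]], path,
                       header_lines=()) -> None:
    rows = [(s, cls, summary[s][cls]) for s in sorted(summary)
            for cls in RELATABILITY_CLASSES]
    df = pd.DataFrame(rows, columns=["species", "class", "count"])
    write_results(df, path, header_lines)


def write_cooccurrence(results: Sequence[CooccurrenceResult], path,
                       header_lines=()) -> None:
    rows = [(r.human_label, r.yeast_label, r.a, r.b, r.c, r.d, r.p_value)
            for r in results]
    df = pd.DataFrame(rows, columns=["H_label", "Y_label", "a", "b", "c", "d",
                                     "p_value"])
    write_results(df, path, header_lines)
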