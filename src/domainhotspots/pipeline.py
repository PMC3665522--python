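"""End-to-end orchestration: map -> entropy -> score -> hotspots -> dedup ->
link -> relatability -> co-occurrence.

Reads the TSV tables of one dataset directory, runs every stage in memory and
writes the result tables (each with a metadata comment header) to an output
directory.  All stage functions live in their own modules; this module only
wires them together.
"""

from __future__ import annotations

import datetime
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from . import __version__
from .domain_data import (read_domain_hits, read_domain_table,
                          read_feature_annotations, read_mutation_table,
                          read_ortholog_pairs, read_protein_table,
                          select_representative_proteins)
from .mutation_mapping import (build_tables, filter_hits, tally_site_classes,
                               write_domain_counts, DEFAULT_E_VALUE_MAX)
from .conservation import (conservation_threshold, conserved_columns,
                           read_frequency_table, write_entropy_table)
from .dsscore import (DEFAULT_THRESHOLDS, call_hotspots, feature_scores,
                      position_scores, write_hotspots, write_scores)
from .hotspot_analysis import (cooccurrence_tests, deduplicate, enrichment_test,
                               link_enrichment, link_hotspots,
                               relatability_summary, write_cooccurrence,
                               write_hotspot_groups, write_links,
                               write_relatability)

logger = logging.getLogger("domainhotspots")

ALL_STAGES = ("map", "entropy", "score", "hotspots", "link", "relate", "cooccur")


@dataclass
class RunConfig:
    input_dir: str
    out_dir: str
    thresholds: Tuple[float, ...] = DEFAULT_THRESHOLDS
    e_value_max: float = DEFAULT_E_VALUE_MAX
    species_pair: Tuple[str, str] = ("yeast", "human")  # link A's hotspots to B
    seed: int = 0
    log_level: str = "INFO"
    no_timestamp: bool = False

    def validate(self) -> None:
        if any(t <= 0 for t in self.thresholds):
            raise ValueError("thresholds must be positive")
        if not os.path.isdir(self.input_dir):
            raise FileNotFoundError(f"input directory {self.input_dir} not found")
        for name in ("mutations", "domains", "proteins", "hits", "features",
                     "orthologs", "freqs"):
            p = os.path.join(self.input_dir, f"{name}.tsv")
            if not os.path.exists(p):
                raise FileNotFoundError(f"missing input table {p}")


def _header(config: RunConfig) -> list:
    lines = [
        f"domainhotspots version={__version__}",
        f"seed={config.seed} thresholds={','.join(str(t) for t in config.thresholds)} "
        f"e_value_max={config.e_value_max}",
        "decisions: e_value boundary inclusive; natural-log entropy; "
        "population SD threshold; tie-break lexicographic",
    ]
    if not config.no_timestamp:
        lines.append(f"generated={datetime.datetime.now().isoformat()}")
    return lines


def run_pipeline(config: RunConfig,
                 stages: Optional[Sequence[str]] = None) -> int:
    """Run the pipeline; write the outputs of the requested ``stages``
    (default: all).  Returns 0 on success; raises on invalid input."""
    config.validate()
    stages = tuple(stages) if stages is not None else ALL_STAGES
    os.makedirs(config.out_dir, exist_ok=True)
    hdr = _header(config)
    ind = lambda n: os.path.join(config.input_dir, f"{n}.tsv")
    out = lambda n: os.path.join(config.out_dir, n)

    domains = read_domain_table(ind("domains"))
    proteins = read_protein_table(ind("proteins"))
    mutations = read_mutation_table(ind("mutations"))
    hits = read_domain_hits(ind("hits"), domains)
    features = read_feature_annotations(ind("features"), domains)
    orthologs = read_ortholog_pairs(ind("orthologs"))

    # --- map ---------------------------------------------------------------
    kept_hits = filter_hits(hits, config.e_value_max)
    representatives = select_representative_proteins(proteins)
    tables = build_tables(mutations, kept_hits, representatives, domains,
                          proteins=proteins)
    tables_by_acc = {t.domain_accession: t for t in tables}
    if "map" in stages:
        write_domain_counts(tables, out("domain_counts.tsv"), hdr)

    # --- entropy -----------------------------------------------------------
    profiles = read_frequency_table(ind("freqs"))
    threshold = conservation_threshold(profiles)
    cons_cols = conserved_columns(profiles, threshold)
    if "entropy" in stages:
        write_entropy_table(profiles, threshold, out("entropy.tsv"), hdr)

    species_a, species_b = config.species_pair

    # accessions present in both species' proteomes (multi-species scope)
    prot_species = {p.protein_id: p.species for p in proteins}
    accs_by_species: Dict[str, set] = {}
    for h in kept_hits:
        accs_by_species.setdefault(prot_species[h.protein_id], set()) \
            .add(h.domain_accession)
    shared_accs = accs_by_species.get(species_a, set()) \
        & accs_by_species.get(species_b, set())

    # --- score -------------------------------------------------------------
    feats_by_acc: Dict[str, list] = {}
    for f in features:
        feats_by_acc.setdefault(f.domain_accession, []).append(f)
    vectors = []
    calls: Dict[tuple, list] = {}  # (scope, kind, threshold) -> [HotspotCall]
    scopes = [(species_a, (species_a,)), (species_b, (species_b,)),
              ("multi", (species_a, species_b))]
    for scope, subset in scopes:
        for t in tables:
            if t.n_total(subset) == 0:
                continue
            if scope == "multi" and t.domain_accession not in shared_accs:
                continue
            pos_kind = "multispecies_position" if scope == "multi" else "position"
            pv = position_scores(t, subset, kind=pos_kind)
            fv = feature_scores(pv, feats_by_acc.get(t.domain_accession, []))
            vectors.extend([pv, fv])
            for thr in config.thresholds:
                for v in (pv, fv):
                    calls.setdefault((scope, v.kind, thr), []) \
                        .extend(call_hotspots(v, thr, t))
    if "score" in stages:
        write_scores(vectors, tables_by_acc, out("scores.tsv"), hdr)

    # --- hotspots + dedup --------------------------------------------------
    groups: Dict[tuple, list] = {}
    for key, call_list in sorted(calls.items()):
        groups[key] = deduplicate(call_list, domains)
    if "hotspots" in stages:
        write_hotspots([c for cl in calls.values() for c in cl],
                       out("hotspots.tsv"), hdr)
        write_hotspot_groups([g for gl in groups.values() for g in gl],
                             out("hotspot_groups.tsv"), hdr)

    # --- link: species-A hotspots vs species-B mutations --------------------
    link_rows = []
    link_summary = {}
    for (scope, kind, thr), grp in sorted(groups.items()):
        if scope != species_a:
            continue
        linked, fraction = link_hotspots(grp, tables_by_acc, species_b, features)
        link_rows.append(((scope, kind, thr), grp, linked))
        table2 = link_enrichment(calls[(scope, kind, thr)], tables_by_acc,
                                 species_a, species_b)
        link_summary[f"{kind}@{thr}"] = {
            "n_groups": len(grp), "n_linked": int(sum(linked)),
            "linked_fraction": fraction,
            "enrichment": [table2.a, table2.b, table2.c, table2.d],
            "enrichment_p": enrichment_test(table2),
        }
    if "link" in stages:
        all_groups = [g for _, grp, linked in link_rows for g in grp]
        all_linked = [l for _, grp, linked in link_rows for l in linked]
        write_links(all_groups, all_linked, out("links.tsv"), hdr)

    # --- relatability ------------------------------------------------------
    shared_for_relate = shared_accs
    relat = relatability_summary(mutations, orthologs, kept_hits, shared_for_relate)
    if "relate" in stages:
        write_relatability(relat, out("relatability.tsv"), hdr)

    # --- co-occurrence -----------------------------------------------------
    cooc = cooccurrence_tests(tables_by_acc, mutations,
                              species_a="human", species_b="yeast")
    if "cooccur" in stages:
        write_cooccurrence(cooc, out("cooccurrence.tsv"), hdr)

    # --- summary -----------------------------------------------------------
    site_tally = tally_site_classes(tables, features, cons_cols, mutations,
                                    kept_hits, representatives)
    summary = {
        "version": __version__,
        "seed": config.seed,
        "conservation_threshold": threshold.value,
        "n_mutations": len(mutations),
        "hotspot_counts": {
            f"{scope}:{kind}@{thr}": {"calls": len(calls[(scope, kind, thr)]),
                                      "groups": len(grp)}
            for (scope, kind, thr), grp in sorted(groups.items())},
        "link_summary": link_summary,
        "relatability": relat,
        "site_classes": {
            s: {"protein_mutations": t.protein_mutations,
                "in_domain_fraction": t.in_domain_fraction,
                "domain_mutations": t.domain_mutations,
                "feature_fraction": t.feature_fraction,
                "conserved_fraction": t.conserved_fraction}
            for s, t in site_tally.items()},
        "top_cooccurrence": [
            {"H": r.human_label, "Y": r.yeast_label, "a": r.a, "p": r.p_value}
            for r in cooc[:5]],
    }
    with open(out("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    logger.info("pipeline finished: %d mutations, %d domains",
                len(mutations), len(domains))
    return 0
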