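"""Seeded synthetic two-species datasets with known ground truth.

The generator emulates the joint structure of the real inputs to a
domain-centric mutation analysis: a redundant domain database (superfamilies
of near-identical copies with exactly one hierarchy root each), two proteomes
(multi-domain human-like proteins, mostly single-domain yeast-like proteins,
plus redundant isoforms per gene), global profile-style alignments with
random insertions, functional feature annotations covering a configurable
fraction of columns, per-column amino-acid frequencies with a planted
low-entropy (conserved) subset, ortholog pairs for a fraction of genes, and
point mutations that are uniform background plus planted positional clusters
and planted disease-phenotype co-occurrences.

Every generated record is recorded in a :class:`GroundTruthLedger` so that
pipeline outputs can be checked against what was planted.  Generation is
deterministic given the seed; independent substreams per stage keep earlier
draws stable when later stages change.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .domain_data import (AMINO_ACIDS, DomainHit, DomainModel,
                          FeatureAnnotation, MutationRecord, OrthologPair,
                          ProteinRecord, write_domain_hits, write_domain_table,
                          write_feature_annotations, write_mutation_table,
                          write_ortholog_pairs, write_protein_table)
from .dsscore import ds_score

HUMAN_LABELS = ("cardiomyopathy", "deafness", "anemia", "neuropathy",
                "retinopathy", "immunodeficiency", "myopathy", "ciliopathy")
YEAST_LABELS = ("slow_growth", "heat_sensitivity", "respiratory_deficiency",
                "mating_defect", "cell_cycle_arrest", "osmotic_sensitivity",
                "sporulation_defect", "drug_resistance")
FEATURE_VOCAB = ("Active_site", "Substrate_binding", "GTP/Mg2+_binding",
                 "DNA_binding", "Dimer_interface", "Metal_binding",
                 "Phosphorylation_site", "Hinge_region")


@dataclass(frozen=True)
class PlantedHotspot:
    """One planted positional cluster: ``fraction`` of a species' mutations
    placed at one column of one superfamily ("both" pools the two species)."""

    superfamily: int
    species: str  # "human", "yeast" or "both"
    fraction: float
    column: Optional[int] = None  # drawn at random when None


@dataclass(frozen=True)
class PlantedCooccurrence:
    human_label: str
    yeast_label: str
    count: int


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Defaults describe a desk-scale two-species dataset: a few dozen
    superfamilies with three redundant copies each, ~80% of domains shared
    between species, a quarter of genes with orthologs, a quarter of
    mutations falling outside any domain, features covering a quarter of
    columns, and a few planted clusters and one planted co-occurring
    disease-phenotype pair.
    """

    seed: int = 0
    n_domains: int = 30
    domain_length_range: Tuple[int, int] = (60, 150)
    redundancy_factor: int = 3
    n_proteins_per_species: int = 60
    n_mutations_per_species: int = 400
    hotspot_plan: Tuple[PlantedHotspot, ...] = (
        PlantedHotspot(superfamily=0, species="yeast", fraction=0.05),
        PlantedHotspot(superfamily=1, species="human", fraction=0.05),
        PlantedHotspot(superfamily=2, species="both", fraction=0.03),
    )
    feature_coverage: float = 0.25
    feature_size_range: Tuple[int, int] = (3, 12)
    ortholog_fraction: float = 0.25
    shared_domain_fraction: float = 0.8
    cooccurrence_plan: Tuple[PlantedCooccurrence, ...] = (
        PlantedCooccurrence("cardiomyopathy", "slow_growth", 6),
    )
    background_placement: str = "uniform"
    outside_domain_fraction: float = 0.25
    low_entropy_fraction: float = 0.3
    extra_isoform_fraction: float = 0.15
    insertion_probability: float = 0.08
    decoy_hit_probability: float = 0.05

    def validate(self) -> None:
        for f in (self.feature_coverage, self.ortholog_fraction,
                  self.shared_domain_fraction, self.outside_domain_fraction,
                  self.low_entropy_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {f} outside [0, 1]")
        per_species = {"human": 0.0, "yeast": 0.0}
        for p in self.hotspot_plan:
            if p.species == "both":
                per_species["human"] += p.fraction
                per_species["yeast"] += p.fraction
            else:
                per_species[p.species] += p.fraction
        for s, tot in per_species.items():
            planted_cooc = sum(c.count for c in self.cooccurrence_plan)
            if tot * self.n_mutations_per_species + planted_cooc \
                    > self.n_mutations_per_species:
                raise ValueError(f"infeasible plan: planted {s} mutations exceed total")
        if self.background_placement != "uniform":
            raise ValueError("only uniform background placement is supported")


@dataclass
class SyntheticDataset:
    domains: list
    proteins: list
    mutations: list
    hits: list
    features: list
    orthologs: list
    frequencies: Dict[str, np.ndarray]  # accession -> (L, 20) frequency matrix


@dataclass
class GroundTruthLedger:
    """Exact record of everything the generator planted."""

    seed: int
    redundancy_map: Dict[str, list] = field(default_factory=dict)
    root_map: Dict[str, str] = field(default_factory=dict)
    species_domains: Dict[str, list] = field(default_factory=dict)
    planted_hotspots: list = field(default_factory=list)
    planted_cooccurrence: list = field(default_factory=list)
    placements: Dict[str, dict] = field(default_factory=dict)
    low_entropy_columns: Dict[str, list] = field(default_factory=dict)
    representative_proteins: Dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_COPY_SOURCES = (("cd", "CDD"), ("pfam", "Pfam"), ("smart", "SMART"),
                 ("COG", "COG"))


def _make_domains(cfg: ScenarioConfig, rng: np.random.Generator,
                  ledger: GroundTruthLedger):
    domains: List[DomainModel] = []
    lengths: Dict[str, int] = {}
    lo, hi = cfg.domain_length_range
    for i in range(cfg.n_domains):
        sfam = f"sf{i:03d}"
        L = int(rng.integers(lo, hi + 1))
        root_idx = int(rng.integers(cfg.redundancy_factor))
        accs = []
        for j in range(cfg.redundancy_factor):
            prefix, source = _COPY_SOURCES[j % len(_COPY_SOURCES)]
            acc = f"{prefix}{10000 + i * 100 + j:05d}"
            domains.append(DomainModel(
                accession=acc, source=source, length=L,
                is_hierarchy_root=(j == root_idx), superfamily_key=sfam))
            accs.append(acc)
            lengths[acc] = L
            if j == root_idx:
                ledger.root_map[sfam] = acc
        ledger.redundancy_map[sfam] = accs
    # species presence at superfamily granularity; the first n_shared
    # superfamilies are shared so plan entries can target them by index
    n_shared = int(round(cfg.shared_domain_fraction * cfg.n_domains))
    shared = set(range(n_shared))
    human_only, yeast_only = set(), set()
    for k, i in enumerate(range(n_shared, cfg.n_domains)):
        (human_only if k % 2 == 0 else yeast_only).add(int(i))
    species_sfams = {"human": shared | human_only, "yeast": shared | yeast_only}
    ledger.species_domains = {
        s: sorted(f"sf{i:03d}" for i in v) for s, v in species_sfams.items()}
    return domains, lengths, species_sfams, shared


def _make_features(cfg: ScenarioConfig, rng: np.random.Generator,
                   sfam_lengths: Dict[int, int],
                   redundancy_map: Dict[str, list]):
    features: List[FeatureAnnotation] = []
    annotated_accs: Set[str] = set()
    lo, hi = cfg.feature_size_range
    feature_layout: Dict[str, list] = {}
    for i, L in sfam_lengths.items():
        sfam = f"sf{i:03d}"
        target = cfg.feature_coverage * L
        covered: Set[int] = set()
        layout = []
        k = 0
        while len(covered) < target and k < 20:
            size = int(rng.integers(lo, min(hi, L) + 1))
            start = int(rng.integers(1, L - size + 2))
            positions = set(range(start, start + size))
            # a couple of scattered residues, mimicking discontiguous sites
            for _ in range(int(rng.integers(0, 3))):
                positions.add(int(rng.integers(1, L + 1)))
            name = FEATURE_VOCAB[k % len(FEATURE_VOCAB)]
            if k >= len(FEATURE_VOCAB):
                name = f"{name}_{k}"
            layout.append((name, frozenset(positions)))
            covered |= positions
            k += 1
        feature_layout[sfam] = layout
        accs = redundancy_map[sfam]
        annotate = [acc for acc in accs if rng.random() < 0.7]
        if not annotate and layout:
            annotate = [accs[0]]
        for acc in annotate:
            annotated_accs.add(acc)
            for name, positions in layout:
                features.append(FeatureAnnotation(
                    domain_accession=acc, feature_name=name, positions=positions))
    return features, annotated_accs, feature_layout


@dataclass
class _Instance:
    superfamily: int
    column_map: tuple              # ((protein_pos, col-or-None), ...)
    match_pos: Dict[int, int]      # domain column -> protein position
    span: Tuple[int, int]


def _make_column_map(L: int, start: int, rng: np.random.Generator,
                     p_ins: float) -> Tuple[tuple, Dict[int, int], int]:
    tokens = []
    match_pos: Dict[int, int] = {}
    p = start
    if rng.random() < 0.05:  # insertion before the first match column
        for _ in range(int(rng.integers(1, 3))):
            tokens.append((p, None))
            p += 1
    for col in range(1, L + 1):
        tokens.append((p, col))
        match_pos[col] = p
        p += 1
        if rng.random() < p_ins:
            for _ in range(int(rng.integers(1, 4))):
                tokens.append((p, None))
                p += 1
    return tuple(tokens), match_pos, p - 1  # last protein position used


def _make_proteins_and_hits(cfg: ScenarioConfig, rng: np.random.Generator,
                            sfam_lengths: Dict[int, int],
                            species_sfams: Dict[str, Set[int]],
                            redundancy_map: Dict[str, list],
                            forced_sfams: Dict[str, list]):
    proteins: List[ProteinRecord] = []
    hits: List[DomainHit] = []
    instances: Dict[str, List[_Instance]] = {}
    arch_choices = {
        "human": ([1, 2, 3], [0.5, 0.35, 0.15]),
        "yeast": ([0, 1, 2], [0.15, 0.7, 0.15]),
    }
    for species in ("human", "yeast"):
        tag = "H" if species == "human" else "Y"
        avail = sorted(species_sfams[species])
        forced = forced_sfams.get(species, [])
        for i in range(cfg.n_proteins_per_species):
            gene = f"{tag}G{i:04d}"
            pid = f"{tag}P{i:04d}"
            ks, ps = arch_choices[species]
            n_inst = int(rng.choice(ks, p=ps))
            sfams = [int(rng.choice(avail)) for _ in range(n_inst)] if avail else []
            # guarantee carriers for planted superfamilies: two per plan entry
            for j, sf in enumerate(forced):
                if i in (2 * j, 2 * j + 1):
                    sfams = [sf] + sfams[:2]
            inst_list = []
            pos = int(rng.integers(10, 41))
            for sf in sfams:
                L = sfam_lengths[sf]
                cmap, match_pos, last = _make_column_map(
                    L, pos, rng, cfg.insertion_probability)
                inst_list.append(_Instance(superfamily=sf, column_map=cmap,
                                           match_pos=match_pos,
                                           span=(cmap[0][0], last)))
                pos = last + int(rng.integers(10, 41))
            length = pos + int(rng.integers(10, 61))
            source = ("swissprot" if rng.random() < 0.8 else "refseq") \
                if species == "human" else "sgd"
            proteins.append(ProteinRecord(protein_id=pid, gene_id=gene,
                                          species=species, length=length,
                                          source=source))
            instances[pid] = inst_list
            for inst in inst_list:
                sfam_key = f"sf{inst.superfamily:03d}"
                for acc in redundancy_map[sfam_key]:
                    e = float(10.0 ** rng.uniform(-30, -4))
                    hits.append(DomainHit(protein_id=pid, domain_accession=acc,
                                          e_value=e, column_map=inst.column_map))
            # occasional decoy hit above the E-value cutoff
            if avail and rng.random() < cfg.decoy_hit_probability:
                sf = int(rng.choice(avail))
                L = sfam_lengths[sf]
                if length >= L + 2:
                    start = int(rng.integers(1, length - L + 1))
                    cmap = tuple((start + k, k + 1) for k in range(L))
                    acc = redundancy_map[f"sf{sf:03d}"][0]
                    hits.append(DomainHit(
                        protein_id=pid, domain_accession=acc,
                        e_value=float(10.0 ** rng.uniform(-2.5, 0.0)),
                        column_map=cmap))
            # redundant isoform (never the representative: shorter, or
            # RefSeq where a Swiss-Prot entry exists)
            if rng.random() < cfg.extra_isoform_fraction:
                if species == "human" and source == "swissprot" and rng.random() < 0.5:
                    iso_len = int(length * rng.uniform(1.05, 1.3))
                    iso_source = "refseq"
                else:
                    iso_len = max(30, int(length * rng.uniform(0.5, 0.9)))
                    iso_source = source
                proteins.append(ProteinRecord(protein_id=pid + "b", gene_id=gene,
                                              species=species, length=iso_len,
                                              source=iso_source))
                instances[pid + "b"] = []
    return proteins, hits, instances


def _mutation_sites(instances: Dict[str, List[_Instance]],
                    proteins: Sequence[ProteinRecord],
                    representatives: Dict[tuple, str], species: str):
    """All (protein_id, position) pairs inside domain spans, and the
    per-protein outside-domain candidate counts, for one species."""
    in_domain: List[Tuple[str, int]] = []
    outside: List[Tuple[str, int]] = []
    rep_ids = set(representatives.values())
    for p in proteins:
        if p.species != species or p.protein_id not in rep_ids:
            continue
        spans = [inst.span for inst in instances[p.protein_id]]
        covered = set()
        for a, b in spans:
            covered.update(range(a, b + 1))
        for pos in sorted(covered):
            in_domain.append((p.protein_id, pos))
        for pos in range(1, p.length + 1):
            if pos not in covered:
                outside.append((p.protein_id, pos))
    return in_domain, outside


def generate(config: ScenarioConfig):
    """Generate a full dataset plus its ground-truth ledger.

    Deterministic given ``config.seed``; substreams are spawned per stage in
    a fixed order (domains, features, frequencies, proteins, mutations,
    labels, orthologs).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (ss_dom, ss_feat, ss_freq, ss_prot, ss_mut, ss_lab, ss_orth) = ss.spawn(7)
    ledger = GroundTruthLedger(seed=config.seed)

    rng = np.random.default_rng(ss_dom)
    domains, acc_lengths, species_sfams, shared = _make_domains(config, rng, ledger)
    sfam_lengths = {i: acc_lengths[ledger.redundancy_map[f"sf{i:03d}"][0]]
                    for i in range(config.n_domains)}

    rng = np.random.default_rng(ss_feat)
    features, annotated_accs, feature_layout = _make_features(
        config, rng, sfam_lengths, ledger.redundancy_map)
    domains = [dataclasses.replace(d, has_feature_annotation=(d.accession in annotated_accs))
               for d in domains]

    # per-column amino-acid frequencies, shared by all copies of a superfamily
    rng = np.random.default_rng(ss_freq)
    frequencies: Dict[str, np.ndarray] = {}
    for i in range(config.n_domains):
        L = sfam_lengths[i]
        low = rng.random(L) < config.low_entropy_fraction
        mat = np.empty((L, 20))
        for j in range(L):
            # conserved columns are near-single-residue; variable columns get
            # a broad concentration spread so the global entropy distribution
            # has a real right tail beyond mean + 1 SD
            alpha = 0.02 if low[j] else float(10.0 ** rng.uniform(-1.0, 0.7))
            mat[j] = rng.dirichlet(np.full(20, alpha))
        sfam = f"sf{i:03d}"
        ledger.low_entropy_columns[sfam] = [int(j + 1) for j in np.nonzero(low)[0]]
        for acc in ledger.redundancy_map[sfam]:
            frequencies[acc] = mat

    # resolve plan targets and force carriers for them
    plan_entries = []
    for p in config.hotspot_plan:
        if p.superfamily >= config.n_domains:
            raise ValueError(f"plan references superfamily {p.superfamily} "
                             f"but only {config.n_domains} exist")
        if p.species == "both" and p.superfamily not in shared:
            raise ValueError(f"plan plants a multi-species cluster on sf{p.superfamily:03d} "
                             "which is not shared between species")
        if p.species in ("human", "yeast") \
                and p.superfamily not in species_sfams[p.species]:
            raise ValueError(f"plan plants on sf{p.superfamily:03d} absent from {p.species}")
        plan_entries.append(p)
    cooc_sfams = sorted(shared)[:len(config.cooccurrence_plan)]
    if len(cooc_sfams) < len(config.cooccurrence_plan):
        raise ValueError("not enough shared superfamilies for the co-occurrence plan")
    forced: Dict[str, list] = {"human": [], "yeast": []}
    for p in plan_entries:
        targets = ("human", "yeast") if p.species == "both" else (p.species,)
        for s in targets:
            forced[s].append(p.superfamily)
    for sf in cooc_sfams:
        forced["human"].append(sf)
        forced["yeast"].append(sf)

    rng = np.random.default_rng(ss_prot)
    proteins, hits, instances = _make_proteins_and_hits(
        config, rng, sfam_lengths, species_sfams, ledger.redundancy_map, forced)
    from .domain_data import select_representative_proteins
    representatives = select_representative_proteins(proteins)
    ledger.representative_proteins = {
        f"{s}:{g}": pid for (s, g), pid in sorted(representatives.items())}

    # mutations
    rng = np.random.default_rng(ss_mut)
    lab_rng = np.random.default_rng(ss_lab)
    mutations: List[MutationRecord] = []
    used_keys: Set[tuple] = set()
    serial = {"human": 0, "yeast": 0}
    vocab = {"human": HUMAN_LABELS, "yeast": YEAST_LABELS}

    def _carriers(species: str, sfam: int) -> list:
        tag = "H" if species == "human" else "Y"
        out = []
        for pid, insts in instances.items():
            if pid.startswith(tag) and not pid.endswith("b"):
                for inst in insts:
                    if inst.superfamily == sfam:
                        out.append((pid, inst))
        return out

    def _emit(species: str, pid: str, pos: int, label: str, kind: str) -> MutationRecord:
        for _ in range(50):
            ref, alt = lab_rng.choice(list(AMINO_ACIDS), size=2, replace=False)
            key = (species, pid, pos, str(ref), str(alt), label)
            if key not in used_keys:
                break
        used_keys.add(key)
        serial[species] += 1
        mid = f"{'H' if species == 'human' else 'Y'}M{serial[species]:05d}"
        m = MutationRecord(mutation_id=mid, species=species, protein_id=pid,
                           gene_id=pid[:2].replace("P", "G") + pid[2:6], position=pos,
                           ref_aa=str(ref), alt_aa=str(alt), label=label)
        ledger.placements[mid] = {"protein_id": pid, "position": pos, "kind": kind}
        mutations.append(m)
        return m

    n_per = config.n_mutations_per_species
    budget = {"human": n_per, "yeast": n_per}

    for p in plan_entries:
        sfam = p.superfamily
        L = sfam_lengths[sfam]
        column = p.column if p.column is not None else int(rng.integers(1, L + 1))
        targets = ("human", "yeast") if p.species == "both" else (p.species,)
        entry = {"superfamily": f"sf{sfam:03d}", "column": column,
                 "species": p.species, "mutation_ids": [],
                 "accessions": ledger.redundancy_map[f"sf{sfam:03d}"]}
        for s in targets:
            k = int(round(p.fraction * n_per))
            carriers = _carriers(s, sfam)
            if not carriers:
                raise ValueError(f"no {s} carrier protein for sf{sfam:03d}")
            for _ in range(k):
                pid, inst = carriers[int(rng.integers(len(carriers)))]
                pos = inst.match_pos[column]
                label = str(lab_rng.choice(vocab[s]))
                m = _emit(s, pid, pos, label, "planted_hotspot")
                entry["mutation_ids"].append(m.mutation_id)
                budget[s] -= 1
        ledger.planted_hotspots.append(entry)

    for plan, sfam in zip(config.cooccurrence_plan, cooc_sfams):
        L = sfam_lengths[sfam]
        column = int(rng.integers(1, L + 1))
        entry = {"superfamily": f"sf{sfam:03d}", "column": column,
                 "human_label": plan.human_label, "yeast_label": plan.yeast_label,
                 "count": plan.count, "human_ids": [], "yeast_ids": []}
        for s, label, key in (("human", plan.human_label, "human_ids"),
                              ("yeast", plan.yeast_label, "yeast_ids")):
            carriers = _carriers(s, sfam)
            if not carriers:
                raise ValueError(f"no {s} carrier protein for sf{sfam:03d}")
            for _ in range(plan.count):
                pid, inst = carriers[int(rng.integers(len(carriers)))]
                m = _emit(s, pid, inst.match_pos[column], label, "planted_cooccurrence")
                entry[key].append(m.mutation_id)
                budget[s] -= 1
        ledger.planted_cooccurrence.append(entry)

    for s in ("human", "yeast"):
        in_dom, outside = _mutation_sites(instances, proteins, representatives, s)
        for _ in range(budget[s]):
            label = str(lab_rng.choice(vocab[s]))
            if outside and rng.random() < config.outside_domain_fraction:
                pid, pos = outside[int(rng.integers(len(outside)))]
                _emit(s, pid, pos, label, "background_outside")
            elif in_dom:
                pid, pos = in_dom[int(rng.integers(len(in_dom)))]
                _emit(s, pid, pos, label, "background")

    # orthologs: pair a fraction of yeast genes with human genes one-to-one
    rng_o = np.random.default_rng(ss_orth)
    n_pairs = int(round(config.ortholog_fraction * config.n_proteins_per_species))
    ygenes = rng_o.permutation(config.n_proteins_per_species)[:n_pairs]
    hgenes = rng_o.permutation(config.n_proteins_per_species)[:n_pairs]
    orthologs = [OrthologPair(gene_id_a=f"YG{y:04d}", species_a="yeast",
                              gene_id_b=f"HG{h:04d}", species_b="human")
                 for y, h in zip(ygenes, hgenes)]

    dataset = SyntheticDataset(domains=domains, proteins=proteins,
                               mutations=mutations, hits=hits, features=features,
                               orthologs=orthologs, frequencies=frequencies)
    return dataset, ledger


def generate_null(config: ScenarioConfig):
    """As :func:`generate` but with nothing planted: purely uniform placement."""
    cfg = dataclasses.replace(config, hotspot_plan=(), cooccurrence_plan=())
    return generate(cfg)


# ---------------------------------------------------------------------------
# fast null-model simulation (calibration harness)
# ---------------------------------------------------------------------------

def simulate_null_count_matrix(n_domains: int, L: int, n_mutations: int,
                               seed) -> np.ndarray:
    """Counts of ``n_mutations`` dropped uniformly on ``L`` columns, for
    ``n_domains`` independent domains (rows)."""
    rng = np.random.default_rng(seed)
    return rng.multinomial(n_mutations, np.full(L, 1.0 / L), size=n_domains)


def null_hotspot_rate(n_domains: int, L: int, n_mutations: int,
                      threshold: float, seed) -> float:
    """Fraction of simulated null domains whose maximum position-based
    DS-Score reaches ``threshold``."""
    counts = simulate_null_count_matrix(n_domains, L, n_mutations, seed)
    cmax = counts.max(axis=1)
    score_of = {int(c): ds_score(int(c), n_mutations, L) for c in np.unique(cmax)}
    return float(np.mean([score_of[int(c)] >= threshold for c in cmax]))


# ---------------------------------------------------------------------------
# writing a dataset to a directory of TSVs
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, out_dir,
                  ledger: Optional[GroundTruthLedger] = None) -> dict:
    """Write all tables (and the ledger as JSON) under ``out_dir``; returns
    the path map."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {name: os.path.join(out_dir, f"{name}.tsv")
             for name in ("mutations", "domains", "proteins", "hits",
                          "features", "orthologs", "freqs")}
    write_mutation_table(dataset.mutations, paths["mutations"])
    write_domain_table(dataset.domains, paths["domains"])
    write_protein_table(dataset.proteins, paths["proteins"])
    write_domain_hits(dataset.hits, paths["hits"])
    write_feature_annotations(dataset.features, paths["features"])
    write_ortholog_pairs(dataset.orthologs, paths["orthologs"])
    with open(paths["freqs"], "w") as fh:
        fh.write("domain_accession\tposition\t" + "\t".join(AMINO_ACIDS) + "\n")
        for acc in sorted(dataset.frequencies):
            mat = dataset.frequencies[acc]
            for j in range(mat.shape[0]):
                # full precision so frequencies still sum to 1 on re-read
                row = "\t".join(f"{x:.17g}" for x in mat[j])
                fh.write(f"{acc}\t{j + 1}\t{row}\n")
    if ledger is not None:
        lpath = os.path.join(out_dir, "ledger.json")
        with open(lpath, "w") as fh:
            fh.write(ledger.to_json())
        paths["ledger"] = lpath
    return paths
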