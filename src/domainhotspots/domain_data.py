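"""Core data model and tab-separated I/O for domain-centric mutation analysis.

The analysis operates on five record types: protein domain models (profile
models with a fixed number of match columns), proteins, point mutations with a
phenotype/disease label, domain-to-protein alignment hits (profile-HMM style,
global over the domain model), and functional feature annotations on domain
columns.  Everything downstream works in 1-based domain-column and
protein-residue coordinates.

All tables are plain TSV with a header row; lines starting with ``#`` are
metadata comments and are skipped on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger("domainhotspots")

SPECIES = ("human", "yeast", "other")
DOMAIN_SOURCES = ("CDD", "Pfam", "SMART", "COG", "synthetic")
PROTEIN_SOURCES = ("swissprot", "refseq", "sgd", "synthetic")

#: single-letter amino acids in fixed alphabetical order (frequency-table columns)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainModel:
    """A protein domain model: ``length`` match columns, grouped into
    (possibly redundant) superfamilies by ``superfamily_key``."""

    accession: str
    source: str
    length: int
    is_hierarchy_root: bool
    superfamily_key: str
    has_feature_annotation: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"domain {self.accession}: length must be >= 1")
        if self.source not in DOMAIN_SOURCES:
            raise ValueError(f"domain {self.accession}: unknown source {self.source!r}")


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    gene_id: str
    species: str
    length: int
    source: str

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"protein {self.protein_id}: length must be >= 1")
        if self.species not in SPECIES:
            raise ValueError(f"protein {self.protein_id}: unknown species {self.species!r}")
        if self.source not in PROTEIN_SOURCES:
            raise ValueError(f"protein {self.protein_id}: unknown source {self.source!r}")


@dataclass(frozen=True)
class MutationRecord:
    """One species-tagged point mutation with a disease/phenotype label."""

    mutation_id: str
    species: str
    protein_id: str
    gene_id: str
    position: int
    ref_aa: str
    alt_aa: str
    label: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"mutation {self.mutation_id}: position must be >= 1")
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"mutation {self.mutation_id}: ref and alt residues equal")
        if self.species not in SPECIES:
            raise ValueError(f"mutation {self.mutation_id}: unknown species {self.species!r}")

    @property
    def dedup_key(self) -> tuple:
        """Uniqueness key used to collapse duplicate rows."""
        return (self.species, self.protein_id, self.position,
                self.ref_aa, self.alt_aa, self.label)


@dataclass(frozen=True)
class DomainHit:
    """A global profile-model alignment of a domain to a protein span.

    ``column_map`` is an ordered tuple of ``(protein_position, domain_column)``
    pairs; ``domain_column`` is ``None`` for protein residues that fall in an
    insertion relative to the domain model.
    """

    protein_id: str
    domain_accession: str
    e_value: float
    column_map: tuple

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"hit {self.protein_id}/{self.domain_accession}: "
                             "negative E-value")
        prev_p = 0
        prev_c = 0
        for p, c in self.column_map:
            if p <= prev_p:
                raise ValueError(
                    f"hit {self.protein_id}/{self.domain_accession}: protein "
                    "positions not strictly increasing")
            prev_p = p
            if c is not None:
                if c < prev_c:
                    raise ValueError(
                        f"hit {self.protein_id}/{self.domain_accession}: domain "
                        "columns decrease")
                prev_c = c

    def validate_against(self, length: int) -> None:
        """Check global-alignment semantics against a domain model length."""
        cols = sorted(c for _, c in self.column_map if c is not None)
        if not cols or cols[0] < 1 or cols[-1] > length:
            raise ValueError(
                f"hit {self.protein_id}/{self.domain_accession}: columns outside "
                f"[1, {length}]")
        if set(cols) != set(range(1, length + 1)):
            raise ValueError(
                f"hit {self.protein_id}/{self.domain_accession}: alignment does "
                f"not cover all {length} match columns (global semantics)")


@dataclass(frozen=True)
class FeatureAnnotation:
    """A named functional feature (e.g. an active site) on domain columns."""

    domain_accession: str
    feature_name: str
    positions: frozenset

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError(
                f"feature {self.domain_accession}/{self.feature_name}: empty positions")
        if min(self.positions) < 1:
            raise ValueError(
                f"feature {self.domain_accession}/{self.feature_name}: positions "
                "must be 1-based")


@dataclass(frozen=True)
class OrthologPair:
    gene_id_a: str
    species_a: str
    gene_id_b: str
    species_b: str

    def __post_init__(self) -> None:
        if self.species_a == self.species_b:
            raise ValueError("ortholog pair must span two species")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                           keep_default_na=False, na_values=[])
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def read_mutation_table(path) -> list:
    """Read mutations.tsv into validated :class:`MutationRecord` rows.

    Filtering mirrors the curation applied to phenotype databases upstream:
    rows whose label is "normal" (case-insensitive) describe no phenotypic
    change and are dropped; rows without allelic information (missing or
    malformed position / ref / alt) are dropped with a logged count; duplicate
    rows under the mutation uniqueness key collapse to one record.
    """
    df = _read_tsv(path)
    if df.empty:
        return []
    records: list = []
    n_dropped = 0
    n_normal = 0
    seen: dict = {}
    n_dup = 0
    for row in df.itertuples(index=False):
        label = str(row.label).strip()
        if label.lower() == "normal":
            n_normal += 1
            continue
        ref = str(row.ref_aa).strip()
        alt = str(row.alt_aa).strip()
        pos_raw = str(row.position).strip()
        if (not pos_raw.isdigit() or len(ref) != 1 or len(alt) != 1
                or ref not in AMINO_ACIDS or alt not in AMINO_ACIDS or ref == alt):
            n_dropped += 1
            continue
        rec = MutationRecord(
            mutation_id=str(row.mutation_id), species=str(row.species),
            protein_id=str(row.protein_id), gene_id=str(row.gene_id),
            position=int(pos_raw), ref_aa=ref, alt_aa=alt, label=label)
        if rec.dedup_key in seen:
            n_dup += 1
            continue
        seen[rec.dedup_key] = rec
        records.append(rec)
    if n_dropped:
        logger.info("read_mutation_table: dropped %d rows lacking allelic information",
                    n_dropped)
    if n_normal:
        logger.info("read_mutation_table: dropped %d 'normal'-label rows", n_normal)
    if n_dup:
        logger.info("read_mutation_table: collapsed %d duplicate rows", n_dup)
    return records


def read_domain_table(path) -> list:
    df = _read_tsv(path)
    return [
        DomainModel(accession=r.accession, source=r.source, length=int(r.length),
                    is_hierarchy_root=bool(int(r.is_root)),
                    superfamily_key=r.superfamily_key,
                    has_feature_annotation=bool(int(r.has_features)))
        for r in df.itertuples(index=False)
    ]


def read_protein_table(path) -> list:
    df = _read_tsv(path)
    return [
        ProteinRecord(protein_id=r.protein_id, gene_id=r.gene_id, species=r.species,
                      length=int(r.length), source=r.source)
        for r in df.itertuples(index=False)
    ]


def _parse_map(token_str: str) -> tuple:
    pairs = []
    for tok in token_str.split(","):
        p, d = tok.split(":")
        pairs.append((int(p), None if d == "-" else int(d)))
    return tuple(pairs)


def _format_map(column_map) -> str:
    return ",".join(f"{p}:{'-' if c is None else c}" for p, c in column_map)


def read_domain_hits(path, domains: Optional[Sequence[DomainModel]] = None) -> list:
    """Read hits.tsv.  If ``domains`` is given, each hit is validated against
    its domain model's length (hard error naming the offending row)."""
    df = _read_tsv(path)
    lengths = {d.accession: d.length for d in domains} if domains is not None else None
    hits = []
    for i, r in enumerate(df.itertuples(index=False)):
        hit = DomainHit(protein_id=r.protein_id, domain_accession=r.domain_accession,
                        e_value=float(r.e_value), column_map=_parse_map(r.map))
        if lengths is not None:
            if hit.domain_accession not in lengths:
                raise ValueError(f"hits row {i}: unknown domain {hit.domain_accession}")
            try:
                hit.validate_against(lengths[hit.domain_accession])
            except ValueError as exc:
                raise ValueError(f"hits row {i}: {exc}") from exc
        hits.append(hit)
    return hits


def read_feature_annotations(path, domains: Optional[Sequence[DomainModel]] = None) -> list:
    df = _read_tsv(path)
    lengths = {d.accession: d.length for d in domains} if domains is not None else None
    feats = []
    for i, r in enumerate(df.itertuples(index=False)):
        positions = frozenset(int(tok) for tok in str(r.positions).split(","))
        feat = FeatureAnnotation(domain_accession=r.domain_accession,
                                 feature_name=r.feature_name, positions=positions)
        if lengths is not None:
            length = lengths.get(feat.domain_accession)
            if length is None:
                raise ValueError(f"features row {i}: unknown domain {feat.domain_accession}")
            if max(positions) > length:
                raise ValueError(
                    f"features row {i}: position {max(positions)} outside domain "
                    f"{feat.domain_accession} length {length}")
        feats.append(feat)
    return feats


def read_ortholog_pairs(path) -> list:
    df = _read_tsv(path)
    return [
        OrthologPair(gene_id_a=r.gene_id_a, species_a=r.species_a,
                     gene_id_b=r.gene_id_b, species_b=r.species_b)
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers above)
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_mutation_table(records, path, header_lines=()) -> None:
    df = pd.DataFrame(
        [(m.mutation_id, m.species, m.protein_id, m.gene_id, m.position,
          m.ref_aa, m.alt_aa, m.label) for m in records],
        columns=["mutation_id", "species", "protein_id", "gene_id", "position",
                 "ref_aa", "alt_aa", "label"])
    _write_tsv(df, path, header_lines)


def write_domain_table(domains, path, header_lines=()) -> None:
    df = pd.DataFrame(
        [(d.accession, d.source, d.length, int(d.is_hierarchy_root),
          d.superfamily_key, int(d.has_feature_annotation)) for d in domains],
        columns=["accession", "source", "length", "is_root", "superfamily_key",
                 "has_features"])
    _write_tsv(df, path, header_lines)


def write_protein_table(proteins, path, header_lines=()) -> None:
    df = pd.DataFrame(
        [(p.protein_id, p.gene_id, p.species, p.length, p.source) for p in proteins],
        columns=["protein_id", "gene_id", "species", "length", "source"])
    _write_tsv(df, path, header_lines)


def write_domain_hits(hits, path, header_lines=()) -> None:
    df = pd.DataFrame(
        [(h.protein_id, h.domain_accession, h.e_value, _format_map(h.column_map))
         for h in hits],
        columns=["protein_id", "domain_accession", "e_value", "map"])
    _write_tsv(df, path, header_lines)


def write_feature_annotations(features, path, header_lines=()) -> None:
    df = pd.DataFrame(
        [(f.domain_accession, f.feature_name,
          ",".join(str(p) for p in sorted(f.positions))) for f in features],
        columns=["domain_accession", "feature_name", "positions"])
    _write_tsv(df, path, header_lines)


def write_ortholog_pairs(pairs, path, header_lines=()) -> None:
    df = pd.DataFrame(
        [(p.gene_id_a, p.species_a, p.gene_id_b, p.species_b) for p in pairs],
        columns=["gene_id_a", "species_a", "gene_id_b", "species_b"])
    _write_tsv(df, path, header_lines)


def write_results(df: pd.DataFrame, path, header_lines=()) -> None:
    """Generic TSV writer for derived result tables (metadata header + body)."""
    _write_tsv(df, path, header_lines)


# ---------------------------------------------------------------------------
# representative-protein selection
# ---------------------------------------------------------------------------

_SOURCE_RANK = {"swissprot": 0, "refseq": 1, "sgd": 2, "synthetic": 2}


def select_representative_proteins(proteins: Sequence[ProteinRecord]) -> dict:
    """Pick one representative protein per (species, gene).

    Databases carry many redundant protein entries per gene; the mapping stage
    only counts mutations on one representative.  Among Swiss-Prot entries the
    longest wins; genes with no Swiss-Prot entry fall back to the longest
    RefSeq entry.  Sources without that distinction (SGD, synthetic) simply
    take the longest protein.  Equal-length ties break to the
    lexicographically smallest protein id so the choice is deterministic.

    Returns a map ``(species, gene_id) -> protein_id``.
    """
    if not proteins:
        raise ValueError("no proteins supplied")
    by_gene: dict = {}
    for p in proteins:
        by_gene.setdefault((p.species, p.gene_id), []).append(p)
    out = {}
    for key, group in by_gene.items():
        best_rank = min(_SOURCE_RANK[p.source] for p in group)
        pool = [p for p in group if _SOURCE_RANK[p.source] == best_rank]
        out[key] = min(pool, key=lambda p: (-p.length, p.protein_id)).protein_id
    return out
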