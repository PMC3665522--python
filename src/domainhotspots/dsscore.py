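"""The binomial order-statistic domain significance score (DS-Score).

Given n mutations aggregated onto the L match columns of one domain model,
the position-based DS-Score at a column carrying c mutations is

    DS(c) = -log10( 1 - F(c - 1; n, 1/L)^L )

where F is the CDF of Binomial(n, 1/L): the score is -log10 of the
probability that the maximum of L i.i.d. Binomial(n, 1/L) counts reaches c.
Columns with equal counts automatically share the same score.  Scores of
1.6, 1.3 and 1.0 correspond to tail probabilities of 0.025, 0.05 and 0.10
on the Fisher scale of evidence.

The feature-based variant distributes, within each functionally annotated
feature, the largest position-based score to every column of that feature —
rewarding mutations that hit *some* column of the same functional site.

Multi-species scores use counts pooled over the species present; the pooling
is additive, so two species' counts at a column simply sum before scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binom

from .domain_data import FeatureAnnotation, write_results
from .mutation_mapping import DomainMutationTable

#: Fisher-scale score thresholds and the tail probabilities they encode
DEFAULT_THRESHOLDS = (1.6, 1.3, 1.0)

#: cap so scores stay finite when 1 - F^L underflows (p floor ~1e-300)
SCORE_CAP = 300.0

SCORE_KINDS = ("position", "feature", "multispecies_position", "multispecies_feature")


def ds_score(c: int, n: int, L: int) -> float:
    """Position-based DS-Score for a column with ``c`` of ``n`` domain
    mutations over ``L`` columns.

    Evaluated in log space: with SF = P(X >= c) for X ~ Binomial(n, 1/L),
    1 - F(c-1)^L = -expm1(L * log1p(-SF)), which is stable when F is near 1.
    Returns 0 when c or n is 0 (no mutations carry no clustering evidence),
    and is capped at :data:`SCORE_CAP`.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if c > n:
        raise ValueError(f"position count c={c} exceeds total n={n}")
    if c <= 0 or n <= 0:
        return 0.0
    sf = float(binom.sf(c - 1, n, 1.0 / L))  # P(X >= c)
    if sf >= 1.0:
        return 0.0  # the maximum reaches c with certainty (e.g. L = 1, c <= n)
    p_max = -math.expm1(L * math.log1p(-sf))
    if p_max <= 0.0:
        return SCORE_CAP
    return min(-math.log10(p_max), SCORE_CAP)


@dataclass
class ScoreVector:
    """Per-column DS-Scores of one kind for one domain.

    ``scores[j-1]`` is the score of column j; zero-mutation columns score 0.
    For feature kinds, ``feature_source[col]`` records (feature_name,
    arg-max column) — the annotated position whose position-based score was
    distributed to ``col``.
    """

    domain_accession: str
    kind: str
    species_set: frozenset
    scores: np.ndarray
    n_total: int
    feature_source: Dict[int, Tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in SCORE_KINDS:
            raise ValueError(f"unknown score kind {self.kind!r}")


def position_scores(table: DomainMutationTable,
                    species_subset: Optional[Iterable[str]] = None,
                    kind: Optional[str] = None) -> ScoreVector:
    """Position-based scores from counts pooled over ``species_subset``
    (default: all species in the table)."""
    if species_subset is None:
        species_set = table.species_present()
    else:
        # species absent from the table simply contribute zero counts
        species_set = frozenset(species_subset)
    counts = table.counts(species_set)
    n = int(counts.sum())
    L = table.length
    scores = np.zeros(L, dtype=float)
    # equal counts share a score: evaluate once per distinct positive count
    for c in np.unique(counts[counts > 0]):
        scores[counts == c] = ds_score(int(c), n, L)
    if kind is None:
        kind = "multispecies_position" if len(species_set) > 1 else "position"
    return ScoreVector(domain_accession=table.domain_accession, kind=kind,
                       species_set=species_set, scores=scores, n_total=n)


def feature_scores(position_vector: ScoreVector,
                   features: Sequence[FeatureAnnotation]) -> ScoreVector:
    """Distribute, per feature, the maximum position-based score to every
    column of that feature.

    Unannotated columns keep their position-based score; a column in several
    features takes the maximum across them.  The arg-max column (smallest on
    ties) is recorded per annotated column so hotspot calls can recover the
    underlying mutation set.
    """
    scores = position_vector.scores.copy()
    source: Dict[int, Tuple[str, int]] = {}
    L = scores.size
    for f in sorted(features, key=lambda f: f.feature_name):
        if f.domain_accession != position_vector.domain_accession:
            raise ValueError(
                f"feature {f.feature_name} belongs to {f.domain_accession}, "
                f"not {position_vector.domain_accession}")
        cols = sorted(p for p in f.positions if p <= L)
        if not cols:
            continue
        base = position_vector.scores[[c - 1 for c in cols]]
        best = float(base.max())
        argmax_col = cols[int(np.argmax(base))]  # smallest column on ties
        for c in cols:
            # best >= the column's own position score by construction, so an
            # annotated column always carries feature provenance; a later
            # feature overrides only with a strictly larger score
            if c not in source or best > scores[c - 1]:
                scores[c - 1] = best
                source[c] = (f.feature_name, argmax_col)
    kind = ("multispecies_feature"
            if position_vector.kind == "multispecies_position" else "feature")
    return ScoreVector(domain_accession=position_vector.domain_accession,
                       kind=kind, species_set=position_vector.species_set,
                       scores=scores, n_total=position_vector.n_total,
                       feature_source=source)


@dataclass(frozen=True)
class HotspotCall:
    """One (domain, column) crossing a DS-Score threshold.

    ``mutation_set_key`` is the canonical sorted tuple of contributing
    mutation ids — for feature-kind calls, the mutations at the feature's
    arg-max column.  It keys de-redundification across domain copies.
    """

    domain_accession: str
    position: int
    score: float
    kind: str
    threshold: float
    mutation_set_key: tuple
    species_set: frozenset
    feature_name: Optional[str] = None


def call_hotspots(vector: ScoreVector, threshold: float,
                  table: DomainMutationTable) -> list:
    """One call per column whose score >= ``threshold`` (inclusive)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    calls = []
    for col in np.nonzero(vector.scores >= threshold)[0] + 1:
        col = int(col)
        if col in vector.feature_source:
            feature_name, key_col = vector.feature_source[col]
        else:
            feature_name, key_col = None, col
        ids = table.mutation_ids_at(key_col, vector.species_set)
        if not ids:
            continue  # score leaked from an unmutated column; cannot happen for position kind
        calls.append(HotspotCall(
            domain_accession=vector.domain_accession, position=col,
            score=float(vector.scores[col - 1]), kind=vector.kind,
            threshold=threshold, mutation_set_key=tuple(sorted(ids)),
            species_set=vector.species_set, feature_name=feature_name))
    return calls


def write_scores(vectors: Sequence[ScoreVector],
                 tables: Dict[str, DomainMutationTable], path,
                 header_lines=()) -> None:
    rows = []
    for v in sorted(vectors, key=lambda v: (v.domain_accession, v.kind)):
        counts = tables[v.domain_accession].counts(v.species_set)
        sp = "+".join(sorted(v.species_set))
        for col in np.nonzero((v.scores > 0) | (counts > 0))[0] + 1:
            rows.append((v.domain_accession, v.kind, sp, int(col),
                         int(counts[col - 1]), float(v.scores[col - 1])))
    df = pd.DataFrame(rows, columns=["domain_accession", "kind", "species_set",
                                     "position", "count", "score"])
    write_results(df, path, header_lines)


def write_hotspots(calls: Sequence[HotspotCall], path, header_lines=()) -> None:
    rows = [(c.domain_accession, int(c.position), c.kind, c.threshold,
             float(c.score), "+".join(sorted(c.species_set)),
             c.feature_name or "", ";".join(c.mutation_set_key))
            for c in sorted(calls, key=lambda c: (c.kind, c.threshold,
                                                  c.domain_accession, c.position))]
    df = pd.DataFrame(rows, columns=["domain_accession", "position", "kind",
                                     "threshold", "score", "species_set",
                                     "feature_name", "mutation_set_key"])
    write_results(df, path, header_lines)
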