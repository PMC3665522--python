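"""Alignment-column entropy and the global conservation threshold.

Conservation of a domain column is measured by the Shannon entropy of its
amino-acid frequency distribution, H_j = -sum_i p(a_i,j) ln p(a_i,j), in nats
(the AL2CO unweighted convention).  A column is called conserved when its
entropy is at or below a global threshold equal to the mean plus one
(population) standard deviation of the entropies of all columns of all
supplied domain profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .domain_data import AMINO_ACIDS, write_results

MAX_ENTROPY = math.log(20.0)


def column_entropy(frequencies) -> float:
    """Entropy (nats) of one alignment column's 20 amino-acid frequencies.

    Zero-frequency residues contribute 0.  Frequencies must be non-negative
    and sum to 1 within 1e-9.
    """
    p = np.asarray(frequencies, dtype=float)
    if p.ndim != 1 or p.size != 20:
        raise ValueError("expected a vector of 20 amino-acid frequencies")
    if (p < 0).any():
        raise ValueError("negative frequency")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


@dataclass(frozen=True)
class EntropyProfile:
    """Per-column entropies (nats) of one domain model."""

    domain_accession: str
    entropies: tuple

    def __post_init__(self) -> None:
        for h in self.entropies:
            if not (-1e-12 <= h <= MAX_ENTROPY + 1e-9):
                raise ValueError(
                    f"{self.domain_accession}: entropy {h} outside [0, ln 20]")

    @property
    def mean_entropy(self) -> float:
        return float(np.mean(self.entropies))


@dataclass(frozen=True)
class ConservationThreshold:
    """mean + 1 population SD over all columns of all profiles."""

    value: float
    mean_all: float
    sd_all: float


def conservation_threshold(profiles: Sequence[EntropyProfile]) -> ConservationThreshold:
    """Global conservation cutoff: mean plus one population standard deviation
    of the entropies of every column of every supplied profile."""
    all_h = np.concatenate([np.asarray(p.entropies, dtype=float) for p in profiles]) \
        if profiles else np.array([])
    if all_h.size < 2:
        raise ValueError("need at least 2 columns to estimate a threshold")
    mean = float(all_h.mean())
    sd = float(all_h.std(ddof=0))
    return ConservationThreshold(value=mean + sd, mean_all=mean, sd_all=sd)


def is_conserved(entropy: float, threshold: ConservationThreshold) -> bool:
    """A column is conserved iff its entropy <= the threshold (inclusive)."""
    if entropy < 0:
        raise ValueError("entropy must be non-negative")
    return entropy <= threshold.value


def conserved_columns(profiles: Sequence[EntropyProfile],
                      threshold: ConservationThreshold) -> Dict[str, Set[int]]:
    """Map domain accession -> set of conserved 1-based columns."""
    return {
        p.domain_accession: {j + 1 for j, h in enumerate(p.entropies)
                             if is_conserved(h, threshold)}
        for p in profiles
    }


def read_frequency_table(path) -> list:
    """Read freqs.tsv (domain_accession, position, then 20 columns A..Y in
    alphabetical amino-acid order) into per-domain entropy profiles."""
    df = pd.read_csv(path, sep="\t", comment="#")
    aa_cols = list(AMINO_ACIDS)
    profiles = []
    for acc, grp in df.groupby("domain_accession", sort=True):
        grp = grp.sort_values("position")
        expected = list(range(1, len(grp) + 1))
        if list(grp["position"]) != expected:
            raise ValueError(f"{acc}: positions not contiguous from 1")
        ent = tuple(column_entropy(row) for row in grp[aa_cols].to_numpy())
        profiles.append(EntropyProfile(domain_accession=acc, entropies=ent))
    return profiles


def write_entropy_table(profiles: Sequence[EntropyProfile],
                        threshold: ConservationThreshold, path,
                        header_lines=()) -> None:
    rows = []
    for p in sorted(profiles, key=lambda p: p.domain_accession):
        for j, h in enumerate(p.entropies, start=1):
            rows.append((p.domain_accession, j, h, int(is_conserved(h, threshold))))
    df = pd.DataFrame(rows, columns=["domain_accession", "position", "entropy",
                                     "conserved"])
    meta = [
        f"conservation_threshold={threshold.value:.6f} "
        f"mean={threshold.mean_all:.6f} sd={threshold.sd_all:.6f} "
        "sd_kind=population comparison=le",
        *header_lines,
    ]
    write_results(df, path, meta)
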