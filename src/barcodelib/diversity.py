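"""Haplotype diversity: collapsing, rarefaction/extrapolation, completeness.

Within each species, specimens are collapsed to haplotypes (distinct sequence
variants). The resulting abundance vector feeds three classical estimators
from sampling theory:

* rarefied richness — the hypergeometric expectation of the number of
  haplotypes seen in a subsample of m specimens,
* the bias-corrected Chao1 asymptote — a lower-bound estimate of the total
  (sampled + unsampled) haplotype richness based on singleton/doubleton
  counts,
* rarefaction–extrapolation — the expected richness when sampling is
  continued beyond the observed n, which approaches the Chao1 asymptote.

Sampling completeness is the observed/asymptotic richness ratio; species
with fewer than six specimens are conventionally excluded from cohort
summaries. Octave profiles bin haplotype abundances into the eight log2
classes 1, 2–3, 4–7, …, 128–255.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from math import comb, lgamma

import numpy as np
import pandas as pd

from .io import SpecimenRecord

logger = logging.getLogger(__name__)

OCTAVE_LABELS = ["1", "2-3", "4-7", "8-15", "16-31", "32-63", "64-127", "128-255"]

#: Cohort inclusion rule for completeness summaries.
MIN_N_COMPLETENESS = 6

_ACGT = frozenset("ACGT")


@dataclass
class HaplotypeTable:
    """Per-species collapsed haplotypes with abundances (sorted descending)."""

    species: str
    n: int
    abundances: tuple[int, ...]

    def __post_init__(self) -> None:
        self.abundances = tuple(sorted((int(a) for a in self.abundances), reverse=True))
        if any(a < 1 for a in self.abundances):
            raise ValueError("abundances must be >= 1")
        if sum(self.abundances) != self.n:
            raise ValueError("abundances must sum to n")

    @property
    def s_obs(self) -> int:
        return len(self.abundances)

    @property
    def f1(self) -> int:
        return sum(1 for a in self.abundances if a == 1)

    @property
    def f2(self) -> int:
        return sum(1 for a in self.abundances if a == 2)


@dataclass
class DiversityEstimate:
    species: str
    n: int
    s_obs: int
    s_hat: float
    completeness: float


def _compatible(a: str, b: str) -> bool:
    # Identical wherever both positions are unambiguous (A/C/G/T).
    return not any(
        x != y and x in _ACGT and y in _ACGT for x, y in zip(a, b)
    )


def collapse_haplotypes(
    records, species: str | None = None, strict: bool = False
) -> HaplotypeTable:
    """Collapse one species' sequences into a haplotype abundance table.

    Two sequences share a haplotype iff they are identical at every position
    where both are unambiguous; grouping is the transitive closure of that
    relation, so an N-rich sequence can bridge otherwise distinct haplotypes.
    ``strict=True`` switches to exact full-frame string equality.
    """
    seqs = [r.sequence if isinstance(r, SpecimenRecord) else str(r) for r in records]
    if not seqs:
        raise ValueError("collapse_haplotypes requires at least one record")
    if species is None:
        first = records[0]
        species = first.species if isinstance(first, SpecimenRecord) else ""

    if strict:
        counts: dict[str, int] = {}
        for s in seqs:
            counts[s] = counts.get(s, 0) + 1
        return HaplotypeTable(species, len(seqs), tuple(counts.values()))

    # Union-find transitive closure over the match-on-overlap relation.
    parent = list(range(len(seqs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    uniq: dict[str, int] = {}
    for i, s in enumerate(seqs):
        if s in uniq:  # exact duplicates need no pairwise scan
            ri, rj = find(i), find(uniq[s])
            parent[ri] = rj
        else:
            uniq[s] = i
    keys = list(uniq)
    for ii in range(len(keys)):
        for jj in range(ii + 1, len(keys)):
            if _compatible(keys[ii], keys[jj]):
                ri, rj = find(uniq[keys[ii]]), find(uniq[keys[jj]])
                if ri != rj:
                    parent[ri] = rj

    groups: dict[int, int] = {}
    for i in range(len(seqs)):
        r = find(i)
        groups[r] = groups.get(r, 0) + 1
    return HaplotypeTable(species, len(seqs), tuple(groups.values()))


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def rarefied_richness(table: HaplotypeTable, m: int) -> float:
    """Expected richness in a random subsample of m of the n specimens.

    S(m) = sum_i [1 - C(n - x_i, m) / C(n, m)].
    """
    n = table.n
    if not (1 <= m <= n):
        raise ValueError(f"m must be in [1, {n}], got {m}")
    total = 0.0
    for x in table.abundances:
        if n - x < m:
            total += 1.0
        elif n <= 1000:
            total += 1.0 - comb(n - x, m) / comb(n, m)
        else:
            total += 1.0 - math.exp(_log_comb(n - x, m) - _log_comb(n, m))
    return total


def chao1_asymptote(table: HaplotypeTable) -> float:
    """Bias-corrected Chao1 estimate of asymptotic haplotype richness."""
    n, f1, f2 = table.n, table.f1, table.f2
    if f1 == 0:
        return float(table.s_obs)
    return table.s_obs + (n - 1) / n * f1 * (f1 - 1) / (2 * (f2 + 1))


def extrapolated_richness(table: HaplotypeTable, m_star: int) -> float:
    """Expected richness after sampling m_star additional specimens.

    S(n + m*) = S_obs + f0_hat * [1 - (1 - f1 / (n f0_hat + f1))**m*] with
    f0_hat = S_hat - S_obs. Flat (S_obs) when there are no singletons.
    """
    if m_star < 0:
        raise ValueError("m_star must be >= 0")
    if m_star == 0:
        return float(table.s_obs)
    f1 = table.f1
    if f1 == 0:
        return float(table.s_obs)
    f0 = chao1_asymptote(table) - table.s_obs
    if f0 <= 0:
        return float(table.s_obs)
    ratio = f1 / (table.n * f0 + f1)
    return table.s_obs + f0 * (1.0 - (1.0 - ratio) ** m_star)


def richness_at(table: HaplotypeTable, m: int) -> float:
    """Rarefaction–extrapolation curve evaluated at any sample size m >= 1."""
    if m <= table.n:
        return rarefied_richness(table, m)
    return extrapolated_richness(table, m - table.n)


def completeness(table: HaplotypeTable) -> DiversityEstimate:
    """Observed/asymptotic richness ratio for one species."""
    s_hat = chao1_asymptote(table)
    return DiversityEstimate(
        species=table.species,
        n=table.n,
        s_obs=table.s_obs,
        s_hat=s_hat,
        completeness=table.s_obs / s_hat,
    )


def cohort_completeness(
    tables, min_n: int = MIN_N_COMPLETENESS
) -> pd.DataFrame:
    """Per-species completeness table, excluding species with n < min_n."""
    rows = []
    for t in tables:
        if t.n < min_n:
            continue
        e = completeness(t)
        rows.append(
            {
                "species": e.species,
                "n": e.n,
                "s_obs": e.s_obs,
                "s_hat": e.s_hat,
                "completeness": e.completeness,
            }
        )
    return pd.DataFrame(rows, columns=["species", "n", "s_obs", "s_hat", "completeness"])


@dataclass
class OctaveProfile:
    labels: list[str]
    per_species: pd.DataFrame  # species x 8 relative frequencies
    mean: np.ndarray
    sd: np.ndarray


def octave_class(abundance: int) -> int:
    """Index (0..7) of the log2 abundance class; >=256 clamps to the top class."""
    if abundance < 1:
        raise ValueError("abundance must be >= 1")
    if abundance > 255:
        logger.warning("abundance %d exceeds top octave class; clamping to 128-255", abundance)
        return 7
    return int(math.floor(math.log2(abundance)))


def octave_profile(tables) -> OctaveProfile:
    """Cross-species profile of haplotype abundances over the 8 log2 classes."""
    tables = list(tables)
    if not tables:
        raise ValueError("octave_profile requires at least one species")
    rows = {}
    for t in tables:
        freq = np.zeros(8)
        for a in t.abundances:
            freq[octave_class(a)] += 1
        rows[t.species] = freq / t.s_obs
    per_species = pd.DataFrame.from_dict(rows, orient="index", columns=OCTAVE_LABELS)
    mean = per_species.to_numpy().mean(axis=0)
    sd = per_species.to_numpy().std(axis=0, ddof=1) if len(rows) > 1 else np.zeros(8)
    return OctaveProfile(list(OCTAVE_LABELS), per_species, mean, sd)


def species_tables(lib, strict: bool = False) -> dict[str, HaplotypeTable]:
    """Collapse every species-identified species of a library."""
    return {
        sp: collapse_haplotypes(recs, species=sp, strict=strict)
        for sp, recs in sorted(lib.by_species().items())
    }
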