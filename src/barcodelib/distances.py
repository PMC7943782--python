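"""Uncorrected p-distances and the taxonomic audits built on them.

The p-distance between two barcodes is the proportion of differing
nucleotides among the positions where both sequences carry an unambiguous
base (pairwise deletion). On top of pairwise distances the module computes
per-species intraspecific summaries, nearest-neighbour distances (a species'
minimum distance to any specimen of any other species), connected components
of zero-distance cross-species links ("barcode sharing" cases), and flags for
deep intraspecific splits and shallow interspecific divergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import ReferenceLibrary

#: Minimum number of jointly unambiguous sites for a pair to be comparable
#: (half of the 658-site barcode frame).
MIN_OVERLAP = 300

#: Deep intraspecific split threshold, percent.
DEEP_SPLIT_THRESHOLD = 2.5
#: Shallow nearest-neighbour threshold, percent (4 substitutions over 658 sites).
LOW_NN_THRESHOLD = 0.61

_ENC = np.zeros(256, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT", start=1):
    _ENC[_c] = _i


def encode(seq: str) -> np.ndarray:
    """uint8 code per position: 1..4 for A/C/G/T, 0 for N or gap."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PairwiseDistance:
    id_a: str
    id_b: str
    compared_sites: int
    differences: int
    p: float
    valid: bool


def p_distance(a: str, b: str, min_overlap: int = MIN_OVERLAP,
               id_a: str = "a", id_b: str = "b") -> PairwiseDistance:
    """Uncorrected p-distance with pairwise deletion of ambiguous sites."""
    ea, eb = encode(a), encode(b)
    if ea.shape != eb.shape:
        raise ValueError("sequences must share the same barcode frame")
    both = (ea > 0) & (eb > 0)
    compared = int(both.sum())
    diffs = int(((ea != eb) & both).sum())
    valid = compared >= min_overlap
    p = diffs / compared if compared else float("nan")
    return PairwiseDistance(id_a, id_b, compared, diffs, p, valid)


def pairwise_p_matrix(seqs, min_overlap: int = MIN_OVERLAP) -> np.ndarray:
    """n x n matrix of p-distances; NaN where the pair overlap is too small.

    Results are identical to calling :func:`p_distance` per pair; the matrix
    form exists only for speed on library-scale inputs.
    """
    E = np.stack([encode(s) for s in seqs])
    valid = E > 0
    n = len(seqs)
    P = np.full((n, n), np.nan)
    np.fill_diagonal(P, 0.0)
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        compared = both.sum(axis=1)
        diffs = ((E[i] != E[i + 1:]) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(compared >= min_overlap, diffs / compared, np.nan)
        P[i, i + 1:] = p
        P[i + 1:, i] = p
    return P


@dataclass
class SpeciesDistanceSummary:
    species: str
    n: int
    mean_intra: float  # NaN for singletons
    max_intra: float
    nn_species: tuple[str, ...]
    nn_dist: float


def _library_matrix(lib: ReferenceLibrary, min_overlap: int):
    recs = list(lib.species_identified())
    P = pairwise_p_matrix([r.sequence for r in recs], min_overlap=min_overlap)
    species = np.array([r.species for r in recs], dtype=object)
    return recs, species, P


def nearest_neighbour(
    lib: ReferenceLibrary, min_overlap: int = MIN_OVERLAP
) -> dict[str, SpeciesDistanceSummary]:
    """Intraspecific summaries and nearest-neighbour distance per species.

    Requires at least two species. Ties in the nearest neighbour are reported
    by listing all tied species. Species whose cross-species pairs are all
    invalid get ``nn_dist = NaN``.
    """
    recs, species, P = _library_matrix(lib, min_overlap)
    names = sorted(set(species))
    if len(names) < 2:
        raise ValueError("nearest_neighbour requires at least two species")
    out: dict[str, SpeciesDistanceSummary] = {}
    for sp in names:
        idx = np.flatnonzero(species == sp)
        other = np.flatnonzero(species != sp)
        sub = P[np.ix_(idx, idx)][np.triu_indices(len(idx), k=1)]
        sub = sub[~np.isnan(sub)]
        if sub.size:
            mean_intra, max_intra = float(sub.mean()), float(sub.max())
        else:
            mean_intra = max_intra = float("nan")
        cross = P[np.ix_(idx, other)]
        finite = ~np.isnan(cross)
        if finite.any():
            nn = float(np.nanmin(cross))
            hit_cols = np.flatnonzero(np.nan_to_num(cross, nan=np.inf).min(axis=0) <= nn)
            nn_species = tuple(sorted(set(species[other[hit_cols]])))
        else:
            nn, nn_species = float("nan"), ()
        out[sp] = SpeciesDistanceSummary(sp, len(idx), mean_intra, max_intra, nn_species, nn)
    return out


@dataclass
class SharingCase:
    """A connected component of species linked by zero-distance barcodes."""

    species: tuple[str, ...]
    n_specimens_involved: dict[str, int]
    classification: str | None = None  # user annotation: operational | biological

    @property
    def size(self) -> int:
        return len(self.species)


def detect_sharing(
    lib: ReferenceLibrary, min_overlap: int = MIN_OVERLAP
) -> list[SharingCase]:
    """Barcode-sharing cases: components of the zero-distance species graph.

    An edge joins two species iff some valid cross-species pair has p = 0;
    the specimens counted per species are those carrying at least one
    zero-distance link to another species of the case.
    """
    recs, species, P = _library_matrix(lib, min_overlap)
    g = nx.Graph()
    g.add_nodes_from(set(species))
    zero = np.argwhere((P == 0.0))
    involved: dict[str, set[str]] = {}
    for i, j in zero:
        if i < j and species[i] != species[j]:
            g.add_edge(species[i], species[j])
            involved.setdefault(species[i], set()).add(recs[i].specimen_id)
            involved.setdefault(species[j], set()).add(recs[j].specimen_id)
    cases = []
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sp = tuple(sorted(comp))
        cases.append(SharingCase(sp, {s: len(involved.get(s, ())) for s in sp}))
    return sorted(cases, key=lambda c: c.species)


def summarize_sharing(cases) -> dict[int, int]:
    """Component-size distribution: {case size: number of cases}."""
    out: dict[int, int] = {}
    for c in cases:
        out[c.size] = out.get(c.size, 0) + 1
    return dict(sorted(out.items()))


@dataclass
class TaxonFlags:
    species: str
    deep_split: bool
    low_divergence: bool
    shared: bool


def flag_taxa(
    summaries: dict[str, SpeciesDistanceSummary],
    deep_threshold: float = DEEP_SPLIT_THRESHOLD,
    low_nn_threshold: float = LOW_NN_THRESHOLD,
) -> dict[str, TaxonFlags]:
    """Audit flags from the distance summaries; thresholds are in percent.

    deep split: max intraspecific p strictly above ``deep_threshold``;
    low divergence: 0 < nearest-neighbour distance < ``low_nn_threshold``;
    shared: nearest-neighbour distance exactly 0.
    """
    out = {}
    for sp, s in summaries.items():
        max_intra_pct = s.max_intra * 100.0
        nn_pct = s.nn_dist * 100.0
        out[sp] = TaxonFlags(
            species=sp,
            deep_split=bool(max_intra_pct > deep_threshold),
            low_divergence=bool(0.0 < nn_pct < low_nn_threshold),
            shared=bool(nn_pct == 0.0),
        )
    return out
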