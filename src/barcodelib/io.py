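"""Reading, writing and validation of barcode reference libraries.

A reference library couples aligned COI barcode sequences (FASTA) with a
BOLD-style specimen metadata table (TSV): one row per specimen carrying a
four-level taxonomy path (family / subfamily / genus / species, the species
field may be empty for specimens identified only to genus) and decimal-degree
collection coordinates. Sequences are assumed pre-trimmed to a fixed barcode
frame of length ``L`` (658 by default); no alignment is performed here.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical metadata column order of the TSV dialect.
METADATA_COLUMNS = [
    "specimen_id",
    "family",
    "subfamily",
    "genus",
    "species",
    "latitude",
    "longitude",
]

ALPHABET = set("ACGTN-")
UNAMBIGUOUS = set("ACGT")

#: Library inclusion rule: minimum number of unambiguous (A/C/G/T) positions.
MIN_INFORMATIVE_SITES = 600


@dataclass(frozen=True)
class SpecimenRecord:
    """One barcoded specimen: sequence + taxonomy path + coordinates.

    ``species`` may be the empty string for a genus-level identification.
    ``latitude``/``longitude`` are NaN when the source coordinate could not
    be parsed (such records are flagged, not dropped).
    """

    specimen_id: str
    family: str
    subfamily: str
    genus: str
    species: str
    latitude: float
    longitude: float
    sequence: str

    @property
    def informative_sites(self) -> int:
        return sum(1 for c in self.sequence if c in UNAMBIGUOUS)

    @property
    def species_identified(self) -> bool:
        return self.species != ""

    @property
    def has_coordinates(self) -> bool:
        return not (math.isnan(self.latitude) or math.isnan(self.longitude))


@dataclass
class ReferenceLibrary:
    """A validated collection of :class:`SpecimenRecord` sharing frame length L."""

    records: list[SpecimenRecord]
    L: int = 658
    n_excluded_short: int = 0
    invalid_coordinate_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if len(r.sequence) != self.L:
                raise ValueError(
                    f"sequence of {r.specimen_id!r} has length {len(r.sequence)}, "
                    f"expected L={self.L}"
                )
            if r.specimen_id in seen:
                raise ValueError(f"duplicate specimen_id {r.specimen_id!r}")
            seen.add(r.specimen_id)
            bad = set(r.sequence) - ALPHABET
            if bad:
                raise ValueError(
                    f"sequence of {r.specimen_id!r} contains characters outside "
                    f"{{A,C,G,T,N,-}}: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def species_identified(self) -> "ReferenceLibrary":
        """Sub-library of records with a non-empty species name."""
        sub = ReferenceLibrary([r for r in self.records if r.species_identified], L=self.L)
        return sub

    def by_species(self) -> dict[str, list[SpecimenRecord]]:
        out: dict[str, list[SpecimenRecord]] = {}
        for r in self.records:
            if r.species_identified:
                out.setdefault(r.species, []).append(r)
        return out

    def species_names(self) -> list[str]:
        return sorted(self.by_species())


def _parse_coord(value, lo: float, hi: float) -> float:
    try:
        x = float(value)
    except (TypeError, ValueError):
        return math.nan
    if math.isnan(x) or not (lo <= x <= hi):
        return math.nan
    return x


def read_metadata(path_or_df) -> pd.DataFrame:
    """Load a specimen metadata TSV (or pass a DataFrame through)."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table lacks required columns: {missing}")
    return df


def read_fasta(
    fasta_path,
    metadata,
    L: int | None = None,
    min_informative: int = MIN_INFORMATIVE_SITES,
) -> ReferenceLibrary:
    """Read a FASTA + metadata pair into a validated :class:`ReferenceLibrary`.

    FASTA ids must resolve 1:1 to metadata ``specimen_id`` rows. Records with
    fewer than ``min_informative`` unambiguous positions are excluded and
    counted in ``n_excluded_short``; records whose coordinates fail to parse
    (or fall outside [-90,90]/[-180,180]) are kept with NaN coordinates and
    listed in ``invalid_coordinate_ids``.
    """
    meta = read_metadata(metadata)
    dup = meta["specimen_id"][meta["specimen_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate specimen_id in metadata: {sorted(set(dup))}")
    meta_by_id = meta.set_index("specimen_id")

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate id in FASTA: {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        logger.warning("empty FASTA %s: returning empty library", fasta_path)
        return ReferenceLibrary([], L=L or 658)

    absent = [sid for sid in seqs if sid not in meta_by_id.index]
    if absent:
        raise ValueError(f"FASTA ids absent from metadata: {absent}")

    if L is None:
        L = len(next(iter(seqs.values())))

    records: list[SpecimenRecord] = []
    n_short = 0
    bad_coords: list[str] = []
    for sid, seq in seqs.items():
        row = meta_by_id.loc[sid]
        lat = _parse_coord(row["latitude"], -90.0, 90.0)
        lon = _parse_coord(row["longitude"], -180.0, 180.0)
        rec = SpecimenRecord(
            specimen_id=sid,
            family=str(row["family"]),
            subfamily=str(row["subfamily"]),
            genus=str(row["genus"]),
            species=str(row["species"]),
            latitude=lat,
            longitude=lon,
            sequence=seq,
        )
        if rec.informative_sites < min_informative:
            n_short += 1
            continue
        if not rec.has_coordinates:
            bad_coords.append(sid)
        records.append(rec)

    return ReferenceLibrary(
        records, L=L, n_excluded_short=n_short, invalid_coordinate_ids=bad_coords
    )


def write_library(lib: ReferenceLibrary, fasta_path, tsv_path) -> None:
    """Write a library back to FASTA + TSV (byte-stable round trip)."""
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.specimen_id, description="") for r in lib),
        str(fasta_path),
        "fasta",
    )
    metadata_frame(lib).to_csv(tsv_path, sep="\t", index=False)


def metadata_frame(lib: ReferenceLibrary) -> pd.DataFrame:
    rows = [
        {
            "specimen_id": r.specimen_id,
            "family": r.family,
            "subfamily": r.subfamily,
            "genus": r.genus,
            "species": r.species,
            "latitude": r.latitude,
            "longitude": r.longitude,
        }
        for r in lib
    ]
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


@dataclass
class TaxonomyReport:
    counts: dict[str, int]
    violations: list[str]
    n_total: int
    n_species_identified: int
    n_genus_level: int


def validate_taxonomy(lib: ReferenceLibrary) -> TaxonomyReport:
    """Check hierarchical consistency and count taxa per level.

    A violation is a taxon placed under more than one parent (e.g. the same
    genus listed under two subfamilies), which would make the four-level
    classification tree ill-defined.
    """
    parent_of: dict[tuple[str, str], set[str]] = {}

    def note(level: str, child: str, parent: str) -> None:
        if child == "":
            return
        parent_of.setdefault((level, child), set()).add(parent)

    fams, subs, gens, spps = set(), set(), set(), set()
    for r in lib:
        fams.add(r.family)
        subs.add(r.subfamily)
        gens.add(r.genus)
        if r.species_identified:
            spps.add(r.species)
        note("subfamily", r.subfamily, r.family)
        note("genus", r.genus, r.subfamily)
        if r.species_identified:
            note("species", r.species, r.genus)

    violations = [
        f"{level} {child!r} placed under multiple parents: {sorted(parents)}"
        for (level, child), parents in sorted(parent_of.items())
        if len(parents) > 1
    ]
    n_sp = sum(1 for r in lib if r.species_identified)
    return TaxonomyReport(
        counts={
            "family": len(fams),
            "subfamily": len(subs),
            "genus": len(gens),
            "species": len(spps),
        },
        violations=violations,
        n_total=len(lib),
        n_species_identified=n_sp,
        n_genus_level=len(lib) - n_sp,
    )


def read_newick(path) -> dendropy.Tree:
    """Read a single rooted Newick tree with branch lengths."""
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    depths = tip_depths(tree)
    if depths and max(depths.values()) - min(depths.values()) > 1e-6 * max(depths.values()):
        warnings.warn(
            "tree is not ultrametric; Pagel's lambda transform is still defined",
            stacklevel=2,
        )
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length per tip label."""
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return {
        leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter() if leaf.taxon
    }


def match_tree_to_library(tree: dendropy.Tree, lib: ReferenceLibrary):
    """Intersect tree tips with library species.

    Returns ``(shared, tips_only, library_only)`` as sorted name lists;
    downstream analyses proceed on the intersection.
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon}
    species = set(lib.by_species())
    return (
        sorted(tips & species),
        sorted(tips - species),
        sorted(species - tips),
    )


def exclude_record(lib: ReferenceLibrary, specimen_id: str) -> ReferenceLibrary:
    """Library with one specimen removed (leave-one-out helper)."""
    kept = [r for r in lib if r.specimen_id != specimen_id]
    if len(kept) == len(lib):
        raise KeyError(specimen_id)
    return ReferenceLibrary(kept, L=lib.L)


def subset(lib: ReferenceLibrary, ids) -> ReferenceLibrary:
    wanted = set(ids)
    return ReferenceLibrary([r for r in lib if r.specimen_id in wanted], L=lib.L)
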