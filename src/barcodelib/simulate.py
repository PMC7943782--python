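"""Seeded synthetic barcode reference libraries with known ground truth.

The generator emulates the statistical shape of a continental barcode
library so every downstream analysis is testable without real data:

* a four-level taxonomy (family / subfamily / genus / species) with
  hierarchically nested sequence divergence (no indels, uniform
  substitutions on a random ancestral barcode — p-distance analyses
  ignore indels, so this is sufficient),
* congeneric species separated by at least ``species_divergence`` private
  substitutions; within-species haplotypes each carrying one private
  substitution (pairwise distinct),
* a skewed (geometric) haplotype abundance law — a few common haplotypes
  and many rare ones,
* range sizes drawn log-uniformly, with specimen counts increasing with
  range (widespread species are sampled more heavily) and true haplotype
  counts following a power law in range size (with lognormal scatter),
* a latitudinal richness gradient: the number of haplotypes locally
  available to sampling peaks at a configurable latitude (southern-refugium
  pattern) via a Gaussian bump in relative richness,
* optional cross-species identical barcodes ("introgression") and
  singleton species,
* a taxonomy-consistent ultrametric cladogram (fixed depth per rank) and a
  species range table for the comparative analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .io import ReferenceLibrary, SpecimenRecord, write_library

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class LatGradient:
    """Relative haplotype richness vs latitude: a Gaussian bump on a floor.

    g(lat) = base + (1 - base) * exp(-(lat - peak)^2 / (2 width^2)); the
    number of haplotypes available to sampling at latitude ``lat`` is
    round(K * g(lat)), clipped to at least one.
    """

    peak: float = 42.5
    width: float = 4.0
    base: float = 0.2

    def __call__(self, lat: float) -> float:
        return self.base + (1.0 - self.base) * math.exp(
            -((lat - self.peak) ** 2) / (2.0 * self.width**2)
        )


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_families: int = 4
    subfamilies_per_family: int = 2
    genera_per_subfamily: int = 2
    species_per_genus: int = 2
    L: int = 658
    #: minimum private substitutions separating congeneric species
    species_divergence: int = 10
    #: geometric abundance law parameter in (0, 1); closer to 1 = more even
    haplotype_shape: float = 0.9
    #: exponent of the power law linking true haplotype count to range size
    range_richness_slope: float = 0.5
    richness_log_intercept: float = 1.0
    richness_noise_sd: float = 0.3
    lat_gradient: LatGradient = field(default_factory=LatGradient)
    lat_range: tuple[float, float] = (35.0, 70.0)
    lon_range: tuple[float, float] = (-9.0, 36.0)
    #: (donor species, recipient species, n specimens) — the recipient
    #: specimens carry a barcode identical to the donor's top haplotype
    introgression_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    #: specimen count law: round(coef * range^0.5 * lognormal effort noise)
    specimens_coef: float = 3.0
    specimens_noise_sd: float = 0.4
    #: when set, every species gets exactly this many specimens
    constant_n: int | None = None
    #: force the first k species (in generation order) to a single specimen
    n_singleton_species: int = 0
    range_min: float = 1.0
    range_max: float = 400.0
    #: substitutions separating sister clades at each internal rank
    family_divergence: int = 40
    subfamily_divergence: int = 20
    genus_divergence: int = 12

    def __post_init__(self) -> None:
        for name in ("n_families", "subfamilies_per_family", "genera_per_subfamily",
                     "species_per_genus"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 < self.haplotype_shape < 1.0):
            raise ValueError("haplotype_shape must be in (0, 1)")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one species, for parameter-recovery tests."""

    species: str
    true_haplotype_count: int
    true_range_size: float
    haplotype_sequences: tuple[str, ...]
    haplotype_probabilities: tuple[float, ...]


@dataclass
class GeneratedDataset:
    library: ReferenceLibrary
    truth: dict[str, TruthRecord]
    tree_newick: str
    ranges: pd.DataFrame
    config: SyntheticConfig

    def tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.tree_newick, schema="newick", preserve_underscores=True)


def geometric_weights(shape: float, K: int) -> np.ndarray:
    """Normalized geometric haplotype weights shape^(k-1), k = 1..K."""
    w = shape ** np.arange(K, dtype=float)
    return w / w.sum()


def sample_abundances(shape: float, K: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Multinomial draw of n specimens over K haplotypes with geometric weights.

    Zero realized abundances are allowed (unobserved haplotypes are exactly
    what makes sampling completeness fall below one).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.multinomial(n, geometric_weights(shape, K))


def _mutate(rng: np.random.Generator, seq: np.ndarray, positions: np.ndarray) -> np.ndarray:
    out = seq.copy()
    for p in positions:
        choices = BASES[BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def _decode(seq: np.ndarray) -> str:
    return seq.tobytes().decode("ascii")


def generate_dataset(cfg: SyntheticConfig) -> GeneratedDataset:
    """Generate a complete synthetic dataset, deterministically from the seed."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.L

    root = rng.choice(BASES, size=L)
    taxonomy: list[tuple[str, str, str, str]] = []  # family, subfamily, genus, species
    species_seq: dict[str, np.ndarray] = {}
    genus_of: dict[str, str] = {}

    # Hierarchically mutate: root -> family -> subfamily -> genus -> species.
    genus_pool: dict[str, np.ndarray] = {}
    for f in range(cfg.n_families):
        fam = f"Fam{f + 1}"
        fam_seq = _mutate(rng, root, rng.choice(L, size=cfg.family_divergence, replace=False))
        for s in range(cfg.subfamilies_per_family):
            sub = f"{fam}_Sub{s + 1}"
            sub_seq = _mutate(
                rng, fam_seq, rng.choice(L, size=cfg.subfamily_divergence, replace=False)
            )
            for g in range(cfg.genera_per_subfamily):
                gen = f"{sub}_Gen{g + 1}"
                gen_seq = _mutate(
                    rng, sub_seq, rng.choice(L, size=cfg.genus_divergence, replace=False)
                )
                # disjoint private-site pool shared by the genus' species
                pool = rng.permutation(L)
                genus_pool[gen] = pool
                used = 0
                for k in range(cfg.species_per_genus):
                    sp = f"{gen}_sp{k + 1}"
                    pos = pool[used : used + cfg.species_divergence]
                    if len(pos) < cfg.species_divergence:
                        raise ValueError("infeasible config: not enough sites in the frame")
                    used += cfg.species_divergence
                    species_seq[sp] = _mutate(rng, gen_seq, pos)
                    genus_of[sp] = gen
                    taxonomy.append((fam, sub, gen, sp))
                genus_pool[gen] = pool[used:]  # remainder available for haplotype sites

    species_list = [t[3] for t in taxonomy]
    n_species = len(species_list)

    # Range sizes (log-uniform) -> true haplotype counts and specimen counts.
    log_r = rng.uniform(math.log(cfg.range_min), math.log(cfg.range_max), size=n_species)
    ranges = np.exp(log_r)
    log_k = (
        cfg.richness_log_intercept
        + cfg.range_richness_slope * log_r
        + rng.normal(0.0, cfg.richness_noise_sd, size=n_species)
    )
    K = np.maximum(1, np.rint(np.exp(log_k))).astype(int)
    if cfg.constant_n is not None:
        n_spec = np.full(n_species, int(cfg.constant_n))
    else:
        effort = np.exp(rng.normal(0.0, cfg.specimens_noise_sd, size=n_species))
        n_spec = np.maximum(1, np.rint(cfg.specimens_coef * np.sqrt(ranges) * effort)).astype(int)
    for i in range(min(cfg.n_singleton_species, n_species)):
        n_spec[i] = 1

    # Haplotype sequences: top haplotype is the species sequence, each further
    # haplotype carries one private substitution from the genus pool.
    truth: dict[str, TruthRecord] = {}
    hap_seqs: dict[str, list[np.ndarray]] = {}
    pool_used: dict[str, int] = {g: 0 for g in genus_pool}
    for i, sp in enumerate(species_list):
        g = genus_of[sp]
        pool = genus_pool[g]
        k = K[i]
        need = k - 1
        if pool_used[g] + need > len(pool):
            raise ValueError(
                f"infeasible config: genus {g} requires more haplotype sites than the "
                f"{cfg.L}-site frame provides"
            )
        haps = [species_seq[sp]]
        for j in range(need):
            pos = np.array([pool[pool_used[g] + j]])
            haps.append(_mutate(rng, species_seq[sp], pos))
        pool_used[g] += need
        hap_seqs[sp] = haps
        truth[sp] = TruthRecord(
            species=sp,
            true_haplotype_count=int(k),
            true_range_size=float(ranges[i]),
            haplotype_sequences=tuple(_decode(h) for h in haps),
            haplotype_probabilities=tuple(geometric_weights(cfg.haplotype_shape, k)),
        )

    # Specimens: coordinates uniform over the window; the haplotype drawn at a
    # given latitude comes from the locally available prefix of the haplotype
    # list (richness gradient), with geometric weights.
    records: list[SpecimenRecord] = []
    lat_lo, lat_hi = cfg.lat_range
    lon_lo, lon_hi = cfg.lon_range
    for i, ((fam, sub, gen, sp)) in enumerate(taxonomy):
        k = K[i]
        for j in range(n_spec[i]):
            lat = float(rng.uniform(lat_lo, lat_hi))
            lon = float(rng.uniform(lon_lo, lon_hi))
            k_eff = max(1, int(round(k * cfg.lat_gradient(lat))))
            k_eff = min(k_eff, k)
            h = int(rng.choice(k_eff, p=geometric_weights(cfg.haplotype_shape, k_eff)))
            records.append(
                SpecimenRecord(
                    specimen_id=f"{sp}_{j + 1:04d}",
                    family=fam,
                    subfamily=sub,
                    genus=gen,
                    species=sp,
                    latitude=lat,
                    longitude=lon,
                    sequence=_decode(hap_seqs[sp][h]),
                )
            )

    # Introgression: overwrite the first n recipient specimens with the
    # donor's most common realized barcode, yielding exact cross-species
    # barcode identity in the sampled library.
    by_sp_idx: dict[str, list[int]] = {}
    for idx, r in enumerate(records):
        by_sp_idx.setdefault(r.species, []).append(idx)
    for donor, recipient, n_intro in cfg.introgression_pairs:
        if donor not in truth or recipient not in truth:
            raise ValueError(f"unknown species in introgression pair: {donor}, {recipient}")
        targets = by_sp_idx.get(recipient, [])
        donors = by_sp_idx.get(donor, [])
        if not donors:
            raise ValueError(f"introgression donor {donor} has no specimens")
        if n_intro > len(targets):
            raise ValueError(
                f"introgression pair asks for {n_intro} specimens of {recipient}, "
                f"only {len(targets)} exist"
            )
        counts: dict[str, int] = {}
        for idx in donors:
            counts[records[idx].sequence] = counts.get(records[idx].sequence, 0) + 1
        donor_seq = max(sorted(counts), key=counts.get)
        for idx in targets[:n_intro]:
            records[idx] = replace(records[idx], sequence=donor_seq)

    library = ReferenceLibrary(records, L=L)
    newick = _taxonomy_newick(taxonomy)
    ranges_df = pd.DataFrame(
        {
            "species": species_list,
            "range_size": ranges,
            "n_specimens": n_spec,
            "true_haplotypes": K,
        }
    )
    return GeneratedDataset(library, truth, newick, ranges_df, cfg)


def _taxonomy_newick(taxonomy) -> str:
    """Ultrametric cladogram mirroring the taxonomy: 0.25 per rank, depth 1."""
    fams: dict[str, dict[str, dict[str, list[str]]]] = {}
    for fam, sub, gen, sp in taxonomy:
        fams.setdefault(fam, {}).setdefault(sub, {}).setdefault(gen, []).append(sp)

    fam_strs = []
    for fam, subs in fams.items():
        sub_strs = []
        for sub, gens in subs.items():
            gen_strs = []
            for gen, spps in gens.items():
                tips = [f"{sp}:0.25" for sp in spps]
                gen_strs.append(_node(tips, 0.25))
            sub_strs.append(_node(gen_strs, 0.25))
        fam_strs.append(_node(sub_strs, 0.25))
    return f"({','.join(fam_strs)});"


def _node(children: list[str], bl: float) -> str:
    if len(children) == 1:
        # collapse unary nodes by extending the child's branch
        child = children[0]
        name, _, length = child.rpartition(":")
        return f"{name}:{float(length) + bl}"
    return f"({','.join(children)}):{bl}"


def write_dataset(ds: GeneratedDataset, outdir) -> None:
    """Write FASTA/TSV/Newick/CSV files in the formats the io module reads."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_library(ds.library, out / "sequences.fasta", out / "specimens.tsv")
    (out / "tree.nwk").write_text(ds.tree_newick + "\n")
    ds.ranges.to_csv(out / "ranges.csv", index=False)
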