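"""Hierarchical probabilistic taxonomic assignment (PROTAX-style).

A query barcode enters the taxonomy at the root with probability one. Each
node partitions its probability among its children with a multinomial
(softmax) regression whose predictors are, per candidate child taxon, the
smallest and the average p-distance between the query and the child's
reference sequences (plus an intercept). Using the average distance makes
the classifier sensitive to haplotype frequency in the reference set — a
species that shares a rare (e.g. introgressed) barcode with another is not
penalized as heavily as one sharing a common barcode. Four levels are
crossed: order→family, family→subfamily, subfamily→genus, genus→species;
a species' probability is the product of the branch probabilities on its
path.

One weight vector is shared by all nodes of a level; predictors are
standardized to zero mean and unit variance on the training set. Weights
are trained by random-walk Metropolis with zero-mean Gaussian priors
(sd 100): an adaptation phase targets an acceptance ratio of 0.44, then
the proposal is frozen for a sampling phase, and the maximum-a-posteriori
draw of the sampling phase is used for classification. Training and
evaluation are leave-one-out: a barcode never serves as a reference for
its own classification, so singleton species have zero probability of
correct self-assignment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .distances import MIN_OVERLAP, encode, pairwise_p_matrix
from .io import ReferenceLibrary

LEVEL_NAMES = ["family", "subfamily", "genus", "species"]
ROOT = "__root__"

PRIOR_SD = 100.0
TARGET_ACCEPTANCE = 0.44
LOG_FLOOR = -30.0  # per-record log-likelihood floor when the true child is unreachable


@dataclass
class TaxonNode:
    name: str
    level: int  # 1 = family ... 4 = species; 0 = root
    parent: str | None
    children: list[str] = field(default_factory=list)
    ref_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


@dataclass
class TaxonomyTree:
    """Four classification levels below the root; leaf reference sets
    partition the species-identified library."""

    nodes: dict[str, TaxonNode]
    paths: dict[str, list[str]]  # species -> [family, subfamily, genus, species]

    @property
    def root(self) -> TaxonNode:
        return self.nodes[ROOT]


def build_taxonomy(lib: ReferenceLibrary) -> tuple[TaxonomyTree, list]:
    """Build the taxonomy tree over the species-identified records.

    Taxon names must be unique across levels (they index the node table).
    Returns the tree and the record list whose positions the reference
    index sets refer to.
    """
    records = list(lib.species_identified())
    nodes: dict[str, TaxonNode] = {ROOT: TaxonNode(ROOT, 0, None)}
    paths: dict[str, list[str]] = {}
    for i, r in enumerate(records):
        path = [r.family, r.subfamily, r.genus, r.species]
        parent = ROOT
        for level, name in enumerate(path, start=1):
            node = nodes.get(name)
            if node is None:
                node = TaxonNode(name, level, parent)
                nodes[name] = node
                nodes[parent].children.append(name)
            elif node.parent != parent or node.level != level:
                raise ValueError(
                    f"taxon {name!r} appears with conflicting placement; "
                    "taxonomy must be hierarchically consistent"
                )
            parent = name
        paths[r.species] = path
    # collect reference index sets bottom-up
    idx_of: dict[str, list[int]] = {name: [] for name in nodes}
    for i, r in enumerate(records):
        for name in (r.family, r.subfamily, r.genus, r.species):
            idx_of[name].append(i)
        idx_of[ROOT].append(i)
    for name, node in nodes.items():
        node.ref_idx = np.asarray(idx_of[name], dtype=int)
        node.children.sort()
    return TaxonomyTree(nodes, paths), records


@dataclass
class Scaler:
    mean: np.ndarray  # (2,)
    sd: np.ndarray  # (2,)

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd


@dataclass
class LevelModel:
    beta: np.ndarray  # (3,): intercept, w_min, w_avg
    scaler: Scaler


@dataclass
class LevelTrainingSet:
    """Padded per-record candidate predictors for one level."""

    X: np.ndarray  # (R, Kmax, 2) raw predictors, NaN where padded
    mask: np.ndarray  # (R, Kmax) valid-candidate flags
    y: np.ndarray  # (R,) true-candidate position, -1 if unreachable
    scaler: Scaler

    @property
    def n_floored(self) -> int:
        return int((self.y < 0).sum())

    def standardized(self) -> np.ndarray:
        Xs = self.scaler.apply(self.X)
        return np.where(self.mask[:, :, None], Xs, 0.0)


@dataclass
class ProtaxModel:
    tree: TaxonomyTree
    levels: list[LevelModel]
    records: list
    seqs: list[str]
    D: np.ndarray  # reference-by-reference p-distance matrix
    traces: list[np.ndarray]
    log_posts: list[np.ndarray]
    acceptance: list[dict]
    n_floored: list[int]
    seed: int
    min_overlap: int = MIN_OVERLAP


def node_probabilities(beta: np.ndarray, X_std: np.ndarray) -> np.ndarray:
    """Softmax probabilities over K candidates with shared weights.

    ``X_std`` is (K, 2) standardized (d_min, d_avg); the shared intercept
    cancels in the softmax but is kept for the stated parameterization.
    """
    X_std = np.atleast_2d(X_std)
    scores = beta[0] + X_std @ beta[1:]
    scores = scores - scores.max()
    e = np.exp(scores)
    return e / e.sum()


def _taxon_stats(D_row: np.ndarray, idx: np.ndarray, exclude: int | None = None):
    """(d_min, d_avg) of a query's distances to one taxon's references."""
    if exclude is not None:
        idx = idx[idx != exclude]
    if idx.size == 0:
        return None
    d = D_row[idx]
    d = d[~np.isnan(d)]
    if d.size == 0:
        return None
    return float(d.min()), float(d.mean())


def build_training_set(tree: TaxonomyTree, records, D: np.ndarray) -> list[LevelTrainingSet]:
    """Labelled, standardized predictor records for every level.

    For every reference sequence and every node on its true path, predictors
    to all candidate children are computed with the focal sequence removed
    from its own reference sets; children left without references are
    excluded for that record (the label becomes unreachable for singletons).
    """
    R = len(records)
    out: list[LevelTrainingSet] = []
    # cache: per taxon, (R,) d_min and d_avg without exclusion
    cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def taxon_columns(name: str):
        if name not in cache:
            idx = tree.nodes[name].ref_idx
            sub = D[:, idx]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                dmin = np.nanmin(sub, axis=1)
                davg = np.nanmean(sub, axis=1)
            cache[name] = (dmin, davg)
        return cache[name]

    for level in range(1, 5):
        # group records by the parent node at this level
        parents: dict[str, list[int]] = {}
        for i, r in enumerate(records):
            path = [ROOT, r.family, r.subfamily, r.genus, r.species]
            parents.setdefault(path[level - 1], []).append(i)
        kmax = max(len(tree.nodes[p].children) for p in parents)
        X = np.full((R, kmax, 2), np.nan)
        mask = np.zeros((R, kmax), dtype=bool)
        y = np.full(R, -1, dtype=int)
        for parent, rec_idx in parents.items():
            children = tree.nodes[parent].children
            cols = [taxon_columns(c) for c in children]
            for i in rec_idx:
                r = records[i]
                true_child = [r.family, r.subfamily, r.genus, r.species][level - 1]
                pos = 0
                for c, (dmin, davg) in zip(children, cols):
                    idx = tree.nodes[c].ref_idx
                    if i in idx:  # focal barcode never references itself
                        stats = _taxon_stats(D[i], idx, exclude=i)
                    else:
                        stats = (dmin[i], davg[i]) if np.isfinite(dmin[i]) else None
                    if stats is None:
                        continue
                    X[i, pos] = stats
                    mask[i, pos] = True
                    if c == true_child:
                        y[i] = pos
                    pos += 1
        vals = X[mask]
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=0)
        sd = np.where(sd < 1e-8, 1.0, sd)
        out.append(LevelTrainingSet(X, mask, y, Scaler(mean, sd)))
    return out


def level_log_likelihood(beta: np.ndarray, ts: LevelTrainingSet,
                         floor: float = LOG_FLOOR) -> float:
    """Sum over records of the log softmax probability of the true child."""
    Xs = ts.standardized()
    scores = beta[0] + Xs @ beta[1:]
    scores = np.where(ts.mask, scores, -np.inf)
    lse = logsumexp(scores, axis=1)
    reachable = ts.y >= 0
    rows = np.flatnonzero(reachable)
    ll = scores[rows, ts.y[rows]] - lse[rows]
    return float(ll.sum() + floor * (~reachable).sum())


def log_posterior(beta: np.ndarray, ts: LevelTrainingSet,
                  prior_sd: float = PRIOR_SD, floor: float = LOG_FLOOR) -> float:
    """Level log posterior: log likelihood + independent N(0, prior_sd²) priors."""
    prior = -0.5 * float(beta @ beta) / prior_sd**2 - beta.size * 0.5 * np.log(
        2 * np.pi * prior_sd**2
    )
    return level_log_likelihood(beta, ts, floor=floor) + prior


def _run_chain(ts: LevelTrainingSet, iters: int, adapt_iters: int,
               rng: np.random.Generator, prior_sd: float = PRIOR_SD):
    beta = np.zeros(3)
    lp = log_posterior(beta, ts, prior_sd)
    if not np.isfinite(lp):  # re-init at zero (floored likelihood keeps this finite)
        beta = np.zeros(3)
        lp = log_posterior(beta, ts, prior_sd)
    scale = 0.1
    n_acc1 = 0
    for t in range(1, adapt_iters + 1):
        prop = beta + scale * rng.standard_normal(3)
        lpp = log_posterior(prop, ts, prior_sd)
        alpha = min(1.0, np.exp(min(0.0, lpp - lp)))
        if rng.random() < alpha:
            beta, lp = prop, lpp
            n_acc1 += 1
        # Robbins-Monro scale update toward the target acceptance; the
        # diminishing gain t^-1/2 still has enough total capacity to cross
        # the wide prior-dominated plateau within the adaptation phase
        scale *= float(np.exp((alpha - TARGET_ACCEPTANCE) * t**-0.5))
    trace = np.empty((iters, 3))
    lps = np.empty(iters)
    n_acc2 = 0
    for t in range(iters):
        prop = beta + scale * rng.standard_normal(3)
        lpp = log_posterior(prop, ts, prior_sd)
        if rng.random() < np.exp(min(0.0, lpp - lp)):
            beta, lp = prop, lpp
            n_acc2 += 1
        trace[t] = beta
        lps[t] = lp
    best = int(np.argmax(lps))  # first-reached sample on ties
    acc = {
        "phase1": n_acc1 / max(adapt_iters, 1),
        "phase2": n_acc2 / max(iters, 1),
        "scale": scale,
    }
    return trace[best].copy(), trace, lps, acc


def train(lib: ReferenceLibrary, iters: int = 1000, adapt_iters: int = 1000,
          seed: int = 0, min_overlap: int = MIN_OVERLAP) -> ProtaxModel:
    """Train the four level models on a reference library by MCMC."""
    tree, records = build_taxonomy(lib)
    seqs = [r.sequence for r in records]
    D = pairwise_p_matrix(seqs, min_overlap=min_overlap)
    training = build_training_set(tree, records, D)
    level_models, traces, lpss, accs, floored = [], [], [], [], []
    child_seeds = np.random.SeedSequence(seed).spawn(4)
    for ts, ss in zip(training, child_seeds):
        rng = np.random.default_rng(ss)
        beta_map, trace, lps, acc = _run_chain(ts, iters, adapt_iters, rng)
        level_models.append(LevelModel(beta_map, ts.scaler))
        traces.append(trace)
        lpss.append(lps)
        accs.append(acc)
        floored.append(ts.n_floored)
    return ProtaxModel(
        tree=tree,
        levels=level_models,
        records=records,
        seqs=seqs,
        D=D,
        traces=traces,
        log_posts=lpss,
        acceptance=accs,
        n_floored=floored,
        seed=seed,
        min_overlap=min_overlap,
    )


@dataclass
class AssignmentResult:
    query_id: str
    taxon_probs: dict[str, float]  # cumulative probability per explored taxon
    species_probs: dict[str, float]
    top_species: str | None
    top_prob: float
    unassigned: float

    def probability(self, species: str) -> float:
        """Probability of a species; exactly 0 for unexplored/excluded species."""
        return self.species_probs.get(species, 0.0)


def _classify_from_distances(model: ProtaxModel, d: np.ndarray, query_id: str,
                             exclude_idx: int | None) -> AssignmentResult:
    tree = model.tree
    taxon_probs: dict[str, float] = {}
    species_probs: dict[str, float] = {}
    unassigned = 0.0
    frontier = [(ROOT, 1.0)]
    for level in range(4):
        lm = model.levels[level]
        nxt: list[tuple[str, float]] = []
        for parent, mass in frontier:
            cand, stats = [], []
            for c in tree.nodes[parent].children:
                st = _taxon_stats(d, tree.nodes[c].ref_idx, exclude=exclude_idx)
                if st is not None:
                    cand.append(c)
                    stats.append(st)
            if not cand:
                unassigned += mass
                continue
            X = lm.scaler.apply(np.asarray(stats))
            p = node_probabilities(lm.beta, X)
            for c, pc in zip(cand, p):
                cum = mass * float(pc)
                taxon_probs[c] = cum
                nxt.append((c, cum))
                if level == 3:
                    species_probs[c] = cum
        frontier = nxt
    if species_probs:
        top = min(species_probs, key=lambda s: (-species_probs[s], s))
        top_prob = species_probs[top]
    else:
        top, top_prob = None, 0.0
    return AssignmentResult(query_id, taxon_probs, species_probs, top, top_prob, unassigned)


def classify(model: ProtaxModel, query_sequence: str | None = None, *,
             query_index: int | None = None, exclude_id: str | None = None,
             query_id: str = "query") -> AssignmentResult:
    """Classify a query barcode, optionally leaving one reference out.

    Either pass a raw ``query_sequence`` or the ``query_index`` of a
    reference record. ``exclude_id`` removes that specimen from every
    reference set (leave-one-out semantics).
    """
    exclude_idx = None
    if exclude_id is not None:
        for i, r in enumerate(model.records):
            if r.specimen_id == exclude_id:
                exclude_idx = i
                break
        else:
            raise KeyError(exclude_id)
    if query_index is not None:
        d = model.D[query_index]
        query_id = model.records[query_index].specimen_id
    else:
        if query_sequence is None:
            raise ValueError("pass query_sequence or query_index")
        eq = encode(query_sequence)
        E = np.stack([encode(s) for s in model.seqs])
        both = (eq > 0) & (E > 0)
        compared = both.sum(axis=1)
        diffs = ((eq != E) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(compared >= model.min_overlap, diffs / compared, np.nan)
        if np.all(np.isnan(d)):
            return AssignmentResult(query_id, {}, {}, None, 0.0, 1.0)
    return _classify_from_distances(model, d, query_id, exclude_idx)


def leave_one_out(model: ProtaxModel) -> pd.DataFrame:
    """Classify every reference barcode with itself removed from the references.

    Returns one row per specimen: the probability assigned to its true
    species, the top species and its probability, and whether the true
    species is a singleton (whose correct-assignment probability is zero by
    construction).
    """
    sp_counts: dict[str, int] = {}
    for r in model.records:
        sp_counts[r.species] = sp_counts.get(r.species, 0) + 1
    rows = []
    for i, r in enumerate(model.records):
        res = _classify_from_distances(model, model.D[i], r.specimen_id, exclude_idx=i)
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "species": r.species,
                "p_true": res.probability(r.species),
                "top_species": res.top_species,
                "p_top": res.top_prob,
                "singleton": sp_counts[r.species] == 1,
            }
        )
    return pd.DataFrame(rows)


def species_average_probability(loo: pd.DataFrame, include_singletons: bool = False):
    """Per-species mean correct-assignment probability and the
    specimen-weighted cohort mean (singleton species excluded by default)."""
    df = loo if include_singletons else loo[~loo["singleton"]]
    per_species = df.groupby("species")["p_true"].mean()
    weighted = float(df["p_true"].mean()) if len(df) else float("nan")
    return per_species, weighted


MODEL_FORMAT_VERSION = 1


def save_model(model: ProtaxModel, path) -> None:
    """Serialize the trained model (weights, scalers, tree, seed) to JSON."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "seed": model.seed,
        "min_overlap": model.min_overlap,
        "acceptance": model.acceptance,
        "n_floored": model.n_floored,
        "levels": [
            {
                "beta": lm.beta.tolist(),
                "scaler_mean": lm.scaler.mean.tolist(),
                "scaler_sd": lm.scaler.sd.tolist(),
            }
            for lm in model.levels
        ],
        "specimen_ids": [r.specimen_id for r in model.records],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path, lib: ReferenceLibrary) -> ProtaxModel:
    """Rebuild a model from JSON plus the reference library it was trained on."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format {payload['format_version']}")
    tree, records = build_taxonomy(lib)
    ids = [r.specimen_id for r in records]
    if ids != payload["specimen_ids"]:
        raise ValueError("library does not match the one the model was trained on")
    seqs = [r.sequence for r in records]
    D = pairwise_p_matrix(seqs, min_overlap=payload["min_overlap"])
    levels = [
        LevelModel(
            np.asarray(lv["beta"]),
            Scaler(np.asarray(lv["scaler_mean"]), np.asarray(lv["scaler_sd"])),
        )
        for lv in payload["levels"]
    ]
    return ProtaxModel(
        tree=tree, levels=levels, records=records, seqs=seqs, D=D,
        traces=[], log_posts=[], acceptance=payload["acceptance"],
        n_floored=payload["n_floored"], seed=payload["seed"],
        min_overlap=payload["min_overlap"],
    )
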