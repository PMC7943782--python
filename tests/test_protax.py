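import math

import numpy as np
import pandas as pd
import pytest

from barcodelib import protax as px
from barcodelib.io import ReferenceLibrary, SpecimenRecord

L = 658
BASE = "ACGT" * 164 + "AC"


def mutate(base, positions):
    s = list(base)
    for p in positions:
        s[p] = "T" if s[p] != "T" else "A"
    return "".join(s)


def toy_library(spec):
    """spec: list of (family, subfamily, genus, species, [sequences])."""
    recs = []
    for fam, sub, gen, sp, seqs in spec:
        for i, s in enumerate(seqs):
            recs.append(SpecimenRecord(f"{sp}_{i}", fam, sub, gen, sp, 40.0, 5.0, s))
    return ReferenceLibrary(recs, L=L)


@pytest.fixture(scope="module")
def separable_library():
    """Two well-separated species in one genus (levels 1-3 are unary)."""
    a = BASE
    b = mutate(BASE, range(0, 40, 2))  # 20 substitutions away
    return toy_library(
        [
            ("F", "S", "G", "G_spA", [a, mutate(a, [600]), a, a, mutate(a, [601])]),
            ("F", "S", "G", "G_spB", [b, b, mutate(b, [600]), b, mutate(b, [603])]),
        ]
    )


class TestNodeProbabilities:
    def test_zero_beta_is_uniform(self):
        p = px.node_probabilities(np.zeros(3), np.zeros((4, 2)))
        assert np.allclose(p, 0.25)

    def test_single_candidate_gets_probability_one(self):
        assert px.node_probabilities(np.array([1.0, -3.0, 2.0]), np.zeros((1, 2)))[0] == 1.0

    def test_hand_computed_softmax(self):
        beta = np.array([0.0, -5.0, 0.0])
        X = np.array([[-2.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
        p = px.node_probabilities(beta, X)
        expected = math.exp(10) / (math.exp(10) + 2)
        assert p[0] == pytest.approx(expected, rel=1e-12)
        assert p.sum() == pytest.approx(1.0)


class TestTrainingSet:
    def test_two_species_genus_gives_two_candidates_each(self, separable_library):
        tree, records = px.build_taxonomy(separable_library)
        D = px.pairwise_p_matrix([r.sequence for r in records])
        ts = px.build_training_set(tree, records, D)
        species_level = ts[3]
        assert species_level.X.shape == (10, 2, 2)
        assert species_level.mask.all()
        assert (species_level.y >= 0).all()
        assert species_level.n_floored == 0

    def test_singleton_species_label_unreachable(self):
        lib = toy_library(
            [
                ("F", "S", "G", "G_spA", [BASE, BASE, mutate(BASE, [5])]),
                ("F", "S", "G", "G_spB", [mutate(BASE, range(20))]),  # singleton
            ]
        )
        tree, records = px.build_taxonomy(lib)
        D = px.pairwise_p_matrix([r.sequence for r in records])
        ts = px.build_training_set(tree, records, D)
        assert ts[3].n_floored == 1  # the singleton's own record

    def test_duplicate_haplotype_zeroes_own_species_dmin(self, separable_library):
        tree, records = px.build_taxonomy(separable_library)
        D = px.pairwise_p_matrix([r.sequence for r in records])
        ts = px.build_training_set(tree, records, D)
        lvl = ts[3]
        i = 0  # G_spA_0 shares its haplotype with records 2 and 3
        assert lvl.X[i, lvl.y[i], 0] == 0.0

    def test_standardization_uses_training_statistics(self, separable_library):
        tree, records = px.build_taxonomy(separable_library)
        D = px.pairwise_p_matrix([r.sequence for r in records])
        lvl = px.build_training_set(tree, records, D)[3]
        std = lvl.standardized()[lvl.mask]
        assert np.allclose(std.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(std.std(axis=0), 1.0, atol=1e-6)


class TestLogPosterior:
    def make_ts(self, X, y):
        X = np.asarray(X, dtype=float)
        mask = np.ones(X.shape[:2], dtype=bool)
        scaler = px.Scaler(np.zeros(2), np.ones(2))
        return px.LevelTrainingSet(X, mask, np.asarray(y), scaler)

    def test_zero_beta_two_candidates(self):
        ts = self.make_ts([[[0.1, 0.2], [0.3, 0.4]]], [0])
        prior_const = -3 * 0.5 * math.log(2 * math.pi * 100**2)
        assert px.log_posterior(np.zeros(3), ts) == pytest.approx(
            math.log(0.5) + prior_const
        )

    def test_duplicated_record_doubles_likelihood(self):
        row = [[0.0, 0.1], [0.5, 0.6]]
        beta = np.array([0.2, -1.0, 0.5])
        single = px.level_log_likelihood(beta, self.make_ts([row], [0]))
        double = px.level_log_likelihood(beta, self.make_ts([row, row], [0, 0]))
        assert double == pytest.approx(2 * single)

    def test_gradient_matches_finite_differences(self, rng):
        X = rng.normal(size=(6, 3, 2))
        y = rng.integers(0, 3, size=6)
        ts = self.make_ts(X, y)
        beta = rng.normal(size=3)
        eps = 1e-6
        for i in range(3):
            e = np.zeros(3)
            e[i] = eps
            num = (px.log_posterior(beta + e, ts) - px.log_posterior(beta - e, ts)) / (2 * eps)
            # analytic gradient via the softmax form
            Xs = ts.standardized()
            scores = beta[0] + Xs @ beta[1:]
            p = np.exp(scores - scores.max(axis=1, keepdims=True))
            p /= p.sum(axis=1, keepdims=True)
            feats = np.concatenate([np.ones((6, 3, 1)), Xs], axis=2)
            rows = np.arange(6)
            grad = (feats[rows, y] - (p[:, :, None] * feats).sum(axis=1)).sum(axis=0)
            grad -= beta / 100**2
            assert num == pytest.approx(grad[i], rel=1e-4, abs=1e-5)

    def test_unreachable_record_contributes_floor(self):
        ts = self.make_ts([[[0.1, 0.2], [0.3, 0.4]]], [-1])
        ll = px.level_log_likelihood(np.zeros(3), ts)
        assert ll == pytest.approx(px.LOG_FLOOR)


class TestMCMC:
    def test_same_seed_identical_trace(self, separable_library):
        m1 = px.train(separable_library, iters=60, adapt_iters=60, seed=9)
        m2 = px.train(separable_library, iters=60, adapt_iters=60, seed=9)
        for t1, t2 in zip(m1.traces, m2.traces):
            assert np.array_equal(t1, t2)

    def test_separable_toy_reaches_high_correct_probability(self, separable_library):
        model = px.train(separable_library, seed=2)
        loo = px.leave_one_out(model)
        assert (loo["p_true"] > 0.99).all()


class TestClassify:
    def test_probability_conservation_and_path_decay(self, trained_model):
        res = px.classify(trained_model, query_index=10)
        total = sum(res.species_probs.values()) + res.unassigned
        assert total == pytest.approx(1.0, abs=1e-9)
        tree = trained_model.tree
        for sp, p in res.species_probs.items():
            path = tree.paths[sp]
            probs = [res.taxon_probs[t] for t in path]
            assert probs[-1] == pytest.approx(p)
            # monotone decay from root (prob 1) down the path
            assert all(probs[i] >= probs[i + 1] - 1e-12 for i in range(len(probs) - 1))
            assert probs[0] <= 1.0 + 1e-12

    def test_query_matching_isolated_species_is_near_certain(
        self, trained_model, identification_dataset
    ):
        sp = "Fam4_Sub2_Gen2_sp2"
        seq = identification_dataset.truth[sp].haplotype_sequences[0]
        res = px.classify(trained_model, query_sequence=seq)
        assert res.probability(sp) > 0.999
        assert res.top_species == sp

    def test_leave_one_out_singleton_probability_exactly_zero(self, loo_results):
        singles = loo_results[loo_results["singleton"]]
        assert len(singles) == 1
        assert (singles["p_true"] == 0.0).all()

    def test_unassignable_query_reports_full_mass(self, trained_model):
        res = px.classify(trained_model, query_sequence="N" * L)
        assert res.unassigned == 1.0 and res.top_species is None


class TestSpeciesAverages:
    def test_simple_means(self):
        loo = pd.DataFrame(
            {
                "species": ["a", "a", "b"],
                "p_true": [1.0, 0.5, 1.0],
                "singleton": [False, False, False],
            }
        )
        per, weighted = px.species_average_probability(loo)
        assert per["a"] == pytest.approx(0.75)
        assert weighted == pytest.approx((1.0 + 0.5 + 1.0) / 3)

    def test_only_introgressed_pair_falls_below_one(self, loo_results):
        per, _ = px.species_average_probability(loo_results)
        below = set(per[per < 0.999].index)
        assert below == {"Fam2_Sub1_Gen1_sp1", "Fam2_Sub1_Gen1_sp2"}

    def test_more_introgressed_haplotypes_lower_victim_mean(self):
        """d_avg carries haplotype frequency: a heavier introgressed share
        drags the recipient species' mean correct probability further down."""
        from barcodelib.simulate import SyntheticConfig, generate_dataset

        means = []
        for n_intro in (2, 8):
            cfg = SyntheticConfig(
                seed=1, constant_n=20,
                introgression_pairs=[("Fam2_Sub1_Gen1_sp1", "Fam2_Sub1_Gen1_sp2", n_intro)],
            )
            ds = generate_dataset(cfg)
            model = px.train(ds.library, seed=5)
            per, _ = px.species_average_probability(px.leave_one_out(model))
            means.append(per["Fam2_Sub1_Gen1_sp2"])
        assert means[1] < means[0]


class TestSerialization:
    def test_save_load_round_trip(self, trained_model, identification_dataset, tmp_path):
        path = tmp_path / "model.json"
        px.save_model(trained_model, path)
        loaded = px.load_model(path, identification_dataset.library)
        a = px.classify(trained_model, query_index=3)
        b = px.classify(loaded, query_index=3)
        assert a.species_probs == b.species_probs

    def test_mismatched_library_rejected(self, trained_model, separable_library, tmp_path):
        path = tmp_path / "model.json"
        px.save_model(trained_model, path)
        with pytest.raises(ValueError, match="does not match"):
            px.load_model(path, separable_library)
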