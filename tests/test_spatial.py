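import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from barcodelib import spatial as sp
from barcodelib.diversity import collapse_haplotypes, rarefied_richness
from barcodelib.io import ReferenceLibrary, SpecimenRecord

L = 40
BASE = "ACGT" * 10


def record(sid, sp_name, lat, lon=5.0, seq=BASE):
    return SpecimenRecord(sid, "F", "S", "G", sp_name, lat, lon, seq)


def mutate(base, positions):
    s = list(base)
    for p in positions:
        s[p] = "T" if s[p] != "T" else "A"
    return "".join(s)


class TestBelts:
    def test_default_latitude_grid_has_71_centers(self):
        lib = ReferenceLibrary([record("a", "G_sp", 40.0)], L=L)
        belts = sp.make_belts(lib)
        assert len(belts) == 71
        assert belts[0].center == 35.0 and belts[-1].center == 70.0

    def test_membership_window(self):
        lib = ReferenceLibrary([record("a", "G_sp", 40.2)], L=L)
        belts = sp.make_belts(lib)
        members = [b.center for b in belts if len(b.member_idx)]
        assert members == [39.5, 40.0, 40.5, 41.0]

    def test_boundary_is_closed(self):
        lib = ReferenceLibrary([record("a", "G_sp", 41.0)], L=L)
        belts = sp.make_belts(lib)
        assert any(b.center == 40.0 and len(b.member_idx) for b in belts)

    def test_every_in_range_specimen_in_at_least_one_belt(self, default_dataset):
        belts = sp.make_belts(default_dataset.library)
        covered = set(itertools.chain.from_iterable(b.member_idx for b in belts))
        records = list(default_dataset.library)
        in_range = {
            i for i, r in enumerate(records) if 34.0 <= r.latitude <= 71.0
        }
        assert in_range <= covered


class TestBeltRichness:
    def toy_two_belt_library(self):
        # species present near 40 (n=6) and near 50 (n=10), fixed haplotypes
        seqs_a = [BASE, BASE, BASE, mutate(BASE, [1]), mutate(BASE, [2]), BASE]
        seqs_b = [BASE] * 6 + [mutate(BASE, [1])] * 3 + [mutate(BASE, [3])]
        recs = [record(f"a{i}", "G_sp", 40.0, seq=s) for i, s in enumerate(seqs_a)]
        recs += [record(f"b{i}", "G_sp", 50.0, seq=s) for i, s in enumerate(seqs_b)]
        return ReferenceLibrary(recs, L=L), seqs_a, seqs_b

    def test_single_belt_species_extrapolated_equals_observed(self):
        seqs = [BASE, mutate(BASE, [1]), mutate(BASE, [2])] * 2
        recs = [record(f"x{i}", "G_sp", 40.0, seq=s) for i, s in enumerate(seqs)]
        tab = sp.belt_species_table(ReferenceLibrary(recs, L=L))
        # the species appears with the same full sample in every covering belt
        assert (tab["richness_extrapolated"] == 3.0).all()

    def test_monomorphic_species_scores_one_everywhere(self):
        recs = [record(f"x{i}", "G_sp", 40.0 + i * 0.01) for i in range(12)]
        tab = sp.belt_species_table(ReferenceLibrary(recs, L=L))
        assert (tab["richness_extrapolated"] == 1.0).all()
        assert (tab["richness_subsampled"] == 1.0).all()

    def test_subsampled_matches_exhaustive_subset_mean(self):
        lib, seqs_a, seqs_b = self.toy_two_belt_library()
        tab = sp.belt_species_table(lib)
        row = tab[(tab.center == 50.0)].iloc[0]
        # oracle: mean distinct haplotypes over all 6-subsets of the 10
        labels = [0] * 6 + [1] * 3 + [2]
        values = [
            len({labels[i] for i in c})
            for c in itertools.combinations(range(10), 6)
        ]
        assert row["richness_subsampled"] == pytest.approx(np.mean(values), abs=1e-9)

    def test_sparse_belt_species_excluded(self):
        recs = [record(f"x{i}", "G_sp", 40.0) for i in range(5)]
        tab = sp.belt_species_table(ReferenceLibrary(recs, L=L))
        assert tab.empty

    def test_subsampling_standardization_converges_under_duplication(self):
        # at fixed m << n the expected rarefied richness depends only on
        # haplotype composition in the many-specimen limit: proportional
        # duplication moves it less and less as n grows
        tables = [
            collapse_haplotypes(
                [BASE] * (6 * f) + [mutate(BASE, [1])] * (3 * f), species="x"
            )
            for f in (1, 10, 100)
        ]
        vals = [rarefied_richness(t, 3) for t in tables]
        multinomial_limit = 2 - (2 / 3) ** 3 - (1 / 3) ** 3  # composition-only form
        gaps = [abs(v - multinomial_limit) for v in vals]
        assert gaps[0] > gaps[1] > gaps[2]
        assert vals[2] == pytest.approx(multinomial_limit, rel=0.005)


class TestGeographicDistances:
    def test_coincident_points_have_zero_distance(self):
        assert sp.mean_pairwise_km([40, 40], [5, 5]) == 0.0

    def test_one_degree_meridian_arc(self):
        expected = 6371.0 * math.pi / 180
        assert sp.haversine_km(40.0, 5.0, 41.0, 5.0) == pytest.approx(expected, abs=0.01)
        assert expected == pytest.approx(111.19, abs=0.01)

    def test_three_points_match_brute_force(self, rng):
        lats = rng.uniform(35, 70, 3)
        lons = rng.uniform(-9, 36, 3)
        expected = np.mean(
            [
                sp.haversine_km(lats[i], lons[i], lats[j], lons[j])
                for i, j in itertools.combinations(range(3), 2)
            ]
        )
        assert sp.mean_pairwise_km(lats, lons) == pytest.approx(expected)

    def test_fewer_than_two_points_undefined(self):
        assert math.isnan(sp.mean_pairwise_km([40], [5]))


class TestLoess:
    def test_reproduces_linear_data_exactly(self, rng):
        x = np.linspace(0, 10, 40)
        y = 2.0 + 0.5 * x
        curve = sp.loess_curve(x, y, span=0.4, grid=x)
        assert np.allclose(curve.yhat, y, atol=1e-6)

    def test_full_span_on_quadratic_equals_global_fit(self):
        x = np.linspace(-3, 3, 25)
        y = 1.0 - 2.0 * x + 0.7 * x**2
        curve = sp.loess_curve(x, y, span=1.0, grid=x)
        coefs = np.polyfit(x, y, 2)
        assert np.allclose(curve.yhat, np.polyval(coefs, x), atol=1e-8)

    def test_peak_location_recovered(self, rng):
        x = np.linspace(0, 10, 80)
        y = np.exp(-((x - 6.2) ** 2) / 2) + rng.normal(0, 0.02, size=x.size)
        curve = sp.loess_curve(x, y, span=0.4)
        step = curve.grid[1] - curve.grid[0]
        assert abs(curve.argmax() - 6.2) <= max(step, x[1] - x[0]) + 0.1

    def test_too_small_span_errors(self):
        x = np.linspace(0, 1, 12)
        with pytest.raises(ValueError, match="span"):
            sp.loess_curve(x, x, span=0.1)

    def test_band_contains_truth_for_smooth_signal(self, rng):
        x = np.linspace(0, 10, 60)
        truth = np.sin(x / 2)
        y = truth + rng.normal(0, 0.05, size=x.size)
        curve = sp.loess_curve(x, y, span=0.5, grid=x)
        lo, hi = curve.band
        inside = np.mean((truth >= lo) & (truth <= hi))
        assert inside > 0.8


class TestTrendFit:
    def null_records(self, rng, n_belts=40, n_species=8):
        rows = []
        for c in np.arange(36.0, 36.0 + 0.5 * n_belts, 0.5):
            for s in range(n_species):
                rows.append(
                    {
                        "center": c,
                        "species": f"sp{s}",
                        "richness_extrapolated": 5.0 + rng.normal(0, 0.5),
                        "richness_subsampled": 3.0,
                        "mean_km": rng.uniform(100, 900),
                    }
                )
        return pd.DataFrame(rows)

    def test_constant_response_smooth_not_significant(self, rng):
        tf = sp.fit_trend(self.null_records(rng))
        assert tf.smooth_p > 0.05
        assert abs(tf.distance_coef) < 2.5 * tf.distance_se

    def test_belt_means_mode_null(self, rng):
        tf = sp.fit_trend(self.null_records(rng), mode="belt-means")
        assert tf.smooth_p > 0.05

    def test_too_few_belts_error(self, rng):
        recs = self.null_records(rng).query("center < 39")
        with pytest.raises(ValueError, match="12 belts"):
            sp.fit_trend(recs)

    def test_peaked_gradient_detected(self, spatial_dataset):
        tab = sp.belt_species_table(spatial_dataset.library)
        tf = sp.fit_trend(tab)
        assert tf.smooth_p < 0.05

    def test_richness_declines_north_of_peak(self, spatial_dataset):
        tab = sp.belt_species_table(spatial_dataset.library)
        means = sp.belt_summary(tab)
        north = means[means.center > 43.5]
        rho, p = sps.spearmanr(north["center"], north["richness_extrapolated"])
        assert rho < 0 and p < 0.05


class TestSubsample:
    def lib(self):
        recs = [record(f"x{i}", "G_sp", 40.1 + 0.001 * i) for i in range(20)]
        recs += [record(f"y{i}", "G_sp", 55.3) for i in range(4)]
        return ReferenceLibrary(recs, L=L)

    def test_generous_cap_is_identity(self):
        out = sp.spatial_subsample(self.lib(), seed=0, cap=50)
        assert len(out) == 24

    def test_cap_enforced_exactly(self):
        out = sp.spatial_subsample(self.lib(), seed=0, cap=5)
        dense = [r for r in out if r.latitude < 41]
        assert len(dense) == 5 and len(out) == 9

    def test_same_seed_same_subset(self):
        a = sp.spatial_subsample(self.lib(), seed=3, cap=5)
        b = sp.spatial_subsample(self.lib(), seed=3, cap=5)
        assert a.records == b.records
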