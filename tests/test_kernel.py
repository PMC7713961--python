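import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sporekernel import (
    DispersalKernel,
    IngestionWindow,
    KernelSummary,
    across_animal_band,
    animal_kernel,
    kernel_max,
    logistic_cdf,
    mix_kernels,
    overall_kernel,
    window_kernel,
)
from sporekernel.kernel import KernelError

from conftest import EPOCH, gut_results


def make_window(offsets, distances, animal="a1", period="p1"):
    return IngestionWindow(animal, period, EPOCH,
                           np.asarray(offsets, float), np.asarray(distances, float))


def uniform_kernel(support):
    support = np.asarray(support, float)
    return DispersalKernel(support, np.full(support.size, 1.0 / support.size))


class TestDispersalKernel:
    def test_masses_must_sum_to_one(self):
        with pytest.raises(KernelError, match="sum"):
            DispersalKernel([1.0, 2.0], [0.5, 0.6])

    def test_negative_mass_rejected(self):
        with pytest.raises(KernelError):
            DispersalKernel([1.0, 2.0], [1.5, -0.5])

    def test_point_mass_quantiles(self):
        k = DispersalKernel.point_mass(42.0)
        for q in (0.01, 0.25, 0.5, 0.95, 0.99):
            assert k.quantile(q) == 42.0

    def test_uniform_support_quantile(self):
        k = uniform_kernel(np.arange(10.0, 101.0, 10.0))
        assert k.quantile(0.25) == 30.0
        assert k.quantile(0.5) == 50.0

    @settings(derandomize=True, max_examples=30)
    @given(qs=st.lists(st.floats(0.01, 0.99), min_size=2, max_size=6))
    def test_quantiles_nondecreasing(self, qs):
        rng = np.random.default_rng(0)
        mass = rng.dirichlet(np.ones(20))
        k = DispersalKernel(rng.uniform(0, 500, 20), mass)
        qs = sorted(qs)
        vals = [k.quantile(q) for q in qs]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_cdf_and_quantile_agree(self):
        k = uniform_kernel([0.0, 10.0, 20.0, 30.0])
        assert k.cdf(10.0) == pytest.approx(0.5)
        assert k.cdf(9.99) == pytest.approx(0.25)
        assert k.cdf(-1.0) == 0.0

    def test_binned_density_sums_to_one(self):
        rng = np.random.default_rng(1)
        k = DispersalKernel(rng.uniform(0, 1000, 50), rng.dirichlet(np.ones(50)))
        d = k.binned_density(25.0)
        assert d["probability"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_point_mass_in_first_bin(self):
        d = DispersalKernel.point_mass(0.0).binned_density(40.0)
        assert d["probability"].iloc[0] == pytest.approx(1.0)

    def test_refined_bins_reaggregate_to_coarse(self):
        rng = np.random.default_rng(2)
        k = DispersalKernel(rng.uniform(0, 300, 40), rng.dirichlet(np.ones(40)))
        coarse = k.binned_density(50.0)["probability"].to_numpy()
        fine = k.binned_density(25.0)["probability"].to_numpy()
        if fine.size % 2:
            fine = np.append(fine, 0.0)
        assert fine.reshape(-1, 2).sum(axis=1) == pytest.approx(coarse, abs=1e-12)

    def test_csv_round_trip_preserves_mass(self, tmp_path):
        rng = np.random.default_rng(3)
        k = DispersalKernel(rng.uniform(0, 100, 30), rng.dirichlet(np.ones(30)))
        path = tmp_path / "k.csv"
        k.to_csv(path)
        back = DispersalKernel.from_csv(path)
        assert back.support == pytest.approx(k.support, abs=1e-12)
        assert back.mass == pytest.approx(k.mass, abs=1e-12)


class TestMixKernels:
    def test_self_mixture_has_identical_cdf(self):
        k = uniform_kernel([5.0, 10.0, 15.0])
        mixed = mix_kernels([k, k])
        grid = np.linspace(0, 20, 50)
        assert mixed.cdf(grid) == pytest.approx(k.cdf(grid), abs=1e-12)

    def test_two_point_masses_jump_half_each(self):
        mixed = mix_kernels([DispersalKernel.point_mass(0.0),
                             DispersalKernel.point_mass(100.0)])
        assert mixed.cdf(0.0) == pytest.approx(0.5)
        assert mixed.cdf(100.0) == pytest.approx(1.0)

    def test_median_of_three_point_masses(self):
        mixed = mix_kernels([DispersalKernel.point_mass(d) for d in (10, 20, 30)])
        assert mixed.quantile(0.5) == 20.0

    def test_weight_count_mismatch_rejected(self):
        with pytest.raises(KernelError, match="count"):
            mix_kernels([DispersalKernel.point_mass(1.0)], weights=[0.5, 0.5])


class TestWindowKernel:
    def test_stationary_window_is_point_mass_at_zero(self, gut30_6):
        w = make_window(np.arange(0.0, 70.0), np.zeros(70))
        k = window_kernel(w, gut30_6)
        assert k.quantile(0.5) == 0.0
        assert k.max_distance() == 0.0

    def test_single_fix_window_is_point_mass_at_zero(self, gut30_6):
        k = window_kernel(make_window([0.0], [0.0]), gut30_6)
        assert len(k) == 1 and k.support[0] == 0.0 and k.mass[0] == 1.0

    def test_constant_velocity_mass_matches_weight_composition(self, gut30_6):
        v = 100.0
        offsets = np.arange(0.0, 70.0)
        k = window_kernel(make_window(offsets, v * offsets), gut30_6)
        c = lambda t: logistic_cdf(t, 30.0, 6.0)
        expected = (c(30.0) - c(29.0)) / (c(69.0) - c(0.0))
        at_3000 = k.mass[np.searchsorted(k.support, 3000.0)]
        assert at_3000 == pytest.approx(expected, rel=1e-12)


class TestAggregation:
    def test_one_window_two_identical_models_equals_window_kernel(self, gut30_6):
        w = make_window([0.0, 10.0, 20.0], [0.0, 50.0, 120.0])
        single = window_kernel(w, gut30_6)
        both = animal_kernel([w], [gut30_6, gut30_6])
        grid = np.linspace(0, 150, 40)
        assert both.cdf(grid) == pytest.approx(single.cdf(grid), abs=1e-12)

    def test_disjoint_point_mass_windows_mix_evenly(self, gut30_6):
        w1 = make_window([0.0], [0.0], period="p1")
        w2 = make_window([0.0], [0.0], period="p2")
        k1 = window_kernel(w1, gut30_6)
        k2 = DispersalKernel.point_mass(500.0)
        mixed = mix_kernels([k1, k2])
        assert mixed.cdf(0.0) == pytest.approx(0.5)
        assert mixed.cdf(500.0) == pytest.approx(1.0)

    def test_overall_single_animal_is_identity(self):
        k = uniform_kernel([1.0, 2.0, 3.0])
        o = overall_kernel([k])
        assert o.cdf([1.0, 2.0, 3.0]) == pytest.approx(k.cdf([1.0, 2.0, 3.0]))

    def test_overall_two_point_animals_lower_median(self):
        o = overall_kernel([DispersalKernel.point_mass(0.0),
                            DispersalKernel.point_mass(1000.0)])
        # lower weighted-empirical convention: smallest d with CDF >= 0.5
        assert o.quantile(0.5) == 0.0

    def test_mass_conserved_through_aggregation(self, gut30_6):
        rng = np.random.default_rng(7)
        animals = []
        for a in range(4):
            wins = []
            for p in range(3):
                offsets = np.sort(rng.uniform(0.1, 69.0, 20))
                offsets = np.concatenate(([0.0], offsets))
                dists = np.concatenate(([0.0], rng.uniform(0, 800, 20)))
                wins.append(make_window(offsets, dists, animal=f"a{a}", period=f"p{p}"))
            animals.append(animal_kernel(wins, [gut30_6, gut_results(24, 5)]))
        o = overall_kernel(animals)
        for k in animals + [o]:
            assert abs(float(k.mass.sum()) - 1.0) < 1e-9

    def test_exchangeability(self, gut30_6):
        rng = np.random.default_rng(11)
        wins = []
        for p in range(5):
            offsets = np.concatenate(([0.0], np.sort(rng.uniform(0.1, 69.0, 10))))
            dists = np.concatenate(([0.0], rng.uniform(0, 500, 10)))
            wins.append(make_window(offsets, dists, period=f"p{p}"))
        a = animal_kernel(wins, [gut30_6])
        b = animal_kernel(wins[::-1], [gut30_6])
        grid = np.linspace(0, 600, 100)
        assert a.cdf(grid) == pytest.approx(b.cdf(grid), abs=1e-12)

    def test_scale_equivariance(self, gut30_6):
        offsets = np.arange(0.0, 69.5, 0.5)
        dists = np.abs(np.sin(offsets)) * 300.0
        dists[0] = 0.0
        k1 = window_kernel(make_window(offsets, dists), gut30_6)
        k3 = window_kernel(make_window(offsets, 3.0 * dists), gut30_6)
        for q in (0.25, 0.5, 0.75, 0.95):
            assert k3.quantile(q) == pytest.approx(3.0 * k1.quantile(q), rel=1e-12)


class TestKernelMax:
    def test_all_stationary_is_zero(self, gut30_6):
        ks = [window_kernel(make_window(np.arange(0.0, 70.0), np.zeros(70)), gut30_6)
              for _ in range(3)]
        assert kernel_max(ks) == 0.0

    def test_positive_weight_reach_counts(self):
        k = DispersalKernel([0.0, 500.0], [1.0 - 1e-6, 1e-6])
        assert kernel_max([k]) == 500.0

    def test_equals_brute_force_over_support(self):
        rng = np.random.default_rng(13)
        ks = [DispersalKernel(rng.uniform(0, 900, 15), rng.dirichlet(np.ones(15)))
              for _ in range(10)]
        brute = max(float(k.support[k.mass > 0].max()) for k in ks)
        assert kernel_max(ks) == pytest.approx(brute)


class TestBandAndSummary:
    def test_identical_animals_give_zero_width_band(self):
        k = uniform_kernel([10.0, 60.0, 110.0])
        band = across_animal_band([k, k, k], bin_width=50.0)
        assert band["lower"].to_numpy() == pytest.approx(band["upper"].to_numpy())
        assert band["mean"].to_numpy() == pytest.approx(band["lower"].to_numpy())

    def test_band_brackets_mean(self):
        rng = np.random.default_rng(17)
        ks = [DispersalKernel(rng.uniform(0, 400, 25), rng.dirichlet(np.ones(25)))
              for _ in range(5)]
        band = across_animal_band(ks)
        assert np.all(band["lower"] <= band["mean"] + 1e-12)
        assert np.all(band["mean"] <= band["upper"] + 1e-12)

    def test_two_animals_band_spans_both(self):
        k1 = DispersalKernel.point_mass(10.0)
        k2 = uniform_kernel([10.0, 60.0])
        band = across_animal_band([k1, k2], bin_width=50.0)
        # bin 0 probabilities are 1.0 and 0.5; the band must cover both
        assert band["lower"].iloc[0] == pytest.approx(0.5)
        assert band["upper"].iloc[0] == pytest.approx(1.0)

    def test_summary_rejects_decreasing_quantiles(self):
        with pytest.raises(KernelError):
            KernelSummary(quantiles={0.25: 50.0, 0.5: 10.0},
                          max_distance=100.0, n_windows=1, n_animals=1)
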