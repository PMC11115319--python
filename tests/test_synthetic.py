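"""Synthetic stimulus / ground-truth generator contracts."""

import numpy as np
import pytest
from scipy import stats as sps

import pointreadout as pr


class TestGenerateImages:
    def test_seeded_determinism(self):
        a = pr.generate_images(10, size=64, seed=7)
        b = pr.generate_images(10, size=64, seed=7)
        np.testing.assert_array_equal(a.images, b.images)

    def test_eight_bit_range_and_shape(self):
        out = pr.generate_images(100, size=64, seed=3)
        assert out.images.shape == (100, 64, 64)
        assert out.images.dtype == np.uint8
        assert out.images.min() >= 0 and out.images.max() <= 255

    @pytest.mark.parametrize("n,size", [(0, 64), (5, 8)])
    def test_invalid_arguments(self, n, size):
        with pytest.raises(ValueError):
            pr.generate_images(n, size=size)

    def test_broadband_content(self):
        # images should not be flat: appreciable within-image contrast
        out = pr.generate_images(5, size=64, seed=1)
        assert (out.images.std(axis=(1, 2)) > 10).all()


class TestMakePopulation:
    def test_full_density_weights(self, tiny_core):
        pop = pr.make_population(tiny_core, 10, weight_sparsity=1.0, seed=0)
        assert all((n.weights != 0).all() for n in pop)

    def test_sparsity_within_binomial_bounds(self, tiny_core):
        # 50 neurons x 2 channels is too small; use a wider bank
        core = pr.GaborBankCore(n_orientations=4, frequencies=(0.1, 0.2),
                                phases=(0.0, np.pi / 2))
        pop = pr.make_population(core, 50, weight_sparsity=0.2, seed=4)
        nonzero = sum(int((n.weights != 0).sum()) for n in pop)
        total = 50 * core.channels
        lo, hi = sps.binom.ppf([0.005, 0.995], total, 0.2)
        assert lo <= nonzero <= hi

    def test_positions_inside_map(self, tiny_core):
        for seed in range(3):
            pop = pr.make_population(tiny_core, 30, seed=seed)
            positions = np.stack([n.position for n in pop])
            assert (np.abs(positions) <= 1).all()

    def test_invalid_sparsity(self, tiny_core):
        with pytest.raises(ValueError):
            pr.make_population(tiny_core, 5, weight_sparsity=0.0)


class TestSimulateResponses:
    def test_rate_is_gain_when_weights_and_bias_zero(self, tiny_core, tiny_images):
        # ELU(0) + 1 = 1, so the rate collapses to the gain exactly
        pop = pr.make_population(tiny_core, 4, weight_sparsity=1.0, gain=3.0,
                                 weight_scale=2.0, seed=0)
        for n in pop.neurons:
            n.weights[:] = 0.0
            n.bias = 0.0
        rates = pop.rates(tiny_images)
        np.testing.assert_allclose(rates, 3.0)

    def test_poisson_mean_equals_variance(self, tiny_core, tiny_images):
        # fixed rate 5.0 via zero weights, gain 5
        pop = pr.make_population(tiny_core, 1, gain=5.0, seed=0)
        pop.neurons[0].weights[:] = 0.0
        pop.neurons[0].bias = 0.0
        counts = pr.simulate_responses(pop, tiny_images[:1], repeats=10_000, seed=9)
        sample = counts[0, :, 0]
        assert sample.mean() == pytest.approx(5.0, abs=0.15)
        assert sample.var(ddof=1) == pytest.approx(5.0, abs=0.3)

    def test_singleton_repeat_axis(self, tiny_core, tiny_images):
        pop = pr.make_population(tiny_core, 3, seed=0)
        counts = pr.simulate_responses(pop, tiny_images, repeats=1, seed=1)
        assert counts.shape == (len(tiny_images), 1, 3)

    def test_rates_strictly_positive(self, tiny_core, tiny_images):
        pop = pr.make_population(tiny_core, 20, seed=2)
        assert (pop.rates(tiny_images) > 0).all()


class TestAssembleAreaDataset:
    def test_shared_test_set_and_split_sizes(self):
        sessions = pr.assemble_area_dataset(
            n_sessions=2, images_per_session=50, neurons_per_session=4,
            n_test_images=20, test_repeats=5, seed=0)
        assert len(sessions) == 2
        np.testing.assert_array_equal(sessions[0].test_images,
                                      sessions[1].test_images)
        assert len(np.unique(sessions[0].test_images, axis=0)) == 20
        # 20% validation split
        assert sessions[0].validation_counts.shape[0] == 10
        assert sessions[0].train_counts.shape[0] == 40

    def test_sessions_draw_distinct_train_images(self):
        sessions = pr.assemble_area_dataset(
            n_sessions=2, images_per_session=40, neurons_per_session=3,
            n_test_images=10, test_repeats=4, seed=1)
        ids0 = set(sessions[0].train_image_ids)
        ids1 = set(sessions[1].train_image_ids)
        assert not ids0 & ids1

    def test_pool_exhaustion_raises(self):
        with pytest.raises(ValueError):
            pr.assemble_area_dataset(
                n_sessions=2, images_per_session=100, neurons_per_session=3,
                n_test_images=10, test_repeats=4, seed=0, pool_size=50)

    def test_ev_increases_with_gain(self, tmp_path):
        """Signal-to-noise (hence EV) rises monotonically along a gain grid."""
        evs = []
        for gain in (0.5, 2.0, 8.0):
            sessions = pr.assemble_area_dataset(
                n_sessions=1, images_per_session=30, neurons_per_session=6,
                n_test_images=40, test_repeats=30, seed=3, gain=gain)
            evs.append(np.nanmedian(
                pr.explainable_variance_ratio(sessions[0].test_counts)))
        assert evs[0] < evs[1] < evs[2]

    def test_hdf5_roundtrip(self, tmp_path):
        sessions = pr.assemble_area_dataset(
            n_sessions=2, images_per_session=30, neurons_per_session=3,
            n_test_images=8, test_repeats=3, seed=5)
        path = tmp_path / "area.h5"
        pr.save_dataset(sessions, path, attrs={"seed": 5})
        loaded = pr.load_dataset(path)
        assert len(loaded) == 2
        for a, b in zip(sessions, loaded):
            np.testing.assert_array_equal(a.train_counts, b.train_counts)
            np.testing.assert_array_equal(a.test_counts, b.test_counts)
            np.testing.assert_array_equal(a.train_images, b.train_images)
            assert a.neuron_ids == b.neuron_ids
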