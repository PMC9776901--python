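"""RBM energies and conditionals against brute-force enumeration; CD training."""

import itertools

import numpy as np
import pytest

from neurotask.dbn import (
    DBNModel,
    RBMParams,
    TrainConfig,
    cd_update,
    dbn_transform,
    load_dbn,
    prob_h_given_v,
    prob_v_given_h,
    rbm_energy,
    reconstruction_error,
    save_dbn,
    train_dbn,
    train_rbm,
)


def enumerate_joint(rbm: RBMParams):
    """Brute-force Boltzmann joint over all binary configurations."""
    m, n = rbm.n_visible, rbm.n_hidden
    configs, weights = [], []
    for v in itertools.product([0, 1], repeat=m):
        for h in itertools.product([0, 1], repeat=n):
            v_arr, h_arr = np.array(v, float), np.array(h, float)
            configs.append((v_arr, h_arr))
            weights.append(np.exp(-rbm_energy(v_arr, h_arr, rbm)))
    weights = np.array(weights)
    return configs, weights / weights.sum()


def exact_log_likelihood(rbm: RBMParams, data: np.ndarray) -> float:
    """Exact log P(v) summed over rows via the brute-force partition function."""
    configs, probs = enumerate_joint(rbm)
    ll = 0.0
    for row in data:
        p_v = sum(p for (v, _), p in zip(configs, probs)
                  if np.array_equal(v, row))
        ll += np.log(p_v)
    return ll


@pytest.fixture
def tiny_rbm(rng):
    return RBMParams(rng.normal(0, 1.0, (2, 2)), rng.normal(0, 1.0, 2),
                     rng.normal(0, 1.0, 2))


class TestEnergyAndConditionals:
    def test_energy_hand_values(self):
        rbm = RBMParams(np.array([[2.0]]), np.zeros(1), np.zeros(1))
        assert rbm_energy(np.array([1.0]), np.array([1.0]), rbm) == -2.0
        zero = RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        assert rbm_energy(np.ones(3), np.ones(2), zero) == 0.0

    def test_joint_normalizes(self, tiny_rbm):
        _, probs = enumerate_joint(tiny_rbm)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_factorized_conditionals_match_joint(self, tiny_rbm):
        configs, probs = enumerate_joint(tiny_rbm)
        for v_fix in itertools.product([0, 1], repeat=2):
            v_fix = np.array(v_fix, float)
            mask = [np.array_equal(v, v_fix) for v, _ in configs]
            p_slice = probs[mask]
            p_slice = p_slice / p_slice.sum()
            hs = [h for (v, h), m in zip(configs, mask) if m]
            means = prob_h_given_v(tiny_rbm, v_fix)
            for h, p in zip(hs, p_slice):
                factorized = np.prod(np.where(h == 1, means, 1 - means))
                assert factorized == pytest.approx(p, abs=1e-10)

    def test_zero_parameters_give_half(self):
        rbm = RBMParams(np.zeros((4, 3)), np.zeros(4), np.zeros(3))
        assert np.all(prob_h_given_v(rbm, np.ones(4)) == 0.5)
        assert np.all(prob_v_given_h(rbm, np.ones(3)) == 0.5)

    def test_saturation_without_overflow(self):
        rbm = RBMParams(np.array([[40.0]]), np.zeros(1), np.zeros(1))
        p = prob_h_given_v(rbm, np.array([1.0]))
        assert p[0] >= 1 - 1e-12
        low = prob_h_given_v(rbm, np.array([-1.0]))
        assert low[0] <= 1e-12

    def test_transpose_symmetry(self, tiny_rbm):
        flipped = RBMParams(tiny_rbm.W.T, tiny_rbm.b_hid, tiny_rbm.b_vis)
        v = np.array([1.0, 0.0])
        assert np.allclose(prob_h_given_v(tiny_rbm, v),
                           prob_v_given_h(flipped, v))


class TestContrastiveDivergence:
    def test_zero_learning_rate_no_change(self, rng):
        rbm = RBMParams.initialize(4, 3, rng)
        cfg = TrainConfig(learning_rate=0.0, epochs=1, batch_size=2)
        new = cd_update(rbm, rng.random((2, 4)), cfg, rng)
        assert np.array_equal(new.W, rbm.W)
        assert np.array_equal(new.b_vis, rbm.b_vis)

    def test_empty_batch_rejected(self, rng):
        rbm = RBMParams.initialize(4, 3, rng)
        with pytest.raises(ValueError):
            cd_update(rbm, np.empty((0, 4)), TrainConfig(), rng)

    def test_training_reduces_reconstruction_error(self, rng):
        patterns = np.array([[1, 1, 0], [0, 0, 1]] * 10, dtype=float)
        cfg = TrainConfig(k_gibbs=5, learning_rate=0.1, epochs=500,
                          batch_size=20, seed=0)
        gen = np.random.default_rng(0)
        rbm0 = RBMParams.initialize(3, 2, gen)
        before = reconstruction_error(rbm0, patterns)
        rbm, log = train_rbm(patterns, 2, cfg, np.random.default_rng(0))
        assert reconstruction_error(rbm, patterns) < before
        assert len(log) == 500


class TestDBN:
    def test_architecture_contract(self, rng):
        data = rng.random((40, 30))
        model = train_dbn(data, (30, 15, 5), TrainConfig(epochs=1,
                                                         batch_size=40))
        assert [r.W.shape for r in model.rbms] == [(30, 15), (15, 5)]

    def test_zero_epochs_transform_well_defined(self, rng):
        data = rng.random((10, 6))
        model = train_dbn(data, (6, 4, 2), TrainConfig(epochs=0))
        latent = dbn_transform(model, data)
        assert latent.shape == (10, 2)
        assert np.all((latent > 0) & (latent < 1))

    def test_deterministic_given_seed(self, rng):
        data = rng.random((20, 8))
        cfg = TrainConfig(epochs=5, batch_size=10, seed=42)
        a = train_dbn(data, (8, 4, 2), cfg)
        b = train_dbn(data, (8, 4, 2), cfg)
        for ra, rb in zip(a.rbms, b.rbms):
            assert np.array_equal(ra.W, rb.W)

    def test_width_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            train_dbn(rng.random((10, 7)), (6, 3), TrainConfig(epochs=0))
        with pytest.raises(ValueError):
            DBNModel([RBMParams.initialize(6, 4, rng),
                      RBMParams.initialize(3, 2, rng)], [6, 4, 2])

    def test_zero_parameter_model_maps_to_half(self):
        model = DBNModel([RBMParams(np.zeros((4, 2)), np.zeros(4), np.zeros(2))],
                         [4, 2])
        latent = dbn_transform(model, np.eye(4))
        assert np.all(latent == 0.5)

    def test_transform_stateless_over_batches(self, rng):
        data = rng.random((12, 5))
        model = train_dbn(data, (5, 3), TrainConfig(epochs=2, batch_size=6,
                                                    seed=1))
        whole = dbn_transform(model, data)
        parts = np.vstack([dbn_transform(model, data[:5]),
                           dbn_transform(model, data[5:])])
        assert np.array_equal(whole, parts)

    def test_hdf5_round_trip(self, rng, tmp_path):
        data = rng.random((10, 6))
        model = train_dbn(data, (6, 4, 2), TrainConfig(epochs=1, seed=3))
        path = str(tmp_path / "dbn.h5")
        save_dbn(model, path)
        back = load_dbn(path)
        assert back.layer_sizes == [6, 4, 2]
        for ra, rb in zip(model.rbms, back.rbms):
            assert np.array_equal(ra.W, rb.W)
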