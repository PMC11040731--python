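"""Charge constraint, charge lift, and the long-range message block."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from conftest import random_structure
from qewald.autodiff import Tensor
from qewald.charge_ewald import (
    ChargeHead,
    FourierGrid,
    FullModelParams,
    ModelConfig,
    charge_embedding,
    direction_set,
    ewald_messages,
    full_forward,
    predict_raw_charges,
    predicted_charges,
    scale_charges,
)
from qewald.nnp_core import AtomEmbeddings, baseline_forward, embed
from qewald.structures import AtomicStructure


@pytest.fixture
def head(rng):
    return ChargeHead.init(rng, n_features=8, hidden=6)


class TestRawCharges:
    def test_identical_embeddings_equal_charges(self, rng, head):
        row = rng.normal(size=8)
        x = AtomEmbeddings(Tensor(np.stack([row, row, rng.normal(size=8)])))
        q = predict_raw_charges(x, head).data
        assert q[0] == q[1]
        assert q[0] != q[2]

    def test_constant_network_hand_case(self, rng, head):
        """With the first layer zeroed, every charge equals the final bias."""
        head.w1.data[:] = 0.0
        head.b1.data[:] = 0.0
        head.b2.data[:] = 0.7  # ssp(0)=0, so q = 0 @ w2 + 0.7
        x = AtomEmbeddings(Tensor(rng.normal(size=(4, 8))))
        assert np.allclose(predict_raw_charges(x, head).data, 0.7, atol=1e-14)

    def test_permutation_equivariance(self, rng, head):
        xd = rng.normal(size=(5, 8))
        perm = rng.permutation(5)
        q = predict_raw_charges(AtomEmbeddings(Tensor(xd)), head).data
        qp = predict_raw_charges(AtomEmbeddings(Tensor(xd[perm])), head).data
        assert np.array_equal(q[perm], qp)


class TestScaleCharges:
    def test_uniform_redistribution(self):
        q = scale_charges(np.array([0.5, 0.7]), 0).data
        assert np.allclose(q, [-0.1, 0.1], atol=1e-12)

    def test_fixed_point_when_already_summing(self):
        raw = np.array([0.25, -1.0, 0.75])
        q = scale_charges(raw, 0).data
        assert np.allclose(q, raw, atol=1e-12)

    def test_single_atom_forced_to_q(self):
        assert np.allclose(scale_charges(np.array([0.37]), -2).data, [-2.0])

    def test_batched_segments(self):
        raw = np.array([0.5, 0.7, 1.0, 1.0, 1.0])
        seg = np.array([0, 0, 1, 1, 1])
        q = scale_charges(raw, np.array([0.0, -1.0]), seg=seg, n_structures=2).data
        assert np.allclose(q[:2], [-0.1, 0.1])
        assert np.allclose(q[2:], 1.0 - 4.0 / 3.0)

    @settings(max_examples=50, deadline=None)
    @given(
        n=st.integers(1, 40),
        q_tot=st.integers(-3, 3),
        seed=st.integers(0, 10_000),
    )
    def test_sum_always_equals_q(self, n, q_tot, seed):
        raw = np.random.default_rng(seed).normal(size=n) * 5
        q = scale_charges(raw, q_tot).data
        assert abs(q.sum() - q_tot) <= 1e-10


class TestChargeEmbedding:
    def test_zeroed_residual_branch_is_lift(self, head):
        for t in (head.w_res1, head.b_res1, head.w_res2, head.b_res2):
            t.data[:] = 0.0
        q = np.array([0.3, -1.2])
        c = charge_embedding(q, head).data
        assert np.array_equal(c, np.outer(q, head.lift.data))

    def test_equal_charges_equal_rows(self, head):
        c = charge_embedding(np.array([0.4, 0.4]), head).data
        assert np.array_equal(c[0], c[1])

    def test_deterministic(self, head):
        q = np.array([0.1, 0.2, -0.3])
        a = charge_embedding(q, head).data
        b = charge_embedding(q, head).data
        assert np.array_equal(a, b)


class TestEwaldMessages:
    def make_grid(self, rng, n_features=8, mode="direct_radial", n_dirs=6,
                  n_freq=3):
        return FourierGrid.init(rng, n_features, n_frequencies=n_freq,
                                k_cutoff=2.0, mode=mode, n_directions=n_dirs)

    def test_single_atom_direct_radial(self, rng):
        grid = self.make_grid(rng)
        c = Tensor(rng.normal(size=(1, 8)))
        out = ewald_messages(c, np.zeros((1, 3)), grid).data
        assert np.allclose(out, grid.weights.data.sum(axis=0) * c.data, atol=1e-12)

    def test_plane_wave_matches_dense_double_loop(self, rng):
        """Factorized structure-factor sum vs the O(N^2) cosine kernel."""
        for n_dirs in (2, 6):
            grid = self.make_grid(rng, mode="plane_wave", n_dirs=n_dirs)
            n = 32
            coords = rng.normal(scale=3.0, size=(n, 3))
            c = rng.normal(size=(n, 8))
            got = ewald_messages(Tensor(c), coords, grid).data
            w = grid.weights.data
            expected = np.zeros((n, 8))
            for i in range(n):
                for j in range(n):
                    ker = np.zeros(8)
                    for m, k in enumerate(grid.frequencies):
                        avg = np.mean(
                            [np.cos(k * u @ (coords[i] - coords[j]))
                             for u in grid.directions]
                        )
                        ker += w[m] * avg
                    expected[i] += ker * c[j]
            rel = np.abs(got - expected).max() / np.abs(expected).max()
            assert rel <= 1e-6

    def test_translation_invariance_both_modes(self, rng):
        for mode in ("direct_radial", "plane_wave"):
            grid = self.make_grid(rng, mode=mode, n_dirs=6)
            coords = rng.normal(scale=2.0, size=(6, 3))
            c = Tensor(rng.normal(size=(6, 8)))
            a = ewald_messages(c, coords, grid).data
            b = ewald_messages(c, coords + np.array([11.0, -4.0, 7.0]), grid).data
            assert np.abs(a - b).max() <= 1e-8

    def test_batched_messages_respect_structure_boundaries(self, rng):
        grid = self.make_grid(rng)
        ca = rng.normal(size=(3, 8))
        cb = rng.normal(size=(4, 8))
        xa = rng.normal(scale=2, size=(3, 3))
        xb = rng.normal(scale=2, size=(4, 3))
        merged = ewald_messages(
            Tensor(np.concatenate([ca, cb])),
            np.concatenate([xa, xb]),
            grid,
            seg=np.array([0] * 3 + [1] * 4),
            n_structures=2,
        ).data
        sep_a = ewald_messages(Tensor(ca), xa, grid).data
        sep_b = ewald_messages(Tensor(cb), xb, grid).data
        assert np.allclose(merged, np.concatenate([sep_a, sep_b]), atol=1e-12)

    def test_empty_frequency_list_rejected(self):
        with pytest.raises(ValueError):
            FourierGrid(n_frequencies=0)

    def test_direction_average_converges_to_radial_kernel(self):
        """Max kernel error over d in [0.5, 10] decreases for M=6, 26, 98."""
        k = 2.0
        d = np.linspace(0.5, 10.0, 120)
        rng = np.random.default_rng(0)
        errs = []
        for m in (6, 26, 98):
            dirs = direction_set(m)
            worst = 0.0
            for _ in range(12):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                approx = np.mean(np.cos(k * (d[:, None] * u) @ dirs.T), axis=1)
                exact = np.sinc(k * d / np.pi)
                worst = max(worst, np.abs(approx - exact).max())
            errs.append(worst)
        assert errs[0] > errs[1] > errs[2]


class TestFullModel:
    def make_params(self, variant="ewald_q", mode="direct_radial", seed=0):
        cfg = ModelConfig(
            variant=variant, n_features=8, n_blocks=2, n_rbf=6, cutoff=3.0,
            charge_hidden=6, ewald_n_frequencies=3, ewald_mode=mode,
        )
        p = FullModelParams.init(cfg, seed=seed)
        if p.w_project is not None:
            p.w_project.data = np.random.default_rng(seed + 1).normal(
                scale=0.1, size=p.w_project.data.shape
            )
        return p

    def test_rigid_motion_invariance_direct_radial(self, rng):
        p = self.make_params()
        s = random_structure(rng, n_atoms=6, charge=1)
        e0 = full_forward(s, p)
        for k in range(10):
            r = Rotation.random(random_state=k).as_matrix()
            s2 = AtomicStructure(
                s.elements, s.coords @ r.T + rng.normal(size=3) * 8, s.total_charge
            )
            assert abs(full_forward(s2, p) - e0) <= 1e-5

    def test_zero_ewald_weights_reduce_to_baseline(self, rng):
        p = self.make_params()
        p.grid.weights.data[:] = 0.0
        for _ in range(5):
            s = random_structure(rng, n_atoms=5)
            assert full_forward(s, p) == baseline_forward(s, p.baseline)

    def test_charges_sum_to_total_charge(self, rng):
        p = self.make_params()
        for _ in range(50):
            s = random_structure(
                rng, n_atoms=int(rng.integers(2, 20)),
                charge=int(rng.integers(-2, 3)),
            )
            q = predicted_charges(s, p)
            assert abs(q.sum() - s.total_charge) <= 1e-6

    def test_nuclear_embedding_variant_ignores_total_charge(self, rng):
        """'ewald' feeds nuclear embeddings: blind to Q by construction."""
        p = self.make_params(variant="ewald")
        s = random_structure(rng, n_atoms=5, charge=0)
        s2 = AtomicStructure(s.elements, s.coords, total_charge=2)
        assert full_forward(s, p) == full_forward(s2, p)

    def test_charged_variant_distinguishes_total_charge(self, rng):
        p = self.make_params(variant="ewald_q")
        s = random_structure(rng, n_atoms=5, charge=0)
        s2 = AtomicStructure(s.elements, s.coords, total_charge=2)
        assert full_forward(s, p) != full_forward(s2, p)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        p = self.make_params()
        s = random_structure(rng, n_atoms=6)
        e0 = full_forward(s, p)
        path = tmp_path / "ckpt.json"
        p.save(path)
        p2 = FullModelParams.load(path)
        assert full_forward(s, p2) == e0
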