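"""Toy potential, metadynamics bias, and the Langevin sampler."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import random_structure
from qewald.sampling import (
    COULOMB_CONSTANT,
    KB_KCAL,
    MetaBiasParams,
    ToyPotentialParams,
    bias_energy,
    bias_forces,
    default_toy_params,
    double_well_system,
    generate_dataset,
    make_cluster,
    metamd_sample,
    toy_energy,
    toy_forces,
)
from qewald.structures import AtomicStructure


def dimer(d, z=(1, 1), charges=(0.0, 0.0), terms=None):
    p = ToyPotentialParams(
        pair_terms={tuple(sorted(z)): terms if terms is not None else []},
        charges=np.array(charges),
        sr_cutoff=50.0,
    )
    s = AtomicStructure(
        list(z), [[0, 0, 0], [0, 0, d]], total_charge=int(round(sum(charges)))
    )
    return s, p


class TestToyEnergy:
    def test_morse_minimum_value(self):
        s, p = dimer(2.2, terms=[("morse", 7.5, 1.8, 2.2)])
        assert np.isclose(toy_energy(s, p), -7.5, atol=1e-12)

    def test_coulomb_constant_definition(self):
        s, p = dimer(1.0, charges=(1.0, 1.0))
        assert np.isclose(toy_energy(s, p), COULOMB_CONSTANT, atol=1e-10)

    def test_matches_hand_written_double_loop(self, rng):
        p = default_toy_params()
        s = make_cluster(rng, n_ligand_range=(4, 4))
        q = p.ground_truth_charges(s)
        expected = 0.0
        for i in range(s.n_atoms):
            for j in range(i + 1, s.n_atoms):
                d = np.linalg.norm(s.coords[i] - s.coords[j])
                key = tuple(sorted((int(s.elements[i]), int(s.elements[j]))))
                if d <= p.sr_cutoff:
                    for kind, depth, width, req in p.pair_terms[key]:
                        assert kind == "morse"
                        e = np.exp(-width * (d - req))
                        expected += depth * (1 - e) ** 2 - depth
                expected += COULOMB_CONSTANT * q[i] * q[j] / d
        assert np.isclose(toy_energy(s, p), expected, atol=1e-9)

    def test_coincident_atoms_rejected(self):
        s, p = dimer(0.0)
        s.coords[1] = s.coords[0]
        with pytest.raises(ValueError, match="coincident"):
            toy_energy(s, p)

    def test_ground_truth_charges_sum_to_q(self, rng):
        p = default_toy_params()
        for q_tot in (-2, 0, 3):
            s = make_cluster(rng, total_charge=q_tot)
            assert np.isclose(p.ground_truth_charges(s).sum(), q_tot, atol=1e-12)

    def test_rigid_motion_invariance(self, rng):
        p = default_toy_params()
        s = make_cluster(rng)
        r = Rotation.random(random_state=0).as_matrix()
        s2 = AtomicStructure(s.elements, s.coords @ r.T + [3, -1, 2], s.total_charge)
        assert abs(toy_energy(s, p) - toy_energy(s2, p)) < 1e-8

    def test_forces_match_central_differences(self, rng):
        p = default_toy_params()
        s = make_cluster(rng)
        f = toy_forces(s, p)
        eps = 1e-6
        for i in range(s.n_atoms):
            for ax in range(3):
                sp, sm = s.copy(), s.copy()
                sp.coords[i, ax] += eps
                sm.coords[i, ax] -= eps
                num = -(toy_energy(sp, p) - toy_energy(sm, p)) / (2 * eps)
                assert abs(f[i, ax] - num) < 1e-5 * max(1.0, abs(num))


class TestBiasEnergy:
    def test_gaussian_at_origin(self, rng):
        s = random_structure(rng, n_atoms=4)
        b = MetaBiasParams([s.copy()], [2.0], [1.0])
        assert np.isclose(bias_energy(s, b), 2.0, atol=1e-12)

    def test_far_tail_vanishes(self):
        a = AtomicStructure([1, 1], [[0, 0, 0], [0, 0, 1.0]])
        # alternate +/- z displacement of 10*sqrt(...) to get Delta = 10
        c = AtomicStructure([1, 1], [[0, 0, -10.0], [0, 0, 11.0]])
        b = MetaBiasParams([a], [1.0], [1.0])
        # Delta is 10 A after alignment; e^{-100} is numerically zero
        assert bias_energy(c, b) < 1e-40

    def test_two_reference_arithmetic(self):
        """V = 1*e^{-0.5} + 2*e^{-2} for (k,a,Delta) = (1,.5,1) and (2,.5,2).

        Breathing-mode references give exactly Delta = 1 and 2 A.
        """
        dirs = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]])

        def at(t):
            return AtomicStructure([6] * 4, (4.0 + t) * dirs)

        s, r1, r2 = at(0.0), at(1.0), at(2.0)
        b = MetaBiasParams([r1, r2], [1.0, 2.0], [0.5, 0.5])
        expected = 1.0 * np.exp(-0.5) + 2.0 * np.exp(-2.0)
        assert np.isclose(bias_energy(s, b), expected, atol=1e-10)

    def test_mismatched_elements_rejected(self):
        a = AtomicStructure([1, 8], [[0, 0, 0], [1, 0, 0]])
        c = AtomicStructure([1, 1], [[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            bias_energy(c, MetaBiasParams([a], [1.0], [1.0]))

    def test_invalid_params_rejected(self):
        a = AtomicStructure([1], [[0, 0, 0]])
        with pytest.raises(ValueError):
            MetaBiasParams([a], [-1.0], [1.0])
        with pytest.raises(ValueError):
            MetaBiasParams([a], [1.0], [0.0])
        with pytest.raises(ValueError):
            MetaBiasParams([a], [1.0, 2.0], [1.0])

    def test_forces_match_central_differences(self, rng):
        """Analytic aligned-RMSD gradient vs numerics, rel err <= 1e-5."""
        base = random_structure(rng, n_atoms=6)
        refs = []
        for _ in range(3):
            r = base.copy()
            r.coords = r.coords + 0.5 * rng.normal(size=r.coords.shape)
            refs.append(r)
        b = MetaBiasParams(refs, [2.0, 1.0, 0.5], [1.0, 2.0, 0.5])
        s = base.copy()
        s.coords = s.coords + 0.2 * rng.normal(size=s.coords.shape)
        f = bias_forces(s, b)
        eps = 1e-6
        num = np.zeros_like(f)
        for i in range(s.n_atoms):
            for ax in range(3):
                sp, sm = s.copy(), s.copy()
                sp.coords[i, ax] += eps
                sm.coords[i, ax] -= eps
                num[i, ax] = -(bias_energy(sp, b) - bias_energy(sm, b)) / (2 * eps)
        assert np.abs(f - num).max() / np.abs(num).max() <= 1e-5


class TestMetaMD:
    def test_zero_steps_returns_start(self, rng):
        s = make_cluster(rng)
        traj = metamd_sample(s, default_toy_params(), k=1.0, alpha=1.0,
                             steps=0, deposit_every=10, seed=0)
        assert len(traj) == 1
        assert np.array_equal(traj[0].coords, s.coords)

    def test_same_seed_identical_trajectory(self, rng):
        s = make_cluster(rng)
        p = default_toy_params()
        kw = dict(k=2.0, alpha=1.0, steps=100, deposit_every=20, seed=11)
        t1 = metamd_sample(s, p, **kw)
        t2 = metamd_sample(s, p, **kw)
        assert len(t1) == len(t2) == 6
        for a, b in zip(t1, t2):
            assert np.array_equal(a.coords, b.coords)

    def test_unbiased_path_matches_independent_baoab(self, rng):
        """k=0 reduces to plain BAOAB Langevin: re-integrate in the test."""
        s, p = dimer(2.2, z=(8, 8), terms=[("morse", 10.0, 1.8, 2.2)])
        seed, steps, dt, temp, fric = 5, 40, 0.5, 300.0, 1e-3
        traj = metamd_sample(s, p, k=0.0, alpha=1.0, steps=steps,
                             deposit_every=1, temperature=temp, timestep=dt,
                             seed=seed, friction=fric)
        # independent re-implementation
        conv = 2390.057
        m = np.array([15.999, 15.999])[:, None]
        rng2 = np.random.default_rng(seed)
        kt = KB_KCAL * temp
        c1 = np.exp(-fric * dt)
        sigma = np.sqrt(kt * (1 - c1**2) / (m * conv))
        v = rng2.normal(size=(2, 3)) * np.sqrt(kt / (m * conv))
        x = s.coords.copy()
        f = toy_forces(AtomicStructure(s.elements, x), p)
        frames = []
        for _ in range(steps):
            v = v + 0.5 * dt * f / (m * conv)
            x = x + 0.5 * dt * v
            v = c1 * v + sigma * rng2.normal(size=v.shape)
            x = x + 0.5 * dt * v
            f = toy_forces(AtomicStructure(s.elements, x), p)
            v = v + 0.5 * dt * f / (m * conv)
            frames.append(x.copy())
        assert len(traj) == steps + 1
        for a, b in zip(traj[1:], frames):
            assert np.abs(a.coords - b).max() < 1e-12

    def test_biased_run_accumulates_references(self, rng):
        s = make_cluster(rng)
        bias = MetaBiasParams()
        metamd_sample(s, default_toy_params(), k=1.0, alpha=1.0, steps=100,
                      deposit_every=25, seed=0, bias=bias)
        assert len(bias.references) == 1 + 4  # start + one per deposit

    def test_nve_energy_conservation_on_dimer(self):
        """Zero friction, zero bias, small timestep: drift < 1% over 1000."""
        s, p = dimer(2.4, z=(8, 8), terms=[("morse", 10.0, 1.8, 2.2)])
        trace = []
        metamd_sample(s, p, k=0.0, alpha=1.0, steps=1000, deposit_every=0,
                      temperature=300.0, timestep=0.2, seed=3, friction=0.0,
                      energy_trace=trace)
        trace = np.array(trace)
        assert np.ptp(trace) < 0.01 * max(abs(trace[0]), 1.0)


class TestGenerateDataset:
    def test_no_deposits_gives_singleton_ensembles(self):
        ens = generate_dataset(
            n_configs=2, per_config=1, schedule=[(1.0, 1.0)], seed=0,
            deposit_every=10, steps_per_run=5,
        )
        assert all(len(e) == 1 for e in ens)

    def test_labels_match_ground_truth(self):
        p = default_toy_params()
        ens = generate_dataset(n_configs=2, per_config=2, p=p,
                               schedule=[(2.0, 1.0)], seed=1, deposit_every=15)
        for e in ens:
            for s in e.members:
                assert abs(s.energy - toy_energy(s, p)) < 1e-10

    def test_deterministic(self):
        a = generate_dataset(n_configs=2, per_config=2, seed=4, deposit_every=10)
        b = generate_dataset(n_configs=2, per_config=2, seed=4, deposit_every=10)
        assert [len(e) for e in a] == [len(e) for e in b]
        for ea, eb in zip(a, b):
            for sa, sb in zip(ea.members, eb.members):
                assert np.array_equal(sa.coords, sb.coords)
                assert sa.energy == sb.energy

    def test_longer_schedule_never_shrinks_ensembles(self):
        """Doubling the schedule keeps >= as many distinct conformers."""
        wins = 0
        for seed in range(20):
            short = generate_dataset(1, 2, schedule=[(2.0, 1.0)], seed=seed,
                                     deposit_every=10)
            long = generate_dataset(1, 2, schedule=[(2.0, 1.0), (2.0, 1.0)],
                                    seed=seed, deposit_every=10)
            if len(long[0]) >= len(short[0]):
                wins += 1
        assert wins >= 18


def test_double_well_bias_drives_barrier_crossing():
    """With the bias on, more seeds visit both basins than without (small n)."""
    start, p, frozen = double_well_system()

    def visits_both(seed, k):
        traj = metamd_sample(start, p, k=k, alpha=8.0, steps=4000,
                             deposit_every=50, seed=seed, frozen=frozen)
        d1 = np.array([np.linalg.norm(t.coords[2] - t.coords[0]) for t in traj])
        d2 = np.array([np.linalg.norm(t.coords[2] - t.coords[1]) for t in traj])
        return bool((d1 < 2.0).any() and (d2 < 2.0).any())

    seeds = range(6)
    biased = sum(visits_both(s, 0.5) for s in seeds)
    unbiased = sum(visits_both(s, 0.0) for s in seeds)
    assert biased > unbiased
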