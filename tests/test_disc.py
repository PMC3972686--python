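"""Adaptor switching, Metropolis clustering, and caspase-8 generation."""

import numpy as np
import pytest

from apoptomc import lattice as L
from apoptomc.config import DiscConfig, LatticeSpec, SimConfig
from apoptomc.disc import (AdaptorField, adaptor_switch, disc_metropolis_move,
                           generate_caspase8, metropolis_sweep)


def _field(n=16, nx=8, ny=8, seed=0, all_active=True, **params):
    return AdaptorField.random(nx, ny, n, seed=seed, all_active=all_active,
                               params=DiscConfig(enabled=True, **params))


class TestSwitching:
    def test_certain_activation(self):
        fld = _field(all_active=False, p_on=1.0)
        assert adaptor_switch(fld, 0, seed=1)
        assert fld.active[0] == 1

    def test_zero_activation_probability_stays_inactive(self):
        fld = _field(all_active=False, p_on=0.0)
        for k in range(200):
            adaptor_switch(fld, 0, seed=k)
        assert fld.active[0] == 0

    def test_mean_active_lifetime_is_geometric(self):
        """Mean lifetime 1/P_off switching attempts (P_off = 0.05)."""
        fld = _field(n=1, p_on=1.0, p_off=0.05)
        lifetimes = []
        alive = 0
        np.random.seed(0)
        from apoptomc import _kernels as K
        K.seed_rng(123)
        for _ in range(30_000):
            if fld.active[0]:
                alive += 1
                if adaptor_switch(fld, 0):
                    lifetimes.append(alive)
                    alive = 0
            else:
                adaptor_switch(fld, 0)
        mean = np.mean(lifetimes)
        se = np.std(lifetimes) / np.sqrt(len(lifetimes))
        assert abs(mean - 20.0) < 3 * se + 1.0


class TestMetropolis:
    def test_zero_energy_move_to_free_site_always_accepted(self):
        # single adaptor: dE = 0 everywhere; only walls can reject
        fld = _field(n=1, p_on=0.0)
        moved = 0
        for k in range(100):
            fld.occ[:, :] = -1
            fld.x[0], fld.y[0] = 4, 4   # interior: all four targets in-lattice
            fld.occ[4, 4] = 0
            moved += disc_metropolis_move(fld, 0, seed=k)
        assert moved == 100

    def test_favourable_move_always_accepted(self):
        """Closing a gap next to an active partner (dE < 0) never rejects."""
        fld = _field(n=2, e_dd=-2.0)
        trials, closed = 1000, 0
        for k in range(trials):
            fld.occ[:, :] = -1
            fld.x[:], fld.y[:] = (2, 4), (3, 3)
            fld.occ[2, 3] = 0
            fld.occ[4, 3] = 1
            disc_metropolis_move(fld, 0, seed=k)
            if (fld.x[0], fld.y[0]) == (3, 3):
                closed += 1
        # the gap-closing direction is drawn 1/4 of the time and, since
        # dE = e_dd < 0, must always be accepted
        se = np.sqrt(0.25 * 0.75 / trials)
        assert abs(closed / trials - 0.25) < 4 * se

    def test_unfavourable_acceptance_rate_matches_boltzmann(self):
        """Breaking one pair at E_DD = -2 is accepted with rate exp(-2)."""
        accepted = 0
        trials = 0
        fld = _field(n=2, e_dd=-2.0)
        from apoptomc import _kernels as K
        K.seed_rng(77)
        for _ in range(8000):
            fld.occ[:, :] = -1
            fld.x[:], fld.y[:] = (3, 4), (3, 3)
            fld.occ[3, 3] = 0
            fld.occ[4, 3] = 1
            if disc_metropolis_move(fld, 0):
                # left/up/down moves break the pair (dE = +2); the move right
                # is blocked by adaptor 1
                accepted += 1
            trials += 1
        # 3 of 4 sampled directions are free and pair-breaking
        expect = 0.75 * np.exp(-2.0)
        se = np.sqrt(expect * (1 - expect) / trials)
        assert abs(accepted / trials - expect) < 4 * se

    def test_clustering_order_with_energy(self):
        """Mean largest cluster grows as E_DD decreases through 0, -1, -2."""
        sizes = {}
        for edd in (0.0, -1.0, -2.0):
            fld = _field(n=10, nx=8, ny=8, e_dd=edd, seed=3)
            acc = []
            for rep in range(40):
                metropolis_sweep(fld, 50, seed=rep)
                acc.append(fld.largest_cluster())
            sizes[edd] = np.mean(acc)
        assert sizes[0.0] < sizes[-1.0] < sizes[-2.0]


class TestGeneration:
    def _state(self, pool=10):
        lat = LatticeSpec(nx=8, ny=8, nz=8, mito_dims=(0, 0, 0))
        cfg = SimConfig(lattice=lat, concentrations={},
                        disc=DiscConfig(enabled=True, proc8_pool=pool,
                                        n_adaptors=0))
        return L.init_state(cfg, seed=0)

    def test_isolated_adaptors_do_not_activate(self):
        fld = _field(n=2, p_c8=1.0, min_active_neighbors=1)
        fld.occ[:, :] = -1
        fld.x[:], fld.y[:] = (0, 7), (0, 7)   # far apart
        fld.occ[0, 0] = 0
        fld.occ[7, 7] = 1
        state = self._state()
        for k in range(100):
            assert not generate_caspase8(fld, state, k % 2, seed=k)
        assert state.counts[L.C8] == 0

    def test_clustered_adaptor_converts_pool_to_caspase8(self):
        fld = _field(n=2, p_c8=1.0, min_active_neighbors=1)
        fld.occ[:, :] = -1
        fld.x[:], fld.y[:] = (3, 4), (3, 3)
        fld.occ[3, 3] = 0
        fld.occ[4, 3] = 1
        state = self._state(pool=2)
        assert generate_caspase8(fld, state, 0, seed=1)
        assert state.counts[L.C8] == 1
        assert int(state.regs[L.LatticeState.R_POOL]) == 1
        # caspase 8 entered at the adaptor's membrane column
        (xyz,) = state.coordinates(state.act[:1])
        assert tuple(xyz) == (3, 3, 0)

    def test_pool_exhaustion_stops_generation(self):
        fld = _field(n=2, p_c8=1.0, min_active_neighbors=1)
        fld.occ[:, :] = -1
        fld.x[:], fld.y[:] = (3, 4), (3, 3)
        fld.occ[3, 3] = 0
        fld.occ[4, 3] = 1
        state = self._state(pool=1)
        assert generate_caspase8(fld, state, 0, seed=1)
        for k in range(20):
            assert not generate_caspase8(fld, state, k % 2, seed=k)
        assert state.counts[L.C8] == 1

    def test_expected_generation_rate_is_binomial(self):
        """m fully clustered adaptors generate ~ m * P_c8 per attempt each."""
        p_c8 = 0.05
        fld = _field(n=4, p_c8=p_c8, min_active_neighbors=1)
        fld.occ[:, :] = -1
        for j, (x, y) in enumerate(((3, 3), (3, 4), (4, 3), (4, 4))):
            fld.x[j], fld.y[j] = x, y
            fld.occ[x, y] = j
        n_attempts = 4000
        state = self._state(pool=10**6)
        from apoptomc import _kernels as K
        K.seed_rng(5)
        made = 0
        for k in range(n_attempts):
            if generate_caspase8(fld, state, k % 4):
                made += 1
                # clear the entry site so placement never saturates
                K._remove_molecule(int(state.act[0]), state.occ, state.msite,
                                   state.species, state.comp, state.act,
                                   state.act_idx, state.counts,
                                   state.free_stack, state.regs)
        expect = n_attempts * p_c8
        # placement rejections are possible but rare on an empty column
        assert abs(made - expect) < 4 * np.sqrt(expect)


class TestSnapshot:
    def test_snapshot_roundtrip(self, tmp_path):
        fld = _field(n=5, seed=9)
        path = tmp_path / "field.tsv"
        fld.save_snapshot(path)
        arr = np.loadtxt(path, skiprows=1, dtype=np.int64)
        assert arr.shape == (5, 3)
        assert set(map(tuple, arr[:, :2])) == set(zip(fld.x, fld.y))
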