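"""Lattice geometry, molecule placement, and diffusion with exclusion."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from apoptomc import lattice as L
from apoptomc import engine
from apoptomc.config import LatticeSpec, SimConfig, StopConfig, DiscConfig


class TestConcentrationMapping:
    @pytest.mark.parametrize("nm,count", [(100.0, 100), (0.0, 0), (30.0, 30),
                                          (2.5, 3), (2.49, 2)])
    def test_one_molecule_per_nanomolar(self, nm, count):
        assert L.concentration_to_count(nm) == count

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            L.concentration_to_count(-1.0)

    @given(st.integers(min_value=0, max_value=10**6))
    def test_inverse_on_integers_is_identity(self, n):
        assert L.concentration_to_count(float(n)) == n


class TestNeighbors:
    SPEC = LatticeSpec(nx=6, ny=6, nz=6, mito_dims=(0, 0, 0))

    def test_interior_cytosol_site_has_six(self):
        assert len(L.neighbors((3, 3, 3), self.SPEC)) == 6

    def test_membrane_site_has_four_in_plane(self):
        assert len(L.neighbors((3, 3), self.SPEC, mobility="membrane")) == 4

    def test_corner_has_three_reflecting_walls(self):
        assert len(L.neighbors((0, 0, 0), self.SPEC)) == 3

    def test_outside_lattice_rejected(self):
        with pytest.raises(ValueError):
            L.neighbors((9, 0, 0), self.SPEC)

    @given(st.tuples(st.integers(0, 5), st.integers(0, 5), st.integers(0, 5)))
    def test_neighbors_in_lattice_and_adjacent(self, site):
        for nb in L.neighbors(site, self.SPEC):
            assert all(0 <= c < 6 for c in nb)
            assert sum(abs(a - b) for a, b in zip(site, nb)) == 1


class TestInitState:
    def test_counts_match_configuration(self, desk_config):
        state = L.init_state(desk_config, seed=1)
        got = state.species_counts()
        for name, conc in desk_config.concentrations.items():
            assert got.get(name, 0) == L.concentration_to_count(conc)

    def test_mitochondrial_species_confined_to_block(self, desk_config):
        state = L.init_state(desk_config, seed=2)
        blk = desk_config.lattice.in_block_mask()
        for sp in (L.CYTC, L.SMAC):
            for x, y, z in state.positions_of(sp):
                assert blk[x, y, z]

    def test_no_two_molecules_share_a_site(self, desk_config):
        L.init_state(desk_config, seed=3).check_exclusion()

    def test_deterministic_given_seed(self, desk_config):
        a = L.init_state(desk_config, seed=7)
        b = L.init_state(desk_config, seed=7)
        assert np.array_equal(a.msite, b.msite)
        assert np.array_equal(a.species, b.species)

    def test_overfilled_compartment_errors_with_name(self):
        lat = LatticeSpec(nx=4, ny=4, nz=4, mito_dims=(2, 2, 2))
        cfg = SimConfig(lattice=lat, concentrations={"cytc": 20.0})
        with pytest.raises(ValueError, match="mitochondrial"):
            L.init_state(cfg, seed=0)


class TestDiffusion:
    def _two_molecule_state(self):
        lat = LatticeSpec(nx=3, ny=3, nz=3, mito_dims=(0, 0, 0))
        cfg = SimConfig(lattice=lat, concentrations={"Apaf": 2.0})
        return L.init_state(cfg, seed=5)

    def test_occupied_target_leaves_state_unchanged(self):
        # fill the lattice completely: every move must be rejected
        lat = LatticeSpec(nx=2, ny=2, nz=2, mito_dims=(0, 0, 0))
        cfg = SimConfig(lattice=lat, concentrations={"Apaf": 8.0})
        state = L.init_state(cfg, seed=1)
        before = state.msite.copy()
        for k in range(50):
            L.attempt_diffusion(state, int(state.act[k % 8]), seed=k,
                                p_diff_cytosol=1.0)
        assert np.array_equal(state.msite, before)

    def test_apoptosome_never_moves(self):
        state = self._two_molecule_state()
        mol = int(state.act[0])
        state.counts[state.species[mol]] -= 1
        state.species[mol] = L.APO
        state.counts[L.APO] += 1
        site = state.msite[mol]
        for k in range(200):
            L.attempt_diffusion(state, mol, seed=k, p_diff_cytosol=1.0)
        assert state.msite[mol] == site

    def test_free_molecule_moves_at_unit_probability(self):
        state = self._two_molecule_state()
        mol = int(state.act[0])
        moved = sum(L.attempt_diffusion(state, mol, seed=k, p_diff_cytosol=1.0)
                    for k in range(100))
        assert moved > 50   # only wall/occupancy rejections remain
        state.check_exclusion()

    def test_conservation_under_diffusion(self):
        state = self._two_molecule_state()
        before = state.counts.copy()
        for k in range(100):
            L.attempt_diffusion(state, int(state.act[k % 2]), seed=k)
        assert np.array_equal(state.counts, before)


class TestDiffusionLaw:
    def test_effective_diffusion_constant(self):
        """Dilute-limit MSD recovers D = P_diff dx^2/dT ~ 0.2 um^2/s."""
        d_est = engine.estimate_diffusion_constant(n_walkers=20_000,
                                                   n_steps=300, seed=4)
        assert d_est == pytest.approx(0.2, rel=0.05)


class TestContainment:
    def test_premito_species_stay_inside_through_dynamics(self, desk_config,
                                                          desk_tables):
        state = L.init_state(desk_config, seed=11)
        blk = desk_config.lattice.in_block_mask()
        engine.K.seed_rng(11)
        for _ in range(300):
            engine.mc_step(state, desk_tables, desk_config)
            if state.released:
                break
            for sp in (L.CYTC, L.SMAC):
                for x, y, z in state.positions_of(sp):
                    assert blk[x, y, z]
        state.check_exclusion()

    def test_membrane_species_live_on_the_shell(self, desk_config,
                                                desk_tables):
        state = L.init_state(desk_config, seed=13)
        shell = desk_config.lattice.shell_mask()
        engine.K.seed_rng(13)
        for _ in range(2000):
            engine.mc_step(state, desk_tables, desk_config)
        live = state.act[: state.n_molecules]
        on_membrane = live[state.comp[live] == L.MITO_MEMBRANE]
        for x, y, z in state.coordinates(on_membrane):
            assert shell[x, y, z]
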