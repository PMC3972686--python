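"""Rate mapping, the reaction catalog, reaction application, release."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from apoptomc import lattice as L
from apoptomc import engine
from apoptomc.config import LatticeSpec, SimConfig
from apoptomc.kinetics import (DEFAULT_RATES, PROV_VIA_C8, PROV_VIA_C9,
                               RateTriple, ReleaseRule, attempt_reaction,
                               check_release, compile_rule_tables,
                               default_rule_catalog, map_kinetic_rates)


class TestRateMapping:
    def test_mapping_is_algebraically_exact(self):
        p = map_kinetic_rates(RateTriple(k_on=1e-4, k_off=1.0, k_cat=3.7))
        assert p.p_on == 1e2 * 1e-4
        assert p.p_off == 1.0 * 1e-4
        assert p.p_cat == 3.7 * 1e-4

    @pytest.mark.parametrize("triple,expect", [
        (RateTriple(k_on=1e-4), ("p_on", 1e-2)),
        (RateTriple(k_off=1.0), ("p_off", 1e-4)),
        (RateTriple(k_cat=0.0), ("p_cat", 0.0)),
    ])
    def test_quoted_examples(self, triple, expect):
        field, value = expect
        assert getattr(map_kinetic_rates(triple), field) == pytest.approx(value)

    def test_too_fast_rate_rejected(self):
        with pytest.raises(ValueError, match="P_off"):
            map_kinetic_rates(RateTriple(k_off=1e5))

    @given(st.floats(0, 1e-2), st.floats(0, 1e3), st.floats(0, 1e3))
    def test_linearity(self, kon, koff, kcat):
        p = map_kinetic_rates(RateTriple(kon, koff, kcat))
        assert p.p_on == 1e2 * kon and p.p_off == 1e-4 * koff


class TestCatalog:
    def test_exactly_two_caspase3_producing_channels(self):
        cats = [r for r in default_rule_catalog()
                if r.kind == "catalyze" and L.C3 in r.products]
        assert sorted(r.provenance for r in cats) == [PROV_VIA_C8, PROV_VIA_C9]

    def test_affinity_anchors(self):
        assert DEFAULT_RATES["c8_bid"].k_A == pytest.approx(1.0)          # nM^-1
        assert DEFAULT_RATES["c8_proc3"].k_A == pytest.approx(1.67e-4, rel=0.01)

    def test_every_rule_is_mass_balanced(self):
        for rule in default_rule_catalog():
            assert rule.mass_balanced(), rule.name

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            default_rule_catalog({"nonsense": RateTriple()})

    def test_catalog_covers_canonical_channels(self):
        names = {r.name for r in default_rule_catalog()}
        for needed in ("c8_proc3", "c8_bid", "tbid_translocation", "bax_dimer",
                       "bid_bax", "bcl2_tbid", "bcl2_bax", "cytc_apaf",
                       "apoptosome", "apo_proc9", "c9_proc3", "xiap_proc9",
                       "xiap_c9", "xiap_c3", "smac_xiap"):
            assert needed in names


def _pair_state(sp_a, sp_b, adjacent=True):
    """Two hand-placed molecules on a 4^3 empty lattice."""
    from apoptomc import _kernels as K
    lat = LatticeSpec(nx=4, ny=4, nz=4, mito_dims=(0, 0, 0))
    cfg = SimConfig(lattice=lat, concentrations={})
    state = L.init_state(cfg, seed=0)
    cap = len(state.species)
    state.free_stack = np.arange(cap - 1, -1, -1, dtype=np.int64)
    state.regs[L.LatticeState.R_NFREE] = cap
    sites = (21, 22) if adjacent else (21, 42)   # flat (1,1,1)+(1,1,2) / (2,2,2)
    for sp, site in zip((sp_a, sp_b), sites):
        K._add_molecule(site, sp, 0, state.occ, state.msite, state.species,
                        state.comp, state.act, state.act_idx, state.counts,
                        state.free_stack, state.regs)
    return state


class TestAttemptReaction:
    def test_adjacent_binding_forms_complex_and_frees_site(self):
        tables = compile_rule_tables({"c8_bid": RateTriple(k_on=1e-2)})
        # P_on = 1: binding certain once the rule is drawn
        state = _pair_state(L.C8, L.BID)
        fired = False
        for k in range(50):
            attempt_reaction(state, int(state.act[0]), tables, seed=k)
            if state.counts[L.C8_BID] == 1:
                fired = True
                break
        assert fired
        assert state.counts[L.C8] == 0 and state.counts[L.BID] == 0
        assert state.n_molecules == 1
        state.check_exclusion()

    def test_non_adjacent_pair_cannot_bind(self):
        tables = compile_rule_tables({"c8_bid": RateTriple(k_on=1e-2)})
        state = _pair_state(L.C8, L.BID, adjacent=False)
        for k in range(100):
            attempt_reaction(state, int(state.act[0]), tables, seed=k)
        assert state.counts[L.C8_BID] == 0

    def test_rejected_unbinding_leaves_state_unchanged(self):
        tables = compile_rule_tables()   # default P_off(c8_bid) = 1e-8
        state = _pair_state(L.C8_BID, L.APAF, adjacent=False)
        before = state.counts.copy()
        for k in range(100):
            attempt_reaction(state, int(state.act[0]), tables, seed=k)
        # catalysis may fire (P_cat = 1e-3); unbinding effectively never does
        assert state.counts[L.BID] == before[L.BID] == 0

    def test_catalysis_reports_provenance(self):
        tables = compile_rule_tables(
            {"c8_proc3": RateTriple(k_on=1e-4, k_off=0.0, k_cat=1e4)})
        state = _pair_state(L.C8_PROC3, L.APAF, adjacent=False)
        provs = [attempt_reaction(state, int(state.act[0]), tables, seed=k)
                 for k in range(20)]
        assert PROV_VIA_C8 in provs
        assert state.counts[L.C3] == 1 and state.counts[L.C8] == 1
        assert int(state.regs[L.LatticeState.R_VIA_C8]) == 1


class TestRelease:
    def _state_with_dimers(self, n_dimers):
        cfg = SimConfig(
            lattice=LatticeSpec(nx=6, ny=6, nz=6, mito_dims=(2, 2, 2)),
            concentrations={"cytc": 4.0, "Smac": 2.0, "Bax": 2 * n_dimers})
        state = L.init_state(cfg, seed=1)
        live = state.act[: state.n_molecules]
        bax = live[state.species[live] == L.BAX][: 2 * n_dimers]
        # convert pairs of Bax into dimers in place
        for a, b in zip(bax[0::2], bax[1::2]):
            from apoptomc import _kernels as K
            K._remove_molecule(int(b), state.occ, state.msite, state.species,
                               state.comp, state.act, state.act_idx,
                               state.counts, state.free_stack, state.regs)
            state.counts[L.BAX] -= 1
            state.species[a] = L.BAX2
            state.counts[L.BAX2] += 1
        return state

    def test_below_threshold_no_release(self):
        state = self._state_with_dimers(2)
        assert not check_release(state, ReleaseRule(threshold=3))
        assert not state.released

    def test_at_threshold_all_mito_species_retagged_same_step(self):
        state = self._state_with_dimers(3)
        assert check_release(state, ReleaseRule(threshold=3))
        live = state.act[: state.n_molecules]
        assert (state.comp[live] != L.MITO_INTERIOR).all()

    def test_idempotent_after_firing(self):
        state = self._state_with_dimers(3)
        rule = ReleaseRule(threshold=3)
        assert check_release(state, rule)
        assert not check_release(state, rule)


class TestReleaseMonotonicity:
    """Mean release step responds monotonically to Bax and Bcl2 levels."""

    def _mean_release(self, over, seeds=10):
        from apoptomc.config import _desk, StopConfig
        cfg = _desk(over, stop=StopConfig(half_max_count=10**6,
                                          max_steps=60_000))
        ens = engine.run_ensemble(cfg, seeds, master_seed=5)
        steps = [t.release_step if t.release_step >= 0 else cfg.stop.max_steps
                 for t in ens.trajectories]
        return float(np.mean(steps))

    def test_more_bax_releases_earlier(self):
        assert self._mean_release({"Bax": 16.0}) < self._mean_release({"Bax": 6.0})

    def test_more_bcl2_releases_later(self):
        assert self._mean_release({"Bcl2": 0.0}) < self._mean_release({"Bcl2": 8.0})
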