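import numpy as np
import pytest
from hypothesis import settings

from apoptomc import config as cfg_mod
from apoptomc import engine
from apoptomc.kinetics import RateTriple

settings.register_profile("ci", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def desk_config():
    return cfg_mod.get_preset("desk_baseline")


@pytest.fixture(scope="session")
def desk_tables(desk_config):
    return engine.build_tables(desk_config)


@pytest.fixture(scope="session")
def pair_config():
    """A single reversible binding pair (Bcl2 + Bax) on a 3x3x3 lattice.

    Only the Bcl2-Bax channel is active; its dissociation is fast enough to
    equilibrate within a short run.
    """
    zero = {k: RateTriple() for k in cfg_mod.DEFAULT_RATES}
    zero["bcl2_bax"] = RateTriple(k_on=1e-4, k_off=10.0)   # P_on 1e-2, P_off 1e-3
    lat = cfg_mod.LatticeSpec(nx=3, ny=3, nz=3, mito_dims=(0, 0, 0))
    return cfg_mod.SimConfig(
        lattice=lat, concentrations={"Bcl2": 1.0, "Bax": 1.0}, rates=zero,
        tbid_translocation_prob=0.0,
        stop=cfg_mod.StopConfig(half_max_count=10**6, max_steps=100_000),
        record_every=1)


@pytest.fixture(scope="session")
def desk_titration():
    """Shared caspase-8 titration ensembles (32 cells each), session-cached."""
    out = {}
    for name in ("desk_c8_low", "desk_c8_mid", "desk_c8_high"):
        out[name] = engine.run_ensemble(cfg_mod.get_preset(name), 32,
                                        master_seed=2024)
    return out


def make_trajectory(seed=0, half_max_step=-1, release_step=-1, apo_step=-1,
                    via_c8=0, via_c9=0, final_step=1000, c3_series=None,
                    half_max_count=50):
    """Hand-built trajectory for analysis-layer tests."""
    if c3_series is None:
        steps = np.array([0, final_step])
        counts = np.zeros((2, 28), dtype=np.int64)
    else:
        steps = np.array(sorted(c3_series))
        counts = np.zeros((len(steps), 28), dtype=np.int64)
        from apoptomc import lattice as L
        for k, s in enumerate(steps):
            counts[k, L.C3] = c3_series[s]
    extra = np.zeros((len(steps), 4), dtype=np.int64)
    return engine.Trajectory(
        seed=seed, steps=steps, counts=counts, extra=extra,
        release_step=release_step, first_apoptosome_step=apo_step,
        half_max_step=half_max_step,
        termination="half_max" if half_max_step >= 0 else "max_steps",
        c3_via_c8=via_c8, c3_via_c9=via_c9, c8_generated=0,
        half_max_count=half_max_count)
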