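"""The Monte Carlo loop: 2N sampling, trajectories, ensembles.

One MC step corresponds to dT = 2e-4 s and consists of 2N random samples,
where N is the number of molecules (plus DISC adaptors) present at step
start; on average each entity is sampled twice, allowing one diffusion and
one reaction/switch move.  A run terminates when the unbound active caspase 3
count reaches its half-maximal value (default 50, i.e. 50 nM) or at the step
cap.  Each run is one cell; ensembles are independent runs with per-cell
seeds spawned from a master seed, so results do not depend on execution
order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from . import lattice as L
from .config import SimConfig
from .kinetics import RuleTables, compile_rule_tables, map_kinetic_rates

logger = logging.getLogger("apoptomc")

TERMINATION_REASONS = {0: "max_steps", 1: "half_max", 2: "first_apoptosome"}


@dataclass
class Trajectory:
    """Time series and event times of one simulated cell.

    ``counts`` has one row per recorded step and one column per species;
    ``extra`` columns are active adaptors, cumulative caspase 8 generated,
    and the caspase-3 provenance counters (via caspase 8 / via caspase 9).
    Event steps are -1 when the event never occurred.
    """

    seed: int
    steps: np.ndarray
    counts: np.ndarray
    extra: np.ndarray
    release_step: int
    first_apoptosome_step: int
    half_max_step: int
    termination: str
    c3_via_c8: int
    c3_via_c9: int
    c8_generated: int
    half_max_count: int

    EXTRA_COLUMNS = ("active_adaptors", "c8_generated", "c3_via_c8", "c3_via_c9")

    @property
    def final_step(self) -> int:
        return int(self.steps[-1])

    @property
    def total_c3_activated(self) -> int:
        return self.c3_via_c8 + self.c3_via_c9

    def species_series(self, name: str) -> np.ndarray:
        return self.counts[:, L.SPECIES_IDS[name]]

    def free_c3_at(self, step: int) -> int:
        """Unbound active caspase 3 count at an arbitrary step.

        Uses the last recorded sample at or before ``step``; cells that
        terminated at half-max stay at the half-max count afterwards.
        """
        if step >= self.final_step:
            return int(self.counts[-1, L.C3])
        idx = int(np.searchsorted(self.steps, step, side="right")) - 1
        return int(self.counts[max(idx, 0), L.C3])

    def normalized_activation(self, step: int) -> float:
        """Caspase 3 activation as a fraction of half-max, capped at 1."""
        if self.half_max_step >= 0 and step >= self.half_max_step:
            return 1.0
        return min(1.0, self.free_c3_at(step) / self.half_max_count)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=L.SPECIES_NAMES)
        df.insert(0, "step", self.steps)
        for k, col in enumerate(self.EXTRA_COLUMNS):
            df[col] = self.extra[:, k]
        return df


@dataclass
class EnsembleResult:
    """Per-cell trajectories of independent single-cell runs."""

    config: SimConfig
    seeds: list[int]
    trajectories: list[Trajectory] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def fraction_dead(self) -> float:
        return float(np.mean([t.half_max_step >= 0 for t in self.trajectories]))

    def provenance_totals(self) -> tuple[int, int]:
        return (sum(t.c3_via_c8 for t in self.trajectories),
                sum(t.c3_via_c9 for t in self.trajectories))


def build_tables(config: SimConfig) -> RuleTables:
    return compile_rule_tables(config.full_rates(),
                               config.tbid_translocation_prob)


def _kernel_args(state: L.LatticeState, tables: RuleTables, config: SimConfig):
    disc = config.disc
    return (
        state.occ, state.msite, state.species, state.comp,
        state.act, state.act_idx, state.counts,
        state.nbr, state.in_block, state.is_shell, state.regs,
        tables.pair_rule, tables.bi_prob, tables.bi_kind, tables.bi_prod_a,
        tables.bi_prod_b, tables.bi_complex_side,
        tables.uni_start, tables.uni_count, tables.uni_kind, tables.uni_prob,
        tables.uni_prod_site, tables.uni_prod_nbr, tables.uni_nbr_comp,
        tables.uni_prov, tables.uni_needs_shell,
        state.free_stack, np.zeros(32, dtype=np.int64),
        config.p_diff_cytosol, config.p_diff_membrane,
        L.immobile_mask(),
        state.mem_occ, state.ad_x, state.ad_y, state.ad_active,
        disc.p_on, disc.p_off, disc.e_dd, disc.p_c8,
        disc.min_active_neighbors, L.C8,
        state.spec.ny, state.spec.nz,
        config.release_threshold, L.BAX2, L.APO, L.APO_PROC9,
    )


def mc_step(state: L.LatticeState, tables: RuleTables, config: SimConfig,
            seed: int | None = None) -> None:
    """Advance the state by one MC step (2N samples + release/event checks)."""
    if seed is not None:
        K.seed_rng(seed)
    K.mc_step(*_kernel_args(state, tables, config))


def run_single_cell(config: SimConfig, seed: int,
                    tables: RuleTables | None = None) -> Trajectory:
    """Run one cell to half-maximal caspase 3 activation or the step cap.

    Identical (config, seed) pairs produce identical trajectories.
    """
    if tables is None:
        tables = build_tables(config)
    state = L.init_state(config, seed)
    stop = config.stop
    n_rows = stop.max_steps // config.record_every + 3
    rec_step = np.zeros(n_rows, dtype=np.int64)
    rec_counts = np.zeros((n_rows, L.N_SPECIES), dtype=np.int64)
    rec_extra = np.zeros((n_rows, 4), dtype=np.int64)

    rows, reason = K.run_cell(
        seed, stop.max_steps, config.record_every,
        *_kernel_args(state, tables, config),
        stop.half_max_count, L.C3,
        1 if stop.stop_on_first_apoptosome else 0,
        rec_step, rec_counts, rec_extra)

    regs = state.regs
    return Trajectory(
        seed=seed,
        steps=rec_step[:rows].copy(),
        counts=rec_counts[:rows].copy(),
        extra=rec_extra[:rows].copy(),
        release_step=int(regs[L.LatticeState.R_RELEASE_STEP]),
        first_apoptosome_step=int(regs[L.LatticeState.R_APO_STEP]),
        half_max_step=int(regs[L.LatticeState.R_HALFMAX_STEP]),
        termination=TERMINATION_REASONS[reason],
        c3_via_c8=int(regs[L.LatticeState.R_VIA_C8]),
        c3_via_c9=int(regs[L.LatticeState.R_VIA_C9]),
        c8_generated=int(regs[L.LatticeState.R_C8GEN]),
        half_max_count=stop.half_max_count)


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Independent per-cell seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n, dtype=np.uint32)]


def run_ensemble(config: SimConfig, seeds: int | list[int],
                 master_seed: int = 0) -> EnsembleResult:
    """Independent single-cell runs, one per seed.

    ``seeds`` may be an explicit seed list or a cell count (seeds are then
    spawned from ``master_seed``).  Results are independent of run order.
    """
    if isinstance(seeds, int):
        seeds = spawn_seeds(master_seed, seeds)
    if len(seeds) < 1:
        raise ValueError("at least one seed is required")
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate seeds in ensemble", stacklevel=2)
        logger.warning("duplicate seeds in ensemble: %s", seeds)
    tables = build_tables(config)
    result = EnsembleResult(config=config, seeds=list(seeds))
    for k, s in enumerate(seeds):
        result.trajectories.append(run_single_cell(config, s, tables))
        if (k + 1) % 16 == 0:
            logger.info("ensemble progress: %d/%d cells", k + 1, len(seeds))
    return result


def estimate_diffusion_constant(n_walkers: int = 10_000, n_steps: int = 400,
                                p_diff: float = 0.1, dx_nm: float = 20.0,
                                dt_s: float = 2e-4, seed: int = 0) -> float:
    """Dilute-limit effective diffusion constant from an MSD simulation.

    Follows the convention D = P_diff * dx^2 / dT (~0.2 um^2/s at defaults):
    the MSD after t steps is P_diff * t * dx^2, so D is estimated as
    MSD / (t * dT).  Uses a lattice large enough that walkers never touch
    the walls.
    """
    n = 2 * n_steps + 3   # walkers cannot reach the boundary
    msd = K.msd_walk(seed, n_walkers, n_steps, n, n, n, p_diff)
    dx_um = dx_nm * 1e-3
    return float(msd * dx_um**2 / (n_steps * dt_s))
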