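"""Membrane DISC model: adaptor switching, Metropolis clustering, caspase 8.

Death-receptor adaptor molecules live on the 2-D plasma-membrane lattice.
An adaptor is *active* while bound to a death receptor-ligand complex;
switching between active and inactive (probabilities P_on / P_off per
sampled attempt) captures death-ligand induction.  Active adaptors attract
each other: each active-active nearest-neighbor pair lowers the free energy
by ``E_DD`` (k_B T units, default -2), and adaptor diffusion is accepted by
the Metropolis criterion min[1, exp(-dE/k_B T)].  Clustered active adaptors
(at least ``min_active_neighbors`` active neighbors) recruit procaspase 8
from a well-mixed pool and convert it to active, cytosol-entering caspase 8
with per-attempt probability ``p_c8``.

This module exposes the adaptor field standalone (for clustering studies and
tests); inside a full cell run the engine schedules the same kernels within
the 2N sampling budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from . import _kernels as K
from .config import DiscConfig


@njit(cache=True)
def _randint_kernel(n):
    return np.random.randint(n)


@njit(cache=True)
def _random_kernel():
    return np.random.random()


@dataclass
class AdaptorField:
    """A 2-D lattice of adaptor molecules with binary activity state."""

    nx: int
    ny: int
    occ: np.ndarray
    x: np.ndarray
    y: np.ndarray
    active: np.ndarray
    params: DiscConfig = field(default_factory=lambda: DiscConfig(enabled=True))

    @classmethod
    def random(cls, nx: int, ny: int, n_adaptors: int, seed: int,
               params: DiscConfig | None = None,
               all_active: bool = False) -> "AdaptorField":
        if n_adaptors > nx * ny:
            raise ValueError("more adaptors than membrane sites")
        rng = np.random.default_rng(seed)
        flat = rng.choice(nx * ny, size=n_adaptors, replace=False)
        occ = np.full((nx, ny), -1, dtype=np.int64)
        x, y = flat // ny, flat % ny
        occ[x, y] = np.arange(n_adaptors)
        active = np.full(n_adaptors, 1 if all_active else 0, dtype=np.uint8)
        return cls(nx=nx, ny=ny, occ=occ, x=x.astype(np.int64),
                   y=y.astype(np.int64), active=active,
                   params=params or DiscConfig(enabled=True))

    @property
    def n_adaptors(self) -> int:
        return len(self.x)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def active_pair_count(self) -> int:
        """Active-active nearest-neighbor pairs (the clustering energy term)."""
        return int(K.adaptor_pair_count(self.occ, self.x, self.y, self.active))

    def cluster_sizes(self) -> np.ndarray:
        """Connected-component sizes of active adaptors (4-neighborhood)."""
        from scipy import ndimage
        grid = np.zeros((self.nx, self.ny), dtype=bool)
        on = self.active == 1
        grid[self.x[on], self.y[on]] = True
        labels, n = ndimage.label(grid)
        if n == 0:
            return np.zeros(0, dtype=np.int64)
        return np.bincount(labels.ravel())[1:].astype(np.int64)

    def largest_cluster(self) -> int:
        sizes = self.cluster_sizes()
        return int(sizes.max()) if len(sizes) else 0

    def snapshot(self) -> np.ndarray:
        """(x, y, active) rows for every adaptor, for cluster visualization."""
        return np.stack([self.x, self.y, self.active.astype(np.int64)], axis=1)

    def save_snapshot(self, path: str | Path) -> None:
        np.savetxt(path, self.snapshot(), fmt="%d", delimiter="\t",
                   header="x\ty\tactive", comments="")


def adaptor_switch(fld: AdaptorField, adaptor: int,
                   seed: int | None = None) -> bool:
    """One activity-switching attempt; returns True if the state flipped.

    Inactive -> active with probability P_on, active -> inactive with P_off.
    """
    if not 0 <= adaptor < fld.n_adaptors:
        raise ValueError(f"no adaptor {adaptor}")
    if seed is not None:
        K.seed_rng(seed)
    before = fld.active[adaptor]
    p = fld.params.p_off if before else fld.params.p_on
    if float(_random_kernel()) >= p:
        return False
    fld.active[adaptor] = 0 if before else 1
    return True


def disc_metropolis_move(fld: AdaptorField, adaptor: int,
                         seed: int | None = None) -> bool:
    """One Metropolis diffusion attempt for an adaptor; True if it moved."""
    if not 0 <= adaptor < fld.n_adaptors:
        raise ValueError(f"no adaptor {adaptor}")
    if seed is not None:
        K.seed_rng(seed)
    return bool(K.adaptor_metropolis_move(fld.occ, fld.x, fld.y, fld.active,
                                          adaptor, fld.params.e_dd))


def generate_caspase8(fld: AdaptorField, state, adaptor: int,
                      seed: int | None = None) -> bool:
    """One caspase-8 generation attempt by an adaptor into a lattice state.

    Requires an active adaptor with at least ``min_active_neighbors`` active
    neighbors and a nonempty procaspase-8 pool; on success one caspase 8
    appears at the adaptor's membrane-adjacent site.
    """
    from . import lattice as L
    if seed is not None:
        K.seed_rng(seed)
    p = fld.params
    before = int(state.regs[L.LatticeState.R_C8GEN])
    K.adaptor_react(
        fld.occ, fld.x, fld.y, fld.active, adaptor,
        0.0, 0.0, p.p_c8, p.min_active_neighbors, L.C8,
        state.occ, state.msite, state.species, state.comp,
        state.act, state.act_idx, state.counts, state.free_stack, state.regs,
        state.spec.ny, state.spec.nz, state.in_block, state.is_shell)
    return int(state.regs[L.LatticeState.R_C8GEN]) > before


def metropolis_sweep(fld: AdaptorField, n_sweeps: int, seed: int,
                     switching: bool = False) -> None:
    """Run ``n_sweeps`` x n_adaptors random single-adaptor attempts.

    Each attempt is a Metropolis move; with ``switching`` every attempt is
    followed by an activity-switching draw.  Used for standalone clustering
    studies at fixed or evolving activity.
    """
    K.seed_rng(seed)
    na = fld.n_adaptors
    for _ in range(n_sweeps * na):
        j = int(_randint_kernel(na))
        K.adaptor_metropolis_move(fld.occ, fld.x, fld.y, fld.active, j,
                                  fld.params.e_dd)
        if switching:
            adaptor_switch(fld, j)
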