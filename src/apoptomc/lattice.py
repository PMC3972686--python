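"""Lattice geometry and molecule representation for the death-signaling simulator.

The cell is a cubic lattice of sites (default 60x60x60, spacing ~20 nm, so the
whole volume is ~1.2 um per side).  One lattice site holds at most one molecule
or complex (mutual physical exclusion).  The volume is chosen so that one
molecule corresponds to one nanomolar of concentration, which makes the
configuration tables read directly in nM.  A centered axis-aligned block
(default 18x18x18) represents the mitochondrion: cytochrome c and Smac start
inside it and stay there until outer-membrane permeabilization.  The z = 0
face of the lattice is the plasma membrane and hosts the DISC adaptor field.

Compartment codes used throughout:

====  =========================  ==============================
code  compartment                mobility
====  =========================  ==============================
0     cytosol                    P_diff = 0.1 per sampled move
1     mitochondrial interior     P_diff = 0.1, confined to block
2     mitochondrial membrane     P_diff = 0.01, confined to the
                                 one-site shell around the block
====  =========================  ==============================

Apoptosome-containing complexes are immobile regardless of compartment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

# --------------------------------------------------------------------------
# species registry
# --------------------------------------------------------------------------

#: Species ids.  Complexes are first-class species occupying a single site.
C8 = 0
PROC3 = 1
C3 = 2
C8_PROC3 = 3
C8_BID = 4
BID = 5
TBID = 6
BAX = 7
TBID_BAX = 8
BAX2 = 9
BID_BAX = 10
BCL2 = 11
BCL2_TBID = 12
BCL2_BAX = 13
CYTC = 14
SMAC = 15
APAF = 16
CYTC_APAF = 17
APO = 18
PROC9 = 19
APO_PROC9 = 20
C9 = 21
C9_PROC3 = 22
XIAP = 23
XIAP_PROC9 = 24
XIAP_C9 = 25
XIAP_C3 = 26
SMAC_XIAP = 27

N_SPECIES = 28

SPECIES_NAMES = [
    "C8", "proC3", "C3", "C8:proC3", "C8:Bid", "Bid", "tBid", "Bax",
    "tBid:Bax", "Bax2*", "Bid:Bax", "Bcl2", "Bcl2:tBid", "Bcl2:Bax",
    "cytc", "Smac", "Apaf", "cytc:Apaf", "apoptosome", "proC9",
    "apo:proC9", "C9", "C9:proC3", "XIAP", "XIAP:proC9", "XIAP:C9",
    "XIAP:C3", "Smac:XIAP",
]

SPECIES_IDS = {name: i for i, name in enumerate(SPECIES_NAMES)}

#: Free species a configuration may seed (name -> id).
SEEDABLE_SPECIES = {
    "C8": C8, "proC3": PROC3, "Bid": BID, "Bax": BAX, "Bcl2": BCL2,
    "cytc": CYTC, "Smac": SMAC, "Apaf": APAF, "proC9": PROC9, "XIAP": XIAP,
}

#: Elementary constituents of each species, for mass-balance audits.  C3 and
#: tBid count as their zymogen/precursor (proC3, Bid); the Bax dimer counts
#: two Bax.
_BASE = ["C8", "proC3", "Bid", "Bax", "Bcl2", "cytc", "Smac", "Apaf",
         "proC9", "XIAP"]
_B = {name: i for i, name in enumerate(_BASE)}

CONSTITUENTS = np.zeros((N_SPECIES, len(_BASE)), dtype=np.int64)
for _sp, _parts in {
    C8: ["C8"], PROC3: ["proC3"], C3: ["proC3"],
    C8_PROC3: ["C8", "proC3"], C8_BID: ["C8", "Bid"],
    BID: ["Bid"], TBID: ["Bid"], BAX: ["Bax"],
    TBID_BAX: ["Bid", "Bax"], BAX2: ["Bax", "Bax"], BID_BAX: ["Bid", "Bax"],
    BCL2: ["Bcl2"], BCL2_TBID: ["Bcl2", "Bid"], BCL2_BAX: ["Bcl2", "Bax"],
    CYTC: ["cytc"], SMAC: ["Smac"], APAF: ["Apaf"],
    CYTC_APAF: ["cytc", "Apaf"], APO: ["cytc", "cytc", "Apaf", "Apaf"],
    PROC9: ["proC9"], APO_PROC9: ["cytc", "cytc", "Apaf", "Apaf", "proC9"],
    C9: ["proC9"], C9_PROC3: ["proC9", "proC3"],
    XIAP: ["XIAP"], XIAP_PROC9: ["XIAP", "proC9"], XIAP_C9: ["XIAP", "proC9"],
    XIAP_C3: ["XIAP", "proC3"], SMAC_XIAP: ["Smac", "XIAP"],
}.items():
    for _p in _parts:
        CONSTITUENTS[_sp, _B[_p]] += 1

#: Species that never move (multimolecular apoptosome assemblies).
IMMOBILE_SPECIES = (APO, APO_PROC9)

CYTOSOL, MITO_INTERIOR, MITO_MEMBRANE = 0, 1, 2


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LatticeSpec:
    """Geometry and clock of one in-silico cell.

    ``mito_dims = (0, 0, 0)`` disables the mitochondrial block (used by small
    test fixtures).  The block is centered; only its size is physically
    constrained.
    """

    nx: int = 60
    ny: int = 60
    nz: int = 60
    dx_nm: float = 20.0
    dt_s: float = 2e-4
    mito_dims: tuple[int, int, int] = (18, 18, 18)

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 2:
            raise ValueError("all lattice dimensions must be >= 2")
        if self.dx_nm <= 0 or self.dt_s <= 0:
            raise ValueError("dx and dT must be positive")
        if any(m < 0 for m in self.mito_dims):
            raise ValueError("mitochondrial dimensions must be >= 0")
        if any(m > n for m, n in zip(self.mito_dims, (self.nx, self.ny, self.nz))):
            raise ValueError("mitochondrial subvolume must fit inside the lattice")

    @property
    def n_sites(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def mito_origin(self) -> tuple[int, int, int]:
        return tuple((n - m) // 2 for n, m in
                     zip((self.nx, self.ny, self.nz), self.mito_dims))

    def in_block_mask(self) -> np.ndarray:
        """Boolean mask over sites inside the mitochondrial block."""
        mask = np.zeros((self.nx, self.ny, self.nz), dtype=bool)
        mx, my, mz = self.mito_dims
        if mx and my and mz:
            ox, oy, oz = self.mito_origin
            mask[ox:ox + mx, oy:oy + my, oz:oz + mz] = True
        return mask

    def neighbor_table(self) -> np.ndarray:
        """(n_sites, 6) flat-index face-neighbor table; -1 = off-lattice."""
        nx, ny, nz = self.nx, self.ny, self.nz
        idx = np.arange(self.n_sites)
        x = idx // (ny * nz)
        y = (idx // nz) % ny
        z = idx % nz
        table = np.full((self.n_sites, 6), -1, dtype=np.int64)
        for d, (dx, dy, dz) in enumerate(_OFFSETS):
            tx, ty, tz = x + dx, y + dy, z + dz
            ok = ((tx >= 0) & (tx < nx) & (ty >= 0) & (ty < ny)
                  & (tz >= 0) & (tz < nz))
            table[ok, d] = (tx[ok] * ny + ty[ok]) * nz + tz[ok]
        return table

    def shell_mask(self) -> np.ndarray:
        """Sites outside the block with a face neighbor inside it."""
        blk = self.in_block_mask()
        shell = np.zeros_like(blk)
        for ax in range(3):
            for sh in (1, -1):
                shell |= np.roll(blk, sh, axis=ax)
        # roll wraps around; wrapped faces are harmless because the block is
        # interior (origin > 0 for every paper geometry), but clear them when
        # the block touches a wall
        shell &= ~blk
        return shell


def concentration_to_count(concentration_nM: float) -> int:
    """Map a nanomolar concentration to a molecule count (1 nM <-> 1 molecule).

    Round-half-up so that user-supplied fractional concentrations behave
    predictably; in-scenario concentrations are integers.
    """
    if concentration_nM < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration_nM}")
    return int(math.floor(concentration_nM + 0.5))


_OFFSETS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


def neighbors(site: tuple[int, ...], spec: LatticeSpec,
              mobility: str = "cytosol") -> list[tuple[int, ...]]:
    """In-lattice face neighbors of a site (reflecting walls).

    Cytosolic molecules have six neighbors, membrane-resident molecules four
    in-plane neighbors.  ``mobility`` is ``"cytosol"`` or ``"membrane"``; for
    membrane sites the 2-D plane coordinates ``(x, y)`` are expected.
    """
    if mobility == "membrane":
        x, y = site
        if not (0 <= x < spec.nx and 0 <= y < spec.ny):
            raise ValueError(f"site {site} outside membrane plane")
        out2 = [(x + dx, y + dy) for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1))]
        return [(a, b) for a, b in out2 if 0 <= a < spec.nx and 0 <= b < spec.ny]
    x, y, z = site
    if not (0 <= x < spec.nx and 0 <= y < spec.ny and 0 <= z < spec.nz):
        raise ValueError(f"site {site} outside lattice")
    out = [(x + dx, y + dy, z + dz) for dx, dy, dz in _OFFSETS]
    return [(a, b, c) for a, b, c in out
            if 0 <= a < spec.nx and 0 <= b < spec.ny and 0 <= c < spec.nz]


# --------------------------------------------------------------------------
# mutable lattice state
# --------------------------------------------------------------------------

@dataclass
class LatticeState:
    """Array-of-struct state shared between the Python API and the kernels.

    ``occ`` maps flat site index -> molecule slot (-1 empty).  ``act`` lists
    the live slots; ``act_idx[slot]`` is the slot's position in ``act`` (-1 if
    dead).  Scalar registers that the kernels mutate live in ``regs``:

    ``regs = [n_live, released, proc8_pool, c3_via_c8, c3_via_c9,
    release_step, first_apoptosome_step, half_max_step, c8_generated, step]``
    """

    spec: LatticeSpec
    occ: np.ndarray
    msite: np.ndarray
    species: np.ndarray
    comp: np.ndarray
    act: np.ndarray
    act_idx: np.ndarray
    counts: np.ndarray
    in_block: np.ndarray
    is_shell: np.ndarray
    nbr: np.ndarray
    regs: np.ndarray
    free_stack: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    # adaptor field (empty arrays when DISC is disabled)
    mem_occ: np.ndarray = field(default_factory=lambda: np.full((0, 0), -1, np.int64))
    ad_x: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    ad_y: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    ad_active: np.ndarray = field(default_factory=lambda: np.zeros(0, np.uint8))

    # registers
    R_NLIVE, R_RELEASED, R_POOL, R_VIA_C8, R_VIA_C9 = 0, 1, 2, 3, 4
    R_RELEASE_STEP, R_APO_STEP, R_HALFMAX_STEP, R_C8GEN, R_STEP = 5, 6, 7, 8, 9
    R_NFREE = 10

    @property
    def n_molecules(self) -> int:
        return int(self.regs[self.R_NLIVE])

    @property
    def n_adaptors(self) -> int:
        return len(self.ad_x)

    @property
    def released(self) -> bool:
        return bool(self.regs[self.R_RELEASED])

    def species_counts(self) -> dict[str, int]:
        return {name: int(self.counts[i]) for i, name in enumerate(SPECIES_NAMES)
                if self.counts[i]}

    def coordinates(self, slots: np.ndarray) -> np.ndarray:
        """(n, 3) integer coordinates of the given molecule slots."""
        s = self.msite[slots]
        ny, nz = self.spec.ny, self.spec.nz
        return np.stack([s // (ny * nz), (s // nz) % ny, s % nz], axis=1)

    def positions_of(self, species_id: int) -> np.ndarray:
        live = self.act[: self.n_molecules]
        return self.coordinates(live[self.species[live] == species_id])

    def constituent_totals(self) -> np.ndarray:
        """Total elementary molecules, counting complexes by composition."""
        return self.counts @ CONSTITUENTS

    def check_exclusion(self) -> None:
        """Assert one molecule per site and occupancy/registry consistency."""
        live = self.act[: self.n_molecules]
        flat = self.msite[live]
        if len(np.unique(flat)) != len(flat):
            raise AssertionError("two molecules share a lattice site")
        if (self.occ >= 0).sum() != len(flat):
            raise AssertionError("occupancy grid out of sync with registry")
        if not np.all(self.occ[flat] == live):
            raise AssertionError("occupancy grid points at wrong molecules")


def _place_uniform(rng: np.random.Generator, free_sites: np.ndarray, n: int,
                   compartment: str) -> np.ndarray:
    if n > len(free_sites):
        raise ValueError(
            f"cannot place {n} molecules in compartment '{compartment}' "
            f"({len(free_sites)} free sites)")
    pick = rng.choice(len(free_sites), size=n, replace=False)
    return free_sites[pick]


def init_state(config, seed: int) -> LatticeState:
    """Place all configured molecules at distinct random sites.

    Cytochrome c and Smac go inside the mitochondrial block, everything else
    into the cytosol (outside the block).  Deterministic given ``seed``.
    """
    spec: LatticeSpec = config.lattice
    rng = np.random.default_rng(seed)
    in_block = spec.in_block_mask()
    is_shell = spec.shell_mask()
    flat_block = np.flatnonzero(in_block.ravel())
    flat_cyto = np.flatnonzero(~in_block.ravel())

    species_counts: list[tuple[int, int, int]] = []   # (species, count, comp)
    for name, conc in config.concentrations.items():
        if name not in SEEDABLE_SPECIES:
            raise ValueError(f"unknown species '{name}' in concentration table")
        cnt = concentration_to_count(conc)
        if cnt == 0:
            continue
        sp = SEEDABLE_SPECIES[name]
        comp = MITO_INTERIOR if sp in (CYTC, SMAC) else CYTOSOL
        species_counts.append((sp, cnt, comp))

    n0 = sum(c for _, c, _ in species_counts)
    pool = config.disc.proc8_pool if config.disc.enabled else 0
    cap = n0 + pool + 8

    occ = np.full(spec.n_sites, -1, dtype=np.int64)
    msite = np.zeros(cap, dtype=np.int64)
    species = np.full(cap, -1, dtype=np.int64)
    comp_arr = np.zeros(cap, dtype=np.int64)
    counts = np.zeros(N_SPECIES, dtype=np.int64)

    mito_free = flat_block.copy()
    cyto_free = flat_cyto.copy()
    slot = 0
    for sp, cnt, comp in species_counts:
        if comp == MITO_INTERIOR:
            if len(flat_block) == 0:
                raise ValueError(
                    "cannot place mitochondrial species: no mitochondrial block")
            sites = _place_uniform(rng, mito_free, cnt, "mitochondrial interior")
            mito_free = np.setdiff1d(mito_free, sites, assume_unique=True)
        else:
            sites = _place_uniform(rng, cyto_free, cnt, "cytosol")
            cyto_free = np.setdiff1d(cyto_free, sites, assume_unique=True)
        for s in sites:
            occ[s] = slot
            msite[slot] = s
            species[slot] = sp
            comp_arr[slot] = comp
            slot += 1
        counts[sp] += cnt

    act = np.full(cap, -1, dtype=np.int64)
    act[:n0] = np.arange(n0)
    act_idx = np.full(cap, -1, dtype=np.int64)
    act_idx[:n0] = np.arange(n0)

    regs = np.zeros(16, dtype=np.int64)
    regs[LatticeState.R_NLIVE] = n0
    regs[LatticeState.R_POOL] = pool
    regs[LatticeState.R_RELEASE_STEP] = -1
    regs[LatticeState.R_APO_STEP] = -1
    regs[LatticeState.R_HALFMAX_STEP] = -1
    free_stack = np.zeros(cap, dtype=np.int64)
    n_free = cap - n0
    free_stack[:n_free] = np.arange(cap - 1, n0 - 1, -1)
    regs[LatticeState.R_NFREE] = n_free

    state = LatticeState(
        spec=spec, occ=occ, msite=msite, species=species,
        comp=comp_arr, act=act, act_idx=act_idx, counts=counts,
        in_block=in_block.ravel().astype(np.uint8),
        is_shell=is_shell.ravel().astype(np.uint8),
        nbr=spec.neighbor_table(), regs=regs, free_stack=free_stack)

    if config.disc.enabled:
        n_ad = config.disc.resolved_adaptor_count(spec)
        if n_ad > spec.nx * spec.ny:
            raise ValueError(
                f"cannot place {n_ad} adaptors on plasma membrane "
                f"({spec.nx * spec.ny} sites)")
        mem_occ = np.full((spec.nx, spec.ny), -1, dtype=np.int64)
        flat = rng.choice(spec.nx * spec.ny, size=n_ad, replace=False)
        ax, ay = flat // spec.ny, flat % spec.ny
        mem_occ[ax, ay] = np.arange(n_ad)
        state.mem_occ = mem_occ
        state.ad_x = ax.astype(np.int64)
        state.ad_y = ay.astype(np.int64)
        state.ad_active = np.zeros(n_ad, dtype=np.uint8)
    return state


def immobile_mask() -> np.ndarray:
    mask = np.zeros(N_SPECIES, dtype=np.uint8)
    for sp in IMMOBILE_SPECIES:
        mask[sp] = 1
    return mask


def attempt_diffusion(state: LatticeState, molecule: int,
                      seed: int | None = None,
                      p_diff_cytosol: float = 0.1,
                      p_diff_membrane: float = 0.01) -> bool:
    """Attempt one diffusion move for ``molecule`` (a live slot id).

    With the mobility-class probability a uniformly chosen face neighbor is
    targeted; the move succeeds only if the target is free and inside the
    molecule's allowed region.  Returns True if the molecule moved.  ``seed``
    reseeds the kernel RNG (for reproducible single moves); by default the
    running kernel stream is used.
    """
    from . import _kernels as K
    if state.act_idx[molecule] < 0:
        raise ValueError(f"molecule {molecule} is not alive")
    if seed is not None:
        K.seed_rng(seed)
    return bool(K.diffuse_one(
        state.occ, state.msite, state.species, state.comp, state.nbr,
        state.in_block, state.is_shell, state.regs, molecule,
        p_diff_cytosol, p_diff_membrane, immobile_mask()))
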