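"""Coarse-grained type 1 / type 2 loop network with stochastic solvers.

The minimal network strips the death pathway to four catalytic channels.  A
stimulus species X0 (the active caspase 8 analog, count fixed) opens both
arms of the loop:

* type 1: X0 converts X3 -> X3* directly (rate ``k_type1``, default 2e-4);
* type 2: X0 converts X1 -> X1* (``k_fast1`` = 1.0), X1* drives the slow
  conversion X2 -> X2* (``k_slow`` = 1e-7), and X2* converts X3 -> X3*
  (``k_fast2`` = 0.1).

X3* is the effector-caspase analog; every X3* produced is attributed to the
channel that made it, which defines the type-1 vs type-2 share.  Each
conversion conserves its species pair (Xi + Xi* constant).

Three interchangeable solvers are provided: exact SSA (Gillespie direct
method), chemical-Langevin Euler-Maruyama, and the hybrid "Poisson-RK"
scheme in which the slow channel fires as a Poisson count with mean
``k_slow * X1* * X2 * dt`` per time step while the remaining channels are
integrated by Euler-Maruyama.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: substrate pool indices
X1, X2, X3 = 0, 1, 2
#: catalyst kinds
CAT_X0, CAT_POOL = 0, 1

METHODS = ("euler_maruyama", "poisson_rk", "ssa")


@dataclass(frozen=True)
class MinimalNetworkSpec:
    """Parameters of the minimal loop network."""

    x0: float = 1.0
    x1: int = 100
    x2: int = 100
    x3: int = 100
    k_type1: float = 2e-4
    k_fast1: float = 1.0
    k_slow: float = 1e-7
    k_fast2: float = 1e-1
    dt: float = 0.01
    horizon: float = 2000.0

    def __post_init__(self) -> None:
        if min(self.k_type1, self.k_fast1, self.k_slow, self.k_fast2) < 0:
            raise ValueError("rate constants must be >= 0")
        if self.x0 < 0 or min(self.x1, self.x2, self.x3) < 0:
            raise ValueError("counts must be >= 0")
        if self.dt <= 0 or self.horizon <= 0:
            raise ValueError("dt and horizon must be positive")


@dataclass(frozen=True)
class Channel:
    """One catalytic conversion channel: catalyst + substrate -> product."""

    name: str
    rate: float
    cat_kind: int      # CAT_X0 or CAT_POOL
    cat_idx: int       # activated-pool index when CAT_POOL
    sub_idx: int       # which (Xi, Xi*) pair is converted
    slow: bool = False  # fired as a Poisson count in the hybrid scheme

    def propensity(self, x0: float, y: np.ndarray, totals: np.ndarray):
        cat = x0 if self.cat_kind == CAT_X0 else y[..., self.cat_idx]
        return self.rate * cat * (totals[self.sub_idx] - y[..., self.sub_idx])


@dataclass
class MinimalNetwork:
    spec: MinimalNetworkSpec
    channels: list = field(default_factory=list)

    @property
    def totals(self) -> np.ndarray:
        return np.array([self.spec.x1, self.spec.x2, self.spec.x3], dtype=float)


def build_minimal_network(spec: MinimalNetworkSpec,
                          channels: list | None = None) -> MinimalNetwork:
    """Assemble the loop network (or any custom wiring passed explicitly).

    The default wiring is a reconstruction of the published schematic: one
    direct slow type-1 channel catalyzed by X0, and a three-step type-2
    cascade whose middle step is the slow one; the printed rate list fixes
    the assignment.
    """
    if channels is None:
        channels = [
            Channel("type1", spec.k_type1, CAT_X0, -1, X3),
            Channel("fast1", spec.k_fast1, CAT_X0, -1, X1),
            Channel("slow", spec.k_slow, CAT_POOL, X1, X2, slow=True),
            Channel("fast2", spec.k_fast2, CAT_POOL, X2, X3),
        ]
    return MinimalNetwork(spec=spec, channels=channels)


def slow_channel_step(k_slow: float, x1_star: float, x2: float, dt: float,
                      rng: np.random.Generator) -> int:
    """Poisson firing count of the slow channel over one time step.

    The count has mean (and variance) ``k_slow * X1* * X2 * dt``, truncated
    so the X2 pool stays non-negative.
    """
    lam = k_slow * x1_star * x2 * dt
    if lam < 0:
        raise ValueError("negative propensity")
    return int(min(rng.poisson(lam), int(x2)))


@dataclass
class MinimalResult:
    """Trajectory ensemble of the minimal network.

    ``y[(traj, time, pool)]`` holds activated counts (X1*, X2*, X3*);
    ``via[(traj, time, 0/1)]`` the cumulative X3* produced through the
    type-1 vs type-2 channel.
    """

    spec: MinimalNetworkSpec
    method: str
    times: np.ndarray
    y: np.ndarray
    via: np.ndarray

    @property
    def x3_star(self) -> np.ndarray:
        return self.y[:, :, X3]

    def type1_share(self) -> np.ndarray:
        """Per-trajectory final share of X3* made by the type-1 channel."""
        via = np.clip(self.via[:, -1, :], 0.0, None)
        tot = via.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, via[:, 0] / np.maximum(tot, 1e-300),
                            np.nan)

    def type2_share(self) -> np.ndarray:
        return 1.0 - self.type1_share()


def _record_times(spec: MinimalNetworkSpec, n_records: int) -> np.ndarray:
    return np.linspace(0.0, spec.horizon, n_records)


def _integrate_hybrid(net: MinimalNetwork, n_traj: int, rng, n_records: int,
                      poisson_slow: bool, noise_scale: float) -> MinimalResult:
    spec = net.spec
    totals = net.totals
    dt = spec.dt
    n_steps = int(round(spec.horizon / dt))
    rec_t = _record_times(spec, n_records)
    rec_idx = np.round(rec_t / dt).astype(np.int64)

    # stability: per-step deterministic drift must not exceed any pool
    for ch in net.channels:
        cat_max = spec.x0 if ch.cat_kind == CAT_X0 else totals[ch.cat_idx]
        if ch.rate * cat_max * totals[ch.sub_idx] * dt > totals[ch.sub_idx]:
            raise ValueError(
                f"dt = {dt} too large for channel '{ch.name}' "
                "(drift per step exceeds the species total)")

    y = np.zeros((n_traj, 3))
    via = np.zeros((n_traj, 2))
    out_y = np.zeros((n_traj, len(rec_t), 3))
    out_via = np.zeros((n_traj, len(rec_t), 2))
    rec_map = {}
    for k, idx in enumerate(rec_idx):
        rec_map.setdefault(int(idx), []).append(k)

    def record(step):
        for k in rec_map.get(step, ()):
            out_y[:, k, :] = y
            out_via[:, k, :] = via

    record(0)
    for step in range(1, n_steps + 1):
        inc = np.zeros((n_traj, 3))
        inc3 = np.zeros((n_traj, 2))
        for ch in net.channels:
            a = np.maximum(ch.propensity(spec.x0, y, totals), 0.0)
            if poisson_slow and ch.slow:
                d = rng.poisson(a * dt).astype(float)
            else:
                d = a * dt + noise_scale * np.sqrt(a * dt) * rng.standard_normal(n_traj)
            inc[:, ch.sub_idx] += d
            if ch.sub_idx == X3:
                inc3[:, 0 if ch.cat_kind == CAT_X0 else 1] += d
        y_new = y + inc
        # clamp to [0, total] per conserved pair; X3 overshoot is scaled back
        # proportionally across the two producing channels
        over = y_new[:, X3] > totals[X3]
        if np.any(over):
            room = totals[X3] - y[over, X3]
            tot_inc = np.maximum(inc[over, X3], 1e-300)
            scale = np.clip(room / tot_inc, 0.0, 1.0)
            inc3[over] *= scale[:, None]
            y_new[over, X3] = y[over, X3] + inc[over, X3] * scale
        # signed increments keep the channel attribution unbiased: the noise
        # of the Langevin terms cancels in expectation instead of being
        # rectified into spurious production
        via += inc3
        y = np.clip(y_new, 0.0, totals)
        record(step)
    return MinimalResult(spec=spec, method="poisson_rk" if poisson_slow
                         else "euler_maruyama", times=rec_t, y=out_y,
                         via=out_via)


def _integrate_ssa(net: MinimalNetwork, n_traj: int, rng,
                   n_records: int) -> MinimalResult:
    spec = net.spec
    totals = net.totals
    rec_t = _record_times(spec, n_records)
    out_y = np.zeros((n_traj, len(rec_t), 3))
    out_via = np.zeros((n_traj, len(rec_t), 2))
    for m in range(n_traj):
        y = np.zeros(3)
        via = np.zeros(2)
        t = 0.0
        k_rec = 0
        while True:
            a = np.array([max(ch.propensity(spec.x0, y, totals), 0.0)
                          for ch in net.channels])
            a0 = a.sum()
            t_next = t + (rng.exponential(1.0 / a0) if a0 > 0 else np.inf)
            while k_rec < len(rec_t) and rec_t[k_rec] < t_next:
                out_y[m, k_rec] = y
                out_via[m, k_rec] = via
                k_rec += 1
            if k_rec >= len(rec_t):
                break
            t = t_next
            c = int(np.searchsorted(np.cumsum(a), rng.random() * a0, side="right"))
            ch = net.channels[min(c, len(net.channels) - 1)]
            y[ch.sub_idx] += 1
            if ch.sub_idx == X3:
                via[0 if ch.cat_kind == CAT_X0 else 1] += 1
    return MinimalResult(spec=spec, method="ssa", times=rec_t, y=out_y,
                         via=out_via)


def integrate(spec: MinimalNetworkSpec, method: str = "poisson_rk",
              n_traj: int = 64, seed: int = 0, n_records: int = 101,
              channels: list | None = None,
              noise_scale: float = 1.0) -> MinimalResult:
    """Run an ensemble of minimal-network trajectories.

    ``noise_scale = 0`` turns Euler-Maruyama into the deterministic Euler
    ODE scheme (used for limit tests).
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    net = build_minimal_network(spec, channels)
    rng = np.random.default_rng(seed)
    if method == "ssa":
        return _integrate_ssa(net, n_traj, rng, n_records)
    return _integrate_hybrid(net, n_traj, rng, n_records,
                             poisson_slow=(method == "poisson_rk"),
                             noise_scale=noise_scale)
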