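"""Trajectory and ensemble statistics.

Pathway classification attributes each activated caspase 3 molecule to the
caspase that produced it (caspase 8 = type 1 channel, caspase 9 = type 2
channel); a cell is type 1 (type 2) when the caspase-8 (caspase-9) share at
half-maximal activation is at least the threshold tau (default 0.8), mixed
otherwise, and unclassified when no caspase 3 was activated.  Summary tables
report caspase 3 activation normalized to its half-maximal value (count 50
at full scale), averaged over cells, with population standard deviations
(divide by n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .engine import EnsembleResult, Trajectory
from .kinetics import RateTriple


@dataclass(frozen=True)
class CellOutcome:
    classification: str           # type1 | type2 | mixed | none
    normalized: dict              # step -> activation fraction (capped at 1)
    release_step: int
    first_apoptosome_step: int
    time_to_death: int            # half-max step, -1 if not reached
    c8_share: float
    c9_share: float


def provenance_shares(traj: Trajectory) -> tuple[float, float]:
    tot = traj.total_c3_activated
    if tot == 0:
        return 0.0, 0.0
    return traj.c3_via_c8 / tot, traj.c3_via_c9 / tot


def classify_pathway(traj: Trajectory, tau: float = 0.8) -> str:
    """Classify a cell from its caspase-3 provenance counters.

    Evaluated at the half-max event (the counters freeze when the run stops;
    for cells that never reach half-max the final counters are used).
    """
    if not 0.5 < tau <= 1.0:
        raise ValueError("tau must be in (0.5, 1]")
    if traj.total_c3_activated == 0:
        return "none"
    c8, c9 = provenance_shares(traj)
    if c8 >= tau:
        return "type1"
    if c9 >= tau:
        return "type2"
    return "mixed"


def cell_outcome(traj: Trajectory, time_points, tau: float = 0.8) -> CellOutcome:
    c8, c9 = provenance_shares(traj)
    return CellOutcome(
        classification=classify_pathway(traj, tau),
        normalized={int(t): traj.normalized_activation(int(t))
                    for t in time_points},
        release_step=traj.release_step,
        first_apoptosome_step=traj.first_apoptosome_step,
        time_to_death=traj.half_max_step,
        c8_share=c8, c9_share=c9)


def _pop_sd(x) -> float:
    """Population standard deviation (divide by n); 0 for a single value."""
    x = np.asarray(x, dtype=float)
    return float(np.sqrt(np.mean((x - x.mean()) ** 2))) if len(x) else float("nan")


def ensemble_summary(ensemble: EnsembleResult, time_points) -> pd.DataFrame:
    """Per-time-point ensemble summary of caspase 3 activation.

    Columns: mean and population SD of normalized activation, fraction of
    cells at half-max, and (once per table, repeated per row) mean
    time-to-release and time-to-first-apoptosome among cells where the event
    occurred, with occurrence counts.
    """
    trajs = ensemble.trajectories
    if not trajs:
        raise ValueError("empty ensemble")
    rel = [t.release_step for t in trajs if t.release_step >= 0]
    apo = [t.first_apoptosome_step for t in trajs if t.first_apoptosome_step >= 0]
    rows = []
    for tp in time_points:
        acts = [t.normalized_activation(int(tp)) for t in trajs]
        dead = [t.half_max_step >= 0 and t.half_max_step <= tp for t in trajs]
        rows.append({
            "step": int(tp),
            "mean_activation": float(np.mean(acts)),
            "sd_activation": _pop_sd(acts),
            "fraction_half_max": float(np.mean(dead)),
            "n_cells": len(trajs),
            "mean_release_step": float(np.mean(rel)) if rel else float("nan"),
            "n_released": len(rel),
            "mean_apoptosome_step": float(np.mean(apo)) if apo else float("nan"),
            "n_apoptosome": len(apo),
        })
    return pd.DataFrame(rows)


def variability_decomposition(ensemble: EnsembleResult) -> pd.DataFrame:
    """Per-cell event-time table: release, first apoptosome, time-to-death.

    Missing events are NaN and excluded from the column SDs (reported in the
    attached ``.attrs['sd']``).
    """
    rows = []
    for t in ensemble.trajectories:
        rows.append({
            "seed": t.seed,
            "release_step": t.release_step if t.release_step >= 0 else np.nan,
            "apoptosome_step": (t.first_apoptosome_step
                                if t.first_apoptosome_step >= 0 else np.nan),
            "time_to_death": t.half_max_step if t.half_max_step >= 0 else np.nan,
        })
    df = pd.DataFrame(rows)
    df.attrs["sd"] = {
        col: _pop_sd(df[col].dropna().to_numpy())
        for col in ("release_step", "apoptosome_step", "time_to_death")}
    return df


def early_time_partition(c8_0: float, bid_0: float, proc3_0: float,
                         rates_bid: RateTriple, rates_proc3: RateTriple,
                         horizon: float, n_points: int = 200):
    """Competitive caspase-8 partitioning between Bid and procaspase 3.

    Integrates the mass-action ODEs of the two competing binding reactions
    (shared free caspase 8; association/dissociation only) and returns
    ``(times, ratio)`` where ratio(t) = [C8:Bid] / [C8:proC3], together with
    the linear early-time approximation k_on,Bid*Bid0 / (k_on,proC3*proC3_0)
    valid while both complexes are scarce.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if min(c8_0, bid_0, proc3_0) < 0:
        raise ValueError("concentrations must be >= 0")

    kon_b, koff_b = rates_bid.k_on, rates_bid.k_off
    kon_p, koff_p = rates_proc3.k_on, rates_proc3.k_off

    def rhs(_t, yv):
        cb, cp = yv
        c8 = c8_0 - cb - cp
        return [kon_b * c8 * (bid_0 - cb) - koff_b * cb,
                kon_p * c8 * (proc3_0 - cp) - koff_p * cp]

    times = np.linspace(0.0, horizon, n_points)
    sol = solve_ivp(rhs, (0.0, horizon), [0.0, 0.0], t_eval=times,
                    method="LSODA", rtol=1e-9, atol=1e-12)
    cb, cp = sol.y
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(cp > 0, cb / np.maximum(cp, 1e-300), np.inf)
    ratio[0] = np.nan   # both complexes are zero at t = 0
    if kon_p * proc3_0 > 0:
        linear = (kon_b * bid_0) / (kon_p * proc3_0)
    else:
        linear = np.inf
    if bid_0 == 0:
        ratio[1:] = 0.0
        linear = 0.0
    return times, ratio, linear


def type1_fraction(ensemble: EnsembleResult, tau: float = 0.8) -> float:
    """Fraction of cells classified type 1."""
    cls = [classify_pathway(t, tau) for t in ensemble.trajectories]
    return float(np.mean([c == "type1" for c in cls]))


def mean_c8_share(ensemble: EnsembleResult) -> float:
    """Mean caspase-8 share of activated caspase 3 over cells with any."""
    shares = [provenance_shares(t)[0] for t in ensemble.trajectories
              if t.total_c3_activated > 0]
    return float(np.mean(shares)) if shares else float("nan")
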