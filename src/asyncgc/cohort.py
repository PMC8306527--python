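"""Scheduling and aggregation of asynchronous representative GCs.

Hundreds of GCs form asynchronously in a lymphoid organ after primary
immunization. The cumulative number formed by time t is modeled with a Hill
function; the formation window is split into equal intervals and one
*representative* GC is simulated per interval, weighted by the Hill mass of
its interval (every non-simulated GC of the interval is assumed to behave
identically to its representative). Cohort observables are the weighted
number of active GCs (live cells above a counting threshold) and the weighted
total volume over time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field
from scipy import stats

from .gc_engine import GCParams, GCRun, run_gc
from .shape_space import Epitope, FounderSpec
from .util import child_seed

__all__ = [
    "HillParams",
    "CohortSchedule",
    "CohortResult",
    "hill_cumulative",
    "build_schedule",
    "gc_lifetime",
    "count_active_gcs",
    "total_volume",
    "run_cohort",
]


class HillParams(BaseModel):
    """Hill-function parameters for cumulative GC formation:
    N(t) = Nmax t^n / (T^n + t^n)."""

    model_config = {"frozen": True}

    nmax: float = Field(gt=0.0, description="maximum cumulative GCs formed")
    t_half: float = Field(gt=0.0, description="time (h) at which N = Nmax/2")
    n: float = Field(gt=0.0, description="Hill coefficient")


def hill_cumulative(t, hp: HillParams):
    """Cumulative number of GCs formed by time t (hours)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    tn = t**hp.n
    out = hp.nmax * tn / (hp.t_half**hp.n + tn)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CohortSchedule:
    """Interval boundaries, representative initiation times and weights."""

    edges: np.ndarray  # (n_intervals + 1,) hours
    init_times: np.ndarray  # (n_intervals,) hours post immunization
    weights: np.ndarray  # GCs represented per interval
    jitter_width: float = 24.0

    @property
    def n_intervals(self) -> int:
        return len(self.init_times)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def build_schedule(
    hp: HillParams,
    n_intervals: int,
    horizon: float,
    jitter_width: float = 24.0,
    rng: Optional[np.random.Generator] = None,
) -> CohortSchedule:
    """Partition [0, horizon] into equal formation intervals.

    The weight of interval i is the Hill mass N(end_i) - N(start_i); the
    representative's initiation time is Gaussian around the interval midpoint
    with sd = jitter_width / 2, truncated to the interval (exactly the
    midpoint when jitter_width = 0).
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    edges = np.linspace(0.0, horizon, n_intervals + 1)
    cum = hill_cumulative(edges, hp)
    weights = np.diff(cum)
    mids = 0.5 * (edges[:-1] + edges[1:])
    if jitter_width <= 0:
        init_times = mids.copy()
    else:
        if rng is None:
            raise ValueError("rng required when jitter_width > 0")
        sd = jitter_width / 2.0
        a = (edges[:-1] - mids) / sd
        b = (edges[1:] - mids) / sd
        u = rng.random(n_intervals)
        init_times = stats.truncnorm.ppf(u, a, b, loc=mids, scale=sd)
    return CohortSchedule(
        edges=edges, init_times=init_times, weights=weights, jitter_width=jitter_width
    )


def gc_lifetime(run: GCRun, threshold: float) -> float:
    """Total time (h) the GC's live-cell count stays strictly above threshold.

    Computed on the recorded grid: each record with live_cells > threshold
    contributes one recording interval; disjoint supra-threshold episodes add.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if len(run.times) < 2:
        return 0.0
    return float(np.count_nonzero(run.live_cells > threshold) * run.record_dt)


def _active_at(run: GCRun, local_t: np.ndarray, threshold: float) -> np.ndarray:
    """Indicator that the GC is above threshold at times on its own clock
    (previous-record convention between grid points; inactive before 0)."""
    out = np.zeros(local_t.shape, dtype=bool)
    inside = (local_t >= 0) & (local_t <= run.times[-1] + 1e-9)
    if np.any(inside):
        pos = np.searchsorted(run.times, local_t[inside] + 1e-9) - 1
        pos = np.clip(pos, 0, len(run.times) - 1)
        out[inside] = run.live_cells[pos] > threshold
    return out


def _volume_at(run: GCRun, local_t: np.ndarray) -> np.ndarray:
    out = np.zeros(local_t.shape, dtype=float)
    inside = (local_t >= 0) & (local_t <= run.times[-1] + 1e-9)
    if np.any(inside):
        out[inside] = np.interp(local_t[inside], run.times, run.volume_proxy)
    return out


def count_active_gcs(
    runs: Sequence[GCRun],
    schedule: CohortSchedule,
    t,
    threshold: float = 100.0,
) -> np.ndarray:
    """Weighted number of active GCs at cohort time(s) t (hours post
    immunization). Each representative's trace is shifted to its initiation
    time; every GC it represents shares that trace and time."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    horizon = max(r.init_time + r.times[-1] for r in runs)
    if np.any(t < 0) or np.any(t > horizon + 1e-9):
        raise ValueError("cohort time outside the simulated horizon")
    total = np.zeros(t.shape)
    for run, w in zip(runs, schedule.weights):
        total += w * _active_at(run, t - run.init_time, threshold)
    return total


def total_volume(runs: Sequence[GCRun], schedule: CohortSchedule, t) -> np.ndarray:
    """Weighted total GC volume (arbitrary units) at cohort time(s) t."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    total = np.zeros(t.shape)
    for run, w in zip(runs, schedule.weights):
        total += w * _volume_at(run, t - run.init_time)
    return total


@dataclass
class CohortResult:
    """Aggregated cohort observables over simulation repeats."""

    times_h: np.ndarray
    ngc_mean: np.ndarray
    ngc_sd: np.ndarray
    volume_mean: np.ndarray
    volume_sd: np.ndarray
    lifetimes_h: np.ndarray  # (n_representatives, n_repeats)
    plasma: np.ndarray  # (n_representatives, n_repeats)
    init_times: np.ndarray
    weights: np.ndarray
    runs: Optional[List[List[GCRun]]] = None  # [repeat][representative]

    @property
    def times_d(self) -> np.ndarray:
        return self.times_h / 24.0

    @property
    def mean_lifetime_d(self) -> float:
        return float(self.lifetimes_h.mean() / 24.0)

    def per_rep_mean_lifetime_d(self) -> np.ndarray:
        return self.lifetimes_h.mean(axis=1) / 24.0


def run_cohort(
    per_gc_params: Sequence[GCParams],
    schedule: CohortSchedule,
    founder_specs: Sequence[FounderSpec],
    epitopes_per_gc: Sequence[Sequence[Epitope]],
    master_seed: int,
    repeats: int = 1,
    grid_h: Optional[np.ndarray] = None,
    threshold: float = 100.0,
    keep_runs: bool = False,
) -> CohortResult:
    """Simulate every representative ``repeats`` times and aggregate.

    Child seeds are spawned from ``master_seed`` per (representative, repeat),
    so results are independent of execution order and adding repeats never
    changes earlier runs.
    """
    n_rep = schedule.n_intervals
    if not (len(per_gc_params) == n_rep == len(founder_specs) == len(epitopes_per_gc)):
        raise ValueError(
            "per_gc_params, founder_specs and epitopes_per_gc must each have "
            "one entry per schedule interval"
        )
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if grid_h is None:
        horizon = max(p.duration for p in per_gc_params)
        grid_h = np.arange(0.0, horizon + 1e-9, 6.0)
    ngc = np.zeros((repeats, len(grid_h)))
    vol = np.zeros((repeats, len(grid_h)))
    lifetimes = np.zeros((n_rep, repeats))
    plasma = np.zeros((n_rep, repeats))
    all_runs: List[List[GCRun]] = []
    for r in range(repeats):
        runs = []
        for i in range(n_rep):
            seed = child_seed(master_seed, i, r)
            run = run_gc(
                per_gc_params[i],
                epitopes_per_gc[i],
                founder_specs[i],
                seed=seed,
                init_time=float(schedule.init_times[i]),
            )
            runs.append(run)
            lifetimes[i, r] = gc_lifetime(run, threshold)
            plasma[i, r] = run.total_plasma
        ngc[r] = count_active_gcs(runs, schedule, grid_h, threshold=threshold)
        vol[r] = total_volume(runs, schedule, grid_h)
        if keep_runs:
            all_runs.append(runs)
    return CohortResult(
        times_h=np.asarray(grid_h, dtype=float),
        ngc_mean=ngc.mean(axis=0),
        ngc_sd=ngc.std(axis=0, ddof=0) if repeats > 1 else np.zeros(len(grid_h)),
        volume_mean=vol.mean(axis=0),
        volume_sd=vol.std(axis=0, ddof=0) if repeats > 1 else np.zeros(len(grid_h)),
        lifetimes_h=lifetimes,
        plasma=plasma,
        init_times=schedule.init_times.copy(),
        weights=schedule.weights.copy(),
        runs=all_runs if keep_runs else None,
    )
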