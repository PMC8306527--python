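"""Scoring simulated cohort observables against experimental-style series.

The model-to-data cost is the sum of squared relative errors
``sum_i ((E_i - S_i) / E_i)^2`` between a data series E and the matched
simulated values S. GC-count series are compared directly; volume series are
compared after normalizing both sides at day 7, following the convention that
experimental volumes are in arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .cohort import CohortResult

__all__ = ["ExperimentalSeries", "cost", "align", "score_scenario_curves", "score_scenario"]

SeriesKind = Literal["gc_count", "gc_volume"]

#: Day at which volume curves are normalized before comparison.
VOLUME_NORM_DAY = 7.0


@dataclass(frozen=True)
class ExperimentalSeries:
    """A measured (or synthetic) time series of GC counts or total GC volume."""

    times_days: np.ndarray
    values: np.ndarray
    kind: SeriesKind = "gc_count"

    def __post_init__(self):
        t = np.asarray(self.times_days, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("values must be non-negative")
        object.__setattr__(self, "times_days", t)
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_days": self.times_days, "value": self.values, "kind": self.kind}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind: Optional[SeriesKind] = None) -> "ExperimentalSeries":
        df = pd.read_csv(path)
        if kind is not None:
            df = df[df["kind"] == kind]
        kinds = df["kind"].unique()
        if len(kinds) != 1:
            raise ValueError(
                f"series file {path} holds kinds {list(kinds)}; pass kind= to pick one"
            )
        return cls(
            times_days=df["time_days"].to_numpy(),
            values=df["value"].to_numpy(),
            kind=str(kinds[0]),
        )


def cost(E: ExperimentalSeries | np.ndarray, S: np.ndarray) -> float:
    """Relative squared-error cost sum_i ((E_i - S_i)/E_i)^2.

    Zero iff the series agree exactly; invariant under joint rescaling of E
    and S. Every E_i must be positive (it is a denominator).
    """
    e = E.values if isinstance(E, ExperimentalSeries) else np.asarray(E, dtype=float)
    s = np.asarray(S, dtype=float)
    if e.shape != s.shape:
        raise ValueError(f"series lengths differ: {e.shape} vs {s.shape}")
    zero = np.nonzero(e == 0)[0]
    if zero.size:
        raise ValueError(f"data value at index {int(zero[0])} is zero; cost undefined")
    return float(np.sum(((e - s) / e) ** 2))


def align(sim: CohortResult, E: ExperimentalSeries) -> np.ndarray:
    """Simulated mean curve interpolated at the data's time points.

    Counts interpolate the weighted active-GC curve directly. Volumes are
    normalized to the simulation's own day-7 value first (the data series is
    expected to be normalized at day 7 as well).
    """
    t_data_h = E.times_days * 24.0
    if t_data_h.min() < sim.times_h.min() - 1e-9 or t_data_h.max() > sim.times_h.max() + 1e-9:
        raise ValueError(
            "data times extend outside the simulated horizon "
            f"[{sim.times_h.min() / 24:.1f}, {sim.times_h.max() / 24:.1f}] days"
        )
    if E.kind == "gc_volume":
        ref = float(np.interp(VOLUME_NORM_DAY * 24.0, sim.times_h, sim.volume_mean))
        if ref == 0:
            raise ValueError("simulated volume at day 7 is zero; cannot normalize")
        curve = sim.volume_mean / ref
    else:
        curve = sim.ngc_mean
    return np.interp(t_data_h, sim.times_h, curve)


def score_scenario_curves(
    sim: CohortResult,
    E_count: ExperimentalSeries,
    E_volume: ExperimentalSeries,
) -> dict:
    """Combined cost of a simulated cohort against count and volume series
    (equal weighting; computed on the across-repeat mean curves)."""
    c_count = cost(E_count, align(sim, E_count))
    c_volume = cost(E_volume, align(sim, E_volume))
    return {
        "cost_count": c_count,
        "cost_volume": c_volume,
        "cost_total": c_count + c_volume,
    }


def score_scenario(
    cfg,
    E_count: ExperimentalSeries,
    E_volume: ExperimentalSeries,
    repeats: int,
    master_seed: int,
) -> dict:
    """Run a hypothesis scenario and score it against both data series.

    Returns the cost breakdown plus the simulated :class:`CohortResult` under
    the key ``"cohort"``.
    """
    from .hypotheses import run_scenario  # local import: avoids module cycle

    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    sim = run_scenario(cfg, master_seed=master_seed, repeats=repeats)
    out = score_scenario_curves(sim, E_count, E_volume)
    out["cohort"] = sim
    return out
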