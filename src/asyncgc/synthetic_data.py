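"""Experimental-style GC count and volume series with known ground truth.

The published cohort data this package is fitted against are digitized from
histology figures and are not deposited, so end-to-end tests of scheduling,
simulation and fitting need a stand-in with a known generating process. The
generator emulates the structure of those measurements: a GC-count curve that
rises to a peak around day 10-12 and contracts until about day 35, and a
total-volume curve normalized to its day-7 value, both with multiplicative
lognormal noise. Formation follows the same Hill law the cohort scheduler
uses; each GC formed at time s persists for a lifetime L(s) that is either
fixed or driven by exponential antigen decay (prolonged contraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .cohort import HillParams, hill_cumulative
from .fitting import ExperimentalSeries
from .hypotheses import AntigenDecay

__all__ = [
    "DEFAULT_TARGET_HILL",
    "SyntheticTruth",
    "expected_count_curve",
    "generate_count_series",
    "generate_volume_series",
    "recover_hill",
]

#: Default sampling days, emulating sparse histology time points. The grid
#: stops where an antigen-decay cohort still has measurably many GCs; the
#: relative-error cost is undefined at zero and unstable near it.
DEFAULT_TIMES_DAYS = (2.0, 4.0, 7.0, 9.0, 11.0, 13.0, 15.0, 17.0, 19.0, 21.0, 23.0, 25.0)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters of a synthetic cohort measurement.

    Exactly one of ``fixed_lifetime_days`` or ``decay`` must be set. With
    ``decay``, a GC formed at time s lives
    ``lifetime_scale_days * log1p(A(s)/antigen_ref)`` days, a monotone map of
    its initial antigen loading, which prolongs the contraction phase. The
    default map constants mirror the cohort simulator's own lifetime response
    to antigen loading (~8.8 days per e-fold, ~14 days at the reference
    loading of 3000 portions/FDC), so a decay-driven truth is the closed-form
    surrogate of a simulated cohort in which loading falls with initiation
    time.
    """

    hill: HillParams
    fixed_lifetime_days: Optional[float] = None
    decay: Optional[AntigenDecay] = None
    lifetime_scale_days: float = 8.8
    antigen_ref: float = 757.0
    noise_sd: float = 0.15
    times_days: Sequence[float] = DEFAULT_TIMES_DAYS
    peak_fraction: float = 0.4  # volume kernel peaks at this fraction of lifetime
    #: volumes below this fraction of the day-7 reference are unmeasurable
    #: (histology detection limit) and are not reported
    volume_detection_limit: float = 0.02

    def __post_init__(self):
        if (self.fixed_lifetime_days is None) == (self.decay is None):
            raise ValueError("set exactly one of fixed_lifetime_days or decay")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        t = np.asarray(self.times_days, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing")

    def lifetime_hours(self, t_init_h: np.ndarray) -> np.ndarray:
        """Lifetime (h) of GCs formed at the given times (h)."""
        t_init_h = np.asarray(t_init_h, dtype=float)
        if self.fixed_lifetime_days is not None:
            return np.full(t_init_h.shape, self.fixed_lifetime_days * 24.0)
        a = self.decay.a0 * np.exp(-self.decay.k * t_init_h)
        return self.lifetime_scale_days * 24.0 * np.log1p(a / self.antigen_ref)


#: Hill law for default synthetic targets. A slightly lower Hill coefficient
#: than the scheduler default puts measurable formation mass into the first
#: day, as the early counts of the emulated data show; without it the
#: longest-lived (earliest) GCs carry negligible mass and the late tail of
#: the count curve collapses to zero.
DEFAULT_TARGET_HILL = HillParams(nmax=100.0, t_half=96.0, n=1.5)

_FINE_DT_H = 1.0  # formation-time integration grid


def _formation_grid(truth: SyntheticTruth) -> tuple[np.ndarray, np.ndarray]:
    """Fine grid of formation times s and Hill mass dN per grid cell."""
    horizon = max(truth.times_days) * 24.0
    s = np.arange(0.0, horizon + _FINE_DT_H, _FINE_DT_H)
    cum = hill_cumulative(s, truth.hill)
    dN = np.diff(cum)
    return 0.5 * (s[:-1] + s[1:]), dN


def expected_count_curve(truth: SyntheticTruth, t_days) -> np.ndarray:
    """Noise-free expected number of active GCs at the given days.

    A GC formed at s is active on [s, s + L(s)); the expected count is the
    Hill formation mass integrated over currently active formation times.
    """
    t_h = np.atleast_1d(np.asarray(t_days, dtype=float)) * 24.0
    s_mid, dN = _formation_grid(truth)
    life = truth.lifetime_hours(s_mid)
    active = (s_mid[None, :] <= t_h[:, None]) & (t_h[:, None] < (s_mid + life)[None, :])
    return active @ dN


def _apply_noise(values: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd <= 0:
        return values.copy()
    return values * rng.lognormal(mean=0.0, sigma=sd, size=values.shape)


def generate_count_series(
    truth: SyntheticTruth, rng: np.random.Generator
) -> ExperimentalSeries:
    """Observed GC-count series: expected curve times lognormal noise."""
    t = np.asarray(truth.times_days, dtype=float)
    expected = expected_count_curve(truth, t)
    return ExperimentalSeries(
        times_days=t, values=_apply_noise(expected, truth.noise_sd, rng), kind="gc_count"
    )


def expected_volume_curve(truth: SyntheticTruth, t_days) -> np.ndarray:
    """Noise-free total GC volume (normalized at day 7).

    Each GC contributes a triangular profile: linear rise from 0 at formation
    to a unit peak at ``peak_fraction`` of its lifetime, then linear decay to
    0 at the end of its lifetime.
    """
    t_h = np.atleast_1d(np.asarray(t_days, dtype=float)) * 24.0
    s_mid, dN = _formation_grid(truth)
    life = truth.lifetime_hours(s_mid)

    def kernel(times_h: np.ndarray) -> np.ndarray:
        age = times_h[:, None] - s_mid[None, :]
        peak = truth.peak_fraction * life
        with np.errstate(divide="ignore", invalid="ignore"):
            rise = np.where(peak > 0, age / peak, 0.0)
            fall = np.where(life > peak, (life - age) / (life - peak), 0.0)
        v = np.where(age < peak[None, :], rise, fall)
        v = np.where((age >= 0) & (age < life[None, :]), v, 0.0)
        return np.clip(v, 0.0, 1.0)

    total = kernel(t_h) @ dN
    ref = float((kernel(np.array([7.0 * 24.0])) @ dN)[0])
    if ref <= 1e-9:
        raise ValueError("expected volume at day 7 is zero; cannot normalize")
    return total / ref


def generate_volume_series(
    truth: SyntheticTruth, rng: np.random.Generator
) -> ExperimentalSeries:
    """Observed total-volume series, normalized at day 7, with noise.

    Time points whose expected volume falls below the detection limit are
    not reported (a measurement with a near-zero denominator would also make
    the relative-error cost meaningless)."""
    t = np.asarray(truth.times_days, dtype=float)
    expected = expected_volume_curve(truth, t)
    keep = expected >= truth.volume_detection_limit
    return ExperimentalSeries(
        times_days=t[keep],
        values=_apply_noise(expected[keep], truth.noise_sd, rng),
        kind="gc_volume",
    )


def recover_hill(series: ExperimentalSeries, rising_until_day: Optional[float] = None) -> HillParams:
    """Least-squares Hill fit to the rising phase of a count series.

    The rising-phase counts approximate cumulative formation (deaths have not
    started), so the Hill law is fitted to those points directly. By default
    the rising phase extends through the series' maximum; pass
    ``rising_until_day`` to override.
    """
    t = series.times_days * 24.0
    v = series.values
    if rising_until_day is None:
        cut = int(np.argmax(v)) + 1
    else:
        cut = int(np.searchsorted(series.times_days, rising_until_day, side="right"))
    t, v = t[:cut], v[:cut]
    if len(t) < 4:
        raise ValueError(
            f"need at least 4 rising-phase points to fit 3 Hill parameters, got {len(t)}"
        )

    if np.any(v <= 0):
        raise ValueError("rising-phase counts must be positive for the Hill fit")

    # multiplicative (lognormal) noise: least squares on log counts is the
    # natural error model and keeps the plateau from dominating the fit
    def log_hill(tt, nmax, t_half, n):
        return np.log(nmax * tt**n / (t_half**n + tt**n))

    vmax = float(v.max())
    half = float(np.interp(0.5 * vmax, v, t))
    p0 = (1.2 * vmax, max(half, 1.0), 3.0)
    try:
        popt, _ = curve_fit(
            log_hill,
            t,
            np.log(v),
            p0=p0,
            bounds=([1e-6, 1e-6, 0.2], [1e6, 1e5, 20.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"Hill fit failed to converge on {len(t)} rising-phase points "
            f"(p0={p0}): {exc}"
        ) from exc
    return HillParams(nmax=float(popt[0]), t_half=float(popt[1]), n=float(popt[2]))
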