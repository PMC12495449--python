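"""Sham-feedback stimulus trajectories and their temporal statistics.

In the emulated task the feedback stimulus is a gray circle (baseline radius
100 px) whose size changes at 1, 5 or 10 Hz (every 1000, 200 or 100 ms).  The
candidate size changes come from a *delta pool*: successive differences of an
alpha band-power series (e.g., from a pilot recording) mapped linearly to
pixels.  At each update instant one delta is drawn uniformly with replacement
and added to the current radius, clipped to bounds.

Because the pool is resampled i.i.d., the generated trajectory preserves the
*distributional* shape of the source variations (skewness, kurtosis) but
destroys their *temporal* structure: lag-1 autocorrelation of the generated
delta series tends to zero regardless of the source dynamics.
:func:`trajectory_stats` / :func:`compare_stats` quantify exactly this —
variance, skewness, excess kurtosis and lag-1 autocorrelation of the
variation (delta) series.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_BASELINE_RADIUS = 100.0
DEFAULT_BOUNDS = (20.0, 180.0)
STANDARD_UPDATE_RATES = (1.0, 5.0, 10.0)


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class DeltaPool:
    """Candidate radius deltas (px) with their provenance."""

    values: tuple[float, ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise GenerationError("delta pool must be non-empty")
        if not all(math.isfinite(v) for v in self.values):
            raise GenerationError("delta pool must contain finite values")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class StimulusTrajectory:
    """Circle radii on a uniform update grid; ``radii[0]`` is the baseline."""

    update_freq: float
    times: np.ndarray
    radii: np.ndarray
    baseline_radius: float = DEFAULT_BASELINE_RADIUS
    bounds: tuple[float, float] = DEFAULT_BOUNDS
    provenance: dict = field(default_factory=dict, compare=False)

    @property
    def deltas(self) -> np.ndarray:
        """The realized variation series (px per update)."""
        return np.diff(self.radii)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "radius_px": self.radii})


@dataclass(frozen=True)
class TrajectoryStats:
    variance: float
    skewness: float
    kurtosis: float          # excess
    lag1_autocorr: float | None

    def to_dict(self) -> dict:
        return {"variance": self.variance, "skewness": self.skewness,
                "kurtosis": self.kurtosis, "lag1_autocorr": self.lag1_autocorr}


def build_delta_pool(power_series: np.ndarray, scale: float = 5.0,
                     source: str = "band-power series") -> DeltaPool:
    """Successive differences of a band-power series (dB) scaled to pixels."""
    series = np.asarray(power_series, dtype=float)
    if series.size < 2:
        raise GenerationError("power series needs at least 2 samples")
    deltas = np.diff(series) * scale
    if np.allclose(deltas, 0):
        warnings.warn("constant power series: delta pool is all zeros", stacklevel=2)
    return DeltaPool(tuple(float(d) for d in deltas),
                     provenance={"source": source, "scale_px_per_db": scale,
                                 "n_source_samples": int(series.size)})


def generate_trajectory(pool: DeltaPool, update_freq: float = 5.0,
                        duration: float = 60.0,
                        baseline: float = DEFAULT_BASELINE_RADIUS,
                        bounds: tuple[float, float] = DEFAULT_BOUNDS,
                        seed: int = 0) -> StimulusTrajectory:
    """Random-resampling trajectory: one pool delta per update instant,
    cumulative, clipped to bounds; deterministic given the seed."""
    if update_freq <= 0 or duration <= 0:
        raise GenerationError("update_freq and duration must be positive")
    lo, hi = bounds
    if not (lo <= baseline <= hi):
        raise GenerationError("baseline radius must lie inside bounds")
    n_updates = int(math.floor(duration * update_freq))
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x57F)))
    draws = rng.choice(pool.as_array(), size=n_updates, replace=True)
    radii = np.empty(n_updates + 1)
    radii[0] = baseline
    r = baseline
    for i, d in enumerate(draws):
        r = min(max(r + d, lo), hi)
        radii[i + 1] = r
    times = np.arange(n_updates + 1) / update_freq
    return StimulusTrajectory(update_freq=update_freq, times=times, radii=radii,
                              baseline_radius=baseline, bounds=bounds,
                              provenance={**pool.provenance, "seed": seed,
                                          "clipping": "hard bounds"})


def delta_series_stats(deltas: np.ndarray) -> TrajectoryStats:
    """Moments and lag-1 autocorrelation of a variation series."""
    d = np.asarray(deltas, dtype=float)
    if d.size < 3:
        raise GenerationError("need at least 3 updates for trajectory statistics")
    var = float(np.var(d, ddof=1))
    if var == 0:
        return TrajectoryStats(variance=0.0, skewness=0.0, kurtosis=-3.0,
                               lag1_autocorr=None)
    skew = float(sps.skew(d, bias=False))
    kurt = float(sps.kurtosis(d, fisher=True, bias=False))
    lag1 = float(np.corrcoef(d[:-1], d[1:])[0, 1])
    return TrajectoryStats(variance=var, skewness=skew, kurtosis=kurt,
                           lag1_autocorr=lag1)


def trajectory_stats(traj: StimulusTrajectory) -> TrajectoryStats:
    """Statistics of the trajectory's *delta* series (the size variations)."""
    return delta_series_stats(traj.deltas)


@dataclass(frozen=True)
class StatsComparison:
    differences: dict[str, float | None]
    flags: dict[str, bool]          # True = matched within tolerance
    tolerances: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"statistic": k, "abs_difference": self.differences[k],
                 "tolerance": self.tolerances[k], "matched": self.flags[k]}
                for k in self.differences]
        return pd.DataFrame(rows)


DEFAULT_STAT_TOLERANCES = {"variance": 0.5, "skewness": 0.2, "kurtosis": 0.2,
                           "lag1_autocorr": 0.1}


def compare_stats(source: TrajectoryStats, generated: TrajectoryStats,
                  tolerances: dict[str, float] | None = None,
                  relative: tuple[str, ...] = ("variance",)) -> StatsComparison:
    """Side-by-side match report; variance compared relatively (it is
    scale-dependent), shape/temporal statistics absolutely."""
    tol = dict(DEFAULT_STAT_TOLERANCES)
    tol.update(tolerances or {})
    diffs: dict[str, float | None] = {}
    flags: dict[str, bool] = {}
    for name in ("variance", "skewness", "kurtosis", "lag1_autocorr"):
        a = getattr(source, name)
        b = getattr(generated, name)
        if a is None or b is None:
            diffs[name] = None
            flags[name] = a is None and b is None
            continue
        d = abs(a - b)
        if name in relative and a != 0:
            d = d / abs(a)
        diffs[name] = float(d)
        flags[name] = d <= tol[name]
    return StatsComparison(differences=diffs, flags=flags, tolerances=tol)
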