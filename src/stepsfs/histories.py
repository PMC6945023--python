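"""Step-function histories: evaluation grids, bootstrap bands, averaging.

A fitted demographic history is a right-continuous step function of
time before present, (start_generation, Ne) pairs.  Bootstrap
replicates and multiple per-sample fits are combined by evaluating
every step function on a common time grid (logarithmic by default)
and taking pointwise summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimation import FitResult, stepwise_fit
from .sfs import SiteFrequencySpectrum, bootstrap_sfs

__all__ = [
    "StepHistory",
    "make_time_grid",
    "bootstrap_histories",
    "quantile_bands",
    "aggregate_histories",
]


@dataclass(frozen=True)
class StepHistory:
    """Right-continuous step function time -> Ne.

    Before its first start time a history contributes its first
    value; beyond its last step, its last value.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.shape != values.shape or times.ndim != 1 or times.size == 0:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if np.any(np.diff(times) < 0):
            raise ValueError("step times must be non-decreasing")
        times.setflags(write=False)
        values.setflags(write=False)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    @classmethod
    def from_fit(cls, fit: FitResult) -> "StepHistory":
        t, v = zip(*fit.step_plot)
        return cls(np.asarray(t), np.asarray(v))

    def __call__(self, grid) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        idx = np.searchsorted(self.times, grid, side="right") - 1
        return self.values[np.clip(idx, 0, len(self.values) - 1)]


def make_time_grid(
    histories,
    points: int = 200,
    lo_quantile: float = 0.01,
    hi_quantile: float = 0.99,
) -> np.ndarray:
    """Logarithmic grid between quantiles of all step times.

    Uses the pooled nonzero step times of the histories; falls back to
    a decade around 1 when there are none.
    """
    all_times = np.concatenate([h.times for h in histories])
    all_times = all_times[all_times > 0]
    if all_times.size == 0:
        lo, hi = 1.0, 10.0
    else:
        lo = np.quantile(all_times, lo_quantile)
        hi = np.quantile(all_times, hi_quantile)
        if hi <= lo:
            hi = lo * 10.0
    return np.geomspace(max(lo, 1e-12), hi, points)


def bootstrap_histories(
    sfs: SiteFrequencySpectrum,
    u: float,
    replicates: int,
    seed: int,
    **fit_kwargs,
):
    """Stepwise fits of multinomial bootstrap replicates of an SFS.

    Returns ``(histories, n_dropped)``; replicates whose size
    optimisation fails to converge are dropped and counted, never
    silently kept.
    """
    histories = []
    dropped = 0
    for rep in bootstrap_sfs(sfs, replicates, seed):
        fit = stepwise_fit(rep, u, **fit_kwargs)
        if fit.converged:
            histories.append(StepHistory.from_fit(fit))
        else:
            dropped += 1
    if not histories:
        raise RuntimeError("all bootstrap replicates failed to converge")
    return histories, dropped


def quantile_bands(
    histories,
    grid: np.ndarray,
    quantiles=(0.05, 0.5, 0.95),
) -> dict:
    """Pointwise mean and quantiles of histories on a grid."""
    values = np.vstack([h(grid) for h in histories])
    out = {
        "grid": np.asarray(grid, dtype=float),
        "mean": values.mean(axis=0),
        "quantiles": {
            float(q): np.quantile(values, q, axis=0) for q in quantiles
        },
    }
    return out


def aggregate_histories(histories, grid: np.ndarray, weights=None) -> dict:
    """Pointwise mean and standard error across histories on a grid.

    This is how per-sample median histories are combined into one
    population summary.  ``weights`` (optional, e.g. site counts)
    switches to a weighted mean; the SE is then the weighted SE of the
    mean with normalised weights.
    """
    histories = list(histories)
    if not histories:
        raise ValueError("need at least one history")
    grid = np.asarray(grid, dtype=float)
    values = np.vstack([h(grid) for h in histories])
    m = len(histories)
    if weights is None:
        mean = values.mean(axis=0)
        if m > 1:
            se = values.std(axis=0, ddof=1) / np.sqrt(m)
        else:
            se = np.zeros_like(mean)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (m,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative, one per history")
        w = w / w.sum()
        mean = w @ values
        if m > 1:
            var = w @ (values - mean) ** 2 / (1.0 - np.sum(w**2))
            se = np.sqrt(var * np.sum(w**2))
        else:
            se = np.zeros_like(mean)
    return {"grid": grid, "mean": mean, "se": se}
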