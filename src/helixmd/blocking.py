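"""Block averaging over a trailing analysis window.

Every trajectory-level summary in the package reports mean +/- error where the
error bar is the (population) standard deviation across the means of
contiguous, equal-duration blocks covering the trailing analysis window.
Defaults: 5 blocks over the trailing half of the series; both configurable.

A circular variant handles angular series (torsions), where block means are
computed on the circle and the spread is measured on wrapped deviations from
the overall circular mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import circmean

from .geometry import wrap_angle

__all__ = ["BlockResult", "block_average", "block_average_circular", "trailing_window"]


@dataclass
class BlockResult:
    mean: float
    error: float  # std across block means (population)
    n_blocks: int
    window: tuple[float, float]  # (t_start, t_end) ns
    block_means: np.ndarray

    def __post_init__(self):
        if self.n_blocks < 2:
            raise ValueError("error bars require n_blocks >= 2")
        if self.error < 0:
            raise ValueError("error must be non-negative")


def trailing_window(times: np.ndarray, window: float | None) -> tuple[float, float]:
    """Resolve the analysis window: trailing ``window`` ns, default last 50%."""
    times = np.asarray(times, float)
    span = times[-1] - times[0]
    if window is None:
        window = span / 2.0
    if window > span + 1e-12:
        raise ValueError(f"window {window} ns exceeds series span {span} ns")
    return (times[-1] - window, times[-1])


def _blocks(times, values, window, n_blocks):
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if len(times) != len(values):
        raise ValueError("times/values length mismatch")
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    t0, t1 = trailing_window(times, window)
    edges = np.linspace(t0, t1, n_blocks + 1)
    out = []
    for b in range(n_blocks):
        lo, hi = edges[b], edges[b + 1]
        lo_ok = times >= (lo - 1e-12 if b == 0 else lo)
        hi_ok = times <= hi + 1e-12 if b == n_blocks - 1 else times < hi
        vals = values[lo_ok & hi_ok]
        if vals.size == 0:
            raise ValueError(f"block {b} (t in [{lo:.4g}, {hi:.4g}] ns) is empty")
        out.append(vals)
    return out, (float(t0), float(t1))


def block_average(times, values, window: float | None = None, n_blocks: int = 5
                  ) -> BlockResult:
    """Mean of block means with std-across-blocks error over the window."""
    blocks, win = _blocks(times, values, window, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return BlockResult(mean=float(means.mean()), error=float(means.std(ddof=0)),
                       n_blocks=n_blocks, window=win, block_means=means)


def block_average_circular(times, values_deg, window: float | None = None,
                           n_blocks: int = 5) -> BlockResult:
    """Block averaging for angular data in degrees, wrap-aware."""
    blocks, win = _blocks(times, values_deg, window, n_blocks)
    means = np.array([circmean(b, high=180.0, low=-180.0) for b in blocks])
    mean = float(circmean(means, high=180.0, low=-180.0))
    dev = wrap_angle(means - mean)
    err = float(np.sqrt(np.mean(dev ** 2)))
    return BlockResult(mean=wrap_angle(mean), error=err, n_blocks=n_blocks,
                       window=win, block_means=means)
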