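"""Replicate-run statistics: mean/SD/95% CI and paired two-tailed t-tests.

Designed around triplicate experiment repeats: the 95% CI uses the Student t
quantile with n-1 degrees of freedom (4.303 for n=3), and paired comparisons
are declared significant when |t| exceeds that same critical value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ReplicateSet", "summarize", "t_critical", "paired_t",
           "format_mean_sd_ci", "pp_delta"]


@dataclass
class ReplicateSet:
    values: tuple[float, ...]

    def __post_init__(self):
        self.values = tuple(float(v) for v in self.values)
        if len(self.values) < 2:
            raise ValueError("a replicate set needs at least 2 runs")
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError("replicate values must be finite")

    def __len__(self):
        return len(self.values)


def _as_set(r) -> ReplicateSet:
    return r if isinstance(r, ReplicateSet) else ReplicateSet(tuple(r))


def summarize(r) -> tuple[float, float, float, float]:
    """(mean, sample SD, CI low, CI high) with CI = mean ± t(0.975, n-1)·SD/√n."""
    r = _as_set(r)
    v = np.asarray(r.values)
    n = len(v)
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    half = t_critical(0.05, n - 1) * sd / math.sqrt(n)
    return mean, sd, mean - half, mean + half


def t_critical(alpha: float, df: int) -> float:
    """Two-tailed critical value of Student's t."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def paired_t(x, y, alpha: float = 0.05) -> tuple[float, bool]:
    """Paired two-tailed t statistic and significance flag.

    Zero-variance differences: t = 0 (not significant) when the means also
    agree, +/-inf (significant) otherwise.
    """
    x, y = _as_set(x), _as_set(y)
    if len(x) != len(y):
        raise ValueError("paired sets must have equal length")
    d = np.asarray(x.values) - np.asarray(y.values)
    n = len(d)
    sd = d.std(ddof=1)
    crit = t_critical(alpha, n - 1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, False
        return math.copysign(math.inf, d.mean()), True
    t = float(d.mean() / (sd / math.sqrt(n)))
    return t, abs(t) > crit


def format_mean_sd_ci(r, decimals: int = 4) -> str:
    """Render a replicate set as ``mean (sd) [lo, hi]`` table-style text."""
    mean, sd, lo, hi = summarize(r)
    f = f"{{:.{decimals}f}}"
    return f"{f.format(mean)} ({f.format(sd)}) [{f.format(lo)},{f.format(hi)}]"


def pp_delta(full: float, ablated: float) -> float:
    """Difference between two aggregate fractions in percentage points."""
    return (full - ablated) * 100.0
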