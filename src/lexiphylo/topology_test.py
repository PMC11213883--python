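"""Per-cognate topology testing via non-overlapping HPD intervals.

Two constrained analyses (A and B) log the corrected log-likelihood of every
cognate set at each sampled generation.  For each cognate the 50% highest
posterior density interval of its log-likelihood trace is computed separately
in the two analyses; cognates whose intervals do not overlap are classified
as supporting whichever analysis gives them the strictly higher interval.
For presentation the intervals can be shifted per cognate by the median of
that cognate's trace in analysis A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HpdInterval", "hpd_interval", "discriminating_cognates",
    "relative_likelihood_table",
]


@dataclass(frozen=True)
class HpdInterval:
    """Shortest interval with endpoints at sample values containing at least
    ceil(mass * N) of the N samples."""

    lower: float
    upper: float
    mass: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower endpoint exceeds upper endpoint")
        if not (0.0 < self.mass < 1.0):
            raise ValueError("mass must lie in (0, 1)")

    def overlaps(self, other: "HpdInterval") -> bool:
        return self.lower <= other.upper and other.lower <= self.upper

    def strictly_above(self, other: "HpdInterval") -> bool:
        return self.lower > other.upper


def hpd_interval(samples: Sequence[float], mass: float = 0.5) -> HpdInterval:
    """Shortest window over sorted samples containing ceil(mass*N) of them.

    Ties in window width are broken by the smallest lower endpoint.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples for an HPD interval")
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must lie in (0, 1)")
    k = max(math.ceil(mass * n), 1)
    if k == n:
        return HpdInterval(float(x[0]), float(x[-1]), mass)
    widths = x[k - 1:] - x[: n - k + 1]
    # argmin returns the first (= smallest lower endpoint) among tied widths
    i = int(np.argmin(widths))
    return HpdInterval(float(x[i]), float(x[i + k - 1]), mass)


def _check_alignment(trace_a: pd.DataFrame, trace_b: pd.DataFrame) -> list[str]:
    cols_a, cols_b = set(trace_a.columns), set(trace_b.columns)
    if cols_a != cols_b:
        raise ValueError(
            "cognate sets differ between the two analyses: "
            f"only in A: {sorted(cols_a - cols_b)[:5]}, "
            f"only in B: {sorted(cols_b - cols_a)[:5]}")
    return list(trace_a.columns)


def discriminating_cognates(trace_a: pd.DataFrame, trace_b: pd.DataFrame,
                            mass: float = 0.5) -> pd.DataFrame:
    """Classify cognates by non-overlapping HPD intervals.

    ``trace_a`` / ``trace_b``: per-cognate log-likelihood traces (one column
    per cognate set, one row per sampled generation).  Returns a frame with
    columns (cognate, support, a_lower, a_upper, b_lower, b_upper) holding
    only the discriminating cognates; ``support`` is "A" when the cognate's
    interval under A lies strictly above its interval under B, and "B" for
    the converse.
    """
    cognates = _check_alignment(trace_a, trace_b)
    rows = []
    for cog in cognates:
        ia = hpd_interval(trace_a[cog].to_numpy(), mass)
        ib = hpd_interval(trace_b[cog].to_numpy(), mass)
        if ia.overlaps(ib):
            continue
        support = "A" if ia.strictly_above(ib) else "B"
        rows.append({"cognate": cog, "support": support,
                     "a_lower": ia.lower, "a_upper": ia.upper,
                     "b_lower": ib.lower, "b_upper": ib.upper})
    return pd.DataFrame(
        rows, columns=["cognate", "support", "a_lower", "a_upper",
                       "b_lower", "b_upper"])


def relative_likelihood_table(trace_a: pd.DataFrame, trace_b: pd.DataFrame,
                              mass: float = 0.5) -> pd.DataFrame:
    """Both analyses' HPD intervals shifted by the A-trace median per cognate.

    After shifting, each cognate's A median maps to 0, so interval positions
    are directly comparable across cognates.
    """
    cognates = _check_alignment(trace_a, trace_b)
    rows = []
    for cog in cognates:
        med = float(np.median(trace_a[cog].to_numpy()))
        ia = hpd_interval(trace_a[cog].to_numpy(), mass)
        ib = hpd_interval(trace_b[cog].to_numpy(), mass)
        rows.append({"cognate": cog, "a_median": med,
                     "a_lower": ia.lower - med, "a_upper": ia.upper - med,
                     "b_lower": ib.lower - med, "b_upper": ib.upper - med})
    return pd.DataFrame(
        rows, columns=["cognate", "a_median", "a_lower", "a_upper",
                       "b_lower", "b_upper"])
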