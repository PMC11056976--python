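"""Block averaging and the significance-testing layer.

Uncertainties on time-averaged observables are standard errors of block
means: the series is cut into contiguous equal blocks (ten by default,
mirroring ten 40 ns blocks over a 400 ns analysis window) and the
spread of the block means estimates the error of the overall mean
under temporal correlation.  Group comparisons use one-way ANOVA with
Tukey HSD post-hoc pairwise tests (Tukey–Kramer for unequal group
sizes) at significance level alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BlockSummary",
    "ComparisonResult",
    "block_average",
    "one_way_anova",
    "tukey_hsd",
    "analysis_window",
]


@dataclass
class BlockSummary:
    """Mean with a block-averaged standard error."""

    mean: float
    sem: float
    n_blocks: int
    block_length: int  # frames per block

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be non-negative")


@dataclass
class ComparisonResult:
    """One-way ANOVA with a Tukey HSD pairwise table.

    ``pairwise`` has one row per unordered group pair with columns
    ``group_a``, ``group_b``, ``mean_diff``, ``p_adj``, ``significant``.
    """

    labels: list[str]
    f_statistic: float
    p_value: float
    alpha: float
    pairwise: pd.DataFrame


def analysis_window(n_frames: int, fraction: float = 0.8) -> slice:
    """Slice selecting the final ``fraction`` of a production run."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    start = int(round(n_frames * (1 - fraction)))
    return slice(start, n_frames)


def block_average(series: Sequence[float] | np.ndarray,
                  n_blocks: int = 10) -> BlockSummary:
    """Mean and SEM of a time series by block averaging.

    The series is split into ``n_blocks`` contiguous equal blocks; a
    trailing remainder that does not fill a block is dropped with a
    warning.  SEM is the sample standard deviation of the block means
    divided by sqrt(n_blocks).
    """
    x = np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise ValueError("n_blocks must be at least 2")
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if len(x) < n_blocks:
        raise ValueError(
            f"series of length {len(x)} cannot fill {n_blocks} blocks"
        )
    block_len = len(x) // n_blocks
    used = block_len * n_blocks
    if used < len(x):
        warnings.warn(
            f"dropping trailing {len(x) - used} values that do not fill a block"
        )
    block_means = x[:used].reshape(n_blocks, block_len).mean(axis=1)
    sem = float(block_means.std(ddof=1) / np.sqrt(n_blocks))
    return BlockSummary(
        mean=float(block_means.mean()), sem=sem,
        n_blocks=n_blocks, block_length=block_len,
    )


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    return arrays


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value across groups."""
    arrays = _check_groups(groups)
    res = sps.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def tukey_hsd(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> ComparisonResult:
    """ANOVA plus Tukey HSD pairwise comparisons.

    Adjusted p-values come from the studentized-range distribution with
    the Tukey–Kramer correction for unequal group sizes.
    """
    arrays = _check_groups(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    labels = [str(l) for l in labels]
    if len(labels) != len(arrays):
        raise ValueError("one label per group required")
    f_stat, p_val = one_way_anova(arrays)
    res = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            p_adj = float(res.pvalue[i, j])
            rows.append({
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                "p_adj": p_adj,
                "significant": bool(p_adj < alpha),
            })
    return ComparisonResult(
        labels=list(labels), f_statistic=f_stat, p_value=p_val,
        alpha=alpha, pairwise=pd.DataFrame(rows),
    )
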