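"""Low-variation gene filtering.

A gene whose expression barely moves across samples (the limiting
case being a constant row) cannot carry signature information, so it
is removed before searching.  The filter statistic is the per-row
range Δ_i = max(y_i) − min(y_i); rows with Δ_i < T are dropped.  The
per-row population standard deviation y_iσ is computed alongside for
reporting.

The threshold T may be given in the data's units (``absolute`` mode)
or as an empirical quantile of the Δ_i distribution (``quantile``
mode, a scriptable stand-in for an interactive slider).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix

__all__ = ["FilterConfig", "row_stddev", "row_range", "filter_low_variation"]


@dataclass(frozen=True)
class FilterConfig:
    """Settings for :func:`filter_low_variation`.

    threshold
        Non-negative cut T on the row range, in the units of the data.
        The default 0 keeps every row, so filtering is always explicit.
    mode
        ``absolute`` uses ``threshold`` directly; ``quantile`` sets T
        to the ``quantile_q`` empirical quantile of the Δ_i values.
    """

    threshold: float = 0.0
    mode: str = "absolute"
    quantile_q: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in {"absolute", "quantile"}:
            raise ValueError(f"unknown filter mode: {self.mode!r}")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if not 0.0 <= self.quantile_q <= 1.0:
            raise ValueError("quantile_q must lie in [0, 1]")


def row_stddev(matrix: ExpressionMatrix) -> np.ndarray:
    """Population standard deviation of each row over non-missing entries.

    y_iσ = sqrt((1/N_i) Σ_j (y_ij − μ_i)²) with N_i the count of
    non-missing entries in row i (divisor N, not N−1).
    """
    return np.nanstd(matrix.values, axis=1, ddof=0)


def row_range(matrix: ExpressionMatrix) -> np.ndarray:
    """Δ_i = max(y_i) − min(y_i) per row, missing entries excluded."""
    return np.nanmax(matrix.values, axis=1) - np.nanmin(matrix.values, axis=1)


def filter_low_variation(
    matrix: ExpressionMatrix, config: FilterConfig = FilterConfig()
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop rows whose range falls below the threshold.

    Returns the surviving matrix (original row order preserved) and the
    removed gene IDs in original order.  Survival is Δ_i ≥ T, i.e. rows
    are removed on the strict inequality Δ_i < T, so T = 0 keeps
    everything and any T > 0 removes constant rows.

    Raises ``ValueError`` if nothing survives.
    """
    deltas = row_range(matrix)
    threshold = config.threshold
    if config.mode == "quantile":
        threshold = float(np.quantile(deltas, config.quantile_q))
    keep = deltas >= threshold
    if not keep.any():
        raise ValueError(
            f"threshold T={threshold:g} removed every row; lower the threshold"
        )
    survivors = [g for g, k in zip(matrix.gene_ids, keep) if k]
    removed = [g for g, k in zip(matrix.gene_ids, keep) if not k]
    filtered = ExpressionMatrix(survivors, list(matrix.sample_labels),
                                matrix.values[keep].copy())
    return filtered, removed
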