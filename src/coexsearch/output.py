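"""Abundance-tiered export and heat-map rendering of search hits.

Hits are split into three files/panels — high, mid, low — by mean
expression level, so strongly and weakly expressed coexpressed genes
can be inspected separately.  The cuts are the empirical terciles of
the hit genes' row means (the number of panels is fixed at three; the
boundaries are data-driven).  The heat map shows hits in ranked order,
one row per gene, red above and blue below the gene's own mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import ExpressionMatrix, SearchResult, write_results

logger = logging.getLogger(__name__)

__all__ = ["TieredOutput", "split_by_abundance", "write_tiered", "render_heatmap"]


@dataclass
class TieredOutput:
    """Three disjoint abundance tiers partitioning the input results."""

    high: list[SearchResult]
    mid: list[SearchResult]
    low: list[SearchResult]
    tier_boundaries: tuple[float, float]  # (low/mid cut, mid/high cut)

    def __len__(self) -> int:
        return len(self.high) + len(self.mid) + len(self.low)


def split_by_abundance(
    matrix: ExpressionMatrix, results: Sequence[SearchResult]
) -> TieredOutput:
    """Partition results into high/mid/low tiers of mean expression.

    Cuts sit at the 1/3 and 2/3 empirical quantiles of μ_i among the
    result genes; a gene whose mean lands exactly on a boundary goes to
    the higher tier.  With fewer than 3 results a tercile split is
    meaningless, so everything goes to ``high`` with a warning.  Each
    result's ``tier`` field is stamped in place.
    """
    results = list(results)
    if len(results) < 3:
        if results:
            logger.warning("fewer than 3 results; placing all in the high tier")
        for res in results:
            res.tier = "high"
        return TieredOutput(high=results, mid=[], low=[],
                            tier_boundaries=(float("nan"), float("nan")))

    means = {res.gene_id: float(np.nanmean(matrix.row(res.gene_id))) for res in results}
    mu = np.array([means[res.gene_id] for res in results])
    cut_low = float(np.quantile(mu, 1.0 / 3.0))
    cut_high = float(np.quantile(mu, 2.0 / 3.0))

    high: list[SearchResult] = []
    mid: list[SearchResult] = []
    low: list[SearchResult] = []
    for res, m in zip(results, mu):
        if m >= cut_high:
            res.tier = "high"
            high.append(res)
        elif m >= cut_low:
            res.tier = "mid"
            mid.append(res)
        else:
            res.tier = "low"
            low.append(res)
    return TieredOutput(high=high, mid=mid, low=low,
                        tier_boundaries=(cut_low, cut_high))


def write_tiered(tiers: TieredOutput, prefix: str | Path) -> dict[str, Path]:
    """Write ``<prefix>.high.tsv``, ``<prefix>.mid.tsv``, ``<prefix>.low.tsv``."""
    prefix = Path(prefix)
    paths: dict[str, Path] = {}
    for name, rows in (("high", tiers.high), ("mid", tiers.mid), ("low", tiers.low)):
        path = prefix.with_name(prefix.name + f".{name}.tsv")
        write_results(rows, path)
        paths[name] = path
    return paths


def render_heatmap(
    matrix: ExpressionMatrix,
    results: Sequence[SearchResult],
    path: str | Path,
    *,
    dpi: int = 100,
) -> None:
    """Render hits as a red/blue heat map PNG.

    Rows are the result genes in ranked order, columns the samples.
    Each row is centered on its own mean, so red marks expression above
    the gene's average and blue below it, independent of the gene's
    absolute level.  Output is deterministic for fixed input (no
    timestamps or software tags are embedded).
    """
    results = list(results)
    if not results:
        raise ValueError("cannot render a heat map of zero results")
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    sub = np.vstack([matrix.row(res.gene_id) for res in results])
    centered = sub - np.nanmean(sub, axis=1, keepdims=True)
    span = np.nanmax(np.abs(centered))
    if span == 0:
        span = 1.0

    n_rows, n_cols = centered.shape
    fig_w = max(3.0, min(10.0, 0.25 * n_cols + 1.5))
    fig_h = max(2.0, min(12.0, 0.12 * n_rows + 1.0))
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("#d9d9d9")
    im = ax.imshow(centered, aspect="auto", cmap=cmap, vmin=-span, vmax=span,
                   interpolation="nearest")
    ax.set_xlabel("sample")
    ax.set_ylabel("gene (ranked by p-value)")
    ax.set_yticks([])
    step = max(1, n_cols // 12)
    ax.set_xticks(range(0, n_cols, step))
    ax.set_xticklabels(matrix.sample_labels[::step], rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="expression − row mean")
    fig.tight_layout()
    # drop the default Software tag so identical inputs give identical bytes
    fig.savefig(path, dpi=dpi, metadata={"Software": None})
    plt.close(fig)
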