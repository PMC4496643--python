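"""Correlation search: rank every gene against a query signature.

Similarity is the sample Pearson correlation r over pairwise-complete
positions, tested with the exact two-sided t-test
t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom.  Pearson
correlation is invariant to per-gene affine rescaling y → a·y + c
(a > 0), which is the scale-independence the signature models rely
on.  Genes with two-sided p below the threshold are reported, sorted
by ascending p.

By default only positively correlated genes are kept, since a
coexpression search looks for profiles that rise and fall together;
anti-correlated hits can be retained with ``keep_anticorrelated``.
P-values are raw by default (the interactive workflow this emulates
thresholds raw p); an optional Benjamini-Hochberg FDR cut is
available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SearchResult
from .models import QuerySignature, SeedGroup

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateProfileError",
    "EnsembleResult",
    "pearson_correlation",
    "correlation_pvalue",
    "search_by_signature",
    "ensemble_search",
]

MIN_PAIRS = 3


class DegenerateProfileError(ValueError):
    """A gene cannot be scored: fewer than 3 complete pairs, or a
    constant pairwise-complete subvector.  Such genes are skipped and
    counted, never fatal to a search."""


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Sample Pearson correlation over pairwise-complete positions.

    Returns ``(r, n_pairs)``.  Raises :class:`DegenerateProfileError`
    when fewer than 3 positions are complete in both vectors or either
    pairwise-complete subvector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < MIN_PAIRS:
        raise DegenerateProfileError(f"only {n} pairwise-complete positions")
    xc = x[ok] - x[ok].mean()
    yc = y[ok] - y[ok].mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        raise DegenerateProfileError("constant pairwise-complete subvector")
    r = float(np.clip((xc @ yc) / denom, -1.0, 1.0))
    return r, n


def correlation_pvalue(r: float, n_pairs: int) -> float:
    """Two-sided p-value for a Pearson r at ``n_pairs`` observations.

    Uses the exact null t = r·sqrt((n−2)/(1−r²)) ~ t(n−2); |r| = 1
    yields p = 0.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation out of [-1, 1]: {r}")
    if n_pairs < MIN_PAIRS:
        raise ValueError("need at least 3 pairs")
    if abs(r) == 1.0:
        return 0.0
    df = n_pairs - 2
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def _sort_results(results: list[tuple[int, SearchResult]]) -> list[SearchResult]:
    # ascending p, ties by descending |r|, then original input order
    results.sort(key=lambda ir: (ir[1].p_value, -abs(ir[1].correlation), ir[0]))
    return [res for _, res in results]


def search_by_signature(
    matrix: ExpressionMatrix,
    signature: QuerySignature,
    p_threshold: float,
    *,
    keep_anticorrelated: bool = False,
    bh_fdr: float | None = None,
) -> list[SearchResult]:
    """Score every gene against the signature and keep significant hits.

    A gene is reported when its two-sided p-value is strictly below
    ``p_threshold`` (and, unless ``keep_anticorrelated``, its r is
    positive).  Seed genes are scored like any other and flagged.
    Results are sorted by ascending p-value, ties broken by descending
    |r| and then input order.

    With ``bh_fdr`` set, the Benjamini-Hochberg adjusted p-value
    (computed over all scoreable genes) must additionally fall below
    that level.
    """
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError("p_threshold must lie in (0, 1]")
    if len(signature) != matrix.n_samples:
        raise ValueError("signature length must equal the matrix sample count")
    seed_ids = set(signature.source_seeds.gene_ids)

    scored: list[tuple[int, SearchResult]] = []
    n_skipped = 0
    sig = signature.values
    for idx, gid in enumerate(matrix.gene_ids):
        try:
            r, n = pearson_correlation(matrix.values[idx], sig)
        except DegenerateProfileError:
            n_skipped += 1
            continue
        p = correlation_pvalue(r, n)
        scored.append((idx, SearchResult(gene_id=gid, correlation=r, p_value=p,
                                         n_pairs=n, seed_flag=gid in seed_ids)))
    if n_skipped:
        logger.info("skipped %d gene(s) with degenerate profiles", n_skipped)

    if bh_fdr is not None:
        pvals = np.array([res.p_value for _, res in scored])
        rejected = multipletests(pvals, alpha=bh_fdr, method="fdr_bh")[0]
    else:
        rejected = np.ones(len(scored), dtype=bool)

    hits = [
        (idx, res)
        for ((idx, res), rej) in zip(scored, rejected)
        if res.p_value < p_threshold
        and rej
        and (keep_anticorrelated or res.correlation > 0.0)
    ]
    return _sort_results(hits)


@dataclass
class EnsembleResult:
    """Union of single-seed searches, redundancy removed.

    ``results`` holds one entry per distinct gene (its best p-value
    across seeds); ``per_seed_hits`` maps each seed gene to the gene
    IDs its own search returned.
    """

    results: list[SearchResult]
    per_seed_hits: dict[str, list[str]] = field(default_factory=dict)


def ensemble_search(
    matrix: ExpressionMatrix,
    seeds: SeedGroup,
    p_threshold: float,
    *,
    keep_anticorrelated: bool = False,
    bh_fdr: float | None = None,
) -> EnsembleResult:
    """Search once per seed gene (its own row as signature) and merge.

    Each constituent search uses a single seed row as the query, so the
    ensemble casts k separate nets.  A gene hit by several seeds keeps
    its best (smallest) p-value and that seed's correlation; the merged
    list is re-sorted by p-value.
    """
    per_seed_hits: dict[str, list[str]] = {}
    best: dict[str, tuple[int, SearchResult]] = {}
    for seed_gene in seeds.gene_ids:
        single = SeedGroup(f"{seeds.name}:{seed_gene}", (seed_gene,))
        signature = QuerySignature(matrix.row(seed_gene).copy(), "delegate", single)
        hits = search_by_signature(
            matrix, signature, p_threshold,
            keep_anticorrelated=keep_anticorrelated, bh_fdr=bh_fdr,
        )
        per_seed_hits[seed_gene] = [h.gene_id for h in hits]
        for order, hit in enumerate(hits):
            hit.seed_flag = hit.gene_id in seeds.gene_ids
            prev = best.get(hit.gene_id)
            if prev is None or hit.p_value < prev[1].p_value:
                kept_order = order if prev is None else prev[0]
                best[hit.gene_id] = (kept_order, hit)
    merged = _sort_results(list(best.values()))
    return EnsembleResult(results=merged, per_seed_hits=per_seed_hits)
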