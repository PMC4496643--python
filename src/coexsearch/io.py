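"""Reading and writing expression matrices and search-result tables.

Two tab-delimited dialects are supported:

* ``generic_tsv`` -- first row is a header (``ID<TAB>sample1<TAB>...``),
  first column holds gene identifiers, remaining cells are expression
  values.
* ``pcl`` -- the Stanford microarray dialect: the header carries
  ``NAME`` and ``GWEIGHT`` annotation columns after the identifier
  column, and the second row is an ``EWEIGHT`` row; both carry no
  expression data and are discarded on load.

Any cell that does not parse as a number (empty, ``NA``, ``NaN``,
``null`` in any case, or arbitrary text) is recorded as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SearchResult",
    "read_expression_table",
    "write_expression_table",
    "write_results",
    "read_results",
]

#: header tokens that identify the gene-ID column in either dialect
_ID_HEADER_NAMES = {"ID", "YORF", "NAME", "GENE", "UID", "CLID"}


@dataclass
class SearchResult:
    """One gene's outcome against a query signature.

    ``tier`` starts as ``"unset"`` and is stamped by the abundance
    split; ``seed_flag`` marks genes that were part of the seed group
    used to build the signature.
    """

    gene_id: str
    correlation: float
    p_value: float
    n_pairs: int
    seed_flag: bool = False
    tier: str = "unset"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.correlation <= 1.0 + 1e-12:
            raise ValueError(f"correlation out of [-1, 1]: {self.correlation}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")
        if self.n_pairs < 3:
            raise ValueError("a result needs at least 3 pairwise-complete positions")


@dataclass
class ExpressionMatrix:
    """A genes-by-samples table of real expression values.

    ``values`` is a float matrix with ``NaN`` marking missing entries.
    Row statistics (mean, population standard deviation, range) are
    always taken over the non-missing entries of the row.
    """

    gene_ids: list[str]
    sample_labels: list[str]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length must match the row count")
        if len(self.sample_labels) != self.values.shape[1]:
            raise ValueError("sample_labels length must match the column count")
        if self.n_samples < 2:
            raise ValueError("an expression matrix needs at least 2 samples")
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValueError(f"duplicate gene ID: {dup!r}")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        """Number of columns N."""
        return self.values.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self._index[gene_id]]
        except KeyError:
            raise KeyError(f"gene not in matrix: {gene_id!r}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def row_means(self) -> np.ndarray:
        """Per-gene mean over non-missing entries (abundance measure)."""
        return np.nanmean(self.values, axis=1)

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        rows = [self._index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_labels),
                                self.values[rows].copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="ID"),
                            columns=self.sample_labels)


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


def _sniff_dialect(header_fields: Sequence[str]) -> str:
    return "pcl" if "GWEIGHT" in header_fields else "generic_tsv"


def read_expression_table(path: str | Path, dialect: str = "auto") -> ExpressionMatrix:
    """Load a tab-delimited expression matrix.

    Parameters
    ----------
    path
        File to read; the first column must hold gene IDs and the
        first row a header of sample labels.
    dialect
        ``generic_tsv``, ``pcl``, or ``auto`` (sniffs the PCL signature
        -- a ``GWEIGHT`` header column -- and otherwise falls back to
        the generic reader).

    Rows with fewer than two non-missing values carry no usable
    profile; they are dropped and the count is logged.
    """
    path = Path(path)
    if dialect not in {"generic_tsv", "pcl", "auto"}:
        raise ValueError(f"unknown dialect: {dialect!r}")
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise ValueError(f"empty expression file: {path}")
    header = header_line.rstrip("\n").rstrip("\r").split("\t")
    if dialect == "auto":
        dialect = _sniff_dialect(header)

    raw = pd.read_csv(path, sep="\t", header=0, dtype=str,
                      keep_default_na=False, engine="c")
    id_col = raw.columns[0]
    drop_cols: list[str] = []
    if dialect == "pcl":
        # NAME / GWEIGHT columns and the EWEIGHT row carry no expression data
        drop_cols = [c for c in raw.columns[1:] if c.strip().upper() in {"NAME", "GWEIGHT"}]
        eweight = raw[id_col].str.strip().str.upper() == "EWEIGHT"
        raw = raw.loc[~eweight]
    data = raw.drop(columns=drop_cols)

    gene_ids = data[id_col].astype(str).str.strip().tolist()
    dup = _first_duplicate(gene_ids)
    if dup is not None:
        raise ValueError(f"duplicate gene ID in {path}: {dup!r}")
    sample_labels = [str(c) for c in data.columns[1:]]
    if len(sample_labels) < 2:
        raise ValueError(f"{path}: an expression matrix needs at least 2 data columns")

    values = data.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    values[~np.isfinite(values)] = np.nan

    keep = np.sum(~np.isnan(values), axis=1) >= 2
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info("dropped %d row(s) with fewer than 2 non-missing values", n_dropped)
    gene_ids = [g for g, k in zip(gene_ids, keep) if k]
    return ExpressionMatrix(gene_ids, sample_labels, values[keep])


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as generic TSV; missing entries become ``NA``.

    Values are serialized with Python's shortest round-trip float
    representation, so ``read(write(M))`` reproduces finite entries
    exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ID\t" + "\t".join(matrix.sample_labels) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            cells = [repr(float(v)) if np.isfinite(v) else "NA" for v in row]
            fh.write(gid + "\t" + "\t".join(cells) + "\n")


_RESULT_COLUMNS = ("gene_id", "correlation", "p_value", "n_pairs", "tier", "seed_flag")


def write_results(results: Sequence[SearchResult], path: str | Path) -> None:
    """Export search results as a tab-delimited table, order preserved."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for res in results:
            fh.write("\t".join([
                res.gene_id,
                repr(float(res.correlation)),
                repr(float(res.p_value)),
                str(res.n_pairs),
                res.tier,
                "1" if res.seed_flag else "0",
            ]) + "\n")


def read_results(path: str | Path) -> list[SearchResult]:
    """Parse a table written by :func:`write_results`."""
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "tier": str})
    return [
        SearchResult(
            gene_id=row.gene_id,
            correlation=float(row.correlation),
            p_value=float(row.p_value),
            n_pairs=int(row.n_pairs),
            seed_flag=bool(int(row.seed_flag)),
            tier=row.tier,
        )
        for row in table.itertuples(index=False)
    ]
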