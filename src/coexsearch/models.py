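"""Query-signature models built from a seed group.

A seed group is a small set of genes already known to share the
expression pattern of interest ("prior knowledge").  Three models turn
the seed rows into a single query signature of length N:

* **mean** -- the per-sample arithmetic mean ȳ of the k seed rows.
  Averaging suppresses independent noise, so the signature sharpens as
  the group grows.
* **regression** -- a degree-p polynomial least-squares fit to the
  seed mean profile over the sample abscissa, smoothing residual noise
  in gradually changing (time-series) data.  The coefficients solve
  the normal equations b = (X'X)⁻¹X'Y for the Vandermonde design
  X = [1, x, x², ..., x^p], computed here by a stable least-squares
  factorization.
* **delegate** -- the single seed row with the largest range
  Δ_i = max(y_i) − min(y_i); a real profile with strong dynamics,
  useful when seed genes differ wildly in scale.

The ensemble model (one search per seed row, union of hits) lives in
:mod:`coexsearch.search`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SeedGroup",
    "QuerySignature",
    "RegressionFit",
    "read_seed_groups",
    "build_mean_signature",
    "fit_polynomial_signature",
    "select_delegate",
]


@dataclass(frozen=True)
class SeedGroup:
    """A named, ordered list of prior-knowledge gene IDs."""

    name: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if len(self.gene_ids) == 0:
            raise ValueError("a seed group needs at least one gene")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"seed group {self.name!r} contains duplicate gene IDs")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class QuerySignature:
    """The sought expression pattern: one real value per sample."""

    values: np.ndarray
    source_model: str
    source_seeds: SeedGroup

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("a signature is a 1-D vector")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.all(finite == finite[0]):
            raise ValueError(
                "signature is constant; it cannot rank genes by correlation"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class RegressionFit:
    """A polynomial least-squares fit y ≈ b0 + b1·x + ... + bp·x^p.

    ``coefficients`` are in ascending degree order; ``fitted_values``
    is the polynomial evaluated at ``design_abscissa``.
    """

    degree: int
    coefficients: np.ndarray
    design_abscissa: np.ndarray
    fitted_values: np.ndarray


def _seed_rows(matrix: ExpressionMatrix, seeds: SeedGroup) -> np.ndarray:
    for gid in seeds.gene_ids:
        if gid not in matrix:
            raise KeyError(f"seed gene not in matrix: {gid!r}")
    return np.vstack([matrix.row(g) for g in seeds.gene_ids])


def _mean_profile(matrix: ExpressionMatrix, seeds: SeedGroup) -> np.ndarray:
    rows = _seed_rows(matrix, seeds)
    counts = np.sum(~np.isnan(rows), axis=0)
    if np.any(counts == 0):
        bad = int(np.argmax(counts == 0))
        raise ValueError(
            f"sample {matrix.sample_labels[bad]!r} has no non-missing value "
            f"in seed group {seeds.name!r}"
        )
    return np.nanmean(rows, axis=0)


def build_mean_signature(matrix: ExpressionMatrix, seeds: SeedGroup) -> QuerySignature:
    """ȳ = (Σ_{i=1..k} y_i) / k, per sample, over the k seed rows.

    Missing entries are excluded column-wise; a column with no
    non-missing seed value is an error.
    """
    return QuerySignature(_mean_profile(matrix, seeds), "mean", seeds)


def fit_polynomial_signature(
    matrix: ExpressionMatrix,
    seeds: SeedGroup,
    degree: int = 3,
    abscissa: np.ndarray | None = None,
) -> tuple[RegressionFit, QuerySignature]:
    """Fit a degree-p polynomial to the seed mean profile.

    Parameters
    ----------
    degree
        Polynomial degree p ≥ 1 with p + 1 ≤ N.  The default 3 captures
        one rise-and-fall with asymmetry, a reasonable shape for short
        time courses.
    abscissa
        Numeric positions of the samples (e.g. time points).  Defaults
        to the column index 0..N−1.

    The least-squares system is solved by QR/SVD factorization
    (``numpy.linalg.lstsq``); its solution coincides with the
    normal-equation closed form b = (X'X)⁻¹X'Y whenever X has full
    column rank, and a rank-deficient design raises an error.
    """
    n = matrix.n_samples
    if degree < 1:
        raise ValueError("polynomial degree must be at least 1")
    if degree + 1 > n:
        raise ValueError(f"degree {degree} needs at least {degree + 1} samples, have {n}")
    y = _mean_profile(matrix, seeds)
    if np.any(np.isnan(y)):
        raise ValueError("seed mean profile has missing samples; cannot fit")
    x = np.arange(n, dtype=float) if abscissa is None else np.asarray(abscissa, dtype=float)
    if x.shape != (n,):
        raise ValueError("abscissa length must equal the number of samples")

    design = np.vander(x, degree + 1, increasing=True)
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < degree + 1:
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {degree + 1}); "
            "need p + 1 distinct abscissa points"
        )
    fitted = design @ coef
    fit = RegressionFit(degree=degree, coefficients=coef,
                        design_abscissa=x, fitted_values=fitted)
    return fit, QuerySignature(fitted, "regression", seeds)


def select_delegate(
    matrix: ExpressionMatrix, seeds: SeedGroup
) -> tuple[str, QuerySignature]:
    """Pick the seed gene with maximal range Δ_i as the signature.

    Ties are broken by seed-list order (first wins).  The signature is
    that gene's row verbatim.
    """
    rows = _seed_rows(matrix, seeds)
    ranges = np.nanmax(rows, axis=1) - np.nanmin(rows, axis=1)
    best = int(np.argmax(ranges))  # argmax returns the first maximum
    delegate_id = seeds.gene_ids[best]
    return delegate_id, QuerySignature(rows[best].copy(), "delegate", seeds)


def read_seed_groups(path: str | Path) -> dict[str, SeedGroup]:
    """Parse a seed file into named groups.

    Two plain-text layouts are accepted:

    * one gene ID per line -> a single group named ``"seeds"``;
    * ``group<TAB>gene_id`` per line -> one group per distinct name,
      in file order (e.g. one group per cell-cycle phase).

    Blank lines and ``#`` comments are ignored.
    """
    groups: dict[str, list[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                name, gid = line.split("\t", 1)
            else:
                name, gid = "seeds", line
            groups.setdefault(name.strip(), []).append(gid.strip())
    if not groups:
        raise ValueError(f"seed file {path} contains no gene IDs")
    return {name: SeedGroup(name, tuple(ids)) for name, ids in groups.items()}
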