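"""Synthetic time-series expression matrices with planted coexpression.

The generator emulates a cell-cycle style experiment: a handful of
gene groups each follow a shared sinusoidal latent signature

    s_g[j] = sin(2π·j / period + φ_g),   j = 0..N−1,

with group-specific phases φ_g spread evenly around the circle (the
way marker genes of successive cell-cycle phases peak at staggered
times).  A member gene's row is an affine, noisy copy

    y[j] = a·s_g[j] + c + ε[j],   ε ~ N(0, noise_sd),

with a gene-specific positive scale a and offset c, so searches must
cope with heterogeneous amplitudes.  Background genes are independent
Gaussian noise around a random offset.  Ground-truth group labels are
returned alongside the matrix for recovery scoring.

Everything derives from one integer seed; the same seed reproduces
the matrix bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .io import ExpressionMatrix, SearchResult

logger = logging.getLogger(__name__)

__all__ = [
    "GenerationParams",
    "SyntheticTruth",
    "RecoveryScore",
    "generate_periodic_matrix",
    "score_recovery",
    "write_truth",
    "read_truth",
]

#: group names used when five groups are requested, matching the five
#: successive cell-cycle phases whose markers peak in this order
_PHASE_NAMES = ("G1S", "S", "G2", "G2M", "MG1")

BACKGROUND = "background"


@dataclass(frozen=True)
class GenerationParams:
    """Study conditions for :func:`generate_periodic_matrix`.

    Defaults mirror a compact cell-cycle experiment: 1000 genes over
    18 samples (one full cycle), five phase groups of 20 genes each,
    measurement noise at 0.3 on unit-amplitude latents, and per-gene
    scales between 0.5 and 3 so group members differ up to six-fold in
    amplitude.
    """

    n_genes: int = 1000
    n_samples: int = 18
    n_groups: int = 5
    group_size: int = 20
    amplitude_range: tuple[float, float] = (0.5, 3.0)
    offset_range: tuple[float, float] = (-2.0, 2.0)
    noise_sd: float = 0.3
    background_sd: float = 1.0
    period: float | None = None  # None -> n_samples (one cycle)
    phases: tuple[float, ...] | None = None  # None -> evenly spaced
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("need at least one group")
        if self.n_groups * self.group_size > self.n_genes:
            raise ValueError(
                f"{self.n_groups} groups of {self.group_size} exceed "
                f"{self.n_genes} genes"
            )
        if self.noise_sd < 0 or self.background_sd < 0:
            raise ValueError("noise levels must be non-negative")
        if self.phases is not None and len(self.phases) != self.n_groups:
            raise ValueError("phases must give one value per group")

    @property
    def group_names(self) -> tuple[str, ...]:
        if self.n_groups == len(_PHASE_NAMES):
            return _PHASE_NAMES
        return tuple(f"group{g + 1}" for g in range(self.n_groups))


@dataclass
class SyntheticTruth:
    """Ground truth emitted with a synthetic matrix."""

    group_of: dict[str, str]  # gene_id -> group name or "background"
    latent_signatures: dict[str, np.ndarray]
    generation_params: GenerationParams

    def members(self, group: str) -> list[str]:
        return [g for g, grp in self.group_of.items() if grp == group]


def generate_periodic_matrix(
    params: GenerationParams,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw a matrix with planted periodic groups plus noise background."""
    rng = np.random.default_rng(params.seed)
    n, k = params.n_samples, params.n_groups
    period = params.period if params.period is not None else float(n)
    j = np.arange(n, dtype=float)
    if params.phases is not None:
        phases = np.asarray(params.phases, dtype=float)
    else:
        phases = 2.0 * np.pi * np.arange(k) / k

    names = params.group_names
    latents = {
        name: np.sin(2.0 * np.pi * j / period + phi)
        for name, phi in zip(names, phases)
    }

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    group_of: dict[str, str] = {}
    lo_a, hi_a = params.amplitude_range
    lo_c, hi_c = params.offset_range
    for name in names:
        s = latents[name]
        for m in range(params.group_size):
            gid = f"{name}_{m + 1:03d}"
            a = rng.uniform(lo_a, hi_a)
            c = rng.uniform(lo_c, hi_c)
            eps = rng.normal(0.0, params.noise_sd, size=n) if params.noise_sd > 0 else 0.0
            gene_ids.append(gid)
            rows.append(a * s + c + eps)
            group_of[gid] = name

    n_background = params.n_genes - k * params.group_size
    for m in range(n_background):
        gid = f"BG_{m + 1:05d}"
        c = rng.uniform(lo_c, hi_c)
        gene_ids.append(gid)
        rows.append(c + rng.normal(0.0, params.background_sd, size=n))
        group_of[gid] = BACKGROUND

    labels = [f"t{i:02d}" for i in range(n)]
    matrix = ExpressionMatrix(gene_ids, labels, np.vstack(rows))
    truth = SyntheticTruth(group_of=group_of, latent_signatures=latents,
                           generation_params=params)
    return matrix, truth


class RecoveryScore(NamedTuple):
    precision: float
    recall: float
    defined: bool  # False when there were no non-seed hits to score


def score_recovery(
    truth: SyntheticTruth,
    results: Sequence[SearchResult],
    target_group: str,
    seed_ids: Sequence[str] = (),
) -> RecoveryScore:
    """Precision/recall of a hit list against one planted group.

    Seed genes are excluded from both numerator and denominator: they
    were handed to the search, so recovering them is not evidence.
    With no scoreable hits, precision is undefined and reported as 0
    with ``defined=False``.
    """
    if target_group not in truth.latent_signatures:
        raise KeyError(f"unknown group: {target_group!r}")
    seeds = set(seed_ids)
    hit_ids = [r.gene_id for r in results if r.gene_id not in seeds]
    members = set(truth.members(target_group)) - seeds
    true_hits = sum(1 for g in hit_ids if g in members)
    if not hit_ids:
        logger.warning("no non-seed hits; precision undefined")
        return RecoveryScore(0.0, 0.0 if members else 1.0, False)
    precision = true_hits / len(hit_ids)
    recall = true_hits / len(members) if members else 1.0
    return RecoveryScore(precision, recall, True)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Write gene→group labels as a two-column TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tgroup\n")
        for gid, grp in truth.group_of.items():
            fh.write(f"{gid}\t{grp}\n")


def read_truth(path: str | Path) -> dict[str, str]:
    """Read the gene→group labels written by :func:`write_truth`."""
    out: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            gid, grp = line.rstrip("\n").split("\t")
            out[gid] = grp
    return out
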