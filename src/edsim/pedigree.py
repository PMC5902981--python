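"""Pedigree inbreeding via generation-wise relationship propagation.

With discrete generations and parents drawn only from the immediately
preceding generation, the additive (numerator) relationship matrix never
needs to be built over the whole pedigree: it suffices to carry the matrix
among the current selected parents.  For animals x, y with parents
(sx, dx) and (sy, dy) whose relationships are known,

    a(x, y) = 0.25 * (a(sx, sy) + a(sx, dy) + a(dx, sy) + a(dx, dy)),  x != y
    a(x, x) = 1 + 0.5 * a(sx, dx)

which is exactly the classic tabular method restricted to the current
parents.  A candidate's inbreeding coefficient is half the additive
relationship of its parents, F = 0.5 * a(sire, dam).

At the default design this keeps the per-generation cost at a ~2100 x 2100
matrix instead of a tabular pass over a ~500,000-animal pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "RelationshipCache",
    "founder_cache",
    "propagate_relationships",
    "offspring_inbreeding",
    "GenerationStats",
    "generation_stats",
]


@dataclass
class RelationshipCache:
    """Additive-relationship matrix among one generation's selected parents.

    ``a`` is symmetric with diagonal 1 + F of each parent and entries in
    [0, 2]; ``ids`` maps matrix rows to animal ids.
    """

    a: np.ndarray
    ids: np.ndarray

    @property
    def n(self) -> int:
        return int(self.ids.size)

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients of the cached parents (diagonal - 1)."""
        return np.diag(self.a) - 1.0


def founder_cache(ids: np.ndarray) -> RelationshipCache:
    """Identity base matrix: founders are unrelated and non-inbred."""
    return RelationshipCache(a=np.eye(ids.size), ids=np.asarray(ids, dtype=np.int64))


def propagate_relationships(
    prev_cache: Optional[RelationshipCache],
    sire_rows: Optional[np.ndarray],
    dam_rows: Optional[np.ndarray],
    ids: np.ndarray,
) -> RelationshipCache:
    """Relationship matrix among newly selected parents.

    ``sire_rows[i]``/``dam_rows[i]`` index the i-th selected animal's
    parents in ``prev_cache``.  With ``prev_cache=None`` the selected
    animals are founders and the identity matrix is returned.
    """
    ids = np.asarray(ids, dtype=np.int64)
    if prev_cache is None:
        return founder_cache(ids)
    if sire_rows is None or dam_rows is None:
        raise ValueError("parent rows are required when a previous cache exists")
    sire_rows = np.asarray(sire_rows)
    dam_rows = np.asarray(dam_rows)
    if sire_rows.max(initial=-1) >= prev_cache.n or dam_rows.max(initial=-1) >= prev_cache.n:
        raise ValueError("parent row index outside the previous relationship cache")
    a_prev = prev_cache.a
    # gather the four parent-pair blocks in two steps to halve the work;
    # np.take is markedly faster than fancy indexing on the column axis
    half = 0.5 * (np.take(a_prev, sire_rows, axis=0) + np.take(a_prev, dam_rows, axis=0))
    a_new = 0.5 * (np.take(half, sire_rows, axis=1) + np.take(half, dam_rows, axis=1))
    np.fill_diagonal(a_new, 1.0 + 0.5 * a_prev[sire_rows, dam_rows])
    return RelationshipCache(a=a_new, ids=ids)


def offspring_inbreeding(cache, sire_rows, dam_rows):
    """F of offspring = half the parents' additive relationship.

    Vectorized over parallel arrays of parent rows; returns 0 where either
    parent is unknown (row < 0).
    """
    sire_rows = np.asarray(sire_rows)
    dam_rows = np.asarray(dam_rows)
    if cache is None:
        return np.zeros(sire_rows.shape)
    f = 0.5 * cache.a[np.clip(sire_rows, 0, None), np.clip(dam_rows, 0, None)]
    return np.where((sire_rows < 0) | (dam_rows < 0), 0.0, f)


@dataclass
class GenerationStats:
    """Per-generation summaries of one candidate cohort."""

    generation: int
    size: int
    allele_freq: float
    mean_tbv: float
    var_tbv: float
    mean_f: float
    response: float  # mean TBV minus previous cohort's mean TBV
    delta_f: float  # mean F minus previous cohort's mean F
    n_subjected: int  # zygotes that underwent the editing procedure
    n_survived_editing: int
    n_fully_edited: int  # subjected zygotes alive with G = 2 afterwards
    n_eligible_matings: int
    n_flagged_matings: int
    n_dominant: int  # animals with G >= 1 (desired phenotype, dominant)
    n_recessive: int  # animals with G = 2 (desired phenotype, recessive)

    @property
    def fixed(self) -> bool:
        return self.allele_freq == 1.0


def generation_stats(
    cohort,
    prev: Optional[GenerationStats] = None,
    n_subjected: int = 0,
    n_survived_editing: int = 0,
    n_fully_edited: int = 0,
    n_eligible_matings: int = 0,
    n_flagged_matings: int = 0,
) -> GenerationStats:
    """Summarize a live cohort; response and delta-F are taken against ``prev``."""
    n = cohort.size
    if n == 0:
        raise ValueError("cannot summarize an empty cohort")
    mean_tbv = float(np.mean(cohort.tbv))
    mean_f = float(np.mean(cohort.f))
    return GenerationStats(
        generation=cohort.generation,
        size=n,
        allele_freq=float(np.sum(cohort.g, dtype=np.int64)) / (2.0 * n),
        mean_tbv=mean_tbv,
        var_tbv=float(np.var(cohort.tbv)),
        mean_f=mean_f,
        response=mean_tbv - prev.mean_tbv if prev is not None else float("nan"),
        delta_f=mean_f - prev.mean_f if prev is not None else float("nan"),
        n_subjected=n_subjected,
        n_survived_editing=n_survived_editing,
        n_fully_edited=n_fully_edited,
        n_eligible_matings=n_eligible_matings,
        n_flagged_matings=n_flagged_matings,
        n_dominant=int(np.count_nonzero(cohort.g >= 1)),
        n_recessive=int(np.count_nonzero(cohort.g == 2)),
    )
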