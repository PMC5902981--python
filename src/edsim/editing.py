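"""Zygote genome editing: mating targeting and per-zygote outcomes.

Editing is applied during reproduction, to zygotes, and never changes the
genotypes of the selected parents.  When only a fraction of matings can be
edited, matings are targeted by (1) the smallest number of desired alleles
carried by the two parents and (2) the best parent average of the selection
index, so that the procedures go where they convert the most alleles in the
best genetic background.  Matings whose parents jointly carry four desired
alleles produce no editable zygotes and are never flagged.

Every zygote of a flagged mating undergoes the procedure: each undesired
allele is independently converted to the desired allele with success
probability ``k``, and the zygote survives the procedure with probability
``s`` (survival risk attaches to being subjected, not to edit success).
Eligibility is decided at the family level, so a zygote that happens to be
homozygous for the desired allele is still subjected and counted; at the
default design this yields exactly 2000 procedures per generation while
eligible matings remain plentiful.  Setting ``subject_noncarriers=False``
restricts the procedure (and its survival risk and cost) to carrier
zygotes instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .population import AnimalRecord

__all__ = ["EditingPlan", "select_matings_for_editing", "apply_editing", "apply_editing_batch"]


@dataclass
class EditingPlan:
    """Which matings are flagged for editing this generation."""

    flagged: np.ndarray  # bool per mating
    n_eligible: int

    @property
    def n_flagged(self) -> int:
        return int(np.count_nonzero(self.flagged))


def select_matings_for_editing(
    parental_allele_count: np.ndarray,
    parent_avg_index: np.ndarray,
    dam_ids: np.ndarray,
    edit_fraction: float,
    rng: Optional[np.random.Generator] = None,
) -> EditingPlan:
    """Flag up to round(edit_fraction * n_matings) matings for editing.

    Eligible matings (parents together carry fewer than four desired
    alleles) are ranked by ascending parental desired-allele count, then
    descending parent-average index, then ascending dam id as a
    deterministic final tie-break; the best-ranked matings are flagged.
    ``rng`` is accepted for interface symmetry but unused: the rule is
    deterministic.
    """
    count = np.asarray(parental_allele_count)
    n_matings = count.size
    n_target = int(edit_fraction * n_matings + 0.5)
    flagged = np.zeros(n_matings, dtype=bool)
    eligible = np.flatnonzero(count < 4)
    if n_target > 0 and eligible.size > 0:
        order = np.lexsort(
            (
                np.asarray(dam_ids)[eligible],
                -np.asarray(parent_avg_index)[eligible],
                count[eligible],
            )
        )
        flagged[eligible[order[:n_target]]] = True
    return EditingPlan(flagged=flagged, n_eligible=int(eligible.size))


def apply_editing_batch(
    g: np.ndarray, k: float, s: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Edit a batch of subjected zygotes; returns (new genotypes, alive mask).

    Each of the ``2 - G`` undesired alleles converts independently with
    probability ``k`` (a binomial draw); survival is an independent
    Bernoulli(s) per zygote, applied regardless of edit success.
    """
    g = np.asarray(g, dtype=np.int8)
    converted = rng.binomial(2 - g, k).astype(np.int8)
    alive = rng.random(g.shape) < s
    return g + converted, alive


def apply_editing(
    zygote: AnimalRecord,
    k: float,
    s: float,
    rng: np.random.Generator,
    allow_noncarrier: bool = True,
) -> AnimalRecord:
    """Subject a single zygote to the editing procedure.

    With ``allow_noncarrier=False`` (the carrier-only convention) calling
    this on a G = 2 zygote is a contract violation: such zygotes are not
    subjected and must not be counted as procedures.
    """
    if zygote.genotype_g == 2 and not allow_noncarrier:
        raise ValueError(
            "apply_editing called on a zygote already homozygous for the desired allele"
        )
    new_g, alive = apply_editing_batch(
        np.array([zygote.genotype_g]), k, s, rng
    )
    zygote.genotype_g = int(new_g[0])
    zygote.alive = bool(alive[0])
    zygote.was_subjected_to_editing = True
    return zygote
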