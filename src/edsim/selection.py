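"""Selection index, truncation selection, mate assignment and reproduction.

Selection is by truncation on the index I = b1 * EBV + b2 * G within each
sex: the ``n_sires`` males and ``n_dams`` females with the highest index
become the parents of the next generation.  With b2 = 0 this is genomic
selection on the polygenic trait alone; b2 = 1000 puts effectively maximal
emphasis on the monogenic genotype while the EBV only breaks ties within a
genotype class.  One sire is assigned to each dam uniformly at random with
replacement and every mating produces a fixed number of zygotes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import ScenarioSpec
from .editing import EditingPlan, apply_editing_batch
from .pedigree import RelationshipCache, offspring_inbreeding
from .population import (
    Cohort,
    MALE,
    FEMALE,
    PopulationState,
    mendelian_sampling_variance,
    simulate_ebv,
    transmit_genotypes,
)

__all__ = [
    "ReplicateError",
    "Matings",
    "compute_index",
    "truncation_select",
    "assign_mates",
    "build_matings",
    "produce_generation",
]


class ReplicateError(RuntimeError):
    """A replicate cannot continue (e.g. too few candidates of one sex)."""


def compute_index(ebv, g, b1: float, b2: float):
    """Selection index I = b1 * EBV + b2 * G (scalar or vectorized)."""
    return b1 * np.asarray(ebv, dtype=float) + b2 * np.asarray(g, dtype=float)


def truncation_select(
    cohort: Cohort, n_sires: int, n_dams: int, b1: float, b2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Positions of the selected sires and dams within ``cohort``.

    Within each sex the candidates with the highest index are chosen; exact
    index ties are broken toward the lower animal id so a given cohort
    always selects the same parents.  Raises :class:`ReplicateError` when a
    sex has fewer candidates than required parents.
    """
    index = compute_index(cohort.ebv, cohort.g, b1, b2)
    males = np.flatnonzero(cohort.sex == MALE)
    females = np.flatnonzero(cohort.sex == FEMALE)
    if males.size < n_sires:
        raise ReplicateError(f"only {males.size} male candidates for {n_sires} sires")
    if females.size < n_dams:
        raise ReplicateError(f"only {females.size} female candidates for {n_dams} dams")
    # lexsort: last key is primary -> descending index, ascending id on ties
    male_order = males[np.lexsort((cohort.ids[males], -index[males]))]
    female_order = females[np.lexsort((cohort.ids[females], -index[females]))]
    return male_order[:n_sires], female_order[:n_dams]


def assign_mates(
    n_sires: int,
    n_dams: int,
    rng: np.random.Generator,
    balanced: bool = False,
) -> np.ndarray:
    """Sire choice for each dam: index into the selected-sire list.

    Default is uniform at random with replacement (a sire may stay unused);
    ``balanced=True`` instead assigns each sire to (nearly) equal numbers
    of dams in a random order, for sensitivity checks.
    """
    if n_sires < 1 or n_dams < 1:
        raise ValueError("need at least one sire and one dam")
    if balanced:
        reps = -(-n_dams // n_sires)  # ceil
        pool = np.tile(np.arange(n_sires), reps)[:n_dams]
        return rng.permutation(pool)
    return rng.integers(0, n_sires, size=n_dams)


@dataclass
class Matings:
    """Struct of arrays describing one generation's matings.

    Row i is the mating of dam i; ``sire_rows``/``dam_rows`` index the
    parents in the relationship cache built over the selected parents.
    """

    sire_rows: np.ndarray
    dam_rows: np.ndarray
    sire_ids: np.ndarray
    dam_ids: np.ndarray
    sire_tbv: np.ndarray
    dam_tbv: np.ndarray
    sire_f: np.ndarray
    dam_f: np.ndarray
    sire_g: np.ndarray
    dam_g: np.ndarray
    parent_avg_index: np.ndarray

    @property
    def n(self) -> int:
        return int(self.dam_ids.size)

    @property
    def parental_allele_count(self) -> np.ndarray:
        """Desired alleles jointly carried by the two parents (0-4)."""
        return self.sire_g.astype(np.int64) + self.dam_g.astype(np.int64)


def build_matings(
    cohort: Cohort,
    sire_pos: np.ndarray,
    dam_pos: np.ndarray,
    sire_choice: np.ndarray,
    b1: float,
    b2: float,
) -> Matings:
    """Assemble the mating table from selected parents and the sire draw.

    Cache rows are laid out sires first (rows 0..n_sires-1) then dams, the
    same order used to propagate the relationship matrix.
    """
    index = compute_index(cohort.ebv, cohort.g, b1, b2)
    sp = sire_pos[sire_choice]  # cohort position of each dam's sire
    n_sires = sire_pos.size
    return Matings(
        sire_rows=sire_choice,
        dam_rows=n_sires + np.arange(dam_pos.size),
        sire_ids=cohort.ids[sp],
        dam_ids=cohort.ids[dam_pos],
        sire_tbv=cohort.tbv[sp],
        dam_tbv=cohort.tbv[dam_pos],
        sire_f=cohort.f[sp],
        dam_f=cohort.f[dam_pos],
        sire_g=cohort.g[sp],
        dam_g=cohort.g[dam_pos],
        parent_avg_index=0.5 * (index[sp] + index[dam_pos]),
    )


def produce_generation(
    matings: Matings,
    spec: ScenarioSpec,
    editing_plan: Optional[EditingPlan],
    rng: np.random.Generator,
    cache: RelationshipCache,
    generation: int,
    next_id: int,
) -> tuple[PopulationState, dict]:
    """Create the next candidate cohort from the mating table.

    Every mating contributes ``n_off_per_mating`` zygotes.  Draw order per
    generation is fixed (Mendelian-sampling normals, genotype transmission,
    edit conversions, edit survival, sexes, EBV of survivors) so replicates
    are bit-reproducible.  Dead zygotes are removed before the cohort is
    assembled; returns the new population state and the editing counters.
    """
    n_off = spec.n_off_per_mating
    m = np.repeat(np.arange(matings.n), n_off)

    msv = mendelian_sampling_variance(matings.sire_f, matings.dam_f)
    ms = rng.standard_normal(m.size) * np.sqrt(msv[m])
    tbv = 0.5 * (matings.sire_tbv[m] + matings.dam_tbv[m]) + ms
    g = transmit_genotypes(matings.sire_g[m], matings.dam_g[m], rng)
    f_mating = offspring_inbreeding(cache, matings.sire_rows, matings.dam_rows)

    alive = np.ones(m.size, dtype=bool)
    edited = np.zeros(m.size, dtype=bool)
    counters = {
        "n_subjected": 0,
        "n_survived_editing": 0,
        "n_fully_edited": 0,
        "n_eligible_matings": 0,
        "n_flagged_matings": 0,
    }
    if editing_plan is not None:
        flagged_z = editing_plan.flagged[m]
        if spec.subject_noncarriers:
            subject = flagged_z
        else:
            subject = flagged_z & (g < 2)
        sub_idx = np.flatnonzero(subject)
        g_sub, alive_sub = apply_editing_batch(
            g[sub_idx], spec.edit_success_k, spec.edit_survival_s, rng
        )
        g[sub_idx] = g_sub
        alive[sub_idx] = alive_sub
        edited[sub_idx] = True
        counters.update(
            n_subjected=int(sub_idx.size),
            n_survived_editing=int(np.count_nonzero(alive_sub)),
            n_fully_edited=int(np.count_nonzero(alive_sub & (g_sub == 2))),
            n_eligible_matings=editing_plan.n_eligible,
            n_flagged_matings=editing_plan.n_flagged,
        )

    keep = np.flatnonzero(alive)
    n_alive = keep.size
    if n_alive == 0:
        raise ReplicateError("editing mortality removed the entire cohort")
    sex = rng.integers(0, 2, size=n_alive).astype(np.int8)
    ebv = np.asarray(simulate_ebv(tbv[keep], spec.reliability_r2, rng))
    cohort = Cohort(
        generation=generation,
        ids=next_id + np.arange(n_alive, dtype=np.int64),
        sire_ids=matings.sire_ids[m[keep]],
        dam_ids=matings.dam_ids[m[keep]],
        sex=sex,
        tbv=tbv[keep],
        ebv=ebv,
        g=g[keep],
        f=f_mating[m[keep]],
        edited=edited[keep],
        mating_index=m[keep],
    )
    state = PopulationState(
        cohort=cohort,
        parent_cache=cache,
        mating_sire_rows=matings.sire_rows,
        mating_dam_rows=matings.dam_rows,
        next_id=next_id + n_alive,
    )
    return state, counters
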