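"""Founder creation and offspring genetics.

The polygenic trait is simulated directly on the true-breeding-value (TBV)
scale: founders draw TBV ~ N(0, 1) and offspring receive the mid-parent TBV
plus a Mendelian sampling deviate whose variance shrinks with parental
inbreeding, N(0, 0.5 * (1 - 0.5 * (F_sire + F_dam))).  Genomic prediction is
emulated with a pseudo-EBV: EBV = r2 * (TBV + PE) with prediction error
PE ~ N(0, (1 - r2) / r2) on the founder genetic-variance scale, which gives
the EBV a reliability (squared accuracy) of r2 in the founder population.

The monogenic locus is a single biallelic gene, unlinked to the polygenic
background; genotypes are stored as the count G in {0, 1, 2} of desired
alleles.  Founder genotypes follow Hardy-Weinberg proportions at the
configured starting frequency and transmission is Mendelian.

Cohorts are stored as structs of numpy arrays (:class:`Cohort`) so that a
20,000-candidate generation is produced with a handful of vectorized draws;
:class:`AnimalRecord` is the scalar per-animal view used at the API edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .config import ScenarioSpec

__all__ = [
    "AnimalRecord",
    "Cohort",
    "PopulationState",
    "init_founders",
    "simulate_ebv",
    "mendelian_sampling_variance",
    "make_offspring",
    "transmit_genotypes",
    "write_pedigree",
]

#: sentinel for an unknown parent in pedigree columns
UNKNOWN_PARENT = 0

MALE = 1
FEMALE = 0


@dataclass
class AnimalRecord:
    """One individual: pedigree links, sex, genetic values and flags."""

    id: int
    sire_id: int  # 0 = unknown (founder)
    dam_id: int
    generation: int
    sex: int  # 1 = male, 0 = female
    tbv: float
    ebv: float
    genotype_g: int  # desired-allele count in {0, 1, 2}
    inbreeding_f: float
    was_subjected_to_editing: bool = False
    alive: bool = True

    def __post_init__(self) -> None:
        if self.genotype_g not in (0, 1, 2):
            raise ValueError(f"genotype_g must be in {{0,1,2}}, got {self.genotype_g}")
        if not 0.0 <= self.inbreeding_f < 1.0:
            raise ValueError(f"inbreeding_f must be in [0,1), got {self.inbreeding_f}")


@dataclass
class Cohort:
    """A candidate generation as a struct of aligned arrays.

    Dead zygotes are dropped before the cohort is constructed, so every row
    is a live selection candidate.
    """

    generation: int
    ids: np.ndarray  # int64, strictly increasing
    sire_ids: np.ndarray  # int64, 0 = unknown
    dam_ids: np.ndarray
    sex: np.ndarray  # int8, 1 = male
    tbv: np.ndarray  # float64
    ebv: np.ndarray
    g: np.ndarray  # int8
    f: np.ndarray  # float64 inbreeding coefficient
    edited: np.ndarray  # bool, zygote was subjected to an editing procedure
    #: per animal, index of the producing mating (-1 for founders); used to
    #: look up the parents' rows in the previous relationship cache.
    mating_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mating_index is None:
            self.mating_index = np.full(self.size, -1, dtype=np.int64)

    @property
    def size(self) -> int:
        return int(self.ids.size)

    def record(self, i: int) -> AnimalRecord:
        """Scalar view of animal at row ``i``."""
        return AnimalRecord(
            id=int(self.ids[i]),
            sire_id=int(self.sire_ids[i]),
            dam_id=int(self.dam_ids[i]),
            generation=self.generation,
            sex=int(self.sex[i]),
            tbv=float(self.tbv[i]),
            ebv=float(self.ebv[i]),
            genotype_g=int(self.g[i]),
            inbreeding_f=float(self.f[i]),
            was_subjected_to_editing=bool(self.edited[i]),
        )


@dataclass
class PopulationState:
    """Current cohort plus the bookkeeping needed to advance one generation.

    ``parent_cache`` holds the additive-relationship matrix among the
    parents that produced ``cohort`` (None for the founder cohort);
    ``mating_sire_rows``/``mating_dam_rows`` map each producing mating to
    its parents' rows in that cache.
    """

    cohort: Cohort
    parent_cache: Optional["RelationshipCache"] = None  # noqa: F821
    mating_sire_rows: Optional[np.ndarray] = None
    mating_dam_rows: Optional[np.ndarray] = None
    next_id: int = 1


def mendelian_sampling_variance(f_sire, f_dam):
    """Variance of the Mendelian sampling deviate, 0.5*(1 - 0.5*(Fs + Fd)).

    Accepts scalars or arrays; fully inbred parents give zero variance.
    """
    return 0.5 * (1.0 - 0.5 * (np.asarray(f_sire) + np.asarray(f_dam)))


def simulate_ebv(tbv, r2: float, rng: np.random.Generator):
    """Pseudo-EBV for one or many animals: r2 * (TBV + PE).

    PE ~ N(0, (1 - r2) / r2) on the founder genetic-variance scale
    (sigma^2_A = 1), held fixed across generations.  ``r2 = 1`` returns the
    TBV itself.
    """
    if not 0.0 < r2 <= 1.0:
        raise ValueError(f"reliability r2 must lie in (0, 1], got {r2!r}")
    tbv = np.asarray(tbv, dtype=float)
    pe_sd = np.sqrt((1.0 - r2) / r2)
    pe = rng.normal(0.0, 1.0, size=tbv.shape) * pe_sd
    out = r2 * (tbv + pe)
    return out if out.shape else float(out)


def init_founders(spec: ScenarioSpec, rng: np.random.Generator) -> PopulationState:
    """Create the unrelated, non-inbred founder cohort.

    Founders sit at generation ``-n_burnin_generations``; TBV ~ N(0, 1),
    monogenic genotypes follow Hardy-Weinberg proportions at frequency
    ``founder_allele_freq``, sexes are Bernoulli(0.5).
    """
    n = spec.n_candidates
    p = spec.founder_allele_freq
    tbv = rng.standard_normal(n)
    # binomial(2, p) reproduces HWE proportions {(1-p)^2, 2p(1-p), p^2}
    g = rng.binomial(2, p, size=n).astype(np.int8)
    sex = rng.integers(0, 2, size=n).astype(np.int8)
    ebv = simulate_ebv(tbv, spec.reliability_r2, rng)
    cohort = Cohort(
        generation=-spec.n_burnin_generations,
        ids=np.arange(1, n + 1, dtype=np.int64),
        sire_ids=np.full(n, UNKNOWN_PARENT, dtype=np.int64),
        dam_ids=np.full(n, UNKNOWN_PARENT, dtype=np.int64),
        sex=sex,
        tbv=tbv,
        ebv=np.asarray(ebv),
        g=g,
        f=np.zeros(n),
        edited=np.zeros(n, dtype=bool),
    )
    return PopulationState(cohort=cohort, next_id=n + 1)


def transmit_genotypes(
    g_sire, g_dam, rng: np.random.Generator
) -> np.ndarray:
    """Mendelian transmission at the monogenic locus, vectorized.

    Each parent passes a desired allele with probability G/2 (never for
    G = 0, always for G = 2, a fair coin for heterozygotes); the offspring
    genotype is the sum of the two transmitted alleles.
    """
    g_sire = np.asarray(g_sire)
    g_dam = np.asarray(g_dam)
    from_sire = rng.random(g_sire.shape) < g_sire / 2.0
    from_dam = rng.random(g_dam.shape) < g_dam / 2.0
    return (from_sire.astype(np.int8) + from_dam.astype(np.int8))


def make_offspring(
    sire: AnimalRecord,
    dam: AnimalRecord,
    f_offspring: float,
    rng: np.random.Generator,
    r2: float = 0.5,
    offspring_id: int = 0,
    generation: int = 0,
) -> AnimalRecord:
    """Produce a single offspring from two selected parents.

    TBV is the mid-parent value plus a Mendelian sampling deviate with
    variance ``mendelian_sampling_variance(F_sire, F_dam)``; the monogenic
    genotype is Mendelian; sex is Bernoulli(0.5); the inbreeding
    coefficient ``f_offspring`` is supplied by the pedigree machinery
    (half the parents' additive relationship).
    """
    msv = float(mendelian_sampling_variance(sire.inbreeding_f, dam.inbreeding_f))
    ms = rng.normal(0.0, np.sqrt(msv)) if msv > 0 else 0.0
    tbv = 0.5 * sire.tbv + 0.5 * dam.tbv + ms
    g = int(transmit_genotypes(sire.genotype_g, dam.genotype_g, rng))
    sex = int(rng.integers(0, 2))
    ebv = float(simulate_ebv(tbv, r2, rng))
    return AnimalRecord(
        id=offspring_id,
        sire_id=sire.id,
        dam_id=dam.id,
        generation=generation,
        sex=sex,
        tbv=tbv,
        ebv=ebv,
        genotype_g=g,
        inbreeding_f=f_offspring,
    )


def write_pedigree(
    cohorts: list[tuple[np.ndarray, np.ndarray, np.ndarray]], path: str | Path
) -> Path:
    """Write a 3-column whitespace-delimited pedigree (id sire dam; 0 = unknown).

    ``cohorts`` is a list of (ids, sire_ids, dam_ids) triples in generation
    order, so the output is topologically sorted and consumable by standard
    pedigree software.
    """
    path = Path(path)
    with path.open("w") as fh:
        for ids, sires, dams, *_ in cohorts:
            for i, s, d in zip(ids, sires, dams):
                fh.write(f"{i} {s} {d}\n")
    return path
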