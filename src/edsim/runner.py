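"""Replicate orchestration, evaluation metrics and report writing.

A replicate runs two phases.  Phase 1 ("burn-in") applies five generations
of truncation selection on the pseudo-EBV alone, which drives the genetic
variance and per-generation response to their Bulmer equilibrium; the
cohort reached at generation 0 is the starting point for comparisons.
Phase 2 selects on the index I = b1*EBV + b2*G for 20 generations, with or
without zygote genome editing.

Scenario evaluation follows the breeding-program bookkeeping: time to
fixation of the desired allele (excluding replicates in which the allele is
lost by drift), loss in polygenic response versus the b2 = 0 genomic
selection baseline (expressed in months via the generation-0 equilibrium
response and a 24-month generation interval, and in units of the
generation-0 equilibrium genetic variance), pedigree inbreeding, cumulative
editing procedures, and the cumulative percentage of animals born with the
desired phenotype under dominant (G >= 1) or recessive (G = 2) gene action.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ScenarioSpec, write_spec
from .editing import select_matings_for_editing
from .pedigree import (
    GenerationStats,
    founder_cache,
    generation_stats,
    propagate_relationships,
)
from .population import init_founders, write_pedigree
from .selection import assign_mates, build_matings, produce_generation, truncation_select

__all__ = [
    "ReplicateResult",
    "AggregateReport",
    "run_replicate",
    "run_experiment",
    "time_to_fixation",
    "loss_in_months",
    "loss_in_sd",
    "cumulative_benefit",
    "breakeven_cost",
    "summarize_scenario",
    "write_report",
]

_STAT_FIELDS = [
    "size",
    "allele_freq",
    "mean_tbv",
    "var_tbv",
    "mean_f",
    "response",
    "delta_f",
    "n_subjected",
    "n_survived_editing",
    "n_fully_edited",
    "n_eligible_matings",
    "n_flagged_matings",
    "n_dominant",
    "n_recessive",
]


@dataclass
class ReplicateResult:
    """Trajectory and outcome flags of one scenario replicate."""

    scenario: str
    replicate: int
    seed: int
    stats: list[GenerationStats]
    fixation_generation: Optional[int]
    allele_lost: bool
    cumulative_procedures: int
    pedigree: Optional[list] = None

    def stat_at(self, generation: int) -> GenerationStats:
        for st in self.stats:
            if st.generation == generation:
                return st
        raise KeyError(f"no stats recorded for generation {generation}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"generation": st.generation, **{f: getattr(st, f) for f in _STAT_FIELDS}}
            for st in self.stats
        ]
        df = pd.DataFrame(rows)
        df.insert(0, "replicate", self.replicate)
        df.insert(0, "scenario", self.scenario)
        return df


def run_replicate(
    spec: ScenarioSpec, seed: int, keep_pedigree: bool = False
) -> ReplicateResult:
    """Run one replicate of ``spec`` with its own seeded random stream.

    Bit-reproducible for a given (spec, seed).  Allele extinction is not an
    error: it is recorded in the ``allele_lost`` flag.
    """
    rng = np.random.default_rng(seed)
    state = init_founders(spec, rng)
    stats: list[GenerationStats] = [generation_stats(state.cohort)]
    pedigree = None
    if keep_pedigree:
        c = state.cohort
        # (ids, sire_ids, dam_ids, F) per generation; F kept for auditing
        # the relationship propagation against full-pedigree methods
        pedigree = [(c.ids.copy(), c.sire_ids.copy(), c.dam_ids.copy(), c.f.copy())]

    n_rounds = spec.n_burnin_generations + spec.n_selection_generations
    prev = stats[0]
    for _ in range(n_rounds):
        cohort = state.cohort
        parent_gen = cohort.generation
        in_phase2 = parent_gen >= 0  # index selection and editing start at gen 0
        b2 = spec.b2 if in_phase2 else 0.0

        sire_pos, dam_pos = truncation_select(
            cohort, spec.n_sires, spec.n_dams, spec.b1, b2
        )
        sel = np.concatenate([sire_pos, dam_pos])
        if state.parent_cache is None:
            cache = founder_cache(cohort.ids[sel])
        else:
            msel = cohort.mating_index[sel]
            cache = propagate_relationships(
                state.parent_cache,
                state.mating_sire_rows[msel],
                state.mating_dam_rows[msel],
                cohort.ids[sel],
            )
        sire_choice = assign_mates(
            spec.n_sires, spec.n_dams, rng, balanced=spec.balanced_matings
        )
        matings = build_matings(cohort, sire_pos, dam_pos, sire_choice, spec.b1, b2)
        plan = None
        if spec.use_editing and in_phase2:
            plan = select_matings_for_editing(
                matings.parental_allele_count,
                matings.parent_avg_index,
                matings.dam_ids,
                spec.edit_fraction,
            )
        state, counters = produce_generation(
            matings, spec, plan, rng, cache, parent_gen + 1, state.next_id
        )
        st = generation_stats(state.cohort, prev, **counters)
        stats.append(st)
        prev = st
        if keep_pedigree:
            c = state.cohort
            pedigree.append(
                (c.ids.copy(), c.sire_ids.copy(), c.dam_ids.copy(), c.f.copy())
            )

    freqs = [st.allele_freq for st in stats if st.generation >= 0]
    fix_gen = time_to_fixation(freqs)
    return ReplicateResult(
        scenario=spec.name,
        replicate=0,
        seed=seed,
        stats=stats,
        fixation_generation=fix_gen,
        allele_lost=stats[-1].allele_freq == 0.0,
        cumulative_procedures=int(sum(st.n_subjected for st in stats)),
        pedigree=pedigree,
    )


@dataclass
class AggregateReport:
    """Replicate-averaged evaluation of one scenario."""

    spec: ScenarioSpec
    base_seed: int
    replicates: list[ReplicateResult]
    per_generation: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        frames = pd.concat([r.to_frame() for r in self.replicates], ignore_index=True)
        grouped = frames.groupby("generation")[_STAT_FIELDS]
        mean = grouped.mean().add_prefix("mean_")
        se = (grouped.std(ddof=1) / math.sqrt(len(self.replicates))).add_prefix("se_")
        self.per_generation = mean.join(se).reset_index()

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def mean_at(self, column: str, generation: int) -> float:
        row = self.per_generation.loc[self.per_generation["generation"] == generation]
        if row.empty:
            raise KeyError(f"generation {generation} not simulated")
        return float(row[f"mean_{column}"].iloc[0])

    def se_at(self, column: str, generation: int) -> float:
        row = self.per_generation.loc[self.per_generation["generation"] == generation]
        return float(row[f"se_{column}"].iloc[0])

    @property
    def equilibrium_response(self) -> float:
        """Replicate-mean per-generation response at generation 0."""
        return self.mean_at("response", 0)

    @property
    def equilibrium_variance(self) -> float:
        """Replicate-mean genetic variance of TBV at generation 0."""
        return self.mean_at("var_tbv", 0)

    @property
    def allele_lost_fraction(self) -> float:
        return sum(r.allele_lost for r in self.replicates) / self.n_replicates

    def mean_fixation_generation(self) -> Optional[float]:
        """Mean time to fixation over replicates where the allele was not
        lost by drift; None if the allele never fixed."""
        times = [
            r.fixation_generation
            for r in self.replicates
            if r.fixation_generation is not None and not r.allele_lost
        ]
        if not times:
            return None
        return float(np.mean(times))

    def mean_cumulative_procedures(self, horizon: Optional[int] = None) -> float:
        """Replicate-mean zygotes subjected to editing over generations
        1..horizon (whole run if ``horizon`` is None)."""
        totals = []
        for r in self.replicates:
            totals.append(
                sum(
                    st.n_subjected
                    for st in r.stats
                    if st.generation >= 1
                    and (horizon is None or st.generation <= horizon)
                )
            )
        return float(np.mean(totals))

    def mean_cumulative_benefit(self, gene_action: str, horizon: int) -> float:
        return float(
            np.mean([cumulative_benefit(r.stats, gene_action, horizon) for r in self.replicates])
        )

    def mean_response_fraction(self, generation: int) -> float:
        """Response in ``generation`` as a fraction of this run's own
        generation-0 equilibrium response."""
        return self.mean_at("response", generation) / self.equilibrium_response

    def min_response_fraction(self) -> float:
        """Minimum over generations 1..T of the replicate-mean response,
        as a fraction of the generation-0 equilibrium response."""
        mask = self.per_generation["generation"] >= 1
        return float(
            self.per_generation.loc[mask, "mean_response"].min() / self.equilibrium_response
        )


def run_experiment(
    spec: ScenarioSpec,
    n_reps: Optional[int] = None,
    base_seed: Optional[int] = None,
) -> AggregateReport:
    """Run ``n_reps`` replicates with seeds base_seed, base_seed+1, ..."""
    n_reps = spec.n_replicates if n_reps is None else n_reps
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base_seed = spec.base_seed if base_seed is None else base_seed
    replicates = []
    for i in range(n_reps):
        rep = run_replicate(spec, base_seed + i)
        rep.replicate = i
        replicates.append(rep)
    return AggregateReport(spec=spec, base_seed=base_seed, replicates=replicates)


def time_to_fixation(frequencies: Sequence[float]) -> Optional[int]:
    """First generation (index in a 0-based trajectory) at frequency 1.0."""
    for t, f in enumerate(frequencies):
        if f >= 1.0:
            return t
    return None


def loss_in_months(
    mean_tbv_scenario_at_t: float,
    mean_tbv_baseline_at_t: float,
    equilibrium_response: float,
    interval_months: float = 24.0,
) -> float:
    """Polygenic-response difference converted to months of breeding progress.

    (scenario - baseline) mean TBV divided by the baseline's generation-0
    equilibrium response times the generation interval; negative = loss.
    """
    if equilibrium_response <= 0:
        raise ValueError("equilibrium_response must be positive")
    delta = mean_tbv_scenario_at_t - mean_tbv_baseline_at_t
    return delta / equilibrium_response * interval_months


def loss_in_sd(delta_tbv: float, sd_divisor: float) -> float:
    """Response difference in units of the equilibrium genetic dispersion."""
    if sd_divisor <= 0:
        raise ValueError("sd_divisor must be positive")
    return delta_tbv / sd_divisor


def cumulative_benefit(
    stats: Iterable[GenerationStats], gene_action: str, horizon: int
) -> float:
    """Percentage of animals born in generations 1..horizon with the
    desired phenotype (G >= 1 if dominant, G = 2 if recessive)."""
    if gene_action not in ("dominant", "recessive"):
        raise ValueError("gene_action must be 'dominant' or 'recessive'")
    born = desired = 0
    for st in stats:
        if 1 <= st.generation <= horizon:
            born += st.size
            desired += st.n_dominant if gene_action == "dominant" else st.n_recessive
    if born == 0:
        raise ValueError("no generations within the requested horizon")
    return 100.0 * desired / born


def breakeven_cost(
    extra_desired_pct: float,
    population_per_generation: float,
    horizon: int,
    dehorn_cost: float,
    total_procedures: float,
) -> float:
    """Editing cost per zygote at which savings equal the editing bill.

    Savings are the extra desired-phenotype animals (percentage-point gain
    over the baseline times the animals born over the horizon) times the
    per-animal cost avoided (e.g. dehorning); dividing by the number of
    editing procedures gives the breakeven price per subjected zygote.
    """
    if total_procedures <= 0:
        raise ValueError("total_procedures must be positive")
    saved = (extra_desired_pct / 100.0) * population_per_generation * horizon * dehorn_cost
    return saved / total_procedures


def summarize_scenario(
    report: AggregateReport,
    baseline: Optional[AggregateReport] = None,
    horizons: tuple[int, ...] = (5, 20),
) -> dict:
    """One summary row per scenario (fixation, losses, inbreeding, costs).

    Loss metrics compare against ``baseline`` (the b2 = 0 genomic-selection
    scenario); they are omitted when no baseline is given.  Losses in
    dispersion units divide the TBV difference by the baseline's
    generation-0 equilibrium genetic variance (the estimated equilibrium
    quantity used directly, mirroring the reported tables); the audit
    column ``sd_loss_sqrt_*`` divides by its square root instead.
    """
    spec = report.spec
    horizons = tuple(h for h in horizons if h <= spec.n_selection_generations)
    if not horizons:
        horizons = (spec.n_selection_generations,)
    h0 = horizons[0]
    row: dict = {
        "scenario": spec.name,
        "n_replicates": report.n_replicates,
        "b2": spec.b2,
        "use_editing": spec.use_editing,
        "edit_success_k": spec.edit_success_k,
        "edit_survival_s": spec.edit_survival_s,
        "equilibrium_response": report.equilibrium_response,
        "equilibrium_variance": report.equilibrium_variance,
        "fixation_generation": report.mean_fixation_generation(),
        "allele_lost_fraction": report.allele_lost_fraction,
        "total_procedures": report.mean_cumulative_procedures(),
    }
    for h in horizons:
        row[f"allele_freq_gen{h}"] = report.mean_at("allele_freq", h)
        row[f"mean_f_gen{h}"] = report.mean_at("mean_f", h)
        row[f"procedures_gen{h}"] = report.mean_cumulative_procedures(h)
        row[f"benefit_dominant_gen{h}"] = report.mean_cumulative_benefit("dominant", h)
        row[f"benefit_recessive_gen{h}"] = report.mean_cumulative_benefit("recessive", h)
    if baseline is not None:
        r_eq = baseline.equilibrium_response
        var_eq = baseline.equilibrium_variance
        for h in horizons:
            delta = report.mean_at("mean_tbv", h) - baseline.mean_at("mean_tbv", h)
            row[f"months_loss_gen{h}"] = loss_in_months(
                report.mean_at("mean_tbv", h),
                baseline.mean_at("mean_tbv", h),
                r_eq,
                spec.generation_interval_months,
            )
            row[f"sd_loss_gen{h}"] = loss_in_sd(delta, var_eq)
            row[f"sd_loss_sqrt_gen{h}"] = loss_in_sd(delta, math.sqrt(var_eq))
            row[f"extra_f_gen{h}"] = report.mean_at("mean_f", h) - baseline.mean_at(
                "mean_f", h
            )
        if spec.use_editing and row[f"procedures_gen{h0}"] > 0:
            extra_pct = (
                row[f"benefit_dominant_gen{h0}"]
                - baseline.mean_cumulative_benefit("dominant", h0)
            )
            row[f"breakeven_cost_gen{h0}"] = breakeven_cost(
                extra_pct,
                spec.n_candidates,
                h0,
                spec.dehorn_cost,
                row[f"procedures_gen{h0}"],
            )
    return row


def write_report(
    report: AggregateReport,
    out_dir: str | Path,
    baseline: Optional[AggregateReport] = None,
) -> dict[str, Path]:
    """Write per-generation, per-replicate and summary CSVs plus the spec.

    Outputs (overwritten deterministically on re-runs):
      - generations.csv: replicate means and standard errors per generation
      - replicates.csv: full per-replicate trajectories, long format
      - summary.csv: one row with the scenario evaluation metrics
      - scenario.yaml: the exact parameterization used
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "generations": out_dir / "generations.csv",
        "replicates": out_dir / "replicates.csv",
        "summary": out_dir / "summary.csv",
        "scenario": out_dir / "scenario.yaml",
    }
    report.per_generation.to_csv(paths["generations"], index=False)
    pd.concat([r.to_frame() for r in report.replicates], ignore_index=True).to_csv(
        paths["replicates"], index=False
    )
    pd.DataFrame([summarize_scenario(report, baseline)]).to_csv(
        paths["summary"], index=False
    )
    write_spec(report.spec, paths["scenario"])
    return paths


def export_replicate_pedigree(result: ReplicateResult, path: str | Path) -> Path:
    """Write the replicate's pedigree (requires keep_pedigree=True)."""
    if result.pedigree is None:
        raise ValueError("replicate was run without keep_pedigree=True")
    return write_pedigree(result.pedigree, path)
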