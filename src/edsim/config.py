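"""Scenario configuration: validation, file I/O and the builtin scenario grid.

A :class:`ScenarioSpec` fully parameterizes one breeding scenario: the
population design (number of sires, dams, offspring per mating), the
pseudo-EBV reliability, the selection-index weight on the monogenic
genotype, and the genome-editing parameters (fraction of matings edited,
per-allele editing success ``k``, per-zygote survival ``s``).

Config files are flat YAML key-value mappings; any key mirrors a
``ScenarioSpec`` field and unknown keys are rejected.  CLI flags override
file values (the CLI wins).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ScenarioSpec",
    "SpecValidationError",
    "load_spec",
    "write_spec",
    "builtin_scenarios",
]


class SpecValidationError(ValueError):
    """A scenario parameter is missing, unknown, or out of range."""


@dataclass(frozen=True)
class ScenarioSpec:
    """Full parameterization of one simulated breeding scenario.

    Defaults correspond to the main design: 100 sires and 2000 dams
    selected per generation from 2000 matings x 10 offspring = 20,000
    candidates, pseudo-EBV reliability r^2 = 0.5, desired-allele starting
    frequency 0.01, five burn-in generations followed by 20 generations of
    index selection.
    """

    name: str = "custom"
    n_sires: int = 100
    n_dams: int = 2000
    n_off_per_mating: int = 10
    reliability_r2: float = 0.5
    b1: float = 1.0
    b2: float = 0.0
    use_editing: bool = False
    edit_fraction: float = 0.10
    edit_success_k: float = 1.0
    edit_survival_s: float = 1.0
    #: if True (default), every zygote of a flagged mating undergoes the
    #: procedure (and its survival risk) even when it already carries two
    #: desired alleles; if False, only carrier zygotes are subjected and
    #: counted.
    subject_noncarriers: bool = True
    #: if True, sires are assigned to dams in (nearly) equal numbers instead
    #: of uniformly at random with replacement.
    balanced_matings: bool = False
    founder_allele_freq: float = 0.01
    n_burnin_generations: int = 5
    n_selection_generations: int = 20
    n_replicates: int = 50
    base_seed: int = 1
    generation_interval_months: float = 24.0
    dehorn_cost: float = 10.0

    def __post_init__(self) -> None:
        counts = {
            "n_sires": self.n_sires,
            "n_dams": self.n_dams,
            "n_off_per_mating": self.n_off_per_mating,
            "n_burnin_generations": self.n_burnin_generations,
            "n_selection_generations": self.n_selection_generations,
            "n_replicates": self.n_replicates,
        }
        for key, value in counts.items():
            if not isinstance(value, int) or value < 1:
                raise SpecValidationError(f"{key} must be an integer >= 1, got {value!r}")
        probs = {
            "edit_fraction": self.edit_fraction,
            "edit_success_k": self.edit_success_k,
            "edit_survival_s": self.edit_survival_s,
            "founder_allele_freq": self.founder_allele_freq,
        }
        for key, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise SpecValidationError(f"{key} must lie in [0, 1], got {value!r}")
        if not 0.0 < self.reliability_r2 <= 1.0:
            raise SpecValidationError(
                f"reliability_r2 must lie in (0, 1], got {self.reliability_r2!r}"
            )
        if self.b2 < 0:
            raise SpecValidationError(f"b2 must be nonnegative, got {self.b2!r}")
        if self.generation_interval_months <= 0:
            raise SpecValidationError("generation_interval_months must be positive")
        if self.dehorn_cost < 0:
            raise SpecValidationError("dehorn_cost must be nonnegative")
        if self.n_sires + self.n_dams > self.n_dams * self.n_off_per_mating:
            raise SpecValidationError(
                "infeasible design: n_sires + n_dams exceeds the expected "
                f"candidate cohort of {self.n_dams * self.n_off_per_mating}"
            )

    @property
    def n_candidates(self) -> int:
        """Nominal cohort size per generation (before editing mortality)."""
        return self.n_dams * self.n_off_per_mating

    @property
    def n_edited_matings(self) -> int:
        """Matings flagged per generation; round(edit_fraction * n_dams),
        half-up for determinism."""
        return int(self.edit_fraction * self.n_dams + 0.5)

    def replace(self, **changes: Any) -> "ScenarioSpec":
        """Return a validated copy with ``changes`` applied."""
        params = asdict(self)
        params.update(changes)
        return ScenarioSpec(**params)


_FIELD_TYPES = {f.name: f.type for f in fields(ScenarioSpec)}
_BOOL_FIELDS = {"use_editing", "subject_noncarriers", "balanced_matings"}
_INT_FIELDS = {
    "n_sires",
    "n_dams",
    "n_off_per_mating",
    "n_burnin_generations",
    "n_selection_generations",
    "n_replicates",
    "base_seed",
}


def _coerce(key: str, value: Any) -> Any:
    if key == "name":
        return str(value)
    if key in _BOOL_FIELDS:
        if isinstance(value, bool):
            return value
        if isinstance(value, str):
            low = value.strip().lower()
            if low in {"true", "yes", "1"}:
                return True
            if low in {"false", "no", "0"}:
                return False
        raise SpecValidationError(f"{key} must be a boolean, got {value!r}")
    if key in _INT_FIELDS:
        if isinstance(value, bool) or not isinstance(value, (int, float, str)):
            raise SpecValidationError(f"{key} must be an integer, got {value!r}")
        as_float = float(value)
        if as_float != int(as_float):
            raise SpecValidationError(f"{key} must be an integer, got {value!r}")
        return int(as_float)
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SpecValidationError(f"{key} must be numeric, got {value!r}") from None


def load_spec(
    source: str | Path | Mapping[str, Any] | None,
    overrides: Mapping[str, Any] | None = None,
) -> ScenarioSpec:
    """Build a validated :class:`ScenarioSpec` from a YAML file or mapping.

    Parameters
    ----------
    source
        Path to a flat YAML file, an in-memory mapping of field values, or
        ``None`` for pure defaults.
    overrides
        Optional mapping applied on top of ``source`` (CLI flags win over
        file values).

    Unknown keys raise :class:`SpecValidationError` naming the key;
    out-of-range values raise with the offending bounds.
    """
    raw: dict[str, Any] = {}
    if source is not None:
        if isinstance(source, Mapping):
            raw.update(source)
        else:
            path = Path(source)
            try:
                loaded = yaml.safe_load(path.read_text())
            except yaml.YAMLError as exc:
                raise SpecValidationError(f"cannot parse {path}: {exc}") from exc
            if loaded is None:
                loaded = {}
            if not isinstance(loaded, dict):
                raise SpecValidationError(
                    f"{path} must contain a flat key-value mapping"
                )
            raw.update(loaded)
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})

    unknown = sorted(set(raw) - set(_FIELD_TYPES))
    if unknown:
        raise SpecValidationError(f"unknown configuration key(s): {', '.join(unknown)}")
    coerced = {key: _coerce(key, value) for key, value in raw.items()}
    return ScenarioSpec(**coerced)


def write_spec(spec: ScenarioSpec, path: str | Path) -> Path:
    """Write ``spec`` as flat YAML; ``load_spec`` round-trips it exactly."""
    path = Path(path)
    path.write_text(yaml.safe_dump(asdict(spec), sort_keys=True))
    return path


def builtin_scenarios() -> dict[str, ScenarioSpec]:
    """Named scenario grid covering the evaluated designs.

    Includes the main genomic-selection (GS) and GS-plus-genome-editing
    (GS+GE) scenarios for index weights b2 in {0, 0.5, 1000}; sweeps of the
    editing success probability k and survival probability s at b2 = 0.5;
    the low-efficiency combination k = s = 0.2; and species-sized designs
    (dairy cattle, pig, fish, and a small nucleus program).
    """
    base = ScenarioSpec()
    scen: dict[str, ScenarioSpec] = {}

    for b2, tag in [(0.0, "b0"), (0.5, "b05"), (1000.0, "b1000")]:
        scen[f"main_gs_{tag}"] = base.replace(name=f"main_gs_{tag}", b2=b2)
        scen[f"main_gs_ge_{tag}"] = base.replace(
            name=f"main_gs_ge_{tag}", b2=b2, use_editing=True
        )

    for k in (1.0, 0.8, 0.6, 0.4, 0.2, 0.1):
        name = f"ge_b05_k{int(round(k * 100)):03d}"
        scen[name] = base.replace(name=name, b2=0.5, use_editing=True, edit_success_k=k)
    for s in (1.0, 0.8, 0.6, 0.4, 0.2, 0.05):
        name = f"ge_b05_s{int(round(s * 100)):03d}"
        scen[name] = base.replace(name=name, b2=0.5, use_editing=True, edit_survival_s=s)

    scen["low_efficiency"] = base.replace(
        name="low_efficiency",
        b2=0.5,
        use_editing=True,
        edit_success_k=0.2,
        edit_survival_s=0.2,
    )

    designs = {
        "cattle": (200, 600, 16),
        "pig": (50, 2000, 20),
        "fish": (120, 240, 40),
        "small": (20, 240, 70),
    }
    for name, (n_sires, n_dams, n_off) in designs.items():
        scen[name] = base.replace(
            name=name, n_sires=n_sires, n_dams=n_dams, n_off_per_mating=n_off
        )
    return scen
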