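"""Scenario configuration: parsing, validation, defaulting, reporting.

A scenario file (YAML or JSON) has sections ``design``, ``params``,
``analysis`` (optional, defaulted from the design and outcome family)
and ``run`` (optional).  Unknown keys are rejected, every offending
key is reported at once, and a serialized scenario re-loads to an
identical object, so a run report can always be replayed.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .design import DesignSpec
from .dgm import BinaryParams, ContinuousParams, FactorialParams
from .inference import AnalysisSpec
from .power import PowerEstimate, Scenario

__all__ = [
    "ConfigError",
    "load_scenario",
    "scenario_from_dict",
    "scenario_to_dict",
    "default_analysis",
    "RunReport",
]

_PARAM_FAMILIES = {
    "continuous": ContinuousParams,
    "binary": BinaryParams,
    "factorial": FactorialParams,
}

_RUN_KEYS = {"n_reps", "alpha", "seed", "fix_assignment"}


class ConfigError(ValueError):
    """One or more schema violations in a scenario configuration."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid scenario configuration:\n  - " + "\n  - ".join(problems))


def _check_keys(section: str, given: dict, allowed: set[str], problems: list[str]) -> None:
    for key in given:
        if key not in allowed:
            problems.append(
                f"{section}: unknown key {key!r} (allowed: {sorted(allowed)})"
            )


def default_analysis(
    design: DesignSpec, params, sidedness: str = "two"
) -> AnalysisSpec:
    """The analysis model implied by a design and outcome family.

    Simple one-treatment designs regress the outcome on the treatment
    indicator.  The factorial design regresses on a follow-up
    indicator, both treatments and their interaction, over both
    timepoints, clustered at the top level — robust to a secular trend
    and using the baseline data.
    """
    if isinstance(params, FactorialParams):
        a = design.cluster_level_treatments[0]
        x = design.unit_level_treatments[0]
        return AnalysisSpec(
            family="linear",
            terms=("time", a, x, f"{a}:{x}"),
            test_terms=(a, x, f"{a}:{x}"),
            sidedness=sidedness,
        )
    family = "logistic" if isinstance(params, BinaryParams) else "linear"
    term = (design.cluster_level_treatments + design.unit_level_treatments)[0]
    return AnalysisSpec(
        family=family, terms=(term,), test_terms=(term,), sidedness=sidedness
    )


def scenario_from_dict(raw: dict) -> Scenario:
    """Build a validated Scenario from a configuration mapping."""
    problems: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping"])
    _check_keys("top level", raw, {"design", "params", "analysis", "run"}, problems)
    for required in ("design", "params"):
        if required not in raw:
            problems.append(f"missing required section {required!r}")
    if problems:
        raise ConfigError(problems)

    design_fields = {f.name for f in dataclasses.fields(DesignSpec)}
    _check_keys("design", raw["design"], design_fields, problems)

    pdict = dict(raw["params"])
    family = pdict.pop("family", None)
    if family not in _PARAM_FAMILIES:
        problems.append(
            f"params: family must be one of {sorted(_PARAM_FAMILIES)}, got {family!r}"
        )
        raise ConfigError(problems)
    cls = _PARAM_FAMILIES[family]
    param_fields = {f.name for f in dataclasses.fields(cls)}
    _check_keys("params", pdict, param_fields, problems)
    for f in dataclasses.fields(cls):
        if (
            f.default is dataclasses.MISSING
            and f.default_factory is dataclasses.MISSING
            and f.name not in pdict
        ):
            problems.append(f"params: missing required key {f.name!r}")

    run = dict(raw.get("run", {}))
    _check_keys("run", run, _RUN_KEYS, problems)
    if problems:
        raise ConfigError(problems)

    try:
        design = DesignSpec(
            **{k: tuple(v) if isinstance(v, list) else v for k, v in raw["design"].items()}
        )
        params = cls(**pdict)
    except (TypeError, ValueError) as exc:
        raise ConfigError([str(exc)]) from exc

    if "analysis" in raw:
        adict = dict(raw["analysis"])
        analysis_fields = {f.name for f in dataclasses.fields(AnalysisSpec)}
        _check_keys("analysis", adict, analysis_fields, problems)
        if problems:
            raise ConfigError(problems)
        for key in ("terms", "test_terms"):
            if key in adict and isinstance(adict[key], list):
                adict[key] = tuple(adict[key])
        try:
            analysis = AnalysisSpec(**adict)
        except (TypeError, ValueError) as exc:
            raise ConfigError([str(exc)]) from exc
    else:
        analysis = default_analysis(design, params)

    try:
        return Scenario(design=design, params=params, analysis=analysis, **run)
    except (TypeError, ValueError) as exc:
        raise ConfigError([str(exc)]) from exc


def scenario_to_dict(scenario: Scenario) -> dict:
    """Serialize a Scenario with every default materialized."""
    family = {
        ContinuousParams: "continuous",
        BinaryParams: "binary",
        FactorialParams: "factorial",
    }[type(scenario.params)]
    as_plain = lambda d: {
        k: list(v) if isinstance(v, tuple) else v for k, v in d.items()
    }
    return {
        "design": as_plain(dataclasses.asdict(scenario.design)),
        "params": {"family": family, **dataclasses.asdict(scenario.params)},
        "analysis": as_plain(dataclasses.asdict(scenario.analysis)),
        "run": {
            "n_reps": scenario.n_reps,
            "alpha": scenario.alpha,
            "seed": scenario.seed,
            "fix_assignment": scenario.fix_assignment,
        },
    }


def load_scenario(path: str | Path) -> Scenario:
    """Load and validate a scenario from a YAML or JSON file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    text = path.read_text()
    raw = yaml.safe_load(text)  # JSON is a YAML subset
    return scenario_from_dict(raw)


@dataclass
class RunReport:
    """Self-contained record of one power run.

    The echoed scenario (all defaults and the seed materialized) is
    sufficient to reproduce the run exactly.
    """

    scenario: dict
    power: dict[str, float]
    mc_se: dict[str, float]
    n_reps_used: int
    n_failed: int
    version: str
    timestamp: str
    wall_seconds: float

    @classmethod
    def from_estimate(
        cls, scenario: Scenario, estimate: PowerEstimate, wall_seconds: float
    ) -> "RunReport":
        return cls(
            scenario=scenario_to_dict(scenario),
            power=estimate.power,
            mc_se=estimate.mc_se,
            n_reps_used=estimate.n_reps_used,
            n_failed=estimate.n_failed,
            version=__version__,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S%z"),
            wall_seconds=wall_seconds,
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text
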