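"""Readers and writers for the tool's plain-text artifact formats.

Parameter specs travel as CSV (``name,reference,class,lower,upper`` with an
optional ``estimated`` column on fit output), constraints as YAML or CSV
(semicolon-separated lists in the CSV dialect), conditions and GA
configuration as YAML, evaluations and comparisons as JSON, trajectories
as tidy CSV.  Every run directory receives a JSON manifest hashing the
inputs so that identical manifests imply identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .ga import GAConfig, GARun
from .plausibility import (
    ConfigurationError,
    EvaluationResult,
    ParameterSpec,
    ParamClass,
    TrainingConstraint,
)
from .synthetic import SyntheticScenario, _condition_from_dict, _condition_to_dict
from .transport import Condition, Trajectory

__all__ = [
    "read_parameter_specs",
    "write_parameter_specs",
    "read_constraints",
    "write_constraints",
    "read_condition",
    "write_condition",
    "read_scenario",
    "write_scenario",
    "read_ga_config",
    "write_evaluation",
    "read_evaluation",
    "write_history",
    "write_trajectory",
    "write_manifest",
]


def _empty(x) -> bool:
    return x is None or (isinstance(x, float) and pd.isna(x)) or x == ""


def read_parameter_specs(path: str | Path) -> list[ParameterSpec]:
    df = pd.read_csv(path)
    required = {"name", "reference", "class"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"{path}: parameter CSV must have columns {sorted(required)}"
        )
    specs = []
    for row in df.to_dict("records"):
        specs.append(
            ParameterSpec(
                name=str(row["name"]),
                reference_value=float(row["reference"]),
                param_class=ParamClass(str(row["class"])),
                lower_bound=None if _empty(row.get("lower")) else float(row["lower"]),
                upper_bound=None if _empty(row.get("upper")) else float(row["upper"]),
            )
        )
    return specs


def write_parameter_specs(
    specs: Sequence[ParameterSpec],
    path: str | Path,
    estimated: Mapping[str, float] | None = None,
) -> None:
    rows = []
    for s in specs:
        row = {
            "name": s.name,
            "reference": s.reference_value,
            "class": s.param_class.value,
            "lower": s.lower_bound,
            "upper": s.upper_bound,
        }
        if estimated is not None:
            row["estimated"] = estimated.get(s.name, s.reference_value)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_estimated_values(path: str | Path) -> dict[str, float]:
    """Parameter values from a spec CSV: 'estimated' if present, else reference."""
    df = pd.read_csv(path)
    col = "estimated" if "estimated" in df.columns else "reference"
    return {str(r["name"]): float(r[col]) for r in df.to_dict("records")}


def _constraint_to_dict(c: TrainingConstraint) -> dict:
    return {
        "constraint_id": c.constraint_id,
        "condition_id": c.condition_id,
        "variable": c.variable_name,
        "kind": c.kind,
        "times": list(c.times),
        "values": list(c.observed_values),
        "epsilon": c.allowable_error,
    }


def _constraint_from_dict(raw: Mapping) -> TrainingConstraint:
    return TrainingConstraint(
        constraint_id=str(raw["constraint_id"]),
        condition_id=str(raw["condition_id"]),
        variable_name=str(raw["variable"]),
        kind=str(raw["kind"]),
        times=tuple(raw.get("times") or ()),
        observed_values=tuple(raw["values"]),
        allowable_error=float(raw["epsilon"]),
    )


def read_constraints(path: str | Path) -> list[TrainingConstraint]:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        out = []
        for row in df.to_dict("records"):
            times = () if _empty(row.get("times")) else tuple(
                float(t) for t in str(row["times"]).split(";")
            )
            values = tuple(float(v) for v in str(row["values"]).split(";"))
            out.append(
                TrainingConstraint(
                    constraint_id=str(row["constraint_id"]),
                    condition_id=str(row["condition_id"]),
                    variable_name=str(row["variable"]),
                    kind=str(row["kind"]),
                    times=times,
                    observed_values=values,
                    allowable_error=float(row["epsilon"]),
                )
            )
        return out
    raw = yaml.safe_load(path.read_text())
    return [_constraint_from_dict(r) for r in raw]


def write_constraints(
    constraints: Sequence[TrainingConstraint], path: str | Path
) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        rows = [
            {
                "constraint_id": c.constraint_id,
                "condition_id": c.condition_id,
                "variable": c.variable_name,
                "kind": c.kind,
                "times": ";".join(repr(t) for t in c.times),
                "values": ";".join(repr(v) for v in c.observed_values),
                "epsilon": c.allowable_error,
            }
            for c in constraints
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        path.write_text(
            yaml.safe_dump([_constraint_to_dict(c) for c in constraints], sort_keys=False)
        )


def read_condition(path: str | Path) -> Condition:
    return _condition_from_dict(yaml.safe_load(Path(path).read_text()))


def write_condition(condition: Condition, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_condition_to_dict(condition), sort_keys=False))


def read_scenario(path: str | Path) -> SyntheticScenario:
    return SyntheticScenario.from_dict(yaml.safe_load(Path(path).read_text()))


def write_scenario(scenario: SyntheticScenario, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario.to_dict(), sort_keys=False))


def read_ga_config(path: str | Path, **overrides) -> GAConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return GAConfig(**raw)


def write_evaluation(result: EvaluationResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2, sort_keys=True))


def read_evaluation(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_history(run: GARun, path: str | Path) -> None:
    run.history.to_csv(path, index=False)


def write_trajectory(traj: Trajectory, outdir: str | Path) -> tuple[Path, Path]:
    """Tidy state CSV (time, variable, value) plus a wide flux CSV."""
    outdir = Path(outdir)
    states = traj.data.melt(
        id_vars="time",
        value_vars=["nhx_int", "gln", "glu", "nh4_int", "nh3_int"],
        var_name="variable",
        value_name="value",
    )
    state_path = outdir / "trajectory.csv"
    states.to_csv(state_path, index=False)
    flux_path = outdir / "fluxes.csv"
    traj.data[["time", "v_amtb", "v_diff", "v_net", "v_gs", "growth_rate"]].to_csv(
        flux_path, index=False
    )
    return state_path, flux_path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    outdir: str | Path,
    command: str,
    inputs: Sequence[str | Path],
    seed: int | None,
    outputs: Sequence[str | Path],
) -> Path:
    """Write run metadata; the config hash digests all input bytes + seed."""
    outdir = Path(outdir)
    input_hashes = {str(p): _sha256(Path(p)) for p in inputs}
    digest = hashlib.sha256()
    for name in sorted(input_hashes):
        digest.update(name.encode())
        digest.update(input_hashes[name].encode())
    digest.update(str(seed).encode())
    manifest = {
        "command": command,
        "config_hash": digest.hexdigest(),
        "seed": seed,
        "tool_version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "inputs": input_hashes,
        "outputs": [str(p) for p in outputs],
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
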