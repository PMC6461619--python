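"""Synthetic ground truth, reference values and noisy training data.

The generator makes the whole estimation/ranking pipeline testable without
any experimental download.  A scenario fixes a ground-truth parameter set
of the reduced ammonium network, an uncertainty-class assignment, how far
the published-style *reference* values sit from the truth (log-normal
dispersion per class, smallest for class I "informed guesses", largest for
class III "rough guesses"), a multiplicative relative noise level for the
observations, the experiment conditions, and an observation plan.

Realizing a scenario yields exactly the artifacts the fitting machinery
consumes: a parameter-spec list (references drawn around the truth) and a
training-constraint list (noisy samples of the simulated truth).  The
default scenario ships three conditions echoing the structure of typical
nitrogen-physiology designs: an N-upshift time course, a low-ammonium
steady state, and a GlnK-knockout steady state.
"""

from __future__ import annotations

import copy
import importlib.resources
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

from .plausibility import (
    ConfigurationError,
    DEFAULT_EPSILONS,
    ParameterSpec,
    ParamClass,
    PenaltyWeights,
    TrainingConstraint,
)
from .problem import KineticFitProblem
from .transport import Condition, ToyNetworkParams, TransportPhysics, observables, simulate, steady_state

__all__ = [
    "ObservationPlanItem",
    "SyntheticScenario",
    "Realization",
    "draw_references",
    "generate_observations",
    "realize_scenario",
    "default_scenario",
    "make_two_model_scenario",
]

#: smallest relative value a noisy observation may take, as a fraction of truth
NOISE_FLOOR = 1e-9
_MAX_RESAMPLE = 100


@dataclass(frozen=True)
class ObservationPlanItem:
    """One planned measurement: where, what, when and how accurately."""

    condition_id: str
    variable: str
    kind: str
    times: tuple[float, ...] = ()
    epsilon: float | None = None
    quality: str = "medium"

    def allowable_error(self) -> float:
        if self.epsilon is not None:
            return float(self.epsilon)
        try:
            return DEFAULT_EPSILONS[self.quality]
        except KeyError:
            raise ConfigurationError(
                f"unknown data-quality label {self.quality!r}"
            ) from None


@dataclass(frozen=True)
class SyntheticScenario:
    true_params: ToyNetworkParams
    class_assignment: dict[str, ParamClass]
    reference_dispersion: dict[ParamClass, float]
    noise_cv: float
    conditions: tuple[Condition, ...]
    observation_plan: tuple[ObservationPlanItem, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError(
                "scenarios must be seeded; unseeded generation is refused"
            )
        assignment = {k: ParamClass(v) for k, v in self.class_assignment.items()}
        object.__setattr__(self, "class_assignment", assignment)
        missing = set(ToyNetworkParams.field_names()) - set(assignment)
        if missing:
            raise ConfigurationError(f"parameters without a class: {sorted(missing)}")
        disp = {ParamClass(k): float(v) for k, v in self.reference_dispersion.items()}
        disp.setdefault(ParamClass.US, 0.0)
        object.__setattr__(self, "reference_dispersion", disp)
        sI = disp.get(ParamClass.I, 0.0)
        sII = disp.get(ParamClass.II, sI)
        sIII = disp.get(ParamClass.III, sII)
        if not (0 <= sI <= sII <= sIII):
            raise ConfigurationError(
                "reference dispersion must grow from class I to class III"
            )
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be non-negative")
        ids = [c.condition_id for c in self.conditions]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate condition ids")
        for item in self.observation_plan:
            if item.condition_id not in ids:
                raise ConfigurationError(
                    f"observation plan references unknown condition "
                    f"{item.condition_id!r}"
                )

    def condition(self, condition_id: str) -> Condition:
        for c in self.conditions:
            if c.condition_id == condition_id:
                return c
        raise KeyError(condition_id)

    # --- YAML round trip ---------------------------------------------------

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SyntheticScenario":
        conditions = tuple(_condition_from_dict(c) for c in raw["conditions"])
        plan = tuple(
            ObservationPlanItem(
                condition_id=p["condition_id"],
                variable=p["variable"],
                kind=p["kind"],
                times=tuple(p.get("times", ())),
                epsilon=p.get("epsilon"),
                quality=p.get("quality", "medium"),
            )
            for p in raw["observation_plan"]
        )
        return cls(
            true_params=ToyNetworkParams(**raw["true_params"]),
            class_assignment=dict(raw["class_assignment"]),
            reference_dispersion=dict(raw["reference_dispersion"]),
            noise_cv=float(raw["noise_cv"]),
            conditions=conditions,
            observation_plan=plan,
            seed=raw.get("seed"),
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "noise_cv": self.noise_cv,
            "true_params": self.true_params.as_dict(),
            "class_assignment": {k: v.value for k, v in self.class_assignment.items()},
            "reference_dispersion": {
                k.value: v for k, v in self.reference_dispersion.items()
            },
            "conditions": [_condition_to_dict(c) for c in self.conditions],
            "observation_plan": [
                {
                    "condition_id": p.condition_id,
                    "variable": p.variable,
                    "kind": p.kind,
                    **({"times": list(p.times)} if p.times else {}),
                    **({"epsilon": p.epsilon} if p.epsilon is not None else
                       {"quality": p.quality}),
                }
                for p in self.observation_plan
            ],
        }


def _condition_from_dict(raw: Mapping) -> Condition:
    phys = raw["physics"]
    nhx = raw["nhx_ext"]
    if isinstance(nhx, (list, tuple)):
        nhx = tuple((float(t), float(v)) for t, v in nhx)
    return Condition(
        condition_id=raw["condition_id"],
        physics=TransportPhysics(
            mode=phys["mode"],
            delta_psi=float(phys.get("delta_psi_mV", -150.0)),
            temperature=float(phys.get("temperature_K", 310.0)),
            ph_ext=float(phys.get("ph_ext", 7.0)),
            ph_int=float(phys.get("ph_int", 7.6)),
        ),
        nhx_ext=nhx,
        pka=float(raw.get("pka", 9.25)),
        initial_state=dict(raw.get("initial_state", {})),
        tau0=float(raw.get("tau0", 52.0)),
        glnk_knockout=bool(raw.get("glnk_knockout", False)),
    )


def _condition_to_dict(c: Condition) -> dict:
    return {
        "condition_id": c.condition_id,
        "physics": {
            "mode": c.physics.mode,
            "delta_psi_mV": c.physics.delta_psi,
            "temperature_K": c.physics.temperature,
            "ph_ext": c.physics.ph_ext,
            "ph_int": c.physics.ph_int,
        },
        "nhx_ext": (
            c.nhx_ext if np.isscalar(c.nhx_ext) else [list(s) for s in c.nhx_ext]
        ),
        "pka": c.pka,
        "initial_state": dict(c.initial_state),
        "tau0": c.tau0,
        "glnk_knockout": c.glnk_knockout,
    }


def draw_references(
    scenario: SyntheticScenario, rng: np.random.Generator
) -> list[ParameterSpec]:
    """Reference values drawn log-normally around the truth, per class.

    ``reference = truth * exp(sigma_class * z)`` with standard-normal z;
    US parameters get the truth exactly and are excluded from the search.
    Bounds follow the class defaults of :class:`ParameterSpec`.
    """
    specs = []
    truth = scenario.true_params.as_dict()
    for name in ToyNetworkParams.field_names():
        cls = scenario.class_assignment[name]
        sigma = scenario.reference_dispersion.get(cls, 0.0)
        z = rng.standard_normal()  # drawn for every parameter: stable stream
        ref = truth[name] if cls is ParamClass.US else truth[name] * math.exp(sigma * z)
        specs.append(ParameterSpec(name=name, reference_value=ref, param_class=cls))
    return specs


def generate_observations(
    scenario: SyntheticScenario, rng: np.random.Generator
) -> list[TrainingConstraint]:
    """Simulate the truth and sample the observation plan with noise.

    Noise is multiplicative relative, ``value * (1 + cv * z)``, truncated
    at a positive floor with bounded resampling.
    """
    truth = scenario.true_params
    cv = scenario.noise_cv

    def noisy(value: float) -> float:
        floor = NOISE_FLOOR * value
        for _ in range(_MAX_RESAMPLE):
            sample = value * (1.0 + cv * rng.standard_normal())
            if sample > floor:
                return sample
        raise ConfigurationError(
            "could not draw a positive observation; noise_cv is too large"
        )

    # one simulation per condition serves every plan item bound to it
    by_condition: dict[str, list[ObservationPlanItem]] = {}
    for item in scenario.observation_plan:
        by_condition.setdefault(item.condition_id, []).append(item)

    constraints: list[TrainingConstraint] = []
    for cid, items in by_condition.items():
        cond = scenario.condition(cid)
        tc_times = sorted({t for it in items if it.kind == "timecourse" for t in it.times})
        traj = (
            simulate(truth, cond, t_end=tc_times[-1], times=tc_times)
            if tc_times
            else None
        )
        ss_obs = None
        if any(it.kind != "timecourse" for it in items):
            state, _ = steady_state(truth, cond)
            ss_obs = observables(state, truth, cond)
        for it in items:
            if it.kind == "timecourse":
                assert traj is not None
                values = tuple(noisy(traj.at(t, it.variable)) for t in it.times)
                times = it.times
            else:
                assert ss_obs is not None
                values = (noisy(ss_obs[it.variable]),)
                times = ()
            constraints.append(
                TrainingConstraint(
                    constraint_id=f"{cid}:{it.variable}:{it.kind}",
                    condition_id=cid,
                    variable_name=it.variable,
                    kind=it.kind,
                    times=times,
                    observed_values=values,
                    allowable_error=it.allowable_error(),
                )
            )
    return constraints


@dataclass(frozen=True)
class Realization:
    """A scenario turned into concrete fit inputs."""

    scenario: SyntheticScenario
    specs: tuple[ParameterSpec, ...]
    constraints: tuple[TrainingConstraint, ...]

    @property
    def conditions(self) -> dict[str, Condition]:
        return {c.condition_id: c for c in self.scenario.conditions}

    def problem(self, weights: PenaltyWeights = PenaltyWeights()) -> KineticFitProblem:
        return KineticFitProblem(
            self.specs, self.constraints, self.conditions, weights
        )


def realize_scenario(
    scenario: SyntheticScenario, rng: np.random.Generator | None = None
) -> Realization:
    """Draw references and observations with the scenario's own seed."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    return Realization(
        scenario=scenario,
        specs=tuple(draw_references(scenario, rng)),
        constraints=tuple(generate_observations(scenario, rng)),
    )


def default_scenario() -> SyntheticScenario:
    """The shipped three-condition scenario (packaged YAML)."""
    text = (
        importlib.resources.files("rubberfit")
        .joinpath("data/default_scenario.yaml")
        .read_text()
    )
    return SyntheticScenario.from_dict(yaml.safe_load(text))


def make_two_model_scenario(
    seed: int,
) -> tuple[Realization, Realization]:
    """Two identically constrained fit setups for model ranking.

    One observation set is generated from the active-mode truth and
    packaged for both transporter variants, so ranking asks which variant
    fits the same data with the smaller parameter deviation.  The
    GlnK-knockout condition is omitted here: its internal-ammonium reading
    lies beyond the passive variant's thermodynamic ceiling for every
    parameter choice, and ranking needs both variants feasible.
    """
    base = default_scenario()
    keep = {"upshift", "lowN"}
    conditions = tuple(c for c in base.conditions if c.condition_id in keep)
    plan = tuple(
        p
        for p in base.observation_plan
        if p.condition_id in keep
        and not (p.condition_id == "lowN" and p.variable == "nhx_int")
    )
    active = replace(base, conditions=conditions, observation_plan=plan, seed=seed)
    realized = realize_scenario(active)

    passive_conditions = tuple(
        replace(c, physics=replace(c.physics, mode="passive")) for c in conditions
    )
    passive = replace(active, conditions=passive_conditions)
    return (
        realized,
        Realization(
            scenario=passive,
            specs=realized.specs,
            constraints=copy.deepcopy(realized.constraints),
        ),
    )
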