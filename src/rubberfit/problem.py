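"""Assembly of a kinetic-model fit into a constrained optimization problem.

:class:`KineticFitProblem` binds parameter specs, penalty weights, training
constraints and experiment conditions to the reduced transport network and
exposes the ``(lower, upper, evaluate)`` surface the genetic algorithm
optimizes.  One evaluation decodes a log10 genome into parameter values,
simulates every condition that carries constraints, computes each residual
g_i, the violation γ and the penalized objective f.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .plausibility import (
    ConfigurationError,
    EvaluationResult,
    ParameterSpec,
    PenaltyWeights,
    SearchSpace,
    TrainingConstraint,
    constraint_residual,
    encode_search_vector,
    objective_f,
)
from .transport import Condition, ToyNetworkParams, observables, simulate, steady_state

__all__ = ["KineticFitProblem"]


class KineticFitProblem:
    """Constrained fit of the reduced ammonium network to training data."""

    def __init__(
        self,
        specs: Sequence[ParameterSpec],
        constraints: Sequence[TrainingConstraint],
        conditions: Mapping[str, Condition] | Sequence[Condition],
        weights: PenaltyWeights = PenaltyWeights(),
    ) -> None:
        if not constraints:
            raise ConfigurationError("no training constraints: nothing to fit")
        if not isinstance(conditions, Mapping):
            conditions = {c.condition_id: c for c in conditions}
        self.specs = list(specs)
        self.constraints = list(constraints)
        self.conditions = dict(conditions)
        self.weights = weights
        self.space: SearchSpace = encode_search_vector(self.specs)
        self.lower = self.space.lower
        self.upper = self.space.upper

        known = set(ToyNetworkParams.field_names())
        unknown = [s.name for s in self.specs if s.name not in known]
        if unknown:
            raise ConfigurationError(f"parameters not in the model: {unknown}")
        missing = known - {s.name for s in self.specs}
        if missing:
            raise ConfigurationError(f"model parameters without a spec: {sorted(missing)}")

        # pre-flight: every constraint must resolve to a condition
        self._timecourse: dict[str, list[TrainingConstraint]] = {}
        self._pointwise: dict[str, list[TrainingConstraint]] = {}
        for c in self.constraints:
            if c.condition_id not in self.conditions:
                raise ConfigurationError(
                    f"constraint {c.constraint_id!r} references unknown "
                    f"condition {c.condition_id!r}"
                )
            bucket = self._timecourse if c.kind == "timecourse" else self._pointwise
            bucket.setdefault(c.condition_id, []).append(c)
        self._tc_times = {
            cid: sorted({t for c in cs for t in c.times})
            for cid, cs in self._timecourse.items()
        }

    @property
    def dimension(self) -> int:
        return self.space.dimension

    def params_from_values(self, values: Mapping[str, float]) -> ToyNetworkParams:
        return ToyNetworkParams(**{n: values[n] for n in ToyNetworkParams.field_names()})

    def evaluate_values(self, values: Mapping[str, float]) -> EvaluationResult:
        """Evaluate a full parameter-value map (reference scale, not log)."""
        params = self.params_from_values(values)
        g: dict[str, float] = {}
        for cid, cons in self._timecourse.items():
            cond = self.conditions[cid]
            times = self._tc_times[cid]
            traj = simulate(params, cond, t_end=times[-1], times=times, rtol=1e-7, atol=1e-10)
            lookup = {
                float(t): row
                for t, row in zip(traj.data["time"], traj.data.to_dict("records"))
            }
            for c in cons:
                sim = [lookup[float(t)][c.variable_name] for t in c.times]
                g[c.constraint_id] = constraint_residual(sim, c)
        for cid, cons in self._pointwise.items():
            cond = self.conditions[cid]
            state, _ = steady_state(params, cond)
            obs = observables(state, params, cond)
            for c in cons:
                if c.variable_name not in obs:
                    raise ConfigurationError(
                        f"constraint {c.constraint_id!r}: unknown observable "
                        f"{c.variable_name!r}"
                    )
                g[c.constraint_id] = constraint_residual([obs[c.variable_name]], c)
        f = objective_f(values, self.specs, self.weights)
        return EvaluationResult.from_f_and_g(f, g)

    def evaluate(self, genome: np.ndarray) -> EvaluationResult:
        return self.evaluate_values(self.space.decode(genome))
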