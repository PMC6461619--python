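"""Penalized objective, fit constraints and model plausibility.

The parameter-estimation problem treated here is a constrained optimization:
minimize the class-weighted squared log-deviation of kinetic parameters from
their reference values (the objective ``f``), subject to the model fitting
every training observation within its allowable error (the constraint vector
``g <= 0``), and subject to box bounds on the parameters.

Parameters are grouped by how well their reference values are known:

* class I   -- directly measured ("informed guesses"), strongest penalty;
* class II  -- educated guesses, weaker penalty;
* class III -- rough guesses, no penalty (free to move);
* class US  -- unsearched constants, fixed at their reference value.

The deviation penalty acts like a rubber band anchored at the reference
value: stiff for class I, soft for class II, absent for class III.  Model
plausibility is ``MP = exp(-f)``, so minimizing ``f`` maximizes plausibility,
and two models fitted to the same data can be ranked by their MP ratio.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "ParamClass",
    "ParameterSpec",
    "PenaltyWeights",
    "TrainingConstraint",
    "EvaluationResult",
    "SearchSpace",
    "ConfigurationError",
    "DomainError",
    "objective_f",
    "model_plausibility",
    "plausibility_ratio",
    "constraint_residual",
    "constraint_violation",
    "encode_search_vector",
    "round_to_sig",
    "DEFAULT_EPSILONS",
]

logger = logging.getLogger(__name__)


class ConfigurationError(Exception):
    """A problem definition is inconsistent (missing values, bad shapes)."""


class DomainError(ValueError):
    """An input is outside the mathematical domain of an operation."""


class ParamClass(str, enum.Enum):
    """Uncertainty class of a model parameter."""

    I = "I"
    II = "II"
    III = "III"
    US = "US"


#: default half-width of the search box, in decades around the reference
DEFAULT_BOUND_DECADES = {
    ParamClass.I: 1.0,
    ParamClass.II: 2.0,
    ParamClass.III: 3.0,
    ParamClass.US: 0.0,
}

#: default allowable errors by data-quality label
DEFAULT_EPSILONS = {"high": 0.1, "medium": 0.2, "rough": 0.5}


@dataclass(frozen=True)
class ParameterSpec:
    """One model parameter: reference value, class and search bounds.

    Bounds left as ``None`` default to the reference value divided and
    multiplied by 10, 100 or 1000 decades for classes I, II and III
    respectively; US parameters get degenerate bounds at the reference.
    """

    name: str
    reference_value: float
    param_class: ParamClass
    lower_bound: float | None = None
    upper_bound: float | None = None

    def __post_init__(self) -> None:
        cls = ParamClass(self.param_class)
        object.__setattr__(self, "param_class", cls)
        if not self.reference_value > 0:
            raise DomainError(
                f"parameter {self.name!r}: reference value must be positive "
                f"(log-deviation penalty), got {self.reference_value}"
            )
        decades = DEFAULT_BOUND_DECADES[cls]
        lo = self.lower_bound
        hi = self.upper_bound
        if lo is None:
            lo = self.reference_value / 10.0**decades
        if hi is None:
            hi = self.reference_value * 10.0**decades
        if not (0 < lo <= self.reference_value <= hi):
            raise ConfigurationError(
                f"parameter {self.name!r}: bounds must satisfy "
                f"0 < lower <= reference <= upper, got "
                f"({lo}, {self.reference_value}, {hi})"
            )
        object.__setattr__(self, "lower_bound", float(lo))
        object.__setattr__(self, "upper_bound", float(hi))

    @property
    def searched(self) -> bool:
        return self.param_class is not ParamClass.US


@dataclass(frozen=True)
class PenaltyWeights:
    """Class-related penalty weights λ for parameter deviations.

    Defaults are the published constants λ_I = 1.0407, λ_II = 0.1930,
    λ_III = 0; the ordering λ_I > λ_II > λ_III >= 0 is enforced.
    """

    lambda_I: float = 1.0407
    lambda_II: float = 0.1930
    lambda_III: float = 0.0

    def __post_init__(self) -> None:
        if not (self.lambda_I > self.lambda_II > self.lambda_III >= 0):
            raise ConfigurationError(
                "penalty weights must satisfy lambda_I > lambda_II > "
                f"lambda_III >= 0, got ({self.lambda_I}, {self.lambda_II}, "
                f"{self.lambda_III})"
            )

    def weight(self, cls: ParamClass) -> float:
        return {
            ParamClass.I: self.lambda_I,
            ParamClass.II: self.lambda_II,
            ParamClass.III: self.lambda_III,
            ParamClass.US: 0.0,
        }[cls]


@dataclass(frozen=True)
class TrainingConstraint:
    """One fit constraint g_i derived from an experimental observation.

    ``kind`` is ``"timecourse"`` (values at the listed times),
    ``"steady_state"`` (a single value of a steady-state observable) or
    ``"scalar"`` (a single value of a named derived quantity such as the
    growth rate).  ``allowable_error`` is the dimensionless relative error
    ε_i within which the fit is considered acceptable.
    """

    constraint_id: str
    condition_id: str
    variable_name: str
    kind: str
    times: tuple[float, ...] = ()
    observed_values: tuple[float, ...] = ()
    allowable_error: float = DEFAULT_EPSILONS["medium"]

    def __post_init__(self) -> None:
        if self.kind not in ("timecourse", "steady_state", "scalar"):
            raise ConfigurationError(
                f"constraint {self.constraint_id!r}: unknown kind {self.kind!r}"
            )
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(
            self, "observed_values", tuple(float(v) for v in self.observed_values)
        )
        if self.kind == "timecourse":
            if len(self.times) != len(self.observed_values) or not self.times:
                raise ConfigurationError(
                    f"constraint {self.constraint_id!r}: a timecourse needs "
                    "matching, non-empty times and values"
                )
            if any(t < 0 for t in self.times):
                raise ConfigurationError(
                    f"constraint {self.constraint_id!r}: negative time point"
                )
        else:
            if len(self.observed_values) != 1:
                raise ConfigurationError(
                    f"constraint {self.constraint_id!r}: {self.kind} takes "
                    "exactly one observed value"
                )
            if self.times:
                raise ConfigurationError(
                    f"constraint {self.constraint_id!r}: {self.kind} takes "
                    "no time points"
                )
        if any(v <= 0 for v in self.observed_values):
            raise DomainError(
                f"constraint {self.constraint_id!r}: observed values must be "
                "positive (the residual divides by the observation)"
            )
        if self.allowable_error < 0:
            raise DomainError(
                f"constraint {self.constraint_id!r}: allowable error must be "
                "non-negative"
            )


@dataclass(frozen=True)
class EvaluationResult:
    """Objective, constraints, violation and plausibility of one candidate."""

    f_value: float
    g_values: dict[str, float]
    gamma: float
    mp: float

    @classmethod
    def from_f_and_g(cls, f_value: float, g_values: Mapping[str, float]) -> "EvaluationResult":
        g = {k: float(v) for k, v in g_values.items()}
        gamma = constraint_violation(np.fromiter(g.values(), dtype=float, count=len(g)))
        return cls(
            f_value=float(f_value),
            g_values=g,
            gamma=gamma,
            mp=model_plausibility(f_value) if np.isfinite(f_value) else 0.0,
        )

    @classmethod
    def failed(cls) -> "EvaluationResult":
        """Sentinel for a candidate whose simulation failed (γ = +inf)."""
        return cls(f_value=math.inf, g_values={}, gamma=math.inf, mp=0.0)

    @property
    def feasible(self) -> bool:
        return self.gamma == 0.0

    def to_dict(self) -> dict:
        return {
            "f": self.f_value,
            "g": dict(self.g_values),
            "gamma": self.gamma,
            "mp": self.mp,
        }


def objective_f(
    values: Mapping[str, float],
    specs: Sequence[ParameterSpec],
    weights: PenaltyWeights = PenaltyWeights(),
) -> float:
    """Class-weighted squared log-deviation of parameters from references.

    ``f = Σ_c λ_c Σ_{p in class c} (ln(p / p*))²`` over classes I-III.
    US parameters contribute nothing and need no entry in ``values``.
    """
    total = 0.0
    for spec in specs:
        if not spec.searched:
            continue
        try:
            value = values[spec.name]
        except KeyError:
            raise ConfigurationError(
                f"no value supplied for searched parameter {spec.name!r}"
            ) from None
        if not value > 0:
            raise DomainError(
                f"parameter {spec.name!r}: value must be positive, got {value}"
            )
        w = weights.weight(spec.param_class)
        if w:
            total += w * math.log(value / spec.reference_value) ** 2
    return total


def model_plausibility(f_value: float) -> float:
    """Model plausibility ``MP = exp(-f)``; strictly decreasing in f."""
    if f_value < 0:
        raise DomainError(f"objective value must be non-negative, got {f_value}")
    return math.exp(-f_value)


def plausibility_ratio(f_a: float, f_b: float) -> float:
    """``MP(f_a) / MP(f_b) = exp(f_b - f_a)`` for two fitted models."""
    return model_plausibility(f_a) / model_plausibility(f_b)


def constraint_residual(
    simulated: Sequence[float], constraint: TrainingConstraint
) -> float:
    """Mean squared relative residual minus ε²; <= 0 means acceptable fit.

    ``g = (1/n) Σ_j ((x_j_sim - x_j_exp) / x_j_exp)² - ε²``
    """
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(constraint.observed_values, dtype=float)
    if sim.shape != obs.shape:
        raise ConfigurationError(
            f"constraint {constraint.constraint_id!r}: {sim.size} simulated "
            f"points for {obs.size} observations"
        )
    rel = (sim - obs) / obs
    return float(np.mean(rel * rel) - constraint.allowable_error**2)


def constraint_violation(g_values: Sequence[float]) -> float:
    """Constraint violation ``γ = Σ_i max(0, g_i)²``; 0 iff all g_i <= 0."""
    g = np.asarray(g_values, dtype=float)
    if g.size == 0:
        logger.warning("constraint_violation called with no constraints")
        return 0.0
    pos = np.maximum(g, 0.0)
    return float(np.dot(pos, pos))


@dataclass(frozen=True)
class SearchSpace:
    """Log10-space search box over the non-US parameters of a spec list.

    Iterating yields ``(names, lower, upper)`` so the object unpacks like
    the plain triple; ``decode`` maps a log10 genome back to a full value
    map including the US parameters pinned at their references.
    """

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    _fixed: dict[str, float] = field(default_factory=dict, repr=False)

    def __iter__(self) -> Iterator:
        return iter((self.names, self.lower, self.upper))

    @property
    def dimension(self) -> int:
        return len(self.names)

    def encode(self, values: Mapping[str, float]) -> np.ndarray:
        return np.array([math.log10(values[n]) for n in self.names])

    def decode(self, genome: np.ndarray) -> dict[str, float]:
        out = {n: 10.0 ** float(x) for n, x in zip(self.names, genome)}
        out.update(self._fixed)
        return out


def encode_search_vector(specs: Sequence[ParameterSpec]) -> SearchSpace:
    """Build the log10 search box; US parameters are excluded and fixed.

    Parameter order follows the input spec order deterministically.
    """
    if not specs:
        raise ConfigurationError("empty parameter spec list")
    searched = [s for s in specs if s.searched]
    if not searched:
        raise ConfigurationError("all parameters are unsearched (US); nothing to fit")
    return SearchSpace(
        names=tuple(s.name for s in searched),
        lower=np.array([math.log10(s.lower_bound) for s in searched]),
        upper=np.array([math.log10(s.upper_bound) for s in searched]),
        _fixed={s.name: s.reference_value for s in specs if not s.searched},
    )


def round_to_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (reporting convention helper)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))
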