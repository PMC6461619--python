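"""Replicated fits, model comparison by plausibility, local sensitivities.

Competing model variants are fitted several times each with independent
seeds; only runs that satisfy every constraint (γ = 0) enter the
comparison.  Each side is summarised by a representative objective value
(median by default), converted to a model plausibility MP = exp(-f), and
the sides are compared by the MP ratio and a two-sided rank-sum test on
the per-run objective values (exact enumeration in the small-sample
regime).  A local sensitivity analysis quantifies how steady-state
outputs respond to relative parameter perturbations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ga import GAConfig, GARun, Problem, optimize
from .plausibility import model_plausibility
from .transport import (
    Condition,
    SteadyStateError,
    ToyNetworkParams,
    observables,
    steady_state,
)

__all__ = [
    "ReplicateSet",
    "ModelComparison",
    "InfeasibleComparisonError",
    "run_replicates",
    "parameter_cv",
    "compare_models",
    "rank_sum_p",
    "local_sensitivity",
    "steady_state_sensitivity",
]

#: largest per-side sample size handled by exact rank-sum enumeration
EXACT_RANKSUM_LIMIT = 8

#: default steady-state outputs for sensitivity tables
SENSITIVITY_OUTPUTS = ("nhx_int", "gln", "glu", "v_amtb", "v_diff", "v_gs", "growth_rate")


class InfeasibleComparisonError(RuntimeError):
    """A side of a model comparison has no feasible (γ = 0) run."""


@dataclass(frozen=True)
class ReplicateSet:
    """Independent optimization runs plus a per-parameter spread summary."""

    runs: tuple[GARun, ...]
    cv_table: pd.DataFrame  # parameter, mean, sd, cv over feasible bests


def run_replicates(
    problem: Problem,
    config: GAConfig,
    n_runs: int,
    base_seed: int,
    parameter_names: Sequence[str] | None = None,
    decode: Callable[[np.ndarray], Mapping[str, float]] | None = None,
) -> ReplicateSet:
    """Run the GA ``n_runs`` times with seeds base_seed .. base_seed+n-1."""
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    runs = tuple(
        optimize(problem, replace(config, seed=base_seed + i)) for i in range(n_runs)
    )
    if decode is None:
        decode = getattr(problem, "space", None) and problem.space.decode  # type: ignore[attr-defined]
    if decode is not None:
        tables = [
            decode(r.best.genome) for r in runs if r.feasible
        ]
        cv = parameter_cv(tables, parameter_names)
    else:
        cv = pd.DataFrame(columns=["parameter", "mean", "sd", "cv"])
    return ReplicateSet(runs=runs, cv_table=cv)


def parameter_cv(
    value_maps: Sequence[Mapping[str, float]],
    parameter_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Coefficient of variation (sample sd / mean) per parameter."""
    if not value_maps:
        return pd.DataFrame(columns=["parameter", "mean", "sd", "cv"])
    names = list(parameter_names) if parameter_names else list(value_maps[0])
    rows = []
    for name in names:
        vals = np.array([m[name] for m in value_maps], dtype=float)
        mean = vals.mean()
        sd = vals.std(ddof=1) if vals.size > 1 else 0.0
        rows.append(
            {"parameter": name, "mean": mean, "sd": sd, "cv": sd / mean if mean else math.nan}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ModelComparison:
    """Outcome of ranking model A against model B on the same constraints."""

    f_a: tuple[float, ...]
    f_b: tuple[float, ...]
    representative: str
    rep_f_a: float
    rep_f_b: float
    mp_a: float
    mp_b: float
    mp_ratio: float
    rank_sum_p: float

    def to_dict(self) -> dict:
        return {
            "f_a": list(self.f_a),
            "f_b": list(self.f_b),
            "representative": self.representative,
            "rep_f_a": self.rep_f_a,
            "rep_f_b": self.rep_f_b,
            "mp_a": self.mp_a,
            "mp_b": self.mp_b,
            "mp_ratio": self.mp_ratio,
            "rank_sum_p": self.rank_sum_p,
        }


_REPRESENTATIVES = {"median": np.median, "min": np.min, "mean": np.mean}


def compare_models(
    runs_a: Sequence[GARun],
    runs_b: Sequence[GARun],
    representative: str = "median",
) -> ModelComparison:
    """Rank two fitted model variants by plausibility.

    Only feasible runs (γ = 0) count; a side without any is refused.
    ``mp_ratio > 1`` favours model A.
    """
    try:
        agg = _REPRESENTATIVES[representative]
    except KeyError:
        raise ValueError(f"unknown representative {representative!r}") from None
    f_a = tuple(sorted(r.best.evaluation.f_value for r in runs_a if r.feasible))
    f_b = tuple(sorted(r.best.evaluation.f_value for r in runs_b if r.feasible))
    for side, fs in (("A", f_a), ("B", f_b)):
        if not fs:
            raise InfeasibleComparisonError(
                f"model {side} has no feasible run; comparison refused"
            )
    rep_a = float(agg(f_a))
    rep_b = float(agg(f_b))
    mp_a = model_plausibility(rep_a)
    mp_b = model_plausibility(rep_b)
    return ModelComparison(
        f_a=f_a,
        f_b=f_b,
        representative=representative,
        rep_f_a=rep_a,
        rep_f_b=rep_b,
        mp_a=mp_a,
        mp_b=mp_b,
        mp_ratio=math.exp(rep_b - rep_a),
        rank_sum_p=rank_sum_p(f_a, f_b) if min(len(f_a), len(f_b)) > 0 else math.nan,
    )


def rank_sum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided rank-sum (Wilcoxon/Mann-Whitney) p-value.

    For tie-free samples with at most :data:`EXACT_RANKSUM_LIMIT` values
    per side the exact permutation null of the rank sum is enumerated by
    dynamic programming; larger or tied samples use the normal
    approximation.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    pooled = x + y
    no_ties = len(set(pooled)) == len(pooled)
    if no_ties and max(len(x), len(y)) <= EXACT_RANKSUM_LIMIT:
        return _exact_rank_sum_p(x, y)
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic").pvalue)


def _exact_rank_sum_p(x: Sequence[float], y: Sequence[float]) -> float:
    m, n = len(x), len(y)
    N = m + n
    ranks = {v: r for r, v in enumerate(sorted(x + list(y)), start=1)}
    w = sum(ranks[v] for v in x)
    # null distribution of the rank sum of m items out of ranks 1..N
    # counts[k][s]: ways to choose k ranks summing to s
    max_sum = N * (N + 1) // 2
    counts = np.zeros((m + 1, max_sum + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(r, m), 0, -1):
            counts[k, r:] += counts[k - 1, :-r]
    total = counts[m].sum()
    mu = m * (N + 1) / 2.0
    d = abs(w - mu)
    sums = np.arange(max_sum + 1)
    extreme = np.abs(sums - mu) >= d - 1e-9
    return float(counts[m, extreme].sum() / total)


def local_sensitivity(
    fun: Callable[[Mapping[str, float]], Mapping[str, float]],
    params: Mapping[str, float],
    outputs: Sequence[str] | None = None,
    delta: float = 1e-3,
) -> pd.DataFrame:
    """Normalized local sensitivities by central finite differences.

    ``S[i, j] = (∂ output_j / output_j) / (∂ p_i / p_i)`` evaluated with a
    relative step ``delta`` on each parameter in turn.  An evaluation
    failure at a perturbed point flags the whole row as missing (NaN)
    rather than zero.
    """
    base = dict(fun(params))
    if outputs is None:
        outputs = list(base)
    rows = {}
    for name, value in params.items():
        try:
            hi = fun({**params, name: value * (1.0 + delta)})
            lo = fun({**params, name: value * (1.0 - delta)})
            rows[name] = [
                (hi[o] - lo[o]) / (2.0 * delta * base[o]) if base[o] != 0 else math.nan
                for o in outputs
            ]
        except Exception:
            rows[name] = [math.nan] * len(outputs)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(outputs))


def steady_state_sensitivity(
    params: ToyNetworkParams,
    condition: Condition,
    targets: Sequence[str] | None = None,
    outputs: Sequence[str] = SENSITIVITY_OUTPUTS,
    delta: float = 1e-3,
) -> pd.DataFrame:
    """Sensitivity of steady-state observables to parameters and physics.

    ``targets`` may name kinetic parameters or the physics inputs
    ``ph_int``, ``ph_ext``, ``delta_psi`` and ``temperature``.
    """
    param_names = set(ToyNetworkParams.field_names())
    physics_names = {"ph_int", "ph_ext", "delta_psi", "temperature"}
    if targets is None:
        targets = list(ToyNetworkParams.field_names())
    base_values = {**params.as_dict()}
    for t in targets:
        if t in physics_names:
            base_values[t] = getattr(condition.physics, t)
        elif t not in param_names:
            raise ValueError(f"unknown sensitivity target {t!r}")

    def fun(values: Mapping[str, float]) -> Mapping[str, float]:
        merged = {**base_values, **values}
        p = ToyNetworkParams(**{k: merged[k] for k in ToyNetworkParams.field_names()})
        phys = condition.physics
        for name in physics_names & set(merged):
            phys = replace(phys, **{name: merged[name]})
        cond = replace(condition, physics=phys)
        state, _ = steady_state(p, cond)
        obs = observables(state, p, cond)
        return {o: obs[o] for o in outputs}

    return local_sensitivity(
        fun, {t: base_values[t] for t in targets}, outputs=list(outputs), delta=delta
    )
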