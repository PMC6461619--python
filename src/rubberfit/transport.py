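"""Transport thermodynamics and a reduced ammonium transport/assimilation model.

Two hypotheses about the AmtB ammonium transporter are expressed through the
accumulation factor φ, the intracellular/extracellular NH4+ ratio at
transporter equilibrium:

* active (electrogenic) transport:  φ = exp(-F·Δψ / (R·T)) — at the usual
  negative membrane potential φ is in the hundreds, so NH4+ can accumulate;
* facilitated passive NH3 transport: φ = 10^(pH_ext - pH_int) — no
  accumulation beyond what the pH difference allows (φ < 1 when the inside
  is more alkaline).

Around φ sits a deliberately small demonstration network with three state
variables (total internal ammonium NHx, glutamine, glutamate):

* AmtB flux with saturable uptake, a thermodynamic driving term that
  vanishes exactly at the equilibrium ratio φ, and GlnK-like inhibition
  modeled as a Hill function of internal NH4+;
* unfacilitated NH3 membrane diffusion (negative = outward back diffusion,
  the dissipative half of the ammonium/ammonia futile cycle);
* a single saturable assimilation flux standing in for GS, feeding a
  glutamine -> glutamate -> biomass chain that yields a growth-rate
  observable.

Intracellular and extracellular NH4+/NH3 speciation is treated as an
instantaneous acid-base equilibrium (protonation is far faster than
transport), so only total NHx is integrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .plausibility import DomainError

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "TransportPhysics",
    "Condition",
    "FluxDecomposition",
    "ToyNetworkParams",
    "Trajectory",
    "SteadyStateError",
    "accumulation_factor_active",
    "accumulation_factor_passive",
    "speciate",
    "toy_rhs",
    "fluxes",
    "observables",
    "simulate",
    "steady_state",
    "futile_cycle_atp_equivalent",
    "glnk_knockout",
    "STATE_VARS",
]

FARADAY = 96485.0  # C/mol
GAS_CONSTANT = 8.314  # J/(mol K)

STATE_VARS = ("nhx_int", "gln", "glu")


def accumulation_factor_active(delta_psi: float, temperature: float) -> float:
    """φ for the electrogenic transporter, from the membrane potential.

    ``delta_psi`` in mV (negative = inside negative), ``temperature`` in K.
    """
    if temperature <= 0:
        raise DomainError(f"temperature must be positive, got {temperature}")
    return math.exp(-FARADAY * (delta_psi / 1000.0) / (GAS_CONSTANT * temperature))


def accumulation_factor_passive(ph_ext: float, ph_int: float) -> float:
    """φ for the facilitated passive NH3 transporter, from the pH difference."""
    return 10.0 ** (ph_ext - ph_int)


def speciate(nhx_total: float, ph: float, pka: float = 9.25) -> tuple[float, float]:
    """Split total ammonium into (NH4+, NH3) at acid-base equilibrium.

    NH3/NH4+ = 10^(pH - pKa); the two species sum to the total.
    """
    if nhx_total < 0:
        raise DomainError(f"total ammonium must be non-negative, got {nhx_total}")
    ratio = 10.0 ** (ph - pka)
    nh4 = nhx_total / (1.0 + ratio)
    return nh4, nhx_total - nh4


@dataclass(frozen=True)
class TransportPhysics:
    """Membrane physics of one experimental condition.

    ``mode`` selects the transporter hypothesis; the active mode derives φ
    from (Δψ, T), the passive mode from (pH_ext, pH_int).  Both pH values
    are always used for NH4+/NH3 speciation on their respective sides.
    """

    mode: str = "active"
    delta_psi: float = -150.0  # mV
    temperature: float = 310.0  # K
    ph_ext: float = 7.0
    ph_int: float = 7.6

    def __post_init__(self) -> None:
        if self.mode not in ("active", "passive"):
            raise DomainError(f"unknown transporter mode {self.mode!r}")
        if self.temperature <= 0:
            raise DomainError("temperature must be positive")

    def phi(self) -> float:
        if self.mode == "active":
            return accumulation_factor_active(self.delta_psi, self.temperature)
        return accumulation_factor_passive(self.ph_ext, self.ph_int)


@dataclass(frozen=True)
class Condition:
    """One experiment configuration: physics, medium, initial state.

    ``nhx_ext`` is the total extracellular ammonium in mM, either a scalar
    or a list of ``(time, value)`` steps (piecewise constant, a step input
    such as an N-upshift).  ``tau0`` is the minimal doubling time proxy in
    minutes used for the growth-rate observable.
    """

    condition_id: str
    physics: TransportPhysics
    nhx_ext: float | tuple[tuple[float, float], ...]
    pka: float = 9.25
    initial_state: Mapping[str, float] = None  # type: ignore[assignment]
    tau0: float = 52.0
    glnk_knockout: bool = False

    def __post_init__(self) -> None:
        init = dict(self.initial_state or {v: 0.0 for v in STATE_VARS})
        for v in STATE_VARS:
            init.setdefault(v, 0.0)
            if init[v] < 0:
                raise DomainError(
                    f"condition {self.condition_id!r}: negative initial {v}"
                )
        object.__setattr__(self, "initial_state", init)
        if self.tau0 <= 0:
            raise DomainError("tau0 must be positive")
        ext = self.nhx_ext
        if not np.isscalar(ext):
            steps = tuple((float(t), float(v)) for t, v in ext)
            if any(v < 0 for _, v in steps) or steps != tuple(sorted(steps)):
                raise DomainError(
                    f"condition {self.condition_id!r}: step input must be "
                    "time-sorted with non-negative values"
                )
            object.__setattr__(self, "nhx_ext", steps)
        elif ext < 0:
            raise DomainError(f"condition {self.condition_id!r}: negative nhx_ext")

    def nhx_ext_at(self, t: float) -> float:
        if np.isscalar(self.nhx_ext):
            return float(self.nhx_ext)
        value = self.nhx_ext[0][1]
        for t_i, v_i in self.nhx_ext:
            if t >= t_i:
                value = v_i
        return value

    def breakpoints(self) -> tuple[float, ...]:
        if np.isscalar(self.nhx_ext):
            return ()
        return tuple(t for t, _ in self.nhx_ext if t > 0)

    def initial_vector(self) -> np.ndarray:
        return np.array([self.initial_state[v] for v in STATE_VARS])


@dataclass(frozen=True)
class FluxDecomposition:
    """Membrane nitrogen fluxes in mM/min; v_net = v_amtb + v_diff."""

    v_amtb: float
    v_diff: float
    v_net: float


@dataclass(frozen=True)
class ToyNetworkParams:
    """Kinetic parameters of the reduced network (mM, mM/min, 1/min).

    vmax_amtb, km_amtb : AmtB transport capacity and affinity
    p_diff             : membrane NH3 permeability rate coefficient (1/min)
    vmax_gs, km_gs     : assimilation (GS-like) capacity and affinity
    k_glnk, n_glnk     : half-inhibition internal NH4+ and Hill coefficient
                         of GlnK-like AmtB blocking
    mu_max             : biomass nitrogen drain rate coefficient (1/min)
    k_growth           : glutamine half-saturation of growth (mM)
    k_dil              : first-order glutamine utilisation rate (1/min)
    """

    vmax_amtb: float
    km_amtb: float
    p_diff: float
    vmax_gs: float
    km_gs: float
    k_glnk: float
    n_glnk: float
    mu_max: float
    k_growth: float
    k_dil: float

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not value > 0:
                raise DomainError(f"parameter {name} must be positive, got {value}")

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(cls.__dataclass_fields__)

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def glnk_knockout(params: ToyNetworkParams) -> ToyNetworkParams:
    """Remove GlnK inhibition (θ forced to 0); the input is not modified."""
    return replace(params, k_glnk=math.inf)


def _rates(
    y: np.ndarray, p: ToyNetworkParams, cond: Condition, t: float
) -> dict[str, float]:
    """All fluxes and observables at one state; the single source of truth."""
    phys = cond.physics
    phi = phys.phi()
    # negative excursions within solver tolerance are treated as zero
    nhx_i = max(float(y[0]), 0.0)
    gln = max(float(y[1]), 0.0)
    glu = max(float(y[2]), 0.0)
    nh4_i, nh3_i = speciate(nhx_i, phys.ph_int, cond.pka)
    nh4_e, nh3_e = speciate(cond.nhx_ext_at(t), phys.ph_ext, cond.pka)

    ratio = (nh4_i / p.k_glnk) ** p.n_glnk if math.isfinite(p.k_glnk) else 0.0
    theta = ratio / (1.0 + ratio)

    if phys.mode == "active":
        if nh4_e > 0:
            v_amtb = (
                p.vmax_amtb
                * (1.0 - theta)
                * nh4_e
                / (p.km_amtb + nh4_e)
                * (1.0 - nh4_i / (phi * nh4_e))
            )
        else:
            v_amtb = 0.0
    else:
        if nh3_e > 0:
            v_amtb = (
                p.vmax_amtb
                * (1.0 - theta)
                * nh3_e
                / (p.km_amtb + nh3_e)
                * (1.0 - nh3_i / nh3_e)
            )
        else:
            v_amtb = 0.0

    v_diff = p.p_diff * (nh3_e - nh3_i)
    v_gs = p.vmax_gs * nh4_i / (p.km_gs + nh4_i)
    mu_frac = gln / (p.k_growth + gln)
    v_use = p.k_dil * gln
    v_bio = p.mu_max * mu_frac * glu
    return {
        "nh4_int": nh4_i,
        "nh3_int": nh3_i,
        "nh4_ext": nh4_e,
        "nh3_ext": nh3_e,
        "theta_glnk": theta,
        "v_amtb": v_amtb,
        "v_diff": v_diff,
        "v_net": v_amtb + v_diff,
        "v_gs": v_gs,
        "v_use": v_use,
        "v_bio": v_bio,
        "growth_rate": math.log(2.0) / cond.tau0 * mu_frac,
    }


def _derivatives(r: Mapping[str, float]) -> np.ndarray:
    return np.array(
        [
            r["v_amtb"] + r["v_diff"] - r["v_gs"],
            r["v_gs"] - r["v_use"],
            r["v_use"] - r["v_bio"],
        ]
    )


def _effective_params(params: ToyNetworkParams, cond: Condition) -> ToyNetworkParams:
    return glnk_knockout(params) if cond.glnk_knockout else params


def toy_rhs(
    state: Mapping[str, float],
    params: ToyNetworkParams,
    condition: Condition,
    t: float = 0.0,
) -> dict[str, float]:
    """Time derivatives (mM/min) of the state variables at one state."""
    for v in STATE_VARS:
        if state[v] < 0:
            raise DomainError(f"negative state value for {v}: {state[v]}")
    y = np.array([state[v] for v in STATE_VARS])
    d = _derivatives(_rates(y, _effective_params(params, condition), condition, t))
    return dict(zip(STATE_VARS, d))


def fluxes(
    state: Mapping[str, float],
    params: ToyNetworkParams,
    condition: Condition,
    t: float = 0.0,
) -> FluxDecomposition:
    """Membrane flux decomposition at one state."""
    y = np.array([state[v] for v in STATE_VARS])
    r = _rates(y, _effective_params(params, condition), condition, t)
    return FluxDecomposition(r["v_amtb"], r["v_diff"], r["v_net"])


def observables(
    state: Mapping[str, float],
    params: ToyNetworkParams,
    condition: Condition,
    t: float = 0.0,
) -> dict[str, float]:
    """All observable quantities (states, speciation, fluxes, growth rate)."""
    y = np.array([state[v] for v in STATE_VARS])
    r = _rates(y, _effective_params(params, condition), condition, t)
    out = dict(zip(STATE_VARS, y))
    out.update(r)
    return out


@dataclass(frozen=True)
class Trajectory:
    """Dense time-course output: states and fluxes at the requested times."""

    condition_id: str
    data: pd.DataFrame  # columns: time, state vars, observables

    def at(self, time: float, variable: str) -> float:
        row = self.data.loc[(self.data["time"] - time).abs().idxmin()]
        if abs(row["time"] - time) > 1e-9 * max(1.0, abs(time)):
            raise KeyError(f"time {time} not on the trajectory grid")
        return float(row[variable])

    def series(self, times: Sequence[float], variable: str) -> np.ndarray:
        return np.array([self.at(t, variable) for t in times])


class SteadyStateError(RuntimeError):
    """No steady state found; names the condition and parameter set."""


def simulate(
    params: ToyNetworkParams,
    condition: Condition,
    t_end: float,
    times: Sequence[float] | None = None,
    rtol: float = 1e-7,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the network ODEs from the condition's initial state.

    Step changes of the external ammonium are handled by splitting the
    integration at the breakpoints.  Output rows are produced at ``times``
    (plus 0 and ``t_end``); fluxes are reported alongside states.
    """
    if t_end <= 0:
        raise DomainError(f"t_end must be positive, got {t_end}")
    p = _effective_params(params, condition)
    t_eval = {0.0, float(t_end)}
    if times is not None:
        t_eval.update(float(t) for t in times)
    t_grid = np.array(sorted(t_eval))
    if t_grid[0] < 0 or t_grid[-1] > t_end:
        raise DomainError("requested times outside [0, t_end]")

    segments = [0.0, *[b for b in condition.breakpoints() if b < t_end], t_end]
    y = condition.initial_vector()
    rows: list[tuple[float, np.ndarray]] = []
    for a, b in zip(segments[:-1], segments[1:]):
        seg_times = t_grid[(t_grid >= a) & (t_grid <= b)]

        def rhs(t: float, yv: np.ndarray) -> np.ndarray:
            return _derivatives(_rates(yv, p, condition, t))

        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            method=method,
            t_eval=seg_times if seg_times.size else None,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SteadyStateError(
                f"integration failed for condition {condition.condition_id!r} "
                f"with parameters {params}: {sol.message}"
            )
        for t_i, y_i in zip(sol.t, sol.y.T):
            if not rows or t_i > rows[-1][0]:
                rows.append((float(t_i), y_i))
        # continue from the exact segment end
        y = sol.y[:, -1] if sol.t[-1] == b else solve_ivp(
            rhs, (sol.t[-1], b), sol.y[:, -1], method=method, rtol=rtol, atol=atol
        ).y[:, -1]

    records = []
    for t_i, y_i in rows:
        r = _rates(y_i, p, condition, t_i)
        rec = {"time": t_i, **dict(zip(STATE_VARS, y_i))}
        rec.update({k: r[k] for k in (
            "nh4_int", "nh3_int", "v_amtb", "v_diff", "v_net", "v_gs", "growth_rate"
        )})
        records.append(rec)
    return Trajectory(condition.condition_id, pd.DataFrame.from_records(records))


def steady_state(
    params: ToyNetworkParams,
    condition: Condition,
    tol: float = 1e-8,
    t_horizon: float = 2000.0,
) -> tuple[dict[str, float], FluxDecomposition]:
    """Locate the metabolic steady state reached from the initial state.

    A Newton solve from the initial state is accepted only if it converges
    to a non-negative, locally stable fixed point; otherwise the ODEs are
    integrated toward the attractor and the endpoint is Newton-refined.
    Raises :class:`SteadyStateError` when neither route converges — never a
    silent near-answer.
    """
    p = _effective_params(params, condition)
    t_ref = condition.breakpoints()[-1] if condition.breakpoints() else 0.0

    def fun(yv: np.ndarray) -> np.ndarray:
        return _derivatives(_rates(yv, p, condition, t_ref))

    def accept(yv: np.ndarray) -> bool:
        if np.any(yv < -1e-9) or not np.all(np.isfinite(yv)):
            return False
        scale = np.maximum(np.abs(yv), 1.0)
        if np.max(np.abs(fun(yv)) / scale) > tol:
            return False
        # local stability via a finite-difference Jacobian
        n = yv.size
        jac = np.empty((n, n))
        h = 1e-7 * scale
        for j in range(n):
            e = np.zeros(n)
            e[j] = h[j]
            jac[:, j] = (fun(yv + e) - fun(yv - e)) / (2 * h[j])
        return bool(np.all(np.real(np.linalg.eigvals(jac)) < tol))

    y0 = np.maximum(condition.initial_vector(), 1e-12)
    sol = root(fun, y0, method="hybr")
    y_ss = np.maximum(sol.x, 0.0)
    if not (sol.success and accept(y_ss)):
        # fall back to integrating toward the attractor
        y = y0
        for t_end in (50.0, 450.0, t_horizon):
            # loose integration toward the attractor; Newton refines afterwards
            traj = solve_ivp(
                lambda t, yv: _derivatives(_rates(yv, p, condition, t_ref)),
                (0.0, t_end),
                y,
                method="LSODA",
                rtol=1e-6,
                atol=1e-9,
            )
            if not traj.success:
                break
            y = traj.y[:, -1]
            sol = root(fun, y, method="hybr")
            y_ss = np.maximum(sol.x, 0.0)
            if sol.success and accept(y_ss):
                break
        else:
            y_ss = None  # type: ignore[assignment]
        if y_ss is None or not (sol.success and accept(y_ss)):
            raise SteadyStateError(
                f"no steady state found for condition "
                f"{condition.condition_id!r} with parameters {params}"
            )
    state = dict(zip(STATE_VARS, (float(v) for v in y_ss)))
    r = _rates(y_ss, p, condition, t_ref)
    return state, FluxDecomposition(r["v_amtb"], r["v_diff"], r["v_net"])


def futile_cycle_atp_equivalent(
    back_diffusion: float, h_per_nh3: float = 1.0, h_per_atp: float = 3.0
) -> float:
    """ATP-equivalent cost (mM/min) of outward NH3 back diffusion.

    Each NH3 leaving the cell wastes the ``h_per_nh3`` protons symported on
    re-import; ``h_per_atp`` protons translocated per ATP by the ATP
    synthase convert the proton loss into an ATP-equivalent rate.
    """
    if back_diffusion < 0:
        raise DomainError("pass the outward back-diffusion magnitude (>= 0)")
    if h_per_nh3 < 0 or h_per_atp <= 0:
        raise DomainError("stoichiometries must be positive")
    return back_diffusion * h_per_nh3 / h_per_atp
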