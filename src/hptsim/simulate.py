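"""Time-course simulation under dosing regimens and steady-state analysis.

Oral doses are bit-exact events: the integrator is stopped at each dose time
and the bolus (converted to umol with MW 777 for T4, 651 for T3) is added to
the corresponding undissolved-pill compartment before restarting.  Constant
T3 (or T4) infusions enter the plasma compartments through the RHS.

Integration uses LSODA (scipy) with rtol 1e-6 / atol 1e-9: simulated TSH
spans four orders of magnitude between euthyroid and athyreotic scenarios.
Simulation time ``t`` is in hours, with the circadian phase tied to ``t``
modulo 24; dose events on 12 h or 24 h grids therefore stay phase-locked to
the circadian cycle, and end-of-day states are phase-comparable across
different course lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import odeint

from .model import IDX, N_STATES, _rhs_core, default_state_guess, rhs_vector
from .parameters import MW_T3, MW_T4, TSH_MU_PER_UMOL, ModelParameters

__all__ = [
    "DoseRegimen",
    "Trajectory",
    "SteadyState",
    "IntegrationError",
    "initial_condition",
    "run_course",
    "steady_state",
    "to_concentrations",
]

RTOL = 1e-6
ATOL = 1e-9


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails; carries the last valid state."""

    def __init__(self, message: str, last_state: np.ndarray | None = None, t: float | None = None):
        super().__init__(message)
        self.last_state = last_state
        self.t = t


@dataclass(frozen=True)
class DoseRegimen:
    """Oral LT4/LT3 doses (ug per administration) with a fixed interval (h).

    ``t3_infusion`` is a constant plasma T3 delivery rate in ug/h (an
    idealized slow-release preparation); it bypasses gut absorption.
    """

    lt4_dose: float = 0.0
    lt3_dose: float = 0.0
    interval: float = 24.0
    t3_infusion: float = 0.0

    def __post_init__(self) -> None:
        if self.lt4_dose < 0 or self.lt3_dose < 0 or self.t3_infusion < 0:
            raise ValueError("doses and infusion rates must be non-negative")
        if not self.interval > 0:
            raise ValueError("dosing interval must be positive")

    @property
    def is_empty(self) -> bool:
        return self.lt4_dose == 0 and self.lt3_dose == 0 and self.t3_infusion == 0

    @classmethod
    def daily(cls, lt4: float = 0.0, lt3: float = 0.0) -> "DoseRegimen":
        return cls(lt4_dose=lt4, lt3_dose=lt3, interval=24.0)

    @classmethod
    def twice_daily(cls, lt4_daily: float = 0.0, lt3_daily: float = 0.0) -> "DoseRegimen":
        """Split daily amounts into two half-doses 12 h apart."""
        return cls(lt4_dose=lt4_daily / 2.0, lt3_dose=lt3_daily / 2.0, interval=12.0)

    @classmethod
    def with_infusion(cls, lt4_daily: float = 0.0, lt3_daily: float = 0.0) -> "DoseRegimen":
        """Once-daily oral LT4 plus the LT3 daily amount as a constant infusion."""
        return cls(lt4_dose=lt4_daily, lt3_dose=0.0, interval=24.0,
                   t3_infusion=lt3_daily / 24.0)


@dataclass
class Trajectory:
    """Sampled hormone time course: time (h), T4/T3 (ug/L), TSH (mU/L)."""

    time: np.ndarray
    t4: np.ndarray
    t3: np.ndarray
    tsh: np.ndarray
    states: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("trajectory time grid must be strictly increasing")

    def final(self) -> tuple[float, float, float]:
        return float(self.t4[-1]), float(self.t3[-1]), float(self.tsh[-1])

    def day_average(self, day: int = -1) -> tuple[float, float, float]:
        """Mean concentrations over one 24 h window (default: the last full day)."""
        t_end = self.time[-1]
        if day == -1:
            lo, hi = t_end - 24.0, t_end
        else:
            lo, hi = 24.0 * day, 24.0 * (day + 1)
        mask = (self.time >= lo - 1e-9) & (self.time <= hi + 1e-9)
        if not np.any(mask):
            raise ValueError("requested day not covered by the trajectory")
        return (
            float(np.mean(self.t4[mask])),
            float(np.mean(self.t3[mask])),
            float(np.mean(self.tsh[mask])),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_h": self.time, "t4_ugL": self.t4, "t3_ugL": self.t3, "tsh_mUL": self.tsh}
        )


@dataclass(frozen=True)
class SteadyState:
    """End-of-course hormone levels plus the final-day cycle averages."""

    t4: float
    t3: float
    tsh: float
    t4_avg: float
    t3_avg: float
    tsh_avg: float
    converged: bool
    days: int


def to_concentrations(
    state: np.ndarray, params: ModelParameters
) -> tuple[float, float, float]:
    """Convert a state vector to plasma T4, T3 (ug/L) and TSH (mU/L)."""
    state = np.asarray(state, dtype=np.float64)
    t4 = MW_T4 * state[..., IDX["T4p"]] / params.Vp
    t3 = MW_T3 * state[..., IDX["T3p"]] / params.Vp
    tsh = TSH_MU_PER_UMOL * state[..., IDX["TSHp"]] / params.VTSH
    if state.ndim == 1:
        return float(t4), float(t3), float(tsh)
    return t4, t3, tsh


def _f(q, t, p):
    dq = np.empty_like(q)
    _rhs_core(t, q, p, dq)
    return dq


def _integrate_segment(pvec, q0, t_eval):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out, info = odeint(
            _f, q0, t_eval, args=(pvec,), rtol=RTOL, atol=ATOL,
            mxstep=100000, full_output=True, tfirst=False,
        )
    if info["message"] != "Integration successful.":
        raise IntegrationError(
            f"LSODA failed: {info['message']}", last_state=out[-1], t=float(t_eval[-1])
        )
    if not np.all(np.isfinite(out)):
        raise IntegrationError("non-finite state during integration",
                               last_state=q0, t=float(t_eval[0]))
    if out.min() < -1e-5:
        raise IntegrationError(
            f"state went negative beyond tolerance (min {out.min():g})",
            last_state=out[-1], t=float(t_eval[-1]),
        )
    return out


def _simulate_events(
    params: ModelParameters,
    q0: np.ndarray,
    duration_h: float,
    events: list[tuple[float, float, float]],
    t3_infusion_ug_h: float = 0.0,
    t4_infusion_ug_h: float = 0.0,
    sample_dt: float = 1.0,
    keep_states: bool = False,
) -> Trajectory:
    """Integrate with bolus events (t_h, lt4_ug, lt3_ug) and constant infusions."""
    pvec = params.to_vector(
        t4_infusion=t4_infusion_ug_h / MW_T4, t3_infusion=t3_infusion_ug_h / MW_T3
    )
    q = np.array(q0, dtype=np.float64)

    events = sorted((float(t), lt4, lt3) for t, lt4, lt3 in events if t < duration_h)
    boundaries = np.unique(np.concatenate(
        [[0.0, duration_h], [e[0] for e in events]]
    ))
    boundaries = boundaries[(boundaries >= 0.0) & (boundaries <= duration_h)]

    ev_at = {}
    for t, lt4, lt3 in events:
        d4, d3 = ev_at.get(t, (0.0, 0.0))
        ev_at[t] = (d4 + lt4, d3 + lt3)

    times, t4s, t3s, tshs = [], [], [], []
    states = [] if keep_states else None

    def _record(t_arr, q_arr, skip_first):
        sl = slice(1, None) if skip_first else slice(None)
        t4, t3, tsh = to_concentrations(q_arr[sl], params)
        times.append(t_arr[sl])
        t4s.append(t4)
        t3s.append(t3)
        tshs.append(tsh)
        if states is not None:
            states.append(q_arr[sl])

    first = True
    for i in range(len(boundaries) - 1):
        t0, t1 = boundaries[i], boundaries[i + 1]
        if t0 in ev_at:
            d4, d3 = ev_at[t0]
            q[IDX["T4PILL"]] += d4 / MW_T4
            q[IDX["T3PILL"]] += d3 / MW_T3
        n_interior = max(int(np.ceil((t1 - t0) / sample_dt)), 1)
        t_eval = np.linspace(t0, t1, n_interior + 1)
        out = _integrate_segment(pvec, q, t_eval)
        q = out[-1]
        _record(t_eval, out, skip_first=not first)
        first = False

    traj = Trajectory(
        time=np.concatenate(times),
        t4=np.concatenate(t4s),
        t3=np.concatenate(t3s),
        tsh=np.concatenate(tshs),
        states=np.concatenate(states) if states is not None else None,
    )
    return traj


def initial_condition(
    params: ModelParameters,
    max_days: int = 300,
    tol: float = 1e-5,
    guess: np.ndarray | None = None,
) -> np.ndarray:
    """Euthyroid periodic steady state of the personalized model (rtf = 1).

    Integrates the undosed system in 10-day blocks until the day-averaged
    hormone triple changes by less than ``tol`` (relative) between blocks.
    The returned state sits on a whole-day circadian phase boundary.
    """
    if params.rtf != 1.0:
        raise ValueError("initial_condition expects rtf = 1 (euthyroid physiology)")
    q = np.array(default_state_guess(params) if guess is None else guess, dtype=np.float64)
    prev = None
    block = 10
    for _ in range(max_days // block):
        traj = _simulate_events(params, q, 24.0 * block, events=[], sample_dt=1.0,
                                keep_states=True)
        q = traj.states[-1]
        cur = np.array(traj.day_average(-1))
        if prev is not None:
            rel = np.max(np.abs(cur - prev) / np.maximum(np.abs(prev), 1e-12))
            if rel < tol:
                return q
        prev = cur
    raise IntegrationError(
        f"euthyroid steady state did not converge within {max_days} days "
        f"(last relative change {rel:.2e})", last_state=q,
    )


def run_course(
    params: ModelParameters,
    regimen: DoseRegimen | None,
    days: float,
    initial: np.ndarray | None = None,
    sample_dt: float = 1.0,
    keep_states: bool = False,
) -> Trajectory:
    """Simulate ``days`` of a dosing regimen from an initial state.

    The first oral dose is administered at t = 0 and repeated every
    ``regimen.interval`` hours.  If ``initial`` is omitted, the euthyroid
    steady state of ``params`` with rtf reset to 1 is computed first (the
    post-thyroidectomy protocol: normal physiology up to t = 0).
    """
    if not days > 0:
        raise ValueError("days must be positive")
    if initial is None:
        initial = initial_condition(params.replace(rtf=1.0))
    regimen = regimen or DoseRegimen()
    duration = 24.0 * days
    events = []
    if regimen.lt4_dose > 0 or regimen.lt3_dose > 0:
        t = 0.0
        while t < duration - 1e-9:
            events.append((t, regimen.lt4_dose, regimen.lt3_dose))
            t += regimen.interval
    return _simulate_events(
        params, initial, duration, events,
        t3_infusion_ug_h=regimen.t3_infusion,
        sample_dt=sample_dt, keep_states=keep_states,
    )


def steady_state(
    params: ModelParameters,
    regimen: DoseRegimen | None = None,
    max_days: int = 50,
    initial: np.ndarray | None = None,
    early_tol: float = 2e-4,
    min_days: int = 10,
    flag_tol: float = 5e-3,
) -> SteadyState:
    """Hormone levels after a long course of a periodic (or empty) regimen.

    Runs up to ``max_days`` (default 50, ample for this system), stopping
    early once consecutive day-averaged triples agree to ``early_tol``
    relative.  ``converged`` is False when the last two day averages still
    differ by more than ``flag_tol`` (0.5%).
    """
    regimen = regimen or DoseRegimen()
    if initial is None:
        initial = initial_condition(params.replace(rtf=1.0))
    q = np.array(initial, dtype=np.float64)
    # relative-change denominators floored at ~1% of low-normal levels so that
    # hormones decaying to zero (athyreotic T4/T3) do not block convergence
    floor = np.array([0.5, 0.01, 0.01])
    prev = None
    rel = np.inf
    day = 0
    while day < max_days:
        traj = run_course(params, regimen, days=1.0, initial=q, keep_states=True)
        q = traj.states[-1]
        cur = np.array(traj.day_average(-1))
        if prev is not None:
            rel = np.max(np.abs(cur - prev) / np.maximum(np.abs(prev), floor))
        day += 1
        if day >= min_days and rel < early_tol:
            break
        prev = cur
    converged = rel < flag_tol
    if not converged:
        warnings.warn(
            f"steady state not reached after {day} days "
            f"(last day-to-day relative change {rel:.2e})", stacklevel=2,
        )
    t4, t3, tsh = traj.final()
    t4a, t3a, tsha = traj.day_average(-1)
    return SteadyState(t4=t4, t3=t3, tsh=tsh, t4_avg=t4a, t3_avg=t3a, tsh_avg=tsha,
                       converged=converged, days=day)
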