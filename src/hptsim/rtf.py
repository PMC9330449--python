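"""Residual thyroid function (RTF) analysis.

For an untreated hypothyroid patient, steady-state T4, T3 and TSH are
monotone functions of the fraction of normal thyroidal secretion that
remains (TSH decreasing, T4/T3 increasing).  Tabulating these curves over an
RTF grid yields an invertible map: a patient's pre-treatment hormone
measurements locate their (unmeasurable) residual thyroid function.

Following the published protocol, the default curves personalize the
patient's plasma and TSH distribution volumes but hold the fractional T3
clearance at its sex-reference value, which renders the curves essentially
BMI-independent (a universal per-sex chart).  Pass ``scale_k05=True`` to use
the fully personalized model including the allometric clearance update; T3
curves then scale inversely with the personalized clearance and are no
longer BMI-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize_scalar

from .anthropometry import PatientProfile, Sex
from .parameters import ModelParameters, apply_rtf, personalize
from .simulate import initial_condition, steady_state

__all__ = [
    "RTFCurve",
    "RTFEstimate",
    "DEFAULT_CURVE_HEIGHTS",
    "rtf_curve",
    "estimate_rtf",
]

#: Fixed heights (m) used for the published per-sex RTF charts.
DEFAULT_CURVE_HEIGHTS = {Sex.MALE: 1.78, Sex.FEMALE: 1.63}


@dataclass
class RTFCurve:
    """Steady-state hormone levels vs residual thyroid function fraction."""

    rtf_grid: np.ndarray
    t4: np.ndarray            # ug/L
    t3: np.ndarray            # ug/L
    tsh: np.ndarray           # mU/L
    patient: PatientProfile | None = None
    converged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rtf_grid = np.asarray(self.rtf_grid, dtype=float)
        if np.any(np.diff(self.rtf_grid) <= 0):
            raise ValueError("rtf_grid must be strictly increasing")

    def channel(self, name: str) -> np.ndarray:
        return {"t4": self.t4, "t3": self.t3, "tsh": self.tsh}[name]

    def check_monotone(self) -> None:
        """TSH must fall and T4/T3 rise strictly along the grid."""
        if not np.all(np.diff(self.tsh) < 0):
            raise ValueError("TSH curve is not strictly decreasing in RTF")
        for name in ("t4", "t3"):
            if not np.all(np.diff(self.channel(name)) > 0):
                raise ValueError(f"{name} curve is not strictly increasing in RTF")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"rtf": self.rtf_grid, "t4_ugL": self.t4, "t3_ugL": self.t3, "tsh_mUL": self.tsh}
        )

    @classmethod
    def from_frame(cls, df) -> "RTFCurve":
        return cls(rtf_grid=df["rtf"].to_numpy(), t4=df["t4_ugL"].to_numpy(),
                   t3=df["t3_ugL"].to_numpy(), tsh=df["tsh_mUL"].to_numpy())


@dataclass(frozen=True)
class RTFEstimate:
    """Combined and per-channel RTF estimates with clamping diagnostics."""

    rtf: float
    per_channel: dict[str, float]
    clamped: bool


def rtf_curve(
    patient: PatientProfile,
    rtf_grid: np.ndarray | None = None,
    params: ModelParameters | None = None,
    days: int = 50,
    scale_k05: bool = False,
) -> RTFCurve:
    """Steady-state hormone levels of the untreated patient over an RTF grid.

    Each grid point is a 50-day undosed simulation started from the
    patient's euthyroid state with secretion scaled to the RTF fraction.
    """
    if rtf_grid is None:
        rtf_grid = np.arange(0.0, 0.5 + 1e-9, 0.01)
    rtf_grid = np.asarray(rtf_grid, dtype=float)
    if np.any((rtf_grid < 0) | (rtf_grid > 1)):
        raise ValueError("rtf values must lie in [0, 1]")
    base = params or ModelParameters()
    model = personalize(base, patient)
    if not scale_k05:
        model = model.replace(k05=base.k05 if patient.sex is Sex.FEMALE
                              else base.C_M * base.k05)
    ic = initial_condition(model.replace(rtf=1.0))
    t4s, t3s, tshs, conv = [], [], [], []
    for r in rtf_grid:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ss = steady_state(apply_rtf(model, float(r)), None, max_days=days, initial=ic)
        t4s.append(ss.t4_avg)
        t3s.append(ss.t3_avg)
        tshs.append(ss.tsh_avg)
        conv.append(ss.converged)
    if not all(conv):
        warnings.warn(
            f"{conv.count(False)} RTF grid point(s) did not fully converge", stacklevel=2
        )
    return RTFCurve(rtf_grid=rtf_grid, t4=np.array(t4s), t3=np.array(t3s),
                    tsh=np.array(tshs), patient=patient, converged=np.array(conv))


def _channel_inverse(curve: RTFCurve, name: str, value: float) -> tuple[float, bool]:
    """Monotone-interpolation inverse of one hormone channel; clamps at ends."""
    y = curve.channel(name)
    x = curve.rtf_grid
    dy = np.diff(y)
    if not (np.all(dy > 0) or np.all(dy < 0)):
        raise ValueError(f"{name} curve is not monotone; cannot invert")
    if dy[0] < 0:  # TSH: decreasing in rtf
        y, x = y[::-1], x[::-1]
    if value <= y[0]:
        return float(x[0]), value < y[0]
    if value >= y[-1]:
        return float(x[-1]), value > y[-1]
    inv = PchipInterpolator(y, x)
    return float(inv(value)), False


def estimate_rtf(
    observed: "dict[str, float] | float",
    curve: RTFCurve,
    channel: str = "tsh",
) -> RTFEstimate:
    """Estimate RTF from hormone measurements taken before treatment.

    ``observed`` is either a single value for ``channel`` or a dict with any
    of the keys t4/t3/tsh.  With several channels, the combined estimate
    minimizes the sum of squared residuals normalized by each channel's
    curve span; per-channel interpolation inverses are returned alongside.
    Values outside a curve's range clamp to the grid boundary with a
    warning.
    """
    if not isinstance(observed, dict):
        observed = {channel: float(observed)}
    unknown = set(observed) - {"t4", "t3", "tsh"}
    if unknown:
        raise ValueError(f"unknown channels: {sorted(unknown)}")
    if not observed:
        raise ValueError("no observations supplied")

    per, clamped = {}, False
    for name, value in observed.items():
        est, cl = _channel_inverse(curve, name, float(value))
        per[name] = est
        clamped = clamped or cl
    if clamped:
        warnings.warn("observation outside curve range; estimate clamped to grid boundary",
                      stacklevel=2)

    if len(per) == 1:
        combined = next(iter(per.values()))
    else:
        interps = {n: PchipInterpolator(curve.rtf_grid, curve.channel(n)) for n in observed}
        spans = {n: float(np.ptp(curve.channel(n))) for n in observed}

        def loss(r: float) -> float:
            return sum(
                ((float(interps[n](r)) - observed[n]) / spans[n]) ** 2 for n in observed
            )

        res = minimize_scalar(
            loss, bounds=(float(curve.rtf_grid[0]), float(curve.rtf_grid[-1])),
            method="bounded", options={"xatol": 1e-6},
        )
        combined = float(res.x)
    return RTFEstimate(rtf=combined, per_channel=per, clamped=clamped)
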