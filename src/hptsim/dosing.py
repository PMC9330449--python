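"""Dose optimizers for LT4 monotherapy and LT4+LT3 combination therapy.

All optimizers are deterministic exhaustive grid searches over clinically
available tablet strengths (LT4 in 12.5 ug steps from 62.5 to 325 ug; LT3 in
2.5 ug steps from 0 to 20 ug), with ties broken toward the lower dose.

Monotherapy mimics the clinical titration protocol of the validation cohort:
a completely thyroidectomized patient (rtf = 0) is simulated for 42 days per
candidate dose and the dose whose end-of-course TSH is closest to the
1.8 mU/L target (or whose joint |T4 - a|/60 + |TSH - b|/4 score is smallest)
is selected.

Combination therapy targets restoration of all three hormones to their
normal-range midpoints at the 50-day steady state, scored by the symmetric
normalized L1 distance sum_h |h - mid_h| / (halfwidth_h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .anthropometry import PatientProfile, Sex
from .parameters import ModelParameters, apply_rtf, personalize
from .simulate import DoseRegimen, initial_condition, run_course, steady_state

__all__ = [
    "NormalRanges",
    "DoseGrid",
    "ComboScenario",
    "ComboResult",
    "default_combination_scenarios",
    "weight_based_dose",
    "snap_to_grid",
    "optimize_lt4_tsh",
    "t4tsh_objective",
    "optimize_lt4_t4tsh",
    "midpoint_objective",
    "optimize_combo",
    "dose_accuracy",
    "cohort_dose_accuracy",
    "DOSE_ACCURACY_TOLERANCE",
    "BMI_BIN_EDGES",
]

#: A predicted dose counts as correct within this distance (ug) of the
#: clinically determined dose — one tablet step.
DOSE_ACCURACY_TOLERANCE = 12.5

#: BMI bin cut points: <=26, (26, 32), >=32.
BMI_BIN_EDGES = (26.0, 32.0)

DEFAULT_TSH_TARGET = 1.8


@dataclass(frozen=True)
class NormalRanges:
    """Clinical reference intervals used as therapy targets.

    TSH bounds follow the validation protocol (0.5-4.5 mU/L); the T4 upper
    bound is the 105 ug/L normal-range maximum, and the T3 interval is the
    standard clinical total-T3 reference interval (0.8-2.0 ug/L), since no
    T3 bounds are fixed by the protocol.
    """

    tsh: tuple[float, float] = (0.5, 4.5)
    t4: tuple[float, float] = (45.0, 105.0)
    t3: tuple[float, float] = (0.8, 2.0)

    def __post_init__(self) -> None:
        for name in ("tsh", "t4", "t3"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} range must satisfy lower < upper")

    @staticmethod
    def _mid(rng: tuple[float, float]) -> float:
        return 0.5 * (rng[0] + rng[1])

    @property
    def midpoints(self) -> tuple[float, float, float]:
        """(T4, T3, TSH) midpoints."""
        return self._mid(self.t4), self._mid(self.t3), self._mid(self.tsh)

    @property
    def halfwidths(self) -> tuple[float, float, float]:
        return (
            0.5 * (self.t4[1] - self.t4[0]),
            0.5 * (self.t3[1] - self.t3[0]),
            0.5 * (self.tsh[1] - self.tsh[0]),
        )


@dataclass(frozen=True)
class DoseGrid:
    """Strictly increasing candidate dose grids in ug/day."""

    lt4: tuple[float, ...] = tuple(62.5 + 12.5 * i for i in range(22))
    lt3: tuple[float, ...] = tuple(2.5 * i for i in range(9))

    def __post_init__(self) -> None:
        for name in ("lt4", "lt3"):
            g = getattr(self, name)
            if len(g) == 0 or any(b <= a for a, b in zip(g, g[1:])):
                raise ValueError(f"{name} grid must be non-empty and strictly increasing")


def weight_based_dose(weight: float, snap: bool = False) -> float:
    """The conventional 1.6 ug LT4 per kg body weight comparator."""
    if not weight > 0:
        raise ValueError(f"weight must be positive, got {weight}")
    dose = 1.6 * weight
    return snap_to_grid(dose) if snap else dose


def snap_to_grid(dose: float, step: float = 12.5) -> float:
    """Round a dose to the nearest available tablet step."""
    return step * round(dose / step)


def _personalized(patient: PatientProfile, rtf: float,
                  params: ModelParameters | None) -> tuple[ModelParameters, np.ndarray]:
    base = personalize(params or ModelParameters(), patient)
    ic = initial_condition(base.replace(rtf=1.0))
    return apply_rtf(base, rtf), ic


def optimize_lt4_tsh(
    patient: PatientProfile,
    rtf: float = 0.0,
    target_tsh: float = DEFAULT_TSH_TARGET,
    grid: DoseGrid | None = None,
    days: float = 42.0,
    params: ModelParameters | None = None,
) -> float:
    """LT4 monotherapy dose whose day-``days`` TSH is closest to the target.

    The end-of-course value is the trough for once-daily dosing (read just
    before the next dose).  Ties break to the lower dose.
    """
    grid = grid or DoseGrid()
    model, ic = _personalized(patient, rtf, params)
    best_dose, best_err = None, math.inf
    for dose in grid.lt4:
        traj = run_course(model, DoseRegimen.daily(lt4=dose), days=days, initial=ic)
        err = abs(traj.final()[2] - target_tsh)
        if err < best_err:
            best_dose, best_err = dose, err
    if best_dose is None:
        raise RuntimeError("all candidate dose simulations failed")
    return best_dose


def t4tsh_objective(t4: float, tsh: float, a: float, b: float,
                    t4_scale: float = 60.0, tsh_scale: float = 4.0) -> float:
    """Joint target score |T4 - a| / 60 + |TSH - b| / 4 (scales configurable)."""
    return abs(t4 - a) / t4_scale + abs(tsh - b) / tsh_scale


def optimize_lt4_t4tsh(
    patient: PatientProfile,
    a: float | None = None,
    b: float | None = None,
    rtf: float = 0.0,
    grid: DoseGrid | None = None,
    days: float = 42.0,
    params: ModelParameters | None = None,
    ranges: NormalRanges | None = None,
    t4_scale: float = 60.0,
    tsh_scale: float = 4.0,
) -> float:
    """LT4 dose minimizing the joint T4+TSH score on end-of-course values.

    Targets default to the normal-range midpoints when not supplied.
    """
    grid = grid or DoseGrid()
    ranges = ranges or NormalRanges()
    mid_t4, _, mid_tsh = ranges.midpoints
    a = mid_t4 if a is None else a
    b = mid_tsh if b is None else b
    model, ic = _personalized(patient, rtf, params)
    best_dose, best_score = None, math.inf
    for dose in grid.lt4:
        traj = run_course(model, DoseRegimen.daily(lt4=dose), days=days, initial=ic)
        t4, _, tsh = traj.final()
        score = t4tsh_objective(t4, tsh, a, b, t4_scale, tsh_scale)
        if score < best_score:
            best_dose, best_score = dose, score
    if best_dose is None:
        raise RuntimeError("all candidate dose simulations failed")
    return best_dose


def midpoint_objective(
    t4: float, t3: float, tsh: float, ranges: NormalRanges
) -> float:
    """Normalized L1 distance of a hormone triple from the range midpoints."""
    mids = ranges.midpoints
    halves = ranges.halfwidths
    return sum(abs(v - m) / h for v, m, h in zip((t4, t3, tsh), mids, halves))


_SCHEDULES = {
    "daily": DoseRegimen.daily,
    "twice_daily": DoseRegimen.twice_daily,
    "infusion": DoseRegimen.with_infusion,
}


@dataclass(frozen=True)
class ComboResult:
    lt4: float
    lt3: float
    t4: float
    t3: float
    tsh: float
    objective: float
    n_nonconverged: int = 0


def optimize_combo(
    patient: PatientProfile,
    rtf: float,
    schedule: str = "daily",
    grid: DoseGrid | None = None,
    ranges: NormalRanges | None = None,
    days: int = 50,
    params: ModelParameters | None = None,
) -> ComboResult:
    """Exhaustive LT4 x LT3 grid search to the normal-range midpoints.

    Doses are daily amounts; ``twice_daily`` splits them into two half-doses
    12 h apart and ``infusion`` delivers the LT3 amount as a constant plasma
    infusion alongside once-daily oral LT4.  Each candidate pair is scored by
    the normalized midpoint distance of the final-day cycle-averaged T4, T3
    and TSH at the ``days``-day steady state.  Non-convergent candidates are
    excluded; ties break lexicographically toward lower (LT4, LT3).
    """
    if schedule not in _SCHEDULES:
        raise ValueError(f"unknown schedule {schedule!r}; expected one of {sorted(_SCHEDULES)}")
    make_regimen = _SCHEDULES[schedule]
    grid = grid or DoseGrid()
    ranges = ranges or NormalRanges()
    model, ic = _personalized(patient, rtf, params)

    best: ComboResult | None = None
    n_bad = 0
    for lt4 in grid.lt4:
        for lt3 in grid.lt3:
            ss = steady_state(model, make_regimen(lt4, lt3), max_days=days, initial=ic)
            if not ss.converged:
                n_bad += 1
                continue
            score = midpoint_objective(ss.t4_avg, ss.t3_avg, ss.tsh_avg, ranges)
            if best is None or score < best.objective:
                best = ComboResult(lt4=lt4, lt3=lt3, t4=ss.t4_avg, t3=ss.t3_avg,
                                   tsh=ss.tsh_avg, objective=score, n_nonconverged=n_bad)
    if best is None:
        raise RuntimeError("no candidate dose pair reached steady state")
    return ComboResult(**{**best.__dict__, "n_nonconverged": n_bad})


@dataclass(frozen=True)
class ComboScenario:
    """One combination-therapy scenario: patient class x schedule x RTF."""

    sex: Sex
    bmi_class: str
    bmi: float
    height: float
    schedule: str
    rtf: float

    @property
    def patient(self) -> PatientProfile:
        return PatientProfile.from_bmi(self.sex, self.height, self.bmi)


#: BMI classes used for the combination-therapy sweep (underweight, normal,
#: overweight) at the reference heights.
_BMI_CLASSES = (("low", 18.5), ("normal", 23.0), ("high", 29.0))
#: Schedule/RTF pairings of the combination protocol: once daily at 10% RTF,
#: twice daily at 15%, oral LT4 + constant LT3 infusion at 25%.
_SCHEDULE_RTFS = (("daily", 0.10), ("twice_daily", 0.15), ("infusion", 0.25))


def default_combination_scenarios(
    params: ModelParameters | None = None,
) -> list[ComboScenario]:
    """The 18 scenarios: M/F x low/normal/high BMI x schedule-RTF pairing."""
    p = params or ModelParameters()
    out = []
    for sex, height in ((Sex.MALE, p.H_Mref), (Sex.FEMALE, p.H_Fref)):
        for cls_name, bmi in _BMI_CLASSES:
            for schedule, rtf in _SCHEDULE_RTFS:
                out.append(ComboScenario(sex=sex, bmi_class=cls_name, bmi=bmi,
                                         height=height, schedule=schedule, rtf=rtf))
    return out


def run_combination_sweep(
    params: ModelParameters | None = None,
    scenarios: "list[ComboScenario] | None" = None,
    grid: DoseGrid | None = None,
    ranges: NormalRanges | None = None,
    days: int = 50,
    progress: bool = False,
) -> list[tuple[ComboScenario, ComboResult]]:
    """Optimize LT4+LT3 for every combination-therapy scenario (default: 18)."""
    scenarios = scenarios if scenarios is not None else default_combination_scenarios(params)
    out = []
    for i, sc in enumerate(scenarios):
        res = optimize_combo(sc.patient, sc.rtf, sc.schedule, grid=grid,
                             ranges=ranges, days=days, params=params)
        if progress:
            print(f"[{i + 1}/{len(scenarios)}] {sc.sex.value} {sc.bmi_class} "
                  f"{sc.schedule} rtf={sc.rtf:.2f} -> LT4={res.lt4:g} LT3={res.lt3:g}",
                  flush=True)
        out.append((sc, res))
    return out


def dose_accuracy(predicted: float, empirical: float) -> bool:
    """Whether a predicted dose is within one tablet step of the empirical dose."""
    if predicted < 0 or empirical < 0:
        raise ValueError("doses must be non-negative")
    return abs(predicted - empirical) <= DOSE_ACCURACY_TOLERANCE


def _bmi_bin(bmi: float) -> str:
    lo, hi = BMI_BIN_EDGES
    if bmi <= lo:
        return f"BMI <= {lo:g}"
    if bmi < hi:
        return f"{lo:g} < BMI < {hi:g}"
    return f"BMI >= {hi:g}"


def cohort_dose_accuracy(
    predicted: "np.ndarray | list[float]",
    empirical: "np.ndarray | list[float]",
    bmi: "np.ndarray | list[float]",
) -> dict[str, float]:
    """Per-BMI-bin and overall proportions of correct dose predictions.

    Empty bins are reported as NaN.
    """
    predicted = np.asarray(predicted, dtype=float)
    empirical = np.asarray(empirical, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    if not (len(predicted) == len(empirical) == len(bmi)):
        raise ValueError("predicted, empirical and bmi must have equal length")
    correct = np.abs(predicted - empirical) <= DOSE_ACCURACY_TOLERANCE
    lo, hi = BMI_BIN_EDGES
    out: dict[str, float] = {}
    for label, mask in (
        (f"BMI <= {lo:g}", bmi <= lo),
        (f"{lo:g} < BMI < {hi:g}", (bmi > lo) & (bmi < hi)),
        (f"BMI >= {hi:g}", bmi >= hi),
    ):
        out[label] = float(np.mean(correct[mask])) if np.any(mask) else float("nan")
    out["overall"] = float(np.mean(correct)) if len(correct) else float("nan")
    return out
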