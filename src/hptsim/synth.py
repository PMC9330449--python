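"""Synthetic-data generators.

The clinical datasets behind the model (blood-volume anthropometry,
thyroidectomized cohorts with empirical euthyroid LT4 doses, hormone time
courses) are not publicly deposited, so every downstream operation is
exercised on synthetic stand-ins generated here: data are drawn from the
model's own equations plus Gaussian noise, with invented but realistic
covariate distributions.  All generators are pure functions of their
configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .anthropometry import (
    BLOOD_VOLUME_A,
    BLOOD_VOLUME_EXPONENT,
    PatientProfile,
    Sex,
)
from .dosing import DoseGrid, optimize_lt4_tsh, snap_to_grid
from .estimation import CHANNELS, HormoneObservations, SimulationDesign, predict_design
from .parameters import ModelParameters

__all__ = [
    "SynthConfig",
    "synth_blood_volume_data",
    "synth_cohort",
    "synth_timecourses",
    "euthyroid_dose_response_designs",
    "lt3_course_design",
    "config_hash",
]


@dataclass(frozen=True)
class SynthConfig:
    """Shared knobs for the generators; identical config + seed is bit-stable."""

    seed: int = 0
    n: int = 20
    noise_sd: float = 0.0
    #: monotherapy optimizer settings used to generate "empirical" doses
    days: float = 42.0
    grid: DoseGrid = field(default_factory=DoseGrid)
    jitter_steps: int = 1           # empirical dose jitter in +/- 12.5 ug tablet steps

    def hash(self) -> str:
        return config_hash(self)


def config_hash(config) -> str:
    """Short stable hash of a configuration dataclass (for output provenance)."""
    if hasattr(config, "__dataclass_fields__"):
        payload = asdict(config)
    else:
        payload = dict(config)
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def synth_blood_volume_data(
    n_per_sex: int = 80,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic per-kg blood volume vs percent deviation from ideal weight.

    Emulates the structure of the anthropometric source data (equal male and
    female groups spanning underweight to obese): percent deviations uniform
    on [-40, 100]%, per-kg blood volume from the fitted power law
    1000 a (100 + d)^(n-1) ml/kg plus Gaussian noise (``noise_sd`` in ml/kg).
    """
    if n_per_sex < 2:
        raise ValueError("need at least 2 patients per sex")
    rng = np.random.default_rng(seed)
    rows = []
    for sex in (Sex.MALE, Sex.FEMALE):
        dev = rng.uniform(-40.0, 100.0, size=n_per_sex)
        vb_per_kg = 1000.0 * BLOOD_VOLUME_A * (100.0 + dev) ** (BLOOD_VOLUME_EXPONENT - 1.0)
        vb_per_kg = vb_per_kg + rng.normal(0.0, noise_sd, size=n_per_sex)
        rows.append(pd.DataFrame(
            {"sex": sex.value, "pct_dev_ibw": dev, "vb_ml_per_kg": vb_per_kg}
        ))
    return pd.concat(rows, ignore_index=True)


def synth_cohort(
    n: int = 20,
    seed: int = 0,
    config: SynthConfig | None = None,
    params: ModelParameters | None = None,
    with_doses: bool = True,
) -> pd.DataFrame:
    """Synthetic thyroidectomized cohort with empirical euthyroid LT4 doses.

    Covariates are invented (the source cohort's distributions are not
    published): sex Bernoulli(1/2); height normal by sex (1.76 m / 1.63 m
    means, sd 0.07 m); BMI log-normal with median 26 (log-sd 0.2).  The
    "empirical" dose is the model's own 42-day TSH-targeted optimum for the
    patient plus a seeded jitter of up to ``jitter_steps`` tablet steps
    (+/- 12.5 ug each), so at zero jitter the dose-prediction accuracy of
    the optimizer is 1.0 by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = config or SynthConfig(seed=seed, n=n)
    rng = np.random.default_rng(seed)
    sexes = rng.choice([Sex.MALE.value, Sex.FEMALE.value], size=n)
    heights = np.where(
        np.asarray(sexes) == Sex.MALE.value,
        rng.normal(1.76, 0.07, size=n),
        rng.normal(1.63, 0.07, size=n),
    ).round(3)
    bmis = np.exp(rng.normal(np.log(26.0), 0.2, size=n))
    weights = (bmis * heights**2).round(1)
    df = pd.DataFrame({
        "patient_id": np.arange(n),
        "sex": sexes,
        "height_m": heights,
        "weight_kg": weights,
    })
    df["bmi"] = df["weight_kg"] / df["height_m"] ** 2
    if with_doses:
        doses, empirical = [], []
        steps = rng.integers(-cfg.jitter_steps, cfg.jitter_steps + 1, size=n)
        for i in range(n):
            pat = PatientProfile(sexes[i], float(heights[i]), float(weights[i]))
            dose = optimize_lt4_tsh(pat, rtf=0.0, grid=cfg.grid, days=cfg.days,
                                    params=params)
            doses.append(dose)
            empirical.append(max(dose + 12.5 * float(steps[i]), cfg.grid.lt4[0]))
        df["predicted_dose_ug"] = doses
        df["empirical_dose_ug"] = empirical
    return df


def euthyroid_dose_response_designs(
    doses_ug: tuple[float, ...] = (400.0, 450.0, 600.0),
    duration_h: float = 120.0,
    dose_time_h: float = 24.0,
) -> list[SimulationDesign]:
    """The euthyroid protocol: single oral LT4 doses at hour 24, 5-day courses,
    simulated for the calibration reference (unpersonalized volumes)."""
    return [
        SimulationDesign(events=((dose_time_h, d, 0.0),), duration_h=duration_h)
        for d in doses_ug
    ]


def lt3_course_design(
    patient: PatientProfile,
    lt3_dose_ug: float = 50.0,
    duration_h: float = 8.0,
    rtf: float = 0.0,
) -> SimulationDesign:
    """An 8-hour LT3 replacement time course for a hypothyroid patient."""
    return SimulationDesign(events=((0.0, 0.0, lt3_dose_ug),),
                            duration_h=duration_h, patient=patient, rtf=rtf)


def synth_timecourses(
    params: ModelParameters,
    design: SimulationDesign,
    sample_times_h: "np.ndarray | dict[str, np.ndarray]",
    sigmas: "dict[str, float] | float" = 0.0,
    seed: int = 0,
) -> HormoneObservations:
    """Noisy hormone observations generated from the model itself.

    ``sample_times_h`` is either one grid shared by all channels or a
    per-channel dict; ``sigmas`` a scalar or per-channel dict of Gaussian
    noise standard deviations (same units as the channel).  Negative noisy
    draws are truncated at zero, as an assay would report.
    """
    if not isinstance(sample_times_h, dict):
        sample_times_h = {ch: np.asarray(sample_times_h, float) for ch in CHANNELS}
    if not isinstance(sigmas, dict):
        sigmas = {ch: float(sigmas) for ch in CHANNELS}
    rng = np.random.default_rng(seed)
    skeleton = HormoneObservations.from_arrays(
        {ch: (t, np.zeros_like(t)) for ch, t in sample_times_h.items() if len(t)}
    )
    preds = predict_design(params, design, skeleton)
    data = {}
    for ch, t in sample_times_h.items():
        if len(t) == 0:
            continue
        mu = preds[ch]
        noisy = mu + rng.normal(0.0, sigmas.get(ch, 0.0), size=len(mu))
        data[ch] = (np.asarray(t, float), np.maximum(noisy, 0.0))
    return HormoneObservations.from_arrays(data)
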