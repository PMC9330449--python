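"""Anthropometry-driven personalization of circulatory volumes and T3 clearance.

A patient's sex, height and body weight determine three quantities that the
HPT-axis model is sensitive to:

* blood volume ``V_B`` and plasma volume ``V_P = V_B (1 - HEM)``, via a
  two-parameter power law in the percent deviation from a sex- and
  height-specific ideal body weight;
* the TSH distribution volume, plasma plus a fixed 2.0 L of non-vascular
  tissue space;
* the fractional T3 clearance rate ``k05``, scaled allometrically with body
  weight (exponent 3/4) and a male/female asymmetry factor.

Because the base model was calibrated at a nominal 3.2 L plasma volume, raw
plasma volumes are rescaled so that an average reference male/female patient
maps exactly onto 3.2 L (and 5.2 L for TSH).

All functions here are deterministic and pure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import ModelParameters

__all__ = [
    "Sex",
    "PatientProfile",
    "VolumeSet",
    "BLOOD_VOLUME_A",
    "BLOOD_VOLUME_EXPONENT",
    "ideal_body_weight",
    "pct_deviation_ibw",
    "blood_volume",
    "plasma_volume_raw",
    "reference_plasma_volume",
    "plasma_volume_scaled",
    "tsh_distribution_volume",
    "t3_clearance_scaled",
    "volume_set",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def parse(cls, value: "str | Sex") -> "Sex":
        if isinstance(value, Sex):
            return value
        v = str(value).strip().lower()
        if v in {"m", "male"}:
            return cls.MALE
        if v in {"f", "female"}:
            return cls.FEMALE
        raise ValueError(f"cannot parse sex from {value!r} (expected m/f/male/female)")


#: Fitted coefficient of the per-kg blood-volume power law (dimensionless).
BLOOD_VOLUME_A = 1.27
#: Fitted exponent; < 1 so per-kg blood volume falls with excess weight.
BLOOD_VOLUME_EXPONENT = 0.373

#: Default hematocrit by sex (volume fraction of red cells in blood).
DEFAULT_HEMATOCRIT = {Sex.MALE: 0.45, Sex.FEMALE: 0.40}

#: Non-vascular tissue volume into which TSH distributes (liters), implicit in
#: the 5.2 L reference TSH volume minus the 3.2 L reference plasma volume.
TSH_TISSUE_VOLUME = 2.0

_HEIGHT_WARN_RANGE = (1.2, 2.2)


@dataclass(frozen=True)
class PatientProfile:
    """Sex, height (m), body weight (kg) and optional hematocrit override.

    ``hematocrit`` defaults to 0.45 for males and 0.40 for females when not
    supplied.  ``bmi`` is derived as weight / height**2.
    """

    sex: Sex
    height: float
    weight: float
    hematocrit: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex.parse(self.sex))
        if not self.height > 0:
            raise ValueError(f"height must be positive, got {self.height}")
        if not self.weight > 0:
            raise ValueError(f"weight must be positive, got {self.weight}")
        if self.hematocrit is None:
            object.__setattr__(self, "hematocrit", DEFAULT_HEMATOCRIT[self.sex])
        if not 0.0 < self.hematocrit < 1.0:
            raise ValueError(f"hematocrit must lie in (0, 1), got {self.hematocrit}")

    @property
    def bmi(self) -> float:
        return self.weight / self.height**2

    @classmethod
    def from_bmi(
        cls, sex: "str | Sex", height: float, bmi: float, hematocrit: float | None = None
    ) -> "PatientProfile":
        """Build a profile with weight implied by a target BMI."""
        return cls(sex=Sex.parse(sex), height=height, weight=bmi * height**2, hematocrit=hematocrit)


@dataclass(frozen=True)
class VolumeSet:
    """Personalized circulatory volumes, all in liters."""

    v_b: float
    v_p: float
    v_p_new: float
    v_tsh_new: float

    def __post_init__(self) -> None:
        for name in ("v_b", "v_p", "v_p_new", "v_tsh_new"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def ideal_body_weight(height: float, sex: "str | Sex") -> float:
    """Sex-specific quadratic ideal body weight (kg) as a function of height (m)."""
    sex = Sex.parse(sex)
    if not height > 0:
        raise ValueError(f"height must be positive, got {height}")
    lo, hi = _HEIGHT_WARN_RANGE
    if not lo <= height <= hi:
        warnings.warn(
            f"height {height} m outside the supported range [{lo}, {hi}] m; "
            "the ideal-weight quadratic is extrapolated",
            stacklevel=2,
        )
    if sex is Sex.MALE:
        return 176.3 - 220.6 * height + 93.5 * height**2
    return 145.8 - 182.7 * height + 79.55 * height**2


def pct_deviation_ibw(weight: float, height: float, sex: "str | Sex") -> float:
    """Percent deviation of body weight from the ideal weight, relative to ideal."""
    if not weight > 0:
        raise ValueError(f"weight must be positive, got {weight}")
    ibw = ideal_body_weight(height, sex)
    return 100.0 * (weight - ibw) / ibw


def blood_volume(weight: float, height: float, sex: "str | Sex") -> float:
    """Total blood volume in liters, V_B = a (100 + dIBW)^(n-1) BW."""
    dev = pct_deviation_ibw(weight, height, sex)
    if 100.0 + dev <= 0:
        raise ValueError(
            f"non-physical weight: percent deviation from ideal weight is {dev:.1f}%"
        )
    return BLOOD_VOLUME_A * (100.0 + dev) ** (BLOOD_VOLUME_EXPONENT - 1.0) * weight


def plasma_volume_raw(
    weight: float, height: float, sex: "str | Sex", hematocrit: float | None = None
) -> float:
    """Plasma volume in liters, V_P = V_B (1 - HEM)."""
    sex = Sex.parse(sex)
    if hematocrit is None:
        hematocrit = DEFAULT_HEMATOCRIT[sex]
    if not 0.0 < hematocrit < 1.0:
        raise ValueError(f"hematocrit must lie in (0, 1), got {hematocrit}")
    return blood_volume(weight, height, sex) * (1.0 - hematocrit)


def _patient_plasma_volume(patient: PatientProfile) -> float:
    return plasma_volume_raw(patient.weight, patient.height, patient.sex, patient.hematocrit)


def reference_plasma_volume(params: "ModelParameters") -> float:
    """Average plasma volume of the reference male and female patients.

    Reference weights follow from the fitted reference BMIs and heights via
    BW_ref = BMI_ref * H_ref**2 (default male 67.53 kg at 1.76 m, female
    64.14 kg at 1.67 m), with default hematocrits.
    """
    bw_m = params.BMI_Mref * params.H_Mref**2
    bw_f = params.BMI_Fref * params.H_Fref**2
    vp_m = plasma_volume_raw(bw_m, params.H_Mref, Sex.MALE)
    vp_f = plasma_volume_raw(bw_f, params.H_Fref, Sex.FEMALE)
    return 0.5 * (vp_m + vp_f)


def plasma_volume_scaled(patient: PatientProfile, params: "ModelParameters") -> float:
    """Plasma volume rescaled onto the base model's 3.2 L reference scale."""
    v_pref = reference_plasma_volume(params)
    return params.Vp_base * _patient_plasma_volume(patient) / v_pref


def tsh_distribution_volume(v_p_new: float) -> float:
    """TSH distribution volume: 5.2 L reference shifted by the plasma change."""
    if not v_p_new > 0:
        raise ValueError(f"v_p_new must be positive, got {v_p_new}")
    v = 5.2 + (v_p_new - 3.2)
    if v <= 0:
        raise ValueError(f"TSH distribution volume is non-positive ({v:.3f} L)")
    return v


def t3_clearance_scaled(patient: PatientProfile, params: "ModelParameters") -> float:
    """Allometrically scaled fractional T3 clearance rate (per hour).

    Three-quarter-power scaling in body weight relative to the sex-matched
    reference weight, with the multiplier C_M applied to males only.
    """
    if patient.sex is Sex.MALE:
        bw_ref = params.BMI_Mref * params.H_Mref**2
        return params.C_M * params.k05 * (patient.weight / bw_ref) ** 0.75
    bw_ref = params.BMI_Fref * params.H_Fref**2
    return params.k05 * (patient.weight / bw_ref) ** 0.75


def volume_set(patient: PatientProfile, params: "ModelParameters") -> VolumeSet:
    """All personalized volumes for a patient in one call."""
    v_b = blood_volume(patient.weight, patient.height, patient.sex)
    v_p = v_b * (1.0 - patient.hematocrit)
    v_p_new = plasma_volume_scaled(patient, params)
    return VolumeSet(v_b=v_b, v_p=v_p, v_p_new=v_p_new, v_tsh_new=tsh_distribution_volume(v_p_new))
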