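"""Model parameters: base kinetic constants plus the refitted submodel values.

The parameter set combines two layers:

* the base THYROSIM-family compartmental constants (transport and clearance
  rates, free-hormone binding polynomials, deiodinase Michaelis--Menten
  constants, gut absorption kinetics, the TSH delay chain) calibrated for a
  nominal mixed-sex normal-weight adult with 3.2 L plasma and a 5.2 L TSH
  distribution volume;
* the personalized-model re-estimates and new Hill-function parameters for
  the brain--pituitary TSH submodel (S4, VmaxD1_fast, k05, A0, B0, k3,
  K_circ, K_SR_TSH, n, m, K_f4, l) together with the anthropometric reference
  parameters (BMI_Mref, BMI_Fref, H_Mref, H_Fref, C_M).

``personalize`` substitutes the patient-specific plasma volume, TSH
distribution volume and T3 clearance; ``apply_rtf`` scales the thyroidal T4
and T3 secretion rates by the residual-thyroid-function fraction.

Parameter sets serialize to flat YAML/JSON key--value mappings and round-trip
losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .anthropometry import (
    PatientProfile,
    plasma_volume_scaled,
    t3_clearance_scaled,
    tsh_distribution_volume,
)

__all__ = [
    "ModelParameters",
    "personalize",
    "apply_rtf",
    "MW_T4",
    "MW_T3",
    "TSH_MU_PER_UMOL",
]

#: Molecular weights used to convert compartment amounts (umol) to mass (ug).
MW_T4 = 777.0
MW_T3 = 651.0
#: Conversion from the TSH compartment's internal units to mU.
TSH_MU_PER_UMOL = 5.6


@dataclass(frozen=True)
class ModelParameters:
    # --- thyroidal secretion (scaled by rtf) ---
    S4: float = 0.00278          # T4 secretion per unit delayed TSH (umol/h per unit)
    S3: float = 3.3572e-4        # T3 secretion per unit delayed TSH

    # --- T4 distribution and clearance ---
    k12: float = 0.868           # fast tissue -> plasma T4 return (1/h)
    k13: float = 0.108           # slow tissue -> plasma T4 return (1/h)
    k31free: float = 584.0       # plasma free T4 -> slow tissue (1/h on free amount)
    k21free: float = 1503.0      # plasma free T4 -> fast tissue
    k02: float = 0.0189          # irreversible T4 clearance from fast tissue (1/h)
    A: float = 0.000289          # free-T4 fraction cubic in plasma T4 amount
    B: float = 0.000214
    C: float = 0.000128
    D: float = -8.83e-6

    # --- deiodinase conversion T4 -> T3 ---
    VmaxD1fast: float = 0.0121   # fast-tissue D1 Vmax (umol/h)
    KmD1fast: float = 2.85
    VmaxD1slow: float = 6.63e-4
    KmD1slow: float = 95.0
    VmaxD2slow: float = 7.4619e-4
    KmD2slow: float = 0.075

    # --- T3 distribution and clearance ---
    k45: float = 5.37            # fast tissue -> plasma T3 return (1/h)
    k46: float = 0.0689          # slow tissue -> plasma T3 return (1/h)
    k64free: float = 127.0       # plasma free T3 -> slow tissue
    k54free: float = 2043.0      # plasma free T3 -> fast tissue
    k05: float = 0.185           # irreversible T3 clearance from fast tissue (1/h)
    a: float = 0.00395           # free-T3 fraction cubic in plasma T3 amount
    b: float = 0.00185
    c: float = 0.00061
    d: float = -0.000505

    # --- TSH secretion and degradation (brain-pituitary submodel) ---
    B0: float = 450.0            # mean TSH secretion rate
    A0: float = 220.0            # maximum circadian oscillation amplitude
    phi: float = -3.71           # circadian phase (h-equivalent radians offset)
    K_SR_TSH: float = 3.1        # Hill midpoint of the brain-T3 suppressor
    m: float = 6.29              # Hill exponent of the suppressor
    K_circ: float = 3.0          # Hill midpoint of the circadian amplitude gate
    n: float = 5.68              # Hill exponent of the amplitude gate
    kdegTSH_HYPO: float = 0.53   # basal TSH degradation (1/h)
    VmaxTSH: float = 0.226       # saturable TSH degradation Vmax
    K50TSH: float = 23.0

    # --- lumped brain T3 and its lag ---
    k3: float = 0.0589           # brain T4->T3 conversion gain floor
    K_f4: float = 8.5            # Hill midpoint of the brain conversion gain
    l: float = 14.4              # Hill exponent of the brain conversion gain
    T4P_EU: float = 0.29         # euthyroid plasma T4 amount normalizer (umol)
    T3P_EU: float = 0.006        # euthyroid plasma T3 amount normalizer (umol)
    KdegT3B: float = 0.037       # brain T3 turnover (1/h)
    KLAG_HYPO: float = 0.0034    # hypothyroid (slow) lag rate (1/h)
    KLAG: float = 5.0            # Hill midpoint of the lag-rate switch

    # --- oral absorption ---
    k4dissolve: float = 1.3      # T4 pill dissolution (1/h)
    k4absorb: float = 0.881      # T4 gut -> plasma absorption (1/h)
    k4excrete: float = 0.119     # T4 gut excretion (1/h); bioavailability 0.88
    k3dissolve: float = 1.78
    k3absorb: float = 0.881
    k3excrete: float = 0.118

    # --- anthropometric reference parameters ---
    BMI_Mref: float = 21.8
    BMI_Fref: float = 23.0
    H_Mref: float = 1.76
    H_Fref: float = 1.67
    C_M: float = 1.05            # male multiplier on the allometric k05 scaling

    # --- volumes (replaced during personalization) ---
    Vp: float = 3.2              # plasma volume (L)
    VTSH: float = 5.2            # TSH distribution volume (L)
    Vp_base: float = 3.2         # calibration reference plasma volume (L)
    VTSH_base: float = 5.2       # calibration reference TSH volume (L)

    # --- residual thyroid function ---
    rtf: float = 1.0             # fraction of normal thyroidal secretion

    def __post_init__(self) -> None:
        if not 0.0 <= self.rtf <= 1.0:
            raise ValueError(f"rtf must lie in [0, 1], got {self.rtf}")
        for name in ("n", "m", "l"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"Hill exponent {name} must be >= 1")
        for name in (
            "S4", "S3", "B0", "A0", "K_circ", "K_SR_TSH", "K_f4", "k3",
            "k05", "VmaxD1fast", "Vp", "VTSH",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")

    # -- construction helpers ------------------------------------------------

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, data: dict[str, float]) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: "str | Path | None" = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: "str | Path") -> "ModelParameters":
        text = str(source)
        if isinstance(source, Path) or ("\n" not in text and Path(text).exists()):
            text = Path(source).read_text()
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "ModelParameters":
        return cls.from_dict(json.loads(text))

    # -- engine vector -------------------------------------------------------

    def to_vector(self, t4_infusion: float = 0.0, t3_infusion: float = 0.0) -> np.ndarray:
        """Flat float64 vector consumed by the compiled right-hand side.

        Infusion rates are in umol/h delivered directly to plasma.
        """
        return np.array(
            [
                self.S4, self.k12, self.k13, self.k31free, self.k21free,
                self.A, self.B, self.C, self.D,
                self.k4absorb, self.k02,
                self.VmaxD1fast, self.KmD1fast,
                self.VmaxD1slow, self.KmD1slow,
                self.VmaxD2slow, self.KmD2slow,
                self.S3, self.k45, self.k46, self.k64free, self.k54free,
                self.a, self.b, self.c, self.d,
                self.k3absorb, self.k05,
                self.B0, self.A0, self.phi,
                self.kdegTSH_HYPO, self.VmaxTSH, self.K50TSH,
                self.k3, self.T4P_EU, self.T3P_EU, self.KdegT3B,
                self.KLAG_HYPO, self.KLAG,
                self.k4dissolve, self.k4excrete, self.k3dissolve, self.k3excrete,
                self.Vp, self.VTSH,
                self.K_circ, self.K_SR_TSH, self.n, self.m, self.K_f4, self.l,
                self.rtf, t4_infusion, t3_infusion,
                self.Vp_base, self.VTSH_base,
            ],
            dtype=np.float64,
        )


def personalize(params: ModelParameters, patient: PatientProfile) -> ModelParameters:
    """Substitute patient-specific volumes and T3 clearance into a parameter set.

    Replaces ``Vp`` with the rescaled plasma volume, ``VTSH`` with the shifted
    TSH distribution volume and ``k05`` with the allometrically scaled
    clearance; every other parameter is left unchanged.
    """
    v_p_new = plasma_volume_scaled(patient, params)
    return params.replace(
        Vp=v_p_new,
        VTSH=tsh_distribution_volume(v_p_new),
        k05=t3_clearance_scaled(patient, params),
    )


def apply_rtf(params: ModelParameters, rtf: float) -> ModelParameters:
    """Scale thyroidal T4 and T3 secretion by a residual-function fraction."""
    if not 0.0 <= rtf <= 1.0:
        raise ValueError(f"rtf must lie in [0, 1], got {rtf}")
    return params.replace(rtf=rtf)
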