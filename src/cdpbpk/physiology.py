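"""Species- and age-dependent anatomy and physiology.

Compartment volumes are expressed as fractions of body weight (assuming unit
tissue density, so 1 kg of tissue occupies 1 L), blood flows as fractions of
cardiac output, and cardiac output / alveolar ventilation scale allometrically
with body weight.  Body weight itself may come from a whole-life polynomial
growth model; the default model is a static adult (0.25 kg rat, 70 kg human),
which is the regime every shipped scenario uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "SpeciesPhysiology",
    "GrowthModel",
    "physiology_at_age",
    "allometric_flows",
    "diet_ppm_to_dose",
    "ADULT_RAT_BW_KG",
    "ADULT_HUMAN_BW_KG",
]

ADULT_RAT_BW_KG = 0.25
ADULT_HUMAN_BW_KG = 70.0

#: Allometric exponent for cardiac output and alveolar ventilation.
FLOW_EXPONENT = 0.74
#: Default allometric constants, L/h per kg^0.74.
QCC_DEFAULT = 15.0
QPC_DEFAULT = 15.0

#: Mass fraction of the body (bone, hair, gut content) treated as
#: non-perfused; the rest-of-body compartment absorbs the remainder of the
#: perfused mass not assigned to a named compartment.
NON_PERFUSED_FRACTION = 0.09

# Tissue volumes as fractions of body weight (Brown et al.-style reference
# values) and perfusion as fractions of cardiac output.  Hepatic flow is the
# total (arterial + portal) flow since the gut is a pseudo-compartment.
_VOLUME_FRACTIONS = {
    "rat": {
        "blood": 0.074,
        "brain": 0.0057,
        "skin": 0.190,
        "adipose": 0.076,
        "liver": 0.0366,
    },
    "human": {
        "blood": 0.079,
        "brain": 0.020,
        "skin": 0.0371,
        "adipose": 0.190,
        "liver": 0.026,
    },
}

_FLOW_FRACTIONS = {
    "rat": {
        "brain": 0.020,
        "skin": 0.058,
        "adipose": 0.070,
        "liver": 0.183,
    },
    "human": {
        "brain": 0.114,
        "skin": 0.058,
        "adipose": 0.052,
        "liver": 0.227,
    },
}

#: Vascular (tissue-blood) sub-compartment volume, as a fraction of the
#: tissue volume, for the permeability-limited compartments.
_TISSUE_BLOOD_FRACTIONS = {
    "brain": 0.03,
    "skin": 0.03,
    "adipose": 0.02,
    "liver": 0.15,
}

PERMEABILITY_LIMITED = ("brain", "skin", "adipose", "liver")


@dataclass(frozen=True)
class SpeciesPhysiology:
    """Resolved anatomy/physiology for one individual at one age.

    All volumes are litres (unit density), flows L/h.
    """

    species: str
    age_years: float
    body_weight_kg: float
    volume_fractions: Mapping[str, float]  # fraction of BW per compartment
    tissue_blood_fractions: Mapping[str, float]
    cardiac_output: float  # QC, L/h
    alveolar_ventilation: float  # QP, L/h
    flow_fractions: Mapping[str, float]  # fraction of QC per compartment

    def __post_init__(self):
        if self.species not in ("rat", "human"):
            raise ValueError(f"unknown species: {self.species!r}")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be positive")
        if self.cardiac_output <= 0 or self.alveolar_ventilation <= 0:
            raise ValueError("QC and QP must be positive")
        vsum = sum(self.volume_fractions.values())
        if any(v <= 0 for v in self.volume_fractions.values()) or vsum > 1.0:
            raise ValueError("volume fractions must be positive and sum to <= 1")
        fsum = sum(self.flow_fractions.values())
        if abs(fsum - 1.0) > 1e-9:
            raise ValueError(f"flow fractions must sum to 1, got {fsum}")

    # -- derived quantities -------------------------------------------------
    def volume(self, compartment: str) -> float:
        """Absolute compartment volume in litres."""
        return self.volume_fractions[compartment] * self.body_weight_kg

    def flow(self, compartment: str) -> float:
        """Blood flow to a compartment in L/h."""
        return self.flow_fractions[compartment] * self.cardiac_output

    def tissue_blood_volume(self, compartment: str) -> float:
        return self.volume(compartment) * self.tissue_blood_fractions[compartment]

    def tissue_matrix_volume(self, compartment: str) -> float:
        return self.volume(compartment) * (1.0 - self.tissue_blood_fractions[compartment])

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["volume_fractions"] = dict(self.volume_fractions)
        d["tissue_blood_fractions"] = dict(self.tissue_blood_fractions)
        d["flow_fractions"] = dict(self.flow_fractions)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SpeciesPhysiology":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SpeciesPhysiology":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class GrowthModel:
    """Polynomial age models for physiological quantities.

    ``coefficients`` maps a quantity name (currently only ``body_weight``)
    to ascending polynomial coefficients in age (years).  Evaluation outside
    ``age_range`` is refused; evaluation must return a positive value.
    """

    coefficients: Mapping[str, tuple]
    age_range: tuple = (0.0, 100.0)
    source: str = "static adult"

    def evaluate(self, quantity: str, age_years: float) -> float:
        lo, hi = self.age_range
        if not (lo <= age_years <= hi):
            raise ValueError(
                f"age {age_years} y outside the growth model's valid range [{lo}, {hi}]"
            )
        coeffs = self.coefficients[quantity]
        value = float(np.polynomial.polynomial.polyval(age_years, np.asarray(coeffs, float)))
        if value <= 0:
            raise ValueError(f"growth model returned non-positive {quantity} at age {age_years}")
        return value

    @classmethod
    def static_adult(cls, species: str) -> "GrowthModel":
        bw = {"rat": ADULT_RAT_BW_KG, "human": ADULT_HUMAN_BW_KG}[species]
        return cls(coefficients={"body_weight": (bw,)}, source="static adult")


def allometric_flows(body_weight_kg: float,
                     qcc: float = QCC_DEFAULT,
                     qpc: float = QPC_DEFAULT) -> tuple[float, float]:
    """Cardiac output and alveolar ventilation (L/h) from body weight.

    QC = QCC * BW**0.74 and QP = QPC * BW**0.74.
    """
    if body_weight_kg <= 0 or qcc <= 0 or qpc <= 0:
        raise ValueError("body weight and allometric constants must be positive")
    scale = body_weight_kg ** FLOW_EXPONENT
    return qcc * scale, qpc * scale


def physiology_at_age(species: str,
                      age_years: float = 25.0,
                      growth_model: GrowthModel | None = None,
                      *,
                      body_weight_kg: float | None = None,
                      qcc: float = QCC_DEFAULT,
                      qpc: float = QPC_DEFAULT) -> SpeciesPhysiology:
    """Resolve a full physiology for one species at one age.

    With the default (static adult) growth model any age yields the adult
    reference body weight (rat 0.25 kg, human 70 kg).  An explicit
    ``body_weight_kg`` overrides the growth model entirely.
    """
    if species not in _VOLUME_FRACTIONS:
        raise ValueError(f"unknown species: {species!r}")
    if body_weight_kg is None:
        gm = growth_model or GrowthModel.static_adult(species)
        body_weight_kg = gm.evaluate("body_weight", age_years)
    qc, qp = allometric_flows(body_weight_kg, qcc, qpc)

    vf = dict(_VOLUME_FRACTIONS[species])
    named = sum(vf.values())
    rest = 1.0 - NON_PERFUSED_FRACTION - named
    if rest <= 0:
        raise ValueError("named volume fractions exceed the perfused mass")
    vf["rest"] = rest

    ff = dict(_FLOW_FRACTIONS[species])
    ff["rest"] = 1.0 - sum(ff.values())

    return SpeciesPhysiology(
        species=species,
        age_years=age_years,
        body_weight_kg=body_weight_kg,
        volume_fractions=vf,
        tissue_blood_fractions=dict(_TISSUE_BLOOD_FRACTIONS),
        cardiac_output=qc,
        alveolar_ventilation=qp,
        flow_fractions=ff,
    )


def diet_ppm_to_dose(diet_ppm: float, food_intake_kg_per_day: float,
                     body_weight_kg: float) -> float:
    """Convert a dietary concentration (mg chemical / kg food) to mg/kg bw/day."""
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    if diet_ppm < 0 or food_intake_kg_per_day < 0:
        raise ValueError("dietary inputs must be non-negative")
    return diet_ppm * food_intake_kg_per_day / body_weight_kg
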