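"""Chemical-specific parameters of the chlordecone PBPK model.

The parameter vector covers tissue:blood partitioning, permeability–area
products for the four permeability-limited tissues, blood protein binding,
gastrointestinal absorption and transit, biliary excretion coupled to
hepatic CDBP binding, enterohepatic reabsorption, lumen reconversion of the
biliary metabolite, enteric and urinary excretion.

Retention fractions (``ka``, ``f_reab``, ``f_reconv``) are *realized* as
first-order uptake rates competing with the lumen transit rate ``kst``.
Each rate is anchored at a frozen reference transit rate ``kst_ref`` so
that, at the nominal transit rate, the realized fraction equals the stated
parameter value; a faster transit then genuinely reduces net absorption and
enterohepatic return.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields, replace
from typing import Mapping

import yaml

__all__ = ["PBPKParameters", "rat_default", "human_default", "rate_from_fraction"]

_FRACTION_FIELDS = ("bind", "ka", "f_prox", "f_dist", "f_lymph",
                    "kbile", "f_reab", "f_reconv")
_RATE_CAP = 1e6  # cap on fraction-derived rates, 1/h, to keep the ODE stiffness bounded


def rate_from_fraction(fraction: float, kst_ref: float) -> float:
    """First-order uptake rate realizing ``fraction`` against transit ``kst_ref``.

    Solves k/(k + kst_ref) = fraction; fractions at or above 1 map to a
    large capped rate, fractions at or below 0 to 0.
    """
    if fraction <= 0.0:
        return 0.0
    if fraction >= 1.0:
        return _RATE_CAP
    return min(fraction / (1.0 - fraction) * kst_ref, _RATE_CAP)


@dataclass(frozen=True)
class PBPKParameters:
    """Full chemical-specific parameter vector (units in field comments)."""

    # tissue:blood partition coefficients, relative to *free* blood concentration
    p_brain: float
    p_skin: float
    p_adipose: float  # "PF": adipose is the deep storage depot
    p_liver: float
    p_rest: float
    # permeability-area products, L/h
    pa_brain: float
    pa_skin: float
    pa_adipose: float
    pa_liver: float
    # blood binding
    bind: float  # bound fraction of CD in blood, [0, 1)
    # gastrointestinal absorption
    ka: float            # absorbed fraction of an oral dose at nominal transit, (0, 1]
    f_prox: float = 1.0  # share of absorbed flux entering at the proximal segment,
    f_dist: float = 0.0  # where lacteal (lymphatic) uptake occurs; distal share is portal-only
    f_lymph: float = 0.3   # fraction of absorbed flux routed to lymph (vs portal)
    k_lymph: float = 0.2   # lymph-to-venous transfer rate, 1/h
    kst: float = 0.3       # lumen transit rate, 1/h
    kst_ref: float = 0.3   # frozen reference transit anchoring the fractions, 1/h
    # biliary elimination and the enterohepatic loop
    cl_bile: float = 0.0   # biliary clearance of CDBP-bound liver CD, L/h
    kbile: float = 0.0     # fraction of biliary output leaving as metabolite
    f_reab: float = 0.95   # fraction of biliary parent reabsorbed at nominal transit
    f_reconv: float = 0.0  # lumen deconjugation/reconversion efficiency of metabolite
    # other excretion
    k_ent: float = 0.0     # enteric (blood -> distal lumen) clearance of free CD, L/h
    k_urine: float = 0.0   # urinary clearance of free CD, L/h
    # hepatic CDBP binding
    libmaxcd1: float = 0.0  # CDBP binding capacity, ug per L liver tissue
    kd_liv: float = 500.0   # CDBP dissociation constant, ug/L
    # unvalidated exposure-route placeholders
    kp_dermal: float = 0.0  # dermal permeation transfer, L/h (shipped disabled)

    def __post_init__(self):
        for name in _FRACTION_FIELDS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.bind >= 1.0:
            raise ValueError("bind must be < 1")
        if self.ka <= 0.0:
            raise ValueError("ka must be > 0")
        if abs(self.f_prox + self.f_dist - 1.0) > 1e-12:
            raise ValueError("f_prox + f_dist must equal 1")
        for name in ("p_brain", "p_skin", "p_adipose", "p_liver", "p_rest",
                     "pa_brain", "pa_skin", "pa_adipose", "pa_liver",
                     "k_lymph", "kst", "kst_ref", "cl_bile", "k_ent",
                     "k_urine", "libmaxcd1", "kd_liv", "kp_dermal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.kd_liv <= 0:
            raise ValueError("kd_liv must be positive")

    # -- realized gut rates -------------------------------------------------
    @property
    def k_abs(self) -> float:
        """Oral absorption rate constant, 1/h."""
        return rate_from_fraction(self.ka, self.kst_ref)

    @property
    def k_reab(self) -> float:
        """Reabsorption rate of biliary parent in the lumen, 1/h."""
        return rate_from_fraction(self.f_reab, self.kst_ref)

    @property
    def k_reconv(self) -> float:
        """Reconversion (deconjugation/reduction) rate of lumen metabolite, 1/h."""
        return rate_from_fraction(self.f_reconv, self.kst_ref)

    def realized_absorbed_fraction(self) -> float:
        """Net absorbed fraction of an oral dose under the current transit rate."""
        ka_p = self.k_abs * self.f_prox
        ka_d = self.k_abs * self.f_dist
        f_p = ka_p / (ka_p + self.kst) if ka_p + self.kst > 0 else 0.0
        f_d = ka_d / (ka_d + self.kst) if ka_d + self.kst > 0 else 0.0
        return f_p + (1.0 - f_p) * f_d

    def realized_reabsorbed_fraction(self) -> float:
        k = self.k_reab
        return k / (k + self.kst) if k + self.kst > 0 else 0.0

    def realized_reconverted_fraction(self) -> float:
        k = self.k_reconv
        return k / (k + self.kst) if k + self.kst > 0 else 0.0

    # -- plumbing -----------------------------------------------------------
    def with_(self, **kwargs) -> "PBPKParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PBPKParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PBPKParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def scalar_field_names(cls) -> tuple:
        return tuple(f.name for f in fields(cls))


def human_default() -> PBPKParameters:
    """Adult human parameter set.

    Calibrated so that the two-anchor scale calibration (steady-state blood
    0.42 ug/L at an external dose of 0.007 ug/kg bw/day; 131-day terminal
    blood half-life) starts at, and barely moves from, this point.
    """
    return PBPKParameters(
        p_brain=5.0,
        p_skin=5.0,
        p_adipose=33.098,
        p_liver=30.0,
        p_rest=1.5,
        pa_brain=2.0,
        pa_skin=2.0,
        pa_adipose=5.0,
        pa_liver=50.0,
        bind=0.8,
        ka=0.9,
        f_lymph=0.3,
        k_lymph=0.2,
        kst=0.3,
        kst_ref=0.3,
        cl_bile=0.0081751,
        kbile=0.9,
        f_reab=0.95,
        f_reconv=0.95,
        k_ent=0.0163502,
        k_urine=0.0054501,
        libmaxcd1=45000.0,
        kd_liv=5000.0,
    )


def rat_default() -> PBPKParameters:
    """Adult rat parameter set.

    Rats lack hepatic chlordecone reductase, so the biliary metabolite
    pathway is off (kbile = 0, f_reconv = 0).  The excretion and adipose
    permeability constants were fitted to the rat single-oral-dose anchors
    (cumulative faecal/urinary excretion at day 84 and the 21-day blood
    half-life on days 14-56 after 40 mg/kg bw).
    """
    return PBPKParameters(
        p_brain=5.0,
        p_skin=5.0,
        p_adipose=340.0,
        p_liver=25.0,
        p_rest=1.5,
        pa_brain=0.03,
        pa_skin=0.03,
        pa_adipose=7.70736e-4,
        pa_liver=0.8,
        bind=0.97,
        ka=0.9,
        f_lymph=0.3,
        k_lymph=0.2,
        kst=0.3,
        kst_ref=0.3,
        cl_bile=3.47434e-4,
        kbile=0.0,
        f_reab=0.9,
        f_reconv=0.0,
        k_ent=4.56674e-4,
        k_urine=3.02561e-5,
        libmaxcd1=45000.0,
        kd_liv=5000.0,
    )


def preset(name: str) -> PBPKParameters:
    """Look up a shipped parameter preset by name."""
    try:
        return {"rat_default": rat_default, "human_default": human_default,
                "rat": rat_default, "human": human_default}[name]()
    except KeyError:
        raise ValueError(f"unknown preset: {name!r}") from None
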