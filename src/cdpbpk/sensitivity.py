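"""Local one-at-a-time sensitivity screen.

Each parameter in the frozen manifest is varied by a multiplicative
+/- delta (default 5%) and the blood concentration at the end of a chronic
low-dose oral exposure (1.0e-3 ug/kg bw/day for 655 days, about five
terminal half-lives) is compared to the baseline:

    SA% = 100 * (C_perturbed - C_baseline) / C_baseline

Parameters whose maximal |SA%| over both directions exceeds the threshold
(default 0.2%) form the sensitive set.  The screen is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import simulate
from .exposure import repeated_daily_oral, ExposureScenario, HOURS_PER_DAY
from .parameters import PBPKParameters, _FRACTION_FIELDS
from .physiology import SpeciesPhysiology, PERMEABILITY_LIMITED

__all__ = ["SensitivityReport", "sa_percent", "sa_screen",
           "parameter_manifest", "sa_default_scenario"]

log = logging.getLogger(__name__)

SA_DOSE_UG_PER_KG_PER_DAY = 1.0e-3
SA_DURATION_DAYS = 655.0
DEFAULT_DELTA = 0.05
DEFAULT_THRESHOLD = 0.2  # percent

#: solver tolerances for the screen; differences of ~0.2% need relative
#: accuracy well below 1e-3, which rtol 1e-8 provides with margin
_SA_SOLVER = {"rtol": 1e-8, "atol": 1e-12}

_PHYS_SCALARS = (
    ["qc", "qp"]
    + [f"vf_{c}" for c in ("blood", "brain", "skin", "adipose", "liver")]
    + [f"tbf_{c}" for c in PERMEABILITY_LIMITED]
    + [f"ff_{c}" for c in PERMEABILITY_LIMITED]
)

#: parameter fields excluded from the screen: the reference transit rate is
#: a structural anchor defining what the absorption/reabsorption fractions
#: mean, not a biological quantity of its own
_EXCLUDED_PARAM_FIELDS = ("kst_ref",)


def parameter_manifest() -> tuple:
    """Frozen, ordered list of the scalar parameters covered by the screen."""
    param_names = [n for n in PBPKParameters.scalar_field_names()
                   if n not in _EXCLUDED_PARAM_FIELDS]
    return tuple(param_names + _PHYS_SCALARS)


def sa_default_scenario(species: str = "human") -> ExposureScenario:
    return repeated_daily_oral(SA_DOSE_UG_PER_KG_PER_DAY, 0.0,
                               SA_DURATION_DAYS * HOURS_PER_DAY, species=species)


def _clip_fraction(name: str, value: float) -> float:
    if name in _FRACTION_FIELDS and not (0.0 <= value <= 1.0):
        clipped = min(max(value, 0.0), 1.0)
        log.warning("perturbed %s=%g clipped to %g", name, value, clipped)
        return clipped
    return value


def _perturb(name: str, factor: float, params: PBPKParameters,
             physiology: SpeciesPhysiology):
    """One perturbed (params, physiology) pair; exactly one scalar changes."""
    if name in PBPKParameters.scalar_field_names():
        value = _clip_fraction(name, getattr(params, name) * factor)
        if value >= 1.0 and name == "bind":
            value = 1.0 - 1e-9
        kwargs = {name: value}
        if name == "f_prox":
            kwargs["f_dist"] = 1.0 - value
        elif name == "f_dist":
            kwargs["f_prox"] = 1.0 - value
        return params.with_(**kwargs), physiology

    d = physiology.to_dict()
    if name == "qc":
        d["cardiac_output"] *= factor
    elif name == "qp":
        d["alveolar_ventilation"] *= factor
    elif name.startswith("vf_"):
        comp = name[3:]
        d["volume_fractions"][comp] *= factor
        named = sum(v for k, v in d["volume_fractions"].items() if k != "rest")
        d["volume_fractions"]["rest"] = max(1.0 - 0.09 - named, 1e-6)
    elif name.startswith("tbf_"):
        comp = name[4:]
        d["tissue_blood_fractions"][comp] = _clip_fraction(
            "f_prox", d["tissue_blood_fractions"][comp] * factor)
    elif name.startswith("ff_"):
        comp = name[3:]
        d["flow_fractions"][comp] *= factor
        named = sum(v for k, v in d["flow_fractions"].items() if k != "rest")
        d["flow_fractions"]["rest"] = max(1.0 - named, 1e-9)
    else:
        raise ValueError(f"unknown parameter: {name!r}")
    return params, SpeciesPhysiology.from_dict(d)


def _cplasma(params: PBPKParameters, physiology: SpeciesPhysiology,
             scenario: ExposureScenario, duration_h: float) -> float:
    grid = np.linspace(0.0, duration_h, 200)
    res = simulate(scenario, params, physiology, duration_h, grid,
                   solver_options=_SA_SOLVER)
    return float(res.blood_concentration()[-1])


def sa_percent(param_name: str, direction: int,
               params: PBPKParameters, physiology: SpeciesPhysiology,
               scenario: ExposureScenario | None = None,
               delta: float = DEFAULT_DELTA,
               baseline_cplasma: float | None = None) -> float:
    """SA% for one parameter and one perturbation direction (+1 or -1)."""
    if param_name not in parameter_manifest():
        raise ValueError(f"unknown parameter: {param_name!r}")
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    scenario = scenario or sa_default_scenario(physiology.species)
    duration_h = SA_DURATION_DAYS * HOURS_PER_DAY
    if baseline_cplasma is None:
        baseline_cplasma = _cplasma(params, physiology, scenario, duration_h)
    if baseline_cplasma <= 0:
        raise RuntimeError("baseline blood concentration is zero; "
                           "the scenario produces no exposure")
    p2, phys2 = _perturb(param_name, 1.0 + direction * delta, params, physiology)
    c = _cplasma(p2, phys2, scenario, duration_h)
    return 100.0 * (c - baseline_cplasma) / baseline_cplasma


@dataclass
class SensitivityReport:
    delta: float
    threshold: float
    scenario_descriptor: str
    baseline_cplasma: float
    sa_plus: dict = field(default_factory=dict)
    sa_minus: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)

    def max_abs(self, name: str) -> float:
        return max(abs(self.sa_plus.get(name, 0.0)),
                   abs(self.sa_minus.get(name, 0.0)))

    @property
    def ranked(self) -> list:
        """Parameter names by |SA%| descending, name ascending for ties."""
        names = [n for n in self.sa_plus if n not in self.failures]
        return sorted(names, key=lambda n: (-self.max_abs(n), n))

    @property
    def sensitive_set(self) -> list:
        return [n for n in self.ranked if self.max_abs(n) > self.threshold]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.ranked,
            "sa_plus_percent": [self.sa_plus[n] for n in self.ranked],
            "sa_minus_percent": [self.sa_minus[n] for n in self.ranked],
            "max_abs_sa_percent": [self.max_abs(n) for n in self.ranked],
            "sensitive": [self.max_abs(n) > self.threshold for n in self.ranked],
        })


def sa_screen(params: PBPKParameters, physiology: SpeciesPhysiology,
              threshold: float = DEFAULT_THRESHOLD,
              delta: float = DEFAULT_DELTA,
              scenario: ExposureScenario | None = None) -> SensitivityReport:
    """Run the +/- screen over every manifest parameter."""
    scenario = scenario or sa_default_scenario(physiology.species)
    duration_h = SA_DURATION_DAYS * HOURS_PER_DAY
    baseline = _cplasma(params, physiology, scenario, duration_h)
    report = SensitivityReport(
        delta=delta, threshold=threshold,
        scenario_descriptor=(f"oral {SA_DOSE_UG_PER_KG_PER_DAY} ug/kg bw/day "
                             f"for {SA_DURATION_DAYS:g} days"),
        baseline_cplasma=baseline)
    for name in parameter_manifest():
        for direction, store in ((+1, report.sa_plus), (-1, report.sa_minus)):
            try:
                store[name] = sa_percent(name, direction, params, physiology,
                                         scenario, delta, baseline)
            except Exception as exc:  # annotate, keep screening
                report.failures[name] = str(exc)
                store[name] = float("nan")
    return report
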