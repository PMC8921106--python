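"""Synthetic datasets emulating the historical study designs.

The generators run the shipped model under each design's dosing schedule
and emit pseudo-observations with multiplicative lognormal noise, so every
pipeline stage (fitting, reverse dosimetry, population workflows) is
testable without any external data.  The sampling schedules are fixture
conventions spanning the published study windows; the fixtures reproduce
the historical *designs* and the model's own predictions, not the
historical numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import ObservationSet
from .core import simulate
from .exposure import (ExposureScenario, single_oral, iv_bolus,
                       repeated_daily_oral, HOURS_PER_DAY)
from .parameters import PBPKParameters
from .physiology import SpeciesPhysiology, physiology_at_age

__all__ = ["DESIGNS", "generate_timecourse_fixture",
           "generate_population_survey", "impute_lod",
           "PopulationBloodSurvey", "survey_quantile_anchors"]

#: sampling days and matrices per emulated design
DESIGNS: dict = {
    "iv_1mgkg": {
        "species": "rat",
        "scenario": lambda: iv_bolus(1000.0),
        "samples": {m: (0.25, 0.5, 1, 2, 4, 7, 14, 28, 56)
                    for m in ("blood", "liver", "adipose")},
    },
    "oral_40mgkg_182d": {
        "species": "rat",
        "scenario": lambda: single_oral(40_000.0),
        "samples": {
            **{m: (1, 2, 4, 7, 14, 28, 56, 84, 112, 140, 182)
               for m in ("blood", "liver", "adipose", "faeces_cum")},
            "urine_cum": (1, 2, 3, 4, 5, 6, 7),
        },
    },
    "dietary_3d": {
        "species": "rat",
        "scenario": lambda: repeated_daily_oral(330.0, 0.0, 3 * HOURS_PER_DAY,
                                                species="rat"),
        "samples": {m: (1, 2, 3, 5, 7, 10, 14, 21, 28)
                    for m in ("blood", "liver", "adipose")},
    },
    "dietary_90d": {
        "species": "rat",
        "scenario": lambda: repeated_daily_oral(125.0, 0.0, 90 * HOURS_PER_DAY,
                                                species="rat"),
        "samples": {m: (7, 14, 28, 56, 90, 91)
                    for m in ("blood", "liver", "adipose")},
    },
    "chronic_occupational": {
        "species": "human",
        "scenario": lambda: repeated_daily_oral(190.0, 0.0, 1000 * HOURS_PER_DAY),
        "samples": {m: (100, 200, 300, 400, 500, 600, 700, 800, 900, 1000)
                    for m in ("blood", "liver", "adipose")},
    },
}

DEFAULT_SIGMA_REL = 0.15
DEFAULT_LOD = 0.06  # ug/L


def _lognormal_multipliers(rng: np.random.Generator, n: int,
                           sigma_rel: float) -> np.ndarray:
    """Mean-1 multiplicative noise with relative SD exactly ``sigma_rel``."""
    if sigma_rel == 0:
        return np.ones(n)
    s = np.sqrt(np.log1p(sigma_rel ** 2))
    return np.exp(s * rng.standard_normal(n) - 0.5 * s * s)


def generate_timecourse_fixture(design: str,
                                params: PBPKParameters,
                                sigma_rel: float = DEFAULT_SIGMA_REL,
                                seed: int = 0,
                                physiology: SpeciesPhysiology | None = None
                                ) -> ObservationSet:
    """Pseudo-observations for one emulated study design.

    Deterministic for a fixed seed; ``sigma_rel = 0`` reproduces the model
    predictions exactly.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; choose from {sorted(DESIGNS)}")
    if sigma_rel < 0:
        raise ValueError("sigma_rel must be non-negative")
    spec = DESIGNS[design]
    physiology = physiology or physiology_at_age(spec["species"])
    scenario = spec["scenario"]()
    t_max_d = max(max(times) for times in spec["samples"].values())
    duration_h = t_max_d * HOURS_PER_DAY * 1.001
    grid = np.unique(np.concatenate([
        np.linspace(0.0, duration_h, 400),
        np.array([t * HOURS_PER_DAY for times in spec["samples"].values()
                  for t in times], float),
    ]))
    res = simulate(scenario, params, physiology, duration_h, grid)

    from .core import StateIndex as S
    rng = np.random.default_rng(seed)
    rows = []
    for matrix, times in sorted(spec["samples"].items()):
        for t in times:
            t_h = t * HOURS_PER_DAY
            if matrix == "blood":
                v = float(np.interp(t_h, res.time_h, res.blood_concentration()))
                unit = "ug/L"
            elif matrix in ("liver", "adipose"):
                v = float(np.interp(t_h, res.time_h, res.tissue_concentration(matrix)))
                unit = "ug/L"
            elif matrix == "faeces_cum":
                v, unit = float(res.at_time(t_h)[S.FAECES]), "ug"
            else:
                v, unit = float(res.at_time(t_h)[S.URINE]), "ug"
            rows.append({"subject": "fixture", "time_days": float(t),
                         "matrix": matrix, "value": v, "unit": unit,
                         "below_lod": False, "lod": 0.0})
    df = pd.DataFrame(rows)
    df["value"] *= _lognormal_multipliers(rng, len(df), sigma_rel)
    return ObservationSet(df)


def impute_lod(value: float, below_lod: bool, lod: float) -> float:
    """Left-censored substitution: censored records become LOD / sqrt(2)."""
    if lod < 0:
        raise ValueError("LOD must be non-negative")
    if not below_lod:
        return value
    if lod == 0:
        raise ValueError("cannot impute with a zero LOD")
    return lod / np.sqrt(2.0)


@dataclass
class PopulationBloodSurvey:
    """Per-subject blood concentrations with LOD censoring and quartile groups."""

    data: pd.DataFrame  # concentration_ug_per_L, below_lod, lod, group

    def group_sizes(self) -> tuple:
        counts = self.data["group"].value_counts()
        return tuple(int(counts.get(g, 0)) for g in ("Gr1", "Gr2", "Gr3"))

    def group_medians(self, imputed: bool = True) -> dict:
        df = self.data.copy()
        if imputed:
            df["concentration_ug_per_L"] = [
                impute_lod(v, c, l) for v, c, l in
                zip(df["concentration_ug_per_L"], df["below_lod"], df["lod"])]
        return {g: float(df.loc[df["group"] == g, "concentration_ug_per_L"].median())
                for g in ("Gr1", "Gr2", "Gr3")}


def survey_quantile_anchors(quartile_medians=(0.04, 0.42, 1.48)):
    """Quantile-function anchors hitting the three quartile-group medians.

    The group medians of a survey sit at the 12.5th, 50th and 87.5th
    percentiles; a piecewise log-linear quantile function in probit space
    through those anchors is a two-piece lognormal that reproduces them.
    """
    z = stats.norm.ppf([0.125, 0.5, 0.875])
    return z, np.log(np.asarray(quartile_medians, float))


def generate_population_survey(n: int = 671,
                               quartile_medians=(0.04, 0.42, 1.48),
                               lod: float = DEFAULT_LOD,
                               seed: int = 0) -> PopulationBloodSurvey:
    """Synthetic population blood survey with LOD censoring.

    Concentrations are drawn from a two-piece lognormal whose quartile-group
    medians match ``quartile_medians``; the quartile group sizes follow the
    reference pattern (166, 337, 168 at n = 671).
    """
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if lod < 0:
        raise ValueError("LOD must be non-negative")
    if not all(m > 0 for m in quartile_medians) or \
            not np.all(np.diff(quartile_medians) > 0):
        raise ValueError("quartile medians must be positive and increasing")
    rng = np.random.default_rng(seed)
    z_anchor, logc_anchor = survey_quantile_anchors(quartile_medians)
    z = rng.standard_normal(n)
    # linear interpolation in (z, log c), linear extrapolation at the tails
    slope_lo = (logc_anchor[1] - logc_anchor[0]) / (z_anchor[1] - z_anchor[0])
    slope_hi = (logc_anchor[2] - logc_anchor[1]) / (z_anchor[2] - z_anchor[1])
    logc = np.interp(z, z_anchor, logc_anchor)
    logc = np.where(z < z_anchor[0],
                    logc_anchor[0] + slope_lo * (z - z_anchor[0]), logc)
    logc = np.where(z > z_anchor[2],
                    logc_anchor[2] + slope_hi * (z - z_anchor[2]), logc)
    conc = np.exp(logc)

    below = conc < lod
    order = np.argsort(conc)
    n1 = n // 4 - (1 if n % 4 == 3 else 0)
    n3 = -(-n // 4)  # ceil
    group = np.empty(n, object)
    group[order[:n1]] = "Gr1"
    group[order[n1:n - n3]] = "Gr2"
    group[order[n - n3:]] = "Gr3"
    df = pd.DataFrame({
        "concentration_ug_per_L": conc,
        "below_lod": below,
        "lod": lod,
        "group": group,
    })
    return PopulationBloodSurvey(df)
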