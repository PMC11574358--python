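"""Applying activity-specific metabolic rates to time budgets, converting
published coefficient sets to common units, and the study's group
comparisons (paired one-tailed t-tests, breeding-stage ANOVA with post hoc
least-squares means).

The core identity is the time-energy-budget equation

    DEE = mass x sum_i MR_i x T_i

with MR in kJ g^-1 day^-1 and T the proportion of time in each behaviour, so
DEE is exactly linear in both the budget and the coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dlw import EnergeticsConstants
from .states import BEHAVIOURS

__all__ = [
    "CoefficientSet",
    "estimate_dee",
    "convert_coefficient_units",
    "paired_t_one_tailed",
    "stage_anova",
]


@dataclass(frozen=True)
class CoefficientSet:
    """A named set of activity-specific metabolic rates (kJ g^-1 day^-1).

    ``mapping`` sends each canonical behaviour to a named coefficient (so
    pooled or foreign behaviour categories can be expressed declaratively,
    e.g. colony and gliding sharing one coefficient, or a published
    "nest attendance"/"loafing" average standing in for both).
    """

    name: str
    coefficients: dict[str, float]
    mapping: dict[str, str] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.coefficients.values()):
            raise ValueError("metabolic rates must be non-negative")

    def rate_for(self, behaviour: str) -> float:
        key = self.mapping.get(behaviour, behaviour)
        if key not in self.coefficients:
            raise KeyError(f"behaviour {behaviour!r} has no mapped coefficient "
                           f"in set {self.name!r}")
        return self.coefficients[key]

    def rate_vector(self) -> np.ndarray:
        return np.array([self.rate_for(b) for b in BEHAVIOURS])


def estimate_dee(budget: dict[str, float] | np.ndarray,
                 coeffs: CoefficientSet,
                 mass_g: float) -> float:
    """Time-energy-budget DEE (kJ/day): mass x sum MR_i T_i.

    Budget proportions must sum to 1; a behaviour with positive time but no
    mapped coefficient raises with the behaviour named.
    """
    if isinstance(budget, dict):
        vec = np.array([budget.get(b, 0.0) for b in BEHAVIOURS])
    else:
        vec = np.asarray(budget, float)
    if abs(vec.sum() - 1.0) > 1e-6:
        raise ValueError(f"budget proportions sum to {vec.sum()}, not 1")
    total = 0.0
    for i, b in enumerate(BEHAVIOURS):
        if vec[i] == 0:
            continue
        try:
            total += coeffs.rate_for(b) * vec[i]
        except KeyError:
            raise KeyError(f"behaviour {b!r} has time share {vec[i]:.3f} but no "
                           f"coefficient in set {coeffs.name!r}") from None
    return mass_g * total


def convert_coefficient_units(value: float, from_unit: str,
                              constants: EnergeticsConstants = EnergeticsConstants()
                              ) -> float:
    """Convert a published activity cost to kJ g^-1 day^-1.

    Supported source units:
      * ``ml_CO2_per_g_per_h`` - via the caloric equivalent (J/ml) x 24 h;
      * ``kJ_per_h_at_365g`` - whole-animal hourly cost for a 365 g bird;
      * ``kJ_per_day_at_450g`` - whole-animal daily cost at the reference mass.
    """
    if value < 0:
        raise ValueError("metabolic rates must be non-negative")
    if from_unit == "ml_CO2_per_g_per_h":
        return value * constants.caloric_equiv * 24.0 / 1000.0
    if from_unit == "kJ_per_h_at_365g":
        return value * 24.0 / 365.0
    if from_unit == "kJ_per_day_at_450g":
        return value / constants.ref_mass_g
    raise ValueError(f"unknown unit {from_unit!r}")


def invert_coefficient_units(value_kj_g_day: float, to_unit: str,
                             constants: EnergeticsConstants = EnergeticsConstants()
                             ) -> float:
    """Inverse of :func:`convert_coefficient_units` (round-trip checks)."""
    if to_unit == "ml_CO2_per_g_per_h":
        return value_kj_g_day * 1000.0 / (constants.caloric_equiv * 24.0)
    if to_unit == "kJ_per_h_at_365g":
        return value_kj_g_day * 365.0 / 24.0
    if to_unit == "kJ_per_day_at_450g":
        return value_kj_g_day * constants.ref_mass_g
    raise ValueError(f"unknown unit {to_unit!r}")


def paired_t_one_tailed(differences: np.ndarray | None = None, *,
                        mean: float | None = None, sem: float | None = None,
                        n: int | None = None) -> dict:
    """One-tailed paired t-test (H1: mean difference > 0).

    Accepts either raw paired differences or a printed summary
    (mean, s.e.m., n).  Returns t, df and the upper-tail p-value.
    """
    if differences is not None:
        d = np.asarray(differences, float)
        if len(d) < 2:
            raise ValueError("need at least two paired differences")
        sd = d.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance in differences")
        n = len(d)
        mean = float(d.mean())
        sem = float(sd / math.sqrt(n))
    else:
        if mean is None or sem is None or n is None:
            raise ValueError("summary form needs mean, sem and n")
        if sem <= 0:
            raise ValueError("sem must be > 0")
        if n < 2:
            raise ValueError("need n >= 2")
    t = mean / sem
    df = n - 1
    p = float(stats.t.sf(t, df))
    return {"t": float(t), "df": df, "p": p, "mean": mean, "sem": sem, "n": n}


def stage_anova(values: np.ndarray, stage_labels: np.ndarray,
                alpha: float = 0.05) -> dict:
    """One-way ANOVA of a response across breeding stages, with Tukey-adjusted
    pairwise contrasts of the group (least-squares) means when significant.

    With a single factor, type II and type I sums of squares coincide.
    Requires >= 2 stages with >= 2 birds each.
    """
    values = np.asarray(values, float)
    stage_labels = np.asarray(stage_labels)
    groups = pd.unique(stage_labels)
    if len(groups) < 2:
        raise ValueError("need at least two stages")
    by_group = [values[stage_labels == g] for g in groups]
    if any(len(g) < 2 for g in by_group):
        raise ValueError("need at least two birds per stage")

    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in by_group)
    if ss_between == 0:
        f, p = 0.0, 1.0  # all group means equal (scipy returns nan here)
    else:
        f, p = stats.f_oneway(*by_group)
    df_between = len(groups) - 1
    df_within = len(values) - len(groups)
    means = pd.DataFrame({
        "stage": groups,
        "mean": [g.mean() for g in by_group],
        "sem": [g.std(ddof=1) / math.sqrt(len(g)) for g in by_group],
        "n": [len(g) for g in by_group],
    })
    result = {"F": float(f), "df": (df_between, df_within), "p": float(p),
              "group_means": means, "posthoc": None}
    if p < alpha:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        tk = pairwise_tukeyhsd(values, stage_labels, alpha=alpha)
        result["posthoc"] = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0])
    return result
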