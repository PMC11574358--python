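"""DLW-behaviour calibration: regression of standardised daily energy
expenditure on time-energy budgets or activity-specific dynamic body
acceleration, with AICc-based backward pooling of behaviours.

The time-energy-budget (TEB) model is ordinary least squares *without an
intercept*:

    DEE_std_b = sum_g beta_g * T_{b,g} + eps_b

where the groups g partition the five behaviours and T_{b,g} is bird b's
summed time share in group g.  Because the shares sum to one, the
coefficients are interpretable directly as the cost (kJ/day at the reference
mass) of spending 100% of the time in that behaviour group.  The DBA
alternative regresses DEE_std on per-behaviour time-weighted daily VeDBA with
an intercept.

Model ranking uses AICc with k = number of regression coefficients + 1 (the
residual variance).  Candidate models with any variance inflation factor
above 10 are discarded.  The pooling search is the backward greedy procedure:
starting from the full five-behaviour model, evaluate every pairwise merge of
current groups, accept the best if it lowers AICc, and repeat; an exhaustive
search over all 52 partitions of the five behaviours is available as an
oracle cross-check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dlw import EnergeticsConstants
from .states import BEHAVIOURS, N_BEHAVIOURS

__all__ = [
    "CalibrationDataset",
    "ModelFit",
    "fit_budget_model",
    "fit_dba_model",
    "aicc",
    "vif",
    "pooling_search",
    "exhaustive_pooling_search",
    "all_partitions",
    "coefficients_report",
]


@dataclass(frozen=True)
class CalibrationDataset:
    """Per-bird inputs to the calibration: DLW-included birds only."""

    dee_std: np.ndarray                   # kJ/day at reference mass
    budgets: np.ndarray                   # (n, 5) proportions, rows sum to 1
    activity_vedba: np.ndarray | None = None   # (n, 5) time-weighted daily VeDBA
    stage: np.ndarray | None = None
    mass_g: np.ndarray | None = None

    def __post_init__(self) -> None:
        b = np.asarray(self.budgets, float)
        if b.shape != (len(self.dee_std), N_BEHAVIOURS):
            raise ValueError("budgets must be (n_birds, 5)")
        if not np.allclose(b.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("budget rows must sum to 1")

    @property
    def n(self) -> int:
        return len(self.dee_std)


@dataclass(frozen=True)
class ModelFit:
    """One fitted candidate model."""

    terms: tuple[str, ...]
    coefficients: np.ndarray
    std_errors: np.ndarray
    log_likelihood: float
    aicc: float
    vifs: np.ndarray
    r_squared: float
    n: int
    k: int
    grouping: tuple[tuple[str, ...], ...] | None = None
    delta_aicc: float = math.nan
    discarded_vif: bool = False
    intercept: bool = False

    def coefficient(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def std_error(self, term: str) -> float:
        return float(self.std_errors[self.terms.index(term)])


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion corrected for small samples.

    AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); undefined for n <= k+1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def vif(design: np.ndarray) -> np.ndarray:
    """Variance inflation factor per column: 1/(1-R2_j) from regressing
    column j on the others (no added intercept: uncentred design, matching
    the no-intercept budget models).  Perfect collinearity gives inf.
    """
    X = np.asarray(design, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least two columns for VIF")
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        y = X[:, j]
        Z = np.delete(X, j, axis=1)
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ coef
        ss_tot = float(y @ y)
        ss_res = float(resid @ resid)
        if ss_tot == 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def _ols(y: np.ndarray, X: np.ndarray, term_names: tuple[str, ...],
         intercept: bool, grouping=None) -> ModelFit:
    """Gaussian-likelihood OLS; k counts coefficients + residual variance."""
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise np.linalg.LinAlgError(
            f"rank-deficient design ({rank} < {p}); collinear terms among {term_names}")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    sigma2 = rss / n  # ML variance, matching the Gaussian log-likelihood
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    dof = max(n - p, 1)
    cov = rss / dof * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    ybar = y.mean()
    ss_tot = float(((y - ybar) ** 2).sum()) if intercept else float(y @ y)
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else math.nan
    k = p + 1
    fit_aicc = aicc(loglik, k, n)
    vifs = vif(X) if p >= 2 else np.array([1.0])
    return ModelFit(terms=term_names, coefficients=coef, std_errors=se,
                    log_likelihood=loglik, aicc=fit_aicc, vifs=vifs,
                    r_squared=r2, n=n, k=k, grouping=grouping,
                    discarded_vif=bool(np.any(vifs > 10.0)), intercept=intercept)


def _pooled_design(budgets: np.ndarray,
                   grouping: tuple[tuple[str, ...], ...]) -> tuple[np.ndarray, tuple[str, ...]]:
    cols, names = [], []
    for group in grouping:
        idx = [BEHAVIOURS.index(b) for b in group]
        cols.append(budgets[:, idx].sum(axis=1))
        names.append("+".join(group))
    return np.column_stack(cols), tuple(names)


def canonical_grouping(grouping) -> tuple[tuple[str, ...], ...]:
    """Order-invariant canonical form of a behaviour partition."""
    groups = [tuple(sorted(g, key=BEHAVIOURS.index)) for g in grouping]
    groups.sort(key=lambda g: BEHAVIOURS.index(g[0]))
    missing = set(BEHAVIOURS) - {b for g in groups for b in g}
    if missing:
        raise ValueError(f"grouping does not cover behaviours: {sorted(missing)}")
    return tuple(groups)


def fit_budget_model(dataset: CalibrationDataset,
                     grouping=None,
                     stage_offset: bool = False) -> ModelFit:
    """No-intercept OLS of DEE_std on (pooled) time proportions.

    Coefficients are kJ/day at 100% occupancy of each behaviour group at the
    reference mass.  ``stage_offset`` adds breeding-stage dummy offsets
    (first stage as baseline) as an additive candidate term.
    """
    grouping = canonical_grouping(grouping or [(b,) for b in BEHAVIOURS])
    X, names = _pooled_design(np.asarray(dataset.budgets, float), grouping)
    if dataset.n < X.shape[1] + 2:
        raise ValueError("need at least 2 more birds than terms")
    if stage_offset:
        if dataset.stage is None:
            raise ValueError("stage_offset requested but dataset has no stages")
        stages = pd.unique(dataset.stage)
        for s in stages[1:]:
            X = np.column_stack([X, (dataset.stage == s).astype(float)])
            names = names + (f"stage[{s}]",)
    return _ols(np.asarray(dataset.dee_std, float), X, names, intercept=False,
                grouping=grouping)


def fit_dba_model(dataset: CalibrationDataset,
                  drop_threshold: float = 0.5) -> ModelFit:
    """OLS of DEE_std on per-behaviour time-weighted daily VeDBA + intercept.

    Behaviours missing (NaN) for more than ``drop_threshold`` of birds are
    dropped with a warning; remaining NaNs are treated as zero contribution.
    """
    if dataset.activity_vedba is None:
        raise ValueError("dataset has no activity VeDBA")
    V = np.asarray(dataset.activity_vedba, float)
    keep, names = [], ["intercept"]
    cols = [np.ones(dataset.n)]
    import logging
    for i, b in enumerate(BEHAVIOURS):
        frac_missing = np.mean(np.isnan(V[:, i]))
        if frac_missing > drop_threshold:
            logging.getLogger(__name__).warning(
                "dropping DBA term %s: missing for %.0f%% of birds", b,
                100 * frac_missing)
            continue
        cols.append(np.nan_to_num(V[:, i]))
        names.append(f"vedba_{b}")
        keep.append(i)
    X = np.column_stack(cols)
    return _ols(np.asarray(dataset.dee_std, float), X, tuple(names), intercept=True)


def _pairwise_merges(grouping):
    for i, j in itertools.combinations(range(len(grouping)), 2):
        merged = grouping[i] + grouping[j]
        rest = [g for k, g in enumerate(grouping) if k not in (i, j)]
        yield canonical_grouping(rest + [merged])


@dataclass
class PoolingResult:
    selected: ModelFit
    ranked: list[ModelFit]          # all evaluated models, best first
    within_2: list[ModelFit] = field(default_factory=list)


def _select_and_rank(evaluated: list[ModelFit]) -> PoolingResult:
    """Rank by AICc; screen the within-2-AICc set by VIF for selection.

    Multicollinearity is tested only among the competitive models: any model
    within 2 AICc of the best with a VIF above 10 is discarded from
    selection.  If every competitive model fails the screen the AICc-best
    model is kept (flagged).
    """
    ranked = sorted(evaluated, key=lambda m: m.aicc)
    best_aicc = ranked[0].aicc
    ranked = [ModelFit(**{**m.__dict__, "delta_aicc": m.aicc - best_aicc})
              for m in ranked]
    within = [m for m in ranked if m.delta_aicc <= 2.0]
    passing = [m for m in within if not m.discarded_vif]
    selected = passing[0] if passing else ranked[0]
    return PoolingResult(selected=selected, ranked=ranked,
                         within_2=passing or within)


def pooling_search(dataset: CalibrationDataset,
                   stage_candidate: bool = False) -> PoolingResult:
    """Backward greedy pooling of behaviours by AICc.

    At each round every pairwise merge of the current groups is fitted; the
    best merge is accepted if it lowers AICc, and the search repeats from the
    merged grouping.  When ``stage_candidate`` is true, each grouping is also
    fitted with an additive breeding-stage offset.  Models within 2 AICc of
    the best are reported, screened by the VIF > 10 discard rule.
    """
    evaluated: dict[tuple, ModelFit] = {}

    def fit(grouping, stage=False) -> ModelFit | None:
        key = (grouping, stage)
        if key in evaluated:
            return evaluated[key]
        try:
            m = fit_budget_model(dataset, grouping, stage_offset=stage)
        except (np.linalg.LinAlgError, ValueError):
            return None
        evaluated[key] = m
        return m

    current = canonical_grouping([(b,) for b in BEHAVIOURS])
    variants = [False] + ([True] if stage_candidate else [])
    starters = [m for v in variants if (m := fit(current, v)) is not None]
    if not starters:
        raise ValueError("too few birds to fit the full five-behaviour model")
    best = min(starters, key=lambda m: m.aicc)
    while len(current) > 1:
        candidates = []
        for g in _pairwise_merges(current):
            for v in variants:
                m = fit(g, v)
                if m is not None:
                    candidates.append(m)
        if not candidates:
            break
        challenger = min(candidates, key=lambda m: m.aicc)
        if challenger.aicc < best.aicc:
            best = challenger
            current = challenger.grouping
        else:
            break
    return _select_and_rank(list(evaluated.values()))


def all_partitions(items: tuple[str, ...] = BEHAVIOURS):
    """Every set partition of the behaviours (52 for five items)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], tuple(items[1:])
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + (first,)] + part[i + 1:]
        yield part + [(first,)]


def exhaustive_pooling_search(dataset: CalibrationDataset) -> PoolingResult:
    """Fit every partition of the five behaviours; oracle for the greedy search."""
    fits = []
    for part in all_partitions():
        grouping = canonical_grouping(part)
        try:
            fits.append(fit_budget_model(dataset, grouping))
        except (np.linalg.LinAlgError, ValueError):
            continue
    return _select_and_rank(fits)


def coefficients_report(fit: ModelFit,
                        constants: EnergeticsConstants = EnergeticsConstants()
                        ) -> pd.DataFrame:
    """Activity-specific metabolic rates in the three reporting unit systems.

    kJ/day at the reference mass (the raw coefficient), kJ/g/day (divided by
    the reference mass) and multiples of BMR (divided by BMR in kJ/day).
    """
    rows = []
    for term, coef, se in zip(fit.terms, fit.coefficients, fit.std_errors):
        if term.startswith(("stage[", "intercept", "vedba_")):
            continue
        rows.append({
            "behaviour_group": term,
            "mr_kj_day": coef,
            "se_kj_day": se,
            "mr_kj_g_day": coef / constants.ref_mass_g,
            "mr_x_bmr": coef / constants.bmr_kj_day,
        })
    df = pd.DataFrame(rows)
    # consistency of the unit conversions
    assert np.allclose(df["mr_kj_g_day"] * constants.ref_mass_g, df["mr_kj_day"],
                       rtol=0, atol=1e-9 * max(1.0, float(np.abs(df["mr_kj_day"]).max())))
    return df


def model_table(result: PoolingResult) -> pd.DataFrame:
    """Ranked model-comparison table (AICc ascending) with a ΔAICc column."""
    rows = []
    for m in result.ranked:
        rows.append({
            "terms": " , ".join(m.terms),
            "k": m.k, "n": m.n,
            "log_likelihood": m.log_likelihood,
            "aicc": m.aicc, "delta_aicc": m.delta_aicc,
            "r_squared": m.r_squared,
            "max_vif": float(np.max(m.vifs)),
            "discarded_vif": m.discarded_vif,
        })
    return pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
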