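"""Hidden Markov behavioural classification of 10 s predictor bins.

Five semantic states (colony, rest on land, swimming, flapping flight,
gliding) are inferred from four conditionally independent emission streams:

* wingbeat frequency (Hz): zero-inflated gamma (exact zeros from bins with no
  flapping signal carry a point mass),
* ground speed (km/h): gamma,
* presence at the colony: Bernoulli,
* presence on land: Bernoulli.

Fitting is Baum-Welch EM with scaled forward-backward recursions; decoding is
Viterbi.  States are assigned semantic labels post hoc: the state with the
highest mean wingbeat frequency is flapping, the highest colony rate is
colony, the highest land rate is rest-on-land, the fastest remaining state is
gliding and the remainder is swimming.  Missing values in any stream are
skipped bin-wise in the likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import gammaln, polygamma, psi

from .states import BEHAVIOURS, BEHAVIOUR_INDEX, N_BEHAVIOURS

logger = logging.getLogger(__name__)

_EPS = 1e-12

__all__ = [
    "HmmSpec",
    "default_spec",
    "sample_bins",
    "fit_hmm",
    "decode_states",
    "compute_time_budget",
    "compute_activity_vedba",
]


@dataclass
class HmmSpec:
    """Parameters of the five-state behaviour HMM.

    Arrays are indexed by state; after labelling, ``labels[s]`` gives the
    behaviour name of state ``s``.
    """

    wbf_zero: np.ndarray          # point mass at wbf == 0
    wbf_shape: np.ndarray
    wbf_scale: np.ndarray
    speed_shape: np.ndarray
    speed_scale: np.ndarray
    p_colony: np.ndarray
    p_land: np.ndarray
    transmat: np.ndarray
    initial: np.ndarray
    labels: tuple[str, ...] | None = None
    log_likelihood: float = np.nan
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        P = np.asarray(self.transmat, float)
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("transition matrix rows must sum to 1")
        for name in ("wbf_shape", "wbf_scale", "speed_shape", "speed_scale"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be strictly positive")
        for name in ("wbf_zero", "p_colony", "p_land"):
            v = np.asarray(getattr(self, name))
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return len(self.initial)

    @property
    def wbf_mean(self) -> np.ndarray:
        """Unconditional mean WBF per state, including the zero mass."""
        return (1.0 - self.wbf_zero) * self.wbf_shape * self.wbf_scale

    @property
    def speed_mean(self) -> np.ndarray:
        return self.speed_shape * self.speed_scale

    def relabelled(self) -> "HmmSpec":
        """Attach semantic labels and reorder states into canonical order."""
        order = _semantic_order(self)
        return replace(
            self,
            wbf_zero=self.wbf_zero[order], wbf_shape=self.wbf_shape[order],
            wbf_scale=self.wbf_scale[order],
            speed_shape=self.speed_shape[order], speed_scale=self.speed_scale[order],
            p_colony=self.p_colony[order], p_land=self.p_land[order],
            transmat=self.transmat[np.ix_(order, order)],
            initial=self.initial[order],
            labels=BEHAVIOURS,
        )


def _semantic_order(spec: HmmSpec) -> np.ndarray:
    """Map canonical behaviour positions to raw state indices.

    Assignment order: flapping by highest mean WBF, colony by colony rate,
    rest-on-land by land rate, gliding by highest speed among the rest,
    swimming is the remainder.
    """
    remaining = list(range(spec.n_states))
    assign: dict[str, int] = {}

    def take(key: np.ndarray) -> int:
        s = remaining[int(np.argmax(key[remaining]))]
        remaining.remove(s)
        return s

    assign["flapping"] = take(spec.wbf_mean)
    assign["colony"] = take(spec.p_colony)
    assign["rest_land"] = take(spec.p_land)
    assign["gliding"] = take(spec.speed_mean)
    assign["swimming"] = remaining.pop()
    return np.array([assign[b] for b in BEHAVIOURS])


def default_spec(wbf_flap_hz: float = 4.0, wbf_flap_sd: float = 0.3) -> HmmSpec:
    """Generator-typical emission parameters in canonical state order.

    Used both to sample synthetic predictor bins and as a reference for
    parameter-recovery checks.
    """
    def gam(mean, sd):
        shape = (mean / sd) ** 2
        return shape, mean / shape

    wbf_shape = np.empty(N_BEHAVIOURS)
    wbf_scale = np.empty(N_BEHAVIOURS)
    speed_shape = np.empty(N_BEHAVIOURS)
    speed_scale = np.empty(N_BEHAVIOURS)
    # spurious low-frequency peaks when not flapping
    wbf_nonflap = gam(1.0, 0.5)
    speeds = {"colony": (0.3, 0.2), "rest_land": (0.3, 0.2), "swimming": (1.5, 0.8),
              "flapping": (35.0, 8.0), "gliding": (20.0, 6.0)}
    for i, b in enumerate(BEHAVIOURS):
        wbf_shape[i], wbf_scale[i] = gam(wbf_flap_hz, wbf_flap_sd) if b == "flapping" else wbf_nonflap
        speed_shape[i], speed_scale[i] = gam(*speeds[b])
    wbf_zero = np.array([0.98 if b != "flapping" else 0.01 for b in BEHAVIOURS])
    p_colony = np.array([0.95, 0.02, 0.01, 0.02, 0.10])
    p_land = np.array([0.02, 0.95, 0.01, 0.02, 0.02])

    from .synthetic import DEFAULT_DWELL_HOURS, STAGE_BUDGETS, transition_matrix
    pi = np.array([STAGE_BUDGETS["incubation"][b] for b in BEHAVIOURS])
    dwell = np.array([DEFAULT_DWELL_HOURS[b] * 360 for b in BEHAVIOURS])
    return HmmSpec(wbf_zero=wbf_zero, wbf_shape=wbf_shape, wbf_scale=wbf_scale,
                   speed_shape=speed_shape, speed_scale=speed_scale,
                   p_colony=p_colony, p_land=p_land,
                   transmat=transition_matrix(pi, dwell), initial=pi,
                   labels=BEHAVIOURS)


def sample_bins(spec: HmmSpec, n_bins: int, seed: int = 0,
                states: np.ndarray | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample predictor bins (and the true state path) from an HMM spec."""
    rng = np.random.default_rng(seed)
    if states is None:
        from .synthetic import sample_markov_chain
        states = sample_markov_chain(spec.transmat, spec.initial, n_bins, rng)
    s = states
    wbf = rng.gamma(spec.wbf_shape[s], spec.wbf_scale[s])
    wbf[rng.random(n_bins) < spec.wbf_zero[s]] = 0.0
    speed = rng.gamma(spec.speed_shape[s], spec.speed_scale[s])
    at_colony = rng.random(n_bins) < spec.p_colony[s]
    on_land = rng.random(n_bins) < spec.p_land[s]
    bins = pd.DataFrame({"wbf": wbf, "ground_speed_kmh": speed,
                         "at_colony": at_colony, "on_land": on_land})
    return bins, states


# ---------------------------------------------------------------------------
# Emission log-likelihoods

def _gamma_logpdf(x: np.ndarray, shape: np.ndarray, scale: np.ndarray) -> np.ndarray:
    x = x[:, None]
    return ((shape - 1) * np.log(x) - x / scale
            - shape * np.log(scale) - gammaln(shape))


def emission_loglik(bins: pd.DataFrame, spec: HmmSpec) -> np.ndarray:
    """(T, S) matrix of per-bin log emission densities; missing streams skip."""
    T = len(bins)
    S = spec.n_states
    logB = np.zeros((T, S))

    wbf = bins["wbf"].to_numpy(float)
    ok = ~np.isnan(wbf)
    zero = ok & (wbf <= 0)
    pos = ok & (wbf > 0)
    z = np.clip(spec.wbf_zero, _EPS, 1 - _EPS)
    logB[zero] += np.log(z)[None, :]
    if pos.any():
        logB[pos] += np.log1p(-z)[None, :] + _gamma_logpdf(
            wbf[pos], spec.wbf_shape, spec.wbf_scale)

    speed = bins["ground_speed_kmh"].to_numpy(float)
    ok = ~np.isnan(speed)
    if ok.any():
        logB[ok] += _gamma_logpdf(np.maximum(speed[ok], 1e-3),
                                  spec.speed_shape, spec.speed_scale)

    for col, p in (("at_colony", spec.p_colony), ("on_land", spec.p_land)):
        x = bins[col].to_numpy(float)
        ok = ~np.isnan(x)
        pc = np.clip(p, _EPS, 1 - _EPS)
        logB[ok] += (x[ok, None] * np.log(pc)[None, :]
                     + (1 - x[ok, None]) * np.log1p(-pc)[None, :])
    return logB


# ---------------------------------------------------------------------------
# Scaled recursions (numba)

@njit(cache=False)
def _forward_backward(B: np.ndarray, offsets: np.ndarray, P: np.ndarray,
                      pi: np.ndarray):
    T, S = B.shape
    alpha = np.empty((T, S))
    beta = np.empty((T, S))
    c = np.empty(T)
    a0 = pi * B[0]
    c[0] = a0.sum()
    alpha[0] = a0 / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ P) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (P @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1).reshape(-1, 1)
    xi = np.zeros((S, S))
    for t in range(T - 1):
        w = B[t + 1] * beta[t + 1] / c[t + 1]
        for i in range(S):
            xi[i] += alpha[t, i] * P[i] * w
    loglik = np.log(c).sum() + offsets.sum()
    return gamma, xi, loglik


@njit(cache=False)
def _viterbi(logB: np.ndarray, logP: np.ndarray, logpi: np.ndarray) -> np.ndarray:
    T, S = logB.shape
    delta = logpi + logB[0]
    back = np.zeros((T, S), dtype=np.int64)
    for t in range(1, T):
        nxt = np.empty(S)
        for j in range(S):
            best, arg = -np.inf, 0
            for i in range(S):
                v = delta[i] + logP[i, j]
                if v > best:  # ties broken by lowest state index
                    best, arg = v, i
            nxt[j] = best + logB[t, j]
            back[t, j] = arg
        delta = nxt
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = np.argmax(delta)
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def _scaled_emissions(logB: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    offsets = logB.max(axis=1)
    return np.exp(logB - offsets[:, None]), offsets


# ---------------------------------------------------------------------------
# M-step helpers

def _weighted_gamma_mle(x: np.ndarray, w: np.ndarray,
                        min_weight: float = 1e-6) -> tuple[float, float]:
    """Weighted gamma MLE (shape, scale) via Newton on the digamma equation."""
    wsum = w.sum()
    if wsum < min_weight or len(x) == 0:
        return 1.0, 1.0
    mean = float((w * x).sum() / wsum)
    meanlog = float((w * np.log(np.maximum(x, 1e-12))).sum() / wsum)
    s = max(np.log(mean) - meanlog, 1e-9)
    a = (3 - s + np.sqrt((s - 3) ** 2 + 24 * s)) / (12 * s)
    for _ in range(25):
        num = np.log(a) - psi(a) - s
        den = 1.0 / a - polygamma(1, a)
        step = num / den
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2
        if abs(a_new - a) < 1e-10 * a:
            a = a_new
            break
        a = a_new
    a = float(np.clip(a, 1e-3, 1e6))
    return a, mean / a


def _m_step(bins: pd.DataFrame, gamma: np.ndarray, spec: HmmSpec) -> HmmSpec:
    S = spec.n_states
    wbf = bins["wbf"].to_numpy(float)
    speed = bins["ground_speed_kmh"].to_numpy(float)

    wbf_zero = spec.wbf_zero.copy()
    wbf_shape = spec.wbf_shape.copy()
    wbf_scale = spec.wbf_scale.copy()
    speed_shape = spec.speed_shape.copy()
    speed_scale = spec.speed_scale.copy()
    p_colony = spec.p_colony.copy()
    p_land = spec.p_land.copy()

    ok_wbf = ~np.isnan(wbf)
    ok_speed = ~np.isnan(speed)
    for s in range(S):
        g = gamma[:, s]
        gw = g[ok_wbf]
        if gw.sum() > 1e-8:
            zeros = wbf[ok_wbf] <= 0
            wbf_zero[s] = float((gw * zeros).sum() / gw.sum())
            pos = ~zeros
            if (gw[pos]).sum() > 1e-6:
                wbf_shape[s], wbf_scale[s] = _weighted_gamma_mle(
                    wbf[ok_wbf][pos], gw[pos])
        gs = g[ok_speed]
        if gs.sum() > 1e-8:
            speed_shape[s], speed_scale[s] = _weighted_gamma_mle(
                np.maximum(speed[ok_speed], 1e-3), gs)

    for col, target in (("at_colony", p_colony), ("on_land", p_land)):
        x = bins[col].to_numpy(float)
        ok = ~np.isnan(x)
        denom = gamma[ok].sum(axis=0)
        with np.errstate(invalid="ignore"):
            est = (gamma[ok] * x[ok, None]).sum(axis=0) / np.maximum(denom, 1e-12)
        target[:] = np.clip(est, _EPS, 1 - _EPS)

    return replace(spec, wbf_zero=wbf_zero, wbf_shape=wbf_shape, wbf_scale=wbf_scale,
                   speed_shape=speed_shape, speed_scale=speed_scale,
                   p_colony=p_colony, p_land=p_land)


def _heuristic_init(bins: pd.DataFrame) -> np.ndarray:
    """Hard seed assignment: wbf>2 Hz seeds flapping, colony/land flags seed
    their states, the rest splits into gliding vs swimming by speed."""
    wbf = np.nan_to_num(bins["wbf"].to_numpy(float))
    speed = np.nan_to_num(bins["ground_speed_kmh"].to_numpy(float))
    at_col = np.nan_to_num(bins["at_colony"].to_numpy(float)) > 0.5
    on_land = np.nan_to_num(bins["on_land"].to_numpy(float)) > 0.5
    lab = np.full(len(bins), BEHAVIOUR_INDEX["swimming"], dtype=np.int64)
    lab[speed > 8.0] = BEHAVIOUR_INDEX["gliding"]
    lab[at_col] = BEHAVIOUR_INDEX["colony"]
    lab[on_land & ~at_col] = BEHAVIOUR_INDEX["rest_land"]
    lab[wbf > 2.0] = BEHAVIOUR_INDEX["flapping"]
    return lab


def _spec_from_hard_labels(bins: pd.DataFrame, labels: np.ndarray,
                           rng: np.random.Generator,
                           perturb: float = 0.0) -> HmmSpec:
    S = N_BEHAVIOURS
    gamma = np.zeros((len(bins), S))
    gamma[np.arange(len(bins)), labels] = 1.0
    gamma = 0.95 * gamma + 0.05 / S  # soften so every state owns some mass
    base = default_spec()
    spec = _m_step(bins, gamma, base)
    counts = np.full((S, S), 1.0)
    np.add.at(counts, (labels[:-1], labels[1:]), 1.0)
    transmat = counts / counts.sum(axis=1, keepdims=True)
    initial = np.bincount(labels, minlength=S) + 1.0
    initial /= initial.sum()
    if perturb > 0:
        spec = replace(
            spec,
            wbf_shape=spec.wbf_shape * np.exp(rng.normal(0, perturb, S)),
            speed_scale=spec.speed_scale * np.exp(rng.normal(0, perturb, S)),
            p_colony=np.clip(spec.p_colony + rng.normal(0, perturb / 4, S), 0.01, 0.99),
        )
    return replace(spec, transmat=transmat, initial=initial, labels=None)


def _check_streams(bins: pd.DataFrame) -> None:
    for col in ("wbf", "ground_speed_kmh", "at_colony", "on_land"):
        x = bins[col].to_numpy(float)
        x = x[~np.isnan(x)]
        if len(x) == 0 or np.nanvar(x) == 0:
            raise ValueError(f"degenerate stream: {col} has no variance")


def fit_hmm(bins: pd.DataFrame, spec_init: HmmSpec | None = None,
            seed: int = 0, max_iter: int = 100, tol: float = 1e-5,
            n_restarts: int = 2,
            loglik_trace: list | None = None) -> HmmSpec:
    """Baum-Welch fit of the five-state model; returns a relabelled spec.

    The default initialisation is a threshold heuristic (wbf > 2 Hz seeds
    flapping, the colony/land flags seed their states) plus ``n_restarts``
    perturbed restarts; the best final likelihood is kept.  The EM log
    likelihood is monotone non-decreasing; non-convergence within
    ``max_iter`` returns the best spec with ``converged=False``.
    """
    _check_streams(bins)
    rng = np.random.default_rng(seed)
    hard = _heuristic_init(bins)
    inits = [spec_init] if spec_init is not None else [
        _spec_from_hard_labels(bins, hard, rng, perturb=0.0 if r == 0 else 0.3)
        for r in range(max(1, n_restarts))]

    best: HmmSpec | None = None
    for init in inits:
        spec = init
        prev = -np.inf
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            logB = emission_loglik(bins, spec)
            B, offsets = _scaled_emissions(logB)
            gamma_r, xi, loglik = _forward_backward(B, offsets, spec.transmat,
                                                    np.maximum(spec.initial, _EPS))
            trace.append(loglik)
            if loglik + 1e-9 < prev:
                logger.warning("EM log-likelihood decreased by %g", prev - loglik)
            # per-observation improvement below tol => converged
            if (loglik - prev) / max(1, len(bins)) < tol:
                converged = True
                break
            prev = loglik
            transmat = xi / np.maximum(xi.sum(axis=1, keepdims=True), _EPS)
            initial = np.maximum(gamma_r[0], _EPS)
            initial /= initial.sum()
            spec = replace(_m_step(bins, gamma_r, spec),
                           transmat=transmat, initial=initial)
        spec = replace(spec, log_likelihood=loglik, converged=converged, n_iter=it)
        if best is None or spec.log_likelihood > best.log_likelihood:
            best = spec
            if loglik_trace is not None:
                loglik_trace[:] = trace
    if not best.converged:
        logger.warning("EM did not converge in %d iterations", max_iter)
    return best.relabelled()


def decode_states(spec: HmmSpec, bins: pd.DataFrame) -> np.ndarray:
    """Viterbi decoding; bins with every stream missing get label -1."""
    logB = emission_loglik(bins, spec)
    all_missing = np.ones(len(bins), dtype=bool)
    for col in ("wbf", "ground_speed_kmh", "at_colony", "on_land"):
        all_missing &= np.isnan(bins[col].to_numpy(float))
    path = _viterbi(logB, np.log(np.maximum(spec.transmat, _EPS)),
                    np.log(np.maximum(spec.initial, _EPS)))
    path = path.astype(np.int64)
    path[all_missing] = -1
    return path


def path_loglik(spec: HmmSpec, bins: pd.DataFrame, states: np.ndarray) -> float:
    """Joint log-likelihood of a given state path (Viterbi optimality checks)."""
    logB = emission_loglik(bins, spec)
    logP = np.log(np.maximum(spec.transmat, _EPS))
    ll = float(np.log(max(spec.initial[states[0]], _EPS)) + logB[0, states[0]])
    ll += float(logP[states[:-1], states[1:]].sum())
    ll += float(logB[np.arange(1, len(states)), states[1:]].sum())
    return ll


# ---------------------------------------------------------------------------
# Budgets and activity VeDBA

def compute_time_budget(labels: np.ndarray,
                        periods: np.ndarray | None = None) -> pd.DataFrame:
    """Proportion of labelled bins per behaviour, by period.

    ``labels`` are behaviour indices (-1 = missing, excluded); ``periods`` is
    an optional per-bin period key (e.g. a UTC calendar day).  Returns one row
    per period with the five proportions, which sum to 1.  Empty periods are
    omitted with a log entry.
    """
    labels = np.asarray(labels)
    if periods is None:
        periods = np.zeros(len(labels), dtype=int)
    periods = np.asarray(periods)
    rows = []
    for p in pd.unique(periods):
        sel = (periods == p) & (labels >= 0)
        if not sel.any():
            logger.info("period %r has no labelled bins; omitted", p)
            continue
        counts = np.bincount(labels[sel], minlength=N_BEHAVIOURS)
        props = counts / counts.sum()
        rows.append({"period": p, **{b: props[i] for i, b in enumerate(BEHAVIOURS)}})
    if not rows:
        raise ValueError("no labelled bins in any period")
    return pd.DataFrame(rows)


def compute_activity_vedba(labels: np.ndarray, vedba: np.ndarray,
                           periods: np.ndarray | None = None) -> pd.DataFrame:
    """Per-behaviour mean VeDBA and its time-weighted counterpart, by period.

    The time-weighted value is the behaviour's mean VeDBA multiplied by its
    time share, so the weighted values sum to the period's overall mean.
    Behaviours absent from a period get NaN (never silently zero).
    """
    labels = np.asarray(labels)
    vedba = np.asarray(vedba, float)
    if len(labels) != len(vedba):
        raise ValueError("labels and vedba must align")
    if periods is None:
        periods = np.zeros(len(labels), dtype=int)
    periods = np.asarray(periods)
    rows = []
    for p in pd.unique(periods):
        sel = (periods == p) & (labels >= 0) & ~np.isnan(vedba)
        if not sel.any():
            continue
        lab, v = labels[sel], vedba[sel]
        total = len(v)
        row: dict = {"period": p}
        for i, b in enumerate(BEHAVIOURS):
            mask = lab == i
            if mask.any():
                row[f"vedba_{b}"] = float(v[mask].mean())
                row[f"vedba_tw_{b}"] = float(v[mask].mean()) * mask.sum() / total
            else:
                row[f"vedba_{b}"] = np.nan
                row[f"vedba_tw_{b}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
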