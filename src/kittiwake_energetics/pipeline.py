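"""End-to-end orchestration: cohort directory -> budgets -> DLW -> calibration.

These functions are the library behind both the command-line interface and
the numbered analysis drivers.  Every exclusion is logged with its reason and
recorded in the outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path


import pandas as pd

from . import calibration as cal
from . import dlw, hmm, signals
from .io import LandMask, read_accel_csv, read_gps_csv
from .states import BEHAVIOURS

logger = logging.getLogger(__name__)


def bird_ids_in(cohort_dir: str | Path) -> list[str]:
    return sorted(p.name.removesuffix("_accel.csv")
                  for p in Path(cohort_dir).glob("*_accel.csv"))


def bins_for_bird(cohort_dir: str | Path, bird_id: str,
                  colony_latlon: tuple[float, float],
                  colony_radius_m: float = 200.0,
                  land_mask: LandMask | None = None) -> pd.DataFrame:
    """Raw files -> calibrated 10 s predictor bins for one bird."""
    cohort_dir = Path(cohort_dir)
    accel, t0 = read_accel_csv(cohort_dir / f"{bird_id}_accel.csv")
    gps = read_gps_csv(cohort_dir / f"{bird_id}_gps.csv", t0)
    trace = signals.AccelTrace(t=accel["t"].to_numpy(), ax=accel["ax"].to_numpy(),
                               ay=accel["ay"].to_numpy(), az=accel["az"].to_numpy())
    return signals.assemble_bins(trace, gps, colony_latlon, colony_radius_m,
                                 land_mask)


def classify_cohort(cohort_dir: str | Path,
                    colony_latlon: tuple[float, float],
                    colony_radius_m: float = 200.0,
                    land_mask: LandMask | None = None,
                    seed: int = 0, max_iter: int = 100, tol: float = 1e-5,
                    n_restarts: int = 2) -> dict:
    """Fit one HMM to the pooled cohort bins and decode every bird.

    Returns per-bird budgets (deployment-level), activity VeDBA and the
    fitted spec.
    """
    birds = bird_ids_in(cohort_dir)
    if not birds:
        raise FileNotFoundError(f"no *_accel.csv files under {cohort_dir}")
    all_bins = []
    for b in birds:
        bins = bins_for_bird(cohort_dir, b, colony_latlon, colony_radius_m, land_mask)
        bins["bird_id"] = b
        all_bins.append(bins)
    pooled = pd.concat(all_bins, ignore_index=True)
    spec = hmm.fit_hmm(pooled, seed=seed, max_iter=max_iter, tol=tol,
                       n_restarts=n_restarts)

    budget_rows, vedba_rows, label_map = [], [], {}
    for b, bins in zip(birds, all_bins):
        labels = hmm.decode_states(spec, bins)
        label_map[b] = labels
        tb = hmm.compute_time_budget(labels)
        tb.insert(0, "bird_id", b)
        budget_rows.append(tb)
        av = hmm.compute_activity_vedba(labels, bins["vedba"].to_numpy())
        av.insert(0, "bird_id", b)
        vedba_rows.append(av)
    return {"spec": spec,
            "budgets": pd.concat(budget_rows, ignore_index=True),
            "activity_vedba": pd.concat(vedba_rows, ignore_index=True),
            "labels": label_map}


def budgets_from_truth(cohort_dir: str | Path) -> pd.DataFrame:
    truth = pd.read_csv(Path(cohort_dir) / "truth.csv")
    out = truth[["bird_id"]].copy()
    for b in BEHAVIOURS:
        out[b] = truth[f"true_budget_{b}"]
    out["period"] = 0
    return out


def run_dlw(cohort_dir: str | Path,
            constants: dlw.EnergeticsConstants = dlw.EnergeticsConstants()
            ) -> pd.DataFrame:
    iso = pd.read_csv(Path(cohort_dir) / "isotopes.csv")
    results = dlw.process_isotope_table(iso, constants)
    for _, row in results[results["excluded"]].iterrows():
        logger.info("DLW exclusion: %s (%s)", row["bird_id"], row["reason"])
    return results


def calibrate_cohort(cohort_dir: str | Path,
                     colony_latlon: tuple[float, float],
                     budgets_from: str = "hmm",
                     constants: dlw.EnergeticsConstants = dlw.EnergeticsConstants(),
                     stage_candidate: bool = False,
                     **classify_kwargs) -> dict:
    """Full calibration: budgets + DLW -> pooling search -> coefficient table."""
    if budgets_from == "truth":
        budgets = budgets_from_truth(cohort_dir)
        vedba = None
    elif budgets_from == "hmm":
        classified = classify_cohort(cohort_dir, colony_latlon, **classify_kwargs)
        budgets = classified["budgets"]
        vedba = classified["activity_vedba"]
    else:
        raise ValueError("budgets_from must be 'hmm' or 'truth'")

    dlw_results = run_dlw(cohort_dir, constants)
    included = dlw_results[~dlw_results["excluded"]]
    if included.empty:
        raise RuntimeError(
            "zero included DLW birds; exclusions: "
            + "; ".join(f"{r.bird_id}: {r.reason}" for r in dlw_results.itertuples()))

    merged = budgets.merge(included[["bird_id", "dee_std_kj_day"]], on="bird_id")
    truth = pd.read_csv(Path(cohort_dir) / "truth.csv")
    merged = merged.merge(truth[["bird_id", "stage"]], on="bird_id", how="left")
    dataset = cal.CalibrationDataset(
        dee_std=merged["dee_std_kj_day"].to_numpy(float),
        budgets=merged[list(BEHAVIOURS)].to_numpy(float),
        stage=merged["stage"].to_numpy() if "stage" in merged else None,
    )
    result = cal.pooling_search(dataset, stage_candidate=stage_candidate)
    coeffs = cal.coefficients_report(result.selected, constants)
    return {"budgets": budgets, "activity_vedba": vedba, "dlw": dlw_results,
            "dataset": dataset, "pooling": result, "coefficients": coeffs,
            "model_table": cal.model_table(result),
            "n_included": int(len(included))}
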