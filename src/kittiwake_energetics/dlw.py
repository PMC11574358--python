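"""Doubly-labelled-water (DLW) energetics: the two-sample computation chain.

The DLW method estimates CO2 production from the differential washout of two
injected isotopes: :sup:`18`O leaves the body water pool via both water and CO2,
while :sup:`2`H leaves via water only, so the difference between their turnover
rates carries the CO2 signal.  The chain implemented here is

1. turnover rates ``k_o``, ``k_d`` from log excess-enrichment decay,
2. dilution spaces ``N_o``, ``N_d`` from the injectate dilution at equilibrium,
3. body-water pool size ``N`` as the mean of the initial and the
   (mass-scaled) final :sup:`18`O dilution space,
4. CO2 production ``rCO2 = (N/2.078)(k_o - k_d) - 0.0062 k_d N`` (single-pool
   two-isotope model),
5. conversion to daily energy expenditure (DEE) via a kittiwake-specific
   caloric equivalent, and mass standardisation to a 450 g reference bird.

All enrichments are absolute ppm with explicit background subtraction; times
are decimal hours since injection with the initial sample taken at isotope
equilibrium (two-sample protocol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "EnergeticsConstants",
    "IsotopeSamples",
    "IsotopeSampleSet",
    "DlwResult",
    "DlwExclusion",
    "turnover_rate",
    "dilution_space",
    "pool_size",
    "co2_production",
    "dee_from_co2",
    "standardize_dee",
    "process_dlw_bird",
    "process_dlw_cohort",
    "process_isotope_table",
    "samples_from_frame",
    "exclusion_cascade",
    "DEPLOYMENT_CASCADE",
    "DLW_CASCADE",
]


@dataclass(frozen=True)
class EnergeticsConstants:
    """Physical and study constants for the energetics conversions.

    caloric_equiv
        J per ml CO2, multi-year kittiwake average.
    molar_volume
        ml of CO2 gas per mol.
    ref_mass_g
        reference body mass for standardised DEE.
    bmr_watt
        basal metabolic rate used when expressing costs as BMR multiples.
    bodywater_fraction
        fraction of body mass assumed to be water when initialising pools.
    mass_exponent
        exponent of the (ref_mass / mass) standardisation; 1 = linear.
    o18_exclusion_frac
        a bird is excluded when its final 18O excess above background falls
        below this fraction of the background level (enrichment exhausted).
    """

    caloric_equiv: float = 27.63
    molar_volume: float = 22_400.0
    ref_mass_g: float = 450.0
    bmr_watt: float = 3.49
    bodywater_fraction: float = 0.70
    mass_exponent: float = 1.0
    o18_exclusion_frac: float = 0.02

    def __post_init__(self) -> None:
        for name in ("caloric_equiv", "molar_volume", "ref_mass_g", "bmr_watt",
                     "bodywater_fraction", "o18_exclusion_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def bmr_kj_day(self) -> float:
        """BMR converted from W to kJ day^-1 (x 86,400 s / 1000)."""
        return self.bmr_watt * 86_400.0 / 1000.0


@dataclass(frozen=True)
class IsotopeSamples:
    """Background/initial/final enrichments (ppm) for one isotope."""

    background: float
    initial: float
    final: float


@dataclass(frozen=True)
class IsotopeSampleSet:
    """Complete isotope record for one DLW bird (two-sample protocol)."""

    bird_id: str
    d2: IsotopeSamples
    o18: IsotopeSamples
    t_initial_h: float
    t_final_h: float
    dose_mol: float
    inj_d2_ppm: float
    inj_o18_ppm: float
    mass_deploy_g: float
    mass_retrieve_g: float
    include: bool = True
    exclude_reason: str | None = None

    def __post_init__(self) -> None:
        if not self.t_final_h > self.t_initial_h > 0:
            raise ValueError("require t_final > t_initial > 0")
        if min(self.mass_deploy_g, self.mass_retrieve_g) <= 0:
            raise ValueError("masses must be > 0")
        if self.dose_mol <= 0:
            raise ValueError("dose_mol must be > 0")


@dataclass(frozen=True)
class DlwResult:
    bird_id: str
    k_o: float = math.nan
    k_d: float = math.nan
    N_o: float = math.nan
    N_d: float = math.nan
    N: float = math.nan
    rco2_mol_h: float = math.nan
    rco2_ml_h: float = math.nan
    dee_kj_day: float = math.nan
    dee_std_kj_day: float = math.nan
    mass_mean_g: float = math.nan
    excluded: bool = False
    reason: str | None = None


class DlwExclusion(Exception):
    """A computation stage signalled that the bird must be excluded."""


def turnover_rate(i_background: float, i_initial: float, i_final: float,
                  t_hours: float) -> float:
    """Isotope turnover rate k (h^-1) from excess-enrichment decay.

    k = [ln(I_initial - I_background) - ln(I_final - I_background)] / T
    """
    if t_hours <= 0:
        raise ValueError("elapsed time must be > 0")
    if i_initial <= i_background:
        raise ValueError("initial enrichment not above background")
    if i_final <= i_background:
        raise DlwExclusion("final enrichment at or below background (enrichment exhausted)")
    if i_final > i_initial:
        raise ValueError("final enrichment above initial: negative turnover")
    return (math.log(i_initial - i_background) - math.log(i_final - i_background)) / t_hours


def dilution_space(mol_inj: float, i_inj: float, i_initial: float,
                   i_background: float) -> float:
    """Dilution space N (mol) from the plateau dilution of the injectate.

    N = Mol_inj * (I_inj - I_initial) / (I_initial - I_background)
    """
    if mol_inj <= 0:
        raise ValueError("mol_inj must be > 0")
    if i_initial <= i_background:
        raise ValueError("no enrichment detected: I_initial <= I_background")
    if i_inj <= i_initial:
        raise ValueError("injectate enrichment must exceed initial enrichment")
    return mol_inj * (i_inj - i_initial) / (i_initial - i_background)


def pool_size(n_o_initial: float, mass_deploy_g: float, mass_retrieve_g: float) -> float:
    """Body-water pool N (mol): mean of initial and mass-scaled final 18O space."""
    if min(n_o_initial, mass_deploy_g, mass_retrieve_g) <= 0:
        raise ValueError("inputs must be > 0")
    n_final = n_o_initial * mass_retrieve_g / mass_deploy_g
    return 0.5 * (n_o_initial + n_final)


def co2_production(n_pool: float, k_o: float, k_d: float) -> float:
    """CO2 production rate (mol h^-1), single-pool two-isotope model.

    rCO2 = (N / 2.078)(k_o - k_d) - 0.0062 * k_d * N
    """
    if n_pool <= 0:
        raise ValueError("pool size must be > 0")
    if k_d < 0 or k_o < k_d:
        raise ValueError("require k_o >= k_d >= 0")
    rco2 = (n_pool / 2.078) * (k_o - k_d) - 0.0062 * k_d * n_pool
    if k_o > 0 and rco2 <= 0:
        raise DlwExclusion("non-positive CO2 production")
    return rco2


def dee_from_co2(rco2_mol_h: float,
                 constants: EnergeticsConstants = EnergeticsConstants()) -> float:
    """Daily energy expenditure (kJ day^-1) from CO2 production (mol h^-1)."""
    if rco2_mol_h < 0:
        raise ValueError("rCO2 must be >= 0")
    ml_per_h = rco2_mol_h * constants.molar_volume
    return ml_per_h * constants.caloric_equiv * 24.0 / 1000.0


def standardize_dee(dee_kj_day: float, mass_deploy_g: float, mass_retrieve_g: float,
                    ref_mass_g: float = 450.0, exponent: float = 1.0) -> float:
    """Standardise DEE to a reference mass: DEE * (ref / mean mass)^exponent.

    Mass is the average of deployment and retrieval mass.
    """
    if min(mass_deploy_g, mass_retrieve_g, ref_mass_g) <= 0:
        raise ValueError("masses must be > 0")
    mass = 0.5 * (mass_deploy_g + mass_retrieve_g)
    return dee_kj_day * (ref_mass_g / mass) ** exponent


def process_dlw_bird(samples: IsotopeSampleSet,
                     constants: EnergeticsConstants = EnergeticsConstants()) -> DlwResult:
    """Run the full two-sample chain for one bird, applying exclusion rules.

    A bird is excluded (not errored) when the final 18O excess is within
    ``o18_exclusion_frac`` of background, when any stage signals exclusion,
    or when it carries a pre-set exclusion flag (e.g. misidentified sex).
    """
    if not samples.include:
        return DlwResult(bird_id=samples.bird_id, excluded=True,
                         reason=samples.exclude_reason or "flagged for exclusion")

    mass_mean = 0.5 * (samples.mass_deploy_g + samples.mass_retrieve_g)
    o18_excess_final = samples.o18.final - samples.o18.background
    if o18_excess_final < constants.o18_exclusion_frac * samples.o18.background:
        return DlwResult(bird_id=samples.bird_id, mass_mean_g=mass_mean, excluded=True,
                         reason="final 18O within "
                                f"{constants.o18_exclusion_frac:.0%} of background")

    t_elapsed = samples.t_final_h - samples.t_initial_h
    try:
        k_o = turnover_rate(samples.o18.background, samples.o18.initial,
                            samples.o18.final, t_elapsed)
        k_d = turnover_rate(samples.d2.background, samples.d2.initial,
                            samples.d2.final, t_elapsed)
        n_o = dilution_space(samples.dose_mol, samples.inj_o18_ppm,
                             samples.o18.initial, samples.o18.background)
        n_d = dilution_space(samples.dose_mol, samples.inj_d2_ppm,
                             samples.d2.initial, samples.d2.background)
        n_pool = pool_size(n_o, samples.mass_deploy_g, samples.mass_retrieve_g)
        rco2 = co2_production(n_pool, k_o, k_d)
    except DlwExclusion as exc:
        return DlwResult(bird_id=samples.bird_id, mass_mean_g=mass_mean,
                         excluded=True, reason=str(exc))

    dee = dee_from_co2(rco2, constants)
    dee_std = standardize_dee(dee, samples.mass_deploy_g, samples.mass_retrieve_g,
                              constants.ref_mass_g, constants.mass_exponent)
    return DlwResult(
        bird_id=samples.bird_id, k_o=k_o, k_d=k_d, N_o=n_o, N_d=n_d, N=n_pool,
        rco2_mol_h=rco2, rco2_ml_h=rco2 * constants.molar_volume,
        dee_kj_day=dee, dee_std_kj_day=dee_std, mass_mean_g=mass_mean,
    )


# Sample-accounting cascades: ordered (description, delta) applied to a starting
# count.  These mirror the study's exclusion bookkeeping and are used by the
# cohort drivers to report how many birds survive each rule.
DEPLOYMENT_CASCADE: tuple[tuple[str, int], ...] = (
    ("GPS-accelerometers deployed", 93),
    ("unit not retrieved", -1),
    ("track unusable", -2),
    ("no 6-O field calibration", -10),
)

DLW_CASCADE: tuple[tuple[str, int], ...] = (
    ("birds injected with DLW", 55),
    ("not recaptured", -1),
    ("final 18O within 2% of background", -1),
    ("final sample destroyed", -1),
    ("misidentified females", -2),
)


def exclusion_cascade(cascade: tuple[tuple[str, int], ...]) -> int:
    """Apply an ordered exclusion cascade; first entry is the starting count."""
    total = 0
    for _desc, delta in cascade:
        total += delta
        if total < 0:
            raise ValueError("cascade produced a negative count")
    return total


def process_dlw_cohort(sample_sets: list[IsotopeSampleSet],
                       constants: EnergeticsConstants = EnergeticsConstants()) -> pd.DataFrame:
    """Process a cohort; one row per bird with every intermediate quantity."""
    rows = [process_dlw_bird(s, constants).__dict__ for s in sample_sets]
    return pd.DataFrame(rows)


def process_isotope_table(df: pd.DataFrame,
                          constants: EnergeticsConstants = EnergeticsConstants()
                          ) -> pd.DataFrame:
    """Process a long-format isotope table; birds with missing sample rows are
    excluded with a recorded reason rather than raising (cohort bookkeeping)."""
    results: list[DlwResult] = []
    for bird_id, grp in df.groupby("bird_id", sort=True):
        present = set(grp["sample_type"])
        missing = {"background", "initial", "final"} - present
        if missing:
            results.append(DlwResult(bird_id=str(bird_id), excluded=True,
                                     reason=f"missing sample rows: {sorted(missing)}"))
            continue
        results.append(process_dlw_bird(samples_from_frame(grp)[0], constants))
    return pd.DataFrame([r.__dict__ for r in results])


def samples_from_frame(df: pd.DataFrame) -> list[IsotopeSampleSet]:
    """Build sample sets from the long isotope CSV layout.

    Expects columns bird_id, sample_type {background, initial, final},
    time_h, d2_ppm, o18_ppm, dose_mol, inj_d2_ppm, inj_o18_ppm,
    mass_deploy_g, mass_retrieve_g, and optionally include / exclude_reason.
    Missing sample rows raise with the missing sample_type named.
    """
    out: list[IsotopeSampleSet] = []
    for bird_id, grp in df.groupby("bird_id", sort=True):
        by_type = {t: g.iloc[0] for t, g in grp.groupby("sample_type")}
        missing = {"background", "initial", "final"} - set(by_type)
        if missing:
            raise ValueError(f"bird {bird_id}: missing sample rows {sorted(missing)}")
        bg, ini, fin = by_type["background"], by_type["initial"], by_type["final"]
        include = bool(grp["include"].iloc[0]) if "include" in grp else True
        reason = None
        if "exclude_reason" in grp and isinstance(grp["exclude_reason"].iloc[0], str):
            reason = grp["exclude_reason"].iloc[0]
        out.append(IsotopeSampleSet(
            bird_id=str(bird_id),
            d2=IsotopeSamples(float(bg["d2_ppm"]), float(ini["d2_ppm"]), float(fin["d2_ppm"])),
            o18=IsotopeSamples(float(bg["o18_ppm"]), float(ini["o18_ppm"]), float(fin["o18_ppm"])),
            t_initial_h=float(ini["time_h"]), t_final_h=float(fin["time_h"]),
            dose_mol=float(ini["dose_mol"]),
            inj_d2_ppm=float(ini["inj_d2_ppm"]), inj_o18_ppm=float(ini["inj_o18_ppm"]),
            mass_deploy_g=float(ini["mass_deploy_g"]),
            mass_retrieve_g=float(ini["mass_retrieve_g"]),
            include=include, exclude_reason=reason,
        ))
    return out
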