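"""Registry-like synthetic cohorts with known ground truth.

The generator emulates the statistical structure that net-survival analyses
assume: each patient's observed mortality is the sum of a deprivation-graded
background hazard, read from a *true* deprivation-stratified life table, and
a cancer excess hazard with a configurable EDI effect.  Patients are
diagnosed uniformly over a diagnosis window (default 2006 through 2009) and
administratively censored at a fixed calendar date (default mid-2013), so
potential follow-up ranges from 3.5 to 7.5 years.

Background mortality is Gompertz in age with a log-linear calendar drift and
a per-quintile rate-ratio gradient; the excess hazard is Weibull with an EDI
effect acting on the log scale:

    lambda_E(t, edi) = lambda_0(t) * exp(b(t) * edi)

with b(t) = 0 (no effect, form 1), b(t) = beta (proportional, form 2), or
b(t) = beta * 1{t < tau} (effect vanishing after ``effect_decay_time``,
form 3) — all with closed-form cumulative hazards, so survival times are
drawn by exact inversion and the ground truth is analytic.

The EDI marginal is a shifted lognormal calibrated to the French summaries
(median about -0.75, range about -17..51); only these summaries, not the
true national distribution, are matched.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .lifetables import HazardPaths, LifeTable
from .lt_simulation import (
    ExternalRateSource,
    RateRatioTable,
    apply_rate_ratios,
    compute_rate_ratios,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "gen_truth_tables",
    "gen_cohort",
    "invert_piecewise_hazard",
    "cohort_summary",
]


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for one simulated registry cohort."""

    n: int = 20_000
    sex_mix: float = 0.5                    # share male
    age_mean: float = 70.0                  # truncated normal, years
    age_sd: float = 12.0
    age_bounds: tuple[float, float] = (15.0, 95.0)
    dx_window: tuple[float, float] = (2006.0, 2010.0)   # [1 Jan 2006, 31 Dec 2009]
    censor_date: float = 2013.5                          # 30 June 2013
    # shifted-lognormal EDI: edi = shift + LogNormal(mu, sigma), clipped
    edi_shift: float = -17.6
    edi_mu: float = 2.824
    edi_sigma: float = 0.4544
    edi_clip: tuple[float, float] = (-17.0, 51.0)
    quintile_cuts: tuple[float, ...] | None = None      # default: theoretical
    # background mortality: a0*exp(b*age)*exp(drift*(year-2006)), per sex factor
    gompertz_a: float = 5e-5
    gompertz_b: float = 0.092
    calendar_drift: float = -0.01
    sex_factors: tuple[float, float] = (1.0, 0.7)       # (male, female)
    background_rr: tuple[float, ...] = (0.80, 0.90, 1.00, 1.15, 1.35)
    lt_ages: tuple[int, int] = (0, 99)
    lt_years: tuple[int, int] = (2006, 2013)
    region: str = "R1"
    # excess hazard: Weibull(shape, scale) with EDI effect on the log scale
    excess_shape: float = 0.8
    excess_scale: float = 8.0
    edi_effect_form: int = 1
    effect_log_ehr: float = 0.0     # log EHR of EDI p90 (4.4) vs p10 (-3.9)
    effect_decay_time: float | None = None   # form 3: effect vanishes after tau
    edi_p10: float = -3.9
    edi_p90: float = 4.4

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.gompertz_a <= 0 or self.gompertz_b <= 0:
            raise ValueError("Gompertz parameters must be positive")
        if self.excess_shape <= 0 or self.excess_scale <= 0:
            raise ValueError("Weibull excess parameters must be positive")
        if len(self.background_rr) != 5 or any(r <= 0 for r in self.background_rr):
            raise ValueError("background_rr must be 5 positive ratios")
        if self.censor_date <= self.dx_window[0]:
            raise ValueError("censoring date precedes the diagnosis window")
        if self.edi_effect_form not in (1, 2, 3):
            raise ValueError("edi_effect_form must be 1, 2 or 3")
        if self.edi_effect_form == 3 and not self.effect_decay_time:
            raise ValueError("form-3 truth needs effect_decay_time")

    @property
    def effect_slope(self) -> float:
        """beta: log-EHR per EDI unit, scaled by the p90 - p10 span."""
        if self.edi_effect_form == 1:
            return 0.0
        return self.effect_log_ehr / (self.edi_p90 - self.edi_p10)

    def default_quintile_cuts(self) -> np.ndarray:
        if self.quintile_cuts is not None:
            return np.asarray(self.quintile_cuts, dtype=float)
        z = stats.norm.ppf([0.2, 0.4, 0.6, 0.8])
        return self.edi_shift + np.exp(self.edi_mu + self.edi_sigma * z)


@dataclasses.dataclass
class GroundTruth:
    """What the generator actually drew from, for recovery tests."""

    config: SimulationConfig
    stratified_lt: LifeTable
    quintile_cuts: np.ndarray
    latent_cause: np.ndarray        # 'excess' | 'background' | 'censored'
    true_form: int = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        self.true_form = self.config.edi_effect_form

    # -- analytic truth -----------------------------------------------------
    def excess_cumhaz(self, t: np.ndarray, edi: np.ndarray | float) -> np.ndarray:
        """Closed-form cumulative excess hazard Lambda_E(t; edi)."""
        c = self.config
        t = np.asarray(t, dtype=float)
        lam0 = (np.clip(t, 0.0, None) / c.excess_scale) ** c.excess_shape
        if c.edi_effect_form == 1:
            return lam0 + 0.0 * np.asarray(edi)
        mult = np.exp(c.effect_slope * np.asarray(edi, dtype=float))
        if c.edi_effect_form == 2:
            return lam0 * mult
        tau = float(c.effect_decay_time)
        lam_tau = (np.clip(np.minimum(t, tau), 0.0, None) / c.excess_scale) ** c.excess_shape
        return mult * lam_tau + (lam0 - lam_tau)

    def true_net_survival(self, t: np.ndarray, edi: np.ndarray | float) -> np.ndarray:
        return np.exp(-self.excess_cumhaz(t, edi))

    def true_ehr_p90_p10(self, t: np.ndarray) -> np.ndarray:
        c = self.config
        t = np.asarray(t, dtype=float)
        span = c.edi_p90 - c.edi_p10
        if c.edi_effect_form == 1:
            return np.ones_like(t)
        if c.edi_effect_form == 2:
            return np.full_like(t, np.exp(c.effect_slope * span))
        return np.where(t < c.effect_decay_time, np.exp(c.effect_slope * span), 1.0)


def _base_rate_array(config: SimulationConfig) -> tuple[np.ndarray, ...]:
    ages = np.arange(config.lt_ages[0], config.lt_ages[1] + 1)
    years = np.arange(config.lt_years[0], config.lt_years[1] + 1)
    sexes = ("male", "female")
    rates = (
        config.gompertz_a
        * np.exp(config.gompertz_b * ages)[None, None, :]
        * np.exp(config.calendar_drift * (years - years[0]))[None, :, None]
        * np.asarray(config.sex_factors)[:, None, None]
    )
    return sexes, years, ages, np.minimum(rates, 1.0)


def gen_truth_tables(
    config: SimulationConfig,
) -> tuple[LifeTable, LifeTable, ExternalRateSource]:
    """Base life table, true deprivation-stratified table, and an external
    source whose gradient reconstructs the stratified table.

    The stratified table is produced by running the life-table simulation
    pipeline (``compute_rate_ratios`` then ``apply_rate_ratios``) on the
    returned source, so the pipeline round-trip is exact by construction.
    """
    sexes, years, ages, rates = _base_rate_array(config)
    idx = pd.MultiIndex.from_product(
        [sexes, [config.region], years, ages],
        names=["sex", "region", "year", "age"],
    )
    base_frame = (
        pd.DataFrame({"rate": rates.reshape(-1)}, index=idx)
        .reset_index()[["sex", "age", "year", "region", "rate"]]
    )
    base = LifeTable(base_frame)

    # year-free external source: overall = year-averaged base rate, levels
    # carry the configured gradient
    overall = rates.mean(axis=1)  # (sex, age)
    rows = []
    for si, sex in enumerate(sexes):
        for ai, age in enumerate(ages):
            for d in range(1, 6):
                rows.append((sex, int(age), d, overall[si, ai] * config.background_rr[d - 1]))
    src = ExternalRateSource(
        pd.DataFrame(rows, columns=["sex", "age", "level", "rate"]),
        overall=pd.DataFrame(
            [(sex, int(age), overall[si, ai])
             for si, sex in enumerate(sexes) for ai, age in enumerate(ages)],
            columns=["sex", "age", "rate"],
        ),
    )
    stratified = apply_rate_ratios(base, compute_rate_ratios(src))
    return base, stratified, src


def invert_piecewise_hazard(
    breaks: np.ndarray, rates: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Draw survival times from one piecewise-constant hazard by inversion.

    Returns inf{t : Lambda(t) >= -log u} for each u in (0, 1]; +inf when the
    cumulative hazard never reaches the target (censored by design).
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if (u <= 0).any() or (u > 1).any():
        raise ValueError("u must lie in (0, 1]")
    n = u.shape[0]
    paths = HazardPaths(
        np.tile(np.asarray(breaks, dtype=float), (n, 1)),
        np.tile(np.asarray(rates, dtype=float), (n, 1)),
    )
    return paths.invert(-np.log(u))


def _draw_excess_times(
    config: SimulationConfig, edi: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Exact inversion of the closed-form excess cumulative hazard."""
    target = -np.log(u)
    k, scale = config.excess_shape, config.excess_scale
    if config.edi_effect_form == 1:
        return scale * target ** (1.0 / k)
    mult = np.exp(config.effect_slope * edi)
    if config.edi_effect_form == 2:
        return scale * (target / mult) ** (1.0 / k)
    tau = float(config.effect_decay_time)
    lam_tau = (tau / scale) ** k
    early = target <= mult * lam_tau
    t_early = scale * (target / mult) ** (1.0 / k)
    t_late = scale * (target - mult * lam_tau + lam_tau) ** (1.0 / k)
    return np.where(early, t_early, t_late)


def gen_cohort(
    config: SimulationConfig,
    stratified_lt: LifeTable,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one registry cohort under the configured study conditions.

    Observed time is min(background death, excess death, administrative
    censoring); the latent cause is recorded in the returned ground truth.
    """
    if config.censor_date <= config.dx_window[0]:
        raise ValueError("censoring date precedes the diagnosis window")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n

    sex = np.where(rng.uniform(size=n) < config.sex_mix, "male", "female").astype(object)
    lo, hi = config.age_bounds
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                              size=n, random_state=rng)
    year = rng.uniform(config.dx_window[0], config.dx_window[1], size=n)
    edi = config.edi_shift + rng.lognormal(config.edi_mu, config.edi_sigma, size=n)
    edi = np.clip(edi, *config.edi_clip)
    cuts = config.default_quintile_cuts()
    quintile = np.searchsorted(cuts, edi, side="left") + 1  # ties to lower quintile

    censor = config.censor_date - year
    horizon = float(np.ceil(config.censor_date - config.dx_window[0]))
    paths = stratified_lt.hazard_paths(
        sex, np.full(n, config.region, dtype=object), age, year,
        t_max=horizon, quintile=quintile,
    )
    t_bg = paths.invert(-np.log(rng.uniform(size=n)))
    t_ex = _draw_excess_times(config, edi, rng.uniform(size=n))

    t_obs = np.minimum(np.minimum(t_bg, t_ex), censor)
    status = (t_obs < censor).astype(int)
    cause = np.where(
        t_obs >= censor, "censored", np.where(t_ex <= t_bg, "excess", "background")
    )

    cohort = pd.DataFrame(
        {
            "id": np.arange(n),
            "sex": sex,
            "age_dx": age,
            "year_dx": year,
            "region": config.region,
            "edi": edi,
            "quintile": quintile,
            "time": t_obs,
            "status": status,
        }
    )
    truth = GroundTruth(
        config=config,
        stratified_lt=stratified_lt,
        quintile_cuts=cuts,
        latent_cause=cause,
    )
    return cohort, truth


def cohort_summary(cohort: pd.DataFrame) -> dict:
    """Marginal summaries of a cohort (EDI spread, quintile shares, ages)."""
    shares = (
        cohort["quintile"].value_counts(normalize=True).reindex(range(1, 6))
        .fillna(0.0)
    )
    return {
        "n": int(len(cohort)),
        "edi_median": float(cohort["edi"].median()),
        "edi_min": float(cohort["edi"].min()),
        "edi_max": float(cohort["edi"].max()),
        "age_min": float(cohort["age_dx"].min()),
        "age_max": float(cohort["age_dx"].max()),
        "quintile_shares": [float(s) for s in shares],
        "death_share": float(cohort["status"].mean()),
    }
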