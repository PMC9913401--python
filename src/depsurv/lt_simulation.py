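"""Simulation of deprivation-specific life tables.

National life tables are usually stratified by sex, age, calendar year and
region only.  To carry a socio-economic gradient into net-survival analyses,
deprivation-specific tables can be *simulated*: take an external source that
reports mortality by deprivation level (five quintiles, or twenty vingtiles of
e.g. household income), form the rate ratio of each level to the overall
population rate, and multiply the base life-table rate of every stratum by
those ratios.  The result is a life table additionally stratified by
deprivation quintile that preserves the base table's age/period structure
while exhibiting the external source's social gradient.

Pipeline: ``aggregate_vingtiles`` (20 -> 5 levels, when needed) ->
``compute_rate_ratios`` -> ``extend_years`` (carry the last covered year
forward) -> ``apply_rate_ratios``.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .lifetables import LifeTable, LifeTableError

logger = logging.getLogger(__name__)

__all__ = [
    "ExternalRateSource",
    "RateRatioTable",
    "read_external_source",
    "aggregate_vingtiles",
    "compute_rate_ratios",
    "extend_years",
    "apply_rate_ratios",
    "smooth_over_age",
]

_UNIT_SCALE = {"per_person_year": 1.0, "per_1000": 1e-3, "per_100000": 1e-5}


@dataclasses.dataclass
class ExternalRateSource:
    """Deprivation-graded mortality rates from an external source.

    ``rates`` has columns ``sex, age[, year], level, rate`` with levels 1..L
    (L = 5 or 20).  ``overall`` optionally gives the all-population rate per
    (sex, age[, year]); when absent, ``level_weights`` (population shares per
    level) must be provided so the overall can be formed as the weighted mean.
    """

    rates: pd.DataFrame
    overall: pd.DataFrame | None = None
    level_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        df = self.rates
        needed = {"sex", "age", "level", "rate"}
        if needed - set(df.columns):
            raise ValueError(f"rates frame needs columns {sorted(needed)}")
        if (df["rate"] < 0).any():
            raise ValueError("external rates must be >= 0")
        levels = np.sort(df["level"].unique())
        if not np.array_equal(levels, np.arange(1, len(levels) + 1)):
            raise ValueError(f"levels must be 1..L, got {levels}")
        counts = df.groupby(self._strata_cols())["level"].nunique()
        if (counts != len(levels)).any():
            raise ValueError("every stratum must carry all levels")
        if self.overall is None and self.level_weights is None:
            raise ValueError("need either an overall rate or level weights")
        if self.level_weights is not None:
            w = np.asarray(self.level_weights, dtype=float)
            if w.shape != (len(levels),) or (w < 0).any() or w.sum() <= 0:
                raise ValueError("level_weights must be L non-negative shares")
            self.level_weights = w / w.sum()

    def _strata_cols(self) -> list[str]:
        return ["sex", "age"] + (["year"] if self.has_year else [])

    @property
    def has_year(self) -> bool:
        return "year" in self.rates.columns

    @property
    def n_levels(self) -> int:
        return int(self.rates["level"].max())

    def overall_rates(self) -> pd.DataFrame:
        """Overall rate per stratum: supplied, or the weight-averaged levels."""
        if self.overall is not None:
            return self.overall.copy()
        w = dict(zip(range(1, self.n_levels + 1), self.level_weights))
        df = self.rates.copy()
        df["w"] = df["level"].map(w)
        g = df.groupby(self._strata_cols(), as_index=False).apply(
            lambda d: pd.Series({"rate": float(np.average(d["rate"], weights=d["w"]))}),
            include_groups=False,
        )
        return g.reset_index(drop=True)


@dataclasses.dataclass
class RateRatioTable:
    """Quintile-to-overall mortality rate ratios per (sex, age[, year])."""

    rr: pd.DataFrame  # columns sex, age[, year], quintile, rr

    def __post_init__(self) -> None:
        needed = {"sex", "age", "quintile", "rr"}
        if needed - set(self.rr.columns):
            raise ValueError(f"rr frame needs columns {sorted(needed)}")
        vals = self.rr["rr"].to_numpy()
        if (vals <= 0).any() or ~np.isfinite(vals).all():
            raise ValueError("rate ratios must be positive and finite")

    @property
    def has_year(self) -> bool:
        return "year" in self.rr.columns

    @property
    def years(self) -> np.ndarray:
        if not self.has_year:
            return np.array([], dtype=int)
        return np.sort(self.rr["year"].unique())


def read_external_source(path, units: str = "per_person_year") -> ExternalRateSource:
    """Read a delimited source (``sex,age[,year],level,rate[,weight]``).

    Rows with ``level == 0`` carry the overall all-population rate.  ``units``
    rescales the rate column to per person-year.
    """
    scale = _UNIT_SCALE[units]
    df = pd.read_csv(path)
    df["rate"] = df["rate"].astype(float) * scale
    overall = None
    if (df["level"] == 0).any():
        keep = ["sex", "age"] + (["year"] if "year" in df.columns else []) + ["rate"]
        overall = df.loc[df["level"] == 0, keep].reset_index(drop=True)
        df = df.loc[df["level"] != 0].reset_index(drop=True)
    weights = None
    if "weight" in df.columns:
        w = df.groupby("level")["weight"].mean().sort_index().to_numpy()
        df = df.drop(columns=["weight"])
        weights = w
    return ExternalRateSource(df, overall=overall, level_weights=weights)


def aggregate_vingtiles(src: ExternalRateSource) -> ExternalRateSource:
    """Collapse 20 vingtiles to 5 levels by averaging blocks 1-4, 5-8, ..., 17-20."""
    if src.n_levels != 20:
        raise ValueError(f"expected 20 levels, got {src.n_levels}")
    df = src.rates.copy()
    df["level"] = (df["level"] - 1) // 4 + 1
    agg = df.groupby(src._strata_cols() + ["level"], as_index=False)["rate"].mean()
    weights = None
    if src.level_weights is not None:
        weights = src.level_weights.reshape(5, 4).sum(axis=1)
    return ExternalRateSource(
        agg, overall=None if src.overall is None else src.overall.copy(),
        level_weights=weights,
    )


def smooth_over_age(src: ExternalRateSource, window: int = 5) -> ExternalRateSource:
    """Centered moving-average over age within (sex[, year], level), for raw sources."""
    df = src.rates.sort_values(src._strata_cols() + ["level"]).copy()
    group_cols = [c for c in ["sex", "year", "level"] if c in df.columns]
    df["rate"] = (
        df.sort_values("age")
        .groupby(group_cols)["rate"]
        .transform(lambda s: s.rolling(window, center=True, min_periods=1).mean())
    )
    return ExternalRateSource(
        df.reset_index(drop=True),
        overall=None if src.overall is None else src.overall.copy(),
        level_weights=src.level_weights,
    )


def compute_rate_ratios(src: ExternalRateSource) -> RateRatioTable:
    """Ratio of each deprivation level's rate to the overall population rate.

    Strata where the overall and every level rate are zero yield rr = 1; a
    zero overall against a non-zero level rate is an error.
    """
    if src.n_levels != 5:
        raise ValueError("rate ratios are computed on a 5-level source "
                         "(aggregate vingtiles first)")
    strata = src._strata_cols()
    overall = src.overall_rates().rename(columns={"rate": "overall"})
    merged = src.rates.merge(overall, on=strata, how="left", validate="m:1")
    if merged["overall"].isna().any():
        missing = merged.loc[merged["overall"].isna(), strata].drop_duplicates()
        raise ValueError(f"overall rate missing for strata:\n{missing.head()}")
    zero_over = merged["overall"] == 0
    bad = zero_over & (merged["rate"] > 0)
    if bad.any():
        raise ZeroDivisionError(
            "overall rate is zero with a non-zero level rate at "
            f"{merged.loc[bad, strata + ['level']].iloc[0].to_dict()}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = merged["rate"] / merged["overall"]
    rr = rr.where(~zero_over, 1.0)
    out = merged[strata + ["level"]].copy()
    out["rr"] = rr.astype(float)
    out = out.rename(columns={"level": "quintile"})
    return RateRatioTable(out)


def extend_years(rrt: RateRatioTable, target_years) -> RateRatioTable:
    """Cover ``target_years``: later years carry the last covered year's
    ratios forward, earlier years carry the first covered year backward.

    Year-free tables are returned unchanged (their ratios already apply to
    every year)."""
    target_years = np.asarray(sorted(set(int(y) for y in np.atleast_1d(target_years))))
    if target_years.size == 0:
        raise ValueError("empty set of target years")
    if not rrt.has_year:
        return RateRatioTable(rrt.rr.copy())
    covered = rrt.years
    pieces = [rrt.rr]
    for y in target_years:
        if y in covered:
            continue
        donor = covered[-1] if y > covered[-1] else covered[0]
        logger.info("extend_years: year %d takes ratios from covered year %d", y, donor)
        chunk = rrt.rr.loc[rrt.rr["year"] == donor].copy()
        chunk["year"] = y
        pieces.append(chunk)
    if len(pieces) == 1:  # targets already covered: identity
        return RateRatioTable(rrt.rr.copy())
    out = pd.concat(pieces, ignore_index=True)
    out = out.sort_values(["sex", "year", "age", "quintile"]).reset_index(drop=True)
    return RateRatioTable(out)


def _rr_lookup_arrays(rrt: RateRatioTable, sexes, years, ages) -> np.ndarray:
    """Dense rr array (n_sex, n_year, n_age, 5) by nearest-age matching."""
    out = np.empty((len(sexes), len(years), len(ages), 5))
    out.fill(np.nan)
    ages = np.asarray(ages)
    for si, sex in enumerate(sexes):
        for yi, year in enumerate(years):
            if rrt.has_year:
                sub = rrt.rr[(rrt.rr["sex"] == sex) & (rrt.rr["year"] == year)]
            else:
                sub = rrt.rr[rrt.rr["sex"] == sex]
            if sub.empty:
                raise LifeTableError(
                    f"no rate ratios for sex={sex!r}, year={year} (extend years first?)"
                )
            pivot = sub.pivot_table(index="age", columns="quintile", values="rr")
            src_ages = pivot.index.to_numpy()
            if pivot.isna().any().any() or pivot.shape[1] != 5:
                raise LifeTableError(f"incomplete quintile set for sex={sex!r}, year={year}")
            # nearest-age matching (coarser external grids expand to the base grid)
            pos = np.searchsorted(src_ages, ages)
            pos = np.clip(pos, 0, len(src_ages) - 1)
            left = np.clip(pos - 1, 0, len(src_ages) - 1)
            use_left = np.abs(ages - src_ages[left]) <= np.abs(src_ages[pos] - ages)
            nearest = np.where(use_left, left, pos)
            if not np.array_equal(np.sort(src_ages), np.sort(np.unique(ages))) and \
                    len(src_ages) < len(ages):
                logger.info(
                    "apply_rate_ratios: external age grid (%d points) expanded to "
                    "%d base ages by nearest matching (sex=%s, year=%s)",
                    len(src_ages), len(ages), sex, year,
                )
            out[si, yi] = pivot.to_numpy()[nearest]
    return out


def apply_rate_ratios(
    base: LifeTable,
    rrt: RateRatioTable,
    renormalize_weights: np.ndarray | None = None,
) -> LifeTable:
    """Multiply every base-table stratum's rate by the five quintile ratios.

    lambda_sim(sex, age, year, region, d) = lambda_base(sex, age, year, region)
    * rr(sex, age[, year], d).  With ``renormalize_weights`` the ratios are
    first divided by their weighted mean per stratum so that the
    population-average rate is preserved exactly (off by default).
    """
    if base.stratified_by_deprivation:
        raise LifeTableError("base life table is already deprivation-stratified")
    rr = _rr_lookup_arrays(rrt, base.sexes, base.years, base.ages)
    if renormalize_weights is not None:
        w = np.asarray(renormalize_weights, dtype=float)
        w = w / w.sum()
        rr = rr / np.tensordot(rr, w, axes=([3], [0]))[..., None]
    # base.rates is (sex, region, year, age); rr is (sex, year, age, 5)
    sim = base.rates[..., None] * rr[:, None, :, :, :]
    idx = pd.MultiIndex.from_product(
        [base.sexes, base.regions, base.years, base.ages, range(1, 6)],
        names=["sex", "region", "year", "age", "quintile"],
    )
    frame = pd.DataFrame({"rate": sim.reshape(-1)}, index=idx).reset_index()
    return LifeTable(frame[["sex", "age", "year", "region", "quintile", "rate"]])
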