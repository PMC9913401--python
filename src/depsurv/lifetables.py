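"""Life tables: expected (background) mortality of the general population.

A life table gives the all-cause mortality hazard ``lambda_P`` of the general
population on a grid of sex x age x calendar year x region, optionally further
stratified by deprivation quintile (1..5).  Rates are per person-year and are
treated as piecewise-constant on unit age x unit calendar-year cells, so that
the expected cumulative hazard of an individual followed from diagnosis is the
integral of the cell rates along the diagonal (age_dx + u, year_dx + u).

The module provides reading/writing of delimited life-table files, scalar rate
lookup, exact diagonal integration of the cumulative expected hazard, and a
vectorized per-subject piecewise-constant hazard representation
(:class:`HazardPaths`) used by the estimation and simulation modules.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LifeTable",
    "DemographicProfile",
    "HazardPaths",
    "LifeTableError",
    "CompletenessError",
    "read_life_table",
    "write_life_table",
    "lookup_rate",
    "cumulative_expected_hazard",
]

QUINTILES = (1, 2, 3, 4, 5)
SEXES = ("male", "female")


class LifeTableError(ValueError):
    """Invalid life-table content (negative rate, duplicate or unknown stratum)."""


class CompletenessError(LifeTableError):
    """The life-table grid has missing cells; the message lists absent strata."""


@dataclasses.dataclass(frozen=True)
class DemographicProfile:
    """Demographics ``z`` of one individual, used to address a life table.

    ``age_at_diagnosis`` and ``year_at_diagnosis`` are continuous; the life
    table is read along the diagonal (age + u, year + u) during follow-up.
    ``quintile`` is required iff the queried table is deprivation-stratified.
    """

    sex: str
    age_at_diagnosis: float
    year_at_diagnosis: float
    region: str
    quintile: int | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise LifeTableError(f"unknown sex {self.sex!r}; expected one of {SEXES}")
        if self.quintile is not None and self.quintile not in QUINTILES:
            raise LifeTableError(f"quintile must be in 1..5, got {self.quintile}")


class LifeTable:
    """Complete gridded mortality-rate table.

    Internally the rates are held in a dense array indexed
    ``[sex, region, year, age(, quintile)]`` for fast vectorized lookup.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        required = {"sex", "age", "year", "region", "rate"}
        missing_cols = required - set(frame.columns)
        if missing_cols:
            raise LifeTableError(f"missing columns: {sorted(missing_cols)}")
        self.stratified_by_deprivation = "quintile" in frame.columns

        frame["age"] = frame["age"].astype(int)
        frame["year"] = frame["year"].astype(int)
        frame["rate"] = frame["rate"].astype(float)
        frame["region"] = frame["region"].astype(str)
        bad_sex = set(frame["sex"].unique()) - set(SEXES)
        if bad_sex:
            raise LifeTableError(f"unknown sex values: {sorted(bad_sex)}")
        if (frame["rate"] < 0).any() or ~np.isfinite(frame["rate"]).all():
            bad = frame.loc[(frame["rate"] < 0) | ~np.isfinite(frame["rate"])]
            raise LifeTableError(
                f"{len(bad)} rate(s) negative or non-finite, e.g. row {bad.iloc[0].to_dict()}"
            )
        if self.stratified_by_deprivation:
            frame["quintile"] = frame["quintile"].astype(int)
            bad_q = set(frame["quintile"].unique()) - set(QUINTILES)
            if bad_q:
                raise LifeTableError(f"quintile values outside 1..5: {sorted(bad_q)}")

        self.sexes: tuple[str, ...] = tuple(s for s in SEXES if s in set(frame["sex"]))
        self.regions: tuple[str, ...] = tuple(sorted(frame["region"].unique()))
        self.years: np.ndarray = np.sort(frame["year"].unique())
        self.ages: np.ndarray = np.sort(frame["age"].unique())
        self.a_max: int = int(self.ages[-1])

        key_cols = ["sex", "region", "year", "age"]
        if self.stratified_by_deprivation:
            key_cols.append("quintile")
        dup = frame.duplicated(subset=key_cols)
        if dup.any():
            raise LifeTableError(
                f"duplicate stratum rows, e.g. {frame.loc[dup, key_cols].iloc[0].to_dict()}"
            )

        shape = [len(self.sexes), len(self.regions), len(self.years), len(self.ages)]
        if self.stratified_by_deprivation:
            shape.append(5)
        expected_n = int(np.prod(shape))
        if len(frame) != expected_n:
            self._raise_completeness(frame, key_cols)

        s_idx = frame["sex"].map({s: i for i, s in enumerate(self.sexes)}).to_numpy()
        r_idx = frame["region"].map({r: i for i, r in enumerate(self.regions)}).to_numpy()
        y_idx = np.searchsorted(self.years, frame["year"].to_numpy())
        a_idx = np.searchsorted(self.ages, frame["age"].to_numpy())
        rates = np.full(shape, np.nan)
        if self.stratified_by_deprivation:
            q_idx = frame["quintile"].to_numpy() - 1
            rates[s_idx, r_idx, y_idx, a_idx, q_idx] = frame["rate"].to_numpy()
        else:
            rates[s_idx, r_idx, y_idx, a_idx] = frame["rate"].to_numpy()
        if np.isnan(rates).any():
            self._raise_completeness(frame, key_cols)
        self.rates: np.ndarray = rates

    def _raise_completeness(self, frame: pd.DataFrame, key_cols: list[str]) -> None:
        index_levels = [self.sexes, self.regions, self.years, self.ages]
        names = ["sex", "region", "year", "age"]
        if self.stratified_by_deprivation:
            index_levels.append(QUINTILES)
            names.append("quintile")
        full = pd.MultiIndex.from_product(index_levels, names=names)
        have = pd.MultiIndex.from_frame(frame[names])
        absent = full.difference(have)
        examples = list(absent[:10])
        raise CompletenessError(
            f"life-table grid incomplete: {len(absent)} missing stratum cells, "
            f"e.g. {examples}"
        )

    # ---------------------------------------------------------------- frame
    def to_frame(self) -> pd.DataFrame:
        """Canonical long-format frame, sorted sex -> region -> year -> age -> quintile."""
        names = ["sex", "region", "year", "age"]
        levels = [self.sexes, self.regions, self.years, self.ages]
        if self.stratified_by_deprivation:
            names.append("quintile")
            levels.append(QUINTILES)
        idx = pd.MultiIndex.from_product(levels, names=names)
        df = pd.DataFrame({"rate": self.rates.reshape(-1)}, index=idx).reset_index()
        return df[["sex", "age", "year", "region"] + (
            ["quintile"] if self.stratified_by_deprivation else []) + ["rate"]]

    # --------------------------------------------------------------- lookup
    def _sex_index(self, sex: np.ndarray | Sequence[str]) -> np.ndarray:
        mapping = {s: i for i, s in enumerate(self.sexes)}
        out = np.array([mapping.get(s, -1) for s in np.asarray(sex, dtype=object)])
        if (out < 0).any():
            bad = sorted({s for s in np.asarray(sex, dtype=object) if s not in mapping})
            raise KeyError(f"sex value(s) not in table: {bad}")
        return out

    def _region_index(self, region: np.ndarray | Sequence[str]) -> np.ndarray:
        mapping = {r: i for i, r in enumerate(self.regions)}
        out = np.array([mapping.get(r, -1) for r in np.asarray(region, dtype=object)])
        if (out < 0).any():
            bad = sorted({r for r in np.asarray(region, dtype=object) if r not in mapping})
            raise KeyError(f"region value(s) not in table: {bad}")
        return out

    def _grid_rate(
        self,
        s_idx: np.ndarray,
        r_idx: np.ndarray,
        age: np.ndarray,
        year: np.ndarray,
        q_idx: np.ndarray | None,
    ) -> np.ndarray:
        """Rate of the unit cell containing (floor(age), floor(year)); clamped at edges."""
        a = np.floor(age).astype(int)
        y = np.floor(year).astype(int)
        n_clamp = int(((a < self.ages[0]) | (a > self.ages[-1])).sum()
                      + ((y < self.years[0]) | (y > self.years[-1])).sum())
        if n_clamp:
            logger.info("life-table lookup clamped %d age/year coordinates to grid edge", n_clamp)
        a_i = np.clip(np.searchsorted(self.ages, a, side="right") - 1, 0, len(self.ages) - 1)
        y_i = np.clip(np.searchsorted(self.years, y, side="right") - 1, 0, len(self.years) - 1)
        if self.stratified_by_deprivation:
            if q_idx is None:
                raise LifeTableError(
                    "life table is deprivation-stratified; a quintile is required"
                )
            return self.rates[s_idx, r_idx, y_i, a_i, q_idx]
        return self.rates[s_idx, r_idx, y_i, a_i]

    # ---------------------------------------------------------------- paths
    def hazard_paths(
        self,
        sex: Sequence[str] | np.ndarray,
        region: Sequence[str] | np.ndarray,
        age_dx: np.ndarray,
        year_dx: np.ndarray,
        t_max: float,
        quintile: np.ndarray | None = None,
    ) -> "HazardPaths":
        """Piecewise-constant expected hazards along each subject's diagonal.

        Breakpoints occur at every integer age and integer calendar-year
        crossing in ``[0, t_max]``; within a segment the rate is the life-table
        cell rate of the segment midpoint.
        """
        age_dx = np.asarray(age_dx, dtype=float)
        year_dx = np.asarray(year_dx, dtype=float)
        n = age_dx.shape[0]
        s_idx = self._sex_index(sex)
        r_idx = self._region_index(region)
        q_idx = None
        if self.stratified_by_deprivation:
            if quintile is None:
                raise LifeTableError(
                    "life table is deprivation-stratified; quintiles are required"
                )
            q = np.asarray(quintile, dtype=int)
            if ((q < 1) | (q > 5)).any():
                raise LifeTableError("quintiles must be in 1..5")
            q_idx = q - 1

        k = int(np.floor(t_max)) + 1
        ks = np.arange(k, dtype=float)
        # crossing times of integer ages / years; frac==0 -> first crossing at 1.0
        fa = age_dx - np.floor(age_dx)
        fy = year_dx - np.floor(year_dx)
        cross_a = (1.0 - fa)[:, None] + ks[None, :]
        cross_y = (1.0 - fy)[:, None] + ks[None, :]
        breaks = np.concatenate(
            [np.zeros((n, 1)), np.clip(cross_a, 0.0, t_max), np.clip(cross_y, 0.0, t_max),
             np.full((n, 1), float(t_max))],
            axis=1,
        )
        breaks.sort(axis=1)
        mids = 0.5 * (breaks[:, :-1] + breaks[:, 1:])
        m = mids.shape[1]
        seg_rates = self._grid_rate(
            np.repeat(s_idx, m),
            np.repeat(r_idx, m),
            (age_dx[:, None] + mids).reshape(-1),
            (year_dx[:, None] + mids).reshape(-1),
            np.repeat(q_idx, m) if q_idx is not None else None,
        ).reshape(n, m)
        return HazardPaths(breaks, seg_rates)


class HazardPaths:
    """Per-subject piecewise-constant hazard on ``[0, t_max]``.

    ``breaks`` has shape (n, K+1) with ``breaks[:, 0] == 0``; ``rates`` has
    shape (n, K).  Zero-length segments (duplicate breakpoints) are allowed.
    Evaluation beyond ``t_max`` extrapolates with the last segment's rate;
    :meth:`invert` instead returns +inf there (censored by design).
    """

    def __init__(self, breaks: np.ndarray, rates: np.ndarray):
        self.breaks = np.asarray(breaks, dtype=float)
        self.rates = np.asarray(rates, dtype=float)
        widths = np.diff(self.breaks, axis=1)
        if (widths < -1e-12).any():
            raise ValueError("breakpoints must be non-decreasing")
        if (self.rates < 0).any():
            raise ValueError("hazard rates must be non-negative")
        self.cum = np.concatenate(
            [np.zeros((self.breaks.shape[0], 1)),
             np.cumsum(self.rates * np.clip(widths, 0.0, None), axis=1)],
            axis=1,
        )
        self.t_max = self.breaks[:, -1]

    @property
    def n(self) -> int:
        return self.breaks.shape[0]

    def cumhaz_at(self, t: np.ndarray) -> np.ndarray:
        """Lambda(t_i) for one time per subject; t shape (n,) -> (n,)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros(self.n)
        last = self.rates.shape[1] - 1
        for k in range(last + 1):
            b0 = self.breaks[:, k]
            b1 = self.breaks[:, k + 1]
            if k == last:
                seg = np.clip(t - b0, 0.0, None)
            else:
                seg = np.clip(np.minimum(t, b1) - b0, 0.0, None)
            out += self.rates[:, k] * seg
        return out

    def cumhaz_grid(self, grid: np.ndarray) -> np.ndarray:
        """Lambda(u) for every subject at every grid time; (m,) -> (n, m)."""
        grid = np.asarray(grid, dtype=float)
        out = np.zeros((self.n, grid.shape[0]))
        last = self.rates.shape[1] - 1
        g = grid[None, :]
        for k in range(last + 1):
            b0 = self.breaks[:, k][:, None]
            b1 = self.breaks[:, k + 1][:, None]
            if k == last:
                seg = np.clip(g - b0, 0.0, None)
            else:
                seg = np.clip(np.minimum(g, b1) - b0, 0.0, None)
            out += self.rates[:, k][:, None] * seg
        return out

    def hazard_at(self, t: np.ndarray) -> np.ndarray:
        """lambda(t_i), right-continuous; t shape (n,) -> (n,)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros(self.n)
        last = self.rates.shape[1] - 1
        for k in range(last + 1):
            inside = (t >= self.breaks[:, k]) & (t < self.breaks[:, k + 1])
            out = np.where(inside, self.rates[:, k], out)
        return np.where(t >= self.breaks[:, -1], self.rates[:, -1], out)

    def hazard_grid(self, grid: np.ndarray) -> np.ndarray:
        """lambda(u) for every subject at every grid time; (m,) -> (n, m)."""
        grid = np.asarray(grid, dtype=float)
        out = np.zeros((self.n, grid.shape[0]))
        last = self.rates.shape[1] - 1
        g = grid[None, :]
        for k in range(last + 1):
            inside = (g >= self.breaks[:, k][:, None]) & (g < self.breaks[:, k + 1][:, None])
            out = np.where(inside, self.rates[:, k][:, None], out)
        return np.where(g >= self.breaks[:, -1][:, None], self.rates[:, -1][:, None], out)

    def survival_at(self, t: np.ndarray) -> np.ndarray:
        """Expected survival S_P(t) = exp(-Lambda(t)) per subject."""
        return np.exp(-self.cumhaz_at(t))

    def survival_grid(self, grid: np.ndarray) -> np.ndarray:
        return np.exp(-self.cumhaz_grid(grid))

    def invert(self, target: np.ndarray) -> np.ndarray:
        """inf{t : Lambda(t) >= target}; +inf when total mass falls short.

        Exact linear inversion within a segment — the sampling primitive for
        piecewise-exponential survival times.
        """
        target = np.asarray(target, dtype=float)
        if (target < 0).any():
            raise ValueError("target cumulative hazard must be >= 0")
        k1 = self.cum.shape[1]
        rows = np.arange(self.n)
        idx = np.empty(self.n, dtype=int)
        for i in range(self.n):  # K is small; per-row searchsorted is cheap
            idx[i] = np.searchsorted(self.cum[i], target[i], side="left")
        out = np.full(self.n, np.inf)
        inside = (idx >= 1) & (idx <= k1 - 1)
        j = np.clip(idx - 1, 0, k1 - 2)
        resid = target - self.cum[rows, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.breaks[rows, j] + resid / self.rates[rows, j]
        t = np.where(resid <= 0, self.breaks[rows, j], t)
        out[inside] = t[inside]
        out[target <= 0] = 0.0
        return out


# ------------------------------------------------------------------ file I/O

def read_life_table(path, prob: bool = False) -> LifeTable:
    """Read a delimited life table (columns sex,age,year,region[,quintile],rate).

    With ``prob=True`` the rate column holds annual death probabilities q and
    is converted to hazards via lambda = -log(1 - q).
    """
    df = pd.read_csv(path)
    if prob:
        q = df["rate"].astype(float)
        if (q >= 1).any() or (q < 0).any():
            raise LifeTableError("death probabilities must lie in [0, 1)")
        df["rate"] = -np.log1p(-q)
    return LifeTable(df)


def write_life_table(lt: LifeTable, path) -> None:
    """Write in canonical order so that write∘read is byte-stable."""
    lt.to_frame().to_csv(path, index=False)


# ------------------------------------------------------- scalar conveniences

def lookup_rate(
    lt: LifeTable,
    profile: DemographicProfile,
    current_age: float,
    current_year: float,
) -> float:
    """Rate of the unit cell containing (floor(current_age), floor(current_year))."""
    if current_age < 0:
        raise LifeTableError("current_age must be >= 0")
    if lt.stratified_by_deprivation and profile.quintile is None:
        raise LifeTableError("profile must carry a quintile for a stratified table")
    s = lt._sex_index([profile.sex])
    r = lt._region_index([profile.region])
    q = np.array([profile.quintile - 1]) if lt.stratified_by_deprivation else None
    return float(
        lt._grid_rate(s, r, np.array([current_age]), np.array([current_year]), q)[0]
    )


def cumulative_expected_hazard(lt: LifeTable, profile: DemographicProfile, t: float) -> float:
    """Lambda_P(t): exact integral of the cell rates along the diagnosis diagonal."""
    if t < 0:
        raise LifeTableError("t must be >= 0")
    if t == 0:
        return 0.0
    paths = lt.hazard_paths(
        [profile.sex],
        [profile.region],
        np.array([profile.age_at_diagnosis]),
        np.array([profile.year_at_diagnosis]),
        t_max=float(t),
        quintile=np.array([profile.quintile]) if lt.stratified_by_deprivation else None,
    )
    return float(paths.cum[0, -1])
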