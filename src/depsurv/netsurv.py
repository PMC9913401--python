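"""Non-parametric net survival: Pohar-Perme estimation and deprivation gaps.

Net survival is the survival that would be observed if the cancer under study
were the only cause of death.  In the relative-survival setting it is
estimated without cause-of-death information by weighting each subject's
counting process by the inverse of their expected survival ``S_Pi`` from a
population life table.  The cumulative excess hazard is

    L_E(t) =  sum_{event times u <= t} [sum_i dN_i(u)/S_Pi(u)]
                                      / [sum_i Y_i(u)/S_Pi(u)]
            - int_0^t [sum_i Y_i(u) lam_Pi(u)/S_Pi(u)]
                    / [sum_i Y_i(u)/S_Pi(u)] du

and NS(t) = exp(-L_E(t)); the estimator is unconstrained and may exceed 1.
The population integral is evaluated by the trapezoid rule on a grid holding
every follow-up time (death or censoring), every requested evaluation time,
and enough equally spaced interior points that no step exceeds
``grid_step`` (default one week, 1/52 year).  Tied death and censoring times
follow the standard risk-set convention: anyone with T_i >= u is at risk at
u, so deaths are processed before the coincident censorings.

Age-standardized net survival (ASNS) averages quintile- or cohort-level
curves over age groups with fixed weights (ICSS-style defaults); the
deprivation gap is the Q1 - Q5 difference in ASNS at a horizon, in
percentage points, with a delta-method confidence interval.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .lifetables import HazardPaths, LifeTable, LifeTableError

__all__ = [
    "NetSurvivalCurve",
    "DeprivationGap",
    "ICSS_AGE_GROUPS",
    "ICSS_WEIGHTS",
    "validate_cohort",
    "pohar_perme",
    "age_standardized_ns",
    "deprivation_gap",
    "read_cohort",
    "write_cohort",
]

#: Default age-standardization groups over [15, inf) and their weights.
ICSS_AGE_GROUPS: tuple[tuple[float, float], ...] = (
    (15.0, 45.0), (45.0, 55.0), (55.0, 65.0), (65.0, 75.0), (75.0, np.inf),
)
ICSS_WEIGHTS: tuple[float, ...] = (0.07, 0.12, 0.23, 0.29, 0.29)

COHORT_COLUMNS = [
    "id", "sex", "age_dx", "year_dx", "region", "edi", "quintile", "time", "status",
]


@dataclasses.dataclass
class NetSurvivalCurve:
    """Net survival estimate on a time grid.

    ``var`` is the variance of the cumulative excess hazard; ``var_ns`` the
    delta-method variance of NS itself (``NS^2 * var``).  Entries beyond the
    last follow-up time are NaN (curve truncated).
    """

    time: np.ndarray
    ns: np.ndarray
    var: np.ndarray
    var_ns: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    cum_excess_hazard: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "ns": self.ns,
                "var": self.var,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


@dataclasses.dataclass
class DeprivationGap:
    """Q1 - Q5 difference in age-standardized net survival, in % points."""

    gap: float
    se: float
    ci_low: float
    ci_high: float
    horizon: float
    quintiles: tuple[int, int]
    n_q1: int
    n_q5: int
    asns_q1: float
    asns_q5: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self) | {"quintiles": list(self.quintiles)}


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort schema and basic invariants; returns the frame."""
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort frame missing columns: {sorted(missing)}")
    t = cohort["time"].to_numpy(dtype=float)
    if (t < 0).any():
        raise ValueError("follow-up times must be >= 0")
    status = cohort["status"].to_numpy()
    if not np.isin(status, (0, 1)).all():
        raise ValueError("status must be 0 (censored) or 1 (dead)")
    if (cohort["age_dx"].to_numpy(dtype=float) < 15).any():
        raise ValueError("ages at diagnosis must be >= 15")
    return cohort


def read_cohort(path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def _paths_for(cohort: pd.DataFrame, lt: LifeTable, t_max: float) -> HazardPaths:
    q = None
    if lt.stratified_by_deprivation:
        q = cohort["quintile"].to_numpy(dtype=int)
    return lt.hazard_paths(
        cohort["sex"].to_numpy(dtype=object),
        cohort["region"].to_numpy(dtype=object),
        cohort["age_dx"].to_numpy(dtype=float),
        cohort["year_dx"].to_numpy(dtype=float),
        t_max=t_max,
        quintile=q,
    )


def integration_grid(knots: np.ndarray, step: float) -> np.ndarray:
    """Sorted grid containing every knot, refined so no gap exceeds ``step``."""
    knots = np.unique(np.asarray(knots, dtype=float))
    pieces = [knots]
    for a, b in zip(knots[:-1], knots[1:]):
        k = int(np.ceil((b - a) / step))
        if k > 1:
            pieces.append(a + (b - a) * np.arange(1, k) / k)
    return np.unique(np.concatenate(pieces))


def pohar_perme(
    cohort: pd.DataFrame,
    lt: LifeTable,
    eval_times: Sequence[float],
    grid_step: float = 1.0 / 52.0,
    _chunk: int = 2048,
) -> NetSurvivalCurve:
    """Pohar-Perme net survival of one cohort under one life table."""
    cohort = validate_cohort(cohort)
    eval_times = np.asarray(sorted(set(float(t) for t in eval_times)))
    if eval_times.size == 0 or (eval_times < 0).any():
        raise ValueError("eval_times must be non-empty and non-negative")
    t_max = float(eval_times[-1])

    T = cohort["time"].to_numpy(dtype=float)
    D = cohort["status"].to_numpy(dtype=int)
    n = T.shape[0]
    if n == 0:
        raise ValueError("empty cohort")
    paths = _paths_for(cohort, lt, t_max=max(t_max, 1e-9))

    # inverse-expected-survival weights at each subject's own follow-up time
    s_own = paths.survival_at(T)
    is_event = (D == 1) & (T <= t_max)
    event_times, ev_inverse = np.unique(T[is_event], return_inverse=True)
    num_dn = np.zeros(event_times.shape[0])   # sum dN/S at each event time
    num_dn2 = np.zeros(event_times.shape[0])  # sum dN/S^2
    np.add.at(num_dn, ev_inverse, 1.0 / s_own[is_event])
    np.add.at(num_dn2, ev_inverse, 1.0 / s_own[is_event] ** 2)

    # trapezoid grid: all follow-up times, all eval times, <= grid_step gaps
    knots = np.concatenate([[0.0], T[T <= t_max], eval_times])
    grid = integration_grid(knots, grid_step)
    den_grid = np.zeros(grid.shape[0])   # sum_i Y_i/S_i
    num_pop = np.zeros(grid.shape[0])    # sum_i Y_i lam_i/S_i
    for lo in range(0, grid.shape[0], _chunk):
        u = grid[lo:lo + _chunk]
        s = paths.survival_grid(u)
        lam = paths.hazard_grid(u)
        y = (T[:, None] >= u[None, :])
        inv_s = np.where(y, 1.0 / s, 0.0)
        den_grid[lo:lo + _chunk] = inv_s.sum(axis=0)
        num_pop[lo:lo + _chunk] = (inv_s * lam).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(den_grid > 0, num_pop / den_grid, 0.0)
    pop_cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (phi[1:] + phi[:-1]) * np.diff(grid))]
    )

    ev_pos = np.searchsorted(grid, event_times)
    den_ev = den_grid[ev_pos]
    term1_steps = np.where(den_ev > 0, num_dn / den_ev, 0.0)
    term1_cum = np.cumsum(term1_steps)
    var_steps = np.where(den_ev > 0, num_dn2 / den_ev**2, 0.0)
    var_cum = np.cumsum(var_steps)

    # assemble at the requested evaluation times
    ev_idx = np.searchsorted(event_times, eval_times, side="right")
    term1 = np.concatenate([[0.0], term1_cum])[ev_idx]
    var = np.concatenate([[0.0], var_cum])[ev_idx]
    grid_idx = np.searchsorted(grid, eval_times)
    cum_excess = term1 - pop_cum[grid_idx]

    last_followup = T.max()
    truncated = eval_times > last_followup
    if truncated.any():
        warnings.warn(
            f"risk set empty beyond t={last_followup:.4g}; curve truncated "
            f"at {int(truncated.sum())} evaluation time(s)",
            stacklevel=2,
        )
        cum_excess = np.where(truncated, np.nan, cum_excess)
        var = np.where(truncated, np.nan, var)

    ns = np.exp(-cum_excess)
    at_risk = (T[:, None] >= eval_times[None, :]).sum(axis=0)
    death_counts = np.bincount(ev_inverse, minlength=event_times.shape[0])
    n_events = np.concatenate([[0.0], np.cumsum(death_counts)])[ev_idx]
    return NetSurvivalCurve(
        time=eval_times,
        ns=ns,
        var=var,
        var_ns=ns**2 * var,
        at_risk=at_risk.astype(int),
        events=n_events.astype(int),
        cum_excess_hazard=cum_excess,
    )


def age_standardized_ns(
    cohort: pd.DataFrame,
    lt: LifeTable,
    eval_times: Sequence[float],
    age_groups: Sequence[tuple[float, float]] = ICSS_AGE_GROUPS,
    weights: Sequence[float] = ICSS_WEIGHTS,
    grid_step: float = 1.0 / 52.0,
) -> NetSurvivalCurve:
    """Weighted average of per-age-group Pohar-Perme curves.

    ASNS(t) = sum_g w_g NS_g(t) with Var = sum_g w_g^2 Var(NS_g); weights are
    renormalized over non-empty groups (with a warning) when a group has no
    members.
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(age_groups):
        raise ValueError("one weight per age group required")
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("weights must sum to 1")
    age = cohort["age_dx"].to_numpy(dtype=float)
    members = [(age >= lo) & (age < hi) for lo, hi in age_groups]
    nonempty = [m.any() for m in members]
    if not any(nonempty):
        raise ValueError("all age groups are empty")
    if not all(nonempty):
        warnings.warn(
            "empty age group(s); weights renormalized over non-empty groups",
            stacklevel=2,
        )
    w = np.where(nonempty, weights, 0.0)
    w = w / w.sum()

    eval_times = np.asarray(sorted(set(float(t) for t in eval_times)))
    asns = np.zeros(eval_times.shape[0])
    var_ns = np.zeros(eval_times.shape[0])
    at_risk = np.zeros(eval_times.shape[0], dtype=int)
    events = np.zeros(eval_times.shape[0], dtype=int)
    for g, mask in enumerate(members):
        if w[g] == 0.0:
            continue
        curve = pohar_perme(cohort.loc[mask], lt, eval_times, grid_step=grid_step)
        asns += w[g] * curve.ns
        var_ns += w[g] ** 2 * curve.var_ns
        at_risk += curve.at_risk
        events += curve.events
    return NetSurvivalCurve(
        time=eval_times,
        ns=asns,
        var=np.full_like(asns, np.nan),
        var_ns=var_ns,
        at_risk=at_risk,
        events=events,
    )


def deprivation_gap(
    cohort: pd.DataFrame,
    lt: LifeTable,
    horizon: float = 5.0,
    age_groups: Sequence[tuple[float, float]] = ICSS_AGE_GROUPS,
    weights: Sequence[float] = ICSS_WEIGHTS,
    grid_step: float = 1.0 / 52.0,
    quintiles: tuple[int, int] = (1, 5),
) -> DeprivationGap:
    """Difference (in % points) of ASNS at ``horizon`` between the least- and
    most-deprived quintiles, with a symmetric delta-method 95% CI."""
    q_lo, q_hi = quintiles
    sub_lo = cohort.loc[cohort["quintile"] == q_lo]
    sub_hi = cohort.loc[cohort["quintile"] == q_hi]
    if sub_lo.empty or sub_hi.empty:
        raise ValueError(f"cohort must contain members of quintiles {q_lo} and {q_hi}")
    curves = {}
    for q, sub in ((q_lo, sub_lo), (q_hi, sub_hi)):
        curves[q] = age_standardized_ns(
            sub, lt, [horizon], age_groups=age_groups, weights=weights,
            grid_step=grid_step,
        )
        if np.isnan(curves[q].ns[0]):
            raise ValueError(
                f"horizon {horizon} beyond the support of quintile {q}'s curve"
            )
    ns_lo = float(curves[q_lo].ns[0])
    ns_hi = float(curves[q_hi].ns[0])
    gap = 100.0 * (ns_lo - ns_hi)
    se = 100.0 * float(np.sqrt(curves[q_lo].var_ns[0] + curves[q_hi].var_ns[0]))
    return DeprivationGap(
        gap=gap,
        se=se,
        ci_low=gap - 1.96 * se,
        ci_high=gap + 1.96 * se,
        horizon=float(horizon),
        quintiles=(q_lo, q_hi),
        n_q1=int(len(sub_lo)),
        n_q5=int(len(sub_hi)),
        asns_q1=ns_lo,
        asns_q5=ns_hi,
    )
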