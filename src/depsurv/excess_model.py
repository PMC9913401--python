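"""Flexible excess-mortality-hazard regression with penalized splines.

The observed hazard of a cancer patient is decomposed as
``lambda(t, age, EDI, z) = lambda_E(t, age, EDI) + lambda_P(age+t, year+t, z)``
where ``lambda_P`` is the expected (background) hazard read from a life table
and treated as a fixed offset, and the excess hazard ``lambda_E`` is modeled
on the log scale with (tensor-product) cubic B-splines.

Four candidate forms describe how deprivation (the continuous EDI score) acts
on the excess hazard:

1. no EDI effect:                log lambda_E = f(t, age)
2. proportional effect:          log lambda_E = f(t, age) + g(EDI)
3. time-dependent effect:        log lambda_E = f(t, age) + g(EDI) + h(t, EDI)
4. time- and/or age-dependent:   log lambda_E = f(t, age, EDI)  (full tensor)

Form 3 is the span of ``tensor(t, age) + tensor(t, EDI)`` written in an
identifiable way: the EDI main effect and the pure t x EDI interaction use
sum-to-zero-constrained marginal bases (the raw additive tensor is
rank-deficient because both blocks contain every function of t alone).

The penalized log-likelihood

    l_pen(b) = sum_i [ d_i log(lambda_E(T_i; x_i) + lambda_Pi(T_i))
                        - int_0^{T_i} lambda_E(u; x_i) du ]
               - 1/2 sum_m s_m b' P_m b

uses Gauss-Legendre quadrature for the cumulative excess hazard, second-derivative curvature
penalties per marginal basis, and damped Newton optimization with
an analytic gradient and Hessian.  Smoothing levels are chosen by minimizing
the corrected AIC, and the best of the four forms is selected the same way.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, solve

from .lifetables import LifeTable
from .netsurv import validate_cohort

__all__ = [
    "ModelForm",
    "FORMS",
    "BasisConfig",
    "ExcessModelFit",
    "EHRCurve",
    "FitError",
    "fit_excess_hazard",
    "aicc",
    "select_model",
    "ehr_vs_edi",
    "ehr_p90_p10_over_time",
    "EDI_P10",
    "EDI_P90",
]

#: National EDI percentiles used as EHR reference abscissas.
EDI_P10 = -3.9
EDI_P90 = 4.4

#: Default AICc search grid for the shared smoothing level.
DEFAULT_PENALTY_GRID = tuple(10.0 ** np.arange(-2.0, 6.5, 1.0))


class FitError(RuntimeError):
    """Optimization failed; the message carries diagnostics."""


@dataclasses.dataclass(frozen=True)
class ModelForm:
    code: int
    description: str


FORMS: dict[int, ModelForm] = {
    1: ModelForm(1, "no EDI effect"),
    2: ModelForm(2, "proportional (not time-dependent) EDI effect"),
    3: ModelForm(3, "time-dependent EDI effect"),
    4: ModelForm(4, "time- and/or age-dependent EDI effect"),
}


@dataclasses.dataclass
class BasisConfig:
    """Knot layout of the marginal cubic B-spline bases.

    ``*_interior_q`` entries are quantile levels of the cohort distribution at
    which interior knots are placed.  The form-4 three-way tensor has its own
    (coarser by default) marginals so that the coefficient count stays modest.
    With ``edi_linear`` the form-2 EDI term is a single linear column instead
    of a spline.
    """

    time_bounds: tuple[float, float] = (0.0, 6.0)
    time_interior: tuple[float, ...] = (0.25, 1.0, 3.0)
    age_interior_q: tuple[float, ...] = (0.5,)
    edi_interior_q: tuple[float, ...] = (0.5,)
    tensor3_time_interior: tuple[float, ...] = (1.0,)
    tensor3_age_interior_q: tuple[float, ...] = ()
    tensor3_edi_interior_q: tuple[float, ...] = ()
    edi_linear: bool = False
    degree: int = 3
    penalty_order: int = 2


# --------------------------------------------------------------- marginals

class _Margin:
    """One marginal B-spline basis on a clamped knot vector."""

    def __init__(self, lo: float, hi: float, interior: Sequence[float], degree: int):
        interior = [k for k in interior if lo < k < hi]
        if hi <= lo:
            hi = lo + 1.0
        self.lo, self.hi, self.degree = float(lo), float(hi), int(degree)
        self.interior = tuple(float(k) for k in sorted(interior))
        self.knots = np.r_[
            np.full(degree + 1, self.lo), self.interior, np.full(degree + 1, self.hi)
        ]
        self.size = len(self.interior) + degree + 1

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def penalty(self, order: int) -> np.ndarray:
        """Curvature penalty: integral of products of order-th derivatives.

        Exact by Gauss-Legendre per knot span (the integrand is piecewise
        polynomial); its null space contains all polynomials below ``order``,
        so e.g. linear effects are never shrunk by the default order 2.
        """
        xq, wq = np.polynomial.legendre.leggauss(self.degree + 1)
        spans = np.unique(self.knots)
        out = np.zeros((self.size, self.size))
        eye = np.eye(self.size)
        for lo, hi in zip(spans[:-1], spans[1:]):
            pts = 0.5 * (hi - lo) * (xq + 1.0) + lo
            w = 0.5 * (hi - lo) * wq
            d = np.column_stack([
                BSpline(self.knots, eye[j], self.degree).derivative(order)(pts)
                for j in range(self.size)
            ])
            out += (d * w[:, None]).T @ d
        return out

    def describe(self) -> dict:
        return {"bounds": [self.lo, self.hi], "interior": list(self.interior),
                "degree": self.degree}


def _row_kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a[:, :, None] * b[:, None, :]).reshape(a.shape[0], -1)


def _nullspace_transform(c: np.ndarray) -> np.ndarray:
    """Orthonormal basis Z of the null space of the 1 x p constraint c."""
    q, _ = np.linalg.qr(np.atleast_2d(c).T, mode="complete")
    return q[:, 1:]


class _Block:
    """One additive block: frozen design builder plus its penalties."""

    def __init__(self, margins, vars_, transform, penalties, label):
        self.margins = margins          # list of _Margin (or None for linear)
        self.vars = vars_               # e.g. ("t", "age")
        self.transform = transform      # Z (p_raw x p) or None
        self.penalties = penalties      # list of (p x p) in the final space
        self.label = label

    def design(self, pts: dict[str, np.ndarray]) -> np.ndarray:
        if self.margins is None:  # linear EDI column
            x = np.asarray(pts["edi"], dtype=float)
            raw = (x - self.transform)[:, None]  # transform holds the center
            return raw
        mats = [m.design(pts[v]) for m, v in zip(self.margins, self.vars)]
        out = mats[0]
        for m in mats[1:]:
            out = _row_kron(out, m)
        if self.transform is not None:
            out = out @ self.transform
        return out

    @property
    def size(self) -> int:
        if self.margins is None:
            return 1
        p = int(np.prod([m.size for m in self.margins]))
        return p if self.transform is None else self.transform.shape[1]


class FormBasis:
    """Design/penalty builder for one model form, frozen on the fit cohort."""

    def __init__(self, form: int, config: BasisConfig, cohort: pd.DataFrame):
        if form not in FORMS:
            raise ValueError(f"form must be 1..4, got {form}")
        self.form = form
        self.config = config
        age = cohort["age_dx"].to_numpy(dtype=float)
        edi = cohort["edi"].to_numpy(dtype=float)
        deg, order = config.degree, config.penalty_order

        def quantile_knots(x, qs):
            return tuple(float(np.quantile(x, q)) for q in qs)

        t_lo, t_hi = config.time_bounds
        self.edi_range = (float(edi.min()), float(edi.max()))
        m_t = _Margin(t_lo, t_hi, config.time_interior, deg)
        m_a = _Margin(age.min(), age.max(), quantile_knots(age, config.age_interior_q), deg)
        m_e = _Margin(*self.edi_range, quantile_knots(edi, config.edi_interior_q), deg)

        blocks: list[_Block] = []
        if form == 4:
            m3t = _Margin(t_lo, t_hi, config.tensor3_time_interior, deg)
            m3a = _Margin(age.min(), age.max(),
                          quantile_knots(age, config.tensor3_age_interior_q), deg)
            m3e = _Margin(*self.edi_range,
                          quantile_knots(edi, config.tensor3_edi_interior_q), deg)
            sizes = [m3t.size, m3a.size, m3e.size]
            pens = []
            for k, m in enumerate((m3t, m3a, m3e)):
                mats = [m.penalty(order) if j == k else np.eye(sizes[j])
                        for j in range(3)]
                pens.append(np.kron(np.kron(mats[0], mats[1]), mats[2]))
            blocks.append(_Block([m3t, m3a, m3e], ("t", "age", "edi"), None, pens,
                                 "tensor(t,age,edi)"))
        else:
            pens = [np.kron(m_t.penalty(order), np.eye(m_a.size)),
                    np.kron(np.eye(m_t.size), m_a.penalty(order))]
            blocks.append(_Block([m_t, m_a], ("t", "age"), None, pens,
                                 "tensor(t,age)"))
            if form >= 2:
                if config.edi_linear:
                    blocks.append(_Block(None, ("edi",), float(edi.mean()), [],
                                         "linear(edi)"))
                else:
                    raw = m_e.design(edi)
                    z_e = _nullspace_transform(raw.mean(axis=0))
                    blocks.append(_Block([m_e], ("edi",), z_e,
                                         [z_e.T @ m_e.penalty(order) @ z_e],
                                         "smooth(edi)"))
            if form == 3:
                t_obs = cohort["time"].to_numpy(dtype=float)
                raw_t = m_t.design(np.clip(t_obs, t_lo, t_hi))
                z_t = _nullspace_transform(raw_t.mean(axis=0))
                raw_e = m_e.design(edi)
                z_e2 = _nullspace_transform(raw_e.mean(axis=0))
                zz = np.kron(z_t, z_e2)
                p_t = z_t.T @ m_t.penalty(order) @ z_t
                p_e = z_e2.T @ m_e.penalty(order) @ z_e2
                pens = [np.kron(p_t, np.eye(z_e2.shape[1])),
                        np.kron(np.eye(z_t.shape[1]), p_e)]
                blocks.append(_Block([m_t, m_e], ("t", "edi"), zz, pens,
                                     "interaction(t,edi)"))
        self.blocks = blocks
        self.sizes = [b.size for b in blocks]
        self.p = int(sum(self.sizes))
        self.penalties = self._embed_penalties()

    def _embed_penalties(self) -> list[np.ndarray]:
        out = []
        offsets = np.concatenate([[0], np.cumsum(self.sizes)])
        for b, off in zip(self.blocks, offsets[:-1]):
            for pen in b.penalties:
                full = np.zeros((self.p, self.p))
                full[off:off + b.size, off:off + b.size] = pen
                out.append(full)
        return out

    def design(self, t: np.ndarray, age: np.ndarray, edi: np.ndarray) -> np.ndarray:
        pts = {
            "t": np.asarray(t, dtype=float),
            "age": np.asarray(age, dtype=float),
            "edi": np.asarray(edi, dtype=float),
        }
        return np.concatenate([b.design(pts) for b in self.blocks], axis=1)

    def describe(self) -> dict:
        return {
            "form": self.form,
            "blocks": [
                {"label": b.label, "size": b.size,
                 "margins": None if b.margins is None
                 else [m.describe() for m in b.margins]}
                for b in self.blocks
            ],
        }


# ------------------------------------------------------------- likelihood

class ExcessHazardModel:
    """Data, design matrices and penalized likelihood for one form.

    Public for testing: :meth:`loglik`, :meth:`score`, :meth:`hessian`
    evaluate the *penalized* quantities at an arbitrary coefficient vector
    (with ``penalty_scale=0`` they are unpenalized).
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        lt: LifeTable | None,
        basis: FormBasis,
        gl_nodes: int = 12,
        time_horizon: float = 6.0,
    ):
        cohort = validate_cohort(cohort)
        t_raw = cohort["time"].to_numpy(dtype=float)
        d_raw = cohort["status"].to_numpy(dtype=int)
        self.T = np.minimum(t_raw, time_horizon)
        self.delta = np.where(t_raw <= time_horizon, d_raw, 0)
        self.n = self.T.shape[0]
        self.n_events = int(self.delta.sum())
        age = cohort["age_dx"].to_numpy(dtype=float)
        edi = cohort["edi"].to_numpy(dtype=float)
        self.age = age
        self.edi = edi
        self.basis = basis

        if lt is None:
            self.offset = np.zeros(self.n)
        else:
            from .netsurv import _paths_for
            paths = _paths_for(cohort, lt, t_max=time_horizon)
            self.offset = paths.hazard_at(self.T)

        self.X_ev = basis.design(self.T, age, edi)
        xq, wq = np.polynomial.legendre.leggauss(gl_nodes)
        s = 0.5 * self.T[:, None] * (xq[None, :] + 1.0)          # (n, Q)
        self.w_gl = (0.5 * self.T[:, None] * wq[None, :]).reshape(-1)
        self.X_gl = basis.design(
            s.reshape(-1), np.repeat(age, gl_nodes), np.repeat(edi, gl_nodes)
        )
        self.penalties = basis.penalties
        self.gl_nodes = gl_nodes

    # s: smoothing parameters, one per penalty
    def _pen_matrix(self, s: np.ndarray) -> np.ndarray:
        p = np.zeros((self.basis.p, self.basis.p))
        for si, pm in zip(s, self.penalties):
            p += si * pm
        return p

    def loglik(self, beta: np.ndarray, s: np.ndarray | float = 0.0) -> float:
        s = self._as_s(s)
        eta_ev = self.X_ev @ beta
        lam = np.exp(np.minimum(eta_ev, 40.0))
        mu = lam + self.offset
        if (mu[self.delta == 1] <= 0).any():
            return -np.inf
        ll = float(np.sum(self.delta * np.log(np.where(self.delta == 1, mu, 1.0))))
        ll -= float(self.w_gl @ np.exp(np.minimum(self.X_gl @ beta, 40.0)))
        if s.any():
            ll -= 0.5 * float(beta @ self._pen_matrix(s) @ beta)
        return ll

    def score(self, beta: np.ndarray, s: np.ndarray | float = 0.0) -> np.ndarray:
        s = self._as_s(s)
        eta_ev = self.X_ev @ beta
        lam = np.exp(np.minimum(eta_ev, 40.0))
        rho = np.where(self.delta == 1, lam / (lam + self.offset), 0.0)
        g = self.X_ev.T @ rho
        g -= self.X_gl.T @ (self.w_gl * np.exp(np.minimum(self.X_gl @ beta, 40.0)))
        if s.any():
            g -= self._pen_matrix(s) @ beta
        return g

    def hessian(self, beta: np.ndarray, s: np.ndarray | float = 0.0) -> np.ndarray:
        s = self._as_s(s)
        eta_ev = self.X_ev @ beta
        lam = np.exp(np.minimum(eta_ev, 40.0))
        rho = np.where(self.delta == 1, lam / (lam + self.offset), 0.0)
        w1 = rho * (1.0 - rho)
        h = (self.X_ev * w1[:, None]).T @ self.X_ev
        w2 = self.w_gl * np.exp(np.minimum(self.X_gl @ beta, 40.0))
        h -= (self.X_gl * w2[:, None]).T @ self.X_gl
        if s.any():
            h -= self._pen_matrix(s)
        return h

    def _as_s(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if s.ndim == 0:
            s = np.full(len(self.penalties), float(s))
        if s.shape[0] != len(self.penalties):
            raise ValueError(f"expected {len(self.penalties)} smoothing parameters")
        return s

    def _init_beta(self) -> np.ndarray:
        total_time = float(self.T.sum())
        level = np.log(max(self.n_events, 1) / max(total_time, 1e-12) + 1e-12)
        beta = np.zeros(self.basis.p)
        # first block's product basis sums to 1 row-wise, so a constant
        # coefficient there sets a flat log-hazard at the crude event rate
        beta[: self.basis.sizes[0]] = level
        return beta

    def newton(
        self,
        s: np.ndarray | float,
        beta0: np.ndarray | None = None,
        tol: float = 1e-6,
        max_iter: int = 100,
        restarts: int = 5,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Damped Newton maximization of the penalized log-likelihood."""
        s = self._as_s(s)
        base0 = self._init_beta() if beta0 is None else np.asarray(beta0, float)
        rng = rng or np.random.default_rng(0)
        last_diag = ""
        for attempt in range(restarts + 1):
            beta = base0 if attempt == 0 else (
                self._init_beta() + rng.normal(0.0, 0.1 * attempt, self.basis.p)
            )
            ll = self.loglik(beta, s)
            if not np.isfinite(ll):
                beta = self._init_beta()
                ll = self.loglik(beta, s)
            ok = False
            for _ in range(max_iter):
                g = self.score(beta, s)
                if np.max(np.abs(g)) < tol * max(1.0, abs(ll)) or np.max(np.abs(g)) < tol:
                    ok = True
                    break
                h = self.hessian(beta, s)
                a = -h
                tau = 0.0
                for _ in range(12):
                    try:
                        chol = cho_factor(a + tau * np.eye(a.shape[0]), lower=True)
                        break
                    except np.linalg.LinAlgError:
                        tau = max(2.0 * tau, 1e-8 * (1.0 + np.abs(np.diag(a)).max()))
                else:
                    break
                step = cho_solve(chol, g)
                alpha = 1.0
                improved = False
                for _ in range(40):
                    cand = beta + alpha * step
                    ll_new = self.loglik(cand, s)
                    if np.isfinite(ll_new) and ll_new > ll - 1e-12:
                        beta, ll = cand, ll_new
                        improved = True
                        break
                    alpha *= 0.5
                if not improved:
                    break
            if ok:
                return beta
            last_diag = (
                f"attempt {attempt}: |score|={np.max(np.abs(self.score(beta, s))):.3g}, "
                f"ll={ll:.6g}"
            )
        raise FitError(
            f"Newton did not converge after {restarts + 1} starts "
            f"(s={np.asarray(s).ravel()}); last: {last_diag}"
        )


# ------------------------------------------------------------------- fits

@dataclasses.dataclass
class ExcessModelFit:
    """A fitted excess-hazard model with its selection metadata."""

    form: int
    basis: FormBasis
    beta: np.ndarray
    covariance: np.ndarray
    smoothing: np.ndarray
    edf: float
    loglik: float            # unpenalized, at beta
    penalized_loglik: float
    aicc: float
    n_events: int
    model: ExcessHazardModel

    def predict_log_hazard(self, t, age, edi) -> np.ndarray:
        x = self.basis.design(np.atleast_1d(t), np.atleast_1d(age), np.atleast_1d(edi))
        return x @ self.beta

    def summary(self) -> dict:
        return {
            "form": self.form,
            "description": FORMS[self.form].description,
            "edf": self.edf,
            "aicc": self.aicc,
            "loglik": self.loglik,
            "n_events": self.n_events,
            "smoothing": list(np.asarray(self.smoothing, float)),
            "basis": self.basis.describe(),
            "coefficients": list(self.beta),
            "covariance": list(self.covariance.reshape(-1)),
        }


def _edf_cov(model: ExcessHazardModel, beta: np.ndarray, s: np.ndarray):
    h_unpen = -model.hessian(beta, 0.0)
    h_pen = h_unpen + model._pen_matrix(s)
    cov = np.linalg.inv(h_pen)
    edf = float(np.trace(solve(h_pen, h_unpen)))
    edf = min(max(edf, 0.0), model.basis.p)
    return edf, cov


def _aicc_value(loglik: float, edf: float, n_events: int) -> float:
    if n_events <= edf + 1:
        raise ValueError(
            f"AICc undefined: n_events={n_events} <= EDF+1={edf + 1:.2f}"
        )
    return -2.0 * loglik + 2.0 * edf + 2.0 * edf * (edf + 1.0) / (n_events - edf - 1.0)


def aicc(fit: ExcessModelFit) -> float:
    """Corrected AIC from the unpenalized log-likelihood and the EDF."""
    return _aicc_value(fit.loglik, fit.edf, fit.n_events)


def fit_excess_hazard(
    cohort: pd.DataFrame,
    lt: LifeTable | None,
    form: int,
    basis_config: BasisConfig | None = None,
    penalty_grid: Sequence[float] = DEFAULT_PENALTY_GRID,
    gl_nodes: int = 12,
    time_horizon: float = 6.0,
    coordinate_sweeps: int = 0,
    tol: float = 1e-6,
) -> ExcessModelFit:
    """Fit one model form; smoothing chosen on ``penalty_grid`` by AICc.

    The default search applies one shared smoothing level to every penalty
    (warm-started across the grid); ``coordinate_sweeps > 0`` refines each
    penalty's level coordinate-wise on the same grid afterwards.
    ``lt=None`` fits with a zero background offset (all-cause reduction).
    """
    config = basis_config or BasisConfig()
    if cohort.empty:
        raise ValueError("empty cohort")
    basis = FormBasis(form, config, cohort)
    model = ExcessHazardModel(cohort, lt, basis, gl_nodes=gl_nodes,
                              time_horizon=time_horizon)
    if model.n_events == 0:
        raise FitError("no events in cohort after truncation")
    n_pen = len(model.penalties)
    grid = [float(g) for g in penalty_grid]

    best = None
    if n_pen == 0:
        beta = model.newton(0.0, tol=tol)
        best = (np.zeros(0), beta)
    else:
        beta_ws = None
        for g in sorted(grid, reverse=True):  # smooth -> rough, warm-started
            s = np.full(n_pen, g)
            try:
                beta = model.newton(s, beta0=beta_ws, tol=tol)
            except FitError:
                warnings.warn(f"fit failed at smoothing {g:g}; skipped", stacklevel=2)
                continue
            beta_ws = beta
            edf, _ = _edf_cov(model, beta, s)
            try:
                crit = _aicc_value(model.loglik(beta, 0.0), edf, model.n_events)
            except ValueError:
                continue
            if best is None or crit < best[0] - 0.0:
                best = (crit, s, beta)
        if best is None:
            raise FitError("no smoothing level produced a valid fit")
        _, s_best, beta = best
        for _ in range(coordinate_sweeps):
            for m in range(n_pen):
                for g in grid:
                    s_try = s_best.copy()
                    s_try[m] = g
                    try:
                        b_try = model.newton(s_try, beta0=beta, tol=tol)
                    except FitError:
                        continue
                    edf, _ = _edf_cov(model, b_try, s_try)
                    try:
                        crit = _aicc_value(model.loglik(b_try, 0.0), edf,
                                           model.n_events)
                    except ValueError:
                        continue
                    if crit < best[0] - 1e-9:
                        best = (crit, s_try, b_try)
                        s_best, beta = s_try, b_try
        best = (s_best, beta)

    s_final, beta = best
    edf, cov = _edf_cov(model, beta, s_final if n_pen else 0.0)
    ll = model.loglik(beta, 0.0)
    return ExcessModelFit(
        form=form,
        basis=basis,
        beta=beta,
        covariance=cov,
        smoothing=np.asarray(s_final, float),
        edf=edf,
        loglik=ll,
        penalized_loglik=model.loglik(beta, s_final if n_pen else 0.0),
        aicc=_aicc_value(ll, edf, model.n_events),
        n_events=model.n_events,
        model=model,
    )


def select_model(
    cohort: pd.DataFrame,
    lt: LifeTable | None,
    basis_config: BasisConfig | None = None,
    penalty_grid: Sequence[float] = DEFAULT_PENALTY_GRID,
    gl_nodes: int = 12,
    time_horizon: float = 6.0,
    forms: Sequence[int] = (1, 2, 3, 4),
) -> tuple[ExcessModelFit, dict[int, float]]:
    """Fit all candidate forms and return the minimum-AICc fit.

    Ties (difference < 1e-6) break toward the lower form code (parsimony);
    forms that fail to fit are excluded with a warning."""
    fits: dict[int, ExcessModelFit] = {}
    table: dict[int, float] = {}
    for form in forms:
        try:
            fit = fit_excess_hazard(
                cohort, lt, form, basis_config=basis_config,
                penalty_grid=penalty_grid, gl_nodes=gl_nodes,
                time_horizon=time_horizon,
            )
        except (FitError, ValueError) as exc:
            warnings.warn(f"form {form} failed: {exc}", stacklevel=2)
            table[form] = float("nan")
            continue
        fits[form] = fit
        table[form] = fit.aicc
    if not fits:
        raise FitError("all candidate forms failed to fit")
    best_val = min(f.aicc for f in fits.values())
    best_form = min(c for c, f in fits.items() if f.aicc < best_val + 1e-6)
    return fits[best_form], table


# ------------------------------------------------------------- EHR curves

@dataclasses.dataclass
class EHRCurve:
    """Excess hazard ratio along an abscissa, with delta-method 95% CI."""

    abscissa: np.ndarray
    ehr: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    reference: float | tuple[float, float]
    age: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"abscissa": self.abscissa, "ehr": self.ehr, "lo": self.lo, "hi": self.hi}
        )
        if self.age is not None:
            df["age"] = self.age
        return df


def _ehr_from_contrast(fit: ExcessModelFit, d: np.ndarray):
    log_ehr = d @ fit.beta
    var = np.einsum("ij,jk,ik->i", d, fit.covariance, d)
    sd = np.sqrt(np.clip(var, 0.0, None))
    return np.exp(log_ehr), np.exp(log_ehr - 1.96 * sd), np.exp(log_ehr + 1.96 * sd)


def ehr_vs_edi(
    fit: ExcessModelFit,
    t_fixed: float,
    age_fixed: float,
    ref_edi: float = EDI_P10,
    edi_grid: Sequence[float] | None = None,
) -> EHRCurve:
    """EHR(e) = lambda_E(t0, age0, e) / lambda_E(t0, age0, ref) over an EDI grid."""
    lo_e, hi_e = fit.basis.edi_range
    if edi_grid is None:
        edi_grid = np.linspace(lo_e, hi_e, 50)
    edi_grid = np.asarray(edi_grid, dtype=float)
    if (edi_grid < lo_e - 1e-9).any() or (edi_grid > hi_e + 1e-9).any():
        warnings.warn("EDI grid extends beyond the basis support; values are "
                      "clamped to the boundary", stacklevel=2)
    m = edi_grid.shape[0]
    x = fit.basis.design(np.full(m, t_fixed), np.full(m, age_fixed), edi_grid)
    x_ref = fit.basis.design([t_fixed], [age_fixed], [ref_edi])
    ehr, lo, hi = _ehr_from_contrast(fit, x - x_ref)
    return EHRCurve(edi_grid, ehr, lo, hi, reference=float(ref_edi))


def ehr_p90_p10_over_time(
    fit: ExcessModelFit,
    time_grid: Sequence[float],
    ages: Sequence[float] | None = None,
    p90: float = EDI_P90,
    p10: float = EDI_P10,
) -> list[EHRCurve]:
    """EHR of EDI p90 vs p10 as a function of follow-up time, one curve per age.

    Default ages are the 25th/50th/75th percentiles of the fitted cohort's
    age-at-diagnosis distribution."""
    time_grid = np.asarray(time_grid, dtype=float)
    if ages is None:
        ages = list(np.quantile(fit.model.age, [0.25, 0.5, 0.75]))
    curves = []
    m = time_grid.shape[0]
    for age in ages:
        x90 = fit.basis.design(time_grid, np.full(m, age), np.full(m, p90))
        x10 = fit.basis.design(time_grid, np.full(m, age), np.full(m, p10))
        ehr, lo, hi = _ehr_from_contrast(fit, x90 - x10)
        curves.append(EHRCurve(time_grid, ehr, lo, hi,
                               reference=(p10, p90), age=float(age)))
    return curves
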