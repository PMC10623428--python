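"""Damped-oscillation modelling of glucose and insulin tolerance tests.

Blood glucose after an intraperitoneal glucose (GTT) or insulin (ITT)
bolus is modelled as a damped harmonic return to a regulated setpoint:

    G(t) = G0 + A * exp(-alpha * t) * sin(2*pi*t/T + phi)

with setpoint ``G0`` (mg/dL, the asymptote), amplitude ``A`` (mg/dL),
damping coefficient ``alpha`` (1/h), basic period ``T`` (h) and phase
``phi`` (rad).  Time is in hours everywhere inside this module; minute
grids are converted at the I/O boundary.

From the fitted model a panel of glycemic parameters is derived:
fasting glucose G(0), the curve extremum (maximum for GTT, first local
minimum for ITT) and its time, the 2-h value G(2), the initial slope
G'(0), the steepest post-peak fall G'_I with its time t_I and glucose
level G_I, and the area under the model curve in closed form alongside
the trapezoidal AUC of the raw measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ToleranceTestSeries",
    "DampedOscillationModel",
    "GlycemicParameters",
    "DampedOscillatorRegressor",
    "damped_oscillation",
    "damped_oscillation_slope",
    "model_auc",
    "fit_damped_oscillator",
    "fit_group_curve",
    "derive_parameters",
    "auc_trapezoid",
]

#: Default box constraints of the nonlinear fit.
DEFAULT_BOUNDS = {
    "G0": (0.0, 1000.0),
    "A": (0.0, 1000.0),
    "alpha": (0.0, 20.0),  # 1/h
    "T": (0.5, 24.0),  # h
    "phi": (-math.pi, math.pi),
}

MIN_POINTS = 6  # 5 free parameters + 1 residual degree of freedom


@dataclass(frozen=True)
class ToleranceTestSeries:
    """One glucose time series from a GTT or ITT.

    times are in hours, strictly increasing, starting at 0 (the fasting
    draw); glucose in mg/dL, all positive.
    """

    subject_id: str
    test_kind: str  # "GTT" or "ITT"
    week: int
    times_h: np.ndarray
    glucose_mgdl: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        g = np.asarray(self.glucose_mgdl, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "glucose_mgdl", g)
        if self.test_kind not in ("GTT", "ITT"):
            raise ValueError(f"test_kind must be GTT or ITT, got {self.test_kind!r}")
        if t.ndim != 1 or t.size == 0 or g.shape != t.shape:
            raise ValueError("times and glucose must be equal-length 1-d arrays")
        if t[0] != 0.0:
            raise ValueError("series must start at t=0 (fasting value)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times_h must be strictly increasing")
        if np.any(g <= 0):
            raise ValueError("glucose values must be positive (mg/dL)")

    @property
    def horizon_h(self) -> float:
        return float(self.times_h[-1])


@dataclass(frozen=True)
class DampedOscillationModel:
    """Fitted damped-oscillation glucose model with fit diagnostics."""

    G0_setpoint: float  # mg/dL
    A: float  # mg/dL
    alpha: float  # 1/h
    T: float  # h
    phi: float  # rad, in [-pi, pi)
    r_squared: float  # NaN when undefined (flat data)
    residual_sd: float  # mg/dL, dof = n - 5
    converged: bool
    test_kind: str = "GTT"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("basic period T must be positive")
        if self.alpha < 0:
            raise ValueError("damping coefficient alpha must be >= 0")

    def __call__(self, t):
        return damped_oscillation(t, self.G0_setpoint, self.A, self.alpha, self.T, self.phi)

    def slope(self, t):
        return damped_oscillation_slope(t, self.A, self.alpha, self.T, self.phi)


@dataclass(frozen=True)
class GlycemicParameters:
    """Derived glycemic parameter panel.

    For a GTT, ``g_extremum`` is the global maximum G_max on
    (0, horizon] and the steepest-fall fields (g_inflect = G_I,
    slope_inflect = G'_I, t_inflect = t_I) are populated.  For an ITT
    the extremum is the first local minimum H_min after t=0 and the
    steepest-fall fields are NaN (the panel the study reports for the
    ITT stops at H'(0)).
    """

    test_kind: str
    g_fasting: float  # G(0) / H(0), mg/dL
    g_extremum: float  # G_max / H_min, mg/dL
    t_extremum: float  # t_max / t_min, h
    g_2h: float  # G(2), mg/dL
    setpoint: float  # G0 / H0, mg/dL
    alpha: float  # 1/h
    period: float  # T, h
    slope_initial: float  # G'(0) / H'(0), mg/dL/h
    g_inflect: float  # G_I, mg/dL
    slope_inflect: float  # G'_I (most negative slope), mg/dL/h
    t_inflect: float  # t_I, h
    auc_model: float  # mg/dL*h, closed form on [0, horizon]
    auc_trapezoid: float = math.nan  # mg/dL*h, from raw measurements
    horizon_h: float = math.nan

    # ITT-flavoured aliases
    @property
    def h_fasting(self) -> float:
        return self.g_fasting

    @property
    def h_min(self) -> float:
        return self.g_extremum

    @property
    def t_min(self) -> float:
        return self.t_extremum

    def as_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def damped_oscillation(t, G0, A, alpha, T, phi):
    """Evaluate G(t) = G0 + A e^(-alpha t) sin(2 pi t / T + phi)."""
    t = np.asarray(t, dtype=float)
    omega = 2.0 * math.pi / T
    return G0 + A * np.exp(-alpha * t) * np.sin(omega * t + phi)


def damped_oscillation_slope(t, A, alpha, T, phi):
    """dG/dt = A e^(-alpha t) [omega cos(omega t + phi) - alpha sin(omega t + phi)]."""
    t = np.asarray(t, dtype=float)
    omega = 2.0 * math.pi / T
    u = omega * t + phi
    return A * np.exp(-alpha * t) * (omega * np.cos(u) - alpha * np.sin(u))


def model_auc(G0, A, alpha, T, phi, horizon):
    """Closed-form integral of the model on [0, horizon].

    int_0^h G dt = G0 h + A [ e^(-a t) (-a sin(w t+phi) - w cos(w t+phi)) / (a^2+w^2) ]_0^h
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    omega = 2.0 * math.pi / T
    denom = alpha**2 + omega**2

    def antiderivative(t):
        u = omega * t + phi
        return math.exp(-alpha * t) * (-alpha * math.sin(u) - omega * math.cos(u)) / denom

    return G0 * horizon + A * (antiderivative(horizon) - antiderivative(0.0))


def _wrap_phase(phi: float) -> float:
    """Wrap to [-pi, pi)."""
    return float((phi + math.pi) % (2.0 * math.pi) - math.pi)


def _canonicalize(params: np.ndarray) -> np.ndarray:
    """Resolve the (A, phi) sign ambiguity: force A >= 0, phi in [-pi, pi)."""
    G0, A, alpha, T, phi = params
    if A < 0:
        A, phi = -A, phi + math.pi
    return np.array([G0, A, alpha, T, _wrap_phase(phi)])


class DampedOscillatorRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for the damped-oscillation glucose model.

    Fits G(t) = G0 + A e^(-alpha t) sin(2 pi t/T + phi) by multi-start
    nonlinear least squares.  The objective is multi-modal in (T, phi),
    so starts are laid over a grid of candidate periods and dampings
    with the phase solved analytically from the fasting residual.

    Parameters
    ----------
    alpha_bounds, T_bounds : (low, high)
        Box constraints on the damping coefficient (1/h) and basic
        period (h).
    extra_periods : sequence of float
        Candidate periods (h) added to the data-driven 4*t_argmax start.
    alpha_starts : sequence of float
        Candidate damping starts (1/h).
    ftol : float
        Convergence tolerance passed to the trust-region solver; a fit
        is flagged non-converged when no start terminates successfully.

    Attributes
    ----------
    setpoint_, amplitude_, damping_, period_, phase_ : float
        Fitted G0 (mg/dL), A (mg/dL), alpha (1/h), T (h), phi (rad).
    r_squared_ : float
        Coefficient of determination on the training points (NaN for a
        flat series, where total variance is zero).
    residual_sd_ : float
        Residual SD with dof = n - 5 (NaN when n == 5).
    converged_ : bool
    model_ : DampedOscillationModel
    """

    def __init__(
        self,
        alpha_bounds: tuple[float, float] = DEFAULT_BOUNDS["alpha"],
        T_bounds: tuple[float, float] = DEFAULT_BOUNDS["T"],
        extra_periods: Sequence[float] = (2.0, 3.0, 4.0, 6.0),
        alpha_starts: Sequence[float] = (0.3, 1.0, 3.0),
        ftol: float = 1e-14,
        test_kind: str = "GTT",
    ):
        self.alpha_bounds = alpha_bounds
        self.T_bounds = T_bounds
        self.extra_periods = extra_periods
        self.alpha_starts = alpha_starts
        self.ftol = ftol
        self.test_kind = test_kind

    # -- internals ---------------------------------------------------------

    def _starts(self, t: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
        g0 = float(np.mean(y[-2:]))
        amp = (float(np.max(y)) - float(np.min(y))) / 2.0
        amp = max(amp, 1e-6)
        t_peak = float(t[int(np.argmax(np.abs(y - g0)))])
        periods = []
        if t_peak > 0:
            periods.append(4.0 * t_peak)
        periods.extend(self.extra_periods)
        lo_T, hi_T = self.T_bounds
        periods = sorted({min(max(p, lo_T), hi_T) for p in periods})
        starts = []
        for T0 in periods:
            for a0 in self.alpha_starts:
                # phase from the fasting residual: y(0) = G0 + A sin(phi)
                s = float(np.clip((y[0] - g0) / amp, -1.0, 1.0))
                phi0 = math.asin(s)
                for phi in (phi0, _wrap_phase(math.pi - phi0)):
                    starts.append(np.array([g0, amp, a0, T0, phi]))
        return starts

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        return self._fit_arrays(t, y)

    def _fit_arrays(self, t: np.ndarray, y: np.ndarray):
        # pooled group fits pass tied time values, so monotonicity is
        # checked only in the public fit()
        if t.size < MIN_POINTS:
            raise ValueError(
                f"insufficient points: need >= {MIN_POINTS}, got {t.size}"
            )
        n = t.size
        sst = float(np.sum((y - y.mean()) ** 2))

        if np.ptp(y) == 0.0:
            # flat series: the amplitude is unidentifiable; report the
            # degenerate A -> 0 solution with an undefined r^2
            self._set_solution(
                np.array([float(y[0]), 0.0, 0.0, sum(self.T_bounds) / 2, 0.0]),
                r2=math.nan,
                rsd=0.0,
                converged=True,
                degenerate=True,
                n=n,
            )
            return self

        lo = np.array([DEFAULT_BOUNDS["G0"][0], 0.0, self.alpha_bounds[0], self.T_bounds[0], -2.0 * math.pi])
        hi = np.array([DEFAULT_BOUNDS["G0"][1], DEFAULT_BOUNDS["A"][1], self.alpha_bounds[1], self.T_bounds[1], 2.0 * math.pi])

        def resid(p):
            return damped_oscillation(t, *p) - y

        best = None
        for p0 in self._starts(t, y):
            p0 = np.clip(p0, lo + 1e-12, hi - 1e-12)
            try:
                sol = least_squares(
                    resid, p0, bounds=(lo, hi), method="trf",
                    ftol=self.ftol, xtol=1e-15, gtol=1e-15, max_nfev=2000,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("all optimisation starts failed")

        # polish the winner from its own solution
        sol = least_squares(
            resid, best.x, bounds=(lo, hi), method="trf",
            ftol=self.ftol, xtol=1e-15, gtol=1e-15, max_nfev=4000,
        )
        if sol.cost <= best.cost:
            best = sol

        params = _canonicalize(best.x)
        ssr = float(np.sum(resid(params) ** 2))
        r2 = 1.0 - ssr / sst if sst > 0 else math.nan
        dof = n - 5
        rsd = math.sqrt(ssr / dof) if dof > 0 else math.nan
        self._set_solution(params, r2=r2, rsd=rsd, converged=bool(best.success),
                           degenerate=False, n=n)
        return self

    def _set_solution(self, params, *, r2, rsd, converged, degenerate, n):
        G0, A, alpha, T, phi = (float(v) for v in params)
        self.setpoint_ = G0
        self.amplitude_ = A
        self.damping_ = alpha
        self.period_ = T
        self.phase_ = phi
        self.r_squared_ = r2
        self.residual_sd_ = rsd
        self.converged_ = converged
        self.n_points_ = n
        self.model_ = DampedOscillationModel(
            G0_setpoint=G0, A=A, alpha=alpha, T=T, phi=phi,
            r_squared=r2, residual_sd=rsd, converged=converged,
            test_kind=self.test_kind, degenerate=degenerate,
        )

    def predict(self, X):
        check_is_fitted(self, "model_")
        t = np.asarray(X, dtype=float).reshape(-1)
        return self.model_(t)


def fit_damped_oscillator(series: ToleranceTestSeries, **options) -> DampedOscillationModel:
    """Fit the damped-oscillation model to one tolerance-test series."""
    est = DampedOscillatorRegressor(test_kind=series.test_kind, **options)
    est.fit(series.times_h, series.glucose_mgdl)
    return est.model_


def fit_group_curve(series_list: Sequence[ToleranceTestSeries], **options) -> DampedOscillationModel:
    """Pool all (t, glucose) points of a group and fit one model.

    Group-level curves are fitted on the pooled point cloud rather than
    on per-animal parameter averages, matching the whole-group
    convention of the study design.
    """
    if len(series_list) == 0:
        raise ValueError("need at least one series")
    kinds = {s.test_kind for s in series_list}
    if len(kinds) > 1:
        raise ValueError(f"mixed test kinds in group fit: {sorted(kinds)}")
    t = np.concatenate([s.times_h for s in series_list])
    y = np.concatenate([s.glucose_mgdl for s in series_list])
    order = np.argsort(t, kind="stable")
    est = DampedOscillatorRegressor(test_kind=kinds.pop(), **options)
    est._fit_arrays(t[order], y[order])
    return est.model_


def auc_trapezoid(series: ToleranceTestSeries) -> float:
    """Composite trapezoidal area under the measured curve, mg/dL * h."""
    if series.times_h.size < 2:
        raise ValueError("trapezoidal AUC needs at least two points")
    return float(np.trapezoid(series.glucose_mgdl, series.times_h))


def _refine_extremum(model: DampedOscillationModel, t0: float, lo: float, hi: float,
                     tol: float = 1e-6) -> float:
    """Refine an extremum near t0 by bisection on the slope.

    Falls back to t0 when the slope does not change sign in the
    bracket (extremum at the boundary of the horizon).
    """
    a = max(lo, t0 - 2e-3)
    b = min(hi, t0 + 2e-3)
    fa, fb = float(model.slope(a)), float(model.slope(b))
    if fa == 0.0:
        return a
    if fb == 0.0:
        return b
    if fa * fb > 0:
        return t0
    while b - a > 1e-12 and abs(float(model.slope(0.5 * (a + b)))) > tol:
        m = 0.5 * (a + b)
        fm = float(model.slope(m))
        if fa * fm <= 0:
            b = m
        else:
            a, fa = m, fm
    return 0.5 * (a + b)


def derive_parameters(
    model: DampedOscillationModel,
    horizon_h: float | None = None,
    series: ToleranceTestSeries | None = None,
    grid_step_h: float = 1e-3,
) -> GlycemicParameters:
    """Derive the glycemic parameter panel from a fitted model.

    Extrema of G and of G' are located on a dense grid (default step
    1e-3 h) and refined locally; the model AUC uses the closed form.
    The default horizon is 4 h for a GTT and 3 h for an ITT (the last
    sampling time of each grid).
    """
    if not model.converged:
        raise ValueError("cannot derive parameters from a non-converged model")
    if horizon_h is None:
        horizon_h = 4.0 if model.test_kind == "GTT" else 3.0
    if horizon_h <= 0:
        raise ValueError("horizon must be positive")

    tgrid = np.arange(0.0, horizon_h + grid_step_h / 2, grid_step_h)
    tgrid[-1] = min(tgrid[-1], horizon_h)
    g = model(tgrid)
    dg = model.slope(tgrid)

    g_fasting = float(model(0.0))
    g_2h = float(model(2.0)) if horizon_h >= 2.0 else math.nan
    slope_initial = float(model.slope(0.0))

    if model.A == 0.0:
        # flat model: the curve sits at the setpoint everywhere
        t_ext, g_ext = float(horizon_h), model.G0_setpoint
    elif model.test_kind == "GTT":
        # global maximum on [0, horizon]; a curve already falling at t=0
        # has its maximum at the fasting draw itself
        i = int(np.argmax(g))
        t_ext = _refine_extremum(model, float(tgrid[i]), 0.0, horizon_h) if i > 0 \
            else 0.0
        g_ext = float(model(t_ext))
    else:
        # ITT: first local minimum after t=0
        sign = np.sign(dg)
        idx = np.where((sign[:-1] < 0) & (sign[1:] >= 0))[0]
        if idx.size:
            i = int(idx[0]) + 1
            t_ext = _refine_extremum(model, float(tgrid[i]), 0.0, horizon_h)
        else:
            t_ext = float(tgrid[1 + int(np.argmin(g[1:]))])
        g_ext = float(model(t_ext))

    if model.A == 0.0:
        # flat model: slope vanishes identically
        t_inf, g_inf, slope_inf = math.nan, model.G0_setpoint, 0.0
    elif model.test_kind == "GTT":
        # steepest fall: most negative G' on [0, horizon]
        j = int(np.argmin(dg))
        t_lo = max(0.0, float(tgrid[j]) - grid_step_h)
        t_hi = min(horizon_h, float(tgrid[j]) + grid_step_h)
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda tt: float(model.slope(tt)), bounds=(t_lo, t_hi), method="bounded",
            options={"xatol": 1e-10},
        )
        t_inf = float(res.x) if res.fun <= dg[j] else float(tgrid[j])
        slope_inf = float(model.slope(t_inf))
        g_inf = float(model(t_inf))
    else:
        # the ITT panel the study reports stops at H'(0)
        t_inf, g_inf, slope_inf = math.nan, math.nan, math.nan

    auc = model_auc(model.G0_setpoint, model.A, model.alpha, model.T, model.phi, horizon_h)
    auc_trap = auc_trapezoid(series) if series is not None else math.nan

    return GlycemicParameters(
        test_kind=model.test_kind,
        g_fasting=g_fasting,
        g_extremum=g_ext,
        t_extremum=t_ext,
        g_2h=g_2h,
        setpoint=model.G0_setpoint,
        alpha=model.alpha,
        period=model.T,
        slope_initial=slope_initial,
        g_inflect=g_inf,
        slope_inflect=slope_inf,
        t_inflect=t_inf,
        auc_model=float(auc),
        auc_trapezoid=auc_trap,
        horizon_h=float(horizon_h),
    )
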