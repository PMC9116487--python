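"""Parameter estimation for discrete power-law models from time series.

The discrete analogue of slope-based collocation: because the model *is* a
recursion, the per-interval change ``X(t_{k+1}) - X(t_k)`` is read directly
off the data, and candidate parameters are scored by advancing the recursion
over each observation interval and summing squared deviations
(:func:`difference_sse`). When observations are spaced ``τ_obs = m·ϑ`` apart,
each interval is covered by ``m`` sub-steps of the recursion started at the
earlier observation. The ODE-style companion (:func:`slope_sse`) matches
estimated slopes to the model right-hand side at each time point.

Optimization is Nelder–Mead with sequential restarts, each restart started
at the previous optimum, stopping when the improvement between consecutive
restarts drops below a tolerance (default 1e-3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.signal import savgol_filter

from .model import ModelSpec, RegimeSet

__all__ = [
    "ObservedSeries",
    "SlopeSeries",
    "FitParameter",
    "FitConfig",
    "FitResult",
    "CompiledModel",
    "smooth_series",
    "estimate_slopes",
    "difference_sse",
    "slope_sse",
    "fit",
]

PENALTY = 1e12  # returned (plus a feasibility distance) for failed evaluations

SpecTemplate = Callable[[Mapping[str, float]], ModelSpec]


@dataclass
class ObservedSeries:
    """Evenly spaced multivariate time series."""

    times: np.ndarray
    values: np.ndarray  # shape (n_times, n_vars)
    names: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (len(self.times), len(self.names)):
            raise ValueError("values must have shape (n_times, n_vars)")
        if len(self.times) >= 2:
            d = np.diff(self.times)
            if not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
                raise ValueError("time grid must be evenly spaced")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("observed values must be finite")

    @property
    def tau_obs(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_data(self) -> int:
        """Total datum count n_vars · n_times (the 4·61 of a four-variable fit)."""
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "time", self.times)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ObservedSeries":
        names = [c for c in df.columns if c != "time"]
        return cls(df["time"].to_numpy(), df[names].to_numpy(), names)


@dataclass
class SlopeSeries:
    """Per-variable slope estimates on the same grid as their series."""

    times: np.ndarray
    slopes: np.ndarray
    names: list[str]


def smooth_series(raw: ObservedSeries, method: str = "none",
                  stiffness: Optional[float] = None) -> ObservedSeries:
    """Smooth each variable's time course on its own grid.

    ``method="none"`` returns the input unchanged; ``"savgol"`` applies a
    Savitzky–Golay filter (window set from *stiffness* as an odd point count,
    default 7); ``"spline"`` fits a smoothing spline with smoothing factor
    *stiffness* (default ``n_times``·var-scale heuristic from scipy).
    Smoothing is never applied implicitly anywhere in the package.
    """
    if method == "none":
        return raw
    if len(raw.times) < 4:
        raise ValueError("need at least 4 time points to smooth")
    if method == "savgol":
        window = int(stiffness) if stiffness else 7
        window = min(window, len(raw.times))
        if window % 2 == 0:
            window -= 1
        window = max(window, 5)
        # quartic local fits keep smooth trends essentially untouched while
        # still averaging out observation noise over the window
        poly = min(4, window - 2)
        vals = savgol_filter(raw.values, window_length=window, polyorder=poly, axis=0)
    elif method == "spline":
        from scipy.interpolate import UnivariateSpline
        vals = np.empty_like(raw.values)
        for j in range(raw.values.shape[1]):
            sp = UnivariateSpline(raw.times, raw.values[:, j], s=stiffness, k=3)
            vals[:, j] = sp(raw.times)
    else:
        raise ValueError(f"unknown smoothing method {method!r}")
    return ObservedSeries(raw.times.copy(), vals, list(raw.names),
                          {**raw.metadata, "smoothed": method})


def estimate_slopes(series: ObservedSeries) -> SlopeSeries:
    """Finite-difference slopes: central in the interior, one-sided at ends.

    Exact for quadratics at interior points; second-order accurate in the
    observation spacing.
    """
    if len(series.times) < 3:
        raise ValueError("need at least 3 time points for slope estimation")
    slopes = np.gradient(series.values, series.times, axis=0)
    return SlopeSeries(series.times.copy(), slopes, list(series.names))


class CompiledModel:
    """Array form of a delay-free, regime-free model for batched evaluation.

    Flattens all terms into exponent/offset matrices so that the recursion
    can be advanced for many start states at once — the workhorse behind the
    collocation objectives, where every observation interval is integrated
    independently.
    """

    def __init__(self, spec: ModelSpec):
        dep = spec.dependent_names
        indep = spec.independent_names
        self.dep = dep
        self.all_names = dep + indep
        self.theta = spec.step_size
        self.indep_values = np.array([spec.variable(v).initial_value for v in indep])
        n_all = len(self.all_names)
        col = {n: i for i, n in enumerate(self.all_names)}

        rates, signs, owners, exps, offs = [], [], [], [], []
        for i, var in enumerate(dep):
            eq = spec.equations[var]
            if isinstance(eq, RegimeSet):
                raise ValueError("threshold regimes are not supported in batched form")
            for term in eq:
                if term.delay:
                    raise ValueError("delays are not supported in batched form")
                rates.append(term.rate_constant)
                signs.append(term.sign)
                owners.append(i)
                e = np.zeros(n_all)
                o = np.zeros(n_all)
                for ref, f in term.exponents.items():
                    e[col[ref]] = f
                for ref, c in term.offset.items():
                    o[col[ref]] = c
                exps.append(e)
                offs.append(o)
        self.rates = np.array(rates)
        self.signs = np.array(signs, dtype=float)
        self.E = np.vstack(exps)          # (T, n_all)
        self.O = np.vstack(offs)
        self.has_offsets = bool(np.any(self.O))
        T = len(rates)
        self.A = np.zeros((T, len(dep)))  # term -> variable assignment
        self.A[np.arange(T), owners] = self.signs

    def _full(self, states: np.ndarray) -> np.ndarray:
        K = states.shape[0]
        if self.indep_values.size:
            return np.concatenate(
                [states, np.broadcast_to(self.indep_values, (K, self.indep_values.size))],
                axis=1)
        return states

    def net_change(self, states: np.ndarray) -> np.ndarray:
        """F(X) for a batch of states, shape (K, n_dep). NaN rows flag domain errors."""
        full = self._full(np.atleast_2d(states))
        base = full[:, None, :] + self.O[None, :, :]
        with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
            powered = np.where(self.E[None] == 0.0, 1.0, base ** self.E[None])
            flux = self.rates * np.prod(powered, axis=2)
            return flux @ self.A

    def advance(self, states: np.ndarray, n_sub: int,
                theta: Optional[float] = None) -> np.ndarray:
        """n_sub recursion steps for each row of *states*."""
        h = self.theta if theta is None else theta
        x = np.atleast_2d(states).astype(float)
        for _ in range(n_sub):
            x = x + h * self.net_change(x)
        return x


def _substep_count(tau_obs: float, theta: float) -> int:
    m = tau_obs / theta
    m_int = round(m)
    if m_int < 1 or abs(m - m_int) > 1e-9:
        raise ValueError(
            f"observation spacing {tau_obs} must be a positive integer "
            f"multiple of the recursion step {theta}")
    return m_int


def _penalty(bad_fraction: float) -> float:
    return PENALTY * (1.0 + bad_fraction)


def difference_sse(params: Mapping[str, float], series: ObservedSeries,
                   template: SpecTemplate, theta: float) -> float:
    """Squared prediction error of the recursion over observation intervals.

    For each consecutive pair of observations the recursion is advanced
    ``m = τ_obs/ϑ`` sub-steps from the earlier observed state; the SSE sums
    squared deviations of the predictions from the later observations over
    all variables and intervals. Domain failures (negative bases under
    fractional powers blowing up the batch) yield a large penalty instead of
    an exception so a simplex search can retreat.
    """
    spec = template(params)
    m = _substep_count(series.tau_obs, theta)
    try:
        compiled = CompiledModel(spec)
    except ValueError:
        raise
    order = [series.names.index(v) for v in compiled.dep]
    obs = series.values[:, order]
    pred = compiled.advance(obs[:-1], m, theta=theta)
    resid = pred - obs[1:]
    if not np.all(np.isfinite(resid)):
        bad = 1.0 - np.mean(np.isfinite(resid))
        return _penalty(bad)
    return float(np.sum(resid ** 2))


def slope_sse(params: Mapping[str, float], series: ObservedSeries,
              slopes: SlopeSeries, template: SpecTemplate) -> float:
    """Squared error between estimated slopes and the model right-hand side."""
    spec = template(params)
    compiled = CompiledModel(spec)
    order = [series.names.index(v) for v in compiled.dep]
    obs = series.values[:, order]
    f = compiled.net_change(obs)
    resid = f - slopes.slopes[:, order]
    if not np.all(np.isfinite(resid)):
        return _penalty(1.0 - np.mean(np.isfinite(resid)))
    return float(np.sum(resid ** 2))


@dataclass
class FitParameter:
    """One free parameter of a fit.

    Rate constants are searched on a log scale (positivity built in);
    kinetic orders are searched linearly within [lower, upper] (default
    [-5, 5]) enforced through a smooth penalty.
    """

    name: str
    lower: float = -5.0
    upper: float = 5.0
    init_low: float = 0.05
    init_high: float = 2.0
    log_scale: bool = False


@dataclass
class FitConfig:
    parameters: list[FitParameter]
    theta: float
    objective: str = "difference"  # "difference" | "slope"
    stop_tol: float = 1e-3
    max_restarts: int = 50
    seed: Optional[int] = None
    maxiter_per_restart: Optional[int] = None
    initial_params: Optional[Mapping[str, float]] = None
    #: independent multi-start repetitions of the whole restart protocol;
    #: the best final optimum is kept. Cheap insurance against the simplex
    #: stalling in a poor basin on multi-step objectives.
    n_starts: int = 3


@dataclass
class FitResult:
    params: dict[str, float]
    sse: float
    sse_per_datum: float
    n_data: int
    trace: list[float]
    n_restarts: int
    converged: bool
    message: str = ""


def _encode(cfg: FitConfig, params: Mapping[str, float]) -> np.ndarray:
    return np.array([math.log(params[p.name]) if p.log_scale else params[p.name]
                     for p in cfg.parameters])


def _decode(cfg: FitConfig, x: np.ndarray) -> dict[str, float]:
    return {p.name: (math.exp(v) if p.log_scale else float(v))
            for p, v in zip(cfg.parameters, x)}


def _draw_initial(cfg: FitConfig, rng: np.random.Generator) -> dict[str, float]:
    out = {}
    for p in cfg.parameters:
        if p.log_scale:
            lo, hi = math.log(p.init_low), math.log(p.init_high)
            out[p.name] = math.exp(rng.uniform(lo, hi))
        else:
            out[p.name] = float(rng.uniform(p.init_low, p.init_high))
    return out


def fit(config: FitConfig, series: ObservedSeries, template: SpecTemplate,
        slopes: Optional[SlopeSeries] = None) -> FitResult:
    """Nelder–Mead collocation fit with sequential restarts.

    Each restart rebuilds the simplex around the previous optimum; the
    sequence stops when two consecutive restarts improve the SSE by less
    than ``stop_tol`` or the restart cap is reached. Deterministic given
    ``config.seed`` (which controls only the initial parameter draw).
    """
    if config.objective == "slope" and slopes is None:
        slopes = estimate_slopes(series)

    def objective(x: np.ndarray) -> float:
        pen = 0.0
        for p, v in zip(config.parameters, x):
            if not p.log_scale:
                if v < p.lower:
                    pen += 1e6 * (p.lower - v) ** 2
                elif v > p.upper:
                    pen += 1e6 * (v - p.upper) ** 2
        params = _decode(config, x)
        try:
            if config.objective == "difference":
                sse = difference_sse(params, series, template, config.theta)
            else:
                sse = slope_sse(params, series, slopes, template)
        except (ValueError, ArithmeticError, OverflowError):
            return PENALTY * 2 + pen
        return sse + pen

    rng = np.random.default_rng(config.seed)

    trace: list[float] = []
    best_x, best_f = None, math.inf
    converged = False
    total_restarts = 0
    for start_idx in range(max(1, config.n_starts)):
        if start_idx == 0 and config.initial_params:
            start = dict(config.initial_params)
        else:
            start = _draw_initial(config, rng)
        x0 = _encode(config, start)
        if best_x is None:
            best_x, best_f = x0, objective(x0)
        prev = math.inf
        for _ in range(config.max_restarts):
            total_restarts += 1
            opts = {"xatol": 1e-9, "fatol": 1e-12, "adaptive": True}
            if config.maxiter_per_restart:
                opts["maxiter"] = config.maxiter_per_restart
            res = minimize(objective, x0, method="Nelder-Mead", options=opts)
            trace.append(float(res.fun))
            if res.fun < best_f:
                best_x, best_f = res.x, float(res.fun)
            x0 = res.x
            # the restart sequence ends once consecutive optima stop
            # improving — but never while stuck on the infeasibility penalty
            if res.fun < PENALTY and abs(prev - res.fun) < config.stop_tol:
                converged = True
                break
            prev = float(res.fun)
    restarts = total_restarts

    if best_f >= PENALTY:
        return FitResult(params=_decode(config, best_x), sse=best_f,
                         sse_per_datum=math.nan, n_data=series.n_data,
                         trace=trace, n_restarts=restarts, converged=False,
                         message="all restarts failed to produce a feasible evaluation")
    n = series.n_data
    return FitResult(params=_decode(config, best_x), sse=best_f,
                     sse_per_datum=best_f / n, n_data=n, trace=trace,
                     n_restarts=restarts, converged=converged,
                     message="" if converged else "restart cap reached")
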