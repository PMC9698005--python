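"""ADAPT: time-varying parameter estimation by step-wise regularized fitting.

ADAPT (Analysis of Dynamic Adaptations in Parameter Trajectories) estimates
how the kinetic parameters of a metabolic model must change slowly over a
diet intervention to stay consistent with longitudinal data.  One estimation
iteration:

1. draw a *data realization*: at every measurement time, sample each
   observable from Normal(mean, SD) and interpolate with a smooth curve;
2. initialize parameters and a steady-state at t=0 by least squares against
   the realization (the slow system starts in steady state);
3. march over a uniform time grid; at each step, re-estimate the full
   parameter vector by minimizing

       sum_k ((yhat_k(t_next; theta) - s_k(t_next)) / sigma_k(t_next))^2
       + lambda * sum_i ((theta_i - theta_i_prev) / (theta_ref_i * dt))^2

   where yhat is the model output after integrating over [t_prev, t_next]
   with constant theta.  The penalty (regularization parameter lambda)
   favours gradual parameter change.

Repeating this over many Monte-Carlo realizations propagates measurement
uncertainty into an ensemble of parameter/state/flux trajectories, summarized
by the pointwise median and the central band holding 30% of solutions around
the median (35th-65th percentiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.optimize import least_squares

from . import network as net
from .data import LongitudinalDataset
from .exceptions import ConfigurationError, EstimationError, EstimationQualityError
from .model import Model
from .reference import reference_parameters

__all__ = [
    "AdaptConfig",
    "DataRealization",
    "AdaptResult",
    "sample_realization",
    "initialize",
    "step_estimate",
    "run",
    "summarize",
    "total_variation",
]

_EPS = 1e-12


@dataclass
class AdaptConfig:
    """Settings of the estimation procedure.

    n_steps / lam are the published settings (200 steps, lambda = 0.01); the
    ensemble size n_iterations is configurable (the number of Monte-Carlo
    data realizations).
    """

    n_steps: int = 200
    lam: float = 0.01
    n_iterations: int = 100
    seed: int = 0
    t_start: float = 0.0
    t_end: float = 196.0  # 28 weeks, in days
    spline: str = "cubic"  # "cubic" | "pchip" | "polynomial"
    band: str = "percentile"  # "percentile" | "median_fraction"
    sigma_floor_frac: float = 0.05
    prior_weight: float = 1e-2
    n_restarts: int = 10
    max_nfev_init: int = 200
    max_nfev_step: int = 40
    ftol: float = 1e-6
    xtol: float = 1e-6
    max_failure_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ConfigurationError("n_steps must be >= 2")
        if self.lam < 0:
            raise ConfigurationError("lambda must be >= 0")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if self.spline not in ("cubic", "pchip", "polynomial"):
            raise ConfigurationError(f"unknown spline type {self.spline!r}")
        if self.band not in ("percentile", "median_fraction"):
            raise ConfigurationError(f"unknown band convention {self.band!r}")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.t_start, self.t_end, self.n_steps + 1)


class _Curve:
    """Clamped, non-negative interpolant through sampled points."""

    def __init__(self, times, values, kind: str):
        self.t_min = float(times[0])
        self.t_max = float(times[-1])
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if len(times) == 1:
            c = float(values[0])
            self._fn = lambda t: np.full_like(np.atleast_1d(np.asarray(t, float)), c)
        elif kind == "pchip":
            self._fn = PchipInterpolator(times, values, extrapolate=False)
        elif kind == "polynomial":
            deg = min(3, len(times) - 1)
            coeffs = np.polyfit(times, values, deg)
            self._fn = lambda t: np.polyval(coeffs, np.asarray(t, float))
        else:
            if len(times) < 3:
                self._fn = lambda t, ts=times, vs=values: np.interp(
                    np.asarray(t, float), ts, vs
                )
            else:
                self._fn = CubicSpline(times, values, bc_type="natural", extrapolate=False)

    def __call__(self, t) -> float:
        tc = np.clip(t, self.t_min, self.t_max)
        val = np.asarray(self._fn(np.atleast_1d(tc)), dtype=float)
        return float(np.maximum(val, 0.0)[0]) if np.ndim(t) == 0 else np.maximum(val, 0.0)


@dataclass
class _RealizedSeries:
    observable: str
    constraint_class: str
    support: tuple[float, float]
    value: _Curve
    sigma: object  # callable t -> float

    def active(self, t: float) -> bool:
        return self.support[0] - 1e-9 <= t <= self.support[1] + 1e-9


@dataclass
class DataRealization:
    """One Monte-Carlo draw of the data, as smooth interpolants."""

    group: str
    series: dict[str, _RealizedSeries]

    def names(self) -> tuple[str, ...]:
        return tuple(self.series)

    def value(self, name: str, t: float) -> float:
        return self.series[name].value(t)


def _sigma_fn(times, mean, sd, floor_frac):
    times = np.asarray(times, float)
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)

    def fn(t):
        t = np.clip(t, times[0], times[-1])
        s = np.interp(t, times, sd)
        m = np.interp(t, times, mean)
        return float(max(s, floor_frac * abs(m), 1e-8))

    return fn


def sample_realization(
    dataset: LongitudinalDataset, rng: np.random.Generator, config: AdaptConfig
) -> DataRealization:
    """Sample one realization: values ~ Normal(mean, SD) truncated at zero.

    Observables with a single time point fall back to a constant curve (a
    warning is issued for longitudinal series, where this indicates a thin
    design rather than a cross-sectional constraint).
    """
    out: dict[str, _RealizedSeries] = {}
    for name in sorted(dataset.series):
        s = dataset.series[name]
        draws = np.maximum(rng.normal(s.mean, s.sd), 0.0)
        if len(s.times) < 2 and s.constraint_class == "longitudinal":
            warnings.warn(
                f"{name}: fewer than 2 time points; using a constant interpolant",
                stacklevel=2,
            )
        out[name] = _RealizedSeries(
            observable=name,
            constraint_class=s.constraint_class,
            support=(float(s.times[0]), float(s.times[-1])),
            value=_Curve(s.times, draws, config.spline),
            sigma=_sigma_fn(s.times, s.mean, s.sd, config.sigma_floor_frac),
        )
    return DataRealization(group=dataset.group, series=out)


# ---------------------------------------------------------------------------
# initialization and stepping
# ---------------------------------------------------------------------------


def _theta_ref_array(theta_ref) -> np.ndarray:
    if theta_ref is None:
        theta_ref = reference_parameters()
    from .model import as_param_array

    ref = as_param_array(theta_ref)
    return np.maximum(ref, _EPS)


def _steady_state_of(model: Model, theta: np.ndarray) -> np.ndarray | None:
    A, b = model.linear_system(theta)
    try:
        x = np.linalg.solve(A, -b)
    except np.linalg.LinAlgError:
        return None
    if np.any(x < -1e-6) or not np.all(np.isfinite(x)):
        return None
    return np.maximum(x, 0.0)


def initialize(
    realization: DataRealization,
    model: Model,
    config: AdaptConfig,
    theta_ref=None,
):
    """Fit (parameters, steady state) to the realization at the fit start.

    Minimizes the weighted squared error between the model's steady-state
    observables and the realization values at t_start, with a weak ridge
    toward the reference parameterization to resolve the indeterminacy of
    fitting 39 parameters to a dozen observables.  Restarts from perturbed
    parameter sets if the first fit stalls.
    """
    ref = _theta_ref_array(theta_ref)
    t0 = config.t_start
    names = [n for n, s in realization.series.items()]
    targets = np.array([realization.series[n].value(t0) for n in names])
    sigmas = np.array([realization.series[n].sigma(t0) for n in names])
    evaluate = model.observable_evaluator(names)
    pw = np.sqrt(config.prior_weight)

    def residuals(theta):
        x = _steady_state_of(model, theta)
        if x is None:
            return np.full(len(names) + len(theta), 1e6)
        j = model._fluxes_unchecked(x, theta)
        y = evaluate(x, j, theta)
        r_data = (y - targets) / sigmas
        r_prior = pw * (theta / ref - 1.0)
        return np.concatenate([r_data, r_prior])

    rng = np.random.default_rng(0)
    best = None
    for attempt in range(max(1, config.n_restarts)):
        theta0 = ref if attempt == 0 else ref * rng.lognormal(0.0, 0.3, size=ref.size)
        try:
            res = least_squares(
                residuals,
                theta0,
                bounds=(0.0, np.inf),
                x_scale=ref,
                ftol=config.ftol,
                xtol=config.xtol,
                max_nfev=config.max_nfev_init,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        data_rms = float(np.sqrt(np.mean(residuals(best.x)[: len(names)] ** 2)))
        if data_rms < 0.5:
            break
    if best is None:
        raise EstimationError("initialization failed in all restarts")
    theta = np.maximum(best.x, 0.0)
    x = _steady_state_of(model, theta)
    if x is None:
        raise EstimationError("initialization produced no feasible steady state")
    resid = float(np.sqrt(np.mean(residuals(theta)[: len(names)] ** 2)))
    return theta, x, resid


def step_estimate(
    model: Model,
    theta_prev: np.ndarray,
    x_prev: np.ndarray,
    realization: DataRealization,
    t_prev: float,
    t_next: float,
    lam: float,
    config: AdaptConfig,
    theta_ref=None,
):
    """One ADAPT step: re-estimate theta over [t_prev, t_next].

    Returns (theta, x_next, data_misfit) where data_misfit is the summed
    squared weighted residual at t_next.  The model output is obtained by
    exact (matrix-exponential) integration with constant theta over the step.
    """
    if t_next <= t_prev:
        raise ConfigurationError("t_next must exceed t_prev")
    ref = _theta_ref_array(theta_ref)
    dt = t_next - t_prev
    active = [n for n, s in realization.series.items() if s.active(t_next)]
    targets = np.array([realization.series[n].value(t_next) for n in active])
    sigmas = np.array([realization.series[n].sigma(t_next) for n in active])
    evaluate = model.observable_evaluator(active)
    sql = np.sqrt(lam)
    pen_scale = ref * dt

    def residuals(theta):
        x = np.maximum(model.propagate(x_prev, theta, dt), 0.0)
        j = model._fluxes_unchecked(x, theta)
        y = evaluate(x, j, theta)
        r_data = (y - targets) / sigmas
        r_pen = sql * (theta - theta_prev) / pen_scale
        return np.concatenate([r_data, r_pen])

    rng = np.random.default_rng(1)
    last_exc = None
    for attempt in range(3):
        theta0 = (
            theta_prev
            if attempt == 0
            else theta_prev * rng.lognormal(0.0, 0.05, size=theta_prev.size)
        )
        try:
            res = least_squares(
                residuals,
                theta0,
                bounds=(0.0, np.inf),
                x_scale=ref,
                ftol=config.ftol,
                xtol=config.xtol,
                max_nfev=config.max_nfev_step,
            )
        except Exception as exc:  # optimizer blow-up: retry perturbed
            last_exc = exc
            continue
        if np.all(np.isfinite(res.x)):
            theta = np.maximum(res.x, 0.0)
            x_next = np.maximum(model.propagate(x_prev, theta, dt), 0.0)
            r = residuals(theta)
            misfit = float(np.sum(r[: len(active)] ** 2))
            return theta, x_next, misfit
    raise EstimationError(f"step estimation failed at t={t_next}: {last_exc}")


# ---------------------------------------------------------------------------
# ensemble run and summaries
# ---------------------------------------------------------------------------


@dataclass
class AdaptResult:
    """Ensemble of parameter/state/flux trajectories for one group."""

    group: str
    grid: np.ndarray
    params: np.ndarray  # (n_ok, 39, n_steps+1)
    states: np.ndarray  # (n_ok, 18, n_steps+1)
    fluxes: np.ndarray  # (n_ok, 41, n_steps+1)
    misfits: np.ndarray  # (n_ok, n_steps)
    init_residuals: np.ndarray  # (n_ok,)
    config: AdaptConfig
    failures: list = field(default_factory=list)
    model: Model | None = None

    @property
    def n_iterations(self) -> int:
        return self.params.shape[0]

    def quantity(self, name: str) -> np.ndarray:
        """Ensemble matrix (n_ok, n_times) for a parameter/state/flux/observable."""
        if name in net.PARAMETER_INDEX:
            return self.params[:, net.PARAMETER_INDEX[name], :]
        if name in net.STATE_INDEX:
            return self.states[:, net.STATE_INDEX[name], :]
        if name in net.FLUX_INDEX:
            return self.fluxes[:, net.FLUX_INDEX[name], :]
        model = self.model if self.model is not None else Model()
        if name in model.observable_names():
            ev = model.observable_evaluator([name])
            out = np.empty(self.params.shape[::2])
            for k in range(self.n_iterations):
                for t in range(self.grid.size):
                    out[k, t] = ev(
                        self.states[k, :, t], self.fluxes[k, :, t], self.params[k, :, t]
                    )[0]
            return out
        raise ConfigurationError(f"unknown quantity {name!r}")

    def summary(self, name: str) -> pd.DataFrame:
        med, lo, hi = summarize(self.quantity(name), self.config.band)
        return pd.DataFrame(
            {"time": self.grid, "median": med, "lo": lo, "hi": hi}
        ).assign(quantity=name, group=self.group)

    def total_misfit(self) -> float:
        return float(np.sum(self.misfits))

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, config: AdaptConfig | None = None) -> "AdaptResult":
        """Rebuild a result from the long-format ensemble CSV."""
        groups = df["group"].unique()
        if len(groups) != 1:
            raise ConfigurationError("expected a single group per ensemble frame")
        grid = np.sort(df["time"].unique())
        iters = np.sort(df["iteration"].unique())
        arrays = {}
        for kind, names in (
            ("parameter", net.PARAMETERS),
            ("state", net.STATES),
            ("flux", tuple(f.name for f in net.FLUXES)),
        ):
            sub = df[df["kind"] == kind]
            pivot = sub.pivot_table(
                index=["iteration", "quantity"], columns="time", values="value", sort=True
            )
            arr = np.empty((iters.size, len(names), grid.size))
            for ki, it in enumerate(iters):
                for qi, q in enumerate(names):
                    arr[ki, qi, :] = pivot.loc[(it, q)].to_numpy()
            arrays[kind] = arr
        if config is None:
            config = AdaptConfig(
                n_steps=grid.size - 1,
                n_iterations=iters.size,
                t_start=float(grid[0]),
                t_end=float(grid[-1]),
            )
        return cls(
            group=str(groups[0]),
            grid=grid,
            params=arrays["parameter"],
            states=arrays["state"],
            fluxes=arrays["flux"],
            misfits=np.zeros((iters.size, grid.size - 1)),
            init_residuals=np.zeros(iters.size),
            config=config,
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Ensemble in long format: iteration, kind, quantity, time, value."""
        blocks = []
        for kind, names, arr in (
            ("parameter", net.PARAMETERS, self.params),
            ("state", net.STATES, self.states),
            ("flux", tuple(f.name for f in net.FLUXES), self.fluxes),
        ):
            K, Q, T = arr.shape
            blocks.append(
                pd.DataFrame(
                    {
                        "iteration": np.repeat(np.arange(K), Q * T),
                        "kind": kind,
                        "quantity": np.tile(np.repeat(list(names), T), K),
                        "time": np.tile(self.grid, K * Q),
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(blocks, ignore_index=True).assign(group=self.group)


def summarize(values: np.ndarray, band: str = "percentile"):
    """Pointwise median and 30%-around-the-median band of an ensemble.

    ``percentile``: band = 35th-65th percentiles (30% of solutions around the
    median).  ``median_fraction``: band = median ± 30% of |median|.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ConfigurationError("empty ensemble")
    med = np.median(values, axis=0)
    if band == "percentile":
        lo = np.percentile(values, 35.0, axis=0)
        hi = np.percentile(values, 65.0, axis=0)
    elif band == "median_fraction":
        lo = med - 0.3 * np.abs(med)
        hi = med + 0.3 * np.abs(med)
    else:
        raise ConfigurationError(f"unknown band convention {band!r}")
    return med, lo, hi


def total_variation(result: AdaptResult, parameter: str) -> np.ndarray:
    """Per-iteration total variation sum_n |theta_n - theta_{n-1}|."""
    traj = result.quantity(parameter)
    return np.sum(np.abs(np.diff(traj, axis=1)), axis=1)


def run(
    dataset: LongitudinalDataset,
    model: Model | None = None,
    config: AdaptConfig | None = None,
    theta_ref=None,
) -> AdaptResult:
    """Full ADAPT procedure: Monte-Carlo realizations -> trajectories.

    Raises EstimationQualityError if more than ``config.max_failure_frac`` of
    the iterations fail.
    """
    model = model if model is not None else Model()
    config = config if config is not None else AdaptConfig()
    dataset.validate()
    grid = config.grid
    n_t = grid.size
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_iterations)

    ref = _theta_ref_array(theta_ref)
    params_list, states_list, fluxes_list, misfit_list, init_list = [], [], [], [], []
    failures: list[dict] = []
    for it, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        realization = sample_realization(dataset, rng, config)
        try:
            theta, x, init_res = initialize(realization, model, config, ref)
            P = np.empty((net.N_PARAMETERS, n_t))
            X = np.empty((net.N_STATES, n_t))
            J = np.empty((net.N_FLUXES, n_t))
            M = np.empty(n_t - 1)
            P[:, 0], X[:, 0] = theta, x
            J[:, 0] = model._fluxes_unchecked(x, theta)
            for i in range(1, n_t):
                theta, x, misfit = step_estimate(
                    model, theta, x, realization, grid[i - 1], grid[i],
                    config.lam, config, ref,
                )
                P[:, i], X[:, i] = theta, x
                J[:, i] = model._fluxes_unchecked(x, theta)
                M[i - 1] = misfit
        except EstimationError as exc:
            failures.append({"iteration": it, "error": str(exc)})
            continue
        params_list.append(P)
        states_list.append(X)
        fluxes_list.append(J)
        misfit_list.append(M)
        init_list.append(init_res)

    n_ok = len(params_list)
    if n_ok < (1 - config.max_failure_frac) * config.n_iterations or n_ok == 0:
        raise EstimationQualityError(
            f"{len(failures)}/{config.n_iterations} iterations failed: {failures}"
        )
    return AdaptResult(
        group=dataset.group,
        grid=grid,
        params=np.stack(params_list),
        states=np.stack(states_list),
        fluxes=np.stack(fluxes_list),
        misfits=np.stack(misfit_list),
        init_residuals=np.asarray(init_list),
        config=config,
        failures=failures,
        model=model,
    )
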