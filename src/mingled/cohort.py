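"""Synthetic longitudinal cohorts with the study's statistical structure.

Two generators are provided:

* :func:`generate_cohort` draws a template-based cohort of individually
  simulated mice in two phenotype groups.  Responders start above 1.0 mM
  plasma TG on chow and develop hypertriglyceridemia on the high-fat
  high-cholesterol diet (TG rising from week 4, peaking at week 20 and
  re-stabilizing at a new plateau by week 24); non-responders stay flat below
  1.0 mM.  A per-mouse latent "bile-acid availability" factor couples fecal
  bile-acid excretion (and its deoxycholate share) positively, and fecal
  fatty-acid excretion negatively, to reproduce the cross-mouse correlation
  structure of the study (low bile-acid output -> poorer fat solubilization
  -> more fecal fat, less weight gain).

* :func:`generate_ground_truth` simulates the kinetic model itself with
  known, slowly drifting parameters and emits a noisy dataset plus the true
  parameter trajectory — the substrate for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .data import LongitudinalDataset, ObservableSeries
from .exceptions import ConfigurationError, IntegrationError
from .model import (
    CROSS_SECTIONAL_OBSERVABLES,
    LONGITUDINAL_OBSERVABLES,
    Model,
    as_param_array,
)
from .reference import reference_parameters

__all__ = [
    "CohortSpec",
    "GroundTruthSpec",
    "BILE_ACID_SPECIES",
    "generate_cohort",
    "generate_ground_truth",
]

PER_MOUSE_COLUMNS = ("mouse_id", "group", "observable", "time_days", "value")

#: deconjugated fecal bile-acid species emitted by the generator
BILE_ACID_SPECIES = ("CA", "CDCA", "DCA", "LCA", "UDCA", "aMCA", "bMCA", "oMCA")

# Group template curves: control points (weeks, values).  The responder
# plasma-TG template spans ~1.5 -> 4 -> 2.5 mM; shapes are free configuration,
# chosen to look like the study's group means, not measured claims.
_TEMPLATES: dict[str, dict[str, tuple[tuple[float, ...], tuple[float, ...]]]] = {
    "responder": {
        "plasma_tg": ((0, 4, 20, 24, 28), (1.5, 1.5, 4.0, 2.5, 2.5)),
        "plasma_tc": ((0, 4, 20, 24, 28), (3.0, 3.0, 6.0, 4.5, 4.5)),
        "plasma_hdl_c": ((0, 28), (1.5, 1.3)),
        "plasma_glucose": ((0, 28), (8.0, 9.0)),
        "body_weight": ((0, 4, 20, 28), (27.0, 30.0, 44.0, 46.0)),
        "fecal_neutral_sterols": ((0, 28), (22.0, 28.0)),
        "fecal_bile_acids": ((0, 28), (25.0, 28.0)),
        "fecal_ffa": ((0, 28), (25.0, 30.0)),
        "food_intake": ((0, 28), (2.5, 2.5)),
    },
    "non_responder": {
        "plasma_tg": ((0, 28), (0.7, 0.7)),
        "plasma_tc": ((0, 28), (2.5, 2.6)),
        "plasma_hdl_c": ((0, 28), (1.4, 1.3)),
        "plasma_glucose": ((0, 28), (8.0, 8.5)),
        "body_weight": ((0, 4, 20, 28), (25.0, 26.5, 31.0, 32.0)),
        "fecal_neutral_sterols": ((0, 28), (28.0, 36.0)),
        "fecal_bile_acids": ((0, 28), (10.0, 12.0)),
        "fecal_ffa": ((0, 28), (55.0, 65.0)),
        "food_intake": ((0, 28), (2.5, 2.5)),
    },
}

# Fecal bile-acid composition templates (molar fractions); non-responders
# carry a more hydrophilic profile (less DCA, more muricholates).
_BA_FRACTIONS: dict[str, dict[str, float]] = {
    "responder": {
        "CA": 0.15, "CDCA": 0.03, "DCA": 0.35, "LCA": 0.05,
        "UDCA": 0.02, "aMCA": 0.05, "bMCA": 0.12, "oMCA": 0.23,
    },
    "non_responder": {
        "CA": 0.10, "CDCA": 0.03, "DCA": 0.15, "LCA": 0.02,
        "UDCA": 0.05, "aMCA": 0.08, "bMCA": 0.27, "oMCA": 0.30,
    },
}

# Measurement-noise CVs per observable (assay + within-mouse variation).
_NOISE_CV: dict[str, float] = {
    "plasma_tg": 0.07,
    "plasma_tc": 0.08,
    "plasma_hdl_c": 0.08,
    "plasma_glucose": 0.08,
    "body_weight": 0.04,
    "fecal_neutral_sterols": 0.12,
    "fecal_bile_acids": 0.12,
    "fecal_ffa": 0.15,
    "food_intake": 0.05,
}

# Whole-cohort cross-sectional constraints (week 4/9/13/28 terminal cohorts),
# consistent with the reference steady state of the kinetic model.
_CROSS_SECTIONAL: dict[str, tuple[float, float]] = {
    "vldl_tg_production": (250.0, 25.0),
    "dnl_liver": (20.0, 3.0),
    "biliary_chol_secretion": (50.0, 6.0),
    "biliary_ba_secretion": (150.0, 18.0),
    "liver_tg": (30.0, 5.0),
    "liver_chol": (10.0, 1.5),
}
_CROSS_SECTIONAL_WEEKS = (4.0, 9.0, 13.0, 28.0)
_CROSS_SECTIONAL_N = 12


@dataclass
class CohortSpec:
    """Study-design conditions for the template cohort generator."""

    n_responders: int = 36
    n_nonresponders: int = 11
    weeks: tuple[float, ...] = (0.0, 4.0, 9.0, 13.0, 20.0, 24.0, 28.0)
    noise_cv: dict = field(default_factory=lambda: dict(_NOISE_CV))
    noise_mode: str = "gaussian"  # "gaussian" (truncated at 0) | "lognormal"
    bile_factor_sigma: float = 0.25
    ffa_bile_exponent: float = 0.8
    weight_bile_exponent: float = 0.10
    tg_bile_exponent: float = 0.15
    dca_bile_exponent: float = 0.6
    follow_up_weeks: dict = field(default_factory=dict)  # group -> weeks kept

    def __post_init__(self) -> None:
        if self.n_responders < 0 or self.n_nonresponders < 0:
            raise ConfigurationError("group sizes must be >= 0")
        if np.any(np.diff(self.weeks) <= 0):
            raise ConfigurationError("weeks must be strictly increasing")
        if any(cv < 0 for cv in self.noise_cv.values()):
            raise ConfigurationError("noise CVs must be >= 0")
        if self.noise_mode not in ("gaussian", "lognormal"):
            raise ConfigurationError(f"unknown noise mode {self.noise_mode!r}")


def _template(group: str, observable: str):
    wk, vals = _TEMPLATES[group][observable]
    if len(wk) == 2:
        return lambda w: np.interp(w, wk, vals)
    return PchipInterpolator(np.asarray(wk, float), np.asarray(vals, float))


def _noisy(rng, value, cv, mode):
    value = np.asarray(value, dtype=float)
    if cv == 0:
        return value.copy()
    if mode == "lognormal":
        sigma = np.sqrt(np.log1p(cv**2))
        return value * rng.lognormal(-0.5 * sigma**2, sigma, size=value.shape)
    return np.maximum(value * (1.0 + cv * rng.standard_normal(value.shape)), 0.0)


def generate_cohort(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, LongitudinalDataset]]:
    """Generate per-mouse measurements and group-aggregated datasets.

    Returns ``(per_mouse, datasets)`` where ``per_mouse`` is a long-format
    frame (mouse_id, group, observable, time_days, value) and ``datasets``
    maps group -> LongitudinalDataset (longitudinal group means plus the
    shared cross-sectional whole-cohort constraints).
    """
    groups = [("responder", spec.n_responders), ("non_responder", spec.n_nonresponders)]
    if all(n == 0 for _, n in groups):
        raise ConfigurationError("cohort has no mice")
    weeks = np.asarray(spec.weeks, dtype=float)
    rows: list[tuple] = []
    mouse_no = 0
    for group, n_mice in groups:
        if n_mice == 0:
            continue
        kept_weeks = np.asarray(spec.follow_up_weeks.get(group, weeks), dtype=float)
        templates = {obs: _template(group, obs) for obs in _TEMPLATES[group]}
        base_fracs = _BA_FRACTIONS[group]
        for _ in range(n_mice):
            mouse_no += 1
            mouse_id = f"m{mouse_no:03d}"
            beta = rng.lognormal(0.0, spec.bile_factor_sigma)
            # diet-response ramp: the latent factor acts after diet start
            ramp = np.clip(kept_weeks / 4.0, 0.0, 1.0)
            for obs, tpl in templates.items():
                base = np.asarray(tpl(kept_weeks), dtype=float)
                if obs == "fecal_bile_acids":
                    base = base * beta
                elif obs == "fecal_ffa":
                    base = base * beta ** (-spec.ffa_bile_exponent)
                elif obs == "body_weight":
                    base = base * beta ** (spec.weight_bile_exponent * ramp)
                elif obs == "plasma_tg":
                    base = base * beta ** (spec.tg_bile_exponent * ramp)
                vals = _noisy(rng, base, spec.noise_cv.get(obs, 0.0), spec.noise_mode)
                for w, v in zip(kept_weeks, vals):
                    rows.append((mouse_id, group, obs, 7.0 * w, float(v)))
            # per-mouse fecal bile-acid species (µmol/day), DCA share coupled
            # to the latent factor; emitted at the fecal-collection weeks
            fracs = dict(base_fracs)
            fracs["DCA"] = fracs["DCA"] * beta**spec.dca_bile_exponent
            total_frac = sum(fracs.values())
            fracs = {s: f / total_frac for s, f in fracs.items()}
            ba_rows = [r for r in rows if r[0] == mouse_id and r[2] == "fecal_bile_acids"]
            for _, _, _, t_days, ba_total in ba_rows:
                for s in BILE_ACID_SPECIES:
                    rows.append(
                        (mouse_id, group, f"fecal_ba_{s}", t_days, ba_total * fracs[s])
                    )
    per_mouse = pd.DataFrame(rows, columns=list(PER_MOUSE_COLUMNS))

    datasets: dict[str, LongitudinalDataset] = {}
    for group, n_mice in groups:
        if n_mice == 0:
            continue
        series = {}
        sub = per_mouse[per_mouse["group"] == group]
        for obs in LONGITUDINAL_OBSERVABLES:
            block = sub[sub["observable"] == obs]
            agg = block.groupby("time_days")["value"].agg(["mean", "std", "count"])
            series[obs] = ObservableSeries(
                observable=obs,
                constraint_class="longitudinal",
                times=agg.index.to_numpy(),
                mean=agg["mean"].to_numpy(),
                sd=np.nan_to_num(agg["std"].to_numpy()),
                n=agg["count"].to_numpy(),
            )
        for obs, (mean, sd) in _CROSS_SECTIONAL.items():
            t = 7.0 * np.asarray(_CROSS_SECTIONAL_WEEKS)
            series[obs] = ObservableSeries(
                observable=obs,
                constraint_class="cross_sectional_group_average",
                times=t,
                mean=np.full(t.size, mean),
                sd=np.full(t.size, sd),
                n=np.full(t.size, _CROSS_SECTIONAL_N),
            )
        datasets[group] = LongitudinalDataset(group=group, series=series).validate()
    return per_mouse, datasets


# ---------------------------------------------------------------------------
# model-consistent ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthSpec:
    """Known-truth simulation: reference parameters with scheduled drift.

    ``drift`` maps parameter name -> ((t_days, multiplier), ...) interpreted
    as a piecewise-linear multiplier on the reference value (e.g. a linear
    fall to 70% over 28 weeks: ((0, 1.0), (196, 0.7))).

    ``noise_cv`` is the per-mouse measurement CV (a float, or a dict with an
    optional "default" key for per-observable values; body weight, being a
    scale reading, is typically far more precise than assay observables).
    The emitted group means carry sampling error CV/sqrt(n); the SD column
    reports the per-mouse dispersion CV * |value|.
    """

    params: dict = field(default_factory=reference_parameters)
    drift: dict = field(default_factory=dict)
    noise_cv: float | dict = 0.05
    weeks: tuple[float, ...] = (0.0, 4.0, 9.0, 13.0, 20.0, 24.0, 28.0)
    group: str = "responder"
    n: int = 12
    observables: tuple[str, ...] = LONGITUDINAL_OBSERVABLES
    cross_sectional: tuple[str, ...] = CROSS_SECTIONAL_OBSERVABLES

    def param_fn(self):
        base = as_param_array(self.params)
        from . import network as net

        schedules = []
        for name, points in self.drift.items():
            if name not in net.PARAMETER_INDEX:
                raise ConfigurationError(f"unknown drift parameter {name!r}")
            pts = np.asarray(points, dtype=float)
            schedules.append((net.PARAMETER_INDEX[name], pts[:, 0], pts[:, 1]))

        def fn(t):
            p = base.copy()
            for idx, ts, mult in schedules:
                p[idx] *= np.interp(t, ts, mult)
            return p

        return fn

    def param_array(self, grid) -> np.ndarray:
        fn = self.param_fn()
        return np.stack([fn(t) for t in np.asarray(grid, float)], axis=1)


def generate_ground_truth(
    spec: GroundTruthSpec, model: Model | None = None, rng=None
) -> tuple[LongitudinalDataset, GroundTruthSpec]:
    """Simulate the model with drifting parameters and emit a noisy dataset.

    Returns ``(dataset, spec)``; the spec doubles as the ground truth
    (``spec.param_array(grid)`` gives the true trajectory on any grid).
    """
    model = model if model is not None else Model()
    rng = rng if rng is not None else np.random.default_rng(0)
    fn = spec.param_fn()
    theta0 = fn(0.0)
    if np.any(theta0 < 0):
        raise ConfigurationError("drifted parameters must remain >= 0")
    x0 = model.solve_steady_state(theta0)
    t_days = 7.0 * np.asarray(spec.weeks, dtype=float)
    horizon = float(t_days[-1]) if t_days[-1] > 0 else 1.0
    times, states = model.integrate(
        x0, None, (0.0, horizon), n_out=max(50, len(t_days)), param_fn=fn
    )
    if not np.all(np.isfinite(states)) or np.max(np.abs(states)) > 1e9:
        raise IntegrationError(
            f"state blow-up under drift of {sorted(spec.drift)}"
        )

    def clean_value(obs: str, t: float) -> float:
        # interpolate states, evaluate fluxes with theta(t)
        x = np.array([np.interp(t, times, states[:, i]) for i in range(states.shape[1])])
        theta = fn(t)
        j = model._fluxes_unchecked(np.maximum(x, 0.0), theta)
        return float(model.observable_evaluator([obs])(x, j, theta)[0])

    def cv_of(obs: str) -> float:
        if isinstance(spec.noise_cv, dict):
            return float(spec.noise_cv.get(obs, spec.noise_cv.get("default", 0.05)))
        return float(spec.noise_cv)

    def make_series(obs: str, t_obs: np.ndarray, constraint_class: str) -> ObservableSeries:
        cv = cv_of(obs)
        clean = np.array([clean_value(obs, t) for t in t_obs])
        sem = cv / np.sqrt(max(spec.n, 1))
        noisy = np.maximum(clean * (1.0 + sem * rng.standard_normal(clean.size)), 0.0)
        sd = np.maximum(cv * np.abs(clean), 1e-8)
        return ObservableSeries(
            observable=obs, constraint_class=constraint_class,
            times=t_obs, mean=noisy, sd=sd, n=np.full(t_obs.size, spec.n),
        )

    series = {}
    for obs in spec.observables:
        series[obs] = make_series(obs, t_days, "longitudinal")
    cs_times = t_days[t_days > 0]
    for obs in spec.cross_sectional:
        series[obs] = make_series(obs, cs_times, "cross_sectional_group_average")
    dataset = LongitudinalDataset(group=spec.group, series=series).validate()
    return dataset, spec
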