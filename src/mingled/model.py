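"""Kinetics, integration, steady states and observable mapping.

The model is linear in the state for a fixed parameter set (every flux is
either a zeroth-order forcing or proportional to a single pool), so the
dynamics can be written dx/dt = A(theta) x + b(theta).  The generic
``integrate``/``solve_steady_state`` entry points use stiff ODE solvers and
root finding, while ``propagate`` exploits the linear structure through the
matrix exponential — the exact solution — which is what makes the step-wise
estimation loop affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.optimize import least_squares

from . import network as net
from .exceptions import ConfigurationError, DomainError, IntegrationError, SteadyStateError

__all__ = [
    "Conversions",
    "Model",
    "as_state_array",
    "as_param_array",
    "LONGITUDINAL_OBSERVABLES",
    "CROSS_SECTIONAL_OBSERVABLES",
    "FLUX_READOUTS",
]


@dataclass
class Conversions:
    """Unit-conversion constants between model pools and measured quantities.

    plasma_volume_ml: plasma volume used to turn µmol pools into mM.
    lean_mass_g: constant lean body mass; body weight = lean + peripheral fat.
    tg_molar_mass: g/mol of an average triglyceride (tripalmitoylglycerol-ish).
    """

    plasma_volume_ml: float = 1.0
    lean_mass_g: float = 25.0
    tg_molar_mass: float = 885.4


def as_state_array(state) -> np.ndarray:
    """Coerce a dict/Series/array state to the canonical 18-vector."""
    if isinstance(state, (dict, pd.Series)):
        missing = [s for s in net.STATES if s not in state]
        if missing:
            raise ConfigurationError(f"missing state entries: {missing}")
        return np.asarray([float(state[s]) for s in net.STATES])
    arr = np.asarray(state, dtype=float)
    if arr.shape != (net.N_STATES,):
        raise ConfigurationError(
            f"state must have length {net.N_STATES}, got shape {arr.shape}"
        )
    return arr


def as_param_array(params) -> np.ndarray:
    """Coerce a dict/Series/array parameter set to the canonical 39-vector."""
    if isinstance(params, (dict, pd.Series)):
        missing = [p for p in net.PARAMETERS if p not in params]
        if missing:
            raise ConfigurationError(f"missing parameters: {missing}")
        return np.asarray([float(params[p]) for p in net.PARAMETERS])
    arr = np.asarray(params, dtype=float)
    if arr.shape != (net.N_PARAMETERS,):
        raise ConfigurationError(
            f"parameter set must have length {net.N_PARAMETERS}, got shape {arr.shape}"
        )
    return arr


# ---------------------------------------------------------------------------
# Observable mapping.  Each entry: name -> (callable, unit).  The callable
# receives (state 18-vector, flux 41-vector, param 39-vector, Conversions).
# ---------------------------------------------------------------------------

def _j(name: str):
    return net.FLUX_INDEX[name]


def _x(name: str):
    return net.STATE_INDEX[name]


_OBSERVABLE_DEFS: dict[str, tuple] = {
    "plasma_tg": (lambda x, j, p, c: x[_x("vldl_tg")] / c.plasma_volume_ml, "mM"),
    "plasma_tc": (
        lambda x, j, p, c: (x[_x("vldl_chol")] + x[_x("hdl_chol")]) / c.plasma_volume_ml,
        "mM",
    ),
    "plasma_hdl_c": (lambda x, j, p, c: x[_x("hdl_chol")] / c.plasma_volume_ml, "mM"),
    "plasma_glucose": (
        lambda x, j, p, c: x[_x("glucose_plasma")] / c.plasma_volume_ml, "mM",
    ),
    "peripheral_fat": (
        lambda x, j, p, c: x[_x("tg_periphery")] * c.tg_molar_mass * 1e-6, "g",
    ),
    "body_weight": (
        lambda x, j, p, c: c.lean_mass_g + x[_x("tg_periphery")] * c.tg_molar_mass * 1e-6,
        "g",
    ),
    "fecal_neutral_sterols": (
        lambda x, j, p, c: j[_j("fecal_ns_excretion")], "umol/day",
    ),
    "fecal_bile_acids": (lambda x, j, p, c: j[_j("fecal_ba_excretion")], "umol/day"),
    "fecal_ffa": (
        lambda x, j, p, c: net.FA_PER_TG
        * p[net.PARAMETER_INDEX["f_fecal_ffa"]]
        * j[_j("fecal_tg_excretion")],
        "umol FA/day",
    ),
    "fecal_fat_excretion": (lambda x, j, p, c: j[_j("fecal_tg_excretion")], "umol TG/day"),
    "vldl_tg_production": (lambda x, j, p, c: j[_j("vldl_tg_production")], "umol TG/day"),
    "dnl_liver": (
        lambda x, j, p, c: j[_j("dnl_liver")] / net.ACETYL_PER_TG, "umol TG/day",
    ),
    "biliary_chol_secretion": (
        lambda x, j, p, c: j[_j("biliary_chol_secretion")], "umol/day",
    ),
    "biliary_ba_secretion": (
        lambda x, j, p, c: j[_j("biliary_ba_secretion")], "umol/day",
    ),
    "liver_tg": (lambda x, j, p, c: x[_x("tg_liver")], "umol"),
    "liver_chol": (lambda x, j, p, c: x[_x("chol_liver")], "umol"),
    "chol_absorption": (lambda x, j, p, c: j[_j("chol_absorption")], "umol/day"),
    "fat_absorption": (
        lambda x, j, p, c: j[_j("fat_absorption_liver")] + j[_j("fat_absorption_periphery")],
        "umol TG/day",
    ),
    "glucose_oxidation": (
        lambda x, j, p, c: j[_j("glycolysis_liver")] + j[_j("glycolysis_periphery")],
        "umol G6P/day",
    ),
    "fat_oxidation": (
        lambda x, j, p, c: j[_j("beta_oxidation_liver")] + j[_j("beta_oxidation_periphery")],
        "umol TG/day",
    ),
    "lumen_tg": (lambda x, j, p, c: x[_x("tg_lumen")], "umol"),
    "tice": (lambda x, j, p, c: j[_j("tice")], "umol/day"),
}

#: observables measured longitudinally per group in the study design
LONGITUDINAL_OBSERVABLES: tuple[str, ...] = (
    "plasma_tg",
    "plasma_tc",
    "plasma_hdl_c",
    "plasma_glucose",
    "body_weight",
    "fecal_neutral_sterols",
    "fecal_bile_acids",
    "fecal_ffa",
)

#: observables measured cross-sectionally and shared between groups
CROSS_SECTIONAL_OBSERVABLES: tuple[str, ...] = (
    "vldl_tg_production",
    "dnl_liver",
    "biliary_chol_secretion",
    "biliary_ba_secretion",
    "liver_tg",
    "liver_chol",
)

#: derived flux readouts used by the phenotype comparisons (not fitted)
FLUX_READOUTS: tuple[str, ...] = (
    "chol_absorption",
    "fat_absorption",
    "glucose_oxidation",
    "fat_oxidation",
    "fecal_fat_excretion",
    "lumen_tg",
    "tice",
)


class Model:
    """The four-compartment whole-body glucose/lipid model.

    Parameters
    ----------
    forcings : dict, optional
        Dietary forcing rates (µmol/day): ``diet_glucose``, ``diet_tg``,
        ``diet_cholesterol``, ``diet_protein``.  Defaults to the reference
        high-fat high-cholesterol diet (60% energy from fat, 0.25 w%
        cholesterol at ~2.5 g/day intake).
    conv : Conversions, optional
        Unit-conversion constants for the observable mapping.
    """

    def __init__(self, forcings: dict | None = None, conv: Conversions | None = None):
        from .reference import reference_forcings

        self.conv = conv if conv is not None else Conversions()
        self.forcings = dict(reference_forcings())
        if forcings:
            unknown = set(forcings) - set(net.FORCINGS)
            if unknown:
                raise ConfigurationError(f"unknown forcing inputs: {sorted(unknown)}")
            self.forcings.update(forcings)

        # Precomputed index machinery for vectorized flux evaluation.
        self.S = net.stoichiometry_matrix()
        ma = [(i, f) for i, f in enumerate(net.FLUXES) if f.kind == "mass_action"]
        self._ma_cols = np.array([i for i, _ in ma])
        self._ma_pidx = np.array([net.PARAMETER_INDEX[f.parameter] for _, f in ma])
        self._ma_xidx = np.array([net.STATE_INDEX[f.rate_state] for _, f in ma])
        self._ma_sub = np.array([net.STATE_INDEX[f.substrate] for _, f in ma])
        self._n_states = net.N_STATES

    # -- fluxes and derivatives ------------------------------------------

    def _forcing_fluxes(self, params: np.ndarray) -> np.ndarray:
        j = np.zeros(net.N_FLUXES)
        for i, f in enumerate(net.FLUXES):
            if f.kind == "forcing":
                j[i] = self.forcings[f.forcing]
            elif f.kind == "scaled_forcing":
                j[i] = params[net.PARAMETER_INDEX[f.parameter]] * self.forcings[f.forcing]
        return j

    def compute_fluxes(self, state, params) -> np.ndarray:
        """Evaluate all 41 fluxes at a state (validates non-negativity)."""
        x = as_state_array(state)
        p = as_param_array(params)
        if np.any(x < -1e-9):
            bad = [net.STATES[i] for i in np.where(x < -1e-9)[0]]
            raise DomainError(f"negative pool size(s): {bad}")
        if np.any(p < 0):
            bad = [net.PARAMETERS[i] for i in np.where(p < 0)[0]]
            raise DomainError(f"negative parameter(s): {bad}")
        return self._fluxes_unchecked(x, p)

    def _fluxes_unchecked(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        j = self._forcing_fluxes(p)
        j[self._ma_cols] = p[self._ma_pidx] * x[self._ma_xidx]
        return j

    def rhs(self, state, params) -> np.ndarray:
        """dx/dt = S @ j(x, theta); length 18."""
        return self.S @ self.compute_fluxes(state, params)

    def _rhs_guarded(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        # Solver-internal right-hand side: clip negative excursions and ramp
        # down any driven flux whose substrate pool approaches exhaustion
        # (only the plasma-TG driven CETP flux can otherwise drain a zero
        # pool); the ramp keeps the field continuous for the stiff solver.
        xc = np.maximum(x, 0.0)
        j = self._forcing_fluxes(p)
        rates = p[self._ma_pidx] * xc[self._ma_xidx]
        driven = self._ma_sub != self._ma_xidx
        if np.any(driven):
            ramp = np.clip(xc[self._ma_sub[driven]] / 1e-6, 0.0, 1.0)
            rates[driven] *= ramp
        j[self._ma_cols] = rates
        return self.S @ j

    # -- linear-system view ----------------------------------------------

    def linear_system(self, params) -> tuple[np.ndarray, np.ndarray]:
        """Return (A, b) with dx/dt = A x + b for fixed parameters."""
        p = as_param_array(params)
        A = np.zeros((self._n_states, self._n_states))
        for col, pidx, xidx in zip(self._ma_cols, self._ma_pidx, self._ma_xidx):
            A[:, xidx] += p[pidx] * self.S[:, col]
        b = self.S @ self._forcing_fluxes(p)
        return A, b

    def propagate(self, state, params, dt: float) -> np.ndarray:
        """Exact linear propagation of the state over dt days (expm)."""
        x = as_state_array(state)
        p = as_param_array(params)
        A, b = self.linear_system(p)
        n = self._n_states
        M = np.zeros((n + 1, n + 1))
        M[:n, :n] = A * dt
        M[:n, n] = b * dt
        E = expm(M)
        return E[:n, :n] @ x + E[:n, n]

    # -- integration ------------------------------------------------------

    def integrate(
        self,
        state0,
        params,
        t_span: tuple[float, float],
        n_out: int = 100,
        param_fn=None,
        rtol: float = 1e-8,
        atol: float = 1e-8,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Integrate the initial-value problem.

        Returns (times, states) with states of shape (n_out, 18).
        ``param_fn(t) -> parameter array`` overrides constant parameters for
        time-varying simulations (ground-truth generation).
        """
        x0 = as_state_array(state0)
        if t_span[1] <= t_span[0]:
            raise DomainError("t_span must be increasing")
        if param_fn is None:
            p_const = as_param_array(params)

            def f(t, x):
                return self._rhs_guarded(x, p_const)

        else:

            def f(t, x):
                return self._rhs_guarded(x, as_param_array(param_fn(t)))

        t_eval = np.linspace(t_span[0], t_span[1], n_out)
        sol = None
        for method in ("BDF", "LSODA", "Radau"):
            sol = solve_ivp(
                f, t_span, x0, method=method, t_eval=t_eval, rtol=rtol, atol=atol
            )
            if sol.success:
                return sol.t, sol.y.T
        raise IntegrationError(f"ODE solver failed: {sol.message}")

    # -- steady state ------------------------------------------------------

    def _inflow_scale(self, params: np.ndarray) -> float:
        j = self._forcing_fluxes(params)
        return max(float(np.sum(j)), 1.0)

    def solve_steady_state(self, params, guess=None) -> np.ndarray:
        """Non-negative steady state with ||rhs|| below 1e-8 * total inflow.

        Solves the linear balance directly; if that yields an infeasible
        (negative) state, falls back to bounded root finding and finally to
        long-horizon integration.
        """
        p = as_param_array(params)
        tol = 1e-8 * self._inflow_scale(p)
        A, b = self.linear_system(p)
        try:
            x = np.linalg.solve(A, -b)
            if np.all(x >= -1e-9):
                x = np.maximum(x, 0.0)
                if np.linalg.norm(self.S @ self._fluxes_unchecked(x, p)) <= tol:
                    return x
        except np.linalg.LinAlgError:
            pass

        x0 = as_state_array(guess) if guess is not None else np.ones(self._n_states)
        res = least_squares(
            lambda x: self.S @ self._fluxes_unchecked(np.maximum(x, 0.0), p),
            x0,
            bounds=(0.0, np.inf),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        x = np.maximum(res.x, 0.0)
        if np.linalg.norm(self.S @ self._fluxes_unchecked(x, p)) <= tol:
            return x

        _, traj = self.integrate(x, p, (0.0, 5000.0), n_out=2, rtol=1e-10, atol=1e-10)
        x = np.maximum(traj[-1], 0.0)
        if np.linalg.norm(self.S @ self._fluxes_unchecked(x, p)) <= tol:
            return x
        raise SteadyStateError(
            "no steady state found by linear solve, root finding or relaxation"
        )

    # -- observables -------------------------------------------------------

    def observables(self, state, fluxes=None, params=None) -> pd.Series:
        """Map (state, fluxes) to the measured quantities.

        If ``fluxes`` is omitted, ``params`` must be given and the fluxes are
        computed from the state.
        """
        x = as_state_array(state)
        if fluxes is None:
            if params is None:
                raise ConfigurationError("observables needs fluxes or params")
            fluxes = self.compute_fluxes(x, params)
        j = np.asarray(fluxes, dtype=float)
        if j.shape != (net.N_FLUXES,):
            raise ConfigurationError(f"flux vector must have length {net.N_FLUXES}")
        p = as_param_array(params) if params is not None else np.zeros(net.N_PARAMETERS)
        vals = {name: fn(x, j, p, self.conv) for name, (fn, _) in _OBSERVABLE_DEFS.items()}
        return pd.Series(vals)

    def observable_evaluator(self, names):
        """Compiled evaluator for a subset of observables.

        Returns ``ev(x, j, p) -> array`` operating on raw canonical vectors;
        used in the estimation inner loop where Series construction and
        validation would dominate the run time.
        """
        try:
            fns = [_OBSERVABLE_DEFS[n][0] for n in names]
        except KeyError as exc:
            raise ConfigurationError(f"unknown observable {exc.args[0]!r}") from None
        conv = self.conv

        def ev(x, j, p):
            return np.array([f(x, j, p, conv) for f in fns])

        return ev

    @staticmethod
    def observable_unit(name: str) -> str:
        try:
            return _OBSERVABLE_DEFS[name][1]
        except KeyError:
            raise ConfigurationError(f"unknown observable {name!r}") from None

    @staticmethod
    def observable_names() -> tuple[str, ...]:
        return tuple(_OBSERVABLE_DEFS)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        from .reference import reference_parameters

        return {
            "compartments": {k: list(v) for k, v in net.COMPARTMENTS.items()},
            "states": list(net.STATES),
            "fluxes": [
                {
                    "index": f.index,
                    "name": f.name,
                    "kind": f.kind,
                    "substrate": f.substrate,
                    "products": dict(f.products),
                    "parameter": f.parameter,
                    "forcing": f.forcing,
                    "rate_state": f.rate_state,
                }
                for f in net.FLUXES
            ],
            "parameters": dict(reference_parameters()),
            "forcings": dict(self.forcings),
            "conversions": asdict(self.conv),
        }

    @classmethod
    def from_dict(cls, cfg: dict) -> "Model":
        names = {f["name"] for f in cfg.get("fluxes", [])}
        if names and names != set(net.FLUX_INDEX):
            raise ConfigurationError(
                "flux inventory mismatch; rate-law semantics are bound to flux "
                f"names: unexpected {sorted(names ^ set(net.FLUX_INDEX))}"
            )
        conv = Conversions(**cfg.get("conversions", {}))
        return cls(forcings=cfg.get("forcings"), conv=conv)
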