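"""Forward integration of the model and protocol-time sampling.

The delay is handled exactly: the stomach and jejunum have closed forms, so
the delayed ileal forcing J(t - tau) is an explicit function of time and
(L, G, I) integrate as a non-autonomous *ordinary* system -- no history
interpolation is ever needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _integrate
from .kinetics import (
    apparent_glycemia,
    delayed_jejunal_forcing,
    gastric_chain_closed_form,
    hepatic_production,
    secretion_fraction,
)
from .params import ParameterSet

PROTOCOL_TIMES = np.array([0.0, 30.0, 60.0, 90.0, 120.0])


class SimulationError(RuntimeError):
    """Integration failed; carries the offending parameter set."""

    def __init__(self, message: str, params: ParameterSet | None = None):
        super().__init__(message)
        self.params = params


@dataclass(frozen=True)
class SolverSettings:
    """Integrator configuration.

    ``method`` is "lsoda" (stiff-capable reference integrator) or "rk4"
    (fixed-step compiled kernel used on the fitting hot path; ``substeps``
    RK4 steps per dense-grid interval).
    """

    rel_tol: float = 1e-8
    abs_tol: float = 1e-8
    horizon: float = 300.0
    dense_step: float = 1.0
    method: str = "lsoda"
    substeps: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.rel_tol <= 1e-2 and 0 < self.abs_tol <= 1e-2):
            raise ValueError("tolerances must lie in (0, 1e-2]")
        if self.horizon < 120:
            raise ValueError("horizon must cover the 120-min OGTT window")
        if self.dense_step <= 0:
            raise ValueError("dense_step must be positive")
        if self.method not in ("lsoda", "rk4"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")

    def grid(self) -> np.ndarray:
        n = int(round(self.horizon / self.dense_step))
        return np.linspace(0.0, n * self.dense_step, n + 1)


@dataclass(frozen=True)
class Trajectory:
    """Dense simulated time courses of all five state variables."""

    times: np.ndarray
    S: np.ndarray
    J: np.ndarray
    L: np.ndarray
    G: np.ndarray
    I: np.ndarray
    params: ParameterSet

    def __post_init__(self) -> None:
        if self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing from 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.times, "S_mg": self.S, "J_mg": self.J,
             "L_mg": self.L, "G_mg_dl": self.G, "I_uU_ml": self.I}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def derivatives(self) -> tuple[np.ndarray, np.ndarray]:
        """(dG/dt, dI/dt) along the grid, evaluated from the model equations
        (not finite differences), used by the critical-point machinery."""
        p = self.params
        gprod = hepatic_production(p, self.G)
        absorption = p.k_gj * self.J + p.k_gl * self.L
        dG = -(p.k_xg + p.k_xgi * self.I) * self.G + gprod + p.eta * absorption
        g_tilde = apparent_glycemia(p, self.G, self.J, self.L)
        dI = p.k_xi * p.I_b * (secretion_fraction(p, g_tilde) - self.I / p.I_b)
        return dG, dI


def simulate(params: ParameterSet, settings: SolverSettings | None = None) -> Trajectory:
    """Integrate the model from (D, 0, 0, G_b, I_b) over the dense grid."""
    settings = settings or SolverSettings()
    t_grid = settings.grid()
    S, J = gastric_chain_closed_form(params, t_grid)
    if settings.method == "rk4":
        L, G, I, ok = _integrate.integrate_lgi(
            params.free_vector(), params.G_b, params.I_b, params.D,
            t_grid, settings.substeps,
        )
        if not ok:
            raise SimulationError(
                f"model left its physiological domain during integration "
                f"(params={params.to_dict()})", params,
            )
        return Trajectory(t_grid, S, J, L, G, I, params)

    theta = params.free_vector()
    Gb, Ib, D = params.G_b, params.I_b, params.D
    gprod0 = params.basal_hepatic_production

    def rhs(t, y):
        L_, G_, I_ = y
        den = params.k_lambda / gprod0 + (G_ - Gb)
        # domain violations surface as NaN so LSODA aborts rather than
        # silently integrating an invalid law
        if den <= 1e-12 or G_ <= 0 or I_ <= 0:
            return [np.nan, np.nan, np.nan]
        gprod = params.k_lambda / den
        _, J_ = gastric_chain_closed_form(params, t)
        dL = delayed_jejunal_forcing(params, t) - params.k_gl * L_
        absorption = params.k_gj * J_ + params.k_gl * L_
        dG = -(params.k_xg + params.k_xgi * I_) * G_ + gprod + params.eta * absorption
        g_tilde = G_ + params.f_gj * absorption
        sigma = secretion_fraction(params, g_tilde)
        dI = params.k_xi * Ib * (sigma - I_ / Ib)
        return [dL, dG, dI]

    sol = solve_ivp(
        rhs, (0.0, t_grid[-1]), [0.0, Gb, Ib], method="LSODA",
        t_eval=t_grid, rtol=settings.rel_tol, atol=settings.abs_tol,
        max_step=max(params.tau, settings.dense_step) if params.tau > 0 else np.inf,
    )
    if not sol.success or sol.y.shape[1] != t_grid.size or not np.all(np.isfinite(sol.y)):
        raise SimulationError(
            f"LSODA integration failed: {sol.message} (params={params.to_dict()})",
            params,
        )
    L, G, I = sol.y
    return Trajectory(t_grid, S, J, L, G, I, params)


def sample_at(traj: Trajectory, times) -> tuple[np.ndarray, np.ndarray]:
    """Glycemia and insulinemia interpolated at the requested times."""
    times = np.asarray(times, dtype=float)
    if np.any(times < traj.times[0]) or np.any(times > traj.times[-1]):
        raise ValueError("requested times outside the simulated horizon")
    G = np.interp(times, traj.times, traj.G)
    I = np.interp(times, traj.times, traj.I)
    return G, I
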