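"""Evaluation machinery: goodness of fit, volcano sensitivity profiles and
stability of fitted parameters under measurement perturbation.

All numbers are emitted as plain tables so tests run headless; plots are a
secondary convenience layer on top of the same data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitResult, OptimizerSettings, fit_patient
from .objective import CostWeights, ObjectiveEvaluator
from .params import FREE_PARAM_NAMES, FeasibleBox, default_box
from .records import OGTTRecord
from .solver import SolverSettings, sample_at, simulate


@dataclass(frozen=True)
class GoodnessOfFit:
    """Predicted-vs-observed diagnostics over a fitted cohort."""

    pairs: pd.DataFrame           # patient_id, variable, time, observed, predicted
    summary: pd.DataFrame         # per variable: mean/sd of relative residual,
                                  # correlation, normality statistic + p-value

    def relative_residuals(self, variable: str | None = None) -> np.ndarray:
        df = self.pairs if variable is None else self.pairs[self.pairs.variable == variable]
        return ((df.predicted - df.observed) / df.observed).to_numpy()


def goodness_of_fit(records: list[OGTTRecord], fits: list[FitResult],
                    settings: SolverSettings | None = None) -> GoodnessOfFit:
    """Residual statistics of fitted trajectories against the measured points.

    Emits predicted/observed pairs for every measurement, per-variable
    relative-residual mean and SD, predicted-observed correlation and a
    D'Agostino-Pearson normality test of the residual distribution.
    """
    if not fits:
        raise ValueError("need at least one fitted patient")
    settings = settings or SolverSettings(method="rk4")
    rows = []
    for rec, fit in zip(records, fits):
        traj = simulate(fit.theta_hat, settings)
        G, I = sample_at(traj, rec.times)
        for t, obs, pred in zip(rec.times, rec.G_exp, G):
            rows.append((rec.patient_id, "glucose", t, obs, pred))
        for t, obs, pred in zip(rec.times, rec.I_exp, I):
            rows.append((rec.patient_id, "insulin", t, obs, pred))
    pairs = pd.DataFrame(rows, columns=["patient_id", "variable", "time",
                                        "observed", "predicted"])
    out = []
    for var, sub in pairs.groupby("variable"):
        rel = (sub.predicted - sub.observed) / sub.observed
        if len(rel) >= 8:
            stat, pval = stats.normaltest(rel)
        else:
            stat, pval = np.nan, np.nan
        out.append({
            "variable": var,
            "n": len(rel),
            "residual_mean": rel.mean(),
            "residual_sd": rel.std(ddof=1) if len(rel) > 1 else 0.0,
            "correlation": np.corrcoef(sub.observed, sub.predicted)[0, 1],
            "normality_stat": stat,
            "normality_p": pval,
        })
    return GoodnessOfFit(pairs=pairs, summary=pd.DataFrame(out))


def residual_histogram(gof: GoodnessOfFit, variable: str,
                       bins: int = 30) -> pd.DataFrame:
    """Probability-normalized histogram of relative residuals (area = 1)."""
    rel = gof.relative_residuals(variable)
    density, edges = np.histogram(rel, bins=bins, density=True)
    return pd.DataFrame({
        "bin_left": edges[:-1], "bin_right": edges[1:], "density": density,
    })


# ---------------------------------------------------------------------------
# volcano sensitivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolcanoProfile:
    """Normalized cost along one parameter axis around its fitted optimum.

    ``percent`` holds percent-of-optimum abscissae; ``normalized_cost`` is
    100 * J_T / J_T(optimum), so the optimum maps to the point (100, 100).
    Infeasible grid points carry NaN and are flagged.
    """

    parameter: str
    percent: np.ndarray
    normalized_cost: np.ndarray
    infeasible: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "percent_of_optimum": self.percent,
            "normalized_cost": self.normalized_cost,
            "infeasible": self.infeasible,
        })


def volcano(record: OGTTRecord, fit: FitResult, weights: CostWeights,
            parameter: str, span: tuple[float, float] = (50.0, 150.0),
            n_grid: int = 21, box: FeasibleBox | None = None,
            theta_ref: np.ndarray | None = None,
            settings: SolverSettings | None = None) -> VolcanoProfile:
    """Vary one parameter over ``span`` percent of its optimum, all others
    held at the fit; evaluate the full cost and normalize to the optimum."""
    if not fit.converged:
        raise ValueError("volcano profiles require a converged fit")
    idx = FREE_PARAM_NAMES.index(parameter)
    ev = ObjectiveEvaluator(record, weights, box=box, theta_ref=theta_ref,
                            settings=settings or SolverSettings(method="rk4"),
                            mode="hard")
    theta0 = fit.theta_hat.free_vector()
    # make the exact optimum part of the grid so the (100, 100) anchor holds
    percent = np.linspace(span[0], span[1], n_grid)
    if not np.any(np.isclose(percent, 100.0)):
        percent = np.sort(np.append(percent, 100.0))
    j0 = ev.evaluate_vector(theta0).total
    costs = np.empty(percent.size)
    infeas = np.zeros(percent.size, dtype=bool)
    for k, pc in enumerate(percent):
        theta = theta0.copy()
        theta[idx] = theta0[idx] * pc / 100.0
        if theta[idx] < 0 or (idx != FREE_PARAM_NAMES.index("tau") and theta[idx] <= 0):
            costs[k], infeas[k] = np.nan, True
            continue
        b = ev.evaluate_vector(theta)
        if not np.isfinite(b.total):
            costs[k], infeas[k] = np.nan, True
        else:
            costs[k] = b.total
    if j0 <= 0:
        norm = np.where(costs == 0, 100.0, np.inf)
        norm[np.isclose(percent, 100.0)] = 100.0
    else:
        norm = 100.0 * costs / j0
        norm[np.isclose(percent, 100.0)] = 100.0
    return VolcanoProfile(parameter=parameter, percent=percent,
                          normalized_cost=norm, infeasible=infeas)


# ---------------------------------------------------------------------------
# stability under measurement noise
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StabilityReport:
    """Per-parameter drift of refitted estimates under measurement noise."""

    noise_max: float
    drifts: pd.DataFrame          # replicate, parameter, original, perturbed, rel_change
    significant: pd.DataFrame     # parameter, p_value, significant flag
    n_failed: int

    def median_drift(self, parameter: str | None = None) -> float:
        df = self.drifts if parameter is None else \
            self.drifts[self.drifts.parameter == parameter]
        return float(df.rel_change.abs().median())


def stability_under_noise(record: OGTTRecord, fit: FitResult,
                          weights: CostWeights,
                          noise_max: float = 0.10, n_reps: int = 10,
                          seed: int = 0,
                          box: FeasibleBox | None = None,
                          opt: OptimizerSettings | None = None,
                          settings: SolverSettings | None = None,
                          group=None) -> StabilityReport:
    """Add uniform multiplicative noise (at most ``noise_max``) to the
    measurements, refit from the original optimum, and summarize drift.

    Significance per parameter uses a Wilcoxon signed-rank test of the
    perturbed estimates against the original at the 5% level (with fewer
    than 6 replicates the test is reported as not significant).
    """
    if not fit.converged:
        raise ValueError("stability analysis requires a converged fit")
    if not 0 <= noise_max <= 0.10:
        raise ValueError("noise_max must lie in [0, 0.10]")
    box = box or default_box()
    settings = settings or SolverSettings(method="rk4")
    # local-only refit: no annealing, fine pattern mesh, gradient polish --
    # the perturbed optimum is expected near the original one
    opt = opt or OptimizerSettings(n_sa=0, n_pattern=400, n_gradient=300,
                                   pattern_mesh=0.02)
    theta0 = fit.theta_hat.free_vector()

    class _Anchor:
        representative = theta0
        member_curves = np.empty((0, 10))
        member_thetas = np.empty((0, len(FREE_PARAM_NAMES)))

    anchor = group if group is not None else _Anchor()
    rows = []
    n_failed = 0
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        g_noisy = record.G_exp * (1 + rng.uniform(-noise_max, noise_max, record.n_points))
        i_noisy = record.I_exp * (1 + rng.uniform(-noise_max, noise_max, record.n_points))
        try:
            noisy = OGTTRecord(record.patient_id + f"_noise{rep}", record.times,
                               g_noisy, i_noisy)
            refit = fit_patient(noisy, anchor, weights, box, settings, opt,
                                seed=rep, initial=fit.theta_hat)
        except Exception:
            n_failed += 1
            continue
        if not np.isfinite(refit.cost.total):
            n_failed += 1
            continue
        theta1 = refit.theta_hat.free_vector()
        for name, o, p in zip(FREE_PARAM_NAMES, theta0, theta1):
            rows.append((rep, name, o, p, (p - o) / o if o != 0 else np.nan))
    drifts = pd.DataFrame(rows, columns=["replicate", "parameter", "original",
                                         "perturbed", "rel_change"])
    sig_rows = []
    for name in FREE_PARAM_NAMES:
        vals = drifts.loc[drifts.parameter == name, "rel_change"].dropna()
        if len(vals) >= 6 and np.any(vals != 0):
            try:
                _, p = stats.wilcoxon(vals)
            except ValueError:
                p = 1.0
        else:
            p = 1.0
        sig_rows.append({"parameter": name, "p_value": p,
                         "significant": p < 0.05})
    return StabilityReport(noise_max=noise_max, drifts=drifts,
                           significant=pd.DataFrame(sig_rows),
                           n_failed=n_failed)


# ---------------------------------------------------------------------------
# plotting (secondary layer; all data also available as tables)
# ---------------------------------------------------------------------------

def plot_fit(record: OGTTRecord, fit: FitResult,
             settings: SolverSettings | None = None, ax=None):
    """Measured points and fitted trajectories for one patient."""
    import matplotlib.pyplot as plt

    traj = simulate(fit.theta_hat, settings or SolverSettings(method="rk4"))
    if ax is None:
        _, ax = plt.subplots(1, 2, figsize=(9, 3.2))
    ax[0].plot(traj.times, traj.G, label="model")
    ax[0].plot(record.times, record.G_exp, "d", label="measured")
    ax[0].set(xlabel="time (min)", ylabel="glycemia (mg/dL)")
    ax[1].plot(traj.times, traj.I, label="model")
    ax[1].plot(record.times, record.I_exp, "d", label="measured")
    ax[1].set(xlabel="time (min)", ylabel="insulinemia (uU/mL)")
    ax[0].legend()
    return ax


def plot_volcano(profiles: list[VolcanoProfile], ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for p in profiles:
        ax.plot(p.percent, p.normalized_cost, label=p.parameter)
    ax.axhline(100, color="k", lw=0.5)
    ax.axvline(100, color="k", lw=0.5)
    ax.set(xlabel="parameter (% of optimum)", ylabel="cost (% of minimum)")
    ax.legend(fontsize=7)
    return ax
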