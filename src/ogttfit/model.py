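"""statsmodels-style modelling surface.

``OGTTModel`` wraps one patient's record together with the fitting
configuration; ``fit()`` runs the full identification pipeline (staged
initial guess, hybrid heuristic/gradient minimization, repeated restarts)
and returns an ``OGTTResults`` carrying the point estimates, empirical 95%
confidence intervals, the cost breakdown and diagnostics helpers.

Example
-------
>>> from ogttfit import OGTTModel, OGTTRecord
>>> rec = OGTTRecord("p1", [0, 30, 60, 90, 120],
...                  [88, 145, 118, 104, 96], [7, 48, 42, 24, 13])
>>> res = OGTTModel(rec).fit(seed=1, n_restarts=3)
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import pandas as pd

from .feasible import ProfileGroup, assign_group, explore_feasible_set
from .fitting import (
    ConfidenceReport,
    FitResult,
    OptimizerSettings,
    fit_patient,
    repeated_fits,
)
from .objective import CostBreakdown, CostWeights
from .params import FREE_PARAM_NAMES, FeasibleBox, ParameterSet, default_box
from .records import OGTTRecord
from .solver import SolverSettings, Trajectory, simulate


class OGTTModel:
    """Delay-differential glucose-insulin model bound to one OGTT record.

    Parameters
    ----------
    record : OGTTRecord
        The patient's 5-point measurements.
    weights : CostWeights, optional
        Fitting-functional weights; defaults are sensible for the protocol.
    box : FeasibleBox, optional
        Feasible parameter box F0.
    groups : list of ProfileGroup, optional
        Pre-explored profile groups.  When omitted, a small exploration of
        the feasible box is run on first use (budget ``explore_budget``).
    """

    def __init__(self, record: OGTTRecord,
                 weights: CostWeights | None = None,
                 box: FeasibleBox | None = None,
                 groups: list[ProfileGroup] | None = None,
                 solver: SolverSettings | None = None,
                 explore_budget: int = 5000,
                 explore_seed: int = 0):
        self.record = record
        self.weights = weights or CostWeights()
        self.box = box or default_box()
        self.solver = solver or SolverSettings(method="rk4")
        self._groups = groups
        self._explore_budget = explore_budget
        self._explore_seed = explore_seed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, patient_id: str | None = None,
                       **kw) -> "OGTTModel":
        """Build from a long-format frame with the record-file columns."""
        if patient_id is not None:
            df = df[df["patient_id"] == patient_id]
        if df.empty:
            raise ValueError(f"no rows for patient {patient_id!r}")
        df = df.sort_values("time_min")
        rec = OGTTRecord(
            patient_id=str(df["patient_id"].iloc[0]),
            times=df["time_min"].to_numpy(float),
            G_exp=df["glucose_mg_dl"].to_numpy(float),
            I_exp=df["insulin_uU_ml"].to_numpy(float),
        )
        return cls(rec, **kw)

    @property
    def groups(self) -> list[ProfileGroup]:
        if self._groups is None:
            self._groups = explore_feasible_set(
                self.box, self._explore_budget, self._explore_seed)
        return self._groups

    def assigned_group(self) -> ProfileGroup:
        return assign_group(self.record, self.groups)

    def simulate(self, params: ParameterSet,
                 solver: SolverSettings | None = None) -> Trajectory:
        return simulate(params, solver or self.solver)

    def fit(self, seed: int = 0, n_restarts: int = 10,
            optimizer: OptimizerSettings | None = None) -> "OGTTResults":
        """Identify the 13 free parameters; ``n_restarts >= 2`` also yields
        empirical confidence intervals from repeated jittered fits."""
        group = self.assigned_group()
        optimizer = optimizer or OptimizerSettings()
        if n_restarts >= 2:
            report, best = repeated_fits(
                self.record, group, self.weights, self.box, self.solver,
                optimizer, n=n_restarts, seed=seed)
        else:
            best = fit_patient(self.record, group, self.weights, self.box,
                               self.solver, optimizer, seed=seed)
            report = None
        return OGTTResults(self, best, report, group)


class OGTTResults:
    """Fitted-model results: estimates, uncertainties, diagnostics."""

    def __init__(self, model: OGTTModel, fit_result: FitResult,
                 confidence: ConfidenceReport | None,
                 group: ProfileGroup):
        self.model = model
        self.fit_result = fit_result
        self.confidence = confidence
        self.group = group

    # -- estimates ----------------------------------------------------------

    @property
    def params(self) -> ParameterSet:
        return self.fit_result.theta_hat

    @property
    def cost(self) -> CostBreakdown:
        return self.fit_result.cost

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    @property
    def insulin_sensitivity(self) -> float:
        """S_I in 1/(min*uU/mL); identically the fitted k_xgi."""
        return self.params.insulin_sensitivity

    def conf_int(self) -> pd.DataFrame:
        """95% intervals per parameter (empirical, across repeated fits)."""
        if self.confidence is None:
            raise ValueError("fit with n_restarts >= 2 to obtain intervals")
        return self.confidence.table.set_index("parameter")[["lo", "hi"]]

    # -- diagnostics --------------------------------------------------------

    def trajectory(self) -> Trajectory:
        return self.model.simulate(self.params)

    def volcano(self, parameter: str, **kw):
        from .diagnostics import volcano

        return volcano(self.model.record, self.fit_result, self.model.weights,
                       parameter, box=self.model.box, **kw)

    def plot(self, ax=None):
        from .diagnostics import plot_fit

        return plot_fit(self.model.record, self.fit_result,
                        self.model.solver, ax=ax)

    def summary(self) -> str:
        """Human-readable parameter table in the statsmodels tradition."""
        rec = self.model.record
        lines = [
            "OGTT delay-differential model fit",
            "=" * 58,
            f"patient:          {rec.patient_id}",
            f"basal G, I:       {rec.basal_glycemia:.1f} mg/dL, "
            f"{rec.basal_insulinemia:.1f} uU/mL",
            f"profile group:    {self.group.group_id}",
            f"converged:        {self.converged}",
            f"total cost:       {self.cost.total:.4e}",
            f"  J_exp={self.cost.j_exp:.3e}  J_spline={self.cost.j_spline:.3e}"
            f"  J_error={self.cost.j_error:.3e}",
            f"information fn:   {'feasible' if self.cost.feasible else 'INFEASIBLE'}",
            f"insulin sens. S_I: {self.insulin_sensitivity:.3e} 1/(min*uU/mL)",
            "-" * 58,
        ]
        header = f"{'parameter':<10}{'estimate':>12}"
        if self.confidence is not None:
            header += f"{'ci 2.5%':>12}{'ci 97.5%':>12}"
        lines.append(header)
        vec = self.params.free_vector()
        for i, name in enumerate(FREE_PARAM_NAMES):
            row = f"{name:<10}{vec[i]:>12.4g}"
            if self.confidence is not None:
                lo, hi = self.confidence.interval(name)
                row += f"{lo:>12.4g}{hi:>12.4g}"
            lines.append(row)
        lines.append("=" * 58)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<OGTTResults patient={self.model.record.patient_id} "
                f"converged={self.converged} cost={self.cost.total:.3e}>")
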