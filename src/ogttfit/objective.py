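"""The multi-component fitting functional.

Per-patient parameter identification minimizes a weighted sum of

* ``J_exp``   -- range-normalized MSE against the 5+5 measured points;
* ``J_spline``-- range-normalized MSE against a densified soft interpolant
  (convex combination of a cubic spline and a least-squares quadratic),
  penalizing non-physiological high-frequency oscillation between samples;
* ``J_error`` -- an elliptical error-bar term: each data point becomes an
  ellipse in (t, value) space (horizontal semi-axis = the temporal
  uncertainty, vertical semi-axis proportional to the value); a model curve
  passing inside an ellipse pays ~nothing;
* ``eps * ||theta - theta*_j||`` -- local regularization toward the
  representative of the patient's profile group, in box-normalized units;

subject to an *information function*: every sign change in the measured
first differences certifies a zero-derivative point of the underlying curve
inside a known time bracket with a known confidence interval on its value,
and parameter vectors whose simulated curves cannot realize all of those
stationary points are tagged unfeasible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .params import FeasibleBox, ParameterSet
from .records import OGTTRecord
from .solver import SimulationError, SolverSettings, Trajectory, simulate

INFEASIBLE_TOTAL = np.inf
#: weight of the smooth violation magnitude in soft (penalty) mode
SOFT_PENALTY_WEIGHT = 100.0

# time scale (min) used to normalize residual derivatives in the smooth
# violation magnitude; half the inter-sample spacing
_DERIV_TIME_SCALE = 15.0


@dataclass(frozen=True)
class CostWeights:
    """Weights and uncertainty scales of the fitting functional.

    Only ``delta_t`` (+-3 min temporal uncertainty) is a published value;
    the component weights are implementation defaults, all overridable.
    ``lambda2`` is deliberately small: the interpolant term is meant to do
    no more than favor smooth, regular solutions, and larger weights
    measurably displace the functional's minimizer away from the parameters
    that generated noiseless synthetic data.
    """

    lambda1: float = 1.0
    lambda2: float = 0.05
    lambda3: float = 0.25
    alpha: float = 1.0
    phi: float = 0.5
    epsilon: float = 1e-4
    delta_t: float = 3.0
    delta_rel: float = 0.05

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3", "alpha", "epsilon",
                     "delta_t", "delta_rel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.phi <= 1:
            raise ValueError("phi must lie in [0, 1]")


@dataclass(frozen=True)
class CriticalPointConstraint:
    """One certified zero-derivative locus of a measured curve."""

    curve: str                       # "glucose" | "insulin"
    index: int                       # interior measurement index i0
    time_interval: tuple[float, float]
    value_interval: tuple[float, float]
    kind: str                        # "maximum" | "minimum"


@dataclass(frozen=True)
class CostBreakdown:
    """Component values of the fitting functional at one parameter vector."""

    j_exp: float
    j_spline: float
    j_error: float
    j_reg: float
    feasible: bool
    violation: float
    total: float

    @classmethod
    def infinite(cls, violation: float = np.inf) -> "CostBreakdown":
        return cls(np.inf, np.inf, np.inf, np.inf, False, violation, np.inf)


# ---------------------------------------------------------------------------
# interpolant and cost components
# ---------------------------------------------------------------------------

def build_interpolant(record: OGTTRecord, weights: CostWeights):
    """Densified reference curves ``(Ghat, Ihat)`` as a callable of time.

    ``hat = phi * spline + (1 - phi) * poly`` where the spline interpolates
    the points exactly (natural cubic) and the polynomial is a least-squares
    quadratic trend.  ``phi = 1`` reduces to the pure spline, ``phi = 0`` to
    the pure polynomial.
    """
    t = record.times
    splines = (CubicSpline(t, record.G_exp, bc_type="natural"),
               CubicSpline(t, record.I_exp, bc_type="natural"))
    polys = (np.polynomial.Polynomial.fit(t, record.G_exp, deg=min(2, t.size - 1)),
             np.polynomial.Polynomial.fit(t, record.I_exp, deg=min(2, t.size - 1)))

    def evaluate(ts):
        ts = np.asarray(ts, dtype=float)
        out = []
        for s, p in zip(splines, polys):
            out.append(weights.phi * s(ts) + (1.0 - weights.phi) * p(ts))
        return out[0], out[1]

    return evaluate


def _ranges(record: OGTTRecord) -> tuple[float, float]:
    """Squared measurement ranges used as MSE normalizers (basal fallback)."""
    out = []
    for vals, label in ((record.G_exp, "glucose"), (record.I_exp, "insulin")):
        rng = float(vals.max() - vals.min())
        if rng <= 0:
            warnings.warn(
                f"patient {record.patient_id}: flat {label} record, "
                "normalizing by the basal value instead of the range",
                stacklevel=3,
            )
            rng = float(vals[0])
        out.append(rng * rng)
    return out[0], out[1]


def _sample_traj(traj: Trajectory, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    G = np.interp(times, traj.times, traj.G)
    I = np.interp(times, traj.times, traj.I)
    return G, I


def cost_exp(record: OGTTRecord, traj_or_params, weights: CostWeights,
             settings: SolverSettings | None = None) -> float:
    """Range-normalized experimental MSE over the measured points."""
    traj = _as_traj(traj_or_params, settings)
    g2, i2 = _ranges(record)
    Gn, In = _sample_traj(traj, record.times)
    n = record.n_points
    return float(
        np.sum((record.G_exp - Gn) ** 2) / (n * g2)
        + weights.alpha * np.sum((record.I_exp - In) ** 2) / (n * i2)
    )


def cost_spline(record: OGTTRecord, traj_or_params, weights: CostWeights,
                settings: SolverSettings | None = None,
                dense_times: np.ndarray | None = None) -> float:
    """Range-normalized MSE against the densified interpolant over the
    record's time span."""
    traj = _as_traj(traj_or_params, settings)
    if dense_times is None:
        dense_times = traj.times[traj.times <= record.times[-1]]
    g2, i2 = _ranges(record)
    Ghat, Ihat = build_interpolant(record, weights)(dense_times)
    Gn, In = _sample_traj(traj, dense_times)
    n = dense_times.size
    return float(
        np.sum((Ghat - Gn) ** 2) / (n * g2)
        + weights.alpha * np.sum((Ihat - In) ** 2) / (n * i2)
    )


def _elliptical_distances(times: np.ndarray, curve: np.ndarray,
                          t_i: np.ndarray, y_i: np.ndarray,
                          weights: CostWeights) -> np.ndarray:
    """Min over the dense curve of the normalized elliptical distance to
    each data point (horizontal semi-axis delta_t, vertical delta_rel*y)."""
    dt = (times[None, :] - t_i[:, None]) / max(weights.delta_t, 1e-9)
    dy = (curve[None, :] - y_i[:, None]) / np.maximum(weights.delta_rel * y_i[:, None], 1e-12)
    d2 = dt * dt + dy * dy
    return np.sqrt(d2.min(axis=1))


def cost_error(record: OGTTRecord, traj_or_params, weights: CostWeights,
               settings: SolverSettings | None = None) -> float:
    """Elliptical error-bar cost.

    Each point contributes ``max(0, d - 1)^2`` where ``d`` is the nearest
    normalized elliptical distance from the model curve: passage inside the
    error ellipse (d <= 1, the truncated support of the polar error density)
    is free, so measurements are matched within error bars rather than
    exactly -- the "mathematical buffer" that stabilizes fits under noise.
    """
    traj = _as_traj(traj_or_params, settings)
    span = traj.times <= record.times[-1] + 3 * weights.delta_t
    ts = traj.times[span]
    n = record.n_points
    dG = _elliptical_distances(ts, traj.G[span], record.times, record.G_exp, weights)
    dI = _elliptical_distances(ts, traj.I[span], record.times, record.I_exp, weights)
    hinge = lambda d: np.maximum(0.0, d - 1.0) ** 2
    return float(hinge(dG).sum() / n + weights.alpha * hinge(dI).sum() / n)


def _as_traj(traj_or_params, settings) -> Trajectory:
    if isinstance(traj_or_params, Trajectory):
        return traj_or_params
    return simulate(traj_or_params, settings)


# ---------------------------------------------------------------------------
# critical points and the information function
# ---------------------------------------------------------------------------

def detect_critical_points(record: OGTTRecord,
                           weights: CostWeights) -> list[CriticalPointConstraint]:
    """Certified interior extrema of the measured curves.

    An interior index i0 with ``(H[i0]-H[i0-1]) * (H[i0+1]-H[i0]) < 0``
    (strict; ties count as no sign change) brackets a zero of the underlying
    curve's derivative in ``[T[i0-1], T[i0+1]]``.  A 5-point curve yields at
    most 3 constraints, so both curves combined yield at most 6.

    The stored ``time_interval`` is the raw bracket (it is widened by the
    temporal uncertainty only when evaluated).  The extremum's confidence
    interval must cover the true between-sample extremum, which generically
    over/undershoots the sampled value by an amount on the scale of the
    adjacent secant variation; the interval therefore combines the relative
    measurement uncertainty with half the largest adjacent first difference,
    applied on the overshoot side of the extremum.
    """
    out: list[CriticalPointConstraint] = []
    for curve, vals in (("glucose", record.G_exp), ("insulin", record.I_exp)):
        d = np.diff(vals)
        for i0 in range(1, record.n_points - 1):
            if d[i0 - 1] * d[i0] < 0:
                kind = "maximum" if d[i0 - 1] > 0 else "minimum"
                t_lo = float(record.times[i0 - 1])
                t_hi = float(record.times[i0 + 1])
                v = float(vals[i0])
                secant = 0.5 * max(abs(d[i0 - 1]), abs(d[i0]))
                if kind == "maximum":
                    lo = v * (1 - weights.delta_rel)
                    hi = v * (1 + weights.delta_rel) + secant
                else:
                    lo = max(v * (1 - weights.delta_rel) - secant, 1e-9)
                    hi = v * (1 + weights.delta_rel)
                out.append(
                    CriticalPointConstraint(
                        curve=curve, index=i0,
                        time_interval=(t_lo, t_hi),
                        value_interval=(lo, hi),
                        kind=kind,
                    )
                )
    return out


def stationary_glycemia(params: ParameterSet, J: float, L: float,
                        I: float, G: float) -> float:
    """Zero-derivative glycemia: (Gprod* + eta*(k_gj*J* + k_gl*L*)) /
    (k_xg + k_xgi*I*), with Gprod* evaluated at the stationary state."""
    from .kinetics import hepatic_production

    gprod = hepatic_production(params, G)
    return float(
        (gprod + params.eta * (params.k_gj * J + params.k_gl * L))
        / (params.k_xg + params.k_xgi * I)
    )


def stationary_insulinemia(params: ParameterSet, J: float, L: float,
                           G: float) -> float:
    """Zero-derivative insulinemia: I* = I_b * sigma(G~*)."""
    from .kinetics import apparent_glycemia, secretion_fraction

    g_tilde = apparent_glycemia(params, G, J, L)
    return float(params.I_b * secretion_fraction(params, g_tilde))


def information_function(traj: Trajectory,
                         constraints: list[CriticalPointConstraint],
                         delta_t: float = 3.0,
                         ) -> tuple[bool, float]:
    """Feasibility of a simulated trajectory under the critical-point loci.

    For each constraint, looks for a time inside the bracket (widened by the
    temporal uncertainty ``delta_t``) where the relevant model derivative
    vanishes and the stationary value -- computed
    from the model's own zero-derivative identity -- falls inside the
    confidence interval.  Returns ``(feasible, violation)`` where
    ``violation`` is a smooth aggregate magnitude (0 when all constraints
    are satisfiable) usable as a penalty.
    """
    if not constraints:
        return True, 0.0
    dG, dI = traj.derivatives()
    deriv = {"glucose": dG, "insulin": dI}
    value = {"glucose": traj.G, "insulin": traj.I}
    feasible = True
    violation = 0.0
    for c in constraints:
        t_lo = max(0.0, c.time_interval[0] - delta_t)
        t_hi = c.time_interval[1] + delta_t
        mask = (traj.times >= t_lo) & (traj.times <= t_hi)
        idx = np.nonzero(mask)[0]
        h = value[c.curve][idx]
        hp = deriv[c.curve][idx]
        lo, hi = c.value_interval
        center, half = 0.5 * (lo + hi), 0.5 * (hi - lo)

        satisfied = False
        for j in range(idx.size - 1):
            a, b = hp[j], hp[j + 1]
            # any vanishing of the derivative qualifies; the value interval
            # does the discriminating
            if a * b > 0 or a == b:
                continue
            w = a / (a - b)
            i0, i1 = idx[j], idx[j + 1]
            interp = lambda arr: (1 - w) * arr[i0] + w * arr[i1]
            Js, Ls, Gs, Is = (interp(traj.J), interp(traj.L),
                              interp(traj.G), interp(traj.I))
            if c.curve == "glucose":
                h_opt = stationary_glycemia(traj.params, Js, Ls, Is, Gs)
            else:
                h_opt = stationary_insulinemia(traj.params, Js, Ls, Gs)
            if lo <= h_opt <= hi:
                satisfied = True
                break
        if satisfied:
            continue
        feasible = False
        # smooth violation: best joint proximity to (derivative = 0,
        # value inside interval), both in units of the interval half-width
        dv = np.maximum(0.0, np.abs(h - center) - half) / half
        dd = hp * _DERIV_TIME_SCALE / half
        violation += float(np.min(dd * dd + dv * dv))
    return feasible, violation


# ---------------------------------------------------------------------------
# assembled objective
# ---------------------------------------------------------------------------

class ObjectiveEvaluator:
    """Precomputed, fast evaluator of the full fitting functional.

    ``mode="soft"`` adds a finite penalty proportional to the information
    -function violation (for heuristic optimizers that need finite values);
    ``mode="hard"`` returns an infinite sentinel total on infeasibility.
    """

    def __init__(self, record: OGTTRecord, weights: CostWeights,
                 box: FeasibleBox | None = None,
                 theta_ref: np.ndarray | None = None,
                 constraints: list[CriticalPointConstraint] | None = None,
                 settings: SolverSettings | None = None,
                 mode: str = "soft"):
        if mode not in ("soft", "hard"):
            raise ValueError("mode must be 'soft' or 'hard'")
        self.record = record
        self.weights = weights
        self.box = box
        self.theta_ref = None if theta_ref is None else np.asarray(theta_ref, float)
        self.constraints = (detect_critical_points(record, weights)
                            if constraints is None else constraints)
        self.settings = settings or SolverSettings(method="rk4")
        self.mode = mode
        self.n_evals = 0

        self._g2, self._i2 = _ranges(record)
        grid = self.settings.grid()
        self._span = grid <= record.times[-1]
        self._dense_times = grid[self._span]
        ghat, ihat = build_interpolant(record, weights)(self._dense_times)
        self._ghat, self._ihat = ghat, ihat
        self._err_span = grid <= record.times[-1] + 3 * weights.delta_t

    def _components(self, traj: Trajectory, theta: np.ndarray) -> CostBreakdown:
        w = self.weights
        rec = self.record
        n = rec.n_points

        Gn, In = _sample_traj(traj, rec.times)
        j_exp = (np.sum((rec.G_exp - Gn) ** 2) / (n * self._g2)
                 + w.alpha * np.sum((rec.I_exp - In) ** 2) / (n * self._i2))

        Gd = traj.G[self._span]
        Id = traj.I[self._span]
        m = self._dense_times.size
        j_spline = (np.sum((self._ghat - Gd) ** 2) / (m * self._g2)
                    + w.alpha * np.sum((self._ihat - Id) ** 2) / (m * self._i2))

        ts = traj.times[self._err_span]
        dGe = _elliptical_distances(ts, traj.G[self._err_span], rec.times, rec.G_exp, w)
        dIe = _elliptical_distances(ts, traj.I[self._err_span], rec.times, rec.I_exp, w)
        j_error = (np.maximum(0.0, dGe - 1.0) ** 2).sum() / n \
            + w.alpha * (np.maximum(0.0, dIe - 1.0) ** 2).sum() / n

        if self.theta_ref is not None and self.box is not None:
            j_reg = float(np.linalg.norm(
                self.box.normalize(theta) - self.box.normalize(self.theta_ref)))
        else:
            j_reg = 0.0

        feasible, violation = information_function(traj, self.constraints,
                                                   self.weights.delta_t)
        total = (w.lambda1 * j_exp + w.lambda2 * j_spline
                 + w.lambda3 * j_error + w.epsilon * j_reg)
        if not feasible:
            if self.mode == "hard":
                total = INFEASIBLE_TOTAL
            else:
                total += SOFT_PENALTY_WEIGHT * violation
        return CostBreakdown(float(j_exp), float(j_spline), float(j_error),
                             j_reg, feasible, violation, float(total))

    def evaluate_params(self, params: ParameterSet) -> CostBreakdown:
        self.n_evals += 1
        try:
            traj = simulate(params, self.settings)
        except (SimulationError, ValueError):
            return CostBreakdown.infinite()
        return self._components(traj, params.free_vector())

    def evaluate_vector(self, theta: np.ndarray) -> CostBreakdown:
        params = ParameterSet.from_free_vector(
            theta, self.record.basal_glycemia, self.record.basal_insulinemia)
        return self.evaluate_params(params)

    def __call__(self, theta: np.ndarray) -> float:
        return self.evaluate_vector(theta).total


def total_cost(record: OGTTRecord, params: ParameterSet, weights: CostWeights,
               theta_ref: np.ndarray | ParameterSet | None = None,
               box: FeasibleBox | None = None,
               settings: SolverSettings | None = None,
               mode: str = "hard") -> CostBreakdown:
    """One-shot assembly of the full cost at a parameter vector."""
    if isinstance(theta_ref, ParameterSet):
        theta_ref = theta_ref.free_vector()
    ev = ObjectiveEvaluator(record, weights, box=box, theta_ref=theta_ref,
                            settings=settings, mode=mode)
    return ev.evaluate_params(params)
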