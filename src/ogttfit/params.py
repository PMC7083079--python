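"""Physiological parameter vectors and the feasible box they live in.

The model has 13 free parameters.  Basal glycemia ``G_b``, basal insulinemia
``I_b`` and the ingested bolus ``D`` are measured / protocol inputs, not fitted
quantities: the basal hepatic production rate is eliminated through the basal
steady-state condition, which is what fixes the free-parameter count at 13.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Names of the 13 free (fitted) parameters, in canonical vector order.
FREE_PARAM_NAMES: tuple[str, ...] = (
    "k_js",      # gastric emptying rate (1/min)
    "k_gj",      # jejunal absorption rate (1/min)
    "k_jl",      # jejunum-to-ileum delivery rate (1/min)
    "k_gl",      # ileal absorption rate (1/min)
    "tau",       # jejunum-to-ileum transit delay (min)
    "k_xg",      # insulin-independent glucose uptake rate (1/min)
    "k_xgi",     # insulin-sensitive uptake rate == insulin sensitivity S_I
    "eta",       # bioavailability/distribution conversion (1/dL)
    "k_lambda",  # hepatic production saturation constant (mg*mg/dL/min)
    "k_xi",      # insulin degradation rate (1/min)
    "beta",      # half-saturation of pancreatic secretion (dimensionless)
    "gamma",     # Hill exponent of pancreatic secretion (dimensionless)
    "f_gj",      # incretin conversion factor (min/dL, so G~ is in mg/dL)
)

N_FREE_PARAMS = len(FREE_PARAM_NAMES)


class ParameterError(ValueError):
    """Raised when a parameter set violates its physiological invariants."""


@dataclass(frozen=True)
class ParameterSet:
    """One patient's full physiological parameter vector.

    All rate constants are first-order kinetic constants in 1/min.  ``tau``
    is the intestinal transit delay in minutes.  ``k_xgi`` doubles as the
    insulin sensitivity index S_I in 1/(min*uU/mL).
    """

    k_js: float
    k_gj: float
    k_jl: float
    k_gl: float
    tau: float
    k_xg: float
    k_xgi: float
    eta: float
    k_lambda: float
    k_xi: float
    beta: float
    gamma: float
    f_gj: float
    G_b: float = 90.0     # basal glycemia (mg/dL)
    I_b: float = 8.0      # basal insulinemia (uU/mL)
    D: float = 75000.0    # ingested glucose bolus (mg); 75-g OGTT protocol

    def __post_init__(self) -> None:
        strictly_positive = (
            "k_js", "k_gj", "k_jl", "k_gl", "k_xg", "eta", "k_lambda",
            "k_xi", "beta", "gamma", "f_gj", "G_b", "I_b",
        )
        for name in strictly_positive:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be finite and > 0, got {v!r}")
        # D = 0 is admitted so the unperturbed (no-bolus) steady state can be
        # simulated directly
        for name in ("tau", "D"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and >= 0, got {v!r}")
        if not np.isfinite(self.k_xgi) or self.k_xgi < 0:
            raise ParameterError(f"k_xgi must be finite and >= 0, got {self.k_xgi!r}")

    # -- derived quantities (never stored) ---------------------------------

    @property
    def basal_hepatic_production(self) -> float:
        """Basal hepatic glucose production Gprod0 = (k_xg + k_xgi*I_b)*G_b.

        This is the unique value for which the basal state (empty gut,
        G = G_b, I = I_b) is an equilibrium of the glycemia equation.
        """
        return (self.k_xg + self.k_xgi * self.I_b) * self.G_b

    @property
    def k2(self) -> float:
        """Monod-form half-saturation constant, k_2 = k_lambda/Gprod0 - G_b."""
        return self.k_lambda / self.basal_hepatic_production - self.G_b

    @property
    def insulin_sensitivity(self) -> float:
        """Bergman insulin sensitivity S_I; identically k_xgi in this model."""
        return self.k_xgi

    # -- vector conversions -------------------------------------------------

    def free_vector(self) -> np.ndarray:
        """The 13 free parameters as a float array in canonical order."""
        return np.array([getattr(self, n) for n in FREE_PARAM_NAMES], dtype=float)

    @classmethod
    def from_free_vector(
        cls, vec: Iterable[float], G_b: float, I_b: float, D: float = 75000.0
    ) -> "ParameterSet":
        vec = np.asarray(list(vec), dtype=float)
        if vec.shape != (N_FREE_PARAMS,):
            raise ParameterError(
                f"free vector must have {N_FREE_PARAMS} entries, got {vec.shape}"
            )
        kw = dict(zip(FREE_PARAM_NAMES, vec.tolist()))
        return cls(G_b=float(G_b), I_b=float(I_b), D=float(D), **kw)

    def replace(self, **kw) -> "ParameterSet":
        return replace(self, **kw)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ParameterSet":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_series(self) -> pd.Series:
        return pd.Series(self.to_dict(), name="value")

    def write_csv(self, path) -> None:
        """Flat key-value delimited table (columns: parameter, value)."""
        df = self.to_series().rename_axis("parameter").reset_index()
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ParameterSet":
        df = pd.read_csv(path)
        return cls.from_dict(dict(zip(df["parameter"], df["value"])))

    def write_yaml(self, path) -> None:
        """Hierarchical config form: free parameters under ``parameters``,
        measured anchors under ``basal``, the bolus under ``protocol``."""
        import yaml

        doc = {
            "parameters": {n: float(getattr(self, n)) for n in FREE_PARAM_NAMES},
            "basal": {"G_b": float(self.G_b), "I_b": float(self.I_b)},
            "protocol": {"D": float(self.D)},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def read_yaml(cls, path) -> "ParameterSet":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        flat = dict(doc.get("parameters", {}))
        flat.update(doc.get("basal", {}))
        flat.update(doc.get("protocol", {}))
        return cls.from_dict(flat)


@dataclass(frozen=True)
class FeasibleBox:
    """Cartesian product of per-parameter plausibility intervals (F0).

    The default bounds are physiology-based implementation choices and
    ship as editable config; see docs/methods.md for the reasoning.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != (N_FREE_PARAMS,) or hi.shape != (N_FREE_PARAMS,):
            raise ParameterError("box bounds must have one interval per free parameter")
        if np.any(lo >= hi):
            raise ParameterError("box requires lower < upper for every parameter")
        tau_idx = FREE_PARAM_NAMES.index("tau")
        non_tau = np.ones(N_FREE_PARAMS, bool)
        non_tau[tau_idx] = False
        if np.any(lo[non_tau] <= 0) or lo[tau_idx] < 0:
            raise ParameterError("lower bounds must be > 0 (tau may be 0)")

    def interval(self, name: str) -> tuple[float, float]:
        i = FREE_PARAM_NAMES.index(name)
        return float(self.lower[i]), float(self.upper[i])

    def contains(self, vec: np.ndarray, atol: float = 0.0) -> bool:
        vec = np.asarray(vec, dtype=float)
        return bool(
            np.all(vec >= self.lower - atol) and np.all(vec <= self.upper + atol)
        )

    def clip(self, vec: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(vec, dtype=float), self.lower, self.upper)

    def normalize(self, vec: np.ndarray) -> np.ndarray:
        """Map a parameter vector to the unit cube (min-max normalization)."""
        return (np.asarray(vec, dtype=float) - self.lower) / (self.upper - self.lower)

    def denormalize(self, unit: np.ndarray) -> np.ndarray:
        return self.lower + np.asarray(unit, dtype=float) * (self.upper - self.lower)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """``n`` independent uniform draws from the box, shape (n, 13)."""
        if n < 1:
            raise ParameterError("need n >= 1 samples")
        u = rng.random((n, N_FREE_PARAMS))
        return self.lower + u * (self.upper - self.lower)

    def with_intervals(self, **intervals: tuple[float, float]) -> "FeasibleBox":
        """A copy with some per-parameter intervals overridden."""
        lo, hi = self.lower.copy(), self.upper.copy()
        for name, (a, b) in intervals.items():
            i = FREE_PARAM_NAMES.index(name)
            lo[i], hi[i] = a, b
        return FeasibleBox(lo, hi)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": FREE_PARAM_NAMES, "lower": self.lower, "upper": self.upper}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "FeasibleBox":
        df = pd.read_csv(path).set_index("parameter")
        lo = [df.loc[n, "lower"] for n in FREE_PARAM_NAMES]
        hi = [df.loc[n, "upper"] for n in FREE_PARAM_NAMES]
        return cls(np.array(lo), np.array(hi))


#: Physiology-motivated default intervals (NOT derived from any published
#: bounds table).  Rates span gastric/intestinal/metabolic half-lives from
#: minutes to hours; eta ~ bioavailability / glucose distribution volume;
#: k_lambda's floor keeps the hepatic production law valid for moderate
#: hypoglycemic dips below basal.
_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k_js": (0.005, 0.10),
    "k_gj": (0.005, 0.10),
    "k_jl": (0.005, 0.10),
    "k_gl": (0.005, 0.10),
    "tau": (0.0, 120.0),
    "k_xg": (1e-4, 0.05),
    "k_xgi": (1e-5, 5e-3),
    "eta": (2e-3, 2e-2),
    "k_lambda": (20.0, 500.0),
    "k_xi": (0.005, 0.10),
    "beta": (0.1, 10.0),
    "gamma": (1.0, 8.0),
    "f_gj": (1e-3, 0.2),
}


def default_box() -> FeasibleBox:
    """The default feasible box F0 over the 13 free parameters."""
    lo = np.array([_DEFAULT_BOUNDS[n][0] for n in FREE_PARAM_NAMES])
    hi = np.array([_DEFAULT_BOUNDS[n][1] for n in FREE_PARAM_NAMES])
    return FeasibleBox(lo, hi)


def default_parameters(G_b: float = 90.0, I_b: float = 8.0) -> ParameterSet:
    """A mid-range normoglycemic parameter set used in examples and tests."""
    return ParameterSet(
        k_js=0.05, k_gj=0.04, k_jl=0.012, k_gl=0.025, tau=30.0,
        k_xg=0.008, k_xgi=1e-3, eta=5e-3, k_lambda=120.0,
        k_xi=0.06, beta=1.8, gamma=3.5, f_gj=0.04,
        G_b=G_b, I_b=I_b,
    )
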