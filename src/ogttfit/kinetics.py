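"""Right-hand sides and closed forms of the glucose-insulin OGTT model.

Five state variables: glucose mass in the stomach ``S`` (mg), jejunum ``J``
(mg) and ileum ``L`` (mg), glycemia ``G`` (mg/dL) and insulinemia ``I``
(uU/mL).  The gastric chain (S, J) is linear and decoupled from the blood
compartments, so it has exact closed forms; the ileum receives jejunal
glucose delayed by the transit time ``tau``, which makes the full system a
delay differential system whose delayed forcing is nevertheless explicitly
computable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet

#: switch to the analytic limit of the jejunum solution when the two
#: exponential rates collide (|k_js - (k_gj + k_jl)| below this, 1/min)
_DEGENERATE_RATE_TOL = 1e-10


class ModelValidityError(ValueError):
    """The model left its physiological domain (e.g. hepatic law breakdown)."""


@dataclass(frozen=True)
class ModelState:
    """One point of the five-variable state space."""

    S: float
    J: float
    L: float
    G: float
    I: float

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.J, self.L, self.G, self.I], dtype=float)


def gastric_chain_closed_form(params: ParameterSet, t):
    """Exact (S(t), J(t)) of the stomach-jejunum chain.

    S decays exponentially from the bolus D; J obeys
    dJ/dt = k_js*S - (k_gj + k_jl)*J with J(0) = 0.  The degenerate case
    k_js == k_gj + k_jl uses the analytic limit D*k_js*t*exp(-k_js*t).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    a = params.k_gj + params.k_jl
    kjs = params.k_js
    S = params.D * np.exp(-kjs * t)
    if abs(a - kjs) < _DEGENERATE_RATE_TOL:
        J = params.D * kjs * t * np.exp(-kjs * t)
    else:
        J = params.D * kjs * (np.exp(-kjs * t) - np.exp(-a * t)) / (a - kjs)
    if t.ndim == 0:
        return float(S), float(J)
    return S, J


def delayed_jejunal_forcing(params: ParameterSet, t):
    """k_jl * phi(t) with phi(t) = 0 for t < tau and J(t - tau) afterwards."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    shifted = np.maximum(t - params.tau, 0.0)
    _, J = gastric_chain_closed_form(params, shifted)
    out = np.where(t >= params.tau, params.k_jl * np.asarray(J), 0.0)
    if t.ndim == 0:
        return float(out)
    return out


def derive_basal_production(params: ParameterSet) -> float:
    """Basal hepatic production Gprod0 = (k_xg + k_xgi*I_b)*G_b.

    Imposing that the basal state with empty gut is a steady state of the
    glycemia equation eliminates Gprod0 as a free parameter.
    """
    return params.basal_hepatic_production


def hepatic_production(params: ParameterSet, G):
    """Saturable hepatic glucose production Gprod(G).

    Michaelis-Menten-like decreasing law
    ``Gprod = k_lambda / (k_lambda/Gprod0 + (G - G_b))``, anchored so that
    Gprod(G_b) = Gprod0.  Equivalent to the Monod complement form
    ``k_lambda / (k_2 + G)`` with ``k_2 = k_lambda/Gprod0 - G_b``.
    """
    G = np.asarray(G, dtype=float)
    gprod0 = params.basal_hepatic_production
    den = params.k_lambda / gprod0 + (G - params.G_b)
    if np.any(den <= 0):
        raise ModelValidityError(
            "hepatic production law invalid: k_lambda/Gprod0 + (G - G_b) <= 0 "
            f"(G={G!r}, G_b={params.G_b}, k_lambda={params.k_lambda})"
        )
    out = params.k_lambda / den
    if G.ndim == 0:
        return float(out)
    return out


def apparent_glycemia(params: ParameterSet, G, J, L):
    """Incretin-enhanced apparent glycemia G~ = G + f_gj*(k_gj*J + k_gl*L).

    Pancreatic beta cells sense the intestinal *absorption rate*, not the
    luminal content, so the correction is proportional to the absorption
    fluxes.
    """
    G = np.asarray(G, dtype=float)
    out = G + params.f_gj * (params.k_gj * np.asarray(J) + params.k_gl * np.asarray(L))
    if G.ndim == 0:
        return float(out)
    return out


def secretion_fraction(params: ParameterSet, G_tilde):
    """Hill secretion factor sigma = (beta^gamma + 1)/(beta^gamma*(G_b/G~)^gamma + 1).

    Evaluated in log space so large gamma with small G~ cannot overflow.
    Equals 1 exactly at G~ = G_b, tends to beta^gamma + 1 as G~ -> inf and
    to 0 as G~ -> 0+.
    """
    G_tilde = np.asarray(G_tilde, dtype=float)
    if np.any(G_tilde <= 0):
        raise ModelValidityError("apparent glycemia must be positive")
    b = params.gamma * np.log(params.beta)
    x = params.gamma * (np.log(params.G_b) - np.log(G_tilde))
    log_num = np.logaddexp(b, 0.0)
    log_den = np.logaddexp(b + x, 0.0)
    out = np.exp(log_num - log_den)
    if G_tilde.ndim == 0:
        return float(out)
    return out


def model_rhs(params: ParameterSet, t: float, state: ModelState) -> np.ndarray:
    """Time derivatives (dS, dJ, dL, dG, dI) of the five-variable system.

    The delayed ileal forcing phi(t) = J(t - tau) is evaluated through the
    gastric closed form (exact, since S and J are decoupled from the blood
    compartments).  At the basal point (0, 0, 0, G_b, I_b) the derivative
    is the zero vector.
    """
    arr = state.as_array()
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite state components")
    if state.G <= 0 or state.I <= 0:
        raise ModelValidityError("G and I must be positive")
    p = params
    dS = -p.k_js * state.S
    dJ = p.k_js * state.S - (p.k_gj + p.k_jl) * state.J
    dL = delayed_jejunal_forcing(p, t) - p.k_gl * state.L
    gprod = hepatic_production(p, state.G)
    absorption = p.k_gj * state.J + p.k_gl * state.L
    dG = -(p.k_xg + p.k_xgi * state.I) * state.G + gprod + p.eta * absorption
    g_tilde = apparent_glycemia(p, state.G, state.J, state.L)
    sigma = secretion_fraction(p, g_tilde)
    dI = p.k_xi * p.I_b * (sigma - state.I / p.I_b)
    return np.array([dS, dJ, dL, dG, dI])


def insulin_sensitivity(params: ParameterSet) -> float:
    """Bergman insulin sensitivity S_I = dE/dI, E = -d(dG/dt)/dG.

    For this model E = k_xg + k_xgi*I - dGprod/dG; the hepatic term does not
    depend on I, so S_I reduces exactly to k_xgi.
    """
    return params.k_xgi
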