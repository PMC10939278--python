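"""Lyapunov, positivity and uniqueness diagnostics for the TCD-IL2-Z model.

These are runtime diagnostics, not proofs: the Lyapunov Sigma/Omega split and
the Mittag-Leffler positivity envelopes are evaluated numerically at given
states and trajectory sup-norms, and the combined growth-bound condition is
reported as a plain number with a verdict.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .model import Parameters, State
from .solver import FFMOrders, Trajectory, ab_normalization

__all__ = [
    "StabilityReport",
    "NormBundle",
    "PositivityReport",
    "lyapunov_terms",
    "mittag_leffler",
    "positivity_envelope",
    "uniqueness_condition",
    "positivity_monitor",
]

#: floating-point dust threshold for trajectory negativity
NEGATIVITY_THRESHOLD = -1e-9


@dataclass(frozen=True)
class StabilityReport:
    """Lyapunov value and its gain/loss decomposition at one state.

    ``dL = Sigma - Omega`` is the Lyapunov derivative along the flow;
    ``Sigma < Omega`` at a state indicates (by LaSalle's invariance argument)
    decay of the Lyapunov function there.
    """

    L: float
    Sigma: float
    Omega: float
    dL: float
    globally_stable_indicator: bool


@dataclass(frozen=True)
class NormBundle:
    """Supremum of each compartment over a trajectory window."""

    sup_T: float
    sup_C: float
    sup_D: float
    sup_IL2: float
    sup_Z: float

    def __post_init__(self) -> None:
        for name in ("sup_T", "sup_C", "sup_D", "sup_IL2", "sup_Z"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def from_trajectory(cls, traj: Trajectory) -> "NormBundle":
        sups = np.max(np.abs(traj.states), axis=0)
        return cls(*(float(s) for s in sups))


def _relative_entropy_term(x: float, xs: float) -> float:
    # x - x* - x* log(x/x*): nonnegative by convexity, zero iff x = x*
    return x - xs - xs * math.log(x / xs)


def lyapunov_terms(state: State, equilibrium: State,
                   params: Parameters) -> StabilityReport:
    """Volterra-type Lyapunov function and its printed Sigma/Omega split.

    L = sum_x (x - x* - x* log(x/x*)) over the five compartments; the
    derivative along the flow is grouped into a gain aggregate Sigma and a
    loss aggregate Omega exactly as published (the grouping carries no terms
    from the Z equation).  Both the state and the equilibrium must be
    strictly positive: the function is undefined on the boundary and no
    regularization is applied.
    """
    if not (state.strictly_positive() and equilibrium.strictly_positive()):
        raise ValueError("Lyapunov terms require strictly positive state and equilibrium")
    p = params
    T, C, D, IL2, Z = state.as_array()
    Ts, Cs, Ds, Is, Zs = equilibrium.as_array()

    L = sum(_relative_entropy_term(x, xs)
            for x, xs in zip((T, C, D, IL2, Z), (Ts, Cs, Ds, Is, Zs)))

    dT, dC, dD = T - Ts, C - Cs, D - Ds
    Sigma = (p.alpha * dT ** 2 / T
             + p.phi * Cs * dT ** 2 / T
             + p.phi * T * dC ** 2 / C
             + p.rho * D * dC ** 2 / C
             + p.mu
             + p.rho * Cs * dD ** 2 / D
             + p.lambda_il2 * D
             + p.lambda_il2 * Ds * Is / IL2)
    Omega = (p.alpha * p.beta * dT ** 3 / T
             + p.gamma * dT ** 2 / T
             + p.phi * C * dT ** 2 / T
             + p.phi * Ts * dC ** 2 / C
             + p.rho * Ds * dC ** 2 / C
             + p.kappa * dC ** 2 / C
             + p.mu * Ds / D
             + p.rho * C * dD ** 2 / D
             + p.omega * dD ** 2 / D
             + p.lambda_il2 * dD ** 2 / D
             + p.lambda_il2 * D * Is / IL2
             + p.lambda_il2 * Ds
             + p.d * (IL2 - Is) ** 2 / IL2)
    dL = Sigma - Omega
    return StabilityReport(L=float(L), Sigma=float(Sigma), Omega=float(Omega),
                           dL=float(dL), globally_stable_indicator=bool(Sigma < Omega))


_ML_MAX_TERMS = 2000
#: largest tolerated ratio of the biggest series term to the result
_ML_CANCEL_LIMIT = 1e4


def _ml_series(xi: float, z: float) -> float:
    """Truncated power series with terms evaluated in log space."""
    log_absz = math.log(abs(z))
    sign = 1.0 if z > 0 else -1.0
    total = 1.0
    term_scale = 1.0
    for k in range(1, _ML_MAX_TERMS):
        term = (sign ** k) * math.exp(k * log_absz - gammaln(xi * k + 1.0))
        total += term
        term_scale = max(term_scale, abs(term))
        if abs(term) < 1e-18 * max(1.0, abs(total)) and k > 4:
            break
    else:
        raise ValueError(f"series for E_{xi}({z}) did not converge")
    if term_scale > 1e12 * max(1.0, abs(total)):
        raise ValueError(
            f"series for E_{xi}({z}) is numerically unstable (cancellation)"
        )
    return float(total)


def _ml_series_cancellation(xi: float, z: float) -> float:
    """Largest log-magnitude a series term reaches (cancellation scale)."""
    log_absz = math.log(abs(z))
    worst = 0.0
    for k in range(1, _ML_MAX_TERMS):
        lt = k * log_absz - gammaln(xi * k + 1.0)
        if lt < worst - 5.0:
            break
        worst = max(worst, lt)
    return worst


def _ml_spectral(xi: float, x: float) -> float:
    """E_xi(-x) for x > 0, 0 < xi < 1, via the spectral (Titchmarsh) integral.

    E_xi(-t**xi) = int_0^inf exp(-r t) K(r) dr with a completely monotone
    density; the substitution u = r**xi makes the integrand smooth:

        E_xi(-x) = sin(pi xi)/(pi xi)
                   * int_0^inf exp(-u**(1/xi) * x**(1/xi)) / (u^2 + 2 u cos(pi xi) + 1) du
    """
    from scipy.integrate import quad

    t = x ** (1.0 / xi)
    c = math.cos(math.pi * xi)
    pref = math.sin(math.pi * xi) / (math.pi * xi)
    val, _ = quad(
        lambda u: math.exp(-(u ** (1.0 / xi)) * t) / (u * u + 2.0 * c * u + 1.0),
        0.0, np.inf, limit=200, epsabs=1e-13, epsrel=1e-12,
    )
    return pref * val


def mittag_leffler(xi: float, z: float) -> float:
    """One-parameter Mittag-Leffler function E_xi(z) = sum z**k / Gamma(xi*k + 1).

    Valid for 0 < xi <= 2 and finite real z (negative arguments are the
    primary use here).  Evaluation branches:

    * xi = 1: the exponential identity E_1(z) = exp(z);
    * truncated series with adaptive term count wherever the alternating-sum
      cancellation stays below 1e4 in term/result ratio (absolute accuracy
      target 1e-10 there);
    * the completely monotone spectral integral for z < 0 with xi < 1, which
      covers arbitrarily large negative arguments.

    Combinations outside these branches (e.g. very large positive z with
    small xi, where the result itself overflows) raise ``ValueError``.
    """
    if not (0.0 < xi <= 2.0):
        raise ValueError(f"xi must lie in (0, 2], got {xi}")
    if not math.isfinite(z):
        raise ValueError("z must be finite")
    z = float(z)
    if xi == 1.0:
        return math.exp(z)
    if z == 0.0:
        return 1.0
    if z > 0 or xi > 1.0:
        return _ml_series(xi, z)
    # z < 0, 0 < xi < 1: series while well conditioned, else spectral integral
    if _ml_series_cancellation(xi, z) < math.log(_ML_CANCEL_LIMIT):
        return _ml_series(xi, z)
    return _ml_spectral(xi, -z)


_ENVELOPE_RATES = {
    "T": lambda p, n: p.alpha * p.beta * n.sup_T + p.gamma + p.phi * n.sup_C,
    "C": lambda p, n: p.kappa - p.phi * n.sup_T - p.rho * n.sup_D,
    "D": lambda p, n: p.rho * n.sup_C + p.omega + p.lambda_il2,
    "IL2": lambda p, n: p.d,
    "Z": lambda p, n: p.a,
}


def positivity_envelope(compartment: str, t: float, init_value: float,
                        params: Parameters, orders: FFMOrders,
                        norms: NormBundle, b: float = 1.0) -> float:
    """Mittag-Leffler lower envelope X(0) * E_xi(-b**(1-lambda_f) xi r t**xi / den).

    ``r`` is the compartment's linear decay aggregate assembled from the
    trajectory sup-norms (for C it can be negative, in which case the
    envelope exceeds the initial value and is still a valid lower-bound
    statement), and ``den = AB(xi) - (1 - xi) r``.  ``b`` is a free positive
    time-scale of the bound.  At xi = lambda_f = 1 the IL2 and Z envelopes
    are the exact exponential solutions of their linear decay bounds.

    Returns NaN (with a warning) when the denominator is nonpositive and the
    bound is undefined.  Diagnostic only.
    """
    if compartment not in _ENVELOPE_RATES:
        raise ValueError(f"unknown compartment {compartment!r}")
    if b <= 0:
        raise ValueError("the time element b must be positive")
    if t < 0:
        raise ValueError("t must be nonnegative")
    xi, lf = orders.xi, orders.lambda_f
    r = _ENVELOPE_RATES[compartment](params, norms)
    den = ab_normalization(xi) - (1.0 - xi) * r
    if den <= 0:
        warnings.warn(
            f"positivity envelope for {compartment} undefined: "
            f"AB(xi) - (1-xi)r = {den:g} <= 0",
            RuntimeWarning, stacklevel=2,
        )
        return math.nan
    arg = -(b ** (1.0 - lf)) * xi * r * t ** xi / den
    return init_value * mittag_leffler(xi, arg)


def uniqueness_condition(norms: NormBundle, params: Parameters) -> tuple[float, bool]:
    """Combined growth-bound condition for solution uniqueness.

    Evaluates the five per-compartment growth-bound ratios

        T:   3 (alpha^2 beta^2 ||T||^2 + gamma^2 + phi^2 ||C||^2) / (alpha^2 ||T||^2)
        C:   2 (phi^2 ||T||^2 + rho^2 ||D||^2) / (kappa^2 ||C||^2)
        D:   3 (rho^2 ||C||^2 + omega^2 + lambda_il2^2) / mu^2
        IL2: d^2 / (lambda_il2^2 ||D||^2)
        Z:   a^2 / (d^2 ||IL2||^2)

    and returns (max ratio, max ratio < 1).  Each ratio is the bracketed
    growth bound divided by the leading coefficient factored out of the
    corresponding linear-growth constant.
    """
    p, n = params, norms
    denoms = {
        "T": p.alpha ** 2 * n.sup_T ** 2,
        "C": p.kappa ** 2 * n.sup_C ** 2,
        "D": p.mu ** 2,
        "IL2": p.lambda_il2 ** 2 * n.sup_D ** 2,
        "Z": p.d ** 2 * n.sup_IL2 ** 2,
    }
    for name, val in denoms.items():
        if val == 0:
            raise ValueError(f"uniqueness condition: zero denominator in the {name} ratio")
    ratios = (
        3.0 * (p.alpha ** 2 * p.beta ** 2 * n.sup_T ** 2 + p.gamma ** 2
               + p.phi ** 2 * n.sup_C ** 2) / denoms["T"],
        2.0 * (p.phi ** 2 * n.sup_T ** 2 + p.rho ** 2 * n.sup_D ** 2) / denoms["C"],
        3.0 * (p.rho ** 2 * n.sup_C ** 2 + p.omega ** 2 + p.lambda_il2 ** 2) / denoms["D"],
        p.d ** 2 / denoms["IL2"],
        p.a ** 2 / denoms["Z"],
    )
    value = float(max(ratios))
    return value, value < 1.0


@dataclass(frozen=True)
class PositivityReport:
    """Per-compartment minimum values and first negativity crossings."""

    min_values: dict[str, float]
    min_times: dict[str, float]
    crossings: dict[str, float | None]   # first time below the dust threshold

    @property
    def all_positive(self) -> bool:
        return all(v is None for v in self.crossings.values())


def positivity_monitor(traj: Trajectory) -> PositivityReport:
    """Scan a trajectory for negativity beyond floating-point dust.

    Reports each compartment's minimum, the time it is attained, and the
    first time (if any) the value drops below -1e-9.  Crossings are reported,
    never raised: scheme-induced negativity is a diagnostic, not an error.
    """
    names = ("T", "C", "D", "IL2", "Z")
    mins, tmins, crossings = {}, {}, {}
    for j, name in enumerate(names):
        col = traj.states[:, j]
        k = int(np.argmin(col))
        mins[name] = float(col[k])
        tmins[name] = float(traj.times[k])
        below = np.nonzero(col < NEGATIVITY_THRESHOLD)[0]
        crossings[name] = float(traj.times[below[0]]) if below.size else None
    return PositivityReport(min_values=mins, min_times=tmins, crossings=crossings)
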