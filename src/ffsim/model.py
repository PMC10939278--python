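"""Vector field, equilibria and reproductive number of the TCD-IL2-Z model.

The model couples five compartments: tumor cells ``T`` growing logistically
and killed by dendritic and CD8+ T cells, CD8+ T cells ``C`` stimulated by
tumor and dendritic contact, dendritic cells ``D`` with a constant source,
the cytokine ``IL2`` sourced from dendritic cells, and an anti-PD-L1
inhibitor ``Z`` produced from IL-2::

    dT/dt   = alpha*T*(1 - beta*T) - gamma*T - phi*C*T
    dC/dt   = phi*C*T + rho*C*D - kappa*C
    dD/dt   = mu - rho*C*D - omega*D - lambda_il2*D
    dIL2/dt = lambda_il2*D - d*IL2
    dZ/dt   = d*IL2 - a*Z

All rates are per arbitrary time unit; the bundled study parameter set is
unitless.  The IL-2 source rate is stored as ``lambda_il2`` to keep it
distinct from the fractal dimension ``lambda_f`` of the integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Parameters",
    "State",
    "EndemicResult",
    "study_parameters",
    "study_initial_state",
    "load_parameters",
    "save_parameters",
    "rhs",
    "rhs_array",
    "reproduction_number",
    "disease_free_equilibrium",
    "endemic_equilibrium",
    "endemic_equilibrium_printed",
    "equilibrium_residual",
]

PARAM_KEYS = (
    "alpha", "beta", "gamma", "phi", "kappa", "mu",
    "rho", "omega", "lambda_il2", "d", "a",
)

STATE_KEYS = ("T", "C", "D", "IL2", "Z")


@dataclass(frozen=True)
class Parameters:
    """The eleven nonnegative rate constants of the model.

    alpha
        Tumor intrinsic growth rate (1/time).
    beta
        Logistic crowding coefficient (1/cells).
    gamma
        Dendritic-mediated tumor kill rate (1/time).
    phi
        CD8-mediated tumor kill coefficient (1/(cells*time)).
    kappa
        CD8 natural death rate (1/time).
    mu
        Dendritic cell source (cells/time).
    rho
        Dendritic inactivation coefficient by CD8 cells (1/(cells*time)).
    omega
        Dendritic natural death rate (1/time).
    lambda_il2
        IL-2 sourcing rate from dendritic cells (1/time).
    d
        Anti-PD-L1 production rate from IL-2 (1/time).
    a
        Anti-PD-L1 natural death rate (1/time).
    """

    alpha: float
    beta: float
    gamma: float
    phi: float
    kappa: float
    mu: float
    rho: float
    omega: float
    lambda_il2: float
    d: float
    a: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name!r} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name!r} must be nonnegative, got {v!r}")

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in PARAM_KEYS}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_KEYS], dtype=float)

    @classmethod
    def from_dict(cls, mapping: dict) -> "Parameters":
        missing = set(PARAM_KEYS) - set(mapping)
        if missing:
            raise ValueError(f"missing parameter keys: {sorted(missing)}")
        extra = set(mapping) - set(PARAM_KEYS)
        if extra:
            raise ValueError(f"unknown parameter keys: {sorted(extra)}")
        return cls(**{k: float(mapping[k]) for k in PARAM_KEYS})


@dataclass(frozen=True)
class State:
    """One point in compartment space (T, C, D, IL2, Z)."""

    T: float
    C: float
    D: float
    IL2: float
    Z: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if not math.isfinite(getattr(self, f.name)):
                raise ValueError(f"state component {f.name!r} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.T, self.C, self.D, self.IL2, self.Z], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "State":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (5,):
            raise ValueError(f"state array must have shape (5,), got {arr.shape}")
        return cls(*(float(x) for x in arr))

    def strictly_positive(self) -> bool:
        return all(getattr(self, k) > 0 for k in STATE_KEYS)


def study_parameters() -> Parameters:
    """The bundled study parameter set (``data/params_paper.yaml``)."""
    with resources.files("ffsim").joinpath("data/params_paper.yaml").open() as fh:
        return Parameters.from_dict(yaml.safe_load(fh))


def study_initial_state() -> State:
    """The study initial condition: T=1.0, C=0.8, D=0.3, IL2=0.4, Z=0.3."""
    return State(T=1.0, C=0.8, D=0.3, IL2=0.4, Z=0.3)


def load_parameters(path: str | Path) -> Parameters:
    """Read a parameter set from a flat YAML/JSON key-value file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    return Parameters.from_dict(data)


def save_parameters(params: Parameters, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(params.as_dict(), fh, sort_keys=False)
    return path


def rhs_array(y, params: Parameters) -> np.ndarray:
    """Time derivatives at a raw 5-vector ``y = (T, C, D, IL2, Z)``.

    Fast path used by the integrators; see :func:`rhs` for the validated
    dataclass interface.
    """
    T, C, D, IL2, Z = y
    p = params
    return np.array([
        p.alpha * T * (1.0 - p.beta * T) - p.gamma * T - p.phi * C * T,
        p.phi * C * T + p.rho * C * D - p.kappa * C,
        p.mu - p.rho * C * D - p.omega * D - p.lambda_il2 * D,
        p.lambda_il2 * D - p.d * IL2,
        p.d * IL2 - p.a * Z,
    ])


def rhs(state: State, params: Parameters) -> np.ndarray:
    """The model vector field evaluated at ``state``.

    Returns the 5-vector of time derivatives (dT, dC, dD, dIL2, dZ).
    """
    if not isinstance(state, State):
        state = State.from_array(state)
    return rhs_array(state.as_array(), params)


def reproduction_number(params: Parameters) -> float:
    """Next-generation reproductive number R0 = mu*rho / (kappa*(lambda_il2+omega)).

    R0 is computed exactly as derived for this model.  Note that tumor
    growth in the T equation is governed by alpha versus gamma, not by R0,
    so R0 < 1 alone does not imply tumor extinction.
    """
    denom = params.kappa * (params.lambda_il2 + params.omega)
    if denom <= 0:
        raise ValueError("reproduction number requires kappa > 0 and lambda_il2 + omega > 0")
    return params.mu * params.rho / denom


def disease_free_equilibrium(params: Parameters) -> State:
    """Closed-form tumor-free steady state.

    D1 = (0, 0, mu/(lambda_il2+omega), lambda_il2*mu/(d*(lambda_il2+omega)),
    lambda_il2*mu/(a*(lambda_il2+omega))).  The result satisfies rhs = 0.
    """
    s = params.lambda_il2 + params.omega
    if s <= 0 or params.d <= 0 or params.a <= 0:
        raise ValueError(
            "disease-free equilibrium requires lambda_il2 + omega > 0, d > 0, a > 0"
        )
    Dstar = params.mu / s
    return State(
        T=0.0,
        C=0.0,
        D=Dstar,
        IL2=params.lambda_il2 * Dstar / params.d,
        Z=params.lambda_il2 * Dstar / params.a,
    )


def equilibrium_residual(state: State, params: Parameters) -> float:
    """Maximum absolute component of the vector field at ``state``."""
    return float(np.max(np.abs(rhs(state, params))))


@dataclass(frozen=True)
class EndemicResult:
    """Interior (endemic) equilibrium with its feasibility audit.

    ``state``/``residual`` come from the exact quadratic reduction of the
    steady-state equations (the reliable branch).  ``printed_state`` holds
    the literal published radical closed forms, which carry sign defects in
    their T and C lines; ``printed_residual`` quantifies the discrepancy.
    ``feasible`` is False when no root gives a fully nonnegative state.
    """

    state: State | None
    feasible: bool
    residual: float | None
    branch: str | None
    printed_state: State | None
    printed_feasible: bool
    printed_residual: float | None

    @property
    def printed_agrees(self) -> bool:
        """Whether the published closed forms pass the residual audit."""
        if not (self.feasible and self.printed_feasible):
            return False
        scale = max(1.0, float(np.max(np.abs(self.state.as_array()))))
        return self.printed_residual <= 1e-6 * scale


def _endemic_from_T(T: float, params: Parameters) -> np.ndarray:
    """Back-substitute the remaining four components given the tumor root."""
    p = params
    C = (p.alpha - p.gamma - p.alpha * p.beta * T) / p.phi
    D = (p.kappa - p.phi * T) / p.rho
    return np.array([T, C, D, p.lambda_il2 * D / p.d, p.lambda_il2 * D / p.a])


def _require_positive(params: Parameters, names: tuple[str, ...], what: str) -> None:
    for name in names:
        if getattr(params, name) <= 0:
            raise ValueError(f"{what} requires parameter {name!r} > 0")


def endemic_equilibrium(params: Parameters) -> EndemicResult:
    """Interior fixed point of the model, with a residual audit.

    The steady-state system reduces exactly to a quadratic in T:

        alpha*beta*rho*phi * T**2 - P * T
            + kappa*(alpha*rho - gamma*rho + phi*(omega+lambda_il2))
            - mu*rho*phi = 0,
        P = alpha*beta*kappa*rho + alpha*rho*phi - gamma*rho*phi
            + phi**2*(lambda_il2 + omega),

    with C, D, IL2, Z recovered by back-substitution.  Both roots are
    evaluated; the first root whose five components are all nonnegative is
    returned (preferring the smaller tumor burden).  The published radical
    closed forms are evaluated alongside and audited through the residual;
    they are never trusted as the primary answer.
    """
    p = params
    _require_positive(p, ("alpha", "beta", "rho", "phi", "d", "a"), "endemic equilibrium")
    P = (p.alpha * p.beta * p.kappa * p.rho + p.alpha * p.rho * p.phi
         - p.gamma * p.rho * p.phi + p.phi ** 2 * (p.lambda_il2 + p.omega))
    Q = P - 2.0 * p.alpha * p.beta * p.kappa * p.rho
    disc = Q * Q + 4.0 * p.alpha * p.beta * p.mu * p.rho ** 2 * p.phi ** 2
    root = math.sqrt(disc)
    denom = 2.0 * p.alpha * p.beta * p.rho * p.phi

    state = residual = branch = None
    feasible = False
    for sign, name in ((-1.0, "minus"), (1.0, "plus")):
        arr = _endemic_from_T((P + sign * root) / denom, p)
        if np.all(np.isfinite(arr)) and np.all(arr >= 0):
            state = State.from_array(arr)
            residual = equilibrium_residual(state, p)
            branch = name
            feasible = True
            break

    printed_state = printed_residual = None
    printed_feasible = False
    try:
        printed_state = endemic_equilibrium_printed(p)
    except ValueError:
        pass
    else:
        arr = printed_state.as_array()
        if np.all(np.isfinite(arr)) and np.all(arr >= 0):
            printed_feasible = True
            printed_residual = equilibrium_residual(printed_state, p)

    return EndemicResult(
        state=state, feasible=feasible, residual=residual, branch=branch,
        printed_state=printed_state, printed_feasible=printed_feasible,
        printed_residual=printed_residual,
    )


def endemic_equilibrium_printed(params: Parameters) -> State:
    """The endemic equilibrium exactly as the radical closed forms print it.

    The T and C lines print the radicand Q**2 - 4*alpha*beta*mu*rho**2*phi**2
    (T with +sqrt, C with -sqrt) while the D, IL2 and Z lines print
    Q**2 + 4*alpha*beta*mu*rho**2*phi**2 with +sqrt.  The D/IL2/Z lines agree
    with the exact reduction; the T/C lines do not (see
    :func:`endemic_equilibrium`, which audits this via the residual).

    Raises ``ValueError`` when the T/C radicand is negative (complex root).
    """
    p = params
    _require_positive(p, ("alpha", "beta", "rho", "phi", "d", "a"),
                      "printed endemic closed forms")
    Q = (p.alpha * p.rho * (p.phi - p.beta * p.kappa)
         + p.phi * (p.phi * (p.lambda_il2 + p.omega) - p.gamma * p.rho))
    four = 4.0 * p.alpha * p.beta * p.mu * p.rho ** 2 * p.phi ** 2
    rad_tc = Q * Q - four
    if rad_tc < 0:
        raise ValueError("printed T*/C* radicand is negative (complex root)")
    root_tc = math.sqrt(rad_tc)
    root_d = math.sqrt(Q * Q + four)

    num_t = (p.alpha * p.beta * p.kappa * p.rho + p.alpha * p.rho * p.phi
             - p.gamma * p.rho * p.phi + p.lambda_il2 * p.phi ** 2
             + p.phi ** 2 * p.omega)
    num_c = (-p.alpha * p.beta * p.kappa * p.rho - p.alpha * p.rho * p.phi
             + p.gamma * p.rho * p.phi + p.lambda_il2 * p.phi ** 2
             + p.phi ** 2 * p.omega)
    num_d = (p.alpha * p.beta * p.kappa * p.rho - p.alpha * p.rho * p.phi
             + p.gamma * p.rho * p.phi - p.lambda_il2 * p.phi ** 2
             - p.phi ** 2 * p.omega) + root_d

    return State(
        T=(num_t + root_tc) / (2.0 * p.alpha * p.beta * p.rho * p.phi),
        C=(num_c - root_tc) / (2.0 * p.rho * p.phi ** 2),
        D=num_d / (2.0 * p.alpha * p.beta * p.rho ** 2),
        IL2=p.lambda_il2 * num_d / (2.0 * p.d * p.alpha * p.beta * p.rho ** 2),
        Z=p.lambda_il2 * num_d / (2.0 * p.a * p.alpha * p.beta * p.rho ** 2),
    )
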