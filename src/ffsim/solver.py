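"""Fractal-fractional Mittag-Leffler integrator with Newton-polynomial weights.

The operator has two indices: a fractional order ``xi`` in (0, 1] (memory,
through the Mittag-Leffler kernel with normalization AB(xi) = 1 - xi +
xi/Gamma(xi)) and a fractal dimension ``lambda_f`` in (0, 1] (differentiation
with respect to t**lambda_f).  Inverting the operator turns the model into a
Volterra equation

    U(t) = U(0) + lambda_f*(1-xi)/AB(xi) * t**(lambda_f-1) * F(t, U(t))
         + xi*lambda_f/(AB(xi)*Gamma(xi))
           * int_0^t tau**(lambda_f-1) * F(tau, U) * (t-tau)**(xi-1) dtau,

which the scheme discretizes on a uniform grid by replacing the integrand on
each interval [t_nu, t_nu+1] with the quadratic Newton polynomial through the
three preceding nodes.  The resulting convolution weights have closed forms
(:func:`newton_weights`).  At xi = lambda_f = 1 the update collapses to the
classical third-order Adams-Bashforth quadrature of int F dtau.

Startup: the three-point sums are defined only from the third interval on.
Under the default ``reduced-order`` policy the first interval is covered by a
constant polynomial and the second by a linear one, in every step, so the
memory integral always spans [0, t_eta+1] with a consistent order build-up.
The ``repeated-first-node`` policy instead preserves the literal truncated
scheme (nodes 1 and 2 copy node 0; the first two intervals never enter the
sums) for comparison.

When lambda_f < 1 the fractal factor t**(lambda_f-1) diverges at the origin;
the node value at t_0 = 0 is assigned the limit convention 0 (the fractal
measure puts no discrete weight at the origin), logged once per run.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.special import gamma as _gamma

from .model import Parameters, State, rhs_array

__all__ = [
    "FFMOrders",
    "SolverConfig",
    "Trajectory",
    "IntegrationError",
    "ab_normalization",
    "newton_weights",
    "newton_weights_quadrature",
    "step",
    "simulate",
    "classical_reference",
    "fractional_quadrature_oracle",
]

logger = logging.getLogger(__name__)

STARTUP_POLICIES = ("reduced-order", "repeated-first-node")


class IntegrationError(RuntimeError):
    """Raised when a trajectory leaves the finite range mid-run."""


@dataclass(frozen=True)
class FFMOrders:
    """Operator indices: fractional order ``xi`` and fractal dimension ``lambda_f``."""

    xi: float = 1.0
    lambda_f: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.xi <= 1.0):
            raise ValueError(f"fractional order xi must lie in (0, 1], got {self.xi}")
        if not (0.0 < self.lambda_f <= 1.0):
            raise ValueError(
                f"fractal dimension lambda_f must lie in (0, 1], got {self.lambda_f}"
            )


@dataclass(frozen=True)
class SolverConfig:
    """Uniform time grid and startup policy for the multistep scheme."""

    dt: float = 0.01
    t_end: float = 50.0
    startup: str = "reduced-order"
    ic_term: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")
        if self.startup not in STARTUP_POLICIES:
            raise ValueError(f"startup must be one of {STARTUP_POLICIES}")
        if self.n_steps < 3:
            raise ValueError("the scheme needs at least three history nodes (t_end/dt >= 3)")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))

    def grid(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt


@dataclass
class Trajectory:
    """Time grid plus state sequence, with per-node rhs evaluations cached."""

    times: np.ndarray
    states: np.ndarray            # shape (N+1, 5)
    rhs_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2 or self.states.shape[1] != 5:
            raise ValueError("states must have shape (N+1, 5)")
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if len(self.times) > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-9, atol=0.0):
                raise ValueError("only uniform time grids are supported")
        if self.rhs_values is not None:
            self.rhs_values = np.asarray(self.rhs_values, dtype=float)
            if self.rhs_values.shape != self.states.shape:
                raise ValueError("rhs_values must match states in shape")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def state_at(self, index: int) -> State:
        return State.from_array(self.states[index])

    def final_state(self) -> State:
        return State.from_array(self.states[-1])

    def ensure_rhs(self, params: Parameters) -> np.ndarray:
        if self.rhs_values is None:
            self.rhs_values = np.array([rhs_array(y, params) for y in self.states])
        return self.rhs_values

    def truncated(self, n_nodes: int) -> "Trajectory":
        """The first ``n_nodes`` nodes as a new trajectory."""
        return Trajectory(
            self.times[:n_nodes].copy(),
            self.states[:n_nodes].copy(),
            None if self.rhs_values is None else self.rhs_values[:n_nodes].copy(),
        )

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.times).tobytes())
        h.update(np.ascontiguousarray(self.states).tobytes())
        return h.hexdigest()


def ab_normalization(xi: float) -> float:
    """Atangana-Baleanu normalization AB(xi) = 1 - xi + xi/Gamma(xi).

    Continuous on (0, 1] with value 1 at both endpoint limits.
    """
    if not (0.0 < xi <= 1.0):
        raise ValueError(f"xi must lie in (0, 1], got {xi}")
    return 1.0 - xi + xi / math.gamma(xi)


def _bracket0(m, xi):
    """Dimensionless part of the zeroth Newton weight, m = eta - nu >= 0."""
    m = np.asarray(m, dtype=float)
    return (m + 1.0) ** xi - m ** xi


def _bracket1(m, xi):
    m = np.asarray(m, dtype=float)
    return (m + 1.0) ** xi * (m + 3.0 + 2.0 * xi) - m ** xi * (m + 3.0 + 3.0 * xi)


def _bracket2(m, xi):
    m = np.asarray(m, dtype=float)
    return ((m + 1.0) ** xi * (2.0 * m * m + (3.0 * xi + 10.0) * m
                               + 2.0 * xi * xi + 9.0 * xi + 12.0)
            - m ** xi * (2.0 * m * m + (5.0 * xi + 10.0) * m
                         + 6.0 * xi * xi + 18.0 * xi + 12.0))


def newton_weights(eta: int, nu: int, xi: float, dt: float) -> tuple[float, float, float]:
    """Closed-form convolution weights of the three-point Newton scheme.

    For the interval [t_nu, t_nu+1] and target node t_eta+1 these are the
    exact kernel moments

        w0 = int (t_eta+1 - tau)**(xi-1) dtau
        w1 = int (tau - t_nu-2) (t_eta+1 - tau)**(xi-1) dtau
        w2 = int (tau - t_nu-2)(tau - t_nu-1) (t_eta+1 - tau)**(xi-1) dtau

    with m = eta - nu:

        w0 = dt**xi/xi * [(m+1)**xi - m**xi]
        w1 = dt**(xi+1)/(xi*(xi+1)) * [(m+1)**xi*(m+3+2xi) - m**xi*(m+3+3xi)]
        w2 = dt**(xi+2)/(xi*(xi+1)*(xi+2))
             * [(m+1)**xi*(2m^2+(3xi+10)m+2xi^2+9xi+12)
                - m**xi*(2m^2+(5xi+10)m+6xi^2+18xi+12)]
    """
    if nu > eta:
        raise IndexError(f"history index nu={nu} exceeds step index eta={eta}")
    if nu < 2:
        raise IndexError("the three-point weights are defined for nu >= 2")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (0.0 < xi <= 1.0):
        raise ValueError(f"xi must lie in (0, 1], got {xi}")
    m = eta - nu
    w0 = dt ** xi / xi * _bracket0(m, xi)
    w1 = dt ** (xi + 1) / (xi * (xi + 1.0)) * _bracket1(m, xi)
    w2 = dt ** (xi + 2) / (xi * (xi + 1.0) * (xi + 2.0)) * _bracket2(m, xi)
    return float(w0), float(w1), float(w2)


def newton_weights_quadrature(
    eta: int, nu: int, xi: float, dt: float
) -> tuple[float, float, float]:
    """Adaptive-quadrature evaluation of the three defining weight integrals.

    Independent oracle for :func:`newton_weights`.  The weakly singular
    kernel is removed exactly by the substitution v = (t_eta+1 - tau)**xi,
    after which ``scipy.integrate.quad`` integrates a smooth function.
    """
    t_target = (eta + 1) * dt
    lo, hi = nu * dt, (nu + 1) * dt
    t2, t1 = (nu - 2) * dt, (nu - 1) * dt
    polys = (
        lambda tau: 1.0,
        lambda tau: tau - t2,
        lambda tau: (tau - t2) * (tau - t1),
    )
    v_lo, v_hi = (t_target - hi) ** xi, (t_target - lo) ** xi
    out = []
    for poly in polys:
        val, _ = integrate.quad(
            lambda v: poly(t_target - v ** (1.0 / xi)) / xi,
            v_lo, v_hi, limit=200, epsabs=0.0, epsrel=1e-12,
        )
        out.append(val)
    return tuple(out)


def _origin_power(t: float, exponent: float) -> float:
    """t**exponent with the origin convention t=0 -> 0 (or 1 when exponent=0)."""
    if t == 0.0:
        return 1.0 if exponent == 0.0 else 0.0
    return t ** exponent


class _SchemeContext:
    """Precomputed grid powers and prefactors shared by all steps of a run."""

    def __init__(self, params: Parameters, orders: FFMOrders, dt: float, n: int,
                 startup: str, ic_term: bool):
        xi, lf = orders.xi, orders.lambda_f
        self.params = params
        self.xi, self.lf = xi, lf
        self.dt = dt
        self.startup = startup
        self.ic_term = ic_term
        self.ab = ab_normalization(xi)
        self.c_local = lf * (1.0 - xi) / self.ab
        base = xi * lf * dt ** xi / self.ab
        self.c0 = base / _gamma(xi + 1.0)
        self.c1 = base / _gamma(xi + 2.0)
        self.c2 = base / (2.0 * _gamma(xi + 3.0))
        # startup-interval prefactor: xi*lf/(AB*Gamma(xi)) with dt**xi folded in
        self.c_start = xi * lf * dt ** xi / (self.ab * _gamma(xi))
        p = np.arange(n + 2, dtype=float)
        self.pow_xi = p ** xi          # p**xi for p = 0..n+1
        self.pow_xi1 = p ** (xi + 1.0)
        times = p[: n + 1] * dt
        if lf == 1.0:
            self.tpow = np.ones(n + 1)
        else:
            self.tpow = np.empty(n + 1)
            self.tpow[0] = 0.0         # origin convention for t**(lambda_f-1)
            self.tpow[1:] = times[1:] ** (lf - 1.0)

    def startup_contribution(self, g: np.ndarray, eta: int) -> np.ndarray:
        """Kernel integral over the first two intervals, reduced-order polynomials.

        Interval [t0, t1] carries the constant polynomial g0; interval
        [t1, t2] the linear polynomial through (t0, g0), (t1, g1).  Both are
        integrated against (t_eta+1 - tau)**(xi-1) exactly.
        """
        xi = self.xi
        px, px1 = self.pow_xi, self.pow_xi1
        # interval 0: g0 * int (t_eta+1 - tau)**(xi-1), tau in [t0, t1]
        j0_first = (px[eta + 1] - px[eta]) / xi
        out = g[0] * j0_first
        if eta >= 1:
            # interval 1: g1*J0 + (g1-g0)/dt * J1 with reference node t1
            j0 = (px[eta] - px[eta - 1]) / xi
            j1 = eta * j0 - (px1[eta] - px1[eta - 1]) / (xi + 1.0)
            out = out + g[1] * j0 + (g[1] - g[0]) * j1
        return self.c_start * out

    def advance(self, u0: np.ndarray, g: np.ndarray, eta: int) -> np.ndarray:
        """State at node eta+1 from the cached fractal-weighted rates g[0..eta]."""
        xi = self.xi
        u = (u0.copy() if self.ic_term else np.zeros_like(u0))
        u += self.c_local * g[eta]
        if self.startup == "reduced-order":
            u += self.startup_contribution(g, eta)
        if eta >= 2:
            im = eta - np.arange(2, eta + 1)  # m = eta - nu for nu = 2..eta
            m = im.astype(float)
            mp = self.pow_xi[im]
            mp1 = self.pow_xi[im + 1]
            b0 = mp1 - mp
            b1 = mp1 * (m + 3.0 + 2.0 * xi) - mp * (m + 3.0 + 3.0 * xi)
            b2 = (mp1 * (2.0 * m * m + (3.0 * xi + 10.0) * m
                         + 2.0 * xi * xi + 9.0 * xi + 12.0)
                  - mp * (2.0 * m * m + (5.0 * xi + 10.0) * m
                          + 6.0 * xi * xi + 18.0 * xi + 12.0))
            d0 = g[0:eta - 1]
            d1 = g[1:eta] - g[0:eta - 1]
            d2 = g[2:eta + 1] - 2.0 * g[1:eta] + g[0:eta - 1]
            u += self.c0 * (b0 @ d0) + self.c1 * (b1 @ d1) + self.c2 * (b2 @ d2)
        return u


def step(history: Trajectory, params: Parameters, orders: FFMOrders,
         config: SolverConfig) -> State:
    """One step of the scheme: the state at node eta+1 from nodes 0..eta.

    ``history`` must hold at least three nodes with cached rhs values (the
    scheme interpolates through three history points).
    """
    n_nodes = len(history)
    if n_nodes < 3:
        raise ValueError("startup required: the step needs at least three history nodes")
    eta = n_nodes - 1
    dt = history.dt
    if not math.isclose(dt, config.dt, rel_tol=1e-9):
        raise ValueError("history grid spacing does not match config.dt")
    F = history.ensure_rhs(params)
    ctx = _SchemeContext(params, orders, dt, eta + 1, config.startup, config.ic_term)
    g = ctx.tpow[: eta + 1, None] * F
    return State.from_array(ctx.advance(history.states[0], g, eta))


def simulate(params: Parameters, orders: FFMOrders, init: State,
             config: SolverConfig) -> Trajectory:
    """Integrate the model with the fractal-fractional Mittag-Leffler scheme.

    Produces nodes 0..N on the uniform grid of ``config``.  Under the default
    ``reduced-order`` startup, nodes 1 and 2 are produced by the constant- and
    linear-polynomial versions of the same quadrature; the full three-point
    scheme takes over from node 3.  Deterministic: identical inputs yield
    bit-identical trajectories.
    """
    n = config.n_steps
    ctx = _SchemeContext(params, orders, config.dt, n, config.startup, config.ic_term)
    if orders.lambda_f < 1.0:
        logger.info(
            "fractal dimension %g < 1: using the origin convention t0**(lambda_f-1) -> 0",
            orders.lambda_f,
        )
    logger.info("startup policy: %s; ic_term=%s", config.startup, config.ic_term)

    times = config.grid()
    states = np.empty((n + 1, 5))
    F = np.empty((n + 1, 5))
    g = np.empty((n + 1, 5))
    u0 = init.as_array()
    states[0] = u0
    F[0] = rhs_array(u0, params)
    g[0] = ctx.tpow[0] * F[0]

    if config.startup == "repeated-first-node":
        for k in (1, 2):
            states[k] = u0
            F[k] = F[0]
            g[k] = ctx.tpow[k] * F[k]
        first = 2
    else:
        first = 0

    with np.errstate(over="ignore", invalid="ignore"):
        for eta in range(first, n):
            u = ctx.advance(u0, g[: eta + 1], eta)
            if not np.all(np.isfinite(u)):
                raise IntegrationError(
                    f"non-finite state at step {eta + 1} (t = {times[eta + 1]:g})"
                )
            states[eta + 1] = u
            F[eta + 1] = rhs_array(u, params)
            g[eta + 1] = ctx.tpow[eta + 1] * F[eta + 1]

    return Trajectory(times, states, F)


def classical_reference(params: Parameters, init: State,
                        config: SolverConfig, rtol: float = 1e-10,
                        atol: float = 1e-12) -> Trajectory:
    """High-accuracy adaptive classical (xi = lambda_f = 1) solution.

    Oracle for the integer-order limit of the scheme; solves dU/dt = F(U)
    with ``scipy.integrate.solve_ivp`` (LSODA) and samples on the config grid.
    """
    times = config.grid()
    sol = integrate.solve_ivp(
        lambda t, y: rhs_array(y, params),
        (0.0, float(times[-1])), init.as_array(),
        method="LSODA", t_eval=times, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"classical reference solver failed: {sol.message}")
    states = sol.y.T
    F = np.array([rhs_array(y, params) for y in states])
    return Trajectory(times, states, F)


def fractional_quadrature_oracle(params: Parameters, orders: FFMOrders,
                                 init: State, config: SolverConfig) -> Trajectory:
    """Brute-force first-order evaluation of the fractal-fractional integral.

    Independent cross-check for :func:`simulate`: the memory integral of the
    Volterra form is evaluated with piecewise-linear interpolation of the
    stored fractal-weighted rates (constant on the newest interval, where the
    right endpoint is not yet known), with the kernel moments integrated
    exactly.  At xi = lambda_f = 1 this reduces to a trapezoid-type
    quadrature of int F dtau.  Intended for small grids (<= 2000 nodes).
    """
    n = config.n_steps
    if n > 2000:
        raise ValueError("the quadrature oracle is limited to 2000 nodes")
    xi, lf = orders.xi, orders.lambda_f
    ab = ab_normalization(xi)
    dt = config.dt
    c_local = lf * (1.0 - xi) / ab
    c_mem = xi * lf * dt ** xi / (ab * _gamma(xi))
    p = np.arange(n + 2, dtype=float)
    pow_xi = p ** xi
    pow_xi1 = p ** (xi + 1.0)
    tpow = np.ones(n + 1) if lf == 1.0 else np.concatenate(
        ([0.0], (p[1: n + 1] * dt) ** (lf - 1.0))
    )

    times = config.grid()
    states = np.empty((n + 1, 5))
    F = np.empty((n + 1, 5))
    g = np.empty((n + 1, 5))
    u0 = init.as_array()
    states[0] = u0
    F[0] = rhs_array(u0, params)
    g[0] = tpow[0] * F[0]

    for eta in range(n):
        # intervals [t_j, t_j+1], j = 0..eta; m = eta - j
        m = (eta - np.arange(eta + 1)).astype(int)
        j0 = (pow_xi[m + 1] - pow_xi[m]) / xi                     # plain moment
        j1 = (m + 1) * j0 - (pow_xi1[m + 1] - pow_xi1[m]) / (xi + 1.0)
        acc = g[: eta + 1].T @ j0
        if eta >= 1:
            slope = g[1: eta + 1] - g[: eta]                      # per interval j < eta
            acc = acc + slope.T @ j1[:eta]
        u = (u0 if config.ic_term else 0.0) + c_local * g[eta] + c_mem * acc
        if not np.all(np.isfinite(u)):
            raise IntegrationError(
                f"non-finite state at step {eta + 1} (t = {times[eta + 1]:g})"
            )
        states[eta + 1] = u
        F[eta + 1] = rhs_array(u, params)
        g[eta + 1] = tpow[eta + 1] * F[eta + 1]

    return Trajectory(times, states, F)
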