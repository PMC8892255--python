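"""Five-compartment glucose–insulin dynamics and OGTT simulation.

State variables: glucose in the stomach ``S``, jejunum ``J`` and ileum
``L`` (mmol), blood glucose ``G`` (mM) and blood insulin ``I`` (pM).
The bolus starts in the stomach; gastric emptying (k_js) feeds the
jejunum, which passes glucose distally (transit time tau) and absorbs it
(k_gj); the ileum absorbs the remainder (k_lg).  Absorbed glucose enters
the blood through the distribution factor eta.  Blood glucose is cleared
by insulin-independent (k_xg) and insulin-dependent (k_xgi) uptake, and
the liver releases (k_lambda) or takes up (gamma) glucose when glycemia
is below or above its basal level.  Insulin is secreted in proportion to
supra-basal glycemia, potentiated by gut glucose through the incretin
coefficient f_gi, and turned over at rate k_xi.

Endogenous basal production P0 = k_xg*G_b + k_xgi*G_b*I_b makes
(0, 0, 0, G_b, I_b) an exact equilibrium: with no dose, nothing moves.

The right-hand side is pluggable (``rhs=`` argument) so alternative
functional forms can replace the default without touching anything
downstream: every statistic in this package depends only on the
parameter vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import IntegrationError
from .params import ModelParameters


def model_rhs(t, state, p: ModelParameters):
    """Time derivative of (S, J, L, G, I) under parameters ``p``."""
    S, J, L, G, I = state
    if not all(map(np.isfinite, (S, J, L, G, I))):
        raise IntegrationError("non-finite state during integration", params=p)
    dS = -p.k_js * S
    dJ = p.k_js * S - (1.0 / p.tau) * J - p.k_gj * J
    dL = (1.0 / p.tau) * J - p.k_lg * L
    P0 = p.k_xg * p.G_b + p.k_xgi * p.G_b * p.I_b
    excess = G - p.G_b
    hepatic = p.k_lambda * max(-excess, 0.0) - p.gamma * max(excess, 0.0)
    dG = p.eta * (p.k_gj * J + p.k_lg * L) + P0 - p.k_xg * G - p.k_xgi * G * I + hepatic
    dI = p.beta * max(excess, 0.0) * (1.0 + p.f_gi * (J + L)) - p.k_xi * (I - p.I_b)
    return (dS, dJ, dL, dG, dI)


@dataclass(frozen=True)
class SimulatedCurves:
    """Dense trajectories plus values at the requested sampling times."""

    t: np.ndarray  # dense grid, min
    S: np.ndarray  # mmol
    J: np.ndarray  # mmol
    L: np.ndarray  # mmol
    G: np.ndarray  # mM
    I: np.ndarray  # pM
    sample_times: np.ndarray
    sampled_G: np.ndarray
    sampled_I: np.ndarray

    @property
    def gut_total(self) -> np.ndarray:
        """Glucose remaining in the gut, S + J + L (mmol)."""
        return self.S + self.J + self.L


def simulate_ogtt(
    params: ModelParameters,
    horizon_min: float = 120.0,
    sample_times=(0.0, 30.0, 60.0, 90.0, 120.0),
    rhs=model_rhs,
    grid_step: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SimulatedCurves:
    """Integrate an OGTT from the basal state with the dose in the stomach.

    Uses an adaptive stiff-capable integrator (LSODA) with tight
    tolerances; the hinge terms around basal glycemia are continuous but
    not smooth, which is why the tolerances default low.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    if sample_times.size and horizon_min < sample_times.max():
        horizon_min = float(sample_times.max())
    y0 = (params.D, 0.0, 0.0, params.G_b, params.I_b)
    t_grid = np.arange(0.0, horizon_min + 0.5 * grid_step, grid_step)
    t_eval = np.unique(np.concatenate([t_grid, sample_times]))
    sol = solve_ivp(
        rhs,
        (0.0, horizon_min),
        y0,
        args=(params,),
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"OGTT integration failed: {sol.message}",
            params=params,
            diagnostics={"status": sol.status, "message": sol.message},
        )
    idx = np.searchsorted(sol.t, sample_times)
    return SimulatedCurves(
        t=sol.t,
        S=sol.y[0],
        J=sol.y[1],
        L=sol.y[2],
        G=sol.y[3],
        I=sol.y[4],
        sample_times=sample_times,
        sampled_G=sol.y[3][idx],
        sampled_I=sol.y[4][idx],
    )


def simulate_sampled_fast(params: ModelParameters, sample_times, dt: float = 0.5):
    """Fast fixed-step (RK4) simulation returning (G, I) at ``sample_times``.

    The workhorse behind parameter fitting, where the ODE is solved tens
    of thousands of times.  Gut compartments are integrated analytically
    (they form a linear chain driven by the stomach), leaving a 2-state
    RK4 for (G, I).  Agrees with :func:`simulate_ogtt` to well below
    measurement noise (checked in the test suite).
    """
    sample_times = np.asarray(sample_times, dtype=float)
    horizon = float(sample_times.max())
    if horizon <= 0:
        return (
            np.full_like(sample_times, params.G_b),
            np.full_like(sample_times, params.I_b),
        )
    n = max(1, int(np.ceil(horizon / dt)))
    dt = horizon / n if horizon > 0 else dt
    ts = np.linspace(0.0, horizon, n + 1)

    k_js, tau, k_gj, k_lg = params.k_js, params.tau, params.k_gj, params.k_lg
    a = 1.0 / tau + k_gj  # total jejunal outflow rate
    D = params.D

    # closed-form gut chain on the fine grid (generic distinct-rate case with
    # a numerically safe divided-difference fallback for near-equal rates)
    S = D * np.exp(-k_js * ts)
    J = D * k_js * _expdiff(k_js, a, ts)
    # L' = J/tau - k_lg L  ->  L = (D k_js / tau) * double convolution
    L = (D * k_js / tau) * _double_expdiff(k_js, a, k_lg, ts)

    G_b, I_b = params.G_b, params.I_b
    k_xg, k_xgi = params.k_xg, params.k_xgi
    k_lambda, gamma = params.k_lambda, params.gamma
    beta, f_gi, k_xi, eta = params.beta, params.f_gi, params.k_xi, params.eta
    P0 = k_xg * G_b + k_xgi * G_b * I_b

    absorb = eta * (k_gj * J + k_lg * L)  # mM/min on the grid
    gut = J + L

    G = np.empty(n + 1)
    I = np.empty(n + 1)
    G[0], I[0] = G_b, I_b
    np_err = np.seterr(over="ignore", invalid="ignore")
    for i in range(n):
        # linear interpolation of the forcing inside the step
        a0, a1 = absorb[i], absorb[i + 1]
        q0, q1 = gut[i], gut[i + 1]
        am, qm = 0.5 * (a0 + a1), 0.5 * (q0 + q1)

        def f(g, ins, ab, q):
            ex = g - G_b
            dg = ab + P0 - k_xg * g - k_xgi * g * ins
            dg += k_lambda * (-ex) if ex < 0 else -gamma * ex
            di = (beta * ex * (1.0 + f_gi * q) if ex > 0 else 0.0) - k_xi * (ins - I_b)
            return dg, di

        g, ins = G[i], I[i]
        if not (-1e12 < g < 1e12 and -1e12 < ins < 1e12):
            np.seterr(**np_err)
            raise IntegrationError(
                "fast OGTT integration diverged", params=params
            )
        k1g, k1i = f(g, ins, a0, q0)
        k2g, k2i = f(g + 0.5 * dt * k1g, ins + 0.5 * dt * k1i, am, qm)
        k3g, k3i = f(g + 0.5 * dt * k2g, ins + 0.5 * dt * k2i, am, qm)
        k4g, k4i = f(g + dt * k3g, ins + dt * k3i, a1, q1)
        G[i + 1] = g + dt / 6.0 * (k1g + 2 * k2g + 2 * k3g + k4g)
        I[i + 1] = ins + dt / 6.0 * (k1i + 2 * k2i + 2 * k3i + k4i)
    np.seterr(**np_err)
    if not (np.all(np.isfinite(G)) and np.all(np.isfinite(I))):
        raise IntegrationError("fast OGTT integration produced non-finite values", params=params)
    return np.interp(sample_times, ts, G), np.interp(sample_times, ts, I)


def _expdiff(r1: float, r2: float, t: np.ndarray) -> np.ndarray:
    """(exp(-r1 t) - exp(-r2 t)) / (r2 - r1), stable as r1 -> r2."""
    if abs(r2 - r1) > 1e-10 * max(r1, r2, 1e-30):
        return (np.exp(-r1 * t) - np.exp(-r2 * t)) / (r2 - r1)
    return t * np.exp(-0.5 * (r1 + r2) * t)


def _double_expdiff(r1: float, r2: float, r3: float, t: np.ndarray) -> np.ndarray:
    """Convolution kernel for a three-stage linear chain with rates r1, r2, r3.

    Returns the integral giving the third-compartment response to a unit
    bolus, i.e. the solution of x3' = x2 - r3 x3 with x2 = expdiff(r1, r2).
    """
    rates = (r1, r2, r3)
    # distinct-rate partial fractions; pairwise-close rates fall back to
    # trapezoidal integration of the exact forcing (rare, still accurate)
    eps = 1e-8 * max(rates)
    if (
        abs(r1 - r2) > eps
        and abs(r1 - r3) > eps
        and abs(r2 - r3) > eps
    ):
        return (
            np.exp(-r1 * t) / ((r2 - r1) * (r3 - r1))
            + np.exp(-r2 * t) / ((r1 - r2) * (r3 - r2))
            + np.exp(-r3 * t) / ((r1 - r3) * (r2 - r3))
        )
    forcing = _expdiff(r1, r2, t)
    out = np.empty_like(t)
    out[0] = 0.0
    for i in range(1, len(t)):
        h = t[i] - t[i - 1]
        # exponential-integrator step for x' = forcing - r3 x
        decay = np.exp(-r3 * h)
        out[i] = out[i - 1] * decay + 0.5 * h * (forcing[i] + forcing[i - 1] * decay)
    return out
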