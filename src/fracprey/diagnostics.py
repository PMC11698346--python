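"""Numerical checks of the model's boundedness and global-stability theory.

Two diagnostics accompany the analytic results:

* **Boundedness.**  The weighted population ``omega = x1 + (a/b) x2``
  satisfies the differential inequality ``D^zeta omega + mu*omega < H``
  for any absorption rate ``0 < mu <= c``, where ::

      H = max_{x1 >= 0} [ r*x1*(1 - x1/rho)*(x1 - alpha)/(x1 + beta) + mu*x1 ]

  (the predator terms are absorbed by ``mu <= c``; the maximand is the prey
  growth plus ``mu*x1`` and is eventually negative, so the maximum over
  ``[0, 2*rho]`` is global).  By the fractional comparison lemma every
  solution enters the region ``omega < H/mu``.  The check verifies this on
  simulated trajectories.

* **Lyapunov monotonicity.**  The Volterra-type function ::

      theta(x1, x2) = (x1 - x1* - x1* ln(x1/x1*))
                      + (a/b) (x2 - x2* - x2* ln(x2/x2*))

  is positive definite about the interior equilibrium and non-increasing
  along solutions inside the domain ``D``: for a strong Allee effect
  ``D = {(x1 - x1*)(x1 - alpha) < 0}``, for a weak one ``D = {x1 < x1*}``.
  The trace evaluates theta along a trajectory, flags domain membership per
  node, and tests monotone decrease over in-domain segments with a small
  per-step slack for discretization error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .caputo import Trajectory
from .model import ModelParams, interior_equilibrium

__all__ = [
    "LyapunovTrace",
    "BoundReport",
    "lyapunov_value",
    "lyapunov_trace",
    "boundedness_check",
    "growth_bound",
]

DOMAIN_BOUNDARY_SLACK = 1e-12  # open-inequality slack at the boundary of D
MONOTONE_STEP_SLACK = 1e-8     # allowed per-step increase of theta (PECE error)


@dataclass
class LyapunovTrace:
    """Lyapunov function values and domain membership along a trajectory."""

    times: np.ndarray
    theta: np.ndarray
    in_domain: np.ndarray  # bool per node
    monotone_decreasing: bool
    exited_domain: bool

    def to_dict(self) -> dict:
        return {
            "monotone_decreasing": self.monotone_decreasing,
            "exited_domain": self.exited_domain,
            "theta_initial": float(self.theta[0]),
            "theta_final": float(self.theta[-1]),
            "n_nodes": int(len(self.times)),
            "n_in_domain": int(self.in_domain.sum()),
        }


@dataclass
class BoundReport:
    """Outcome of the omega = x1 + (a/b) x2 boundedness check."""

    mu: float
    H: float
    bound: float  # H / mu
    omega_tail_sup: float
    omega_min: float
    satisfied: bool

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "H": self.H,
            "bound": self.bound,
            "omega_tail_sup": self.omega_tail_sup,
            "omega_min": self.omega_min,
            "satisfied": self.satisfied,
        }


def lyapunov_value(p: ModelParams, state: np.ndarray) -> float:
    """theta(x1, x2) about the interior equilibrium; requires x1, x2 > 0."""
    eq = interior_equilibrium(p)
    x1s, x2s = eq.x1, eq.x2
    x1, x2 = float(state[0]), float(state[1])
    if x1 <= 0.0 or x2 <= 0.0:
        raise ValueError(f"theta undefined at non-positive state ({x1}, {x2})")
    return (x1 - x1s - x1s * np.log(x1 / x1s)) + (p.a / p.b) * (
        x2 - x2s - x2s * np.log(x2 / x2s)
    )


def _in_domain(p: ModelParams, x1: np.ndarray) -> np.ndarray:
    x1s = interior_equilibrium(p).x1
    if p.regime == "strong":
        return (x1 - x1s) * (x1 - p.alpha) < -DOMAIN_BOUNDARY_SLACK
    return x1 < x1s - DOMAIN_BOUNDARY_SLACK


def lyapunov_trace(
    p: ModelParams,
    traj: Trajectory,
    step_slack: float = MONOTONE_STEP_SLACK,
) -> LyapunovTrace:
    """Evaluate theta along a trajectory and test in-domain monotonicity.

    The monotone verdict considers only consecutive node pairs that both
    lie inside D; a per-step increase up to ``step_slack`` is tolerated.
    Excursions outside D are flagged (``exited_domain``) but not judged —
    the decrease guarantee only holds inside D.

    Raises
    ------
    ValueError
        If the interior equilibrium does not exist, or the trajectory
        touches a non-positive state (theta is undefined there); the error
        names the first offending node.
    """
    eq = interior_equilibrium(p)
    if not eq.exists:
        raise ValueError("interior equilibrium does not exist for these parameters")
    states = traj.states
    bad = np.where((states[:, 0] <= 0.0) | (states[:, 1] <= 0.0))[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"non-positive state at node {i} (t = {traj.times[i]:g}): {states[i]}"
        )
    x1s, x2s = eq.x1, eq.x2
    x1, x2 = states[:, 0], states[:, 1]
    theta = (x1 - x1s - x1s * np.log(x1 / x1s)) + (p.a / p.b) * (
        x2 - x2s - x2s * np.log(x2 / x2s)
    )
    inside = _in_domain(p, x1)
    pair_inside = inside[:-1] & inside[1:]
    increments = np.diff(theta)
    monotone = bool(np.all(increments[pair_inside] <= step_slack))
    return LyapunovTrace(
        times=traj.times,
        theta=theta,
        in_domain=inside,
        monotone_decreasing=monotone,
        exited_domain=bool(~inside.all()),
    )


def growth_bound(p: ModelParams, mu: float, tol: float = 1e-8) -> float:
    """Supremum H of ``phi(x1) = prey growth + mu*x1`` over x1 >= 0.

    phi is a rational function with a negative cubic numerator at large
    x1, so its global maximum lies in [0, 2*rho]; it is located by a coarse
    grid scan refined with bounded scalar minimization of -phi.
    """

    def phi(x1: float) -> float:
        return (
            p.r * x1 * (1.0 - x1 / p.rho) * (x1 - p.alpha) / (x1 + p.beta) + mu * x1
        )

    grid = np.linspace(0.0, 2.0 * p.rho, 4001)
    vals = np.array([phi(x) for x in grid])
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(lambda x: -phi(x), bounds=(lo, hi), method="bounded",
                          options={"xatol": tol})
    return float(max(-res.fun, vals[i]))


def boundedness_check(
    p: ModelParams,
    mu: float,
    traj: Trajectory,
    transient_fraction: float = 0.5,
) -> BoundReport:
    """Verify omega = x1 + (a/b) x2 enters the region omega < H/mu.

    ``mu`` must satisfy ``0 < mu <= c`` so the predator mortality absorbs
    the ``mu * (a/b) * x2`` term; larger mu breaks the inequality the bound
    is derived from.  The comparison uses the post-transient tail, since the
    bound is asymptotic (early transients may legitimately exceed it).
    """
    if not (0.0 < mu <= p.c):
        raise ValueError(f"mu must lie in (0, c] = (0, {p.c}], got {mu}")
    H = growth_bound(p, mu)
    if H <= 0.0:
        raise RuntimeError("computed growth bound H is non-positive")
    bound = H / mu
    omega = traj.states[:, 0] + (p.a / p.b) * traj.states[:, 1]
    tail = traj.tail(transient_fraction)
    omega_tail = tail.states[:, 0] + (p.a / p.b) * tail.states[:, 1]
    tail_sup = float(omega_tail.max())
    return BoundReport(
        mu=mu,
        H=H,
        bound=bound,
        omega_tail_sup=tail_sup,
        omega_min=float(omega.min()),
        satisfied=tail_sup <= bound + 1e-6,
    )
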