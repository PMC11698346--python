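"""Matignon stability classification and the Hopf critical order.

For a Caputo system of order ``zeta`` an equilibrium is locally
asymptotically stable iff every Jacobian eigenvalue satisfies
``|arg(lambda)| > zeta*pi/2`` (Matignon's condition).  The signed margins

    nu_i = zeta*pi/2 - |arg(lambda_i)|

are negative at a stable point.  When the interior Jacobian carries a
complex-conjugate pair with positive real part (equivalently
``tr^2/4 < det`` and ``tr > 0``), the margin crosses zero at the critical
derivative order

    zeta* = (2/pi) * |arg(lambda)|,

and the equilibrium undergoes a Hopf bifurcation as ``zeta`` crosses
``zeta*``: stable below, an emerging limit cycle above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    RESIDUAL_TOL,
    EquilibriumPoint,
    ModelParams,
    check_equilibrium,
    interior_equilibrium,
    jacobian,
)

__all__ = [
    "EquilibriumReport",
    "classify",
    "critical_order",
    "theorem_conditions",
    "eigenvalues_closed_form",
]

NONHYPERBOLIC_BAND = 1e-9  # |nu| below this is reported as non-hyperbolic


@dataclass
class EquilibriumReport:
    """Stability verdict for one equilibrium at a given derivative order."""

    equilibrium: EquilibriumPoint
    zeta: float
    jacobian: np.ndarray
    eigenvalues: np.ndarray  # complex pair
    arg_margins: np.ndarray  # nu_i = zeta*pi/2 - |arg(lambda_i)|
    verdict: str  # stable | unstable | saddle | non-hyperbolic
    critical_order: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "kind": self.equilibrium.kind,
            "point": [self.equilibrium.x1, self.equilibrium.x2],
            "zeta": self.zeta,
            "eigenvalues": [[ev.real, ev.imag] for ev in self.eigenvalues],
            "margins": list(map(float, self.arg_margins)),
            "verdict": self.verdict,
            "critical_order": self.critical_order,
        }


def eigenvalues_closed_form(J: np.ndarray) -> np.ndarray:
    """Eigenvalues of a 2x2 matrix from the characteristic quadratic.

    Independent of LAPACK; used to cross-check the eigendecomposition
    route to tight tolerance.
    """
    tr = J[0, 0] + J[1, 1]
    det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    disc = tr * tr / 4.0 - det
    if disc >= 0.0:
        s = math.sqrt(disc)
        return np.array([tr / 2.0 - s, tr / 2.0 + s], dtype=complex)
    s = math.sqrt(-disc)
    return np.array([complex(tr / 2.0, -s), complex(tr / 2.0, s)])


def _margins(eigenvalues: np.ndarray, zeta: float) -> np.ndarray:
    return zeta * np.pi / 2.0 - np.abs(np.angle(eigenvalues))


def classify(
    p: ModelParams,
    zeta: float,
    eq: EquilibriumPoint,
    residual_tol: float = RESIDUAL_TOL,
) -> EquilibriumReport:
    """Matignon classification of an equilibrium at derivative order ``zeta``.

    Verdicts: ``stable`` if every eigenvalue satisfies
    ``|arg| > zeta*pi/2``; ``saddle`` for a real pair with one positive and
    one negative eigenvalue (arguments 0 and pi, unstable for every order);
    ``non-hyperbolic`` if any margin sits within ``NONHYPERBOLIC_BAND`` of
    zero; otherwise ``unstable``.

    Raises
    ------
    ValueError
        If ``eq`` fails the equilibrium residual check for ``p``.
    """
    if not (0.0 < zeta <= 1.0):
        raise ValueError(f"zeta must lie in (0, 1], got {zeta}")
    check_equilibrium(p, eq, tol=residual_tol)
    J = jacobian(p, eq.point)
    lam = np.linalg.eigvals(J)
    # stable sort by (real, imag) so reports are order-independent
    lam = lam[np.lexsort((lam.imag, lam.real))]
    nu = _margins(lam, zeta)
    if np.any(np.abs(nu) < NONHYPERBOLIC_BAND):
        verdict = "non-hyperbolic"
    elif np.all(np.isreal(lam)) and lam.real.min() < 0.0 < lam.real.max():
        verdict = "saddle"
    elif np.all(nu < 0.0):
        verdict = "stable"
    else:
        verdict = "unstable"
    zc = _critical_order_from_eigs(lam)
    return EquilibriumReport(
        equilibrium=eq,
        zeta=zeta,
        jacobian=J,
        eigenvalues=lam,
        arg_margins=nu,
        verdict=verdict,
        critical_order=zc,
    )


def _critical_order_from_eigs(lam: np.ndarray) -> Optional[float]:
    if np.any(lam.imag != 0.0) and np.all(lam.real > 0.0):
        return float(2.0 / np.pi * np.abs(np.angle(lam[0])))
    return None


def critical_order(p: ModelParams) -> Optional[float]:
    """Hopf critical derivative order ``zeta*`` for the interior point.

    Returns ``(2/pi)*|arg(lambda)|`` when the interior Jacobian has a
    complex pair with positive real part (which requires
    ``tr^2/4 < det``); returns ``None`` when the eigenvalues are real or
    have non-positive real part, in which case no order-driven Hopf
    bifurcation occurs in (0, 1].

    Raises
    ------
    ValueError
        If the interior equilibrium does not exist for ``p``.
    """
    eq = interior_equilibrium(p)
    if not eq.exists:
        raise ValueError("interior equilibrium does not exist for these parameters")
    lam = np.linalg.eigvals(jacobian(p, eq.point))
    return _critical_order_from_eigs(lam)


@dataclass
class ConditionCheck:
    """A closed-form stability inequality and its eigenvalue cross-check."""

    equilibrium: str
    condition: str
    holds: bool
    eigen_verdict: str
    consistent: bool
    caveat: str = ""


def theorem_conditions(p: ModelParams, zeta: float = 1.0) -> list[ConditionCheck]:
    """Evaluate the closed-form stability inequalities per equilibrium.

    Checks, against the eigenvalue-based verdict at the given order:

    * extinction (0,0): always stable in the strong regime, always a
      saddle in the weak one;
    * carrying-capacity point (rho, 0): stable iff ``alpha < rho < c/b``
      (strong) or ``rho < c/b`` (weak);
    * Allee point (alpha, 0), strong only: stable iff ``rho < alpha < c/b``
      (vacuous whenever alpha < rho);
    * interior: determinant positivity ``a*b*x1*x2 > 0`` follows from the
      existence condition; the sign of the trace decides stability at
      integer order.  The printed closed-form trace inequality for the
      interior point is typographically ambiguous in its source, so it is
      reported under the reading ``c < (rho + alpha) * b / 2`` with a
      caveat, and never used for the verdict — eigenvalues decide.
    """
    from .model import equilibria

    checks: list[ConditionCheck] = []
    cb = p.c / p.b
    for eq in equilibria(p):
        rep = classify(p, zeta, eq)
        if eq.kind == "extinction":
            if p.regime == "strong":
                cond, holds, expect = "always stable (strong regime)", True, "stable"
            else:
                cond, holds, expect = "always a saddle (weak regime)", True, "saddle"
            consistent = rep.verdict == expect
            checks.append(
                ConditionCheck(eq.kind, cond, holds, rep.verdict, consistent)
            )
        elif eq.kind == "axial_carrying":
            if p.regime == "strong":
                cond = "alpha < rho < c/b"
                holds = p.alpha < p.rho < cb
            else:
                cond = "rho < c/b"
                holds = p.rho < cb
            consistent = holds == (rep.verdict == "stable")
            checks.append(ConditionCheck(eq.kind, cond, holds, rep.verdict, consistent))
        elif eq.kind == "axial_allee":
            cond = "rho < alpha < c/b"
            holds = p.rho < p.alpha < cb
            consistent = holds == (rep.verdict == "stable")
            checks.append(ConditionCheck(eq.kind, cond, holds, rep.verdict, consistent))
        elif eq.kind == "interior":
            J = rep.jacobian
            det = float(np.linalg.det(J))
            cond = "alpha < c/b < rho (det > 0)" if p.regime == "strong" else "c/b < rho (det > 0)"
            holds = det > 0.0
            checks.append(
                ConditionCheck(eq.kind, cond, holds, rep.verdict, holds)
            )
            trace_reading = p.c < (p.rho + p.alpha) * p.b / 2.0
            tr = float(np.trace(J))
            checks.append(
                ConditionCheck(
                    eq.kind,
                    "c < (rho + alpha)*b/2 (trace reading)",
                    trace_reading,
                    rep.verdict,
                    trace_reading == (tr < 0.0),
                    caveat=(
                        "closed-form trace inequality is reported for reference only; "
                        "stability verdicts come from eigenvalues"
                    ),
                )
            )
    return checks
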