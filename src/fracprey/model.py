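"""Double-Allee predator-prey model: vector field, equilibria, Jacobian.

The system couples a prey population subject to a multiplicative double
Allee effect with a predator feeding through a Holling type-I (linear)
functional response::

    dx1/dt = r*x1/(x1+beta) * (1 - x1/rho) * (x1 - alpha) - a*x1*x2
    dx2/dt = b*x1*x2 - c*x2

The Allee effect is *strong* when the threshold ``alpha`` is positive
(per-capita prey growth is negative below ``alpha``) and *weak* when
``-beta < alpha <= 0``.  The same right-hand side is used verbatim for the
Caputo fractional-order version of the model; the derivative order enters
only through the solver and the Matignon stability condition.

The interior (coexistence) equilibrium follows from the nullclines: the
predator nullcline ``b*x1 = c`` pins the prey coordinate at ``x1* = c/b``
(independent of r, rho, alpha, beta), and the prey nullcline then gives
``x2* = r*(1 - x1*/rho)*(x1* - alpha) / (a*(x1* + beta))``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "EquilibriumPoint",
    "vector_field",
    "jacobian",
    "equilibria",
    "RESIDUAL_TOL",
    "JACOBIAN_FD_RTOL",
    "DEGENERACY_TOL",
]

# Package-level numerical tolerances (overridable by passing explicitly).
RESIDUAL_TOL = 1e-10      # max |vector field| accepted at an equilibrium
JACOBIAN_FD_RTOL = 1e-6   # relative agreement with finite differences
DEGENERACY_TOL = 1e-12    # |c/b - rho| or |c/b - alpha| below this is degenerate


@dataclass(frozen=True)
class ModelParams:
    """The seven ecological parameters of the double-Allee system.

    Parameters
    ----------
    r : float
        Intrinsic per-capita prey growth rate (1/time).
    rho : float
        Prey carrying capacity (density).
    a : float
        Predator capture rate (1/(density*time)).
    alpha : float
        Allee threshold (density).  Positive for a strong Allee effect,
        in ``(-beta, 0]`` for a weak one.
    beta : float
        Auxiliary Allee intensity parameter (density), strictly positive.
    b : float
        Prey-to-predator biomass conversion rate (1/(density*time)).
    c : float
        Predator natural mortality rate (1/time).
    """

    r: float
    rho: float
    a: float
    alpha: float
    beta: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("r", "rho", "a", "beta", "b", "c"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {name!r} must be finite and > 0, got {v}")
        if not np.isfinite(self.alpha):
            raise ValueError("alpha must be finite")
        # alpha = -beta is the degenerate boundary where the two Allee
        # factors cancel to plain logistic growth; it is permitted, while
        # alpha < -beta (negative growth factor at x1 = 0+) is rejected.
        if self.alpha < -self.beta:
            raise ValueError(
                f"alpha must be >= -beta (got alpha={self.alpha}, beta={self.beta})"
            )

    @property
    def regime(self) -> str:
        """``"strong"`` if alpha > 0, else ``"weak"`` (alpha = 0 included)."""
        return "strong" if self.alpha > 0 else "weak"

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        keys = {"r", "rho", "a", "alpha", "beta", "b", "c"}
        extra = set(d) - keys
        if extra:
            raise ValueError(f"unknown parameter keys: {sorted(extra)}")
        return cls(**{k: float(d[k]) for k in keys})

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        """Read parameters from a flat JSON or YAML key-value file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yml", ".yaml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() in {".yml", ".yaml"}:
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


@dataclass(frozen=True)
class EquilibriumPoint:
    """A steady state of the model with its structural classification.

    ``kind`` is one of ``extinction`` (0,0), ``axial_carrying`` (rho,0),
    ``axial_allee`` (alpha,0, strong regime only) or ``interior``.
    ``exists`` is False for an interior point whose existence condition
    fails; ``degenerate`` flags the boundary cases c/b = rho or c/b = alpha.
    """

    x1: float
    x2: float
    kind: str
    exists: bool = True
    degenerate: bool = False

    @property
    def point(self) -> np.ndarray:
        return np.array([self.x1, self.x2])

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "x1": self.x1,
            "x2": self.x2,
            "exists": self.exists,
            "degenerate": self.degenerate,
        }


def _as_state(s: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(s, dtype=float)
    if arr.shape != (2,):
        raise ValueError(f"state must have two components, got shape {arr.shape}")
    return arr


def vector_field(p: ModelParams, s: Sequence[float] | np.ndarray) -> np.ndarray:
    """Right-hand side (dx1/dt, dx2/dt) at state ``s = (x1, x2)``.

    Raises
    ------
    FloatingPointError
        If the state is non-finite (signals solver blow-up upstream).
    """
    s = _as_state(s)
    if not np.all(np.isfinite(s)):
        raise FloatingPointError(f"non-finite state {s} passed to vector_field")
    x1, x2 = s
    # overflow here only happens on a diverging solver iterate; the solver
    # detects the resulting non-finite value and raises a blow-up error
    with np.errstate(over="ignore", invalid="ignore"):
        prey = (
            p.r * x1 / (x1 + p.beta) * (1.0 - x1 / p.rho) * (x1 - p.alpha)
            - p.a * x1 * x2
        )
        pred = p.b * x1 * x2 - p.c * x2
    return np.array([prey, pred])


def jacobian(p: ModelParams, s: Sequence[float] | np.ndarray) -> np.ndarray:
    """Analytic 2x2 Jacobian of :func:`vector_field` at ``s``.

    The (1,1) entry expands the product rule of the prey equation::

        s11 = r*beta/(x1+beta)^2 * (1-x1/rho)*(x1-alpha)
              + r*x1/(x1+beta) * (1 + alpha/rho - 2*x1/rho) - a*x2
    """
    s = _as_state(s)
    if not np.all(np.isfinite(s)):
        raise FloatingPointError(f"non-finite state {s} passed to jacobian")
    x1, x2 = s
    r, rho, a, alpha, beta, b, c = p.r, p.rho, p.a, p.alpha, p.beta, p.b, p.c
    s11 = (
        r * beta / (x1 + beta) ** 2 * (1.0 - x1 / rho) * (x1 - alpha)
        + r * x1 / (x1 + beta) * (1.0 + alpha / rho - 2.0 * x1 / rho)
        - a * x2
    )
    s12 = -a * x1
    s21 = b * x2
    s22 = b * x1 - c
    return np.array([[s11, s12], [s21, s22]])


def interior_equilibrium(p: ModelParams) -> EquilibriumPoint:
    """Interior equilibrium from the nullclines, with existence flags.

    ``x1* = c/b`` from the predator nullcline; ``x2*`` from the prey
    nullcline.  Existence requires ``alpha < c/b < rho`` in the strong
    regime and ``c/b < rho`` in the weak one (where ``c/b > 0 > alpha``
    holds automatically).  Within ``DEGENERACY_TOL`` of either boundary the
    point is flagged degenerate and reported as non-existing.
    """
    x1 = p.c / p.b
    x2 = p.r * (1.0 - x1 / p.rho) * (x1 - p.alpha) / (p.a * (x1 + p.beta))
    degenerate = abs(x1 - p.rho) < DEGENERACY_TOL or abs(x1 - p.alpha) < DEGENERACY_TOL
    exists = (p.alpha < x1 < p.rho) and not degenerate
    return EquilibriumPoint(x1=x1, x2=x2, kind="interior", exists=exists, degenerate=degenerate)


def equilibria(p: ModelParams, include_nonexistent: bool = False) -> list[EquilibriumPoint]:
    """All biologically feasible equilibria of the model.

    Strong regime: extinction (0,0), carrying capacity (rho,0), Allee
    threshold (alpha,0), and the interior point when ``alpha < c/b < rho``.
    Weak regime (alpha <= 0): the Allee-threshold point is not feasible
    (non-positive prey), leaving (0,0), (rho,0) and the interior point when
    ``c/b < rho``.

    With ``include_nonexistent=True`` the interior point is returned even
    when its existence condition fails (``exists=False``), which lets
    parameter sweeps cross degeneracies without special-casing.
    """
    pts = [
        EquilibriumPoint(0.0, 0.0, "extinction"),
        EquilibriumPoint(p.rho, 0.0, "axial_carrying"),
    ]
    if p.regime == "strong":
        pts.append(EquilibriumPoint(p.alpha, 0.0, "axial_allee"))
    interior = interior_equilibrium(p)
    if interior.exists or include_nonexistent:
        pts.append(interior)
    return pts


def residual(p: ModelParams, eq: EquilibriumPoint) -> float:
    """Max-norm of the vector field at an equilibrium point."""
    return float(np.max(np.abs(vector_field(p, eq.point))))


def check_equilibrium(p: ModelParams, eq: EquilibriumPoint, tol: float = RESIDUAL_TOL) -> None:
    res = residual(p, eq)
    if res > tol:
        raise ValueError(
            f"point ({eq.x1}, {eq.x2}) is not an equilibrium: residual {res:.3e} > {tol:.1e}"
        )
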