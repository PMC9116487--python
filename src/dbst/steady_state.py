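"""Fixed points of power-law systems.

Two routes:

* :func:`ssystem_steady_state` — the classical closed form. When every
  dependent variable has exactly one aggregate production and one aggregate
  degradation term, equating the two term-wise and taking logarithms turns
  the fixed-point condition into a linear system in ``y = log X``, solved
  exactly.
* :func:`gma_steady_state` — damped Newton iteration on ``F(exp(y)) = 0`` in
  log coordinates for general multi-term (GMA) systems. Working in log space
  makes positivity structural; results are reported in linear units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .model import ModelSpec, RegimeSet, rhs, validate_model

__all__ = ["SteadyStateResult", "NotSSystemError", "ssystem_steady_state",
           "gma_steady_state", "steady_state_grid"]

DEFAULT_TOL = 1e-10


class NotSSystemError(ValueError):
    """The model lacks the one-production/one-degradation S-system shape."""


@dataclass
class SteadyStateResult:
    state: dict[str, float]
    residual_norm: float
    method: str  # "closed_form" | "newton"
    iterations: int = 0
    converged: bool = True
    message: str = ""
    extra: dict = field(default_factory=dict)

    def vector(self, names: list[str]) -> np.ndarray:
        return np.array([self.state[n] for n in names])


def _fixed_values(spec: ModelSpec, overrides: Optional[Mapping[str, float]]) -> dict[str, float]:
    vals = {v.name: v.initial_value for v in spec.variables if v.role == "independent"}
    if overrides:
        vals.update(overrides)
    return vals


def ssystem_steady_state(spec: ModelSpec,
                         independent_values: Optional[Mapping[str, float]] = None,
                         tolerance: float = DEFAULT_TOL) -> SteadyStateResult:
    """Closed-form fixed point of an S-system.

    Requires each dependent variable to carry exactly one production and one
    degradation term, with no regimes, delays or offsets. Equating the two
    terms and taking logs gives ``A y = b`` with ``A`` the matrix of kinetic
    order differences over dependent variables; independent variables enter
    the right-hand side as constants (override their values via
    *independent_values*).
    """
    spec = validate_model(spec)
    dep = spec.dependent_names
    fixed = _fixed_values(spec, independent_values)

    rows, b = [], []
    for var in dep:
        eq = spec.equations[var]
        if isinstance(eq, RegimeSet):
            raise NotSSystemError(f"{var!r} uses threshold regimes")
        prod = [t for t in eq if t.sign > 0]
        deg = [t for t in eq if t.sign < 0]
        if len(prod) != 1 or len(deg) != 1:
            raise NotSSystemError(
                f"{var!r} has {len(prod)} production / {len(deg)} degradation "
                "terms; the closed form needs exactly one of each")
        p, d = prod[0], deg[0]
        for t in (p, d):
            if t.delay or t.offset:
                raise NotSSystemError(f"{var!r}: delays/offsets preclude the closed form")
            if t.rate_constant <= 0:
                raise NotSSystemError(f"{var!r}: zero rate constant")
        row = np.zeros(len(dep))
        rhs_val = math.log(p.rate_constant) - math.log(d.rate_constant)
        for ref, f in p.exponents.items():
            if ref in dep:
                row[dep.index(ref)] -= f
            else:
                rhs_val += f * math.log(fixed[ref])
        for ref, f in d.exponents.items():
            if ref in dep:
                row[dep.index(ref)] += f
            else:
                rhs_val -= f * math.log(fixed[ref])
        rows.append(row)
        b.append(rhs_val)

    A = np.vstack(rows)
    try:
        y = np.linalg.solve(A, np.array(b))
    except np.linalg.LinAlgError as exc:
        raise NotSSystemError(f"log-linear system is singular: {exc}") from exc
    state = dict(zip(dep, np.exp(y)))
    state.update(fixed)
    res = float(np.max(np.abs(rhs(spec, state))))
    return SteadyStateResult(state=state, residual_norm=res, method="closed_form",
                             converged=res < max(tolerance, 1e-8))


def _residual(spec: ModelSpec, dep: list[str], fixed: dict[str, float],
              y: np.ndarray) -> np.ndarray:
    state = dict(zip(dep, np.exp(y)))
    state.update(fixed)
    return rhs(spec, state)


def gma_steady_state(spec: ModelSpec,
                     guess: Optional[Mapping[str, float]] = None,
                     independent_values: Optional[Mapping[str, float]] = None,
                     tolerance: float = DEFAULT_TOL,
                     max_iter: int = 200) -> SteadyStateResult:
    """Damped Newton search for an interior fixed point of a GMA system.

    Iterates on ``y = log X`` with a numerically differenced Jacobian and
    simple backtracking; a singular Jacobian triggers a small perturbation
    and retry. Non-convergence is flagged on the result, not raised, and the
    best iterate found is reported.
    """
    spec = validate_model(spec)
    dep = spec.dependent_names
    fixed = _fixed_values(spec, independent_values)
    n = len(dep)

    if guess is None:
        y = np.zeros(n)  # all-ones state
    else:
        g = np.array([guess[v] for v in dep], dtype=float)
        if np.any(g <= 0):
            raise ValueError("initial guess must be positive")
        y = np.log(g)

    def fval(yv: np.ndarray) -> np.ndarray:
        return _residual(spec, dep, fixed, yv)

    f = fval(y)
    best_y, best_norm = y.copy(), float(np.max(np.abs(f)))
    it = 0
    for it in range(1, max_iter + 1):
        norm = float(np.max(np.abs(f)))
        if norm < best_norm:
            best_y, best_norm = y.copy(), norm
        if norm < tolerance:
            break
        J = np.empty((n, n))
        eps = 1e-7
        for j in range(n):
            yp, ym = y.copy(), y.copy()
            yp[j] += eps
            ym[j] -= eps
            J[:, j] = (fval(yp) - fval(ym)) / (2 * eps)
        try:
            dy = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            y = y + 1e-6 * (1 + np.arange(n))  # deterministic nudge off the singularity
            f = fval(y)
            continue
        lam, accepted = 1.0, False
        for _ in range(30):
            y_try = y + lam * dy
            if np.max(np.abs(y_try)) > 50:  # keep exp() in range
                lam *= 0.5
                continue
            f_try = fval(y_try)
            if np.max(np.abs(f_try)) < norm:
                y, f, accepted = y_try, f_try, True
                break
            lam *= 0.5
        if not accepted:
            break

    norm = float(np.max(np.abs(f)))
    if norm < best_norm:
        best_y, best_norm = y, norm
    state = dict(zip(dep, np.exp(best_y)))
    state.update(fixed)
    converged = best_norm < tolerance
    # a root pinned against the positivity floor is a boundary artifact,
    # not an interior fixed point of the power-law system
    interior = bool(np.all(np.exp(best_y) > 1e-10))
    msg = "" if converged else f"stopped after {it} iterations with ‖F‖∞ = {best_norm:.3e}"
    if converged and not interior:
        msg = "root lies on the positivity floor (non-interior)"
    return SteadyStateResult(state=state, residual_norm=best_norm, method="newton",
                             iterations=it, converged=converged, message=msg,
                             extra={"interior": interior})


def steady_state_grid(spec: ModelSpec, guesses: list[Mapping[str, float]],
                      independent_values: Optional[Mapping[str, float]] = None,
                      tolerance: float = DEFAULT_TOL,
                      rel_dedup: float = 1e-6) -> list[SteadyStateResult]:
    """Newton from a grid of guesses; distinct converged roots, deduplicated."""
    roots: list[SteadyStateResult] = []
    dep = spec.dependent_names
    for g in guesses:
        res = gma_steady_state(spec, g, independent_values, tolerance)
        if not res.converged:
            continue
        v = res.vector(dep)
        dup = any(np.allclose(v, r.vector(dep), rtol=rel_dedup, atol=1e-12)
                  for r in roots)
        if not dup:
            roots.append(res)
    return roots
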