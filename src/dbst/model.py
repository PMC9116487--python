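"""Domain types for discrete power-law (BST-style) models.

A model is a set of variables, each *dependent* variable governed by a sum of
signed power-law terms ``±γ·∏(X_j + offset_j)^f_j``, optionally with
per-variable time lags, threshold regimes, and multiplicative noise hooks.
Dependent variables are advanced by the explicit recursion
``X̃_i = X_i + ϑ·F_i(X)`` (see :mod:`dbst.solver`); independent variables are
driven by event processes or held constant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Mapping, Optional, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .solver import HistoryBuffer
    from .stochastic import EventProcess, StochasticModifier

__all__ = [
    "VariableSpec",
    "PowerLawTerm",
    "Regime",
    "RegimeSet",
    "ModelSpec",
    "ModelValidationError",
    "PowerDomainError",
    "validate_model",
    "evaluate_term",
    "rhs",
]

#: Positivity floor used when base clamping is explicitly enabled.
DEFAULT_CLAMP_FLOOR = 1e-12

#: Tolerance for deciding whether a delay already sits on the ϑ grid.
DELAY_SNAP_TOL = 1e-9


class ModelValidationError(ValueError):
    """Raised when a model specification violates its structural contract.

    Carries the full list of violations in :attr:`violations`.
    """

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class PowerDomainError(ArithmeticError):
    """Fractional power of a non-positive base inside a term evaluation."""


@dataclass
class VariableSpec:
    """One model variable.

    Dependent variables own a term list in :attr:`ModelSpec.equations`;
    independent variables take their value from an event process or stay at
    ``initial_value``.
    """

    name: str
    role: str = "dependent"  # "dependent" | "independent"
    initial_value: float = 0.0
    description: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("dependent", "independent"):
            raise ValueError(f"unknown role {self.role!r} for variable {self.name!r}")


@dataclass
class PowerLawTerm:
    """One signed rate term ``sign·γ·∏(X_j + offset_j)^f_j``.

    Parameters
    ----------
    rate_constant
        Nonnegative multiplier γ. Signs live in :attr:`sign` (BST convention);
        a negative rate constant supplied by a user config is normalized by
        flipping the sign.
    exponents
        Kinetic orders, keyed by variable name. Negative orders encode
        inhibition; a zero order drops the variable from the product.
    sign
        +1 for production, -1 for consumption.
    delay
        Per-variable lag τ ≥ 0 (time units). A lagged variable is read from
        the history buffer at ``t - τ`` instead of the current state.
    noise_id
        Optional id of a :class:`~dbst.stochastic.StochasticModifier` whose
        per-step draw multiplies this term's flux.
    offset
        Per-variable additive constant applied before exponentiation, e.g.
        the ``(X + 1)^g`` device used to keep inhibition finite at ``X = 0``.
    """

    rate_constant: float
    exponents: dict[str, float] = field(default_factory=dict)
    sign: int = 1
    delay: dict[str, float] = field(default_factory=dict)
    noise_id: Optional[str] = None
    offset: dict[str, float] = field(default_factory=dict)


@dataclass
class Regime:
    """One branch of a threshold rule: term list active on an interval."""

    terms: list[PowerLawTerm]
    label: str = ""


@dataclass
class RegimeSet:
    """Threshold-switched equation for one dependent variable.

    The right-hand side of the variable switches between three term lists
    depending on where the switch variable ``s`` sits relative to two
    thresholds: ``below`` when ``s < low``, ``middle`` when ``low ≤ s ≤ high``
    (both boundaries belong to the middle regime), ``above`` when ``s > high``.
    Either threshold may be infinite, degenerating to a two- or one-regime
    rule.
    """

    switch_variable: str
    low: float
    high: float
    below: Regime
    middle: Regime
    above: Regime

    def active(self, switch_value: float) -> Regime:
        if switch_value < self.low:
            return self.below
        if switch_value > self.high:
            return self.above
        return self.middle

    @property
    def all_terms(self) -> list[PowerLawTerm]:
        return self.below.terms + self.middle.terms + self.above.terms


@dataclass
class ModelSpec:
    """A complete discrete power-law system."""

    name: str
    variables: list[VariableSpec]
    equations: dict[str, "list[PowerLawTerm] | RegimeSet"]
    step_size: float = 0.1
    event_processes: "list[EventProcess]" = field(default_factory=list)
    noise_modifiers: "list[StochasticModifier]" = field(default_factory=list)
    time_unit: str = "arbitrary"
    max_delay: Optional[float] = None
    clamp_nonpositive_bases: bool = False
    clamp_floor: float = DEFAULT_CLAMP_FLOOR
    metadata: dict = field(default_factory=dict)

    @property
    def dependent_names(self) -> list[str]:
        return [v.name for v in self.variables if v.role == "dependent"]

    @property
    def independent_names(self) -> list[str]:
        return [v.name for v in self.variables if v.role == "independent"]

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def initial_values(self) -> dict[str, float]:
        return {v.name: v.initial_value for v in self.variables}

    def terms_of(self, var: str) -> list[PowerLawTerm]:
        eq = self.equations[var]
        if isinstance(eq, RegimeSet):
            return eq.all_terms
        return list(eq)

    def largest_delay(self) -> float:
        lags = [0.0]
        for var in self.dependent_names:
            for term in self.terms_of(var):
                lags.extend(term.delay.values())
        return max(lags)


def _snap_delay(tau: float, theta: float, context: str, violations: list[str],
                strict: bool) -> float:
    """Round a lag to the nearest multiple of ϑ; complain if it moved."""
    steps = round(tau / theta)
    snapped = steps * theta
    if abs(snapped - tau) > DELAY_SNAP_TOL:
        msg = (f"{context}: delay {tau} is not a multiple of step size {theta}; "
               f"snapped to {snapped}")
        if strict:
            violations.append(msg)
        else:
            warnings.warn(msg, stacklevel=4)
    return snapped


def validate_model(spec: ModelSpec, strict: bool = False) -> ModelSpec:
    """Check structural invariants and return a normalized copy of *spec*.

    Normalization: negative rate constants folded into the sign, delays
    snapped to the ϑ grid (hard error in ``strict`` mode if snapping moves a
    delay). All violations are collected and raised together as a
    :class:`ModelValidationError`.
    """
    violations: list[str] = []
    names = [v.name for v in spec.variables]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        violations.append(f"duplicate variable names: {dupes}")
    for v in spec.variables:
        if not math.isfinite(v.initial_value):
            violations.append(f"variable {v.name!r}: initial_value not finite")
    if not spec.step_size > 0:
        violations.append(f"step_size must be positive, got {spec.step_size}")

    known = set(names)
    dep = set(spec.dependent_names)
    for var in dep:
        if var not in spec.equations:
            violations.append(f"dependent variable {var!r} has no equation")
    for var in spec.equations:
        if var not in dep:
            violations.append(f"equation for {var!r}, which is not a dependent variable")

    def check_terms(var: str, terms: list[PowerLawTerm]) -> list[PowerLawTerm]:
        if not terms:
            violations.append(f"equation for {var!r} has an empty term list")
        out = []
        for i, term in enumerate(terms):
            ctx = f"{var!r} term {i}"
            rate, sign = term.rate_constant, term.sign
            if rate < 0:  # normalize signed constants into the BST convention
                rate, sign = -rate, -sign
            if sign not in (1, -1):
                violations.append(f"{ctx}: sign must be ±1, got {term.sign}")
            if not math.isfinite(rate):
                violations.append(f"{ctx}: rate constant not finite")
            for ref in term.exponents:
                if ref not in known:
                    violations.append(f"{ctx}: exponent references unknown variable {ref!r}")
            for ref in list(term.delay) + list(term.offset):
                if ref not in known:
                    violations.append(f"{ctx}: delay/offset references unknown variable {ref!r}")
            new_delay = {}
            for ref, tau in term.delay.items():
                if tau < 0:
                    violations.append(f"{ctx}: negative delay for {ref!r}")
                    tau = 0.0
                new_delay[ref] = _snap_delay(tau, spec.step_size, ctx, violations, strict)
            out.append(replace(term, rate_constant=rate, sign=sign, delay=new_delay,
                               exponents=dict(term.exponents), offset=dict(term.offset)))
        return out

    new_equations: dict[str, "list[PowerLawTerm] | RegimeSet"] = {}
    for var, eq in spec.equations.items():
        if isinstance(eq, RegimeSet):
            if eq.switch_variable not in known:
                violations.append(
                    f"regimes of {var!r}: unknown switch variable {eq.switch_variable!r}")
            if not eq.low <= eq.high:
                violations.append(f"regimes of {var!r}: low threshold exceeds high")
            new_equations[var] = RegimeSet(
                switch_variable=eq.switch_variable, low=eq.low, high=eq.high,
                below=Regime(check_terms(var, eq.below.terms), eq.below.label),
                middle=Regime(check_terms(var, eq.middle.terms), eq.middle.label),
                above=Regime(check_terms(var, eq.above.terms), eq.above.label))
        else:
            new_equations[var] = check_terms(var, list(eq))

    horizon = spec.max_delay
    largest = ModelSpec(name=spec.name, variables=spec.variables,
                        equations=new_equations, step_size=spec.step_size).largest_delay()
    if horizon is not None and largest > horizon + DELAY_SNAP_TOL:
        violations.append(f"largest delay {largest} exceeds declared horizon {horizon}")

    noise_ids = {m.id for m in spec.noise_modifiers}
    for var in spec.equations:
        for term in (new_equations[var] if not isinstance(new_equations[var], RegimeSet)
                     else new_equations[var].all_terms):
            if term.noise_id is not None and term.noise_id not in noise_ids:
                violations.append(f"{var!r}: term references unknown noise id {term.noise_id!r}")
    for proc in spec.event_processes:
        if proc.target not in known:
            violations.append(f"event process targets unknown variable {proc.target!r}")
        elif proc.target in dep:
            violations.append(f"event process targets dependent variable {proc.target!r}")

    if violations:
        raise ModelValidationError(violations)
    return replace(spec, equations=new_equations,
                   max_delay=horizon if horizon is not None else largest)


def _resolve(var: str, term: PowerLawTerm, state: Mapping[str, float],
             t: float, history: "Optional[HistoryBuffer]") -> float:
    tau = term.delay.get(var, 0.0)
    if tau > 0.0 and history is not None:
        return history.lookup(var, t - tau)
    return state[var]


def evaluate_term(term: PowerLawTerm, state: Mapping[str, float],
                  t: float = 0.0,
                  history: "Optional[HistoryBuffer]" = None,
                  noise_draws: Optional[Mapping[str, float]] = None,
                  clamp: bool = False,
                  clamp_floor: float = DEFAULT_CLAMP_FLOOR) -> float:
    """Unsigned flux magnitude of one power-law term.

    Returns ``γ·∏(X_j + offset_j)^f_j`` with lagged values resolved through
    *history* and the term's noise draw (if any) multiplied in. The sign is
    applied by :func:`rhs`.

    Raises
    ------
    PowerDomainError
        If a non-integer kinetic order meets a non-positive base and clamping
        is off.
    """
    flux = term.rate_constant
    for var, order in term.exponents.items():
        if order == 0.0:
            continue
        base = _resolve(var, term, state, t, history) + term.offset.get(var, 0.0)
        if base <= 0.0:
            if order == int(order):
                if base == 0.0 and order < 0:
                    raise PowerDomainError(
                        f"zero base for negative power of {var!r} in term {term}")
            elif clamp:
                base = clamp_floor
            else:
                raise PowerDomainError(
                    f"fractional power {order} of non-positive base {base!r} "
                    f"for variable {var!r} in term {term}")
        try:
            flux *= base ** order
        except OverflowError:
            flux = math.inf  # surfaced as a step failure by the solver
    if term.noise_id is not None and noise_draws:
        flux *= noise_draws.get(term.noise_id, 1.0)
    return flux


def rhs(spec: ModelSpec, state: Mapping[str, float], t: float = 0.0,
        history: "Optional[HistoryBuffer]" = None,
        noise_draws: Optional[Mapping[str, float]] = None) -> np.ndarray:
    """Net change F_i for every dependent variable, in declaration order.

    *state* must hold current values for all variables, independent ones
    included (the solver keeps those updated from their event processes).
    For a threshold-switched equation only the active regime's terms
    contribute.
    """
    out = np.empty(len(spec.dependent_names))
    clamp, floor = spec.clamp_nonpositive_bases, spec.clamp_floor
    for i, var in enumerate(spec.dependent_names):
        eq = spec.equations[var]
        if isinstance(eq, RegimeSet):
            terms = eq.active(state[eq.switch_variable]).terms
        else:
            terms = eq
        acc = 0.0
        for term in terms:
            acc += term.sign * evaluate_term(term, state, t, history, noise_draws,
                                             clamp=clamp, clamp_floor=floor)
        out[i] = acc
    return out
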