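"""Fixed-step recursive solver for discrete power-law systems.

The engine advances every dependent variable by the explicit recursion

    X_i(t + ϑ) = X_i(t) + ϑ · F_i(X(t))

where F_i is the signed sum of the variable's power-law fluxes evaluated at
the *previous* grid state (and at lagged states for delayed terms). This is
the model definition, not a numerical approximation scheme: there is no
implicit or adaptive stepping. Independent variables are updated from their
event processes before each step; noise draws are taken before the step and
logged so that any stochastic run can be replayed exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import ModelSpec, ModelValidationError, rhs, validate_model
from .stochastic import apply_schedule, generate_renewal_events, state_coupled_event, substream

__all__ = [
    "HistoryBuffer",
    "Trajectory",
    "SimulationError",
    "step",
    "simulate",
    "lagged_state",
]


class SimulationError(RuntimeError):
    """A step produced a non-finite or domain-invalid value.

    Carries the partial :class:`Trajectory` accumulated so far in
    :attr:`trajectory` (``None`` when failing on the very first step).
    """

    def __init__(self, message: str, trajectory: "Optional[Trajectory]" = None):
        super().__init__(message)
        self.trajectory = trajectory


class HistoryBuffer:
    """Past states on the ϑ grid, for resolving lagged variable values.

    Before the start of the simulation the system is assumed to have sat at
    its initial state, so lookups at or before t₀ return initial values
    (constant pre-history).
    """

    def __init__(self, t0: float, theta: float, names: Sequence[str],
                 initial: Mapping[str, float]):
        self.t0 = float(t0)
        self.theta = float(theta)
        self.names = list(names)
        self._col = {n: i for i, n in enumerate(self.names)}
        self._states = [np.array([initial[n] for n in self.names], dtype=float)]

    def __len__(self) -> int:
        return len(self._states)

    def append(self, state: Mapping[str, float]) -> None:
        self._states.append(np.array([state[n] for n in self.names], dtype=float))

    def lookup(self, var: str, time: float) -> float:
        """Value of *var* at the grid point for *time* (initial value if ≤ t₀)."""
        q = round((time - self.t0) / self.theta)
        if q <= 0:
            q = 0
        if q >= len(self._states):
            raise KeyError(
                f"history lookup for {var!r} at t={time} is beyond the last "
                f"recorded grid point {self.t0 + (len(self._states) - 1) * self.theta}")
        return float(self._states[q][self._col[var]])


def lagged_state(history: HistoryBuffer, var: str, t: float, tau: float) -> float:
    """Value of *var* at ``t - tau`` under the constant pre-history policy."""
    if tau < 0:
        raise ValueError("lag must be nonnegative")
    return history.lookup(var, t - tau)


@dataclass
class Trajectory:
    """Time-indexed result of a simulation run."""

    times: np.ndarray
    states: np.ndarray  # rows = times, columns = variables
    columns: list[str]
    metadata: dict = field(default_factory=dict)
    event_log: list[dict] = field(default_factory=list)
    noise_log: list[dict] = field(default_factory=list)

    def value(self, var: str) -> np.ndarray:
        return self.states[:, self.columns.index(var)]

    def final_state(self) -> dict[str, float]:
        return dict(zip(self.columns, self.states[-1]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.columns)
        df.insert(0, "time", self.times)
        return df


def step(spec: ModelSpec, state: Mapping[str, float], history: Optional[HistoryBuffer],
         t: float, noise_draws: Optional[Mapping[str, float]] = None,
         theta: Optional[float] = None) -> dict[str, float]:
    """One explicit recursion step from the state at time *t*.

    Returns the full state at ``t + ϑ``; independent variables are carried
    over unchanged (the simulation loop owns their event processes). Raises
    :class:`SimulationError` if any updated value is non-finite.
    """
    h = spec.step_size if theta is None else theta
    f = rhs(spec, state, t, history, noise_draws)
    nxt = dict(state)
    for i, var in enumerate(spec.dependent_names):
        val = state[var] + h * f[i]
        if not math.isfinite(val):
            raise SimulationError(f"non-finite value for {var!r} at t={t + h}")
        nxt[var] = val
    return nxt


def simulate(spec: ModelSpec, t_end: float, seed: Optional[int] = None,
             t0: float = 0.0, record_every: int = 1,
             initial_state: Optional[Mapping[str, float]] = None,
             theta: Optional[float] = None,
             noise_override: Optional[Sequence[Mapping[str, float]]] = None,
             validate: bool = True) -> Trajectory:
    """Run the recursion from t₀ to at least *t_end*.

    Deterministic given ``(spec, seed)``: every stochastic mechanism draws
    from its own sub-stream keyed by the seed and the mechanism's id.
    ``record_every`` thins the stored rows without changing the stepping.
    ``noise_override`` replays previously logged per-step draw dictionaries
    instead of drawing fresh ones.

    Raises :class:`SimulationError` on a failed step; the exception carries
    the partial trajectory recorded so far.
    """
    if validate:
        spec = validate_model(spec)
    h = spec.step_size if theta is None else float(theta)
    if h <= 0:
        raise ValueError("step size must be positive")
    if not t_end > t0:
        raise ValueError("t_end must exceed t0")
    if record_every < 1:
        raise ValueError("record_every must be ≥ 1")
    n_steps = math.ceil((t_end - t0) / h - 1e-9)

    state = spec.initial_values()
    if initial_state:
        unknown = set(initial_state) - set(state)
        if unknown:
            raise ModelValidationError([f"initial_state has unknown variables {sorted(unknown)}"])
        state.update({k: float(v) for k, v in initial_state.items()})
    # the un-noised process value of each independent variable
    base_indep = {v: state[v] for v in spec.independent_names}

    event_log: list[dict] = []
    noise_log: list[dict] = []
    renewal_tables: dict[str, list[tuple[float, float]]] = {}
    proc_rngs = {}
    for proc in spec.event_processes:
        if proc.mode == "renewal":
            rng = substream(seed or 0, f"event:{proc.target}")
            renewal_tables[proc.target] = generate_renewal_events(
                proc.rate, t_end - t0,
                rng, proc.magnitude_mu, proc.magnitude_sigma, proc.magnitude_lower)
            for et, ev in renewal_tables[proc.target]:
                event_log.append({"t": t0 + et, "variable": proc.target,
                                  "value": ev, "kind": "renewal"})
        elif proc.mode == "state_coupled":
            proc_rngs[proc.target] = substream(seed or 0, f"event:{proc.target}")

    mod_rngs = {m.id: substream(seed or 0, f"noise:{m.id}") for m in spec.noise_modifiers}
    term_mods = [m for m in spec.noise_modifiers if m.target == "term"]
    var_mods = [m for m in spec.noise_modifiers if m.target == "variable"]
    current_draws: dict[str, float] = {}

    columns = spec.variable_names
    history = HistoryBuffer(t0, h, columns, state)
    rec_times = [t0]
    rec_states = [np.array([state[c] for c in columns])]

    def record(t: float) -> None:
        rec_times.append(t)
        rec_states.append(np.array([state[c] for c in columns]))

    def partial() -> Trajectory:
        return Trajectory(np.array(rec_times), np.vstack(rec_states), columns,
                          metadata=meta, event_log=event_log, noise_log=noise_log)

    meta = {"seed": seed, "theta": h, "t0": t0, "t_end": t_end,
            "model": spec.name, "record_every": record_every}

    for q in range(n_steps):
        t = t0 + q * h
        # events first: independent variables take their process value at t
        for proc in spec.event_processes:
            if proc.mode == "table":
                if proc.table and t >= proc.table[0][0]:
                    base_indep[proc.target] = apply_schedule(proc, t)
            elif proc.mode == "renewal":
                tbl = [e for e in renewal_tables[proc.target]]
                val = base_indep[proc.target]
                for et, ev in tbl:
                    if t0 + et <= t:
                        val = ev
                    else:
                        break
                base_indep[proc.target] = val
            else:  # state_coupled: Bernoulli trial against the current state
                new = state_coupled_event(state, proc, proc_rngs[proc.target])
                if new is not None:
                    base_indep[proc.target] = new
                    event_log.append({"t": t, "variable": proc.target,
                                      "value": new, "kind": "state_coupled"})

        # noise draws, taken before the step and logged for replay
        if noise_override is not None:
            current_draws = dict(noise_override[q])
        else:
            for m in term_mods + var_mods:
                if q % m.refresh == 0:
                    current_draws[m.id] = m.draw(mod_rngs[m.id])
        noise_log.append(dict(current_draws))

        for v in spec.independent_names:
            state[v] = base_indep[v]
        for m in var_mods:
            state[m.variable] = base_indep[m.variable] * current_draws[m.id]

        try:
            nxt = step(spec, state, history, t, current_draws, theta=h)
        except SimulationError as exc:
            raise SimulationError(str(exc), partial()) from None
        except ArithmeticError as exc:
            raise SimulationError(f"domain error at t={t}: {exc}", partial()) from None
        state.update(nxt)
        history.append(state)
        if (q + 1) % record_every == 0 or q == n_steps - 1:
            record(t0 + (q + 1) * h)

    return partial()
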