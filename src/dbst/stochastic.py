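"""Random mechanisms for discrete power-law simulations.

Four kinds of randomness appear in discrete biochemical models and are all
supported here:

* per-step jitter of a rate constant within ±f of its nominal value,
* multiplicative flux noise, e.g. N(1, 0.1) draws applied to transcription
  and translation fluxes,
* external inputs that switch at scheduled or renewal-process event times,
* state-coupled events, where the current state sets the firing probability
  and the magnitude distribution of an external input.

Every mechanism draws from a :class:`numpy.random.Generator`. The solver
gives each modifier and event process its own sub-stream derived from the
simulation seed and the modifier's id, so adding one mechanism never
perturbs the draws of another.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "StochasticModifier",
    "EventProcess",
    "substream",
    "sample_rate_jitter",
    "flux_noise_draw",
    "truncated_normal_draw",
    "generate_renewal_events",
    "apply_schedule",
    "state_coupled_event",
]


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent generator keyed by (seed, label).

    The stream depends only on the pair, never on what other streams exist,
    which keeps stochastic runs replayable when modifiers are added or
    removed.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + list(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class StochasticModifier:
    """A reusable noise source.

    ``distribution`` is one of:

    * ``"uniform_pm"`` — multiplier uniform on ``[1-fraction, 1+fraction]``
      (rate jitter within ±fraction of nominal),
    * ``"normal"`` — multiplier ~ N(mu, sigma),
    * ``"truncated_normal"`` — N(mu, sigma) resampled until ≥ ``lower``.

    ``target`` says what the draw multiplies: the flux of every term carrying
    this modifier's id (``"term"``), or the value of one independent variable
    each step (``"variable"``, with ``variable`` set).
    """

    id: str
    distribution: str = "normal"
    fraction: float = 0.0
    mu: float = 1.0
    sigma: float = 0.0
    lower: Optional[float] = None
    refresh: int = 1
    target: str = "term"  # "term" | "variable"
    variable: Optional[str] = None

    def __post_init__(self) -> None:
        if self.distribution not in ("uniform_pm", "normal", "truncated_normal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.distribution == "uniform_pm" and not 0.0 <= self.fraction < 1.0:
            raise ValueError("uniform_pm fraction must lie in [0, 1)")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.refresh < 1:
            raise ValueError("refresh must be a positive step count")
        if self.target == "variable" and not self.variable:
            raise ValueError("variable-targeted modifier needs a variable name")

    def draw(self, rng: np.random.Generator) -> float:
        if self.distribution == "uniform_pm":
            if self.fraction == 0.0:
                return 1.0
            return float(rng.uniform(1.0 - self.fraction, 1.0 + self.fraction))
        return flux_noise_draw(self, rng)


def sample_rate_jitter(nominal: float, fraction: float,
                       rng: np.random.Generator) -> float:
    """Uniform draw on ``[nominal(1-f), nominal(1+f)]``.

    Models a rate constant that varies stochastically within ±f of its
    nominal value, resampled at every iteration.
    """
    if nominal <= 0:
        raise ValueError(f"nominal rate must be positive, got {nominal}")
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must lie in [0, 1), got {fraction}")
    if fraction == 0.0:
        return nominal
    return float(rng.uniform(nominal * (1.0 - fraction), nominal * (1.0 + fraction)))


def flux_noise_draw(modifier: StochasticModifier, rng: np.random.Generator) -> float:
    """One multiplier from a normal / truncated-normal modifier."""
    if modifier.sigma == 0.0:
        return modifier.mu
    if modifier.distribution == "truncated_normal" and modifier.lower is not None:
        return truncated_normal_draw(modifier.mu, modifier.sigma, modifier.lower, rng)
    return float(rng.normal(modifier.mu, modifier.sigma))


def truncated_normal_draw(mu: float, sigma: float, lower: float,
                          rng: np.random.Generator,
                          max_tries: int = 10_000) -> float:
    """N(mu, sigma) conditioned on being ≥ lower, by resampling.

    Resampling (rather than clipping) avoids a point mass at the bound.
    ``sigma = 0`` degenerates to the point mass at ``max(mu, lower)``.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0.0:
        return max(mu, lower)
    for _ in range(max_tries):
        x = float(rng.normal(mu, sigma))
        if x >= lower:
            return x
    raise RuntimeError("truncated normal rejection sampling failed "
                       f"(mu={mu}, sigma={sigma}, lower={lower})")


@dataclass
class EventProcess:
    """Driver for one independent variable.

    Modes
    -----
    ``table``
        A priori known schedule: list of ``(time, value)`` pairs, applied
        step-and-hold (the value of the latest entry with time ≤ t).
    ``renewal``
        Event times from an exponential renewal process with rate ``rate``;
        at each event the variable jumps to a fresh magnitude drawn from
        N(``magnitude_mu``, ``magnitude_sigma``) truncated below at
        ``magnitude_lower`` (concentrations cannot go negative). The value
        holds between events.
    ``state_coupled``
        Each step, a Bernoulli trial with success probability
        ``clamp(state[probability_variable], 0, 1)`` decides whether an event
        fires; on success the variable jumps to a truncated-normal draw with
        mean ``magnitude_mu`` and a standard deviation read from
        ``sd_variable``'s current value.
    """

    target: str
    mode: str = "table"
    table: list[tuple[float, float]] = field(default_factory=list)
    rate: float = 0.0
    magnitude_mu: float = 0.5
    magnitude_sigma: float = 0.25
    magnitude_lower: float = 0.0
    probability_variable: Optional[str] = None
    sd_variable: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("table", "renewal", "state_coupled"):
            raise ValueError(f"unknown event mode {self.mode!r}")
        if self.mode == "table":
            times = [t for t, _ in self.table]
            if times != sorted(times) or len(set(times)) != len(times):
                raise ValueError("table times must be strictly increasing")
        if self.mode == "renewal" and not self.rate > 0:
            raise ValueError("renewal rate must be positive")
        if self.mode == "state_coupled" and not self.probability_variable:
            raise ValueError("state_coupled process needs a probability variable")


def apply_schedule(process: EventProcess, t: float) -> float:
    """Step-and-hold lookup: value of the latest table entry with time ≤ t."""
    if not process.table:
        raise ValueError("schedule table is empty")
    times = [e[0] for e in process.table]
    idx = bisect.bisect_right(times, t) - 1
    if idx < 0:
        raise ValueError(f"t={t} precedes first scheduled event at {times[0]}")
    return process.table[idx][1]


def generate_renewal_events(rate: float, t_end: float, rng: np.random.Generator,
                            magnitude_mu: float = 0.5,
                            magnitude_sigma: float = 0.25,
                            magnitude_lower: float = 0.0,
                            ) -> list[tuple[float, float]]:
    """Events of an exponential renewal process on ``(0, t_end]``.

    Inter-arrival times are Exp(rate); the cumulative sums are the event
    times. Each event carries a magnitude drawn from
    N(magnitude_mu, magnitude_sigma) truncated below at ``magnitude_lower``.
    """
    if rate <= 0 or t_end <= 0:
        raise ValueError("rate and t_end must be positive")
    events: list[tuple[float, float]] = []
    t = 0.0
    while True:
        t += float(rng.exponential(1.0 / rate))
        if t > t_end:
            break
        mag = truncated_normal_draw(magnitude_mu, magnitude_sigma,
                                    magnitude_lower, rng)
        events.append((t, mag))
    return events


def state_coupled_event(state: Mapping[str, float], process: EventProcess,
                        rng: np.random.Generator) -> Optional[float]:
    """One Bernoulli-gated event draw; ``None`` when the trial fails.

    The success probability is the probability variable's current value
    clamped to [0, 1]. On success the new value is a truncated normal whose
    standard deviation is read from the state (``sd_variable``); a
    non-positive standard deviation degenerates to the point mass at the
    mean.
    """
    p = float(np.clip(state[process.probability_variable], 0.0, 1.0))
    if p == 0.0 or rng.random() >= p:
        return None
    sigma = state[process.sd_variable] if process.sd_variable else process.magnitude_sigma
    if sigma <= 0.0:
        return max(process.magnitude_mu, process.magnitude_lower)
    return truncated_normal_draw(process.magnitude_mu, float(sigma),
                                 process.magnitude_lower, rng)
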