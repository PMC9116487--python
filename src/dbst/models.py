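"""Packaged model fixtures and the synthetic-data generator.

Every worked example ships here as a parameterized builder returning a
validated :class:`~dbst.model.ModelSpec`:

* :func:`linear_pathway` — two-variable linear pathway with constant input
  and a power-law conversion step; its steady state is known in closed form.
* :func:`limit_cycle_oscillator` — two-variable power-law oscillator with a
  stable limit cycle.
* :func:`lorenz_discrete` — a discrete power-law rendition of the Lorenz
  convection system, exhibiting deterministic chaos at ϑ = 1.
* :func:`lac_operon` — S-system model of lac operon induction by external
  lactose, with scheduled, renewal, threshold-switched and state-coupled
  input variants.
* :func:`ahr_model` — aryl-hydrocarbon receptor signal transduction with
  transcription/translation delays and multiplicative noise.
* :func:`branched_pathway_truth` / :func:`branched_pathway_template` — the
  four-variable branched pathway used as the estimation benchmark.
"""

from __future__ import annotations

import math
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .estimation import CompiledModel, FitParameter, ObservedSeries
from .model import ModelSpec, PowerLawTerm, Regime, RegimeSet, VariableSpec, validate_model
from .solver import simulate
from .stochastic import EventProcess, StochasticModifier

__all__ = [
    "linear_pathway",
    "limit_cycle_oscillator",
    "lorenz_discrete",
    "lac_operon",
    "ahr_model",
    "AHR_RATE_CONSTANTS",
    "branched_pathway_template",
    "branched_pathway_truth",
    "BRANCHED_TRUTH",
    "branched_fit_parameters",
    "generate_synthetic_timeseries",
    "MODEL_CATALOG",
    "build_catalog_model",
]


def linear_pathway(x0: float = 1.0, r: float = 1.75, theta: float = 0.5,
                   input_step: Optional[tuple[float, float]] = None,
                   rate_jitter: float = 0.0) -> ModelSpec:
    """Two-variable linear pathway: constant input 2·X0, conversion r·X1^0.8,
    efflux 2.5·X2^0.5.

    ``input_step=(t, v)`` schedules a persistent switch of the input X0 to
    *v* at time *t*. ``rate_jitter=f`` makes the conversion rate *r* vary
    uniformly within ±f of nominal, redrawn every step (the same draw is
    applied to both fluxes sharing the rate).
    """
    events = []
    if input_step is not None:
        t_sw, v_sw = input_step
        events.append(EventProcess(target="X0", mode="table",
                                   table=[(0.0, x0), (float(t_sw), float(v_sw))]))
    modifiers = []
    noise_id = None
    if rate_jitter > 0:
        noise_id = "r_jitter"
        modifiers.append(StochasticModifier(id=noise_id, distribution="uniform_pm",
                                            fraction=rate_jitter))
    conv = dict(rate_constant=r, exponents={"X1": 0.8}, noise_id=noise_id)
    spec = ModelSpec(
        name="linear_pathway",
        variables=[
            VariableSpec("X0", "independent", x0, "constant pathway input"),
            VariableSpec("X1", "dependent", 1.18, "intermediate"),
            VariableSpec("X2", "dependent", 0.64, "product pool"),
        ],
        equations={
            "X1": [PowerLawTerm(2.0, {"X0": 1.0}, sign=+1),
                   PowerLawTerm(sign=-1, **conv)],
            "X2": [PowerLawTerm(sign=+1, **conv),
                   PowerLawTerm(2.5, {"X2": 0.5}, sign=-1)],
        },
        step_size=theta,
        event_processes=events,
        noise_modifiers=modifiers,
    )
    return validate_model(spec)


def limit_cycle_oscillator(theta: float = 0.1,
                           initial: Sequence[float] = (0.7249193, 0.8685822)) -> ModelSpec:
    """Two-variable power-law oscillator with a stable limit cycle.

    Initial states inside the cycle spiral outward, states outside spiral
    inward; the default initial state sits essentially on the cycle.
    """
    x1, x2 = initial
    spec = ModelSpec(
        name="limit_cycle_oscillator",
        variables=[VariableSpec("X1", "dependent", x1),
                   VariableSpec("X2", "dependent", x2)],
        equations={
            "X1": [PowerLawTerm(0.011, {"X1": 2.0, "X2": 3.0}, sign=+1),
                   PowerLawTerm(0.011, {"X1": 1.0, "X2": 1.0}, sign=-1)],
            "X2": [PowerLawTerm(0.01, {"X1": -1.0, "X2": 4.0}, sign=+1),
                   PowerLawTerm(0.01, {"X1": 3.0, "X2": 5.0}, sign=-1)],
        },
        step_size=theta,
    )
    return validate_model(spec)


def lorenz_discrete(theta: float = 1.0,
                    initial: Sequence[float] = (10.0, 10.0, 30.0)) -> ModelSpec:
    """Discrete power-law form of the Lorenz convection system (chaotic at ϑ=1)."""
    x1, x2, x3 = initial
    spec = ModelSpec(
        name="lorenz_discrete",
        variables=[VariableSpec("X1", "dependent", x1),
                   VariableSpec("X2", "dependent", x2),
                   VariableSpec("X3", "dependent", x3)],
        equations={
            "X1": [PowerLawTerm(0.2, {"X2": 1.0}, sign=+1),
                   PowerLawTerm(0.2, {"X1": 1.0}, sign=-1)],
            "X2": [PowerLawTerm(0.6, {"X1": 1.0}, sign=+1),
                   PowerLawTerm(0.02, {"X2": 1.0}, sign=-1),
                   PowerLawTerm(0.02, {"X1": 1.0, "X3": 1.0}, sign=-1)],
            "X3": [PowerLawTerm(0.02, {"X1": 1.0, "X2": 1.0}, sign=+1),
                   PowerLawTerm(0.05, {"X3": 1.0}, sign=-1)],
        },
        step_size=theta,
    )
    return validate_model(spec)


#: A priori known stimulus schedule for the lac operon demonstrations.
LAC_SCHEDULE: list[tuple[float, float]] = [
    (0.0, 0.1), (10.0, 1.0), (60.0, 0.5), (110.0, 0.1),
    (160.0, 1.2), (210.0, 0.4), (260.0, 1.0), (310.0, 0.1),
]

#: Threshold-regime constants for the `piecewise` lac operon variant.
#: The thresholds are NOT part of the published model (no numeric values were
#: given); they are package choices straddling the base steady state's
#: internal lactose level, with the low/high rate constants chosen so the
#: transcription rate law is continuous at both boundaries.
LAC_THRESHOLDS = {
    "X3_low": 0.3,
    "X3_high": 0.7,
    "alpha_low": 0.2 * 0.3 ** 2,   # continuity: α1L = α1·X3L^g13
    "alpha_high": 0.2 * 0.7 ** 2,  # continuity: α1H = α1·X3H^g13
}


def lac_operon(variant: str = "base", theta: float = 0.1) -> ModelSpec:
    """S-system lac operon model driven by external lactose X4.

    X1 = lac mRNA, X2 = β-galactosidase, X3 = intracellular lactose,
    X4 = external lactose (independent). Variants:

    * ``base`` — X4 constant at 0.1; the system starts at its steady state.
    * ``scheduled`` — X4 follows the a priori known switch schedule.
    * ``renewal`` — X4 switches at exponential renewal times (rate 1/60)
      to truncated-normal magnitudes N(0.5, 0.25) ≥ 0.
    * ``piecewise`` — the mRNA equation switches between low/saturated/high
      transcription regimes on internal lactose thresholds, under the
      scheduled stimulus.
    * ``state_coupled`` — each step a Bernoulli trial with success
      probability clamp(X3, 0, 1) resets X4 to a truncated-normal draw with
      mean 0.5 and standard deviation equal to the current X1.
    """
    x4 = 0.1
    x3 = x4 ** (1.0 / 3.0)
    x1, x2 = 2.0 * x3 ** 2, x3 ** 2
    events: list[EventProcess] = []
    if variant in ("scheduled", "piecewise"):
        events.append(EventProcess("X4", "table", table=list(LAC_SCHEDULE)))
    elif variant == "renewal":
        events.append(EventProcess("X4", "renewal", rate=1.0 / 60.0,
                                   magnitude_mu=0.5, magnitude_sigma=0.25,
                                   magnitude_lower=0.0))
    elif variant == "state_coupled":
        events.append(EventProcess("X4", "state_coupled",
                                   probability_variable="X3", magnitude_mu=0.5,
                                   sd_variable="X1", magnitude_lower=0.0))
    elif variant != "base":
        raise ValueError(f"unknown lac operon variant {variant!r}")

    mrna_production = PowerLawTerm(0.2, {"X3": 2.0}, sign=+1)
    mrna_decay = PowerLawTerm(0.1, {"X1": 1.0}, sign=-1)
    if variant == "piecewise":
        thr = LAC_THRESHOLDS
        x1_eq: "list[PowerLawTerm] | RegimeSet" = RegimeSet(
            switch_variable="X3", low=thr["X3_low"], high=thr["X3_high"],
            below=Regime([PowerLawTerm(thr["alpha_low"], {}, sign=+1), mrna_decay],
                         label="low transcription"),
            middle=Regime([mrna_production, mrna_decay], label="lactose-responsive"),
            above=Regime([PowerLawTerm(thr["alpha_high"], {}, sign=+1), mrna_decay],
                         label="saturated transcription"))
    else:
        x1_eq = [mrna_production, mrna_decay]

    spec = ModelSpec(
        name=f"lac_operon_{variant}",
        variables=[
            VariableSpec("X1", "dependent", x1, "lac operon mRNA"),
            VariableSpec("X2", "dependent", x2, "beta-galactosidase"),
            VariableSpec("X3", "dependent", x3, "intracellular lactose"),
            VariableSpec("X4", "independent", x4, "external lactose"),
        ],
        equations={
            "X1": x1_eq,
            "X2": [PowerLawTerm(0.5, {"X1": 1.0}, sign=+1),
                   PowerLawTerm(1.0, {"X2": 1.0}, sign=-1)],
            "X3": [PowerLawTerm(0.1, {"X4": 1.0}, sign=+1),
                   PowerLawTerm(0.1, {"X2": 1.0, "X3": 1.0}, sign=-1)],
        },
        step_size=theta,
        event_processes=events,
        metadata={"thresholds": dict(LAC_THRESHOLDS)} if variant == "piecewise" else {},
    )
    return validate_model(spec)


#: Rate constants k1..k13 of the AhR signal transduction model, time roughly
#: in hours. Process assignment: k1/k2 ligand binding/unbinding, k3/k4
#: transcription-factor assembly/dissociation, k5/k6 repressor-complex
#: assembly/dissociation, k7/k8 protein turnover (AhRR, TP), k9/k10 mRNA
#: turnover, k11/k12 translation, k13 transcription (shared by both genes).
AHR_RATE_CONSTANTS = (1.0, 2.0, 1.0, 1.0, 1.0, 2.0, 2.0, 2.0,
                      10.0, 10.0, 10.0, 10.0, 6.0)
AHR_G = -4.0     # kinetic order of repression by the AhRR·ARNT complex
AHR_TAU1 = 3.0   # transcription delay, hours
AHR_TAU2 = 4.0   # translation/activation delay, hours

#: Variable roles. X6 (the AhRR·ARNT complex) is the transcriptional
#: repressor, entering transcription as (X6+1)^g so repression stays finite
#: at X6 = 0. X7 and X8 (the two mRNAs) share rate constants and therefore
#: identical dynamics in the deterministic scenarios.
AHR_ROLES = {
    "L": "xenobiotic ligand (independent, scheduled)",
    "X1": "free AhR",
    "X2": "ligand-bound AhR",
    "X3": "free ARNT",
    "X4": "AhR·L·ARNT transcription factor",
    "X5": "AhRR repressor protein",
    "X6": "AhRR·ARNT repressor complex",
    "X7": "AhRR mRNA",
    "X8": "target-protein mRNA",
    "X9": "target protein (TP)",
}

AHR_SCENARIOS = ("no_delay_no_noise", "delays_only", "delays_and_noise")


def ahr_model(scenario: str = "delays_only", theta: float = 0.1,
              ligand_on: float = 2.0, ligand_off: float = 12.0,
              ligand_level: float = 2.0) -> ModelSpec:
    """AhR signal transduction with delays and stochastic gene expression.

    Ligand binds free AhR; the bound receptor recruits ARNT into a
    transcription factor that drives expression of AhRR and of a
    representative target protein. AhRR in turn sequesters ARNT into a
    repressor complex that shuts transcription down — a delayed negative
    feedback loop. Scenarios:

    * ``no_delay_no_noise`` — the instantaneous deterministic skeleton.
    * ``delays_only`` — transcription lagged by τ₁ = 3 h, translation by a
      further τ₂ = 4 h.
    * ``delays_and_noise`` — additionally, transcription and translation
      fluxes are multiplied by N(1, 0.1) draws (σ₁…σ₄) and ligand
      availability fluctuates multiplicatively with the same distribution.

    The ligand-free initial state (10, 0, 10, 0, …, 0) is a fixed point of
    the deterministic equations; construction fails if this invariant is
    ever broken.
    """
    if scenario not in AHR_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; pick one of {AHR_SCENARIOS}")
    k = AHR_RATE_CONSTANTS
    k1, k2, k3, k4, k5, k6, k7, k8, k9, k10, k11, k12, k13 = k
    delays = scenario != "no_delay_no_noise"
    noise = scenario == "delays_and_noise"

    d_tx = {"X4": AHR_TAU1, "X6": AHR_TAU1} if delays else {}
    d_tl7 = {"X7": AHR_TAU2} if delays else {}
    d_tl8 = {"X8": AHR_TAU2} if delays else {}

    modifiers = []
    sid = {i: None for i in range(1, 5)}
    if noise:
        for i in range(1, 5):
            sid[i] = f"sigma{i}"
            modifiers.append(StochasticModifier(id=f"sigma{i}", distribution="normal",
                                                mu=1.0, sigma=0.1))
        modifiers.append(StochasticModifier(id="ligand_noise", distribution="normal",
                                            mu=1.0, sigma=0.1, target="variable",
                                            variable="L"))

    inhib = {"X6": AHR_G}
    offs = {"X6": 1.0}
    equations = {
        "X1": [PowerLawTerm(k1, {"L": 1.0, "X1": 1.0}, sign=-1),
               PowerLawTerm(k2, {"X2": 1.0}, sign=+1)],
        "X2": [PowerLawTerm(k1, {"L": 1.0, "X1": 1.0}, sign=+1),
               PowerLawTerm(k2, {"X2": 1.0}, sign=-1),
               PowerLawTerm(k3, {"X2": 1.0, "X3": 1.0}, sign=-1),
               PowerLawTerm(k4, {"X4": 1.0}, sign=+1)],
        "X3": [PowerLawTerm(k3, {"X2": 1.0, "X3": 1.0}, sign=-1),
               PowerLawTerm(k4, {"X4": 1.0}, sign=+1),
               PowerLawTerm(k5, {"X3": 1.0, "X5": 1.0}, sign=-1),
               PowerLawTerm(k6, {"X6": 1.0}, sign=+1)],
        "X4": [PowerLawTerm(k3, {"X2": 1.0, "X3": 1.0}, sign=+1),
               PowerLawTerm(k4, {"X4": 1.0}, sign=-1)],
        "X5": [PowerLawTerm(k11, {"X7": 1.0}, sign=+1, delay=d_tl7, noise_id=sid[3]),
               PowerLawTerm(k5, {"X3": 1.0, "X5": 1.0}, sign=-1),
               PowerLawTerm(k6, {"X6": 1.0}, sign=+1),
               PowerLawTerm(k7, {"X5": 1.0}, sign=-1)],
        "X6": [PowerLawTerm(k5, {"X3": 1.0, "X5": 1.0}, sign=+1),
               PowerLawTerm(k6, {"X6": 1.0}, sign=-1)],
        "X7": [PowerLawTerm(k13, {"X4": 1.0, **inhib}, sign=+1, delay=d_tx,
                            offset=dict(offs), noise_id=sid[1]),
               PowerLawTerm(k9, {"X7": 1.0}, sign=-1)],
        "X8": [PowerLawTerm(k13, {"X4": 1.0, **inhib}, sign=+1, delay=dict(d_tx),
                            offset=dict(offs), noise_id=sid[2]),
               PowerLawTerm(k10, {"X8": 1.0}, sign=-1)],
        "X9": [PowerLawTerm(k12, {"X8": 1.0}, sign=+1, delay=d_tl8, noise_id=sid[4]),
               PowerLawTerm(k8, {"X9": 1.0}, sign=-1)],
    }
    init = (10.0, 0.0, 10.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    variables = [VariableSpec("L", "independent", 0.0, AHR_ROLES["L"])]
    variables += [VariableSpec(f"X{i}", "dependent", init[i - 1], AHR_ROLES[f"X{i}"])
                  for i in range(1, 10)]
    spec = ModelSpec(
        name=f"ahr_{scenario}",
        variables=variables,
        equations=equations,
        step_size=theta,
        event_processes=[EventProcess("L", "table",
                                      table=[(0.0, 0.0), (float(ligand_on), ligand_level),
                                             (float(ligand_off), 0.0)])],
        noise_modifiers=modifiers,
        time_unit="hours (approximate)",
        metadata={"scenario": scenario, "tau1": AHR_TAU1, "tau2": AHR_TAU2, "g": AHR_G},
    )
    spec = validate_model(spec)
    _check_ligand_free_fixed_point(spec)
    return spec


def _check_ligand_free_fixed_point(spec: ModelSpec, tol: float = 1e-10) -> None:
    from .model import rhs  # local import to keep module load order simple
    state = spec.initial_values()
    state["L"] = 0.0
    f = rhs(spec, state)
    if float(np.max(np.abs(f))) >= tol:
        raise AssertionError(
            "AhR fixture: the ligand-free initial state is not a fixed point "
            f"of the transcribed equations (‖F‖∞ = {np.max(np.abs(f)):.3e})")


#: Parameters used to generate the estimation benchmark data.
BRANCHED_TRUTH: dict[str, float] = {
    "a1": 0.25, "b1": 0.08, "b2": 0.2, "b3": 0.3, "c1": 0.15, "c2": 0.25,
    "g1": -2.0, "h11": 1.0, "h12": 2.0, "h13": 0.5,
    "h2": 0.4, "h3": 0.6, "h4": 0.8,
}


def branched_pathway_template(params: Mapping[str, float], theta: float = 1.0,
                              include_x0: bool = False,
                              include_d1: bool = False,
                              initial_state: Sequence[float] = (1.0, 1.0, 1.0, 1.0),
                              ) -> ModelSpec:
    """Branched pathway with feedback inhibition of the influx by X3.

    X1 splits into a chain X1→X2→X3 (with X3 feedback-inhibiting the influx,
    kinetic order g1 < 0) and a branch X1→X4 activated by X3. The optional
    ``include_x0`` multiplies the influx by a constant input X0; the optional
    ``include_d1`` adds an extra first-order drain d1·X1 — both are flagged
    extensions that are *off* by default because they are structurally
    redundant with a1/b1 and essentially non-identifiable from data.
    """
    p = dict(params)
    x1_terms = [
        PowerLawTerm(p["a1"], ({"X0": 1.0} if include_x0 else {}) | {"X3": p["g1"]}, sign=+1),
        PowerLawTerm(p["b1"], {"X1": p["h11"]}, sign=-1),
        PowerLawTerm(p["c1"], {"X1": p["h12"], "X3": p["h13"]}, sign=-1),
    ]
    if include_d1:
        x1_terms.append(PowerLawTerm(p["d1"], {"X1": 1.0}, sign=-1))
    variables = [VariableSpec(f"X{i}", "dependent", float(initial_state[i - 1]))
                 for i in range(1, 5)]
    if include_x0:
        variables.append(VariableSpec("X0", "independent", p.get("X0", 1.0)))
    spec = ModelSpec(
        name="branched_pathway",
        variables=variables,
        equations={
            "X1": x1_terms,
            "X2": [PowerLawTerm(p["b1"], {"X1": p["h11"]}, sign=+1),
                   PowerLawTerm(p["b2"], {"X2": p["h2"]}, sign=-1)],
            "X3": [PowerLawTerm(p["b2"], {"X2": p["h2"]}, sign=+1),
                   PowerLawTerm(p["b3"], {"X3": p["h3"]}, sign=-1)],
            "X4": [PowerLawTerm(p["c1"], {"X1": p["h12"], "X3": p["h13"]}, sign=+1),
                   PowerLawTerm(p["c2"], {"X4": p["h4"]}, sign=-1)],
        },
        step_size=theta,
    )
    return spec


def branched_pathway_truth(theta: float = 1.0) -> ModelSpec:
    """The branched pathway at the data-generating parameter values."""
    return validate_model(branched_pathway_template(BRANCHED_TRUTH, theta=theta))


def branched_fit_parameters() -> list[FitParameter]:
    """Search space for the branched-pathway fit.

    Rate constants are searched log-uniformly over a generic kinetic range;
    kinetic orders start from sign-informed intervals (the feedback order g1
    is known to be inhibitory from the pathway diagram) within hard bounds
    of [-5, 5].
    """
    rates = [FitParameter(n, lower=1e-4, upper=50.0, init_low=0.02, init_high=1.0,
                          log_scale=True)
             for n in ("a1", "b1", "b2", "b3", "c1", "c2")]
    orders = [
        FitParameter("g1", init_low=-3.0, init_high=-0.5),
        FitParameter("h11", init_low=0.3, init_high=2.0),
        FitParameter("h12", init_low=0.5, init_high=3.0),
        FitParameter("h13", init_low=0.1, init_high=1.5),
        FitParameter("h2", init_low=0.2, init_high=1.5),
        FitParameter("h3", init_low=0.2, init_high=1.5),
        FitParameter("h4", init_low=0.2, init_high=1.5),
    ]
    return rates + orders


def generate_synthetic_timeseries(spec: ModelSpec, t_grid: Sequence[float],
                                  noise_fraction: float = 0.0,
                                  seed: Optional[int] = None,
                                  generator: str = "recursion",
                                  initial_state: Optional[Mapping[str, float]] = None,
                                  ) -> ObservedSeries:
    """Sample a trajectory of *spec* at the observation grid *t_grid*.

    ``generator="recursion"`` runs the model's own fixed-step recursion and
    samples it at the grid (grid times must sit on the ϑ grid).
    ``generator="fine_grid_reference"`` integrates the deterministic,
    delay-free skeleton of the model as an ODE system with a high-accuracy
    adaptive solver — the benchmark case where data originate from a
    continuous-time process and the discrete model is fitted to them.

    ``noise_fraction`` adds multiplicative Gaussian noise (resampled until
    positive) on top of either generator; the seed controls both the
    simulation sub-streams and the observation noise.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2:
        raise ValueError("t_grid must contain at least two times")
    dep = spec.dependent_names
    if generator == "recursion":
        traj = simulate(spec, t_end=float(t_grid[-1]), seed=seed,
                        initial_state=initial_state)
        theta = spec.step_size
        idx = np.round((t_grid - traj.times[0]) / theta).astype(int)
        if np.any(np.abs(traj.times[idx] - t_grid) > 1e-9):
            raise ValueError("t_grid times must lie on the recursion grid")
        cols = [traj.columns.index(v) for v in dep]
        values = traj.states[np.ix_(idx, cols)]
    elif generator == "fine_grid_reference":
        from scipy.integrate import solve_ivp
        compiled = CompiledModel(spec)
        init = spec.initial_values()
        if initial_state:
            init.update(initial_state)
        y0 = np.array([init[v] for v in dep])

        def odef(_t: float, y: np.ndarray) -> np.ndarray:
            return compiled.net_change(y[None, :])[0]

        sol = solve_ivp(odef, (float(t_grid[0]), float(t_grid[-1])), y0,
                        t_eval=t_grid, rtol=1e-9, atol=1e-11, method="RK45")
        if not sol.success:
            raise RuntimeError(f"reference integration failed: {sol.message}")
        values = sol.y.T
    else:
        raise ValueError(f"unknown generator {generator!r}")

    if noise_fraction > 0:
        rng = np.random.default_rng(np.random.SeedSequence(
            [int(seed or 0) & 0x7FFFFFFF, 0x6E6F6973]))  # observation-noise stream
        mult = rng.normal(1.0, noise_fraction, size=values.shape)
        for _ in range(100):
            bad = mult <= 0
            if not bad.any():
                break
            mult[bad] = rng.normal(1.0, noise_fraction, size=int(bad.sum()))
        values = values * mult

    init_used = {**spec.initial_values(), **(initial_state or {})}
    return ObservedSeries(t_grid, values, dep,
                          metadata={"model": spec.name, "seed": seed,
                                    "generator": generator,
                                    "noise_fraction": noise_fraction,
                                    "initial_state": {v: init_used[v] for v in dep}})


#: Name → (builder, kwargs-schema description) registry for the CLI.
MODEL_CATALOG: dict[str, Callable[..., ModelSpec]] = {
    "linear_pathway": linear_pathway,
    "limit_cycle_oscillator": limit_cycle_oscillator,
    "lorenz_discrete": lorenz_discrete,
    "lac_operon": lac_operon,
    "ahr": ahr_model,
    "branched_pathway": branched_pathway_truth,
}


def build_catalog_model(name: str, **kwargs) -> ModelSpec:
    if name not in MODEL_CATALOG:
        known = ", ".join(sorted(MODEL_CATALOG))
        raise KeyError(f"unknown model {name!r}; available models: {known}")
    return MODEL_CATALOG[name](**kwargs)
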