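"""Random-mutation hill climbing for models and informative tests.

Model evolution perturbs the free parameters of each string (rest length and
cross-section) with the bounded multiplicative-step mutation law

    c_new = c +/- (c_U - c_L) * exp(R1 + r * R2),   r ~ U[0, 1],

with R1 = -8 and R2 = 9, so realised step magnitudes range from
3.35e-4 (c_U - c_L) to 2.72 (c_U - c_L) before clamping into [c_L, c_U].
Each parameter mutates independently with probability ``p_rate`` (default
8%); a small rate keeps the hill climber from degenerating into random
search.  Two auxiliary regimes reshape the search: *fine* proposals restrict
steps to <1% of the range at five times the rate, *coarse* proposals to >20%
of the range at a fifth of the rate.

Acceptance is strictly better-than for models (lower training error) and
strictly higher-than for tests (larger across-model disagreement), so the
accepted-error trace of any model is non-increasing and the accepted e_test
trace non-decreasing by construction.  Termination follows the counter
scheme: a favourable change anywhere resets the stagnation counter G and
increments the favourable counter G_L; evolution stops when G > 2 G_L with
G >= G_min, when a hard iteration limit is reached, or when every model is
below the training-error threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .fitness import (_training_error_many, _training_error_value,
                      test_informativeness)
from .network import F_LOWER, F_UPPER, LoadSetDatabase, Mesh
from .solver import DEFAULT_SOLVER, SolverConfig, TrussSystem

__all__ = [
    "MutationSpec",
    "EvolutionCounters",
    "TestCandidate",
    "HillClimbResult",
    "InformativeTestResult",
    "mutate_parameter",
    "mutate_model",
    "hill_climb",
    "evolve_informative_test",
    "extract_topology",
    "rmhc_minimize",
]

STRATEGIES = ("standard", "fine", "coarse")
_FINE_STEP_FRAC = 0.01
_COARSE_STEP_FRAC = 0.20


@dataclass(frozen=True)
class MutationSpec:
    R1: float = -8.0
    R2: float = 9.0
    p_rate: float = 0.08
    fine_rate_multiplier: float = 5.0
    coarse_rate_multiplier: float = 0.2
    # per-proposal probability of choosing the standard/fine/coarse regime
    strategy_weights: tuple[float, float, float] = (0.6, 0.3, 0.1)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_rate < 0.15):
            raise ValueError("p_rate must lie in (0, 0.15)")
        if abs(sum(self.strategy_weights) - 1.0) > 1e-9:
            raise ValueError("strategy weights must sum to 1")

    def rate(self, strategy: str) -> float:
        if strategy == "fine":
            return min(1.0, self.fine_rate_multiplier * self.p_rate)
        if strategy == "coarse":
            return self.coarse_rate_multiplier * self.p_rate
        return self.p_rate

    def r_window(self, strategy: str) -> tuple[float, float]:
        """Admissible range of the uniform draw r for each step regime."""
        if strategy == "standard":
            return (0.0, 1.0)
        if strategy == "fine":
            hi = (math.log(_FINE_STEP_FRAC) - self.R1) / self.R2
            return (0.0, min(1.0, max(0.0, hi)))
        if strategy == "coarse":
            lo = (math.log(_COARSE_STEP_FRAC) - self.R1) / self.R2
            return (min(1.0, max(0.0, lo)), 1.0)
        raise ValueError(f"unknown strategy {strategy!r}")


@dataclass
class EvolutionCounters:
    """Stagnation bookkeeping and stopping rules for one evolution stage."""

    G: int = 0
    G_L: int = 0
    G_min: int = 5000
    hard_iteration_limit: int = 100_000
    training_threshold: float = 0.5     # percent

    def should_stop(self, iteration: int) -> bool:
        if iteration >= self.hard_iteration_limit:
            return True
        return self.G > 2 * self.G_L and self.G >= self.G_min


@dataclass(frozen=True)
class TestCandidate:
    magnitudes: tuple[float, float, float]
    angles: tuple[float, float, float]
    bounds: tuple[float, float] = (F_LOWER, F_UPPER)

    __test__ = False      # "Test" here means tensile test, not a pytest item


@dataclass
class HillClimbResult:
    population: list[Mesh]
    errors: list[float]                 # final e_training per model, percent
    history: pd.DataFrame               # iteration, model, proposal, accepted, error
    counters: EvolutionCounters
    evaluations: int


@dataclass
class InformativeTestResult:
    candidate: TestCandidate
    e_test: float
    history: pd.DataFrame
    evaluations: int
    informative: bool                   # False when models never disagreed


# ----------------------------------------------------------------------
# Mutation operators
# ----------------------------------------------------------------------

def mutate_parameter(c: float, c_L: float, c_U: float, spec: MutationSpec,
                     rng: np.random.Generator, strategy: str = "standard") -> float:
    """One bounded mutation of a scalar free parameter (see module docstring)."""
    if not (c_L < c_U):
        raise ValueError(f"degenerate bounds ({c_L}, {c_U})")
    lo, hi = spec.r_window(strategy)
    r = rng.uniform(lo, hi)
    step = (c_U - c_L) * math.exp(spec.R1 + r * spec.R2)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return float(np.clip(c + sign * step, c_L, c_U))


def _mutate_param_arrays(l0: np.ndarray, area: np.ndarray,
                         lb: tuple[float, float], ab: tuple[float, float],
                         spec: MutationSpec, rng: np.random.Generator,
                         strategy: str) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorised mutation of the two per-string parameter arrays."""
    rate = spec.rate(strategy)
    lo, hi = spec.r_window(strategy)
    n = len(l0)
    out = []
    changed = 0
    for arr, (c_L, c_U) in ((l0, lb), (area, ab)):
        hit = rng.random(n) < rate
        r = rng.uniform(lo, hi, size=n)
        sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        step = (c_U - c_L) * np.exp(spec.R1 + r * spec.R2)
        new = np.where(hit, np.clip(arr + sign * step, c_L, c_U), arr)
        changed += int(hit.sum())
        out.append(new)
    return out[0], out[1], changed


def mutate_model(model: Mesh, spec: MutationSpec, strategy: str,
                 rng: np.random.Generator) -> Mesh:
    """Mutated copy of ``model``: node set and connectivity are untouched,
    each string's rest length and cross-section mutate independently with the
    strategy's rate and step regime."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if not model.strings:
        return model
    lb = model.strings[0].length_bounds
    ab = model.strings[0].area_bounds
    l0 = np.array([s.l0 for s in model.strings])
    area = np.array([s.area for s in model.strings])
    new_l0, new_area, _ = _mutate_param_arrays(l0, area, lb, ab, spec, rng, strategy)
    return model.with_string_params(new_l0, new_area)


# ----------------------------------------------------------------------
# Stage II: model evolution
# ----------------------------------------------------------------------

def hill_climb(population: list[Mesh], db: LoadSetDatabase,
               spec: MutationSpec | None = None,
               counters: EvolutionCounters | None = None,
               rng: np.random.Generator | None = None,
               solver: SolverConfig = DEFAULT_SOLVER,
               mode: str = "force_and_distance",
               crossover_window: int = 2000,
               collect_history: bool = True) -> HillClimbResult:
    """Evolve every model of the population independently by RMHC.

    Each iteration proposes one mutation per still-active model (strategy
    drawn with the spec's weights) and accepts it iff it strictly lowers that
    model's training error.  Models reaching the training threshold stop
    individually; the population stops via the counter rules.  When the worst
    model has not improved for ``crossover_window`` iterations it is crossed
    over with a random other model (uniform per-string parameter exchange),
    the child replacing it only on improvement.
    """
    if not population:
        raise ValueError("empty population")
    spec = spec or MutationSpec()
    counters = counters if counters is not None else EvolutionCounters()
    rng = rng if rng is not None else np.random.default_rng()
    records = db.exposed_training()
    if not records:
        raise ValueError("database exposes no training records")

    npop = len(population)
    streams = rng.spawn(npop + 1)
    aux = streams[-1]                       # strategy choice, crossover

    systems = [TrussSystem(m) for m in population]
    l0 = [s.l0.copy() for s in systems]
    area = [s.area.copy() for s in systems]
    lb = [m.strings[0].length_bounds for m in population]
    ab = [m.strings[0].area_bounds for m in population]
    evals = 0

    def evaluate(i: int, l0_i: np.ndarray, area_i: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        sysi = systems[i].with_params(l0=l0_i, area=area_i)
        return _training_error_value(sysi, records, mode, solver)

    errors = [evaluate(i, l0[i], area[i]) for i in range(npop)]
    active = [errors[i] >= counters.training_threshold for i in range(npop)]
    last_improved = [0] * npop
    hist: list[tuple] = []
    weights = np.asarray(spec.strategy_weights)

    # models evolved from one primordial mesh share structure, so their
    # proposals can ride in a single batched Newton sweep
    same_structure = all(
        np.array_equal(s.conn, systems[0].conn) and s.material == systems[0].material
        and np.array_equal(s.X, systems[0].X) for s in systems[1:])

    iteration = 0
    while any(active) and not counters.should_stop(iteration):
        iteration += 1
        improved_any = 0
        proposals: list[tuple[int, str, np.ndarray, np.ndarray]] = []
        for i in range(npop):
            if not active[i]:
                continue
            strategy = STRATEGIES[aux.choice(3, p=weights)]
            cand_l0, cand_area, changed = _mutate_param_arrays(
                l0[i], area[i], lb[i], ab[i], spec, streams[i], strategy)
            if changed == 0:
                continue                    # identical proposal, nothing to test
            proposals.append((i, strategy, cand_l0, cand_area))
        if same_structure and len(proposals) > 1:
            e_batch = _training_error_many(
                systems[0],
                np.stack([p[2] for p in proposals]),
                np.stack([p[3] for p in proposals]),
                records, mode, solver)
            evals += len(proposals)
        else:
            e_batch = [evaluate(i, c_l0, c_a) for i, _, c_l0, c_a in proposals]
        for (i, strategy, cand_l0, cand_area), e_new in zip(proposals, e_batch):
            e_new = float(e_new)
            accepted = e_new < errors[i]
            if collect_history:
                hist.append((iteration, i, strategy, e_new, accepted,
                             e_new if accepted else errors[i]))
            if accepted:
                l0[i], area[i], errors[i] = cand_l0, cand_area, e_new
                improved_any += 1
                last_improved[i] = iteration
                if errors[i] < counters.training_threshold:
                    active[i] = False
        if improved_any:
            counters.G = 0
            counters.G_L += improved_any
        else:
            counters.G += 1

        # crossover rescue of a stagnant worst model
        if npop >= 2:
            worst = int(np.argmax(errors))
            if active[worst] and iteration - last_improved[worst] >= crossover_window:
                partner = int(aux.integers(npop - 1))
                partner += partner >= worst
                pick = aux.random(len(l0[worst])) < 0.5
                child_l0 = np.where(pick, l0[worst], l0[partner])
                child_area = np.where(pick, area[worst], area[partner])
                e_child = evaluate(worst, child_l0, child_area)
                if collect_history:
                    hist.append((iteration, worst, "crossover", e_child,
                                 e_child < errors[worst],
                                 min(e_child, errors[worst])))
                if e_child < errors[worst]:
                    l0[worst], area[worst], errors[worst] = child_l0, child_area, e_child
                    counters.G = 0
                    counters.G_L += 1
                    if errors[worst] < counters.training_threshold:
                        active[worst] = False
                last_improved[worst] = iteration

    evolved = [m.with_string_params(l0[i], area[i]) for i, m in enumerate(population)]
    history = pd.DataFrame(
        hist, columns=["iteration", "model", "strategy", "proposal_error",
                       "accepted", "current_error"])
    return HillClimbResult(population=evolved, errors=errors, history=history,
                           counters=counters, evaluations=evals)


# ----------------------------------------------------------------------
# Stage III: informative-test evolution
# ----------------------------------------------------------------------

def evolve_informative_test(models: Sequence[Mesh | TrussSystem],
                            spec: MutationSpec | None = None,
                            rng: np.random.Generator | None = None,
                            angles: Sequence[float] = (-135.0, -90.0, -45.0),
                            bounds: tuple[float, float] = (F_LOWER, F_UPPER),
                            hard_limit: int = 20_000,
                            G_min: int = 5000,
                            solver: SolverConfig = DEFAULT_SOLVER,
                            init: Sequence[float] | None = None,
                            collect_history: bool = True) -> InformativeTestResult:
    """Hill-climb the three input magnitudes to maximise model disagreement.

    Angles stay fixed; magnitudes mutate with the same bounded step law as
    the string parameters and are clamped into [F_L, F_U].  A mutated test
    replaces the incumbent iff its e_test is strictly higher.  Termination
    mirrors the model-evolution counters with the threshold replaced by the
    iteration budget.
    """
    if len(models) < 2:
        raise ValueError("need at least two models to evolve a test")
    spec = spec or MutationSpec()
    rng = rng if rng is not None else np.random.default_rng()
    systems = [m if isinstance(m, TrussSystem) else TrussSystem(m) for m in models]
    lo, hi = bounds

    mags = np.asarray(init, dtype=float) if init is not None else rng.uniform(lo, hi, size=3)
    mags = np.clip(mags, lo, hi)
    angles = tuple(float(a) for a in angles)
    score = test_informativeness(systems, mags, angles, solver).e_test
    evals = 1
    best_ever = score
    G = G_L = 0
    hist: list[tuple] = [(0, *mags, score, True)]
    for iteration in range(1, hard_limit + 1):
        hit = rng.random(3) < spec.p_rate
        if not hit.any():
            hit[rng.integers(3)] = True     # always propose something
        cand = mags.copy()
        for k in np.flatnonzero(hit):
            cand[k] = mutate_parameter(cand[k], lo, hi, spec, rng)
        e_new = test_informativeness(systems, cand, angles, solver).e_test
        evals += 1
        accepted = e_new > score
        if collect_history:
            hist.append((iteration, *cand, e_new, accepted))
        if accepted:
            mags, score = cand, e_new
            G = 0
            G_L += 1
        else:
            G += 1
        if G > 2 * G_L and G >= G_min:
            break
        best_ever = max(best_ever, score)
    history = pd.DataFrame(hist, columns=["iteration", "F1", "F2", "F3", "e_test", "accepted"])
    cand = TestCandidate(magnitudes=tuple(float(m) for m in mags), angles=angles, bounds=bounds)
    return InformativeTestResult(candidate=cand, e_test=score, history=history,
                                 evaluations=evals, informative=score > 0.0)


def extract_topology(model: Mesh, tests: Sequence[TestCandidate | tuple],
                     solver: SolverConfig = DEFAULT_SOLVER,
                     strain_tol: float = 1e-12) -> set[int]:
    """String ids taut (carrying tension) under at least one test.

    Strings slack under every test are excluded from the reported topology
    but remain in the model, since they may become taut under later tests.
    Tests may be :class:`TestCandidate` or plain ``(magnitudes, angles)``
    pairs; a non-convergent test is skipped with a warning.
    """
    import warnings

    system = TrussSystem(model)
    taut_ids: set[int] = set()
    for t in tests:
        mags, angles = (t.magnitudes, t.angles) if isinstance(t, TestCandidate) else t
        sim = system.simulate(mags, angles, solver)
        if not sim.converged:
            warnings.warn(f"test {tuple(mags)} did not converge; skipped in topology readout")
            continue
        taut = sim.state.element_strain > strain_tol
        taut_ids.update(int(sid) for sid in system.string_ids[taut])
    return taut_ids


# ----------------------------------------------------------------------
# Generic bounded RMHC kernel (also the demo-function driver)
# ----------------------------------------------------------------------

def rmhc_minimize(f: Callable[[np.ndarray], float], bounds: Sequence[tuple[float, float]],
                  rng: np.random.Generator, max_iter: int = 5000,
                  spec: MutationSpec | None = None,
                  x0: Sequence[float] | None = None) -> tuple[np.ndarray, float, pd.DataFrame]:
    """Minimise ``f`` over a box with the same mutate-and-keep-if-better kernel
    used for model evolution.  Every coordinate is proposed each iteration.
    Returns (best x, best f, accepted-trace DataFrame)."""
    spec = spec or MutationSpec()
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    x = (np.array([rng.uniform(lo, hi) for lo, hi in bounds])
         if x0 is None else np.asarray(x0, dtype=float))
    fx = float(f(x))
    trace = [(0, fx)]
    for it in range(1, max_iter + 1):
        cand = np.array([mutate_parameter(xi, lo, hi, spec, rng)
                         for xi, (lo, hi) in zip(x, bounds)])
        fc = float(f(cand))
        if fc < fx:
            x, fx = cand, fc
            trace.append((it, fx))
    return x, fx, pd.DataFrame(trace, columns=["iteration", "f"])
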