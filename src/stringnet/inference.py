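"""End-to-end estimation-exploration inference runs and comparisons.

One inference run cycles three stages until the configured number of
training load sets has been exposed:

1. **Seeding** -- one training record is drawn at random from the
   precollected database to start the exposed set.
2. **Model evolution** -- the population hill-climbs its string parameters to
   minimise the training error on the exposed records; each model is then
   cross-validated on the held-out grid.
3. **Test evolution** -- a candidate test is evolved to maximise the
   across-model disagreement, and the nearest available (not yet served)
   training record is appended to the exposed set.  In ``random_tests`` mode
   stage 3 is replaced by a uniform draw without replacement, and in
   ``parametric_only`` mode the primordial mesh is the fixed 6-string
   all-in-all topology so only parameters are inferred.

All randomness descends from the single run seed; a run is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .builders import build_all_in_all_mesh, build_primordial_mesh, build_target_network
from .evolve import (EvolutionCounters, MutationSpec, TestCandidate, evolve_informative_test,
                     extract_topology, hill_climb)
from .fitness import cross_validation_error
from .lab import (Protocol, build_database, measure, nearest_available_test,
                  seed_database)
from .network import LoadSetDatabase, Mesh
from .solver import DEFAULT_SOLVER, SolverConfig

__all__ = ["RunConfig", "RunReport", "run_inference", "run_parametric_only",
           "compare_protocols", "report"]

MODES = ("informative", "random_tests", "parametric_only")


@dataclass
class RunConfig:
    """Everything one inference run depends on."""

    target_kind: str = "random"
    target_seed: int = 0
    primordial_kind: str = "afh"            # afh | awr | extensor | all_in_all
    population_size: int = 8
    max_informative_sets: int = 20
    mode: str = "informative"
    information_mode: str = "force_and_distance"
    seed: int = 0
    protocol: Protocol | None = None
    spec: MutationSpec = field(default_factory=MutationSpec)
    solver: SolverConfig = DEFAULT_SOLVER
    # per-cycle Stage II budget
    G_min: int = 5000
    hard_iteration_limit: int = 100_000
    training_threshold: float = 0.5
    crossover_window: int = 2000
    # Stage III budget
    test_hard_limit: int = 20_000
    test_G_min: int = 5000
    with_replacement: bool = False
    # "grid": requests answered by the nearest precollected record (the
    # offline experimental protocol); "oracle": the virtual lab measures the
    # exact requested test, as an automated real-time rig would.
    serving: str = "grid"
    collect_history: bool = True

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; choose from {MODES}")
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.mode == "parametric_only" and self.primordial_kind not in (
                "all_in_all", "afh", "awr", "extensor"):
            raise ValueError("parametric_only requires an all-in-all basic topology")
        if self.serving not in ("grid", "oracle"):
            raise ValueError(f"unknown serving mode {self.serving!r}")
        proto = self.resolved_protocol()
        if self.max_informative_sets > len(proto.training_levels) ** 3:
            raise ValueError("max_informative_sets exceeds the training grid size")

    def resolved_protocol(self) -> Protocol:
        if self.protocol is not None:
            return self.protocol
        kind = "extensor" if self.target_kind == "extensor_rhombus" else "afh"
        return Protocol.for_kind(kind)

    def build_primordial(self) -> Mesh:
        if self.mode == "parametric_only" or self.primordial_kind == "all_in_all":
            base = "extensor" if self.target_kind == "extensor_rhombus" else "afh"
            return build_all_in_all_mesh(base)
        return build_primordial_mesh(self.primordial_kind)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["protocol"] = dataclasses.asdict(self.protocol) if self.protocol else None
        return d


@dataclass
class RunReport:
    curves: pd.DataFrame            # cycle, n_exposed, model, e_training, e_cross
    tests: pd.DataFrame             # cycle, F1..F3, e_test, served_index, mode
    population: list[Mesh]
    topologies: list[set[int]]
    final_errors: list[float]
    db: LoadSetDatabase
    config: RunConfig
    histories: pd.DataFrame | None  # concatenated per-cycle hill-climb logs
    evaluations: int
    wall_time_s: float


def _served_tests(db: LoadSetDatabase, angles) -> list[TestCandidate]:
    return [TestCandidate(magnitudes=r.input_magnitudes, angles=tuple(angles))
            for r in db.exposed_training()]


def run_inference(config: RunConfig) -> RunReport:
    """Execute one full estimation-exploration run (see module docstring)."""
    config.validate()
    t0 = time.perf_counter()
    protocol = config.resolved_protocol()
    ss = np.random.SeedSequence(config.seed)
    rng_db, rng_seed, rng_evo, rng_test = [np.random.default_rng(s) for s in ss.spawn(4)]

    target = build_target_network(config.target_kind, config.target_seed)
    db = build_database(target, protocol, rng_db, solver=config.solver)
    db = seed_database(db, rng_seed)
    served = set(db.exposed_ids)

    primordial = config.build_primordial()
    population = [Mesh(name=f"model-{k}", material=primordial.material,
                       nodes=list(primordial.nodes), strings=list(primordial.strings))
                  for k in range(config.population_size)]

    curve_rows, test_rows, hist_frames = [], [], []
    evaluations = 0
    cycle = 0
    while True:
        cycle += 1
        counters = EvolutionCounters(G_min=config.G_min,
                                     hard_iteration_limit=config.hard_iteration_limit,
                                     training_threshold=config.training_threshold)
        result = hill_climb(population, db, spec=config.spec, counters=counters,
                            rng=rng_evo, solver=config.solver,
                            mode=config.information_mode,
                            crossover_window=config.crossover_window,
                            collect_history=config.collect_history)
        population = result.population
        evaluations += result.evaluations
        if config.collect_history and len(result.history):
            hist_frames.append(result.history.assign(cycle=cycle))
        for k, model in enumerate(population):
            e_cv = cross_validation_error(model, db, mode=config.information_mode,
                                          solver=config.solver)
            curve_rows.append({"cycle": cycle, "n_exposed": db.n_exposed, "model": k,
                               "e_training": result.errors[k], "e_cross": e_cv})
        if db.n_exposed >= config.max_informative_sets:
            break

        if config.mode in ("informative", "parametric_only"):
            t_res = evolve_informative_test(
                population, spec=config.spec, rng=rng_test, angles=protocol.angles,
                hard_limit=config.test_hard_limit, G_min=config.test_G_min,
                solver=config.solver, collect_history=False)
            evaluations += t_res.evaluations * len(population)
            e_test = t_res.e_test
            mags = t_res.candidate.magnitudes
            if config.serving == "oracle":
                rec = measure(target, mags, protocol, rng_db, tag="training",
                              solver=config.solver)
                db.records.append(rec)
                idx = len(db.records) - 1
            else:
                exclude = set() if config.with_replacement else served
                idx, _rec = nearest_available_test(mags, db, exclude=exclude)
        else:                                   # random tests, without replacement
            avail = [k for k in db.training_indices() if k not in served]
            idx = int(avail[rng_test.integers(len(avail))])
            e_test = float("nan")
            mags = db.records[idx].input_magnitudes
        if idx not in db.exposed_ids:
            db.expose(idx)
        elif cycle > 3 * config.max_informative_sets:
            break                               # with_replacement kept re-serving
        served.add(idx)
        test_rows.append({"cycle": cycle, "F1": mags[0], "F2": mags[1], "F3": mags[2],
                          "e_test": e_test, "served_index": idx, "mode": config.mode})

    angles = protocol.angles
    tests = _served_tests(db, angles)
    topologies = [extract_topology(m, tests, solver=config.solver) for m in population]
    curves = pd.DataFrame(curve_rows)
    tests_df = pd.DataFrame(test_rows, columns=["cycle", "F1", "F2", "F3",
                                                "e_test", "served_index", "mode"])
    histories = pd.concat(hist_frames, ignore_index=True) if hist_frames else None
    return RunReport(curves=curves, tests=tests_df, population=population,
                     topologies=topologies, final_errors=result.errors, db=db,
                     config=config, histories=histories, evaluations=evaluations,
                     wall_time_s=time.perf_counter() - t0)


def run_parametric_only(config: RunConfig) -> RunReport:
    """Inference with the fixed all-in-all 6-string topology (12 parameters)."""
    cfg = dataclasses.replace(config, mode="parametric_only")
    return run_inference(cfg)


def compare_protocols(config: RunConfig, n_seeds: int,
                      modes: tuple[str, ...] = ("informative", "random_tests")) -> pd.DataFrame:
    """Paired-seed comparison of serving protocols.

    Runs every mode on identical targets and database seeds ``config.seed +
    0..n_seeds-1`` and summarises mean and standard error of the training and
    cross-validation errors per exposed-set count.
    """
    if n_seeds < 3:
        raise ValueError("need at least 3 seeds for a standard-error summary")
    rows = []
    for s in range(n_seeds):
        for mode in modes:
            cfg = dataclasses.replace(config, seed=config.seed + s, mode=mode,
                                      collect_history=False)
            rep = run_inference(cfg)
            per_cycle = rep.curves.groupby("n_exposed")[["e_training", "e_cross"]].mean()
            for n_exposed, r in per_cycle.iterrows():
                rows.append({"mode": mode, "seed": cfg.seed, "n_exposed": int(n_exposed),
                             "e_training": r["e_training"], "e_cross": r["e_cross"]})
    raw = pd.DataFrame(rows)
    summary = (raw.groupby(["mode", "n_exposed"])[["e_training", "e_cross"]]
               .agg(["mean", "sem"]))
    summary.columns = ["_".join(c) for c in summary.columns]
    return summary.reset_index()


def report(run: RunReport, outdir: str | Path) -> list[Path]:
    """Write CSV curves, JSON population and metadata files for one run."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    curves_path = out / "curves.csv"
    run.curves.to_csv(curves_path, index=False)
    written.append(curves_path)

    tests_path = out / "tests.csv"
    run.tests.to_csv(tests_path, index=False)
    written.append(tests_path)

    pop_path = out / "population.json"
    pop_path.write_text(json.dumps(
        [m.to_dict() for m in run.population], indent=2, sort_keys=True))
    written.append(pop_path)

    topo_path = out / "topologies.json"
    topo_path.write_text(json.dumps([sorted(t) for t in run.topologies], indent=2))
    written.append(topo_path)

    # deformed configurations of every final model under the strongest
    # exposed test, for taut/slack plotting
    from .solver import TrussSystem
    exposed = run.db.exposed_training()
    strongest = max(exposed, key=lambda r: sum(r.input_magnitudes))
    snaps = []
    for model in run.population:
        system = TrussSystem(model)
        sim = system.simulate(strongest.input_magnitudes, strongest.input_angles,
                              run.config.solver)
        snaps.append(system.snapshot(sim.state))
    snap_path = out / "snapshots.json"
    snap_path.write_text(json.dumps(
        {"test_magnitudes_N": list(strongest.input_magnitudes),
         "test_angles_deg": list(strongest.input_angles),
         "models": snaps}, indent=2))
    written.append(snap_path)

    cfg = run.config.to_dict()
    cfg_json = json.dumps(cfg, indent=2, sort_keys=True, default=str)
    meta = {
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "evaluations": run.evaluations,
        "wall_time_s": run.wall_time_s,
        "final_errors": run.final_errors,
    }
    meta_path = out / "run.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    written.append(meta_path)
    return written
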