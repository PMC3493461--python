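"""Model-data agreement metrics and test informativeness.

Three quantities drive the inference loop:

* ``training error`` -- average-based percent discrepancy between a model's
  simulated responses and the exposed experimental load sets.  The reaction
  block ``obj_R`` averages relative errors over N_R x N_DS reaction
  comparisons, the deformation block ``obj_D`` over N_D x N_DS distance
  comparisons, and ``error = (obj_R + obj_D) / 2``.
* ``cross-validation error e_cross`` -- the max-based analogue evaluated on
  held-out load sets: the mean of the two per-block maxima, quantifying the
  worst-case functional disagreement between a model and the target.  By
  construction it is never smaller than the average-based error on the same
  sets.
* ``test informativeness e_test`` -- across-model dispersion of the predicted
  responses to a candidate test: the sum over the 2 reaction and 6 distance
  components of the population standard deviation across models, measured in
  instrument-resolution units (the 0.0196 N dynamometer step for reactions,
  the 1 mm caliper step for distances).  Dispersion is thus counted by how
  observable it is to the measurement system, which makes the two blocks
  commensurable; normalising by the across-model component means instead
  makes near-zero-force tests look maximally informative and starves the
  training set of high-force coverage.  e_test is zero iff all models answer
  the candidate test identically.

All relative discrepancies divide by the measured (target) value with a small
floor (1e-3 N / 1e-3 mm) guarding against division by near-zero measurements;
the floor is an implementation guard, not part of the measurement protocol.
A non-convergent analysis poisons the whole evaluation with a large finite
sentinel (1e6 %) so the hill climber can discard the candidate while the
search space stays totally ordered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import LoadSet, LoadSetDatabase, Mesh
from .solver import DEFAULT_SOLVER, SolverConfig, TrussSystem

__all__ = [
    "FLOOR_FORCE",
    "FLOOR_DISTANCE",
    "SENTINEL_ERROR",
    "FitnessReport",
    "TestScore",
    "training_error",
    "cross_validation_error",
    "test_informativeness",
    "ablate_strings",
]

FLOOR_FORCE = 1e-3       # N
FLOOR_DISTANCE = 1e-3    # mm
SENTINEL_ERROR = 1e6     # percent; assigned when any required analysis fails

# instrument-resolution units for the e_test dispersion blocks
SCALE_FORCE = 0.0196     # N, the 2 gram-force dynamometer step
SCALE_DISTANCE = 1.0     # mm, the dial-caliper step


@dataclass
class FitnessReport:
    obj_R: float                 # percent
    obj_D: float                 # percent
    error: float                 # percent; (obj_R + obj_D)/2, or obj_R in force-only mode
    per_set: pd.DataFrame        # one row per load set with per-block mean discrepancies
    converged: bool              # every underlying analysis converged


@dataclass
class TestScore:
    __test__ = False      # "Test" here means tensile test, not a pytest item

    e_test: float
    reaction_dispersion: np.ndarray   # (2,) per-component relative std across models
    distance_dispersion: np.ndarray   # (6,)
    n_models: int                     # models that converged and entered the score


def _as_system(model: Mesh | TrussSystem) -> TrussSystem:
    return model if isinstance(model, TrussSystem) else TrussSystem(model)


def _responses(system: TrussSystem, records: list[LoadSet], solver: SolverConfig):
    mags = np.array([r.input_magnitudes for r in records], dtype=float)
    # all records of one database share the experiment's fixed angles
    angles = records[0].input_angles
    return system.simulate_batch(mags, angles, solver)


def _rel(pred: np.ndarray, meas: np.ndarray, floor: float) -> np.ndarray:
    return np.abs(pred - meas) / np.maximum(np.abs(meas), floor)


def _training_error_value(system: TrussSystem, records: list[LoadSet], mode: str,
                          solver: SolverConfig) -> float:
    """Scalar training error without the per-set report; hot path of the
    hill climber.  Same arithmetic as :func:`training_error`."""
    R, D, ok = _responses(system, records, solver)
    if not ok.all():
        return SENTINEL_ERROR
    R_meas = np.array([r.reactions for r in records], dtype=float)
    obj_R = 100.0 * float(_rel(R, R_meas, FLOOR_FORCE).mean())
    if mode == "force_only":
        return obj_R
    D_meas = np.array([r.distances for r in records], dtype=float)
    obj_D = 100.0 * float(_rel(D, D_meas, FLOOR_DISTANCE).mean())
    return 0.5 * (obj_R + obj_D)


def _training_error_many(system: TrussSystem, l0_rows: np.ndarray, area_rows: np.ndarray,
                         records: list[LoadSet], mode: str,
                         solver: SolverConfig) -> np.ndarray:
    """Training error of ``p`` parameter proposals sharing one structure.

    ``l0_rows``/``area_rows`` are (p, n_strings); all proposals are solved on
    all records in a single batched Newton sweep.  Same arithmetic as
    :func:`training_error`; returns (p,) percent errors with the sentinel for
    proposals containing any non-convergent analysis.
    """
    p, r = len(l0_rows), len(records)
    mags = np.array([rec.input_magnitudes for rec in records], dtype=float)
    angles = records[0].input_angles
    R, D, ok = system.simulate_batch(
        np.tile(mags, (p, 1)), angles, solver,
        l0=np.repeat(l0_rows, r, axis=0), area=np.repeat(area_rows, r, axis=0))
    ok_p = ok.reshape(p, r).all(axis=1)
    R_meas = np.array([rec.reactions for rec in records], dtype=float)
    err_R = 100.0 * _rel(R.reshape(p, r, 2), R_meas, FLOOR_FORCE).mean(axis=(1, 2))
    if mode == "force_only":
        err = err_R
    else:
        D_meas = np.array([rec.distances for rec in records], dtype=float)
        err_D = 100.0 * _rel(D.reshape(p, r, 6), D_meas, FLOOR_DISTANCE).mean(axis=(1, 2))
        err = 0.5 * (err_R + err_D)
    return np.where(ok_p, err, SENTINEL_ERROR)


def training_error(model: Mesh | TrussSystem, db: LoadSetDatabase,
                   mode: str = "force_and_distance",
                   solver: SolverConfig = DEFAULT_SOLVER,
                   records: list[LoadSet] | None = None) -> FitnessReport:
    """Average-based percent discrepancy of ``model`` against training data.

    Uses the database's exposed training records (all of them when the
    database does not track exposure), or an explicit ``records`` list.
    ``mode="force_only"`` ignores the deformation block, reproducing the
    force-information-only ablation.
    """
    if mode not in ("force_and_distance", "force_only"):
        raise ValueError(f"unknown information mode {mode!r}")
    recs = records if records is not None else db.exposed_training()
    if not recs:
        raise ValueError("no training records exposed")
    system = _as_system(model)
    R, D, ok = _responses(system, recs, solver)
    R_meas = np.array([r.reactions for r in recs], dtype=float)
    D_meas = np.array([r.distances for r in recs], dtype=float)
    rel_R = _rel(R, R_meas, FLOOR_FORCE)
    rel_D = _rel(D, D_meas, FLOOR_DISTANCE)
    per_set = pd.DataFrame({
        "tag": [r.tag for r in recs],
        "rel_R_mean_pct": 100.0 * rel_R.mean(axis=1),
        "rel_D_mean_pct": 100.0 * rel_D.mean(axis=1),
        "converged": ok,
    })
    if not ok.all():
        return FitnessReport(obj_R=SENTINEL_ERROR, obj_D=SENTINEL_ERROR,
                             error=SENTINEL_ERROR, per_set=per_set, converged=False)
    obj_R = 100.0 * float(rel_R.mean())
    obj_D = 100.0 * float(rel_D.mean())
    error = obj_R if mode == "force_only" else 0.5 * (obj_R + obj_D)
    return FitnessReport(obj_R=obj_R, obj_D=obj_D, error=error, per_set=per_set, converged=True)


def cross_validation_error(model: Mesh | TrussSystem, db: LoadSetDatabase,
                           mode: str = "force_and_distance",
                           solver: SolverConfig = DEFAULT_SOLVER) -> float:
    """Max-based percent discrepancy on the held-out cross-validation sets."""
    recs = db.cv_records()
    if not recs:
        raise ValueError("database has no cross-validation records")
    system = _as_system(model)
    R, D, ok = _responses(system, recs, solver)
    if not ok.all():
        return SENTINEL_ERROR
    R_meas = np.array([r.reactions for r in recs], dtype=float)
    D_meas = np.array([r.distances for r in recs], dtype=float)
    max_R = 100.0 * float(_rel(R, R_meas, FLOOR_FORCE).max())
    if mode == "force_only":
        return max_R
    max_D = 100.0 * float(_rel(D, D_meas, FLOOR_DISTANCE).max())
    return 0.5 * (max_R + max_D)


def test_informativeness(models: list[Mesh | TrussSystem],
                         candidate_magnitudes, angles,
                         solver: SolverConfig = DEFAULT_SOLVER) -> TestScore:
    """Across-model response dispersion for one candidate test.

    Models whose analysis does not converge are excluded from the score (and
    reflected in ``n_models``); with fewer than two converged models the test
    carries no information and scores zero.
    """
    if len(models) < 2:
        raise ValueError("need at least two models to score a test")
    R_rows, D_rows = [], []
    for m in models:
        sim = _as_system(m).simulate(candidate_magnitudes, angles, solver)
        if sim.converged:
            R_rows.append(sim.reactions)
            D_rows.append(sim.distances)
    n = len(R_rows)
    if n < 2:
        return TestScore(e_test=0.0, reaction_dispersion=np.zeros(2),
                         distance_dispersion=np.zeros(6), n_models=n)
    R = np.array(R_rows)
    D = np.array(D_rows)
    disp_R = R.std(axis=0) / SCALE_FORCE
    disp_D = D.std(axis=0) / SCALE_DISTANCE
    return TestScore(e_test=float(disp_R.sum() + disp_D.sum()),
                     reaction_dispersion=disp_R, distance_dispersion=disp_D, n_models=n)


def ablate_strings(model: Mesh, db: LoadSetDatabase,
                   solver: SolverConfig = DEFAULT_SOLVER,
                   mode: str = "force_and_distance") -> pd.DataFrame:
    """Cross-validation error after removing each string in turn.

    Returns a table with one row per string plus an intact-model row
    (string_id = -1).  Removal that breaks every load path shows up as the
    sentinel error, not a crash.
    """
    if not model.strings:
        raise ValueError("model has no strings to ablate")
    system = TrussSystem(model)
    rows = [{"string_id": -1, "e_cross": cross_validation_error(system, db, mode, solver)}]
    for s in model.strings:
        reduced = system.drop_strings([s.id])
        rows.append({"string_id": s.id,
                     "e_cross": cross_validation_error(reduced, db, mode, solver)})
    return pd.DataFrame(rows)
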