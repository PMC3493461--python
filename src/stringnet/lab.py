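"""Virtual measurement laboratory for in-silico targets.

Stands in for the physical testing rig: it applies the measurement protocol
(three tensions at fixed angles; two grounded reaction forces read from
swivelling dynamometers with 2 g resolution; six input-output inter-nodal
distances read from a dial caliper at 1 mm resolution) to a known
ground-truth network, producing the 64-point training grid (4 force levels
per input, full factorial) plus the 8-point cross-validation grid (2 levels
per input).  Records are shuffled so no loading-order bias can creep into
the inference loop, and informative-test requests are answered with the
nearest precollected training record in the least-squares sense -- exactly
the serving protocol of an offline experimental session.  An *oracle mode*
(``exact=True`` in :func:`measure`) measures the requested test itself, for
studies of what an automated real-time rig would allow.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .network import F_LOWER, F_UPPER, LoadSet, LoadSetDatabase, Mesh
from .solver import DEFAULT_SOLVER, SolverConfig, TrussSystem

__all__ = [
    "Protocol",
    "design_grid",
    "measure",
    "build_database",
    "nearest_available_test",
    "seed_database",
]

#: 2 gram-force dynamometer resolution in newtons
FORCE_QUANTUM_2G = 0.0196

#: fixed per-experiment input-tension angles, degrees from horizontal
EXPERIMENT_ANGLES = {
    "afh": (-135.0, -90.0, -45.0),
    "awr": (-105.0, -90.0, -75.0),
    "extensor": (-115.0, -90.0, -75.0),
}


@dataclass(frozen=True)
class Protocol:
    """Measurement protocol: grid levels, angles, instrument resolutions."""

    training_levels: tuple[float, ...] = (1.25, 2.50, 3.75, 5.00)
    cv_levels: tuple[float, ...] = (1.9, 4.4)
    angles: tuple[float, float, float] = EXPERIMENT_ANGLES["afh"]
    force_quantum: float = FORCE_QUANTUM_2G      # N; 0 disables quantization
    distance_quantum: float = 1.0                # mm; 0 disables quantization
    noise_sd_force: float = 0.0                  # N
    noise_sd_distance: float = 0.0               # mm

    def __post_init__(self) -> None:
        for lv in (*self.training_levels, *self.cv_levels):
            if not (F_LOWER <= lv <= F_UPPER):
                raise ValueError(f"force level {lv} N outside [{F_LOWER}, {F_UPPER}] N")
        for q in (self.force_quantum, self.distance_quantum):
            if q < 0:
                raise ValueError("quantization steps must be non-negative")

    @classmethod
    def for_kind(cls, kind: str, **overrides) -> "Protocol":
        """Protocol with the fixed pull angles of the named experiment."""
        if kind not in EXPERIMENT_ANGLES:
            raise ValueError(f"unknown experiment kind {kind!r}")
        return cls(angles=EXPERIMENT_ANGLES[kind], **overrides)

    def ideal(self) -> "Protocol":
        """Noise- and quantization-free variant, for exact recovery studies."""
        return dc_replace(self, force_quantum=0.0, distance_quantum=0.0,
                          noise_sd_force=0.0, noise_sd_distance=0.0)


def design_grid(protocol: Protocol) -> list[tuple[tuple[float, float, float], str]]:
    """Full factorial input-magnitude grids, deterministic order.

    Training: len(training_levels)^3 combinations (64 by default); cross
    validation: len(cv_levels)^3 (8 by default), appended after training.
    """
    grid = [(combo, "training")
            for combo in itertools.product(protocol.training_levels, repeat=3)]
    grid += [(combo, "cross_validation")
             for combo in itertools.product(protocol.cv_levels, repeat=3)]
    return grid


def _quantize(x: np.ndarray, q: float) -> np.ndarray:
    return np.round(x / q) * q if q > 0 else x


def measure(target: Mesh | TrussSystem, magnitudes, protocol: Protocol,
            rng: np.random.Generator | None = None, tag: str = "training",
            solver: SolverConfig = DEFAULT_SOLVER) -> LoadSet:
    """One measured load set from the ground-truth network.

    Simulates the test, optionally perturbs the readouts with Gaussian noise,
    then quantizes reactions to the dynamometer resolution and distances to
    the caliper resolution.  The commanded magnitudes are recorded as the
    inputs.  A ground-truth target must be solvable on its own grid, so a
    non-convergent analysis raises.
    """
    system = target if isinstance(target, TrussSystem) else TrussSystem(target)
    sim = system.simulate(magnitudes, protocol.angles, solver)
    if not sim.converged:
        raise RuntimeError(f"target analysis did not converge for magnitudes {tuple(magnitudes)}")
    reactions = sim.reactions.copy()
    distances = sim.distances.copy()
    if rng is not None and protocol.noise_sd_force > 0:
        reactions = reactions + rng.normal(0.0, protocol.noise_sd_force, size=2)
    if rng is not None and protocol.noise_sd_distance > 0:
        distances = distances + rng.normal(0.0, protocol.noise_sd_distance, size=6)
    reactions = np.maximum(_quantize(np.maximum(reactions, 0.0), protocol.force_quantum), 0.0)
    distances = _quantize(distances, protocol.distance_quantum)
    distances = np.maximum(distances, max(protocol.distance_quantum, 1e-9))
    rec = LoadSet(
        input_magnitudes=tuple(float(m) for m in magnitudes),
        input_angles=protocol.angles,
        reactions=tuple(float(r) for r in reactions),
        distances=tuple(float(d) for d in distances),
        tag=tag,
    )
    rec.validate()
    return rec


def build_database(target: Mesh | TrussSystem, protocol: Protocol,
                   rng: np.random.Generator | None = None,
                   solver: SolverConfig = DEFAULT_SOLVER) -> LoadSetDatabase:
    """Measure the full design grid and shuffle the record order.

    The shuffle (driven by ``rng``) mirrors the random loading order of the
    physical sessions; with ``rng=None`` the database is a pure function of
    (target, protocol) in grid order.  Every training record starts exposed;
    use :func:`seed_database` to begin an inference run from a single seed
    record.
    """
    system = target if isinstance(target, TrussSystem) else TrussSystem(target)
    records = [measure(system, mags, protocol, rng=rng, tag=tag, solver=solver)
               for mags, tag in design_grid(protocol)]
    if rng is not None:
        order = rng.permutation(len(records))
        records = [records[k] for k in order]
    db = LoadSetDatabase(records=records, exposed_ids=None)
    db.validate()
    return db


def nearest_available_test(requested, db: LoadSetDatabase,
                           exclude: set[int] | None = None) -> tuple[int, LoadSet]:
    """Training record closest to the requested magnitudes in least squares.

    Ties break deterministically toward the lexicographically smallest
    magnitude triple.  Cross-validation records are never served.  Returns
    ``(record_index, load_set)``.
    """
    req = np.asarray(requested, dtype=float)
    exclude = exclude or set()
    best: tuple | None = None
    for k in db.training_indices():
        if k in exclude:
            continue
        mags = db.records[k].input_magnitudes
        d2 = float(np.sum((np.asarray(mags) - req) ** 2))
        key = (d2, mags)
        if best is None or key < best[0]:
            best = (key, k)
    if best is None:
        raise ValueError("no available training records to serve")
    k = best[1]
    return k, db.records[k]


def seed_database(db: LoadSetDatabase, rng: np.random.Generator) -> LoadSetDatabase:
    """Copy of ``db`` with a single uniformly chosen training record exposed."""
    train = db.training_indices()
    if not train:
        raise ValueError("database has no training records")
    pick = int(train[rng.integers(len(train))])
    return LoadSetDatabase(records=list(db.records), exposed_ids=[pick])
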