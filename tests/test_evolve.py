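"""Mutation law, hill climbing, informative-test evolution, topology readout."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stringnet as sn
from stringnet.evolve import (EvolutionCounters, MutationSpec, TestCandidate,
                              evolve_informative_test, extract_topology, hill_climb,
                              mutate_model, mutate_parameter, rmhc_minimize)


# ----------------------------------------------------------------------
# mutation law
# ----------------------------------------------------------------------

def test_step_multiplier_extremes_match_printed_values():
    """R1=-8, R2=9 give step multipliers 3.35e-4 and 2.72 at r=0 and r=1."""
    spec = MutationSpec()
    assert math.exp(spec.R1) == pytest.approx(3.35e-4, rel=2e-3)
    assert math.exp(spec.R1 + spec.R2) == pytest.approx(2.72, rel=2e-3)


def test_mutation_clamps_at_bounds():
    spec = MutationSpec()
    rng = np.random.default_rng(0)
    # at the lower bound a negative step must return the bound itself
    lows = [mutate_parameter(0.01, 0.01, 100.0, spec, rng) for _ in range(200)]
    assert min(lows) >= 0.01
    highs = [mutate_parameter(100.0, 0.01, 100.0, spec, rng) for _ in range(200)]
    assert max(highs) <= 100.0


def test_degenerate_bounds_rejected():
    with pytest.raises(ValueError):
        mutate_parameter(1.0, 5.0, 5.0, MutationSpec(), np.random.default_rng(0))


def test_p_rate_bounds_enforced():
    with pytest.raises(ValueError):
        MutationSpec(p_rate=0.2)
    with pytest.raises(ValueError):
        MutationSpec(p_rate=0.0)


@settings(max_examples=200, derandomize=True)
@given(c=st.floats(0.01, 100.0), seed=st.integers(0, 2**31 - 1))
def test_mutated_parameter_always_within_bounds(c, seed):
    spec = MutationSpec()
    rng = np.random.default_rng(seed)
    for strategy in ("standard", "fine", "coarse"):
        out = mutate_parameter(c, 0.01, 100.0, spec, rng, strategy)
        assert 0.01 <= out <= 100.0


def test_unclamped_step_magnitudes_within_mutation_window():
    """Interior starting point: realised steps lie in [e^R1, e^(R1+R2)] x range."""
    spec = MutationSpec()
    rng = np.random.default_rng(3)
    c, lo, hi = 50.0, 0.0, 100.0
    for _ in range(2000):
        out = mutate_parameter(c, lo, hi, spec, rng)
        if out in (lo, hi):
            continue
        step = abs(out - c) / (hi - lo)
        assert math.exp(spec.R1) - 1e-12 <= step <= math.exp(spec.R1 + spec.R2) + 1e-12


def test_fine_strategy_steps_below_one_percent():
    spec = MutationSpec()
    rng = np.random.default_rng(4)
    for _ in range(2000):
        out = mutate_parameter(50.0, 0.0, 100.0, spec, rng, strategy="fine")
        assert abs(out - 50.0) <= 1.0 + 1e-9          # 1% of the range


def test_coarse_strategy_steps_above_twenty_percent():
    spec = MutationSpec()
    rng = np.random.default_rng(5)
    for _ in range(500):
        out = mutate_parameter(50.0, 0.0, 100.0, spec, rng, strategy="coarse")
        if out not in (0.0, 100.0):
            assert abs(out - 50.0) >= 20.0 - 1e-9


def test_mutate_model_preserves_structure_and_bounds():
    mesh = sn.build_primordial_mesh("afh")
    rng = np.random.default_rng(1)
    out = mutate_model(mesh, MutationSpec(), "standard", rng)
    assert [s.id for s in out.strings] == [s.id for s in mesh.strings]
    assert [(s.i, s.j) for s in out.strings] == [(s.i, s.j) for s in mesh.strings]
    for s in out.strings:
        assert s.length_bounds[0] <= s.l0 <= s.length_bounds[1]
        assert s.area_bounds[0] <= s.area <= s.area_bounds[1]


def test_expected_mutation_count_matches_binomial():
    """Over many proposals, ~2 * n_strings * p_rate parameters change."""
    mesh = sn.build_primordial_mesh("afh")
    spec = MutationSpec()
    rng = np.random.default_rng(2)
    n_draws, total = 400, 0
    for _ in range(n_draws):
        out = mutate_model(mesh, spec, "standard", rng)
        total += sum(a.l0 != b.l0 for a, b in zip(out.strings, mesh.strings))
        total += sum(a.area != b.area for a, b in zip(out.strings, mesh.strings))
    n_params = 2 * len(mesh.strings)
    expected = n_draws * n_params * spec.p_rate
    sd = math.sqrt(n_draws * n_params * spec.p_rate * (1 - spec.p_rate))
    assert abs(total - expected) < 4 * sd


# ----------------------------------------------------------------------
# hill climbing
# ----------------------------------------------------------------------

def _small_db(target, n=6):
    proto = sn.Protocol.for_kind("afh").ideal()
    db = sn.build_database(target, proto, np.random.default_rng(0))
    train = db.training_indices()[:n]
    return sn.LoadSetDatabase(records=db.records, exposed_ids=train)


def test_model_seeded_at_target_terminates_immediately(target_mesh):
    db = _small_db(target_mesh)
    res = hill_climb([target_mesh], db, rng=np.random.default_rng(0),
                     counters=EvolutionCounters(G_min=10, hard_iteration_limit=50))
    assert res.errors[0] < 0.5
    assert res.evaluations == 1            # initial evaluation only
    assert len(res.history) == 0


def test_accepted_training_error_is_non_increasing(target_mesh):
    primordial = sn.build_all_in_all_mesh("afh")
    db = _small_db(target_mesh)
    pop = [primordial, primordial]
    res = hill_climb(pop, db, rng=np.random.default_rng(7),
                     counters=EvolutionCounters(G_min=60, hard_iteration_limit=250),
                     crossover_window=100)
    for m in range(2):
        trace = res.history[res.history.model == m].current_error.to_numpy()
        assert np.all(np.diff(trace) <= 1e-12)
    assert min(res.errors) < sn.training_error(primordial, db).error


def test_hill_climb_reproducible_with_fixed_seed(target_mesh):
    primordial = sn.build_all_in_all_mesh("afh")
    db = _small_db(target_mesh)
    out = []
    for _ in range(2):
        res = hill_climb([primordial, primordial], db, rng=np.random.default_rng(42),
                         counters=EvolutionCounters(G_min=30, hard_iteration_limit=120),
                         crossover_window=60)
        out.append((tuple(res.errors),
                    tuple(s.l0 for s in res.population[0].strings)))
    assert out[0] == out[1]


def test_empty_population_rejected(target_mesh):
    with pytest.raises(ValueError):
        hill_climb([], _small_db(target_mesh), rng=np.random.default_rng(0))


def test_counter_stopping_rule():
    c = EvolutionCounters(G_min=10, hard_iteration_limit=1000)
    c.G, c.G_L = 11, 5
    assert c.should_stop(100)
    c.G, c.G_L = 11, 6
    assert not c.should_stop(100)
    assert c.should_stop(1000)


# ----------------------------------------------------------------------
# informative-test evolution
# ----------------------------------------------------------------------

def test_identical_models_give_uninformative_flag(target_mesh):
    res = evolve_informative_test([target_mesh, target_mesh],
                                  rng=np.random.default_rng(0),
                                  hard_limit=30, G_min=10)
    assert res.e_test == 0.0
    assert not res.informative
    lo, hi = res.candidate.bounds
    assert all(lo <= m <= hi for m in res.candidate.magnitudes)


def test_accepted_e_test_is_non_decreasing(target_mesh):
    other = target_mesh.with_string_params(
        [s.l0 for s in target_mesh.strings],
        [max(s.area_bounds[0], s.area * 0.7) for s in target_mesh.strings])
    res = evolve_informative_test([target_mesh, other], rng=np.random.default_rng(1),
                                  hard_limit=150, G_min=40)
    accepted = res.history[res.history.accepted].e_test.to_numpy()
    assert np.all(np.diff(accepted) >= -1e-15)
    assert res.informative


def test_evolved_test_at_least_as_good_as_exhaustive_grid(target_mesh):
    """Two-model toy (one model carries 4% extra rest-length slack, so the
    engagement threshold discriminates them): the evolved candidate scores at
    least as well as the best point of an exhaustive 1 N screening grid."""
    other = target_mesh.with_string_params(
        [s.l0 * 1.04 for s in target_mesh.strings],
        [s.area for s in target_mesh.strings])
    models = [target_mesh, other]
    angles = (-135.0, -90.0, -45.0)
    from stringnet.fitness import test_informativeness as informativeness
    best_grid = max(
        informativeness(models, (f1, f2, f3), angles).e_test
        for f1 in np.arange(0.0, 5.01, 1.0)
        for f2 in np.arange(0.0, 5.01, 1.0)
        for f3 in np.arange(0.0, 5.01, 1.0))
    res = evolve_informative_test(models, rng=np.random.default_rng(5),
                                  angles=angles, hard_limit=400, G_min=150)
    assert res.e_test >= 0.9 * best_grid


# ----------------------------------------------------------------------
# topology readout
# ----------------------------------------------------------------------

def test_all_strings_taut_under_pull(target_mesh):
    tests = [TestCandidate((5.0, 5.0, 5.0), (-135.0, -90.0, -45.0))]
    topo = extract_topology(target_mesh, tests)
    assert topo == {s.id for s in target_mesh.strings}


def test_never_taut_string_excluded(target_mesh):
    extra = sn.StringElement(99, 0, 4, 190.0, 4.0, length_bounds=(0.01, 200.0))
    mesh = sn.Mesh(name="padded", material=target_mesh.material,
                   nodes=list(target_mesh.nodes),
                   strings=list(target_mesh.strings) + [extra])
    tests = [TestCandidate((2.0, 2.0, 2.0), (-135.0, -90.0, -45.0))]
    topo = extract_topology(mesh, tests)
    assert 99 not in topo


def test_empty_test_list_gives_empty_topology(target_mesh):
    assert extract_topology(target_mesh, []) == set()


# ----------------------------------------------------------------------
# generic RMHC kernel on the multimodal demo function
# ----------------------------------------------------------------------

def _demo(x):
    return float((1 + x[0] ** 2) * (1 - 0.5 * np.sin(4 * x[0])))


def test_rmhc_finds_global_minimum_of_demo_function():
    """The kernel reaches the dense-grid global minimum in 3/3 seeded runs."""
    xs = np.linspace(-10, 10, 200001)
    fs = (1 + xs**2) * (1 - 0.5 * np.sin(4 * xs))
    x_star, f_star = xs[np.argmin(fs)], fs.min()
    for seed in (0, 1, 2):
        x, fx, trace = rmhc_minimize(_demo, [(-10.0, 10.0)],
                                     np.random.default_rng(seed), max_iter=4000)
        assert abs(x[0] - x_star) < 0.05
        assert fx <= f_star + 1e-3
        accepted = trace.f.to_numpy()
        assert np.all(np.diff(accepted) < 0)
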