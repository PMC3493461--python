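"""Nonlinear statics: element formulas, Newton equilibrium, energy oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize

import stringnet as sn
from stringnet.solver import DEFAULT_SOLVER, SolverConfig, TrussSystem

EA = 1.62 * 4.0  # Latex string stiffness used in the closed forms, N


# ----------------------------------------------------------------------
# independent potential-energy oracle (used by several tests)
# ----------------------------------------------------------------------

def _potential_factory(mesh: sn.Mesh, applied: dict[int, tuple[float, float]]):
    """Total potential energy of a linear-material tension-only network,
    derived independently of the solver: Pi(U) = sum 1/2 E A l0 eps+^2 - F.U."""
    idx = {n.id: k for k, n in enumerate(mesh.nodes)}
    X = mesh.positions()
    E = mesh.material.E
    elems = [(idx[s.i], idx[s.j], s.l0, s.area) for s in mesh.strings]
    free = [k for k, n in enumerate(mesh.nodes) if not n.grounded]
    fmap = {k: c for c, k in enumerate(free)}
    F = np.zeros(2 * len(free))
    for nid, f in applied.items():
        c = fmap[idx[nid]]
        F[2 * c: 2 * c + 2] = f

    def expand(u_free):
        U = np.zeros_like(X)
        for k, c in fmap.items():
            U[k] = u_free[2 * c: 2 * c + 2]
        return U

    def energy(u_free):
        U = expand(u_free)
        xy = X + U
        total = 0.0
        for i, j, l0, A in elems:
            l = np.hypot(*(xy[j] - xy[i]))
            eps = max(0.0, (l - l0) / l0)
            total += 0.5 * E * A * l0 * eps * eps
        return total - F @ u_free

    def gradient(u_free):
        # d/du of the elastic terms: sigma * A * (unit chord vector)
        U = expand(u_free)
        xy = X + U
        g = np.zeros_like(X)
        for i, j, l0, A in elems:
            d = xy[j] - xy[i]
            l = np.hypot(*d)
            eps = (l - l0) / l0
            if eps <= 0 or l == 0:
                continue
            n = d / l
            g[j] += E * eps * A * n
            g[i] -= E * eps * A * n
        gf = np.concatenate([g[k] for k in free])
        return gf - F

    return energy, gradient, expand, free


def _energy_min_displacements(mesh, applied):
    energy, gradient, expand, free = _potential_factory(mesh, applied)
    res = minimize(energy, np.zeros(2 * len(free)), jac=gradient, method="L-BFGS-B",
                   options={"ftol": 1e-18, "gtol": 1e-12, "maxiter": 50000})
    return expand(res.x)


# ----------------------------------------------------------------------
# element-level formulas
# ----------------------------------------------------------------------

def test_string_length_undeformed_and_stretched():
    pos = np.array([[0.0, 0.0], [100.0, 0.0]])
    elem = sn.StringElement(0, 0, 1, 100.0, 4.0)
    assert sn.string_length(pos, elem, np.zeros((2, 2))) == pytest.approx(100.0)
    u = np.array([[0.0, 0.0], [1.0, 0.0]])
    pos3 = np.array([[0.0, 0.0], [3.0, 0.0]])
    elem3 = sn.StringElement(0, 0, 1, 3.0, 4.0)
    assert sn.string_length(pos3, elem3, u) == pytest.approx(4.0)
    # out-of-axis displacement: plain Pythagoras
    u = np.array([[0.0, 0.0], [0.0, 4.0]])
    assert sn.string_length(pos3, elem3, u) == pytest.approx(np.hypot(3.0, 4.0))


def test_element_response_zero_strain_and_slack():
    elem = sn.StringElement(0, 0, 1, 100.0, 4.0)
    taut0 = sn.element_response(elem, sn.LATEX, 100.0)
    assert taut0.axial_force == 0.0
    slack = sn.element_response(elem, sn.LATEX, 90.0)
    assert slack.axial_force == 0.0
    assert np.all(slack.nodal_force_vector == 0.0)


def test_element_response_closed_form_tension():
    elem = sn.StringElement(0, 0, 1, 100.0, 4.0)
    l = 115.432
    out = sn.element_response(elem, sn.LATEX, l)
    assert out.strain == pytest.approx((l - 100.0) / 100.0)
    assert out.axial_force == pytest.approx(1.62 * 4.0 * 0.15432, rel=1e-12)
    # equal and opposite nodal forces along the chord
    f = out.nodal_force_vector
    assert np.allclose(f[:2], -f[2:])


def test_tendon_toe_shrunk_to_zero_matches_linear():
    tendon0 = sn.Material.tendon_default(sn.TendonParams(E_linear=1000.0, eps_toe=0.0))
    linear = sn.Material.linear(1000.0)
    eps = np.linspace(0.0, 0.05, 20)
    assert np.allclose(tendon0.stress(eps), linear.stress(eps))
    assert np.allclose(tendon0.tangent(eps), linear.tangent(eps))


def test_tendon_curve_is_monotone_c1():
    mat = sn.TENDON
    eps = np.linspace(-0.01, 0.05, 400)
    sig = mat.stress(eps)
    assert sig[eps <= 0].max() == 0.0
    assert np.all(np.diff(sig[eps >= 0]) >= -1e-15)
    p = mat.tendon
    # tangent continuous at the toe-to-linear junction
    assert mat.tangent(p.eps_toe - 1e-9) == pytest.approx(p.E_linear, rel=1e-4)


# ----------------------------------------------------------------------
# equilibrium solves
# ----------------------------------------------------------------------

def test_single_string_axial_pull_closed_form(single_string_mesh):
    state = sn.solve_equilibrium(single_string_mesh, {1: (1.0, 0.0)})
    assert state.converged
    assert state.U[1, 0] == pytest.approx(100.0 / EA, rel=1e-9)   # eps = T/(E A)
    assert state.U[1, 1] == pytest.approx(0.0, abs=1e-9)


def test_zero_load_is_trivial_equilibrium(target_mesh):
    state = sn.solve_equilibrium(target_mesh, {})
    assert state.converged
    assert state.iterations <= 1
    assert np.allclose(state.U, 0.0)
    assert np.allclose(state.residual, 0.0, atol=1e-12)


def test_grounded_displacements_exactly_zero(v_mesh):
    state = sn.solve_equilibrium(v_mesh, {2: (0.3, -1.0)})
    assert state.converged
    assert np.all(state.U[:2] == 0.0)


def test_v_mesh_matches_energy_minimization(v_mesh):
    applied = {2: (0.0, -1.5)}
    state = sn.solve_equilibrium(v_mesh, applied)
    assert state.converged
    U_oracle = _energy_min_displacements(v_mesh, applied)
    scale = max(np.abs(state.U).max(), 1.0)
    assert np.abs(state.U - U_oracle).max() / scale < 1e-6


def test_randomized_networks_match_energy_minimization():
    """Newton equilibria equal direct potential-energy minimisation on
    randomized pre-tensioned networks with up to 6 free nodes."""
    rng = np.random.default_rng(2024)
    for trial in range(12):
        n_free = int(rng.integers(1, 7))
        nodes = [sn.Node(0, 0.0, 0.0, "output", True),
                 sn.Node(1, 100.0, 0.0, "output", True)]
        for k in range(n_free):
            nodes.append(sn.Node(2 + k, float(rng.uniform(10, 90)),
                                 float(rng.uniform(20, 100)), "input" if k == 0 else "internal"))
        coords = {n.id: (n.x, n.y) for n in nodes}
        edges = set()
        for k in range(n_free):
            # first anchor goes to ground or an earlier free node, so every
            # free node has a load path to ground; second anchor is arbitrary
            earlier = [0, 1] + [2 + j for j in range(k)]
            others = [nid for nid in coords if nid != 2 + k]
            a1 = earlier[int(rng.integers(len(earlier)))]
            a2 = others[int(rng.integers(len(others)))]
            edges.add(tuple(sorted((2 + k, a1))))
            if a2 != a1:
                edges.add(tuple(sorted((2 + k, a2))))
        strings = []
        for sid, (a, b) in enumerate(sorted(edges)):
            chord = np.hypot(coords[b][0] - coords[a][0], coords[b][1] - coords[a][1])
            strings.append(sn.StringElement(sid, a, b, 0.9 * chord, 2.0,
                                            length_bounds=(0.01, 200.0)))
        mesh = sn.Mesh(name=f"rand{trial}", material=sn.LATEX, nodes=nodes, strings=strings)
        mesh.validate()
        applied = {2 + k: tuple(rng.uniform(-1.5, 1.5, size=2)) for k in range(n_free)}
        state = sn.solve_equilibrium(mesh, applied)
        assert state.converged, f"trial {trial} did not converge"
        U_oracle = _energy_min_displacements(mesh, applied)
        scale = max(np.abs(state.U).max(), 1e-9)
        assert np.abs(state.U - U_oracle).max() / scale < 1e-6, f"trial {trial}"


def test_force_balance_at_convergence(target_mesh):
    """Applied inputs plus grounded reactions sum to zero at equilibrium."""
    system = TrussSystem(target_mesh)
    sim = system.simulate([2.0, 3.0, 1.0], (-135.0, -90.0, -45.0))
    assert sim.converged
    applied = sim.state.external_force.sum(axis=0)
    grounded = [k for k, n in enumerate(target_mesh.nodes) if n.grounded]
    support = sim.state.internal_force[grounded].sum(axis=0)
    assert np.allclose(applied + support, 0.0, atol=1e-7)


def test_tension_only_no_negative_axial_force(target_mesh):
    system = TrussSystem(target_mesh)
    for mags in ([0.5, 0.5, 0.5], [5.0, 0.0, 5.0], [1.25, 3.75, 2.5]):
        sim = system.simulate(mags, (-135.0, -90.0, -45.0))
        axial = system.material.stress(sim.state.element_strain) * system.area
        assert np.all(np.where(sim.state.element_taut, axial, 0.0) >= 0.0)


def test_quadratic_convergence_tail(v_mesh):
    """Residual norms of the final Newton iterations decay quadratically
    on a smooth (no slack/taut switching) problem."""
    state = sn.solve_equilibrium(v_mesh, {2: (0.2, -1.0)},
                                 SolverConfig(tol=1e-12, max_iter=100))
    assert state.converged
    hist = state.residual_history
    pairs = [(a, b) for a, b in zip(hist[:-1], hist[1:]) if a < 1e-1]
    assert len(pairs) >= 2
    for a, b in pairs:
        # allow the floating-point floor once the prediction drops below it
        assert b <= max(10.0 * a * a, 1e-13)


def test_singular_configuration_flags_nonconvergence():
    """A free node attached to nothing but loaded cannot equilibrate."""
    mesh = sn.Mesh(name="mechanism", material=sn.LATEX,
                   nodes=[sn.Node(0, 0.0, 0.0, "output", True),
                          sn.Node(1, 100.0, 100.0, "output", True),
                          sn.Node(2, 50.0, 50.0, "input")],
                   strings=[sn.StringElement(0, 0, 1, 141.4, 4.0,
                                             length_bounds=(0.01, 200.0))])
    state = sn.solve_equilibrium(mesh, {2: (1.0, 0.0)},
                                 SolverConfig(max_iter=40))
    assert not state.converged   # flagged, not raised


# ----------------------------------------------------------------------
# load-set simulation readout
# ----------------------------------------------------------------------

def test_zero_magnitudes_give_rest_distances(target_mesh):
    sim = sn.simulate_loadset(target_mesh, [0.0, 0.0, 0.0], (-135.0, -90.0, -45.0))
    assert sim.converged
    assert np.allclose(sim.reactions, 0.0, atol=1e-12)
    X = target_mesh.positions()
    idx = target_mesh.node_index()
    expected = [np.hypot(*(X[idx[i.id]] - X[idx[g.id]]))
                for i in target_mesh.input_nodes for g in target_mesh.grounded_nodes]
    assert np.allclose(sim.distances, expected)


def test_straight_chain_transmits_full_reaction():
    """1 N pulled along a string anchored straight to ground reacts with 1 N."""
    mesh = sn.Mesh(name="chain", material=sn.LATEX,
                   nodes=[sn.Node(0, 0.0, 0.0, "input"),
                          sn.Node(1, 60.0, 0.0, "input"),
                          sn.Node(2, 90.0, 0.0, "input"),
                          sn.Node(3, 0.0, 100.0, "output", True),
                          sn.Node(4, 70.0, 100.0, "output", True)],
                   strings=[sn.StringElement(0, 0, 3, 100.0, 4.0)])
    sim = sn.simulate_loadset(mesh, [1.0, 0.0, 0.0], (-90.0, -90.0, -90.0))
    assert sim.converged
    assert sim.reactions[0] == pytest.approx(1.0, abs=1e-8)
    assert sim.reactions[1] == pytest.approx(0.0, abs=1e-10)


def test_doubling_modulus_keeps_determinate_reaction_halves_stretch():
    def run(E):
        mesh = sn.Mesh(name="det", material=sn.Material.linear(E),
                       nodes=[sn.Node(0, 0.0, 100.0, "output", True),
                              sn.Node(1, 0.0, 0.0, "input")],
                       strings=[sn.StringElement(0, 0, 1, 100.0, 4.0)])
        state = sn.solve_equilibrium(mesh, {1: (0.0, -2.0)})
        assert state.converged
        system = TrussSystem(mesh)
        reaction = np.linalg.norm(state.internal_force[0])
        return reaction, -state.U[1, 1]

    r1, s1 = run(1.62)
    r2, s2 = run(3.24)
    assert r2 == pytest.approx(r1, rel=1e-9)
    assert s2 == pytest.approx(s1 / 2.0, rel=1e-9)


def test_batch_simulation_matches_scalar(target_mesh, ideal_protocol):
    system = TrussSystem(target_mesh)
    rng = np.random.default_rng(5)
    mags = rng.uniform(0.0, 5.0, size=(10, 3))
    R, D, ok = system.simulate_batch(mags, ideal_protocol.angles)
    assert ok.all()
    for k in range(10):
        sim = system.simulate(mags[k], ideal_protocol.angles)
        assert np.allclose(sim.reactions, R[k], atol=1e-9)
        assert np.allclose(sim.distances, D[k], atol=1e-9)


def test_snapshot_export_is_json_serialisable(target_mesh):
    import json
    system = TrussSystem(target_mesh)
    sim = system.simulate([1.0, 1.0, 1.0], (-135.0, -90.0, -45.0))
    snap = system.snapshot(sim.state)
    text = json.dumps(snap)
    assert '"taut"' in text and snap["converged"]
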