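"""Geometrically nonlinear static analysis of tension-only string networks.

Each taut string behaves as a large-displacement truss finite element with
engineering strain measured on the current chord (large deformation, small
strain).  A string whose current chord length falls below its rest length is
slack: it carries no force and contributes no stiffness.  Equilibrium of the
free degrees of freedom under the applied nodal tensions is found with
Newton-Raphson iterations on the force residual

    g(U) = F(U) - F_e,

where ``F`` is the assembled internal force vector and ``F_e`` the external
one; each step solves ``K dU = -g`` with ``K`` the consistently linearised
tangent stiffness of the taut elements.  Convergence is declared when the
infinity norm of the free-DOF residual drops below the tolerance.

Two robustness devices handle the pathologies of tension-only assemblies
(documented in the methods note): a tiny stiffness floor added to the
free-free tangent only (the residual is never altered, so the converged
solution is unaffected), and an infinity-norm cap on the Newton step so a
momentarily singular transverse direction of a just-taut string cannot throw
the iterate to infinity.  Units are mm / N / MPa throughout, so that
MPa * mm^2 = N and no conversion factors appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._kernels import HAVE_NUMBA, newton_batch
from .materials import Material
from .network import Mesh, StringElement

__all__ = [
    "SolverConfig",
    "SolverState",
    "SimResult",
    "ElementForce",
    "TrussSystem",
    "string_length",
    "element_response",
    "solve_equilibrium",
    "simulate_loadset",
]


@dataclass(frozen=True)
class SolverConfig:
    """Newton-Raphson settings.

    tol is on the infinity norm of the free-DOF residual in newtons;
    stiffness_floor (N/mm) regularises the tangent only; max_step (mm) caps
    the per-iteration displacement increment.
    """

    tol: float = 1e-8
    max_iter: int = 100
    stiffness_floor: float = 1e-9
    max_step: float = 20.0


DEFAULT_SOLVER = SolverConfig()


@dataclass
class SolverState:
    """Converged (or abandoned) equilibrium state of one analysis."""

    U: np.ndarray                      # (n_nodes, 2) displacements, mm
    internal_force: np.ndarray         # (n_nodes, 2) assembled internal forces, N
    external_force: np.ndarray         # (n_nodes, 2) applied forces, N
    residual: np.ndarray               # (n_nodes, 2) g(U) = F - F_e, N
    converged: bool
    iterations: int
    residual_history: list[float] = field(default_factory=list)
    element_strain: np.ndarray | None = None
    element_taut: np.ndarray | None = None


@dataclass
class SimResult:
    """Measured response of one simulated tensile test."""

    reactions: np.ndarray              # (2,) reaction magnitudes, N
    distances: np.ndarray              # (6,) input-output distances, mm
    converged: bool
    state: SolverState


@dataclass(frozen=True)
class ElementForce:
    """Force state of a single string element."""

    length: float                      # current chord length, mm
    strain: float
    stress: float                      # MPa
    axial_force: float                 # N, >= 0 (tension-only)
    nodal_force_vector: np.ndarray     # (4,) internal forces [fxi, fyi, fxj, fyj], N


def string_length(positions: np.ndarray, element: StringElement,
                  displacements: np.ndarray, node_index: Mapping[int, int] | None = None) -> float:
    """Euclidean length of the displaced chord of ``element``.

    ``positions`` and ``displacements`` are (n_nodes, 2) arrays; node ids map
    to rows through ``node_index`` (identity if omitted).
    """
    idx = node_index if node_index is not None else {k: k for k in range(len(positions))}
    i, j = idx[element.i], idx[element.j]
    d = (positions[j] + displacements[j]) - (positions[i] + displacements[i])
    return float(np.hypot(d[0], d[1]))


def element_response(element: StringElement, material: Material, length: float,
                     direction: Sequence[float] = (1.0, 0.0)) -> ElementForce:
    """Axial force state of one string at current chord length ``length``.

    Slack (``length < l0``) strings return all zeros.  For a taut string the
    axial force is ``sigma(eps) * A`` directed along ``direction`` (the unit
    vector from node i to node j), equal and opposite at the two nodes.
    """
    if not np.isfinite(length) or length < 0:
        raise ValueError(f"non-finite or negative string length {length}")
    if length < element.l0 or length == 0.0:
        return ElementForce(length=float(length), strain=min(0.0, (length - element.l0) / element.l0),
                            stress=0.0, axial_force=0.0, nodal_force_vector=np.zeros(4))
    eps = (length - element.l0) / element.l0
    sigma = float(material.stress(eps))
    axial = sigma * element.area
    n = np.asarray(direction, dtype=float)
    f = np.concatenate([-axial * n, axial * n])
    return ElementForce(length=float(length), strain=eps, stress=sigma,
                        axial_force=axial, nodal_force_vector=f)


class TrussSystem:
    """Compiled, array-based view of a mesh for fast repeated analysis.

    Model evolution mutates only rest lengths and cross-sections, so the
    geometry, connectivity and assembly index arrays are built once and the
    parameter vectors swapped cheaply via :meth:`with_params`.
    """

    def __init__(self, mesh: Mesh):
        mesh.validate()
        self.mesh = mesh
        self.material = mesh.material
        idx = mesh.node_index()
        self.X = mesh.positions()                       # (n, 2)
        self.n_nodes = len(mesh.nodes)
        self.conn = np.array([[idx[s.i], idx[s.j]] for s in mesh.strings], dtype=int)
        self.l0 = np.array([s.l0 for s in mesh.strings], dtype=float)
        self.area = np.array([s.area for s in mesh.strings], dtype=float)
        self.string_ids = np.array([s.id for s in mesh.strings], dtype=int)
        grounded = np.array([n.grounded for n in mesh.nodes], dtype=bool)
        self.free_dofs = np.flatnonzero(np.repeat(~grounded, 2))
        self.input_rows = np.array([idx[n.id] for n in mesh.input_nodes], dtype=int)
        self.grounded_rows = np.array([idx[n.id] for n in mesh.grounded_nodes], dtype=int)
        # 16 assembly targets per element: dofs of node i then node j
        d = np.empty((len(self.conn), 4), dtype=int)
        d[:, 0] = 2 * self.conn[:, 0]
        d[:, 1] = 2 * self.conn[:, 0] + 1
        d[:, 2] = 2 * self.conn[:, 1]
        d[:, 3] = 2 * self.conn[:, 1] + 1
        self._edofs = d
        if self.material.kind == "linear":
            self._mat_kind, self._mat_params = 0, np.array([self.material.E])
        else:
            p = self.material.tendon
            self._mat_kind = 1
            self._mat_params = np.array([p.E_linear, p.eps_toe, p.shape, p.sigma_toe])

    def with_params(self, l0: np.ndarray | None = None, area: np.ndarray | None = None) -> "TrussSystem":
        """Shallow copy sharing geometry but with new string parameters."""
        new = object.__new__(TrussSystem)
        new.__dict__.update(self.__dict__)
        if l0 is not None:
            new.l0 = np.asarray(l0, dtype=float)
        if area is not None:
            new.area = np.asarray(area, dtype=float)
        return new

    def drop_strings(self, string_ids: Sequence[int]) -> "TrussSystem":
        """Copy with the named strings removed from the assembly."""
        keep = ~np.isin(self.string_ids, np.asarray(list(string_ids), dtype=int))
        new = object.__new__(TrussSystem)
        new.__dict__.update(self.__dict__)
        new.conn = self.conn[keep]
        new.l0 = self.l0[keep]
        new.area = self.area[keep]
        new.string_ids = self.string_ids[keep]
        new._edofs = self._edofs[keep]
        return new

    # -- element kinematics and assembly ------------------------------
    def element_state(self, U: np.ndarray):
        """Chord lengths, unit directions, strains and taut mask at ``U``."""
        xy = self.X + U
        d = xy[self.conn[:, 1]] - xy[self.conn[:, 0]]
        length = np.hypot(d[:, 0], d[:, 1])
        ok = length > 0.0
        n = np.zeros_like(d)
        n[ok] = d[ok] / length[ok, None]
        eps = (length - self.l0) / self.l0
        taut = ok & (length >= self.l0)
        return length, n, eps, taut

    def assemble(self, U: np.ndarray):
        """Internal force vector (2n,) and dense tangent stiffness (2n, 2n)."""
        length, n, eps, taut = self.element_state(U)
        axial = np.where(taut, self.material.stress(eps) * self.area, 0.0)
        km = np.where(taut, self.material.tangent(eps) * self.area / self.l0, 0.0)
        kg = np.divide(axial, length, out=np.zeros_like(axial), where=length > 0)

        F = np.zeros(2 * self.n_nodes)
        contrib = axial[:, None] * n                      # force on dof-block of node j
        np.add.at(F, self._edofs[:, 2:].ravel(), contrib.ravel())
        np.add.at(F, self._edofs[:, :2].ravel(), (-contrib).ravel())

        eye = np.eye(2)
        nnT = n[:, :, None] * n[:, None, :]
        kb = km[:, None, None] * nnT + kg[:, None, None] * (eye - nnT)
        ke = np.empty((len(self.conn), 4, 4))
        ke[:, :2, :2] = kb
        ke[:, 2:, 2:] = kb
        ke[:, :2, 2:] = -kb
        ke[:, 2:, :2] = -kb
        K = np.zeros((2 * self.n_nodes, 2 * self.n_nodes))
        np.add.at(K, (self._edofs[:, :, None], self._edofs[:, None, :]), ke)
        return F, K

    # -- equilibrium --------------------------------------------------
    def external_force(self, applied: Mapping[int, Sequence[float]]) -> np.ndarray:
        """(2n,) external force vector from {node_id: (fx, fy)} in newtons."""
        idx = self.mesh.node_index()
        grounded_ids = {n.id for n in self.mesh.grounded_nodes}
        F_e = np.zeros(2 * self.n_nodes)
        for nid, f in applied.items():
            if nid in grounded_ids:
                raise ValueError(f"cannot apply a force at grounded node {nid}")
            row = idx[nid]
            F_e[2 * row: 2 * row + 2] = np.asarray(f, dtype=float)
        return F_e

    def solve(self, F_e: np.ndarray, config: SolverConfig = DEFAULT_SOLVER) -> SolverState:
        """Newton-Raphson equilibrium starting from U = 0.

        Slack/taut status is re-evaluated at every iteration.  A singular or
        non-finite tangent flags non-convergence instead of raising; callers
        treat a non-converged state as worst-case fitness.
        """
        nd = 2 * self.n_nodes
        U = np.zeros(nd)
        fd = self.free_dofs
        history: list[float] = []
        converged = False
        iterations = 0
        F = np.zeros(nd)
        for it in range(config.max_iter + 1):
            F, K = self.assemble(U.reshape(-1, 2))
            g = F - F_e
            res = float(np.max(np.abs(g[fd]))) if len(fd) else 0.0
            history.append(res)
            iterations = it
            if res <= config.tol:
                converged = True
                break
            if it == config.max_iter:
                break
            Kff = K[np.ix_(fd, fd)] + config.stiffness_floor * np.eye(len(fd))
            try:
                dU = np.linalg.solve(Kff, -g[fd])
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(dU)):
                break
            step = float(np.max(np.abs(dU)))
            if step > config.max_step:
                dU *= config.max_step / step
            U[fd] += dU
        Ur = U.reshape(-1, 2)
        length, n, eps, taut = self.element_state(Ur)
        return SolverState(
            U=Ur,
            internal_force=F.reshape(-1, 2),
            external_force=F_e.reshape(-1, 2),
            residual=(F - F_e).reshape(-1, 2),
            converged=converged,
            iterations=iterations,
            residual_history=history,
            element_strain=eps,
            element_taut=taut,
        )

    # -- measurement protocol readout ---------------------------------
    def simulate(self, magnitudes: Sequence[float], angles: Sequence[float],
                 config: SolverConfig = DEFAULT_SOLVER) -> SimResult:
        """Apply three tensions along fixed angles and read the response.

        The input nodes move with the deformation but the lines of action
        stay fixed in the global frame.  Reactions are reported as the
        Euclidean norm of the net internal force transmitted to each
        grounded node (the physical dynamometers swivel).
        """
        magnitudes = np.asarray(magnitudes, dtype=float)
        angles = np.asarray(angles, dtype=float)
        if magnitudes.shape != (3,) or angles.shape != (3,):
            raise ValueError("expected 3 input magnitudes and 3 angles")
        if np.any(magnitudes < -1e-12) or np.any(magnitudes > 5.0 + 1e-9):
            raise ValueError("input magnitudes must lie within [0, 5] N")
        theta = np.radians(angles)
        F_e = np.zeros(2 * self.n_nodes)
        for row, mag, th in zip(self.input_rows, magnitudes, theta):
            F_e[2 * row] = mag * np.cos(th)
            F_e[2 * row + 1] = mag * np.sin(th)
        state = self.solve(F_e, config)
        reactions = np.linalg.norm(state.internal_force[self.grounded_rows], axis=1)
        xy = self.X + state.U
        pairs = xy[self.input_rows][:, None, :] - xy[self.grounded_rows][None, :, :]
        distances = np.linalg.norm(pairs, axis=2).reshape(-1)
        return SimResult(reactions=reactions, distances=distances,
                         converged=state.converged, state=state)

    def simulate_batch(self, magnitudes: np.ndarray, angles: Sequence[float],
                       config: SolverConfig = DEFAULT_SOLVER,
                       l0: np.ndarray | None = None, area: np.ndarray | None = None):
        """Vectorised :meth:`simulate` over a batch of magnitude triples.

        ``magnitudes`` is (b, 3); returns ``(reactions (b, 2), distances
        (b, 6), converged (b,))``.  All batch members share the fixed angles.
        ``l0``/``area`` optionally override the string parameters, either
        shared ((m,)) or per batch member ((b, m)) -- the latter lets the
        hill climber evaluate a whole population's proposals in one call.
        Newton iterations run on the batch simultaneously; members whose
        residual drops below tolerance leave the working set.  Results are
        identical to the scalar path up to round-off.
        """
        magnitudes = np.asarray(magnitudes, dtype=float)
        if magnitudes.ndim != 2 or magnitudes.shape[1] != 3:
            raise ValueError("expected magnitudes of shape (batch, 3)")
        b = len(magnitudes)
        m = len(self.conn)
        l0b = np.broadcast_to(self.l0 if l0 is None else np.asarray(l0, float), (b, m))
        areab = np.broadcast_to(self.area if area is None else np.asarray(area, float), (b, m))
        theta = np.radians(np.asarray(angles, dtype=float))
        nd = 2 * self.n_nodes
        fd = self.free_dofs
        nf = len(fd)
        F_e = np.zeros((b, nd))
        for col, (row, th) in enumerate(zip(self.input_rows, theta)):
            F_e[:, 2 * row] = magnitudes[:, col] * np.cos(th)
            F_e[:, 2 * row + 1] = magnitudes[:, col] * np.sin(th)

        if HAVE_NUMBA:
            U, F_out, converged = newton_batch(
                self.X, self.conn, np.ascontiguousarray(l0b),
                np.ascontiguousarray(areab), F_e, fd,
                config.tol, config.max_iter, config.stiffness_floor,
                config.max_step, self._mat_kind, self._mat_params)
            return self._batch_readout(U, F_out, converged)

        U = np.zeros((b, nd))
        F_out = np.zeros((b, nd))
        converged = np.zeros(b, dtype=bool)
        conn0, conn1 = self.conn[:, 0], self.conn[:, 1]
        ed = self._edofs
        eye2 = np.eye(2)
        live = np.arange(b)
        for it in range(config.max_iter + 1):
            nb = len(live)
            xy = self.X[None, :, :] + U[live].reshape(nb, -1, 2)
            d = xy[:, conn1] - xy[:, conn0]
            length = np.hypot(d[..., 0], d[..., 1])
            ok = length > 0.0
            n = np.zeros_like(d)
            n[ok] = d[ok] / length[ok, None]
            ll, aa = l0b[live], areab[live]
            eps = (length - ll) / ll
            taut = ok & (length >= ll)
            axial = np.where(taut, self.material.stress(eps) * aa, 0.0)
            F = np.zeros((nb, nd))
            contrib = axial[..., None] * n
            rows = np.arange(nb)[:, None]
            np.add.at(F, (rows, ed[None, :, 2:].reshape(1, -1)), contrib.reshape(nb, -1))
            np.add.at(F, (rows, ed[None, :, :2].reshape(1, -1)), -contrib.reshape(nb, -1))
            g = F - F_e[live]
            res = np.max(np.abs(g[:, fd]), axis=1) if nf else np.zeros(nb)
            done = res <= config.tol
            if done.any():
                F_out[live[done]] = F[done]
                converged[live[done]] = True
            if it == config.max_iter or done.all():
                left = ~done
                F_out[live[left]] = F[left]
                break
            keep = ~done
            live = live[keep]
            nb = len(live)
            g, eps, taut, axial, n, length, ll, aa = (
                g[keep], eps[keep], taut[keep], axial[keep], n[keep], length[keep],
                ll[keep], aa[keep])
            km = np.where(taut, self.material.tangent(eps) * aa / ll, 0.0)
            kg = np.divide(axial, length, out=np.zeros_like(axial), where=length > 0)
            nnT = n[..., :, None] * n[..., None, :]
            kb = km[..., None, None] * nnT + kg[..., None, None] * (eye2 - nnT)
            ke = np.empty((nb, m, 4, 4))
            ke[..., :2, :2] = kb
            ke[..., 2:, 2:] = kb
            ke[..., :2, 2:] = -kb
            ke[..., 2:, :2] = -kb
            K = np.zeros((nb, nd, nd))
            np.add.at(K, (np.arange(nb)[:, None, None, None],
                          ed[None, :, :, None], ed[None, :, None, :]), ke)
            Kff = K[np.ix_(np.arange(nb), fd, fd)]
            Kff += config.stiffness_floor * np.eye(nf)
            try:
                dU = np.linalg.solve(Kff, -g[:, fd][..., None])[..., 0]
            except np.linalg.LinAlgError:
                # singular somewhere in the batch: fall back to per-item solves
                dU = np.zeros((nb, nf))
                for k in range(nb):
                    try:
                        dU[k] = np.linalg.solve(Kff[k], -g[k, fd])
                    except np.linalg.LinAlgError:
                        dU[k] = 0.0
            bad = ~np.all(np.isfinite(dU), axis=1)
            if bad.any():
                dU[bad] = 0.0
            step = np.max(np.abs(dU), axis=1)
            big = step > config.max_step
            dU[big] *= (config.max_step / step[big])[:, None]
            Unew = U[live]
            Unew[:, fd] += dU
            U[live] = Unew

        return self._batch_readout(U, F_out, converged)

    def _batch_readout(self, U: np.ndarray, F_out: np.ndarray, converged: np.ndarray):
        b = len(U)
        Fr = F_out.reshape(b, -1, 2)
        reactions = np.linalg.norm(Fr[:, self.grounded_rows], axis=2)
        xy = self.X[None, :, :] + U.reshape(b, -1, 2)
        pairs = xy[:, self.input_rows][:, :, None, :] - xy[:, self.grounded_rows][:, None, :, :]
        distances = np.linalg.norm(pairs, axis=3).reshape(b, -1)
        return reactions, distances, converged

    def snapshot(self, state: SolverState) -> dict:
        """JSON-serialisable deformed-configuration export for plotting."""
        xy = self.X + state.U
        return {
            "nodes": [
                {"id": int(n.id), "x_mm": float(x), "y_mm": float(y)}
                for n, (x, y) in zip(self.mesh.nodes, xy)
            ],
            "strings": [
                {"id": int(sid), "taut": bool(t), "strain": float(e)}
                for sid, t, e in zip(self.string_ids, state.element_taut, state.element_strain)
            ],
            "converged": bool(state.converged),
        }


# ----------------------------------------------------------------------
# Mesh-level convenience wrappers
# ----------------------------------------------------------------------

def solve_equilibrium(mesh: Mesh, applied: Mapping[int, Sequence[float]],
                      config: SolverConfig = DEFAULT_SOLVER) -> SolverState:
    """Equilibrium of ``mesh`` under nodal forces {node_id: (fx, fy)} N."""
    system = TrussSystem(mesh)
    return system.solve(system.external_force(applied), config)


def simulate_loadset(mesh: Mesh, magnitudes: Sequence[float], angles: Sequence[float],
                     config: SolverConfig = DEFAULT_SOLVER) -> SimResult:
    """Three-tension tensile test on ``mesh``; see :meth:`TrussSystem.simulate`."""
    return TrussSystem(mesh).simulate(magnitudes, angles, config)
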