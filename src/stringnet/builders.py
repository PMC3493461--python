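"""Builders for primordial meshes, basic (all-in-all) topologies and targets.

There is no canonical coordinate table for these string fabrics; the
builders place nodes on regular row layouts spanning the experimental
footprints (100x100 mm for the Latex experiments, ~50 mm for the extensor
tissue) while honouring every quantitative constraint of the study designs:
the exact string counts of the three primordial fabrics (36, 54 and 71), the
per-fabric length and cross-section bounds, three movable input nodes, two
grounded output nodes, and grounded-node spacing identical between a
primordial mesh and its target.
Node coordinates are recorded in the serialized mesh so every downstream
result is reproducible from the files alone.

Node id convention: inputs get ids 0..2 left to right, grounded outputs ids
3..4 left to right, internal nodes follow.  The fixed ordering makes the six
input-output distance components comparable between any model and any target.
"""

from __future__ import annotations

import itertools

import numpy as np

from .materials import LATEX, TENDON, Material
from .network import Mesh, Node, StringElement

__all__ = [
    "build_primordial_mesh",
    "build_all_in_all_mesh",
    "build_target_network",
    "PRIMORDIAL_KINDS",
    "TARGET_KINDS",
]

PRIMORDIAL_KINDS = ("afh", "awr", "extensor")
TARGET_KINDS = ("a_letter", "afh", "awr", "extensor_rhombus", "random")

# per-kind evolution bounds: (length_bounds mm, area_bounds mm^2)
_BOUNDS = {
    "afh": ((0.01, 100.0), (0.01, 5.0)),
    "awr": ((0.01, 70.0), (0.01, 5.0)),
    "extensor": ((0.01, 33.0), (0.01, 11.0)),
}

#: default string cross-section of the laser-cut targets: 4 mm wide x 1 mm thick
TARGET_AREA = 4.0



def _chord(nodes: dict[int, tuple[float, float]], i: int, j: int) -> float:
    (xi, yi), (xj, yj) = nodes[i], nodes[j]
    return float(np.hypot(xj - xi, yj - yi))


def _make_mesh(name: str, material: Material, coords: dict[int, tuple[float, float]],
               roles: dict[int, str], edges: list[tuple[int, int]],
               length_bounds: tuple[float, float], area_bounds: tuple[float, float],
               area: float | None = None, l0: dict[tuple[int, int], float] | None = None) -> Mesh:
    nodes = [
        Node(id=i, x=coords[i][0], y=coords[i][1], role=roles[i],
             grounded=(roles[i] == "output"))
        for i in sorted(coords)
    ]
    # fresh primordial strings start at the middle of the evolvable
    # cross-section range; rest lengths start at the chord (just slack)
    area = 0.5 * (area_bounds[0] + area_bounds[1]) if area is None else area
    strings = []
    for sid, (i, j) in enumerate(edges):
        rest = l0[(i, j)] if l0 is not None else _chord(coords, i, j)
        rest = float(np.clip(rest, *length_bounds))
        strings.append(
            StringElement(id=sid, i=i, j=j, l0=rest,
                          area=float(np.clip(area, *area_bounds)),
                          length_bounds=length_bounds, area_bounds=area_bounds)
        )
    mesh = Mesh(name=name, material=material, nodes=nodes, strings=strings)
    mesh.validate()
    return mesh


def _row_layout(kind: str):
    """Node rows (bottom to top) for each primordial fabric."""
    if kind == "afh":
        rows = [
            [(20.0, 0.0), (50.0, 0.0), (80.0, 0.0)],        # inputs
            [(20.0, 33.0), (50.0, 33.0), (80.0, 33.0)],
            [(30.0, 66.0), (70.0, 66.0)],
            [(30.0, 100.0), (70.0, 100.0)],                 # grounded
        ]
    elif kind == "awr":
        rows = [
            [(30.0, 0.0), (50.0, 0.0), (70.0, 0.0)],
            [(20.0, 25.0), (40.0, 25.0), (60.0, 25.0), (80.0, 25.0)],
            [(30.0, 50.0), (50.0, 50.0), (70.0, 50.0)],
            [(20.0, 75.0), (40.0, 75.0), (60.0, 75.0), (80.0, 75.0)],
            [(30.0, 100.0), (70.0, 100.0)],
        ]
    elif kind == "extensor":
        rows = [
            [(15.0, 0.0), (25.0, 0.0), (35.0, 0.0)],
            [(10.0, 12.5), (20.0, 12.5), (30.0, 12.5), (40.0, 12.5)],
            [(10.0, 25.0), (20.0, 25.0), (30.0, 25.0), (40.0, 25.0)],
            [(10.0, 37.5), (20.0, 37.5), (30.0, 37.5), (40.0, 37.5)],
            [(15.0, 50.0), (35.0, 50.0)],
        ]
    else:
        raise ValueError(f"unknown primordial mesh kind {kind!r}")
    return rows


def build_primordial_mesh(kind: str) -> Mesh:
    """Over-complete starting fabric from which models evolve.

    ``afh`` has 36 strings, ``awr`` 54 and ``extensor`` 71, with the
    documented per-kind length and cross-section bounds.  Every string starts
    at its chord length (just slack) with a 1 mm^2 cross-section; evolution
    owns both parameters from there.
    """
    if kind not in PRIMORDIAL_KINDS:
        raise ValueError(f"unknown primordial mesh kind {kind!r}; choose from {PRIMORDIAL_KINDS}")
    rows = _row_layout(kind)
    length_bounds, area_bounds = _BOUNDS[kind]

    # assign ids: inputs 0-2, grounded 3-4, internals onward
    coords: dict[int, tuple[float, float]] = {}
    roles: dict[int, str] = {}
    row_ids: list[list[int]] = []
    next_internal = 5
    for r, row in enumerate(rows):
        ids = []
        for c, xy in enumerate(row):
            if r == 0:
                nid, role = c, "input"
            elif r == len(rows) - 1:
                nid, role = 3 + c, "output"
            else:
                nid, role = next_internal, "internal"
                next_internal += 1
            coords[nid] = xy
            roles[nid] = role
            ids.append(nid)
        row_ids.append(ids)

    edges: list[tuple[int, int]] = []
    # complete bipartite connections between consecutive rows
    for a, b in zip(row_ids[:-1], row_ids[1:]):
        edges.extend(itertools.product(a, b))
    # adjacent-neighbour links within each non-grounded row
    for r, ids in enumerate(row_ids[:-1]):
        edges.extend(zip(ids[:-1], ids[1:]))
    # kind-specific skip connections to reach the published string counts
    if kind == "afh":
        edges.extend(itertools.product(row_ids[0], row_ids[2]))   # inputs -> row 2
        edges.extend(itertools.product(row_ids[1], row_ids[3]))   # row 1 -> grounded
    elif kind == "extensor":
        edges.extend(itertools.product(row_ids[2], row_ids[4]))   # mid row -> grounded
    mesh = _make_mesh(f"primordial-{kind}", TENDON if kind == "extensor" else LATEX,
                      coords, roles, edges, length_bounds, area_bounds)
    return mesh


def build_all_in_all_mesh(kind: str = "afh") -> Mesh:
    """Basic 6-string topology joining every input node to every output node.

    This is the fixed topology used for parametric-only inference: 5 nodes,
    6 strings, 12 free parameters, no internal nodes.  The layout is more
    compact than the primordial fabrics so that even the diagonal chords stay
    within the per-kind rest-length bounds; grounded-node spacing matches the
    corresponding targets.
    """
    if kind not in PRIMORDIAL_KINDS:
        raise ValueError(f"unknown kind {kind!r}; choose from {PRIMORDIAL_KINDS}")
    if kind == "extensor":
        inputs = [(15.0, 0.0), (25.0, 0.0), (35.0, 0.0)]
        grounded = [(15.0, 42.0), (35.0, 42.0)]
    else:
        inputs = [(30.0, 0.0), (50.0, 0.0), (70.0, 0.0)]
        grounded = [(30.0, 85.0), (70.0, 85.0)]
    coords = {c: xy for c, xy in enumerate(inputs)}
    coords.update({3 + c: xy for c, xy in enumerate(grounded)})
    roles = {0: "input", 1: "input", 2: "input", 3: "output", 4: "output"}
    edges = list(itertools.product((0, 1, 2), (3, 4)))
    length_bounds, area_bounds = _BOUNDS[kind]
    return _make_mesh(f"all-in-all-{kind}", TENDON if kind == "extensor" else LATEX,
                      coords, roles, edges, length_bounds, area_bounds)


# ----------------------------------------------------------------------
# Ground-truth target networks
# ----------------------------------------------------------------------

def _target(name, material, coords, roles, edges, bounds_kind="afh", area=TARGET_AREA,
            l0=None) -> Mesh:
    length_bounds, area_bounds = _BOUNDS[bounds_kind]
    return _make_mesh(name, material, coords, roles, edges,
                      length_bounds, area_bounds, area=area, l0=l0)


def build_target_network(kind: str, rng_seed: int = 0) -> Mesh:
    """Fully specified ground-truth network for in-silico experiments.

    All targets fit a 100x100 mm footprint (50x50 mm for the extensor-scale
    rhombus), use the default 4 mm^2 cross-section, and rest-length equal to
    the chord so the unloaded configuration is an equilibrium.  The
    ``random`` kind is the all-in-all 5-node, 6-string core with seed-drawn
    rest-length slack factors and cross-sections; it is deterministic given
    the seed.
    """
    if kind not in TARGET_KINDS:
        raise ValueError(f"unknown target kind {kind!r}; choose from {TARGET_KINDS}")

    if kind == "a_letter":
        coords = {0: (25.0, 0.0), 1: (50.0, 0.0), 2: (75.0, 0.0),
                  3: (40.0, 100.0), 4: (60.0, 100.0),
                  5: (32.0, 50.0), 6: (68.0, 50.0)}
        roles = {0: "input", 1: "input", 2: "input", 3: "output", 4: "output",
                 5: "internal", 6: "internal"}
        edges = [(0, 5), (5, 3), (2, 6), (6, 4), (1, 5), (1, 6), (5, 6)]
        return _target("target-a_letter", LATEX, coords, roles, edges)

    if kind == "afh":
        coords = {0: (20.0, 0.0), 1: (50.0, 0.0), 2: (80.0, 0.0),
                  3: (30.0, 100.0), 4: (70.0, 100.0),
                  5: (20.0, 60.0), 6: (40.0, 60.0), 7: (60.0, 60.0), 8: (80.0, 60.0),
                  9: (35.0, 30.0), 10: (65.0, 30.0)}
        roles = {0: "input", 1: "input", 2: "input", 3: "output", 4: "output"}
        roles.update({i: "internal" for i in range(5, 11)})
        edges = [(0, 9), (1, 9), (1, 10), (2, 10),
                 (9, 5), (9, 6), (10, 7), (10, 8),
                 (5, 3), (6, 3), (7, 4), (8, 4),
                 (6, 7), (5, 6), (7, 8)]
        return _target("target-afh", LATEX, coords, roles, edges)

    if kind in ("awr", "extensor_rhombus"):
        scale = 1.0 if kind == "awr" else 0.5
        base = {0: (30.0, 0.0), 1: (50.0, 0.0), 2: (70.0, 0.0),
                3: (30.0, 100.0), 4: (70.0, 100.0),
                5: (30.0, 40.0), 6: (70.0, 40.0),      # lateral junctions
                7: (50.0, 55.0),                       # central band split
                8: (38.0, 75.0), 9: (62.0, 75.0)}      # upper rhombus corners
        coords = {i: (x * scale, y * scale) for i, (x, y) in base.items()}
        roles = {0: "input", 1: "input", 2: "input", 3: "output", 4: "output",
                 5: "internal", 6: "internal", 7: "internal", 8: "internal", 9: "internal"}
        # lateral bands, central band splitting at the rhombus, diagonal bands
        edges = [(0, 5), (5, 8), (8, 3), (2, 6), (6, 9), (9, 4),
                 (1, 7), (7, 8), (7, 9), (5, 9), (6, 8)]
        if kind == "awr":
            return _target("target-awr", LATEX, coords, roles, edges, bounds_kind="awr")
        return _target("target-extensor_rhombus", TENDON, coords, roles, edges,
                       bounds_kind="extensor")

    # kind == "random": all-in-all core with randomized parameters
    rng = np.random.default_rng(rng_seed)
    base = build_all_in_all_mesh("afh")
    slack = 1.0 + rng.uniform(0.0, 0.05, size=len(base.strings))
    areas = rng.uniform(2.0, 5.0, size=len(base.strings))
    l0 = {}
    coords = {n.id: (n.x, n.y) for n in base.nodes}
    for s, f in zip(base.strings, slack):
        l0[(s.i, s.j)] = _chord(coords, s.i, s.j) * f
    roles = {n.id: n.role for n in base.nodes}
    edges = [(s.i, s.j) for s in base.strings]
    mesh = _target(f"target-random-{rng_seed}", LATEX, coords, roles, edges, l0=l0)
    mesh.strings = [
        StringElement(id=s.id, i=s.i, j=s.j, l0=s.l0, area=float(np.clip(a, *s.area_bounds)),
                      length_bounds=s.length_bounds, area_bounds=s.area_bounds)
        for s, a in zip(mesh.strings, areas)
    ]
    mesh.validate()
    return mesh
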