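"""Domain types for string networks and load sets, plus JSON/CSV file formats.

Coordinate convention: 2D plane, x rightward, y upward, millimetres.  Input
pull directions are given as angles in degrees from the horizontal, negative
meaning downward (so -90 deg pulls straight down).

A :class:`Mesh` is a set of nodes joined by tension-only string elements.
Strings that merely cross in the plane without sharing a node do not interact
mechanically (free crossing, no contact or friction).  Three movable *input*
nodes receive the applied tensions; two grounded *output* nodes provide the
measured reaction forces.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .materials import Material

__all__ = [
    "MeshValidationError",
    "StructuralError",
    "Node",
    "StringElement",
    "Mesh",
    "LoadSet",
    "LoadSetDatabase",
    "load_mesh",
    "save_mesh",
    "load_loadsets",
    "save_loadsets",
    "export_loadsets_csv",
    "F_LOWER",
    "F_UPPER",
]

#: Bounds on any commanded input tension, newtons.
F_LOWER = 0.0
F_UPPER = 5.0

_ROLES = ("input", "output", "internal")


class MeshValidationError(ValueError):
    """A mesh or load-set file violates the schema or an invariant."""


class StructuralError(MeshValidationError):
    """A string references a node id absent from the node list."""


@dataclass(frozen=True)
class Node:
    id: int
    x: float
    y: float
    role: str = "internal"
    grounded: bool = False

    def validate(self) -> None:
        if self.role not in _ROLES:
            raise MeshValidationError(f"node {self.id}: unknown role {self.role!r}")
        if self.grounded and self.role != "output":
            raise MeshValidationError(f"node {self.id}: grounded node must have role 'output'")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise MeshValidationError(f"node {self.id}: non-finite position")


@dataclass(frozen=True)
class StringElement:
    """A tension-only string between two nodes.

    ``l0`` is the rest length (mm) and ``area`` the cross-section (mm^2); both
    are the free parameters of model evolution and must stay within their
    bounds.
    """

    id: int
    i: int
    j: int
    l0: float
    area: float
    length_bounds: tuple[float, float] = (0.01, 100.0)
    area_bounds: tuple[float, float] = (0.01, 5.0)

    def validate(self) -> None:
        if self.i == self.j:
            raise MeshValidationError(f"string {self.id}: endpoints coincide (node {self.i})")
        for name, (lo, hi) in (("length_bounds", self.length_bounds), ("area_bounds", self.area_bounds)):
            if not (0 < lo < hi):
                raise MeshValidationError(f"string {self.id}: invalid {name} {(lo, hi)}")
        if not (self.length_bounds[0] <= self.l0 <= self.length_bounds[1]):
            raise MeshValidationError(
                f"string {self.id}: rest length {self.l0} outside bounds {self.length_bounds}"
            )
        if not (self.area_bounds[0] <= self.area <= self.area_bounds[1]):
            raise MeshValidationError(
                f"string {self.id}: area {self.area} outside bounds {self.area_bounds}"
            )


@dataclass
class Mesh:
    """A string network: nodes, string elements and one material law."""

    name: str
    material: Material
    nodes: list[Node] = field(default_factory=list)
    strings: list[StringElement] = field(default_factory=list)

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise MeshValidationError("duplicate node ids")
        for n in self.nodes:
            n.validate()
        sids = [s.id for s in self.strings]
        if len(set(sids)) != len(sids):
            raise MeshValidationError("duplicate string ids")
        known = set(ids)
        for s in self.strings:
            s.validate()
            for end in (s.i, s.j):
                if end not in known:
                    raise StructuralError(
                        f"string {s.id} references node id {end} absent from nodes"
                    )

    # -- convenience accessors ----------------------------------------
    @property
    def input_nodes(self) -> list[Node]:
        return sorted((n for n in self.nodes if n.role == "input"), key=lambda n: n.id)

    @property
    def grounded_nodes(self) -> list[Node]:
        return sorted((n for n in self.nodes if n.grounded), key=lambda n: n.id)

    def node_index(self) -> dict[int, int]:
        return {n.id: k for k, n in enumerate(self.nodes)}

    def positions(self) -> np.ndarray:
        return np.array([[n.x, n.y] for n in self.nodes], dtype=float)

    def string_by_id(self, sid: int) -> StringElement:
        for s in self.strings:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def with_string_params(self, l0: Sequence[float], area: Sequence[float]) -> "Mesh":
        """Copy of the mesh with new per-string rest lengths and areas."""
        if len(l0) != len(self.strings) or len(area) != len(self.strings):
            raise ValueError("parameter arrays must match the number of strings")
        new = [replace(s, l0=float(a), area=float(b)) for s, a, b in zip(self.strings, l0, area)]
        return Mesh(name=self.name, material=self.material, nodes=list(self.nodes), strings=new)

    def without_string(self, sid: int) -> "Mesh":
        kept = [s for s in self.strings if s.id != sid]
        if len(kept) == len(self.strings):
            raise KeyError(sid)
        return Mesh(name=f"{self.name}-minus-{sid}", material=self.material,
                    nodes=list(self.nodes), strings=kept)

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "material": self.material.to_dict(),
            "nodes": [
                {"id": n.id, "x_mm": n.x, "y_mm": n.y, "role": n.role, "grounded": n.grounded}
                for n in self.nodes
            ],
            "strings": [
                {
                    "id": s.id,
                    "i": s.i,
                    "j": s.j,
                    "l0_mm": s.l0,
                    "A_mm2": s.area,
                    "l_bounds": list(s.length_bounds),
                    "A_bounds": list(s.area_bounds),
                }
                for s in self.strings
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Mesh":
        for key in ("name", "material", "nodes", "strings"):
            if key not in d:
                raise MeshValidationError(f"mesh file missing top-level field {key!r}")
        try:
            nodes = [
                Node(id=int(nd["id"]), x=float(nd["x_mm"]), y=float(nd["y_mm"]),
                     role=str(nd["role"]), grounded=bool(nd.get("grounded", False)))
                for nd in d["nodes"]
            ]
        except KeyError as exc:
            raise MeshValidationError(f"node entry missing field {exc.args[0]!r}") from exc
        try:
            strings = [
                StringElement(
                    id=int(sd["id"]), i=int(sd["i"]), j=int(sd["j"]),
                    l0=float(sd["l0_mm"]), area=float(sd["A_mm2"]),
                    length_bounds=tuple(float(v) for v in sd["l_bounds"]),
                    area_bounds=tuple(float(v) for v in sd["A_bounds"]),
                )
                for sd in d["strings"]
            ]
        except KeyError as exc:
            raise MeshValidationError(f"string entry missing field {exc.args[0]!r}") from exc
        mesh = cls(name=str(d["name"]), material=Material.from_dict(d["material"]),
                   nodes=nodes, strings=strings)
        mesh.validate()
        return mesh


@dataclass(frozen=True)
class LoadSet:
    """One experiment record.

    Three commanded input tensions (N, along fixed angles) together with the
    measured two grounded-node reaction magnitudes (N) and the six
    input-output inter-nodal distances (mm).  The distance order is
    (input 1, output 1), (input 1, output 2), (input 2, output 1), ... with
    inputs and outputs each sorted by node id.
    """

    input_magnitudes: tuple[float, float, float]
    input_angles: tuple[float, float, float]
    reactions: tuple[float, float]
    distances: tuple[float, ...]
    tag: str = "training"

    def validate(self) -> None:
        if self.tag not in ("training", "cross_validation"):
            raise MeshValidationError(f"unknown load-set tag {self.tag!r}")
        if len(self.input_magnitudes) != 3 or len(self.input_angles) != 3:
            raise MeshValidationError("load set needs 3 input magnitudes and 3 angles")
        if len(self.reactions) != 2:
            raise MeshValidationError("load set needs 2 reaction magnitudes")
        if len(self.distances) != 6:
            raise MeshValidationError("load set needs 6 inter-nodal distances")
        for m in self.input_magnitudes:
            if not (F_LOWER <= m <= F_UPPER):
                raise MeshValidationError(
                    f"input magnitude {m} N outside [{F_LOWER}, {F_UPPER}] N"
                )
        if any(r < 0 for r in self.reactions):
            raise MeshValidationError("reaction magnitudes must be non-negative")
        if any(d <= 0 for d in self.distances):
            raise MeshValidationError("inter-nodal distances must be positive")

    def to_row(self, set_id: int) -> dict:
        row = {"set_id": set_id, "tag": self.tag}
        for k in range(3):
            row[f"F{k + 1}_N"] = self.input_magnitudes[k]
        for k in range(3):
            row[f"ang{k + 1}_deg"] = self.input_angles[k]
        row["R1_N"], row["R2_N"] = self.reactions
        names = ["d11_mm", "d12_mm", "d21_mm", "d22_mm", "d31_mm", "d32_mm"]
        for name, d in zip(names, self.distances):
            row[name] = d
        return row


@dataclass
class LoadSetDatabase:
    """An ordered collection of load sets with an exposure bookkeeping.

    ``exposed_ids`` lists the indices (into ``records``) of training records
    revealed to the model-evolution stage so far, in the order served.  When
    ``None`` every training record counts as exposed, which is the convenient
    default for direct fitness evaluation outside the inference loop.
    Cross-validation records are never exposed for training.
    """

    records: list[LoadSet] = field(default_factory=list)
    exposed_ids: list[int] | None = None

    def validate(self) -> None:
        for k, rec in enumerate(self.records):
            try:
                rec.validate()
            except MeshValidationError as exc:
                raise MeshValidationError(f"record {k}: {exc}") from exc
        if self.exposed_ids is not None:
            for idx in self.exposed_ids:
                if not (0 <= idx < len(self.records)):
                    raise MeshValidationError(f"exposed index {idx} out of range")
                if self.records[idx].tag != "training":
                    raise MeshValidationError(
                        f"exposed index {idx} refers to a cross-validation record"
                    )
            if len(set(self.exposed_ids)) != len(self.exposed_ids):
                raise MeshValidationError("duplicate exposed indices")

    # -- views --------------------------------------------------------
    def training_indices(self) -> list[int]:
        return [k for k, r in enumerate(self.records) if r.tag == "training"]

    def training_records(self) -> list[LoadSet]:
        return [r for r in self.records if r.tag == "training"]

    def cv_records(self) -> list[LoadSet]:
        return [r for r in self.records if r.tag == "cross_validation"]

    def exposed_training(self) -> list[LoadSet]:
        if self.exposed_ids is None:
            return self.training_records()
        return [self.records[k] for k in self.exposed_ids]

    @property
    def n_exposed(self) -> int:
        return len(self.exposed_training())

    def expose(self, index: int) -> None:
        if self.records[index].tag != "training":
            raise MeshValidationError("cannot expose a cross-validation record")
        if self.exposed_ids is None:
            raise MeshValidationError("database already exposes every training record")
        if index in self.exposed_ids:
            raise MeshValidationError(f"record {index} already exposed")
        self.exposed_ids.append(index)


# ----------------------------------------------------------------------
# File formats
# ----------------------------------------------------------------------

def save_mesh(mesh: Mesh, path: str | Path) -> None:
    mesh.validate()
    Path(path).write_text(json.dumps(mesh.to_dict(), indent=2, sort_keys=True))


def load_mesh(path: str | Path) -> Mesh:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    try:
        data = json.loads(p.read_text())
    except json.JSONDecodeError as exc:
        raise MeshValidationError(f"{p}: not valid JSON ({exc})") from exc
    return Mesh.from_dict(data)


def save_loadsets(db: LoadSetDatabase, path: str | Path) -> None:
    db.validate()
    payload = {
        "records": [r.to_row(k) for k, r in enumerate(db.records)],
        "exposed_ids": db.exposed_ids,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def _loadset_from_row(row: dict) -> LoadSet:
    names = ["d11_mm", "d12_mm", "d21_mm", "d22_mm", "d31_mm", "d32_mm"]
    return LoadSet(
        input_magnitudes=tuple(float(row[f"F{k}_N"]) for k in (1, 2, 3)),
        input_angles=tuple(float(row[f"ang{k}_deg"]) for k in (1, 2, 3)),
        reactions=(float(row["R1_N"]), float(row["R2_N"])),
        distances=tuple(float(row[n]) for n in names),
        tag=str(row["tag"]),
    )


def load_loadsets(path: str | Path) -> LoadSetDatabase:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    data = json.loads(p.read_text())
    records = []
    for k, row in enumerate(data.get("records", [])):
        try:
            rec = _loadset_from_row(row)
            rec.validate()
        except (KeyError, ValueError) as exc:
            raise MeshValidationError(f"load-set row {k}: {exc}") from exc
        records.append(rec)
    db = LoadSetDatabase(records=records, exposed_ids=data.get("exposed_ids"))
    db.validate()
    return db


def export_loadsets_csv(db: LoadSetDatabase, path: str | Path) -> None:
    """Spreadsheet-friendly CSV export with one row per load set."""
    db.validate()
    rows = [r.to_row(k) for k, r in enumerate(db.records)]
    pd.DataFrame(rows).to_csv(path, index=False)
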