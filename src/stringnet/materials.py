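"""Stress-strain laws for string elements.

Two constitutive models are supported, both tension-only (a string carries no
force in compression; that cutoff lives in the solver, not here):

* ``linear`` -- Hookean rubber-like behaviour, ``sigma = E * eps``.  The
  default elastic modulus for the Latex strings used throughout the synthetic
  experiments is 1.62 MPa.
* ``tendon`` -- collagenous tissue with the classic exponential "toe" region
  followed by a linear region.  The curve is C1-continuous and parameterised
  by the linear-region modulus, the strain at which the toe ends, and a
  dimensionless shape factor.  Shrinking the toe to zero strain recovers the
  purely linear law, which is used as a consistency check in the tests.

Units are MPa for stress and dimensionless engineering strain, so that
``stress * area_mm2`` is directly a force in newtons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TendonParams",
    "Material",
    "LATEX",
    "TENDON",
    "LINEAR_TENDON_CONTROL",
]


@dataclass(frozen=True)
class TendonParams:
    """Parameters of the exponential-toe + linear tendon curve.

    Attributes
    ----------
    E_linear : float
        Tangent modulus of the linear region beyond the toe, MPa.  Generic
        mammalian tendon is of order 1.2 GPa.
    eps_toe : float
        Strain at which the toe region ends and the linear region begins.
    shape : float
        Dimensionless exponent controlling the curvature of the toe.
    """

    E_linear: float = 1200.0
    eps_toe: float = 0.015
    shape: float = 3.0

    def __post_init__(self) -> None:
        if self.E_linear <= 0:
            raise ValueError("E_linear must be positive")
        if self.eps_toe < 0:
            raise ValueError("eps_toe must be non-negative")
        if self.shape <= 0:
            raise ValueError("shape must be positive")

    @property
    def sigma_toe(self) -> float:
        """Stress at the end of the toe region (MPa), fixed by C1 continuity."""
        a = self.shape
        return self.E_linear * self.eps_toe * np.expm1(a) / (a * np.exp(a))


@dataclass(frozen=True)
class Material:
    """A stress-strain law, either linear or tendon-like.

    Invariants: ``stress(0) == 0`` and ``stress`` is monotone non-decreasing
    for non-negative strain.  Negative strains map to zero stress and zero
    tangent; the slack/taut logic in the solver relies on this.
    """

    kind: str
    E: float | None = None
    tendon: TendonParams | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "tendon"):
            raise ValueError(f"unknown material kind {self.kind!r}")
        if self.kind == "linear":
            if self.E is None or self.E <= 0:
                raise ValueError("linear material requires a positive elastic modulus")
        else:
            if self.tendon is None:
                object.__setattr__(self, "tendon", TendonParams())

    # -- constructors -------------------------------------------------
    @classmethod
    def linear(cls, E: float) -> "Material":
        return cls(kind="linear", E=E)

    @classmethod
    def tendon_default(cls, params: TendonParams | None = None) -> "Material":
        return cls(kind="tendon", tendon=params or TendonParams())

    # -- constitutive response ----------------------------------------
    def stress(self, eps):
        """Stress (MPa) at engineering strain ``eps`` (scalar or array)."""
        eps = np.asarray(eps, dtype=float)
        if self.kind == "linear":
            return np.where(eps > 0.0, self.E * eps, 0.0)
        p = self.tendon
        if p.eps_toe == 0.0:
            return np.where(eps > 0.0, p.E_linear * eps, 0.0)
        a = p.shape
        toe = p.sigma_toe * np.expm1(a * np.clip(eps, 0.0, p.eps_toe) / p.eps_toe) / np.expm1(a)
        lin = p.sigma_toe + p.E_linear * (eps - p.eps_toe)
        out = np.where(eps >= p.eps_toe, lin, toe)
        return np.where(eps > 0.0, out, 0.0)

    def tangent(self, eps):
        """Tangent modulus d(sigma)/d(eps) in MPa, evaluated from the taut side.

        At ``eps == 0`` the one-sided (taut) tangent is returned so that a
        just-taut string contributes material stiffness to the assembly.
        """
        eps = np.asarray(eps, dtype=float)
        if self.kind == "linear":
            return np.where(eps >= 0.0, self.E, 0.0)
        p = self.tendon
        if p.eps_toe == 0.0:
            return np.where(eps >= 0.0, p.E_linear, 0.0)
        a = p.shape
        toe_slope = (
            p.sigma_toe
            * (a / p.eps_toe)
            * np.exp(a * np.clip(eps, 0.0, p.eps_toe) / p.eps_toe)
            / np.expm1(a)
        )
        out = np.where(eps >= p.eps_toe, p.E_linear, toe_slope)
        return np.where(eps >= 0.0, out, 0.0)

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        if self.kind == "linear":
            return {"kind": "linear", "E_MPa": self.E}
        p = self.tendon
        return {
            "kind": "tendon",
            "tendon_params": {
                "E_linear_MPa": p.E_linear,
                "eps_toe": p.eps_toe,
                "shape": p.shape,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Material":
        if "kind" not in d:
            raise ValueError("material block missing 'kind'")
        if d["kind"] == "linear":
            if "E_MPa" not in d:
                raise ValueError("linear material block missing 'E_MPa'")
            return cls.linear(float(d["E_MPa"]))
        if d["kind"] == "tendon":
            tp = d.get("tendon_params", {})
            return cls.tendon_default(
                TendonParams(
                    E_linear=float(tp.get("E_linear_MPa", 1200.0)),
                    eps_toe=float(tp.get("eps_toe", 0.015)),
                    shape=float(tp.get("shape", 3.0)),
                )
            )
        raise ValueError(f"unknown material kind {d['kind']!r}")


#: Latex rubber used for the synthetic cut-sheet networks.
LATEX = Material.linear(1.62)

#: Generic nonlinear tendon curve used for the extensor-mechanism models.
TENDON = Material.tendon_default()

#: Linear 1 GPa control material (the "what if tendon were Hookean" case).
LINEAR_TENDON_CONTROL = Material.linear(1000.0)
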