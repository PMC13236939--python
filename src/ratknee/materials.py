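"""Constitutive constants and laws for the rat knee contact model.

All defaults are the study values: homogeneous linear-elastic articular
cartilage (E = 6 MPa, nu = 0.49, 0.25 mm per layer), the rat-specific bone
density-modulus power law E = 8362.8 * rho^2.56 (rho in g/cm^3, E in MPa),
tension-only ligament springs (ACL/PCL 35 N/mm at 5 % pretension, MCL/LCL
20 N/mm at 4 %) and frictionless cartilage-cartilage contact.

Bone is treated as rigid in the contact solver: its modulus (~GPa) exceeds
the cartilage modulus by three orders of magnitude, so bone compliance is
negligible against cartilage compliance.  The density-modulus law is still
implemented and carried through the appearance block of the shape model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MaterialError(ValueError):
    """Raised for out-of-range material parameters."""


def density_to_modulus(rho, a: float = 8362.8, exponent: float = 2.56):
    """Bone compressive modulus (MPa) from equivalent mineral density (g/cm^3).

    ``E = a * rho ** exponent``; strictly monotone increasing, 0 at 0.
    """
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr < 0):
        raise MaterialError("equivalent mineral density must be >= 0")
    out = a * rho_arr**exponent
    return float(out) if np.isscalar(rho) or rho_arr.ndim == 0 else out


def foundation_modulus(E: float, nu: float) -> float:
    """Confined (elastic-foundation) modulus E(1-nu)/((1+nu)(1-2nu)) in MPa.

    Diverges as nu -> 0.5, so nu >= 0.499 is rejected.
    """
    if not 0.0 <= nu < 0.499:
        raise MaterialError("Poisson ratio must be in [0, 0.499)")
    if E <= 0:
        raise MaterialError("Young's modulus must be positive")
    return E * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu))


def ligament_force(current_length: float, reference_length: float, stiffness: float, pretension: float) -> float:
    """Tension (N) of a tension-only spring with slack length L0 = (1 - pretension) * L_ref.

    At the reference pose the spring carries ``stiffness * reference_length *
    pretension``; below slack length the force is exactly zero.
    """
    if current_length <= 0 or reference_length <= 0:
        raise MaterialError("ligament lengths must be positive")
    slack = reference_length * (1.0 - pretension)
    return stiffness * max(0.0, current_length - slack)


@dataclass
class MaterialSet:
    """Bundle of all constitutive parameters with study defaults."""

    cartilage_E: float = 6.0            # MPa
    cartilage_nu: float = 0.49
    cartilage_thickness: float = 0.25   # mm per layer
    bone_law_a: float = 8362.8          # MPa at rho = 1 g/cm^3
    bone_law_exponent: float = 2.56
    # name -> (stiffness N/mm, pretension fraction of reference length)
    ligament_table: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "ACL": (35.0, 0.05),
            "PCL": (35.0, 0.05),
            "MCL": (20.0, 0.04),
            "LCL": (20.0, 0.04),
        }
    )
    friction: float = 0.0
    density_scale: float = 1.0  # unit conversion hook for the density law input

    def __post_init__(self) -> None:
        if not 0.0 < self.cartilage_nu < 0.5:
            raise MaterialError("cartilage Poisson ratio must be in (0, 0.5)")
        if self.cartilage_E <= 0 or self.cartilage_thickness <= 0:
            raise MaterialError("cartilage stiffness and thickness must be positive")
        for name, (k, pre) in self.ligament_table.items():
            if k <= 0:
                raise MaterialError(f"{name}: stiffness must be positive")
            if not 0.0 <= pre <= 0.2:
                raise MaterialError(f"{name}: pretension must be in [0, 0.2]")

    @property
    def foundation(self) -> float:
        """Confined modulus of the cartilage layer (MPa)."""
        return foundation_modulus(self.cartilage_E, self.cartilage_nu)

    @property
    def total_thickness(self) -> float:
        """Two cartilage layers in series across the joint space (mm)."""
        return 2.0 * self.cartilage_thickness

    def bone_modulus(self, rho):
        return density_to_modulus(np.asarray(rho) * self.density_scale, self.bone_law_a, self.bone_law_exponent)

    def to_dict(self) -> dict:
        return {
            "cartilage_E": self.cartilage_E,
            "cartilage_nu": self.cartilage_nu,
            "cartilage_thickness": self.cartilage_thickness,
            "bone_law_a": self.bone_law_a,
            "bone_law_exponent": self.bone_law_exponent,
            "ligament_table": {k: list(v) for k, v in self.ligament_table.items()},
            "friction": self.friction,
            "density_scale": self.density_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialSet":
        d = dict(d)
        if "ligament_table" in d:
            d["ligament_table"] = {k: tuple(v) for k, v in d["ligament_table"].items()}
        return cls(**d)
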