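"""Elastic-foundation tibiofemoral contact under prescribed varus loading.

The continuum finite-element stage of the original workflow is replaced by a
bed-of-springs (elastic foundation) contact model: local pressure is the
foundation modulus ``E(1-nu)/((1+nu)(1-2nu))`` times local layer compression
divided by the total cartilage thickness (two 0.25 mm layers in series).
Bone is rigid.  The joint is posed at 80 deg flexion in the joint coordinate
system (JCS); loading is either

* fraction mode -- the 2.94 N standing load is split between compartments as
  (50/50, 75/25, 100/0) % for the 0/50/100 % varus levels and each
  compartment is solved independently for its prescribed force; or
* angle mode -- the femur is additionally tilted 0/3/6 deg about the JCS Y
  axis and a single femoral translation is solved so that total contact
  force plus the vertical ligament components balances the applied load;
  the medial force fraction then emerges from the geometry.

Contact search uses the 0.1 mm pinball rule: tibial elements whose initial
cartilage-to-cartilage gap exceeds the pinball radius are excluded from the
candidate set.  Gaps are measured along the JCS Z axis (the plateau is
near-perpendicular to Z at the standing pose) and element areas are
projected onto the plateau plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import KneeSpecimen, LIGAMENT_NAMES
from .materials import MaterialSet, ligament_force
from .mesh import directed_distances, rotate_points


class GeometryError(ValueError):
    """Raised when a loaded compartment has no candidate contact."""


class SolverError(RuntimeError):
    """Raised on non-convergence of the equilibrium search."""


# ----------------------------------------------------------------------
# joint coordinate system
# ----------------------------------------------------------------------

@dataclass
class JointCS:
    """Origin at the epicondylar midpoint; X lateral, Z femur->tibia, Y = X x Z.

    The literal cross product X x Z yields a left-handed triad under the
    right-handed world convention used here; the axes are kept exactly as
    defined (they are mutually orthonormal) and +Y points anteriorly in the
    generated cohort.  Rotations are always specified about an explicit axis,
    so handedness never enters silently.
    """

    origin: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray

    def __post_init__(self) -> None:
        for a in (self.X, self.Y, self.Z):
            if abs(np.linalg.norm(a) - 1.0) > 1e-9:
                raise GeometryError("JCS axes must be unit length")
        for a, b in ((self.X, self.Y), (self.X, self.Z), (self.Y, self.Z)):
            if abs(float(a @ b)) > 1e-9:
                raise GeometryError("JCS axes must be mutually orthogonal")


def build_jcs(s: KneeSpecimen) -> JointCS:
    """JCS from landmarks: epicondylar line, plateau normal, their cross product.

    Z is adjusted minimally to be orthogonal to X before forming Y = X x Z.
    """
    lm = s.landmarks
    med, lat = lm["medial_epicondyle"], lm["lateral_epicondyle"]
    if np.linalg.norm(lat - med) < 1e-9:
        raise GeometryError("coincident epicondyle landmarks")
    origin = 0.5 * (med + lat)
    X = (lat - med) / np.linalg.norm(lat - med)
    z0 = lm["plateau_normal_ref"] - lm["plateau_center"]
    if np.linalg.norm(z0) < 1e-9:
        raise GeometryError("degenerate plateau normal reference")
    z0 = z0 / np.linalg.norm(z0)
    Z = z0 - (z0 @ X) * X
    if np.linalg.norm(Z) < 1e-9:
        raise GeometryError("plateau normal parallel to epicondylar line")
    Z = Z / np.linalg.norm(Z)
    Y = np.cross(X, Z)
    return JointCS(origin=origin, X=X, Y=Y / np.linalg.norm(Y), Z=Z)


# ----------------------------------------------------------------------
# posing
# ----------------------------------------------------------------------

def _rotate_femoral_side(s: KneeSpecimen, axis: np.ndarray, origin: np.ndarray,
                         angle_rad: float) -> KneeSpecimen:
    """Rotate femur (patella follows the femur) about an axis through origin."""
    out = s.copy()
    out.femur.vertices = rotate_points(out.femur.vertices, axis, origin, angle_rad)
    out.patella.vertices = rotate_points(out.patella.vertices, axis, origin, angle_rad)
    return out


def pose_flexion(s: KneeSpecimen, jcs: JointCS, flexion_deg: float) -> KneeSpecimen:
    """Hinge the femur about the epicondylar (JCS X) axis; tibia stays fixed.

    Positive flexion carries the femoral shaft posteriorly.  Because the
    condylar articular surfaces are bands of spheres centred on this axis,
    the articulation is geometrically consistent at any flexion angle.
    """
    if flexion_deg == 0:
        return s.copy()
    return _rotate_femoral_side(s, jcs.X, jcs.origin, math.radians(flexion_deg))


def pose_varus(s: KneeSpecimen, jcs: JointCS, varus_deg: float) -> KneeSpecimen:
    """Tilt the femur about the JCS Y axis so the medial condyle approaches the tibia.

    The rotation sign is resolved geometrically: of the two candidate senses,
    the one that moves the medial femoral cartilage centroid along +Z (toward
    the tibia) is varus.  Deterministic for any specimen orientation.
    """
    if varus_deg == 0:
        return s.copy()
    patch = s.cartilage_patch("femur", "medial")
    centroid = s.femur.face_centroids()[patch.face_indices].mean(axis=0)
    moved = rotate_points(centroid[None, :], jcs.Y, jcs.origin, math.radians(varus_deg))[0]
    sign = 1.0 if (moved - centroid) @ jcs.Z > 0 else -1.0
    return _rotate_femoral_side(s, jcs.Y, jcs.origin, sign * math.radians(varus_deg))


def translate_femur(s: KneeSpecimen, direction: np.ndarray, distance: float) -> KneeSpecimen:
    out = s.copy()
    out.femur.vertices = out.femur.vertices + distance * direction
    out.patella.vertices = out.patella.vertices + distance * direction
    return out


# ----------------------------------------------------------------------
# load cases and results
# ----------------------------------------------------------------------

VARUS_LEVELS = (0, 50, 100)


@dataclass
class LoadCase:
    """Varus loading description: 2.94 N at 80 deg flexion, fraction or angle mode."""

    total_force: float = 2.94          # N
    flexion_deg: float = 80.0
    mode: str = "fraction"             # fraction | angle
    varus_level: int = 0               # % (fraction mode)
    varus_angle: float = 0.0           # deg (angle mode)
    pinball: float = 0.1               # mm contact-search cutoff

    def __post_init__(self) -> None:
        if self.total_force <= 0:
            raise ValueError("total force must be positive")
        if self.mode not in ("fraction", "angle"):
            raise ValueError("mode must be 'fraction' or 'angle'")
        if self.mode == "fraction" and self.varus_level not in VARUS_LEVELS:
            raise ValueError(f"varus level must be one of {VARUS_LEVELS}")
        if self.mode == "angle" and not 0.0 <= self.varus_angle <= 10.0:
            raise ValueError("varus angle must be in [0, 10] deg")


def redistribute_load(total: float, varus_level: int) -> tuple[float, float]:
    """(medial, lateral) compartment forces for a varus level in {0, 50, 100} %.

    Neutral is an even split; at 50 % the medial share is 1.5x and the
    lateral 0.5x the neutral half; at 100 % the lateral compartment is
    unloaded.  The sum always equals the total.
    """
    if varus_level not in VARUS_LEVELS:
        raise ValueError(f"unsupported varus level {varus_level!r}")
    half = 0.5 * total
    factor = {0: 1.0, 50: 1.5, 100: 2.0}[varus_level]
    medial = factor * half
    return medial, total - medial


@dataclass
class GapField:
    """Initial cartilage-to-cartilage separation over one compartment."""

    side: str
    gaps: np.ndarray           # mm, along -Z; may be negative (interpenetration)
    areas: np.ndarray          # mm^2, projected onto the plateau plane
    face_ids: np.ndarray       # tibial host-mesh face indices
    candidates: np.ndarray     # pinball mask
    patch_area: float          # total projected compartment area, mm^2

    @property
    def near_contact_area(self) -> float:
        """Projected area of candidate (within-pinball) elements, mm^2."""
        return float(self.areas[self.candidates].sum())


def compartment_gap_field(s: KneeSpecimen, jcs: JointCS, side: str,
                          femoral_thickness: float = 0.25, tibial_thickness: float = 0.25,
                          pinball: float = 0.1) -> GapField:
    """Per-element initial gap between opposing outer cartilage surfaces.

    For each tibial plateau cartilage element of the given side, the bone-to-
    bone separation along -Z to the femoral cartilage surface is ray-cast,
    and both surfaces are offset outward by their cartilage thickness, so
    ``gap = separation - (t_femoral + t_tibial)``.  Elements farther than the
    pinball radius are kept in the field but flagged out of the candidate
    set.  A side with no opposing femoral surface yields an empty field.
    """
    tib_patch = s.cartilage_patch("tibia_fibula", side)
    mesh = s.tibia_fibula
    centroids = mesh.face_centroids()[tib_patch.face_indices]
    normals, areas = mesh.face_normals_areas()
    proj = areas[tib_patch.face_indices] * np.abs(normals[tib_patch.face_indices] @ jcs.Z)
    fem_faces = np.concatenate([
        s.cartilage_patch("femur", "medial").face_indices,
        s.cartilage_patch("femur", "lateral").face_indices,
    ])
    fem_mask = np.zeros(s.femur.n_faces, dtype=bool)
    fem_mask[fem_faces] = True
    sep = directed_distances(s.femur, centroids, -jcs.Z, face_mask=fem_mask)
    hit = np.isfinite(sep)
    gaps = sep[hit] - (femoral_thickness + tibial_thickness)
    return GapField(
        side=side,
        gaps=gaps,
        areas=proj[hit],
        face_ids=tib_patch.face_indices[hit],
        candidates=gaps <= pinball,
        patch_area=float(proj.sum()),
    )


@dataclass
class CompartmentResult:
    """Per-compartment outcome: peak pressure, contact area, pressure field."""

    side: str
    prescribed_force: float | None
    achieved_force: float
    peak_pressure: float       # MPa
    contact_area: float        # mm^2 of elements with pressure > 0
    pressures: np.ndarray = field(repr=False, default=None)
    areas: np.ndarray = field(repr=False, default=None)
    face_ids: np.ndarray = field(repr=False, default=None)
    near_contact_area: float = 0.0


@dataclass
class ContactOutcome:
    medial: CompartmentResult
    lateral: CompartmentResult
    ligament_forces: dict[str, float]
    equilibrium_residual: float
    mode: str
    varus_level: int | None = None
    varus_angle: float | None = None
    medial_fraction: float | None = None
    indentation: float | None = None

    @property
    def total_contact_force(self) -> float:
        return self.medial.achieved_force + self.lateral.achieved_force


# ----------------------------------------------------------------------
# foundation solve
# ----------------------------------------------------------------------

def _foundation_force(u: float, gaps: np.ndarray, areas: np.ndarray, k: float) -> float:
    pen = u - gaps
    return float(k * np.sum(np.where(pen > 0, pen, 0.0) * areas))


def solve_indentation(gap_field: GapField, E_foundation: float, total_thickness: float,
                      target_force: float, tol: float = 1e-6, max_iter: int = 200
                      ) -> tuple[float, CompartmentResult]:
    """Find the rigid approach u with total spring force equal to the target.

    Pressure on candidate element i is ``(E/t) * max(0, u - g_i)``; the force
    balance is solved by bisection on a geometrically grown bracket to a
    tolerance of 1e-6 N.  ``target_force = 0`` returns an empty field.
    """
    if target_force < 0 or E_foundation <= 0 or total_thickness <= 0:
        raise ValueError("invalid foundation solve parameters")
    g = gap_field.gaps[gap_field.candidates]
    A = gap_field.areas[gap_field.candidates]
    ids = gap_field.face_ids[gap_field.candidates]
    empty = CompartmentResult(
        side=gap_field.side, prescribed_force=target_force, achieved_force=0.0,
        peak_pressure=0.0, contact_area=0.0,
        pressures=np.zeros(len(g)), areas=A, face_ids=ids,
        near_contact_area=gap_field.near_contact_area,
    )
    if target_force == 0.0:
        return 0.0, empty
    if len(g) == 0:
        raise GeometryError(f"{gap_field.side}: no candidate contact for a loaded compartment")
    k = E_foundation / total_thickness

    lo = float(g.min())                     # no penetration anywhere at u = g.min()
    hi = lo + max(total_thickness, 1e-3)
    it = 0
    while _foundation_force(hi, g, A, k) < target_force:
        hi = lo + 2.0 * (hi - lo)
        it += 1
        if it > 60:
            raise SolverError("could not bracket the target force")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = _foundation_force(mid, g, A, k)
        if abs(f - target_force) <= tol:
            lo = hi = mid
            break
        if f < target_force:
            lo = mid
        else:
            hi = mid
    else:
        raise SolverError("foundation solve did not converge within 200 iterations")
    u = 0.5 * (lo + hi)
    pen = np.maximum(0.0, u - g)
    pressures = k * pen
    achieved = float(np.sum(pressures * A))
    peak_i = int(np.argmax(pressures)) if len(pressures) else 0
    return u, CompartmentResult(
        side=gap_field.side, prescribed_force=target_force, achieved_force=achieved,
        peak_pressure=float(pressures[peak_i]) if len(pressures) else 0.0,
        contact_area=float(A[pressures > 0].sum()),
        pressures=pressures, areas=A, face_ids=ids,
        near_contact_area=gap_field.near_contact_area,
    )


# ----------------------------------------------------------------------
# ligaments
# ----------------------------------------------------------------------

def ligament_lengths(s: KneeSpecimen) -> dict[str, float]:
    return {name: float(np.linalg.norm(ins - org)) for name, (org, ins) in s.ligaments.items()}


# ----------------------------------------------------------------------
# full load cases
# ----------------------------------------------------------------------

def solve_load_case_fraction(s: KneeSpecimen, materials: MaterialSet, case: LoadCase,
                             jcs: JointCS | None = None) -> ContactOutcome:
    """Prescribed per-compartment forces; compartments solved independently.

    Ligament tensions are reported at the posed neutral configuration but are
    excluded from the force balance in this mode, so the achieved compartment
    forces sum to the applied total by construction.
    """
    if case.mode != "fraction":
        raise ValueError("load case is not in fraction mode")
    return solve_fraction_sweep(s, materials, [case.varus_level], case, jcs)[case.varus_level]


def solve_fraction_sweep(s: KneeSpecimen, materials: MaterialSet, levels,
                         case: LoadCase | None = None, jcs: JointCS | None = None
                         ) -> dict[int, ContactOutcome]:
    """Solve several varus levels reusing one posed specimen and gap field."""
    if case is None:
        case = LoadCase()
    if jcs is None:
        jcs = build_jcs(s)
    posed = pose_flexion(s, jcs, case.flexion_deg)
    t = materials.cartilage_thickness
    fields = {side: compartment_gap_field(posed, jcs, side, t, t, case.pinball)
              for side in ("medial", "lateral")}
    ref_len = ligament_lengths(posed)
    tensions = {name: materials.ligament_table[name][0] * materials.ligament_table[name][1] * L
                for name, L in ref_len.items()}
    E, tt = materials.foundation, materials.total_thickness
    out = {}
    for level in levels:
        f_med, f_lat = redistribute_load(case.total_force, level)
        _, med = solve_indentation(fields["medial"], E, tt, f_med)
        _, lat = solve_indentation(fields["lateral"], E, tt, f_lat)
        residual = abs(med.achieved_force + lat.achieved_force - case.total_force)
        out[level] = ContactOutcome(
            medial=med, lateral=lat, ligament_forces=dict(tensions),
            equilibrium_residual=residual, mode="fraction", varus_level=level,
            medial_fraction=f_med / case.total_force,
        )
    return out


def solve_load_case_angle(s: KneeSpecimen, materials: MaterialSet, case: LoadCase,
                          jcs: JointCS | None = None, tol: float = 1e-6,
                          max_iter: int = 200) -> ContactOutcome:
    """Prescribed varus angulation; a single femoral translation balances the load.

    The femur is rotated by the varus angle about the JCS Y axis through the
    origin, then translated along +Z until total contact force plus the
    vertical (Z) component of the tension-only ligament forces equals the
    applied load.  Ligament reference lengths are taken at the flexion-posed
    neutral configuration, so each ligament carries its pretension there.
    Compartment forces emerge from the geometry; the medial fraction is
    reported.
    """
    if case.mode != "angle":
        raise ValueError("load case is not in angle mode")
    if jcs is None:
        jcs = build_jcs(s)
    posed = pose_flexion(s, jcs, case.flexion_deg)
    ref_len = ligament_lengths(posed)
    tilted = pose_varus(posed, jcs, case.varus_angle)
    t = materials.cartilage_thickness
    fields = {side: compartment_gap_field(tilted, jcs, side, t, t, case.pinball)
              for side in ("medial", "lateral")}
    E, tt = materials.foundation, materials.total_thickness
    k = E / tt

    lig = {name: materials.ligament_table[name] for name in LIGAMENT_NAMES}
    attach = tilted.ligaments

    def lig_pull(u: float) -> tuple[dict[str, float], float]:
        """Tensions and their net pull on the femur along +Z after translation u."""
        tensions, fz = {}, 0.0
        for name, (org0, ins) in attach.items():
            org = org0 + u * jcs.Z
            length = float(np.linalg.norm(ins - org))
            tension = ligament_force(length, ref_len[name], *lig[name])
            tensions[name] = tension
            if tension > 0 and length > 0:
                fz += tension * float(((ins - org) / length) @ jcs.Z)
        return tensions, fz

    def contact_force(u: float) -> float:
        return sum(_foundation_force(u, f.gaps[f.candidates], f.areas[f.candidates], k)
                   for f in fields.values())

    def residual(u: float) -> float:
        # equilibrium of the femur along Z: applied + ligament pull = contact
        _, fz = lig_pull(u)
        return contact_force(u) - (case.total_force + fz)

    lo = min(float(f.gaps.min(initial=0.0)) for f in fields.values()) - materials.total_thickness
    hi = lo + max(materials.total_thickness, 1e-3)
    it = 0
    while residual(hi) < 0:
        hi = lo + 2.0 * (hi - lo)
        it += 1
        if it > 60:
            raise SolverError("could not bracket angle-mode equilibrium")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = residual(mid)
        if abs(r) <= tol:
            lo = hi = mid
            break
        if r < 0:
            lo = mid
        else:
            hi = mid
    else:
        raise SolverError("angle-mode solve did not converge")
    u = 0.5 * (lo + hi)

    results = {}
    for side, f in fields.items():
        g = f.gaps[f.candidates]
        A = f.areas[f.candidates]
        pen = np.maximum(0.0, u - g)
        p = k * pen
        peak = float(p.max()) if len(p) else 0.0
        results[side] = CompartmentResult(
            side=side, prescribed_force=None,
            achieved_force=float(np.sum(p * A)),
            peak_pressure=peak,
            contact_area=float(A[p > 0].sum()),
            pressures=p, areas=A, face_ids=f.face_ids[f.candidates],
            near_contact_area=f.near_contact_area,
        )
    tensions, fz = lig_pull(u)
    total_contact = results["medial"].achieved_force + results["lateral"].achieved_force
    residual_n = abs(total_contact - case.total_force - fz)
    frac = results["medial"].achieved_force / total_contact if total_contact > 0 else np.nan
    return ContactOutcome(
        medial=results["medial"], lateral=results["lateral"],
        ligament_forces=tensions, equilibrium_residual=residual_n,
        mode="angle", varus_angle=case.varus_angle, medial_fraction=frac,
        indentation=u,
    )
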