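"""Synthetic bilateral rat-knee cohort and pressure-film measurement emulator.

The generator stands in for the micro-CT specimens of the varus-loading
study: 10 hind limbs from 5 animals, bilateral, with left limbs mirrored to a
right-side representation.  Each specimen is a deformation of one shared
template grid, so nodal correspondence across the cohort holds by
construction (the stand-in for deformable mesh registration).

Geometry primitives: each femoral condyle is a band of a sphere centred on
the epicondylar axis; each tibial plateau compartment is a concave dish that
follows the condylar sphere offset by a standoff plus a paraboloid
conformity-mismatch term.  The initial cartilage-to-cartilage gap over a
compartment is therefore exactly ``conformity * r^2 / 2`` -- smooth,
conforming-but-nonconforming contact with analytically known curvature.

Anatomical variation is parametric: a small set of dimension and density
parameters is drawn per animal (between-animal SDs) and per limb around the
animal value (within-animal SDs), all as multiplicative perturbations of the
nominal geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .mesh import (
    SurfaceMesh,
    concat_meshes,
    open_cylinder,
    plateau_dish,
    spherical_band,
    uv_ellipsoid,
)


class ConfigurationError(ValueError):
    """Raised for invalid generator or film configuration."""


# parameters subject to biological variation (multiplicative perturbations)
VARIED_PARAMETERS = (
    "scale",
    "condyle_spacing",
    "conformity_medial",
    "conformity_lateral",
    "cortical_density",
    "trabecular_density",
)


def _default_between_sd() -> dict[str, float]:
    return {
        "scale": 0.02,
        "condyle_spacing": 0.015,
        "conformity_medial": 0.10,
        "conformity_lateral": 0.10,
        "cortical_density": 0.05,
        "trabecular_density": 0.05,
    }


def _default_within_sd() -> dict[str, float]:
    return {
        "scale": 0.005,
        "condyle_spacing": 0.004,
        "conformity_medial": 0.03,
        "conformity_lateral": 0.03,
        "cortical_density": 0.01,
        "trabecular_density": 0.01,
    }


@dataclass
class GeneratorConfig:
    """Cohort-level study conditions and nominal rat-knee geometry (mm, g/cm^3)."""

    n_animals: int = 5
    limbs_per_animal: int = 2
    seed: int = 0

    # nominal geometry
    scale: float = 1.0                    # global uniform size factor
    condyle_radius: float = 2.6           # articular sphere radius
    condyle_spacing: float = 4.6          # medial-lateral centre distance
    conformity_medial: float = 0.00402    # gap curvature mismatch, 1/mm
    conformity_lateral: float = 0.00472
    plateau_radius: float = 2.0           # compartment planform radius
    standoff: float = 0.5                 # bone-to-bone apex separation
    epicondyle_halfwidth: float = 3.8
    femur_length: float = 9.0
    tibia_length: float = 10.0
    shaft_radius: float = 1.6
    patella_radii: tuple[float, float, float] = (1.0, 0.6, 1.4)
    patella_offset: tuple[float, float, float] = (0.0, -3.0, -1.0)

    # density field (two-level: periosteal/cortical shell vs articular/subchondral)
    cortical_density: float = 1.2
    trabecular_density: float = 0.6

    # mesh resolution targets; articular contact patches are refined well
    # below the bone average so facet sagitta stays far under the micron-scale
    # cartilage compressions resolved by the foundation solver
    edge_length_bone: float = 0.3
    edge_length_patella: float = 0.2
    edge_length_articular: float = 0.08
    cartilage_thickness: float = 0.25

    between_animal_sd: dict[str, float] = field(default_factory=_default_between_sd)
    within_animal_sd: dict[str, float] = field(default_factory=_default_within_sd)

    def __post_init__(self) -> None:
        if self.n_animals <= 0 or self.limbs_per_animal <= 0:
            raise ConfigurationError("animal and limb counts must be positive")
        for name, table in (("between", self.between_animal_sd), ("within", self.within_animal_sd)):
            for key, sd in table.items():
                if key not in VARIED_PARAMETERS:
                    raise ConfigurationError(f"unknown varied parameter {key!r}")
                if sd < 0:
                    raise ConfigurationError(f"{name}-animal SD for {key!r} must be >= 0")
        for val in (
            self.condyle_radius,
            self.condyle_spacing,
            self.plateau_radius,
            self.standoff,
            self.edge_length_bone,
            self.edge_length_patella,
            self.cartilage_thickness,
            self.scale,
        ):
            if val <= 0:
                raise ConfigurationError("geometry parameters must be positive")

    def scaled(self, factor: float) -> "GeneratorConfig":
        """Uniformly scale every nominal linear dimension (conformity is 1/length)."""
        d = self.to_dict()
        # standoff stays equal to the summed cartilage thickness (a material
        # constant), so the cartilage surfaces keep touching at the apex
        for key in (
            "condyle_radius", "condyle_spacing", "plateau_radius",
            "epicondyle_halfwidth", "femur_length", "tibia_length", "shaft_radius",
        ):
            d[key] = d[key] * factor
        d["patella_radii"] = tuple(r * factor for r in self.patella_radii)
        d["patella_offset"] = tuple(o * factor for o in self.patella_offset)
        d["conformity_medial"] = self.conformity_medial / factor
        d["conformity_lateral"] = self.conformity_lateral / factor
        # edge-length targets scale with the geometry so the template grid
        # (and hence cohort correspondence) is unchanged by calibration
        d["edge_length_bone"] = self.edge_length_bone * factor
        d["edge_length_patella"] = self.edge_length_patella * factor
        d["edge_length_articular"] = self.edge_length_articular * factor
        return GeneratorConfig(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["patella_radii"] = tuple(self.patella_radii)
        d["patella_offset"] = tuple(self.patella_offset)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("patella_radii", "patella_offset"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class CartilagePatch:
    """Articular cartilage as a thickness attribute on a subset of host faces."""

    host_body: str
    side: str  # medial | lateral
    face_indices: np.ndarray
    thickness: float = 0.25

    def __post_init__(self) -> None:
        self.face_indices = np.asarray(self.face_indices, dtype=np.int64)
        if self.host_body not in ("femur", "tibia_fibula"):
            raise ConfigurationError("cartilage host must be femur or tibia_fibula")
        if self.side not in ("medial", "lateral"):
            raise ConfigurationError("cartilage side must be medial or lateral")
        if self.thickness <= 0:
            raise ConfigurationError("cartilage thickness must be positive")


LANDMARK_NAMES = ("medial_epicondyle", "lateral_epicondyle", "plateau_center", "plateau_normal_ref")
LIGAMENT_NAMES = ("ACL", "PCL", "MCL", "LCL")


@dataclass
class KneeSpecimen:
    """One limb: three bone meshes, cartilage patches, landmarks, ligaments."""

    animal_id: int
    side_as_acquired: str  # left | right
    is_mirrored: bool
    femur: SurfaceMesh
    tibia_fibula: SurfaceMesh
    patella: SurfaceMesh
    cartilage: list[CartilagePatch]

    def __post_init__(self) -> None:
        if self.side_as_acquired not in ("left", "right"):
            raise ConfigurationError("side must be left or right")
        if len(self.cartilage) != 4:
            raise ConfigurationError("a specimen carries exactly 4 cartilage patches")

    # ------------------------------------------------------------------
    @property
    def limb_id(self) -> str:
        return f"a{self.animal_id}_{self.side_as_acquired[0].upper()}"

    def body(self, name: str) -> SurfaceMesh:
        return {"femur": self.femur, "tibia_fibula": self.tibia_fibula, "patella": self.patella}[name]

    def bodies(self) -> list[SurfaceMesh]:
        return [self.femur, self.tibia_fibula, self.patella]

    @property
    def landmarks(self) -> dict[str, np.ndarray]:
        return {
            "medial_epicondyle": self.femur.marker_point("medial_epicondyle"),
            "lateral_epicondyle": self.femur.marker_point("lateral_epicondyle"),
            "plateau_center": self.tibia_fibula.marker_point("plateau_center"),
            "plateau_normal_ref": self.tibia_fibula.marker_point("plateau_normal_ref"),
        }

    @property
    def ligaments(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """name -> (femoral origin, tibial insertion), current coordinates."""
        return {
            name: (
                self.femur.marker_point(f"{name}_origin"),
                self.tibia_fibula.marker_point(f"{name}_insertion"),
            )
            for name in LIGAMENT_NAMES
        }

    def cartilage_patch(self, host_body: str, side: str) -> CartilagePatch:
        for p in self.cartilage:
            if p.host_body == host_body and p.side == side:
                return p
        raise KeyError(f"no cartilage patch {host_body}/{side}")

    def copy(self) -> "KneeSpecimen":
        return KneeSpecimen(
            animal_id=self.animal_id,
            side_as_acquired=self.side_as_acquired,
            is_mirrored=self.is_mirrored,
            femur=self.femur.copy(),
            tibia_fibula=self.tibia_fibula.copy(),
            patella=self.patella.copy(),
            cartilage=[
                CartilagePatch(p.host_body, p.side, p.face_indices.copy(), p.thickness)
                for p in self.cartilage
            ],
        )


# ----------------------------------------------------------------------
# template resolution (fixed across a cohort -> shared topology)
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class _Resolution:
    band_nu: int
    band_nv: int
    band_u_range: tuple[float, float]
    band_v_max: float
    dish_nr: int
    dish_nt: int
    shaft_nz_femur: int
    shaft_nz_tibia: int
    shaft_nc: int
    patella_nu: int
    patella_nv: int


def _template_resolution(cfg: GeneratorConfig) -> _Resolution:
    e = cfg.edge_length_bone
    ea = cfg.edge_length_articular
    rc = cfg.condyle_radius
    # the band spans [0, 160] deg so the 80 deg standing pose faces the
    # plateau symmetrically (+-80 deg of sagittal coverage after posing)
    u_range = (0.0, math.radians(160.0))
    v_max = min(math.radians(80.0), math.asin(min(0.97, cfg.plateau_radius / rc)) + math.radians(6.0))
    band_nu = max(4, round(rc * (u_range[1] - u_range[0]) / ea))
    band_nv = max(4, round(rc * 2 * v_max / ea))
    dish_nr = max(4, round(cfg.plateau_radius / ea))
    dish_nt = max(8, round(2 * math.pi * cfg.plateau_radius / ea))
    shaft_nc = max(8, round(2 * math.pi * cfg.shaft_radius / e))
    shaft_nz_femur = max(4, round((cfg.femur_length - 1.5) / e))
    shaft_nz_tibia = max(4, round((cfg.tibia_length - 1.0) / e))
    ep = cfg.edge_length_patella
    patella_nv = max(8, round(2 * math.pi * max(cfg.patella_radii) / ep))
    patella_nu = max(4, round(math.pi * max(cfg.patella_radii) / ep))
    return _Resolution(
        band_nu, band_nv, u_range, v_max, dish_nr, dish_nt,
        shaft_nz_femur, shaft_nz_tibia, shaft_nc, patella_nu, patella_nv,
    )


# ----------------------------------------------------------------------
# specimen construction
# ----------------------------------------------------------------------

def _build_right_specimen(
    cfg: GeneratorConfig, params: dict[str, float], res: _Resolution, animal_id: int, side: str
) -> KneeSpecimen:
    """Build a specimen in right-side representation from drawn parameters."""
    s = params["scale"]
    rc = cfg.condyle_radius
    half = params["condyle_spacing"] / 2.0

    band_med = spherical_band(
        np.array([-half, 0.0, 0.0]), rc, res.band_u_range, res.band_v_max,
        res.band_nu, res.band_nv, "medial",
    )
    band_lat = spherical_band(
        np.array([half, 0.0, 0.0]), rc, res.band_u_range, res.band_v_max,
        res.band_nu, res.band_nv, "lateral",
    )
    fem_shaft = open_cylinder((0.0, 0.0), (-1.5, -cfg.femur_length), cfg.shaft_radius,
                              res.shaft_nz_femur, res.shaft_nc, "femur")

    n_band = band_med.n_vertices
    femur = concat_meshes([band_med, band_lat, fem_shaft], "femur")
    e = cfg.epicondyle_halfwidth
    fem_markers = {
        "medial_epicondyle": [-e, 0.0, 0.0],
        "lateral_epicondyle": [e, 0.0, 0.0],
        "ACL_origin": [0.5, 0.3, 0.3],
        "PCL_origin": [-0.5, 0.3, 0.4],
        "MCL_origin": [-e, 0.0, 0.2],
        "LCL_origin": [e, 0.0, 0.2],
    }
    femur = _append_markers(femur, fem_markers)
    fem_density = np.full(femur.n_vertices, params["cortical_density"])
    fem_density[: 2 * n_band] = params["trabecular_density"]
    femur.vertex_density = fem_density
    femur.validate()

    dish_med = plateau_dish(-half, rc, params["conformity_medial"], cfg.standoff,
                            cfg.plateau_radius, res.dish_nr, res.dish_nt, "medial")
    dish_lat = plateau_dish(half, rc, params["conformity_lateral"], cfg.standoff,
                            cfg.plateau_radius, res.dish_nr, res.dish_nt, "lateral")
    tib_shaft = open_cylinder((0.0, 0.0), (rc + 1.0, rc + cfg.tibia_length), cfg.shaft_radius,
                              res.shaft_nz_tibia, res.shaft_nc, "tibia_fibula")
    n_dish = dish_med.n_vertices
    tibia = concat_meshes([dish_med, dish_lat, tib_shaft], "tibia_fibula")
    tib_markers = {
        "plateau_center": [0.0, 0.0, rc + cfg.standoff],
        "plateau_normal_ref": [0.0, 0.0, rc + cfg.standoff + 1.0],
        "ACL_insertion": [-0.2, -0.8, rc + 0.7],
        "PCL_insertion": [0.0, 1.0, rc + 1.0],
        "MCL_insertion": [-0.8 * e, 0.2, rc + 4.5],
        "LCL_insertion": [0.8 * e, 0.2, rc + 4.3],
    }
    tibia = _append_markers(tibia, tib_markers)
    tib_density = np.full(tibia.n_vertices, params["cortical_density"])
    tib_density[: 2 * n_dish] = params["trabecular_density"]
    tibia.vertex_density = tib_density
    tibia.validate()

    patella = uv_ellipsoid(np.asarray(cfg.patella_offset), cfg.patella_radii,
                           res.patella_nu, res.patella_nv)
    patella.vertex_density = np.full(patella.n_vertices, params["cortical_density"])
    patella.validate()

    # uniform size factor applied to every linear dimension
    for mesh in (femur, tibia, patella):
        mesh.vertices *= s

    n_band_faces = band_med.n_faces
    n_dish_faces = dish_med.n_faces
    t = cfg.cartilage_thickness
    cartilage = [
        CartilagePatch("femur", "medial", np.arange(n_band_faces), t),
        CartilagePatch("femur", "lateral", np.arange(n_band_faces, 2 * n_band_faces), t),
        CartilagePatch("tibia_fibula", "medial", np.arange(n_dish_faces), t),
        CartilagePatch("tibia_fibula", "lateral", np.arange(n_dish_faces, 2 * n_dish_faces), t),
    ]
    return KneeSpecimen(animal_id, side, False, femur, tibia, patella, cartilage)


def _append_markers(mesh: SurfaceMesh, markers: dict[str, list[float]]) -> SurfaceMesh:
    verts = np.vstack([mesh.vertices, np.asarray(list(markers.values()), dtype=float)])
    marker_idx = {name: mesh.n_vertices + i for i, name in enumerate(markers)}
    dens = mesh.vertex_density
    if dens is not None:
        dens = np.concatenate([dens, np.zeros(len(markers))])
    return SurfaceMesh(verts, mesh.faces, mesh.body, vertex_density=dens,
                       face_region=mesh.face_region, markers={**mesh.markers, **marker_idx})


# ----------------------------------------------------------------------
# cohort generation
# ----------------------------------------------------------------------

def mirror_specimen(s: KneeSpecimen) -> KneeSpecimen:
    """Sagittal-plane reflection of every body, landmark and attachment.

    Face winding is flipped so outward orientation is preserved; applying the
    operation twice restores the specimen exactly (involution).
    """
    out = s.copy()
    out.femur = out.femur.mirrored_x()
    out.tibia_fibula = out.tibia_fibula.mirrored_x()
    out.patella = out.patella.mirrored_x()
    out.is_mirrored = not s.is_mirrored
    return out


def generate_cohort(config: GeneratorConfig) -> list[KneeSpecimen]:
    """Generate ``n_animals * limbs_per_animal`` specimens, all right-represented.

    Animal-level parameters are drawn from the between-animal distributions;
    limb-level parameters from the within-animal distributions around the
    animal value.  Left limbs are built in their as-acquired left orientation
    and then mirrored to the right representation (``is_mirrored`` set).
    Deterministic for a fixed seed: each animal and limb consumes an
    independent substream spawned from the master seed.
    """
    res = _template_resolution(config)
    master = np.random.SeedSequence(config.seed)
    sides = ["right", "left"] * ((config.limbs_per_animal + 1) // 2)
    cohort: list[KneeSpecimen] = []
    for a in range(config.n_animals):
        streams = master.spawn(1 + config.limbs_per_animal)
        animal_ss, limb_ss = streams[0], streams[1:]
        rng_animal = np.random.default_rng(animal_ss)
        # freeze the animal draw once, reuse for each limb
        animal_eps = {key: rng_animal.normal(0.0, config.between_animal_sd.get(key, 0.0))
                      for key in VARIED_PARAMETERS}
        for li in range(config.limbs_per_animal):
            rng_limb = np.random.default_rng(limb_ss[li])
            params = {}
            for key in VARIED_PARAMETERS:
                eps_w = rng_limb.normal(0.0, config.within_animal_sd.get(key, 0.0))
                val = getattr(config, key) * (1.0 + animal_eps[key]) * (1.0 + eps_w)
                params[key] = max(val, 1e-12)
            side = sides[li]
            spec = _build_right_specimen(config, params, res, animal_id=a, side=side)
            if side == "left":
                # as-acquired left orientation, then normalised back to right
                spec = mirror_specimen(spec)      # right template -> left as acquired
                spec.is_mirrored = False
                spec = mirror_specimen(spec)      # mirrored to right representation
            cohort.append(spec)
    return cohort


# ----------------------------------------------------------------------
# pressure-film measurement emulator
# ----------------------------------------------------------------------

@dataclass
class FilmModel:
    """Pressure-sensitive film response: floor, saturation, noise, quantisation.

    Emulates the film measurement protocol of the physical rig: per trial the
    true element pressures receive multiplicative lognormal noise, saturate at
    the ceiling, fall below the detection floor to zero and are quantised;
    peak and stained area are averaged over ``n_trials`` repeated tests.
    """

    detection_floor: float = 0.05      # MPa
    saturation_ceiling: float = 10.0   # MPa
    multiplicative_noise_sd: float = 0.03
    quantization_step: float = 0.0     # MPa; 0 disables quantisation
    n_trials: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_floor < self.saturation_ceiling:
            raise ConfigurationError("require 0 <= floor < ceiling")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.multiplicative_noise_sd < 0 or self.quantization_step < 0:
            raise ConfigurationError("noise SD and quantisation step must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilmModel":
        return cls(**d)


def emulate_pressure_film(
    pressures: np.ndarray,
    areas: np.ndarray,
    film: FilmModel,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Measured (peak pressure MPa, contact area mm^2), averaged over trials.

    An empty field yields (0, 0).  With zero noise, zero floor and no
    quantisation the emulator is the identity on (peak, area).
    """
    pressures = np.asarray(pressures, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if np.any(pressures < 0):
        raise ConfigurationError("film input pressures must be >= 0")
    if pressures.size == 0:
        return 0.0, 0.0
    if rng is None:
        rng = np.random.default_rng(film.seed)
    peaks, measured_areas = [], []
    for _ in range(film.n_trials):
        if film.multiplicative_noise_sd > 0:
            sigma = film.multiplicative_noise_sd
            noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=pressures.shape)
        else:
            noise = 1.0
        p = np.clip(pressures * noise, 0.0, film.saturation_ceiling)
        p = np.where(p < film.detection_floor, 0.0, p)
        if film.quantization_step > 0:
            p = np.round(p / film.quantization_step) * film.quantization_step
        registered = p > film.detection_floor if film.detection_floor > 0 else p > 0
        peaks.append(float(p.max()) if p.size else 0.0)
        measured_areas.append(float(areas[registered].sum()))
    return float(np.mean(peaks)), float(np.mean(measured_areas))


def cohort_shape_variance(cohort: list[KneeSpecimen]) -> float:
    """Trace of the vertex-coordinate covariance over a cohort (mm^2).

    Diagnostic used by the generator's variance-monotonicity property.
    """
    X = np.stack([np.concatenate([b.vertices.ravel() for b in s.bodies()]) for s in cohort])
    Xc = X - X.mean(axis=0)
    return float((Xc**2).sum() / (len(cohort) - 1))
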