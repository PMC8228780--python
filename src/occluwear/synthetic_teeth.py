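"""Synthetic premolar/molar crowns with construction-known wear ground truth.

The generator replaces physical plaster teeth: each crown is a watertight,
outward-oriented mesh built from a tapered wall (gingival rim on z = 0), a
cusped occlusal table, and seeded low-amplitude surface relief.  Two wear
operators emulate the in-vitro protocol:

* occlusal grinding — vertices above a cut height are pressed down onto a
  gently undulating (seeded) grinding surface, removing roughly 0.5/1/2 mm
  of vertical crown height;
* shallow lateral patches — smooth cosine-profile scoops of 3-5 mm extent
  and 0.100-0.250 mm depth on the buccal and lingual walls.

Because both time points live in one coordinate frame before a recorded
rigid "scan displacement" is applied, the true alignment and the true
removed volumes are known exactly — the synthetic stand-in for
superimposition on intact neighbouring structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mesh_core import RigidTransform, SurfaceMesh, random_rigid_transform

__all__ = [
    "CrownSpec",
    "PatchSpec",
    "WearSpec",
    "CrownPair",
    "StudyTooth",
    "generate_crown",
    "apply_occlusal_wear",
    "apply_surface_patch_wear",
    "make_crown_pair",
    "study_replica",
    "premolar_spec",
    "molar_spec",
]

#: default amplitude (mm) of the seeded grinding-surface undulation
GRINDING_ROUGHNESS = 0.05
#: azimuth of the buccal surface in the crown frame (+y); lingual is opposite
BUCCAL_AZIMUTH_DEG = 90.0


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrownSpec:
    """Parameters of one synthetic crown.

    ``crown_height`` is the height of the occlusal table above the gingival
    plane (cusps rise above it by about ``cusp_height``).  ``axis_tilt_deg``
    tips the whole crown off the +z axis — the stand-in for teeth sitting
    tilted in a crowded arch.
    """

    tooth_type: str = "premolar"
    base_radius: float = 4.2
    crown_height: float = 7.5
    cusp_count: int = 2
    cusp_height: float = 1.6
    surface_bumpiness: float = 0.12
    mesh_resolution: int = 17000
    random_seed: int = 0
    axis_tilt_deg: float = 0.0
    #: relative elongation of the buccolingual over the mesiodistal width
    ovality: float = 0.09
    #: relative buccal bulge breaking the 180-degree crown symmetry
    buccal_bulge: float = 0.05

    def __post_init__(self):
        if self.tooth_type not in ("premolar", "molar"):
            raise ValueError(f"unknown tooth_type {self.tooth_type!r}")


def premolar_spec(**kw) -> CrownSpec:
    return CrownSpec(tooth_type="premolar", base_radius=4.2, crown_height=7.5,
                     cusp_count=2, cusp_height=1.6, ovality=0.09, **kw)


def molar_spec(**kw) -> CrownSpec:
    return CrownSpec(tooth_type="molar", base_radius=5.2, crown_height=7.0,
                     cusp_count=4, cusp_height=1.5, ovality=0.05, **kw)


@dataclass(frozen=True)
class PatchSpec:
    """One shallow lateral wear patch.

    ``extent`` is the maximum footprint diameter (mm, 3-5 in the study) and
    ``depth`` the peak inward displacement (mm, 0.100-0.250).  The profile is
    a cosine bump, C1-smooth and vanishing at the footprint rim.
    """

    side: str = "buccal"
    extent: float = 4.0
    depth: float = 0.15
    center_height_frac: float = 0.35
    azimuth_deg: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.depth <= 0.5:
            raise ValueError("patch depth must be within [0, 0.5] mm")
        if not 0.0 <= self.extent <= 10.0:
            raise ValueError("patch extent must be within [0, 10] mm")
        if self.side not in ("buccal", "lingual"):
            raise ValueError(f"unknown patch side {self.side!r}")


@dataclass(frozen=True)
class WearSpec:
    """Wear applied between T0 and T1."""

    occlusal_depth: float = 1.0
    buccal_patch: PatchSpec | None = None
    lingual_patch: PatchSpec | None = None
    random_seed: int = 0

    def __post_init__(self):
        if self.occlusal_depth < 0:
            raise ValueError("occlusal_depth must be non-negative")


@dataclass(frozen=True)
class CrownPair:
    """T0/T1 crown pair with construction ground truth.

    ``t1`` lives in an independently displaced frame; ``true_alignment``
    maps it back onto ``t0`` exactly on every unworn vertex.
    """

    t0: SurfaceMesh
    t1: SurfaceMesh
    true_alignment: RigidTransform
    true_occlusal_wear_volume: float
    true_buccolingual_wear_volume: float
    crown_spec: CrownSpec
    wear_spec: WearSpec
    displacement_seed: int = 0

    @property
    def true_total_wear_volume(self) -> float:
        return self.true_occlusal_wear_volume + self.true_buccolingual_wear_volume

    @property
    def t1_aligned(self) -> SurfaceMesh:
        return self.t1.transformed(self.true_alignment)


# ---------------------------------------------------------------------------
# smooth seeded random fields
# ---------------------------------------------------------------------------


def _random_field(rng: np.random.Generator, amplitude: float, n_waves: int = 6,
                  wavelength_range=(3.0, 6.0), dim: int = 3):
    """Sum of seeded sinusoids: a smooth pseudo-random scalar field on R^dim."""
    lam = rng.uniform(*wavelength_range, size=n_waves)
    dirs = rng.normal(size=(n_waves, dim))
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    k = (2 * np.pi / lam)[:, None] * dirs
    phase = rng.uniform(0, 2 * np.pi, size=n_waves)

    def f(points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)[:, :dim]
        return (amplitude / n_waves) * np.sin(p @ k.T + phase).sum(axis=1)

    return f


# ---------------------------------------------------------------------------
# crown geometry
# ---------------------------------------------------------------------------


def _cusp_centers(spec: CrownSpec, top_radius: float) -> np.ndarray:
    if spec.cusp_count == 2:
        az = np.deg2rad([90.0, 270.0])
    else:
        az = np.deg2rad(45.0 + 90.0 * np.arange(spec.cusp_count))
    r = 0.55 * top_radius
    return np.column_stack([r * np.cos(az), r * np.sin(az)])


def cross_section_shape(spec: CrownSpec, theta: np.ndarray) -> np.ndarray:
    """Azimuthal radius multiplier of the (oval, buccally bulged) section.

    Crowns are wider buccolingually than mesiodistally and bulge slightly
    to the buccal (+y); both features break the rotational symmetry a
    surface of revolution would have, which real registration relies on.
    """
    theta = np.asarray(theta, float)
    return (1.0 - spec.ovality * np.cos(2 * theta)
            + spec.buccal_bulge * np.sin(theta))


def cap_height(spec: CrownSpec, u: np.ndarray) -> np.ndarray:
    """Smooth occlusal-table height (mm above the wall top) at 2D points ``u``.

    The parametric form integrated by the volume oracle: a dome of amplitude
    ``crown_height - wall_height``, Gaussian cusp mounds, a central fossa
    dip, all windowed by ``(1 - rho^4)`` so the table meets the wall rim
    exactly (``rho`` is the radius fraction within the oval rim).
    """
    u = np.atleast_2d(u)
    top_radius = _top_radius(spec)
    theta = np.arctan2(u[:, 1], u[:, 0])
    rim = top_radius * cross_section_shape(spec, theta)
    rho = np.linalg.norm(u, axis=1) / rim
    dome_amp = spec.crown_height - _wall_height(spec)
    sigma = 0.30 * top_radius
    sigma_f = 0.25 * top_radius
    g = np.full(len(u), dome_amp)
    for c in _cusp_centers(spec, top_radius):
        d2 = ((u - c) ** 2).sum(axis=1)
        g = g + spec.cusp_height * np.exp(-d2 / (2 * sigma ** 2))
    g = g - 0.5 * spec.cusp_height * np.exp(-(u ** 2).sum(axis=1) / (2 * sigma_f ** 2))
    return (1.0 - np.clip(rho, 0, 1) ** 4) * g


def _wall_height(spec: CrownSpec) -> float:
    return 0.7 * spec.crown_height


def _top_radius(spec: CrownSpec) -> float:
    return 0.78 * spec.base_radius


def wall_radius(spec: CrownSpec, z: np.ndarray) -> np.ndarray:
    """Tapered wall radius at height ``z`` (linear from base to table rim)."""
    hw = _wall_height(spec)
    return spec.base_radius + (_top_radius(spec) - spec.base_radius) * (np.asarray(z) / hw)


def _tilt_transform(spec: CrownSpec) -> RigidTransform:
    if spec.axis_tilt_deg == 0.0:
        return RigidTransform.identity()
    rng = np.random.default_rng(np.int64(spec.random_seed) * 7 + 3)
    az = rng.uniform(0, 2 * np.pi)
    axis = np.array([np.cos(az), np.sin(az), 0.0])
    return RigidTransform.from_rotvec(axis * np.deg2rad(spec.axis_tilt_deg),
                                      np.zeros(3))


def generate_crown(spec: CrownSpec) -> SurfaceMesh:
    """Build a watertight crown mesh from ``spec``.

    Deterministic for a fixed spec (the seed drives the surface relief).
    The gingival boundary circle lies exactly on z = 0 and is closed with a
    flat fan, so the mesh encloses a volume.  Face count lands within +-30%
    of ``mesh_resolution``.
    """
    if spec.mesh_resolution < 500:
        raise ValueError("mesh_resolution below 500 faces is too coarse")
    rng = np.random.default_rng(spec.random_seed)
    relief = _random_field(rng, spec.surface_bumpiness,
                           wavelength_range=(3.0, 6.0))

    hw = _wall_height(spec)
    rt = _top_radius(spec)
    meridian = hw + rt
    aspect = 2 * np.pi * spec.base_radius / meridian
    m = max(16, int(round(np.sqrt(spec.mesh_resolution * aspect / 2))))
    k = max(8, int(round(spec.mesh_resolution / (2 * m))))
    n_wall = max(4, int(round(k * hw / meridian)))
    n_cap = max(4, k - n_wall)

    theta = 2 * np.pi * np.arange(m) / m
    ct, st = np.cos(theta), np.sin(theta)

    shape = cross_section_shape(spec, theta)
    rings = []
    for i in range(n_wall + 1):
        z = hw * i / n_wall
        r = wall_radius(spec, z) * shape
        rings.append(np.column_stack([r * ct, r * st, np.full(m, z)]))
    for j in range(1, n_cap):
        rho = 1.0 - j / n_cap
        r = rho * rt * shape
        u = np.column_stack([r * ct, r * st])
        z = hw + cap_height(spec, u)
        rings.append(np.column_stack([u, z]))
    ring_v = np.concatenate(rings)
    apex = np.array([[0.0, 0.0, hw + float(cap_height(spec, np.zeros((1, 2)))[0])]])
    base_center = np.array([[0.0, 0.0, 0.0]])
    vertices = np.concatenate([ring_v, apex, base_center])
    apex_i = len(ring_v)
    base_i = apex_i + 1
    n_rings = n_wall + n_cap  # rings 0 .. n_rings-1 stacked, apex on top

    # seeded anatomical relief (ridges/grooves): radial on the wall — the
    # gingival boundary stays exactly on z = 0 but need not be circular —
    # and vertical on the occlusal table
    bump = relief(vertices[:len(ring_v)])
    for i in range(n_rings):
        sl = slice(i * m, (i + 1) * m)
        if i <= n_wall:
            r_xy = np.linalg.norm(vertices[sl, :2], axis=1)
            scale = (r_xy + bump[sl]) / r_xy
            vertices[sl, 0] *= scale
            vertices[sl, 1] *= scale
        else:
            vertices[sl, 2] += bump[sl]

    faces = []
    idx = np.arange(m)
    nxt = (idx + 1) % m
    for i in range(n_rings - 1):
        a = i * m + idx
        b = i * m + nxt
        c = (i + 1) * m + idx
        d = (i + 1) * m + nxt
        faces.append(np.column_stack([a, b, d]))
        faces.append(np.column_stack([a, d, c]))
    top = (n_rings - 1) * m
    faces.append(np.column_stack([top + idx, top + nxt,
                                  np.full(m, apex_i)]))
    faces.append(np.column_stack([nxt, idx, np.full(m, base_i)]))
    mesh = SurfaceMesh(vertices, np.concatenate(faces))
    tilt = _tilt_transform(spec)
    if spec.axis_tilt_deg != 0.0:
        mesh = mesh.transformed(tilt)
    return mesh


# ---------------------------------------------------------------------------
# wear operators
# ---------------------------------------------------------------------------


def apply_occlusal_wear(crown: SurfaceMesh, depth: float, seed: int = 0,
                        roughness: float = GRINDING_ROUGHNESS):
    """Grind the occlusal surface down by ``depth`` mm.

    Vertices above the cut height ``z_max - depth`` are displaced down onto
    a seeded, gently undulating grinding surface (amplitude at most
    ``roughness``, and never more than a quarter of the depth, so the worn
    table is not perfectly planar but stays below the wear step).  The mesh
    topology is untouched, so the result stays watertight.  Returns
    ``(worn_mesh, removed_volume_mm3)`` with the volume taken exactly as the
    difference of the two enclosed volumes.
    """
    z = crown.vertices[:, 2]
    height = z.max() - z.min()
    if depth >= height:
        raise ValueError(f"wear depth {depth} mm >= crown height {height:.3f} mm")
    if depth == 0:
        return crown.copy(), 0.0
    v0 = crown.enclosed_volume()
    rng = np.random.default_rng(seed)
    amp = min(roughness, depth / 4.0)
    g = _random_field(rng, amp, wavelength_range=(2.5, 5.0), dim=2)
    cut = z.max() - depth
    target = cut + g(crown.vertices[:, :2])
    worn_v = crown.vertices.copy()
    worn_v[:, 2] = np.minimum(z, target)
    worn = SurfaceMesh(worn_v, crown.faces.copy())
    return worn, v0 - worn.enclosed_volume()


def _resolve_patch_center(crown: SurfaceMesh, patch: PatchSpec):
    """Pick the patch center on the requested lateral wall."""
    az = patch.azimuth_deg
    if az is None:
        az = BUCCAL_AZIMUTH_DEG if patch.side == "buccal" else BUCCAL_AZIMUTH_DEG + 180.0
    az = np.deg2rad(az)
    normals = crown.vertex_normals
    lateral = np.abs(normals[:, 2]) <= np.sin(np.deg2rad(60.0))
    if not lateral.any():
        raise ValueError("crown has no identifiable lateral surface")
    v = crown.vertices
    z = v[:, 2]
    z_target = z.min() + patch.center_height_frac * (z.max() - z.min())
    theta = np.arctan2(v[:, 1], v[:, 0])
    d_az = np.abs(np.angle(np.exp(1j * (theta - az))))
    score = np.where(lateral, d_az * 3.0 + np.abs(z - z_target), np.inf)
    i = int(np.argmin(score))
    return v[i], normals[i]


def apply_surface_patch_wear(crown: SurfaceMesh, patch: PatchSpec,
                             center: np.ndarray | None = None,
                             direction: np.ndarray | None = None,
                             occlusal_exclusion_z: float | None = None):
    """Scoop a shallow cosine-profile patch out of a lateral surface.

    Vertices within ``extent/2`` of the patch center move inward along
    their own normals by ``depth/2 * (1 + cos(pi * rho / rho0))`` — peak
    displacement ``depth`` at the center, zero with zero slope at the rim.
    Topology is unchanged, so the mesh stays watertight.  Returns
    ``(worn_mesh, removed_volume_mm3)`` by closed-mesh differencing.

    ``center``/``direction`` override the spec-side placement (used for
    analytic fixtures); ``occlusal_exclusion_z`` raises if the footprint
    reaches a region reserved for occlusal grinding.
    """
    if patch.depth == 0 or patch.extent == 0:
        return crown.copy(), 0.0
    v0 = crown.enclosed_volume()
    if center is None or direction is None:
        center, direction = _resolve_patch_center(crown, patch)
    center = np.asarray(center, float)
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    rho0 = patch.extent / 2.0
    d = np.linalg.norm(crown.vertices - center, axis=1)
    normals = crown.vertex_normals
    same_side = normals @ direction > 0.2
    inside = (d < rho0) & same_side
    if occlusal_exclusion_z is not None and \
            (crown.vertices[inside, 2] > occlusal_exclusion_z).any():
        raise ValueError(
            "lateral patch footprint overlaps the occlusal wear region")
    w = np.zeros(len(d))
    w[inside] = 0.5 * patch.depth * (1.0 + np.cos(np.pi * d[inside] / rho0))
    worn_v = crown.vertices - w[:, None] * normals
    worn = SurfaceMesh(worn_v, crown.faces.copy())
    return worn, v0 - worn.enclosed_volume()


# ---------------------------------------------------------------------------
# pair assembly
# ---------------------------------------------------------------------------


def make_crown_pair(crown_spec: CrownSpec, wear_spec: WearSpec,
                    displacement_seed: int = 0) -> CrownPair:
    """Generate a T0/T1 pair with recorded truth.

    T1 is the T0 crown with lateral patch wear, then occlusal grinding,
    then a seeded rigid displacement (rotation <= 30 deg, translation
    <= 10 mm) emulating an independent scan frame; the inverse displacement
    is stored as ``true_alignment``.  Wear is applied in the upright crown
    frame; any axis tilt in the spec is applied to both time points
    afterwards so it is shared geometry, not wear.
    """
    upright = replace(crown_spec, axis_tilt_deg=0.0)
    t0u = generate_crown(upright)
    z = t0u.vertices[:, 2]
    cut_z = z.max() - wear_spec.occlusal_depth if wear_spec.occlusal_depth > 0 else None

    worn = t0u
    true_bl = 0.0
    for patch in (wear_spec.buccal_patch, wear_spec.lingual_patch):
        if patch is None:
            continue
        worn, removed = apply_surface_patch_wear(
            worn, patch, occlusal_exclusion_z=cut_z)
        true_bl += removed
    worn, true_occ = apply_occlusal_wear(
        worn, wear_spec.occlusal_depth, seed=wear_spec.random_seed)

    tilt = _tilt_transform(crown_spec)
    t0 = t0u.transformed(tilt) if crown_spec.axis_tilt_deg else t0u
    t1_aligned = worn.transformed(tilt) if crown_spec.axis_tilt_deg else worn

    rng = np.random.default_rng(displacement_seed)
    displacement = random_rigid_transform(rng, 30.0, 10.0)
    t1 = t1_aligned.transformed(displacement)
    return CrownPair(t0=t0, t1=t1, true_alignment=displacement.inverse(),
                     true_occlusal_wear_volume=true_occ,
                     true_buccolingual_wear_volume=true_bl,
                     crown_spec=crown_spec, wear_spec=wear_spec,
                     displacement_seed=displacement_seed)


# ---------------------------------------------------------------------------
# study replica
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyTooth:
    """One tooth of the 36-tooth study replica."""

    tooth_id: int
    tooth_type: str
    crowding: str        # "aligned" or "crowded"
    nominal_depth: float
    pair: CrownPair


def study_replica(n_teeth: int = 36, seed: int = 1,
                  mesh_resolution: int = 6000) -> list[StudyTooth]:
    """Build the in-silico analogue of the 36-tooth sample.

    18 premolars and 18 molars; nominal occlusal wear depths cycle through
    0.5/1/2 mm (six per depth per tooth type); half the teeth per type carry
    the "crowded" label, realised as a seeded 5-15 deg crown-axis tilt.
    Buccal and lingual patch extents are drawn from 3-5 mm and depths from
    0.100-0.250 mm.  Fully deterministic for a given ``seed``.
    """
    depths = [0.5, 1.0, 2.0]
    teeth = []
    master = np.random.default_rng(seed)
    for i in range(n_teeth):
        tooth_type = "premolar" if i < (n_teeth + 1) // 2 else "molar"
        depth = depths[i % 3]
        crowded = (i // 3) % 2 == 1
        rng = np.random.default_rng(int(master.integers(0, 2 ** 31 - 1)))
        tilt = float(rng.uniform(5.0, 15.0)) if crowded else 0.0
        base = premolar_spec() if tooth_type == "premolar" else molar_spec()
        cspec = replace(base, mesh_resolution=mesh_resolution,
                        random_seed=int(rng.integers(0, 2 ** 31 - 1)),
                        axis_tilt_deg=tilt)
        wspec = WearSpec(
            occlusal_depth=depth,
            buccal_patch=PatchSpec(side="buccal",
                                   extent=float(rng.uniform(3.0, 5.0)),
                                   depth=float(rng.uniform(0.100, 0.250))),
            lingual_patch=PatchSpec(side="lingual",
                                    extent=float(rng.uniform(3.0, 5.0)),
                                    depth=float(rng.uniform(0.100, 0.250))),
            random_seed=int(rng.integers(0, 2 ** 31 - 1)))
        pair = make_crown_pair(cspec, wspec,
                               displacement_seed=int(rng.integers(0, 2 ** 31 - 1)))
        teeth.append(StudyTooth(tooth_id=i, tooth_type=tooth_type,
                                crowding="crowded" if crowded else "aligned",
                                nominal_depth=depth, pair=pair))
    return teeth
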