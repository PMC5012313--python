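"""Synthetic pelvis phantom and EMDA electrode voxelization.

The phantom stands in for a patient CT segmentation: a parametric adult
pelvis built from geometric primitives (body ellipsoid with subcutaneous
fat shell, posterior spine/pelvis bone cylinders, an intestine region
above the bladder, a spherical-shell bladder with saline lumen and an
optional superior air pocket, a prostate below the bladder) plus the
treatment hardware: a helical intravesical wire electrode, an insulating
catheter balloon just above the bladder neck, and two dispersive patch
electrodes on the anterior abdominal skin.

Using analytic primitives keeps every region's volume checkable in closed
form, which a real segmentation would not allow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grid import ConductivityVolume, LabelVolume, VoxelGrid

__all__ = [
    "HelixSpec",
    "PatchSpec",
    "BalloonSpec",
    "PhantomParams",
    "PlacementError",
    "ResolutionError",
    "LABELS",
    "TABLE1_CONDUCTIVITY_S_PER_M",
    "EXCLUDED_TISSUES",
    "SIGMA_ELECTRODE_S_PER_M",
    "generate_pelvis_phantom",
    "voxelize_helix",
    "voxelize_patch",
    "voxelize_balloon",
    "assign_conductivity",
]


class PlacementError(ValueError):
    """An electrode does not sit inside / on its required host region."""


class ResolutionError(ValueError):
    """The grid is too coarse to represent a geometric feature."""


#: Fixed label numbering used by the generator.
LABELS: dict[str, int] = {
    "background": 0,
    "muscle": 1,
    "fat": 2,
    "bone": 3,
    "intestines": 4,
    "prostate": 5,
    "bladder_wall": 6,
    "bladder_lumen": 7,
    "internal_air": 8,
    "balloon": 9,
    "electrode_helix": 10,
    "electrode_patch": 11,
}

#: Literature tissue conductivities (S/m) used by the volume-conductor model.
TABLE1_CONDUCTIVITY_S_PER_M: dict[str, float] = {
    "bladder_wall": 0.2,
    "bladder_lumen": 1.5,
    "prostate": 0.41,
    "fat": 0.012,
    "muscle": 0.2,
    "intestines": 0.4,
    "bone": 0.02,
}

#: Structures treated as perfect insulators and removed from the solve.
EXCLUDED_TISSUES = frozenset({"background", "internal_air", "balloon"})

#: Conductivity stamped on electrode metal voxels.  Electrode voxels are
#: collapsed into equipotential terminal nodes, so this value only enters
#: the half-cell face conductance toward the adjacent tissue (and there the
#: harmonic mean saturates at 2*sigma_tissue for any metal-like value).
SIGMA_ELECTRODE_S_PER_M = 6.3e7  # silver

#: Coarsest grid spacing (mm) at which the helical wire (2.9 mm envelope)
#: can still be voxelized as a connected conductor.
MAX_HELIX_SPACING_MM = 2.0


# ===================================================================== #
# Electrode specifications
# ===================================================================== #
@dataclass(frozen=True)
class HelixSpec:
    """Helical intravesical wire electrode.

    Defaults match the clinical catheter electrode: 0.4 mm silver wire
    wound into 20 turns of 1.25 mm major radius at 1.6 mm pitch, for a
    32 mm combined axial length.
    """

    wire_diameter: float = 0.4  # mm
    turns: int = 20
    major_radius: float = 1.25  # mm
    pitch: float = 1.6  # mm
    axis_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm, start of axis
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.turns < 0:
            raise ValueError("turns must be >= 0")
        if min(self.wire_diameter, self.major_radius, self.pitch) <= 0:
            raise ValueError("helix geometric parameters must be > 0")
        d = np.asarray(self.axis_direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("axis_direction must be nonzero")
        object.__setattr__(self, "axis_direction", tuple(float(v) for v in d / n))

    @property
    def axial_extent(self) -> float:
        """Axial length of the winding in mm (turns x pitch)."""
        return self.turns * self.pitch

    @property
    def arc_length(self) -> float:
        """Centerline arc length in mm."""
        return self.turns * np.hypot(2 * np.pi * self.major_radius, self.pitch)

    def centerline(self, step_mm: float) -> np.ndarray:
        """Sample the helix centerline at arc-length steps <= step_mm; (n, 3) mm."""
        if self.turns == 0:
            return np.empty((0, 3))
        n = max(2, int(np.ceil(self.arc_length / step_mm)) + 1)
        theta = np.linspace(0.0, 2 * np.pi * self.turns, n)
        w = np.asarray(self.axis_direction)
        # orthonormal frame (u, v, w)
        seed = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(seed, w)) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        u = seed - np.dot(seed, w) * w
        u /= np.linalg.norm(u)
        v = np.cross(w, u)
        r, p = self.major_radius, self.pitch
        pts = (
            np.asarray(self.axis_origin)
            + r * np.cos(theta)[:, None] * u
            + r * np.sin(theta)[:, None] * v
            + (p * theta / (2 * np.pi))[:, None] * w
        )
        return pts


@dataclass(frozen=True)
class PatchSpec:
    """Dispersive surface patch electrodes (default two 5 x 7 cm patches).

    ``width`` spans the left-right (x) direction, ``height`` the
    superior-inferior (z) direction; patches are projected along
    ``normal`` onto the outermost body-surface voxels.
    """

    width: float = 70.0  # mm, x extent
    height: float = 50.0  # mm, z extent
    centers: tuple[tuple[float, float, float], ...] = ((-45.0, 90.0, 30.0), (45.0, 90.0, 30.0))
    normal: tuple[float, float, float] = (0.0, 1.0, 0.0)  # anterior
    count: int = 2

    def __post_init__(self) -> None:
        if min(self.width, self.height) <= 0:
            raise ValueError("patch dimensions must be > 0")
        if not 1 <= self.count <= len(self.centers):
            raise ValueError("count must be between 1 and len(centers)")


@dataclass(frozen=True)
class BalloonSpec:
    """Insulating catheter balloon (default 12 mm diameter sphere)."""

    diameter: float = 12.0  # mm
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("balloon diameter must be > 0")


# ===================================================================== #
# Phantom parameters
# ===================================================================== #
@dataclass(frozen=True)
class PhantomParams:
    """All knobs of the synthetic pelvis phantom.

    Lengths in millimetres.  ``seed`` drives a small (<= 5%) jitter of
    organ centers and radii for sensitivity studies; seed 0 means no
    jitter.  Identical params (including seed) give a bit-identical
    phantom.
    """

    spacing_mm: float = 2.0
    torso_half_axes: tuple[float, float, float] = (125.0, 90.0, 140.0)
    torso_half_height_crop: float = 90.0  # domain z half-extent (CT-like truncation)
    fat_thickness: float = 12.0
    bladder_center: tuple[float, float, float] = (0.0, 25.0, 0.0)
    bladder_outer_radius: float = 35.0
    bladder_wall_thickness: float = 3.0
    lumen_fill_fraction: float = 1.0  # saline fraction of lumen (rest = air pocket zone)
    air_pocket_fraction: float = 0.05  # fraction of lumen volume turned into air, from the top
    prostate_radius: float = 20.0
    spine_center_y: float = -55.0
    spine_radius: float = 18.0
    pelvis_wing_offset: tuple[float, float] = (45.0, -45.0)  # (|x|, y) of lateral bone cylinders
    pelvis_wing_radius: float = 12.0
    intestine_center: tuple[float, float, float] = (0.0, 10.0, 62.0)
    intestine_half_axes: tuple[float, float, float] = (70.0, 52.0, 45.0)
    helix: HelixSpec = field(default_factory=HelixSpec)
    patches: PatchSpec = field(default_factory=PatchSpec)
    balloon: BalloonSpec = field(default_factory=BalloonSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be > 0")
        if not 0 < self.bladder_wall_thickness < self.bladder_outer_radius:
            raise ValueError("wall thickness must be in (0, bladder_outer_radius)")
        if not 0.0 <= self.air_pocket_fraction <= 0.3:
            raise ValueError("air_pocket_fraction must be in [0, 0.3]")
        if min(self.torso_half_axes) <= 0 or self.prostate_radius <= 0:
            raise ValueError("all dimensions must be > 0")

    def make_grid(self) -> VoxelGrid:
        """Grid covering the (cropped) torso with a one-voxel margin."""
        s = self.spacing_mm
        hx = self.torso_half_axes[0] + 2 * s
        hy = self.torso_half_axes[1] + 2 * s
        hz = self.torso_half_height_crop
        shape = tuple(int(np.floor(2 * h / s)) + 1 for h in (hx, hy, hz))
        origin = tuple(-((n - 1) / 2.0) * s for n in shape)
        return VoxelGrid(shape=shape, spacing=(s, s, s), origin=origin)


def _jittered(params: PhantomParams) -> PhantomParams:
    """Apply seeded <=5% jitter to organ centers/radii; seed 0 = identity."""
    if params.seed == 0:
        return params
    rng = np.random.default_rng(params.seed)

    def j(x, frac=0.05):
        return x * (1.0 + frac * rng.uniform(-1, 1))

    cx, cy, cz = params.bladder_center
    r_b = params.bladder_outer_radius
    return replace(
        params,
        bladder_center=(cx + 0.05 * r_b * rng.uniform(-1, 1), j(cy), cz + 0.05 * r_b * rng.uniform(-1, 1)),
        bladder_outer_radius=j(r_b),
        prostate_radius=j(params.prostate_radius),
        intestine_half_axes=tuple(j(a) for a in params.intestine_half_axes),
    )


# ===================================================================== #
# Voxelizers
# ===================================================================== #
def voxelize_helix(spec: HelixSpec, grid: VoxelGrid) -> np.ndarray:
    """Voxel mask of the helical wire electrode.

    Membership: voxel centers within ``wire_diameter/2`` of the swept
    centerline, plus every voxel the centerline passes through (stamped
    from a dense sampling).  The stamping guarantees a 26-connected
    conductor even when the wire is thinner than the voxel; grids coarser
    than the helix envelope raise :class:`ResolutionError`.
    """
    if spec.turns == 0:
        return np.zeros(grid.shape, dtype=bool)
    if max(grid.spacing) > MAX_HELIX_SPACING_MM:
        raise ResolutionError(
            f"grid spacing {max(grid.spacing):g} mm too coarse for the helical "
            f"electrode (needs <= {MAX_HELIX_SPACING_MM:g} mm)"
        )
    step = 0.25 * min(min(grid.spacing), spec.wire_diameter)
    pts = spec.centerline(step_mm=step)
    mask = np.zeros(grid.shape, dtype=bool)

    # stamp centerline voxels (dense sampling => consecutive samples land in
    # the same or 26-adjacent voxels => connected conductor)
    idx = grid.index(pts)
    inside = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
    if not np.all(inside):
        raise PlacementError("electrode_helix extends outside the grid")
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    # swept-tube membership on the candidate neighborhood of the centerline
    r = spec.wire_diameter / 2.0
    lo = np.maximum(np.floor(grid.index(pts.min(axis=0) - 2 * r)), 0).astype(int)
    hi = np.minimum(grid.index(pts.max(axis=0) + 2 * r) + 1, grid.shape).astype(int)
    ii, jj, kk = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    centers = grid.world(np.stack([ii, jj, kk], axis=-1)).reshape(-1, 3)
    # chunked min-distance to the sampled centerline
    dmin = np.full(len(centers), np.inf)
    for start in range(0, len(pts), 512):
        seg = pts[start:start + 512]
        d = np.linalg.norm(centers[:, None, :] - seg[None, :, :], axis=2).min(axis=1)
        np.minimum(dmin, d, out=dmin)
    tube = (dmin <= r).reshape(ii.shape)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= tube
    return mask


def voxelize_balloon(spec: BalloonSpec, grid: VoxelGrid) -> np.ndarray:
    """Voxel mask of the spherical catheter balloon (center-in-sphere test)."""
    x, y, z = grid.coordinate_arrays()
    cx, cy, cz = spec.center
    r = spec.diameter / 2.0
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 < r**2


def voxelize_patch(
    spec: PatchSpec, grid: VoxelGrid, skin_surface: np.ndarray
) -> list[np.ndarray]:
    """Voxel masks of surface patch electrodes, one per patch.

    ``skin_surface`` is the body mask (any non-background structure); each
    patch claims, for every (x, z) column inside its rectangle, the
    outermost body voxel along the patch normal (anterior +y by default).
    Returns ``spec.count`` disjoint masks; a patch with no body underneath
    yields an empty mask and a warning.
    """
    if tuple(np.round(spec.normal, 6)) not in {(0.0, 1.0, 0.0), (0.0, -1.0, 0.0)}:
        raise ValueError("patch normal must be +y (anterior) or -y (posterior)")
    anterior = spec.normal[1] > 0
    xs = grid.axis_coords(0)
    zs = grid.axis_coords(2)
    has_body = skin_surface.any(axis=1)  # (nx, nz)
    # outermost body voxel index along y per column
    ny = grid.shape[1]
    ycells = np.arange(ny)[None, :, None]
    if anterior:
        outer = np.where(skin_surface, ycells, -1).max(axis=1)
    else:
        outer = np.where(skin_surface, ycells, ny).min(axis=1)

    masks: list[np.ndarray] = []
    for c in spec.centers[: spec.count]:
        cx, _, cz = c
        in_rect = (np.abs(xs[:, None] - cx) <= spec.width / 2.0) & (
            np.abs(zs[None, :] - cz) <= spec.height / 2.0
        )
        cols = in_rect & has_body
        mask = np.zeros(grid.shape, dtype=bool)
        if not cols.any():
            warnings.warn(f"patch at {c} lies entirely off the body; empty mask")
            masks.append(mask)
            continue
        i_idx, k_idx = np.nonzero(cols)
        mask[i_idx, outer[i_idx, k_idx], k_idx] = True
        masks.append(mask)
    for a in range(len(masks)):
        for b in range(a + 1, len(masks)):
            if np.any(masks[a] & masks[b]):
                raise PlacementError("electrode_patch masks overlap")
    return masks


# ===================================================================== #
# Phantom generator
# ===================================================================== #
def generate_pelvis_phantom(params: PhantomParams) -> LabelVolume:
    """Build the synthetic segmented pelvis with electrodes.

    Structures are stamped outside-in (muscle body, fat shell, intestines,
    bone, prostate, bladder wall, lumen, air pocket) and the hardware last
    (balloon, helix, patches overwrite underlying tissue).  Deterministic
    for fixed params; raises :class:`PlacementError` if an electrode falls
    outside its host region.
    """
    p = _jittered(params)
    grid = p.make_grid()
    x, y, z = grid.coordinate_arrays()
    lab = np.zeros(grid.shape, dtype=np.int16)

    ax, ay, az = p.torso_half_axes
    body = (x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2 < 1.0
    lab[body] = LABELS["fat"]
    t = p.fat_thickness
    inner = (x / (ax - t)) ** 2 + (y / (ay - t)) ** 2 + (z / (az - t)) ** 2 < 1.0
    lab[inner] = LABELS["muscle"]

    def stamp(mask: np.ndarray, name: str, host: np.ndarray = inner) -> None:
        lab[mask & host] = LABELS[name]

    icx, icy, icz = p.intestine_center
    ia, ib, ic = p.intestine_half_axes
    stamp(((x - icx) / ia) ** 2 + ((y - icy) / ib) ** 2 + ((z - icz) / ic) ** 2 < 1.0,
          "intestines")

    spine = (x**2 + (y - p.spine_center_y) ** 2) < p.spine_radius**2
    wx, wy = p.pelvis_wing_offset
    wings = ((np.abs(x) - wx) ** 2 + (y - wy) ** 2) < p.pelvis_wing_radius**2
    stamp(spine | wings, "bone")

    bcx, bcy, bcz = p.bladder_center
    r_out = p.bladder_outer_radius
    r_in = r_out - p.bladder_wall_thickness
    d2 = (x - bcx) ** 2 + (y - bcy) ** 2 + (z - bcz) ** 2
    pz = bcz - (r_out + p.prostate_radius)
    stamp((x - bcx) ** 2 + (y - bcy) ** 2 + (z - pz) ** 2 < p.prostate_radius**2,
          "prostate")
    stamp(d2 < r_out**2, "bladder_wall")
    lumen = d2 < r_in**2
    stamp(lumen, "bladder_lumen")

    # superior air pocket: horizontal cut claiming the requested volume
    # fraction of the lumen (buoyancy puts air at the top)
    if p.air_pocket_fraction > 0 and lumen.any():
        zvals = np.broadcast_to(z, grid.shape)[lumen]
        z_cut = np.quantile(zvals, 1.0 - p.air_pocket_fraction)
        air = lumen & (np.broadcast_to(z, grid.shape) > z_cut)
        lab[air] = LABELS["internal_air"]

    # hardware — placed relative to the (possibly jittered) bladder
    balloon_spec = replace(
        p.balloon, center=(bcx, bcy, bcz - r_in + p.balloon.diameter / 2.0)
    )
    balloon = voxelize_balloon(balloon_spec, grid)
    if np.any(balloon & ~lumen):
        raise PlacementError("balloon extends outside the bladder lumen")
    lab[balloon] = LABELS["balloon"]

    ext = p.helix.axial_extent
    helix_spec = replace(p.helix, axis_origin=(bcx, bcy, bcz - ext / 2.0),
                         axis_direction=(0.0, 0.0, 1.0))
    helix = voxelize_helix(helix_spec, grid)
    if not helix.any():
        raise PlacementError("electrode_helix mask is empty")
    if np.any(helix & ~(lab == LABELS["bladder_lumen"])):
        raise PlacementError("electrode_helix extends outside the saline lumen")
    lab[helix] = LABELS["electrode_helix"]

    patch_masks = voxelize_patch(p.patches, grid, skin_surface=(lab != 0))
    if not all(m.any() for m in patch_masks):
        raise PlacementError("electrode_patch has no body surface underneath")
    for m in patch_masks:
        lab[m] = LABELS["electrode_patch"]

    legend = {v: k for k, v in LABELS.items() if v != 0 and np.any(lab == v)}
    return LabelVolume(grid=grid, labels=lab, legend=legend)


def patch_terminal_masks(volume: LabelVolume) -> list[np.ndarray]:
    """Split the electrode_patch label into per-patch connected components."""
    m = volume.mask("electrode_patch")
    comp, n = ndimage.label(m, structure=np.ones((3, 3, 3), dtype=bool))
    return [comp == i for i in range(1, n + 1)]


# ===================================================================== #
# Conductivity assignment
# ===================================================================== #
def assign_conductivity(
    labels: LabelVolume,
    table: dict[str, float] | None = None,
    excluded: frozenset[str] | set[str] = EXCLUDED_TISSUES,
) -> ConductivityVolume:
    """Map tissue labels to conductivities (S/m).

    ``table`` defaults to the literature values used by the model
    (bladder wall 0.2, lumen 1.5, prostate 0.41, fat 0.012, muscle 0.2,
    intestines 0.4, bone 0.02).  Background, internal air and the catheter
    balloon are flagged excluded (perfect insulators); electrode metal
    gets a silver-like conductivity (it only influences the half-cell face
    conductance, as electrode voxels are equipotential terminal nodes).
    Raises KeyError naming any label without a table entry.
    """
    if table is None:
        table = TABLE1_CONDUCTIVITY_S_PER_M
    sigma = np.zeros(labels.grid.shape, dtype=float)
    excl = np.zeros(labels.grid.shape, dtype=bool)
    present = set(np.unique(labels.labels).tolist())
    for lab in sorted(present):
        name = "background" if lab == 0 else labels.legend[lab]
        m = labels.labels == lab
        if name in excluded:
            excl[m] = True
        elif name in ("electrode_helix", "electrode_patch"):
            sigma[m] = SIGMA_ELECTRODE_S_PER_M
        elif name in table:
            sigma[m] = float(table[name])
        else:
            raise KeyError(
                f"no conductivity for label {lab} ({name!r}) and it is not excluded"
            )
    return ConductivityVolume(grid=labels.grid, sigma=sigma, excluded=excl)
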