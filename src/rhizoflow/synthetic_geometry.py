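"""Synthetic three-phase soil geometries and quasi-static drainage.

Two pore architectures are emulated:

``sand_like``
    A granular medium: random sequential addition of spherical grains
    with a rejection rule on centre separation.  The pore space is the
    interstitial network between grains, with a broad range of pore
    radii.

``clay_like``
    An aggregated medium: a solid matrix partitioned into aggregates by
    a thin inter-aggregate void network (the boundary set of a Voronoi
    tessellation of aggregate centres) plus a small number of planar
    crack/macropore slabs.  The resulting pore-radius distribution is
    bimodal: many narrow micropores and a few wide cracks.

Drainage follows the quasi-static Young–Laplace / invasion-percolation
picture on the drainage branch only: at matric potential P (kPa, <= 0)
air occupies every pore voxel whose local pore radius (maximal inscribed
sphere, computed from the Euclidean distance transform) is at least the
critical radius r_c = 2 sigma cos(theta_c) / |P|, provided the voxel is
reachable from the invasion face through voxels satisfying the same
criterion (or through already-drained air).  Air never reverts to water.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phase_io import AIR, SOIL, STRUCT_6, WATER, PhaseVolume

#: Air–water surface tension, N/m.
DEFAULT_SURFACE_TENSION = 0.072


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic three-phase geometry.

    Lengths are micrometres.  ``grain_radius_range`` applies to the
    sand-like texture; ``aggregate_radius_range``, ``crack_count`` and
    ``crack_aperture_range`` to the clay-like texture.  The default
    voxel size (1 um) resolves micropores that remain water-filled over
    the 0 to -75 kPa schedule while macropores drain, which a coarser
    CT-like voxel could not represent at desk-scale grids.
    """

    texture: str = "sand_like"
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_um: float = 1.0
    target_porosity: float = 0.45
    #: None scales the radii with the grid (a 64^3 grid gives 8-14 voxel
    #: grains); explicit values are in micrometres.
    grain_radius_range: tuple[float, float] | None = None
    aggregate_radius_range: tuple[float, float] | None = None
    crack_count: int = 3
    crack_aperture_range: tuple[float, float] = (10.0, 14.0)
    rng_seed: int = 0
    #: Maximum fractional overlap of two grains (fraction of the smaller
    #: radius); grains may touch and slightly interpenetrate, as sintered
    #: or cemented grains do, which lets dense packings reach the porosity
    #: of repacked sands.
    max_overlap: float = 0.35

    def __post_init__(self) -> None:
        if self.texture not in {"sand_like", "clay_like"}:
            raise ValueError(f"unknown texture {self.texture!r}")
        if not 0.0 < self.target_porosity < 1.0:
            raise ValueError("target_porosity must lie strictly in (0, 1)")
        if len(self.grid_shape) != 3 or any(s < 16 for s in self.grid_shape):
            raise ValueError("grid_shape components must be >= 16")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        if self.crack_aperture_range[0] < 2 * self.voxel_size_um:
            raise ValueError(
                "crack apertures below 2 voxels are unresolvable; increase "
                "crack_aperture_range minimum"
            )

    def resolved_grain_range_vox(self) -> tuple[float, float]:
        """Grain radii in voxels, scaled to the grid when unspecified."""
        if self.grain_radius_range is not None:
            return tuple(r / self.voxel_size_um for r in self.grain_radius_range)
        n = min(self.grid_shape)
        lo = max(3.0, n / 8.0)
        return lo, max(lo + 2.0, n / 4.5)

    def resolved_aggregate_range_vox(self) -> tuple[float, float]:
        """Aggregate radii in voxels, scaled to the grid when unspecified."""
        if self.aggregate_radius_range is not None:
            return tuple(r / self.voxel_size_um for r in self.aggregate_radius_range)
        n = min(self.grid_shape)
        lo = max(4.0, 6.0 * n / 64.0)
        return lo, max(lo + 2.0, 10.0 * n / 64.0)


@dataclass
class DrainageSchedule:
    """An ordered matric-potential series for quasi-static drainage.

    The first potential must be 0 (full saturation) and the series must
    be strictly decreasing (drainage branch only).  Defaults follow the
    standard successive-vacuum series 0, -5, -10, -20, -40, -60, -75 kPa.
    """

    potentials_kpa: tuple[float, ...] = (0.0, -5.0, -10.0, -20.0, -40.0, -60.0, -75.0)
    surface_tension_n_m: float = DEFAULT_SURFACE_TENSION
    contact_angle_deg: float = 0.0
    invasion_face: str = "top"

    def __post_init__(self) -> None:
        p = np.asarray(self.potentials_kpa, dtype=float)
        if p.size == 0 or p[0] != 0.0:
            raise ValueError("schedule must start at 0 kPa (saturation)")
        if np.any(np.diff(p) >= 0):
            raise ValueError("potentials must be strictly decreasing")
        if np.any(p > 0):
            raise ValueError("matric potentials must be non-positive")

    def critical_radius_um(self, potential_kpa: float) -> float:
        """Young–Laplace critical pore radius at a matric potential.

        r_c = 2 sigma cos(theta_c) / |P|; infinite at saturation.
        """
        if potential_kpa > 0:
            raise ValueError("matric potential must be non-positive")
        if potential_kpa == 0:
            return np.inf
        pressure_pa = abs(potential_kpa) * 1e3
        r_m = (
            2.0
            * self.surface_tension_n_m
            * np.cos(np.deg2rad(self.contact_angle_deg))
            / pressure_pa
        )
        return r_m * 1e6


# ---------------------------------------------------------------------
# Sphere packing
# ---------------------------------------------------------------------

def _pack_spheres(
    shape: tuple[int, int, int],
    radius_range_vox: tuple[float, float],
    target_solid_fraction: float,
    rng: np.random.Generator,
    max_overlap: float,
    max_attempts_factor: int = 4000,
) -> np.ndarray:
    """Random sequential addition of spheres with a rejection rule.

    Spheres are accepted unless their centre lies closer to an accepted
    sphere than ``r_i + r_j - max_overlap * min(r_i, r_j)``.  Insertion
    stops once the voxelized solid fraction reaches the target; returns
    the solid mask.
    """
    solid = np.zeros(shape, dtype=bool)
    total = solid.size
    centres: list[np.ndarray] = []
    radii: list[float] = []
    grid = [np.arange(n) for n in shape]
    target_voxels = int(round(target_solid_fraction * total))
    n_solid = 0
    attempts = 0
    max_attempts = max_attempts_factor * max(
        1, int(target_solid_fraction * total / max(1.0, radius_range_vox[0] ** 3))
    )
    while n_solid < target_voxels and attempts < max_attempts:
        attempts += 1
        r = rng.uniform(*radius_range_vox)
        c = rng.uniform(0, 1, 3) * np.asarray(shape)
        ok = True
        for cj, rj in zip(centres, radii):
            min_dist = r + rj - max_overlap * min(r, rj)
            if np.sum((c - cj) ** 2) < min_dist**2:
                ok = False
                break
        if not ok:
            continue
        centres.append(c)
        radii.append(r)
        zz = (grid[0][:, None, None] - c[0]) ** 2
        yy = (grid[1][None, :, None] - c[1]) ** 2
        xx = (grid[2][None, None, :] - c[2]) ** 2
        solid |= zz + yy + xx <= r**2
        n_solid = int(solid.sum())
    return solid


def generate_sand_like(spec: SyntheticSpec) -> PhaseVolume:
    """Generate a water-saturated sand-like granular medium.

    The solid phase is a rejection-constrained random sphere packing of
    grains; all non-solid voxels start water-filled.  The achieved
    porosity must land within ±0.03 of ``spec.target_porosity``.
    """
    if spec.texture != "sand_like":
        raise ValueError("spec.texture must be 'sand_like'")
    r_vox = spec.resolved_grain_range_vox()
    if 2 * r_vox[0] > min(spec.grid_shape):
        raise ValueError(
            f"grain diameter {2 * r_vox[0]:.1f} voxels exceeds grid extent "
            f"{min(spec.grid_shape)}"
        )
    rng = np.random.default_rng(spec.rng_seed)
    solid = _pack_spheres(
        spec.grid_shape,
        r_vox,
        target_solid_fraction=1.0 - spec.target_porosity,
        rng=rng,
        max_overlap=spec.max_overlap,
    )
    achieved = 1.0 - solid.mean()
    if abs(achieved - spec.target_porosity) > 0.03:
        raise RuntimeError(
            f"porosity unreachable: achieved {achieved:.3f} vs target "
            f"{spec.target_porosity:.3f} (grains may be too large or the "
            "overlap allowance too small)"
        )
    labels = np.where(solid, SOIL, WATER).astype(np.uint8)
    return PhaseVolume(
        labels,
        spec.voxel_size_um,
        0.0,
        {"texture": "sand_like", "seed": spec.rng_seed, "achieved_porosity": achieved},
    )


# ---------------------------------------------------------------------
# Clay-like: aggregates + cracks
# ---------------------------------------------------------------------

def generate_clay_like(spec: SyntheticSpec) -> PhaseVolume:
    """Generate a water-saturated clay-like aggregated medium.

    The solid matrix is partitioned into aggregates; voxels near the
    boundary between the two nearest aggregate centres form a thin
    micropore network whose width is tuned by bisection to meet the
    target porosity.  ``crack_count`` planar slab voids of sampled
    aperture are then carved, rejected and resampled if they would touch
    an existing crack, so the cracks remain distinct planar objects.
    """
    if spec.texture != "clay_like":
        raise ValueError("spec.texture must be 'clay_like'")
    rng = np.random.default_rng(spec.rng_seed)
    shape = spec.grid_shape
    r_vox = spec.resolved_aggregate_range_vox()
    mean_r = 0.5 * (r_vox[0] + r_vox[1])
    # evenly spaced aggregate centres (rejection on minimum separation):
    # clustered centres would leave thick void pockets instead of a thin
    # inter-aggregate network
    n_centres = max(8, int(np.prod(shape) / ((4.0 / 3.0) * np.pi * (0.75 * mean_r) ** 3)))
    centres_list: list[np.ndarray] = []
    min_sep2 = (0.9 * mean_r) ** 2
    tries = 0
    while len(centres_list) < n_centres and tries < 200 * n_centres:
        tries += 1
        c = rng.uniform(0, 1, 3) * np.asarray(shape)
        if all(np.sum((c - cj) ** 2) >= min_sep2 for cj in centres_list):
            centres_list.append(c)
    centres = np.asarray(centres_list)

    # distance to nearest and second-nearest aggregate centre per voxel
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3).astype(float)
    from scipy.spatial import cKDTree

    tree = cKDTree(centres)
    dists, _ = tree.query(pts, k=2)
    margin = (dists[:, 1] - dists[:, 0]).reshape(shape)

    crack_mask, crack_planes = _carve_cracks(spec, rng)
    crack_porosity = crack_mask.mean()
    micro_target = spec.target_porosity - crack_porosity
    if micro_target <= 0:
        raise RuntimeError(
            f"cracks alone exceed target porosity ({crack_porosity:.3f} > "
            f"{spec.target_porosity:.3f})"
        )

    # keep a solid collar between cracks and the micropore network: a
    # flaring junction would blur the two pore-size modes together
    exclude = ndimage.binary_dilation(crack_mask, structure=STRUCT_6, iterations=3)

    # bisect the boundary-margin threshold to hit the micropore porosity
    lo, hi = 0.0, float(margin.max())
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        frac = float(((margin < mid) & ~exclude).mean())
        if frac < micro_target:
            lo = mid
        else:
            hi = mid
    micro_mask = (margin < 0.5 * (lo + hi)) & ~exclude

    # prune the pockets where several aggregate boundaries meet: their
    # inscribed radii would otherwise bridge the micropore and crack modes
    lt_micro = local_pore_radius(micro_mask)
    micro_mask &= lt_micro < 2.5

    pore = micro_mask | crack_mask
    achieved = float(pore.mean())
    if abs(achieved - spec.target_porosity) > 0.03:
        raise RuntimeError(
            f"porosity unreachable: achieved {achieved:.3f} vs target "
            f"{spec.target_porosity:.3f}"
        )
    labels = np.where(pore, WATER, SOIL).astype(np.uint8)
    return PhaseVolume(
        labels,
        spec.voxel_size_um,
        0.0,
        {
            "texture": "clay_like",
            "seed": spec.rng_seed,
            "achieved_porosity": achieved,
            "crack_planes": crack_planes,
        },
    )


def _carve_cracks(
    spec: SyntheticSpec, rng: np.random.Generator, max_tries: int = 400
) -> tuple[np.ndarray, list[dict]]:
    """Sample ``crack_count`` non-touching planar slab voids.

    Cracks are penny-shaped planar voids (finite in-plane extent, as
    shrinkage fissures are) forming a parallel, grid-aligned family: one
    random axis per volume, offsets evenly spaced with a small jitter.
    Grid alignment keeps each crack's aperture exact on the voxel
    lattice (a tilted slab acquires a staircase boundary that smears its
    pore-radius signature); the even spacing guarantees the cracks stay
    disjoint, so each labels as a single planar object, and a rejection
    check enforces it.
    """
    shape = spec.grid_shape
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    coords = np.stack([zz, yy, xx]).astype(float)
    centre = (np.asarray(shape) - 1) / 2.0
    axis = int(rng.integers(0, 3))
    half_span = shape[axis] / 2.0

    crack_mask = np.zeros(shape, dtype=bool)
    planes: list[dict] = []
    tries = 0
    i = 0
    while len(planes) < spec.crack_count and tries < max_tries:
        tries += 1
        aperture_vox = rng.uniform(*spec.crack_aperture_range) / spec.voxel_size_um
        # evenly spaced offsets with a small jitter keep the family disjoint
        if spec.crack_count == 1:
            frac = 0.0
        else:
            frac = -0.6 + 1.2 * i / (spec.crack_count - 1)
        offset = frac * half_span + rng.uniform(-1.5, 1.5)
        penny_r = rng.uniform(0.22, 0.3) * min(shape)
        in_centre = centre + rng.uniform(-0.08, 0.08, 3) * np.asarray(shape)
        rel = coords - in_centre[:, None, None, None]
        d_perp = coords[axis] - centre[axis] - offset
        d_rad = np.sqrt(np.sum(rel**2, axis=0) - rel[axis] ** 2)
        # rounded rim (union of half-aperture balls centred on the
        # mid-plane disc): a sharp edge would carry arbitrarily small
        # inscribed radii and smear the crack mode of the histogram
        overhang = np.maximum(d_rad - penny_r, 0.0)
        slab = overhang**2 + d_perp**2 <= (aperture_vox / 2.0) ** 2
        if not slab.any():
            continue
        # a penny clipped by a volume face acquires an open rim whose
        # pore-radius signature smears the crack mode; keep cracks interior
        if (
            slab[0].any() or slab[-1].any()
            or slab[:, 0].any() or slab[:, -1].any()
            or slab[:, :, 0].any() or slab[:, :, -1].any()
        ):
            continue
        grown = ndimage.binary_dilation(slab, structure=STRUCT_6, iterations=2)
        if (grown & crack_mask).any():
            continue
        crack_mask |= slab
        i += 1
        planes.append(
            {
                "axis": axis,
                "offset_vox": float(offset),
                "aperture_um": float(aperture_vox * spec.voxel_size_um),
                "penny_radius_vox": float(penny_r),
            }
        )
    if len(planes) < spec.crack_count:
        raise RuntimeError(
            f"could not place {spec.crack_count} disjoint cracks "
            f"(placed {len(planes)} in {tries} tries)"
        )
    return crack_mask, planes


# ---------------------------------------------------------------------
# Local pore radius and drainage
# ---------------------------------------------------------------------

def local_pore_radius(pore_mask: np.ndarray, voxel_size_um: float = 1.0) -> np.ndarray:
    """Local thickness: radius of the largest inscribed sphere containing
    each pore voxel.

    The Euclidean distance transform gives the inscribed-sphere radius at
    sphere centres (with the solid surface taken half a voxel beyond the
    outermost pore-voxel centre); each sphere is then swept over the
    voxels it covers, from large radii down, so every pore voxel inherits
    the largest covering sphere.  Returned in the same length unit as
    ``voxel_size_um`` (0 outside the pore space).
    """
    if not pore_mask.any():
        return np.zeros(pore_mask.shape, dtype=float)
    # the volume faces are open (drainage enters through them), so the
    # distance transform sees in-volume solids only
    edt = ndimage.distance_transform_edt(pore_mask)
    radius = np.maximum(edt - 0.5, 0.0)
    lt = np.zeros(pore_mask.shape, dtype=float)
    # descending sweep over quantized radii; dilation by r via EDT from centres
    r_values = np.unique(np.round(radius[pore_mask], 2))[::-1]
    # quantize to at most ~40 levels to bound the number of dilations
    if r_values.size > 40:
        r_values = np.unique(np.round(r_values, 0))[::-1]
    for r in r_values:
        if r <= 0:
            continue
        centres = radius >= r
        if not centres.any():
            continue
        dist_to_centre = ndimage.distance_transform_edt(~centres)
        # one-voxel tolerance: a voxel centre marginally outside the
        # inscribed ball (a discretization artefact of the staircased
        # boundary) still belongs to the pore body the ball measures
        covered = (dist_to_centre <= r + 1.0) & pore_mask & (lt == 0)
        lt[covered] = r
    lt[pore_mask & (lt == 0)] = radius[pore_mask & (lt == 0)]
    return lt * voxel_size_um


def pore_radius_histogram(
    volume: PhaseVolume, bin_width_vox: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of local pore radii (voxel units) over the pore space.

    Returns (counts, bin_edges).  Bimodality of a clay-like medium shows
    as two local maxima (micropore and crack modes) separated by at
    least one empty bin.
    """
    pore = volume.pore_mask
    lt = local_pore_radius(pore, 1.0)
    vals = lt[pore]
    if vals.size == 0:
        return np.array([]), np.array([0.0])
    edges = np.arange(0.0, vals.max() + bin_width_vox, bin_width_vox)
    counts, edges = np.histogram(vals, bins=edges)
    return counts, edges


def histogram_modes(counts: np.ndarray) -> int:
    """Number of local maxima separated by empty bins in a histogram."""
    modes = 0
    in_block = False
    block_has_mass = False
    for c in counts:
        if c > 0:
            block_has_mass = True
            in_block = True
        else:
            if in_block and block_has_mass:
                modes += 1
            in_block = False
            block_has_mass = False
    if in_block and block_has_mass:
        modes += 1
    return modes


_FACE_SLICES = {
    "top": (0, 0),
    "bottom": (0, -1),
    "left": (1, 0),
    "right": (1, -1),
    "front": (2, 0),
    "back": (2, -1),
}


def apply_drainage(
    volume: PhaseVolume,
    potential_kpa: float,
    schedule: DrainageSchedule | None = None,
    pore_radius_um: np.ndarray | None = None,
) -> PhaseVolume:
    """Drain a volume to a matric potential by invasion percolation.

    Air occupies every pore voxel whose local pore radius is >= the
    Young–Laplace critical radius *and* that is face-connected to the
    invasion face through voxels satisfying the same criterion (or
    through air already present).  Previously drained air never reverts
    to water.  ``pore_radius_um`` may carry a precomputed local-thickness
    map to avoid recomputation across a schedule.
    """
    if potential_kpa > 0:
        raise ValueError("matric potential must be non-positive")
    schedule = schedule or DrainageSchedule()
    labels = volume.labels.copy()

    r_c_um = schedule.critical_radius_um(potential_kpa)
    if np.isinf(r_c_um):  # saturation: nothing drains
        return PhaseVolume(labels, volume.voxel_size_um, 0.0, dict(volume.meta))

    pore = labels != SOIL
    if pore_radius_um is None:
        pore_radius_um = local_pore_radius(pore, volume.voxel_size_um)
    if r_c_um < volume.voxel_size_um:
        warnings.warn(
            f"critical radius {r_c_um:.2f} um is below one voxel "
            f"({volume.voxel_size_um} um); step acts as full drainage of "
            "connected pores",
            stacklevel=2,
        )
        drainable = pore.copy()
    else:
        drainable = pore & (pore_radius_um >= r_c_um)
    pathway = drainable | (labels == AIR)

    axis, end = _FACE_SLICES[schedule.invasion_face]
    lab, _ = ndimage.label(pathway, structure=STRUCT_6)
    face = [slice(None)] * 3
    face[axis] = end
    seeds = np.unique(lab[tuple(face)])
    seeds = seeds[seeds > 0]
    invaded = np.isin(lab, seeds) & pathway

    labels[invaded & (labels == WATER)] = AIR
    return PhaseVolume(
        labels,
        volume.voxel_size_um,
        float(potential_kpa),
        {**volume.meta, "r_c_um": float(r_c_um)},
    )


def drainage_series(
    volume: PhaseVolume, schedule: DrainageSchedule | None = None
) -> list[PhaseVolume]:
    """Drain a saturated volume over a full potential schedule.

    Returns one PhaseVolume per potential (the first is the saturated
    input restamped at 0 kPa).  The local-thickness map is computed once;
    air accumulates monotonically down the schedule.
    """
    schedule = schedule or DrainageSchedule()
    radius = local_pore_radius(volume.pore_mask, volume.voxel_size_um)
    out: list[PhaseVolume] = []
    current = volume
    for p in schedule.potentials_kpa:
        current = apply_drainage(current, p, schedule, pore_radius_um=radius)
        out.append(current)
    return out
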