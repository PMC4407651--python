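"""Three-phase volume containers, file I/O, segmentation and noise filtering.

Volumes are 3D voxel grids labelled soil/water/air (uint8 codes 0/1/2)
with an isotropic voxel edge length in micrometres.  Greyscale volumes
carry the calibration greys of two reference objects (a water sample and
finely sieved soil) used to place the segmentation thresholds.

On disk a volume is a multi-page TIFF stack plus a JSON sidecar holding
the voxel size and acquisition/provenance metadata; a ``.raw`` + JSON
pair is supported as well.  Voxel size is never silently defaulted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage import measure

logger = logging.getLogger(__name__)

#: Phase label codes used throughout the package.
SOIL, WATER, AIR = 0, 1, 2

PHASE_NAMES = {SOIL: "soil", WATER: "water", AIR: "air"}

#: 26-connectivity structuring element used for object counting.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
#: 6-connectivity (face) structuring element used for flow pathways.
STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class PhaseVolume:
    """A labelled three-phase voxel volume.

    Parameters
    ----------
    labels
        3D ``uint8`` array with values in ``{SOIL, WATER, AIR}``.
    voxel_size_um
        Isotropic voxel edge length in micrometres (must be positive).
    potential_kpa
        Matric potential at which the configuration holds, if any
        (non-positive; ``None`` for potential-free volumes).
    meta
        Free-form provenance metadata (seed, generator spec, ...).
    """

    labels: np.ndarray
    voxel_size_um: float
    potential_kpa: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.isin(self.labels, (SOIL, WATER, AIR)).all():
            raise ValueError("labels must be drawn from {soil=0, water=1, air=2}")
        if self.labels.dtype != np.uint8:
            self.labels = self.labels.astype(np.uint8)
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")

    # -- masks ---------------------------------------------------------
    @property
    def soil_mask(self) -> np.ndarray:
        return self.labels == SOIL

    @property
    def water_mask(self) -> np.ndarray:
        return self.labels == WATER

    @property
    def air_mask(self) -> np.ndarray:
        return self.labels == AIR

    @property
    def pore_mask(self) -> np.ndarray:
        return self.labels != SOIL

    # -- scalar summaries ---------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def porosity(self) -> float:
        return float(self.pore_mask.mean())

    @property
    def water_fraction(self) -> float:
        """Volumetric water content (water voxels / total voxels)."""
        return float(self.water_mask.mean())

    @property
    def air_fraction(self) -> float:
        return float(self.air_mask.mean())

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size_um * 1e-3) ** 3

    def phase_counts(self) -> dict[str, int]:
        return {
            PHASE_NAMES[code]: int((self.labels == code).sum())
            for code in (SOIL, WATER, AIR)
        }

    def copy(self) -> "PhaseVolume":
        return PhaseVolume(
            self.labels.copy(), self.voxel_size_um, self.potential_kpa, dict(self.meta)
        )


@dataclass
class GreyscaleVolume:
    """A reconstructed greyscale CT volume with calibration references.

    ``water_ref_grey`` and ``soil_ref_grey`` are the mean greys of the
    two reference objects scanned with each core; water attenuates less
    than mineral soil, so ``water_ref_grey < soil_ref_grey`` is enforced.
    """

    intensities: np.ndarray
    voxel_size_um: float
    water_ref_grey: float
    soil_ref_grey: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        if not self.water_ref_grey < self.soil_ref_grey:
            raise ValueError(
                "reference greys inverted or equal: water must attenuate "
                f"less than soil (water={self.water_ref_grey}, "
                f"soil={self.soil_ref_grey})"
            )


# ---------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(volume: PhaseVolume | GreyscaleVolume, path: str | Path) -> None:
    """Write a volume as a TIFF stack plus a JSON sidecar.

    Labelled volumes are stored as uint8 pages; greyscale volumes keep
    their dtype (float stacks round-trip losslessly).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(volume, PhaseVolume):
        tifffile.imwrite(path, volume.labels)
        sidecar = {
            "kind": "phase",
            "voxel_size_um": volume.voxel_size_um,
            "potential_kPa": volume.potential_kpa,
            "meta": volume.meta,
        }
    elif isinstance(volume, GreyscaleVolume):
        tifffile.imwrite(path, volume.intensities)
        sidecar = {
            "kind": "greyscale",
            "voxel_size_um": volume.voxel_size_um,
            "water_ref_grey": volume.water_ref_grey,
            "soil_ref_grey": volume.soil_ref_grey,
            "meta": volume.meta,
        }
    else:  # pragma: no cover - defensive
        raise TypeError(f"unsupported volume type {type(volume)!r}")
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_volume(path: str | Path) -> PhaseVolume | GreyscaleVolume:
    """Read a TIFF (or raw) volume with its JSON sidecar.

    Raises
    ------
    FileNotFoundError
        If the sidecar with the voxel-size metadata is missing; voxel
        size is never silently defaulted.
    """
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing sidecar metadata {sidecar_path}; voxel size must be explicit"
        )
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    if "voxel_size_um" not in sidecar:
        raise ValueError(f"sidecar {sidecar_path} lacks voxel_size_um")

    if path.suffix.lower() in {".tif", ".tiff"}:
        data = tifffile.imread(path)
    elif path.suffix.lower() == ".raw":
        dtype = np.dtype(sidecar["dtype"])
        shape = tuple(sidecar["shape"])
        data = np.fromfile(path, dtype=dtype).reshape(shape)
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r}")

    kind = sidecar.get("kind", "phase")
    if kind == "phase":
        return PhaseVolume(
            data.astype(np.uint8),
            float(sidecar["voxel_size_um"]),
            sidecar.get("potential_kPa"),
            sidecar.get("meta", {}),
        )
    return GreyscaleVolume(
        data,
        float(sidecar["voxel_size_um"]),
        float(sidecar["water_ref_grey"]),
        float(sidecar["soil_ref_grey"]),
        sidecar.get("meta", {}),
    )


# ---------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------

def segment_threshold(
    grey: GreyscaleVolume, air_ref_grey: float | None = None
) -> PhaseVolume:
    """Segment a greyscale volume into air/water/soil by reference-calibrated
    thresholds.

    Two cut points are placed at midpoints between class references: the
    air/water cut halfway between the air grey and the water reference,
    and the water/soil cut halfway between the water and soil references.
    The air grey defaults to the histogram's lowest mode (only the water
    and soil references are calibrated by scanning physical objects).
    """
    if air_ref_grey is None:
        air_ref_grey = _lowest_histogram_mode(grey)
    if not air_ref_grey < grey.water_ref_grey:
        raise ValueError(
            f"air reference grey ({air_ref_grey}) must lie below the water "
            f"reference ({grey.water_ref_grey})"
        )
    cut_air_water = 0.5 * (air_ref_grey + grey.water_ref_grey)
    cut_water_soil = 0.5 * (grey.water_ref_grey + grey.soil_ref_grey)
    labels = np.full(grey.intensities.shape, WATER, dtype=np.uint8)
    labels[grey.intensities < cut_air_water] = AIR
    labels[grey.intensities >= cut_water_soil] = SOIL
    return PhaseVolume(
        labels,
        grey.voxel_size_um,
        None,
        {
            **grey.meta,
            "segmentation": {
                "air_ref_grey": float(air_ref_grey),
                "cut_air_water": float(cut_air_water),
                "cut_water_soil": float(cut_water_soil),
            },
        },
    )


def _lowest_histogram_mode(grey: GreyscaleVolume) -> float:
    """Lowest local mode of the intensity histogram, below the water grey."""
    values = grey.intensities[grey.intensities < grey.water_ref_grey]
    if values.size == 0:
        return float(grey.intensities.min())
    hist, edges = np.histogram(values.ravel(), bins=64)
    centres = 0.5 * (edges[:-1] + edges[1:])
    # first local maximum scanning upward
    for i in range(len(hist)):
        left = hist[i - 1] if i > 0 else -1
        right = hist[i + 1] if i < len(hist) - 1 else -1
        if hist[i] >= left and hist[i] >= right and hist[i] > 0:
            return float(centres[i])
    return float(centres[int(np.argmax(hist))])


# ---------------------------------------------------------------------
# Noise filtering
# ---------------------------------------------------------------------

def filter_noise(
    volume: PhaseVolume,
    mode: str = "3D",
    min_extent_voxels: int = 2,
    min_volume_mm3: float | None = None,
) -> PhaseVolume:
    """Remove sub-resolution pore specks following the CT noise rule.

    In 3D mode any connected non-soil object (water or air, counted with
    26-connectivity) whose bounding box is below ``min_extent_voxels`` in
    any axis, or whose volume falls below ``min_volume_mm3``, is
    relabelled to the majority phase of its face neighbours (ties broken
    toward water, so filtering never invents solid).  The default volume
    cutoff is ``(2 * voxel edge)**3`` — 8e-6 mm^3 at a 10.17 um voxel.
    In 2D mode the per-slice analogue applies the minimum-diameter rule
    (0.02 mm at that resolution) within each z-slice.

    The number of removed objects per phase is logged and recorded in
    ``meta['noise_filter']``.
    """
    if mode not in {"2D", "3D"}:
        raise ValueError("mode must be '2D' or '3D'")
    if min_volume_mm3 is None:
        min_volume_mm3 = (min_extent_voxels * volume.voxel_size_um * 1e-3) ** 3

    labels = volume.labels.copy()
    removed = {"water": 0, "air": 0}
    voxel_mm3 = volume.voxel_volume_mm3

    for phase, name in ((WATER, "water"), (AIR, "air")):
        if mode == "3D":
            removed[name] += _filter_phase_3d(
                labels, phase, min_extent_voxels, min_volume_mm3, voxel_mm3
            )
        else:
            for z in range(labels.shape[0]):
                removed[name] += _filter_phase_2d(
                    labels[z], phase, min_extent_voxels
                )

    if removed["water"] or removed["air"]:
        logger.info(
            "noise filter removed %d water and %d air objects",
            removed["water"],
            removed["air"],
        )
    out = PhaseVolume(
        labels,
        volume.voxel_size_um,
        volume.potential_kpa,
        {**volume.meta, "noise_filter": {"mode": mode, "removed": removed}},
    )
    return out


def _filter_phase_3d(labels, phase, min_extent, min_volume_mm3, voxel_mm3) -> int:
    mask = labels == phase
    lab, n = ndimage.label(mask, structure=STRUCT_26)
    if n == 0:
        return 0
    removed = 0
    slices = ndimage.find_objects(lab)
    counts = np.bincount(lab.ravel())
    for i, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        extents = [s.stop - s.start for s in sl]
        vol_mm3 = counts[i] * voxel_mm3
        if min(extents) < min_extent or vol_mm3 < min_volume_mm3:
            _relabel_component(labels, lab, i, sl)
            removed += 1
    return removed


def _filter_phase_2d(slice_labels, phase, min_extent) -> int:
    mask = slice_labels == phase
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return 0
    removed = 0
    slices = ndimage.find_objects(lab)
    for i, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        extents = [s.stop - s.start for s in sl]
        if min(extents) < min_extent:  # diameter below twice the resolution
            comp = lab[sl] == i
            _relabel_slice_component(slice_labels, sl, comp)
            removed += 1
    return removed


def _majority_neighbour_phase(labels, comp_mask) -> int:
    """Majority phase among face neighbours of a component; ties -> water."""
    dilated = ndimage.binary_dilation(comp_mask, structure=STRUCT_6 if comp_mask.ndim == 3 else ndimage.generate_binary_structure(2, 1))
    border = dilated & ~comp_mask
    neigh = labels[border]
    if neigh.size == 0:
        return WATER
    counts = np.bincount(neigh, minlength=3)
    best = counts.max()
    if counts[WATER] == best:
        return WATER  # tie-break toward water: never invent solid
    return int(np.argmax(counts))


def _relabel_component(labels, lab, index, sl) -> None:
    pad = tuple(
        slice(max(s.start - 1, 0), min(s.stop + 1, dim))
        for s, dim in zip(sl, labels.shape)
    )
    comp = lab[pad] == index
    labels[pad][comp] = _majority_neighbour_phase(labels[pad], comp)


def _relabel_slice_component(slice_labels, sl, comp) -> None:
    pad = tuple(
        slice(max(s.start - 1, 0), min(s.stop + 1, dim))
        for s, dim in zip(sl, slice_labels.shape)
    )
    comp_pad = np.zeros(
        tuple(p.stop - p.start for p in pad), dtype=bool
    )
    off = tuple(s.start - p.start for s, p in zip(sl, pad))
    comp_pad[
        off[0] : off[0] + comp.shape[0], off[1] : off[1] + comp.shape[1]
    ] = comp
    slice_labels[pad][comp_pad] = _majority_neighbour_phase(
        slice_labels[pad], comp_pad
    )


# ---------------------------------------------------------------------
# Surface export
# ---------------------------------------------------------------------

def export_stl(volume: PhaseVolume, phase: int, path: str | Path) -> None:
    """Export the isosurface of one phase as an STL mesh.

    The phase mask is padded by one background voxel so the surface is
    closed, triangulated by marching cubes, and scaled to millimetres.
    """
    import trimesh

    mask = (volume.labels == phase).astype(np.float32)
    padded = np.pad(mask, 1)
    if padded.max() == 0:
        raise ValueError(f"phase {PHASE_NAMES.get(phase, phase)} is empty")
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts = (verts - 1.0) * (volume.voxel_size_um * 1e-3)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.export(str(path))
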