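"""REV subsampling: random cubes, dyadic volume series, and reflection.

A representative elementary volume (REV) is a cubic subvolume of a
labelled sample.  Conductivity convergence is studied on a dyadic series
V_j = V_0 / 2^j (j = 0..8 by default), each level a concentric cube of
the level above.  Reflection of an REV in all three axes yields a truly
periodic geometry whose unit cell is 8x the REV — the construction that
justifies the mirror-symmetry boundary conditions of the cell problem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phase_io import PhaseVolume


@dataclass
class REVSample:
    """A cubic subvolume used as homogenization domain.

    ``origin`` is the voxel coordinate of the low corner in the parent
    volume; ``level`` the dyadic index j (volume V_0 / 2^j); ``parent_id``
    identifies the level-0 cube the sample was refined from.
    """

    volume: PhaseVolume
    origin: tuple[int, int, int]
    level: int = 0
    parent_id: str = ""

    def __post_init__(self) -> None:
        s = self.volume.shape
        if not (s[0] == s[1] == s[2]):
            raise ValueError(f"REV must be cubic, got shape {s}")

    @property
    def side_voxels(self) -> int:
        return self.volume.shape[0]

    @property
    def side_mm(self) -> float:
        return self.side_voxels * self.volume.voxel_size_um * 1e-3

    @property
    def volume_mm3(self) -> float:
        return self.side_mm**3


def extract_subsamples(
    volume: PhaseVolume,
    n: int,
    side_mm: float | None = None,
    side_voxels: int | None = None,
    seed: int = 0,
) -> list[REVSample]:
    """Extract ``n`` cubic subsamples at seeded-random origins.

    Origins are drawn uniformly so each cube lies fully inside the
    volume; overlap between cubes is permitted.  With a fixed seed the
    origins are reproducible, so the same coordinates can be reused for
    the drained configurations of the same sample (see
    :func:`resample_at_origins`).
    """
    if (side_mm is None) == (side_voxels is None):
        raise ValueError("give exactly one of side_mm or side_voxels")
    if side_voxels is None:
        side_voxels = int(round(side_mm / (volume.voxel_size_um * 1e-3)))
    if side_voxels < 4:
        raise ValueError(f"cube side {side_voxels} voxels is too small")
    if any(side_voxels > s for s in volume.shape):
        raise ValueError(
            f"cube of side {side_voxels} voxels does not fit in volume "
            f"of shape {volume.shape}"
        )
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        origin = tuple(
            int(rng.integers(0, dim - side_voxels + 1)) for dim in volume.shape
        )
        samples.append(_crop(volume, origin, side_voxels, parent_id=f"cube{i}"))
    return samples


def resample_at_origins(
    volume: PhaseVolume, samples: list[REVSample]
) -> list[REVSample]:
    """Re-extract cubes from another configuration at identical origins.

    Used to sample the same coordinates across the matric potentials of
    one sample, so the REV series is geometrically paired.
    """
    return [
        _crop(volume, s.origin, s.side_voxels, parent_id=s.parent_id, level=s.level)
        for s in samples
    ]


def _crop(
    volume: PhaseVolume,
    origin: tuple[int, int, int],
    side: int,
    parent_id: str = "",
    level: int = 0,
) -> REVSample:
    sl = tuple(slice(o, o + side) for o in origin)
    sub = PhaseVolume(
        volume.labels[sl].copy(),
        volume.voxel_size_um,
        volume.potential_kpa,
        {**volume.meta, "origin": tuple(int(o) for o in origin)},
    )
    return REVSample(sub, tuple(int(o) for o in origin), level=level, parent_id=parent_id)


def dyadic_series(sample: REVSample, j_max: int = 8) -> list[REVSample]:
    """Nested concentric cubes with V_j = V_0 / 2^j, j = 0..j_max.

    Side lengths scale by 2^(-j/3) and are rounded to whole voxels (the
    achieved side is what enters the conductivity scaling).  The series
    truncates with a warning once a sub-cube would fall below 4 voxels
    per side.
    """
    if j_max < 0:
        raise ValueError("j_max must be >= 0")
    side0 = sample.side_voxels
    out: list[REVSample] = []
    for j in range(j_max + 1):
        side = int(round(side0 * 2.0 ** (-j / 3.0)))
        if side < 4:
            warnings.warn(
                f"dyadic series truncated at j={j - 1}: side would be "
                f"{side} voxels",
                stacklevel=2,
            )
            break
        off = (side0 - side) // 2
        origin_local = (off, off, off)
        sl = tuple(slice(o, o + side) for o in origin_local)
        sub = PhaseVolume(
            sample.volume.labels[sl].copy(),
            sample.volume.voxel_size_um,
            sample.volume.potential_kpa,
            dict(sample.volume.meta),
        )
        origin_global = tuple(int(a + b) for a, b in zip(sample.origin, origin_local))
        out.append(
            REVSample(sub, origin_global, level=j, parent_id=sample.parent_id)
        )
    return out


def reflect(sample: REVSample) -> PhaseVolume:
    """Mirror an REV in x, y and z to build a truly periodic geometry.

    The result has twice the side in each axis (8x the voxel count);
    opposite boundary faces are identical voxel-by-voxel, and all phase
    fractions are preserved exactly.
    """
    labels = sample.volume.labels
    for axis in range(3):
        labels = np.concatenate([np.flip(labels, axis=axis), labels], axis=axis)
    return PhaseVolume(
        labels,
        sample.volume.voxel_size_um,
        sample.volume.potential_kpa,
        {**sample.volume.meta, "reflected": True},
    )


def manifest(samples: list[REVSample]) -> pd.DataFrame:
    """Tabulate a set of REVs: id, origin, level, side and volume."""
    rows = [
        {
            "sample_id": s.parent_id,
            "origin_z": s.origin[0],
            "origin_y": s.origin[1],
            "origin_x": s.origin[2],
            "j": s.level,
            "L_y_mm": s.side_mm,
            "achieved_voxels": s.side_voxels,
            "volume_mm3": s.volume_mm3,
        }
        for s in samples
    ]
    return pd.DataFrame(rows)
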