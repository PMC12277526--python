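"""ALPS index from spherical ROIs on template-space diffusivity maps.

At the body of the lateral ventricle the perivascular space runs
left–right (x), perpendicular both to projection fibers (inferior–superior,
z) and association fibers (anterior–posterior, y). The index contrasts
x-diffusivity in those two fiber regions against the corresponding
off-fiber, non-perivascular diffusivities:

    ALPS = mean(Dxproj, Dxassoc) / mean(Dyproj, Dzassoc)

computed per hemisphere; the bilateral average is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from dtialps.tensor import DiffusivityMaps

#: Grid shape of the 1 mm template the published ROI coordinates index.
TEMPLATE_SHAPE = (182, 218, 182)
#: Reduced grid used by fast tests and smoke runs, with re-homed ROIs.
REDUCED_SHAPE = (64, 64, 32)

ROI_DIAMETER_MM = 5.0


@dataclass(frozen=True)
class ROISpec:
    """A spherical ROI on the template grid.

    ``center`` is a voxel index (0-based by default; see ``default_rois``);
    ``diameter`` is in mm.
    """

    name: str
    side: str  # left | right
    fiber: str  # projection | association
    center: tuple[int, int, int]
    diameter: float = ROI_DIAMETER_MM

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"bad side {self.side!r}")
        if self.fiber not in ("projection", "association"):
            raise ValueError(f"bad fiber {self.fiber!r}")
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")


@dataclass(frozen=True)
class ALPSResult:
    """ROI mean diffusivities (mm²/s) and the three ALPS ratios."""

    dx_proj_left: float
    dx_assoc_left: float
    dy_proj_left: float
    dz_assoc_left: float
    dx_proj_right: float
    dx_assoc_right: float
    dy_proj_right: float
    dz_assoc_right: float
    alps_left: float
    alps_right: float
    alps_mean: float

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


# Published ROI centers on the 1 mm template, interpreted as 0-based voxel
# indices: (x, y, z) with left at the higher x index.
_DEFAULT_CENTERS = {
    ("left", "projection"): (116, 109, 99),
    ("left", "association"): (126, 109, 99),
    ("right", "projection"): (64, 109, 101),
    ("right", "association"): (54, 109, 101),
}

# Re-homed centers for the reduced 64×64×32 test grid, preserving the
# left/right layout (left = higher x) and the small z offset between sides.
_REDUCED_CENTERS = {
    ("left", "projection"): (40, 16, 15),
    ("left", "association"): (45, 16, 15),
    ("right", "projection"): (23, 16, 16),
    ("right", "association"): (18, 16, 16),
}


def _build(centers, one_based: bool = False) -> tuple[ROISpec, ...]:
    rois = []
    for (side, fiber), c in centers.items():
        if one_based:
            c = tuple(v - 1 for v in c)
        rois.append(ROISpec(name=f"{side}_{fiber}", side=side, fiber=fiber, center=c))
    return tuple(rois)


def default_rois(one_based: bool = False) -> tuple[ROISpec, ...]:
    """The four published ROIs (5 mm diameter) on the 1 mm template grid.

    ``one_based`` shifts the printed coordinates down by one voxel for
    sources that index from 1.
    """
    return _build(_DEFAULT_CENTERS, one_based)


def reduced_rois() -> tuple[ROISpec, ...]:
    """The four ROIs re-homed into the reduced test grid."""
    return _build(_REDUCED_CENTERS)


def mirror_rois(rois, grid_shape) -> tuple[ROISpec, ...]:
    """Reflect ROI centers across the grid's x mid-plane and swap sides."""
    nx = grid_shape[0]
    out = []
    flip = {"left": "right", "right": "left"}
    for r in rois:
        cx, cy, cz = r.center
        side = flip[r.side]
        out.append(
            ROISpec(
                name=f"{side}_{r.fiber}",
                side=side,
                fiber=r.fiber,
                center=(nx - 1 - cx, cy, cz),
                diameter=r.diameter,
            )
        )
    return tuple(out)


@lru_cache(maxsize=32)
def sphere_offsets(diameter_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Integer voxel offsets whose centers lie within diameter/2 of the
    center-voxel center. On a 1 mm grid a 5 mm sphere contains 81 voxels."""
    radius_vox = (diameter_mm / 2.0) / voxel_size_mm
    r = int(np.floor(radius_vox))
    ax = np.arange(-r, r + 1)
    i, j, k = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = i * i + j * j + k * k <= radius_vox * radius_vox
    return np.column_stack([i[inside], j[inside], k[inside]])


def roi_mean(volume: np.ndarray, roi: ROISpec, voxel_size: float = 1.0) -> float:
    """Unweighted mean of ``volume`` over the ROI sphere.

    Raises if the sphere is clipped by the grid boundary.
    """
    offs = sphere_offsets(roi.diameter, voxel_size)
    idx = offs + np.asarray(roi.center)
    if np.any(idx < 0) or np.any(idx >= np.asarray(volume.shape)):
        raise ValueError(f"ROI {roi.name!r} sphere extends outside the grid")
    # sort before summing so the mean is bit-stable under any voxel
    # enumeration order (e.g. mirrored ROIs gather identical value sets)
    return float(np.sort(volume[idx[:, 0], idx[:, 1], idx[:, 2]]).mean())


def compute_alps(maps: DiffusivityMaps, rois) -> ALPSResult:
    """Compute left/right/average ALPS from dxx/dyy/dzz maps and four ROIs.

    Dx is read from dxx at both the projection and association ROI; the
    off-fiber denominators are dyy at the projection ROI and dzz at the
    association ROI.
    """
    by_key = {(r.side, r.fiber): r for r in rois}
    needed = {(s, f) for s in ("left", "right") for f in ("projection", "association")}
    missing = needed - set(by_key)
    if missing or len(list(rois)) != 4:
        raise ValueError(f"need one ROI per (side, fiber); missing {sorted(missing)}")

    vs = maps.voxel_size
    vals = {}
    for side in ("left", "right"):
        proj = by_key[(side, "projection")]
        assoc = by_key[(side, "association")]
        vals[f"dx_proj_{side}"] = roi_mean(maps.dxx, proj, vs)
        vals[f"dx_assoc_{side}"] = roi_mean(maps.dxx, assoc, vs)
        vals[f"dy_proj_{side}"] = roi_mean(maps.dyy, proj, vs)
        vals[f"dz_assoc_{side}"] = roi_mean(maps.dzz, assoc, vs)

    def ratio(side: str) -> float:
        num = 0.5 * (vals[f"dx_proj_{side}"] + vals[f"dx_assoc_{side}"])
        den = 0.5 * (vals[f"dy_proj_{side}"] + vals[f"dz_assoc_{side}"])
        if den <= 0:
            raise ValueError(
                f"non-positive ALPS denominator on the {side}: "
                f"Dyproj={vals[f'dy_proj_{side}']:.3e}, "
                f"Dzassoc={vals[f'dz_assoc_{side}']:.3e}"
            )
        return num / den

    left, right = ratio("left"), ratio("right")
    return ALPSResult(
        **vals, alps_left=left, alps_right=right, alps_mean=0.5 * (left + right)
    )
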