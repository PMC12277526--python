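"""Atlas-label summaries of scalar diffusion maps (bilateral hippocampi).

Labels 37 and 38 are the conventional left/right hippocampus IDs of the
90-region anatomical parcellation; any user-supplied integer label volume
on the same grid works.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dtialps.tensor import DiffusivityMaps

HIPPOCAMPUS_LEFT = 37
HIPPOCAMPUS_RIGHT = 38
DEFAULT_LABEL_NAMES = {37: "hippocampus_left", 38: "hippocampus_right"}


@dataclass
class LabelVolume:
    """Integer 3-D label field with a label-ID → region-name dictionary."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)
    voxel_size: float = 1.0
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if self.labels.min() < 0:
            raise ValueError("negative label ID")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            self.names = {**DEFAULT_LABEL_NAMES, **self.names}
            missing = present - set(self.names)
        if missing:
            raise ValueError(f"label dictionary missing IDs {sorted(missing)}")


@dataclass(frozen=True)
class RegionSummary:
    """Per-region means of FA/MD/AD/RD plus voxel accounting."""

    region_id: int
    region_name: str
    n_voxels: int
    n_excluded: int
    fa: float
    md: float
    ad: float
    rd: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def aggregate_region_metrics(
    maps: DiffusivityMaps, labels: LabelVolume, region_ids=(HIPPOCAMPUS_LEFT, HIPPOCAMPUS_RIGHT)
) -> list[RegionSummary]:
    """Unweighted mean of each scalar map over each requested label.

    Voxels flagged by the tensor fit (degenerate or clamped) are excluded
    and counted. Raises when the grids mismatch, a requested ID is absent,
    or a label has no usable voxels.
    """
    if labels.labels.shape != maps.fa.shape:
        raise ValueError(
            f"label grid {labels.labels.shape} does not match map grid {maps.fa.shape}"
        )
    out = []
    for rid in region_ids:
        sel = labels.labels == rid
        if not sel.any():
            raise ValueError(f"label {rid} absent from the label volume")
        usable = sel & ~maps.flags
        n_excl = int(sel.sum() - usable.sum())
        if not usable.any():
            raise ValueError(f"label {rid} has no usable (unflagged) voxels")
        out.append(
            RegionSummary(
                region_id=int(rid),
                region_name=labels.names.get(int(rid), str(rid)),
                n_voxels=int(usable.sum()),
                n_excluded=n_excl,
                fa=float(maps.fa[usable].mean()),
                md=float(maps.md[usable].mean()),
                ad=float(maps.ad[usable].mean()),
                rd=float(maps.rd[usable].mean()),
            )
        )
    return out
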