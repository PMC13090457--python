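"""Embolization quantification: intersection counts, efficiency, percent
embolized cortex, per-region particle counts and volume ratios.

The central measurement overlays the segmented embolic/vessel mask on a
depth-stratified cortical shell. Both masks are binary, so the "intersection
at positive integers" is a voxel-wise AND; the intersecting-voxel count
divided by kidney volume is the *embolization efficiency* (voxels/ml), and
the same count as a fraction of the shell's own voxel count is the *percent
embolized cortex*.

Conventions this package fixes (the measurements themselves do not dictate
them):

- percent_embolized_cortex divides by the shell's own voxel count by
  default ("percentage of the embolized cortex" as a fraction of cortex);
  the whole-kidney denominator is available via ``denominator="whole"``.
- a particle (connected component) belongs to a region iff its voxel
  centroid — the component's mean voxel index, rounded half-up — lies in
  the region. Because shell and inner masks partition the kidney, this
  rule partitions the components.
- kidney volume for normalization defaults to the mask-derived volume
  (voxels x spacing^3); the ultrasound-style ellipsoid volume can be used
  instead when axis measurements are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import label_components
from .stratify import stratify
from .volio import BinaryMask, mask_volume_ml, require_same_grid

__all__ = [
    "KidneyQuantification",
    "count_intersection_voxels",
    "embolization_efficiency",
    "percent_embolized_cortex",
    "count_particles_in_region",
    "component_centroid_voxels",
    "embolic_to_kidney_ratio",
    "percent_difference",
    "sum_particle_counts",
    "quantify_kidney",
]


@dataclass
class DepthMetrics:
    """Quantities measured in one cortical shell."""

    depth_px: int
    intersect_voxels: int
    shell_voxels: int
    particle_count: int
    efficiency_per_ml: float
    percent_embolized_cortex: float


@dataclass
class KidneyQuantification:
    """All measured quantities for one kidney."""

    kidney_id: str
    subject: int
    side: str
    regime: str
    kidney_volume_ml: float
    embolic_volume_ml: float
    total_particle_count: int
    per_depth: dict[int, DepthMetrics] = field(default_factory=dict)

    @property
    def load_volume_ratio(self) -> float:
        """Injected embolic volume over kidney parenchymal volume."""
        return embolic_to_kidney_ratio(self.embolic_volume_ml, self.kidney_volume_ml)


def count_intersection_voxels(vessel_mask: BinaryMask, region_mask: BinaryMask) -> int:
    """Voxels true in both masks (binary volumes, so AND-and-sum)."""
    require_same_grid(vessel_mask, region_mask)
    return int(np.count_nonzero(vessel_mask.data & region_mask.data))


def embolization_efficiency(intersect_voxels: int, kidney_volume_ml: float) -> float:
    """Intersecting-voxel count normalized by kidney volume (voxels per ml)."""
    if kidney_volume_ml <= 0:
        raise ValueError("kidney volume must be positive")
    return intersect_voxels / kidney_volume_ml


def percent_embolized_cortex(intersect_voxels_in_shell: int, shell_voxels: int) -> float:
    """Embolized fraction of the cortical shell, in percent."""
    if shell_voxels <= 0:
        raise ValueError("shell is empty; percent embolized cortex is undefined")
    if intersect_voxels_in_shell > shell_voxels:
        raise ValueError("intersection cannot exceed the shell size")
    return 100.0 * intersect_voxels_in_shell / shell_voxels


def component_centroid_voxels(label_grid: np.ndarray, n_components: int) -> np.ndarray:
    """(n, 3) voxel indices of component centroids (mean index, rounded half-up)."""
    if n_components == 0:
        return np.zeros((0, 3), dtype=np.int64)
    flat = np.flatnonzero(label_grid.ravel())
    labs = label_grid.ravel()[flat]
    coords = np.column_stack(np.unravel_index(flat, label_grid.shape)).astype(float)
    out = np.empty((n_components, 3))
    counts = np.bincount(labs, minlength=n_components + 1)[1:]
    for axis in range(3):
        sums = np.bincount(labs, weights=coords[:, axis], minlength=n_components + 1)[1:]
        out[:, axis] = sums / counts
    return np.floor(out + 0.5).astype(np.int64)


def count_particles_in_region(
    label_grid: np.ndarray,
    region_mask: BinaryMask,
    n_components: int | None = None,
) -> int:
    """Number of components whose voxel centroid lies inside the region."""
    if label_grid.shape != region_mask.shape:
        raise ValueError(
            f"label grid {label_grid.shape} and region {region_mask.shape} differ in shape"
        )
    if n_components is None:
        n_components = int(label_grid.max())
    cent = component_centroid_voxels(label_grid, n_components)
    if len(cent) == 0:
        return 0
    return int(np.count_nonzero(region_mask.data[cent[:, 0], cent[:, 1], cent[:, 2]]))


def embolic_to_kidney_ratio(embolic_ml: float, kidney_ml: float) -> float:
    """Injected embolic volume over kidney parenchymal volume."""
    if kidney_ml <= 0:
        raise ValueError("kidney volume must be positive")
    return embolic_ml / kidney_ml


def percent_difference(a: float, b: float) -> float:
    """Relative difference of a vs baseline b, in percent: 100 (a - b) / b."""
    if b == 0:
        raise ValueError("baseline is zero; percent difference undefined")
    return 100.0 * (a - b) / b


def sum_particle_counts(per_subject_counts) -> int:
    """Total particle load across subjects (plain sum of non-negative counts)."""
    counts = [int(c) for c in per_subject_counts]
    if any(c < 0 for c in counts):
        raise ValueError("particle counts must be non-negative")
    return sum(counts)


def quantify_kidney(
    vessel_mask: BinaryMask,
    kidney_mask: BinaryMask,
    depths_px=(50, 100),
    *,
    kidney_id: str = "kidney",
    subject: int = 0,
    side: str = "",
    regime: str = "",
    embolic_volume_ml: float = float("nan"),
    kidney_volume_ml: float | None = None,
    connectivity: int = 26,
    percent_denominator: str = "shell",
    distance_field: np.ndarray | None = None,
) -> KidneyQuantification:
    """Full quantification of one kidney at every requested depth.

    ``kidney_volume_ml`` defaults to the mask-derived volume; pass the
    ultrasound ellipsoid volume to normalize the way a pre-embolization
    sonographic measurement would.
    """
    require_same_grid(vessel_mask, kidney_mask)
    if percent_denominator not in ("shell", "whole"):
        raise ValueError("percent_denominator must be 'shell' or 'whole'")
    if kidney_volume_ml is None:
        kidney_volume_ml = mask_volume_ml(kidney_mask)
    labels, n_comp = label_components(vessel_mask, connectivity)
    strata = stratify(kidney_mask, depths_px, distance_field=distance_field)
    whole_voxels = kidney_mask.voxel_count()
    q = KidneyQuantification(
        kidney_id=kidney_id,
        subject=subject,
        side=side,
        regime=regime,
        kidney_volume_ml=float(kidney_volume_ml),
        embolic_volume_ml=float(embolic_volume_ml),
        total_particle_count=n_comp,
    )
    for s in strata:
        inter = count_intersection_voxels(vessel_mask, s.shell)
        shell_vox = s.shell.voxel_count()
        denom = shell_vox if percent_denominator == "shell" else whole_voxels
        q.per_depth[s.depth_px] = DepthMetrics(
            depth_px=s.depth_px,
            intersect_voxels=inter,
            shell_voxels=shell_vox,
            particle_count=count_particles_in_region(labels, s.shell, n_comp),
            efficiency_per_ml=embolization_efficiency(inter, kidney_volume_ml),
            percent_embolized_cortex=percent_embolized_cortex(inter, denom),
        )
    return q
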