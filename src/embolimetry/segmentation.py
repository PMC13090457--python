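"""Extraction of the radiopaque embolic signal from an intensity volume.

Radiopaque beads are engineered to be high-contrast against parenchyma, so
segmentation is a deterministic global threshold followed by a
minimum-component-size filter (the size filter is what excludes residual
parenchyma/noise speckle). This is a deliberate, declared replacement for
interactive pixel-classifier segmentation: it is reproducible, testable and
monotone in its threshold.

"Particle count" in this package means the number of connected components
of the segmented mask. Beads that touch after deposition merge into one
component and under-count; the default 26-connectivity avoids the opposite
artifact of one bead splitting across a diagonal into two counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volio import BinaryMask, Volume3D

__all__ = ["SegmentationParams", "segment_particles", "label_components"]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class SegmentationParams:
    """Threshold segmentation parameters.

    threshold
        Intensity cutoff; strictly greater-than survives.
    min_component_voxels
        Components smaller than this are removed (>= 1; 1 disables).
    connectivity
        Voxel adjacency: 6 (faces), 18 (+edges) or 26 (+corners).
    """

    threshold: float
    min_component_voxels: int = 1
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.min_component_voxels < 1:
            raise ValueError("min_component_voxels must be >= 1")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be one of 6, 18, 26")


def segment_particles(volume: Volume3D, params: SegmentationParams) -> BinaryMask:
    """Threshold the volume and drop components below the size floor.

    mask = (intensity > threshold), then connected components (at
    ``params.connectivity``) with fewer than ``min_component_voxels`` voxels
    are removed. Raising the threshold never adds a foreground voxel.
    """
    if not np.all(np.isfinite(volume.data)):
        raise ValueError("volume contains non-finite intensities")
    mask = volume.data > params.threshold
    if params.min_component_voxels > 1 and mask.any():
        labels, n = label_components(
            BinaryMask(mask, volume.spacing_mm, volume.origin_mm), params.connectivity
        )
        sizes = np.bincount(labels.ravel(), minlength=n + 1)
        keep = sizes >= params.min_component_voxels
        keep[0] = False
        mask = keep[labels]
    return BinaryMask(mask, volume.spacing_mm, volume.origin_mm)


def label_components(mask: BinaryMask, connectivity: int = 26) -> tuple[np.ndarray, int]:
    """Connected-component labeling: labels 1..count, background 0."""
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, count = ndimage.label(mask.data, structure=structure)
    return labels, int(count)
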