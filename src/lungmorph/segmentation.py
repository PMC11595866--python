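"""NAA segmentation: attenuation-interval thresholding and components.

The Normal Attenuation Area (NAA) is the set of voxels with HU strictly
above -950 and at most -700 — intact lung parenchyma, excluding
emphysema/air below and soft tissue / consolidation above. The interval
is left-open, right-closed: -700 HU is included, -950 HU is excluded.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import ImageVolume, VoxelMask

HU_LOW_DEFAULT = -950.0
HU_HIGH_DEFAULT = -700.0

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def naa_mask(
    volume: ImageVolume,
    hu_low: float = HU_LOW_DEFAULT,
    hu_high: float = HU_HIGH_DEFAULT,
    roi: VoxelMask | None = None,
) -> VoxelMask:
    """Binary NAA mask: voxels with hu_low < HU <= hu_high, within the ROI.

    Parameters
    ----------
    volume
        HU volume.
    hu_low, hu_high
        Attenuation interval bounds; the interval is open at ``hu_low``
        and closed at ``hu_high``.
    roi
        Optional region restriction (e.g. a lung mask) of the same shape.
    """
    if hu_low >= hu_high:
        raise ValueError(f"inverted thresholds: hu_low={hu_low} >= hu_high={hu_high}")
    fg = (volume.values > hu_low) & (volume.values <= hu_high)
    if roi is not None:
        if roi.shape != volume.shape:
            raise ValueError(
                f"ROI shape {roi.shape} does not match volume shape {volume.shape}"
            )
        fg &= roi.foreground
    return VoxelMask(foreground=fg, spacing=volume.spacing)


def largest_component(mask: VoxelMask, connectivity: int = 26) -> VoxelMask:
    """Largest connected component under 6/18/26-connectivity.

    Empty input yields an empty mask. Ties in component size are broken
    by the component containing the lexicographically smallest voxel
    (scipy labels components in raster-scan order of first encounter).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    if mask.is_empty():
        return VoxelMask(foreground=np.zeros(mask.shape, bool), spacing=mask.spacing)
    labels, n = ndimage.label(mask.foreground, structure=_STRUCTURES[connectivity])
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = int(np.argmax(sizes))  # argmax takes the first (raster-first) label on ties
    return VoxelMask(foreground=labels == best, spacing=mask.spacing)
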