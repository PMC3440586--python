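"""Automatic sagittal-plane rotation of a SPECT volume.

Before surface fitting, the volume is rotated in the sagittal (y-z) view so
that the long axis of the brain lies horizontal.  The tilt is estimated as
the orientation of the first principal axis of the above-threshold voxel
cloud projected onto the sagittal plane; a configurable offset angle can be
added on top, and a manual override replaces the estimate entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume


class SegmentationError(ValueError):
    """No above-threshold brain voxels found."""


@dataclass
class OrientConfig:
    threshold_frac: float = 0.30   # of the 99.5th-percentile intensity
    offset_deg: float = 0.0        # added to the PCA angle


@dataclass
class RotationEstimate:
    angle_deg: float       # in-plane tilt incl. offset, in (-90, 90]
    offset_deg: float
    threshold_used: float


def brain_threshold_mask(volume: Volume, threshold_frac: float = 0.30) -> np.ndarray:
    thr = threshold_frac * volume.robust_max()
    mask = volume.data > thr
    if not mask.any():
        raise SegmentationError("no voxels above the brain-tissue threshold")
    return mask


def estimate_rotation(volume: Volume, config: OrientConfig | None = None) -> RotationEstimate:
    """Tilt of the brain's largest extension in the sagittal plane.

    PCA of the (y, z) coordinates of above-threshold voxels; the first
    principal axis makes an angle with the +y (anterior) axis which is folded
    into (-90, 90] to remove the head/tail ambiguity of a principal axis.
    """
    cfg = config or OrientConfig()
    thr = cfg.threshold_frac * volume.robust_max()
    mask = volume.data > thr
    if not mask.any():
        raise SegmentationError("no voxels above the brain-tissue threshold")
    idx = np.argwhere(mask)
    yz = np.column_stack(
        [volume.axis_coords(1)[idx[:, 1]], volume.axis_coords(2)[idx[:, 2]]]
    )
    yz = yz - yz.mean(axis=0)
    cov = yz.T @ yz / len(yz)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, -1]  # first principal axis in the (y, z) plane
    angle = np.degrees(np.arctan2(v[1], v[0]))
    # fold into (-90, 90]
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return RotationEstimate(
        angle_deg=float(angle + cfg.offset_deg),
        offset_deg=cfg.offset_deg,
        threshold_used=float(thr),
    )


def rotate_volume(volume: Volume, angle_deg: float) -> Volume:
    """Rotate by ``angle_deg`` in the sagittal plane about the volume centre,
    trilinear interpolation, grid shape preserved."""
    if not np.isfinite(angle_deg):
        raise ValueError("rotation angle must be finite")
    if angle_deg == 0.0:
        return volume.copy_with(volume.data.copy())
    # ndimage.rotate with axes=(1, 2) rotates +axis1 toward +axis2 for
    # positive angles under our centred world convention
    rotated = ndimage.rotate(
        volume.data, angle_deg, axes=(1, 2), reshape=False, order=1, mode="constant"
    )
    return volume.copy_with(rotated)
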