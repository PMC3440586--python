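"""Brain-lobe region vocabulary shared by the phantom, atlas and quantifier.

Naming follows clinical laterality convention: ``dx`` (dexter) is the right
hemisphere, ``sin`` (sinister) the left.  In the package's world frame +x is
left, so ``sin`` regions have x > 0 and ``dx`` regions x < 0.  Median (``med``)
regions straddle the midline and are unpaired.
"""

from __future__ import annotations

import numpy as np

CEREBELLUM_DX = "cerebellum_dx"
CEREBELLUM_SIN = "cerebellum_sin"

#: Atomic atlas labels, in enumeration (tie-break) order.
REGIONS: list[str] = [
    "cerebellum_dx",
    "cerebellum_sin",
    "frontal_med",
    "frontal_dx",
    "frontal_sin",
    "temporal_dx",
    "temporal_sin",
    "temporal_med_dx",
    "temporal_med_sin",
    "parietal_dx",
    "parietal_sin",
    "occipital",
]

#: Rows of a regional report (atomic labels + the pooled cerebellum).
REPORT_REGIONS: list[str] = [
    "cerebellum",
    "cerebellum_dx",
    "cerebellum_sin",
    "frontal_dx",
    "frontal_sin",
    "frontal_med",
    "temporal_dx",
    "temporal_sin",
    "temporal_med_dx",
    "temporal_med_sin",
    "parietal_dx",
    "parietal_sin",
    "occipital",
]

#: Left/right pairs used for asymmetry indices: name -> (dx label, sin label).
PAIRED_REGIONS: dict[str, tuple[str, str]] = {
    "cerebellum": ("cerebellum_dx", "cerebellum_sin"),
    "frontal": ("frontal_dx", "frontal_sin"),
    "temporal": ("temporal_dx", "temporal_sin"),
    "temporal_med": ("temporal_med_dx", "temporal_med_sin"),
    "parietal": ("parietal_dx", "parietal_sin"),
}


def mirror_label(region: str) -> str:
    """Swap dx <-> sin; median and unpaired regions map to themselves."""
    if region.endswith("_dx"):
        return region[:-3] + "_sin"
    if region.endswith("_sin"):
        return region[:-4] + "_dx"
    return region


def label_points_geometric(points: np.ndarray, spec, in_cerebellum=None) -> np.ndarray:
    """Assign atlas labels (indices into REGIONS) to surface points by the
    phantom's analytic geometry, evaluated in the unrotated anatomical frame."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    cx, cy, cz = spec.brain_center
    ax, ay, az = spec.brain_axes_mm
    y_front = cy + spec.frontal_y_frac * ay
    y_occ = cy + spec.occipital_y_frac * ay
    z_par = cz + spec.parietal_z_frac * az
    x_med = spec.medial_x_frac * ax

    if in_cerebellum is None:
        q = (pts - np.asarray(spec.cerebellum_center)) / np.asarray(spec.cerebellum_axes_mm)
        in_cerebellum = np.einsum("ij,ij->i", q, q) <= 1.0 + 1e-6

    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    sin_side = x > 0
    medial = np.abs(x) <= x_med

    labels = np.empty(len(pts), dtype=np.int64)

    def code(name):
        return REGIONS.index(name)

    # default: temporal
    labels[:] = code("temporal_dx")
    labels[sin_side] = code("temporal_sin")
    labels[medial & ~sin_side] = code("temporal_med_dx")
    labels[medial & sin_side] = code("temporal_med_sin")

    parietal = z >= z_par
    labels[parietal & ~sin_side] = code("parietal_dx")
    labels[parietal & sin_side] = code("parietal_sin")

    occ = y <= y_occ
    labels[occ] = code("occipital")

    front = y >= y_front
    labels[front & ~sin_side] = code("frontal_dx")
    labels[front & sin_side] = code("frontal_sin")
    labels[front & medial] = code("frontal_med")

    labels[in_cerebellum & ~sin_side] = code("cerebellum_dx")
    labels[in_cerebellum & sin_side] = code("cerebellum_sin")
    return labels
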