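"""Lobe atlas construction and the normal-value database.

The atlas assigns every model landmark to a brain lobe with the help of
single-lobe phantom volumes (uptake in one region only), then mirrors the
left-hemisphere division onto the right so the atlas is exactly symmetric.
The normal database aggregates per-point and per-region means and standard
deviations over a group of normal examinations, separately for each of the
three count normalizations, and supports z-scoring a new patient against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .asm_fit import landmark_normals
from .quantify import RegionalReport
from .regions import REGIONS, REPORT_REGIONS, mirror_label
from .shape_model import ShapeModel
from .volume import Volume


class UnassignedLandmarkError(ValueError):
    def __init__(self, indices):
        self.indices = list(indices)
        super().__init__(f"landmarks with zero uptake in all lobe phantoms: {self.indices}")


class ConfigurationError(ValueError):
    """Inconsistent mesh/point configuration between inputs."""


@dataclass
class LobeAtlas:
    """Region label (index into regions.REGIONS) per landmark correspondence id."""

    labels: np.ndarray
    region_names: list[str] = field(default_factory=lambda: list(REGIONS))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if np.any(self.labels < 0) or np.any(self.labels >= len(self.region_names)):
            raise ValueError("atlas contains out-of-range labels")

    def __len__(self) -> int:
        return len(self.labels)

    def counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.labels == i))
            for i, name in enumerate(self.region_names)
        }

    def apply_overrides(self, overrides: dict[int, str]) -> "LobeAtlas":
        """Machine-readable replacement for manual visual adjustment:
        landmark id -> region name."""
        labels = self.labels.copy()
        for idx, region in overrides.items():
            labels[int(idx)] = self.region_names.index(region)
        return LobeAtlas(labels, list(self.region_names))

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"labels": self.labels.tolist(), "region_names": self.region_names}, fh
            )

    @classmethod
    def load(cls, path: str) -> "LobeAtlas":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["labels"]), list(d["region_names"]))


def mirror_correspondence(points: np.ndarray, tol_mm: float = 1e-6) -> np.ndarray:
    """Index of each landmark's mirror partner across the mid-sagittal plane
    (x -> -x), found as the nearest landmark to the reflected position."""
    reflected = points.copy()
    reflected[:, 0] *= -1.0
    tree = cKDTree(points)
    _, partner = tree.query(reflected)
    return partner


def assign_lobes(
    model: ShapeModel,
    lobe_phantoms: dict[str, Volume],
    probe_depth_mm: float = 6.0,
    transform: tuple[float, np.ndarray, np.ndarray] | None = None,
) -> LobeAtlas:
    """Label each mean-shape landmark with the region whose single-lobe phantom
    is hottest at (or slightly beneath) its position, then mirror the left
    hemisphere's division onto the right.

    ``transform`` is an optional similarity ``(s, R, t)`` registering the
    model frame to the phantom frame.  Ties go to the earlier region in the
    enumeration order.  Landmarks that see zero uptake in every phantom raise
    :class:`UnassignedLandmarkError`.
    """
    pts = model.mean_shape.points
    if model.n_theta is None:
        raise ConfigurationError("model lacks ring-layout metadata (n_theta)")
    inward = -landmark_normals(model.mean_shape, model.n_theta)
    if transform is not None:
        s, R, t = transform
        pts = s * pts @ R.T + t
        inward = inward @ R.T
    offsets = np.arange(0.0, probe_depth_mm + 1.0, 2.0)
    probes = pts[:, None, :] + offsets[None, :, None] * inward[:, None, :]
    probes = probes.reshape(-1, 3)

    intensity = np.zeros((len(REGIONS), len(pts)))
    for r, region in enumerate(REGIONS):
        vol = lobe_phantoms.get(region)
        if vol is None:
            continue
        intensity[r] = vol.sample(probes).reshape(len(pts), -1).max(axis=1)
    unassigned = np.flatnonzero(intensity.max(axis=0) <= 0)
    if unassigned.size:
        raise UnassignedLandmarkError(unassigned)
    labels = np.argmax(intensity, axis=0)  # first (smallest-index) max wins

    # mirror the left (sin, x > 0) hemisphere onto the right
    partner = mirror_correspondence(pts)
    left = np.flatnonzero(pts[:, 0] > 1e-6)
    mirrored = labels.copy()
    for i in left:
        mirrored[partner[i]] = REGIONS.index(mirror_label(REGIONS[labels[i]]))
    return LobeAtlas(mirrored)


# ---------------------------------------------------------------------------
# normal-value database


@dataclass
class NormalStats:
    point_mean: np.ndarray
    point_sd: np.ndarray
    region_mean: dict[str, float]
    region_sd: dict[str, float]
    cortical_index_mean: float
    cortical_index_sd: float


@dataclass
class NormalDatabase:
    """Per-point and per-region normal statistics for each normalization."""

    stats: dict[str, NormalStats]
    n_subjects: int
    n_points: int
    note: str = ""

    def save(self, path: str) -> None:
        meta = {
            "n_subjects": self.n_subjects,
            "n_points": self.n_points,
            "note": self.note,
            "methods": list(self.stats),
            "region_stats": {
                m: {
                    "region_mean": s.region_mean,
                    "region_sd": s.region_sd,
                    "cortical_index_mean": s.cortical_index_mean,
                    "cortical_index_sd": s.cortical_index_sd,
                }
                for m, s in self.stats.items()
            },
        }
        arrays = {}
        for m, s in self.stats.items():
            arrays[f"{m}_point_mean"] = s.point_mean
            arrays[f"{m}_point_sd"] = s.point_sd
        np.savez(path, meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str) -> "NormalDatabase":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["meta"]))
            stats = {}
            for m in meta["methods"]:
                rs = meta["region_stats"][m]
                stats[m] = NormalStats(
                    point_mean=npz[f"{m}_point_mean"],
                    point_sd=npz[f"{m}_point_sd"],
                    region_mean=rs["region_mean"],
                    region_sd=rs["region_sd"],
                    cortical_index_mean=rs["cortical_index_mean"],
                    cortical_index_sd=rs["cortical_index_sd"],
                )
        return cls(
            stats=stats,
            n_subjects=meta["n_subjects"],
            n_points=meta["n_points"],
            note=meta["note"],
        )


def build_normal_database(reports: list[RegionalReport], note: str = "") -> NormalDatabase:
    """Sample mean and SD (n - 1 denominator) of every sample point, every
    report region and the cortical index, per normalization method."""
    if len(reports) < 2:
        raise ConfigurationError("need at least two subjects")
    n_points = reports[0].n_points
    methods = list(reports[0].methods)
    for rep in reports:
        if rep.n_points != n_points or list(rep.methods) != methods:
            raise ConfigurationError("reports differ in mesh or normalization configuration")
    stats = {}
    for m in methods:
        values = np.stack([rep.methods[m].point_values for rep in reports])
        region_table = {
            region: np.array([rep.methods[m].region_means[region] for rep in reports])
            for region in REPORT_REGIONS
        }
        ci = np.array([rep.methods[m].cortical_index for rep in reports])
        stats[m] = NormalStats(
            point_mean=values.mean(axis=0),
            point_sd=values.std(axis=0, ddof=1),
            region_mean={r: float(v.mean()) for r, v in region_table.items()},
            region_sd={r: float(v.std(ddof=1)) for r, v in region_table.items()},
            cortical_index_mean=float(ci.mean()),
            cortical_index_sd=float(ci.std(ddof=1)),
        )
    return NormalDatabase(
        stats=stats, n_subjects=len(reports), n_points=n_points, note=note
    )


@dataclass
class PatientZScores:
    point_z: dict[str, np.ndarray]        # NaN where the normal SD is zero
    point_defined: dict[str, np.ndarray]  # False where SD was zero
    region_z: dict[str, dict[str, float]]
    cortical_index_z: dict[str, float]


def zscore_patient(report: RegionalReport, db: NormalDatabase) -> PatientZScores:
    """Standardize a patient's values against the normal database:
    ``z = (value - mean) / SD`` per point, region and cortical index."""
    if report.n_points != db.n_points or set(report.methods) != set(db.stats):
        raise ConfigurationError("patient report does not match database configuration")
    point_z, defined, region_z, ci_z = {}, {}, {}, {}
    for m, s in db.stats.items():
        rep = report.methods[m]
        ok = s.point_sd > 0
        z = np.full(db.n_points, np.nan)
        z[ok] = (rep.point_values[ok] - s.point_mean[ok]) / s.point_sd[ok]
        point_z[m] = z
        defined[m] = ok
        region_z[m] = {
            r: (rep.region_means[r] - s.region_mean[r]) / s.region_sd[r]
            if s.region_sd[r] > 0
            else float("nan")
            for r in s.region_mean
        }
        ci_z[m] = (
            (rep.cortical_index - s.cortical_index_mean) / s.cortical_index_sd
            if s.cortical_index_sd > 0
            else float("nan")
        )
    return PatientZScores(
        point_z=point_z, point_defined=defined, region_z=region_z, cortical_index_z=ci_z
    )
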