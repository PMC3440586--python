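"""Triangulated-surface helpers for ring-structured landmark sets.

Landmarks are laid out as ``n_rings`` closed rings of ``n_theta`` points each,
stacked along the left-right (sagittal, ``x``) axis: landmark ``r * n_theta + j``
is the ``j``-th point of ring ``r``.  This mirrors how brain-surface outlines
are drawn as one closed curve per sagittal slice.  Two pole vertices (the
centroids of the extreme rings) are appended to close the tube into a
watertight surface for triangulation; they are bookkeeping vertices, not
landmarks.
"""

from __future__ import annotations

import numpy as np


def ring_layout(n_landmarks: int, n_theta: int) -> tuple[int, int]:
    """Validate and return ``(n_rings, n_theta)`` for a landmark count."""
    if n_landmarks % n_theta != 0:
        raise ValueError(f"{n_landmarks} landmarks do not divide into rings of {n_theta}")
    n_rings = n_landmarks // n_theta
    if n_rings < 2:
        raise ValueError("need at least 2 rings")
    return n_rings, n_theta


def _mid_band(n_rings: int) -> int | None:
    """Index of the band that maps to itself under the ring mirror, if any."""
    n_bands = n_rings - 1
    return (n_bands - 1) // 2 if n_bands % 2 == 1 else None


def ring_faces(n_rings: int, n_theta: int) -> np.ndarray:
    """Faces of the closed ring tube; poles are vertices L and L+1.

    The triangulation is symmetric under the left-right ring mirror
    (ring ``r`` -> ``n_rings - 1 - r``): quad diagonals flip between the two
    halves, and the self-mirrored middle band (present when the band count is
    odd) is split 4 ways through centre vertices appended after the poles.
    """
    L = n_rings * n_theta
    pole0, pole1 = L, L + 1
    mid = _mid_band(n_rings)
    faces = []
    for i in range(n_rings - 1):
        for j in range(n_theta):
            j1 = (j + 1) % n_theta
            p00 = i * n_theta + j
            p01 = i * n_theta + j1
            p10 = (i + 1) * n_theta + j
            p11 = (i + 1) * n_theta + j1
            if mid is not None and i == mid:
                c = L + 2 + j
                faces.extend([(p00, p01, c), (p01, p11, c), (p11, p10, c), (p10, p00, c)])
            elif mid is not None and i > mid or mid is None and 2 * i >= n_rings - 1:
                faces.extend([(p00, p01, p10), (p01, p11, p10)])
            else:
                faces.extend([(p00, p01, p11), (p00, p11, p10)])
    for j in range(n_theta):
        j1 = (j + 1) % n_theta
        faces.append((pole0, j1, j))
        faces.append((pole1, (n_rings - 1) * n_theta + j, (n_rings - 1) * n_theta + j1))
    return np.asarray(faces, dtype=np.int64)


def with_poles(landmarks: np.ndarray, n_rings: int, n_theta: int) -> np.ndarray:
    """Append the bookkeeping vertices used by :func:`ring_faces`: the two
    pole vertices (extreme-ring centroids) and, when present, the middle-band
    quad centres."""
    pts = np.asarray(landmarks, dtype=np.float64).reshape(n_rings * n_theta, 3)
    # poles extrapolated beyond the extreme rings, assuming the standard ring
    # spacing (stations at cos(pi (i + 1/2) / n_rings) along the tube axis)
    phi = np.pi * (np.arange(2) + 0.5) / n_rings
    t = (1.0 - np.cos(phi[0])) / (np.cos(phi[0]) - np.cos(phi[1]))
    c0, c1 = pts[:n_theta].mean(axis=0), pts[n_theta : 2 * n_theta].mean(axis=0)
    cm1, cm0 = pts[-2 * n_theta : -n_theta].mean(axis=0), pts[-n_theta:].mean(axis=0)
    pole0 = c0 + t * (c0 - c1)
    pole1 = cm0 + t * (cm0 - cm1)
    out = [pts, pole0[None], pole1[None]]
    mid = _mid_band(n_rings)
    if mid is not None:
        j = np.arange(n_theta)
        j1 = (j + 1) % n_theta
        ring_a = pts[mid * n_theta :][:n_theta]
        ring_b = pts[(mid + 1) * n_theta :][:n_theta]
        centres = (ring_a[j] + ring_a[j1] + ring_b[j] + ring_b[j1]) / 4.0
        out.append(centres)
    return np.vstack(out)


def signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    v0, v1, v2 = (vertices[faces[:, k]] for k in range(3))
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def oriented_faces(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip the winding (if needed) so face normals point outward."""
    if signed_volume(vertices, faces) < 0:
        faces = faces[:, [0, 2, 1]]
    return faces


def vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted outward unit vertex normals of a closed mesh."""
    faces = oriented_faces(vertices, faces)
    v0, v1, v2 = (vertices[faces[:, k]] for k in range(3))
    fn = np.cross(v1 - v0, v2 - v0)  # magnitude = 2 * face area
    normals = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(normals, faces[:, k], fn)
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return normals / norm


def subdivide(
    vertices: np.ndarray, faces: np.ndarray, return_edges: bool = False
):
    """One midpoint (1-to-4) subdivision pass.

    New vertices are appended after the input vertices in the deterministic
    order in which edges are first encountered when scanning faces.  With
    ``return_edges`` the edge -> midpoint-index map is returned as well.
    """
    vertices = np.asarray(vertices, dtype=np.float64)
    edge_mid: dict[tuple[int, int], int] = {}
    new_pts: list[np.ndarray] = []

    def midpoint(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        idx = edge_mid.get(key)
        if idx is None:
            idx = len(vertices) + len(new_pts)
            edge_mid[key] = idx
            new_pts.append((vertices[a] + vertices[b]) / 2.0)
        return idx

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces.extend([(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)])
    all_vertices = np.vstack([vertices] + [np.asarray(new_pts)]) if new_pts else vertices
    new_faces = np.asarray(new_faces, dtype=np.int64)
    if return_edges:
        return all_vertices, new_faces, edge_mid
    return all_vertices, new_faces


def base_mirror_permutation(n_rings: int, n_theta: int) -> np.ndarray:
    """Topological left-right mirror of the ring layout (incl. bookkeeping
    vertices): ring ``r`` maps to ring ``n_rings - 1 - r`` at the same
    in-ring angle, poles swap, middle-band centres are fixed points."""
    L = n_rings * n_theta
    n_extra = 2 + (n_theta if _mid_band(n_rings) is not None else 0)
    M = np.empty(L + n_extra, dtype=np.int64)
    for r in range(n_rings):
        for j in range(n_theta):
            M[r * n_theta + j] = (n_rings - 1 - r) * n_theta + j
    M[L], M[L + 1] = L + 1, L
    if n_extra > 2:
        M[L + 2 :] = np.arange(L + 2, L + n_extra)
    return M


def extend_mirror_permutation(
    M: np.ndarray, edge_mid: dict[tuple[int, int], int], n_new: int
) -> np.ndarray:
    """Propagate a vertex mirror permutation through one subdivision pass:
    the midpoint of edge (a, b) mirrors to the midpoint of (M[a], M[b])."""
    M_new = np.concatenate([M, np.full(n_new, -1, dtype=np.int64)])
    for (a, b), idx in edge_mid.items():
        ma, mb = M[a], M[b]
        key = (ma, mb) if ma < mb else (mb, ma)
        M_new[idx] = edge_mid[key]
    if np.any(M_new < 0):  # pragma: no cover - topology is always mirror-closed
        raise ValueError("mirror permutation could not be propagated")
    return M_new
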