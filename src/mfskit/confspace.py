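"""Conformational state space of MFS-fold transporters.

A PCA basis is built from core Calpha coordinate sets of reference
structures (outward/inward-facing families, including occluded variants),
after iterative superposition onto a converged mean.  Trajectory frames are
then projected onto this space and classified by proximity to the pooled
OF- and IF-family centroids — the rocker-switch picture in which PC1
separates "V"-shaped (OF) from "Lambda"-shaped (IF) bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import TMHCoreMap, extract_core_coordinates
from .structures import Structure, Trajectory

OF_FAMILY = {"OF", "OFocc"}
IF_FAMILY = {"IF", "IFocc"}


class GeometryError(ValueError):
    pass


class DimensionError(ValueError):
    pass


def superpose_kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal least-squares rigid superposition (Kabsch, SVD form).

    Returns ``(rotation, translation, rmsd)`` with the convention
    ``mobile @ rotation.T + translation ~= reference``; the rotation is
    proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("point sets must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("need at least 3 points")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    a = mobile - mc
    b = reference - rc
    h = a.T @ b
    try:
        u, s, vt = np.linalg.svd(h)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise GeometryError(f"degenerate point sets: {exc}") from exc
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise GeometryError("rank-deficient point sets (collinear/coincident)")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = rc - rot @ mc
    moved = a @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return rot, t, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, float) @ rotation.T + translation


@dataclass
class ConformationalSpace:
    """PCA basis over core coordinates plus labelled reference projections."""

    mean_coords: np.ndarray            # (K, 3), centroid at origin
    components: np.ndarray             # (k, 3K), orthonormal rows
    explained_variance: np.ndarray     # (k,), Angstrom^2, non-increasing
    total_variance: float
    reference_projections: list[tuple[str, str, np.ndarray]]  # (id, label, pc)
    points_per_tmh: int | None = None

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def project_vector(self, core_coords: np.ndarray) -> np.ndarray:
        """Superpose a (K, 3) core coordinate set onto the mean and project."""
        rot, t, _ = superpose_kabsch(core_coords, self.mean_coords)
        aligned = apply_transform(core_coords, rot, t)
        return self.components @ (aligned - self.mean_coords).ravel()

    def family_centroids(self, n_dims: int = 2):
        dims = min(n_dims, self.n_components)
        of = [pc[:dims] for _, lab, pc in self.reference_projections
              if lab in OF_FAMILY]
        if_ = [pc[:dims] for _, lab, pc in self.reference_projections
               if lab in IF_FAMILY]
        if not of or not if_:
            raise ValueError("need at least one OF-family and one IF-family "
                             "reference projection")
        return np.mean(of, axis=0), np.mean(if_, axis=0)


def iterative_mean_alignment(vectors: np.ndarray, tol: float = 1e-9,
                             max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Superpose all coordinate sets onto an iteratively refined mean.

    Returns ``(aligned, mean)``; iteration stops when the RMS mean shift
    drops below ``tol`` (Angstrom)."""
    vectors = np.asarray(vectors, dtype=float)  # (m, K, 3)
    mean = vectors[0] - vectors[0].mean(axis=0)
    aligned = vectors.copy()
    for _ in range(max_iter):
        for i in range(len(vectors)):
            rot, t, _ = superpose_kabsch(vectors[i], mean)
            aligned[i] = apply_transform(vectors[i], rot, t)
        new_mean = aligned.mean(axis=0)
        new_mean = new_mean - new_mean.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    # final pass so the returned sets are aligned to the returned mean
    for i in range(len(vectors)):
        rot, t, _ = superpose_kabsch(vectors[i], mean)
        aligned[i] = apply_transform(vectors[i], rot, t)
    return aligned, mean


def fit_conformational_space(core_vectors, labels, n_components: int = 2,
                             ids=None) -> ConformationalSpace:
    """PCA over labelled core coordinate sets.

    ``core_vectors`` is (m, K, 3); labels are per-structure state labels
    (OF / OFocc / IF / IFocc).  PC1's sign is fixed so OF-family references
    project to positive mean PC1."""
    vectors = np.asarray(core_vectors, dtype=float)
    m = vectors.shape[0]
    if m < 3:
        raise DimensionError("need at least 3 reference structures")
    if n_components > m - 1:
        raise DimensionError(
            f"requested {n_components} components from {m} structures "
            f"(rank limit {m - 1})")
    if ids is None:
        ids = [f"ref{i:03d}" for i in range(m)]
    aligned, mean = iterative_mean_alignment(vectors)
    x = aligned.reshape(m, -1) - mean.ravel()
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s ** 2 / (m - 1)
    components = vt[:n_components]
    explained = var[:n_components]
    proj = x @ components.T
    # sign convention: OF-family references have positive mean PC1
    of_mask = np.array([lab in OF_FAMILY for lab in labels])
    if of_mask.any() and proj[of_mask, 0].mean() < 0:
        components = components.copy()
        components[0] = -components[0]
        proj[:, 0] = -proj[:, 0]
    refs = [(str(i), str(lab), proj[k].copy())
            for k, (i, lab) in enumerate(zip(ids, labels))]
    return ConformationalSpace(
        mean_coords=mean,
        components=components,
        explained_variance=explained,
        total_variance=float(var.sum()),
        reference_projections=refs,
    )


def fit_space_from_structures(structures, labels, cmaps, n_components: int = 2,
                              points_per_tmh: int = 20, ids=None) -> ConformationalSpace:
    """Convenience wrapper: extract cores, then fit the PCA space."""
    if isinstance(cmaps, TMHCoreMap):
        cmaps = [cmaps] * len(structures)
    vectors = np.stack([
        extract_core_coordinates(s, m, points_per_tmh)
        for s, m in zip(structures, cmaps)
    ])
    space = fit_conformational_space(vectors, labels, n_components, ids=ids)
    space.points_per_tmh = points_per_tmh
    return space


@dataclass
class ProjectionResult:
    coordinates: np.ndarray  # (n_frames, k)

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


def project_frames(traj: Trajectory, cmap: TMHCoreMap,
                   space: ConformationalSpace,
                   points_per_tmh: int | None = None) -> ProjectionResult:
    """Project every trajectory frame onto the conformational space."""
    ppt = points_per_tmh or space.points_per_tmh
    if ppt is None:
        ppt = space.mean_coords.shape[0] // 12
    out = np.empty((traj.n_frames, space.n_components))
    for i in range(traj.n_frames):
        core = extract_core_coordinates(traj.frame_structure(i), cmap, ppt)
        out[i] = space.project_vector(core)
    return ProjectionResult(coordinates=out)


def classify_state(projection: np.ndarray, space: ConformationalSpace,
                   margin: float = 0.1) -> str:
    """Nearest pooled-family centroid in the first two PCs.

    Returns ``"OF"``, ``"IF"`` or ``"intermediate"`` (when the two centroid
    distances differ by less than ``margin`` times their mean)."""
    of_c, if_c = space.family_centroids()
    p = np.asarray(projection, float)[: len(of_c)]
    d_of = float(np.linalg.norm(p - of_c))
    d_if = float(np.linalg.norm(p - if_c))
    mean_d = 0.5 * (d_of + d_if)
    if mean_d > 0 and abs(d_of - d_if) < margin * mean_d:
        return "intermediate"
    if d_of == d_if:
        return "intermediate"
    return "OF" if d_of < d_if else "IF"


def rmsd_timeseries(traj: Trajectory, selection, reference_frame: int = 0) -> np.ndarray:
    """Per-frame Kabsch-minimized RMSD (Angstrom) to a reference frame."""
    selection = np.asarray(list(selection), dtype=int)
    if selection.size < 3:
        raise GeometryError("selection must contain at least 3 atoms")
    if not 0 <= reference_frame < traj.n_frames:
        raise IndexError(f"reference frame {reference_frame} out of range")
    ref = traj.frames[reference_frame][selection]
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        _, _, rmsd = superpose_kabsch(traj.frames[i][selection], ref)
        out[i] = rmsd
    return out


def save_space(space: ConformationalSpace, path: str) -> None:
    """Serialize to a portable compressed matrix archive (.npz)."""
    ref_ids = np.array([r[0] for r in space.reference_projections])
    ref_labels = np.array([r[1] for r in space.reference_projections])
    ref_pcs = np.array([r[2] for r in space.reference_projections])
    np.savez_compressed(
        path,
        mean_coords=space.mean_coords,
        components=space.components,
        explained_variance=space.explained_variance,
        total_variance=np.array([space.total_variance]),
        ref_ids=ref_ids, ref_labels=ref_labels, ref_pcs=ref_pcs,
        points_per_tmh=np.array([space.points_per_tmh or 0]),
    )


def load_space(path: str) -> ConformationalSpace:
    with np.load(path, allow_pickle=False) as z:
        ppt = int(z["points_per_tmh"][0])
        return ConformationalSpace(
            mean_coords=z["mean_coords"],
            components=z["components"],
            explained_variance=z["explained_variance"],
            total_variance=float(z["total_variance"][0]),
            reference_projections=[
                (str(i), str(l), p) for i, l, p in
                zip(z["ref_ids"], z["ref_labels"], z["ref_pcs"])
            ],
            points_per_tmh=ppt or None,
        )
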