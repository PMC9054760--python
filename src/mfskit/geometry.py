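"""TMH geometry: tilt profiles, kink detection, gating distances,
HOLE-style pore-radius profiles and dynamic cross-correlation matrices.

The membrane normal is +z by default (z-embedded bilayers); every function
takes an explicit normal or axis where that matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .confspace import superpose_kabsch, apply_transform, GeometryError
from .core import TMHCoreMap, _calpha_trace
from .structures import Structure, Trajectory

Z_NORMAL = np.array([0.0, 0.0, 1.0])


# 5-tap symmetric kernel whose discrete Fourier response vanishes at the
# canonical alpha-helix twist (100 deg/residue): convolving a Calpha trace
# with it cancels the helical winding exactly, leaving near-axis points.
_DEWIND_MID = -2.0 * np.cos(np.radians(200.0)) - 2.0 * np.cos(np.radians(100.0))
_DEWIND_KERNEL = np.array([1.0, 1.0, _DEWIND_MID, 1.0, 1.0])
_DEWIND_KERNEL /= _DEWIND_KERNEL.sum()


def dewind(calpha_coords: np.ndarray) -> np.ndarray:
    """Smooth a Calpha trace onto its local helix axis (loses 4 points)."""
    xyz = np.asarray(calpha_coords, dtype=float)
    return np.column_stack([
        np.convolve(xyz[:, d], _DEWIND_KERNEL, mode="valid")
        for d in range(3)])


def helix_axis(calpha_coords: np.ndarray) -> np.ndarray:
    """Dominant direction of a Calpha trace, oriented N- to C-terminal.

    Traces of >= 9 points are first dewound (winding-cancelling smoothing),
    which removes the axis bias the helical winding causes when the trace
    covers a non-integer number of turns."""
    xyz = np.asarray(calpha_coords, dtype=float)
    if len(xyz) < 4:
        raise GeometryError("need at least 4 Calpha points")
    if len(xyz) >= 9:
        xyz = dewind(xyz)
    centered = xyz - xyz.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise GeometryError("degenerate (coincident) points")
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    if np.dot(axis, xyz[-1] - xyz[0]) < 0:
        axis = -axis
    return axis


def helix_axis_and_tilt(calpha_coords: np.ndarray,
                        normal: np.ndarray = Z_NORMAL) -> float:
    """Tilt angle (degrees, in [0, 90]) between a helix and the bilayer
    normal; insensitive to helix direction reversal."""
    axis = helix_axis(calpha_coords)
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    cosang = min(1.0, abs(float(np.dot(axis, normal))))
    return float(np.degrees(np.arccos(cosang)))


@dataclass
class TiltProfile:
    mean_tilt: np.ndarray  # (12,) degrees
    sd_tilt: np.ndarray    # (12,)
    frames_used: int


def tilt_profile(trajs, cmap: TMHCoreMap,
                 normal: np.ndarray = Z_NORMAL) -> TiltProfile:
    """Per-TMH tilt mean +/- sd over frames, pooling replicas when a list of
    trajectories is given."""
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    per_tmh = [[] for _ in cmap.tmh_ranges]
    frames_used = 0
    for traj in trajs:
        idx_per_tmh = []
        for (s, e) in cmap.tmh_ranges:
            by_res = {a.residue_id: i for i, a in enumerate(traj.topology.atoms)
                      if a.name == "CA" and s <= a.residue_id <= e}
            idx_per_tmh.append([by_res[r] for r in sorted(by_res)])
        for f in range(traj.n_frames):
            for k, idx in enumerate(idx_per_tmh):
                per_tmh[k].append(
                    helix_axis_and_tilt(traj.frames[f][idx], normal))
        frames_used += traj.n_frames
    mean = np.array([np.mean(v) for v in per_tmh])
    sd = np.array([np.std(v) for v in per_tmh])
    return TiltProfile(mean_tilt=mean, sd_tilt=sd, frames_used=frames_used)


@dataclass
class KinkReport:
    evaluable: bool
    kink_present: bool = False
    kink_residue: int | None = None
    kink_angle: float = 0.0


def _fit_line(points: np.ndarray):
    """Least-squares line through 3-D points: (direction, squared residual)."""
    c = points.mean(axis=0)
    d = points - c
    _, s, vt = np.linalg.svd(d)
    return vt[0], float((d ** 2).sum() - s[0] ** 2)


def _point_line_distances(pts: np.ndarray, center: np.ndarray,
                          axis: np.ndarray) -> np.ndarray:
    w = pts - center
    par = (w @ axis)[:, None] * axis
    return np.linalg.norm(w - par, axis=1)


def kink_analysis(calpha_coords: np.ndarray, min_segment: int = 6,
                  angle_threshold: float = 15.0,
                  resids=None) -> KinkReport:
    """Two-segment kink model on the dewound Calpha trace.

    The trace is first smoothed onto its local axis (:func:`dewind`).  The
    split point minimizing the total residual of a two-line fit locates the
    bend; the kink angle is then measured between lines fit to the two
    segments after excluding a 4-point margin around the split (the
    smoothing kernel blurs the junction over its own width, so near-split
    points belong to neither segment cleanly).  The kink residue is the
    point where the trace switches from preferring one fitted axis line to
    the other.  Helices shorter than ``2*min_segment`` (or 12 residues)
    are flagged not evaluable rather than raising."""
    xyz = np.asarray(calpha_coords, dtype=float)
    n = len(xyz)
    if n < 2 * min_segment or n < 12:
        return KinkReport(evaluable=False)
    if resids is None:
        resids = list(range(1, n + 1))
    sm = dewind(xyz)
    m = len(sm)
    min_pts = max(3, min_segment - 3)
    best = None
    for s in range(min_pts, m - min_pts + 1):
        _, r1 = _fit_line(sm[:s])
        _, r2 = _fit_line(sm[s:])
        if best is None or r1 + r2 < best[1]:
            best = (s, r1 + r2)
    s = best[0]
    margin = 4
    lo = max(2, s - margin)
    hi = min(m - 2, s + margin)
    a1, _ = _fit_line(sm[:lo])
    a2, _ = _fit_line(sm[hi:])
    c1 = sm[:lo].mean(axis=0)
    c2 = sm[hi:].mean(axis=0)
    chain = xyz[-1] - xyz[0]
    if np.dot(a1, chain) < 0:
        a1 = -a1
    if np.dot(a2, chain) < 0:
        a2 = -a2
    angle = float(np.degrees(np.arccos(np.clip(np.dot(a1, a2), -1.0, 1.0))))
    # locate the kink: where the trace switches from the first axis line to
    # the second (sign crossing of the distance preference, interpolated)
    pref = (_point_line_distances(sm, c1, a1)
            - _point_line_distances(sm, c2, a2))
    on_first = np.where(pref <= 0)[0]
    r = int(on_first[-1]) if len(on_first) else 0
    frac = 0.0
    if r + 1 < m and pref[r + 1] > pref[r]:
        frac = float(-pref[r] / (pref[r + 1] - pref[r]))
    kink_idx = int(np.clip(round(r + frac + 2), 0, n - 1))
    return KinkReport(
        evaluable=True,
        kink_present=angle >= angle_threshold,
        kink_residue=int(resids[kink_idx]),
        kink_angle=angle,
    )


def pairwise_com_distance(traj: Trajectory, selection_a,
                          selection_b) -> np.ndarray:
    """Per-frame distance between unweighted geometric centers of two atom
    selections (Angstrom)."""
    a = np.asarray(list(selection_a), dtype=int)
    b = np.asarray(list(selection_b), dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("selections must be non-empty")
    ca = traj.frames[:, a].mean(axis=1)
    cb = traj.frames[:, b].mean(axis=1)
    return np.linalg.norm(ca - cb, axis=1)


def gate_selection(structure: Structure, cmap: TMHCoreMap, tmh: int,
                   n_res: int = 8, side: str = "extracellular") -> np.ndarray:
    """Calpha indices of the terminal segment of a TMH on the requested
    membrane side (extracellular = larger z)."""
    s, e = cmap.tmh_ranges[tmh - 1]
    idx = [i for i, a in enumerate(structure.atoms)
           if a.name == "CA" and s <= a.residue_id <= e]
    idx.sort(key=lambda i: structure.atoms[i].residue_id)
    head, tail = idx[:n_res], idx[-n_res:]
    z_head = structure.coords[head, 2].mean()
    z_tail = structure.coords[tail, 2].mean()
    if side == "extracellular":
        return np.array(tail if z_tail >= z_head else head)
    if side == "intracellular":
        return np.array(head if z_tail >= z_head else tail)
    raise ValueError(f"unknown side {side!r}")


# ---------------------------------------------------------------------------
# Pore profiling (HOLE-style sphere probe, reimplemented)
# ---------------------------------------------------------------------------

@dataclass
class PoreProfile:
    z: np.ndarray            # (nz,) strictly increasing
    mean_radius: np.ndarray  # (nz,)
    sd_radius: np.ndarray    # (nz,)
    capped: np.ndarray       # (nz,) bool; any snapshot hit the radius cap


def _probe_f(p_xy: np.ndarray, z: float, atom_xyz: np.ndarray,
             radii: np.ndarray) -> np.ndarray:
    """f(p) = min over atoms of (|probe - atom| - vdw), clamped at 0."""
    p = np.atleast_2d(p_xy)
    d2 = ((p[:, None, 0] - atom_xyz[None, :, 0]) ** 2
          + (p[:, None, 1] - atom_xyz[None, :, 1]) ** 2
          + (z - atom_xyz[None, :, 2]) ** 2)
    f = np.sqrt(d2) - radii[None, :]
    return np.maximum(f.min(axis=1), 0.0)


def _slice_radius(z: float, atom_xyz: np.ndarray, radii: np.ndarray,
                  center_xy: np.ndarray, search_radius: float,
                  grid_step: float, cap: float,
                  refine: bool = True) -> tuple[float, bool]:
    """Max-over-probe-positions min-clearance radius at one z slice."""
    rmax = radii.max() if len(radii) else 0.0
    near = np.abs(atom_xyz[:, 2] - z) <= cap + rmax
    sub = atom_xyz[near]
    subr = radii[near]
    if len(sub) == 0:
        return cap, True
    # candidate probe centers: square grid, kept inside the convex hull of
    # nearby atoms (prevents the probe escaping the protein)
    g = np.arange(-search_radius, search_radius + grid_step / 2, grid_step)
    gx, gy = np.meshgrid(g, g)
    cand = np.column_stack([gx.ravel(), gy.ravel()]) + center_xy
    slab = np.abs(sub[:, 2] - z) <= max(6.0, 3 * grid_step)
    hull = None
    if slab.sum() >= 4:
        try:
            hull = Delaunay(sub[slab][:, :2])
        except QhullError:
            hull = None
    if hull is not None:
        inside = hull.find_simplex(cand) >= 0
        if inside.any():
            cand = cand[inside]
    fvals = _probe_f(cand, z, sub, subr)
    best = int(np.argmax(fvals))
    best_xy = cand[best]
    best_f = float(fvals[best])
    if refine:
        step = grid_step / 2.0
        while step > 0.005:
            moves = best_xy + step * np.array(
                [[1, 0], [-1, 0], [0, 1], [0, -1],
                 [1, 1], [1, -1], [-1, 1], [-1, -1]])
            if hull is not None:
                ok = hull.find_simplex(moves) >= 0
                moves = moves[ok]
            if len(moves):
                fm = _probe_f(moves, z, sub, subr)
                j = int(np.argmax(fm))
                if fm[j] > best_f:
                    best_f = float(fm[j])
                    best_xy = moves[j]
                    continue
            step /= 2.0
    if best_f >= cap:
        return cap, True
    return best_f, False


def pore_radius_profile(traj: Trajectory, z_step: float = 1.0,
                        axis_xy=(0.0, 0.0), n_snapshots: int = 500,
                        search_radius: float = 8.0, grid_step: float = 0.2,
                        cap: float = 15.0, z_range=None,
                        selection=None, refine: bool = True) -> PoreProfile:
    """z-dependent pore radius by sphere-probe search.

    At each z slice the radius is the maximum over probe center positions
    (2-D grid search at ``grid_step``, then coordinate-descent refinement)
    of the minimum atom clearance ``|probe - atom| - vdw``, clamped at 0 and
    capped at ``cap`` (capped slices are flagged).  ``n_snapshots`` frames
    are evenly subsampled; mean +/- sd over snapshots is reported.
    """
    if selection is None:
        selection = [i for i, a in enumerate(traj.topology.atoms) if a.is_protein]
    selection = np.asarray(list(selection), dtype=int)
    radii = np.array([traj.topology.atoms[i].vdw_radius for i in selection])
    n_snap = min(n_snapshots, traj.n_frames)
    frame_idx = np.unique(np.linspace(0, traj.n_frames - 1, n_snap).round().astype(int))
    if z_range is None:
        zs = traj.frames[frame_idx[0]][selection, 2]
        z_range = (zs.min() + z_step, zs.max() - z_step)
    z_grid = np.arange(z_range[0], z_range[1] + z_step / 2, z_step)
    center_xy = np.asarray(axis_xy, dtype=float)
    vals = np.empty((len(frame_idx), len(z_grid)))
    capped = np.zeros(len(z_grid), dtype=bool)
    for fi, f in enumerate(frame_idx):
        xyz = traj.frames[f][selection]
        for zi, z in enumerate(z_grid):
            r, was_capped = _slice_radius(z, xyz, radii, center_xy,
                                          search_radius, grid_step, cap,
                                          refine=refine)
            vals[fi, zi] = r
            capped[zi] |= was_capped
    return PoreProfile(z=z_grid, mean_radius=vals.mean(axis=0),
                       sd_radius=vals.std(axis=0), capped=capped)


# ---------------------------------------------------------------------------
# Dynamic cross-correlation
# ---------------------------------------------------------------------------

@dataclass
class DCCMatrix:
    values: np.ndarray   # (n, n), symmetric, diag 1
    defined: np.ndarray  # (n, n) bool; False where an atom had zero variance
    resids: np.ndarray   # (n,) residue ids of the selected atoms


def dccm(traj: Trajectory, selection, superpose: bool = True) -> DCCMatrix:
    """Normalized dynamic cross-correlation of atomic displacements.

    Frames are first superposed onto frame 0 over the selection (disable
    with ``superpose=False`` for pre-aligned data); then
    ``C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>)`` with dr the
    displacement from the time-mean position.  Zero-variance atoms yield
    undefined (masked) rows/columns instead of NaN propagation."""
    selection = np.asarray(list(selection), dtype=int)
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    ref = traj.frames[0][selection]
    pos = np.empty((traj.n_frames, len(selection), 3))
    for f in range(traj.n_frames):
        if superpose:
            rot, t, _ = superpose_kabsch(traj.frames[f][selection], ref)
            pos[f] = apply_transform(traj.frames[f][selection], rot, t)
        else:
            pos[f] = traj.frames[f][selection]
    delta = pos - pos.mean(axis=0)
    cov = np.einsum("fid,fjd->ij", delta, delta) / traj.n_frames
    var = np.diag(cov).copy()
    ok = var > 1e-12
    denom = np.sqrt(np.outer(np.where(ok, var, 1.0), np.where(ok, var, 1.0)))
    values = cov / denom
    defined = np.outer(ok, ok)
    values[~defined] = np.nan
    np.fill_diagonal(values, np.where(ok, 1.0, np.nan))
    resids = np.array([traj.topology.atoms[i].residue_id for i in selection])
    return DCCMatrix(values=values, defined=defined, resids=resids)


def write_dccm(matrix: DCCMatrix, path: str) -> None:
    """Square matrix text with residue-id header row/column."""
    with open(path, "w") as fh:
        fh.write("resid\t" + "\t".join(str(r) for r in matrix.resids) + "\n")
        for r, row in zip(matrix.resids, matrix.values):
            fh.write(str(r) + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
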