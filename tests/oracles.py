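"""Independent oracles used by the tests: quaternion superposition,
brute-force eigen/contact/H-bond/pore computations and fixture builders.
These deliberately avoid the code paths they check."""

import numpy as np

from mfskit.structures import AtomRecord, Structure, Trajectory
from mfskit.synthetic import helix_trace


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Horn's quaternion method for the minimal RMSD of paired point sets."""
    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    ga = (a ** 2).sum()
    gb = (b ** 2).sum()
    msd = max(0.0, (ga + gb - 2.0 * lam) / len(a))
    return float(np.sqrt(msd))


def gram_eigenvalues(x_centered: np.ndarray) -> np.ndarray:
    """PCA eigenvalues via the (m x m) Gram matrix, descending."""
    m = x_centered.shape[0]
    g = x_centered @ x_centered.T / (m - 1)
    vals = np.linalg.eigvalsh(g)[::-1]
    return vals


def brute_force_contacts(xyz: np.ndarray, idx_a, idx_b, cutoff: float) -> bool:
    for i in idx_a:
        for j in idx_b:
            if np.linalg.norm(xyz[i] - xyz[j]) < cutoff:
                return True
    return False


def brute_force_hbonds(xyz, donors, acceptors, max_dist, min_angle,
                       same_residue) -> set:
    """All (donor_heavy, hydrogen, acceptor) index triples satisfying the
    cutoffs, by exhaustive double loop."""
    out = set()
    for d, h in donors:
        for a in acceptors:
            if a in (d, h) or same_residue(d, a):
                continue
            if np.linalg.norm(xyz[d] - xyz[a]) > max_dist:
                continue
            v1 = xyz[d] - xyz[h]
            v2 = xyz[a] - xyz[h]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if ang >= min_angle:
                out.add((d, h, a))
    return out


def brute_force_pore_radius(z, atom_xyz, radii, center_xy, search_radius,
                            step=0.02) -> float:
    """Exhaustive fine-grid probe search on one slice."""
    g = np.arange(-search_radius, search_radius + step / 2, step)
    best = 0.0
    for gx in g:
        x = center_xy[0] + gx
        d2x = (x - atom_xyz[:, 0]) ** 2 + (z - atom_xyz[:, 2]) ** 2
        for gy in g:
            y = center_xy[1] + gy
            f = np.sqrt(d2x + (y - atom_xyz[:, 1]) ** 2) - radii
            best = max(best, f.min())
    return max(best, 0.0)


def ca_structure(coords, resids=None, chain="A", resname="ALA") -> Structure:
    coords = np.asarray(coords, dtype=float)
    if resids is None:
        resids = range(1, len(coords) + 1)
    atoms = [AtomRecord(serial=i + 1, name="CA", element="C",
                        residue_name=resname, residue_id=int(r), chain=chain,
                        is_protein=True, vdw_radius=1.7)
             for i, r in enumerate(resids)]
    return Structure(atoms=atoms, coords=coords)


def single_frame_traj(structure: Structure) -> Trajectory:
    return Trajectory(topology=structure, frames=structure.coords[None])


def kinked_helix(kink_deg: float, n1: int = 12, n2: int = 12) -> np.ndarray:
    """Two ideal helices joined at a known angle; junction is residue n1
    (1-based)."""
    h1 = helix_trace(n1, (0, 0, 1), (0, 0, 0))
    ang = np.radians(kink_deg)
    axis2 = np.array([np.sin(ang), 0.0, np.cos(ang)])
    h2 = helix_trace(n2, axis2, h1[-1] + axis2 * 1.5)
    return np.vstack([h1, h2])


def cylinder_structure(inner_radius=5.0, vdw=1.7, z_max=20.0, z_step=1.0,
                       n_per_ring=24) -> Structure:
    """Atoms on rings so the clearance at the axis is exactly inner_radius."""
    zs = np.arange(0.0, z_max + z_step / 2, z_step)
    ang = np.linspace(0, 2 * np.pi, n_per_ring, endpoint=False)
    coords = []
    for z in zs:
        for a in ang:
            coords.append(((inner_radius + vdw) * np.cos(a),
                           (inner_radius + vdw) * np.sin(a), z))
    return ca_structure(np.array(coords))


def cone_structure(r0=3.0, r1=6.0, vdw=1.7, z_max=10.0, z_step=0.5,
                   n_per_ring=48) -> Structure:
    zs = np.arange(0.0, z_max + z_step / 2, z_step)
    ang = np.linspace(0, 2 * np.pi, n_per_ring, endpoint=False)
    coords = []
    for z in zs:
        r = r0 + (r1 - r0) * z / z_max + vdw
        for a in ang:
            coords.append((r * np.cos(a), r * np.sin(a), z))
    return ca_structure(np.array(coords))
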