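"""Lipid-protein interaction analysis: type-resolved H-bond counts,
per-residue headgroup occupancy, hotspot residues and leaflet density maps.

Lipid chemistry is reduced to headgroup donor/acceptor definitions
(:class:`LipidTypeDef`): PE carries an ammonium donor, cholesterol a single
hydroxyl donor/acceptor, PC only acceptors — the feature hierarchy that
drives PE > PC > cholesterol H-bonding with membrane proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .interactions import HBondCriteria, detect_hbonds_frame, find_donors_acceptors
from .structures import Trajectory, _WATER_NAMES


class LipidTypingError(ValueError):
    pass


@dataclass(frozen=True)
class LipidTypeDef:
    name: str
    donors: tuple = ()          # ((heavy, (h, ...)), ...)
    acceptors: tuple = ()       # atom names
    headgroup: tuple = ()       # atom names

    def __post_init__(self):
        if self.name == "PE" and not self.donors:
            raise ValueError("PE must define at least one donor (ammonium)")
        if self.name == "PC" and any(h.startswith("N") for h, _ in self.donors):
            raise ValueError("PC has no N-donor")
        if self.name in ("CHL", "CHOL") and (
                len(self.donors) != 1 or len(self.acceptors) != 1):
            raise ValueError("cholesterol has exactly one donor and one "
                             "acceptor (the hydroxyl)")


def standard_lipid_types() -> dict[str, LipidTypeDef]:
    """Definitions matching the synthetic coarse headgroup layout."""
    return {
        "PC": LipidTypeDef("PC", donors=(), acceptors=("P",),
                           headgroup=("N", "P")),
        "PE": LipidTypeDef("PE", donors=(("N", ("HN",)),), acceptors=("P",),
                           headgroup=("N", "HN", "P")),
        "CHL": LipidTypeDef("CHL", donors=(("O3", ("H3",)),),
                            acceptors=("O3",), headgroup=("O3", "H3")),
    }


def _index_lipids(traj: Trajectory, lipid_defs: dict[str, LipidTypeDef]):
    """Per-type donor pairs, acceptor indices, headgroup indices and
    per-atom lipid residue ids; unknown non-protein residues raise."""
    topo = traj.topology
    donors = {t: [] for t in lipid_defs}
    acceptors = {t: [] for t in lipid_defs}
    headgroup = {t: [] for t in lipid_defs}
    by_res: dict[int, dict[str, int]] = {}
    res_type: dict[int, str] = {}
    for i, a in enumerate(topo.atoms):
        if a.is_protein or a.residue_name in _WATER_NAMES:
            continue
        if a.residue_name not in lipid_defs:
            raise LipidTypingError(
                f"unknown lipid residue name {a.residue_name!r} "
                f"(residue {a.residue_id})")
        by_res.setdefault(a.residue_id, {})[a.name] = i
        res_type[a.residue_id] = a.residue_name
    for resid, atoms in by_res.items():
        t = res_type[resid]
        d = lipid_defs[t]
        for heavy, hnames in d.donors:
            if heavy in atoms:
                donors[t].extend(
                    (atoms[heavy], atoms[h]) for h in hnames if h in atoms)
        acceptors[t].extend(atoms[x] for x in d.acceptors if x in atoms)
        headgroup[t].extend(atoms[x] for x in d.headgroup if x in atoms)
    return donors, acceptors, headgroup


def lipid_protein_hbond_counts(traj: Trajectory,
                               lipid_defs: dict[str, LipidTypeDef] | None = None,
                               criteria: HBondCriteria = HBondCriteria(),
                               protein_donors=None,
                               protein_acceptors=None) -> dict[str, np.ndarray]:
    """Per-frame lipid-protein H-bond count for each lipid type.

    Counts bonds in both directions (lipid donors to protein acceptors and
    protein donors to lipid acceptors).  Protein donors/acceptors default
    to the standard-residue tables; pass them explicitly for coarse or
    nonstandard protein models."""
    if lipid_defs is None:
        lipid_defs = standard_lipid_types()
    topo = traj.topology
    if protein_donors is None or protein_acceptors is None:
        auto_d, auto_a = find_donors_acceptors(topo)
        prot = {i for i, a in enumerate(topo.atoms) if a.is_protein}
        if protein_donors is None:
            protein_donors = [(d, h) for d, h in auto_d if d in prot]
        if protein_acceptors is None:
            protein_acceptors = [a for a in auto_a if a in prot]
    lip_d, lip_a, _ = _index_lipids(traj, lipid_defs)
    out = {t: np.zeros(traj.n_frames) for t in lipid_defs}
    for f in range(traj.n_frames):
        xyz = traj.frames[f]
        for t in lipid_defs:
            n = len(detect_hbonds_frame(topo, lip_d[t], protein_acceptors,
                                        criteria, coords=xyz, frame=f))
            n += len(detect_hbonds_frame(topo, protein_donors, lip_a[t],
                                         criteria, coords=xyz, frame=f))
            out[t][f] = n
    return out


@dataclass
class OccupancyProfile:
    fractions: dict[int, dict[str, float]]  # residue id -> type -> fraction
    n_frames: int


def residue_lipid_occupancy(traj: Trajectory,
                            lipid_defs: dict[str, LipidTypeDef] | None = None,
                            cutoff: float = 4.0,
                            headgroup_only: bool = True) -> OccupancyProfile:
    """Per-residue contact fraction with each lipid type.

    A residue is in contact in a frame iff any of its heavy atoms lies
    within ``cutoff`` of any headgroup atom of any lipid of that type —
    individual lipids may exchange while the site stays occupied."""
    if lipid_defs is None:
        lipid_defs = standard_lipid_types()
    topo = traj.topology
    _, _, headgroup = _index_lipids(traj, lipid_defs)
    if not headgroup_only:
        headgroup = {t: [] for t in lipid_defs}
        for i, a in enumerate(topo.atoms):
            if not a.is_protein and a.residue_name in lipid_defs:
                headgroup[a.residue_name].append(i)
    prot_idx = np.array([i for i, a in enumerate(topo.atoms)
                         if a.is_protein and a.element != "H"], dtype=int)
    prot_resid = np.array([topo.atoms[i].residue_id for i in prot_idx])
    resids = sorted(set(prot_resid.tolist()))
    counts = {r: {t: 0 for t in lipid_defs} for r in resids}
    for f in range(traj.n_frames):
        xyz = traj.frames[f]
        tree = cKDTree(xyz[prot_idx])
        for t, lip_idx in headgroup.items():
            if not lip_idx:
                continue
            hit: set[int] = set()
            for neigh in tree.query_ball_point(xyz[np.array(lip_idx)], cutoff):
                hit.update(int(prot_resid[j]) for j in neigh)
            for r in hit:
                counts[r][t] += 1
    fractions = {r: {t: counts[r][t] / traj.n_frames for t in lipid_defs}
                 for r in resids}
    return OccupancyProfile(fractions=fractions, n_frames=traj.n_frames)


@dataclass
class HotspotSet:
    threshold: float
    residues: list[tuple[int, str, float]]  # (residue id, lipid type, fraction)


def hotspot_residues(profile: OccupancyProfile,
                     threshold: float = 0.8) -> HotspotSet:
    """Residues in contact with a lipid type for at least ``threshold`` of
    the frames (threshold 0 keeps every residue with nonzero contact)."""
    members = []
    for r, per_type in sorted(profile.fractions.items()):
        for t, f in per_type.items():
            if (f >= threshold and f > 0) if threshold > 0 else f > 0:
                members.append((r, t, f))
    return HotspotSet(threshold=threshold, residues=members)


def leaflet_density_map(traj: Trajectory,
                        lipid_defs: dict[str, LipidTypeDef] | None = None,
                        leaflet: str = "upper", grid: float = 2.0,
                        xy_range=None) -> dict[str, dict]:
    """Normalized 2-D xy occupancy histogram of headgroup atoms per lipid
    type in one leaflet.  Leaflet assignment is by headgroup z sign
    relative to the bilayer midplane (mean headgroup z), recomputed per
    frame.  Each non-empty map integrates (sums) to 1."""
    if leaflet not in ("upper", "lower"):
        raise ValueError("leaflet must be 'upper' or 'lower'")
    if lipid_defs is None:
        lipid_defs = standard_lipid_types()
    _, _, headgroup = _index_lipids(traj, lipid_defs)
    all_idx = np.array(sorted({i for v in headgroup.values() for i in v}), dtype=int)
    if xy_range is None:
        xs = traj.frames[:, all_idx, 0]
        ys = traj.frames[:, all_idx, 1]
        xy_range = ((xs.min(), xs.max()), (ys.min(), ys.max()))
    (x0, x1), (y0, y1) = xy_range
    nx = max(1, int(np.ceil((x1 - x0) / grid)))
    ny = max(1, int(np.ceil((y1 - y0) / grid)))
    xedges = np.linspace(x0, x1, nx + 1)
    yedges = np.linspace(y0, y1, ny + 1)
    out = {}
    sign = 1.0 if leaflet == "upper" else -1.0
    for t, idx in headgroup.items():
        idx = np.array(idx, dtype=int)
        hist = np.zeros((nx, ny))
        total = 0
        for f in range(traj.n_frames):
            if idx.size == 0:
                break
            mid = traj.frames[f][all_idx, 2].mean()
            pts = traj.frames[f][idx]
            pts = pts[sign * (pts[:, 2] - mid) > 0]
            if len(pts) == 0:
                continue
            h, _, _ = np.histogram2d(pts[:, 0], pts[:, 1],
                                     bins=[xedges, yedges])
            hist += h
            total += len(pts)
        empty = total == 0
        out[t] = {
            "histogram": hist / total if total else hist,
            "xedges": xedges, "yedges": yedges, "empty": empty,
        }
    return out


def write_occupancy_tsv(profile: OccupancyProfile, path: str) -> None:
    types = sorted({t for v in profile.fractions.values() for t in v})
    with open(path, "w") as fh:
        fh.write("residue\t" + "\t".join(types) + "\n")
        for r, per_type in sorted(profile.fractions.items()):
            fh.write(str(r) + "\t"
                     + "\t".join(f"{per_type.get(t, 0.0):.4f}" for t in types)
                     + "\n")
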