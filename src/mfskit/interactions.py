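"""Non-covalent interaction analysis: contacts, hydrogen bonds, per-pair
time-fraction tables, salt-bridge classification and the intracellular
"charge-relay" triad summary.

Hydrogen bonds use the donor-heavy-atom...acceptor distance (default 3.0 A)
and the D-H...A angle (default >= 135 deg); both cutoffs and the distance
convention are switchable.  Fractions are summed per-frame bond counts over
the frame count, so a salt bridge held by two simultaneous H-bonds reports
a fraction of 2.0.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import MotifHit
from .structures import STANDARD_AMINO_ACIDS, Structure, Trajectory

# Donor heavy atoms (with their hydrogens) and acceptor atoms for the 20
# standard residues, Amber-style atom names; protonation-variant histidines
# accepted.  Editable by users.
BACKBONE_DONOR = ("N", ["H", "HN", "H1", "H2", "H3"])
BACKBONE_ACCEPTORS = ["O", "OXT"]

RESIDUE_DONORS: dict[str, list[tuple[str, list[str]]]] = {
    "SER": [("OG", ["HG"])],
    "THR": [("OG1", ["HG1"])],
    "TYR": [("OH", ["HH"])],
    "CYS": [("SG", ["HG"])],
    "ASN": [("ND2", ["HD21", "HD22"])],
    "GLN": [("NE2", ["HE21", "HE22"])],
    "LYS": [("NZ", ["HZ1", "HZ2", "HZ3"])],
    "ARG": [("NE", ["HE"]), ("NH1", ["HH11", "HH12"]),
            ("NH2", ["HH21", "HH22"])],
    "TRP": [("NE1", ["HE1"])],
    "HIS": [("NE2", ["HE2"])],
    "HID": [("ND1", ["HD1"])],
    "HIE": [("NE2", ["HE2"])],
    "HIP": [("ND1", ["HD1"]), ("NE2", ["HE2"])],
}

RESIDUE_ACCEPTORS: dict[str, list[str]] = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"],
    "ASN": ["OD1"], "GLN": ["OE1"],
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"],
    "HIS": ["ND1"], "HID": ["NE2"], "HIE": ["ND1"],
    "MET": ["SD"],
}

# sidechain groups defining a salt bridge: basic donor atoms vs acidic
# acceptor atoms (backbone H-bonds never qualify)
BASIC_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIP": {"ND1", "NE2"},
    "HIS": {"ND1", "NE2"},
}
ACIDIC_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class HBondCriteria:
    max_da_distance: float = 3.0
    min_dha_angle: float = 135.0
    distance_mode: str = "donor-acceptor"  # or "hydrogen-acceptor"

    def __post_init__(self):
        if self.max_da_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0.0 < self.min_dha_angle <= 180.0:
            raise ValueError("angle cutoff must be in (0, 180]")


@dataclass(frozen=True)
class InteractionEvent:
    frame: int
    donor: tuple[int, str]      # (residue id, atom name)
    hydrogen: str
    acceptor: tuple[int, str]
    type: str = "hbond"


def find_donors_acceptors(structure: Structure, include_backbone: bool = True):
    """Donor (heavy, hydrogen) index pairs and acceptor indices from the
    standard-residue tables.  A donor heavy atom without its hydrogen in
    the structure raises :class:`ConfigurationError`."""
    by_res: dict[tuple[str, int], dict[str, int]] = defaultdict(dict)
    resname: dict[tuple[str, int], str] = {}
    for i, a in enumerate(structure.atoms):
        key = (a.chain, a.residue_id)
        by_res[key][a.name] = i
        resname[key] = a.residue_name
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    missing: list[str] = []
    for key, atoms in by_res.items():
        rn = resname[key]
        donor_defs = list(RESIDUE_DONORS.get(rn, []))
        acc_defs = list(RESIDUE_ACCEPTORS.get(rn, []))
        if include_backbone and rn in STANDARD_AMINO_ACIDS:
            if "N" in atoms and rn != "PRO":
                donor_defs.append(BACKBONE_DONOR)
            acc_defs = acc_defs + [x for x in BACKBONE_ACCEPTORS if x in atoms]
        for heavy, hnames in donor_defs:
            if heavy not in atoms:
                continue
            hs = [atoms[h] for h in hnames if h in atoms]
            if not hs:
                missing.append(f"{rn}{key[1]}:{heavy}")
                continue
            donors.extend((atoms[heavy], h) for h in hs)
        acceptors.extend(atoms[x] for x in acc_defs if x in atoms)
    if missing:
        raise ConfigurationError(
            "donor heavy atoms without attached hydrogens: "
            + ", ".join(missing))
    return donors, acceptors


def detect_hbonds_frame(structure: Structure, donors, acceptors,
                        criteria: HBondCriteria = HBondCriteria(),
                        coords: np.ndarray | None = None,
                        frame: int = 0) -> list[InteractionEvent]:
    """Hydrogen bonds in one frame.

    ``donors`` are (heavy, hydrogen) atom-index pairs, ``acceptors`` atom
    indices.  An event requires distance <= ``max_da_distance`` (measured
    per ``distance_mode``) and D-H...A angle >= ``min_dha_angle``."""
    xyz = structure.coords if coords is None else np.asarray(coords, float)
    if not donors or not acceptors:
        return []
    donors = list(donors)
    acc = np.asarray(list(acceptors), dtype=int)
    d_idx = np.array([d for d, _ in donors], dtype=int)
    h_idx = np.array([h for _, h in donors], dtype=int)
    ref_idx = d_idx if criteria.distance_mode == "donor-acceptor" else h_idx
    eps = 1e-9  # keep exact-boundary geometries inclusive despite rounding
    tree = cKDTree(xyz[acc])
    neighbor_lists = tree.query_ball_point(xyz[ref_idx],
                                           criteria.max_da_distance + eps)
    events = []
    for k, neighbors in enumerate(neighbor_lists):
        if not neighbors:
            continue
        d, h = d_idx[k], h_idx[k]
        for j in neighbors:
            a = int(acc[j])
            if a == d or a == h:
                continue
            da = structure.atoms[d]
            aa = structure.atoms[a]
            if da.residue_id == aa.residue_id and da.chain == aa.chain:
                continue  # intra-residue pairs are not interactions
            dist = float(np.linalg.norm(xyz[ref_idx[k]] - xyz[a]))
            if dist > criteria.max_da_distance + eps:
                continue
            v1 = xyz[d] - xyz[h]
            v2 = xyz[a] - xyz[h]
            cosang = float(np.dot(v1, v2)
                           / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle < criteria.min_dha_angle - 1e-9:
                continue
            events.append(InteractionEvent(
                frame=frame,
                donor=(da.residue_id, da.name),
                hydrogen=structure.atoms[h].name,
                acceptor=(aa.residue_id, aa.name),
            ))
    return events


@dataclass
class FractionTable:
    """Residue-pair H-bond time fractions.

    ``fractions`` holds every observed pair (raw); :meth:`reported` filters
    at ``threshold``.  In the default count mode a fraction is the summed
    per-frame H-bond count over the frame count and may exceed 1.0
    (multi-H-bond salt bridges)."""

    fractions: dict[tuple[int, int], float]
    n_frames: int
    threshold: float = 0.1
    pair_atoms: dict[tuple[int, int], set] = field(default_factory=dict)

    def reported(self) -> dict[tuple[int, int], float]:
        return {p: f for p, f in self.fractions.items() if f >= self.threshold}


def interaction_fractions(traj: Trajectory, donors, acceptors,
                          criteria: HBondCriteria = HBondCriteria(),
                          threshold: float = 0.1,
                          mode: str = "count") -> FractionTable:
    """Per-residue-pair H-bond fraction over a trajectory.

    ``mode="count"`` sums per-frame bond counts (values may exceed 1);
    ``mode="indicator"`` counts frames with at least one bond."""
    counts: dict[tuple[int, int], float] = defaultdict(float)
    atoms_meta: dict[tuple[int, int], set] = defaultdict(set)
    topo = traj.topology
    resname = {a.residue_id: a.residue_name for a in topo.atoms}
    for f in range(traj.n_frames):
        events = detect_hbonds_frame(topo, donors, acceptors, criteria,
                                     coords=traj.frames[f], frame=f)
        per_pair_frame: dict[tuple[int, int], int] = defaultdict(int)
        for ev in events:
            pair = tuple(sorted((ev.donor[0], ev.acceptor[0])))
            per_pair_frame[pair] += 1
            atoms_meta[pair].add((
                resname[ev.donor[0]], ev.donor[1],
                resname[ev.acceptor[0]], ev.acceptor[1]))
        for pair, c in per_pair_frame.items():
            counts[pair] += c if mode == "count" else 1
    fractions = {p: c / traj.n_frames for p, c in counts.items()}
    return FractionTable(fractions=fractions, n_frames=traj.n_frames,
                         threshold=threshold, pair_atoms=dict(atoms_meta))


def classify_salt_bridges(table: FractionTable,
                          structure: Structure | None = None) -> dict[tuple[int, int], bool]:
    """Flag reported pairs coupling a basic sidechain donor group with an
    acidic sidechain acceptor group (backbone-only H-bonds never qualify)."""
    out = {}
    for pair, frac in table.reported().items():
        flag = False
        for (d_rn, d_atom, a_rn, a_atom) in table.pair_atoms.get(pair, ()):
            if (d_atom in BASIC_SIDECHAIN_DONORS.get(d_rn, ())
                    and a_atom in ACIDIC_SIDECHAIN_ACCEPTORS.get(a_rn, ())):
                flag = True
                break
        out[pair] = flag
    return out


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def contact_map(traj: Trajectory, residues_a, residues_b,
                cutoff: float = 4.0) -> tuple[np.ndarray, list[int], list[int]]:
    """Residue-pair contact fractions: two residues are in contact in a
    frame iff any heavy-atom pair distance is strictly below ``cutoff``.
    Returns (fraction matrix, residues_a, residues_b)."""
    residues_a = list(residues_a)
    residues_b = list(residues_b)
    if not residues_a or not residues_b:
        raise ValueError("residue groups must be non-empty")
    topo = traj.topology
    heavy = [i for i, a in enumerate(topo.atoms) if a.element != "H"]
    idx_a = {r: [i for i in heavy if topo.atoms[i].residue_id == r]
             for r in residues_a}
    idx_b = {r: [i for i in heavy if topo.atoms[i].residue_id == r]
             for r in residues_b}
    counts = np.zeros((len(residues_a), len(residues_b)))
    for f in range(traj.n_frames):
        xyz = traj.frames[f]
        flat_b = [i for r in residues_b for i in idx_b[r]]
        owner_b = np.array([bi for bi, r in enumerate(residues_b)
                            for _ in idx_b[r]])
        tree = cKDTree(xyz[flat_b])
        for ai, ra in enumerate(residues_a):
            hit = np.zeros(len(residues_b), dtype=bool)
            for i in idx_a[ra]:
                for j in tree.query_ball_point(xyz[i], cutoff):
                    if np.linalg.norm(xyz[i] - xyz[flat_b[j]]) < cutoff:
                        hit[owner_b[j]] = True
            counts[ai] += hit
    return counts / traj.n_frames, residues_a, residues_b


# ---------------------------------------------------------------------------
# Charge-relay summary
# ---------------------------------------------------------------------------

TRIAD_MOTIFS = ("A-motif", "EX6R", "PETL")


@dataclass
class ChargeRelayReport:
    triads: dict[str, dict[str, tuple[int, int]]]  # bundle -> motif -> range
    intra_bundle: list[dict]
    inter_bundle: list[dict]
    tmh_extensions: list[dict]


def charge_relay_summary(table: FractionTable, motif_hits: list[MotifHit],
                         salt_bridges: dict | None = None) -> ChargeRelayReport:
    """Partition reported H-bond pairs over the two signature-motif triads.

    Needs all six motifs (A-motif, E[X6]R, PETL-family in each bundle),
    named ``<motif>/<bundle>`` as :func:`mfskit.core.motif_scan` emits them.
    Pairs within one bundle's triad are intra-bundle, pairs across bundles
    inter-bundle; a pair with one residue outside every motif is listed as a
    TMH-contact extension."""
    triads: dict[str, dict[str, tuple[int, int]]] = {"N": {}, "C": {}}
    for hit in motif_hits:
        if "/" not in hit.pattern_name:
            continue
        motif, bundle = hit.pattern_name.split("/")
        if motif in TRIAD_MOTIFS and bundle in triads:
            triads[bundle].setdefault(motif, (hit.start, hit.end))
    for bundle in ("N", "C"):
        for motif in TRIAD_MOTIFS:
            if motif not in triads[bundle]:
                raise ConfigurationError(
                    f"missing motif {motif} in bundle {bundle}")

    def locate(res: int):
        for bundle, motifs in triads.items():
            for motif, (s, e) in motifs.items():
                if s <= res <= e:
                    return bundle, motif
        return None

    if salt_bridges is None:
        salt_bridges = classify_salt_bridges(table)
    intra, inter, ext = [], [], []
    for pair, frac in sorted(table.reported().items()):
        loc_a, loc_b = locate(pair[0]), locate(pair[1])
        entry = {
            "residues": pair, "fraction": frac,
            "salt_bridge": bool(salt_bridges.get(pair, False)),
            "motifs": (loc_a, loc_b),
        }
        if loc_a is None or loc_b is None:
            ext.append(entry)
        elif loc_a[0] == loc_b[0]:
            intra.append(entry)
        else:
            inter.append(entry)
    return ChargeRelayReport(triads=triads, intra_bundle=intra,
                             inter_bundle=inter, tmh_extensions=ext)


def write_fraction_table_tsv(table: FractionTable, path: str,
                             reported_only: bool = True) -> None:
    rows = table.reported() if reported_only else table.fractions
    with open(path, "w") as fh:
        fh.write("residue_a\tresidue_b\tfraction\n")
        for (a, b), f in sorted(rows.items()):
            fh.write(f"{a}\t{b}\t{f:.4f}\n")
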