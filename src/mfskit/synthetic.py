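"""Synthetic data with the statistical structure the analyses assume.

Real MFS transporter trajectories are rarely shareable, so every analysis in
this package can be exercised on generated data: idealized 12-helix bundles
in parametric outward-facing ("V"-shape) and inward-facing ("Lambda"-shape)
arrangements, rigid-body gating trajectories with thermal noise, coarse
membrane patches (PC/PE/cholesterol headgroup pseudo-atoms), explicit
donor-H-acceptor hydrogen-bond fixtures, and a motif-annotated stand-in
protein sequence.  All generators are pure functions of their spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .core import TMHCoreMap
from .structures import AtomRecord, Structure, Trajectory, BONDI_VDW

HELIX_RADIUS = 2.3       # Angstrom, canonical alpha-helix Calpha radius
HELIX_TWIST = 100.0      # degrees per residue
DEFAULT_RISE = 1.5       # Angstrom per residue


@dataclass
class BundleSpec:
    """Parametric two-state 12-helix bundle.

    ``state_param`` interpolates the rocker-switch geometry: 0 gives an
    outward-facing "V" (helices flare at the extracellular, +z, end), 1 an
    inward-facing "Lambda" (flare at the intracellular end); 0.5 is an
    occluded-like straight bundle.  ``tilt_deg`` is the helix tilt magnitude
    at the pure states.
    """

    n_helices: int = 12
    residues_per_helix: int = 24
    bundle_radius: float = 18.0
    state_param: float = 0.0
    rise_per_residue: float = DEFAULT_RISE
    tilt_deg: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.n_helices % 2 != 0:
            raise ValueError("n_helices must be even")
        if not 0.0 <= self.state_param <= 1.0:
            raise ValueError("state_param must lie in [0, 1]")


@dataclass
class GatingTrajectorySpec:
    """Extracellular gating of a TMH1/TMH7-like pair plus thermal noise.

    ``gate_schedule[t]`` is the per-frame extra extracellular opening
    (Angstrom) of the C-bundle relative to the base bundle; gating is a
    rigid rotation of the C-bundle about an intracellular pivot."""

    bundle: BundleSpec
    gate_schedule: np.ndarray = field(default_factory=lambda: np.zeros(2))
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.gate_schedule = np.asarray(self.gate_schedule, dtype=float)
        if len(self.gate_schedule) < 2:
            raise ValueError("need n_frames >= 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def n_frames(self) -> int:
        return len(self.gate_schedule)


@dataclass
class MembranePatchSpec:
    """Coarse two-leaflet membrane patch of headgroup pseudo-atoms."""

    composition: dict[str, float] = field(
        default_factory=lambda: {"PC": 0.5, "PE": 0.25, "CHL": 0.25})
    lipids_per_leaflet: int = 64
    box_xy: float = 120.0
    leaflet_z: float = 18.0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition fractions sum to {total}, not 1")


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Proper rotation taking +z to ``axis`` (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    v = np.cross(z, axis)
    c = float(np.dot(z, axis))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _ca_structure(coords: np.ndarray, resids, chain: str = "A",
                  resname: str = "ALA") -> Structure:
    atoms = [
        AtomRecord(serial=i + 1, name="CA", element="C", residue_name=resname,
                   residue_id=int(r), chain=chain, is_protein=True,
                   vdw_radius=BONDI_VDW["C"])
        for i, r in enumerate(resids)
    ]
    return Structure(atoms=atoms, coords=np.asarray(coords, dtype=float))


def build_ideal_helix(n_res: int, axis=(0.0, 0.0, 1.0),
                      origin=(0.0, 0.0, 0.0), phase: float = 0.0,
                      rise: float = DEFAULT_RISE,
                      start_resid: int = 1) -> Structure:
    """Canonical alpha-helix Calpha trace: 2.3 A radius, 1.5 A rise,
    100 deg/residue twist, laid along ``axis`` from ``origin``."""
    if n_res < 4:
        raise ValueError("need n_res >= 4")
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if abs(norm - 1.0) > 1e-9:
        import warnings

        warnings.warn("axis is not a unit vector; normalizing", stacklevel=2)
    coords = helix_trace(n_res, axis, origin, phase=phase, rise=rise)
    return _ca_structure(coords, range(start_resid, start_resid + n_res))


def helix_trace(n_res: int, axis, origin, phase: float = 0.0,
                rise: float = DEFAULT_RISE) -> np.ndarray:
    """Bare coordinate array of the canonical helix (see build_ideal_helix)."""
    i = np.arange(n_res)
    ang = np.radians(HELIX_TWIST * i + np.degrees(phase))
    local = np.column_stack([HELIX_RADIUS * np.cos(ang),
                             HELIX_RADIUS * np.sin(ang),
                             rise * i])
    rot = _rotation_to(axis)
    return local @ rot.T + np.asarray(origin, dtype=float)


def build_two_state_bundle(spec: BundleSpec) -> tuple[Structure, TMHCoreMap]:
    """Idealized two-state helix bundle plus its matching core map.

    Helices sit evenly on a circle of ``bundle_radius``; helix 1 is at
    azimuth 0 and helix 1 + n/2 (the TMH7 analog) diametrically opposite.
    Each helix axis is tilted in its radial plane by
    ``tilt_deg * (1 - 2*state_param)``: positive tilt flares the
    extracellular ends (V shape), negative the intracellular ends."""
    n = spec.residues_per_helix
    length = (n - 1) * spec.rise_per_residue
    theta = np.radians(spec.tilt_deg) * (1.0 - 2.0 * spec.state_param)
    coords = []
    resids = []
    ranges = []
    for k in range(spec.n_helices):
        phi = 2.0 * np.pi * k / spec.n_helices
        u = np.array([np.cos(phi), np.sin(phi), 0.0])
        axis = np.sin(theta) * u + np.cos(theta) * np.array([0.0, 0.0, 1.0])
        center = spec.bundle_radius * u
        origin = center - axis * (length / 2.0)
        coords.append(helix_trace(n, axis, origin, phase=phi,
                                  rise=spec.rise_per_residue))
        start = k * n + 1
        resids.extend(range(start, start + n))
        ranges.append((start, start + n - 1))
    structure = _ca_structure(np.vstack(coords), resids)
    cmap = TMHCoreMap(structure_id=f"bundle-state{spec.state_param:g}",
                      tmh_ranges=ranges)
    return structure, cmap


def generate_state_ensemble(spec: BundleSpec, n_structures: int,
                            noise_sigma: float) -> list[Structure]:
    """Noisy copies of the bundle: i.i.d. Gaussian displacement (sigma in
    Angstrom) on every coordinate, seeded from ``spec.seed``."""
    base, _ = build_two_state_bundle(spec)
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(n_structures):
        noise = rng.normal(0.0, noise_sigma, size=base.coords.shape)
        out.append(base.with_coords(base.coords + noise))
    return out


def _extracellular_segment_centroid(coords: np.ndarray, n_seg: int = 8) -> np.ndarray:
    order = np.argsort(coords[:, 2])
    return coords[order[-n_seg:]].mean(axis=0)


def generate_gating_trajectory(spec: GatingTrajectorySpec) -> Trajectory:
    """Gating trajectory: per-frame rigid rotation of the C-bundle about an
    intracellular pivot so the TMH1/TMH7-analog extracellular distance
    increases by exactly ``gate_schedule[t]`` (before noise), plus i.i.d.
    Gaussian coordinate noise."""
    base, cmap = build_two_state_bundle(spec.bundle)
    n = spec.bundle.residues_per_helix
    nh = spec.bundle.n_helices
    c_bundle = np.arange((nh // 2) * n, nh * n)  # atom indices of helices 7-12
    tmh1 = base.coords[0:n]
    tmh7 = base.coords[(nh // 2) * n:(nh // 2) * n + n]
    g1 = _extracellular_segment_centroid(tmh1)
    g7 = _extracellular_segment_centroid(tmh7)
    base_gate = float(np.linalg.norm(g1 - g7))
    length = (n - 1) * spec.bundle.rise_per_residue
    pivot = np.array([0.0, 0.0, -length / 2.0])

    def gate_at(theta: float) -> float:
        rot = _roty(-theta)
        g7r = (g7 - pivot) @ rot.T + pivot
        return float(np.linalg.norm(g1 - g7r))

    theta_cache: dict[float, float] = {}

    def solve_theta(opening: float) -> float:
        key = round(float(opening), 9)
        if key not in theta_cache:
            if abs(opening) < 1e-12:
                theta_cache[key] = 0.0
            else:
                f = lambda th: gate_at(th) - (base_gate + opening)
                theta_cache[key] = brentq(f, -1.2, 1.2, xtol=1e-12)
        return theta_cache[key]

    rng = np.random.default_rng(spec.seed)
    frames = np.empty((spec.n_frames, base.n_atoms, 3))
    for t, opening in enumerate(spec.gate_schedule):
        xyz = base.coords.copy()
        theta = solve_theta(opening)
        if theta != 0.0:
            rot = _roty(-theta)
            xyz[c_bundle] = (xyz[c_bundle] - pivot) @ rot.T + pivot
        if spec.noise_sigma > 0:
            xyz += rng.normal(0.0, spec.noise_sigma, size=xyz.shape)
        frames[t] = xyz
    return Trajectory(topology=base, frames=frames)


def _roty(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


# ---------------------------------------------------------------------------
# Membranes
# ---------------------------------------------------------------------------

# atom layout per coarse lipid type: (name, element, dz from leaflet plane
# toward the bilayer midplane)
_LIPID_ATOMS = {
    "PC": [("N", "N", 0.0), ("P", "P", 1.0)],
    "PE": [("N", "N", 0.0), ("HN", "H", 1.0), ("P", "P", 1.5)],
    "CHL": [("O3", "O", 0.0), ("H3", "H", 1.0)],
}


def largest_remainder_counts(composition: dict[str, float], total: int) -> dict[str, int]:
    """Integer apportionment of ``total`` by largest-remainder rounding."""
    raw = {k: v * total for k, v in composition.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = total - sum(counts.values())
    order = sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in order[:short]:
        counts[k] += 1
    return counts


def generate_membrane_patch(spec: MembranePatchSpec) -> Structure:
    """Two-leaflet patch of headgroup pseudo-atoms at z = +/- leaflet_z.

    PE carries an ammonium-like donor (N-HN), cholesterol a single
    hydroxyl donor/acceptor (O3-H3), PC choline/phosphate only acceptors.
    Per-leaflet counts follow the composition by largest-remainder
    rounding; xy positions are uniform in the box."""
    counts = largest_remainder_counts(spec.composition, spec.lipids_per_leaflet)
    rng = np.random.default_rng(spec.seed)
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = 0
    resid = 0
    for leaflet_sign in (+1.0, -1.0):
        zplane = leaflet_sign * spec.leaflet_z
        for lipid_type in spec.composition:
            layout = _LIPID_ATOMS[lipid_type]
            for _ in range(counts[lipid_type]):
                resid += 1
                x, y = rng.uniform(0.0, spec.box_xy, size=2)
                for name, element, dz in layout:
                    serial += 1
                    atoms.append(AtomRecord(
                        serial=serial, name=name, element=element,
                        residue_name=lipid_type, residue_id=resid,
                        chain="L", is_protein=False,
                        vdw_radius=BONDI_VDW.get(element, 1.7)))
                    coords.append(np.array([x, y, zplane - leaflet_sign * dz]))
    return Structure(atoms=atoms, coords=np.array(coords))


def generate_membrane_trajectory(spec: MembranePatchSpec, n_frames: int,
                                 diffusion_step: float = 2.0) -> Trajectory:
    """Membrane patch with per-frame lateral lipid diffusion (random walk,
    wrapped into the box).  Emulates the lipid exchange seen in bilayer
    simulations; z positions stay on the leaflet planes."""
    base = generate_membrane_patch(spec)
    rng = np.random.default_rng(spec.seed + 1)
    resids = np.array([a.residue_id for a in base.atoms])
    frames = np.empty((n_frames, base.n_atoms, 3))
    xyz = base.coords.copy()
    for t in range(n_frames):
        frames[t] = xyz
        step = rng.normal(0.0, diffusion_step, size=(resids.max(), 2))
        xyz = xyz.copy()
        xyz[:, :2] += step[resids - 1]
        xyz[:, :2] %= spec.box_xy
    return Trajectory(topology=base, frames=frames)


# ---------------------------------------------------------------------------
# Hydrogen-bond and charge-relay fixtures
# ---------------------------------------------------------------------------

def hbond_triplet(d_a_distance: float, dha_angle_deg: float,
                  dh_length: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Donor/hydrogen/acceptor coordinates with exact D...A distance and
    D-H...A angle (degrees).  D at the origin, H along +x."""
    d = np.zeros(3)
    h = np.array([dh_length, 0.0, 0.0])
    # acceptor along a ray from H making the requested angle with H->D
    theta = np.radians(180.0 - dha_angle_deg)
    u = np.array([np.cos(theta), np.sin(theta), 0.0])
    # |h + t*u| = d_a_distance
    b = 2.0 * np.dot(h, u)
    c = np.dot(h, h) - d_a_distance ** 2
    t = (-b + np.sqrt(b * b - 4 * c)) / 2.0
    return d, h, h + t * u


def _rec(serial, name, element, resname, resid, chain="A", protein=True):
    return AtomRecord(serial=serial, name=name, element=element,
                      residue_name=resname, residue_id=resid, chain=chain,
                      is_protein=protein,
                      vdw_radius=BONDI_VDW.get(element, 1.7))


def build_charge_relay_fixture(n_frames: int = 20):
    """Mini-trajectory emulating a charge-relay H-bond network.

    Four engineered interactions at motif-consistent residue numbers:

    * Arg162-Glu212 (A-motif / E[X6]R, N-bundle): two simultaneous
      sidechain H-bonds every frame -> fraction 2.0 (salt bridge);
    * Ser271-Glu270 (within the N-bundle PETL-family motif): bonded in
      70% of frames -> fraction 0.7;
    * Thr218-Glu506 (E[X6]R N-bundle to PETL C-bundle): bonded in 1 frame
      in 20 -> fraction 0.05, below the 0.1 reporting threshold;
    * Arg219-Glu447 (the two E[X6]R motifs across bundles): one H-bond
      every frame -> fraction 1.0.

    Returns ``(trajectory, donors, acceptors)`` where donors are
    (donor_index, hydrogen_index) pairs and acceptors atom indices.
    """
    d0, h0, a0 = hbond_triplet(2.8, 170.0)
    blocks = []  # (atoms, base coords)
    atoms = [
        _rec(1, "NH1", "N", "ARG", 162), _rec(2, "HH11", "H", "ARG", 162),
        _rec(3, "NH2", "N", "ARG", 162), _rec(4, "HH21", "H", "ARG", 162),
        _rec(5, "OE1", "O", "GLU", 212), _rec(6, "OE2", "O", "GLU", 212),
        _rec(7, "OG", "O", "SER", 271), _rec(8, "HG", "H", "SER", 271),
        _rec(9, "OE1", "O", "GLU", 270),
        _rec(10, "OG1", "O", "THR", 218), _rec(11, "HG1", "H", "THR", 218),
        _rec(12, "OE1", "O", "GLU", 506),
        _rec(13, "NH1", "N", "ARG", 219), _rec(14, "HH11", "H", "ARG", 219),
        _rec(15, "OE1", "O", "GLU", 447),
    ]
    off = lambda y, z=0.0: np.array([0.0, y, z])
    base = np.array([
        d0 + off(0), h0 + off(0), d0 + off(0, 3), h0 + off(0, 3),
        a0 + off(0), a0 + off(0, 3),
        d0 + off(30), h0 + off(30), a0 + off(30),
        d0 + off(60), h0 + off(60), a0 + off(60),
        d0 + off(90), h0 + off(90), a0 + off(90),
    ])
    structure = Structure(atoms=atoms, coords=base)
    frames = np.repeat(base[None], n_frames, axis=0)
    n_on_ser = int(round(0.7 * n_frames))
    frames[n_on_ser:, 8, 2] += 8.0       # Ser271-Glu270 off in 30% of frames
    frames[1:, 11, 2] += 8.0             # Thr218-Glu506 on in frame 0 only
    donors = [(0, 1), (2, 3), (6, 7), (9, 10), (12, 13)]
    acceptors = [4, 5, 8, 11, 14]
    return Trajectory(topology=structure, frames=frames), donors, acceptors


# ---------------------------------------------------------------------------
# Stand-in sequence (synthetic)
# ---------------------------------------------------------------------------

# published 1-based start positions of the six intracellular signature
# motifs of hOAT1 (N-bundle A-motif, E[X6]R, PESXRW; C-bundle A-motif,
# E[X6]R, PETL)
MOTIF_ANNOTATION = {
    "A-motif/N": (153, "GYLADRLGRR"),
    "EX6R/N": (212, "EWMPIHTR"),
    "PETL/N": (269, "IESARWH"),
    "A-motif/C": (390, "NSLGRR"),
    "EX6R/C": (447, "ELYPTMIR"),
    "PETL/C": (505, "PETL"),
}

# filler alphabet excludes E/D/R/K so no spurious signature-motif matches
# can arise outside the annotated positions
_FILLER = "ACFGHILMNPQSTVWY"


def synthetic_transporter_sequence(length: int = 563) -> str:
    """Synthetic stand-in for an MFS transporter sequence.

    NOT a natural sequence: a deterministic filler (alphabet without
    E/D/R/K) of the canonical hOAT1 length carrying the six intracellular
    signature-motif sequences at their published residue positions, so a
    motif scan recovers exactly the annotated starts.  Useful as a
    positive/negative control for :func:`mfskit.core.motif_scan`.
    """
    rng = np.random.default_rng(20220429)
    seq = list(rng.choice(list(_FILLER), size=length))
    for start, motif in MOTIF_ANNOTATION.values():
        seq[start - 1:start - 1 + len(motif)] = list(motif)
    return "".join(seq)


def write_fasta(sequence: str, path: str, header: str = "synthetic") -> None:
    with open(path, "w") as fh:
        fh.write(f">{header}\n")
        for i in range(0, len(sequence), 60):
            fh.write(sequence[i:i + 60] + "\n")
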