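"""Coordinate-file I/O and the uniform atom/frame data model.

Structures are held as a flat, file-ordered list of :class:`AtomRecord` plus a
``(n_atoms, 3)`` coordinate array in Angstrom.  Trajectories pair one topology
:class:`Structure` with a stack of per-frame coordinate arrays.  Parsing of
PDB/mmCIF goes through :mod:`gemmi`; binary trajectory formats (DCD/XTC) go
through :mod:`mdtraj`.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

# Bondi van der Waals radii (Angstrom), user-overridable via the
# ``vdw_overrides`` argument of read_structure or by editing this mapping.
BONDI_VDW = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "ZN": 1.39, "CA": 2.31,
}
DEFAULT_VDW = 1.70

_WATER_NAMES = {"HOH", "WAT", "TIP", "TIP3", "SOL"}

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # protonation-variant histidines
    "HID", "HIE", "HIP",
}


class FormatError(ValueError):
    """File failed to parse under the named standard."""


class UnsupportedFeatureError(ValueError):
    """Input uses a feature the data model deliberately rejects."""


class TopologyError(ValueError):
    """Frame/topology atom counts disagree."""


class SelectionError(ValueError):
    """Malformed selection expression (carries the offending position)."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str
    is_protein: bool
    vdw_radius: float

    def __post_init__(self):
        if self.residue_id < 1:
            raise ValueError(f"residue_id must be >= 1, got {self.residue_id}")
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")


@dataclass
class Structure:
    """Atoms plus one coordinate set; ``box`` holds optional orthorhombic
    box lengths (Angstrom) for minimal-image distance calculations."""

    atoms: list[AtomRecord]
    coords: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a structure")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def subset(self, indices) -> "Structure":
        indices = list(indices)
        return Structure(
            atoms=[self.atoms[i] for i in indices],
            coords=self.coords[indices],
            box=self.box,
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(atoms=self.atoms, coords=coords, box=self.box)


@dataclass
class Trajectory:
    """Topology plus per-frame coordinates; ``frame_interval`` is metadata
    only (ps between saved snapshots)."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval: float = 10.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise TopologyError("trajectory needs >= 1 frame of (n, 3) coords")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"atom count {self.topology.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name.upper()
    if not el or el == "X":
        # fall back on the first alphabetic character of the atom name
        for ch in atom.name:
            if ch.isalpha():
                return ch.upper()
        return "C"
    return el


def _gemmi_to_structure(st: gemmi.Structure, vdw_overrides=None) -> Structure:
    vdw = dict(BONDI_VDW)
    if vdw_overrides:
        vdw.update({k.upper(): v for k, v in vdw_overrides.items()})
    model = st[0]
    atoms: list[AtomRecord] = []
    coords: list[tuple[float, float, float]] = []
    serial = 0
    altloc_dropped = 0
    for chain in model:
        for res in chain:
            if res.seqid.icode not in ("", " "):
                raise UnsupportedFeatureError(
                    f"insertion code {res.seqid.icode!r} on residue "
                    f"{res.name} {res.seqid.num} is not supported"
                )
            # keep highest-occupancy altloc per atom name
            by_name: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = by_name.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    if prev is not None:
                        altloc_dropped += 1
                    by_name[atom.name] = atom
                elif prev is not None:
                    altloc_dropped += 1
            is_prot = res.name in STANDARD_AMINO_ACIDS
            for atom in by_name.values():
                serial += 1
                el = _element_of(atom)
                atoms.append(AtomRecord(
                    serial=serial,
                    name=atom.name,
                    element=el,
                    residue_name=res.name,
                    residue_id=res.seqid.num,
                    chain=chain.name,
                    is_protein=is_prot and res.name not in _WATER_NAMES,
                    vdw_radius=vdw.get(el, DEFAULT_VDW),
                ))
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if altloc_dropped:
        logger.info("dropped %d lower-occupancy altloc atoms", altloc_dropped)
    box = None
    cell = st.cell
    if cell.a > 1.0 and cell.alpha == 90 and cell.beta == 90 and cell.gamma == 90:
        box = np.array([cell.a, cell.b, cell.c])
    return Structure(atoms=atoms, coords=np.array(coords, dtype=float), box=box)


def read_structure(path: str, fmt: str = "auto",
                   vdw_overrides: dict | None = None) -> Structure:
    """Read a single-model coordinate file (PDB or mmCIF).

    Residue numbering is taken verbatim from the file (1-based); HETATM
    lipids/waters are flagged ``is_protein=False``.  Insertion codes raise
    :class:`UnsupportedFeatureError`.
    """
    if fmt == "auto":
        fmt = "mmcif" if str(path).lower().endswith((".cif", ".mmcif")) else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if len(st) == 0 or st[0].count_atom_sites() == 0:
        raise FormatError(f"no atoms found in {path}")
    return _gemmi_to_structure(st, vdw_overrides)


def _structure_to_gemmi(structure: Structure,
                        frames: np.ndarray | None = None) -> gemmi.Structure:
    st = gemmi.Structure()
    if structure.box is not None:
        b = structure.box
        st.cell = gemmi.UnitCell(b[0], b[1], b[2], 90, 90, 90)
    coord_sets = frames if frames is not None else structure.coords[None]
    for mi, coords in enumerate(coord_sets):
        model = gemmi.Model(mi + 1)
        chain_map: dict[str, gemmi.Chain] = {}
        res_key = None
        res = None
        for rec, xyz in zip(structure.atoms, coords):
            if rec.chain not in chain_map:
                chain_map[rec.chain] = gemmi.Chain(rec.chain)
                model.add_chain(chain_map[rec.chain])
                res_key = None
            chain = model[rec.chain]
            key = (rec.chain, rec.residue_id, rec.residue_name)
            if key != res_key:
                res = gemmi.Residue()
                res.name = rec.residue_name
                res.seqid = gemmi.SeqId(rec.residue_id, " ")
                res.het_flag = "A" if rec.is_protein else "H"
                chain.add_residue(res)
                res_key = key
            atom = gemmi.Atom()
            atom.name = rec.name
            atom.element = gemmi.Element(rec.element.capitalize())
            atom.serial = rec.serial
            atom.pos = gemmi.Position(*xyz)
            chain[-1].add_atom(atom)
        st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str) -> None:
    """Write a single-model PDB file (fixed-column format)."""
    _structure_to_gemmi(structure).write_pdb(str(path))


def write_trajectory(traj: Trajectory, path: str) -> None:
    """Write a multi-model PDB, one MODEL per frame."""
    _structure_to_gemmi(traj.topology, frames=traj.frames).write_pdb(str(path))


def read_trajectory(topology: Structure, path: str, fmt: str = "auto",
                    frame_interval: float = 10.0) -> Trajectory:
    """Read a multi-frame coordinate file against a known topology.

    ``fmt`` is one of ``pdb`` (multi-model), ``dcd``, ``xtc`` or ``auto``
    (by extension).  Frames keep file order; an atom-count mismatch raises
    :class:`TopologyError`.
    """
    if fmt == "auto":
        ext = os.path.splitext(str(path))[1].lower().lstrip(".")
        fmt = ext if ext in ("dcd", "xtc") else "pdb"
    if fmt == "pdb":
        st = gemmi.read_pdb(str(path))
        frames = []
        for model in st:
            xyz = []
            for chain in model:
                for res in chain:
                    for atom in res:
                        xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
            frames.append(xyz)
        frames = np.array(frames, dtype=float)
    elif fmt in ("dcd", "xtc"):
        import mdtraj  # binary formats only; deferred import

        with tempfile.TemporaryDirectory() as tmp:
            top_path = os.path.join(tmp, "top.pdb")
            write_structure(topology, top_path)
            mt = mdtraj.load(str(path), top=top_path)
        frames = np.asarray(mt.xyz, dtype=float) * 10.0  # nm -> Angstrom
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")
    if frames.ndim != 3 or frames.shape[1] != topology.n_atoms:
        raise TopologyError(
            f"trajectory atom count {frames.shape[1] if frames.ndim == 3 else '?'}"
            f" does not match topology ({topology.n_atoms})"
        )
    return Trajectory(topology=topology, frames=frames,
                      frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

_KEYWORDS = {"and", "or", "not", "resid", "name", "chain", "protein"}


def _tokenize(expr: str):
    tokens = []  # (text, position)
    i = 0
    while i < len(expr):
        ch = expr[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            tokens.append((ch, i))
            i += 1
            continue
        j = i
        while j < len(expr) and not expr[j].isspace() and expr[j] not in "()":
            j += 1
        tokens.append((expr[i:j], i))
        i = j
    return tokens


class _Parser:
    """Recursive-descent parser for the small selection grammar:

    expr     := term ('or' term)*
    term     := factor ('and' factor)*
    factor   := 'not' factor | '(' expr ')' | primitive
    primitive:= 'resid' ranges | 'name' names | 'chain' ids | 'protein'
    """

    def __init__(self, expr: str, structure: Structure):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.pos = 0
        self.structure = structure

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.expr))

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionError("empty selection expression", 0)
        mask = self.expr_rule()
        tok, at = self.peek()
        if tok is not None:
            raise SelectionError(f"unexpected token {tok!r}", at)
        return mask

    def expr_rule(self):
        mask = self.term_rule()
        while self.peek()[0] == "or":
            self.take()
            mask = mask | self.term_rule()
        return mask

    def term_rule(self):
        mask = self.factor_rule()
        while self.peek()[0] == "and":
            self.take()
            mask = mask & self.factor_rule()
        return mask

    def factor_rule(self):
        tok, at = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression", at)
        if tok == "not":
            self.take()
            return ~self.factor_rule()
        if tok == "(":
            self.take()
            mask = self.expr_rule()
            tok, at = self.take()
            if tok != ")":
                raise SelectionError("expected ')'", at)
            return mask
        return self.primitive_rule()

    def _values(self):
        vals = []
        while True:
            tok, _ = self.peek()
            if tok is None or tok in _KEYWORDS or tok in "()":
                break
            vals.append(self.take()[0])
        return vals

    def primitive_rule(self):
        atoms = self.structure.atoms
        n = len(atoms)
        tok, at = self.take()
        if tok == "protein":
            return np.array([a.is_protein for a in atoms], dtype=bool)
        if tok == "resid":
            vals = self._values()
            if not vals:
                raise SelectionError("'resid' needs residue ids/ranges", at)
            selected = set()
            for v in vals:
                for part in v.split(","):
                    if not part:
                        continue
                    if "-" in part:
                        s, _, e = part.partition("-")
                        try:
                            lo, hi = int(s), int(e)
                        except ValueError:
                            raise SelectionError(f"bad residue range {part!r}", at)
                        selected.update(range(lo, hi + 1))
                    else:
                        try:
                            selected.add(int(part))
                        except ValueError:
                            raise SelectionError(f"bad residue id {part!r}", at)
            return np.array([a.residue_id in selected for a in atoms], dtype=bool)
        if tok == "name":
            vals = self._values()
            if not vals:
                raise SelectionError("'name' needs atom names", at)
            names = {x for v in vals for x in v.split(",") if x}
            return np.array([a.name in names for a in atoms], dtype=bool)
        if tok == "chain":
            vals = self._values()
            if not vals:
                raise SelectionError("'chain' needs chain ids", at)
            chains = {x for v in vals for x in v.split(",") if x}
            return np.array([a.chain in chains for a in atoms], dtype=bool)
        raise SelectionError(f"unknown selection keyword {tok!r}", at)


def select_atoms(structure: Structure, expr: str) -> np.ndarray:
    """Evaluate a selection expression, returning an ordered index array.

    Grammar: ``resid`` ranges (``212-219``), ``name`` lists, ``chain`` ids,
    ``protein``, combined with ``and``/``or``/``not`` and parentheses.
    """
    mask = _Parser(expr, structure).parse()
    return np.flatnonzero(mask)


def minimum_image_distance(a: np.ndarray, b: np.ndarray,
                           box: np.ndarray) -> float:
    """Minimal-image distance for an orthorhombic box."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d -= box * np.round(d / box)
    return float(np.linalg.norm(d))
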