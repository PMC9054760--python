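"""The 12-TMH MFS core: residue-range maps, helix classes, core-coordinate
extraction, geometric helicity assignment, and signature-motif scanning.

MFS transporters share a 12-transmembrane-helix fold split into an N-bundle
(TMH1-6) and a C-bundle (TMH7-12).  Helices fall into three functional
classes: A-helices (1,4,7,10) line the substrate cavity, B-helices
(2,5,8,11) keep the inter-bundle interface, C-helices (3,6,9,12) face the
lipids.  The conserved intracellular signature motifs (A-motif, E[X6]R,
PETL-family) are shipped as data and scanned with a small pattern language
(one-letter codes, ``X`` wildcard, ``[A/B]`` alternatives, ``[Xn]`` repeats).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import yaml

from .structures import Structure

N_TMH = 12
_CLASS_OF = {1: "A", 2: "B", 3: "C"}  # cycle of period 3 over TMH index


class CoreMapError(ValueError):
    """Invalid TMH core-map definition."""


class CoreDataError(ValueError):
    """Structure cannot supply the mapped core residues."""


class SequenceError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass
class TMHCoreMap:
    """Twelve ordered (start, end) residue-id ranges defining the MFS core."""

    structure_id: str
    tmh_ranges: list[tuple[int, int]]

    def __post_init__(self):
        if len(self.tmh_ranges) != N_TMH:
            raise CoreMapError(
                f"{self.structure_id}: expected 12 TMH ranges, "
                f"got {len(self.tmh_ranges)}"
            )
        self.tmh_ranges = [(int(s), int(e)) for s, e in self.tmh_ranges]
        prev_end = 0
        for k, (s, e) in enumerate(self.tmh_ranges, start=1):
            if s > e:
                raise CoreMapError(
                    f"{self.structure_id}: TMH{k} range ({s},{e}) is descending"
                )
            if s <= prev_end:
                raise CoreMapError(
                    f"{self.structure_id}: TMH{k} overlaps or is out of order"
                )
            prev_end = e

    def bundle_of(self, tmh: int) -> str:
        if not 1 <= tmh <= N_TMH:
            raise ValueError(f"TMH index {tmh} out of range 1..12")
        return "N" if tmh <= 6 else "C"

    def class_of(self, tmh: int) -> str:
        if not 1 <= tmh <= N_TMH:
            raise ValueError(f"TMH index {tmh} out of range 1..12")
        return _CLASS_OF[(tmh - 1) % 3 + 1]

    def to_dict(self) -> dict:
        return {"tmh_ranges": [list(r) for r in self.tmh_ranges]}


def load_core_map(path: str) -> dict[str, TMHCoreMap]:
    """Load per-structure core maps from a YAML mapping file.

    Layout: ``{structure_id: {tmh_ranges: [[start, end], ... x12]}}``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise CoreMapError("core-map file must be a mapping of structure ids")
    out = {}
    for sid, entry in raw.items():
        ranges = entry["tmh_ranges"] if isinstance(entry, dict) else entry
        out[sid] = TMHCoreMap(structure_id=str(sid), tmh_ranges=ranges)
    return out


def save_core_map(maps: dict[str, TMHCoreMap], path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({sid: m.to_dict() for sid, m in maps.items()}, fh)


# ---------------------------------------------------------------------------
# Core-coordinate extraction
# ---------------------------------------------------------------------------

def _calpha_trace(structure: Structure, start: int, end: int) -> np.ndarray:
    """Ordered Calpha coordinates for a residue range; errors list gaps."""
    by_res: dict[int, int] = {}
    for i, a in enumerate(structure.atoms):
        if a.name == "CA" and start <= a.residue_id <= end:
            by_res.setdefault(a.residue_id, i)
    missing = [r for r in range(start, end + 1) if r not in by_res]
    if missing:
        raise CoreDataError(
            f"missing Calpha for residues {missing} in range {start}-{end}"
        )
    idx = [by_res[r] for r in range(start, end + 1)]
    return structure.coords[idx]


def resample_polyline(points: np.ndarray, n_out: int) -> np.ndarray:
    """Arc-length resampling of a 3-D polyline to ``n_out`` points.

    When the polyline already has exactly ``n_out`` vertices they are
    returned verbatim (identity resampling).
    """
    points = np.asarray(points, dtype=float)
    if len(points) == n_out:
        return points.copy()
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, t[-1], n_out)
    return np.column_stack([np.interp(targets, t, points[:, d]) for d in range(3)])


def extract_core_coordinates(structure: Structure, cmap: TMHCoreMap,
                             points_per_tmh: int = 20) -> np.ndarray:
    """Fixed-length Calpha representation of the 12-TMH core.

    Each TMH trace is resampled by arc length to ``points_per_tmh`` points,
    making structures with different TMH lengths directly comparable.
    Returns an array of shape ``(12 * points_per_tmh, 3)``.
    """
    blocks = []
    for (s, e) in cmap.tmh_ranges:
        trace = _calpha_trace(structure, s, e)
        if len(trace) < 4:
            raise CoreDataError(f"TMH range {s}-{e} has fewer than 4 Calpha")
        blocks.append(resample_polyline(trace, points_per_tmh))
    return np.vstack(blocks)


# ---------------------------------------------------------------------------
# Geometric helicity
# ---------------------------------------------------------------------------

def _virtual_torsion(p0, p1, p2, p3) -> float:
    """Dihedral (degrees) of four consecutive Calpha positions; a
    right-handed alpha-helix gives ~+50 deg."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def detect_helices_geometric(structure: Structure,
                             d13_range: tuple[float, float] = (4.4, 5.6),
                             torsion_range: tuple[float, float] = (35.0, 65.0),
                             min_length: int = 5) -> list[tuple[int, int]]:
    """Helical segments from Calpha geometry alone.

    Residue *i* is helical iff the Ca(i)->Ca(i+3) distance lies in
    ``d13_range`` (Angstrom) and the virtual torsion over Ca(i-1..i+2) lies
    in ``torsion_range`` (degrees).  Segments are maximal helical runs of at
    least ``min_length`` residues, reported as (start, end) residue ids.
    """
    ca_idx = [i for i, a in enumerate(structure.atoms) if a.name == "CA"]
    if len(ca_idx) < 4:
        return []
    resids = [structure.atoms[i].residue_id for i in ca_idx]
    xyz = structure.coords[ca_idx]
    n = len(xyz)
    helical = np.zeros(n, dtype=bool)
    for i in range(1, n - 3):
        d13 = np.linalg.norm(xyz[i + 3] - xyz[i])
        if not d13_range[0] <= d13 <= d13_range[1]:
            continue
        tor = _virtual_torsion(xyz[i - 1], xyz[i], xyz[i + 1], xyz[i + 2])
        if torsion_range[0] <= tor <= torsion_range[1]:
            helical[i:i + 4] = True  # the whole i -> i+3 window is helical
    segments = []
    run_start = None
    for i in range(n + 1):
        if i < n and helical[i]:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start >= min_length:
                segments.append((resids[run_start], resids[i - 1]))
            run_start = None
    return segments


# ---------------------------------------------------------------------------
# Signature motifs
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MotifPattern:
    name: str
    bundle: str  # "N" or "C"
    pattern: str

    def to_regex(self) -> str:
        return _compile_pattern(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    pattern_name: str
    start: int  # 1-based
    end: int    # 1-based inclusive
    matched: str

    def __post_init__(self):
        assert self.end - self.start + 1 == len(self.matched)


# The conserved intracellular signature motifs as usually written for MFS
# transporters, duplicated over the two pseudo-symmetric bundles.  LGRR is
# the conserved tail of the A-motif, useful as an anchor where a bundle's
# A-motif diverges from the canonical pattern.
TABLE_MOTIFS: list[MotifPattern] = [
    MotifPattern("A-motif", "N", "G[X3]D[R/K]XGR[R/K]"),
    MotifPattern("EX6R", "N", "E[X6]R"),
    MotifPattern("PETL", "N", "[P/X]ESXRW[L/X]"),
    MotifPattern("A-motif", "C", "[D/N][R/H]LGRR"),
    MotifPattern("EX6R", "C", "E[X6]R"),
    MotifPattern("PETL", "C", "PET[K/L]"),
]

LGRR_ANCHOR = MotifPattern("A-motif-LGRR", "*", "LGRR")


def _compile_pattern(pattern: str) -> str:
    """Compile the motif pattern language into a Python regex."""
    out = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.index("]", i)
            body = pattern[i + 1:j]
            m = re.fullmatch(r"X(\d+)", body)
            if m:
                out.append(".{%d}" % int(m.group(1)))
            else:
                alts = body.split("/")
                if any(a == "X" for a in alts):
                    out.append(".")
                else:
                    out.append("[" + "".join(alts) + "]")
            i = j + 1
        elif ch == "X":
            out.append(".")
            i += 1
        elif ch in _AA:
            out.append(ch)
            i += 1
        else:
            raise ValueError(f"bad motif pattern character {ch!r} in {pattern!r}")
    return "".join(out)


def motif_scan(sequence: str, patterns=None,
               overlapping: bool = False) -> list[MotifHit]:
    """Scan a one-letter amino-acid sequence for signature motifs.

    Returns 1-based hits.  By default matches may not start inside an
    earlier match of the same pattern; ``overlapping=True`` reports every
    match start.
    """
    if patterns is None:
        patterns = TABLE_MOTIFS
    for pos, ch in enumerate(sequence):
        if ch not in _AA:
            raise SequenceError(f"invalid residue character {ch!r}", pos + 1)
    hits = []
    for pat in patterns:
        rx = re.compile(pat.to_regex())
        if overlapping:
            matches = [(m.start(1), m.group(1))
                       for m in re.finditer("(?=(" + rx.pattern + "))", sequence)]
        else:
            matches = [(m.start(), m.group()) for m in rx.finditer(sequence)]
        for start0, text in matches:
            hits.append(MotifHit(
                pattern_name=pat.name if pat.bundle == "*"
                else f"{pat.name}/{pat.bundle}",
                start=start0 + 1,
                end=start0 + len(text),
                matched=text,
            ))
    hits.sort(key=lambda h: (h.start, h.pattern_name))
    return hits


def write_motif_hits_tsv(hits: list[MotifHit], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("pattern\tstart\tend\tmatched\n")
        for h in hits:
            fh.write(f"{h.pattern_name}\t{h.start}\t{h.end}\t{h.matched}\n")
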