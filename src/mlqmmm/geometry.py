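"""Molecular structures, internal coordinates, hydrogen bonds and file I/O.

The central container is :class:`Structure`: a flat list of labelled atoms with
Cartesian coordinates in Å, optional point charges (e) and optional QM/MM region
tags.  Site labels follow the common quantum-chemistry convention of element
symbol plus site number ("C8", "O10", "H10"); the element is parsed from the
label.

Internal coordinates (bond lengths, bending angles, signed torsions) are
measured with :func:`measure`; torsions follow the IUPAC sign convention
(cis = 0°, positive clockwise looking from the first atom toward the second)
and are reported in (−180°, 180°].

Hydrogen bonds are detected geometrically from donor–H covalent connectivity
(inferred by covalent-radius distance criteria) plus H···acceptor distance and
donor–H···acceptor angle cutoffs.

XYZ files are read/written directly (plain "count / comment / element x y z"
records); PDB files go through biotite.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import ATOMIC_MASSES, COVALENT_RADII

__all__ = [
    "Structure",
    "InternalCoordinate",
    "HBond",
    "GeometryDiffReport",
    "GeometryError",
    "measure",
    "measure_all",
    "detect_hbonds",
    "mean_hbond_distance",
    "compare_geometries",
    "infer_bonds",
    "read_xyz",
    "write_xyz",
    "read_xyz_frames",
    "write_xyz_frames",
    "read_pdb",
    "write_pdb",
]


class GeometryError(ValueError):
    """Raised for malformed structures, unknown sites or degenerate geometry."""


_LABEL_RE = re.compile(r"^([A-Z][a-z]?)")


def element_of(label: str) -> str:
    """Element symbol parsed from a site label like ``"C8"`` or ``"Cl1"``."""
    m = _LABEL_RE.match(label)
    if not m:
        raise GeometryError(f"cannot parse an element symbol from label {label!r}")
    sym = m.group(1)
    # Two-letter symbols only if known; "CA" in PDB naming means C-alpha, not Ca.
    if sym not in ATOMIC_MASSES and sym[0] in ATOMIC_MASSES:
        sym = sym[0]
    return sym


@dataclass
class Structure:
    """A molecular structure: labelled atoms with coordinates in Å.

    Parameters
    ----------
    labels
        Site labels, element symbol + site id (e.g. ``"N7"``).
    coords
        ``(n, 3)`` Cartesian coordinates, Å.
    charges
        Optional per-atom point charges, e.
    region
        Optional per-atom region tags, each ``"QM"`` or ``"MM"``.
    """

    labels: list[str]
    coords: np.ndarray
    charges: np.ndarray | None = None
    region: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.labels), 3):
            raise GeometryError(
                f"coordinate array shape {self.coords.shape} does not match "
                f"{len(self.labels)} labels"
            )
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError("non-finite coordinates")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
            if self.charges.shape != (len(self.labels),):
                raise GeometryError("charge array length does not match atom count")
        if self.region is not None:
            self.region = np.asarray(self.region, dtype=object)
            if self.region.shape != (len(self.labels),):
                raise GeometryError("region array length does not match atom count")
            bad = [r for r in self.region if r not in ("QM", "MM")]
            if bad:
                raise GeometryError(f"invalid region tags: {sorted(set(map(str, bad)))}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def elements(self) -> list[str]:
        return [element_of(lb) for lb in self.labels]

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[el] for el in self.elements])

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise GeometryError(f"unknown site name {label!r}") from None

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(list(self.labels), np.array(coords, dtype=float),
                         None if self.charges is None else self.charges.copy(),
                         None if self.region is None else self.region.copy())

    def copy(self) -> "Structure":
        return self.with_coords(self.coords.copy())


@dataclass(frozen=True)
class InternalCoordinate:
    """A measured (or specified) bond, angle or dihedral.

    ``value`` is in Å for bonds and degrees for angles/dihedrals; it is ``None``
    for a bare specification that has not been measured yet.
    """

    kind: str  # "bond" | "angle" | "dihedral"
    sites: tuple[str, ...]
    value: float | None = None

    _NSITES = {"bond": 2, "angle": 3, "dihedral": 4}

    def __post_init__(self) -> None:
        if self.kind not in self._NSITES:
            raise GeometryError(f"unknown coordinate kind {self.kind!r}")
        if len(self.sites) != self._NSITES[self.kind]:
            raise GeometryError(
                f"{self.kind} requires {self._NSITES[self.kind]} sites, "
                f"got {len(self.sites)}"
            )
        if len(set(self.sites)) != len(self.sites):
            raise GeometryError(f"duplicate sites in {self.kind} spec {self.sites}")
        if self.value is not None:
            if self.kind == "bond" and self.value <= 0:
                raise GeometryError("bond length must be positive")
            if self.kind == "angle" and not 0.0 <= self.value <= 180.0:
                raise GeometryError("angle must lie in [0, 180] degrees")
            if self.kind == "dihedral" and not -180.0 < self.value <= 180.0:
                raise GeometryError("dihedral must lie in (-180, 180] degrees")

    @property
    def key(self) -> tuple:
        return (self.kind, self.sites)


@dataclass(frozen=True)
class HBond:
    """A geometric hydrogen bond D–H···A."""

    donor: str
    hydrogen: str
    acceptor: str
    distance: float  # H···A, Å
    angle: float  # D–H···A, degrees


def bond_length(p1: np.ndarray, p2: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(p2) - np.asarray(p1)))


def bend_angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Interior angle at ``p2`` in degrees, in [0, 180]."""
    u = np.asarray(p1) - np.asarray(p2)
    v = np.asarray(p3) - np.asarray(p2)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise GeometryError("degenerate angle: coincident atoms")
    c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion in degrees, IUPAC convention, in (−180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("degenerate dihedral: three collinear atoms")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def measure(structure: Structure, coord: InternalCoordinate) -> InternalCoordinate:
    """Measure a bond/angle/dihedral specification on a structure.

    Returns a new :class:`InternalCoordinate` carrying the measured value.
    """
    pts = [structure.coords[structure.index(s)] for s in coord.sites]
    if coord.kind == "bond":
        val = bond_length(*pts)
    elif coord.kind == "angle":
        val = bend_angle(*pts)
    else:
        val = dihedral_angle(*pts)
    return InternalCoordinate(coord.kind, coord.sites, val)


def measure_all(structure: Structure,
                coords: list[InternalCoordinate]) -> list[InternalCoordinate]:
    return [measure(structure, c) for c in coords]


# ---------------------------------------------------------------------------
# connectivity and hydrogen bonds
# ---------------------------------------------------------------------------

def infer_bonds(structure: Structure, scale: float = 1.2) -> list[tuple[int, int]]:
    """Covalent bonds inferred by distance: r < scale·(r_cov,i + r_cov,j)."""
    els = structure.elements
    xyz = structure.coords
    n = len(structure)
    bonds = []
    for i in range(n):
        ri = COVALENT_RADII.get(els[i])
        if ri is None:
            continue
        d = np.linalg.norm(xyz[i + 1:] - xyz[i], axis=1)
        for k, dist in enumerate(d):
            j = i + 1 + k
            rj = COVALENT_RADII.get(els[j])
            if rj is not None and dist < scale * (ri + rj):
                bonds.append((i, j))
    return bonds


def detect_hbonds(structure: Structure,
                  max_distance: float = 3.0,
                  min_angle: float = 120.0,
                  donor_elements: tuple[str, ...] = ("N", "O"),
                  include_carbon_donors: bool = False,
                  bond_scale: float = 1.2) -> list[HBond]:
    """Geometric hydrogen-bond census.

    A hydrogen bond D–H···A is reported when H is covalently bound to a donor
    heavy atom D (element in ``donor_elements``, optionally also C), A is an N
    or O atom not covalently bound to H, the H···A distance is at most
    ``max_distance`` Å and the D–H···A angle is at least ``min_angle`` degrees.

    Structures without hydrogens yield an empty list plus a warning (not an
    error), so heavy-atom-only models degrade gracefully.
    """
    els = structure.elements
    if "H" not in els:
        warnings.warn("structure contains no hydrogen atoms; no hydrogen bonds "
                      "can be detected", stacklevel=2)
        return []
    donors = set(donor_elements) | ({"C"} if include_carbon_donors else set())
    adjacency: dict[int, set[int]] = {i: set() for i in range(len(structure))}
    for i, j in infer_bonds(structure, scale=bond_scale):
        adjacency[i].add(j)
        adjacency[j].add(i)

    acceptors = [i for i, el in enumerate(els) if el in ("N", "O")]
    out: list[HBond] = []
    for h in (i for i, el in enumerate(els) if el == "H"):
        for d in adjacency[h]:
            if els[d] not in donors:
                continue
            for a in acceptors:
                if a == d or a in adjacency[h]:
                    continue
                dist = bond_length(structure.coords[h], structure.coords[a])
                if dist > max_distance:
                    continue
                ang = bend_angle(structure.coords[d], structure.coords[h],
                                 structure.coords[a])
                if ang >= min_angle:
                    out.append(HBond(structure.labels[d], structure.labels[h],
                                     structure.labels[a], dist, ang))
    return out


def mean_hbond_distance(hbonds: list[HBond]) -> float:
    """Arithmetic mean of the H···A distances (Å)."""
    if not hbonds:
        raise GeometryError("no hydrogen bonds to average")
    return float(np.mean([hb.distance for hb in hbonds]))


# ---------------------------------------------------------------------------
# geometry comparison statistics
# ---------------------------------------------------------------------------

def wrapped_difference(a: float, b: float) -> float:
    """Minimal absolute angular distance in degrees (wraps at ±360)."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


@dataclass
class GeometryDiffReport:
    """Per-coordinate absolute differences and unsigned means per kind."""

    entries: list[dict] = field(default_factory=list)

    @property
    def means(self) -> dict[str, float]:
        out = {}
        for kind in ("bond", "angle", "dihedral"):
            diffs = [e["diff"] for e in self.entries if e["kind"] == kind]
            if diffs:
                out[kind] = float(np.mean(diffs))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)


def compare_geometries(a: list[InternalCoordinate],
                       b: list[InternalCoordinate]) -> GeometryDiffReport:
    """Pairwise unsigned differences between two matched coordinate lists.

    Coordinates are matched by (kind, site tuple).  Bond differences are plain
    absolute differences in Å; angle and dihedral differences use the minimal
    wrapped angular distance in degrees, which never exceeds 180°.
    """
    bmap = {c.key: c for c in b}
    amap = {c.key: c for c in a}
    unmatched = sorted(set(amap) ^ set(bmap))
    if unmatched:
        raise GeometryError(f"unmatched coordinate specs: {unmatched}")
    report = GeometryDiffReport()
    for c in a:
        other = bmap[c.key]
        if c.value is None or other.value is None:
            raise GeometryError(f"unmeasured coordinate {c.key}")
        if c.kind == "bond":
            diff = abs(c.value - other.value)
        else:
            diff = wrapped_difference(c.value, other.value)
        report.entries.append({
            "kind": c.kind, "sites": "-".join(c.sites),
            "a": c.value, "b": other.value, "diff": diff,
        })
    return report


# ---------------------------------------------------------------------------
# XYZ I/O
# ---------------------------------------------------------------------------

def _parse_xyz_block(lines: list[str], start: int, path: str) -> tuple[Structure, str, int]:
    if start >= len(lines):
        raise GeometryError(f"{path}: unexpected end of file at line {start + 1}")
    try:
        n = int(lines[start].split()[0])
    except (IndexError, ValueError):
        raise GeometryError(
            f"{path}: line {start + 1}: expected an atom count, got "
            f"{lines[start]!r}") from None
    comment = lines[start + 1].rstrip("\n") if start + 1 < len(lines) else ""
    labels, coords = [], []
    for k in range(n):
        ln = start + 2 + k
        if ln >= len(lines):
            raise GeometryError(f"{path}: truncated frame, expected atom at line {ln + 1}")
        parts = lines[ln].split()
        if len(parts) < 4:
            raise GeometryError(f"{path}: line {ln + 1}: malformed atom record "
                                f"{lines[ln]!r}")
        labels.append(parts[0])
        try:
            coords.append([float(x) for x in parts[1:4]])
        except ValueError:
            raise GeometryError(f"{path}: line {ln + 1}: non-numeric coordinate "
                                f"in {lines[ln]!r}") from None
    return Structure(labels, np.array(coords)), comment, start + 2 + n


def read_xyz(path) -> Structure:
    """Read a single-frame XYZ file (count / comment / element x y z)."""
    with open(path) as fh:
        lines = fh.readlines()
    if not any(ln.strip() for ln in lines):
        raise GeometryError(f"{path}: empty file")
    structure, _, _ = _parse_xyz_block(lines, 0, str(path))
    return structure


def read_xyz_frames(path) -> list[Structure]:
    """Read a multi-frame (trajectory) XYZ file."""
    with open(path) as fh:
        lines = fh.readlines()
    if not any(ln.strip() for ln in lines):
        raise GeometryError(f"{path}: empty file")
    frames = []
    pos = 0
    while pos < len(lines) and lines[pos].strip():
        structure, _, pos = _parse_xyz_block(lines, pos, str(path))
        frames.append(structure)
    return frames


def write_xyz(structure: Structure, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        _write_xyz_frame(structure, fh, comment)


def write_xyz_frames(frames: list[Structure], path, comments=None) -> None:
    comments = comments or ["" for _ in frames]
    with open(path, "w") as fh:
        for frame, comment in zip(frames, comments):
            _write_xyz_frame(frame, fh, comment)


def _write_xyz_frame(structure: Structure, fh, comment: str) -> None:
    fh.write(f"{len(structure)}\n{comment}\n")
    for lb, (x, y, z) in zip(structure.labels, structure.coords):
        fh.write(f"{lb:<4s} {x:12.6f} {y:12.6f} {z:12.6f}\n")


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)
# ---------------------------------------------------------------------------

def read_pdb(path) -> Structure:
    """Read ATOM/HETATM records of a PDB file into a :class:`Structure`.

    When alternate locations are present only the first is kept (a warning is
    issued).  Site labels are taken from the PDB atom-name column.
    """
    from biotite.structure.io.pdb import PDBFile

    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise GeometryError(f"{path}: empty file")
    altlocs = {ln[16] for ln in text.splitlines()
               if ln.startswith(("ATOM", "HETATM")) and len(ln) > 16}
    if altlocs - {" "}:
        warnings.warn(f"{path}: alternate locations present; keeping the first",
                      stacklevel=2)
    pdb = PDBFile.read(path)
    try:
        arr = pdb.get_structure(model=1, altloc="first")
    except Exception as exc:  # pragma: no cover - biotite error path
        raise GeometryError(f"{path}: malformed PDB ({exc})") from exc
    if arr.array_length() == 0:
        raise GeometryError(f"{path}: no ATOM/HETATM records")
    return Structure(list(arr.atom_name), np.array(arr.coord, dtype=float))


def write_pdb(structure: Structure, path, residue_names=None) -> None:
    """Write a structure as HETATM records (fixed PDB columns, via biotite)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(structure)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(structure.coords, dtype=np.float32)
    arr.atom_name = np.array(structure.labels, dtype="U6")
    arr.element = np.array(structure.elements, dtype="U2")
    arr.res_name = np.array(residue_names if residue_names is not None
                            else ["MOL"] * n, dtype="U5")
    arr.res_id = np.ones(n, dtype=int)
    arr.chain_id = np.array(["A"] * n, dtype="U4")
    arr.hetero = np.ones(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(path)
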