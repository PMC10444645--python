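"""PDB structures, bond topology and neighbor-pair enumeration.

Structures are ordered collections of atoms with Cartesian coordinates in
Angstroms.  PDB residue numbering (including insertion codes) is preserved
verbatim and never re-indexed.  Bond topology is inferred from covalent
radii and can be edited with explicit ADD/DEL pair directives, mirroring
the selective-deletion workflow needed for crystal structures whose
clashes masquerade as covalent bonds.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from ._elements import (
    UnknownElementError,
    covalent_radius,
    normalize_element,
)

__all__ = [
    "Atom",
    "Structure",
    "BondGraph",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "infer_topology",
    "neighbor_pairs",
    "parse_topology_edits",
]


class PDBParseError(ValueError):
    pass


@dataclasses.dataclass
class Atom:
    """One ATOM/HETATM record: identity plus Cartesian coordinates (A)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    xyz: np.ndarray
    is_het: bool = False
    insertion_code: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.serial} ({self.name}): coordinates must be a finite 3-vector")
        self.element = normalize_element(self.element)
        covalent_radius(self.element)  # raises UnknownElementError for unrecognized symbols

    @property
    def residue_id(self) -> tuple[str, int, str, str]:
        """Full residue identity: (chain, number, insertion code, name)."""
        return (self.chain_id, self.residue_number, self.insertion_code, self.residue_name)


@dataclasses.dataclass
class Structure:
    atoms: list[Atom]
    title: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a Structure must contain at least one atom")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serial numbers must be unique")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in Angstroms (a copy)."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of the structure with replaced coordinates (same atom identities)."""
        coords = np.asarray(coords, dtype=float).reshape(len(self.atoms), 3)
        atoms = [dataclasses.replace(a, xyz=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms, title=self.title)


def _prescan(lines: Sequence[str]) -> None:
    """Fail early, naming the line, on malformed fixed-width coordinates."""
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line.rstrip("\n")) < 54:
            raise PDBParseError(f"line {lineno}: record too short for coordinate fields")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            field = line[lo:hi]
            try:
                float(field)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed {what} coordinate field {field!r}"
                ) from None


def _dedup_altlocs(records: list[tuple[Atom, str]]) -> list[Atom]:
    """Keep the highest-occupancy altloc per atom site (first wins on ties)."""
    best: dict[tuple, int] = {}
    out: list[Atom | None] = []
    for atom, altloc in records:
        if altloc == "":
            out.append(atom)
            continue
        key = (*atom.residue_id, atom.name)
        if key in best:
            prev = out[best[key]]
            assert prev is not None
            if atom.occupancy > prev.occupancy:
                out[best[key]] = atom
        else:
            best[key] = len(out)
            out.append(atom)
    return [a for a in out if a is not None]


def read_pdb(path: str | Path) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    One atom per ATOM/HETATM record; the element comes from columns 77-78
    when present, otherwise it is inferred from the atom name.  Among
    alternate locations only the highest-occupancy conformer is kept
    (first on ties).  Malformed records raise :class:`PDBParseError`
    naming the offending line.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    _prescan(lines)
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    records: list[tuple[Atom, str]] = []
    model = st[0]
    for chain in model:
        for res in chain:
            for at in res:
                elem = at.element.name
                if elem in ("", "X"):
                    raise UnknownElementError(
                        f"atom serial {at.serial} {at.name!r} in {res.name} "
                        f"{chain.name}{res.seqid.num}: unknown element"
                    )
                try:
                    atom = Atom(
                        serial=at.serial,
                        name=at.name,
                        element=elem,
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        chain_id=chain.name,
                        xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        is_het=(res.het_flag == "H"),
                        insertion_code=res.seqid.icode.strip(),
                        occupancy=at.occ,
                    )
                except UnknownElementError as exc:
                    raise UnknownElementError(
                        f"atom serial {at.serial} {at.name!r} in {res.name} "
                        f"{chain.name}{res.seqid.num}: {exc}"
                    ) from None
                records.append((atom, at.altloc))
    if not records:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    atoms = _dedup_altlocs(records)
    title = ""
    for line in lines:
        if line.startswith("TITLE"):
            title = line[10:].strip()
            break
    return Structure(atoms, title=title)


def _format_atom_name(name: str, element: str) -> str:
    # one- and two-letter elements start in different columns of the name field
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write fixed-width ATOM/HETATM records (coordinates to 3 decimals)."""
    path = Path(path)
    lines = []
    if structure.title:
        lines.append(f"TITLE     {structure.title[:70]}")
    for a in structure.atoms:
        rec = "HETATM" if a.is_het else "ATOM  "
        x, y, z = a.xyz
        lines.append(
            f"{rec}{a.serial:>5d} {_format_atom_name(a.name, a.element)}"
            f" {a.residue_name:<3s} {a.chain_id:>1s}{a.residue_number:>4d}"
            f"{a.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element.upper():>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


class BondGraph:
    """Covalent bond set plus derived 1-3 and 1-4 neighbor sets."""

    def __init__(self, n_atoms: int, bonds: Iterable[tuple[int, int]]):
        self.n_atoms = int(n_atoms)
        self.bonds: set[tuple[int, int]] = set()
        for i, j in bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n_atoms and 0 <= j < n_atoms):
                raise IndexError(f"bond ({i}, {j}) references a nonexistent atom")
            self.bonds.add((min(i, j), max(i, j)))
        self._derive()

    def _derive(self) -> None:
        adj: list[set[int]] = [set() for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        self.adjacency = adj
        one_three: set[tuple[int, int]] = set()
        one_four: set[tuple[int, int]] = set()
        for j in range(self.n_atoms):
            nbrs = sorted(adj[j])
            for ii in range(len(nbrs)):
                for kk in range(ii + 1, len(nbrs)):
                    i, k = nbrs[ii], nbrs[kk]
                    if (i, k) not in self.bonds:
                        one_three.add((i, k))
        for i, j in self.bonds:
            for k in self.adjacency[j]:
                if k == i:
                    continue
                for m in self.adjacency[k]:
                    if m in (i, j):
                        continue
                    pair = (min(i, m), max(i, m))
                    if pair not in self.bonds and pair not in one_three:
                        one_four.add(pair)
            for k in self.adjacency[i]:
                if k == j:
                    continue
                for m in self.adjacency[k]:
                    if m in (i, j):
                        continue
                    pair = (min(j, m), max(j, m))
                    if pair not in self.bonds and pair not in one_three:
                        one_four.add(pair)
        self.one_three = one_three
        self.one_four = one_four
        #: pairs excluded from nonbonded sums: direct bonds and 1-3 neighbors
        self.excluded = self.bonds | self.one_three

    def bonded(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.bonds

    def angles(self) -> list[tuple[int, int, int]]:
        """All 1-3 paths as (i, center, k) triples, i < k."""
        out = []
        for j in range(self.n_atoms):
            nbrs = sorted(self.adjacency[j])
            for ii in range(len(nbrs)):
                for kk in range(ii + 1, len(nbrs)):
                    out.append((nbrs[ii], j, nbrs[kk]))
        return out


def parse_topology_edits(text: str) -> list[tuple[str, int, int]]:
    """Parse "ADD i j" / "DEL i j" directives (0-based atom indices)."""
    edits = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3 or parts[0].upper() not in ("ADD", "DEL"):
            raise ValueError(f"topology edit line {lineno}: expected 'ADD i j' or 'DEL i j'")
        edits.append((parts[0].upper(), int(parts[1]), int(parts[2])))
    return edits


def infer_topology(
    structure: Structure,
    scale: float = 1.15,
    edits: Sequence[tuple[str, int, int]] = (),
) -> BondGraph:
    """Infer covalent bonds from covalent radii, then apply explicit edits.

    Atoms i, j are bonded iff ``d(i, j) <= scale * (r_cov_i + r_cov_j)``
    (closed interval).  Edits are ("ADD"|"DEL", i, j) pairs applied
    verbatim after inference; 1-3/1-4 sets are recomputed afterwards.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    n = len(structure)
    coords = structure.coords
    radii = np.array([covalent_radius(e) for e in structure.elements])
    rmax = scale * 2.0 * radii.max()
    tree = cKDTree(coords)
    bonds: set[tuple[int, int]] = set()
    for i, j in tree.query_pairs(r=rmax * (1 + 1e-9)):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d <= scale * (radii[i] + radii[j]):
            bonds.add((min(i, j), max(i, j)))
    for op, i, j in edits:
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"topology edit {op} ({i}, {j}) references a nonexistent atom")
        pair = (min(i, j), max(i, j))
        if op == "ADD":
            bonds.add(pair)
        elif op == "DEL":
            bonds.discard(pair)
        else:
            raise ValueError(f"unknown topology edit {op!r}")
    return BondGraph(n, bonds)


def neighbor_pairs(structure: Structure, cutoff: float) -> list[tuple[int, int, float]]:
    """All unordered atom pairs with distance <= cutoff, each reported once.

    Spatial binning is used internally but the contract is set-equality
    with exhaustive enumeration (closed interval at the cutoff).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    coords = structure.coords
    tree = cKDTree(coords)
    out = []
    for i, j in sorted(tree.query_pairs(r=cutoff * (1 + 1e-9))):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d <= cutoff:
            out.append((i, j, d))
    return out
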