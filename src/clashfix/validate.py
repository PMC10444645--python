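"""Protein-geometry validation protocol.

Implements the Molprobity-style evaluation used to judge optimized
structures: overlap-based clash detection and the per-1000-atom
clashscore, Kabsch backbone RMSD, probe-augmented grid volume, a survey
of O-H...O hydrogen-bond lengths, a scan for residue-internal bond/angle
outliers, and the aggregation statistics (plain mean, count-weighted
mean, excess kurtosis) used to summarize per-protein and per-set survey
tables.

A clash is a non-bonded, non-hydrogen-bonded atom pair whose distance is
at least 0.4 A shorter than the sum of the two vdW radii; the clashscore
is the number of such pairs per 1000 atoms (hydrogens included).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from importlib import resources

import numpy as np
import pandas as pd

from ._elements import HBOND_HEAVY, POLAR_H_VDW, vdw_radius
from .structures import BondGraph, Structure, neighbor_pairs

__all__ = [
    "Clash",
    "ClashReport",
    "HBondSurvey",
    "detect_clashes",
    "atom_vdw_radii",
    "backbone_rmsd",
    "kabsch_superpose",
    "sas_volume",
    "hbond_survey",
    "geometry_outliers",
    "survey_stats",
    "load_survey_table",
    "IDEAL_GEOMETRY",
]

CLASH_THRESHOLD = 0.4  # A of vdW overlap that defines a clash


@dataclasses.dataclass(frozen=True)
class Clash:
    i: int
    j: int
    distance: float
    expected: float  # sum of vdW radii

    @property
    def overlap(self) -> float:
        return self.expected - self.distance


@dataclasses.dataclass
class ClashReport:
    clashes: list[Clash]
    atom_count: int

    @property
    def clashscore(self) -> float:
        """Clashes per 1000 atoms."""
        return 1000.0 * len(self.clashes) / self.atom_count

    def worst(self, n: int | None = None) -> list[Clash]:
        ranked = sorted(self.clashes, key=lambda c: -c.overlap)
        return ranked if n is None else ranked[:n]

    def to_tsv(self) -> str:
        lines = ["i\tj\tdistance\texpected\toverlap"]
        for c in self.worst():
            lines.append(f"{c.i}\t{c.j}\t{c.distance:.3f}\t{c.expected:.3f}\t{c.overlap:.3f}")
        lines.append(f"# atoms: {self.atom_count}  clashscore: {self.clashscore:.2f}")
        return "\n".join(lines) + "\n"


def atom_vdw_radii(structure: Structure, graph: BondGraph) -> np.ndarray:
    """Per-atom vdW radii; hydrogens bound to N/O/S get the polar-H radius."""
    radii = np.empty(len(structure))
    elements = structure.elements
    for idx, el in enumerate(elements):
        if el == "H" and any(elements[n] in HBOND_HEAVY for n in graph.adjacency[idx]):
            radii[idx] = POLAR_H_VDW
        else:
            radii[idx] = vdw_radius(el)
    return radii


def _hbond_excluded_pairs(
    structure: Structure,
    graph: BondGraph,
    max_dist: float = 2.5,
    min_angle_deg: float = 120.0,
) -> set[tuple[int, int]]:
    """Donor-H / acceptor pairs meeting the hydrogen-bond geometric criterion.

    Donor hydrogens are H atoms covalently bound to N/O/S; acceptors are
    non-bonded N/O/S atoms with H...acceptor distance <= 2.5 A and
    donor-H...acceptor angle >= 120 degrees.
    """
    coords = structure.coords
    elements = structure.elements
    excluded: set[tuple[int, int]] = set()
    donors = [
        (h, next(iter(graph.adjacency[h])))
        for h in range(len(structure))
        if elements[h] == "H"
        and len(graph.adjacency[h]) >= 1
        and elements[next(iter(graph.adjacency[h]))] in HBOND_HEAVY
    ]
    if not donors:
        return excluded
    acceptor_idx = [i for i, el in enumerate(elements) if el in HBOND_HEAVY]
    for h, d in donors:
        for a in acceptor_idx:
            if a == d or graph.bonded(h, a):
                continue
            r_ha = coords[a] - coords[h]
            dist = float(np.linalg.norm(r_ha))
            if dist > max_dist or dist == 0.0:
                continue
            r_hd = coords[d] - coords[h]
            cosang = np.dot(r_hd, r_ha) / (np.linalg.norm(r_hd) * dist)
            angle = math.degrees(math.acos(float(np.clip(cosang, -1.0, 1.0))))
            if angle >= min_angle_deg:
                excluded.add((min(h, a), max(h, a)))
    return excluded


def detect_clashes(
    structure: Structure,
    graph: BondGraph,
    radii: np.ndarray | None = None,
    hbond_exclusions: bool = True,
    threshold: float = CLASH_THRESHOLD,
) -> ClashReport:
    """Find all clashes and the clashscore of a structure.

    Candidate pairs are non-bonded pairs excluding 1-2/1-3 neighbors and,
    when ``hbond_exclusions`` is set, donor-H/acceptor pairs meeting the
    hydrogen-bond criterion.  A pair clashes iff
    ``expected - distance >= threshold`` (default 0.4 A, closed bound).
    """
    if graph.n_atoms != len(structure):
        raise ValueError("bond graph is inconsistent with the structure")
    if "H" not in structure.elements:
        warnings.warn(
            "structure contains no hydrogens; the clashscore is not comparable "
            "to the hydrogen-complete protocol",
            stacklevel=2,
        )
    if radii is None:
        radii = atom_vdw_radii(structure, graph)
    excluded = _hbond_excluded_pairs(structure, graph) if hbond_exclusions else set()
    cutoff = 2.0 * float(np.max(radii))
    clashes = []
    for i, j, d in neighbor_pairs(structure, cutoff):
        if (i, j) in graph.excluded or (i, j) in excluded:
            continue
        expected = radii[i] + radii[j]
        # tiny guard so a pair constructed exactly at the threshold is a
        # clash regardless of floating-point representation
        if expected - d >= threshold - 1e-9:
            clashes.append(Clash(i, j, d, float(expected)))
    return ClashReport(clashes, len(structure))


# ---------------------------------------------------------------- RMSD


def kabsch_superpose(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares proper rotation R and translation t mapping q onto p.

    Returns (R, t, rmsd) with reflections excluded (det R = +1).
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = qc.T @ pc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = p.mean(axis=0) - r @ q.mean(axis=0)
    moved = (r @ q.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - p) ** 2, axis=1))))
    return r, t, rmsd


BACKBONE_NAMES = ("N", "CA", "C")


def _backbone_atoms(structure: Structure) -> list[tuple[tuple, int]]:
    out = []
    for idx, a in enumerate(structure.atoms):
        if a.name in BACKBONE_NAMES and a.residue_name != "HOH":
            out.append(((a.chain_id, a.residue_number, a.insertion_code, a.name), idx))
    return out


def backbone_rmsd(a: Structure, b: Structure) -> float:
    """RMSD over matched N/CA/C backbone atoms after optimal rigid superposition.

    The two structures must yield identical ordered backbone atom lists
    (matched by chain, residue number, insertion code and atom name);
    otherwise an error names the first mismatch.
    """
    ba = _backbone_atoms(a)
    bb = _backbone_atoms(b)
    for (ka, _), (kb, _) in zip(ba, bb):
        if ka != kb:
            raise ValueError(f"backbone atom mismatch: {ka} vs {kb}")
    if len(ba) != len(bb):
        longer, shorter = (ba, bb) if len(ba) > len(bb) else (bb, ba)
        raise ValueError(f"backbone atom mismatch: unmatched {longer[len(shorter)][0]}")
    if not ba:
        raise ValueError("no backbone (N/CA/C) atoms to match")
    pa = a.coords[[i for _, i in ba]]
    pb = b.coords[[i for _, i in bb]]
    return kabsch_superpose(pa, pb)[2]


# -------------------------------------------------------------- volume


def sas_volume(
    structure: Structure,
    probe_radius: float = 1.4,
    grid_spacing: float = 0.3,
    radii: np.ndarray | None = None,
) -> float:
    """Volume (A^3) of the union of probe-augmented vdW spheres.

    Grid-occupancy estimate of the volume enclosed by the solvent-
    accessible surface; converges to the exact union volume as the grid
    spacing shrinks.
    """
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")
    if grid_spacing <= 0:
        raise ValueError("grid spacing must be positive")
    coords = structure.coords
    if radii is None:
        radii = np.array([vdw_radius(e) for e in structure.elements])
    radii = np.asarray(radii, float) + probe_radius
    lo = (coords - radii[:, None]).min(axis=0) - grid_spacing
    hi = (coords + radii[:, None]).max(axis=0) + grid_spacing
    shape = np.ceil((hi - lo) / grid_spacing).astype(int) + 1
    occupied = np.zeros(shape, dtype=bool)
    axes = [lo[k] + grid_spacing * np.arange(shape[k]) for k in range(3)]
    for center, r in zip(coords, radii):
        i0 = np.maximum(((center - r - lo) / grid_spacing).astype(int), 0)
        i1 = np.minimum(((center + r - lo) / grid_spacing).astype(int) + 2, shape)
        gx = axes[0][i0[0]:i1[0]][:, None, None]
        gy = axes[1][i0[1]:i1[1]][None, :, None]
        gz = axes[2][i0[2]:i1[2]][None, None, :]
        d2 = (gx - center[0]) ** 2 + (gy - center[1]) ** 2 + (gz - center[2]) ** 2
        occupied[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= d2 <= r * r
    return float(occupied.sum()) * grid_spacing**3


# ----------------------------------------------------- hydrogen bonds

HBOND_RANGE = (1.5, 2.5)
HBOND_BIN_WIDTH = 0.1


@dataclasses.dataclass
class HBondSurvey:
    """O-bound H ... acceptor-O distances binned over [1.5, 2.5] A."""

    bin_edges: np.ndarray
    counts: np.ndarray
    contacts: list[tuple[int, int, float]]  # (hydrogen, acceptor O, distance)
    double_donations: list[tuple[int, int]]  # (water O, acceptor O)

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)


def hbond_survey(structure: Structure, graph: BondGraph) -> HBondSurvey:
    """Survey non-covalent O-H...O contacts and doubly-donating waters.

    Collects every distance from an O-bound hydrogen to a non-bonded
    acceptor oxygen within [1.5, 2.5] A, and flags acceptor oxygens that
    receive both hydrogens of a single water (an oxygen bearing exactly
    two hydrogens and nothing else).
    """
    coords = structure.coords
    elements = structure.elements
    lo, hi = HBOND_RANGE
    edges = np.round(np.arange(lo, hi + HBOND_BIN_WIDTH / 2, HBOND_BIN_WIDTH), 10)
    contacts = []
    per_water: dict[int, dict[int, int]] = {}
    o_idx = [i for i, el in enumerate(elements) if el == "O"]
    for h in range(len(structure)):
        if elements[h] != "H":
            continue
        donors = [n for n in graph.adjacency[h] if elements[n] == "O"]
        if not donors:
            continue
        donor = donors[0]
        for acc in o_idx:
            if acc == donor or graph.bonded(h, acc):
                continue
            d = float(np.linalg.norm(coords[h] - coords[acc]))
            if lo <= d <= hi:
                contacts.append((h, acc, d))
                nbrs = graph.adjacency[donor]
                is_water = len(nbrs) == 2 and all(elements[n] == "H" for n in nbrs)
                if is_water:
                    per_water.setdefault(donor, {}).setdefault(acc, 0)
                    per_water[donor][acc] += 1
    double = sorted(
        (wo, acc)
        for wo, accs in per_water.items()
        for acc, cnt in accs.items()
        if cnt >= 2
    )
    counts, _ = np.histogram([d for _, _, d in contacts], bins=edges)
    return HBondSurvey(edges, counts, contacts, double)


# ------------------------------------------------------------ outliers

#: idealized residue-internal geometry: bond entries are
#: (resname, (name1, name2)) -> (length A, tolerance A); angle entries
#: (resname, (name1, center, name3)) -> (degrees, tolerance degrees).
#: "*" matches any residue name.  Values follow standard engh-huber-style
#: ideals for the backbone/alanine fragment plus the side-chain bonds
#: most prone to systematic stretch.
IDEAL_GEOMETRY: dict[str, dict] = {
    "bonds": {
        ("*", ("CA", "N")): (1.458, 0.025),
        ("*", ("C", "CA")): (1.525, 0.025),
        ("*", ("C", "O")): (1.231, 0.025),
        ("*", ("H", "N")): (1.010, 0.025),
        ("*", ("CA", "HA")): (1.090, 0.025),
        ("*", ("CA", "CB")): (1.521, 0.025),
        ("*", ("CB", "HB1")): (1.090, 0.025),
        ("*", ("CB", "HB2")): (1.090, 0.025),
        ("*", ("CB", "HB3")): (1.090, 0.025),
        ("HIS", ("CE1", "ND1")): (1.321, 0.025),
        ("ARG", ("CZ", "NE")): (1.326, 0.025),
    },
    "angles": {
        ("*", ("N", "CA", "C")): (111.0, 4.0),
        ("*", ("CA", "C", "O")): (120.8, 4.0),
        ("*", ("N", "CA", "CB")): (110.4, 4.0),
        ("*", ("CB", "CA", "C")): (110.5, 4.0),
        ("*", ("CA", "CB", "CG")): (113.8, 4.0),
    },
}


@dataclasses.dataclass(frozen=True)
class GeometryOutlier:
    kind: str  # "bond" or "angle"
    residue: tuple[str, int, str, str]
    atoms: tuple[str, ...]
    observed: float
    expected: float
    deviation: float


def _lookup(table: dict, resname: str, names: tuple[str, ...]):
    for res in (resname, "*"):
        for key in (names, names[::-1]):
            hit = table.get((res, key))
            if hit is not None:
                return hit
    return None


def geometry_outliers(
    structure: Structure,
    graph: BondGraph,
    reference: dict | None = None,
) -> list[GeometryOutlier]:
    """Residue-internal bonds/angles deviating beyond the reference tolerance."""
    ref = reference or IDEAL_GEOMETRY
    coords = structure.coords
    atoms = structure.atoms
    out = []
    for i, j in sorted(graph.bonds):
        if atoms[i].residue_id != atoms[j].residue_id:
            continue
        names = tuple(sorted((atoms[i].name, atoms[j].name)))
        hit = _lookup(ref["bonds"], atoms[i].residue_name, names)
        if hit is None:
            continue
        expected, tol = hit
        observed = float(np.linalg.norm(coords[i] - coords[j]))
        if abs(observed - expected) > tol:
            out.append(
                GeometryOutlier("bond", atoms[i].residue_id, names, observed, expected, observed - expected)
            )
    for i, j, k in graph.angles():
        rid = atoms[j].residue_id
        if atoms[i].residue_id != rid or atoms[k].residue_id != rid:
            continue
        names = (atoms[i].name, atoms[j].name, atoms[k].name)
        hit = _lookup(ref["angles"], atoms[j].residue_name, names)
        if hit is None:
            continue
        expected, tol = hit
        u = coords[i] - coords[j]
        v = coords[k] - coords[j]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        observed = math.degrees(math.acos(float(np.clip(cosang, -1.0, 1.0))))
        if abs(observed - expected) > tol:
            out.append(GeometryOutlier("angle", rid, names, observed, expected, observed - expected))
    return out


# ----------------------------------------------------- survey statistics


def survey_stats(
    table: pd.DataFrame,
    column: str,
    mode: str,
    counts_column: str | None = None,
    exclude_rows=None,
) -> float:
    """Aggregate one column of a survey table.

    mode "mean": arithmetic mean over included rows;
    mode "count_weighted_mean": sum(count_i * v_i) / sum(count_i);
    mode "excess_kurtosis": m4 / m2**2 - 3 on the raw value list.
    ``exclude_rows`` drops rows by index label before aggregating.
    """
    if column not in table.columns:
        raise KeyError(f"no column {column!r} in survey table")
    sub = table.drop(index=list(exclude_rows)) if exclude_rows is not None else table
    values = sub[column].to_numpy(dtype=float)
    if len(values) == 0:
        raise ValueError("empty row set after exclusions")
    if mode == "mean":
        return float(np.mean(values))
    if mode == "count_weighted_mean":
        if counts_column is None:
            raise ValueError("count_weighted_mean requires a counts column")
        counts = sub[counts_column].to_numpy(dtype=float)
        if np.any(counts <= 0):
            raise ValueError("row counts must be positive")
        return float(np.sum(counts * values) / np.sum(counts))
    if mode == "excess_kurtosis":
        centered = values - values.mean()
        m2 = np.mean(centered**2)
        m4 = np.mean(centered**4)
        return float(m4 / m2**2 - 3.0)
    raise ValueError(f"unknown mode {mode!r}")


#: shipped survey-table transcriptions (tab-separated, provenance in headers)
SURVEY_TABLES = {
    "interaction_sets": "interaction_sets.tsv",
    "protein_clashscores": "protein_clashscores.tsv",
    "protein_backbone_rmsd": "protein_backbone_rmsd.tsv",
    "protein_volumes": "protein_volumes.tsv",
}


def load_survey_table(name: str) -> pd.DataFrame:
    """Load one of the shipped published survey tables by short name."""
    try:
        fname = SURVEY_TABLES[name]
    except KeyError:
        raise KeyError(f"unknown survey table {name!r}; available: {sorted(SURVEY_TABLES)}")
    ref = resources.files("clashfix.tables").joinpath(fname)
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", index_col=0)
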