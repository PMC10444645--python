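"""Proxy reference data for diatomic vdW repulsions, weights and AUE.

A single diatomic repulsive interaction is represented by a *proxy*: two
small rigid molecules placed twice — once far apart (typically 50 A) and
once with a designated atom of each molecule at the vdW contact distance,
oriented so that the designated pair is strictly the nearest cross-pair.
The energy difference between the two placements isolates that one
diatomic interaction and serves as its training observation.

Training observations carry class-dependent dimensionless-making weights
(1/(kcal/mol)): ordinary heats of formation ~1, hydrogen bonds ~10, and
clash proxies 30 rising to at most 100, reflecting how minute the
energies at 2.5-3 A separations are and how few proxy data exist
relative to conventional reference data.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from ._elements import vdw_radius
from .structures import Atom, BondGraph, Structure, infer_topology
from .surrogate import SurrogateModel, surrogate_energy

__all__ = [
    "RIGID_MOLECULES",
    "ProxySpec",
    "ReferenceDatum",
    "SurveySet",
    "OrientationError",
    "rigid_molecule",
    "build_proxy_pair",
    "combine",
    "proxy_datum",
    "assign_weight",
    "set_aue",
    "DATUM_CLASSES",
]

#: rigid idealized geometries (element, atom name, xyz in A) from standard
#: experimental bond lengths/angles for the proxy-system library
_DEG = np.pi / 180.0


def _bent(center_el, h_len, angle_deg, center_name, h_names):
    half = angle_deg * _DEG / 2.0
    return [
        (center_el, center_name, (0.0, 0.0, 0.0)),
        ("H", h_names[0], (h_len * np.cos(half), h_len * np.sin(half), 0.0)),
        ("H", h_names[1], (h_len * np.cos(half), -h_len * np.sin(half), 0.0)),
    ]


def _nh3():
    # N-H 1.012 A, H-N-H 106.7 deg -> H's on a cone about the C3 axis
    r, hnh = 1.012, 106.7 * _DEG
    # cone half-angle beta about the C3 axis giving the H-N-H angle:
    # sin(beta) = sin(hnh/2) / sin(60 deg)
    beta = np.arcsin(np.sin(hnh / 2.0) / np.sin(60.0 * _DEG))
    atoms = [("N", "N", (0.0, 0.0, 0.0))]
    for k, name in enumerate(("H1", "H2", "H3")):
        phi = k * 120.0 * _DEG
        atoms.append(
            ("H", name, (r * np.cos(beta), r * np.sin(beta) * np.cos(phi), r * np.sin(beta) * np.sin(phi)))
        )
    return atoms


RIGID_MOLECULES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "H2": [("H", "H1", (0.0, 0.0, 0.0)), ("H", "H2", (0.741, 0.0, 0.0))],
    "N2": [("N", "N1", (0.0, 0.0, 0.0)), ("N", "N2", (1.098, 0.0, 0.0))],
    "CO2": [
        ("O", "O1", (-1.162, 0.0, 0.0)),
        ("C", "C", (0.0, 0.0, 0.0)),
        ("O", "O2", (1.162, 0.0, 0.0)),
    ],
    "HNC": [
        ("H", "H", (-0.996, 0.0, 0.0)),
        ("N", "N", (0.0, 0.0, 0.0)),
        ("C", "C", (1.169, 0.0, 0.0)),
    ],
    "NH3": _nh3(),
    "H2O": _bent("O", 0.958, 104.5, "O", ("H1", "H2")),
    "H2S": _bent("S", 1.336, 92.1, "S", ("H1", "H2")),
}


class OrientationError(ValueError):
    pass


def rigid_molecule(name: str, chain_id: str = "A", serial_start: int = 1) -> Structure:
    """Instantiate a library molecule as a single-residue HETATM Structure."""
    try:
        spec = RIGID_MOLECULES[name]
    except KeyError:
        raise KeyError(f"molecule {name!r} not in the rigid library: {sorted(RIGID_MOLECULES)}")
    atoms = [
        Atom(
            serial=serial_start + k,
            name=atom_name,
            element=el,
            residue_name="LIG",
            residue_number=1,
            chain_id=chain_id,
            xyz=np.array(xyz),
            is_het=True,
        )
        for k, (el, atom_name, xyz) in enumerate(spec)
    ]
    return Structure(atoms, title=name)


@dataclasses.dataclass
class ProxySpec:
    """Geometry recipe for one diatomic proxy system."""

    pair: tuple[str, str]  # element pair represented, e.g. ("O", "H")
    molecule_a: str
    molecule_b: str
    contact_atom_a: int  # atom index within molecule A
    contact_atom_b: int
    contact_separation: float | None = None  # A; default: sum of vdW radii
    reference_separation: float = 50.0

    def __post_init__(self) -> None:
        if self.contact_separation is None:
            self.contact_separation = vdw_radius(self.pair[0]) + vdw_radius(self.pair[1])
        if not self.contact_separation < self.reference_separation:
            raise ValueError("contact separation must be below the reference separation")


def _align_to_axis(coords: np.ndarray, pivot: int, direction: np.ndarray) -> np.ndarray:
    """Rotate so (coords[pivot] - centroid) points along ``direction``; pivot at origin."""
    centroid = coords.mean(axis=0)
    v = coords[pivot] - centroid
    nv = np.linalg.norm(v)
    if nv < 1e-9:
        raise OrientationError("contact atom coincides with the molecular centroid")
    v = v / nv
    d = direction / np.linalg.norm(direction)
    cross = np.cross(v, d)
    dot = float(np.dot(v, d))
    if np.linalg.norm(cross) < 1e-12:
        rot = np.eye(3) if dot > 0 else np.diag([1.0, -1.0, -1.0]) @ _flip_about(v)
    else:
        k = cross / np.linalg.norm(cross)
        theta = np.arccos(np.clip(dot, -1.0, 1.0))
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        rot = np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)
    out = (rot @ (coords - coords[pivot]).T).T
    return out


def _flip_about(v: np.ndarray) -> np.ndarray:
    # 180-degree rotation about any axis perpendicular to v
    perp = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(perp, v)) > 0.9:
        perp = np.array([0.0, 1.0, 0.0])
    axis = np.cross(v, perp)
    axis /= np.linalg.norm(axis)
    return 2.0 * np.outer(axis, axis) - np.eye(3)


def _place(spec: ProxySpec, separation: float, audit: bool) -> Structure:
    mol_a = rigid_molecule(spec.molecule_a, chain_id="A", serial_start=1)
    mol_b = rigid_molecule(spec.molecule_b, chain_id="B", serial_start=len(mol_a) + 1)
    ca, cb = spec.contact_atom_a, spec.contact_atom_b
    if not (0 <= ca < len(mol_a)) or not (0 <= cb < len(mol_b)):
        raise IndexError("contact atom index outside the molecule")
    xa = _align_to_axis(mol_a.coords, ca, np.array([1.0, 0.0, 0.0]))
    xb = _align_to_axis(mol_b.coords, cb, np.array([-1.0, 0.0, 0.0]))
    xb = xb + np.array([separation, 0.0, 0.0])
    atoms = []
    for atom, xyz in zip(mol_a.atoms, xa):
        atoms.append(dataclasses.replace(atom, xyz=xyz.copy()))
    for atom, xyz in zip(mol_b.atoms, xb):
        atoms.append(dataclasses.replace(atom, xyz=xyz.copy()))
    out = Structure(atoms, title=f"{spec.molecule_a}-{spec.molecule_b}")
    if audit:
        na = len(mol_a)
        coords = out.coords
        for i in range(na):
            for j in range(na, len(out)):
                if (i, j) == (ca, na + cb):
                    continue
                d = float(np.linalg.norm(coords[i] - coords[j]))
                if d < separation + 0.5:
                    raise OrientationError(
                        f"orientation constraint unsatisfiable: cross pair "
                        f"({out.atoms[i].name}, {out.atoms[j].name}) at {d:.3f} A is "
                        f"within 0.5 A of the contact-pair distance {separation:.3f} A"
                    )
    return out


def build_proxy_pair(spec: ProxySpec) -> tuple[Structure, Structure]:
    """(contact geometry, separated geometry) for a proxy spec.

    The two contact atoms lie on the intermolecular axis at the requested
    separation and are audited to be strictly the nearest cross-molecule
    pair, every other cross pair being at least 0.5 A further away.
    """
    contact = _place(spec, float(spec.contact_separation), audit=True)
    separated = _place(spec, float(spec.reference_separation), audit=False)
    return contact, separated


def combine(*placed: Structure, title: str = "") -> Structure:
    """Concatenate structures into one, re-serializing atoms."""
    atoms = []
    serial = 1
    for s in placed:
        for a in s.atoms:
            atoms.append(dataclasses.replace(a, serial=serial))
            serial += 1
    return Structure(atoms, title=title)


DATUM_CLASSES = ("heat_of_formation", "hydrogen_bond", "clash_proxy", "interaction")

_CLASS_WEIGHTS = {
    "heat_of_formation": 1.0,
    "hydrogen_bond": 10.0,
    "clash_proxy": 30.0,  # adjustable upward to 100 by the reweighting loop
    "interaction": 10.0,
}

CLASH_WEIGHT_CEILING = 100.0


def assign_weight(datum_class: str) -> float:
    """Initial dimensionless-making weight (1/(kcal/mol)) for a datum class."""
    try:
        return _CLASS_WEIGHTS[datum_class]
    except KeyError:
        raise ValueError(f"unknown datum class {datum_class!r}; expected one of {DATUM_CLASSES}")


@dataclasses.dataclass
class ReferenceDatum:
    """One training observation.

    ``payload`` is one of
      ("difference", (s1, g1), (s0, g0))            -> E(s1) - E(s0)
      ("single", (s, g))                            -> E(s)
      ("interaction", (c, gc), (a, ga), (b, gb))    -> E(c) - E(a) - E(b)
    evaluated under the surrogate model handed to :meth:`predict`.
    """

    id: str
    datum_class: str
    reference: float  # kcal/mol
    weight: float  # 1/(kcal/mol)
    payload: tuple
    element_pair: Optional[tuple[str, str]] = None  # for clash proxies

    def __post_init__(self) -> None:
        if self.datum_class not in DATUM_CLASSES:
            raise ValueError(f"unknown datum class {self.datum_class!r}")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")
        if self.element_pair is not None:
            self.element_pair = tuple(sorted(self.element_pair))  # type: ignore[assignment]

    def predict(self, model: SurrogateModel) -> float:
        """Predicted value (kcal/mol) under the given model parameters."""
        m = model.replace(bond_refs=None, angle_refs=None)  # bind refs per payload geometry

        def e(pair):
            return surrogate_energy(pair[0], pair[1], m)[0]

        kind = self.payload[0]
        if kind == "difference":
            return e(self.payload[1]) - e(self.payload[2])
        if kind == "single":
            return e(self.payload[1])
        if kind == "interaction":
            return e(self.payload[1]) - e(self.payload[2]) - e(self.payload[3])
        raise ValueError(f"unknown payload kind {kind!r}")


def proxy_datum(spec: ProxySpec, model: SurrogateModel, target: float) -> ReferenceDatum:
    """Clash-proxy datum whose prediction is E(contact) - E(separated)."""
    contact, separated = build_proxy_pair(spec)
    g1 = infer_topology(contact)
    g0 = infer_topology(separated)
    pair = tuple(sorted(spec.pair))
    return ReferenceDatum(
        id=f"proxy:{pair[0]}-{pair[1]}:{spec.molecule_a}-{spec.molecule_b}:{spec.contact_separation:.3f}",
        datum_class="clash_proxy",
        reference=float(target),
        weight=assign_weight("clash_proxy"),
        payload=("difference", (contact, g1), (separated, g0)),
        element_pair=pair,  # type: ignore[arg-type]
    )


def set_aue(predictions: Sequence[float], references: Sequence[float]) -> float:
    """Average unsigned error: mean |prediction - reference| in kcal/mol."""
    p = np.asarray(predictions, dtype=float)
    r = np.asarray(references, dtype=float)
    if p.shape != r.shape:
        raise ValueError("prediction and reference lists must have equal length")
    if p.size == 0:
        raise ValueError("cannot compute the AUE of an empty set")
    return float(np.mean(np.abs(p - r)))


@dataclasses.dataclass
class SurveySet:
    """A labeled set of interaction-energy records for AUE accounting."""

    name: str
    records: list[tuple]  # ((complex, gc), (a, ga), (b, gb), reference kcal/mol)

    @property
    def count(self) -> int:
        return len(self.records)

    def references(self) -> list[float]:
        return [rec[3] for rec in self.records]

    def predictions(self, model: SurrogateModel) -> list[float]:
        from .surrogate import interaction_energy

        out = []
        for (c, gc), (a, ga), (b, gb), _ in self.records:
            out.append(interaction_energy(c, gc, a, ga, b, gb, model))
        return out

    def aue(self, model: SurrogateModel) -> float:
        return set_aue(self.predictions(model), self.references())
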