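"""Deterministic generators for every fixture the toolkit needs.

Three families:

* rigid small-molecule dimers — the proxy systems of the training set
  (the canonical diatomic pairs are in :data:`CANONICAL_PROXIES`);
* miniature protein-like chains — extended poly-alanine built from
  idealized internal geometry, optionally with clashes planted at exact
  vdW overlaps (the construction ledger lists precisely the planted
  pairs, so detector output can be cross-checked pair for pair);
* synthetic interaction-energy survey sets — dimers sampled across the
  attractive wells and up the repulsive walls of a surrogate model
  (repulsive points sit about 2 kcal/mol above the separated monomers),
  with reference values equal to true model energies plus seeded
  Gaussian noise.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from ._elements import vdw_radius
from .refdata import (
    ProxySpec,
    ReferenceDatum,
    SurveySet,
    _place,
    assign_weight,
    build_proxy_pair,
    proxy_datum,
)
from .repulsion import PairRepulsionParams, RepulsionParamSet
from .structures import Atom, BondGraph, Structure, infer_topology
from .surrogate import SurrogateModel, Well, interaction_energy
from .validate import atom_vdw_radii, detect_clashes

__all__ = [
    "CANONICAL_PROXIES",
    "make_dimer",
    "make_toy_chain",
    "make_survey_set",
    "pathological_model",
    "make_training_set",
    "make_recovery_training",
]

#: the six diatomic clash pairs and their proxy molecule pairs:
#: element pair -> (molecule_a, contact atom index, molecule_b, contact atom index)
CANONICAL_PROXIES: dict[tuple[str, str], tuple[str, int, str, int]] = {
    ("H", "H"): ("H2", 0, "H2", 0),
    ("C", "H"): ("HNC", 2, "H2", 0),
    ("C", "O"): ("HNC", 2, "CO2", 0),
    ("O", "H"): ("CO2", 0, "H2", 0),
    ("N", "O"): ("NH3", 0, "CO2", 0),
    ("O", "S"): ("H2S", 0, "CO2", 0),
}

#: additional pairs needed to cover every contact type that arises in the
#: protein-like test chains (the published table lists examples only; the
#: proxy construction is extensible to any pair the clash survey turns up)
EXTENDED_PROXIES: dict[tuple[str, str], tuple[str, int, str, int]] = {
    ("H", "N"): ("N2", 0, "H2", 0),
    ("C", "C"): ("HNC", 2, "HNC", 2),
    ("C", "N"): ("HNC", 2, "N2", 0),
    ("O", "O"): ("CO2", 0, "CO2", 0),
    ("N", "N"): ("N2", 0, "N2", 0),
}

#: full proxy library: canonical six plus chain-coverage extensions
ALL_PROXIES: dict[tuple[str, str], tuple[str, int, str, int]] = {
    **CANONICAL_PROXIES,
    **EXTENDED_PROXIES,
}


def canonical_spec(pair: tuple[str, str], contact_separation: float | None = None) -> ProxySpec:
    key = tuple(sorted(pair))
    for (e1, e2), (ma, ia, mb, ib) in ALL_PROXIES.items():
        if tuple(sorted((e1, e2))) == key:
            return ProxySpec(
                pair=(e1, e2),
                molecule_a=ma,
                molecule_b=mb,
                contact_atom_a=ia,
                contact_atom_b=ib,
                contact_separation=contact_separation,
            )
    raise KeyError(f"no canonical proxy system for element pair {pair}")


def make_dimer(
    pair: tuple[str, str],
    contact_separation: float | None = None,
    seed: int = 0,
) -> tuple[Structure, Structure, ProxySpec]:
    """(contact, separated, spec) for a canonical diatomic proxy pair.

    Purely deterministic; the seed is accepted for interface uniformity.
    """
    spec = canonical_spec(pair, contact_separation)
    contact, separated = build_proxy_pair(spec)
    return contact, separated, spec


# ------------------------------------------------------------ toy chains

# idealized internal geometry (consistent with validate.IDEAL_GEOMETRY)
_B = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,
    "C-O": 1.231,
    "N-H": 1.010,
    "CA-HA": 1.090,
    "CA-CB": 1.521,
    "CB-HB": 1.090,
}
_A = {
    "N-CA-C": 111.0,
    "CA-C-N": 116.2,
    "C-N-CA": 121.7,
    "CA-C-O": 120.8,
    "C-N-H": 119.2,
    "N-CA-CB": 110.4,
    "N-CA-HA": 108.0,
    "CA-CB-HB": 109.5,
}
# extended (beta-strand-like) backbone, clash-free by construction with a
# comfortable margin to the 0.4 A clash threshold (the nearest non-bonded
# pair, the peptide-unit O...CA 1-4 contact, overlaps by 0.377 A).  The
# builder's torsion parameter is the negative of the measured dihedral,
# so these produce (phi, psi) = (-150, 140).
_PHI, _PSI, _OMEGA = 150.0, -140.0, 180.0


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given chain A-B-C, |CD|, angle BCD and torsion ABCD."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            -bond * math.sin(ang) * math.sin(tor),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d2


def _plant_position(
    coords: np.ndarray,
    graph: BondGraph,
    radii: np.ndarray,
    h: int,
    o: int,
    parent: int,
    target: float,
    bond_ideal: float,
    max_stretch: float = 0.75,
    clearance: float = 0.35,
) -> np.ndarray | None:
    """Position for atom ``h`` at exactly ``target`` from ``o`` that neither
    over-stretches the bond to ``parent`` nor grazes any third atom.

    Candidate directions are a deterministic Fibonacci sphere around the
    acceptor, ranked by closeness to the original approach direction.
    """
    orig_dir = coords[h] - coords[o]
    orig_dir = orig_dir / np.linalg.norm(orig_dir)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    npts = 200
    ks = np.arange(npts)
    z = 1.0 - 2.0 * (ks + 0.5) / npts
    rad = np.sqrt(1.0 - z**2)
    theta = golden * ks
    dirs = np.column_stack([rad * np.cos(theta), rad * np.sin(theta), z])
    order = np.argsort(-dirs @ orig_dir)
    for d in dirs[order]:
        cand = coords[o] + target * d
        if abs(np.linalg.norm(cand - coords[parent]) - bond_ideal) > max_stretch:
            continue
        ok = True
        for m in range(len(coords)):
            if m in (h, o) or (min(h, m), max(h, m)) in graph.excluded:
                continue
            if radii[h] + radii[m] - float(np.linalg.norm(cand - coords[m])) >= clearance:
                ok = False
                break
        if ok:
            return cand
    return None


def make_toy_chain(
    residues: int,
    planted_clashes: int = 0,
    overlaps: tuple[float, ...] = (),
    seed: int = 0,
) -> tuple[Structure, BondGraph, list[tuple[int, int, float]]]:
    """Extended poly-alanine chain with optional planted vdW clashes.

    Returns (structure, bond graph, ledger); the ledger lists exactly the
    planted pairs as (i, j, overlap).  Clashes are planted by displacing
    a carbon-bound hydrogen toward a backbone oxygen until the pair
    overlap equals the requested value; a planting that would stretch the
    hydrogen off its bond by more than 0.75 A is rejected as
    geometrically impossible.
    """
    if residues < 2:
        raise ValueError("need at least 2 residues")
    if planted_clashes and len(overlaps) != planted_clashes:
        raise ValueError("one overlap value per planted clash required")
    if any(o < 0.4 for o in overlaps):
        raise ValueError("planted overlaps must be at least 0.4 A (the clash threshold)")

    atoms: list[Atom] = []
    serial = 1

    def add(name: str, element: str, xyz: np.ndarray, resnum: int) -> int:
        nonlocal serial
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=element,
                residue_name="ALA",
                residue_number=resnum,
                chain_id="A",
                xyz=np.asarray(xyz, float),
            )
        )
        serial += 1
        return len(atoms) - 1

    # first residue backbone, in the xy plane
    n_xyz = np.zeros(3)
    ca_xyz = np.array([_B["N-CA"], 0.0, 0.0])
    ang = math.radians(_A["N-CA-C"])
    c_xyz = ca_xyz + _B["CA-C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    backbone = [(n_xyz, ca_xyz, c_xyz)]
    for _ in range(residues - 1):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_next = _nerf(n_prev, ca_prev, c_prev, _B["C-N"], _A["CA-C-N"], _PSI)
        ca_next = _nerf(ca_prev, c_prev, n_next, _B["N-CA"], _A["C-N-CA"], _OMEGA)
        c_next = _nerf(c_prev, n_next, ca_next, _B["CA-C"], _A["N-CA-C"], _PHI)
        backbone.append((n_next, ca_next, c_next))

    for ri, (n_xyz, ca_xyz, c_xyz) in enumerate(backbone, start=1):
        i_n = add("N", "N", n_xyz, ri)
        add("CA", "C", ca_xyz, ri)
        add("C", "C", c_xyz, ri)
        # carbonyl O: anti to the next amide nitrogen (torsion psi + 180)
        add("O", "O", _nerf(n_xyz, ca_xyz, c_xyz, _B["C-O"], _A["CA-C-O"], _PSI + 180.0), ri)
        if ri > 1:
            c_prev = backbone[ri - 2][2]
            add("H", "H", _nerf(c_prev, ca_xyz, n_xyz, _B["N-H"], _A["C-N-H"], 180.0), ri)
        ha = _nerf(c_xyz, n_xyz, ca_xyz, _B["CA-HA"], _A["N-CA-HA"], 240.0)
        add("HA", "H", ha, ri)
        cb = _nerf(c_xyz, n_xyz, ca_xyz, _B["CA-CB"], _A["N-CA-CB"], 120.0)
        i_cb = add("CB", "C", cb, ri)
        for k, hb_name in enumerate(("HB1", "HB2", "HB3")):
            hb = _nerf(n_xyz, ca_xyz, cb, _B["CB-HB"], _A["CA-CB-HB"], 60.0 + 120.0 * k)
            add(hb_name, "H", hb, ri)

    structure = Structure(atoms, title=f"toy-chain-{residues}")
    graph = infer_topology(structure)
    ledger: list[tuple[int, int, float]] = []
    if planted_clashes:
        coords = structure.coords
        elements = structure.elements
        radii = atom_vdw_radii(structure, graph)
        h_idx = [
            i
            for i in range(len(structure))
            if elements[i] == "H"
            and any(elements[nb] == "C" for nb in graph.adjacency[i])
        ]
        o_idx = [i for i, el in enumerate(elements) if el == "O"]
        candidates = []
        for h in h_idx:
            for o in o_idx:
                pair = (min(h, o), max(h, o))
                if pair in graph.excluded:
                    continue
                d = float(np.linalg.norm(coords[h] - coords[o]))
                candidates.append((d, h, o))
        candidates.sort()  # nearest eligible pairs are planted first (deterministic)
        chosen: list[tuple[int, int]] = []
        used: set[int] = set()
        k = 0
        for d, h, o in candidates:
            if k >= planted_clashes:
                break
            if h in used or o in used:
                continue
            overlap = overlaps[k]
            target = radii[h] + radii[o] - overlap
            parent = next(nb for nb in graph.adjacency[h] if elements[nb] == "C")
            new_h = _plant_position(
                coords, graph, radii, h, o, parent, target, _B["CB-HB"]
            )
            if new_h is None:
                continue
            coords[h] = new_h
            used.update((h, o))
            chosen.append((h, o))
            ledger.append((min(h, o), max(h, o), overlap))
            k += 1
        if k < planted_clashes:
            raise ValueError(
                f"geometrically impossible planting: only {k} of {planted_clashes} "
                "requested clashes could be placed without breaking a bond"
            )
        structure = structure.with_coords(coords)
    return structure, graph, ledger


# ------------------------------------------------- surrogate + training


def pathological_model() -> SurrogateModel:
    """Surrogate lacking long-range repulsion, with an overshooting O...H well.

    The oxygen-hydrogen attraction well optimum (2.0 A) sits inside the
    O/H vdW contact distance minus the 0.4 A clash threshold, so
    unconstrained geometry optimization pulls hydrogens onto carbonyl
    oxygens and, through the backbone's coupling, drags further pairs
    into clashes — the pathology that a long-range repulsion term cures.
    """
    return SurrogateModel(
        wells={("O", "H"): Well(depth=1.2, r_opt=2.0, width=2.0)},
        softcore_scale=4.0,
        softcore_exponent=4,
    )


#: parameter bounds used when fitting against the toy-chain study
#: conditions: the width is kept in a physically sensible window so the
#: term keeps a vdW-scale onset, and the switch distance near contact
LOOP_BOUNDS = {"b": (0.5, 2.0), "c": (1.5, 4.2)}


def chain_optimizer_settings() -> "OptimizerSettings":
    """Optimizer settings used for the toy-chain geometry optimizations."""
    from .surrogate import OptimizerSettings

    return OptimizerSettings(max_cycles=4000, energy_tol=1e-7, max_step=0.1)


def make_test_chains(
    n_chains: int = 2,
    residues: int = 6,
    perturbation: float = 0.03,
    seed: int = 0,
) -> list[tuple[Structure, BondGraph]]:
    """Seeded toy-chain starting geometries for optimization studies.

    Each chain is the clean extended conformation with a small Gaussian
    coordinate perturbation (sigma in A) so replicate chains explore
    slightly different descent paths.
    """
    base, graph, _ = make_toy_chain(residues)
    out = []
    for k in range(n_chains):
        rng = np.random.default_rng(seed + k)
        coords = base.coords + perturbation * rng.normal(size=(len(base), 3))
        out.append((base.with_coords(coords), graph))
    return out


def default_init_params(pairs=None, a0: float = 0.5, b0: float = 1.2) -> RepulsionParamSet:
    """Initial repulsion parameters: plateau at the vdW contact distance."""
    out = RepulsionParamSet()
    for pair in pairs or ALL_PROXIES:
        c0 = vdw_radius(pair[0]) + vdw_radius(pair[1])
        out.add(PairRepulsionParams(pair, a0, b0, c0))
    return out


def _difference_datum(
    datum_id: str,
    datum_class: str,
    spec: ProxySpec,
    base: SurrogateModel,
    reference: float | None,
) -> ReferenceDatum:
    contact, separated = build_proxy_pair(spec)
    g1, g0 = infer_topology(contact), infer_topology(separated)
    if reference is None:
        from .surrogate import surrogate_energy

        m = base.replace(bond_refs=None, angle_refs=None, repulsion=None)
        reference = (
            surrogate_energy(contact, g1, m)[0] - surrogate_energy(separated, g0, m)[0]
        )
    return ReferenceDatum(
        id=datum_id,
        datum_class=datum_class,
        reference=float(reference),
        weight=assign_weight(datum_class),
        payload=("difference", (contact, g1), (separated, g0)),
    )


def make_training_set(
    model: SurrogateModel,
    proxy_target: float = 2.5,
    n_hbond_anchors: int = 4,
    n_far_anchors: int = 6,
    seed: int = 0,
) -> list[ReferenceDatum]:
    """Clash proxies for every covered pair plus conventional anchor data.

    Three layers, mirroring the composition of a real training set:

    * clash proxies (weight 30, one per element pair) carrying the
      requested repulsion target at the vdW contact distance;
    * hydrogen-bond-like anchors (weight 10): attractive O...H dimer
      placements inside the well region whose references are the true
      energies of the repulsion-free model — the bulk of the set, which
      any repulsion leakage into binding energetics must fight;
    * far anchors (weight 1): placements in the 3.3-4.5 A decay region,
      likewise with repulsion-free references, which pin the switch
      distance and width so the term genuinely decays.
    """
    base = model.replace(repulsion=None)
    training: list[ReferenceDatum] = []
    for pair in ALL_PROXIES:
        training.append(proxy_datum(canonical_spec(pair), base, proxy_target))
    rng = np.random.default_rng(seed)
    well = base.wells.get(("H", "O")) or base.wells.get(("O", "H"))
    r_anchor = well.r_opt if well is not None else 2.0
    for k in range(n_hbond_anchors):
        sep = float(r_anchor + 0.2 * rng.uniform(-1.0, 1.0))
        spec = canonical_spec(("O", "H"), contact_separation=sep)
        training.append(_difference_datum(f"anchor:hb:{k}:{sep:.3f}", "hydrogen_bond", spec, base, None))
    for k in range(n_far_anchors):
        sep = float(rng.uniform(3.3, 4.5))
        spec = canonical_spec(("O", "H"), contact_separation=sep)
        training.append(_difference_datum(f"anchor:far:{k}:{sep:.3f}", "heat_of_formation", spec, base, None))
    return training


def make_recovery_training(
    true_params: PairRepulsionParams,
    separations: tuple[float, ...] = (),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[list[ReferenceDatum], SurrogateModel]:
    """Training data generated from known (a, b, c) for parameter recovery.

    Proxy data at several contact separations spanning the plateau and the
    decay region of the true term; references are the true model's proxy
    energies plus seeded Gaussian noise.  Returns (training, bare model).
    """
    pair = true_params.element_pair
    c = true_params.c
    if not separations:
        separations = (0.75 * c, 0.95 * c, c + 0.15, c + 0.35, c + 0.6, c + 0.9)
    bare = SurrogateModel(wells={}, softcore_scale=0.0)
    truth = bare.replace(repulsion=RepulsionParamSet([true_params]))
    rng = np.random.default_rng(seed)
    training = []
    for sep in separations:
        spec = canonical_spec(pair, contact_separation=float(sep))
        datum = proxy_datum(spec, bare, target=0.0)
        datum.reference = datum.predict(truth) + (rng.normal(0.0, noise_sigma) if noise_sigma else 0.0)
        training.append(datum)
    return training, bare


def make_survey_set(
    n_records: int,
    noise_sigma: float,
    seed: int,
    model: SurrogateModel,
    repulsive_fraction: float = 0.3,
) -> tuple[SurveySet, list[float], list[str]]:
    """Synthetic interaction-energy survey set with known truths.

    Attractive records place a canonical dimer at separations around its
    well region; repulsive records push the dimer up the wall until the
    true interaction energy is about +2 kcal/mol above the separated
    monomers (found by bisection).  Returns (set, true energies, kinds).
    """
    if n_records < 1:
        raise ValueError("need at least one record")
    rng = np.random.default_rng(seed)
    pairs = list(CANONICAL_PROXIES)
    records = []
    truths: list[float] = []
    kinds: list[str] = []

    def interaction_at(spec: ProxySpec, sep: float) -> tuple:
        placed = _place(spec, sep, audit=False)
        from .refdata import rigid_molecule

        n_a = len(rigid_molecule(spec.molecule_a))
        a_struct = Structure([dataclasses.replace(x) for x in placed.atoms[:n_a]], title="a")
        b_struct = Structure([dataclasses.replace(x) for x in placed.atoms[n_a:]], title="b")
        ga = infer_topology(a_struct)
        gb = infer_topology(b_struct)
        # rigid molecules keep their own topology at any separation: the
        # complex graph is the union of the monomer graphs, never re-inferred
        gc = BondGraph(
            len(placed),
            list(ga.bonds) + [(i + n_a, j + n_a) for i, j in gb.bonds],
        )
        e = interaction_energy(placed, gc, a_struct, ga, b_struct, gb, model)
        return e, (placed, gc), (a_struct, ga), (b_struct, gb)

    n_rep = int(round(repulsive_fraction * n_records))
    for k in range(n_records):
        pair = pairs[int(rng.integers(len(pairs)))]
        spec = canonical_spec(pair)
        contact = float(spec.contact_separation)
        if k < n_rep:
            # bisect on the inner wall for a true interaction energy of
            # +2 kcal/mol above the well-separated components (zero)
            lo, hi = 0.3 * contact, 1.2 * contact
            target = 2.0
            for _ in range(50):
                mid = 0.5 * (lo + hi)
                if interaction_at(spec, mid)[0] > target:
                    lo = mid
                else:
                    hi = mid
            sep = 0.5 * (lo + hi)
            kind = "repulsive"
        else:
            sep = float(contact * rng.uniform(0.85, 1.45))
            kind = "attractive"
        e, c_pair, a_pair, b_pair = interaction_at(spec, sep)
        truths.append(e)
        kinds.append(kind)
        ref = e + (float(rng.normal(0.0, noise_sigma)) if noise_sigma else 0.0)
        records.append((c_pair, a_pair, b_pair, ref))
    return SurveySet("synthetic-survey", records), truths, kinds
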