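"""A toy baseline energy model plus geometry optimizer.

The surrogate is a deliberately simple molecular-mechanics-style energy:
harmonic bonds, harmonic 1-3 angles, Gaussian attraction wells between
configured non-bonded element pairs, a soft-core r**-p very-short-range
term, and (optionally) the piecewise-Gaussian vdW repulsion term.  Its
defining property is what it *lacks* by default: any long-range repulsion
around the vdW contact distance.  Attraction wells whose optimum lies
inside the contact distance therefore pull non-bonded pairs into clashes
during geometry optimization — the pathology the repulsion term exists to
cure.  Torsions are unrestrained, so the softest coordinates (side-chain
and backbone rotations) move first, as they do in real structures.

Reference bond lengths and angles are captured from a structure's own
geometry via :meth:`SurrogateModel.with_reference`, so a clean input
geometry is a harmonic minimum by construction.

The optimizer is a limited-memory BFGS with Armijo backtracking (factor
0.5) and a stall-based stopping rule: iteration ends once the best energy
has not improved by more than the tolerance over a window of cycles
(default 60).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .repulsion import RepulsionParamSet
from .structures import BondGraph, Structure

__all__ = [
    "Well",
    "SurrogateModel",
    "OptimizerSettings",
    "Trajectory",
    "NonFiniteEnergyError",
    "surrogate_energy",
    "optimize_geometry",
    "interaction_energy",
]


class NonFiniteEnergyError(RuntimeError):
    """Raised when the energy turns non-finite; carries the last good geometry."""

    def __init__(self, message: str, last_good: Optional[Structure] = None):
        super().__init__(message)
        self.last_good = last_good


def _canonical_pair(e1: str, e2: str) -> tuple[str, str]:
    return (e1, e2) if e1 <= e2 else (e2, e1)


@dataclasses.dataclass(frozen=True)
class Well:
    """Gaussian attraction well: E(r) = -depth * exp(-width * (r - r_opt)**2)."""

    depth: float  # kcal/mol, >= 0
    r_opt: float  # A
    width: float  # 1/A^2

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("well depth must be non-negative")
        if self.width <= 0 or self.r_opt <= 0:
            raise ValueError("well optimum distance and width must be positive")


@dataclasses.dataclass
class SurrogateModel:
    bond_k: float = 300.0  # kcal/mol/A^2
    angle_k: float = 50.0  # kcal/mol/rad^2
    wells: dict[tuple[str, str], Well] = dataclasses.field(default_factory=dict)
    softcore_scale: float = 4.0  # kcal/mol * A^p
    softcore_exponent: int = 4
    repulsion: Optional[RepulsionParamSet] = None
    cutoff: float = 12.0  # A, nonbonded evaluation cutoff
    bond_refs: Optional[dict[tuple[int, int], float]] = None
    angle_refs: Optional[dict[tuple[int, int, int], float]] = None

    def __post_init__(self) -> None:
        if self.bond_k <= 0 or self.angle_k <= 0:
            raise ValueError("stiffnesses must be positive")
        self.wells = {_canonical_pair(*k): v for k, v in self.wells.items()}

    def replace(self, **kw) -> "SurrogateModel":
        return dataclasses.replace(self, **kw)

    def with_reference(self, structure: Structure, graph: BondGraph) -> "SurrogateModel":
        """Copy of the model whose bond/angle references are the given geometry."""
        coords = structure.coords
        bond_refs = {
            (i, j): float(np.linalg.norm(coords[i] - coords[j])) for i, j in graph.bonds
        }
        angle_refs = {}
        for i, j, k in graph.angles():
            u = coords[i] - coords[j]
            v = coords[k] - coords[j]
            cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            angle_refs[(i, j, k)] = float(np.arccos(np.clip(cosang, -1.0, 1.0)))
        return self.replace(bond_refs=bond_refs, angle_refs=angle_refs)


class _Evaluator:
    """Precomputed index arrays for fast repeated energy/gradient evaluation."""

    def __init__(self, structure: Structure, graph: BondGraph, model: SurrogateModel):
        if graph.n_atoms != len(structure):
            raise ValueError("bond graph is inconsistent with the structure")
        if model.bond_refs is None or model.angle_refs is None:
            model = model.with_reference(structure, graph)
        self.model = model
        self.n = len(structure)
        elements = structure.elements
        # donor-hydrogen typing for the attraction-well lookup: an H bound to
        # N/O/S may carry its own well key "Hd" (hydrogen-bond-like terms)
        well_elements = [
            "Hd"
            if el == "H" and any(elements[nb] in ("N", "O", "S") for nb in graph.adjacency[i])
            else el
            for i, el in enumerate(elements)
        ]

        bonds = sorted(graph.bonds)
        for pair in bonds:
            if pair not in model.bond_refs:
                raise ValueError(f"no reference bond length for bonded pair {pair}")
        self.bi = np.array([i for i, _ in bonds], dtype=int)
        self.bj = np.array([j for _, j in bonds], dtype=int)
        self.b0 = np.array([model.bond_refs[p] for p in bonds])

        angles = graph.angles()
        self.ai = np.array([a[0] for a in angles], dtype=int)
        self.aj = np.array([a[1] for a in angles], dtype=int)
        self.ak = np.array([a[2] for a in angles], dtype=int)
        self.th0 = np.array([model.angle_refs.get(a, 0.0) for a in angles]) if angles else np.zeros(0)

        ii, jj = np.triu_indices(self.n, k=1)
        keep = np.array([(i, j) not in graph.excluded for i, j in zip(ii, jj)], dtype=bool)
        self.pi = ii[keep]
        self.pj = jj[keep]
        npair = len(self.pi)
        self.well_D = np.zeros(npair)
        self.well_r = np.ones(npair)
        self.well_w = np.ones(npair)
        self.rep_a = np.zeros(npair)
        self.rep_b = np.ones(npair)
        self.rep_c = np.ones(npair)
        residue_ids = [a.residue_id for a in structure.atoms]
        for idx, (i, j) in enumerate(zip(self.pi, self.pj)):
            pair = _canonical_pair(elements[i], elements[j])
            # attraction wells model inter-fragment non-covalent stabilization:
            # they act only between residues and beyond 1-4 neighbors
            if (i, j) in graph.one_four or residue_ids[i] == residue_ids[j]:
                continue
            well = model.wells.get(_canonical_pair(well_elements[i], well_elements[j]))
            if well is None and "Hd" in (well_elements[i], well_elements[j]):
                well = model.wells.get(pair)  # plain-element well also covers donor H
            if well is not None:
                self.well_D[idx] = well.depth
                self.well_r[idx] = well.r_opt
                self.well_w[idx] = well.width
            if model.repulsion is not None:
                p = model.repulsion.get(*pair)
                if p is not None:
                    self.rep_a[idx] = p.a
                    self.rep_b[idx] = p.b
                    self.rep_c[idx] = p.c

    def __call__(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        m = self.model
        x = coords.reshape(self.n, 3)
        energy = 0.0
        grad = np.zeros_like(x)

        if len(self.bi):
            dvec = x[self.bi] - x[self.bj]
            d = np.linalg.norm(dvec, axis=1)
            delta = d - self.b0
            energy += m.bond_k * float(np.sum(delta**2))
            f = (2.0 * m.bond_k * delta / np.maximum(d, 1e-12))[:, None] * dvec
            np.add.at(grad, self.bi, f)
            np.add.at(grad, self.bj, -f)

        if len(self.ai):
            u = x[self.ai] - x[self.aj]
            v = x[self.ak] - x[self.aj]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            cosang = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
            theta = np.arccos(cosang)
            dtheta = theta - self.th0
            energy += m.angle_k * float(np.sum(dtheta**2))
            sin = np.sqrt(np.maximum(1.0 - cosang**2, 1e-12))
            dEdth = 2.0 * m.angle_k * dtheta
            coef = -dEdth / sin
            dcos_di = (v / nv[:, None] - cosang[:, None] * u / nu[:, None]) / nu[:, None]
            dcos_dk = (u / nu[:, None] - cosang[:, None] * v / nv[:, None]) / nv[:, None]
            gi = coef[:, None] * dcos_di
            gk = coef[:, None] * dcos_dk
            np.add.at(grad, self.ai, gi)
            np.add.at(grad, self.ak, gk)
            np.add.at(grad, self.aj, -(gi + gk))

        if len(self.pi):
            dvec = x[self.pi] - x[self.pj]
            d = np.linalg.norm(dvec, axis=1)
            within = d <= m.cutoff
            dedr = np.zeros_like(d)

            dwell = d - self.well_r
            gw = np.exp(-self.well_w * dwell**2)
            ew = np.where(within, -self.well_D * gw, 0.0)
            energy += float(np.sum(ew))
            dedr += np.where(within, 2.0 * self.well_D * self.well_w * dwell * gw, 0.0)

            if m.softcore_scale > 0:
                p = m.softcore_exponent
                safe = np.maximum(d, 1e-6)
                esc = np.where(within, m.softcore_scale / safe**p, 0.0)
                energy += float(np.sum(esc))
                dedr += np.where(within, -p * m.softcore_scale / safe ** (p + 1), 0.0)

            drep = d - self.rep_c
            outside = drep > 0
            grep = np.exp(-self.rep_b * drep**2)
            erep = np.where(outside, self.rep_a * grep, self.rep_a)
            energy += float(np.sum(np.where(within, erep, 0.0)))
            dedr += np.where(within & outside, -2.0 * self.rep_a * self.rep_b * drep * grep, 0.0)

            f = (dedr / np.maximum(d, 1e-12))[:, None] * dvec
            np.add.at(grad, self.pi, f)
            np.add.at(grad, self.pj, -f)

        return energy, grad


def surrogate_energy(
    structure: Structure, graph: BondGraph, model: SurrogateModel
) -> tuple[float, np.ndarray]:
    """Energy (kcal/mol) and analytic per-atom gradient (kcal/mol/A)."""
    return _Evaluator(structure, graph, model)(structure.coords)


@dataclasses.dataclass
class OptimizerSettings:
    max_step: float = 0.2  # A, cap on per-atom displacement per cycle
    history: int = 10  # L-BFGS memory
    stall_window: int = 60  # cycles without improvement before stopping
    energy_tol: float = 1e-8  # kcal/mol, what counts as an improvement
    max_cycles: int = 3000

    def __post_init__(self) -> None:
        if self.stall_window < 1:
            raise ValueError("stall window must be at least 1 cycle")


@dataclasses.dataclass
class Trajectory:
    cycles: list[int]
    energies: list[float]
    gradient_norms: list[float]
    converged: bool
    message: str

    def to_tsv(self) -> str:
        lines = ["cycle\tenergy\tgradient_norm"]
        for c, e, g in zip(self.cycles, self.energies, self.gradient_norms):
            lines.append(f"{c}\t{e:.8f}\t{g:.8f}")
        return "\n".join(lines) + "\n"


def optimize_geometry(
    structure: Structure,
    graph: BondGraph,
    model: SurrogateModel,
    settings: OptimizerSettings | None = None,
    seed: int = 0,
) -> tuple[Structure, Trajectory]:
    """Quasi-Newton (L-BFGS) descent with Armijo line search.

    Terminates when the best energy has not decreased by more than the
    tolerance over the stall window.  The returned structure's energy is
    never above the starting energy, and the trajectory of accepted steps
    is monotone non-increasing.  Deterministic given identical inputs;
    ``seed`` is accepted for interface uniformity and recorded use only.
    """
    o = settings or OptimizerSettings()
    ev = _Evaluator(structure, graph, model)
    n = ev.n
    x = structure.coords.ravel().copy()
    e, g = ev(x)
    g = g.ravel()
    if not np.isfinite(e) or not np.all(np.isfinite(g)):
        raise NonFiniteEnergyError("energy or gradient non-finite at the starting geometry")
    cycles, energies, gnorms = [0], [e], [float(np.linalg.norm(g))]
    best = e
    stall = 0
    s_hist: list[np.ndarray] = []
    y_hist: list[np.ndarray] = []
    message = "cycle budget exhausted"
    converged = False
    for cycle in range(1, o.max_cycles + 1):
        # two-loop recursion
        q = g.copy()
        alphas = []
        for s, y in zip(reversed(s_hist), reversed(y_hist)):
            rho = 1.0 / np.dot(y, s)
            a_i = rho * np.dot(s, q)
            alphas.append((a_i, rho, s, y))
            q -= a_i * y
        if y_hist:
            y_last = y_hist[-1]
            q *= np.dot(s_hist[-1], y_last) / np.dot(y_last, y_last)
        for a_i, rho, s, y in reversed(alphas):
            q += s * (rho * np.dot(y, q) - a_i)
        direction = -q
        if np.dot(direction, g) >= 0:  # not a descent direction: reset
            direction = -g
            s_hist.clear()
            y_hist.clear()
        max_disp = np.max(np.linalg.norm(direction.reshape(n, 3), axis=1))
        if max_disp > o.max_step:
            direction *= o.max_step / max_disp
        # Armijo backtracking, factor 0.5
        slope = np.dot(direction, g)
        step = 1.0
        accepted = False
        for _ in range(40):
            x_new = x + step * direction
            e_new, g_new = ev(x_new)
            g_new = g_new.ravel()
            if np.isfinite(e_new) and e_new <= e + 1e-4 * step * slope:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            if s_hist:  # discard stale curvature and retry from steepest descent
                s_hist.clear()
                y_hist.clear()
                continue
            message = "line search failed to find a lower energy"
            converged = True
            break
        if not np.all(np.isfinite(g_new)):
            raise NonFiniteEnergyError(
                "gradient became non-finite during optimization",
                last_good=structure.with_coords(x.reshape(n, 3)),
            )
        s_vec = x_new - x
        y_vec = g_new - g
        if np.dot(s_vec, y_vec) > 1e-12:
            s_hist.append(s_vec)
            y_hist.append(y_vec)
            if len(s_hist) > o.history:
                s_hist.pop(0)
                y_hist.pop(0)
        x, e, g = x_new, e_new, g_new
        cycles.append(cycle)
        energies.append(e)
        gnorms.append(float(np.linalg.norm(g)))
        if best - e > o.energy_tol:
            best = e
            stall = 0
        else:
            stall += 1
            if stall >= o.stall_window:
                message = f"no improvement over {o.stall_window} cycles"
                converged = True
                break
    traj = Trajectory(cycles, energies, gnorms, converged, message)
    return structure.with_coords(x.reshape(n, 3)), traj


def interaction_energy(
    complex_structure: Structure,
    complex_graph: BondGraph,
    monomer_a: Structure,
    graph_a: BondGraph,
    monomer_b: Structure,
    graph_b: BondGraph,
    model: SurrogateModel,
) -> float:
    """E(complex) - E(a) - E(b) under identical model settings.

    Bond/angle references are taken from each structure's own geometry, so
    for rigid placements the intramolecular terms cancel exactly and the
    result is the intermolecular energy.
    """
    if len(complex_structure) != len(monomer_a) + len(monomer_b):
        raise ValueError("complex atom count must equal the sum of the monomers'")
    if sorted(complex_structure.elements) != sorted(monomer_a.elements + monomer_b.elements):
        raise ValueError("complex and monomers have inconsistent element multisets")
    e_c, _ = surrogate_energy(complex_structure, complex_graph, model)
    e_a, _ = surrogate_energy(monomer_a, graph_a, model)
    e_b, _ = surrogate_energy(monomer_b, graph_b, model)
    return e_c - e_a - e_b
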