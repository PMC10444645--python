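"""The piecewise-Gaussian van der Waals repulsion pair term.

For one element pair with parameters (a, b, c) the term is

    E(r) = a * exp(-b * (c - r)**2)   for r > c
    E(r) = a                          for r <= c

i.e. a single-sided Gaussian that plateaus at the amplitude ``a`` inside
the switch distance ``c`` and decays smoothly beyond it.  It is continuous
and once-differentiable at r = c, repulsive (dE/dr <= 0 everywhere), and
numerically zero a few widths past c, so it exerts a weak outward force
around the vdW contact distance while leaving binding energetics at
ordinary separations essentially untouched.

Realized here as an additive pair energy over non-bonded atom pairs
(1-2 and 1-3 neighbors excluded, 1-4 included).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable

import numpy as np

from .structures import BondGraph, Structure, neighbor_pairs

__all__ = [
    "PairRepulsionParams",
    "RepulsionParamSet",
    "repulsion_term",
    "structure_repulsion",
]


def _canonical_pair(e1: str, e2: str) -> tuple[str, str]:
    return (e1, e2) if e1 <= e2 else (e2, e1)


@dataclasses.dataclass(frozen=True)
class PairRepulsionParams:
    """(a, b, c) for one unordered element pair.

    a: amplitude, kcal/mol (>= 0); b: Gaussian width, 1/A^2 (> 0);
    c: switch/plateau distance, A (> 0).
    """

    element_pair: tuple[str, str]
    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "element_pair", _canonical_pair(*self.element_pair))
        if self.a < 0:
            raise ValueError("amplitude a must be non-negative")
        if self.b <= 0:
            raise ValueError("width b must be positive")
        if self.c <= 0:
            raise ValueError("switch distance c must be positive")


class RepulsionParamSet:
    """Parameter table keyed by unordered element pair.

    Pairs absent from the table contribute zero energy.  Lookup is
    symmetric in element order.
    """

    def __init__(self, params: Iterable[PairRepulsionParams] = ()):
        self._table: dict[tuple[str, str], PairRepulsionParams] = {}
        for p in params:
            self._table[p.element_pair] = p

    def add(self, p: PairRepulsionParams) -> None:
        self._table[p.element_pair] = p

    def get(self, e1: str, e2: str) -> PairRepulsionParams | None:
        return self._table.get(_canonical_pair(e1, e2))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return _canonical_pair(*pair) in self._table

    def __iter__(self):
        return iter(sorted(self._table.values(), key=lambda p: p.element_pair))

    def __len__(self) -> int:
        return len(self._table)

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self._table)

    @property
    def max_c(self) -> float:
        return max((p.c for p in self._table.values()), default=0.0)

    def replace(self, p: PairRepulsionParams) -> "RepulsionParamSet":
        out = RepulsionParamSet(self)
        out.add(p)
        return out

    # --- declarative parameter file (pair  a  b  c), round-trips losslessly ---

    def to_text(self) -> str:
        lines = ["# pair\ta\tb\tc"]
        for p in self:
            lines.append(f"{p.element_pair[0]}-{p.element_pair[1]}\t{p.a!r}\t{p.b!r}\t{p.c!r}")
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "RepulsionParamSet":
        params = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 4 or "-" not in fields[0]:
                raise ValueError(f"parameter file line {lineno}: expected 'E1-E2 a b c'")
            e1, e2 = fields[0].split("-", 1)
            params.append(
                PairRepulsionParams((e1, e2), float(fields[1]), float(fields[2]), float(fields[3]))
            )
        return cls(params)

    @classmethod
    def load(cls, path: str | Path) -> "RepulsionParamSet":
        return cls.from_text(Path(path).read_text())


def repulsion_term(r, p: PairRepulsionParams):
    """Energy (kcal/mol) and dE/dr (kcal/mol/A) of the pair term at distance r.

    Accepts a scalar or an ndarray of distances.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("interatomic distance must be non-negative")
    dr = r - p.c
    outside = dr > 0
    gauss = np.exp(-p.b * dr**2)
    energy = np.where(outside, p.a * gauss, p.a)
    deriv = np.where(outside, -2.0 * p.a * p.b * dr * gauss, 0.0)
    if energy.ndim == 0:
        return float(energy), float(deriv)
    return energy, deriv


def structure_repulsion(
    structure: Structure,
    graph: BondGraph,
    params: RepulsionParamSet,
    cutoff: float = 12.0,
) -> tuple[float, np.ndarray]:
    """Total repulsion energy and analytic per-atom gradient for a structure.

    Sums :func:`repulsion_term` over all non-bonded pairs (1-2 and 1-3
    neighbors excluded) within ``cutoff`` whose element pair is
    parameterized.  The gradient is the exact derivative of that sum.
    """
    if graph.n_atoms != len(structure):
        raise ValueError("bond graph is inconsistent with the structure")
    if len(params) and cutoff < params.max_c:
        warnings.warn(
            f"cutoff {cutoff} A is below the largest switch distance "
            f"{params.max_c} A: the repulsion term is truncated before it decays",
            stacklevel=2,
        )
    coords = structure.coords
    elements = structure.elements
    total = 0.0
    grad = np.zeros_like(coords)
    for i, j, d in neighbor_pairs(structure, cutoff):
        if (i, j) in graph.excluded:
            continue
        p = params.get(elements[i], elements[j])
        if p is None:
            continue
        e, dedr = repulsion_term(d, p)
        total += e
        if d > 0:
            f = dedr / d * (coords[i] - coords[j])
            grad[i] += f
            grad[j] -= f
    return total, grad
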