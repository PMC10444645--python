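"""Element tables shared by all geometric modules.

Covalent radii are the single-bond consensus values of Cordero et al.
(Dalton Trans. 2008, 2832); van der Waals radii follow the Word et al.
small-probe contact lineage used by Molprobity-style clash analysis
(J. Mol. Biol. 1999, 285, 1711), with a reduced radius for polar
hydrogens (H bonded to N/O/S). All values in Angstroms.
"""

from __future__ import annotations

COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "Na": 1.66,
    "Mg": 1.41,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "K": 2.03,
    "Ca": 1.76,
    "Fe": 1.32,
    "Co": 1.26,
    "Zn": 1.22,
    "Se": 1.20,
    "Br": 1.20,
    "I": 1.39,
}

VDW_RADII: dict[str, float] = {
    "H": 1.17,
    "C": 1.75,
    "N": 1.55,
    "O": 1.40,
    "F": 1.30,
    "Na": 2.27,
    "Mg": 1.73,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.77,
    "K": 2.75,
    "Ca": 2.31,
    "Fe": 2.00,
    "Co": 2.00,
    "Zn": 2.10,
    "Se": 1.90,
    "Br": 1.85,
    "I": 1.98,
}

#: radius for a hydrogen covalently bound to N, O or S
POLAR_H_VDW = 1.00

#: elements that act as hydrogen-bond donors (via a bound H) or acceptors
HBOND_HEAVY = frozenset({"N", "O", "S"})


def normalize_element(symbol: str) -> str:
    """Title-case an element symbol; deuterium is treated as hydrogen."""
    sym = symbol.strip().capitalize()
    if sym == "D":
        sym = "H"
    return sym


class UnknownElementError(ValueError):
    pass


def covalent_radius(element: str) -> float:
    try:
        return COVALENT_RADII[element]
    except KeyError:
        raise UnknownElementError(f"no covalent radius tabulated for element {element!r}")


def vdw_radius(element: str) -> float:
    try:
        return VDW_RADII[element]
    except KeyError:
        raise UnknownElementError(f"no vdW radius tabulated for element {element!r}")
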