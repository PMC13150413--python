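"""Element reference data: van der Waals radii and atomic numbers.

The vdW radii (Å) are the Bondi compilation with the common extensions for
elements Bondi did not list (Alvarez-style values); analyses accept a
per-element override dict, so the shipped table is a default, not a policy.
"""

from __future__ import annotations

VDW_RADII: dict[str, float] = {
    "H": 1.20, "He": 1.40,
    "Li": 1.82, "Be": 1.53, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "Ne": 1.54,
    "Na": 2.27, "Mg": 1.73, "Al": 1.84, "Si": 2.10, "P": 1.80, "S": 1.80,
    "Cl": 1.75, "Ar": 1.88,
    "K": 2.75, "Ca": 2.31, "Ti": 2.15, "Fe": 2.04, "Ni": 1.63, "Cu": 1.40,
    "Zn": 1.39, "Ga": 1.87, "Ge": 2.11, "As": 1.85, "Se": 1.90, "Br": 1.85,
    "Kr": 2.02,
    "Rb": 3.03, "Sr": 2.49, "Zr": 2.36, "Mo": 2.17, "Ru": 2.07, "Rh": 1.95,
    "Pd": 1.63, "Ag": 1.72, "Cd": 1.58, "In": 1.93, "Sn": 2.17, "Sb": 2.06,
    "Te": 2.06, "I": 1.98, "Xe": 2.16,
    "Cs": 3.43, "Ba": 2.68, "W": 2.18, "Re": 2.16, "Os": 2.16, "Ir": 2.13,
    "Pt": 1.75, "Au": 1.66, "Hg": 1.55, "Tl": 1.96, "Pb": 2.02, "Bi": 2.07,
}

ATOMIC_NUMBERS: dict[str, int] = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Ti": 22, "Fe": 26,
    "Ni": 28, "Cu": 29, "Zn": 30, "Br": 35, "Ag": 47, "I": 53, "Pt": 78,
    "Au": 79, "Pb": 82,
}


def vdw_radius(symbol: str, overrides: dict[str, float] | None = None) -> float:
    if overrides and symbol in overrides:
        return overrides[symbol]
    try:
        return VDW_RADII[symbol]
    except KeyError:
        raise KeyError(
            f"no van der Waals radius for element {symbol!r}; "
            "supply it via the overrides table") from None


def atomic_number(symbol: str) -> int:
    return ATOMIC_NUMBERS.get(symbol, 0)
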