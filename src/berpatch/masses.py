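"""Elemental compositions and neutral-mass arithmetic for DNA fragments.

Oligonucleotide chain masses are computed as the sum of the free
2'-deoxynucleoside 5'-monophosphate residues minus one water per
phosphodiester linkage.  End chemistry is adjusted from that reference
state: a 5'-hydroxyl terminus removes one HPO3, a 3'-phosphate adds one.

Stable-isotope labels are modeled as full substitution of a residue's
carbons by 13C and nitrogens by 15N (the commercial fully labeled dATP
and dGTP).  For both dA and dG (10 C, 5 N in base + sugar) the label
adds 10*1.0033548 + 5*0.9970349 = 15.0187 Da - the spacing of the
repair-product mass ladder.

Negative-mode ESI charge arithmetic uses the assay's reduction
M = (m/z + 1.008) * z; the charge-carrier constant is configurable
(the exact proton mass 1.007276 may be substituted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "ElementalComposition",
    "MassValue",
    "composition_of",
    "neutral_mass",
    "mz_for_charge",
    "deconvolve",
    "residue_formulas",
    "HEAVY_SHIFT_DA",
    "WATER_MONO",
    "CHARGE_CARRIER",
]

# Monoisotopic atomic masses (Da); C13/N15 are the heavy isotopes used
# for labeling, tracked separately from the light elements.
ATOMIC_MONO = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "C13": 13.0033548378,
    "N15": 15.0001088982,
}

# Standard atomic weights (Da).  Heavy positions are isotopically pure,
# so their "average" mass is the isotope mass itself.
ATOMIC_AVG = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973762,
    "C13": 13.0033548378,
    "N15": 15.0001088982,
}

#: Default charge-carrier constant for negative-mode deconvolution.
CHARGE_CARRIER = 1.008

#: Mass added by one fully 13C,15N-substituted dA or dG relative to the
#: light residue (10 carbons, 5 nitrogens).
HEAVY_SHIFT_DA = 10 * (ATOMIC_MONO["C13"] - ATOMIC_MONO["C"]) + 5 * (
    ATOMIC_MONO["N15"] - ATOMIC_MONO["N"]
)

_ELEMENTS = ("C", "H", "N", "O", "P", "C13", "N15")

_HEAVY_ALLOWED = {"A", "G"}


@dataclass(frozen=True)
class ElementalComposition:
    """Atom counts of a fragment; heavy isotopes are kept separate."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    P: int = 0
    C13: int = 0
    N15: int = 0

    def __post_init__(self):
        for el in _ELEMENTS:
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count in composition")

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            **{el: getattr(self, el) + getattr(other, el) for el in _ELEMENTS}
        )

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            **{el: getattr(self, el) - getattr(other, el) for el in _ELEMENTS}
        )

    def formula(self) -> str:
        parts = []
        for el in _ELEMENTS:
            n = getattr(self, el)
            if n:
                parts.append(f"{el}{n if n > 1 else ''}")
        return "".join(parts)


WATER = ElementalComposition(H=2, O=1)
WATER_MONO = 2 * ATOMIC_MONO["H"] + ATOMIC_MONO["O"]
_HPO3 = ElementalComposition(H=1, O=3, P=1)


@dataclass(frozen=True)
class MassValue:
    monoisotopic: float
    average: float


def _load_residue_formulas() -> dict:
    text = resources.files("berpatch.data").joinpath("residues.json").read_text()
    raw = json.loads(text)["residues"]
    return {
        code: ElementalComposition(**counts) for code, counts in raw.items()
    }


_RESIDUE_FORMULAS: dict | None = None


def residue_formulas() -> dict:
    """Shipped residue formula table (code -> ElementalComposition)."""
    global _RESIDUE_FORMULAS
    if _RESIDUE_FORMULAS is None:
        _RESIDUE_FORMULAS = _load_residue_formulas()
    return _RESIDUE_FORMULAS


def _residue_composition(code: str, heavy: bool) -> ElementalComposition:
    table = residue_formulas()
    if code not in table:
        raise ValueError(f"unknown residue code {code!r}")
    comp = table[code]
    if not heavy:
        return comp
    if code not in _HEAVY_ALLOWED:
        raise ValueError(f"heavy label not permitted on residue {code!r}")
    # full substitution: every C -> C13, every N -> N15
    return ElementalComposition(
        C=0, H=comp.H, N=0, O=comp.O, P=comp.P,
        C13=comp.C + comp.C13, N15=comp.N + comp.N15,
    )


def composition_of(
    residues,
    five_prime: str = "phosphate",
    three_prime: str = "hydroxyl",
) -> ElementalComposition:
    """Elemental composition of a single-stranded DNA fragment.

    Parameters
    ----------
    residues
        Iterable of residues; each element is either a plain code string
        (``"A"``, ``"AP"``, ...) or a ``(code, heavy)`` pair / object
        with ``code`` and ``heavy`` attributes.
    five_prime, three_prime
        End chemistry: ``"phosphate"`` or ``"hydroxyl"``.
    """
    items = list(residues)
    if not items:
        raise ValueError("empty fragment")
    total = ElementalComposition()
    for r in items:
        if isinstance(r, str):
            code, heavy = r, False
        elif hasattr(r, "code"):
            code, heavy = r.code, r.heavy
        else:
            code, heavy = r
        total = total + _residue_composition(code, heavy)
    # one water per phosphodiester linkage
    for _ in range(len(items) - 1):
        total = total - WATER
    if five_prime == "hydroxyl":
        total = total - _HPO3
    elif five_prime != "phosphate":
        raise ValueError(f"unknown 5' chemistry {five_prime!r}")
    if three_prime == "phosphate":
        total = total + _HPO3
    elif three_prime != "hydroxyl":
        raise ValueError(f"unknown 3' chemistry {three_prime!r}")
    return total


def neutral_mass(comp: ElementalComposition) -> MassValue:
    """Monoisotopic and average neutral mass of a composition."""
    mono = sum(getattr(comp, el) * ATOMIC_MONO[el] for el in _ELEMENTS)
    avg = sum(getattr(comp, el) * ATOMIC_AVG[el] for el in _ELEMENTS)
    return MassValue(monoisotopic=mono, average=avg)


def deconvolve(mz: float, z: int, carrier: float = CHARGE_CARRIER) -> float:
    """Neutral mass from a negative-mode m/z at charge z: (m/z + carrier) * z."""
    if z < 1:
        raise ValueError("charge must be a positive integer")
    return (mz + carrier) * z


def mz_for_charge(M: float, z: int, carrier: float = CHARGE_CARRIER) -> float:
    """Exact inverse of :func:`deconvolve`: m/z = M/z - carrier."""
    if z < 1:
        raise ValueError("charge must be a positive integer")
    return M / z - carrier
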