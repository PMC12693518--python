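"""Restriction-enzyme table and IUPAC recognition-site scanning.

The enzyme table is data, not code: six enzymes used by the plasmid
probe design ship in ``data/enzymes.json`` and users may load their
own table.  Scanning treats U as T (restriction enzymes read
U-containing DNA), while abasic residues (AP, rAP, F) match nothing,
which is what makes the lesion-in-site diagnostic digest work.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = ["EnzymeSpec", "Site", "load_enzyme_table", "find_sites", "iupac_match"]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}


@dataclass(frozen=True)
class EnzymeSpec:
    """One restriction or nicking enzyme.

    Cut offsets count from the 5' end of the recognition string on the
    top strand; ``cut_offset_bottom`` is expressed in the same frame.
    ``nicking`` is ``"none"`` for double-strand cutters, else the strand
    that is nicked.
    """

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int
    nicking: str = "none"

    def __post_init__(self):
        if not self.recognition:
            raise ValueError("empty recognition sequence")
        for ch in self.recognition:
            if ch not in IUPAC:
                raise ValueError(f"non-IUPAC character {ch!r} in recognition")
        if self.nicking not in ("none", "top", "bottom"):
            raise ValueError(f"invalid nicking mode {self.nicking!r}")
        if self.nicking == "none":
            L = len(self.recognition)
            for off in (self.cut_offset_top, self.cut_offset_bottom):
                if not 0 <= off <= L:
                    raise ValueError("cut offset outside recognition site")

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement_iupac(self.recognition) == self.recognition


@dataclass(frozen=True)
class Site:
    """A recognition-site match: 0-based start on the top strand.

    ``strand`` is the strand on which the recognition string reads
    5'->3'.  Palindromic matches are reported once, as top-strand sites.
    """

    start: int
    strand: str  # "top" | "bottom"
    enzyme: str


def reverse_complement_iupac(s: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(s))


def load_enzyme_table(path: str | Path | None = None) -> dict:
    """Load an enzyme table (name -> EnzymeSpec); defaults to the shipped one."""
    if path is None:
        text = resources.files("berpatch.data").joinpath("enzymes.json").read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)["enzymes"]
    table = {}
    for entry in raw:
        spec = EnzymeSpec(**entry)
        table[spec.name] = spec
    return table


def get_enzyme(name: str, table: dict | None = None) -> EnzymeSpec:
    table = table if table is not None else load_enzyme_table()
    if name not in table:
        raise KeyError(f"unknown enzyme {name!r}")
    return table[name]


def iupac_match(pattern: str, window: str) -> bool:
    """True if every window base is allowed by the IUPAC pattern."""
    if len(pattern) != len(window):
        return False
    for p, b in zip(pattern, window):
        if b not in IUPAC[p]:
            return False
    return True


def _scan_chars(residues) -> str:
    """Top-strand scan string: U reads as T, abasic residues as '?'."""
    out = []
    for r in residues:
        code = r if isinstance(r, str) else r.code
        if code == "U":
            out.append("T")
        elif code in ("AP", "rAP", "F"):
            out.append("?")  # matches no IUPAC class
        else:
            out.append(code)
    return "".join(out)


def find_sites(sequence, enzyme: EnzymeSpec, topology: str = "linear") -> list:
    """All recognition-site matches of ``enzyme`` on a duplex sequence.

    ``sequence`` is the top strand (a string or residue list); the
    bottom strand is its complement.  Positions are 0-based top-strand
    starts of the recognition window; for circular topology,
    origin-spanning matches are reported with wrapped (mod L) starts.
    Palindromic recognition sites are reported once (strand="top").
    """
    chars = _scan_chars(sequence)
    if not chars:
        raise ValueError("empty sequence")
    if topology not in ("linear", "circular"):
        raise ValueError(f"unknown topology {topology!r}")
    L = len(chars)
    m = len(enzyme.recognition)
    fwd = enzyme.recognition
    rev = reverse_complement_iupac(fwd)
    scan = chars + chars[: m - 1] if topology == "circular" and L >= m else chars
    sites = []
    for i in range(len(scan) - m + 1):
        window = scan[i : i + m]
        if "?" in window:
            continue
        hit_fwd = iupac_match(fwd, window)
        # a bottom-strand site reads rev-comp(recognition) on the top strand
        hit_rev = iupac_match(rev, window)
        pos = i % L
        if hit_fwd:
            sites.append(Site(pos, "top", enzyme.name))
        if hit_rev and not (hit_fwd and enzyme.is_palindromic):
            sites.append(Site(pos, "bottom", enzyme.name))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites
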