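"""Mass-labeled plasmid probe: representation, in-silico digestion, and
design validation.

A probe is a circular (plasmid) or linear duplex carrying, on the top
strand, a single BER lesion (U, AP, rAP, or F) and a set of fully
13C,15N-substituted dA or dG residues.  The labels sit either on the
3' (downstream) side of the lesion - reading out the repair patch
size - or on the 5' (upstream) side - reading out 5' excision.

Coordinates are 0-based, half-open, on the top (lesion) strand.
Restriction cuts leave 5'-phosphate / 3'-hydroxyl chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json
from pathlib import Path

from .enzymes import EnzymeSpec, Site, find_sites, get_enzyme, load_enzyme_table

__all__ = [
    "Residue",
    "ProbeDesign",
    "FragmentInterval",
    "digest",
    "analysis_fragment",
    "fragment_residues",
    "simulate_diagnostic",
    "validate_design",
    "ValidationReport",
]

RESIDUE_CODES = {"A", "C", "G", "T", "U", "AP", "rAP", "F"}
LESION_KINDS = {"U", "AP", "rAP", "F"}
_BASE_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class Residue:
    code: str
    heavy: bool = False

    def __post_init__(self):
        if self.code not in RESIDUE_CODES:
            raise ValueError(f"unknown residue code {self.code!r}")
        if self.heavy and self.code not in ("A", "G"):
            raise ValueError("only dA and dG residues can carry the heavy label")


@dataclass(frozen=True)
class FragmentInterval:
    """Half-open top-strand-coordinate interval; for circular parents
    ``end`` may be <= ``start``, meaning the fragment wraps the origin."""

    start: int
    end: int
    strand: str = "top"
    five_prime_chemistry: str = "phosphate"
    three_prime_chemistry: str = "hydroxyl"

    def length(self, parent_length: int) -> int:
        if self.end > self.start:
            return self.end - self.start
        return parent_length - self.start + self.end

    def positions(self, parent_length: int) -> list:
        return [(self.start + i) % parent_length for i in range(self.length(parent_length))]

    def contains(self, index: int, parent_length: int) -> bool:
        return index in set(self.positions(parent_length))


@dataclass(frozen=True)
class ProbeDesign:
    """Top-strand description of a mass-labeled BER probe.

    ``sequence`` is the top strand over A/C/G/T/U; the residue at
    ``lesion_index`` is interpreted as ``lesion_kind`` (so abasic
    probes store the pre-excision base there).  ``label_indices`` are
    the heavy positions.  ``analysis_enzymes`` release the fragment
    sent to the mass spectrometer; ``diagnostic_enzyme`` (if any) has
    its recognition site overlapping the lesion, so the unrepaired
    probe resists cleavage after glycosylase treatment.
    """

    sequence: str
    topology: str  # "circular" | "linear"
    lesion_index: int
    lesion_kind: str
    opposite_base: str
    label_indices: frozenset
    label_side: str  # "downstream_G" | "upstream_A"
    analysis_enzymes: tuple = ()
    diagnostic_enzyme: str | None = None
    name: str = "probe"

    def __post_init__(self):
        object.__setattr__(self, "label_indices", frozenset(self.label_indices))
        L = len(self.sequence)
        if not 0 <= self.lesion_index < L:
            raise ValueError("lesion_index out of range")
        if self.lesion_kind not in LESION_KINDS:
            raise ValueError(f"unknown lesion kind {self.lesion_kind!r}")
        if self.opposite_base not in ("A", "C", "G"):
            raise ValueError("opposite_base must be A, C or G")
        if self.topology not in ("circular", "linear"):
            raise ValueError("topology must be circular or linear")
        if self.label_side not in ("downstream_G", "upstream_A"):
            raise ValueError("label_side must be downstream_G or upstream_A")
        if self.lesion_index in self.label_indices:
            raise ValueError("lesion position cannot carry a heavy label")
        # dual labeling (heavy A upstream plus heavy G downstream) is legal,
        # so each label must sit on a purine, not necessarily the side's one
        for i in self.label_indices:
            if not 0 <= i < L:
                raise ValueError("label index out of range")
            if self.sequence[i] not in ("A", "G"):
                raise ValueError(
                    f"label at {i} sits on {self.sequence[i]!r}; only dA/dG can be heavy"
                )

    # -- residue views ------------------------------------------------
    @property
    def repaired_base(self) -> str:
        """Base installed at the lesion by faithful repair (T for U:A)."""
        return _BASE_COMPLEMENT[self.opposite_base]

    def residues(self, state: str = "substrate") -> list:
        """Top strand as Residue objects.

        ``state="substrate"`` places the lesion; ``state="repaired"``
        places the repaired base (heavy labels untouched).
        """
        out = []
        for i, ch in enumerate(self.sequence):
            if i == self.lesion_index:
                code = self.repaired_base if state == "repaired" else self.lesion_kind
                out.append(Residue(code))
            else:
                out.append(Residue(ch, heavy=i in self.label_indices))
        return out

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "sequence": self.sequence,
            "topology": self.topology,
            "lesion_index": self.lesion_index,
            "lesion_kind": self.lesion_kind,
            "opposite_base": self.opposite_base,
            "label_indices": sorted(self.label_indices),
            "label_side": self.label_side,
            "analysis_enzymes": list(self.analysis_enzymes),
            "diagnostic_enzyme": self.diagnostic_enzyme,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProbeDesign":
        d = dict(d)
        d["label_indices"] = frozenset(d.get("label_indices", ()))
        d["analysis_enzymes"] = tuple(d.get("analysis_enzymes", ()))
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ProbeDesign":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------
# digestion


def _cut_positions(design_seq, enzyme: EnzymeSpec, topology: str, L: int):
    """(top_cuts, bottom_cuts) in top-strand coordinates, mod L."""
    top, bottom = [], []
    for site in find_sites(design_seq, enzyme, topology):
        m = len(enzyme.recognition)
        if site.strand == "top":
            t = site.start + enzyme.cut_offset_top
            b = site.start + enzyme.cut_offset_bottom
        else:
            # recognition reads on the bottom strand; mirror the offsets
            t = site.start + m - enzyme.cut_offset_bottom
            b = site.start + m - enzyme.cut_offset_top
        if enzyme.nicking in ("none", "top"):
            top.append(t % L)
        if enzyme.nicking in ("none", "bottom"):
            bottom.append(b % L)
    return sorted(set(top)), sorted(set(bottom))


def digest(design: ProbeDesign, enzymes, enzyme_table: dict | None = None) -> list:
    """Double-strand digest of the probe; returns top-strand fragments.

    Fragments carry 5'-phosphate / 3'-hydroxyl chemistry.  Nicking
    enzymes are rejected (they do not produce duplex fragments).  A
    circular substrate with no sites returns a single "uncut" full-
    length interval.
    """
    table = enzyme_table if enzyme_table is not None else load_enzyme_table()
    specs = [get_enzyme(e, table) if isinstance(e, str) else e for e in enzymes]
    for spec in specs:
        if spec.nicking != "none":
            raise ValueError(f"{spec.name} is a nicking enzyme; digest needs double-strand cutters")
    L = len(design.sequence)
    seq = design.residues("substrate")
    cuts = []
    for spec in specs:
        t, _ = _cut_positions(seq, spec, design.topology, L)
        cuts.extend(t)
    cuts = sorted(set(cuts))
    if design.topology == "circular":
        if not cuts:
            return [FragmentInterval(0, L, five_prime_chemistry="phosphate")]
        frags = []
        for i, start in enumerate(cuts):
            end = cuts[(i + 1) % len(cuts)]
            frags.append(FragmentInterval(start, end % L if end != start else start))
        if len(cuts) == 1:
            # single cut on a circle: one linear full-length fragment
            frags = [FragmentInterval(cuts[0], cuts[0])]
        return frags
    # linear
    bounds = [0] + [c for c in cuts if 0 < c < L] + [L]
    frags = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        five = "phosphate" if a in cuts else "hydroxyl"
        frags.append(FragmentInterval(a, b, five_prime_chemistry=five))
    return frags


def analysis_fragment(design: ProbeDesign, enzyme_table: dict | None = None) -> FragmentInterval:
    """The fragment released by the two analysis enzymes that contains
    the lesion (and, by design, every heavy label)."""
    if not design.analysis_enzymes:
        # linear oligonucleotide probes analyze the whole top strand
        return FragmentInterval(0, len(design.sequence), five_prime_chemistry="hydroxyl")
    frags = digest(design, list(design.analysis_enzymes), enzyme_table)
    L = len(design.sequence)
    for f in frags:
        if f.contains(design.lesion_index, L):
            return f
    raise ValueError("no analysis fragment contains the lesion")


def fragment_residues(design: ProbeDesign, interval: FragmentInterval, state: str = "substrate") -> list:
    seq = design.residues(state)
    return [seq[i] for i in interval.positions(len(design.sequence))]


# ---------------------------------------------------------------------
# diagnostic digest logic


def simulate_diagnostic(design: ProbeDesign, treatments, state: str = "unrepaired") -> dict:
    """Cut/uncut verdicts for a treatment series on one molecule state.

    ``treatments`` is an ordered list of tokens: ``"UDG"`` (U -> AP),
    ``"APE1"`` (nicks 5' of an abasic residue), or an enzyme name.
    ``state`` is ``"unrepaired"`` (lesion present) or ``"repaired"``
    (lesion replaced by the faithful repair base).

    An enzyme is reported uncleavable when its recognition site
    contains an abasic residue or an APE1 nick; U reads as T.
    """
    if state not in ("unrepaired", "repaired"):
        raise ValueError(f"unknown molecule state {state!r}")
    residues = design.residues("repaired" if state == "repaired" else "substrate")
    codes = [r.code for r in residues]
    nicks = set()
    verdicts = {}
    table = load_enzyme_table()
    for token in treatments:
        if token == "UDG":
            codes = ["AP" if c == "U" else c for c in codes]
        elif token == "APE1":
            for i, c in enumerate(codes):
                if c in ("AP", "rAP", "F"):
                    nicks.add(i)  # incision 5' of the abasic residue
        elif token in table:
            spec = table[token]
            if spec.nicking != "none":
                raise ValueError(f"{token} is a nicking enzyme; not a diagnostic cutter")
            sites = find_sites(codes, spec, design.topology)
            L = len(codes)
            m = len(spec.recognition)
            cleavable = []
            for s in sites:
                span = {(s.start + k) % L for k in range(m)}
                if any(codes[p] in ("AP", "rAP", "F") for p in span):
                    continue
                if nicks & span:
                    continue
                cleavable.append(s)
            verdicts[token] = "cut" if cleavable else "uncut"
        else:
            raise KeyError(f"unknown treatment token {token!r}")
    return verdicts


# ---------------------------------------------------------------------
# design validation


@dataclass
class ValidationReport:
    checks: list = field(default_factory=list)  # (name, passed, detail)

    def add(self, name: str, passed: bool, detail: str = "") -> None:
        self.checks.append((name, bool(passed), detail))

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.checks)

    def failures(self) -> list:
        return [(n, d) for n, ok, d in self.checks if not ok]

    def as_dict(self) -> dict:
        return {n: {"passed": ok, "detail": d} for n, ok, d in self.checks}


def validate_design(design: ProbeDesign, enzyme_table: dict | None = None,
                    min_separation: float = 5.0) -> ValidationReport:
    """Run the named design checks; failures are report entries, never
    exceptions."""
    table = enzyme_table if enzyme_table is not None else load_enzyme_table()
    report = ValidationReport()
    seq_sub = design.residues("substrate")
    seq_rep = design.residues("repaired")
    L = len(design.sequence)

    # (1) unique nicking sites (plasmid swap-region engineering)
    if design.topology == "circular":
        for name in ("Nt.BspQI", "Nb.BbvCI"):
            n = len(find_sites(seq_rep, table[name], design.topology))
            report.add(
                f"unique_{name}_site", n == 1,
                f"{n} site(s) found, expected exactly 1",
            )
    else:
        report.add("unique_nicking_sites", True, "skipped: linear probe")

    # (2) lesion inside the diagnostic-enzyme site (scanning the
    # repaired strand, since the lesion itself blocks recognition)
    if design.diagnostic_enzyme:
        spec = table[design.diagnostic_enzyme]
        m = len(spec.recognition)
        inside = False
        for s in find_sites(seq_rep, spec, design.topology):
            span = {(s.start + k) % L for k in range(m)}
            if design.lesion_index in span:
                inside = True
        report.add(
            "lesion_in_diagnostic_site", inside,
            f"lesion at {design.lesion_index} vs {design.diagnostic_enzyme} sites",
        )
    else:
        report.add("lesion_in_diagnostic_site", True, "skipped: no diagnostic enzyme declared")

    # (3) analysis enzymes cut exactly once each, flanking the lesion
    if design.analysis_enzymes:
        ok = True
        details = []
        for name in design.analysis_enzymes:
            spec = table[name]
            t, _ = _cut_positions(seq_rep, spec, design.topology, L)
            details.append(f"{name}: {len(t)} cut(s)")
            if len(t) != 1:
                ok = False
        frag = None
        if ok:
            try:
                frag = analysis_fragment(design, table)
            except ValueError:
                ok = False
        report.add("analysis_enzymes_single_cut", ok, "; ".join(details))
    else:
        frag = analysis_fragment(design, table)
        report.add("analysis_enzymes_single_cut", True, "skipped: whole-strand analysis")

    # (4) labels inside the analysis fragment
    if frag is not None:
        pos = set(frag.positions(L))
        ok = design.label_indices <= pos
        report.add("labels_in_analysis_fragment", ok,
                   f"fragment [{frag.start},{frag.end}) length {frag.length(L)}")
    else:
        report.add("labels_in_analysis_fragment", False, "no analysis fragment")

    # (5) collision-free mass ladder
    try:
        from .ladder import build_ladder, collision_check, enumerate_outcomes

        outcomes = enumerate_outcomes(design)
        lad = build_ladder(outcomes, design, enzyme_table=table)
        pairs = collision_check(lad, min_separation=min_separation)
        report.add("ladder_collision_free", not pairs,
                   f"{len(pairs)} ambiguous pair(s) at {min_separation} Da")
    except Exception as exc:  # a ladder that cannot be built is a failed check
        report.add("ladder_collision_free", False, f"ladder construction failed: {exc}")
    return report
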