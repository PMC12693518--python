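"""Enumeration of distinguishable repair outcomes and the theoretical
mass ladder.

A repair event replaces the lesion (plus k-1 nucleotides downstream,
the "patch") and possibly j nucleotides strictly upstream (the 5'
excision) with normal-mass nucleotides.  Every heavy residue inside
the replaced window is exchanged for a light one, shifting the product
mass down by 15.0187 Da per label.  Outcomes that remove the same
number of labels are indistinguishable by mass and are folded into an
open-ended top bin (">=K-nt").

Downstream-G probes read out the patch size k (j fixed at 0);
upstream-A probes read out the excision length j (k does not change
the mass because no downstream label exists - asserted here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import masses
from .masses import HEAVY_SHIFT_DA, MassValue, composition_of, neutral_mass, mz_for_charge
from .probe import ProbeDesign, analysis_fragment, fragment_residues, Residue

__all__ = [
    "RepairOutcome",
    "LadderEntry",
    "MassLadder",
    "enumerate_outcomes",
    "build_ladder",
    "collision_check",
    "UNREPAIRED_LABEL",
]

UNREPAIRED_LABEL = "unrepaired"


@dataclass(frozen=True)
class RepairOutcome:
    """One distinguishable product class.

    ``excision5`` (j) counts nucleotides strictly upstream of the
    lesion that were replaced; ``patch`` (k >= 1) counts the lesion
    plus downstream replacements.  ``open_ended`` marks the ">=" top
    bin, for which the stored j/k are the smallest members.
    """

    state: str  # "repaired" | "unrepaired"
    excision5: int = 0
    patch: int = 1
    lesion_result: str = "T"
    heavy_removed: int = 0
    open_ended: bool = False
    label: str = ""
    degenerate: bool = False


@dataclass(frozen=True)
class LadderEntry:
    label: str
    outcome: RepairOutcome
    mass: MassValue
    mz_by_charge: dict  # z -> m/z, window-restricted
    non_repair: bool = False


@dataclass
class MassLadder:
    entries: list
    window: tuple = (900.0, 1800.0)
    charge_range: tuple = (4, 8)
    fragment_length: int = 0

    def repair_entries(self) -> list:
        return [e for e in self.entries if not e.non_repair]

    def labels(self) -> list:
        return [e.label for e in self.entries]

    def by_label(self, label: str) -> LadderEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)


def _window_positions(design: ProbeDesign, j: int, k: int, L: int) -> set:
    """Top-strand positions replaced by outcome (j, k)."""
    return {(design.lesion_index + d) % L for d in range(-j, k)}


def _heavy_removed(design: ProbeDesign, j: int, k: int) -> int:
    return len(design.label_indices & _window_positions(design, j, k, len(design.sequence)))


def enumerate_outcomes(design: ProbeDesign, j_max: int = 6, k_max: int = 8) -> list:
    """Distinguishable repair outcomes for a probe.

    Returns the informative classes in increasing patch/excision order,
    the open-ended top bin last.  The intact unrepaired substrate is
    not part of this list (it is added by :func:`build_ladder`).
    """
    if j_max < 1 or k_max < 1:
        raise ValueError("j_max and k_max must be >= 1")
    frag = analysis_fragment(design)
    L = len(design.sequence)
    frag_pos = set(frag.positions(L))
    lesion_result = design.repaired_base

    if not design.label_indices:
        out = RepairOutcome(
            state="repaired", excision5=0, patch=1, lesion_result=lesion_result,
            heavy_removed=0, open_ended=True, label="repaired", degenerate=True,
        )
        return [out]

    if design.label_side == "downstream_G":
        values = range(1, k_max + 1)

        def window(v):
            return _window_positions(design, 0, v, L)

        def make(v, open_ended, removed):
            lab = (f">={v}-nt" if open_ended else f"{v}-nt")
            return RepairOutcome("repaired", 0, v, lesion_result, removed, open_ended, lab)

    else:
        values = range(0, j_max + 1)

        def window(v):
            return _window_positions(design, v, 1, L)

        def make(v, open_ended, removed):
            lab = (f">={v}-nt" if open_ended else f"{v}-nt")
            return RepairOutcome("repaired", v, 1, lesion_result, removed, open_ended, lab)

        # k is marginalized for upstream probes: no downstream labels
        for k in range(1, k_max + 1):
            extra = design.label_indices & _window_positions(design, 0, k, L)
            assert not extra, "upstream-A probe has labels downstream of the lesion"

    outcomes = []
    removed_counts = []
    for v in values:
        w = window(v)
        if not w <= frag_pos:
            raise ValueError(
                f"replaced window for class {v} extends outside the analysis fragment"
            )
        removed_counts.append(len(design.label_indices & w))

    values = list(values)
    top_start = None
    for i in range(len(values) - 1):
        if removed_counts[i] == removed_counts[i + 1]:
            top_start = i
            break
    if top_start is None:
        top_start = len(values) - 1
    for i, v in enumerate(values[: top_start + 1]):
        open_ended = i == top_start
        outcomes.append(make(v, open_ended, removed_counts[i]))
    return outcomes


def _apply_outcome(design: ProbeDesign, outcome: RepairOutcome) -> list:
    """Top-strand residues after the outcome's replacements."""
    L = len(design.sequence)
    res = design.residues("substrate")
    if outcome.state == "unrepaired":
        return res
    replaced = _window_positions(design, outcome.excision5, outcome.patch, L)
    out = []
    for i, r in enumerate(res):
        if i == design.lesion_index:
            out.append(Residue(outcome.lesion_result))
        elif i in replaced and r.heavy:
            out.append(Residue(r.code, heavy=False))
        else:
            out.append(r)
    return out


def build_ladder(
    outcomes,
    design: ProbeDesign,
    charge_range: tuple = (4, 8),
    window: tuple = (900.0, 1800.0),
    enzyme_table: dict | None = None,
    carrier: float = masses.CHARGE_CARRIER,
) -> MassLadder:
    """Neutral masses and in-window charge-state m/z for every outcome,
    plus the intact unrepaired substrate (flagged ``non_repair``).

    Entries are sorted by monoisotopic mass (ascending); a ladder none
    of whose entries has any in-window charge state is still returned
    (callers may warn)."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("no outcomes to build a ladder from")
    frag = analysis_fragment(design, enzyme_table)
    L = len(design.sequence)
    frag_idx = frag.positions(L)
    z_lo, z_hi = charge_range
    lo, hi = window

    def entry_for(outcome: RepairOutcome, non_repair: bool) -> LadderEntry:
        seq = _apply_outcome(design, outcome)
        residues = [seq[i] for i in frag_idx]
        comp = composition_of(
            residues,
            five_prime=frag.five_prime_chemistry,
            three_prime=frag.three_prime_chemistry,
        )
        mv = neutral_mass(comp)
        mzs = {}
        for z in range(z_lo, z_hi + 1):
            mz = mz_for_charge(mv.average, z, carrier)
            if lo <= mz <= hi:
                mzs[z] = mz
        return LadderEntry(outcome.label, outcome, mv, mzs, non_repair=non_repair)

    entries = [entry_for(o, False) for o in outcomes]
    unrepaired = RepairOutcome(
        state="unrepaired", excision5=0, patch=0,
        lesion_result=design.lesion_kind, heavy_removed=0, label=UNREPAIRED_LABEL,
    )
    entries.append(entry_for(unrepaired, True))
    entries.sort(key=lambda e: e.mass.monoisotopic)
    labels = [e.label for e in entries]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate class labels in ladder")
    return MassLadder(entries, window=window, charge_range=charge_range,
                      fragment_length=len(frag_idx))


def collision_check(ladder: MassLadder, min_separation: float = 5.0,
                    tolerance: float = 0.35) -> list:
    """Class pairs the assay cannot distinguish.

    Repair-class pairs closer than ``min_separation`` at neutral-mass
    level are reported; additionally any pair (including the
    unrepaired entry) whose peaks at a shared charge state would both
    fall within the matching ``tolerance`` of one another.  The
    unrepaired substrate is excluded from the spacing criterion - it
    is quantified separately and sits one U->T step off the ladder.
    """
    if min_separation <= 0:
        raise ValueError("min_separation must be positive")
    pairs = []
    rep = ladder.repair_entries()
    for i in range(len(rep)):
        for j in range(i + 1, len(rep)):
            if abs(rep[i].mass.monoisotopic - rep[j].mass.monoisotopic) < min_separation:
                pairs.append((rep[i].label, rep[j].label))
    ent = ladder.entries
    for i in range(len(ent)):
        for j in range(i + 1, len(ent)):
            dm = abs(ent[i].mass.average - ent[j].mass.average)
            shared = set(ent[i].mz_by_charge) & set(ent[j].mz_by_charge)
            if shared and dm < 2 * tolerance:
                pair = (ent[i].label, ent[j].label)
                if pair not in pairs:
                    pairs.append(pair)
    return pairs
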