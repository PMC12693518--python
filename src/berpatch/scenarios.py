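"""Reference repair-product compositions from published extract assays.

These compositions are the stated experimental world used by the
recovery benchmarks: each entry records the class mixture measured for
one extract condition (Xenopus egg HSS or HEK293 whole-cell extract)
on the uracil plasmid probe.  Where a report gives only the dominant
classes, the small remainder is split across the longer-patch classes
it mentions; the benchmarked class proportions themselves are as
printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Scenario", "SCENARIOS"]


@dataclass(frozen=True)
class Scenario:
    name: str
    label_side: str
    truth: dict
    description: str
    report_classes: tuple  # classes whose (summed) proportion is the readout


SCENARIOS = {
    # Unsupplemented Xenopus HSS, relaxed U:A plasmid: ~20% 1-nt, ~80% 2-nt.
    "hss_ua": Scenario(
        name="hss_ua",
        label_side="downstream_G",
        truth={"1-nt": 0.20, "2-nt": 0.80},
        description="Xenopus HSS, U:A plasmid, unsupplemented",
        report_classes=("2-nt",),
    ),
    # HSS + 50 nM recombinant Polbeta: ~75% 1-nt patches.
    "hss_polb50": Scenario(
        name="hss_polb50",
        label_side="downstream_G",
        truth={"1-nt": 0.75, "2-nt": 0.25},
        description="Xenopus HSS supplemented with 50 nM Polbeta, U:A plasmid",
        report_classes=("1-nt",),
    ),
    # 5'-excision distribution, HSS on U:A: ~15% none, ~80% 1-2 nt
    # (split evenly), <10% >=3 nt (split 3:2 over the 3-nt and >=4 bins).
    "hss_excision_ua": Scenario(
        name="hss_excision_ua",
        label_side="upstream_A",
        truth={"0-nt": 0.15, "1-nt": 0.40, "2-nt": 0.40, "3-nt": 0.03, ">=4-nt": 0.02},
        description="Xenopus HSS, U:A plasmid, upstream 5'-excision readout",
        report_classes=("1-nt", "2-nt"),
    ),
    # Relaxed plasmid pre-incised with UDG + Ape1: ~60% 1-nt, remainder 2-nt.
    "udg_ape1_relaxed": Scenario(
        name="udg_ape1_relaxed",
        label_side="downstream_G",
        truth={"1-nt": 0.60, "2-nt": 0.40},
        description="Xenopus HSS, relaxed plasmid pretreated with UDG and Ape1",
        report_classes=("1-nt",),
    ),
    # HEK293 WCE at six-fold extract concentration: ~35% 1-nt, ~25% 2-nt,
    # longer patches (3-nt and a doubled >=7-nt bin) making up the rest.
    "hek_6x": Scenario(
        name="hek_6x",
        label_side="downstream_G",
        truth={"1-nt": 0.35, "2-nt": 0.25, "3-nt": 0.20, ">=7-nt": 0.20},
        description="HEK293 WCE at 6x concentration, U:A plasmid",
        report_classes=("1-nt",),
    ),
}
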