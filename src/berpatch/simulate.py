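"""Synthetic-data generation: compliant probe sequences, simulated
ESI-QTOF negative-mode spectra, and replicate composition tables.

The generator emulates what the wet experiments provide:

* ``make_probe`` builds a plasmid (or linear 52-mer) probe satisfying
  the assay's design constraints - unique Nt.BspQI and Nb.BbvCI sites,
  a diagnostic NdeI site overlapping the U lesion (patch-size probes),
  HaeII/PstI flanks releasing an analysis fragment that contains the
  lesion and every heavy label.  The true plasmid sequence is not
  public; generated sequences are constraint-compliant stand-ins.
* ``simulate_spectrum`` places one envelope-collapsed Gaussian peak
  per product class and charge state inside the 900-1800 m/z
  acquisition window, heights proportional to the ground-truth
  composition times a discrete-Gaussian charge envelope (z 4-8,
  centered on 6), over a flat baseline with Gaussian noise.
* ``simulate_replicates`` draws replicate compositions from a
  Dirichlet around a mean, emulating day-to-day scatter of n
  independent experiments.

All randomness flows from the config seed; outputs are deterministic
per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .ladder import MassLadder, UNREPAIRED_LABEL
from .probe import ProbeDesign, validate_design
from .spectrum import Spectrum

__all__ = ["SimulationConfig", "make_probe", "simulate_spectrum", "simulate_replicates"]

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    label_side: str = "downstream_G"  # or "upstream_A"
    n_labels: int | None = None       # default: 6 downstream G / 4 upstream A
    lesion_kind: str = "U"
    opposite_base: str = "A"
    mode: str = "plasmid"             # or "linear" (52-mer duplex)
    charge_range: tuple = (4, 8)
    charge_center: float = 6.0
    charge_sigma: float = 1.2
    window: tuple = (900.0, 1800.0)
    grid_step: float = 0.02
    peak_sigma_mz: float = 0.15
    scale: float = 1000.0
    baseline: float = 10.0
    noise_sd: float = 5.0
    n_replicates: int = 3
    dirichlet_precision: float = 200.0

    def resolved_n_labels(self) -> int:
        if self.n_labels is not None:
            return self.n_labels
        return 6 if self.label_side == "downstream_G" else 4

    def as_manifest(self) -> dict:
        d = asdict(self)
        d["charge_range"] = list(self.charge_range)
        d["window"] = list(self.window)
        return d


def _filler(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _plasmid_sequence_g(rng: np.random.Generator, n_labels: int) -> tuple:
    """Patch-size probe: U in the NdeI site, heavy G run on its 3' side."""
    f1 = _filler(rng, 18)
    f2 = _filler(rng, 8)
    f3 = _filler(rng, 6)
    f4 = _filler(rng, 4)
    f5 = _filler(rng, 8)
    f6 = _filler(rng, 18)
    parts = [f1, "GCTCTTC", f2, "CTGCAG", f3, "CATAUG", "G" * n_labels, f4,
             "AGCGCT", f5, "CCTCAGC", f6]
    seq = "".join(parts)
    ndei_start = len(f1) + 7 + len(f2) + 6 + len(f3)
    lesion = ndei_start + 4  # the second T of CATATG carries the U
    labels = frozenset(range(lesion + 1, lesion + 1 + n_labels))
    return seq, lesion, labels, ("NdeI", "HaeII"), "NdeI"


def _plasmid_sequence_a(rng: np.random.Generator, n_labels: int) -> tuple:
    """5'-excision probe: heavy A run on the 5' side of the lesion.

    No enzyme site among the shipped six can both contain the lesion
    and present a poly-A run immediately upstream, so excision probes
    carry no diagnostic enzyme; HaeII and NdeI flank the lesion and
    release the analysis fragment.
    """
    f1 = _filler(rng, 18)
    f2 = _filler(rng, 8)
    f3 = _filler(rng, 6)
    f4 = _filler(rng, 8)
    f5 = _filler(rng, 6)
    f6 = _filler(rng, 8)
    f7 = _filler(rng, 18)
    parts = [f1, "GCTCTTC", f2, "AGCGCT", f3, "A" * n_labels, "U", f4,
             "CATATG", f5, "CTGCAG", f6, "CCTCAGC", f7]
    seq = "".join(parts)
    lesion = len(f1) + 7 + len(f2) + 6 + len(f3) + n_labels
    labels = frozenset(range(lesion - n_labels, lesion))
    return seq, lesion, labels, ("HaeII", "NdeI"), None


def _linear_sequence(rng: np.random.Generator, cfg: SimulationConfig) -> tuple:
    """52-mer duplex with the lesion at the central position."""
    n_labels = cfg.resolved_n_labels()
    lesion = 26
    chars = list(_filler(rng, 52))
    chars[lesion] = "U"
    if cfg.label_side == "downstream_G":
        labels = frozenset(range(lesion + 1, lesion + 1 + n_labels))
        for i in labels:
            chars[i] = "G"
    else:
        labels = frozenset(range(lesion - n_labels, lesion))
        for i in labels:
            chars[i] = "A"
    return "".join(chars), lesion, labels, (), None


def make_probe(config: SimulationConfig, max_tries: int = 100) -> ProbeDesign:
    """Generate a probe passing every design check; deterministic per seed.

    Random filler can create spurious recognition sites, so candidates
    are drawn until :func:`validate_design` passes (bounded retries).
    """
    rng = np.random.default_rng(config.seed)
    last_failures = None
    for _ in range(max_tries):
        if config.mode == "linear":
            seq, lesion, labels, analysis, diagnostic = _linear_sequence(rng, config)
            topology = "linear"
        elif config.mode == "plasmid":
            n = config.resolved_n_labels()
            if config.label_side == "downstream_G":
                seq, lesion, labels, analysis, diagnostic = _plasmid_sequence_g(rng, n)
            else:
                seq, lesion, labels, analysis, diagnostic = _plasmid_sequence_a(rng, n)
            topology = "circular"
        else:
            raise ValueError(f"unknown probe mode {config.mode!r}")
        design = ProbeDesign(
            sequence=seq,
            topology=topology,
            lesion_index=lesion,
            lesion_kind=config.lesion_kind,
            opposite_base=config.opposite_base,
            label_indices=labels,
            label_side=config.label_side,
            analysis_enzymes=analysis,
            diagnostic_enzyme=diagnostic,
            name=f"synthetic-{config.label_side}-{config.mode}-seed{config.seed}",
        )
        report = validate_design(design)
        if report.passed:
            return design
        last_failures = report.failures()
    raise RuntimeError(
        f"probe generation failed after {max_tries} tries; last failures: {last_failures}"
    )


def _charge_weights(cfg: SimulationConfig) -> dict:
    z_lo, z_hi = cfg.charge_range
    return {
        z: float(np.exp(-0.5 * ((z - cfg.charge_center) / cfg.charge_sigma) ** 2))
        for z in range(z_lo, z_hi + 1)
    }


def simulate_spectrum(ladder: MassLadder, truth: dict, config: SimulationConfig,
                      seed: int | None = None,
                      unrepaired_fraction: float = 0.0) -> Spectrum:
    """Synthetic averaged spectrum for a ground-truth class mixture.

    ``truth`` maps repair-class labels (a subset of the ladder's) to
    proportions summing to 1.  ``unrepaired_fraction`` adds the intact
    substrate peak as that fraction of the total signal.
    """
    repair_labels = [e.label for e in ladder.repair_entries()]
    unknown = set(truth) - set(repair_labels)
    if unknown:
        raise ValueError(f"truth classes not in ladder: {sorted(unknown)}")
    tot = sum(truth.values())
    if not np.isclose(tot, 1.0, atol=1e-6):
        raise ValueError(f"truth proportions sum to {tot:g}, expected 1")
    if not 0 <= unrepaired_fraction < 1:
        raise ValueError("unrepaired_fraction must be in [0, 1)")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.window
    grid = np.arange(lo, hi + config.grid_step / 2, config.grid_step)
    y = np.full(grid.size, config.baseline, dtype=float)
    weights = _charge_weights(config)
    amounts = {lab: truth.get(lab, 0.0) * (1.0 - unrepaired_fraction)
               for lab in repair_labels}
    amounts[UNREPAIRED_LABEL] = unrepaired_fraction
    sig = config.peak_sigma_mz
    for entry in ladder.entries:
        amount = amounts.get(entry.label, 0.0)
        if amount <= 0:
            continue
        for z, mz in entry.mz_by_charge.items():
            h = config.scale * amount * weights[z]
            lo_i, hi_i = np.searchsorted(grid, [mz - 6 * sig, mz + 6 * sig])
            x = grid[lo_i:hi_i]
            y[lo_i:hi_i] += h * np.exp(-0.5 * ((x - mz) / sig) ** 2)
    if config.noise_sd > 0:
        y += rng.normal(0.0, config.noise_sd, size=grid.size)
    np.clip(y, 0.0, None, out=y)
    meta = {
        "source": "synthetic",
        "seed": int(config.seed if seed is None else seed),
        "window": [lo, hi],
        "truth": dict(truth),
        "unrepaired_fraction": unrepaired_fraction,
    }
    return Spectrum(grid, y, meta)


def simulate_replicates(mean_composition: dict, precision: float, n: int,
                        seed: int = 0, group: str | None = None) -> pd.DataFrame:
    """Replicate composition table with Dirichlet scatter around a mean.

    Rows are drawn from Dirichlet(precision * mean); higher precision
    means tighter replicates.
    """
    labels = list(mean_composition)
    mean = np.array([mean_composition[k] for k in labels], dtype=float)
    if np.any(mean < 0) or not np.isclose(mean.sum(), 1.0, atol=1e-6):
        raise ValueError("mean composition must lie on the simplex")
    if precision <= 0:
        raise ValueError("precision must be positive")
    if n < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    rows = rng.dirichlet(precision * mean, size=n)
    df = pd.DataFrame(rows, columns=labels)
    df.insert(0, "replicate", [f"r{i+1}" for i in range(n)])
    if group is not None:
        df.insert(0, "group", group)
    return df
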