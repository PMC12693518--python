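"""Raw-spectrum processing: averaging, peak picking, charge-aware
assignment against a mass ladder, and peak-height quantification.

Quantification follows the assay's rule: the apex height of every peak
assigned to a product class is summed over all charge states, and the
class proportion is that sum divided by the total over all repair
classes.  The intact unrepaired substrate is excluded from the
denominator and reported as a separate fraction of the total assigned
height.

Matching operates on deconvolved neutral mass with a single absolute
tolerance (default 0.35 Da) - the discriminations that matter are the
15.0187 Da heavy-label step and the 14.0157 Da U->T step, both well
above 1 Da at neutral level.  Average mass drives matching by default
because simulated peaks are envelope-collapsed single Gaussians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

from . import masses
from .ladder import MassLadder

__all__ = [
    "Spectrum",
    "PeakList",
    "Assignment",
    "CompositionEstimate",
    "average_spectra",
    "pick_peaks",
    "assign_peaks",
    "quantify",
]


@dataclass
class Spectrum:
    """An m/z-intensity trace with strictly ascending m/z."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if self.mz.size < 2 or np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")


@dataclass
class PeakList:
    centroid_mz: np.ndarray
    height: np.ndarray
    snr: np.ndarray

    def __post_init__(self):
        self.centroid_mz = np.asarray(self.centroid_mz, dtype=float)
        self.height = np.asarray(self.height, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)

    def __len__(self):
        return self.centroid_mz.size


@dataclass(frozen=True)
class Assignment:
    peak_index: int
    label: str
    charge: int
    mass_error_da: float
    mass_error_ppm: float
    ambiguous: bool = False
    non_repair: bool = False


@dataclass
class CompositionEstimate:
    labels: list
    heights: np.ndarray
    proportions: np.ndarray
    unrepaired_fraction: float

    def as_dict(self) -> dict:
        return {lab: float(p) for lab, p in zip(self.labels, self.proportions)}


def average_spectra(spectra) -> Spectrum:
    """Pointwise-mean spectrum on a common grid.

    Spectra on different grids are linearly interpolated onto the
    densest input grid before averaging; the scan count is recorded in
    the metadata.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to average")
    grid = max(spectra, key=lambda s: s.mz.size).mz
    stack = np.vstack([
        s.intensity if s.mz.size == grid.size and np.allclose(s.mz, grid)
        else np.interp(grid, s.mz, s.intensity)
        for s in spectra
    ])
    meta = {"averaged_scans": len(spectra)}
    return Spectrum(grid.copy(), stack.mean(axis=0), meta)


def pick_peaks(spectrum: Spectrum, min_snr: float = 5.0,
               min_rel_height: float = 0.001) -> PeakList:
    """Local-maximum peak picking with parabolic centroiding.

    The noise floor is the median absolute deviation of the intensity
    trace (scaled to sigma); the baseline is its median.  Peaks must
    rise above ``max(min_snr * noise, min_rel_height * max)`` over the
    baseline and show at least that much prominence - the prominence
    requirement stops noise riding on a peak's flanks from splitting
    it into several local maxima.  Heights are baseline-subtracted.
    """
    y = spectrum.intensity
    baseline = float(np.median(y))
    noise = 1.4826 * float(np.median(np.abs(y - baseline)))
    if noise == 0.0:
        # detector clipping at zero collapses the MAD: the surviving
        # positive residuals are half-normal, whose median is 0.6745
        # sigma, so recover sigma from them (sub-signal region only)
        low = y[(y > baseline) & (y <= np.quantile(y, 0.9))]
        if low.size:
            noise = float(np.median(low - baseline)) / 0.6745
    span = float(y.max()) - baseline
    rise = max(min_snr * noise, min_rel_height * span)
    idx, _ = _scipy_find_peaks(y, height=baseline + rise, prominence=rise)
    mzs, heights, snrs = [], [], []
    x = spectrum.mz
    for i in idx:
        if 0 < i < y.size - 1:
            ym, y0, yp = y[i - 1], y[i], y[i + 1]
            denom = ym - 2 * y0 + yp
            delta = 0.5 * (ym - yp) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
            step = 0.5 * (x[i + 1] - x[i - 1])
            centroid = x[i] + delta * step
        else:
            centroid = x[i]
        h = float(y[i]) - baseline
        mzs.append(centroid)
        heights.append(h)
        snrs.append(h / noise if noise > 0 else np.inf)
    order = np.argsort(mzs)
    return PeakList(np.array(mzs)[order], np.array(heights)[order], np.array(snrs)[order])


def assign_peaks(peaks: PeakList, ladder: MassLadder, tolerance: float = 0.35,
                 use: str = "average", carrier: float = masses.CHARGE_CARRIER) -> list:
    """Match picked peaks to ladder classes across the charge range.

    Every peak is deconvolved at every charge in the ladder's range;
    candidates are ladder entries within ``tolerance`` (Da, neutral
    level) of any deconvolved mass.  A peak with candidates in more
    than one class is flagged ambiguous (and later excluded from
    quantification); otherwise the closest match wins.
    """
    if not ladder.entries:
        raise ValueError("empty ladder")
    if use not in ("average", "monoisotopic"):
        raise ValueError("use must be 'average' or 'monoisotopic'")
    z_lo, z_hi = ladder.charge_range
    assignments = []
    for p in range(len(peaks)):
        mz = peaks.centroid_mz[p]
        candidates = []  # (abs_err, signed_err, label, z, non_repair, M)
        for z in range(z_lo, z_hi + 1):
            M = masses.deconvolve(mz, z, carrier)
            for e in ladder.entries:
                ref = e.mass.average if use == "average" else e.mass.monoisotopic
                err = M - ref
                if abs(err) <= tolerance:
                    candidates.append((abs(err), err, e.label, z, e.non_repair, ref))
        if not candidates:
            continue
        labels = {c[2] for c in candidates}
        ambiguous = len(labels) > 1
        best = min(candidates, key=lambda c: c[0])
        _, err, label, z, non_repair, ref = best
        assignments.append(Assignment(
            peak_index=p, label=label, charge=z,
            mass_error_da=err, mass_error_ppm=1e6 * err / ref,
            ambiguous=ambiguous, non_repair=non_repair,
        ))
    return assignments


def quantify(assignments, peaks: PeakList, class_labels=None) -> CompositionEstimate:
    """Per-class proportions from summed apex heights.

    ``class_labels`` fixes the set and order of repair classes (classes
    without an assigned peak get proportion 0); by default the repair
    classes present in the assignments are used, sorted by label.
    Ambiguous assignments are excluded.  The unrepaired class is
    excluded from the proportion denominator and reported as a
    fraction of the total assigned height.
    """
    heights: dict = {}
    unrepaired_height = 0.0
    total_assigned = 0.0
    for a in assignments:
        if a.ambiguous:
            continue
        h = float(peaks.height[a.peak_index])
        total_assigned += h
        if a.non_repair:
            unrepaired_height += h
        else:
            heights[a.label] = heights.get(a.label, 0.0) + h
    if class_labels is None:
        class_labels = sorted(heights)
    class_labels = list(class_labels)
    hvec = np.array([heights.get(lab, 0.0) for lab in class_labels])
    total = hvec.sum()
    if total <= 0:
        raise ValueError("no repair detected: zero repair-class signal")
    props = hvec / total
    unrep = unrepaired_height / total_assigned if total_assigned > 0 else 0.0
    return CompositionEstimate(class_labels, hvec, props, unrep)
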