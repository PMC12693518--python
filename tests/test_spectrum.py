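"""Spectrum processing: averaging, peak picking, assignment, and
peak-height quantification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from berpatch import SimulationConfig, analyze_spectrum, simulate_spectrum
from berpatch.spectrum import (
    Assignment,
    PeakList,
    Spectrum,
    assign_peaks,
    average_spectra,
    pick_peaks,
    quantify,
)


def _gaussian_spectrum(centers, heights, sigma=0.15, noise=0.0, seed=0,
                       lo=900.0, hi=1100.0, baseline=0.0):
    x = np.arange(lo, hi, 0.02)
    y = np.full_like(x, baseline)
    for c, h in zip(centers, heights):
        y += h * np.exp(-0.5 * ((x - c) / sigma) ** 2)
    if noise:
        y += np.random.default_rng(seed).normal(0, noise, x.size)
    return Spectrum(x, np.clip(y, 0, None))


class TestSpectrum:
    def test_invariants(self):
        with pytest.raises(ValueError):
            Spectrum([1.0, 1.0, 2.0], [0.0, 0.0, 0.0])  # not strictly ascending
        with pytest.raises(ValueError):
            Spectrum([1.0, 2.0], [0.0, -1.0])  # negative intensity
        with pytest.raises(ValueError):
            Spectrum([1.0, 2.0, 3.0], [0.0, 1.0])  # length mismatch


class TestAverage:
    def test_identical_inputs_unchanged(self):
        s = _gaussian_spectrum([1000.0], [50.0])
        avg = average_spectra([s, s, s])
        assert np.allclose(avg.intensity, s.intensity)
        assert avg.metadata["averaged_scans"] == 3

    def test_mean_of_zero_and_signal(self):
        s = _gaussian_spectrum([1000.0], [50.0])
        z = Spectrum(s.mz, np.zeros_like(s.intensity))
        avg = average_spectra([s, z])
        assert np.allclose(avg.intensity, s.intensity / 2)

    def test_noise_shrinks_like_sqrt_n(self):
        """Monte-Carlo: averaging n noisy replicates divides the noise
        standard deviation by ~sqrt(n)."""
        singles = [_gaussian_spectrum([], [], noise=5.0, seed=s) for s in range(16)]
        avg = average_spectra(singles)
        sd1 = np.std(np.clip(singles[0].intensity, None, None))
        sdn = np.std(avg.intensity)
        assert sdn == pytest.approx(sd1 / 4, rel=0.25)

    def test_resampling_onto_densest_grid(self):
        a = _gaussian_spectrum([1000.0], [50.0])
        coarse = Spectrum(a.mz[::2], a.intensity[::2])
        avg = average_spectra([a, coarse])
        assert avg.mz.size == a.mz.size

    def test_empty_list(self):
        with pytest.raises(ValueError):
            average_spectra([])


class TestPickPeaks:
    def test_single_gaussian_centroid(self):
        s = _gaussian_spectrum([1000.123], [100.0], noise=0.5, seed=1, baseline=5.0)
        peaks = pick_peaks(s)
        assert len(peaks) == 1
        assert peaks.centroid_mz[0] == pytest.approx(1000.123, abs=0.01)

    def test_two_separated_gaussians(self):
        s = _gaussian_spectrum([1000.0, 1002.0], [100.0, 60.0], noise=0.5, seed=2,
                               baseline=5.0)
        peaks = pick_peaks(s)
        assert len(peaks) == 2

    def test_clipped_zero_baseline_trace_still_clean(self):
        """A trace clipped at zero (no detector offset) must not flood
        the peak list with noise maxima."""
        s = _gaussian_spectrum([1000.123], [100.0], noise=0.5, seed=1)
        peaks = pick_peaks(s)
        assert 1 <= len(peaks) <= 3
        assert abs(peaks.centroid_mz[np.argmax(peaks.height)] - 1000.123) < 0.01

    def test_pure_noise_false_positive_rate(self):
        """At min_snr=5, pure-noise spectra essentially never yield peaks."""
        n_with_peaks = 0
        for seed in range(100):
            s = _gaussian_spectrum([], [], noise=3.0, seed=seed, baseline=20.0)
            if len(pick_peaks(s, min_snr=5.0)) > 0:
                n_with_peaks += 1
        assert n_with_peaks <= 1  # < 1% of spectra


class TestAssign:
    def test_exact_peak_assigned(self, g_ladder):
        entry = g_ladder.by_label("2-nt")
        mz = entry.mz_by_charge[6]
        peaks = PeakList([mz], [100.0], [50.0])
        asg = assign_peaks(peaks, g_ladder)
        assert len(asg) == 1
        assert asg[0].label == "2-nt" and asg[0].charge == 6
        assert abs(asg[0].mass_error_da) < 1e-6

    def test_far_peak_unassigned(self, g_ladder):
        entry = g_ladder.by_label("2-nt")
        mz = entry.mz_by_charge[6] + 10.0 / 6  # 10 Da off at neutral level
        asg = assign_peaks(PeakList([mz], [100.0], [50.0]), g_ladder)
        assert asg == []

    def test_close_entries_flag_ambiguous(self, g_ladder):
        """Two ladder entries within 2x tolerance of a peak are both
        candidates: the peak is flagged and excluded downstream."""
        from berpatch.ladder import LadderEntry, MassLadder, RepairOutcome
        from berpatch.masses import MassValue, mz_for_charge

        M = 6000.0
        entries = [
            LadderEntry("a", RepairOutcome("repaired", 0, 1, "T", 0, label="a"),
                        MassValue(M, M), {6: mz_for_charge(M, 6)}),
            LadderEntry("b", RepairOutcome("repaired", 0, 2, "T", 1, label="b"),
                        MassValue(M - 0.3, M - 0.3), {6: mz_for_charge(M - 0.3, 6)}),
        ]
        lad = MassLadder(entries, charge_range=(6, 6))
        peaks = PeakList([mz_for_charge(M - 0.15, 6)], [100.0], [50.0])
        asg = assign_peaks(peaks, lad, tolerance=0.5)
        assert len(asg) == 1 and asg[0].ambiguous

    def test_empty_ladder_rejected(self):
        from berpatch.ladder import MassLadder

        with pytest.raises(ValueError):
            assign_peaks(PeakList([1000.0], [1.0], [1.0]), MassLadder([]))


class TestQuantify:
    def _asg(self, label, idx, non_repair=False, ambiguous=False):
        return Assignment(idx, label, 6, 0.0, 0.0, ambiguous=ambiguous,
                          non_repair=non_repair)

    def test_proportions_by_definition(self):
        peaks = PeakList([1000.0, 1010.0], [80.0, 20.0], [10, 10])
        est = quantify([self._asg("2-nt", 0), self._asg("1-nt", 1)], peaks)
        assert est.as_dict() == {"1-nt": pytest.approx(0.2), "2-nt": pytest.approx(0.8)}

    def test_heights_summed_across_charge_states(self):
        peaks = PeakList([1000.0, 1010.0, 1200.0], [30.0, 60.0, 10.0], [9, 9, 9])
        asg = [self._asg("a", 0), self._asg("b", 1), self._asg("a", 2)]
        est = quantify(asg, peaks)
        assert est.as_dict()["a"] == pytest.approx(0.4)
        assert est.as_dict()["b"] == pytest.approx(0.6)

    def test_unrepaired_excluded_from_denominator(self):
        peaks = PeakList([1000.0, 1010.0, 1020.0], [60.0, 40.0, 100.0], [9, 9, 9])
        asg = [self._asg("a", 0), self._asg("b", 1),
               self._asg("unrepaired", 2, non_repair=True)]
        est = quantify(asg, peaks)
        assert est.as_dict() == {"a": pytest.approx(0.6), "b": pytest.approx(0.4)}
        assert est.unrepaired_fraction == pytest.approx(0.5)

    def test_zero_classes_reported(self):
        peaks = PeakList([1000.0], [10.0], [9])
        est = quantify([self._asg("a", 0)], peaks, class_labels=["a", "b"])
        assert est.as_dict() == {"a": pytest.approx(1.0), "b": 0.0}

    def test_ambiguous_excluded(self):
        peaks = PeakList([1000.0, 1010.0], [50.0, 50.0], [9, 9])
        asg = [self._asg("a", 0), self._asg("b", 1, ambiguous=True)]
        est = quantify(asg, peaks)
        assert est.as_dict()["a"] == pytest.approx(1.0)

    def test_no_repair_signal_is_an_error(self):
        peaks = PeakList([1000.0], [50.0], [9])
        with pytest.raises(ValueError, match="no repair"):
            quantify([self._asg("unrepaired", 0, non_repair=True)], peaks)

    @settings(max_examples=25, derandomize=True)
    @given(st.permutations(range(4)), st.floats(min_value=0.1, max_value=10.0))
    def test_permutation_and_scale_invariance(self, perm, scale):
        """Input peak order and global intensity scaling never change
        the composition estimate."""
        mzs = np.array([1000.0, 1010.0, 1020.0, 1030.0])
        hs = np.array([40.0, 30.0, 20.0, 10.0])
        labels = ["a", "b", "a", "c"]
        ref = quantify([self._asg(labels[i], i) for i in range(4)],
                       PeakList(mzs, hs, hs)).as_dict()
        perm = list(perm)
        mzs2, hs2 = mzs[perm] , hs[perm] * scale
        labels2 = [labels[i] for i in perm]
        order = np.argsort(mzs2)
        mzs3, hs3 = mzs2[order], hs2[order]
        labels3 = [labels2[i] for i in order]
        got = quantify([self._asg(labels3[i], i) for i in range(4)],
                       PeakList(mzs3, hs3, hs3)).as_dict()
        for k, v in ref.items():
            assert got[k] == pytest.approx(v, abs=1e-12)


class TestEndToEnd:
    def test_recovery_within_3pp_over_20_seeds(self, g_probe, g_ladder, g_config):
        """Full pick->assign->quantify on simulated spectra recovers the
        ground truth within 0.03 per class, averaged over 20 seeds."""
        truth = {"1-nt": 0.2, "2-nt": 0.55, "3-nt": 0.15, ">=7-nt": 0.1}
        labels = [e.label for e in g_ladder.repair_entries()]
        tvec = np.array([truth.get(lab, 0.0) for lab in labels])
        errs = []
        for seed in range(20):
            spec = simulate_spectrum(g_ladder, truth, g_config, seed=seed)
            est = analyze_spectrum(spec, g_ladder)
            evec = np.array([est.as_dict()[lab] for lab in labels])
            errs.append(np.abs(evec - tvec))
        assert np.mean(errs, axis=0).max() < 0.03

    def test_unrepaired_fraction_does_not_distort_proportions(self, g_ladder, g_config):
        # leave the 2-nt class empty: the intact substrate sits only
        # 15.019 - 14.016 = 1.003 Da above it, inside the peak width at
        # these charge states, so a 2-nt component would merge with it
        truth = {"1-nt": 0.3, "3-nt": 0.7}
        spec = simulate_spectrum(g_ladder, truth, g_config, seed=5,
                                 unrepaired_fraction=0.4)
        est = analyze_spectrum(spec, g_ladder)
        assert est.as_dict()["3-nt"] == pytest.approx(0.7, abs=0.03)
        assert est.unrepaired_fraction == pytest.approx(0.4, abs=0.05)
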