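# Methods

This note documents the models and numerical choices behind
`berpatch`, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Probe model

A probe is described entirely on the top (lesion) strand with 0-based,
half-open coordinates.  The residue alphabet is A, C, G, T, U plus
three abasic species: AP (intact 2-deoxyribose, cyclic hemiacetal),
rAP (its borohydride-reduced, ring-opened alcohol; AP + H₂) and F
(tetrahydrofuran analog; AP − O).  Heavy labels (full ¹³C,¹⁵N
substitution) are legal only on dA/dG, matching the commercially
available labeled triphosphates.

Recognition-site scanning applies two rules that together reproduce
the diagnostic digest logic with no special cases:

* **U reads as T** — restriction enzymes cleave U-containing DNA, so
  the uracil substrate is cut until a glycosylase acts;
* **abasic residues match nothing** — a site containing AP/rAP/F (or
  an APE1 nick) is uncleavable.

Hence the diagnostic series "UDG then NdeI": on the unrepaired U
probe, UDG converts U→AP inside the NdeI site and cleavage is lost;
on a repaired molecule (U→T) UDG finds nothing and NdeI cuts.

The enzyme table ships as data (`data/enzymes.json`): the six enzymes
the plasmid design uses, with supplier-convention cut offsets counted
from the 5′ end of the recognition string.  Nicking enzymes carry a
strand annotation and are used only for the site-uniqueness design
checks — the oligonucleotide-swap chemistry itself (annealing,
ligation, exonuclease cleanup) is out of scope; its computational
content is the constraint set that `validate_design` tests.

`validate_design` reports five named checks (unique nicking sites,
lesion inside the diagnostic site, single cuts by the analysis
enzymes, labels inside the analysis fragment, collision-free ladder);
failures are report entries, never exceptions.

### Design choice: excision probes carry no diagnostic enzyme

The 5′-excision readout needs a contiguous run of heavy dA
immediately upstream of the lesion (otherwise the excision classes
are not in one-to-one correspondence with label counts).  No
recognition site among the six assay enzymes can both contain the
lesion and offer four upstream A positions, so the generated
upstream-A probe sets `diagnostic_enzyme=None` (the corresponding
check reports "skipped") while HaeII/NdeI still flank the lesion and
release the analysis fragment.  The published probe sequences are in
supplementary material that is not reproduced here; generated
sequences are constraint-compliant stand-ins that yield the published
class structure (0, 1, 2, 3, ≥4-nt).

## Mass engine

Chain masses are sums of free 2′-deoxynucleoside 5′-monophosphate
residue formulas minus one water per linkage; a 5′-hydroxyl end
removes one HPO₃, a 3′-phosphate adds one.  Residue formulas are
shipped as data (`data/residues.json`) and cross-checked against
Biopython's DNA masses in the test suite.  Both monoisotopic and
average masses are always computed; average mass drives spectrum
matching by default because simulated peaks are envelope-collapsed
(see below), while monoisotopic matching is selectable for
isotope-resolved centroid data.

The heavy-label shift is 10·(¹³C−¹²C) + 5·(¹⁵N−¹⁴N) = 15.0187 Da for
both dA and dG — the ladder spacing.  Charge-state arithmetic uses
the assay's stated reduction M = (m/z + 1.008)·z; the constant 1.008
is kept for fidelity with that definition (the physically exact
proton mass 1.007276 can be passed via the `carrier` argument).

## Product space

A repair outcome is (j, k): j nucleotides strictly upstream of the
lesion replaced (5′ excision) and a patch of k nucleotides starting
at the lesion.  Its mass applies lesion→repaired-base and heavy→light
replacement inside the window.  Classes whose heavy-removed counts
saturate are folded into an open-ended top bin: six downstream labels
give classes 1–6-nt plus "≥7-nt"; four upstream labels give 0–3-nt
plus "≥4-nt".  For upstream-A probes k is mass-silent (no downstream
labels), which is asserted, not assumed.

The intact unrepaired substrate (U plus all labels) is included in
every ladder, flagged `non_repair`.  Note an intrinsic near-
degeneracy of the chemistry: the unrepaired substrate lies only
15.0187 − 14.0157 = 1.003 Da above the class that removes exactly one
label (the 2-nt patch class on a downstream-G probe).  At z = 4–6
this is 0.17–0.25 m/z — inside the simulated peak width — so when an
unrepaired component is present that one class cannot be quantified
reliably.  `collision_check` therefore (a) reports repair-class pairs
closer than `min_separation` at neutral mass, and (b) reports any
pair, including the unrepaired entry, whose peaks would fall within
twice the matching tolerance at a shared charge state; the unrepaired
entry is excluded from criterion (a) because its 1.003 Da offset is a
fixed property of the chemistry, not a design flaw.

## Spectrum pipeline

* **Averaging**: pointwise mean after linear interpolation onto the
  densest input grid.
* **Peak picking**: local maxima above
  max(`min_snr`·noise, `min_rel_height`·span) over the baseline
  (median), with the *same* threshold required as topographic
  prominence.  The prominence requirement matters: without it, noise
  riding on a peak's flanks splits one product into several local
  maxima that each get assigned and summed, biasing compositions by
  several percentage points.  The noise floor is the scaled MAD of
  the trace; if clipping at zero collapses the MAD, it is recovered
  from the positive residuals (half-normal median = 0.6745 σ).
  Centroids are parabolic three-point interpolations; heights are
  baseline-subtracted apex heights.
* **Assignment**: every peak is deconvolved at every charge in the
  ladder's range and matched to entries within an absolute neutral-
  mass tolerance (default 0.35 Da — comfortably below the 1.003 Da
  minimum class separation, robust across charge states with one
  knob).  A peak matching two classes is flagged ambiguous and
  excluded from quantification (an equal-split option exists, off by
  default).
* **Quantification**: class proportion = summed apex height over all
  charge states ÷ total over repair classes.  Heights, not areas,
  match the assay's stated peak-height rule; summation across charge
  states is used (the source protocol does not state whether heights
  were summed or read from one charge state).  The unrepaired class
  is excluded from the denominator and reported as a separate
  fraction of total assigned height.

## Compositional statistics

Closure adds a pseudocount (default 1e-6; the source states only
"small") to zeros and renormalizes each row.  The Dirichlet
regression uses the common parametrization with log link,
α_id = exp(x_i·β_d), maximized by L-BFGS with the analytic digamma
gradient from a moment-matching start (max 500 iterations, gradient
tolerance 1e-8); the fitted log-likelihood is checked against the
start value.  The global test is the plain likelihood-ratio statistic
2·ΔlogL against χ² with D·(G−1) degrees of freedom.

**Small-sample caveat**: at the benchmark design (D=3, two groups of
six) the plain LRT is anticonservative — its measured size at nominal
α = 0.05 is ≈ 0.09–0.11, the textbook behavior of an asymptotic χ²
test with 12 observations and 3 extra parameters.  The package
implements the prescribed test as-is rather than recalibrating it;
treat small-n global p-values near the threshold with caution.

Per-class inference fits a beta regression (logit mean link, constant
precision, MLE via statsmodels `BetaModel` with L-BFGS) and tests the
group effect by likelihood ratio (Wald optional); BH adjustment runs
across the classes of one dataset.  Classes that are constant to
numerical precision — including classes that were all-zero before
closure — are reported as `degenerate` and excluded from the BH
family rather than fitted.  Stacked-bar visualization of fitted
compositions is left to the caller; the package returns tidy tables.

## Synthetic data: what it emulates, what it does not

`make_probe` draws random filler around the fixed architectural
elements and retries until every design check passes, so "the
validator passes on generated probes" is a real constraint-
satisfaction statement, not a tautology on a hard-coded sequence.
Defaults: plasmid mode ≈ 100 bp circular top strand (a compact
stand-in for the real several-kb plasmid — only the analysis fragment
matters for the mass readout), six downstream heavy G / four upstream
heavy A labels, U:A lesion; linear mode emits the 52-mer duplex with
a central lesion used in the oligonucleotide assays.

`simulate_spectrum` places one Gaussian per class and charge state at
the class's average-mass m/z, height ∝ truth × a discrete-Gaussian
charge envelope over z ∈ [4, 8] centered at 6 (σ = 1.2) — chosen so a
~6 kDa fragment puts three to four charge states inside the 900–1800
m/z window.  Peak σ = 0.15 m/z approximates QTOF resolution at these
masses; the flat baseline (10) plus Gaussian noise (σ = 5, i.e. 0.5%
of the full-scale 1000) reflects a well-averaged scan.  Peaks are
envelope-collapsed single Gaussians — no isotopologue fine structure,
no chromatographic dimension, no adducts, no in-source decay.  A
green end-to-end test therefore establishes that the deconvolution
and quantification logic is unbiased under this peak model, not that
the pipeline is robust to isotope-envelope interference or
calibration drift in real spectra.

`simulate_replicates` draws rows from Dirichlet(precision·mean) with
default precision 200, giving a standard deviation of ≈ 2–3
percentage points on a 20–80% component — the scale of the error bars
reported for three-replicate extract experiments.

Benchmark ground truths (`berpatch.scenarios`) are the published
compositions for five extract conditions; where a report names only
the dominant classes, the small remainder is split across the longer
classes it mentions (choices fixed once, documented in the scenario
table).  All randomness descends from one explicit seed; every CLI
run writes a manifest recording command, config, and seed.

## Known limitations

* The true probe sequences (supplementary material) are not used;
  everything downstream of the analysis fragment is faithful, but
  absolute fragment masses differ from the published instrument
  values.
* Quantification assumes equal ionization/detection efficiency across
  classes (they differ by isotopes only, so this is mild) and across
  charge states within a class (exact in the simulator, approximate
  on a real instrument).
* The unrepaired/one-label near-degeneracy (1.003 Da) limits
  quantification of the adjacent class whenever unrepaired substrate
  survives in the analyzed mixture.
* The Dirichlet LRT is anticonservative at n ≲ 10 per group (above);
  the beta-regression per-class tests share the small-sample caveat.
* mzML support is a minimal first-MS1-scan reader (64/32-bit floats,
  optional zlib); vendor formats and indexed mzML are out of scope.
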