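# Methods

This note documents the models and numerical choices behind pepquant, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the package's known limitations.

## Signal model and quantification

Quantification is identification-anchored: nothing is quantified that was
not first identified (or transferred from a run where it was). For a PSM
with sequence *s*, modifications and charge *z*:

1. **Envelope prediction.** The elemental composition is the sum of
   residue formulas + H₂O + modification formulas (modifications without a
   known formula contribute mass only and are flagged). The isotope
   envelope is computed by per-element convolution of isotope
   distributions (NIST masses/abundances via pyteomics), aggregated to one
   centroid per nominal isotopologue — fine structure is deliberately not
   modelled, matching the resolution regime where isotopologues are single
   centroids ~1.003355/z apart. Enriched label elements (¹³C, ²H, ¹⁵N,
   ¹⁸O) are two-point distributions with an enrichment fraction; at
   sub-unity enrichment the envelope acquires satellites *below* the
   all-heavy monoisotopic peak, which the pattern type represents with a
   nonzero monoisotopic index.

2. **XIC construction (the filter stack).** (i) a ±tol ppm m/z window at
   extraction (default 10 ppm); (ii) moving-average smoothing (default 3
   points, reflected ends); (iii) an isotope-envelope consistency filter —
   the +1/+2 isotopologue traces must correlate with the monoisotopic
   trace (Pearson ≥ 0.6 over the integration bounds) or the feature is
   flagged `low_quality_envelope`; (iv) charge consistency comes from the
   PSM itself. Boundaries are detected on the *smoothed* monoisotopic
   trace (apex = maximum within ±15 s of the anchor; bounds extend until
   intensity ≤ 5 % of apex, a local minimum below 50 % of apex is crossed,
   or the window ends) but areas integrate the *raw* traces, so the
   smoother never biases the area. The feature area is the sum of the
   first three isotopologue areas over the shared bounds.

3. **Dynamic matching tolerance** (labeled pipeline, per run): a first
   pass matches predicted envelopes against the MS1 scan nearest each
   identification at a wide window (20 ppm); with ≥ 20 observed matched
   ppm errors the window becomes `|median(e)| + 4·MAD(e)·1.4826`, clamped
   to [1 ppm, initial]. Fewer observations keep the initial window. The
   4-robust-SD width keeps ~99.99 % of a Gaussian error mass while
   rejecting distant interference.

## Labeled quantification

Channels share integration bounds (co-elution assumption — exact for
SILAC/¹⁵N; ¹⁸O's small RT shifts are absorbed by the ±15 s apex search).
The identified channel is inferred as the one whose monoisotopic m/z is
closest to the PSM's experimental m/z, so identification may come from
any channel and partners are inferred by mass arithmetic. When channel
spacing falls below 6 isotopologue widths, observed areas are unmixed by
solving `A·x = b` with non-negative least squares, where `A[i,j]` is the
fraction of channel *j*'s theoretical envelope landing in the positions
integrated for channel *i* (diagonal = 1). Beyond that spacing `A` is the
identity and areas pass through. Ratio quality is
`min(envelope scores) × max(0, shape correlation)`; ratios below 0.3 are
flagged low-confidence and excluded from protein rollup.

## Retention-time alignment

"Reversible" is implemented as a strictly increasing warp: robust LOWESS
(bandwidth 0.3, 2 robustness iterations) of reference RT on source RT,
pool-adjacent-violators projection to monotonicity with 1e-6 s separation,
monotone piecewise-cubic (PCHIP) interpolation through the knots, linear
extrapolation with boundary slopes. Inversion is numerical (Brent) and
round-trips within 1e-3 s; on affine anchor sets the warp is exact.
Multi-run experiments align star-topology to the run with the most
confident PSMs. Anchors are peptides identified in both runs (one per
sequence/modifications/charge, highest score wins), with RT refined to
the monoisotopic XIC apex; fewer than 10 shared peptides raises an
alignment-infeasible error and the caller falls back to identity.
Transferred features search for their apex in a widened ±30 s window and
are flagged `transferred`.

## Rollup and statistics

Protein intensity = sum of unique peptides' areas per run (shared
peptides are excluded, no razor assignment; linear in abundance, which is
what makes dilution ratios propagate to the protein level). Protein log₂
ratio = median of surviving peptide log₂ ratios (robust to one outlier at
n ≥ 3); `min_peptides` defaults to the permissive 1. Matrix normalization
equalizes per-run median log intensity over fully observed peptides
(first run = reference); ratio normalization median-centers protein log₂
ratios. Both assume most proteins unchanged, so spike-in and fixed-ratio
benchmark designs run with normalization off. Replicate precision is the
coefficient of variation (sample SD / mean) per protein across replicate
runs.

Reporter aggregation sums PSM channel intensities per peptide/protein and
takes ratios to channel 0. The default 0.003 Th reporter tolerance cannot
separate the 6.32 mDa N/C variant pairs of TMT 10-plex — they merge
unless the tolerance is tightened for instruments that resolve them.
Impurity matrices default to identity; lot-specific values are user
input (CSV).

## Synthetic data: what it emulates, what it does not

`synth_fixtures` generates the designs the engine is validated on. MS1
scans on a 1 s cycle carry Gaussian elution profiles (σ = 8 s) times the
peptide's theoretical envelope at exact m/z; channels add shifted
envelopes at their multipliers; every peak gets multiplicative log-normal
noise (σ = 0.05) and each scan ~10 exponential baseline peaks; one MS2
identification event is placed near each apex; per-run drift (shift + 
sinusoid) displaces apexes. Truth tables record area, apex and ratio per
peptide/channel/run, and the analytic identity
`area = height · σ·√(2π)` makes zero-noise recovery checkable in closed
form. Sequences come from a deterministic tryptic-like table (fixed
syllable inventory, terminal K/R), so isotope arithmetic runs on
realistic compositions, and generation is bit-reproducible per seed.

The dilution design uses the printed series 1 : 5 : 25 : 125 (four groups
× 3 replicates) over a constant background, spike base abundances
log-uniform over two decades; absolute amounts are abstract area units —
only the ratios are normative. The SILAC design guarantees labelable
(K/R-terminated) peptides; the ¹⁵N variant defaults to 98 % enrichment,
reflecting incomplete metabolic labeling. Problem sizes used by the
benchmark script — 220 proteins × 2 peptides × 12 runs for the dilution
series, 500 peptides × 3 runs for SILAC — were chosen as the smallest
designs that give stable medians over ≥ 20 spike and 100 protein ratios.

Deliberately *not* emulated: chimeric/co-isolated spectra, real fragment
ions (MS2 peaks beyond reporters are decoys), false identifications,
profile peak shapes, detector saturation, charge-state envelopes beyond
the identified charge, and global run-to-run intensity scaling in the
replicate designs (so simulated replicate CVs reflect measurement noise
only and are optimistic relative to real technical replicates). Passing
the recovery suites therefore demonstrates correctness of the
quantification arithmetic and alignment under the stated signal model,
not robustness to every artifact of real data.

## Numerical and design choices

- RT is seconds everywhere; source unit attributes are normalized on read.
- Only centroided spectra are accepted; a profile-mode flag raises a
  format error rather than silently mis-integrating.
- Rank-1 PSMs only; ties by higher score then lexicographic id. q-values
  are the single confidence currency (default threshold 0.01); TSV
  posterior probabilities convert via the running-mean transform
  `q(i) = mean(1 − p)` over the top-i PSMs only when no q-value column
  exists.
- Charge states are quantified separately and summed per
  sequence+modifications at matrix assembly; one feature per peptide per
  run, anchored at the highest-scoring PSM.
- Missing cells stay missing unless cross-run transfer is enabled
  (default off); no imputation.
- The mzML writer targets round-trip fidelity (64-bit, zlib arrays,
  minimal CV terms), not archival export.

## Limitations

Vendor raw files, pepXML, profile-mode data, ion mobility, MS3 reporter
quantification, protein inference/grouping, MaxLFQ-style ratio
optimization, iBAQ, and downstream differential testing are out of scope.
Fine isotope structure and sulfur anomaly corrections are not modelled.
Precursor multiplexing beyond 3 channels is untested.
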