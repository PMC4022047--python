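# Methods

`maldiprof` implements a label-free differential profiling workflow for
reflectron MALDI-TOF spectra of peptide-rich tissue extracts — the use
case it was built around is comparing neuropeptide levels across groups
of individually analyzed *Drosophila melanogaster* brains, where mature
neuropeptides appear as singly charged ions between m/z 500 and 4000.
This note records the models, the defaults and why they were chosen, and
what the synthetic data generator does and does not emulate.

## The profiling chain

Spectra enter as plain-text two-column (m/z, intensity) profiles with a
manifest assigning each file a sample, group and replicate-experiment
label. The chain is linear:

1. **Internal recalibration.** Local intensity maxima near known
   reference masses (within 200 ppm by default — twice a typical
   externally calibrated TOF accuracy of ~100 ppm) are matched and an
   affine model m/z' = a·m/z + b is least-squares fitted and applied to
   the whole axis. At least 3 matches are required; otherwise the
   spectrum passes through unchanged with a warning flag in its
   processing history, so one poor spectrum cannot abort a batch.
2. **Resampling.** All spectra are linearly interpolated onto one
   uniform axis spanning the intersection of their ranges; `auto` sets
   the point count to the median input length. Linear interpolation is
   exact on piecewise-linear profiles and introduces no ringing;
   anti-alias filtering is unnecessary because profiling spectra are not
   down-sampled in this workflow.
3. **Denoising.** Undecimated (stationary) discrete wavelet transform
   with a Daubechies filter of 8 taps (`db4`), soft thresholding of
   detail coefficients at the universal threshold σ̂·√(2 ln N), with
   σ̂ = median(|finest detail|)/0.6745, and thresholding of the low-pass
   channel enabled by default. The signal is symmetrically extended to
   the next power of two so the transform is exactly invertible.
   **Decomposition depth matters:** at 10 levels, soft-thresholding the
   (strongly correlated) coarse channels visibly erodes genuine peaks —
   on a planted Gaussian (height 100, σ = 0.2 Th, noise σ = 1) the RMSE
   to truth *rose* from 1.0 to 3.1. The default is therefore 5 levels
   (RMSE 0.53 on the same input), which removes fine-scale noise while
   leaving peptide-width structures essentially untouched. The depth is
   configurable (`decomposition_level`).
4. **Baseline subtraction.** Within consecutive 200-Th windows the
   baseline level is the 0.10 quantile of intensities; the nodes are
   interpolated with a monotone piecewise cubic (PCHIP) and subtracted.
   Each node is placed at the m/z where the window quantile is
   *realized*, not at the window center: on a monotonically decaying
   baseline the quantile of a window is attained near its downhill edge,
   and center placement would bias the curve low by ~10% at realistic
   decay rates. Negative residuals are retained (downstream feature
   extraction floors at zero); quantile, window and interpolation are
   configurable.
5. **Total average spectrum and binning.** The pointwise mean of all
   denoised/baseline-subtracted spectra across every group is base-peak
   normalized (max = 1). Local maxima above 1% of the base peak inside
   the 900–4000 analysis window become peaks; each peak's bin runs
   between its full-width-at-half-height crossings (linear
   interpolation), falling back to the adjacent valley where the half
   height is not reached, with overlapping neighbours clipped at the
   connecting valley minimum. Plateau apexes take the leftmost index so
   detection is deterministic. Detecting peaks once, in the average,
   gives every feature a value in every sample and avoids missing
   values, at the cost of averaging out signals present in only a few
   samples.
6. **Normalization and feature extraction.** Each spectrum is divided
   by its summed intensity over the full axis (so features are relative
   abundances and uniform intensity rescalings cancel), and the feature
   value of bin i in sample j is the maximum normalized intensity inside
   the bin, floored at 0.
7. **Deisotoping.** Peak bins of the average spectrum are grouped into
   singly charged isotope envelopes by a greedy low-to-high m/z scan
   with exclusive membership: a chain grows while some later unassigned
   bin lies within 1 ± 0.03 Th of the previous member (the candidate
   with spacing closest to 1.0 wins ties), and a maximal chain is kept
   iff it has ≥ 3 members, its first (monoisotopic) peak is the most
   intense for distributions below 1700 m/z, and its second peak is more
   intense than the third — and than the fourth when one exists. The
   1700 boundary is exclusive; the fourth-peak clause applies only when
   a fourth member exists; members beyond the fourth face only the
   spacing rule. Rejected chains leave their bins available to later
   starts. Overlapping envelopes (e.g. a sodium adduct riding on another
   distribution's tail) are deliberately not deconvolved — they stay
   undetected, as in manual reading of profile spectra.
8. **Statistics.** Distribution-level features (member-bin rows summed)
   are compared across groups with the tie-corrected Kruskal-Wallis test
   (chi-square p with k−1 df; a Monte-Carlo permutation p is available
   for very small designs). Raw p-values are Bonferroni-multiplied by
   the number of distributions tested and called significant below
   α = 0.01. Significant features receive rank-based
   least-significant-difference pairwise post-hoc comparisons at
   α = 0.05: group mean ranks with standard error √(S²(1/nᵢ+1/nⱼ)),
   S² the tie-corrected variance of the joint ranks, two-sided normal
   critical value, no multiplicity adjustment. The post-hoc operates on
   the rank scale for consistency with the omnibus test. All-tied
   features report H = 0, p = 1 rather than undefined.

The chi-square approximation at group sizes of 4–10 is accurate in the
tail where decisions are made (agreement with a 20,000-draw permutation
null within ~0.007 at p ≈ 0.01 and N = 12) but can deviate by up to
~0.04 in the irrelevant high-p regime; this is why the permutation
option exists.

## Peptide mass calculus

Neutral monoisotopic masses are sums of standard residue masses plus
water (18.010565 Da), adjusted by modification deltas: C-terminal
amidation −0.984016, N-terminal pyroglutamate from Gln −17.026549, Met
oxidation +15.994915 and Tyr sulfation +79.956815 per site. Cationized
m/z values default to the *atom* convention — adding the neutral H
(1.007825), Na (22.989770) or K (38.963707) atom mass with no electron
correction — because that is how calculated values are conventionally
printed to three decimals in profiling reference tables; the physically
exact *ion* convention (−0.000549 for the electron) is available by
flag. The packaged Drosophila reference table (44 rows, 41 unique
peptide/modification combinations: 14 MS/MS-confirmed profile peaks plus
30 tentative mass-matched assignments, including [M+Na]+ and [M+K]+
forms) reproduces every printed calculated m/z within 0.002 Th under the
atom convention. One external table gives a theoretical PDNFMRFamide
[M+H]+ of 925.43594, about 0.6 mDa above the standard-constant value
925.4354 that this package computes; the standard value is reported.

Fragment ladders are singly protonated b/y/a series (bᵢ = first i
residues + proton, yᵢ = last i residues + water + proton,
aᵢ = bᵢ − CO); N-terminal modifications ride on b/a ions, C-terminal
amidation on y ions. Oxidation and sulfation are not positionally
tracked, so fragment generation refuses peptides carrying them. The
confirmation rule for MS/MS identifications requires ≥ 3 consecutive
matched indices within one series. Ile/Leu are distinct residues of
identical mass and are never disambiguated.

## The synthetic data generator

`simulate_experiment` produces profile spectra whose ground truth is
known exactly, so every pipeline stage can be tested against planted
values. The default design mirrors a three-strain differential
experiment: 50 peptide analytes between m/z 900 and 3900 with
log-uniform base abundances (20–400 intensity units), nine samples per
group, and one mid-abundance analyte at fold changes 0× / 1× / 5× across
the groups (an expression-null strain, wild type, and an
overexpressor). Each spectrum gets:

* averagine-model isotope envelopes (C₄.₉₃₈₄H₇.₇₅₈₃N₁.₃₅₇₇O₁.₄₇₇₃S₀.₀₄₁₇
  per 111.1254 Da, counts rounded with hydrogen balancing, elemental
  isotope distributions convolved, isotopologue spacing 1.00235 Th),
  split into H/Na/K adduct channels;
* per-spectrum Beta-distributed adduct fractions — Na ~ Beta(2, 48)
  (mean 4%), K ~ Beta(1.5, 8.5) (mean 15%, deliberately dispersed to
  emulate unevenly distributed residual potassium across samples);
* Gaussian peak shapes of FWHM = m/z / 8000 (a benchtop reflectron
  TOF resolution) on a uniform 120,001-point axis over 500–4000 Th;
* an exponential-decay baseline 40·exp(−m/700) + 2;
* heteroscedastic shot-noise-like Gaussian noise
  σ = 1 + 0.05·√signal, chosen over additive-only noise so that TIC
  normalization and the S/N estimator are exercised realistically;
* per-spectrum affine calibration jitter (30 ppm SD multiplicative,
  0.01 Th SD additive);
* lognormal biological abundance variation with CV 0.35.

All randomness flows from one integer seed; per-spectrum substreams are
derived from (seed, group index, sample index), so spectra are
bit-reproducible and independent of simulation order.

What the generator does **not** emulate: matrix-cluster chemical noise,
detector saturation, ion-suppression between co-desorbing analytes,
peak-shape asymmetry, and spot-to-spot extraction heterogeneity.
Passing tests on synthetic data therefore demonstrate that the
algorithms recover planted truth under a realistic noise/adduct/jitter
model — not that any particular real-tissue experiment will show the
same power.

## Signal-to-noise estimation

S/N of a peak is its apex intensity divided by 1.4826 × the median
absolute deviation of baseline-subtracted intensities within ±50 Th,
excluding points inside detected peak bins. This MAD-based definition is
this package's own (vendor software reports proprietary S/N values);
per-spectrum counts of deisotoped distributions above an S/N threshold
(default 6) are a QC metric, not a calibrated reproduction of any
instrument's count.

## Problem sizes and numerical choices

The test suite runs the full chain on simulated experiments of 21–27
spectra at 60,001–120,001 axis points, sizes at which an experiment
simulates in ~1 s and profiles in ~5 s; the familywise-error simulation
uses 200 repetitions of a 50-feature null design at the feature-matrix
level. Tolerances asserted in tests come from the constructions
themselves: 0.002 Th for reproducing printed reference m/z values
(printed precision), 2% for the FWHH of an ideal Gaussian (axis
discretization), 10% RMS for planted-baseline recovery, 0.02 for
chi-square vs permutation p in the tail. Ties are broken
deterministically throughout (leftmost plateau index, lowest-m/z
monoisotopic candidate, spacing closest to 1.0 Th), so identical inputs
and configuration yield identical outputs; output tables embed the
package version and a configuration hash.

## Known limitations

* Only singly charged species are modeled; multiply charged ions and
  charge-state deconvolution are out of scope.
* Envelope grouping is rule-based, not model-fitting: convolved or
  barely resolved envelopes are left ungrouped rather than decomposed.
* The total-average-spectrum binning trades per-sample sensitivity for
  a complete (missing-value-free) feature matrix.
* Bonferroni control with ~50–70 simultaneous tests is conservative;
  genuinely small effects will need larger group sizes than the 7–10
  this workflow was designed around.
* Annotation is by mass match alone (default 100 ppm); identical-mass
  peptides and isobaric modifications cannot be distinguished without
  MS/MS evidence.
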