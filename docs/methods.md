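# Methods note

This note records the generative models behind `rloopkit.simulate`, the
estimators in the scoring modules, the numerical choices, and the known
limits of realism. Everything here is recomputable from a `SimConfig`; no
fixed datasets ship with the package.

## 1. Flow-cytometry screen (screen I)

**Model.** The fraction of fluorescent cells in a well is logit-normal:

```
logit(frac) = logit(baseline × fold) + plate_effect + well_noise
plate_effect ~ N(0, plate_effect_sd²)   (shared by all wells of a plate)
well_noise   ~ N(0, well_noise_sd²)
```

Working on the logit scale keeps fractions in (0, 1) while making plate
effects and planted fold-changes approximately multiplicative at the small
baselines typical of recombination reporters (default baseline 1%). The
price is a Jensen bias: the mean of a logit-normal is not exactly
`expit(mean)`, so the mutant/wild-type ratio of *mean* fractions differs
from the planted fold by ~0.5% at the default noise SDs. Tests compare
recovered ratios within Monte-Carlo error, not exactly.

**Scoring.** Plate-median normalization removes the plate effect exactly in
the small-fraction regime (both numerator and median carry the same
multiplicative plate factor). The recombination index is a midrank
percentile — `100 × (#{wt < v} + ½ #{wt = v}) / n` — making it invariant
under any strictly monotone transform of the measurement scale. Pooled
wild-type wells are partitioned into 10 seeded comparison groups (sizes
differ by ≤ 1) so each mutant is tested against an independent wild-type
sample; p-values are two-sided Mann–Whitney with a Benjamini–Hochberg
column appended.

## 2. Replica-pinning screen (screen II)

Each strain yields 16 × 3 = 48 i.i.d. Bernoulli colony calls at its planted
recombination probability; positives get colony size 2.0, negatives 0.0, so
any size threshold in (0, 2] reproduces the planted calls. The wild-type
baseline call probability defaults to 0.02: at the 48-call depth this gives
a two-sided Fisher exact test ≥ 90% power against a 10-fold planted effect
versus the pooled wild-type reference (68 strains × 48 = 3264 calls),
matching the screen's intended operating point; a 0.01 baseline would leave
the per-strain expected positive count below 1 and power near 85%. Strains
whose fraction of growth-OK positions falls below 0.75 are excluded before
testing and carry no p-value.

## 3. Spike-in-calibrated DRIP

**Genome.** A single chromosome (default 200 kb) with 200 genes on a
regular grid, each body 60% of its slot and bin-aligned (20-bp bins), with
random strand and log-normal transcription level. True IP occupancy is a
flat background on both strands plus hybrid signal only on each gene's
**template** strand (Crick for `+` genes), proportional to
`txn_level × hybrid_per_txn`, scaled by `condition_fold` when treated and
by `rnh_residual` (default 0.1) after in vitro RNase H.

**Read model.** The IP read pool of a sample splits between the
experimental genome and the spike genome in proportion to their
immunoprecipitable material: experimental S (summed true density) versus a
fixed spike contribution `K = ip_efficiency × S_ref`, where `S_ref` is the
control/mock total. Per-bin counts are Poisson. Under this model the
calibration `calibrated = count × 1e6/ip_total × OR`, with
`OR = spike-fraction(input)/spike-fraction(IP)`, has expectation

```
calibrated_b = 1e6 × f_input × d_b / K
```

— linear in the true density `d_b` with a **sample-independent** constant,
and exactly invariant under a uniform rescaling of sequencing depth (all
counts and totals scale together; OR is a ratio of fractions). This is what
the acceptance suite checks.

**Background correction.** Raw per-gene densities include the nonspecific
background, which biases condition fold-changes toward 1 and RNase H
sensitivities downward (rnh retains the full background). The pipeline
therefore estimates each sample's background as the mean calibrated
intergenic density and subtracts it (clipping at 0) before computing
fold-changes, sensitivities, and specificities. With the default parameters
this recovers median fold ≈ 2.0 (planted 2), median sensitivity ≈ 0.90
(planted 1 − rnh_residual = 0.9), and mean template specificity ≈ 0.996.

**Interval arithmetic.** All coordinates are 0-based half-open. Gene
densities are overlap-weighted per-bp means over the body; metagene rows
are fixed 20-bp flank bins plus a body resampled to 50 bins, oriented
5'→3' and sorted by template body density (descending).

## 4. OK-seq orientation

The replication-direction proxy is piecewise linear and continuous across
intervals, with optional Gaussian noise. Fork direction is the sign of the
OLS slope (`scipy.stats.linregress`) under the
`positive_slope_means_rightward` convention; calls with `|slope| < 2 × SE`
are ambiguous. A gene is CD when the fork travels in its transcription
direction. At the default geometry (10-kb intervals, 100-bp steps) the
planted slope is ≈ 58 SE even at noise SD equal to half the slope, so
classification stays at 100% there; the acceptance bound is ≥ 95%.

## 5. Dot blots, quartiles, DE, qPCR

Standard curves are fitted in log-log space; if R² < 0.98 the
highest-amount point (the usual saturation culprit) is dropped and the line
refitted while ≥ 3 points remain. Relative hybrid level is the
(S9.6/dsDNA) amount ratio of sample over reference, so the reference scores
exactly 1 and membrane-wide exposure changes cancel. Quartiles are
contiguous descending-rank blocks with sizes differing by ≤ 1 (Q1 =
highest). Differential-expression categories use strict thresholds
(`log2FC > 0.58`, `p < 0.05`); boundary values are `unaffected`. qPCR %IP
is `100 × input_fraction × efficiency^(ct_input − ct_ip)` (defaults 0.05
and 2.0); adjusted %IP divides by the spike-in amplicon's %IP, cancelling
global IP-efficiency changes.

## 6. Imaging

Nuclei are flat disks (amplitude 10·√background over a Poisson background),
foci are σ = 1.2 px Gaussian spots whose peak amplitude is
`foci_snr × √background` (SNR = peak over shot-noise SD), placed ≥ 9 px
apart (Chebyshev) and within 0.75 r of the nucleus center so they stay
resolvable by a detector with `min_distance = 5`. The counter smooths the
projection (σ = 1.0) to suppress shot-noise maxima, then keeps peaks above
`median + prominence × (max − median)` (default prominence 0.4) — a
threshold invariant to uniform intensity rescaling. With these defaults
recovery is exact on noiseless images and ≥ 95% within ±1 focus at SNR 5.

## 7. Determinism and numerics

Every generator draws from `np.random.default_rng([seed, stream_id])` with
a fixed per-generator stream id, so stages are independent and reruns are
byte-identical; the pipeline summary is serialized with sorted keys.
Exact-test p-values come from `scipy.stats` (`fisher_exact`,
`mannwhitneyu`); the test suite validates them against independent
enumeration oracles (exhaustive hypergeometric tail sums, rank-assignment
enumeration) rather than trusting the library blindly.

## Limitations

* The Poisson read model ignores PCR duplication, mappability, and GC bias;
  calibrated-density linearity is exact only in expectation.
* Hybrid signal covers whole gene bodies uniformly; no 5'/3' asymmetry,
  antisense transcription, or read-through.
* The logit-normal well model has a small deterministic Jensen bias (see
  §1); effects planted near saturation (fold × baseline → 1) compress.
* Nuclei never touch and are perfectly circular, so segmentation is easier
  than in real micrographs; no watershed splitting is implemented.
* DE log-fold-changes and p-values are classified, not estimated — no
  count-model fitting is in scope.
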