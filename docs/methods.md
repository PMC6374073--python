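# Methods

## Scope and data flow

The package analyzes paired recordings from larval zebrafish cerebellum
during visuomotor behavior: cell-attached Purkinje/granule traces, a
ventral-root (VR) nerve recording reporting fictive swimming, eye traces,
stimulus epoch tables, calcium time series, 3D nuclear-GCaMP volumes, and
SWC-like morphologies. The stages are: spike extraction → behavioral event
extraction → design-matrix construction → encoding regression and phenotype
classification → spike-interaction statistics → population clustering and
spatial indices → anatomy (nucleus counting, planarity). A synthetic-data
generator produces all inputs with known ground truth, so each stage is
validated by parameter recovery rather than against irreproducible
recordings.

## Spike extraction

Cell-attached traces are zero-phase high-pass filtered (first-order
Butterworth, 3 Hz default within 1–10 Hz) and thresholded by amplitude: one
event per contiguous supra-threshold excursion, timestamped at the
excursion peak (the peak convention avoids double-counting multiphasic
complex-spike waveforms). Excursions whose peak exceeds the CS threshold
are complex spikes; remaining excursions above the SS threshold are simple
spikes, except within a 2.5-ms blanking window after each CS, which removes
late components of the CS waveform. Thresholding is applied to signed
positive excursions by default; a `rectify` flag thresholds |x| instead.
An automatic initializer splits excursion-peak amplitudes into noise /
SS / CS classes by a multi-level Otsu threshold on log amplitude, floored
at 4 robust noise SDs; thresholds can always be set manually.

Firing-rate series are the spike delta train convolved with a unit-area
20-ms boxcar, so the rate integral equals the spike count. Baseline rates
use blank trials when present, else the 2-s pre-stimulus window of each
trial; no eligible window is an error.

## Behavioral events

The VR envelope is a centered rolling standard deviation (population SD,
shrink-to-valid at edges). The VR window defaults to 10 ms — short enough
to resolve the ~27-Hz burst cycle for binarization, long enough to smooth
single spikes; the tail-trace vigor window is fixed at 50 ms, followed by a
200-ms median filter that extends vigor across the whole bout (both median
window and VR window are conventions of this package; only the 50-ms tail
window and the 100-ms merge gap are fixed by the protocol being emulated).
Bouts are supra-threshold runs of the envelope; runs separated by strictly
less than 100 ms merge into one bout (an exact 100-ms gap stays split, with
a 1-ns float tolerance). The default binarization threshold is 3x the
envelope median, which rest periods dominate. Swim frequency is the first
significant positive peak of the autocorrelation of the binarized in-bout
envelope, averaged across bouts; significance is assessed against the 95th
percentile of a within-bout sample-shuffle null (100 shuffles), and the
peak lag is refined by parabolic interpolation. Eye kinematics expand each
eye's position into signed position, smoothed-derivative velocity, and
positive/negative rectifications of each — 12 channels for the two eyes;
this decomposition of "position and velocity in different directions" is a
documented convention.

## Design matrices

The canonical electrophysiology design has 24 columns:

* 4 motion-onset boxcars (500 ms from each grating-motion onset, one per
  cardinal direction) — the window absorbs the 100–200 ms retino-cerebellar
  latency;
* 4 motion-duration boxcars; 1 graded grating-speed column;
* 4 rectified windmill velocities (CW/CCW x whole/half field), 1
  direction-change impulse train;
* 2 luminance-transition columns and 1 ambient-luminance level. Transition
  responses carry the same synaptic latency as motion onsets, so each
  transition opens a 500-ms window rather than an impulse;
* 7 swim columns: onset and offset impulses, duration boxcar, max-normalized
  graded vigor, and three derived timing variants (300-ms post-onset window,
  300-ms post-offset window, duration-graded boxcar).

Complex-spike analyses drop the post-offset window and the duration-graded
boxcar (22 columns); which two of the 24 are dropped is a package
convention, and the whole composition is configurable. Imaging designs use
the coarser duration/velocity/luminance set without onset windows and are
causally convolved with k(t) = exp(−t/τ), τ = 1.6 s, then renormalized to
unit maximum (renormalization convention: max-abs). Electrophysiology
designs are smoothed with the same unit-area 20-ms boxcar as the rates.
Columns are z-scored inside the encoder, not in the design module.

## Encoding model

OLS (λ = 0) serves calcium responses; the elastic net serves spike rates.
The solver is cyclic coordinate descent (via scikit-learn's `ElasticNet`,
whose objective is algebraically identical to the penalized least-squares
form above), intercept unpenalized, convergence tolerance 1e-8; tests check
the solver's objective value against an independent dense-grid search on
all systems with ≤ 3 regressors.

**Penalty scaling.** The reference values α = 0.2 with λ = 0.9 (CS) / 0.8
(SS) apply to responses in raw rate units (the originating MATLAB solver
standardizes the design but not the response). This package z-scores both
X and y, which divides the effective λ by the response SD; for
20-ms-filtered spike rates the shot-noise SD is ~4–6 Hz, so the z-scored
equivalents are ≈ 0.15–0.2, and the desk-scale pipeline default is
λ = 0.1. On z-scored data the raw values 0.9/0.8 zero every coefficient
(the soft threshold λα = 0.18 exceeds any attainable spike-rate
correlation) — a scaling artifact, not a property of the data.
`select_lambda` implements the selection procedure itself: λ minimizing
summed RMSE across a dataset, scored by K-fold out-of-fold prediction by
default (in-sample scoring is available but degenerates to the smallest λ
on any grid); ties prefer the sparser model.

A coefficient is "significant" when it survives elastic-net selection.
Normalized weights are |β|/Σ|β| (sum-abs convention); category fractions
sum to 1 within each level (sensory/motor groups, and subcategories).
Phenotype labels collapse per-direction onsets to `motion_onset`, CW/CCW to
`rotational_velocity`, both transition signs to `luminance`, and graded
grating speed to `motion_duration`; ties break by summed category weight,
then by a fixed category order, and are flagged ambiguous. The calcium
CS/SS decomposition regresses dF/F on kernel-convolved CS- and SS-rate
regressors and reports |β_s|·SD(regressor_s) shares (identical to plain
|β| shares on z-scored designs, up to scaling).

## Spike-interaction statistics

CS-triggered SS histograms use 10-ms bins over ±300 ms (covering
modulations lasting hundreds of milliseconds), normalized to the mean
per-bin count in the 100 ms preceding each trigger; cells with fewer than
10 triggers in a condition are excluded. Context splits assign a trigger to
the motor condition iff it falls inside a detected bout; sensory subsets
use the full containing epoch. Bout-triggered rates average the
20-ms-filtered rate aligned to bout edges and report the 300-ms post-onset
mean used for sorting. In-bout autocorrelation uses 5-ms bins concatenated
across bouts with a Ljung-Box Q test at 20 lags (both bin width and lag
count are package conventions); calibration is verified against the
binomial confidence interval of the nominal level over 500 null runs. The
direction-selectivity index defaults to the preferred-versus-opposite
contrast (R_p − R_o)/(R_p + R_o); a vector-sum variant is available behind
a flag since the printed 0.2–0.9 range cannot disambiguate the formula.

## Population analysis

Voxelwise correlation maps are Pearson r per voxel (zero-variance voxels
flagged as 0). Preference maps label a pixel sensory or motor only when the
winning map leads by at least `min_distance`, else neutral. Functional
clustering is PCA on per-ROI correlation (default) or coefficient vectors
followed by k-means on the first 10 PCs with k = 10, fixed seed, 50
restarts. The anatomical clustering index divides the expected distance
from a cluster ROI to a random same-fish ROI by the mean within-cluster
distance; the random draw is computed in expectation (exact mean over all
other ROIs) rather than by sampling, with a Monte-Carlo equivalent implied
by permutation tests. The stereotypy index divides cross-fish
other-cluster distance by cross-fish same-cluster distance. Both average
per fish and then over fish (fish-weighted, a documented choice), equal 1
under chance and are scale-invariant.

## Anatomy

Nucleus counting cross-correlates the volume with a spherical Gaussian
template (radius 3σ, normalized cross-correlation) and takes local maxima
above a score threshold (default 0.25) with non-maximum suppression at 3
voxels; suppression uses a Chebyshev neighborhood, so the radius is kept
below the physical nucleus spacing. The manual false-positive curation this
emulates is replaced by the threshold + suppression rule for automation.
Planarity is λ₃/λ₂ of the point-cloud covariance eigenvalues (variance
convention; a singular-value option returns the square root), 0 for planar
arbors, 1 for isotropic clouds; collinear sets are an error.

## Synthetic-data generator

The generator's defaults are the study conditions. Complex-spike baselines
are 0.20 / 0.77 / 0.28 / 0.34 Hz for motion-onset / rotational / luminance /
motor phenotypes. Motion-onset cells respond in the 500-ms windows after
their two adjacent preferred directions with an expected 1.2 spikes per
window; rotational cells fire at 4.4x baseline during preferred-sign
half-cycles of the windmill, 0.32 Hz during the opposite sign, and are
depressed to 37% of baseline for 1 s after each rotation epoch (clockwise
preference is tied to the left hemisphere); luminance cells emit one spike
with probability 0.80 per preferred transition at a fixed per-cell latency
(150–400 ms, ≤ 10 ms jitter); motor cells add a CS with probability 0.38
per bout. Simple spikes rest at 7.6 Hz and run at a 14.5-Hz in-bout time
average, scaled linearly with the instantaneous planted vigor; granule
cells rest at 1.3 Hz and average 25.7 Hz in-bout, optionally phase-locked
to the burst cycle. All spikes are thinned inhomogeneous Poisson with a
2-ms dead time whose intensity is compensated pointwise
(λ* = λ/(1−λτ_d)) so the observed rate equals the planted rate — without
compensation the rate contract (empirical → planted as T → ∞) cannot hold.

Behavior: bout onsets form an inhomogeneous renewal process (0.15/s
spontaneous, +0.45/s during forward/lateral motion, no elevation for
reverse motion, ≥ 1-s gaps); durations are drawn from 0.2–0.6 s and then
quantized to whole 26.7-Hz burst cycles plus one burst so VR activity
starts and ends exactly at the bout edges; amplitudes vary with CV 0.3
(floored at 0.4). Within a bout the VR noise SD is modulated by a
trapezoidal profile (20-ms attack/decay, as in real bout envelopes) times a
burst/inter-burst duty cycle (duty 0.4, peak 14x rest SD). The planted
vigor is the smooth cycle-free profile. Eyes follow the windmill velocity
with per-epoch gain jitter (CV 0.3), 50–150 ms latency and slow drift, and
no saccades. Sessions default to 5 stimulus trials plus 3 blank trials of
100 s each — a realistic ~13-minute cell-attached recording that gives
every per-cell statistic a usable precision at desk scale.

Calcium is A_cs·(δ_cs ⊗ k_τ) + A_ss·(δ_ss ⊗ k_τ) + Gaussian noise sampled
at 30 Hz, with the exponential implemented as an exact recursive (IIR)
filter. The amplitude ratio A_cs/A_ss is derived in closed form from
Campbell's theorem so that, at the default paired-recording rates (CS
0.5 Hz, SS 7.6 Hz), complex spikes carry 78.4% of the signal variance;
paired recordings are stationary blank-condition segments because the
decomposition isolates indicator amplitudes, not behavioral modulation.
Volumes place 433 spherical-Gaussian nuclei (σ = 2 voxels) at ≥ 8-voxel
spacing in a 128x128x48 volume with SNR 5; packing failures after bounded
retries are an error. Morphologies are anisotropic Gaussian clouds with
axis variances (1, 0.4, 0.4·target), giving the requested PC3/PC2 ratio in
expectation.

**What the generator does not emulate:** bursty non-Poisson spike
statistics (CS doublets, SS regularity), electrode drift and waveform
nonstationarity, eye saccades, optics (point-spread functions, bleaching,
neuropil contamination), correlated noise across voxels, and
behavior-locked artifacts in the VR electrode. Passing recovery tests
therefore demonstrates correctness of the analysis chain under the stated
generative model, not robustness to every artifact of real recordings.

## Numerical conventions and degenerate inputs

Impulses land on the nearest sample; epoch windows use half-open
[t_on, t_off) intervals; envelope edges shrink to the valid part of the
window; zero-variance design columns get zero coefficients; rank-deficient
OLS falls back to the pseudoinverse and is flagged; a decomposition with no
spikes of one type returns a flagged 100/0 split; all-zero encoding fits
classify as "unclassified". Random streams derive from a single seed via
named substreams (CRC32 tags), so identical configurations are
bit-reproducible and different components never share a stream.

## Desk-scale problem sizes

The recovery studies run at the sizes the emulated study reports: 61
Purkinje cells (31 motion-onset, 12 rotational, 10 luminance, 8 motor; one
synthetic fish each), 30 fish for the swim-frequency estimate, 8 paired
ephys+calcium cells, 6 granule cells, and one 433-nucleus volume. These
sizes keep the whole acceptance computation under a minute on one CPU while
leaving every population estimate's sampling error several times smaller
than the tolerance it is checked against.

## Known limitations

The exact identity of the original 24-regressor set is not published, so
the canonical composition above is a stand-in with the printed counts; the
λ-scaling argument maps the printed penalties to z-scored data but cannot
recover the original response units exactly; the spatial indices'
ROI-versus-fish weighting is a choice; and the elastic-net path at very
high collinearity (|r| > 0.95 between columns) inherits coordinate
descent's known slow convergence — the design deliberately avoids such
pairs.
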