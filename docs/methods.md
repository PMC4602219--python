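# Methods

`mouseerp` implements a spatio-temporal analysis of auditory event-related
potentials (ERPs) recorded from six epidural electrodes over the mouse
cortex (frontal, parietal and occipital pairs), aimed at a single question:
how well do time-domain ERP features predict an animal's genotype (wild
type vs. *Sp4*-hypomorph-like mutant), and how much does the multi-channel
waveform add over classical single-channel peak analysis?

## Pipeline

1. **Epoching.** Continuous 1 kHz recordings are cut into (−500, 500) ms
   windows around each click onset, half-open in samples — exactly 1000
   samples per epoch with t = 0 included. Events whose window is truncated
   by the recording edges are dropped. No baseline correction is applied by
   default (an optional pre-stimulus-mean subtraction exists but is off),
   matching the minimal acquisition chain being modelled.
2. **Artifact rejection.** An epoch is discarded if any sample on any EEG
   channel exceeds 1 mV in magnitude, with a strict inequality: an extreme
   of exactly 1000 µV is retained. The mask is monotone — rejection never
   resurrects an epoch.
3. **Block averaging.** Retained epochs are grouped into consecutive,
   non-overlapping blocks of k (k ∈ {1, 2, 4, 8, 16, 32}) in trial order
   within each animal and averaged sample-wise; a trailing remainder
   shorter than k is discarded. Consecutive-in-time grouping was chosen
   over random subsets: it is deterministic, respects session order, and
   reuses no epoch.
4. **Features**, computed on the (0, 250) ms post-stimulus window:
   - *Peak components*: latency and signed amplitude of N1, P1, N2 per
     channel (6 features/channel; 5 channels FL, FR, PR, OL, OR for the
     multi-channel family, FR alone for the single-channel family).
   - *Waveform principal components*: the per-channel waveforms are
     concatenated in a fixed channel order (1250 dimensions at 1 kHz) and
     compressed by mean-centred PCA; the scores on the first q components
     are the features, with q selected by nested cross-validation.
5. **Classification.** A two-class Fisher linear discriminant with a scalar
   threshold, evaluated by leave-one-animal-out cross-validation.
6. **Spatial maps.** The discriminant weight vector is mapped back to
   waveform space, factorized into a temporal profile and per-channel
   weights, and each animal's mean ERP is projected onto the temporal
   profile to yield one scalar per electrode, interpolated over the
   cortical plane.

## Peak detection

The waveform is smoothed with a 5 ms moving average; local extrema of the
smoothed trace are scanned in time order and the first three extrema of
alternating type (minimum/maximum) fill the N1, P1, N2 slots. A minimum
fills an N slot, a maximum a P slot; if the first extremum is a maximum it
fills P1 and N1 stays invalid. The reported amplitude is the signed raw
(unsmoothed) value at the extremum sample; the latency is its time. A
component whose raw amplitude contradicts its slot sign is invalid, and
invalid slots are imputed downstream with the column mean over valid
entries of the *training* partition (imputation statistics are fitted
pipeline state; rows are never dropped, keeping sample counts identical
across feature families).

Only *prominent* deflections count as extrema: a peak must have a
prominence of at least 10 % of the smoothed waveform's range. Without this
floor, residual noise wiggles of a microvolt or two claim the first
component slots and scramble the N1/P1/N2 assignment even on 32-trial
averages; with it, detection keys on the same major deflections a human
would mark on the average trace. The relative definition keeps the
detector equivariant to amplitude scaling. On noise-free templates the
floor is inactive (all three planted components are far more prominent).

## Fisher discriminant

With pooled within-class scatter S_w, class means μ₁ (WT) and μ₀ (HYPO)
and dimension d, the weight vector is

    w ∝ (S_w + λI)⁻¹ (μ₁ − μ₀),    λ = 10⁻⁶ · tr(S_w)/d ,

normalized to unit length. The small ridge keeps the solve well-posed when
features outnumber what mild averaging leaves of the sample budget; when
the scatter is exactly zero (noise-free data) the ridge floor makes w fall
back to the mean-difference direction. If the class means coincide to
numerical precision the classifier is flagged degenerate and predicts the
majority class (ties resolve to WT).

The threshold b is chosen by an exhaustive scan over the midpoints of
consecutive sorted training projections, minimizing the **class-balanced**
training misclassification (each sample weighted inversely to its class
count); ties are broken by the widest margin between the flanking
projections. The balance weighting matters: under leave-one-animal-out
folds the held-out animal's class is always the training minority (e.g.
512 vs. 576 samples), and an unweighted scan then systematically pushes
the boundary into the held-out class's territory — on a null cohort this
inflates the cross-validated error far above chance (we measured 0.66–0.92
where 0.5 is expected; even with i.i.d. features, 0.58–0.71). The balanced
criterion removes this artifact and is identical to the unweighted one
whenever classes are balanced or separable. Samples projecting exactly
onto b are assigned to the class above b.

## Cross-validation protocol

Leave-one-animal-out: all samples of one animal form the test set of a
fold, so no subject-identity information can leak. Within each fold, every
piece of fitted state — peak-imputation statistics, the PCA basis, the
number of components q, the discriminant — is computed from the training
animals only. q is selected by an inner leave-one-animal-out loop over the
training animals, minimizing the pooled inner error over a grid
(1…100 by default); ties go to the smallest q. The selected q is then used
for a final PCA + discriminant fit on the full training partition. The
aggregate error is the pooled per-sample error over all held-out samples;
per-animal majority-vote calls are reported alongside (vote ties resolve
to WT). An animal left with no complete k-block is excluded from that cell
with a warning.

Performance note: within an inner fold the scatter matrix is computed once
at the largest q and sliced for each grid value (the scatter of a column
prefix is the corresponding leading submatrix), which makes the dense grid
affordable; a test asserts the sliced path is bit-equal to direct fits.
PCA in cross-validation caps its rank at the grid maximum; on large
matrices scikit-learn's randomized solver runs under a fixed seed, so
repeated runs are identical.

## Temporal discriminant and cortical maps

The PC-space weight vector is mapped back through the PCA loadings to
waveform space, reshaped to channels × time, and factorized by singular
value decomposition. The leading right-singular vector (unit norm, sign
fixed so its largest-magnitude sample is positive) is the *temporal
discriminant*; the leading left-singular vector scaled by the leading
singular value gives per-channel spatial weights, with the compensating
sign kept on the spatial side so the rank-1 product is invariant. The
rank-1 SVD factorization is our operationalization of "projecting out the
temporal component": it is unique, deterministic, and cleanly separates
space × time. Projecting each channel's animal-mean (0, 250) ms ERP onto
the temporal discriminant yields one scalar per electrode; thin-plate
radial-basis interpolation through the electrode coordinates (exact at the
electrodes) produces the cortical map on a 0.1 mm grid over AP ∈ [−6, 3],
ML ∈ [−4, 4] mm. For the map product only, the discriminant is fitted on
all animals pooled (never fed back into cross-validation).

The channel-cluster geometry uses the affine plane through the three grand
averages of FR, PR and OR: origin at their centroid, basis by Gram–Schmidt
on the first two mean-centred waveforms (the order (FR, PR) is a
convention affecting only the 2-D orientation, not distances). Covariance
ellipses are the nσ contours of 2-D sample covariances; a Mahalanobis
separation readout between clusters is provided.

## Synthetic cohorts

No animal data ship with the package; a generator produces cohorts with
known ground truth. Each channel's evoked response is a sum of three
Gaussian components. Wild-type frontal template: N1 (−30 µV, 25 ms, 8 ms
SD), P1 (+40 µV, 60 ms, 15 ms), N2 (−20 µV, 120 ms, 30 ms); parietal =
frontal × 0.7 with +5 ms latencies; occipital = frontal × 0.5 with +10 ms;
left/right are symmetric. The mutant effect flips occipital N1 polarity
(amplitude scale −0.8), attenuates frontal P1 (scale 0.7) and delays
frontal N1 by 10 ms — amplitude, polarity and latency alterations of the
kind the disease model is reported to show, with magnitudes chosen once so
that multi-channel waveform features at 4-trial averages classify the
default cohort with a single-digit error while the null cohort stays near
chance. A cohort has 9 animals per genotype (sexes alternating, 5 F / 4 M
per group), 1100 click trials per session at 2.5 s inter-stimulus
interval, sampled at 1 kHz; the signal is quantized to 0.1 µV steps as a
16-bit digitizer would.

Noise is 1/f^β (β = 1) synthesized by spectral shaping of white Gaussian
noise with content below 0.1 Hz zeroed (the amplifier low-cut), scaled to
20 µV per single trial. Each animal carries a multiplicative evoked-gain
factor drawn once from N(1, 0.1²) — a subject random effect. Artifact
spikes of ±1.5 mV land in a random 2 % of inter-stimulus windows so the
rejection rule is exercised. Optional trial-to-trial latency jitter exists
but defaults to off. Per-animal seeds derive deterministically from the
cohort seed, so any animal can be regenerated in isolation.

What the generator does **not** emulate: EMG and behavioral state,
sleep–wake structure, stimulus acoustics, volume-conduction correlations
between channels (noise is independent per channel), electrode impedance
drift, or line noise. Passing tests therefore demonstrate correctness of
the analysis pipeline under a plausible statistical twin of the recording
conditions, not performance on real mouse EEG.

A note on the null cohort: even with the genotype effect removed, the
leave-one-animal-out error is not exactly 50 %. Two genuine small-sample
effects remain. First, excluding the held-out animal shifts its own class
mean away from it, anti-correlating the discriminant with that animal's
session mean. Second, animal-level variance (the evoked-gain factor and
the < 0.4 Hz band of the 1/f noise, which correlates epochs within a
session) makes the pooled error behave like ~18 partially-unanimous
subject-level draws, with a standard deviation near 8 percentage points
across cohorts. Both effects are well-known hazards of subject-level
cross-validation in small cohorts and are left visible rather than
corrected away.

## Problem sizes

Simulations in the test-suite and the acceptance script use cohorts of 18
animals with 256–512 trials per session (with 20-seed sweeps at 512 trials
for the ordering and map-sign checks), a deliberate scale-down of the
1100-trial reference sessions: the quantities being checked (error rates
at fixed k, orderings between feature families, sign patterns of maps) are
stable at these sizes while keeping a full run in minutes on one core.

## Known limitations

- Peak labeling assumes the N1–P1–N2 polarity sequence; waveforms whose
  first prominent deflection is positive leave N1 empty by design.
- The inner component-count selection minimizes a cross-validated error
  that is itself a noisy, slightly biased estimate; on null data the
  chosen q is essentially arbitrary (as it should be).
- Thin-plate maps extrapolate beyond the electrode hull; values far from
  the montage are smooth extensions, not measurements.
- The 2-D covariance-ellipse separations between channel clusters are
  descriptive; no calibrated statistic is attached to them.
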