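# Methods

`glucotyper` classifies continuous glucose monitoring (CGM) traces into three
glycemic-signature classes — low, moderate, and severe variability — and
summarizes subjects by the class in which they spend most of their time
(their *glucotype*). This note documents the model, the numerical choices,
and what the synthetic cohort generator does and does not emulate.

## Preprocessing

CGM readings (nominally every 5 minutes, mg/dL) are snapped to a uniform
5-minute grid. Interior gaps strictly shorter than 15 minutes are linearly
interpolated and marked imputed; longer gaps stay missing and disqualify any
window that overlaps them. The trace is segmented into sliding windows of
2.5 h (30 samples) with 75% overlap. A 75% overlap of a 150-minute window
implies a 37.5-minute shift, which is off the 5-minute grid; cumulative
starts are realized as `round(i × 37.5 / 5) × 5` minutes (shifts alternate
40/35 minutes, preserving the overlap on average), and a fixed on-grid shift
can be configured instead. Each complete window is smoothed with a
Savitzky-Golay filter (order 3, 5-sample window by default — the filter
passes constants and ramps unchanged and attenuates isolated spikes) and
z-scored with the sample (n−1) standard deviation. Zero-variance windows are
flagged degenerate and excluded. Per-subject window counts are equalized to
the cohort minimum N by keeping each subject's N earliest windows.

## Dissimilarity: CID-DTW

Window dissimilarity is complexity-invariant dynamic time warping on the
z-scored values. The DTW kernel uses the classical symmetric step pattern
(diagonal steps doubly weighted; a unit-weight variant is a flag), local
cost |a−b|, and a Sakoe-Chiba band of ⌈0.10 × window length⌉ samples (3 for
the default window). The complexity estimate is CE(x) = √Σ(xᵢ−xᵢ₊₁)², and
the complexity correction multiplies the banded DTW value by
max(CE)/max(min(CE), ε) with ε = 10⁻¹², so mismatched waveform complexity
inflates the distance and the correction never decreases it. The kernels are
numba-compiled; a 3,000-window matrix (~4.5M pairs) takes seconds on one
core.

## Spectral clustering

The affinity graph is the symmetrized n-nearest-neighbor graph with unit
weights, with n the smallest value for which the graph is connected —
connectivity is verified spectrally, as exactly one (near-)zero eigenvalue
of the unnormalized Laplacian L = Deg − W. Ties at the n-th neighbor break
by window order, so the graph is deterministic.

The number of classes k comes from the eigengap of L. Because the spectrum
tail of a binary kNN graph grows roughly linearly, the single largest
absolute difference between consecutive eigenvalues is often a tail
artifact, and when the between-community cuts have heterogeneous weights the
largest *relative* gap latches onto the single weakest cut. The default rule
therefore takes the largest candidate k with λ_k ≤ ⅓ λ_{k+1} — the last
point at which the leading eigenvalues are still collectively small relative
to the successor, which is the textbook prescription ("λ₁…λ_k all very
small, λ_{k+1} comparatively large") read literally. Both max-gap variants
remain available via a flag, and candidates are bounded to 2 ≤ k and
k < W/2.

Windows are embedded in the rows of the first k eigenvectors of L and
partitioned with k-means (50 seeded restarts). Clusters are ranked by the
mean raw glucose of their member windows; ascending rank maps onto
low / moderate / severe (generic ordinal names for k ≠ 3). With CGM data
the classes increase in variability and mean glucose together, so this
ranking is stable.

## Out-of-sample classification

New windows are scaled with the *global* training mean and standard
deviation (not per-window z-scores); the reference windows are represented
in the same global scale so the new-versus-reference CID-DTW distances live
in one space. References are a per-class stratified sample of the training
windows — max(200, number of windows to classify), capped at the pool —
drawn with probability proportional to a Gaussian kernel density (Scott
bandwidth) of the training points in eigenvector space, which concentrates
references around the class centroids; a class too degenerate for a KDE
falls back to uniform weights. Selection is deterministic given the seed.

Distances to the references become affinities via the similarity-network-
fusion kernel w = exp(−d²/(σ·ε)), where ε averages the mean 20-nearest-
neighbor distance of the row, of the column, and d itself. The kernel scale
σ is precomputed at training as the value that makes the median off-diagonal
training affinity equal 0.5 (σ = median(d²/ε)/ln 2). Each new window's
embedding is its affinity-weighted average of the reference eigenvector
rows, normalized to unit length; the label is the class of the nearest
centroid (centroids also unit-normalized), with ties broken toward the more
severe class as the conservative choice for risk flagging. An all-zero
affinity row is reported as unclassifiable rather than silently defaulted.

## Variability metrics

Descriptive statistics, rate-of-change measures (first differences over the
5-minute interval; the mean rate uses absolute differences), distance
traveled Σ|Δg|, coefficient of variation, and threshold counts (upward
crossings of 140 and 200 mg/dL — entries into the range, not sample counts)
are computed per window or per trace. MAGE follows the Baghurst
autodetection algorithm: turning points are located on the smoothed trace,
then iteratively pruned — same-direction runs re-merged, interior turning
points whose excursions on both sides fall below one sample SD of the whole
trace deleted — until the retained extrema strictly alternate; MAGE is the
mean amplitude of the retained excursions measured on the raw values, with
ascending-only and descending-only variants also available. The J index is
0.001 × (mean + SD)². MODD anchors at 06:00 each day (nearest sample within
±15 minutes, a tolerance for sensor grid jitter) and averages absolute
differences between consecutive anchored days. Cluster quality uses the
distance-based sum-of-squares decomposition SS(C) = Σ_{i<j∈C} d²ᵢⱼ/|C|
(reducing to the Euclidean decomposition exactly when d is Euclidean),
silhouette on the precomputed distances with singletons scored 0, CH =
(totBSS/(k−1))/(totWSS/(W−k)), entropy of cluster-size fractions in nats,
and Dunn = min between-cluster distance / max cluster diameter.

## Subject summaries

Class fractions are window counts over total windows; the glucotype is the
argmax fraction with ties resolved toward the more severe class. ADA
diagnosis: diabetic at HbA1c ≥ 6.5%, fasting glucose ≥ 126 mg/dL, or 2-h
OGTT ≥ 200 mg/dL; prediabetic at HbA1c in (5.7, 6.5) — the strict lower
bound is deliberate and documented — fasting glucose 100–125, or OGTT
140–199; otherwise normoglycemic, with missing measurements skipped and
raising any measurement never lowering the category. Time-in-range uses the
prediabetic (140, 200] and diabetic (200, ∞) mg/dL glycemic bands over all
retained readings. A standardized-meal response is scored by the windows
starting within ±20 minutes of the annotated consumption time (inclusive)
and takes the most severe class among them; meals without a usable
annotation are unclassifiable. The meal-by-class contingency is tested with
an uncorrected chi-squared statistic.

## Synthetic cohorts

The generator is phenomenological: glucose(t) = regime baseline + circadian
sinusoid + a pulse train + AR(1) sensor noise (sd 4 mg/dL, lag-1
autocorrelation 0.7 — autocorrelated because CGM sensor error is, and white
noise would make DTW trivially easy), clipped to the 40–400 mg/dL device
range, with Poisson sensor-dropout gaps (0.3/day, log-normal lengths around
20 minutes).

The three regimes are *stereotyped waveform classes*, not one shape at
three amplitudes: per-window z-scoring erases amplitude, so regimes that
differ only in pulse height are not recoverable at the window level —
within-regime phase heterogeneity then exceeds between-regime gaps.
Defaults: low = a fast ultradian ripple (15–25 mg/dL bumps every 30
minutes; the period is at most twice the DTW band, so any two low windows
align under banded DTW), moderate = broad single postprandial domes
(40–60 mg/dL, ~55 minutes to peak, every 3 h), severe = sharp high-amplitude
spikes (80–120 mg/dL, ~22 minutes to peak, every 2.4 h) with a rebound
undershoot of 0.25 × height, the signature of delayed counter-regulation.
Baselines 80/90/120 mg/dL and circadian amplitudes 5/8/12 mg/dL grade
upward with severity (fasting hyperglycemia dominates the severe class
mean, keeping the low < moderate < severe ordering of mean glucose). Pulse
timing jitter is ±5 minutes, within the Sakoe-Chiba band, so same-regime
windows across subjects and days are mutually alignable.

Standardized meals (each of three meal types twice, at the habitual
breakfast slot) scale the nearest scheduled pulse by a net-carbohydrate
factor (0.8/1.0/1.3) without changing its shape or timing. Clinical records
draw fasting glucose, HbA1c, OGTT, and SSPG from regime-shifted normals so
diagnosis-versus-glucotype cross-tabulations have signal.

What passing tests on this generator do and do not show: regimes are
regime-homogeneous by construction (every window of a subject carries the
regime's waveform), so window-level recovery of subject regimes is a
well-posed parameter-recovery test; real cohorts are heterogeneous within
subject — the published analysis reports *fractions* of time per class —
so recovery scores here do not transfer to real data. Meal responses
modulate amplitude only, so the meal-type-by-severity association is null
by construction in the generator; the association machinery is exercised,
not its effect size. Sensor artifacts beyond AR(1) noise and dropout
(calibration jumps, compression lows, drift) are not emulated.

## Problem sizes and determinism

The default test and acceptance cohort is 12 subjects × 7 days (~2,900
windows after equalization), which exercises the full pipeline in about half
a minute on one core. All stochastic stages (simulation, k-means,
reference selection) take explicit seeds; repeated runs with the same seed
are bit-identical for deterministic stages and label-identical for seeded
ones. Eigendecompositions use a dense solver below 200 windows and
shift-invert Lanczos above, with a 10⁻⁸ zero-eigenvalue tolerance.
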