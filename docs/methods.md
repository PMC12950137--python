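# Methods

## The analysis model

`caldyn` treats a calcium-imaging session as a neurons × frames fluorescence
matrix F sampled at a known rate (default 10 Hz) over a known schedule of
behavioral/pharmacological conditions (default: 100 s awake, 600 s isoflurane
split into induction + maintenance, 700 s recovery split into early + late;
1400 s total). Two complementary analyses are layered on top:

* a **temporal** analysis that asks, without using the schedule, which
  stretches of the recording share the same population-activity regime
  ("brain states"), and
* a **per-neuron** analysis that asks which activity class each neuron
  occupies within each regime, and how neurons move between classes as the
  regimes change.

### ΔF/F and event detection

ΔF/F = (F_t − F₀)/F₀ per neuron, with F₀ the 10th percentile (linear
interpolation between order statistics — percentile dialects differ, so the
convention is fixed here) of that neuron's fluorescence inside consecutive,
non-overlapping windows of `baseline_window_s` (default 100 s) aligned to
frame 0. A trailing partial window is allowed. F₀ ≤ 0 is an error rather than
a silent clamp.

Events are local maxima of the ΔF/F trace strictly exceeding
median + `threshold_mad` · 1.4826 · MAD of the whole trace. The MAD rule is
scale-free across neurons; 1.4826 makes it a robust σ estimate. The default
`threshold_mad` is 3.5: a 3σ threshold over a 14,000-frame recording admits
on the order of ten noise peaks per neuron, enough to contaminate the
near-silent class whose biological count is ≤ 1 event per window. Peaks
closer than `min_separation_s` (default 0.8 s) are resolved greedily in
descending amplitude (ties → earlier frame), which is deterministic and
order-independent; so at most one event is reported per refractory interval.
The reported event time is the **peak frame time**; it trails the true event
onset by the kernel's rise-to-peak lag (≈ 0.17 s for the default kernel), a
fixed offset that round-trip tests account for. Whether peaks should be
detected on ΔF/F, raw F, or deconvolved traces is genuinely ambiguous in this
analysis style; ΔF/F is the default and the function accepts any ΔF/F-scale
input.

### Temporal segmentation

Frames are cut into contiguous, non-overlapping 100-frame windows (trailing
remainder dropped). One shared PCA basis is fitted over the neuron dimension
of the whole recording and the smallest number of leading components whose
cumulative explained variance reaches `variance_target` (default 0.96) is
retained; windows become C-channel sequences in a common coordinate system.
A per-window basis was rejected: windows projected into different bases have
no common geometry, and inter-window DTW would be meaningless. The
"flattened 1-D vector" alternative (PCA across flattened windows, DTW over
the coefficient index) is implemented as `make_windows_flat` for comparison.
Component signs are fixed (largest-magnitude loading positive) so the basis
is deterministic.

DTW uses the classic symmetric step pattern (1,1), (1,0), (0,1) with
Euclidean local cost between column vectors, no slope weighting and no
path-length normalization. DTW is symmetric, nonnegative, and zero on
identical series, but it is not a metric (no triangle inequality), which is
why clustering uses average linkage on the raw dissimilarity rather than any
embedding. An optional Sakoe–Chiba band is exposed for speed; the default is
unconstrained, since 100-frame windows are cheap (a 140-window recording is
9,730 DTW evaluations, a few seconds). The pairwise cost matrix is computed
via the Gram expansion with a relative-epsilon clamp so that identical
columns yield an exact zero cost despite float cancellation.

Average-linkage agglomeration is implemented directly on the distance
matrix: at each step the pair of clusters with the smallest mean pairwise
inter-cluster distance merges (ties → the smallest pair of cluster
representatives, a cluster's representative being its smallest window
index). Exact pairwise sums are maintained, so heights are true means of
original distances. Labels at a cut are numbered 1..k by each cluster's
smallest window index.

The class count is suggested by the knee of W(k), the sum over classes of
all within-class pairwise distances for nested cuts k = 1..k_max (default
10): the interior k maximizing the discrete second difference
W(k−1) − 2W(k) + W(k+1), ties → smallest k. **Known limitation:** W(k) sums
grow with the square of class sizes, so when the true classes are very
unequal in size (the default schedule yields 10/10/50/35/35 windows) the
largest curvature sits at the first big merge and the rule recommends a
small k even when the five-class cut is essentially perfect (adjusted Rand
index 1.0 against the planted states). This mirrors the general fragility
of sum-based elbow criteria under unbalanced clusters. The cut count is
therefore manually overridable everywhere (`k_temporal` in the pipeline
config), exactly as one would fix it from inspection of the dendrogram.

One representative 100-s block per temporal class is then chosen: for each
class, in order of first appearance, the contiguous run of ten 10-s windows
with the highest fraction of that class's label (ties → earliest; a purity
≤ 0.5 triggers a warning). Blocks are renamed P1..P5 in temporal order.

### Feature extraction and classification

Per (neuron, phase): firing count f over the half-open window [start, end)
(half-open so counts are additive over partitions); ISI mean, the mean gap
between consecutive events; ISI CV, the population-SD (divisor n) over mean
of the gaps. Population SD makes the two-event case well defined (CV 0);
`ddof=1` is available for the sample convention. Rows with fewer than two
events have no defined ISI and carry documented sentinels — ISI mean = the
window duration, CV = 0 — flagged `isi_valid = False`. The sentinels are
deliberate: near-silent rows form their own stratum of feature space and the
low-activity cluster can emerge from the clustering itself rather than from
a hand-written rule. The longest inter-event interval is available as an
optional extra feature.

All phases' rows enter one pooled K-means so cluster identities are
comparable across phases (a prerequisite for transition matrices). Features
are z-scored per column first — a count, a duration in seconds and a
dimensionless ratio are incommensurate, and an unscaled fit would be
dominated by whichever column has the largest variance; constant columns are
left at zero and flagged. K-means is Lloyd's algorithm: k distinct rows
sampled uniformly as initial centroids, iteration until assignments stop
changing, an emptied cluster reseeded to the point farthest from its
centroid, best SSE over `n_restarts` (default 10) kept; SSE is asserted
non-increasing every fit, and final labels are re-checked to be
nearest-centroid. Model selection reports the SSE elbow (same second-
difference rule) alongside the mean silhouette (computed on a seeded
subsample of at most 5,000 rows to bound the O(n²) cost); the final k is
overridable, and k = 3 is the scientific default for the
low/moderate/high-activity triad. Semantic names are assigned by ranking
clusters on mean firing count in original units, which is invariant to
cluster-id permutations.

### Phase dynamics

Cluster proportions per phase are offered pooled and per-mouse-then-averaged
(unweighted across mice); the per-mouse form is the default when mouse ids
exist, and the two differ whenever mice contribute unequal neuron counts —
which is also the natural explanation for small inconsistencies between
published aggregate proportions and change rates recomputed from them.
Relative change rate = 100·(Pₙ − P₁)/P₁ with P1 the awake baseline; a zero
baseline yields a flagged undefined value, not ±∞. Transition matrices count
neurons by (source phase label, destination phase label) and row-normalize;
zero-count rows are flagged empty rather than divided by zero. Column sums
of the counts equal destination-phase class counts by construction, so
composition propagates exactly through the matrix. Region-wise compositions
and a seeded membership track (the raster behind membership-change heatmaps)
are emitted as analysis-ready tables; hypothesis tests on them are left to
standard tools.

## The synthetic-data generator

The generator emulates what reaches this pipeline after source extraction in
a real experiment: per-neuron ΔF/F-scale traces (optionally re-embedded as
raw fluorescence around a baseline of 100 a.u. so the ΔF/F stage is
exercised), with planted ground truth for every quantity the pipeline
estimates.

**Classes and transitions.** Each neuron holds one of three activity classes
per state. The awake composition (low/moderate/high = 0.10/0.25/0.65) and
one 3 × 3 row-stochastic matrix per consecutive state pair drive a Markov
chain over states; the planted matrices default to the anesthesia
trajectory — high-activity membership collapsing through induction into
maintenance and rebounding through recovery — and are fully configurable.
An optional label noise (`transition_noise`, default 0) can perturb
scheduled classes.

**Event times.** Each state carries a shared population burst rhythm: a
quasi-periodic grid at the state's burst rate (defaults 0.4/0.2/0.5/0.3/0.6
bursts/s for awake/induction/maintenance/early/late recovery — all dividing
the 10-s analysis window so windows within a state are rhythm-aligned) with
a small shared timing jitter. A neuron joins each burst with probability
min(1, rate·sync/burst_rate) (so it fires at most once per burst), with
per-neuron Gaussian jitter (sd 30 ms); the remainder of its rate is an
independent renewal process whose gaps are a hard 0.8-s refractory period
plus an exponential. The per-state synchrony fractions default to
0.85/0.90/0.95/0.80/0.95 — nearly all firing burst-locked under anesthesia
(slow-wave/burst-suppression physiology), most of it burst-locked awake
(population coupling in superficial cortex is high, and recoverable brain
states require it). Class rates default to low 0.002 events/s everywhere
("fired only once or remained silent"), moderate 0.053–0.152, and high
0.22–0.63, with each state's high rate tied to its rhythm so the
power-carrying class participates in every burst. The refractory bound
rate ≤ 1/0.8 events/s is enforced at validation so detection can in
principle recover every event. Merged event streams are re-thinned to the
0.8-s minimum gap (earlier event wins), which costs a few percent of nominal
rate where burst-locked and independent events collide — recovery tests use
either the exact brute-force oracle of this generative definition or
tolerant bands.

**Traces.** Each event adds a double-exponential transient
a·(e^{−t/τ_d} − e^{−t/τ_r}) normalized to unit peak at the sampled frame
resolution (so a single noiseless event's maximum equals its amplitude
exactly), τ_r = 0.08 s and τ_d = 0.5 s by default (GCaMP6f-like order of
magnitude), amplitudes log-normal with mean 1.0 ΔF/F and CV 0.25. Every
population burst additionally contributes a coherent subthreshold "up-state"
waveform — the unit-peak kernel scaled by a per-state amplitude (defaults
0.6/1.3/1.3/0.7/0.6 ΔF/F; deepest anesthetic states largest) — carried by
each neuron in proportion to its firing engagement in that state (times a
mild log-normal heterogeneity, redrawn per state so states also differ in
their spatial participation pattern). Because the waveform is burst-aligned
and absent from silent neurons, it rides under true event peaks instead of
creating spurious ones. Gaussian noise (sd 0.05 ΔF/F) is added last.

**What the generator does and does not emulate.** It reproduces the
features this pipeline is sensitive to: state-specific population rhythms,
synchrony levels and coherent up-state amplitudes; class-composition shifts
with planted transition statistics; refractory event trains with realistic
calcium kernels and noise. It does not emulate optics (PSF, photobleaching,
motion), spatial footprints, neuropil contamination, per-mouse rhythm
differences (the burst backbone is shared across the whole population, as if
all neurons came from one cortex — per-mouse labels exist only for
aggregation semantics), non-stationarity within a state, or the long-tailed
rate distributions of real cortex (three discrete classes stand in for a
continuum). Passing recovery tests therefore demonstrates that the pipeline
correctly inverts this family of generative structure at realistic noise
levels — not that it would segment any particular real recording, where
state boundaries are softer and rhythms drift.

## Reproducibility and numerics

A single global seed derives per-stage seeds through
`SeedSequence(seed, spawn_key=(stage_index,))`; every stochastic stage
(simulation, K-means restarts, silhouette subsampling, membership-track
subsampling) is seeded, and two pipeline runs with one config are
byte-identical (HDF5 objects are created with `track_times=False`).
Problem sizes used by the test suite and the acceptance script — 300
neurons for the recovery scenario, 2,000 for transition-rate recovery, 120
or fewer for pipeline smoke runs — were chosen so the full suite completes
in a few minutes on one CPU while leaving the statistical margins
comfortable; all scale linearly upward via configuration. Degenerate inputs
fail loudly and early: non-positive baselines, non-stochastic transition
rows, asymmetric distance matrices, unsorted event times, k outside its
valid range, and unknown configuration keys are all errors, not warnings.
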