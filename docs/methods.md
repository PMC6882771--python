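# Methods

This note documents the model, the concrete numerical choices behind each
stage, the parameters that matter, what the simulator does and does not
emulate, and the package's known limitations.

## Generative model

A band-limited single-channel trace is modeled as a two-regime process: at
rest the network produces stationary Gaussian background z(t) with
parameters (μ_Z, σ_Z); in the active regime the trace is a sparse
superposition of weighted, shifted, unit-ℓ2-norm burst waveforms (atoms)
drawn from a dictionary D = {d_ω}, plus independent sensor noise ε(t):

    y(t) = Σ_ω Σ_{i=1..n_ω} α_i^ω d_ω(t − τ_i^ω) + ε(t)

The triple (τ, α, ω) per event forms a temporal marked point process.
Timing resolution is exactly one sample period; no sub-sample interpolation
is performed anywhere.  Event timings are referenced to the atom's
energy-centroid sample (identical to the support midpoint for symmetric
waveforms), and the simulator places events by the same convention, so
recovery errors are measured on a common clock.  Edge events are rejected
at plan validation rather than truncated, keeping the superposition exact.

## Preprocessing

Rhythm bands are isolated with a zero-phase (forward–backward) Butterworth
bandpass, order 4 per pass, because event timings must not inherit a group
delay.  The band registry ships the clinical rhythm bands with high gamma
(85–145 Hz, Q ≈ 1.9) as the default.  Resampling is polyphase with built-in
anti-aliasing; output length follows the `ceil(n·fs_out/fs_in)` convention.
The pipeline downsamples first, then filters.

## Detection (the norm embedding)

Snippet centers are chosen in two passes per trace: (1) peaks of the
analytic-signal magnitude smoothed by an M/2 moving average, with minimum
spacing M/2 and height above the envelope's **median + 3 robust SDs**
(1.4826 × MAD) — a robust threshold, because in burst-rich data the bursts
themselves would inflate a mean/SD threshold and go undetected, leaving
bursts split across tiling boundaries; (2) the unmodulated remainder is
tiled every M samples, skipping tiles that overlap a peak window.

Each M-snippet maps to its ℓ2-norm.  Under the Gaussian background the
norms are chi-distributed with M degrees of freedom (approximately Gaussian
at the M used here).  The background mode is fitted robustly: the mean is
the half-sample mode and σ comes from the mean squared deviation of the
values at or below the mode (active snippets contaminate only the right
tail; for a Gaussian, E[(X−μ)² | X ≤ μ] = σ²).  A plain mean/SD fit is
available via `robust=False`.  The selection threshold is
γ = μ_ZM + γ′·σ_ZM with γ′ = 1 by default; ties at γ are selected.  At
γ′ = 1 the Gaussian null implies ≈ 84 % of background snippets are
excluded (the Φ(1) value; 66 % is a safe lower bound).

## Dictionary learning by MDL

### Bit accounting

* Sequences are quantized to L = 64 amplitude levels by per-sequence
  min–max scaling ("64-level" rather than 64-bit floating point, which
  would make residual entropy coding meaningless).  Min–max quantization is
  affine-invariant, so description lengths from clusters of different
  durations and scales are directly comparable.  DL(T) = length × empirical
  Shannon entropy of the symbol histogram, in bits.
* Conditional description length DL(A|H): H (unit-normalized) is aligned
  to A at the lag maximizing |normalized cross-correlation| (the sign is
  stored — bandpassed bursts are polarity-ambiguous; disable with
  `polarity=False`), rescaled to the aligned window's norm, and subtracted.
  The residual is charged **over the full length of A** (out-of-support
  samples at their raw cost) and quantized with A's own step, so an exact
  embedded copy of H costs 0 bits and a short hypothesis cannot delete
  unexplained samples from the ledger.
* Cluster description length is the minimum of two realizable codes:
  the **exemplar code** (the member best matching the average center is
  stored raw; every other member as its residual against the carrier's
  aligned window) and the **center code** (the quantized center itself is
  transmitted; every member as its residual against it).  The exemplar code
  is what lets a two-member cluster pay for itself at moderate SNR; the
  center code wins for populous clusters — the averaged center is cleaner
  than any single member — and makes merging two same-waveform clusters
  save an entire center transmission.  Both codes coincide on
  duplicate-member clusters, so the classic identities hold exactly:
  a cluster of two identical sequences costs DL(A), a singleton costs
  DL(H), creating a cluster from an identical pair saves exactly DL(A),
  and independent-noise pairs do not compress.

The noise-rejection property "bitsave ≤ 0 for independent-noise pairs" is
asymptotic in the sequence length m: the genuine mismatch penalty grows
like ~0.4 bits/sample while the plug-in entropy estimate is biased downward
by ~K/2m bits/sample.  Per-draw rejection rates are ≈ 85 % at m = 50,
≈ 94 % at m = 70 and ≈ 99 % at m = 100; the expectation is negative at
every length.  Property tests therefore use m = 100 (mid-range of the
method's application scales — M = 50 samples for gamma bursts, hundreds for
spindle-scale events) for per-draw assertions and expectation-level
assertions elsewhere.

### The greedy loop

Per iteration the candidates are: for each cluster, adding the unassigned
snippet whose windows best correlate with its center; merging every cluster
pair; and, per duration δ in the grid Δ, creating a cluster from the
top-scoring unassigned motif pairs (maximal windowed normalized
cross-correlation over all placements — the motif matrices).  The applied
operation maximizes the **bitsave per snippet consumed** (a create encodes
two snippets, an add one, so raw bitsaves are not commensurable across
operators; comparing them raw lets a pair-create outbid two individually
better adds and strand small satellite clusters).  The applied operation
must still have a positive raw bitsave; the loop stops when none does, or
at `max_iterations`.  Ties break add > merge > create, then candidate
order.  The trajectory is fully deterministic given (X, config).

Two further safeguards:

* **Create gate.**  The best motif pair among featureless snippets is a
  maximum over ~Ψ² pairs × window placements and can be large by selection
  alone.  Candidate pairs must therefore beat the maximum best-pair score
  observed over `null_gate_perms` (default 19) within-snippet sample
  permutations of X — a calibration of the selection effect on featureless
  data.  On pure-noise X this yields K = 0.
* **Merge candidates.**  A merge evaluates five candidate merged centers —
  the member-count-weighted average of the parents over the union of their
  aligned supports (optionally edge-trimmed; trimming is off by default
  because shaving low-amplitude burst tails erodes durations run over run),
  and each parent's center both refreshed over all members and as-is
  (refreshing toward a small incoming cluster can cost the host cluster
  more than the merge gains) — and keeps the one with the smallest cluster
  DL.  Union-support candidates are how learned durations leave the grid Δ
  (capped at M).

Cluster centers are the unit-norm, sign-aligned average of the aligned
member windows, iterated to a fixed point (≤ 4 passes) after every add and
merge.  K, the atom durations, and the snippet assignments are outputs, not
inputs.

## Encoding

Each selected snippet is explained by exactly one atom: the one with the
largest |normalized cross-correlation| over admissible lags.  τ is the
energy-centroid sample of the aligned atom in trial time; α is the raw
inner product of the aligned window with the unit-norm atom (signed when
polarity matching is on; log α² removes the sign downstream).  Re-encoding
a noiseless reconstruction reproduces the train (idempotence).

Per-trial features: event count in the analysis window (default −0.5 to
2 s relative to the cue); mean natural log of inter-burst intervals (NaN
for < 2 events); mean τ and mean ln α² (NaN for event-free trials).  NaNs
are imputed with the class mean before MANOVA (`impute_class_mean`),
a documented choice where the convention is genuinely open.  Baselines:
short-time band power on 250 ms windows with 50 % overlap, and log mean
squared amplitude per trial.

## Statistics

* **One-way MANOVA** with sequential dimensionality tests: eigenvalues of
  the between-group SSCP relative to the within-group SSCP; for each nested
  null "the group means lie in a d-dimensional subspace"
  (d = 0 … min(p, g−1) − 1), Wilks Λ_d = Π_{k>d} 1/(1+λ_k) with Bartlett's
  χ² approximation, −(n−1−(p+g)/2)·ln Λ_d on (p−d)(g−1−d) degrees of
  freedom.  All dimension tests are always reported.  Canonical
  coefficients are scaled to unit within-group variance of the variates
  (they maximize Mahalanobis separation between groups).  A singular
  within-class scatter is ridge-regularized (1e-8 × trace/p on the
  diagonal) with a warning.
* **Silhouette** S_i = (b_i − a_i)/max(a_i, b_i) with a_i, b_i exposed;
  singleton-cluster members score 0 by convention.
* **Timing–power correlation**: Pearson r between sliding event counts and
  sliding trace variance (250 ms windows, 50 % hop); NaN when either series
  is degenerate.
* **Randomization test**: labels shuffled n_perm times (default 1000) with
  a seeded generator; statistic is the mean silhouette or the
  highest-dimension MANOVA p; the observed value is located on the null.
* **Sample-wise detection**: half-open predicted and true event spans are
  rasterized over [0, n_samples) and scored TP/FP/TN/FN, TPR = TP/(TP+FN),
  FPR = FP/(FP+TN).

## Synthetic data: what it does and does not emulate

The generator produces multi-trial, single-channel ensembles at 500 Hz with
scale-specific bursts (hann- or gaussian-enveloped sinusoids, 50–120 ms)
sparsely superimposed on white Gaussian background, with class-dependent
rates and amplitude laws, homogeneous-rate timings thinned to a refractory
gap, and full ground truth retained.  The background is white Gaussian by
default — the model's stated rest-state premise after bandpassing — with an
optional 1/f background for realism checks only.  The amplitude law
defaults to lognormal (the amplitude distribution of real gamma bursts is
not established; this is a stand-in, not a claim).

It does **not** emulate: multi-channel spatial correlation, EMG/EOG/movement
artifacts, nonstationary background regimes, phase diversity within an atom
(planted events share the atom's phase), or overlapping events (the
refractory gap forbids them).  Passing tests therefore demonstrate correct
recovery under the model's own assumptions, not robustness to artifacts or
overlap.

## Test conditions and problem sizes

The recovery benchmark plants two atoms (80 ms @ 115 Hz and 120 ms @
100 Hz) with 100 events each in 50 trials of 2.5 s at 500 Hz, amplitudes
lognormal around √(10·δ)·σ_Z — i.e., event energy 10 dB above the
background across the atom support (the package's SNR convention) — with
log-scale jitter 0.15 so that weight recovery is measurable as a
correlation.  M = 70 samples (the 120 ms atom must fit inside a snippet)
and Δ = {40, 60} samples; the grid is a suggestion, and these runs also
recover the durations.  Under these conditions the clustering returns K = 2
with atom correlations ≥ 0.99, median timing error ≤ 1 sample, and weight
correlation > 0.9; this held at every simulation seed tried during
development.  Null checks use 1e5 snippets; permutation nulls use
99–1000 shuffles; tiny-instance exhaustive checks use Ψ = 6, M = 8,
δ ∈ {4, 6}, L = 4.

## Known limitations

* The greedy loop is a local optimizer; on data with many near-duplicate
  generators the final K can exceed the true generator count by small
  satellite clusters when their self-compression genuinely beats
  absorption.  On real recordings K is expected in the tens, not the true
  small count of an idealized simulation.
* First-order entropy coding ignores residual autocorrelation; bitsaves are
  conservative for smooth residuals.
* Sub-sample (fractional-phase) alignment is deliberately absent; atoms
  whose carrier phase drifts across events by fractions of a sample blur
  the learned center.
* The DET assumes the background dominates: when more than roughly half of
  all snippets contain events, the background fit (mode + left tail)
  degrades.
* EDF reading returns the continuous record as a single trial; epoching
  into a trial matrix is the caller's responsibility.
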