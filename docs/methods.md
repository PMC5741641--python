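# Methods

This note documents the model implemented by `mppeep`, the estimation
procedures, the numerical choices that were genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Generative model

A single-channel extracellular trace sampled at fs is modelled as

    x[n] = n0[n] + Σᵢ yᵢ[n],      yᵢ[n] = Σⱼ αᵢⱼ · dᵢ,ωⱼ[n − τᵢⱼ]

where i indexes frequency bands (rhythms), n0 is background activity with a
1/f-type power spectrum, and each band contributes sparse, amplitude-scaled
copies of K unit-norm M-sample FIR atoms. Within one band the model is a
single-input single-output convolutional sparse code; bands are treated
independently, on the assumption that one neuronal assembly does not emit
transients in two rhythms simultaneously. The decoded representation per
band is a *marked point process*: events (τ, α, ω) with τ the window start
in samples, α the signed projection amplitude, and ω the atom index. Both
the window start and the sample of the fitted waveform's largest absolute
peak are recorded, since either is a defensible event time; analytics use
the peak.

Assumptions that matter in practice:

- **Temporal sparsity.** Events rarely overlap; both training (one atom per
  snippet) and decoding (one event per `min_separation` window) encode
  sparsity one. The noise threshold additionally assumes events are a small
  *fraction* of the embedded snippets (see below).
- **Linearity.** Events superpose additively on the background.
- **Band specificity.** All learning happens on the band-passed trace.

## Band-pass pre-filter

Per band the trace is filtered with a Butterworth band-pass whose −3 dB
bandwidth is set to (center frequency)/q_target with q_target = 2, edges
geometrically symmetric around the band's geometric center. The quality
factor is a design *target* rather than whatever the nominal band edges
imply, because narrow, high-order filters ring and imprint artificial
transient structure — exactly what an event detector must not hallucinate.
With constant-Q edges the measured −3 dB quality factor is
order-independent, so the order scan settles on the lowest order (a single
second-order section). Default application is zero-phase
(forward–backward, reflect padding 3× the effective order), so event
timings carry no group delay; a causal mode exists for on-line use.
Degenerate bands (f_hi ≥ Nyquist, empty passband, realized Q off target by
more than 50%) are rejected at design time.

## Embedding and the noise threshold γ

The band-passed trace is embedded in M dimensions: local maxima of the
Hilbert envelope above its 75th percentile claim M-windows centered on the
peak (processed in descending amplitude, overlapping claims dropped, edge
peaks shifted inward); remaining samples are tiled into contiguous
M-windows, with runs shorter than M discarded. The percentile rule is
scale-free; the spec-level question of re-centering conflicting peak
windows is resolved by dropping rather than shifting them, which keeps
claims independent of processing order. Under this rule each unclaimed run
loses at most M−1 samples, so coverage is high but not complete; no
guarantee stronger than the per-run bound is possible without overlapping
windows.

For background-only snippets the Euclidean norm is a smooth function of M
weakly dependent samples: by the central limit theorem its distribution's
main lobe is close to Gaussian (excess kurtosis ≈ 0), while genuine
transients populate a heavy right tail. γ is estimated by sorting the norms
and trimming the largest one at a time until the bias-corrected sample
excess kurtosis of the retained set falls to ≤ +0.1, with a floor of 50% of
the data retained; γ is the largest retained norm and events are snippets
with norm strictly above γ. Two deliberate choices:

- **One-sided stopping.** Right-trimming can only *lower* excess kurtosis;
  a sample that starts at or below the Gaussian value carries no tail
  evidence and is left untouched. A symmetric |kurtosis| ≤ tol rule can
  chase a slightly negative starting kurtosis into deep, harmful trimming
  (we measured a 21.8% false-event rate on one Gaussian-null seed before
  adopting the one-sided rule; after it, the worst rate over 40 seeds is
  0.02%).
- **Trimming operates on norms**, the chi-like quantity whose main lobe the
  CLT argument concerns, not on raw samples.

The estimator needs ≥ 200 norms and non-degenerate spread; the full
trimming path (retained fraction, kurtosis) is stored in the model for
audit, and γ scales exactly linearly with the data.

**Regime of validity.** The kurtosis test reads "Gaussian bulk + sparse
tail". If events occupy a large fraction of snippets (duty cycles of tens
of percent) the norm density becomes bimodal, whose kurtosis is *low*
before any trimming, and γ degenerates. The synthetic study conditions keep
the event duty cycle near 5% for this reason (see below); real recordings
with dense events need a different separation rule.

## Dictionary learning

Per band, K atoms are learned from the event snippets by shift-invariant
k-means:

- **Seeding.** Candidates are snippets at or above the 90th norm
  percentile; the first seed is drawn at random, subsequent seeds greedily
  minimise the running mutual coherence, and all are normalised with the
  sign fixed (largest-magnitude entry positive).
- **Assignment.** Each snippet is matched by FFT cross-correlation against
  every atom over integer lags in [−S, S], S = ⌊M/4⌋ by default (keeping
  ≥ 3M/4 valid overlap). The winner maximises |correlation|; α is the
  signed value. Ties break deterministically: smallest atom index, then
  smallest |lag|, preferring the negative lag. The FFT path is tested to
  agree exactly with an explicit loop over every (atom, lag).
- **Update.** Members of each cluster are lag-aligned (zero-filled) and the
  atom re-estimated as the robust first principal direction (below); empty
  clusters keep their previous atom, avoiding an unstated randomness
  source.
- **Termination and restarts.** Iterations stop when the Frobenius norm of
  the dictionary change drops below 10⁻², or after 20 iterations. Each of
  n_init = 5 restarts seeds independently (seeds derived by seed-sequence
  spawning, so runs are bitwise reproducible); the restart whose final
  dictionary has the lowest mutual coherence wins. For K = 1 coherence is
  undefined and the first restart wins.

α is allowed to be negative (polarity-inverted events); atom matching is on
|correlation|, and polarity survives in the event table.

### Correntropy-robust rank-1 update

The cluster matrix X (rows = aligned snippets) is reduced not by plain SVD
— whose quadratic loss lets outlier rows bias the atom — but by maximising
a correntropy (Gaussian-kernel) similarity, solved half-quadratically:
starting from the ordinary first right singular vector d, iterate

    e_k = ‖x_k − (x_kᵀd) d‖
    σ   = max( 1.06 · std(e) · n^(−1/5),  rms(e)/√2 )
    w_k = exp(−e_k² / 2σ²)
    d   ← first right singular vector of diag(√w) X

until the largest weight change is below 10⁻⁶ or 50 iterations. Silverman's
rule lets the kernel width anneal as the fit improves; the rms floor is
essential: for homogeneous (outlier-free) clusters the residual norms
concentrate (std ≪ mean), Silverman's bandwidth alone collapses the kernel,
and the estimate would be driven by the few smallest-residual rows instead
of reducing to ordinary SVD in the clean limit. With the floor the update
matches plain SVD to |cos| ≥ 0.9999 on outlier-free data while still
driving the weights of gross-outlier rows to ~0 (beating plain SVD on
20/20 paired simulations). Zero residual spread (exact rank-1 input) falls
back to uniform weights. The sign convention (largest-magnitude entry
positive) removes the SVD sign ambiguity.

## Decoding

The band-passed test trace is cross-correlated ('valid' mode) with every
atom; candidates are scanned in descending max-over-atoms |correlation| and
accepted iff |α| > γ and the window start is ≥ `min_separation` from every
accepted event. `min_separation` defaults to M (non-overlapping events, the
training-side sparsity rule) and may be lowered to M/2. Thresholding uses
the projection |α| against γ: for a genuine event the snippet is α·atom +
noise, so its norm and its projection coincide up to the noise floor, and
the projection is the quantity the decomposition actually assigns.
Scanning one combined correlation (rather than per-atom passes) enforces a
single event per location across the whole dictionary. On noiseless input
the recovered τ are exact — the temporal resolution is the sampling period
— and deconvolve→reconstruct round-trips to relative L2 error ~1e−16.

## Point-process analytics

- **Rate**: each event contributes a unit-mass Gaussian bump (σ = 100
  samples, support 200 samples, renormalised after truncation — at ±1σ the
  clipped mass is substantial, and renormalising keeps the series
  integrating to the event count) centered on the event peak.
- **Delay**: Pearson correlation per lag on the overlapping segments;
  positive lag means events lead the reference, and `causal_only` restricts
  the search to non-negative lags (brain→muscle delays). Ties prefer the
  smallest |lag|.
- **Density**: events tallied relative to triggers into bins over
  [−pre, +post), normalised by trigger count × bin width — a PSTH-style
  estimate of the point-process intensity in events/s per trigger.

## Synthetic ground truth and study conditions

`make_atoms` draws Hann-windowed sinusoids with frequencies spread across
the band and random phases (redrawn until pairwise coherence < 0.95);
`make_colored_noise` shapes white Gaussian noise to a 1/f^a spectrum (a = 1
by default) at unit variance; `make_eep` draws event times from a
homogeneous Poisson process thinned to a hard-core separation of M, with
the candidate rate inflated by the dead-time correction rate/(1 − rate·M/fs)
so the realised rate matches the request, amplitudes uniform on (1, 3), and
noise scaled so the event-to-noise power ratio *on the event-bearing
support* hits the requested SNR (support-restricted SNR keeps the
difficulty independent of event rate). The emitted trace minus the clean
reconstruction equals the stored noise bitwise.

The benchmark conditions, fixed once: fs = 100 Hz, M = 50 (500 ms, a
spindle-scale transient at one-fifth the clinical sampling rate), sigma
band 11–16 Hz, K = 3 atoms, event rate 0.1/s (≈6/min, the upper range of
realistic spindle density; 5% duty cycle, honouring the sparsity regime of
the noise model), SNR 10 dB on support, trace length 300 000 samples
(3000 s, ≈300 events). Under these conditions the full unsupervised
pipeline (filter → embed → γ → learn → decode) recovers each true atom at
|corr| ≥ 0.94 after bipartite matching and detects events at F1 ≥ 0.99
with ±5-sample tolerance, across seeds.

What the synthetic benchmark does *not* show: robustness to EMG/EOG
artifacts or line noise (no artifact model), performance under
non-stationary background, overlapping events from one band (excluded by
the hard core), multi-channel structure, or agreement with human scorers
on clinical recordings — the generator draws events from the same model
class the learner fits, so recovery measures internal consistency and
noise robustness, not clinical validity.

## Known limitations

- One rhythm at a time; multi-band analysis is L independent runs.
- The γ estimator requires a sparse event regime and enough snippets
  (≥ 200) for the CLT argument; dense-event recordings violate it.
- No amplitude re-fitting after detection, and no unmixing of overlapping
  events (closest-window suppression only).
- EDF support covers plain EDF with per-channel physical scaling; EDF+
  annotations beyond (onset, duration) lists, BrainVision/FIF and streaming
  input are out of scope.
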