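# Methods notes

This note records the models, parameter choices and numerical conventions
behind the package, in the order the pipeline applies them.

## Synthetic recordings

Each subject is a 90 × 40960 array: 90 AAL regions, ten 8-second epochs at
512 Hz.  Every region receives

- **1/f background rhythm** (`background_sd`, default 1.0): Gaussian noise
  with a 1/f amplitude spectrum, flattened below 0.5 Hz.  This is the
  ongoing broadband activity of resting-state recordings; within any
  narrow analysis band its phase drifts and dwells the way real
  oscillations do, which is what sets the realistic fluctuation floor of
  per-epoch PLI estimates (~0.1 for uncoupled pairs at 8 s).  Without it,
  regions driven by a planted coupling would look "too clean" and acquire
  systematically fewer spanning-tree attachments than uncoupled regions —
  a generator artifact, not a network effect.
- **white sensor-like noise** (`noise_sd`, default 0.5).
- **coupling components** (below).

A planted coupling is driven by a latent oscillator whose unwrapped phase
accumulates increments 2π(f_c + ε_t)/fs, ε_t i.i.d. N(0, σ_f²) with
σ_f = 0.3 Hz; the carrier f_c is drawn once per (source, band) from the
central half of the band so distinct oscillators are spectrally separated.
The source region carries cos θ(t); the target carries
a·cos(θ(t) + lag + η(t)).

Two jitter conventions matter and both are deliberate:

- **η is temporally correlated**, an Ornstein–Uhlenbeck process with
  correlation time τ = 0.3 s and stationary sd `jitter_sd`.  White
  per-sample phase jitter lives almost entirely outside a 4-Hz-wide band
  and is removed by the band-pass filter, leaving the PLI nearly blind to
  it; an OU process with τ comparable to the filter's impulse response
  survives filtering, so PLI decreases monotonically in `jitter_sd`
  (measured: 0.92, 0.84, 0.74, 0.54, 0.30 at sd 0, 0.3, 0.6, 1.0, 1.5 rad,
  the ceiling below 1 coming from the 1/f background).
- **All hub couplings share one lag value** (drawn once from
  [0.1π, 0.9π]; the end ranges are excluded because lags of exactly 0 or π
  are invisible to the PLI by construction).  Partners of the hub are then
  pairwise related at *zero* lag, which the PLI discards — so the planted
  structure is a genuine hub, not a clique.  With independent per-coupling
  lags the partners would synchronise with each other at low jitter and
  the minimum spanning tree would route around the hub, inverting the
  intended group difference.

The two-cohort defaults are the study conditions: 26 vs 29 subjects, hub at
Hippocampus_R with 10 partners in the theta band, jitter 0.1 rad (group A)
vs 1.5 rad (group B), coupling amplitude 0.35.  The amplitude was fixed by
a design sweep on the generator itself: it must keep the group-A hub–partner
PLI (≈0.6) well above the null floor while leaving the partners' own MST
degrees equal between groups (A 2.16 vs B 2.18 at amplitude 0.35, against a
background degree of ≈1.9).  Larger amplitudes make the group-B hub edges
strong enough (PLI ≈ 0.3) to attract extra tree degree to partners in
group B only, which shows up as spurious partner-level group differences.
MST degree is zero-sum (Σk = 2(N−1)), so a planted +Δ at the hub must be
compensated somewhere; at amplitude 0.35 the compensation diffuses across
all 89 remaining regions and drowns in between-subject noise.

Per-subject seeds are spawned from the dataset seed (numpy `SeedSequence`),
so identical specs give bit-identical datasets; dataset-level structure
(partner set, lags, carrier frequencies) is a separate deterministic
function of the seed, identical across subjects and groups.

## Spectral processing

Filtering is a 4th-order Butterworth band-pass applied forward–backward
(`sosfiltfilt`): zero phase distortion at the cost of squaring the
magnitude response (≈48 dB/octave skirts).  Instantaneous-phase estimates
feed the PLI directly, so phase linearity is worth more than matching a
one-pass magnitude; a causal one-pass option (`zero_phase=False`) is kept
for comparison.  By default the per-band filters are applied to a 0.5–48 Hz
pre-filtered signal (`pre_band`), each band independently, never cascaded.

Epochs are the *first* `n_epochs` non-overlapping clean 8-s windows in
temporal order; an externally supplied boolean artifact mask (True = bad
sample) shifts the scan past any flagged sample.  Too few clean windows is
a hard error that reports the count found.

Phase is the argument of the analytic signal per channel and epoch.  No
edge samples are trimmed by default: the PLI's sign statistic is robust to
mild Hilbert edge distortion, and the definition averages over all samples
of the epoch.  (A pure-tone pair with constant π/4 lag comes through the
full filter + Hilbert path at PLI exactly 1.0.)

## Connectivity and trees

`sign(0) = 0` (signum convention), so identical channels give PLI exactly
0.  The all-pairs kernel evaluates sign(sin(φ_i − φ_j)) via
sin a cos b − cos a sin b, which cancels exactly for identical channels; a
numba JIT compiles the 90 × 90 × 4096 loop (~12 ms per epoch), with a
vectorised numpy fallback.  Per-epoch matrices and their arithmetic average
are both produced; the default analysis path builds one MST *per epoch* and
averages the metrics across epochs (`mst_mode="per-epoch"`), since that is
the conventional order; the MST of the epoch-averaged matrix is available
behind `mst_mode="averaged-matrix"`.

Kruskal runs on weights 1/PLI.  PLI = 0 entries get a deterministic
sentinel weight one order of magnitude above the largest finite weight in
the matrix, so degenerate inputs stay total-ordered; ties break by
ascending (min(i,j), max(i,j)) for bit-reproducibility (real ties are
measure-zero but occur in toy examples).

Metric conventions, chosen where the literature leaves slack:

- degree divergence κ = ⟨k²⟩/⟨k⟩ — the standard broadness measure.
- betweenness normalised by (N−1)(N−2)/2; path endpoints are not interior.
  For trees this is computed by subtree-size counting (O(N) per tree), and
  eccentricity by the double-BFS diameter property; both are tested against
  explicit path-enumeration oracles.
- tree hierarchy Th = L/(2·M·BC_max), which is bounded in (0, 1]; the
  literal ratio L/BC_max is unbounded and kept only as `th_mode="literal"`.
- eccentricity counts hops: after construction the tree is treated as
  unweighted, as is conventional in MST analyses of M/EEG networks.
- trees with N < 3 raise for tree hierarchy (betweenness is degenerate).

## Group statistics

The permutation test permutes the *sorted pooled* sample and resplits at
the smaller group size: the Monte-Carlo null then depends only on the
pooled values and the two sizes, making the p-value exactly invariant to
swapping group labels under a fixed seed.  The two-sided p uses the add-one
correction p = (1 + #{|diff_perm| ≥ |diff_obs|})/(n_perm + 1), valid for
any number of draws; 10,000 draws by default (exhaustive enumeration of
C(55, 26) splits is impossible).  Empirical size at α = 0.05 over 500 null
datasets: 0.046.

FDR families follow the reporting structure: Benjamini–Hochberg within each
(band, metric) family of 90 nodal tests, and within each band's family of
3 global metrics; `fdr_family="pooled"` corrects everything together
instead.  BH is delegated to statsmodels; a ten-value worked vector is
checked against the hand step-up in the tests.

## Problem sizes and what the tests show

The replicated hub-recovery experiment runs 20 full datasets (55 subjects
each) in the theta band with n_perm = 2000 — about 40 s per replicate —
and requires the hub's degree row to be FDR-significant with direction "+"
in ≥ 90% of replicates with a median of ≤ 2 other significant regions.
Unit and property tests run at toy scale (6–20 nodes, seconds).

Passing these tests shows the chain is correct and well-calibrated *for
the generative model above*.  The generator emulates band-limited phase
coupling, 1/f background and stationary noise; it does not emulate
volume-conduction leakage patterns of a real inverse solution,
non-stationary artifacts, heartbeat/eye-blink contamination, or
inter-subject anatomical variability.  Conclusions about real recordings
still depend on the upstream source reconstruction and artifact handling,
which are outside this package (an artifact mask can be supplied, and any
(channels × samples, fs, labels) source can be adapted).

## Known limitations

- PLI discards true zero-lag coupling by design; the generator therefore
  refuses couplings with lag exactly 0 or π rather than silently producing
  an undetectable ground truth.
- Per-epoch PLI at 8 s has a null floor of ≈0.1 for narrowband signals;
  metrics averaged over ten epochs inherit corresponding variance.
- The permutation test assumes exchangeability under the null; no
  covariate adjustment is provided.
- `resample` uses a rational approximation of the rate ratio (exact for
  the common 1024 → 512 Hz case).
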