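# Methods

## Signal model and detection

A recording is a time × channel matrix of extracellular voltages in
microvolts sampled at `fs_hz` (20 kHz by convention); sample *k* is time
*k/fs* seconds, 0-based. Detection operates per channel and is entirely
nonparametric:

* **Noise level.** σₙ = median(|Sₜ|)/0.6745 over the *full* trace,
  including spikes. For Gaussian noise median(|Z|) = 0.6745 σ, so the
  estimator is Fisher-consistent; because spikes occupy a small fraction
  of samples (≈ rate × waveform length, under 1 % at a few Hz), the
  median's 50 % breakdown point makes masking them unnecessary. The test
  suite verifies < 1 % bias at 10⁶ samples and < 5 % shift under 1 %
  suprathreshold contamination.
* **Threshold and window isolation.** Samples with |Sₜ| ≥ 5 σₙ (both
  polarities by default; a `polarity="negative"` option restricts to
  downward deflections) are grouped: suprathreshold samples closer than
  the 3.5 ms window belong to one event. The event time is the sample of
  largest |Sₜ| in the group, ties resolved to the earlier sample. This
  guarantees returned peaks on one channel are never closer than the
  window.
* **Waveforms and SNR.** Each event carries a snippet of
  round(fs·3.5 ms) samples centered on the peak (peak at index
  `length // 2`). Events whose snippet would cross a recording edge are
  dropped rather than padded, keeping all waveforms equal length. SNR is
  the absolute peak amplitude divided by the channel's σₙ.

Whether thresholding happens on raw or band-passed data is a caller
choice: the pipeline applies a zero-phase Butterworth band-pass
(300–3000 Hz, order 4, `sosfiltfilt`) by default and offers `--no-filter`.
Zero-phase application keeps peak times unshifted (verified to ≤ 1 sample
on injected templates); the band edges see the squared magnitude response,
so the measured mid-band gain criterion is [0.9, 1.0].

## Merging and matching

Within one electrode group, detections with peak times differing by
**strictly less than 2 ms** are the same spike. We apply this by
single-linkage chaining on time-sorted events: consecutive gaps < 2 ms
join a cluster. A chain may span more than 2 ms end-to-end; this is
accepted because true source events are refractory-separated (> 4 ms),
so long chains only arise from genuine co-detections. Each cluster is
summarized by its maximum-SNR member (time and SNR taken from that
member; SNR ties broken by the lexicographically smallest channel id for
deterministic builds).

Cross-group pairing ("spikes detected in common") uses one-to-one greedy
matching: all candidate pairs with |Δt| < 2 ms, processed in increasing
|Δt| (ties by earlier first-train time), each spike used at most once.
The union (merged) count always satisfies
max per-channel count ≤ union ≤ Σ per-channel counts; `count_summary`
asserts this sandwich bound on every call.

## Statistics

* **Mann-Kendall trend.** S = Σ_{i<j} sign(x_j − x_i);
  var S = [n(n−1)(2n+5) − Σ_ties t(t−1)(2t+5)]/18; z applies the ±1
  continuity correction and is 0 when S = 0 (degenerate all-tied inputs
  flagged, z = 0). The sequence fed to the trend test is the merged-spike
  SNR sequence ordered by (round, time); with rounds concatenated on one
  time axis this equals plain time order. Implementation is checked
  against an O(n²) enumeration oracle for n ≤ 50.
* **Rank-sum permutation test.** Observed statistic: sum of midranks of
  the first sample in the pooled ranking. Null: re-assignment of pooled
  values to groups of the original sizes — exhaustive enumeration when
  C(n, n₁) ≤ 10⁵ (exact tail proportion), otherwise sampled with the
  add-one estimator (b+1)/(n_perm+1), which keeps p ≥ 1/(n_perm+1) and is
  valid under the null. Two-sided p uses distance from the null mean
  n₁(n+1)/2. Calibration is verified: rejection rate at α = 0.05 inside
  the binomial envelope [0.037, 0.064] over 1000 null simulations.
* **Group trend comparison.** Observed statistic Δ = z_shell − z_planar.
  The permutation unit is the **channel**, not the spike: spikes within a
  channel are serially dependent and not exchangeable, whereas electrode
  labels are exchangeable under the null that electrode type carries no
  information. Each permuted label assignment re-merges the two groups
  from the per-channel events and recomputes Δ. The full roster of
  channels — including electrodes that detected nothing — must enter the
  permutation universe; the pipeline persists it as `channels.csv` so a
  restart from intermediate artifacts sees the same universe. With
  3 + 4 channels the C(7,3) = 35 assignments are enumerated exactly, so
  the smallest attainable one-sided p is 1/35 ≈ 0.029. One-sided
  ("greater") by default, matching a directional sensitivity question;
  the paired-SNR comparison defaults to two-sided.
* **Descriptors.** Median percent change 100·(med(after) −
  med(before))/med(before); per-channel counts, mean rates, ISIs, median
  SNR.

## Synthetic data generator

The generator emulates what the analysis assumes, with known ground
truth:

* **Template.** Biphasic waveform (difference of two Gaussians in
  normalized time, tapered by a half-sine so both endpoints are exactly
  zero): a dominant negative lobe followed by a smaller positive lobe,
  peak normalized to 1, lobe areas balanced within 20 %. Duration default
  2 ms — the observed extracellular spike width — i.e. 40 samples at
  20 kHz.
* **Events.** Per round, a homogeneous Poisson process (default 2 Hz)
  thinned to a refractory gap (default 5 ms ≥ template length, so source
  events never overlap) and kept clear of round edges by one template
  length plus the worst-case jitter.
* **Amplitudes.** Channel c receives
  base_amplitude · exp(−d_c/λ) · round_gain[r]: a single-parameter,
  monotone, bounded attenuation law (λ default 150 µm) standing in for
  the proximal-shell vs distal-planar contrast; `round_gain` injects a
  stimulation trend (default all 1).
* **Jitter.** Per channel and event, uniform in ±0.5 ms — strictly below
  half the 2 ms merge window, so merging can be exact on ground truth.
* **Noise.** White Gaussian, σ default 5 µV per channel; an optional
  pink-noise mixing fraction (off by default) is available because real
  MEA noise has excess low-frequency power.
* **Rounds.** Five by default, concatenated on one time axis with 1 s of
  silence between rounds, so (round, time) order equals time order.
* **Determinism.** One integer seed drives a single `numpy` Generator;
  identical configs give bit-identical recordings and ground truth.

Defaults for quantities no reference pins down (noise σ, firing rate,
base amplitude, distances, band edges) are plausible placeholders for
organoid field-potential recordings, chosen once and exposed in
`SimConfig`; they are conditions of the validation experiments, not
fitted values.

### What the generator does not emulate

No biophysical neuron or cable model, no electrode impedance or
interface chemistry, no bursting/non-stationary rate structure, no
waveform diversity across units (a single template), no electrode drift
or movement artifacts, no line noise. Consequently, passing tests show
the *analysis chain* is correct under its own assumptions (robust σ,
threshold crossings, temporal merging, permutation inference) — they do
not certify performance on real recordings with overlapping units,
bursts or artifacts.

## Validation experiment sizes

The test suite validates on: 10⁶ samples (estimator consistency); a 60 s,
7-channel, 20 kHz session with 10 σ spikes at 2 Hz (detection recall and
precision ≥ 0.99 at ±1 ms); a 60 s pure-noise channel (< 0.1 false
events/s at 5 σ; the Gaussian tail predicts ≈ 0.01/s); an 8 s, 3-channel
session with 0.4 ms jitter and 5 ms refractory (merged count equals
ground-truth events detected on ≥ 1 channel); 100 random sequences of
n ≤ 50 (trend oracle); 1000 null simulations × 999 permutations
(calibration); 100 seeds of a five-round ramped session with planar
electrodes at 600 µm (trend recovery: shell z > 0 and label-permutation
p < 0.05 in ≥ 95 %); and two repeated demo runs (byte-identical CSVs).
These sizes make the whole suite run in a couple of minutes while keeping
every Monte-Carlo margin comfortable.

## Numerical and design choices

* Tie-breaks are specified everywhere (earlier peak sample; smaller
  channel id; earlier a-time in matching) so outputs are reproducible to
  the byte.
* Strict inequality (<) in both the 2 ms merge rule and the matching
  window; a gap of exactly 2 ms separates.
* Permutation tests compare with a 10⁻¹² slack so exact rational ties in
  rank sums are counted as extreme (conservative).
* Master-seed fan-out: named child seeds derived by SHA-256 of
  `"{seed}:{stream}"`, reduced mod 2³¹, logged in the report.
* Recording files are little-endian float32, time-major, with a YAML
  sidecar carrying fs, channel ids, groups, distances, round intervals,
  units, dtype and byte order; payload length is validated against the
  sidecar (divisibility and sample count) before reshaping.
* Units are microvolts throughout; conversion is the caller's job.

## Known limitations

Detection is single-threshold with no spike sorting, so coincident
events from different units within 2 ms merge into one; SNR comparisons
therefore concern event amplitudes, not unit identities. The
channel-label permutation test has a granularity floor set by the number
of channels (p ≥ 1/C(n, n_shell) with exhaustive enumeration), which is
the honest resolution of a seven-electrode experiment. The false-positive
budget assumes roughly Gaussian noise tails; heavy-tailed artifacts
would require an artifact-rejection stage this package does not provide.
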