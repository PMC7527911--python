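# Methods note

This note records how each quantity in `voicepd` is defined, the parameter
defaults with their rationale, the numerical choices that materially affect
results, and the known limitations. Everything here is implemented in
`src/voicepd/` and verified by `tests/` and `scripts/acceptance.py`.

## Signal conditioning

- **Rate.** All analysis runs at 10 kHz (`audio_io.PIPELINE_RATE`). Input
  WAVs are resampled polyphase (`scipy.signal.resample_poly`, Kaiser β=5)
  with the exact rational ratio; output length is `round(N·target/rate)`.
  Stereo inputs use the left channel by default (`channel_policy="left"`),
  optionally a mono mix.
- **Pre-emphasis.** `y(n) = x(n) − a·x(n−1)` with `a = 0.9375`, `y(0)=x(0)`.
  This flattens the ~−6 dB/octave glottal spectral tilt before framing and
  energy analysis. The coefficient must lie in (0, 1).
- **Framing.** 25 ms frames, 10 ms shift, Hamming window (symmetric
  `np.hamming` form). Frame count is `floor((N−L)/S)+1`; a trailing partial
  frame is dropped.

## Voiced-region detection

Short-time energy `E_t = Σ (w·x_t)²` per frame feeds a double-threshold
detector: frames above `T_h = 0.25·max E` seed voiced cores, which are
extended in both directions while energy stays ≥ `T_l = 0.05·max E`;
overlapping or adjacent runs merge; segments shorter than `min_voiced_ms =
100 ms` are discarded. Both thresholds are relative to the recording's own
maximum, so detection is invariant to overall gain. The defaults assume a
sustained-vowel recording with leading/trailing silence, not running speech.

## Pitch and cycle marking

- **Frame-level F0.** 40 ms pitch frames every 10 ms, mean removed,
  normalized autocorrelation via FFT. The finite window biases lag `k` by a
  factor `(N−k)/N`; we correct with `r(k)·N/(N−k)` before peak picking.
  Without this correction the autocorrelation peak underestimates the
  harmonics-to-noise ratio by several dB at typical lags.
- **Peak rule.** Search lags in `[rate/fmax, rate/fmin]` (`fmin=60`,
  `fmax=400` Hz, spanning adult phonation). We take the *first* local
  maximum whose corrected value exceeds
  `max(voicing_threshold, 0.8·global max)`, falling back to the global
  maximum. Taking the first strong peak rather than the global one prevents
  octave-down errors that the bias correction would otherwise induce (the
  two-period peak can be inflated above the one-period peak). The local-max
  test is edge-inclusive so a true peak sitting on the search boundary is
  not skipped. Sub-sample lag comes from parabolic interpolation over the
  three points around the chosen peak; the frame is unvoiced if the peak is
  below `voicing_threshold = 0.30`.
- **Pitch runs on the raw (non-pre-emphasized) signal** by default
  (`use_preemphasis=False`): pre-emphasis boosts high-frequency noise and
  weakens the autocorrelation periodicity evidence. The energy/VAD path
  does use the pre-emphasized signal.
- **Wild-point removal.** A single pass drops voiced frames whose F0
  deviates more than 25 % relative from the track median. The pass is
  idempotent on its own output.
- **Cycle marking.** Starting from the largest signal peak inside a voiced
  interval, cycle peaks are placed one estimated period apart, searching
  ±20 % of the period for the local maximum, then refined to sub-sample
  precision by parabolic interpolation of the sample triplet. Sub-sample
  refinement matters: at 10 kHz a 150 Hz vowel has ~67-sample periods, and
  integer quantization alone contributes ~1 % apparent jitter, an order of
  magnitude above the clean-signal floor. Periods are differences of
  refined peak times; cycle amplitude is the refined peak height minus the
  refined trough between that peak and the next (peak-to-trough of the same
  cycle — letting the window reach the next peak smooths the amplitude
  sequence and underestimates shimmer by ~30 %). Periods outside
  `[1/fmax, 1/fmin]` are discarded.

## Perturbation measures

With periods `{T_i}` and amplitudes `{A_i}` (n cycles), and `PQ_K(v)` the
mean absolute deviation of each value from its centered K-point moving mean,
normalized by the overall mean:

| Measure | Definition |
| --- | --- |
| Jitter (%) | `mean|ΔT| / mean T · 100` |
| Jitter_abs (s) | `mean|ΔT|` |
| Jitter_rap, Jitter_PPQ5 | `PQ_3(T)`, `PQ_5(T)` ·100 |
| Jitter_ddp | mean absolute second difference / mean ·100 (= 3·RAP) |
| Shimmer (%), APQ3/5/11, dda | same family on `A_i` (dda = 3·APQ3) |
| Shimmer_dB | `mean|20·log₁₀(A_{i+1}/A_i)|` |
| HNR (dB) | `10·log₁₀(r/(1−r))`, `r` the corrected autocorrelation peak, clipped to `r ∈ [10⁻⁴, 1−10⁻⁴]`, HNR ∈ [−20, 40] |
| NHR | `(1−r)/r` |

HNR/NHR are reported as mean and standard deviation over voiced frames;
F0 statistics (mean/max/min/median/std) use the cleaned track, population
standard deviation.

For i.i.d. Gaussian period perturbation with relative SD σ, the expected
Jitter (%) is `100·(2/√π)·σ` (folded-normal mean of the difference of two
independent deviates). The acceptance battery checks recovery against this.

## Nonlinear measures

- **DFA.** Cumulative-sum profile, per-window linear detrend, fluctuation
  `F(s)` over 10 log-spaced scales from 40 to `min(1000, N/4)` samples;
  the reported value is the raw log–log slope α (0.5 for white noise, 1.5
  for a random walk), *not* rescaled to any unit interval.
- **RPDE.** Signal standardized, delay-embedded with `m=4`, `τ=14`
  samples; for ε-balls of radius `0.12·(embedding scale)` around anchor
  points, first return times after leaving the ball are histogrammed and
  the normalized entropy `H/ln T_max` reported (near 0 for a pure tone,
  large for noise). Anchors are strided to at most 6000 and returns
  capped at 1500 samples for bounded runtime.
- **D2.** Grassberger–Procaccia with `m=5`, τ from the first minimum of
  the 16-bin auto-mutual information (capped at 50), Theiler window τ,
  at most 10⁶ seeded pair samples, correlation integral over 20 log
  radii between the 1st and 50th distance percentiles, slope from the
  most-stable contiguous third of the curve. Recovered: ≈1 for a sine,
  ≈2 for a two-incommensurate-tone torus.
- **PPE.** Voiced F0 converted to semitones relative to the *track median*
  (a self-reference; no population baseline is assumed), whitened by an
  order-2 linear predictor fit to the sequence itself, and the residuals'
  30-bin normalized entropy `H/ln 30` reported. A constant track gives 0.

## Synthetic vowel generator

`synth_vowel` advances phase cycle-by-cycle: each cycle's period is
`T₀·(1+δ_i)` and amplitude `A·(1+ε_i)` with `δ_i, ε_i` truncated-normal
(±3σ) draws; the waveform is a fixed 5-harmonic shape (`Σ sin(2πhφ)/h`,
peak-normalized) so cycle peaks are sharp and markable. Gaussian noise is
added over the voiced region only, scaled to a target harmonics-to-noise
ratio in dB. The returned ground truth contains the drawn periods,
amplitudes, cycle boundaries, and the separate harmonic/noise components,
so recovery can be checked against what was actually injected rather than
the nominal σ.

What it does **not** emulate: formant structure, onset/offset dynamics,
tremor (low-frequency F0 modulation), subharmonics, or any
disease-specific waveform change. It validates the *measurement chain*,
not clinical discrimination.

Synthetic tables: classification tables are two spherical unit Gaussians
in feature space separated by a stated multiple of the SD along a random
direction (Bayes accuracy `Φ(separation/2)`); regression tables are a
sparse linear model with Gaussian noise, affinely mapped to the UPDRS
range [0, 199].

## Modeling

- **Cross-validation.** Seeded permutation split by `np.array_split` into
  k folds; standardization is fit on each training fold only and applied
  to the held-out fold (no leakage — this is tested by spying on
  `StandardScaler.fit` inputs). Metrics are pooled over fold confusion
  matrices (micro-average) by default; per-fold reporting is available.
  PD is the positive class.
- **Metrics.** Accuracy, precision, recall, F1 in percent from TP/FP/FN/TN;
  MAE, MSE, RMSE for regression. Degenerate denominators return 0 with a
  logged warning.
- **Classifiers.** RBF-SVM (C=1, γ=scale), logistic regression (C=1),
  MLPs (16,) and (16, 8) with early stopping (patience 30, lr 0.05,
  validation fraction 0.15, max 2000 iters — defaults chosen so a
  separable toy table is fit reliably), Gaussian naive Bayes.
- **Regressors.** 4:1:1 train/validation/test split (seeded 6-way
  permutation); the validation third selects C (SVR) or α (LASSO) from a
  log grid, then the model refits on train+validation and reports test
  metrics. SVR standardizes the target internally.
- **Feature ranking.** LASSO on standardized features/target with α chosen
  on a 4:1 holdout; features with nonzero weights ranked by |weight|.
- **Significance.** Two-sided Mann–Whitney U per feature (p=1 for constant
  features), Benjamini–Hochberg adjusted p-values alongside the raw ones.
  Type-I calibration at α=0.05 is verified on pure-noise tables.

## Known limitations

- The VAD and pitch defaults target sustained vowels; running speech needs
  different thresholds and voicing logic.
- Cycle marking assumes one dominant peak per period; strongly
  subharmonic or diplophonic voices can halve/double the marked rate.
- HNR inherits any residual autocorrelation bias not removed by the
  `N/(N−k)` correction (window tapering, jitter-induced peak widening);
  measured HNR on the generator sits within ~0.5 dB of target at 10–20 dB
  but saturates at the 40 dB clip for clean signals.
- D2 and RPDE parameters (m, τ, ε) follow common practice for sustained
  phonation at 10 kHz; they are not adaptive per recording beyond the
  AMI-selected τ for D2.
- The synthetic tables validate the estimators and the evaluation
  protocol, not clinical performance; numbers on real cohorts depend on
  the cohort.
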