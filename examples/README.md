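# Examples

Each script is self-contained (synthetic inputs only) and runnable as
`python examples/<name>.py`:

- `01_synthesize_and_extract.py` — generator → WAV → 24-feature vector.
- `02_vad_and_pitch.py` — the intermediate analyses: endpoint detection
  against the known voiced span, and the pitch track against the
  programmed F0.
- `03_perturbation_recovery.py` — measured jitter vs. the folded-normal
  expectation across a sweep of injected perturbation levels.
- `04_classification.py` — 5-fold cross-validation of all five
  classifiers on a table with known Bayes accuracy.
- `05_regression_ranking_significance.py` — severity regression against
  the injected noise floor, LASSO recovery of a planted support, and the
  Mann–Whitney/Benjamini–Hochberg feature screen.
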