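"""Cross-validate all five classifiers on a synthetic two-class table.

The table is two spherical Gaussians separated by 3 SD, so the Bayes
accuracy is Phi(1.5) ~ 93%. All classifiers should sit near it, and none
should exceed it by much — that would indicate leakage.
"""

from voicepd.modeling import run_classification
from voicepd.synth import synth_classification_table

table, _ = synth_classification_table(n_per_class=150, n_features=22,
                                      separation=3.0, seed=5)
print(f"{'algo':>8} {'acc %':>7} {'prec %':>7} {'rec %':>7} {'F1 %':>7}")
for algo in ("svm", "logreg", "nn1", "nn2", "gnb"):
    rep = run_classification(table, algo, k=5, seed=5)
    print(f"{algo:>8} {rep.accuracy:7.2f} {rep.precision:7.2f} "
          f"{rep.recall:7.2f} {rep.f1:7.2f}")
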