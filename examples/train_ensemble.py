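"""Train the base-classifier bank and the ensemble meta-classifier (EMC).

Splits a synthetic Ramanome 70/30, fits the six classical + two deep base
learners, weights the top five by normalized validation accuracy
(w_n = acc_n / sum acc), fuses their class probabilities, and evaluates on
the held-out 30%.
"""

import numpy as np

from ramanid import (ConfusionMatrix, SyntheticConfig, build_emc,
                     compute_metrics, generate_ramanome, preprocess_set,
                     split_train_test, train_and_validate_suite)

data = preprocess_set(generate_ramanome(SyntheticConfig(
    cells_per_replicate=20, seed=1)))  # 9 species x 3 replicates x 20 cells
train, test = split_train_test(data, 0.7, seed=1)
print(f"{train.n_cells} training / {test.n_cells} test cells")

suite = train_and_validate_suite(train, seed=1)
for name, acc in zip(suite.names, suite.val_accuracy):
    print(f"  {name:8s} validation accuracy {acc:6.2f}%")

ens = build_emc(suite, k=5)
print("ensemble members and weights:")
for name, w in zip(ens.member_names, ens.weights):
    print(f"  {name:8s} w = {w:.4f}")

y_hat = ens.predict(test.intensities)
cm = ConfusionMatrix.from_labels(test.species, y_hat, classes=ens.classes)
m = compute_metrics(cm)
print(f"EMC test accuracy {m.accuracy:.2f}%  "
      f"sensitivity {m.mean_sensitivity:.2f}%  "
      f"specificity {m.mean_specificity:.2f}%  kappa {m.kappa:.4f}")
print("The ensemble matches or beats its best member because misclassified")
print("cells rarely fool all five members the same way.")
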