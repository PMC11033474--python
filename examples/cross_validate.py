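"""Repeated stratified cross-validation of classifiers and ensemble.

Runs a reduced protocol (2 repeats x 3 folds, classical models) on a small
synthetic Ramanome and prints the per-model metric distribution the way the
full 10 x 10-fold protocol would.
"""

from ramanid import SyntheticConfig, generate_ramanome, preprocess_set, repeated_cv
from ramanid.classifiers import default_specs
from ramanid.evaluation import confusion_report

data = preprocess_set(generate_ramanome(SyntheticConfig(
    n_replicates=1, cells_per_replicate=20, axis_step=2.0, seed=3)))

report = repeated_cv(data, default_specs(seed=3, include_deep=False),
                     repeats=2, folds=3, seed=3, k=3)
summary = report.summary()
acc = summary[summary.metric == "accuracy"]
print(f"{report.records.repeat.nunique()} repeats x "
      f"{report.records.fold.nunique()} folds = "
      f"{report.records.groupby('model').size().iloc[0]} resamples per model")
for _, row in acc.iterrows():
    print(f"  {row['model']:8s} accuracy median {row['median']:6.2f}% "
          f"IQR [{row['q1']:6.2f}, {row['q3']:6.2f}]")
print("pooled ensemble confusion matrix (rows true, cols predicted, % margins):")
print(confusion_report(report.confusion).round(1).to_string())
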