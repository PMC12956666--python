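"""Train the GMDH polynomial network and score it on a held-out 30% split.

The network grows layer by layer from two-input quadratic neurons, keeping
the best units per layer by validation-set error (the decremental schedule
40-38-27-22-16-10-8-5), and decodes its single output into one of 8 classes.
"""

import numpy as np

from eegmdh import (FitConfig, GeneratorConfig, evaluate_predictions,
                    extract_features, fit_gmdh, generate_dataset, predict,
                    train_test_split)

dataset = generate_dataset(GeneratorConfig(seed=0))
X = np.vstack([extract_features(t) for t in dataset.trials])
codes = dataset.encoded_labels()

train, test = train_test_split(codes, test_fraction=0.30, seed=1)
print(f"{train.size} training / {test.size} test trials")

model = fit_gmdh(X[train], codes[train], FitConfig(seed=2))
print(f"realized layer widths: {model.realized_widths()}")

report = evaluate_predictions(codes[test], predict(model, X[test]),
                              dataset.vocabulary.n_classes,
                              dataset.vocabulary.labels)
print("\nheld-out test performance:")
print(report.to_text())
# accuracy is the diagonal fraction of the confusion matrix; kappa corrects
# it for chance agreement; macro F1 averages per-class F1 without weighting.
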