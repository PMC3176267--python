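"""Full pipeline: encode -> standardize -> select -> tune -> train -> test.

Runs the whole workflow on a synthetic two-class benchmark with a strong
composition signal, then evaluates the refit model on held-out sequences.
The grid search tunes (C, gamma) by stratified 5-fold cross-validation;
the test block reports accuracy, sensitivity, specificity, MCC and AUC.
"""

import numpy as np

from physprot import (
    PipelineConfig,
    SynthSpec,
    evaluate,
    make_benchmark,
    run_train,
)
from physprot.pipeline import _prepare_features
from physprot.svm_model import decision_values

spec = SynthSpec(n_pos=100, n_neg=100, n_tables=40, n_informative=5,
                 delta=0.3, seed=5)
train, test, tables, informative = make_benchmark(spec, 50, 50)

cfg = PipelineConfig(selector="relieff", n_features=20, seed=5,
                     C_grid=(0.5, 2.0, 8.0, 32.0),
                     gamma_grid=(0.005, 0.02, 0.08))
result = run_train(train, cfg)
print(f"CV accuracy {result.grid.best_accuracy:.2f}% at "
      f"C={result.grid.best_C:g}, gamma={result.grid.best_gamma:g} "
      f"({len(result.selected)} selected features)")

X = _prepare_features(result.model, test)
f = decision_values(result.model, X)
pred = np.where(f > 0, 1, -1)
rep = evaluate(test.y, pred, f)
print(f"held-out: accuracy {rep['accuracy']:.2f}%  "
      f"sensitivity {rep['sensitivity']:.2f}%  "
      f"specificity {rep['specificity']:.2f}%  "
      f"MCC {rep['mcc']:.4f}  AUC {rep['auc']:.4f}")
print()
print("CV accuracy estimates generalization from the training set alone;")
print("the held-out block is the honest measure. MCC near 1 and AUC near 1")
print("mean the composition signal was recovered almost perfectly.")
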