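"""Train a multiple-kernel nu-SVM with hand-chosen weights.

Embeds a planted two-class multi-view dataset in dissimilarity space,
gives the informative view (3) all the kernel weight, and evaluates on
the validation split.
"""

import numpy as np

from mkmd import (
    ConfusionCounts,
    Genome,
    PrototypeMask,
    SynthSpec,
    basic_metrics,
    build_stacks,
    one_vs_all_labels,
    planted_multiview_dataset,
    stratified_split,
)
from mkmd.ga_search import fit_and_predict

spec = SynthSpec(n_per_class=100, seed=0)
patterns, labels = planted_multiview_dataset(spec)
y = one_vs_all_labels(labels, 2)
tr, va, te = stratified_split(y, seed=0)
ts, vs, _ = build_stacks(
    [patterns[i] for i in tr], [patterns[i] for i in va], [patterns[i] for i in te]
)

genome = Genome(
    nu=0.3,
    beta=tuple(1.0 if v == 3 else 0.0 for v in range(1, 9)),
    gamma=(0.005,) * 8,
    mask=PrototypeMask.all_ones(ts.shape[1]),
)
model, pred, _ = fit_and_predict(genome, ts, vs, y[tr])
report = basic_metrics(ConfusionCounts.from_predictions(y[va], pred))
print(f"support vectors:          {model.n_support} of {model.n_train}")
print(f"validation accuracy:      {report.accuracy:.3f}")
print(f"validation informedness:  {report.informedness_normalized:.3f}")
# With all weight on the informative view the classifier recovers the
# planted separation; moving weight to noise views degrades it.
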