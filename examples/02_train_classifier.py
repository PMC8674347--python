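"""Train the Random-Forest pixel classifier on a synthetic library.

Builds a balanced 11-class library (polymers + stearate decoy + NMP)
spanning a wide range of signal quality, preprocesses it, trains a forest
and prints the out-of-bag (OOB) diagnostics.  A small forest is used here
to keep the example quick; the production default is 1500 trees.
"""

import ramanmp as rm

lib = rm.generate_training_library(n_per_class=20, snr_range=(3, 30), seed=1)
print(f"library: {len(lib)} spectra over classes {lib.classes}")

model = rm.train(rm.preprocess_library(lib), n_trees=300, seed=1)
print(f"OOB error: {model.oob_error:.4f}  (fraction of training spectra "
      "misclassified by trees that never saw them)")

df = rm.report_confusion(model)
worst = df["error"].idxmax()
print(f"per-class OOB error:\n{df['error'].round(3)}")
print(f"-> hardest class: {worst}; PE/stearate is the classic confusable pair "
      "because stearates share PE's band pattern.")
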