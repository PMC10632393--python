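"""End-to-end run at reduced scale: simulate, preprocess, segment, extract
CNN features, train the gray-wolf-optimized MLP, and evaluate held out.

Takes a minute or two on one CPU. All artifacts (masks, features.csv,
classifier.json, report.json) land in the run directory.
"""

import numpy as np

from melanopt import pipeline as pl

config = pl.PipelineConfig(out_dir="example_run", n_images=60, seed=0)
report = pl.run_pipeline(config)

print(f"stage timings (s): { {k: round(v, 1) for k, v in report.timings.items()} }")
print(f"median segmentation Dice: {np.median(report.dice_per_image):.3f}")
print(f"CNN final training accuracy: {report.cnn_history[-1]['accuracy']:.3f}")
print(f"IGWO best training fitness: {report.igwo_best_fitness:.3f}")
print(f"held-out confusion: {report.confusion}")
print(f"held-out accuracy: {report.test_metrics['accuracy']:.3f}, "
      f"ROC AUC: {report.roc_auc:.3f}")
# the held-out accuracy is what the method is judged on: the fraction of
# unseen synthetic lesions whose melanoma/benign label is predicted right
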