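"""Train the tanh-hidden MLP with the gray wolf optimizer on synthetic
features, comparing the archive-augmented mode against the canonical one.

The genome's first gene picks the hidden-layer size H in [5, 30]; the rest
are the weight/bias vector in [-2, 2]. Fitness is the raw training
misclassification rate F/N, so 0.05 means 5% of training samples wrong.
"""

from melanopt import classifier as clf
from melanopt import igwo
from melanopt import synthetic as syn

features, labels = syn.generate_feature_dataset(
    syn.FeatureGenConfig(n_per_class=100, separation=3.0, seed=0))

for mode in ("igwo", "gwo"):
    config = igwo.IGWOConfig(population_size=30, max_iterations=60,
                             stagnation_limit=30, seed=0, mode=mode)
    model, result = clf.train_classifier(features, labels, config)
    print(f"{mode:5s}: final training fitness {result.best_fitness:.3f} "
          f"after {result.n_iterations} iterations "
          f"(H={model.n_hidden} hidden units, stop: {result.termination})")
# lower fitness is better; the history of best-so-far fitness per iteration
# is in result.history if you want to plot convergence
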