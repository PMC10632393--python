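# melanopt

Automated melanoma screening from dermoscopy images, built as a fully
testable pipeline: artifact removal, unsupervised lesion segmentation,
learned image features, and a neural classifier whose architecture *and*
weights are found by a metaheuristic rather than gradient descent.

The package is aimed at researchers studying hybrid neuro-evolutionary
diagnosis pipelines who need every stage to be reproducible and
independently inspectable. Because public dermoscopy sets are large and
external, the package ships a synthetic dermoscopy generator (textured skin
background, darker irregular lesion, hair strands, blur, noise, exact
ground-truth masks) so the whole chain runs and is tested offline.

## The method

Given an RGB dermoscopy image `I`:

1. **Preprocessing** — thin dark artifacts (hairs, vessels, < 10 px across)
   are removed by a grey closing `Î = (I ⊕ C) ⊖ C` with a cross-shaped
   structuring element C (10-px vertical + horizontal line arms), and the
   result is sharpened by subtracting a zero-sum Laplacian-of-Gaussian
   response: `P = Î − Î * K_LoG`, with
   `K_LoG(x, y) ∝ −(1 − (x²+y²)/2δ²)·exp(−(x²+y²)/2δ²)`.
2. **Segmentation** — a small Kohonen network (SOM, 2×2 competitive units,
   winner update `w ← (1−α)w + αx`, α decaying linearly) quantizes the
   grayscale intensities of `P`; the darkest cluster seeds a binary mask
   `u`, refined greedily to a fixed point by
   `u' = u + [(X − K(I_out))² − (X − K(I_in))²]·|∇u|`, binarized at > 0,
   where `K(I_in)`, `K(I_out)` are the codebook coefficients nearest the
   current inside/outside mean intensity.
3. **Features** — the masked region is cropped to 150×150 and passed
   through a small CNN (two conv/ReLU/maxpool blocks, 64 filters of 7×7
   and 5×5, then FC 500→250→100); the 100-dimensional third-FC-layer
   activation is the image's feature vector. A temporary softmax head is
   attached for training only. The CNN is implemented in numpy
   (im2col + BLAS, Adam).
4. **Classification** — an MLP with X=100 inputs, one tansig hidden layer
   of H ∈ [5, 30] units and 2 softmax outputs. A single genome encodes H
   and the full weight vector (`H(X+1) + C(H+1)` values in [−2, 2]); the
   Gray Wolf Optimizer minimizes the training error `Fit = F/N`. The
   improved variant (IGWO) keeps an archive S of elite solutions with
   selection probabilities `z_i = (1 − Fit_i)/Σ(1 − Fit_j)` and steers half
   of the pack toward roulette-selected archive members.
5. **Evaluation** — confusion-matrix suite: accuracy, per-class and
   macro-averaged precision/recall/F-measure, sensitivity, specificity,
   MCC, CSI (= PPV + TPR − 1), and ROC/AUC.

## Worked example

The metric suite applied to a published ISIC-2016 test-split confusion
matrix (379 samples, 75 melanoma / 304 benign; 73 + 295 correct):

```bash
$ python examples/evaluate_metrics.py
accuracy        97.0976 %
sensitivity     97.3333 %  (melanoma recall)
specificity     97.0395 %  (benign recall)
macro precision 94.1755 %
macro recall    97.1864 %
macro F-measure 95.5817 %
MCC             0.9131
CSI             0.8636
```

Accuracy is the fraction of all 379 test images classified correctly;
sensitivity/specificity split that by class. The macro values average each
metric over the two classes. MCC summarizes the whole matrix on a −1…1
scale; CSI rewards a classifier that is simultaneously precise and
complete on the melanoma class.

An end-to-end run on synthetic data (`python examples/full_pipeline.py`,
60 images, reduced CNN profile, ~20 s):

```
median segmentation Dice: 0.897
CNN final training accuracy: 0.905
IGWO best training fitness: 0.024
held-out confusion: {'tp': 8, 'tn': 9, 'fp': 0, 'fn': 1}
held-out accuracy: 0.944, ROC AUC: 0.988
```

The other scripts in `examples/` each demonstrate one stage. The same
stages are exposed as a CLI: `melanopt simulate|preprocess|segment|run-all|
evaluate`.

## Layout

- `src/melanopt/` — `synthetic`, `preprocess`, `segmentation`, `features`,
  `igwo`, `classifier`, `metrics`, `pipeline`, `cli`
- `examples/` — one short narrative script per capability
- `docs/methods.md` — modeling choices, parameters, limitations
- `tests/` — unit, property and acceptance tests
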