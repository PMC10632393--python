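"""The full evaluation-metric suite on a published confusion matrix.

Counts are the ISIC-2016 test-split result reported for the method this
package implements: 379 samples, 75 melanoma / 304 benign, of which 73
melanoma and 295 benign were classified correctly.
"""

from melanopt import metrics as met

cm = met.ConfusionMatrix(tp=73, tn=295, fp=9, fn=2)

binary = met.binary_metrics(cm)
macro = met.macro_metrics(cm)
print(f"accuracy        {100 * binary['accuracy']:.4f} %")
print(f"sensitivity     {100 * binary['sensitivity']:.4f} %  (melanoma recall)")
print(f"specificity     {100 * binary['specificity']:.4f} %  (benign recall)")
print(f"macro precision {100 * macro['macro_precision']:.4f} %")
print(f"macro recall    {100 * macro['macro_recall']:.4f} %")
print(f"macro F-measure {100 * macro['macro_f_measure']:.4f} %")
print(f"MCC             {met.mcc(cm):.4f}")
print(f"CSI             {met.csi(cm):.4f}")
# macro values average the melanoma and benign per-class metrics; MCC and
# CSI are single-class summaries (1 = perfect, 0/-1 = chance / inverted)
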