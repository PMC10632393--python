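"""Generate a small synthetic dermoscopy dataset and inspect it.

Each sample is a skin-textured frame with a darker elliptical lesion
(melanoma: irregular boundary, multi-tone fill; benign: regular, single
tone), thin hair strands, blur and noise, plus the exact ground-truth mask.
"""

import numpy as np
import pandas as pd

from melanopt import synthetic as syn

config = syn.ImageGenConfig(seed=0)
manifest = syn.generate_dataset(config, n=10, melanoma_fraction=0.5,
                                out_dir="example_data")
table = pd.read_csv(manifest)
print(table)

sample = syn.generate_lesion_sample(config, syn.MELANOMA)
print(f"\nimage shape {sample.image.shape}, intensity range "
      f"[{sample.image.min():.2f}, {sample.image.max():.2f}]")
print(f"lesion mask area: {sample.mask.sum()} px "
      f"({100 * sample.mask.mean():.1f}% of the frame)")
# the mask area tells you how much of the frame the classifier's ROI crop
# will cover; the manifest is the input every pipeline stage starts from
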