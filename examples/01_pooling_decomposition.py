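"""Three pooling operators and the three-level decomposition.

Builds the worked 3x3 block (middle column 8, 9, 25, zeros elsewhere),
applies the three operators, then decomposes a synthetic 64x64 image and
prints the nine compressed-image shapes.
"""

import numpy as np

from octfuse import (
    SyntheticSpec,
    decompose,
    make_dataset,
    max_mean_pool,
    max_min_pool,
    max_pool,
)

block = np.zeros((3, 3))
block[:, 1] = [8, 9, 25]
print("worked 3x3 block:\n", block)
print("max pooling     ->", max_pool(block, 3)[0, 0])        # global maximum
print("max-mean pooling->", max_mean_pool(block, 3)[0, 0])   # best column mean
print("max-min pooling ->", max_min_pool(block, 3)[0, 0])    # best column min

images, _ = make_dataset(SyntheticSpec(n_classes=2, n_per_class=1, seed=0))
result = decompose(images[0])
print("\ncompressed images from one 64x64 input:", len(result))
for i, c in enumerate(result, 1):
    print(f"  c{i}: {c.shape[0]}x{c.shape[1]}")
print("Each level emits max / max-mean / max-min of the current carrier;")
print("the carrier is then 2x2 max-pooled, so shapes shrink level by level.")
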