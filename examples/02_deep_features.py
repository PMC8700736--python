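"""Fused deep-feature vectors: 10 segments of D features per image.

A deterministic mock extractor (D=1000) stands in for a pre-trained CNN's
final fully-connected layer; the fused vector concatenates features of the
original image and its nine decomposition outputs.
"""

from octfuse import (
    MockExtractorSpec,
    SyntheticSpec,
    build_dataset,
    generate_deep_features,
    make_dataset,
    make_extractor,
)

images, labels = make_dataset(
    SyntheticSpec(n_classes=3, n_per_class=4, seed=1))
extractor = make_extractor(MockExtractorSpec(kind="informative", D=1000,
                                             seed=0))

vec = generate_deep_features(extractor, images[0])
print(f"one image -> fused vector of length {vec.shape[0]} "
      f"(10 segments x D={extractor.output_dim})")

dataset = build_dataset(extractor, images, labels)
print(f"dataset matrix: {dataset.n} images x {dataset.p} features")
name, segment, index = dataset.provenance[4321]
print(f"column 4321 came from extractor {name!r}, segment {segment} "
      f"(0 = original image, 1-9 = c1..c9), within-segment index {index}")
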