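"""Generate a small synthetic field corpus with the 17:3 crop:weed imbalance.

Builds 20 top-down scenes, checks the aggregate object ratio, and writes
PNG images + YOLO-txt labels + a manifest to ./example_output/corpus.
"""

from weeddet import SceneParams, class_ratio, generate_corpus
from weeddet.synthdata import write_corpus

params = SceneParams(seed=7)
images, manifest = generate_corpus(20, params, class_ratio=(17, 3))
manifest = write_corpus(images, manifest, "example_output/corpus")

pair, value = class_ratio(images)
total = sum(len(img.boxes) for img in images)
print(f"images: {len(images)}, objects: {total}")
print(f"aggregate crop:weed ratio = {pair[0]}:{pair[1]} ({value:.2f})")
# The ratio is exactly the imbalance a weed-scarce field corpus shows:
# many large crop plants for every small weed.
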