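"""The three detection blocks on toy feature maps.

Runs a transformer encoder, an involution/CFFI bridge and an ASFF fusion
head on random inputs and prints the contracts each one satisfies.
"""

import numpy as np

from weeddet import autodiff as ad
from weeddet.nnblocks import (
    ASFFHead,
    CFFI,
    Involution,
    InvolutionConfig,
    TransformerConfig,
    TransformerEncoder,
)

rng = np.random.default_rng(0)

# transformer encoder: global self-attention over feature-map cells
te = TransformerEncoder(TransformerConfig(embed_dim=16, n_heads=2), rng)
x = ad.Tensor(rng.normal(size=(1, 16, 6, 6)))
print("transformer:", x.shape, "->", te(x).shape, "(shape preserved)")

# involution: per-position kernels shared across channels
inv = Involution(8, InvolutionConfig(kernel_size=3), rng)
y = inv(ad.Tensor(rng.normal(size=(1, 8, 6, 6))))
print("involution :", y.shape, f"({inv.n_parameters()} params, "
      "independent of which channels share a group)")

# CFFI: parallel 1x1 conv + 1x1 involution, concatenated
cffi = CFFI(32, 16, rng)
z = cffi(ad.Tensor(rng.normal(size=(1, 32, 4, 4))))
print("cffi       :", z.shape, "(2 x width channels)")

# ASFF: rescale three pyramid levels and fuse with per-position softmax
head = ASFFHead([8, 16, 32], [8, 16, 32], target_index=0, rng=rng)
maps = [ad.Tensor(rng.normal(size=(1, 8, 8, 8))),
        ad.Tensor(rng.normal(size=(1, 16, 4, 4))),
        ad.Tensor(rng.normal(size=(1, 32, 2, 2)))]
fused, w = head(maps, return_weights=True)
print("asff fused :", fused.shape,
      f"| weights in [{w.data.min():.3f}, {w.data.max():.3f}], "
      f"per-position sum max err {abs(w.data.sum(axis=1) - 1).max():.1e}")
# The alpha/beta/gamma maps are a per-position convex combination: each
# output pixel chooses how much of each pyramid scale to trust.
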