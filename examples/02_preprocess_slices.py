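"""Turn a 3D phantom case into the 2D network input.

The chain: extract one axial slice per modality (slice 90 of 155, else the
middle), centre-crop, Gaussian-denoise, z-score each channel to mean 0 /
std 1, and stack in the fixed modality order [t1, t1ce, t2]. The label
slice rides along geometrically and is remapped from file code 4 to the
dense internal class 3.
"""

import numpy as np

from brainseg import phantom, preprocess

volumes, labels = phantom.generate_phantom(phantom.PhantomConfig(seed=11))
mm, seg = preprocess.preprocess_case(volumes, labels, target=64)

print("network input:", mm.pixels.shape, "channels", mm.channel_order)
for i, name in enumerate(mm.channel_order):
    ch = mm.pixels[..., i]
    print(f"  {name:>5}: mean {ch.mean():+.2e}, std {ch.std():.6f}")
print("label classes present:", sorted(np.unique(seg.labels).tolist()),
      "(0 bg, 1 necrotic, 2 edema, 3 enhancing)")

augmented = preprocess.augment(mm, seg, seed=0)
print(f"augmentation emits {len(augmented)} aligned pairs "
      "(original, flips, right-angle rotations, noise, translation)")
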