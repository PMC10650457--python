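"""Tile an image into the exemplar pyramid and count the views.

Builds a random 224x224 image, splits it into non-overlapping 28/56/112-px
patch grids plus the full image, and prints the view count per scale.
"""

import numpy as np

from pyrafex import PyramidConfig, pyramid_views

config = PyramidConfig()  # working side 224, patches 28/56/112, full image
image = np.random.default_rng(0).random((300, 240, 3))

views = pyramid_views(image, config)
per_scale: dict[int, int] = {}
for addr, view in views:
    per_scale[addr.scale_side] = per_scale.get(addr.scale_side, 0) + 1

for side, count in sorted(per_scale.items()):
    print(f"scale {side:>3} px : {count:>2} views")
print(f"total        : {len(views)} views, each {views[0][1].shape}")
# 64 + 16 + 4 + 1 = 85 views; with a 1000-dim backbone that is the
# 85,000-column exemplar feature vector.
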