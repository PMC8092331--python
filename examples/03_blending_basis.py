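"""Compare the three blending basis functions on one pair.

Blends the same instrument foreground onto the same tissue background
with trivial copy-paste, Gaussian feathering and Laplacian pyramid
blending, then measures how much each differs from copy-paste near and
far from the tool boundary. The labels of all three are identical — only
pixel appearance near the seam changes.
"""

import numpy as np
from scipy import ndimage

from chromablend import FixtureSpec, make_background_fixture, make_foreground_fixture
from chromablend.blending import BASIS_ORDER, basis_blends

fg, _ = make_foreground_fixture(FixtureSpec(n_tools=1, seed=3))
bg = make_background_fixture(FixtureSpec(seed=4))

results = basis_blends(fg, bg)
trivial = results[0].image
near = ndimage.distance_transform_edt(1 - fg.mask) <= 4
near &= fg.mask == 0  # the background ring just outside the tool

for mode, res in zip(BASIS_ORDER, results):
    diff_near = np.abs(res.image - trivial)[near].mean()
    print(f"{mode:16s} label==mask: {np.array_equal(res.label, fg.mask)}  "
          f"mean |diff vs copy-paste| near seam: {diff_near:.4f}")
# trivial: 0 by definition; feathering and the pyramid spread foreground
# colour across the seam, which is exactly the blending artifact the
# mix-blend training strategy randomizes over.
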