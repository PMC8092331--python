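"""Sample the on-the-fly mix-blend training stream.

Draws five composite training samples: each picks a random
foreground-background pair, augments both (flying distractors and
endoscopic padding included), blends with all three basis functions and
emits the Dirichlet-weighted sum. The printed λ vectors are the random
blend weights; labels stay binary tool masks whatever λ is drawn.
"""

import numpy as np

from chromablend import (
    FixtureSpec,
    StreamConfig,
    make_background_fixture,
    make_foreground_fixture,
    sample_stream,
)

fgs = [make_foreground_fixture(FixtureSpec(n_tools=1 + i % 3, seed=i))[0] for i in range(3)]
bgs = [make_background_fixture(FixtureSpec(seed=100 + i)) for i in range(4)]

cfg = StreamConfig(n_iterations=5, alpha=(1.0, 1.0, 1.0), seed=11)
for comp in sample_stream(fgs, bgs, cfg):
    lam = np.array(comp.provenance["blend"])
    print(f"pair ({comp.provenance['fg_id']}, {comp.provenance['bg_id']})  "
          f"lambda = {np.round(lam, 3)}  tool pixels = {comp.label.sum()}")
# with alpha=(1,1,1) the weights are uniform over the simplex; a tiny alpha
# such as (0.001,)*3 would instead land at the corners, recovering the
# one-basis-per-image multi-blend scheme as a corner case.
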