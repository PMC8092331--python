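"""Refine a corrupted probability map with GrabCut certainty bands.

Builds a composite whose ground truth is known, corrupts the truth into
a plausible network probability map (blur + 30% of pixels pushed into
the uncertain band), then compares plain 0.5-binarization against
GrabCut refinement seeded from the certainty bands (<0.2 sure
background, >=0.8 sure foreground). Refinement re-decides only uncertain
pixels, using the image's own colour statistics.
"""

from chromablend import (
    CertaintyBands,
    FixtureSpec,
    binarize,
    blend_trivial,
    grabcut_postprocess,
    iou,
    make_background_fixture,
    make_foreground_fixture,
    make_probmap_fixture,
    make_rng,
    sequence_miou,
)

records_raw, records_ref = [], []
for seed in range(5):
    fg, truth = make_foreground_fixture(FixtureSpec(n_tools=2, seed=seed))
    bg = make_background_fixture(FixtureSpec(seed=50 + seed))
    image = blend_trivial(fg, bg).image
    prob = make_probmap_fixture(truth, flip_rate=0.3, blur_sigma=1.0,
                                rng=make_rng(seed, "pm"))
    raw = binarize(prob, 0.5)
    refined = grabcut_postprocess(image, prob, CertaintyBands(),
                                  rng=make_rng(seed, "gc"))
    records_raw.append(iou(raw, truth, frame_id=f"f{seed}"))
    records_ref.append(iou(refined, truth, frame_id=f"f{seed}"))

print(f"binarized mIoU: {sequence_miou(records_raw).mean_percent:6.2f}%")
print(f"refined   mIoU: {sequence_miou(records_ref).mean_percent:6.2f}%")
# the certainty-band seeding lets GrabCut repair the scattered uncertain
# pixels from colour contrast alone -- the refined score should be close
# to 100% while plain binarization sits far below.
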