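"""Build paired surface-derived ground truths with a controlled GM bias.

The tight variant thresholds the cortical partial volume at 0.5; the
large variant displaces the boundaries so the GM volume grows by a target
ratio (25% by default), emulating two different-but-plausible annotation
pipelines for the same anatomy.
"""

from neosynth import (PhantomSpec, calibrate_gt_bias, dice_score,
                      make_gt_variants, make_phantom)

spec = PhantomSpec((64, 64, 64), 1.0, folding=0.4, seed=6)
label_map, surfaces = make_phantom(spec)

bias = calibrate_gt_bias(label_map, surfaces, target_ratio=1.25)
tight, large = make_gt_variants(label_map, surfaces, bias)

ratio = large.volume_mm3("gm") / tight.volume_mm3("gm")
gm_dice = dice_score(tight.mask("gm"), large.mask("gm"))
print(f"calibrated boundary bias: {bias:.3f} mm")
print(f"GM volume ratio large/tight: {ratio:.3f}")
print(f"dice between the two GM ground truths: {gm_dice:.3f}")
for name in ("deepgm", "cerebellum", "brainstem", "hipamy",
             "ventricles"):
    assert dice_score(tight.mask(name), large.mask(name)) == 1.0
print("all non-cortical structures identical between variants")
# A 1.25 volume ratio between nested masks implies an inter-GT dice near
# 2/2.25 = 0.89 — the systematic annotation bias the third experiment
# quantifies.
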