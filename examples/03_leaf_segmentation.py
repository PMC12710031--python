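"""Color-threshold leaf segmentation before and after correction.

Pixels whose CIEDE2000 distance to a reference leaf color is below 10
count as "leaf". On a color-cast frame the raw segmentation misses most
leaf area; after CCM correction it recovers it.
"""

import numpy as np

import aircolor as ac
from aircolor.evaluate import delta_e_map, overlap_ratio, segment_by_threshold

chart = ac.load_reference_chart()
template = ac.render_chart_template(chart)

# ground-truth leaf color used by the synthetic generator
leaf_lab = ac.srgb_to_lab([72, 112, 52])

# a strongly attenuated frame, as under heavy cloud or a poor sensor
truth = ac.sample_scene_truth(seed=13, chart=chart, gain_range=(0.5, 0.65))
frame = ac.render_scene(truth, chart)

# truth mask: pixels that are leaf-colored in an undistorted render
ideal = ac.render_scene(
    ac.SceneTruth(seed=truth.seed, homography=truth.homography,
                  background=truth.background, noise_sigma=0.0,
                  dims=truth.dims), chart)
truth_mask = segment_by_threshold(delta_e_map(ideal, leaf_lab), 10.0).mask

_, obs = ac.observe_chart(frame, template, chart)
ccm = ac.fit_ccm(ac.filter_overexposed(obs), chart)
corrected = ac.apply_ccm(frame, ccm)

for label, img in (("original", frame), ("corrected", corrected)):
    seg = segment_by_threshold(delta_e_map(img, leaf_lab), 10.0)
    print(f"{label:>9}: {seg.n_selected:6d} px selected, overlap with truth "
          f"{overlap_ratio(seg.mask, truth_mask):.2f}")
# The overlap ratio is |predicted AND truth| / |truth|; higher means the
# image's colors are closer to their true values.
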