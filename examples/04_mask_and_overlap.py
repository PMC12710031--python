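"""Chart-occlusion masks and flight-overlap sufficiency.

Before frames are mosaicked, the chart (and the platform carrying it)
must be blanked out. The mask grows the detected chart quadrilateral by
30 % per direction along its long axis and 50 % along its short axis;
flight overlap must exceed the mask so neighbouring frames can fill the
hole.
"""

import numpy as np

import aircolor as ac
from aircolor.mosaic import make_mask, overlap_pixels

chart = ac.load_reference_chart()
template = ac.render_chart_template(chart)

truth = ac.sample_scene_truth(seed=2, chart=chart)
frame = ac.render_scene(truth, chart)
detection, _ = ac.observe_chart(frame, template, chart)

spec, raster = make_mask(detection, length_expand=0.3, width_expand=0.5,
                         image_shape=frame.shape)
print("chart corners (px):", np.round(spec.corners_image, 1).tolist())
print("masked pixels:", int((raster > 0).sum()))

# the flight geometry: 8192 x 5460 px frames at 80 % forward/side overlap,
# checked against a ~450 x 360 px mask
res = overlap_pixels((8192, 5460), 0.8, 0.8, mask_extents=(450, 360))
print(f"forward overlap {res.forward_px} px, side overlap {res.side_px} px, "
      f"sufficient: {res.sufficient}")
# Both overlaps far exceed the mask, so every masked region is covered by
# at least one neighbouring frame in the mosaic.
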