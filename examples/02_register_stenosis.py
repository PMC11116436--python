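"""Standardize a stenosis box and register the video onto it.

The stenosis box is resized to a 17.5 mm square (50 px at 0.35 mm spacing),
tracked through all frames with a correlation template tracker, smoothed with
a short moving average, and the motion-compensated clip is cropped out.  The
printed error compares recovered against programmed displacements.
"""

import numpy as np

from coroquant import registration as reg
from coroquant.phantom import PhantomSpec, StenosisSpec, generate_phantom

spec = PhantomSpec(stenoses=[StenosisSpec("mid-RCA", 0.5, 60.0)], seed=7)
video, truth = generate_phantom(spec)

ref = video.n_frames // 2
box = reg.standardize_box(
    truth.stenoses[0].box.translated(*truth.displacements[ref], frame_index=ref),
    video.pixel_spacing_mm, video.frame_shape,
)
print(f"standardized box: {box.width} px = {box.width * video.pixel_spacing_mm:.2f} mm square")

series = reg.smooth_displacements(reg.track_displacements(video, box, ref))
tdx = truth.displacements[:, 0] - truth.displacements[ref, 0]
tdy = truth.displacements[:, 1] - truth.displacements[ref, 1]
err = np.mean(np.hypot(series.dx - tdx, series.dy - tdy))
print(f"mean |recovered - true| displacement: {err:.2f} px "
      "(sub-pixel-scale residual means the crop stays locked on the stenosis)")

clip = reg.extract_clip_window(reg.apply_registration(video, series, box), 24)
print(f"registered clip: {clip.frames.shape} — 24 frames centred on the reference area")
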