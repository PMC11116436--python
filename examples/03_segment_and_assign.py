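"""Segment a clip with an ensemble and assign the stenosis to its segment.

Truth-backed reference segmenters stand in for the trained networks: their
probability maps are averaged, each pixel takes the most probable of 12
classes, and the stenosis box is assigned to the coronary segment whose
pixels come closest to the box centre (majority, then lowest SYNTAX index,
on ties).  A video-level majority vote pools the per-frame assignments.
"""

from coroquant import assignment, segmentation
from coroquant.phantom import PhantomSpec, StenosisSpec, generate_phantom, truth_backed_models
from coroquant.types import BoundingBox

spec = PhantomSpec(stenoses=[StenosisSpec("dist-RCA", 0.5, 45.0)], seed=3)
video, truth = generate_phantom(spec)
models = truth_backed_models(truth, n_segmenters=7, label_noise=0.05, seed=1)

st_box = truth.stenoses[0].box
frames = [10, 30, 50]
segmap = segmentation.segment_video(
    video.frames[frames], models.segmenters, frame_indices=frames,
)
votes = [assignment.assign_frame(segmap[i], st_box, "RCA") for i in range(len(frames))]
decision = assignment.assign_video(votes)
print(f"per-frame assignments: {votes}")
print(f"video-level majority vote: {decision} "
      f"(programmed: {truth.stenoses[0].segment_id})")
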