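"""Flag and remove PCI-related videos from a synthetic cohort.

Method 1 flags a video when the fraction of frames showing an instrument
(guidewire/balloon/stent) reaches 0.16; Method 2 flags videos acquired inside
a reported procedure interval widened by 25 minutes; either flag excludes the
video, all later videos of that patient, and every video of CABG patients.
"""

from coroquant import exclusion as ex
from coroquant import segments as seg
from coroquant.phantom import CohortConfig, generate_cohort
from coroquant.types import BoundingBox, StenosisRecord

cases, rows = generate_cohort(30, CohortConfig(pci_fraction=0.4, cabg_fraction=0.1), seed=11)

records, decisions = [], {}
for case in cases:
    spec = case.spec
    boxes = [BoundingBox(t, 10, 10, 30, 30, "guidewire")
             for f0, f1 in spec.instrument_frames for t in range(f0, min(f1, spec.n_frames))]
    intervals = case.report_rows[0].pci_intervals if case.report_rows else []
    decisions[spec.dicom_id] = ex.decide_pci(
        boxes, spec.n_frames, spec.acquisition_time, intervals, artery_side=spec.artery_side
    )
    segment = spec.stenoses[0].segment_id if spec.stenoses else seg.segments_of_side(spec.artery_side)[0]
    records.append(StenosisRecord(
        patient_id=spec.patient_id, study_date=spec.study_date, dicom_id=spec.dicom_id,
        reference_frame=spec.n_frames // 2, n_frames=spec.n_frames,
        artery_side=spec.artery_side, segment_id=segment,
        acquisition_time=spec.acquisition_time,
    ))

kept, audit = ex.apply_exclusions(records, decisions, rows)
reasons = {}
for entry in audit:
    reasons[entry.reason] = reasons.get(entry.reason, 0) + 1
print(f"{len(records)} videos in; {len(kept)} kept")
print(f"removed by reason: {reasons} "
      "(pci = flagged procedure video, post_pci = later video of the same patient, "
      "cabg = bypass patient)")
truth_pci = sum(1 for c in cases if c.is_pci_video)
flagged = sum(1 for c in cases if c.is_pci_video and decisions[c.spec.dicom_id].combined_flag)
print(f"combined-method recall on true PCI videos: {flagged}/{truth_pci}")
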