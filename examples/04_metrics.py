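"""The metric suite on hand-built cases, showing what each score rewards
and penalizes."""

import numpy as np

from cmttrack.metrics import (TrackMatch, aji, complete_tracks, dice, iou,
                              match_tracks, mota, mt_ml, track_fraction)

# two 10-px nuclei; a prediction that merges them keeps pixel Dice high
# but halves the object-level AJI
g = np.zeros((10, 10), np.uint16)
g[0:2, 0:5], g[4:6, 0:5] = 1, 2
merged = ((g > 0)).astype(np.uint16)
print(f"merged prediction: Dice {dice(g > 0, merged > 0):.2f}  "
      f"IOU {iou(g > 0, merged > 0):.2f}  AJI {aji(g, merged):.2f}")

# MOTA folds misses, false alarms and identity switches into one number
print("MOTA(GT=20, FN=2, FP=1, IDSW=1) =",
      mota(TrackMatch(fn=2, fp=1, idsw=1, gt=20)))

# a track covered by two different predicted identities: high TF, zero CT
ref = {1: {f: (20.0, 20.0, 10.0, 10.0) for f in range(10)}}
pred = {1: {f: (20.0, 20.0, 10.0, 10.0) for f in range(7)},
        2: {f: (20.0, 20.0, 10.0, 10.0) for f in range(7, 10)}}
tm = match_tracks(pred, ref)
print(f"broken track: CT {complete_tracks(pred, ref, tm):.1f}  "
      f"TF {track_fraction(pred, ref, tm):.1f}  MT/ML {mt_ml(pred, ref, tm)}")
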