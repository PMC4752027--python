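"""The frame-count arithmetic of the timeline.

Places five key frames one second apart and expands them: the timeline is
calibrated at 30 interpolated frames per second, so each of the four
segments contributes 30 frames and the final key frame is appended once —
(5 - 1) * 30 + 1 = 121 frames in total.
"""

from graphmotion import (FixtureSpec, Timeline, add_keyframe, capture_frame,
                         make_frames, make_scenes, reconcile_timeline,
                         segment_counts, shift_following)

scenes = make_scenes(FixtureSpec(n_nodes=5, n_edges=5, seed=1,
                                 script_kind="mixed"))[:5]
tl = Timeline()
for i, scene in enumerate(scenes):
    tl = add_keyframe(tl, capture_frame(scene, float(i), frame_id=f"kf{i}"))

counts = segment_counts(tl)
_, reconciled = reconcile_timeline(tl.entries)
seq = make_frames(reconciled, counts)
print("segment counts:", counts)          # [30, 30, 30, 30]
print("total frames:  ", len(seq))        # 121

# Dragging the third key frame (and everything after it) one second to the
# right doubles the middle gap; that segment alone now expands to 60 frames.
tl2 = shift_following(tl, "kf2", 1.0)
print("after shift:   ", segment_counts(tl2))  # [30, 60, 30, 30]
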