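"""Animating an object that exists in only some key frames.

A node deleted between two captures is not dropped: the union universe
keeps it everywhere, the frame that lacks it carries it hidden (styled
from the nearest frame that has it), and the expansion fades it out
through the Visible interpolator.
"""

from graphmotion import (FixtureSpec, capture_frame, make_frames, make_scenes,
                         reconcile_timeline)

first, second = make_scenes(FixtureSpec(n_nodes=4, n_edges=3, seed=2,
                                        script_kind="visibility_toggle"))
frames = [capture_frame(first, 0.0), capture_frame(second, 1.0)]
print("nodes per key frame:", [len(f.node_map) for f in frames])

universe, reconciled = reconcile_timeline(frames)
print("universe nodes:     ", sorted(universe.node_ids))
gone = (frames[0].object_ids("node") - frames[1].object_ids("node")).pop()
print("deleted node:       ", gone)
print("hidden in frame 2?  ",
      reconciled[1].node_map[gone]["visible"] is False)

seq = make_frames(reconciled, [4])
opacities = [f.opacity_of("node", gone) for f in seq]
print("fade-out opacities: ", opacities)
# The deleted node's rendered opacity ramps linearly 1.0 -> 0.0 across the
# segment; its geometry in the hidden frame was donated by the frame that
# still contained it, so a later fade-in would start from the same place.
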