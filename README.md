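# graphmotion

A headless keyframe-animation engine for styled node-link network scenes.

Biological networks — pathways, signaling cascades, interaction maps — are
usually drawn as static node-link diagrams, yet the systems they describe
change with time, condition, and treatment. Animating between two states of
the same network exploits motion to defeat change blindness: instead of
flipping between two pictures and hunting for differences, the viewer sees
positions glide, colors shift, and objects fade in and out. graphmotion
provides that animation step as a library: it captures full visual-property
snapshots of network scenes ("key frames"), interpolates between consecutive
key frames with a per-property interpolator taxonomy, and exports the result
as PNG frame sequences, animated GIFs, or MP4/H.264 movies.

## The model

A **key frame** is a snapshot of one scene at a timeline position *t*
(seconds): four total property maps (network, nodes, edges, annotations)
covering every registered visual property of every object. Key frames that
contain different objects are first **reconciled** against the union object
universe — an object a frame lacks is carried hidden (`visible = false`),
styled from the nearest-in-time frame that contains it — so interpolation is
always defined object-by-object.

Every visual property has exactly one of nine **interpolation kinds**:

| Kind | Behavior on a segment, local *t* ∈ [0, 1] |
|---|---|
| Color | per-channel linear RGB: *c(t) = c₀ + t (c₁ − c₀)*; alpha eased on a cubic Bezier |
| Size | linear: *v(t) = v₀ + t (v₁ − v₀)* |
| Transparency | linear on the 0–255 opacity integer |
| Position | linear in x, y (and stored z) |
| ObjectPosition | linear in the anchored offsets; anchor changes snap |
| Crossfade | categorical: old value fades out on [0, ½], new fades in on [½, 1] |
| CustomGraphicsCrossfade | both images drawn at once, weights 1 − *t* and *t* |
| Visible | opacity ramp *t* (appearing) or 1 − *t* (disappearing) |
| None | held at the old value, snapping at the segment end |

The **timeline** is measured in seconds and calibrated at 30 interpolated
frames per second: a segment of gap *g* seconds expands to
*n = max(1, round(30 g))* frames. A sequence of *k* key frames with *n*
interpolations per segment expands to *(k − 1) n + 1* frames — five key
frames at the default one-second spacing yield 121. The export frame rate
(25 PAL, 29.97 NTSC, 30, or 60) only sets playback timing of the written
movie, never the counts.

## Worked example

```python
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
print("segment counts:", counts)
print("total frames:  ", len(seq))
print("after shift:   ", segment_counts(shift_following(tl, "kf2", 1.0)))
```

prints

```
segment counts: [30, 30, 30, 30]
total frames:   121
after shift:    [30, 60, 30, 30]
```

Four one-second segments each expand to 30 frames, plus the final key frame:
121. Dragging key frame `kf2` (and everything after it) one second right
widens only the middle gap, so that segment alone doubles to 60. The
`examples/` directory has one narrative script per capability — manual
tweening, timeline arithmetic, reconciliation of added/removed objects, and
movie export.

A thin CLI wraps the same pipeline:

```sh
graphmotion fixtures --script mixed --seed 1 --out scenes/
graphmotion render scenes/mixed_seed1_storyboard.json \
    --format gif --fps 30 --resolution 200 --out movie.gif
graphmotion inspect scenes/mixed_seed1_storyboard.json
```

## Scene, storyboard, and session files

Scenes are single JSON documents (`network` / `nodes` / `edges` /
`annotations`, colors as `#RRGGBBAA`, coordinates in model units), a
storyboard lists scene files with times in seconds, and a session bundle
embeds every captured key frame losslessly. GraphML topology import is
supported. See `docs/formats.md` for annotated examples and
`docs/methods.md` for the full account of the interpolation model and its
numerical choices.

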