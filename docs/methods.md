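# Methods

This note records the animation model graphmotion implements, the
numerical conventions it fixes where the behavior was genuinely open, and
what the synthetic test corpus does and does not establish.

## Snapshot model

A scene holds four property maps — network-level, per-node, per-edge,
per-annotation — over a fixed vocabulary of visual properties, each typed
by a value domain (color, number, position, anchored offset, text, enum,
boolean, image reference). Capture produces a *total* deep snapshot: every
registered key of every object is recorded, with unset keys filled from
documented defaults (opaque grey `(200,200,200,255)` fill, node size 35,
edge width 2, visibility true, full table in `properties.py`). Totality is
what makes interpolation pairs well-defined without per-key existence
checks. Colors are RGBA integer 4-tuples; where an object also carries a
separate transparency property, that property overrides the color's alpha
channel at render time. Coordinates follow the raster convention (x right,
y down); node x/y denote the node center, annotation x/y its top-left
corner. Network z location and depth are stored and interpolated but
ignored by the 2D renderer.

Whether a capture should record all properties or only those differing
from a style default was an open choice; we record all, which costs a few
hundred bytes per object and buys exact round-trips.

## Reconciliation

Key frames may disagree about which objects exist. All scenes of one
storyboard are treated as one network collection sharing a single object
universe: the exact union of ids over the contributing frames, with edge
endpoints (and annotation classes) required to be consistent everywhere. A
frame is completed by inserting each missing object with
`visible = false`, its remaining style copied from the nearest frame in
|Δt| that contains it, ties resolving to the earlier frame. The donor
policy is ours: a hidden object still needs coordinates and size so a
later fade-in starts from a sensible state, and the nearest appearance is
the least surprising source. An edge with a hidden endpoint is forced
hidden too — a dangling rendered edge is visually meaningless.
Reconciliation is idempotent and leaves originally present objects
untouched (except for that endpoint rule).

## Interpolators

Nine kinds, with one kind registered per property:

- **Color** — linear per RGB channel, channels rounded half-up; the alpha
  channel goes through the Bezier easing below. Linear RGB is the simplest
  faithful reading of "linearly interpolated"; the color space is isolated
  behind `lerp_color` if an HSV variant is ever wanted.
- **Size / Transparency / Position** — plain linear interpolation;
  transparency rounds half-up back to the 0–255 integer grid. The network
  scale factor (zoom) is a Size property and therefore interpolates
  linearly, not logarithmically; log-zoom would be a one-line extension.
- **ObjectPosition** — offsets interpolate linearly; changes of anchor or
  justification are not tweenable, so the value holds at the start and
  snaps at the segment end, with an `UnsupportedChangeWarning`.
- **Crossfade** — for categorical values (shape, label text, font face,
  line type...): the old value fades out on [0, ½] with opacity 1 − 2t,
  the new fades in on [½, 1] with 2t − 1. The new value owns the t = 0.5
  frame (at opacity zero, so the choice is invisible); some assignment had
  to be fixed. The fade applies to the property's rendered element — a
  shape change fades the node body, a label change only the label.
- **CustomGraphicsCrossfade** — per-node graphics blend *simultaneously*
  (old at weight 1 − t over new at t) rather than sequentially, so an
  image-to-image transition never passes through a blank midpoint; an
  empty slot simply fades the other image in or out.
- **Visible** — a linear opacity ramp (t appearing, 1 − t disappearing),
  composed multiplicatively with crossfade multipliers and the object's
  own transparencies. Multiplication is the only composition that keeps
  both endpoint states exact.
- **None** — held at the old value until t = 1 so the arriving key frame
  is exact.

**Bezier easing.** Alpha fades use a unit cubic Bezier with endpoints
(0,0) and (1,1) and configurable control points, default
((0.25, 0.1), (0.25, 1.0)) — the standard "ease" curve. Control points are
confined to the unit square, which makes curve-x monotone in the
parameter; the inverse x(s) = t is solved by bisection to well below 1e−6
and the eased value is the curve's y there. Equal endpoints short-circuit.
A dense-sampling inversion oracle in the test suite agrees within ±1 alpha
level on a 101-point grid.

## Frame expansion

Segment j with count n_j emits frames at local t = i/n_j for
i = 0..n_j − 1 — the segment's start key frame included, the end key frame
owned by the next segment — and the final key frame is appended once:
Σ n_j + 1 frames, (k − 1)·n + 1 at constant n. This is the unique
convention reproducing the engine's published count of 121 frames for
five key frames at 30. Counts come from the timeline at the fixed 30 fps
calibration, n_j = max(1, round_half_up(30·gap)); coincident key frames
clamp to n = 1, an instantaneous cut that still satisfies the count law.
Timeline times stay continuous seconds; quantization happens only in the
count derivation. Round-half-up is used for counts, color channels, and
pixel dimensions alike.

## Rendering and export

Rendering is deliberately deterministic: Pillow primitives only, the font
bundled with Pillow, draw order background-canvas annotations → edges →
nodes (body, custom-graphics slots, label) → foreground-canvas
annotations, every object composited through its own RGBA overlay so
opacity multipliers blend correctly. Custom graphics render as procedural
glyphs colored by a hash of the image reference — enough to exercise and
test the crossfade path without binary image assets. The camera maps model
coordinates to pixels from the network center and scale factor; the base
canvas defaults to 1280×720 and the resolution option expands linear
dimensions by its percentage (300 → exactly 3×).

PNG export writes one file per frame (no time encoding, so the frame-rate
option does not apply). GIF export assembles the GIF89a container
directly — screen descriptor, NETSCAPE loop extension when looping, one
graphic-control block per frame with delay round(100/fps) centiseconds —
while delegating palette quantization and LZW compression to Pillow's
`GifImagePlugin.getdata`. Writing the container ourselves is deliberate:
stock multi-frame GIF writers coalesce byte-identical consecutive frames
into one longer-delay frame, and hold segments (two identical key frames
used to keep a view on screen) legitimately produce such runs; the
contract here is frames-in = frames-out. GIF's centisecond granularity
maps both 30 and 29.97 fps to 3 cs. MP4 encodes H.264 through imageio's
ffmpeg backend, with 29.97 carried on the NTSC 30000/1001 time base; when
no backend is installed, `write_mp4` raises an error naming the package
to install, and `h264_available()` lets callers probe first.

## Synthetic corpus

The fixture module generates seeded toy networks (circular layout with
seeded radial jitter, palette fills) and seven scene scripts, each
exercising a specific interpolator family; the 13-scene `mixed` script
mirrors a typical expression-overlay movie (full view, zoom onto a hub,
label/shape restyle, degree-scaled sizes, highlight annotations, three
data colorings separated by hold frames, per-node charts fading in). The
same (spec, seed) always yields byte-identical files. Test and acceptance
runs use small canvases (around 120×90 to 320×240) and short timelines;
problem sizes are stated in each test.

What the corpus emulates is structure and styling dynamics, not data: it
contains no real expression values, no curved edges, no genuine raster
images, and no fonts beyond the bundled one. Passing tests therefore
establish the interpolation, reconciliation, timing, and export contracts
exactly, but say nothing about visual fidelity to any particular GUI
renderer's output.

## Known limitations

- Edge bends are not modeled or interpolated; edges render as straight
  lines (dashed/dotted supported).
- Label placements that depend on the rendered text extent are not
  supported; offsets are relative to the node center.
- Nested-network visibility is registered but never interpolated (kind
  None) and not rendered.
- MP4 export requires an external ffmpeg backend at run time.
- Session bundles are this package's own JSON format; no compatibility
  with any GUI host's session files is claimed.
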