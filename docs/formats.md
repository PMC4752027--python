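# File formats

All formats are plain JSON (plus GraphML import). Colors are
`#RRGGBBAA` hex strings (`#RRGGBB` accepted on read, alpha = FF);
coordinates are model units — the camera maps them to pixels only at
render time.

## Scene

One network state. Unknown property names are rejected with a JSON
pointer to the offending key; omitted properties take the documented
defaults.

```json
{
  "network": {
    "background_paint": "#FFFFFFFF",
    "center_x": 0.0,
    "center_y": 0.0,
    "scale_factor": 1.0
  },
  "nodes": {
    "n0": {"x": -120.0, "y": 0.0, "label": "MCM1",
           "fill_color": "#1F77B4FF", "shape": "ellipse"},
    "n1": {"x": 120.0, "y": 40.0, "label": "GAL4",
           "custom_graphics_1": "chart:expr", "custom_graphics_size_1": 28.0}
  },
  "edges": {
    "e0": {"source": "n0", "target": "n1", "width": 2.0,
           "paint": "#646464FF", "line_type": "solid"}
  },
  "annotations": {
    "a0": {"type": "text", "canvas": "foreground",
           "x": -150.0, "y": -160.0, "text": "condition 1",
           "font_size": 14.0}
  }
}
```

Annotation `type` is one of `shape | text | image | arrow`; `canvas`
selects the background layer (behind edges) or foreground (in front of
nodes). Label and custom-graphics positions are anchored offsets:

```json
"label_position": {"anchor": "center", "justification": "center",
                   "offset_x": 0.0, "offset_y": 27.5}
```

## Storyboard

Ordered scenes with timeline positions in seconds (non-decreasing), plus
optional export defaults. Scene paths are relative to the storyboard
file.

```json
{
  "scenes": [
    {"scene": "mixed_seed1_scene00.json", "time_s": 0.0},
    {"scene": "mixed_seed1_scene01.json", "time_s": 1.0}
  ],
  "defaults": {"fps": 30, "resolution_pct": 200, "format": "gif"}
}
```

## Session bundle

A single JSON file embedding every captured key frame with its full
property maps and time — the saved state of an animation in progress.
`load(save(timeline))` is an exact structural round trip. The `version`
field is mandatory; an unknown version raises a documented error.

```json
{
  "version": 1,
  "fps_base": 30,
  "frames": [
    {"frame_id": "kf0", "time_s": 0.0,
     "network": {"...": "..."}, "nodes": {"...": "..."},
     "edges": {"...": "..."}, "annotations": {"...": "..."}}
  ]
}
```

## GraphML import

`import_graphml(path, style_defaults)` takes topology (and optional `x`,
`y`, `label` node attributes) from standard GraphML. Nodes without
positions are placed deterministically on a circle of radius 200 in
document order. GraphML is read-only interop; scenes are the native
format.
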