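"""Capture two styled scenes and tween one property by hand.

Builds a red node and recolors it green in a second scene, then asks the
interpolator for the fill color at a few points of the transition.
"""

from graphmotion import SceneState, capture_frame, interpolate_property, key

scene = SceneState(nodes={"cell": {"x": 0.0, "y": 0.0,
                                   "fill_color": (255, 0, 0, 255)}})
start = capture_frame(scene, time_s=0.0, frame_id="start")

scene.nodes["cell"]["fill_color"] = (0, 255, 0, 255)
end = capture_frame(scene, time_s=1.0, frame_id="end")

fill = key("node", "fill_color")
for t in (0.0, 0.25, 0.5, 0.75, 1.0):
    v0 = start.node_map["cell"]["fill_color"]
    v1 = end.node_map["cell"]["fill_color"]
    value, _ = interpolate_property(fill, v0, v1, t)
    print(f"t={t:4.2f}  fill_color={value}")

# Each line is the node's RGBA fill partway through the transition: the red
# channel ramps 255 -> 0 and green 0 -> 255, linearly per channel, while the
# alpha channel stays constant (equal endpoints skip the Bezier easing).
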