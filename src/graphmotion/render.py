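"""Deterministic 2D rasterization of frames.

Draw order is: background fill, background-canvas annotations, edges,
nodes (body, custom graphics, label), foreground-canvas annotations.  The
camera transform maps model coordinates to pixels from the network's
center x/y and scale factor; the network z location and depth are stored
and interpolated but ignored by this 2D renderer.

Everything is drawn with Pillow primitives and the font bundled with
Pillow, so identical inputs produce identical pixels — a requirement for
reproducible movie export and for testing.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Any, Callable

from PIL import Image, ImageDraw, ImageFont

from .errors import ConfigurationError
from .frame_model import KeyFrame
from .interpolation import RenderFrame, frame_as_render_frame, round_half_up


@dataclass(frozen=True)
class RenderSettings:
    """Raster geometry: base canvas size and percent expansion.

    ``resolution_pct`` expands linear dimensions: 300 renders at 300% (3x)
    of the base size.  At least 200 is sensible for published movies.
    """

    base_width: int = 1280
    base_height: int = 720
    resolution_pct: int = 100

    def __post_init__(self) -> None:
        if self.base_width <= 0 or self.base_height <= 0:
            raise ConfigurationError(
                f"canvas dimensions must be positive, got "
                f"{self.base_width}x{self.base_height}")
        if self.resolution_pct < 1:
            raise ConfigurationError(
                f"resolution_pct must be >= 1, got {self.resolution_pct}")

    @property
    def output_size(self) -> tuple[int, int]:
        s = self.resolution_pct / 100.0
        return (round_half_up(self.base_width * s),
                round_half_up(self.base_height * s))


def _font(size: float) -> ImageFont.ImageFont:
    return ImageFont.load_default(size=max(1, round_half_up(size)))


def _ref_color(ref: str) -> tuple[int, int, int]:
    """Deterministic display color for an image reference (procedural glyph)."""
    h = hashlib.md5(ref.encode("utf8")).digest()
    return h[0], h[1], h[2]


def _shape_polygon(shape: str, x0: float, y0: float, x1: float, y1: float):
    cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
    if shape == "diamond":
        return [(cx, y0), (x1, cy), (cx, y1), (x0, cy)]
    if shape == "triangle":
        return [(cx, y0), (x1, y1), (x0, y1)]
    if shape == "hexagon":
        w4 = (x1 - x0) / 4
        return [(x0 + w4, y0), (x1 - w4, y0), (x1, cy),
                (x1 - w4, y1), (x0 + w4, y1), (x0, cy)]
    if shape == "octagon":
        w3, h3 = (x1 - x0) / 3, (y1 - y0) / 3
        return [(x0 + w3, y0), (x1 - w3, y0), (x1, y0 + h3), (x1, y1 - h3),
                (x1 - w3, y1), (x0 + w3, y1), (x0, y1 - h3), (x0, y0 + h3)]
    return None


class _Canvas:
    """Alpha-compositing helper: each object is stamped via an overlay so

    partial opacities blend correctly, and an opacity multiplier scales the
    whole overlay's alpha channel.
    """

    def __init__(self, img: Image.Image):
        self.img = img

    def stamp(self, opacity: float, draw_fn: Callable[[ImageDraw.ImageDraw], None]) -> None:
        if opacity <= 0.0:
            return
        overlay = Image.new("RGBA", self.img.size, (0, 0, 0, 0))
        draw_fn(ImageDraw.Draw(overlay))
        if opacity < 1.0:
            alpha = overlay.getchannel("A").point(
                lambda a: int(a * opacity))
            overlay.putalpha(alpha)
        self.img.alpha_composite(overlay)


def _dash_pattern(line_type: str, scale: float) -> list[float] | None:
    if line_type == "dashed":
        return [8.0 * scale, 5.0 * scale]
    if line_type == "dotted":
        return [2.0 * scale, 4.0 * scale]
    return None  # solid and anything unknown draw solid


def _draw_line(d: ImageDraw.ImageDraw, p0, p1, color, width, pattern) -> None:
    if pattern is None:
        d.line([p0, p1], fill=color, width=width)
        return
    import math
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    length = math.hypot(dx, dy)
    if length == 0:
        return
    ux, uy = dx / length, dy / length
    pos, i = 0.0, 0
    while pos < length:
        seg = min(pattern[i % 2], length - pos)
        if i % 2 == 0:
            a = (p0[0] + ux * pos, p0[1] + uy * pos)
            b = (p0[0] + ux * (pos + seg), p0[1] + uy * (pos + seg))
            d.line([a, b], fill=color, width=width)
        pos += seg
        i += 1


def render_frame(frame: RenderFrame | KeyFrame,
                 settings: RenderSettings = RenderSettings()) -> Image.Image:
    """Rasterize one fully specified frame to an RGBA image."""
    if isinstance(frame, KeyFrame):
        frame = frame_as_render_frame(frame)

    W, H = settings.output_size
    scale = settings.resolution_pct / 100.0
    net = frame.network_map
    sf = float(net.get("scale_factor", 1.0)) * scale
    cx, cy = float(net.get("center_x", 0.0)), float(net.get("center_y", 0.0))

    def to_px(x: float, y: float) -> tuple[float, float]:
        return ((x - cx) * sf + W / 2.0, (y - cy) * sf + H / 2.0)

    bg = net.get("background_paint", (255, 255, 255, 255))
    img = Image.new("RGBA", (W, H), tuple(bg))
    canvas = _Canvas(img)

    def annotations_on(which: str):
        for aid in sorted(frame.annotation_map):
            rec = frame.annotation_map[aid]
            if rec.props.get("canvas", "foreground") == which:
                _draw_annotation(canvas, frame, aid, rec, to_px, sf)

    annotations_on("background")
    for eid in sorted(frame.edge_map):
        _draw_edge(canvas, frame, eid, to_px, sf)
    for nid in sorted(frame.node_map):
        _draw_node(canvas, frame, nid, to_px, sf)
    annotations_on("foreground")
    return img


def _rgba(color, alpha) -> tuple[int, int, int, int]:
    # a separate transparency property overrides the color's alpha channel
    return (color[0], color[1], color[2], int(alpha))


def _draw_edge(canvas: _Canvas, frame: RenderFrame, eid: str, to_px, sf) -> None:
    rec = frame.edge_map[eid]
    p = rec.props
    src = frame.node_map[rec.source]
    tgt = frame.node_map[rec.target]
    p0 = to_px(src["x"], src["y"])
    p1 = to_px(tgt["x"], tgt["y"])
    width = max(1, round_half_up(p["width"] * sf))
    body_op = frame.opacity_of("edge", eid, "body")
    color = _rgba(p["paint"], p["transparency"])
    pattern = _dash_pattern(p.get("line_type", "solid"), sf)
    canvas.stamp(body_op, lambda d: _draw_line(d, p0, p1, color, width, pattern))

    if p.get("label"):
        label_op = frame.opacity_of("edge", eid, "label")
        mid = ((p0[0] + p1[0]) / 2, (p0[1] + p1[1]) / 2)
        lcolor = _rgba(p["label_color"], p["label_transparency"])
        font = _font(p["label_size"] * sf)
        canvas.stamp(label_op, lambda d: d.text(mid, p["label"], font=font,
                                                fill=lcolor, anchor="mm"))


def _draw_node(canvas: _Canvas, frame: RenderFrame, nid: str, to_px, sf) -> None:
    p = frame.node_map[nid]
    cxp, cyp = to_px(p["x"], p["y"])
    w, h = p["width"] * sf, p["height"] * sf
    x0, y0, x1, y1 = cxp - w / 2, cyp - h / 2, cxp + w / 2, cyp + h / 2
    body_op = frame.opacity_of("node", nid, "body")
    fill = _rgba(p["fill_color"], p["transparency"])
    border = _rgba(p["border_paint"], p["border_transparency"])
    bw = round_half_up(p["border_width"] * sf)
    shape = p.get("shape", "ellipse")

    def draw_body(d: ImageDraw.ImageDraw) -> None:
        poly = _shape_polygon(shape, x0, y0, x1, y1)
        if poly is not None:
            d.polygon(poly, fill=fill, outline=border if bw else None, width=max(bw, 1))
        elif shape in ("rectangle", "round_rectangle"):
            if shape == "round_rectangle":
                d.rounded_rectangle([x0, y0, x1, y1], radius=min(w, h) / 4,
                                    fill=fill, outline=border if bw else None,
                                    width=max(bw, 1))
            else:
                d.rectangle([x0, y0, x1, y1], fill=fill,
                            outline=border if bw else None, width=max(bw, 1))
        else:  # ellipse and any unknown shape
            d.ellipse([x0, y0, x1, y1], fill=fill,
                      outline=border if bw else None, width=max(bw, 1))

    canvas.stamp(body_op, draw_body)
    _draw_custom_graphics(canvas, frame, nid, p, (cxp, cyp), sf)

    if p.get("label"):
        label_op = frame.opacity_of("node", nid, "label")
        op = p["label_position"]
        pos = (cxp + op.offset_x * sf, cyp + op.offset_y * sf)
        lcolor = _rgba(p["label_color"], p["label_transparency"])
        font = _font(p["label_size"] * sf)
        canvas.stamp(label_op, lambda d: d.text(pos, p["label"], font=font,
                                                fill=lcolor, anchor="mm"))


def _draw_custom_graphics(canvas, frame, nid, p, center, sf) -> None:
    body_op = frame.opacity_of("node", nid, "body")
    for slot in range(1, 10):
        value = p.get(f"custom_graphics_{slot}")
        if value is None:
            continue
        layers = value if isinstance(value, tuple) and value \
            and isinstance(value[0], tuple) else ((value, 1.0),)
        size = p.get(f"custom_graphics_size_{slot}", 35.0) * sf
        op = p.get(f"custom_graphics_position_{slot}")
        gx = center[0] + (op.offset_x * sf if op else 0.0)
        gy = center[1] + (op.offset_y * sf if op else 0.0)
        box = [gx - size / 2, gy - size / 2, gx + size / 2, gy + size / 2]
        for ref, weight in layers:
            if ref is None or weight <= 0:
                continue
            color = _ref_color(ref) + (round_half_up(255 * weight),)
            canvas.stamp(body_op,
                         lambda d, c=color: d.ellipse(box, fill=c))


def _draw_annotation(canvas, frame, aid, rec, to_px, sf) -> None:
    p = rec.props
    op = frame.opacity_of("annotation", aid, "body")
    label_op = frame.opacity_of("annotation", aid, "label")
    zoom = p.get("zoom", 1.0)
    x0, y0 = to_px(p["x"], p["y"])  # annotation origin: top-left corner
    w, h = p["width"] * zoom * sf, p["height"] * zoom * sf
    x1, y1 = x0 + w, y0 + h
    bw = round_half_up(p["border_width"] * sf)

    if rec.kind == "shape":
        fill = _rgba(p["color"], p["opacity"])
        border = _rgba(p["border_color"], p["opacity"])

        def draw(d):
            if p.get("shape", "rectangle") == "ellipse":
                d.ellipse([x0, y0, x1, y1], fill=fill,
                          outline=border if bw else None, width=max(bw, 1))
            else:
                d.rectangle([x0, y0, x1, y1], fill=fill,
                            outline=border if bw else None, width=max(bw, 1))
        canvas.stamp(op, draw)
    elif rec.kind == "image":
        ref = p.get("image_url", "")
        fill = _ref_color(ref or "missing") + (int(p["image_opacity"]),)
        canvas.stamp(op, lambda d: d.rectangle([x0, y0, x1, y1], fill=fill))
    elif rec.kind == "arrow":
        color = _rgba(p["arrow_color"], p["opacity"])
        width = max(1, round_half_up(p["arrow_width"] * sf))
        head = p["arrow_target_size"] * sf

        def draw(d):
            d.line([(x0, y0), (x1, y1)], fill=color, width=width)
            if p.get("arrow_target_type", "arrow") != "none":
                import math
                ang = math.atan2(y1 - y0, x1 - x0)
                for side in (-1, 1):
                    a = ang + math.pi + side * 0.5
                    d.line([(x1, y1),
                            (x1 + head * math.cos(a), y1 + head * math.sin(a))],
                           fill=color, width=width)
        canvas.stamp(op, draw)

    text = p.get("text", "")
    if rec.kind == "text" and text:
        fcolor = _rgba(p["font_color"], p["opacity"])
        font = _font(p["font_size"] * zoom * sf)
        canvas.stamp(label_op,
                     lambda d: d.text((x0, y0), text, font=font, fill=fcolor,
                                      anchor="la"))
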