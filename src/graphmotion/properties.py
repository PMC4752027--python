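"""Visual-property vocabulary and the interpolator registry.

A scene is styled through a fixed vocabulary of *visual properties*, each
belonging to one of four object categories (network, node, edge, annotation)
and one value domain (color, number, position, ...).  Every property is
assigned exactly one of nine interpolation kinds; the registry here is the
single source of truth for that assignment and for per-property defaults.

The taxonomy:

=========================  =====================================================
Kind                       Behaviour between two key frames
=========================  =====================================================
COLOR                      per-channel linear RGB blend; alpha eased on a Bezier
SIZE                       linear interpolation of a numeric value
TRANSPARENCY               linear interpolation of a 0-255 opacity integer
OBJECT_POSITION            linear blend of anchored offsets (anchor fixed)
POSITION                   linear interpolation of x/y(/z) coordinates
CROSSFADE                  categorical: fade out the old value, fade in the new
CUSTOM_GRAPHICS_CROSSFADE  simultaneous alpha blend of two per-node graphics
VISIBLE                    opacity ramp when an object appears or disappears
NONE                       not interpolated; the value snaps at the segment end
=========================  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Any, Optional

from .errors import UnregisteredPropertyError, ValidationError

CATEGORIES = ("network", "node", "edge", "annotation")

#: Annotation classes a scene may contain.
ANNOTATION_KINDS = ("shape", "text", "image", "arrow")


class Domain(str, Enum):
    """Value domain of a visual property."""

    COLOR = "color"
    NUMBER = "number"
    POSITION = "position"
    OBJECT_POSITION = "object_position"
    TEXT = "text"
    ENUM = "enum"
    BOOLEAN = "boolean"
    IMAGE_REF = "image_ref"


class InterpolationKind(str, Enum):
    """The nine interpolator categories."""

    COLOR = "Color"
    SIZE = "Size"
    TRANSPARENCY = "Transparency"
    OBJECT_POSITION = "ObjectPosition"
    POSITION = "Position"
    CROSSFADE = "Crossfade"
    CUSTOM_GRAPHICS_CROSSFADE = "CustomGraphicsCrossfade"
    VISIBLE = "Visible"
    NONE = "None"


@dataclass(frozen=True)
class VisualPropertyKey:
    """Typed identifier of one visual attribute.

    ``slot`` is set only for per-node custom-graphics properties, which come
    in nine numbered slots.
    """

    name: str
    category: str
    domain: Domain
    slot: Optional[int] = None

    def __post_init__(self) -> None:
        if self.slot is not None and not (1 <= self.slot <= 9):
            raise ValidationError(
                f"custom-graphics slot must lie in [1, 9], got {self.slot} "
                f"for key {self.name!r}"
            )


@dataclass(frozen=True)
class ObjectPosition:
    """Anchored offset placing a label or custom graphic relative to a node."""

    anchor: str = "center"
    justification: str = "center"
    offset_x: float = 0.0
    offset_y: float = 0.0


# ---------------------------------------------------------------------------
# Registry construction
#
# Each row: (name, domain, kind, default).  Slot-numbered rows are expanded
# with ``_1`` .. ``_9`` suffixes.
# ---------------------------------------------------------------------------

_GREY = (200, 200, 200, 255)
_BLACK = (0, 0, 0, 255)
_WHITE = (255, 255, 255, 255)

_NETWORK_ROWS = [
    ("background_paint", Domain.COLOR, InterpolationKind.COLOR, _WHITE),
    ("center_x", Domain.POSITION, InterpolationKind.POSITION, 0.0),
    ("center_y", Domain.POSITION, InterpolationKind.POSITION, 0.0),
    ("center_z", Domain.POSITION, InterpolationKind.POSITION, 0.0),
    ("depth", Domain.NUMBER, InterpolationKind.SIZE, 0.0),
    ("height", Domain.NUMBER, InterpolationKind.SIZE, 600.0),
    ("scale_factor", Domain.NUMBER, InterpolationKind.SIZE, 1.0),
    ("size", Domain.NUMBER, InterpolationKind.SIZE, 1.0),
    ("width", Domain.NUMBER, InterpolationKind.SIZE, 800.0),
]

_NODE_ROWS = [
    ("border_paint", Domain.COLOR, InterpolationKind.COLOR, _BLACK),
    ("fill_color", Domain.COLOR, InterpolationKind.COLOR, _GREY),
    ("label_color", Domain.COLOR, InterpolationKind.COLOR, _BLACK),
    ("border_transparency", Domain.NUMBER, InterpolationKind.TRANSPARENCY, 255),
    ("label_transparency", Domain.NUMBER, InterpolationKind.TRANSPARENCY, 255),
    ("transparency", Domain.NUMBER, InterpolationKind.TRANSPARENCY, 255),
    ("border_width", Domain.NUMBER, InterpolationKind.SIZE, 1.0),
    ("height", Domain.NUMBER, InterpolationKind.SIZE, 35.0),
    ("width", Domain.NUMBER, InterpolationKind.SIZE, 35.0),
    ("size", Domain.NUMBER, InterpolationKind.SIZE, 35.0),
    ("label_size", Domain.NUMBER, InterpolationKind.SIZE, 12.0),
    ("x", Domain.POSITION, InterpolationKind.POSITION, 0.0),
    ("y", Domain.POSITION, InterpolationKind.POSITION, 0.0),
    ("z", Domain.POSITION, InterpolationKind.POSITION, 0.0),
    ("shape", Domain.ENUM, InterpolationKind.CROSSFADE, "ellipse"),
    ("label", Domain.TEXT, InterpolationKind.CROSSFADE, ""),
    ("font_face", Domain.ENUM, InterpolationKind.CROSSFADE, "sans"),
    ("label_position", Domain.OBJECT_POSITION, InterpolationKind.OBJECT_POSITION,
     ObjectPosition()),
    ("nested_network_visible", Domain.BOOLEAN, InterpolationKind.NONE, False),
    ("visible", Domain.BOOLEAN, InterpolationKind.VISIBLE, True),
]

# Custom graphics come in nine slots: the image itself, its size, its position.
for _i in range(1, 10):
    _NODE_ROWS.append(
        (f"custom_graphics_{_i}", Domain.IMAGE_REF,
         InterpolationKind.CUSTOM_GRAPHICS_CROSSFADE, None)
    )
    _NODE_ROWS.append(
        (f"custom_graphics_size_{_i}", Domain.NUMBER, InterpolationKind.SIZE, 35.0)
    )
    _NODE_ROWS.append(
        (f"custom_graphics_position_{_i}", Domain.OBJECT_POSITION,
         InterpolationKind.OBJECT_POSITION, ObjectPosition())
    )

_EDGE_ROWS = [
    ("label_color", Domain.COLOR, InterpolationKind.COLOR, _BLACK),
    ("paint", Domain.COLOR, InterpolationKind.COLOR, (100, 100, 100, 255)),
    ("label", Domain.TEXT, InterpolationKind.CROSSFADE, ""),
    ("font_face", Domain.ENUM, InterpolationKind.CROSSFADE, "sans"),
    ("line_type", Domain.ENUM, InterpolationKind.CROSSFADE, "solid"),
    ("label_transparency", Domain.NUMBER, InterpolationKind.TRANSPARENCY, 255),
    ("transparency", Domain.NUMBER, InterpolationKind.TRANSPARENCY, 255),
    ("width", Domain.NUMBER, InterpolationKind.SIZE, 2.0),
    ("label_size", Domain.NUMBER, InterpolationKind.SIZE, 10.0),
    ("visible", Domain.BOOLEAN, InterpolationKind.VISIBLE, True),
]

_ANNOTATION_ROWS = [
    ("x", Domain.POSITION, InterpolationKind.POSITION, 0.0),
    ("y", Domain.POSITION, InterpolationKind.POSITION, 0.0),
    ("zoom", Domain.NUMBER, InterpolationKind.SIZE, 1.0),
    ("width", Domain.NUMBER, InterpolationKind.SIZE, 100.0),
    ("height", Domain.NUMBER, InterpolationKind.SIZE, 40.0),
    ("border_width", Domain.NUMBER, InterpolationKind.SIZE, 1.0),
    ("font_size", Domain.NUMBER, InterpolationKind.SIZE, 12.0),
    ("image_contrast", Domain.NUMBER, InterpolationKind.SIZE, 0.0),
    ("image_brightness", Domain.NUMBER, InterpolationKind.SIZE, 0.0),
    ("arrow_source_size", Domain.NUMBER, InterpolationKind.SIZE, 5.0),
    ("arrow_width", Domain.NUMBER, InterpolationKind.SIZE, 2.0),
    ("arrow_target_size", Domain.NUMBER, InterpolationKind.SIZE, 5.0),
    ("color", Domain.COLOR, InterpolationKind.COLOR, _WHITE),
    ("font_color", Domain.COLOR, InterpolationKind.COLOR, _BLACK),
    ("border_color", Domain.COLOR, InterpolationKind.COLOR, _BLACK),
    ("arrow_source_color", Domain.COLOR, InterpolationKind.COLOR, _BLACK),
    ("arrow_target_color", Domain.COLOR, InterpolationKind.COLOR, _BLACK),
    ("arrow_color", Domain.COLOR, InterpolationKind.COLOR, _BLACK),
    ("opacity", Domain.NUMBER, InterpolationKind.TRANSPARENCY, 255),
    ("image_opacity", Domain.NUMBER, InterpolationKind.TRANSPARENCY, 255),
    ("shape", Domain.ENUM, InterpolationKind.CROSSFADE, "rectangle"),
    ("text", Domain.TEXT, InterpolationKind.CROSSFADE, ""),
    ("font_style", Domain.ENUM, InterpolationKind.CROSSFADE, "normal"),
    ("font_family", Domain.ENUM, InterpolationKind.CROSSFADE, "sans"),
    ("image_url", Domain.TEXT, InterpolationKind.CROSSFADE, ""),
    ("arrow_source_anchor", Domain.ENUM, InterpolationKind.CROSSFADE, "none"),
    ("arrow_target_anchor", Domain.ENUM, InterpolationKind.CROSSFADE, "none"),
    ("arrow_source_type", Domain.ENUM, InterpolationKind.CROSSFADE, "none"),
    ("arrow_target_type", Domain.ENUM, InterpolationKind.CROSSFADE, "arrow"),
    ("canvas", Domain.ENUM, InterpolationKind.NONE, "foreground"),
    ("visible", Domain.BOOLEAN, InterpolationKind.VISIBLE, True),
]

_ROWS = {
    "network": _NETWORK_ROWS,
    "node": _NODE_ROWS,
    "edge": _EDGE_ROWS,
    "annotation": _ANNOTATION_ROWS,
}


def _slot_of(name: str) -> Optional[int]:
    if name.startswith("custom_graphics") and name[-1].isdigit() and name[-2] == "_":
        return int(name[-1])
    return None


#: ``KEYS[category][name]`` -> :class:`VisualPropertyKey`
KEYS: dict[str, dict[str, VisualPropertyKey]] = {}
#: ``REGISTRY[key]`` -> :class:`InterpolationKind` (total over all keys)
REGISTRY: dict[VisualPropertyKey, InterpolationKind] = {}
#: ``DEFAULTS[(category, name)]`` -> default value
DEFAULTS: dict[tuple[str, str], Any] = {}

for _cat, _rows in _ROWS.items():
    KEYS[_cat] = {}
    for _name, _dom, _kind, _default in _rows:
        _key = VisualPropertyKey(_name, _cat, _dom, _slot_of(_name))
        KEYS[_cat][_name] = _key
        REGISTRY[_key] = _kind
        DEFAULTS[(_cat, _name)] = _default


def key(category: str, name: str) -> VisualPropertyKey:
    """Look up the registered key for ``(category, name)``."""
    try:
        return KEYS[category][name]
    except KeyError:
        raise UnregisteredPropertyError(
            f"unknown visual property {name!r} for category {category!r}"
        ) from None


def interpolator_for(k: VisualPropertyKey) -> InterpolationKind:
    """Return the interpolation kind registered for ``k``."""
    try:
        return REGISTRY[k]
    except KeyError:
        raise UnregisteredPropertyError(
            f"visual property {k.name!r} ({k.category}) is not registered"
        ) from None


def kind_of(category: str, name: str) -> InterpolationKind:
    return interpolator_for(key(category, name))


def default_of(category: str, name: str) -> Any:
    return DEFAULTS[(category, name)]


# ---------------------------------------------------------------------------
# Value validation
# ---------------------------------------------------------------------------

def _is_finite_real(v: Any) -> bool:
    return isinstance(v, (int, float)) and not isinstance(v, bool) \
        and v == v and abs(v) != float("inf")


def validate_value(k: VisualPropertyKey, value: Any, where: str = "") -> None:
    """Check ``value`` against the domain of ``k``; raise ValidationError."""
    ctx = f" at {where}" if where else ""
    dom = k.domain
    if dom is Domain.COLOR:
        ok = (
            isinstance(value, tuple) and len(value) == 4
            and all(isinstance(c, int) and not isinstance(c, bool)
                    and 0 <= c <= 255 for c in value)
        )
        if not ok:
            raise ValidationError(
                f"{k.name!r}{ctx}: colors are 4-tuples of integers 0-255, "
                f"got {value!r}"
            )
    elif dom in (Domain.NUMBER, Domain.POSITION):
        if not _is_finite_real(value):
            raise ValidationError(
                f"{k.name!r}{ctx}: expected a finite number, got {value!r}"
            )
        if REGISTRY[k] is InterpolationKind.TRANSPARENCY and (
            not isinstance(value, int) or not 0 <= value <= 255
        ):
            raise ValidationError(
                f"{k.name!r}{ctx}: transparencies are integers 0-255, "
                f"got {value!r}"
            )
    elif dom is Domain.OBJECT_POSITION:
        if not isinstance(value, ObjectPosition):
            raise ValidationError(
                f"{k.name!r}{ctx}: expected an ObjectPosition, got {value!r}"
            )
        if not (_is_finite_real(value.offset_x) and _is_finite_real(value.offset_y)):
            raise ValidationError(f"{k.name!r}{ctx}: non-finite offsets")
    elif dom in (Domain.TEXT, Domain.ENUM):
        if not isinstance(value, str):
            raise ValidationError(
                f"{k.name!r}{ctx}: expected a string, got {value!r}"
            )
    elif dom is Domain.BOOLEAN:
        if not isinstance(value, bool):
            raise ValidationError(
                f"{k.name!r}{ctx}: expected a boolean, got {value!r}"
            )
    elif dom is Domain.IMAGE_REF:
        if value is not None and not isinstance(value, str):
            raise ValidationError(
                f"{k.name!r}{ctx}: expected an image reference string or None, "
                f"got {value!r}"
            )
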