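"""Exception hierarchy.

Every error raised by graphmotion derives from :class:`GraphMotionError` so
callers (and the CLI) can map failures onto stable exit-code classes:
usage errors, validation/consistency errors, and I/O or backend errors.
"""

from __future__ import annotations


class GraphMotionError(Exception):
    """Base class for all graphmotion errors."""


class ValidationError(GraphMotionError):
    """A scene, frame, or property value violates its declared domain."""


class ConsistencyError(GraphMotionError):
    """Cross-object state disagrees (unreconciled frames, unknown ids)."""


class ConflictError(ConsistencyError):
    """The same object id carries contradictory structure in two frames."""


class RangeError(GraphMotionError, ValueError):
    """A numeric argument lies outside its admissible range."""


class ConfigurationError(GraphMotionError):
    """Invalid engine configuration (easing curve, render dimensions...)."""


class UnregisteredPropertyError(GraphMotionError, KeyError):
    """A visual-property key is not present in the interpolator registry."""


class NotFoundError(GraphMotionError, KeyError):
    """A referenced frame or object id does not exist."""


class SceneIOError(GraphMotionError):
    """File-level failure while reading or writing a scene_io format."""


class SessionVersionError(SceneIOError):
    """A session bundle declares a version this build cannot read."""


class EncoderUnavailableError(GraphMotionError):
    """A movie encoder backend required for the requested export is missing."""


class UnsupportedChangeWarning(UserWarning):
    """A property changed in a way its interpolator cannot tween (it snaps)."""
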