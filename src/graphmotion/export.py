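"""Movie export: PNG frame sequences, animated GIF, MP4/H.264.

Three output types are offered.  *Frames* writes one PNG per interpolated
frame (no time encoding, so the frame rate does not apply).  *GIF* writes
an animated GIF whose per-frame delay is ``round(100/fps)`` centiseconds.
*MP4* encodes H.264 through imageio's ffmpeg backend when one is
installed.  Four frame rates are offered: the two broadcast standards 25
(PAL) and 29.97 (NTSC), plus 30 and 60; 30 matches the timeline
calibration and is the natural default.

The GIF container is assembled here block by block (screen descriptor,
NETSCAPE loop extension, one graphic-control block per frame) with
palette quantization and LZW compression delegated to Pillow's
``GifImagePlugin.getdata``.  Writing the container ourselves keeps the
frame count exact: stock multi-frame GIF writers coalesce byte-identical
consecutive frames — which hold segments legitimately produce — into one
longer-delay frame, breaking the frames-in = frames-out contract.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from PIL import GifImagePlugin, Image

from .errors import (ConfigurationError, EncoderUnavailableError, RangeError,
                     SceneIOError)
from .interpolation import FrameSequence, round_half_up
from .render import RenderSettings, render_frame

#: The four offered export frame rates.
ALLOWED_FPS = (25, 29.97, 30, 60)

FORMATS = ("frames", "gif", "mp4")


@dataclass(frozen=True)
class ExportSettings:
    """Output type, frame rate, and loop flag (GIF only)."""

    format: str = "frames"
    fps: float = 30
    loop: bool = True
    out_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.format not in FORMATS:
            raise ConfigurationError(
                f"format must be one of {FORMATS}, got {self.format!r}")
        if self.fps not in ALLOWED_FPS:
            raise RangeError(
                f"fps must be one of {ALLOWED_FPS} "
                f"(25 PAL, 29.97 NTSC, 30, 60); got {self.fps}")


def _rendered(seq: FrameSequence, settings: RenderSettings):
    for frame in seq:
        yield render_frame(frame, settings)


def write_frames(seq: FrameSequence, out_dir: Union[str, Path],
                 settings: RenderSettings = RenderSettings()) -> list[Path]:
    """Write one zero-padded PNG per frame: frame_000001.png, ..."""
    if len(seq) == 0:
        raise SceneIOError("cannot export an empty frame sequence")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise SceneIOError(f"cannot create output directory {out}: {e}") from e
    paths = []
    for i, img in enumerate(_rendered(seq, settings), start=1):
        p = out / f"frame_{i:06d}.png"
        img.save(p, format="PNG")
        paths.append(p)
    return paths


def gif_frame_delay_cs(fps: float) -> int:
    """Per-frame GIF delay in centiseconds: round(100/fps).

    GIF granularity is 10 ms, so 30 and 29.97 fps both round to 3 cs.
    """
    return round_half_up(100.0 / fps)


def _quantize(img: Image.Image) -> Image.Image:
    return img.convert("RGB").quantize(colors=256, dither=Image.Dither.NONE)


def write_gif(seq: FrameSequence, path: Union[str, Path],
              export: ExportSettings = ExportSettings(format="gif"),
              settings: RenderSettings = RenderSettings()) -> Path:
    """Write an animated GIF; every frame is kept, delays are exact."""
    if len(seq) == 0:
        raise SceneIOError("cannot export an empty frame sequence")
    path = Path(path)
    delay_cs = gif_frame_delay_cs(export.fps)
    try:
        with open(path, "wb") as fp:
            first = _quantize(render_frame(seq[0], settings))
            w, h = first.size
            fp.write(b"GIF89a")
            fp.write(struct.pack("<HH", w, h))
            fp.write(bytes([0x70, 0x00, 0x00]))  # no global color table
            if export.loop:  # NETSCAPE application extension: loop forever
                fp.write(b"\x21\xff\x0bNETSCAPE2.0\x03\x01" +
                         struct.pack("<H", 0) + b"\x00")
            for img in _rendered(seq, settings):
                frame = _quantize(img)
                for chunk in GifImagePlugin.getdata(
                        frame, offset=(0, 0), duration=delay_cs * 10,
                        disposal=1, include_color_table=True):
                    fp.write(chunk)
            fp.write(b"\x3b")
    except OSError as e:
        raise SceneIOError(f"cannot write GIF to {path}: {e}") from e
    return path


def h264_available() -> bool:
    """True when an ffmpeg backend usable by imageio is present."""
    try:
        import imageio.plugins.ffmpeg
        imageio.plugins.ffmpeg.get_exe()
        return True
    except Exception:
        return False


def write_mp4(seq: FrameSequence, path: Union[str, Path],
              export: ExportSettings = ExportSettings(format="mp4"),
              settings: RenderSettings = RenderSettings()) -> Path:
    """Encode the sequence as an H.264 MP4 at the requested frame rate.

    29.97 is encoded on the NTSC 30000/1001 time base.  Requires an ffmpeg
    backend (the ``imageio-ffmpeg`` package or an ``ffmpeg`` executable on
    PATH); without one, an :class:`EncoderUnavailableError` explains what
    to install.
    """
    if len(seq) == 0:
        raise SceneIOError("cannot export an empty frame sequence")
    import imageio
    import numpy as np

    fps = 30000.0 / 1001.0 if export.fps == 29.97 else float(export.fps)
    path = Path(path)
    try:
        writer = imageio.get_writer(
            str(path), format="FFMPEG", mode="I", fps=fps,
            codec="libx264", pixelformat="yuv420p",
            # H.264 4:2:0 needs even dimensions
            macro_block_size=2,
        )
    except ImportError as e:
        raise EncoderUnavailableError(
            "MP4/H.264 export needs an ffmpeg backend for imageio: install "
            "the 'imageio-ffmpeg' package or put an 'ffmpeg' executable on "
            f"PATH (backend error: {e})"
        ) from e
    with writer:
        for img in _rendered(seq, settings):
            writer.append_data(np.asarray(img.convert("RGB")))
    return path


def count_gif_frames(path: Union[str, Path]) -> int:
    """Decode a GIF and count its frames (round-trip check helper)."""
    with Image.open(path) as im:
        return im.n_frames


def count_mp4_frames(path: Union[str, Path]) -> int:
    """Decode an MP4 and count its frames (round-trip check helper)."""
    import imageio
    reader = imageio.get_reader(str(path), format="FFMPEG")
    with reader:
        return sum(1 for _ in reader)


def export_sequence(seq: FrameSequence, export: ExportSettings,
                    settings: RenderSettings = RenderSettings()):
    """Dispatch on the export format; returns written path(s)."""
    if export.out_path is None:
        raise ConfigurationError("export settings carry no out_path")
    if export.format == "frames":
        return write_frames(seq, export.out_path, settings)
    if export.format == "gif":
        return write_gif(seq, export.out_path, export, settings)
    return write_mp4(seq, export.out_path, export, settings)
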