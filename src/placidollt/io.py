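"""Reading videokeratoscopy recordings and their annotation sidecars.

The Oculus Keratograph 5M records the reflected Placido pattern at 32 frames
per second, 680 x 512 px.  Recordings reach the pipeline either as a video
container or -- preferred for bit-exact processing -- as a lossless PNG/TIFF
frame stack in filename order.  Frame times are expressed in seconds after
the last complete blink; the authoritative blink time comes from the
annotation sidecar (blink detection here is advisory only, mirroring
examiner-driven frame selection on the instrument).

Coordinate convention: 0-based, (column, row) order, origin at the top-left
pixel centre.  Used everywhere in this package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import imageio.v3 as iio
import numpy as np

from .exceptions import EmptyInputError, FormatError, FrameRangeError, ParameterError

__all__ = [
    "PupilCircle",
    "PupilPolygon",
    "Annotation",
    "FrameSequence",
    "SelectedFrame",
    "round_half_up",
    "decompose_video",
    "read_frame_stack",
    "write_frame_stack",
    "select_frame",
    "detect_blink",
]

_STACK_SUFFIXES = (".png", ".tif", ".tiff")


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up.

    Used for mapping post-blink times to frame indices; minimises
    |realized - requested| and is deterministic at exact halves.
    """
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class PupilCircle:
    """Circular pupil region: centre in (col, row) pixels, radius in pixels."""

    centre: tuple[float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ParameterError(f"pupil radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class PupilPolygon:
    """Polygonal pupil region; vertices as an (N, 2) array of (col, row)."""

    vertices: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ParameterError("polygon needs an (N>=3, 2) vertex array")
        object.__setattr__(self, "vertices", v)


@dataclass
class Annotation:
    """Per-recording sidecar: pattern centre, pupil region, blink time.

    ``centre`` is the examiner-clicked centre of the Placido ring pattern,
    (col, row).  ``fps`` overrides the container frame rate when given.
    """

    centre: tuple[float, float]
    pupil: PupilCircle | PupilPolygon
    blink_time: float = 0.0
    fps: float | None = None

    def to_dict(self) -> dict:
        if isinstance(self.pupil, PupilCircle):
            pupil = {
                "type": "circle",
                "centre": list(self.pupil.centre),
                "radius": self.pupil.radius,
            }
        else:
            pupil = {"type": "polygon", "vertices": self.pupil.vertices.tolist()}
        out = {"centre": list(self.centre), "pupil": pupil, "blink_time": self.blink_time}
        if self.fps is not None:
            out["fps"] = self.fps
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "Annotation":
        p = d["pupil"]
        if p["type"] == "circle":
            pupil: PupilCircle | PupilPolygon = PupilCircle(tuple(p["centre"]), p["radius"])
        elif p["type"] == "polygon":
            pupil = PupilPolygon(np.asarray(p["vertices"], dtype=float))
        else:
            raise FormatError(f"unknown pupil type {p['type']!r}")
        return cls(
            centre=tuple(d["centre"]),
            pupil=pupil,
            blink_time=float(d.get("blink_time", 0.0)),
            fps=d.get("fps"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Annotation":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class FrameSequence:
    """Ordered frames of one recording.

    frames: (T, H, W) grey or (T, H, W, 3) RGB uint8 array.
    fps: frames per second (the K5M records at 32, i.e. 0.03125 s between
    frames; the instrument UI rounds this to 0.031 s).
    blink_frame: 0-based index of the last complete blink.
    """

    frames: np.ndarray
    fps: float
    blink_frame: int = 0

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise FormatError("frames must be (T,H,W) or (T,H,W,3)")
        if self.frames.ndim == 4 and self.frames.shape[-1] != 3:
            raise FormatError("colour frames must have 3 channels")
        if len(self.frames) == 0:
            raise EmptyInputError("frame sequence is empty")
        if self.fps <= 0:
            raise ParameterError(f"fps must be positive, got {self.fps}")
        if not 0 <= self.blink_frame < len(self.frames):
            raise ParameterError(
                f"blink_frame {self.blink_frame} outside [0, {len(self.frames) - 1}]"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.fps

    @property
    def max_post_blink_time(self) -> float:
        """Largest post-blink offset (s) with an available frame."""
        return (len(self.frames) - 1 - self.blink_frame) / self.fps


class SelectedFrame(NamedTuple):
    """A frame picked at a requested post-blink time, with bookkeeping."""

    image: np.ndarray
    index: int
    requested_time: float
    realized_time: float


def _sorted_stack_files(path: Path) -> list[Path]:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _STACK_SUFFIXES)
    if not files:
        raise EmptyInputError(f"no PNG/TIFF frames found in {path}")
    return files


def read_frame_stack(
    source: str | Path | Sequence[str | Path],
    fps: float,
    blink_time: float = 0.0,
) -> FrameSequence:
    """Read a lossless frame stack (directory or explicit file list)."""
    if isinstance(source, (str, Path)):
        files = _sorted_stack_files(Path(source))
    else:
        files = [Path(p) for p in source]
        if not files:
            raise EmptyInputError("empty frame file list")
    frames = np.stack([iio.imread(f) for f in files])
    return FrameSequence(frames, fps=fps, blink_frame=round_half_up(blink_time * fps))


def write_frame_stack(seq: FrameSequence, directory: str | Path, prefix: str = "frame") -> list[Path]:
    """Write each frame as PNG (lossless) so re-reading is pixel-identical."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(seq) - 1)))
    paths = []
    for i, frame in enumerate(seq.frames):
        p = directory / f"{prefix}_{i:0{width}d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths


def decompose_video(
    path: str | Path,
    annotation: Annotation | None = None,
    *,
    fps: float | None = None,
) -> FrameSequence:
    """Decompose a recording into frames in temporal order.

    ``path`` may be a video container or a directory of PNG/TIFF frames.
    fps precedence: annotation override > ``fps`` argument > container
    metadata.  blink_frame = round_half_up(blink_time * fps).
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"recording not found: {p}")
    blink_time = annotation.blink_time if annotation is not None else 0.0
    fps_override = annotation.fps if annotation is not None and annotation.fps else fps

    if p.is_dir():
        if fps_override is None:
            raise ParameterError(
                "frame stacks carry no frame rate; supply fps via the annotation or argument"
            )
        return read_frame_stack(p, fps=fps_override, blink_time=blink_time)

    try:
        meta = iio.immeta(p)
        frames = [np.asarray(f) for f in iio.imiter(p)]
    except Exception as exc:  # unreadable container
        raise IOError(f"could not decode recording {p}: {exc}") from exc
    if not frames:
        raise EmptyInputError(f"recording {p} decoded to zero frames")
    container_fps = meta.get("fps")
    use_fps = fps_override if fps_override is not None else container_fps
    if use_fps is None:
        raise ParameterError(f"no frame rate in {p} metadata; supply fps explicitly")
    return FrameSequence(
        np.stack(frames), fps=float(use_fps), blink_frame=round_half_up(blink_time * float(use_fps))
    )


def select_frame(seq: FrameSequence, t_after_blink: float) -> SelectedFrame:
    """Pick the frame nearest to ``t_after_blink`` seconds after the blink.

    index = blink_frame + round_half_up(t * fps); the realized time differs
    from the requested one by at most half a frame interval.
    """
    if t_after_blink < 0:
        raise ParameterError(f"t_after_blink must be >= 0, got {t_after_blink}")
    offset = round_half_up(t_after_blink * seq.fps)
    index = seq.blink_frame + offset
    if index >= len(seq):
        raise FrameRangeError(
            f"t = {t_after_blink:.2f} s after blink is beyond the recording; "
            f"maximum available post-blink time is {seq.max_post_blink_time:.3f} s",
            max_time=seq.max_post_blink_time,
        )
    return SelectedFrame(
        image=seq.frames[index],
        index=index,
        requested_time=t_after_blink,
        realized_time=offset / seq.fps,
    )


def detect_blink(seq: FrameSequence, drop_fraction: float = 0.6) -> int | None:
    """Suggest a blink frame from the global-mean-intensity trace.

    Eyelid closure darkens the whole frame, so the blink shows as a trough in
    per-frame mean intensity.  Returns the last index attaining the deepest
    trough, or None when no frame drops below ``drop_fraction`` of the median
    frame intensity ("no blink detected").  Advisory only: the authoritative
    blink time comes from the annotation.
    """
    if len(seq) < 3:
        raise EmptyInputError("blink detection needs at least 3 frames")
    if not 0 < drop_fraction < 1:
        raise ParameterError("drop_fraction must lie in (0, 1)")
    means = seq.frames.reshape(len(seq), -1).mean(axis=1)
    deepest = means.min()
    if deepest >= drop_fraction * float(np.median(means)):
        return None
    candidates = np.flatnonzero(means == deepest)
    return int(candidates[-1])
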