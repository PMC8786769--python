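"""Synthetic Placido-disk videokeratoscopy phantoms with known ground truth.

The phantom emulates what the topographer sees: the tear film mirrors the
illuminated ring pattern, so concentric bright rings appear over the dark
pupil disk; around it lies a textured iris annulus, and additive Gaussian
sensor noise covers everything.  Ring amplitude plays the role of lipid
layer reflectivity -- the simulated counterpart of lipid layer thickness --
and a cohort maps LLT grades to increasing amplitudes with per-subject
jitter.  After an optional break-up time, dark feathered patches of growing
area mimic the local pattern degradation of a destabilising tear film.

All randomness flows from explicit seeds (numpy PCG64 via
``numpy.random.default_rng``), so frames are bit-identical across runs and
platforms for a fixed spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io import Annotation, FrameSequence, PupilCircle, write_frame_stack

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "FrameRecord",
    "PhantomCohort",
    "generate_frame",
    "generate_sequence",
    "generate_cohort",
    "default_annotation",
]

#: Default grade -> ring amplitude map (grey levels): A = 30 g + 15.
GRADE_AMPLITUDE = {1: 45.0, 2: 75.0, 3: 105.0, 4: 135.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Scene parameters of one synthetic recording.

    shape: (height, width) px; defaults to the instrument's 512 x 680.
    ring_period: radial period of the rings, px.
    ring_profile: 'sinusoid' or 'square'; profile values lie in [0, 1], so
        intensity runs from ``background`` (gap) to ``background +
        ring_amplitude`` (ring crest) -- rings are brighter than the gaps.
    ring_amplitude: ring brightness above the gap level (the LLT surrogate).
    background: inter-ring gap level inside the pupil (the dark pupil floor).
    pupil_centre/pupil_radius: the region where the reflected pattern is
        analysed; the pattern centre coincides with the pupil centre.
    iris_level/iris_texture_sd/iris_outer_radius: ring-free textured annulus.
    noise_sd: additive Gaussian sensor noise, grey levels.
    breakup_time/breakup_strength: after breakup_time seconds post blink,
        dark elliptical patches appear; their number and area grow with
        (t - breakup_time) * breakup_strength.
    """

    shape: tuple[int, int] = (512, 680)
    ring_period: float = 16.0
    ring_profile: str = "sinusoid"
    ring_amplitude: float = 90.0
    background: float = 40.0
    pupil_centre: tuple[float, float] = (340.0, 256.0)  # (col, row)
    pupil_radius: float = 100.0
    iris_level: float = 150.0
    iris_texture_sd: float = 10.0
    iris_outer_radius: float = 230.0
    noise_sd: float = 8.0
    breakup_time: float | None = None
    breakup_strength: float = 1.0
    fps: float = 32.0
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.ring_period < 4:
            raise ParameterError("ring_period must be at least 4 px")
        if self.ring_profile not in ("sinusoid", "square"):
            raise ParameterError(f"unknown ring profile {self.ring_profile!r}")
        if not (0 <= self.background and self.background + self.ring_amplitude <= 255):
            raise ParameterError(
                f"levels overflow 8 bits: background {self.background} + "
                f"amplitude {self.ring_amplitude} must stay within [0, 255]"
            )
        if not (0 <= self.iris_level <= 255):
            raise ParameterError("iris_level must lie in [0, 255]")
        if self.ring_amplitude < 0 or self.noise_sd < 0:
            raise ParameterError("amplitude and noise_sd must be non-negative")


def default_annotation(spec: PhantomSpec, blink_time: float = 0.0) -> Annotation:
    """Ground-truth annotation matching the phantom geometry."""
    return Annotation(
        centre=spec.pupil_centre,
        pupil=PupilCircle(spec.pupil_centre, spec.pupil_radius),
        blink_time=blink_time,
        fps=spec.fps,
    )


def _ring_profile(phase: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sinusoid":
        return 0.5 * (1.0 + np.sin(phase))
    return (np.sin(phase) >= 0).astype(float)


def _breakup_patches(
    img: np.ndarray, spec: PhantomSpec, t_after_blink: float, rng: np.random.Generator
) -> np.ndarray:
    """Darken seeded elliptical patches with Gaussian-feathered edges."""
    dt = t_after_blink - float(spec.breakup_time)
    growth = max(dt, 0.0) * spec.breakup_strength
    n_patches = 1 + int(growth)
    cx, cy = spec.pupil_centre
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_patches):
        angle = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 0.8 * spec.pupil_radius)
        px, py = cx + rad * np.cos(angle), cy + rad * np.sin(angle)
        ax = rng.uniform(0.1, 0.25) * spec.pupil_radius * (1.0 + growth)
        ay = rng.uniform(0.1, 0.25) * spec.pupil_radius * (1.0 + growth)
        depth = 0.8 * spec.ring_amplitude * min(1.0, 0.5 + 0.5 * growth)
        blob = depth * np.exp(-0.5 * (((xx - px) / ax) ** 2 + ((yy - py) / ay) ** 2))
        img = img - blob
    return img


def generate_frame(
    spec: PhantomSpec,
    t_after_blink: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Render one phantom frame; returns (uint8 image, ground-truth record).

    Inside the pupil disk: rings on the dark gap level.  Iris annulus:
    textured, ring-free.  Beyond the iris: gap level.  Seeded Gaussian noise
    is added everywhere and the result clipped to [0, 255].
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    cx, cy = spec.pupil_centre
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(xx - cx, yy - cy)

    rings = spec.background + spec.ring_amplitude * _ring_profile(
        2.0 * np.pi * r / spec.ring_period, spec.ring_profile
    )
    img = np.full((h, w), float(spec.background))
    in_pupil = r < spec.pupil_radius
    in_iris = (r >= spec.pupil_radius) & (r < spec.iris_outer_radius)
    img[in_pupil] = rings[in_pupil]
    iris = spec.iris_level + (
        rng.normal(0.0, spec.iris_texture_sd, size=(h, w)) if spec.iris_texture_sd > 0 else 0.0
    )
    img[in_iris] = np.broadcast_to(iris, (h, w))[in_iris]

    if spec.breakup_time is not None and t_after_blink > spec.breakup_time:
        img = _breakup_patches(img, spec, t_after_blink, rng)

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=(h, w))
    frame = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = {
        "ring_amplitude": spec.ring_amplitude,
        "background": spec.background,
        "t_after_blink": t_after_blink,
        "broken_up": bool(spec.breakup_time is not None and t_after_blink > spec.breakup_time),
    }
    return frame, truth


def generate_sequence(spec: PhantomSpec, blink_index: int | None = None) -> FrameSequence:
    """Render a frame sequence; an optional blink darkens one frame.

    Frames after the blink are rendered at their post-blink times; the blink
    frame itself is an 80%-darkened eyelid-closure frame.
    """
    rng = np.random.default_rng(spec.seed)
    blink = 0 if blink_index is None else int(blink_index)
    frames = []
    for i in range(spec.n_frames):
        t = max(i - blink, 0) / spec.fps
        frame, _ = generate_frame(spec, t_after_blink=t, rng=rng)
        if blink_index is not None and i == blink_index:
            frame = (frame.astype(float) * 0.2).astype(np.uint8)
        frames.append(frame)
    return FrameSequence(np.stack(frames), fps=spec.fps, blink_frame=blink)


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort.

    subjects_per_grade: one count for all grades or a per-grade mapping.
    grade_amplitude: grade -> mean ring amplitude; must be strictly
        increasing in the grade.  jitter_sd: between-subject amplitude SD.
    replicates: repeated recordings per subject (repeatability design).
    timepoints: post-blink sampling times in seconds.
    """

    subjects_per_grade: int | dict[int, int] = 10
    grade_amplitude: dict[int, float] = field(default_factory=lambda: dict(GRADE_AMPLITUDE))
    jitter_sd: float = 6.0
    replicates: int = 3
    timepoints: tuple[float, ...] = (0.33, 5.33)
    seed: int = 0

    def counts(self) -> dict[int, int]:
        grades = sorted(self.grade_amplitude)
        if isinstance(self.subjects_per_grade, int):
            out = {g: self.subjects_per_grade for g in grades}
        else:
            out = {g: self.subjects_per_grade.get(g, 0) for g in grades}
        if any(n < 1 for n in out.values()):
            raise ParameterError("every grade group needs at least one subject")
        return out

    def __post_init__(self):
        grades = sorted(self.grade_amplitude)
        amps = [self.grade_amplitude[g] for g in grades]
        if any(a2 <= a1 for a1, a2 in zip(amps, amps[1:])):
            raise ParameterError("grade -> amplitude map must be strictly increasing")


@dataclass(frozen=True)
class FrameRecord:
    """One rendered cohort frame with its provenance."""

    subject: str
    grade: int
    replicate: int
    t_after_blink: float
    image: np.ndarray
    annotation: Annotation


@dataclass
class PhantomCohort:
    """A generated cohort: frame records plus the ground-truth table."""

    records: list[FrameRecord]
    truth: pd.DataFrame

    def __len__(self) -> int:
        return len(self.records)


def generate_cohort(cohort: CohortSpec, template: PhantomSpec | None = None) -> PhantomCohort:
    """Render a full cohort from a template scene.

    Each subject draws a jittered amplitude around its grade mean; each
    replicate is an independent noise realisation of the same subject at
    every requested timepoint.  The truth table links subject -> grade ->
    amplitude -> seed.
    """
    template = template or PhantomSpec()
    master = np.random.default_rng(cohort.seed)
    records: list[FrameRecord] = []
    truth_rows = []
    for grade, n_subjects in cohort.counts().items():
        base_amp = cohort.grade_amplitude[grade]
        for i in range(n_subjects):
            amp = base_amp + master.normal(0.0, cohort.jitter_sd)
            amp = float(np.clip(amp, 0.0, 255.0 - template.background))
            subject = f"g{grade}s{i:02d}"
            subject_seed = int(master.integers(2**31))
            truth_rows.append(
                {"subject": subject, "grade": grade, "amplitude": amp, "seed": subject_seed}
            )
            spec = replace(template, ring_amplitude=amp, seed=subject_seed)
            annotation = default_annotation(spec)
            sub_rng = np.random.default_rng(subject_seed)
            for rep in range(cohort.replicates):
                for t in cohort.timepoints:
                    frame, _ = generate_frame(spec, t_after_blink=t, rng=sub_rng)
                    records.append(
                        FrameRecord(
                            subject=subject,
                            grade=grade,
                            replicate=rep,
                            t_after_blink=t,
                            image=frame,
                            annotation=annotation,
                        )
                    )
    return PhantomCohort(records=records, truth=pd.DataFrame(truth_rows))
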