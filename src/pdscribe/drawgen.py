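"""Seeded simulator of spiral/meander/wave drawing tasks with Parkinsonian distortions.

Real clinical drawing archives pair each subject with one drawing per task and
a diagnosis label. This module emulates that structure so the full pipeline
(preprocessing, network, training, evaluation, explanation) is exercisable
without any external download. Three distortion channels map onto the motor
signs described for PD handwriting:

* radial/lateral sinusoidal tremor  -> tremor-related jaggedness,
* white positional jitter           -> loss of smooth motor control,
* per-revolution amplitude shrink   -> micrographia.

All outputs are pure functions of their arguments including the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import line as _bresenham_line
from skimage.morphology import dilation, disk

__all__ = [
    "TASKS",
    "MotorProfile",
    "ProfileSpread",
    "Trajectory",
    "DrawingImage",
    "CohortManifest",
    "EFFECT_PROFILES",
    "CONTROL_PROFILE",
    "generate_trajectory",
    "rasterize",
    "synthesize_cohort",
    "trajectory_roughness",
]

#: Closed enumeration of supported drawing tasks.
TASKS = ("spiral", "meander", "wave")

# Geometry of the base curves, in units of the canvas size.
_SPIRAL_TURNS = 6.0
_MEANDER_FOLDS = 6.0
_WAVE_CYCLES = 5.0
_CURVE_EXTENT = 0.42  # max radius / half-amplitude as a fraction of canvas


@dataclass(frozen=True)
class MotorProfile:
    """Class-level writer model.

    tremor_amplitude : peak tremor displacement in pixels (>= 0)
    tremor_frequency : tremor cycles per radian of the parameter sweep (> 0)
    jitter_sd        : white positional noise s.d. in pixels (>= 0)
    micrographia_factor : per-revolution amplitude multiplier in (0, 1];
                          1 means no shrink
    drift_sd         : total slow positional drift s.d. in pixels (>= 0)
    label            : 0 = control, 1 = PD
    """

    tremor_amplitude: float = 0.0
    tremor_frequency: float = 1.2
    jitter_sd: float = 0.0
    micrographia_factor: float = 1.0
    drift_sd: float = 0.0
    label: int = 0

    def __post_init__(self) -> None:
        vals = (self.tremor_amplitude, self.tremor_frequency, self.jitter_sd,
                self.micrographia_factor, self.drift_sd)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("motor profile fields must be finite")
        if self.tremor_amplitude < 0 or self.jitter_sd < 0 or self.drift_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if self.tremor_frequency <= 0:
            raise ValueError("tremor_frequency must be positive")
        if not (0.0 < self.micrographia_factor <= 1.0):
            raise ValueError("micrographia_factor must lie in (0, 1]")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (control) or 1 (PD)")


@dataclass(frozen=True)
class ProfileSpread:
    """Per-subject heterogeneity: s.d. of seeded Gaussian perturbations applied
    to the class-level profile, truncated back to valid ranges."""

    tremor_amplitude: float = 0.3
    jitter_sd: float = 0.2
    micrographia_factor: float = 0.02
    drift_sd: float = 0.3


@dataclass
class Trajectory:
    """Ordered pen path in canvas pixel coordinates.

    points   : (n, 2) float array of (x, y)
    pen_down : (n,) bool array; ink is laid between consecutive pen-down points
    """

    points: np.ndarray
    pen_down: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.pen_down = np.asarray(self.pen_down, dtype=bool).reshape(-1)
        if self.points.shape[0] != self.pen_down.shape[0]:
            raise ValueError("points and pen_down must have equal length")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("trajectory coordinates must be finite")


@dataclass
class DrawingImage:
    """Greyscale drawing on a fixed canvas; background 0, ink > 0."""

    pixels: np.ndarray
    subject_id: str = ""
    task: str = "spiral"
    label: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")


@dataclass
class CohortManifest:
    """Subject-level registry of drawings: one image per subject per task."""

    records: pd.DataFrame
    seed: int
    tasks: tuple = TASKS

    def subjects(self) -> pd.DataFrame:
        return self.records.drop_duplicates("subject_id")[["subject_id", "label"]]

    def validate(self) -> None:
        per = self.records.groupby("subject_id")
        if not (per["label"].nunique() == 1).all():
            raise ValueError("labels must be constant within subject")
        counts = per["task"].nunique()
        if not (counts == len(self.tasks)).all():
            raise ValueError("every subject needs exactly one image per task")


#: Baseline smooth writer shared by all effect presets.
CONTROL_PROFILE = MotorProfile(tremor_amplitude=0.0, tremor_frequency=1.2,
                               jitter_sd=0.5, micrographia_factor=1.0,
                               drift_sd=1.0, label=0)

#: PD writer presets by effect strength. "strong" sits well above the 3 px
#: tremor amplitude at which PD/control stroke roughness separates reliably.
EFFECT_PROFILES = {
    "mild": MotorProfile(tremor_amplitude=1.5, tremor_frequency=1.2,
                         jitter_sd=1.0, micrographia_factor=0.97,
                         drift_sd=2.0, label=1),
    "moderate": MotorProfile(tremor_amplitude=3.0, tremor_frequency=1.2,
                             jitter_sd=1.5, micrographia_factor=0.93,
                             drift_sd=3.0, label=1),
    "strong": MotorProfile(tremor_amplitude=5.0, tremor_frequency=1.2,
                           jitter_sd=2.0, micrographia_factor=0.88,
                           drift_sd=4.0, label=1),
}


def _base_spiral(u: np.ndarray, canvas: int, micro: np.ndarray) -> np.ndarray:
    # Archimedean spiral r = a*u, shrunk per revolution by the micrographia factor.
    a = _CURVE_EXTENT * canvas / (2.0 * math.pi * _SPIRAL_TURNS)
    r = a * u * micro
    c = canvas / 2.0
    return np.stack([c + r * np.cos(u), c + r * np.sin(u)], axis=1)


def _base_meander(u: np.ndarray, canvas: int, micro: np.ndarray) -> np.ndarray:
    # Square-wave folded path: triangle-wave sweep in x, linear advance in y.
    t = u / u[-1] if u[-1] > 0 else u
    phase = _MEANDER_FOLDS * t
    tri = 2.0 * np.abs(phase - np.floor(phase + 0.5))  # in [0, 1]
    amp = _CURVE_EXTENT * canvas * micro
    c = canvas / 2.0
    x = c + amp * (tri - 0.5) * 2.0
    y = canvas * (0.08 + 0.84 * t)
    return np.stack([x, y], axis=1)


def _base_wave(u: np.ndarray, canvas: int, micro: np.ndarray) -> np.ndarray:
    t = u / u[-1] if u[-1] > 0 else u
    amp = 0.3 * canvas * micro
    x = canvas * (0.05 + 0.90 * t)
    y = canvas / 2.0 + amp * np.sin(u)
    return np.stack([x, y], axis=1)


_SWEEP_SPAN = {
    "spiral": 2.0 * math.pi * _SPIRAL_TURNS,
    "meander": 2.0 * math.pi * _MEANDER_FOLDS,
    "wave": 2.0 * math.pi * _WAVE_CYCLES,
}


def generate_trajectory(task: str, profile: MotorProfile, n_points: int,
                        seed: int, canvas: int = 512) -> Trajectory:
    """Simulate one drawing as a pen trajectory.

    The base curve (spiral r = a*theta, square meander, sinusoid wave) is
    distorted by a radial (spiral) or normal-direction (meander/wave) tremor
    sinusoid of the profile's amplitude and frequency, white positional
    jitter, a slow random-walk drift, and per-revolution amplitude
    multiplication by the micrographia factor. Identical arguments always
    yield identical output.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")

    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * math.pi)

    u = np.linspace(0.0, _SWEEP_SPAN[task], n_points)
    micro = profile.micrographia_factor ** (u / (2.0 * math.pi))

    if task == "spiral":
        pts = _base_spiral(u, canvas, micro)
        if profile.tremor_amplitude > 0:
            dr = profile.tremor_amplitude * np.sin(
                2.0 * math.pi * profile.tremor_frequency * u + phase)
            pts = pts + dr[:, None] * np.stack([np.cos(u), np.sin(u)], axis=1)
    else:
        base = _base_meander(u, canvas, micro) if task == "meander" \
            else _base_wave(u, canvas, micro)
        pts = base
        if profile.tremor_amplitude > 0:
            tangent = np.gradient(base, axis=0)
            norm = np.linalg.norm(tangent, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            normal = np.stack([-tangent[:, 1], tangent[:, 0]], axis=1) / norm
            off = profile.tremor_amplitude * np.sin(
                2.0 * math.pi * profile.tremor_frequency * u + phase)
            pts = pts + off[:, None] * normal

    if profile.jitter_sd > 0:
        pts = pts + rng.normal(0.0, profile.jitter_sd, size=pts.shape)
    if profile.drift_sd > 0:
        steps = rng.normal(0.0, profile.drift_sd / math.sqrt(n_points),
                           size=pts.shape)
        pts = pts + np.cumsum(steps, axis=0)

    return Trajectory(points=pts, pen_down=np.ones(n_points, dtype=bool))


def trajectory_roughness(traj: Trajectory) -> float:
    """High-frequency energy: sum of squared second differences along the stroke."""
    d2 = np.diff(traj.points, n=2, axis=0)
    return float(np.sum(d2 ** 2))


def rasterize(traj: Trajectory, height: int, width: int,
              stroke_width: int = 1) -> DrawingImage:
    """Draw pen-down segments onto a binary canvas.

    Consecutive pen-down points are connected with Bresenham lines so that the
    inked-pixel count of a single segment is exactly enumerable; widths > 1
    dilate the 1-pixel skeleton with a disk of radius ``stroke_width // 2``.
    Out-of-canvas coordinates are clipped (their in-canvas portions still ink).
    """
    if height < 8 or width < 8:
        raise ValueError("canvas dimensions must be >= 8")
    if stroke_width < 1:
        raise ValueError("stroke_width must be a positive integer")

    canvas = np.zeros((height, width), dtype=bool)
    pts = np.rint(traj.points).astype(int)
    down = traj.pen_down
    for i in range(len(pts) - 1):
        if down[i] and down[i + 1]:
            rr, cc = _bresenham_line(pts[i, 1], pts[i, 0], pts[i + 1, 1], pts[i + 1, 0])
            keep = (rr >= 0) & (rr < height) & (cc >= 0) & (cc < width)
            canvas[rr[keep], cc[keep]] = True
    if stroke_width > 1:
        canvas = dilation(canvas, disk(stroke_width // 2))
    return DrawingImage(pixels=canvas.astype(float))


def _perturb_profile(profile: MotorProfile, spread: ProfileSpread,
                     rng: np.random.Generator) -> MotorProfile:
    tremor = max(0.0, profile.tremor_amplitude + rng.normal(0, spread.tremor_amplitude))
    jitter = max(0.0, profile.jitter_sd + rng.normal(0, spread.jitter_sd))
    micro = float(np.clip(profile.micrographia_factor
                          + rng.normal(0, spread.micrographia_factor), 0.5, 1.0))
    drift = max(0.0, profile.drift_sd + rng.normal(0, spread.drift_sd))
    return replace(profile, tremor_amplitude=tremor, jitter_sd=jitter,
                   micrographia_factor=micro, drift_sd=drift)


def synthesize_cohort(n_control: int, n_pd: int, tasks=TASKS,
                      control_profile: MotorProfile = CONTROL_PROFILE,
                      pd_profile: MotorProfile = EFFECT_PROFILES["moderate"],
                      spread: ProfileSpread = ProfileSpread(),
                      seed: int = 0, out_dir=None, canvas: int = 512,
                      n_points: int = 1500, stroke_width: int = 2,
                      ) -> CohortManifest:
    """Generate a two-class cohort: one drawing per subject per task.

    Per-subject profiles are drawn around the class profile with the seeded
    Gaussian spread. When ``out_dir`` is given, images are written as 8-bit
    greyscale PNGs, the manifest as ``manifest.csv`` and the generation
    parameters as a JSON sidecar; otherwise images are kept in memory on the
    returned manifest (column ``image``).
    """
    tasks = tuple(tasks)
    if not tasks:
        raise ValueError("tasks must be non-empty")
    for t in tasks:
        if t not in TASKS:
            raise ValueError(f"unknown task {t!r}")
    if n_control < 0 or n_pd < 0:
        raise ValueError("cohort sizes must be non-negative")

    rng = np.random.default_rng(seed)
    root = None
    if out_dir is not None:
        root = Path(out_dir)
        root.mkdir(parents=True, exist_ok=True)

    rows = []
    roster = [("C", 0, control_profile, i) for i in range(n_control)] + \
             [("P", 1, pd_profile, i) for i in range(n_pd)]
    for prefix, label, class_profile, idx in roster:
        sid = f"{prefix}{idx:03d}"
        subj_profile = _perturb_profile(class_profile, spread, rng)
        for task in tasks:
            traj_seed = int(rng.integers(0, 2 ** 31 - 1))
            traj = generate_trajectory(task, subj_profile, n_points, traj_seed,
                                       canvas=canvas)
            img = rasterize(traj, canvas, canvas, stroke_width=stroke_width)
            img.subject_id, img.task, img.label = sid, task, label
            row = {"subject_id": sid, "label": label, "task": task}
            if root is not None:
                path = root / f"{sid}_{task}.png"
                Image.fromarray((img.pixels * 255).astype(np.uint8)).save(path)
                row["path"] = str(path)
            else:
                row["path"] = ""
                row["image"] = img
            rows.append(row)

    records = pd.DataFrame(rows)
    manifest = CohortManifest(records=records, seed=seed, tasks=tasks)
    if root is not None:
        records[["subject_id", "label", "task", "path"]].to_csv(
            root / "manifest.csv", index=False)
        sidecar = {
            "seed": seed, "n_control": n_control, "n_pd": n_pd,
            "tasks": list(tasks), "canvas": canvas, "n_points": n_points,
            "stroke_width": stroke_width,
            "control_profile": asdict(control_profile),
            "pd_profile": asdict(pd_profile),
            "spread": asdict(spread),
        }
        (root / "cohort.json").write_text(json.dumps(sidecar, indent=2))
    return manifest
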