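"""Synthetic sensorimotor trajectories: curve equations, channel encoding,
noise model, and the dataset protocol.

A "presenter" moves a colored ball along a closed planar curve in its torso
frame (coordinates in centimeters; the sagittal x stays fixed at 12).  An
"observer" sees the ball as a 2-D point; we model the camera as an
orthographic projection of the torso-frame (y, z) pair.  The observation at
each time step is a 4-vector over two color layers:

    (layer1_y, layer1_z, layer2_y, layer2_z)

A *yellow* ball occupies layer 1 and leaves layer 2 at exactly zero; a
*green* ball occupies layer 2.  Active coordinates are affinely normalized
into [0.1, 0.9] with fixed bounds derived from the generating equations, and
seeded Gaussian noise (in normalized units) emulates the imperfect position
control of the presenter's arm.

Three curves are available, each parameterized by a phase t in (-pi, pi]:

* ``cosine`` — a cosine in z drawn against a linear sweep in y;
* ``square`` — a closed piecewise-linear loop with slopes +-16/pi;
* ``circle`` — a circle of radius 4 (used only for generalization tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COLORS",
    "CURVES",
    "NORM_BOUNDS",
    "Trajectory3D",
    "SensorimotorSequence",
    "DatasetProtocol",
    "cosine_curve",
    "square_curve",
    "circle_curve",
    "curve_function",
    "phase_values",
    "make_sequence",
    "make_dataset",
    "speed_variant",
    "normalize",
    "denormalize",
    "write_sequences_csv",
    "read_sequences_csv",
]

COLORS = ("yellow", "green")
CURVES = ("cosine", "square", "circle")

_SLOPE = 16.0 / math.pi  # slope of the square curve's linear segments

# Normalized target range for active coordinates.
NORM_LO = 0.1
NORM_HI = 0.9


def _check_phase(t: float) -> None:
    if not (-math.pi < t <= math.pi):
        raise ValueError(f"phase t={t} outside (-pi, pi]")


def cosine_curve(t: float) -> tuple[float, float, float]:
    """Cosine trajectory: z oscillates as cos(2t) while y sweeps linearly.

    y = 8*(-t/2) + 0.04 reads the printed linear form of the sweep; the
    quadratic alternative 8*(-t^2) + 0.04 is available via
    ``curve_function("cosine_quadratic")``.
    """
    _check_phase(t)
    return 12.0, 8.0 * (-t / 2.0) + 0.04, 4.0 * math.cos(2.0 * t) + 0.10


def cosine_curve_quadratic(t: float) -> tuple[float, float, float]:
    """Alternative reading of the cosine curve's sweep: y = 8*(-t^2) + 0.04."""
    _check_phase(t)
    return 12.0, 8.0 * (-(t ** 2)) + 0.04, 4.0 * math.cos(2.0 * t) + 0.10


def square_curve(t: float) -> tuple[float, float, float]:
    """Square trajectory: closed piecewise-linear loop.

    y rises 0 -> 8, holds, falls back to 0 (trapezoid centered on t = 0);
    z is the same trapezoid a quarter-loop out of phase, holding at 14 and 6.
    The printed source of the z branches is internally inconsistent; the
    form below is the unique continuous closed loop that keeps the printed
    slopes +-16/pi, the hold value 14, the falling branch -16/pi*t + 10 and
    the rising branch 16/pi*t - 6, repairing only the first branch's
    intercept (26, printed 20) and filling the omitted hold value (6).
    """
    _check_phase(t)
    if t <= -3.0 * math.pi / 4.0:
        y = 0.0
        z = _SLOPE * t + 26.0
    elif t <= -math.pi / 4.0:
        y = _SLOPE * t + 12.0
        z = 14.0
    elif t <= math.pi / 4.0:
        y = 8.0
        z = -_SLOPE * t + 10.0
    elif t <= 3.0 * math.pi / 4.0:
        y = -_SLOPE * t + 12.0
        z = 6.0
    else:
        y = 0.0
        z = _SLOPE * t - 6.0
    return 12.0, y, z


def circle_curve(t: float) -> tuple[float, float, float]:
    """Circle trajectory of radius 4: (y - 0.04)^2 + (z - 0.10)^2 = 16."""
    _check_phase(t)
    return 12.0, 4.0 * math.sin(2.0 * t) + 0.04, 4.0 * math.cos(2.0 * t) + 0.10


_CURVE_FUNCS = {
    "cosine": cosine_curve,
    "cosine_quadratic": cosine_curve_quadratic,
    "square": square_curve,
    "circle": circle_curve,
}


def curve_function(name: str):
    try:
        return _CURVE_FUNCS[name]
    except KeyError:
        raise ValueError(
            f"unknown curve {name!r}; valid: {sorted(_CURVE_FUNCS)}"
        ) from None


def _curve_extent(name: str, n: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    f = curve_function(name)
    ts = np.linspace(-math.pi, math.pi, n + 1)[1:]
    pts = np.array([f(float(t)) for t in ts])
    return pts[:, 1:].min(axis=0), pts[:, 1:].max(axis=0)


def _global_bounds() -> np.ndarray:
    """Per-coordinate (y, z) bounds over all three curves, from the
    generating equations (closed forms; checked against dense sampling in
    the tests)."""
    y_lo = 0.04 - 4.0 * math.pi  # cosine sweep at t -> -pi ... t = pi
    y_hi = 0.04 + 4.0 * math.pi
    z_lo = -3.90  # cosine / circle minimum 4*(-1) + 0.10
    z_hi = 14.0  # square hold value
    return np.array([[y_lo, y_hi], [z_lo, z_hi]])


#: Fixed per-input-column normalization bounds, (4, 2): rows are
#: (layer1_y, layer1_z, layer2_y, layer2_z), columns (lo, hi).
NORM_BOUNDS = np.vstack([_global_bounds(), _global_bounds()])


def normalize(raw: np.ndarray, bounds: np.ndarray = None) -> np.ndarray:
    """Affinely map raw coordinates into [0.1, 0.9] per column."""
    if bounds is None:
        bounds = NORM_BOUNDS
    raw = np.asarray(raw, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    return NORM_LO + (NORM_HI - NORM_LO) * (raw - lo) / (hi - lo)


def denormalize(values: np.ndarray, bounds: np.ndarray = None) -> np.ndarray:
    """Inverse of :func:`normalize` (for reporting in raw coordinates)."""
    if bounds is None:
        bounds = NORM_BOUNDS
    values = np.asarray(values, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    return lo + (values - NORM_LO) * (hi - lo) / (NORM_HI - NORM_LO)


@dataclass
class Trajectory3D:
    """Raw 3-D presenter-frame curve samples (centimeters)."""

    points: np.ndarray  # (T, 3)
    t_values: np.ndarray  # (T,)


@dataclass
class SensorimotorSequence:
    """A T x 4 normalized observation series with its class labels."""

    values: np.ndarray  # (T, 4) normalized
    color_label: str
    curve_label: str
    sequence_id: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 4:
            raise ValueError(f"values must be (T, 4), got {self.values.shape}")
        if self.values.shape[0] < 2:
            raise ValueError("sequence needs at least 2 time steps")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def inputs(self) -> np.ndarray:
        """Teacher-forced inputs (all but the last step)."""
        return self.values[:-1]

    @property
    def targets(self) -> np.ndarray:
        """One-step-ahead targets (all but the first step)."""
        return self.values[1:]


@dataclass(frozen=True)
class DatasetProtocol:
    """The dataset recipe: which classes, how many repetitions, sampling and
    noise.  The default reproduces the 20-sequence training protocol —
    5 repetitions x 2 colors x 2 curve types, 20 points per loop."""

    reps_per_class: int = 5
    colors: tuple[str, ...] = ("yellow", "green")
    curves: tuple[str, ...] = ("cosine", "square")
    points_per_loop: int = 20
    noise_sigma: float = 0.01
    speed_factor: float = 1.0
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.reps_per_class < 1:
            raise ValueError("reps_per_class must be >= 1")
        if self.points_per_loop < 2:
            raise ValueError("points_per_loop must be >= 2")
        if self.speed_factor <= 0:
            raise ValueError("speed_factor must be positive")
        for c in self.colors:
            if c not in COLORS:
                raise ValueError(f"unknown color {c!r}; valid: {COLORS}")


def phase_values(points_per_loop: int, speed_factor: float = 1.0) -> np.ndarray:
    """Evenly spaced phases over (-pi, pi], wrapped when the phase step is
    scaled by ``speed_factor`` (faster apparent motion keeps T fixed but
    traverses the loop more than once)."""
    step = 2.0 * math.pi / points_per_loop * speed_factor
    raw = -math.pi + step * np.arange(1, points_per_loop + 1)
    # wrap into (-pi, pi]
    wrapped = np.mod(raw + math.pi, 2.0 * math.pi) - math.pi
    wrapped[np.isclose(wrapped, -math.pi)] = math.pi
    return wrapped


def make_sequence(
    curve: str,
    color: str,
    protocol: DatasetProtocol = DatasetProtocol(),
    seed: int | None = 0,
    sequence_id: str | None = None,
) -> SensorimotorSequence:
    """Generate one labeled observation sequence.

    Samples the curve at ``points_per_loop`` phases, projects to the 2-D
    (y, z) observation, normalizes with the fixed global bounds, places the
    point in the color's layer (the other layer stays exactly zero) and adds
    seeded Gaussian noise to the active coordinates.
    """
    if color not in COLORS:
        raise ValueError(f"unknown color {color!r}; valid: {COLORS}")
    f = curve_function(curve)
    ts = phase_values(protocol.points_per_loop, protocol.speed_factor)
    pts = np.array([f(float(t)) for t in ts])  # (T, 3)
    obs = pts[:, 1:]  # orthographic (y, z) projection
    norm = NORM_LO + (NORM_HI - NORM_LO) * (obs - _global_bounds()[:, 0]) / (
        _global_bounds()[:, 1] - _global_bounds()[:, 0]
    )
    T = norm.shape[0]
    values = np.zeros((T, 4))
    cols = slice(0, 2) if color == "yellow" else slice(2, 4)
    values[:, cols] = norm
    if protocol.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values[:, cols] += rng.normal(0.0, protocol.noise_sigma, size=(T, 2))
    if sequence_id is None:
        sequence_id = f"{curve}_{color}_s{seed}"
    return SensorimotorSequence(
        values=values,
        color_label=color,
        curve_label=curve,
        sequence_id=sequence_id,
        seed=seed,
    )


def make_dataset(protocol: DatasetProtocol = DatasetProtocol()) -> list[SensorimotorSequence]:
    """Generate the full dataset: reps x colors x curves sequences with
    distinct derived seeds and unique ids."""
    seqs = []
    ss = np.random.SeedSequence(protocol.base_seed)
    n = protocol.reps_per_class * len(protocol.colors) * len(protocol.curves)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]
    k = 0
    for curve in protocol.curves:
        for color in protocol.colors:
            for rep in range(protocol.reps_per_class):
                seqs.append(
                    make_sequence(
                        curve,
                        color,
                        protocol,
                        seed=child_seeds[k],
                        sequence_id=f"{curve}_{color}_{rep}",
                    )
                )
                k += 1
    return seqs


def speed_variant(protocol: DatasetProtocol, speed_factor: float) -> DatasetProtocol:
    """Protocol with the phase step scaled by ``speed_factor`` at fixed T
    (apparent motion is faster; the loop is traversed multiple times)."""
    if speed_factor <= 0:
        raise ValueError("speed_factor must be positive")
    return replace(protocol, speed_factor=protocol.speed_factor * speed_factor)


# ---------------------------------------------------------------------------
# Sequence CSV interface: one row per time step.

CSV_COLUMNS = [
    "sequence_id",
    "t_index",
    "in1",
    "in2",
    "in3",
    "in4",
    "color_label",
    "curve_label",
]


def write_sequences_csv(seqs: list[SensorimotorSequence], path: str | Path) -> None:
    rows = []
    for s in seqs:
        for t in range(len(s)):
            rows.append(
                {
                    "sequence_id": s.sequence_id,
                    "t_index": t,
                    "in1": s.values[t, 0],
                    "in2": s.values[t, 1],
                    "in3": s.values[t, 2],
                    "in4": s.values[t, 3],
                    "color_label": s.color_label,
                    "curve_label": s.curve_label,
                }
            )
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_sequences_csv(path: str | Path) -> list[SensorimotorSequence]:
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sequence CSV {path} missing columns: {sorted(missing)}")
    seqs = []
    for sid, grp in df.groupby("sequence_id", sort=False):
        grp = grp.sort_values("t_index")
        seqs.append(
            SensorimotorSequence(
                values=grp[["in1", "in2", "in3", "in4"]].to_numpy(),
                color_label=str(grp["color_label"].iloc[0]),
                curve_label=str(grp["curve_label"].iloc[0]),
                sequence_id=str(sid),
            )
        )
    return seqs
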