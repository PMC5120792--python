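"""EMA preprocessing and articulatory parameterization.

Coil trajectories from electromagnetic articulography are expressed in the
reference coil's rigid frame (head-movement correction), down-sampled from
400 Hz to 100 Hz, and reduced to one of four parameterizations:

- ``raw27``: x/y/z of all 9 sensors;
- ``midsag14``: x/y of the 7 midsagittal sensors (lip corners dropped);
- ``pca10`` / ``pca7``: principal components of the z-scored 27-dim data.

Frames are z-scored with statistics fit on training data only, silence frames
are removed using phone segmentations, and each frame is concatenated with
its 4 preceding frames (50 ms causal context) before entering the DNN.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.spatial.transform import Rotation
from sklearn.decomposition import PCA

log = logging.getLogger("emasynth")

#: Canonical sensor order used by every matrix and file in this package.
CANONICAL_SENSORS = (
    "tongue_tip",
    "tongue_dorsum",
    "tongue_back",
    "upper_lip",
    "lower_lip",
    "lip_corner_l",
    "lip_corner_r",
    "jaw",
    "velum",
)

#: Midsagittal subset (lip corners carry mostly lateral information).
MIDSAGITTAL_SENSORS = tuple(
    s for s in CANONICAL_SENSORS if not s.startswith("lip_corner")
)

SILENCE_LABEL = "SILENCE"

PARAMETERIZATION_DIMS = {"raw27": 27, "midsag14": 14, "pca10": 10, "pca7": 7}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class EmaRecording:
    """Named 3-D sensor trajectories plus the 6-DOF reference-coil pose.

    ``reference_pose`` rows are (tx, ty, tz, rx, ry, rz): translation in mm
    and intrinsic xyz Euler angles in radians of the reference coil in the
    device frame.
    """

    sensors: dict[str, np.ndarray]  # name -> T x 3, mm
    reference_pose: np.ndarray  # T x 6
    rate: float

    def __post_init__(self) -> None:
        self.sensors = {k: np.asarray(val, dtype=np.float64) for k, val in self.sensors.items()}
        self.reference_pose = np.asarray(self.reference_pose, dtype=np.float64)
        lengths = {val.shape[0] for val in self.sensors.values()}
        lengths.add(self.reference_pose.shape[0])
        if len(lengths) != 1:
            raise ValueError("sensor trajectories have unequal frame counts")
        for k, val in self.sensors.items():
            if val.shape[1:] != (3,):
                raise ValueError(f"sensor {k} is not T x 3")
            if not np.all(np.isfinite(val)):
                raise ValueError(f"sensor {k} contains non-finite coordinates")
        if self.reference_pose.shape[1] != 6:
            raise ValueError("reference pose must be T x 6")
        if not np.all(np.isfinite(self.reference_pose)):
            raise ValueError("reference pose contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.reference_pose.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate


@dataclass
class Segmentation:
    """Sorted, non-overlapping (label, start_s, end_s) phone intervals."""

    intervals: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        for lab, start, end in self.intervals:
            if not start < end:
                raise ValueError(f"interval {lab!r}: start {start} >= end {end}")
        starts = [s for _, s, _ in self.intervals]
        if starts != sorted(starts):
            raise ValueError("intervals must be sorted by start time")
        for (_, _, e0), (_, s1, _) in zip(self.intervals, self.intervals[1:]):
            if s1 < e0 - 1e-12:
                raise ValueError("intervals overlap")

    def silence_mask(self, times: np.ndarray) -> np.ndarray:
        """True where a time falls inside a SILENCE interval."""
        mask = np.zeros(len(times), dtype=bool)
        for lab, start, end in self.intervals:
            if lab == SILENCE_LABEL:
                mask |= (times >= start) & (times < end)
        return mask

    @property
    def duration(self) -> float:
        return self.intervals[-1][2] if self.intervals else 0.0


@dataclass
class ArticulatoryFeatures:
    """T x d frame matrix with parameterization provenance."""

    frames: np.ndarray
    parameterization: str
    rate: float = 100.0

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=np.float64))
        tag = self.parameterization
        if tag in PARAMETERIZATION_DIMS:
            expected = PARAMETERIZATION_DIMS[tag]
        elif tag.startswith("pca") and tag[3:].isdigit():
            expected = int(tag[3:])
        else:
            raise ValueError(f"unknown parameterization {tag!r}")
        if self.frames.shape[1] != expected:
            raise ValueError(
                f"{self.parameterization} requires {expected} dims, "
                f"got {self.frames.shape[1]}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("feature frames contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def dim(self) -> int:
        return self.frames.shape[1]


@dataclass
class Normalizer:
    """Per-dimension z-scoring statistics (fit on training frames only)."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        if np.any(self.sd <= 0):
            raise ValueError("normalizer sd must be positive")


@dataclass
class PcaModel:
    """Principal axes of the z-scored 27-dim articulatory data."""

    mean: np.ndarray  # 27
    sd: np.ndarray  # 27 (z-scoring applied before the rotation)
    components: np.ndarray  # k x 27, row-orthonormal

    def __post_init__(self) -> None:
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(len(self.components)), atol=1e-8):
            raise ValueError("PCA components must be row-orthonormal")

    @property
    def k(self) -> int:
        return self.components.shape[0]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _pose_rotations(pose: np.ndarray) -> Rotation:
    return Rotation.from_euler("xyz", pose[:, 3:6])


def _decimate(traj: np.ndarray, factor: int) -> np.ndarray:
    """Order-8 Butterworth zero-phase anti-alias filter, then decimate.

    Butterworth (maximally flat passband) keeps constants and slow
    trajectories amplitude-true, unlike a rippled Chebyshev design.
    """
    traj = np.atleast_2d(traj)
    b, a = sps.butter(8, 0.8 / factor)
    filtered = sps.filtfilt(b, a, traj, axis=0)
    return filtered[::factor]


def head_correct(rec: EmaRecording) -> EmaRecording:
    """Express every sensor in the reference coil's rigid frame.

    For each frame, the inverse of the reference coil pose (rotation R,
    translation t) is applied: p_corrected = R^T (p - t).  The output's
    reference pose is the identity.
    """
    rot = _pose_rotations(rec.reference_pose)
    trans = rec.reference_pose[:, :3]
    inv = rot.inv()
    corrected = {
        name: inv.apply(traj - trans) for name, traj in rec.sensors.items()
    }
    return EmaRecording(
        sensors=corrected,
        reference_pose=np.zeros((rec.n_frames, 6)),
        rate=rec.rate,
    )


def downsample_frames(rec: EmaRecording, factor: int = 4) -> EmaRecording:
    """Anti-alias low-pass filter then decimate (e.g. 400 Hz -> 100 Hz)."""
    if factor != int(factor) or factor < 1:
        raise ValueError("decimation factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return rec
    sensors = {
        name: _decimate(traj, factor) for name, traj in rec.sensors.items()
    }
    n_out = next(iter(sensors.values())).shape[0]
    pose = rec.reference_pose[::factor][:n_out]
    if pose.shape[0] < n_out:  # defensive; decimate yields ceil(T/factor)
        pose = np.pad(pose, ((0, n_out - pose.shape[0]), (0, 0)), mode="edge")
    return EmaRecording(sensors=sensors, reference_pose=pose, rate=rec.rate / factor)


def to_raw27(rec: EmaRecording) -> ArticulatoryFeatures:
    """Stack x/y/z of the 9 sensors in canonical order (27 dims)."""
    missing = [s for s in CANONICAL_SENSORS if s not in rec.sensors]
    if missing:
        raise ValueError(f"missing sensors: {missing}")
    frames = np.hstack([rec.sensors[s] for s in CANONICAL_SENSORS])
    return ArticulatoryFeatures(frames, "raw27", rate=rec.rate)


def project_midsagittal(rec: EmaRecording) -> ArticulatoryFeatures:
    """Project a head-corrected recording to the midsagittal plane.

    The midsagittal plane is taken as the x-y plane of the reference coil
    frame, so the projection keeps (x, y) and drops the lateral z.  The two
    lip-corner sensors are removed, leaving 7 sensors x 2 dims = 14.
    """
    missing = [s for s in MIDSAGITTAL_SENSORS if s not in rec.sensors]
    if missing:
        raise ValueError(f"missing sensors: {missing}")
    frames = np.hstack([rec.sensors[s][:, :2] for s in MIDSAGITTAL_SENSORS])
    return ArticulatoryFeatures(frames, "midsag14", rate=rec.rate)


def fit_pca(features: ArticulatoryFeatures, k: int) -> PcaModel:
    """Fit the top-k principal axes of the z-scored raw27 data."""
    if features.parameterization != "raw27":
        raise ValueError("PCA is fit on the raw27 parameterization")
    x = features.frames
    if k > x.shape[1]:
        raise ValueError(f"k={k} exceeds data dimension {x.shape[1]}")
    if x.shape[0] <= x.shape[1]:
        raise ValueError("need more frames than dimensions to fit PCA")
    sd = x.std(axis=0, ddof=0)
    dead = np.nonzero(sd <= 1e-12 * (np.abs(x.mean(axis=0)) + 1.0))[0]
    if dead.size:
        raise ValueError(f"zero-variance dimensions {dead.tolist()}: cannot fit PCA")
    mean = x.mean(axis=0)
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit((x - mean) / sd)
    return PcaModel(mean=mean, sd=sd, components=pca.components_)


def apply_pca(model: PcaModel, features: ArticulatoryFeatures) -> ArticulatoryFeatures:
    if features.dim != model.components.shape[1]:
        raise ValueError("feature dimension does not match PCA model")
    z = (features.frames - model.mean) / model.sd
    return ArticulatoryFeatures(z @ model.components.T, f"pca{model.k}", rate=features.rate)


def reconstruct_pca(model: PcaModel, scores: np.ndarray) -> np.ndarray:
    """Map PCA scores back to the raw27 space (for error diagnostics)."""
    return (np.atleast_2d(scores) @ model.components) * model.sd + model.mean


def remove_silence(
    frames: np.ndarray, seg: Segmentation, rate: float = 100.0
) -> tuple[np.ndarray, np.ndarray]:
    """Drop frames whose center time falls in a SILENCE interval.

    Returns (kept_frames, index_map) where index_map holds the original
    indices of the kept frames.
    """
    frames = np.atleast_2d(frames)
    centers = (np.arange(frames.shape[0]) + 0.5) / rate
    silent = seg.silence_mask(centers)
    keep = np.nonzero(~silent)[0]
    if keep.size == 0:
        warnings.warn("all frames fall in silence; output is empty", stacklevel=2)
    return frames[keep], keep


def fit_normalizer(frames: np.ndarray) -> Normalizer:
    frames = np.atleast_2d(frames)
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames to fit a normalizer")
    sd = frames.std(axis=0, ddof=0)
    dead = np.nonzero(sd <= 1e-12 * (np.abs(frames.mean(axis=0)) + 1.0))[0]
    if dead.size:
        raise ValueError(f"zero-variance dimensions {dead.tolist()}: cannot z-score")
    return Normalizer(mean=frames.mean(axis=0), sd=sd)


def apply_normalizer(norm: Normalizer, frames: np.ndarray) -> np.ndarray:
    return (np.atleast_2d(frames) - norm.mean) / norm.sd


def invert_normalizer(norm: Normalizer, frames: np.ndarray) -> np.ndarray:
    return np.atleast_2d(frames) * norm.sd + norm.mean


def stack_context(frames: np.ndarray, n_past: int = 4) -> np.ndarray:
    """Concatenate each frame with its n_past predecessors (causal context).

    Row t is [x_t, x_{t-1}, ..., x_{t-n_past}]; rows near the start replicate
    the first frame, keeping the output row count equal to the input's.
    """
    frames = np.atleast_2d(frames)
    t_total = frames.shape[0]
    cols = []
    for lag in range(n_past + 1):
        idx = np.maximum(np.arange(t_total) - lag, 0)
        cols.append(frames[idx])
    return np.hstack(cols)
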