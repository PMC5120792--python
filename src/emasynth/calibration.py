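"""Cross-speaker articulatory calibration: affine map plus integer delay.

A new speaker's articulatory frames are mapped frame-by-frame (no temporal
context) into the reference speaker's articulatory space by an affine model
y = A x + b.  A global integer frame delay between the two streams —
speaker and system latency — is estimated first by a grid search: for each
candidate delay the sequences are shifted and cut, a least-squares model is
fit, and the delay with the smallest MSE wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_DELAY_GRID = range(-30, 31)  # frames at 100 Hz, i.e. +/- 300 ms


@dataclass
class LinearCalibration:
    matrix: np.ndarray  # d_ref x d_new
    bias: np.ndarray  # d_ref
    delay: int  # frames: new-speaker stream lags the reference by `delay`
    fit_mse: float = np.nan
    delay_grid: tuple[int, int] = (-30, 30)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if not (np.all(np.isfinite(self.matrix)) and np.all(np.isfinite(self.bias))):
            raise ValueError("calibration parameters must be finite")
        if self.matrix.shape[0] != self.bias.shape[0]:
            raise ValueError("matrix/bias dimension mismatch")


@dataclass
class SensorErrorReport:
    """Per-sensor Euclidean prediction error (mm) in the midsagittal plane."""

    sensors: list[str]
    mean_mm: np.ndarray
    sd_mm: np.ndarray
    pooled_mean_mm: float
    pooled_sd_mm: float


def _as_item_list(x) -> list[np.ndarray]:
    if isinstance(x, np.ndarray):
        return [np.atleast_2d(x)]
    return [np.atleast_2d(np.asarray(a, dtype=np.float64)) for a in x]


def _aligned_frames(new_items, ref_items, delay, masks=None):
    """Shift-and-cut each item pair by `delay`, keeping speech frames only.

    ``new[t]`` is paired with ``ref[t - delay]``; partial-overlap frames are
    discarded.  ``masks`` are per-item boolean speech masks in reference time.
    """
    xs, ys = [], []
    for i, (new, ref) in enumerate(zip(new_items, ref_items)):
        t = min(len(new), len(ref))
        new, ref = new[:t], ref[:t]
        if delay >= 0:
            n, r = new[delay:], ref[:t - delay] if delay else ref
        else:
            n, r = new[:t + delay], ref[-delay:]
        if masks is not None:
            m = np.asarray(masks[i], dtype=bool)[:t]
            m = m[:t - abs(delay)] if delay >= 0 else m[-delay:]
            n, r = n[m], r[m]
        if len(n):
            xs.append(n)
            ys.append(r)
    if not xs:
        raise ValueError(f"delay {delay} leaves no overlapping frames")
    return np.vstack(xs), np.vstack(ys)


def _ols(x: np.ndarray, y: np.ndarray, check_rank: bool = False):
    """Least squares y ~ A x + b; returns (A, b, mse)."""
    design = np.column_stack([x, np.ones(len(x))])
    if check_rank:
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            # name the offending columns for the error message
            _, r = np.linalg.qr(design)
            dep = np.nonzero(np.abs(np.diag(r)) < 1e-10 * np.abs(r[0, 0]))[0]
            raise ValueError(
                f"rank-deficient design (rank {rank} < {design.shape[1]}); "
                f"dependent columns: {dep.tolist()}"
            )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    pred = design @ coef
    mse = float(np.mean((pred - y) ** 2))
    return coef[:-1].T, coef[-1], mse


def estimate_delay(new, ref, grid=DEFAULT_DELAY_GRID, masks=None):
    """Grid-search the integer frame delay minimizing the affine-fit MSE.

    ``new``/``ref`` are T x d arrays or lists of per-item arrays.  Returns
    (best_delay, mse_curve) with the MSE curve indexed like ``grid``; ties are
    broken toward the smallest |delay|.
    """
    new_items, ref_items = _as_item_list(new), _as_item_list(ref)
    grid = list(grid)
    d_new = new_items[0].shape[1]
    max_abs = max(abs(g) for g in grid)
    t_min = min(min(len(a) for a in new_items), min(len(a) for a in ref_items))
    if max_abs >= t_min:
        raise ValueError(f"delay grid (+/-{max_abs}) exceeds sequence length {t_min}")
    mse_curve = np.empty(len(grid))
    for j, delta in enumerate(grid):
        x, y = _aligned_frames(new_items, ref_items, delta, masks)
        if len(x) < 10 * d_new:
            mse_curve[j] = np.inf
            continue
        _, _, mse_curve[j] = _ols(x, y)
    order = sorted(range(len(grid)), key=lambda j: (mse_curve[j], abs(grid[j])))
    return grid[order[0]], mse_curve


def fit_linear(new, ref, delay: int = 0, masks=None,
               grid=DEFAULT_DELAY_GRID) -> LinearCalibration:
    """Frame-wise affine fit of the reference space from new-speaker frames."""
    new_items, ref_items = _as_item_list(new), _as_item_list(ref)
    x, y = _aligned_frames(new_items, ref_items, delay, masks)
    if len(x) <= x.shape[1] + 1:
        raise ValueError("not enough frames to fit the affine map")
    a, b, mse = _ols(x, y, check_rank=True)
    grid = list(grid)
    return LinearCalibration(matrix=a, bias=b, delay=delay, fit_mse=mse,
                             delay_grid=(min(grid), max(grid)))


def split_calibration_items(n_items: int, n_train: int = 40,
                            seed: int = 0) -> tuple[list[int], list[int]]:
    """Random train/test item split of a calibration session (default 40/10).

    The calibration recording is a fixed set of short sentences; the affine
    map is fit on the training items and its articulatory error is reported
    on the held-out items.
    """
    if not 0 < n_train < n_items:
        raise ValueError("need 0 < n_train < n_items")
    perm = np.random.default_rng(seed).permutation(n_items)
    return sorted(perm[:n_train].tolist()), sorted(perm[n_train:].tolist())


def calibrate(new, ref, grid=DEFAULT_DELAY_GRID, masks=None) -> LinearCalibration:
    """Delay estimation followed by the final affine fit at the best delay."""
    delay, _ = estimate_delay(new, ref, grid, masks)
    return fit_linear(new, ref, delay, masks, grid)


def apply_calibration(cal: LinearCalibration, frames: np.ndarray) -> np.ndarray:
    """Map frames into the reference articulatory space, y = A x + b."""
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    if frames.shape[1] != cal.matrix.shape[1]:
        raise ValueError(
            f"frame dim {frames.shape[1]} != calibration input {cal.matrix.shape[1]}"
        )
    return frames @ cal.matrix.T + cal.bias


def sensor_error_report(predicted: np.ndarray, ref: np.ndarray,
                        sensors=None) -> SensorErrorReport:
    """Per-sensor mean/sd Euclidean distance between midsagittal positions.

    Inputs are T x 14 midsagittal matrices (x, y per sensor in canonical
    order); distances are in the input's units (mm).
    """
    from .artic import MIDSAGITTAL_SENSORS

    predicted = np.atleast_2d(predicted)
    ref = np.atleast_2d(ref)
    if predicted.shape != ref.shape:
        raise ValueError("predicted/reference shape mismatch")
    if predicted.shape[1] % 2:
        raise ValueError("expected paired (x, y) columns")
    n_sensors = predicted.shape[1] // 2
    sensors = list(sensors) if sensors is not None else list(MIDSAGITTAL_SENSORS[:n_sensors])
    diff = (predicted - ref).reshape(len(predicted), n_sensors, 2)
    dist = np.linalg.norm(diff, axis=2)  # T x n_sensors
    return SensorErrorReport(
        sensors=sensors,
        mean_mm=dist.mean(axis=0),
        sd_mm=dist.std(axis=0),
        pooled_mean_mm=float(dist.mean()),
        pooled_sd_mm=float(dist.std()),
    )
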