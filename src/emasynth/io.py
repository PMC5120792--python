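"""File formats: WAV, EMA trajectories, segmentations, mel-cepstrograms,
model and calibration containers.

All tabular formats are plain tab-separated text with '#' header comments;
real EMA exports in the same dialect are drop-in replacements for the
synthetic generator's files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .artic import CANONICAL_SENSORS, EmaRecording, Normalizer, Segmentation
from .calibration import LinearCalibration
from .dnn import DNNModel
from .vocoder import MelCepstrogram, Waveform

FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# WAV
# ---------------------------------------------------------------------------


def read_wav(path, expected_rate: int | None = None) -> Waveform:
    """Read a mono PCM16/float32 WAV file into a float waveform in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    if expected_rate is not None and rate != expected_rate:
        raise ValueError(f"{path}: sample rate {rate} != expected {expected_rate}")
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(np.float64) / 2147483648.0
    else:
        data = data.astype(np.float64)
    return Waveform(data, rate=rate)


def write_wav(path, wave: Waveform, pcm16: bool = True) -> None:
    if pcm16:
        peak = np.max(np.abs(wave.samples))
        scale = 0.99 / peak if peak > 1.0 else 1.0
        data = np.round(wave.samples * scale * 32767.0).astype(np.int16)
    else:
        data = wave.samples.astype(np.float32)
    wavfile.write(path, wave.rate, data)


# ---------------------------------------------------------------------------
# EMA trajectories and segmentations
# ---------------------------------------------------------------------------


def write_ema(path, rec: EmaRecording) -> None:
    names = [s for s in CANONICAL_SENSORS if s in rec.sensors]
    names += [s for s in rec.sensors if s not in names]
    cols = [np.arange(rec.n_frames) / rec.rate]
    header_cols = ["time_s"]
    for name in names:
        cols.append(rec.sensors[name])
        header_cols += [f"{name}_{ax}" for ax in "xyz"]
    cols.append(rec.reference_pose)
    header_cols += [f"ref_{c}" for c in ("tx", "ty", "tz", "rx", "ry", "rz")]
    mat = np.column_stack(cols)
    with open(path, "w") as fh:
        fh.write(f"# rate_hz\t{rec.rate}\n")
        fh.write(f"# sensors\t{','.join(names)}\n")
        fh.write("# " + "\t".join(header_cols) + "\n")
        np.savetxt(fh, mat, fmt="%.6f", delimiter="\t")


def read_ema(path) -> EmaRecording:
    rate = None
    names: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].strip().split("\t")
            if parts[0] == "rate_hz":
                rate = float(parts[1])
            elif parts[0] == "sensors":
                names = parts[1].split(",")
    if rate is None or not names:
        raise ValueError(f"{path}: missing rate/sensor header")
    mat = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)
    expected = 1 + 3 * len(names) + 6
    if mat.shape[1] != expected:
        raise ValueError(f"{path}: expected {expected} columns, got {mat.shape[1]}")
    sensors = {
        name: mat[:, 1 + 3 * i:1 + 3 * (i + 1)] for i, name in enumerate(names)
    }
    return EmaRecording(sensors=sensors, reference_pose=mat[:, -6:], rate=rate)


def write_segmentation(path, seg: Segmentation) -> None:
    with open(path, "w") as fh:
        for lab, start, end in seg.intervals:
            fh.write(f"{start:.6f}\t{end:.6f}\t{lab}\n")


def read_segmentation(path) -> Segmentation:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            start, end, lab = line.split("\t")
            intervals.append((lab, float(start), float(end)))
    return Segmentation(intervals)


def write_features(path, frames: np.ndarray, rate: float = 100.0,
                   parameterization: str | None = None) -> None:
    """Plain T x d feature matrix, one frame per tab-separated row."""
    with open(path, "w") as fh:
        fh.write(f"# rate_hz\t{rate}\n")
        if parameterization:
            fh.write(f"# parameterization\t{parameterization}\n")
        np.savetxt(fh, np.atleast_2d(frames), fmt="%.6f", delimiter="\t")


def read_features(path) -> tuple[np.ndarray, float]:
    rate = 100.0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].strip().split("\t")
            if parts[0] == "rate_hz":
                rate = float(parts[1])
    return np.loadtxt(path, delimiter="\t", comments="#", ndmin=2), rate


# ---------------------------------------------------------------------------
# Mel-cepstrograms
# ---------------------------------------------------------------------------


def write_mel_cepstrogram(path, cep: MelCepstrogram) -> None:
    with open(path, "w") as fh:
        fh.write(f"# alpha\t{cep.alpha}\n")
        fh.write(f"# frame_rate_hz\t{cep.frame_rate}\n")
        fh.write(f"# hop_samples\t{cep.hop}\n")
        fh.write(f"# window_samples\t{cep.window}\n")
        np.savetxt(fh, cep.frames, fmt="%.8e", delimiter="\t")


def read_mel_cepstrogram(path) -> MelCepstrogram:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, val = line[1:].strip().split("\t")
            meta[key] = float(val)
    frames = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)
    return MelCepstrogram(
        frames,
        alpha=meta.get("alpha", 0.455),
        frame_rate=meta.get("frame_rate_hz", 100.0),
        hop=int(meta.get("hop_samples", 220)),
        window=int(meta.get("window_samples", 512)),
    )


# ---------------------------------------------------------------------------
# Model / calibration containers (versioned JSON)
# ---------------------------------------------------------------------------


def save_model(path, model: DNNModel) -> None:
    payload = {
        "format": "emasynth-dnn",
        "version": FORMAT_VERSION,
        "layer_sizes": model.layer_sizes,
        "slope": model.slope,
        "n_past": model.n_past,
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "in_norm": {"mean": model.in_norm.mean.tolist(), "sd": model.in_norm.sd.tolist()},
        "out_norm": {"mean": model.out_norm.mean.tolist(), "sd": model.out_norm.sd.tolist()},
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> DNNModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "emasynth-dnn":
        raise ValueError(f"{path}: not a model container")
    return DNNModel(
        weights=[np.array(w) for w in payload["weights"]],
        biases=[np.array(b) for b in payload["biases"]],
        slope=payload["slope"],
        in_norm=Normalizer(np.array(payload["in_norm"]["mean"]),
                           np.array(payload["in_norm"]["sd"])),
        out_norm=Normalizer(np.array(payload["out_norm"]["mean"]),
                            np.array(payload["out_norm"]["sd"])),
        n_past=payload.get("n_past", 4),
    )


def save_calibration(path, cal: LinearCalibration) -> None:
    payload = {
        "format": "emasynth-calibration",
        "version": FORMAT_VERSION,
        "matrix": cal.matrix.tolist(),
        "bias": cal.bias.tolist(),
        "delay": cal.delay,
        "fit_mse": cal.fit_mse,
        "delay_grid": list(cal.delay_grid),
    }
    Path(path).write_text(json.dumps(payload))


def load_calibration(path) -> LinearCalibration:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "emasynth-calibration":
        raise ValueError(f"{path}: not a calibration container")
    return LinearCalibration(
        matrix=np.array(payload["matrix"]),
        bias=np.array(payload["bias"]),
        delay=int(payload["delay"]),
        fit_mse=float(payload["fit_mse"]),
        delay_grid=tuple(payload["delay_grid"]),
    )
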