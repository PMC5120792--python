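"""End-to-end synthesis: offline driver and causal streaming simulation.

The closed-loop cascade maps each incoming articulatory frame through the
cross-speaker linear calibration, the articulatory-to-acoustic DNN, and one
hop of MLSA filtering of the fixed-template excitation.  The offline driver
and the frame-by-frame streaming path share every numeric kernel, so their
outputs are sample-identical; the streaming path holds only a bounded
context buffer and filter state (constant work per frame, no lookahead).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calibration import LinearCalibration, apply_calibration
from .dnn import DNNModel
from .vocoder import (
    DEFAULT_ALPHA,
    DEFAULT_HOP,
    DEFAULT_RATE,
    Excitation,
    F0Contour,
    MlsaState,
    Waveform,
    _PADE5,
    _mlsa_run,
    build_pitch_excitation,
    build_template_excitation,
    interpolate_filter_coeffs,
    mc2b,
)


def _frames_of(features) -> np.ndarray:
    frames = getattr(features, "frames", features)
    return np.atleast_2d(np.asarray(frames, dtype=np.float64))


def _predict_mel_frames(features: np.ndarray, model: DNNModel) -> np.ndarray:
    """Row-wise DNN prediction with causal first-frame-replicated context."""
    t_total, d = features.shape
    out = np.empty((t_total, len(model.out_norm.mean)))
    n_ctx = model.n_past + 1
    ctx = np.repeat(features[:1], n_ctx, axis=0)
    for t in range(t_total):
        ctx[1:] = ctx[:-1]
        ctx[0] = features[t]
        out[t] = model.predict_frame(ctx.reshape(-1))
    return out


def synthesize_offline(features, model: DNNModel, excitation,
                       rate: int = DEFAULT_RATE, hop: int = DEFAULT_HOP,
                       alpha: float = DEFAULT_ALPHA, seed: int = 0,
                       calibration: LinearCalibration | None = None) -> Waveform:
    """Synthesize audio from articulatory features in one batch call.

    ``excitation`` is either an :class:`F0Contour` (pulse/noise source) or a
    1-D template array (fixed-pitch tiled source).  Output length is exactly
    T * hop samples.
    """
    frames = _frames_of(features)
    if frames.shape[1] != len(model.in_norm.mean):
        if calibration is None or frames.shape[1] != calibration.matrix.shape[1]:
            raise ValueError(
                f"feature dim {frames.shape[1]} does not match the model"
                f" input dim {len(model.in_norm.mean)}"
            )
    if calibration is not None:
        # row-wise application keeps the offline path numerically identical
        # to the per-frame streaming path
        frames = np.vstack([apply_calibration(calibration, f) for f in frames])
    t_total = frames.shape[0]
    n_samples = t_total * hop
    mel = _predict_mel_frames(frames, model)
    b = mc2b(mel, alpha)
    bs = interpolate_filter_coeffs(b, hop, n_samples)
    if isinstance(excitation, F0Contour):
        exc = build_pitch_excitation(excitation, rate, n_samples, seed=seed, hop=hop)
    else:
        exc = build_template_excitation(np.asarray(excitation), n_samples)
    state = MlsaState(mel.shape[1])
    y = _mlsa_run(exc.samples, bs, alpha, _PADE5, False,
                  state.pt1, state.d1, state.pt2, state.u2)
    return Waveform(y, rate=rate)


# ---------------------------------------------------------------------------
# Streaming
# ---------------------------------------------------------------------------


@dataclass
class StreamState:
    """Persistent state of the causal frame-by-frame synthesis cascade."""

    model: DNNModel
    template: np.ndarray
    calibration: LinearCalibration | None = None
    hop: int = DEFAULT_HOP
    rate: int = DEFAULT_RATE
    alpha: float = DEFAULT_ALPHA
    context: np.ndarray | None = None  # (n_past+1) x d, newest first
    prev_b: np.ndarray | None = None
    mlsa: MlsaState | None = None
    sample_pos: int = 0
    frames_seen: int = 0

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=np.float64)
        if self.template.size == 0:
            raise ValueError("empty excitation template")
        if self.mlsa is None:
            self.mlsa = MlsaState(len(self.model.out_norm.mean))

    @property
    def context_size(self) -> int:
        return 0 if self.context is None else self.context.shape[0]


def stream_step(state: StreamState, frame: np.ndarray) -> np.ndarray:
    """Consume one articulatory frame, emit one hop of audio samples.

    Output depends only on frames received so far; the context buffer is
    replicated from the first frame on the cold start.
    """
    frame = np.asarray(frame, dtype=np.float64).reshape(-1)
    if state.calibration is not None:
        frame = apply_calibration(state.calibration, frame)[0]
    d = len(state.model.in_norm.mean)
    if frame.shape[0] != d:
        raise ValueError(f"frame dim {frame.shape[0]} != model input dim {d}")
    if state.context is None:
        state.context = np.repeat(frame[None, :], state.model.n_past + 1, axis=0)
    else:
        state.context[1:] = state.context[:-1]
        state.context[0] = frame
    mel = state.model.predict_frame(state.context.reshape(-1))
    b = mc2b(mel[None, :], state.alpha)[0]
    bs = interpolate_filter_coeffs(b[None, :], state.hop, state.hop,
                                   b_prev=state.prev_b)
    idx = (state.sample_pos + np.arange(state.hop)) % len(state.template)
    exc = state.template[idx]
    y = _mlsa_run(exc, bs, state.alpha, _PADE5, False,
                  state.mlsa.pt1, state.mlsa.d1, state.mlsa.pt2, state.mlsa.u2)
    state.prev_b = b
    state.sample_pos += state.hop
    state.frames_seen += 1
    return y


def stream_synthesize(features, model: DNNModel, template: np.ndarray,
                      calibration: LinearCalibration | None = None,
                      hop: int = DEFAULT_HOP, rate: int = DEFAULT_RATE,
                      alpha: float = DEFAULT_ALPHA) -> Waveform:
    """Feed features one frame at a time through :func:`stream_step`."""
    state = StreamState(model=model, template=template, calibration=calibration,
                        hop=hop, rate=rate, alpha=alpha)
    chunks = [stream_step(state, f) for f in _frames_of(features)]
    return Waveform(np.concatenate(chunks) if chunks else np.empty(0), rate=rate)


def run_closed_loop_session(items, calibration: LinearCalibration | None,
                            model: DNNModel, template: np.ndarray,
                            out_dir, rate: int = DEFAULT_RATE,
                            hop: int = DEFAULT_HOP) -> list[dict]:
    """Stream-synthesize a list of (name, frames) items to WAV files.

    Returns a manifest of per-item records; I/O failures are recorded per
    item and the session continues.
    """
    from .io import write_wav

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for name, frames in items:
        record = {"name": name, "wav": str(out_dir / f"{name}.wav")}
        try:
            t0 = time.perf_counter()
            wave = stream_synthesize(frames, model, template,
                                     calibration=calibration, hop=hop, rate=rate)
            record["n_frames"] = int(_frames_of(frames).shape[0])
            record["n_samples"] = len(wave)
            record["elapsed_s"] = time.perf_counter() - t0
            write_wav(record["wav"], wave)
            record["ok"] = True
        except Exception as exc:  # noqa: BLE001 - per-item fault isolation
            record["ok"] = False
            record["error"] = str(exc)
        manifest.append(record)
    return manifest
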