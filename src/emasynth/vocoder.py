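"""Mel-cepstral vocoder: analysis, MLSA synthesis / inverse filtering, excitation.

The spectral envelope of each analysis frame is represented by ``n_coef``
mel-cepstral coefficients :math:`c_\\alpha(m)` on a warped frequency axis

.. math::

    H(z) = \\exp \\sum_{m=0}^{M} c_\\alpha(m)\\,\\tilde z^{-m},
    \\qquad \\tilde z^{-1} = \\frac{z^{-1} - \\alpha}{1 - \\alpha z^{-1}},

with all-pass warp coefficient ``alpha`` (0.455 approximates the mel scale at
22,050 Hz).  Synthesis drives the exponential transfer function, realized by a
two-stage Padé approximation (the MLSA filter), with a pulse/noise or
fixed-template excitation signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

DEFAULT_RATE = 22050
DEFAULT_ALPHA = 0.455
DEFAULT_N_COEF = 25
DEFAULT_WINDOW = 512
DEFAULT_HOP = 220  # nominal 10 ms at 22,050 Hz
DEFAULT_FRAME_RATE = 100.0

# Padé coefficients for exp(x) of order 5 (numerically optimized variant in
# common use for MLSA filters).
_PADE5 = np.array(
    [1.0, 0.4999391, 0.1107098, 0.01369984, 0.0009564853, 0.00003041721]
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Waveform:
    """Mono audio signal with sample rate."""

    samples: np.ndarray
    rate: int = DEFAULT_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class MelCepstrogram:
    """Frame sequence of mel-cepstral coefficients c_alpha(m)."""

    frames: np.ndarray  # T x n_coef
    alpha: float = DEFAULT_ALPHA
    frame_rate: float = DEFAULT_FRAME_RATE
    hop: int = DEFAULT_HOP
    window: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=np.float64))
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("cepstral frames contain non-finite values")
        if self.frames.shape[1] < 1:
            raise ValueError("need at least one cepstral coefficient")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_coef(self) -> int:
        return self.frames.shape[1]


@dataclass
class F0Contour:
    """Per-frame fundamental frequency; 0 Hz on unvoiced frames."""

    f0: np.ndarray
    voiced: np.ndarray

    def __post_init__(self) -> None:
        self.f0 = np.asarray(self.f0, dtype=np.float64)
        self.voiced = np.asarray(self.voiced, dtype=bool)
        if self.f0.shape != self.voiced.shape:
            raise ValueError("f0 and voiced must have the same length")
        if np.any((self.f0 > 0) != self.voiced):
            raise ValueError("f0 > 0 must hold exactly on voiced frames")

    def __len__(self) -> int:
        return len(self.f0)


@dataclass
class Excitation:
    """Source signal for the MLSA filter."""

    samples: np.ndarray
    mode: str  # "pitch_driven" or "fixed_template"
    template: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("excitation contains non-finite samples")
        if self.mode not in ("pitch_driven", "fixed_template"):
            raise ValueError(f"unknown excitation mode {self.mode!r}")

    def __len__(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# Mel-cepstral analysis
# ---------------------------------------------------------------------------


def warped_basis(alpha: float, n_fft: int, n_coef: int) -> tuple[np.ndarray, np.ndarray]:
    """Cosine basis cos(m * beta(w)) on the one-sided FFT grid.

    beta(w) is the phase response of the all-pass warp, i.e. the warped
    frequency corresponding to linear frequency w.  Returns (basis, weights)
    where weights implement the trapezoid rule over [0, pi].
    """
    k = n_fft // 2 + 1
    omega = np.linspace(0.0, np.pi, k)
    # phase of (e^{-jw} - a) / (1 - a e^{-jw})
    z = np.exp(-1j * omega)
    beta = -np.angle((z - alpha) / (1.0 - alpha * z))
    basis = np.cos(np.outer(beta, np.arange(n_coef)))
    weights = np.ones(k)
    weights[0] = weights[-1] = 0.5
    return basis, weights


def _frame_signal(x: np.ndarray, window: int, hop: int) -> np.ndarray:
    n_frames = (len(x) - window) // hop + 1
    idx = np.arange(window)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def mel_cepstral_criterion(c: np.ndarray, log_periodogram: np.ndarray,
                           basis: np.ndarray, weights: np.ndarray) -> float:
    """Spectral-matching criterion mean[exp(R) - R - 1], R = log I - log|H|^2."""
    r = log_periodogram - 2.0 * (basis @ c)
    return float(np.sum(weights * (np.exp(r) - r - 1.0)) / np.sum(weights))


def _solve_frame(log_i: np.ndarray, basis: np.ndarray, weights: np.ndarray,
                 max_iter: int, tol: float) -> np.ndarray:
    """Newton minimization of the mel-cepstral criterion for one frame."""
    wsum = np.sum(weights)
    # warm start: least-squares fit of the warped log amplitude spectrum
    c, *_ = np.linalg.lstsq(basis * weights[:, None], 0.5 * log_i * weights, rcond=None)
    crit = mel_cepstral_criterion(c, log_i, basis, weights)
    for _ in range(max_iter):
        r = log_i - 2.0 * (basis @ c)
        er = np.exp(r)
        grad = -2.0 * basis.T @ (weights * (er - 1.0)) / wsum
        hess = 4.0 * basis.T @ (basis * (weights * er)[:, None]) / wsum
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        # backtracking keeps the Newton iteration monotone
        scale = 1.0
        for _ in range(20):
            c_new = c - scale * step
            crit_new = mel_cepstral_criterion(c_new, log_i, basis, weights)
            if crit_new <= crit:
                break
            scale *= 0.5
        else:
            break
        improved = crit - crit_new
        c, crit = c_new, crit_new
        if improved < tol:
            break
    return c


def analyze_mel_cepstrum(wave: Waveform, n_coef: int = DEFAULT_N_COEF,
                         alpha: float = DEFAULT_ALPHA, window: int = DEFAULT_WINDOW,
                         hop: int = DEFAULT_HOP, max_iter: int = 30,
                         tol: float = 1e-6) -> MelCepstrogram:
    """Frame-wise mel-cepstral analysis of an audio signal.

    Each frame of ``window`` samples (Blackman-windowed, advanced by ``hop``)
    yields ``n_coef`` coefficients minimizing the mel-cepstral spectral
    matching criterion, refined by a damped Newton iteration.
    """
    x = wave.samples
    if len(x) == 0:
        raise ValueError("cannot analyze an empty signal")
    if len(x) < window:
        raise ValueError(
            f"signal ({len(x)} samples) shorter than one analysis window ({window})"
        )
    if n_coef < 1:
        raise ValueError("n_coef must be >= 1")
    win = np.blackman(window)
    frames = _frame_signal(x, window, hop) * win
    spec = np.abs(np.fft.rfft(frames, n=window, axis=1)) ** 2 / np.sum(win**2)
    # 80 dB dynamic-range floor: keeps the exponential synthesis filter within
    # the stable range of its Padé approximation on steeply tilted spectra
    floor = max(np.max(spec), 1e-30) * 1e-8
    log_i = np.log(np.maximum(spec, floor))
    basis, weights = warped_basis(alpha, window, n_coef)
    cep = np.empty((frames.shape[0], n_coef))
    for t in range(frames.shape[0]):
        cep[t] = _solve_frame(log_i[t], basis, weights, max_iter, tol)
    return MelCepstrogram(cep, alpha=alpha, frame_rate=wave.rate / hop,
                          hop=hop, window=window)


# ---------------------------------------------------------------------------
# Mel-cepstrum <-> MLSA filter coefficients
# ---------------------------------------------------------------------------


def mc2b(frames: np.ndarray, alpha: float) -> np.ndarray:
    """Mel-cepstrum rows -> MLSA digital filter coefficient rows.

    b(M) = c(M); b(m) = c(m) - alpha * b(m+1).  With alpha = 0 the transform
    is the identity.
    """
    c = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    b = np.empty_like(c)
    b[:, -1] = c[:, -1]
    for m in range(c.shape[1] - 2, -1, -1):
        b[:, m] = c[:, m] - alpha * b[:, m + 1]
    return b


def mel_to_filter_coeffs(cep: MelCepstrogram) -> np.ndarray:
    """Per-frame MLSA filter coefficients of a cepstrogram (see :func:`mc2b`)."""
    return mc2b(cep.frames, cep.alpha)


def filter_coeffs_to_mel(b: np.ndarray, alpha: float) -> np.ndarray:
    """Inverse of :func:`mel_to_filter_coeffs` (the b2mc recursion)."""
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    c = np.empty_like(b)
    c[:, -1] = b[:, -1]
    for m in range(b.shape[1] - 2, -1, -1):
        c[:, m] = b[:, m] + alpha * b[:, m + 1]
    return c


# ---------------------------------------------------------------------------
# MLSA filter kernel (per-sample, streaming-capable)
# ---------------------------------------------------------------------------
#
# H(z) = exp(b0) * exp(F1(z)) * exp(F2(z)) with
#   F1 = b(1) * Phi_1(z),      F2 = sum_{m>=2} b(m) * Phi_m(z),
#   Phi_1 = (1 - a^2) z^-1 / (1 - a z^-1),  Phi_m = Phi_1 * ztilde^-(m-1).
# Each exp(F) is approximated by the order-5 Pade rational R(F) = N(F)/N(-F),
# realized with L feedback branches; R(-F) = 1/R(F) exactly, which makes
# inverse filtering with negated coefficients the exact inverse of the
# synthesis filter (up to the time variation of the coefficients).


@njit(cache=False)
def _stage1_step(x, b1, alpha, pade, pt_prev, d1):
    L = len(pade) - 1
    a2 = 1.0 - alpha * alpha
    out = 0.0
    xc = x
    pt_new = np.empty(L + 1)
    for i in range(L, 0, -1):
        d1[i] = alpha * d1[i] + a2 * pt_prev[i - 1]
        vi = b1 * d1[i]
        pt_new[i] = vi
        v = pade[i] * vi
        if i % 2 == 1:
            xc += v
        else:
            xc -= v
        out += v
    pt_new[0] = xc
    out += xc
    for i in range(L + 1):
        pt_prev[i] = pt_new[i]
    return out


@njit(cache=False)
def _stage2_step(x, b, alpha, pade, pt_prev, u_prev):
    L = len(pade) - 1
    M = b.shape[0] - 1  # coefficients b[0..M]
    a2 = 1.0 - alpha * alpha
    out = 0.0
    xc = x
    pt_new = np.empty(L + 1)
    cur = np.empty(M + 1)
    for i in range(L, 0, -1):
        cur[0] = 0.0
        cur[1] = alpha * u_prev[i, 1] + a2 * pt_prev[i - 1]
        vi = 0.0
        for m in range(2, M + 1):
            cur[m] = u_prev[i, m - 1] - alpha * cur[m - 1] + alpha * u_prev[i, m]
            vi += b[m] * cur[m]
        pt_new[i] = vi
        v = pade[i] * vi
        if i % 2 == 1:
            xc += v
        else:
            xc -= v
        out += v
        for m in range(M + 1):
            u_prev[i, m] = cur[m]
    pt_new[0] = xc
    out += xc
    for i in range(L + 1):
        pt_prev[i] = pt_new[i]
    return out


@njit(cache=False)
def _mlsa_run(x, bs, alpha, pade, inverse,
              pt1, d1, pt2, u2):
    """Run the MLSA filter over x with per-sample coefficients bs (n x M+1).

    inverse=False: y = exp(b0) * R(F2)(R(F1)(x))        (synthesis)
    inverse=True:  y = R(-F1)(R(-F2)(exp(-b0) * x))     (residual extraction)
    State arrays are updated in place, so successive calls stream.
    """
    n = x.shape[0]
    y = np.empty(n)
    for t in range(n):
        b = bs[t]
        if inverse:
            s = x[t] * np.exp(-b[0])
            s = _stage2_step(s, -b, alpha, pade, pt2, u2)
            s = _stage1_step(s, -b[1], alpha, pade, pt1, d1)
            y[t] = s
        else:
            s = _stage1_step(x[t], b[1], alpha, pade, pt1, d1)
            s = _stage2_step(s, b, alpha, pade, pt2, u2)
            y[t] = s * np.exp(b[0])
    return y


@dataclass
class MlsaState:
    """Streaming state of the MLSA filter (one Padé branch set per stage)."""

    n_coef: int
    pt1: np.ndarray = field(default=None)  # type: ignore[assignment]
    d1: np.ndarray = field(default=None)  # type: ignore[assignment]
    pt2: np.ndarray = field(default=None)  # type: ignore[assignment]
    u2: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        L = len(_PADE5) - 1
        if self.pt1 is None:
            self.pt1 = np.zeros(L + 1)
            self.d1 = np.zeros(L + 1)
            self.pt2 = np.zeros(L + 1)
            self.u2 = np.zeros((L + 1, self.n_coef))


def interpolate_filter_coeffs(b_frames: np.ndarray, hop: int, n_samples: int,
                              b_prev: np.ndarray | None = None) -> np.ndarray:
    """Causal per-sample linear interpolation of frame coefficients.

    Samples of frame t ramp from the previous frame's coefficients to frame
    t's, reaching them on the hop's last sample.  The first frame ramps from
    ``b_prev`` (cold start: its own value, i.e. constant).
    """
    b_frames = np.atleast_2d(b_frames)
    n_frames = b_frames.shape[0]
    if n_samples > n_frames * hop:
        raise ValueError("more samples requested than frames provide")
    ramp = (np.arange(1, hop + 1) / hop)[:, None]
    out = np.empty((n_frames * hop, b_frames.shape[1]))
    prev = b_frames[0] if b_prev is None else b_prev
    for t in range(n_frames):
        out[t * hop:(t + 1) * hop] = prev + ramp * (b_frames[t] - prev)
        prev = b_frames[t]
    return out[:n_samples]


def _per_sample_coeffs(cep: MelCepstrogram, n_samples: int) -> np.ndarray:
    b = mel_to_filter_coeffs(cep)
    total = cep.n_frames * cep.hop
    if n_samples <= total:
        return interpolate_filter_coeffs(b, cep.hop, n_samples)
    # tail beyond the last full hop (e.g. the final partial analysis window)
    # holds the last frame's coefficients
    bs = interpolate_filter_coeffs(b, cep.hop, total)
    tail = np.repeat(b[-1][None, :], n_samples - total, axis=0)
    return np.vstack([bs, tail])


def _check_length(n: int, cep: MelCepstrogram, what: str) -> None:
    lo = (cep.n_frames - 1) * cep.hop + 1
    hi = cep.n_frames * cep.hop + cep.window
    if not lo <= n <= hi:
        raise ValueError(
            f"{what} length {n} inconsistent with {cep.n_frames} frames "
            f"(hop {cep.hop}, window {cep.window})"
        )


def mlsa_synthesize(excitation: Excitation, cep: MelCepstrogram,
                    rate: int = DEFAULT_RATE,
                    state: MlsaState | None = None) -> Waveform:
    """Drive the MLSA filter defined by ``cep`` with an excitation signal."""
    n = len(excitation)
    _check_length(n, cep, "excitation")
    if state is None:
        state = MlsaState(cep.n_coef)
    bs = _per_sample_coeffs(cep, n)
    y = _mlsa_run(excitation.samples, bs, cep.alpha, _PADE5, False,
                  state.pt1, state.d1, state.pt2, state.u2)
    return Waveform(y, rate=rate)


def mlsa_inverse_filter(wave: Waveform, cep: MelCepstrogram,
                        state: MlsaState | None = None) -> Waveform:
    """Inverse MLSA filtering: recover the excitation (residual) from audio."""
    n = len(wave)
    _check_length(n, cep, "waveform")
    if state is None:
        state = MlsaState(cep.n_coef)
    bs = _per_sample_coeffs(cep, n)
    y = _mlsa_run(wave.samples, bs, cep.alpha, _PADE5, True,
                  state.pt1, state.d1, state.pt2, state.u2)
    return Waveform(y, rate=wave.rate)


def warped_log_spectrum(c: np.ndarray, alpha: float, n_fft: int) -> np.ndarray:
    """Analytic log magnitude response sum_m c(m) cos(m beta(w)) on the FFT grid."""
    c = np.asarray(c, dtype=np.float64)
    basis, _ = warped_basis(alpha, n_fft, len(c))
    return basis @ c


# ---------------------------------------------------------------------------
# Pitch extraction and excitation construction
# ---------------------------------------------------------------------------


def extract_pitch(wave: Waveform, window: int = DEFAULT_WINDOW * 2,
                  hop: int = DEFAULT_HOP,
                  f0_range: tuple[float, float] = (50.0, 400.0),
                  voicing_threshold: float = 0.3,
                  energy_gate: float = 0.02) -> F0Contour:
    """Frame-wise autocorrelation pitch tracking with a voicing decision.

    A frame is voiced when its normalized autocorrelation peak within the lag
    range exceeds ``voicing_threshold`` and its RMS exceeds ``energy_gate``
    times the loudest frame's RMS.
    """
    x = wave.samples
    if len(x) == 0:
        raise ValueError("cannot extract pitch from an empty signal")
    f_lo, f_hi = f0_range
    if not 0.0 < f_lo < f_hi < wave.rate / 2:
        raise ValueError("f0_range must satisfy 0 < lo < hi < rate/2")
    window = min(window, len(x))
    lag_min = max(2, int(np.floor(wave.rate / f_hi)))
    lag_max = min(window - 2, int(np.ceil(wave.rate / f_lo)))
    n_frames = max(1, (len(x) - window) // hop + 1)
    f0 = np.zeros(n_frames)
    voiced = np.zeros(n_frames, dtype=bool)
    frames = _frame_signal(x[: window + hop * (n_frames - 1)], window, hop)
    frames = frames - frames.mean(axis=1, keepdims=True)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    gate = energy_gate * (rms.max() if rms.max() > 0 else 1.0)
    for t in range(n_frames):
        if rms[t] <= gate or rms[t] == 0.0:
            continue
        fr = frames[t]
        ac = np.correlate(fr, fr, mode="full")[window - 1:]
        if ac[0] <= 0:
            continue
        acn = ac / ac[0]
        seg = acn[lag_min:lag_max + 1]
        k = int(np.argmax(seg)) + lag_min
        if acn[k] < voicing_threshold:
            continue
        # parabolic refinement of the peak lag
        if 1 <= k < len(acn) - 1:
            denom = acn[k - 1] - 2 * acn[k] + acn[k + 1]
            delta = 0.5 * (acn[k - 1] - acn[k + 1]) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        f0[t] = wave.rate / (k + delta)
        voiced[t] = True
    return F0Contour(f0, voiced)


def build_pitch_excitation(f0: F0Contour, rate: int, length: int,
                           seed: int = 0, hop: int = DEFAULT_HOP) -> Excitation:
    """Pulse train (voiced) / white noise (unvoiced) excitation.

    Voiced spans use phase accumulation with per-sample linear interpolation
    of f0; pulses have amplitude sqrt(period) so the voiced excitation has
    unit average power, and noise spans are unit-variance.
    """
    if np.any(f0.f0 >= rate / 2):
        raise ValueError("f0 must be below the Nyquist frequency")
    n_frames = len(f0)
    if n_frames * hop < length:
        raise ValueError("f0 contour does not cover the requested length")
    rng = np.random.default_rng(seed)
    t_idx = np.minimum(np.arange(length) // hop, n_frames - 1)
    f0_s = f0.f0[t_idx]
    voiced_s = f0.voiced[t_idx]
    out = np.zeros(length)
    phase = 0.0
    for t in range(length):
        if voiced_s[t]:
            phase += f0_s[t] / rate
            if phase >= 1.0:
                phase -= 1.0
                out[t] = np.sqrt(rate / f0_s[t])
        else:
            phase = 1.0  # pulse fires immediately when voicing resumes
            out[t] = rng.standard_normal()
    return Excitation(out, mode="pitch_driven")


def build_template_excitation(template: np.ndarray, length: int) -> Excitation:
    """Tile a single-period glottal template end-to-end to ``length`` samples."""
    template = np.asarray(template, dtype=np.float64)
    if template.size == 0:
        raise ValueError("excitation template is empty")
    reps = int(np.ceil(length / len(template)))
    out = np.tile(template, reps)[:length]
    return Excitation(out, mode="fixed_template", template=template)


def template_from_vowel(wave: Waveform, cep: MelCepstrogram,
                        f0_hint: float | None = None) -> np.ndarray:
    """Extract a single-period excitation template from a sustained vowel.

    Inverse-filters the vowel, estimates its period by autocorrelation (or
    uses ``f0_hint``), and cuts one period from the middle of the residual.
    """
    residual = mlsa_inverse_filter(wave, cep)
    if f0_hint is None:
        contour = extract_pitch(residual)
        f0_voiced = contour.f0[contour.voiced]
        if f0_voiced.size == 0:
            raise ValueError("no voiced frames found in the vowel")
        f0_hint = float(np.median(f0_voiced))
    period = int(round(wave.rate / f0_hint))
    mid = len(residual) // 2
    start = max(0, mid - period // 2)
    return residual.samples[start:start + period].copy()
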