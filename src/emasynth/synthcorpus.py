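"""Synthetic paired articulatory-acoustic corpus generator.

Emulates the structure of a reference articulatory-acoustic recording
session so that every stage of the pipeline — DNN training, cross-speaker
calibration, streaming synthesis, intelligibility scoring — can be exercised
with known ground truth and no external data:

- a pseudo-phone inventory (10 vowels + 7 consonants by default), each phone
  owning a fixed articulatory target drawn once from the seed;
- items (isolated vowels, VCV pseudo-words, short pseudo-sentences) whose
  articulatory trajectories interpolate between successive targets with
  raised-cosine 50 ms transitions plus coloured noise, sampled at 400 Hz and
  down-sampled to 100 Hz;
- mel-cepstral frames produced by a fixed smooth nonlinear ground-truth map
  of the stacked trajectory, plus observation noise;
- "new speaker" variants x_new(t) = A x_ref(t - delay) + b + noise for the
  calibration module to invert.

Targets live on a millimetre-like scale (a few mm of articulator travel);
mel outputs are scaled like z-scored cepstra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .artic import SILENCE_LABEL, Segmentation, _decimate, stack_context
from .dnn import N_PAST

VOWELS = tuple(f"V{i}" for i in range(10))
CONSONANTS = tuple(f"C{i}" for i in range(7))


@dataclass
class SyntheticSpec:
    """Conditions of the emulated recording session."""

    n_items: int = 50
    item_mix: tuple[float, float, float] = (0.15, 0.25, 0.60)  # vowel / VCV / sentence
    artic_dim: int = 14
    phone_duration: tuple[float, float] = (0.12, 0.28)  # s
    vowel_hold: float = 0.5  # s, isolated-vowel steady state
    edge_silence: tuple[float, float] = (0.20, 0.40)  # s of silence at item edges
    sentence_len: tuple[int, int] = (6, 12)  # phones per pseudo-sentence
    target_scale_mm: float = 8.0
    transition_s: float = 0.05
    traj_noise_mm: float = 0.3
    obs_noise_sd: float = 0.3  # mel units, vs output spread ~1
    rate_raw: float = 400.0
    rate: float = 100.0
    n_mel: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phone_duration[0] <= 0 or self.traj_noise_mm < 0 or self.obs_noise_sd < 0:
            raise ValueError("invalid synthetic spec")


@dataclass
class SyntheticItem:
    name: str
    tokens: list[str]
    traj400: np.ndarray  # T400 x d
    traj100: np.ndarray  # T100 x d
    seg: Segmentation
    mel: np.ndarray  # T100 x 25
    clean_mel: np.ndarray  # mel before observation noise


@dataclass
class SyntheticCorpus:
    spec: SyntheticSpec
    phone_targets: dict[str, np.ndarray]
    items: list[SyntheticItem]
    ground_truth: "GroundTruthMap"


@dataclass
class GroundTruthMap:
    """Fixed smooth map g: stacked articulatory context -> 25 mel coefficients.

    A shallow random network of tanh basis functions; Lipschitz-bounded and
    reproducible from its seed.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    input_scale: float

    def __call__(self, stacked: np.ndarray) -> np.ndarray:
        h = np.tanh((np.atleast_2d(stacked) / self.input_scale) @ self.w1 + self.b1)
        return h @ self.w2 + self.b2


def make_ground_truth_map(seed: int, d_in: int = 5 * 14, n_basis: int = 50,
                          n_out: int = 25, input_scale: float = 8.0) -> GroundTruthMap:
    rng = np.random.default_rng(seed)
    w1 = rng.normal(0.0, 1.5 / np.sqrt(d_in), size=(d_in, n_basis))
    b1 = rng.normal(0.0, 0.5, size=n_basis)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(n_basis), size=(n_basis, n_out))
    # keep coefficients in a range the exponential synthesis filter tolerates
    w2 *= 0.6 / np.std(w2) / np.sqrt(n_basis)
    b2 = rng.normal(0.0, 0.05, size=n_out)
    b2[0] = -0.5  # modest overall gain
    return GroundTruthMap(w1, b1, w2, b2, input_scale)


def _draw_targets(spec: SyntheticSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    targets = {SILENCE_LABEL: np.zeros(spec.artic_dim)}
    for phone in VOWELS + CONSONANTS:
        targets[phone] = rng.uniform(-spec.target_scale_mm, spec.target_scale_mm,
                                     spec.artic_dim)
    return targets


def _item_tokens(spec: SyntheticSpec, rng: np.random.Generator) -> tuple[str, list[str]]:
    kind = rng.choice(3, p=np.asarray(spec.item_mix) / np.sum(spec.item_mix))
    if kind == 0:
        return "vowel", [str(rng.choice(VOWELS))]
    if kind == 1:
        v = str(rng.choice(VOWELS[:3]))
        return "vcv", [v, str(rng.choice(CONSONANTS)), v]
    n = int(rng.integers(spec.sentence_len[0], spec.sentence_len[1] + 1))
    return "sentence", [str(p) for p in rng.choice(VOWELS + CONSONANTS, size=n)]


def _coloured_noise(shape, sd, rate, rng, cutoff_hz=8.0):
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    b, a = sps.butter(2, cutoff_hz / (rate / 2))
    low = sps.lfilter(b, a, white, axis=0)
    scale = low.std(axis=0, keepdims=True)
    scale[scale == 0] = 1.0
    return low / scale * sd


def _build_item(name, tokens, targets, spec, gmap, rng) -> SyntheticItem:
    durations = []
    labels = []
    lead = float(rng.uniform(*spec.edge_silence))
    tail = float(rng.uniform(*spec.edge_silence))
    labels.append(SILENCE_LABEL)
    durations.append(lead)
    for tok in tokens:
        if len(tokens) == 1:
            dur = spec.vowel_hold
        else:
            dur = float(rng.uniform(*spec.phone_duration))
        labels.append(tok)
        durations.append(dur)
    labels.append(SILENCE_LABEL)
    durations.append(tail)

    # frame-exact segment boundaries at the raw rate keep the segmentation
    # tiling the item exactly
    n_frames = [max(1, int(round(d * spec.rate_raw))) for d in durations]
    bounds = np.concatenate([[0], np.cumsum(n_frames)])
    intervals = [
        (lab, bounds[i] / spec.rate_raw, bounds[i + 1] / spec.rate_raw)
        for i, lab in enumerate(labels)
    ]
    seg = Segmentation(intervals)

    t400 = int(bounds[-1])
    path = np.empty((t400, spec.artic_dim))
    for i, lab in enumerate(labels):
        path[bounds[i]:bounds[i + 1]] = targets[lab]
    # raised-cosine smoothing of the piecewise-constant target path
    win_len = max(1, int(round(spec.transition_s * spec.rate_raw)))
    if win_len > 1:
        win = np.hanning(win_len + 2)[1:-1]
        win /= win.sum()
        pad = np.vstack([
            np.repeat(path[:1], win_len, axis=0),
            path,
            np.repeat(path[-1:], win_len, axis=0),
        ])
        path = np.column_stack([
            np.convolve(pad[:, j], win, mode="same")[win_len:win_len + t400]
            for j in range(spec.artic_dim)
        ])
    traj400 = path + _coloured_noise(path.shape, spec.traj_noise_mm, spec.rate_raw, rng)

    factor = int(round(spec.rate_raw / spec.rate))
    traj100 = _decimate(traj400, factor)

    clean_mel = gmap(stack_context(traj100, N_PAST))
    mel = clean_mel + rng.normal(0.0, spec.obs_noise_sd, size=clean_mel.shape)
    return SyntheticItem(name=name, tokens=tokens, traj400=traj400,
                         traj100=traj100, seg=seg, mel=mel, clean_mel=clean_mel)


def generate_reference_corpus(spec: SyntheticSpec | None = None) -> SyntheticCorpus:
    """Generate the reference speaker's paired articulatory-acoustic corpus."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    targets = _draw_targets(spec, rng)
    gmap = make_ground_truth_map(spec.seed + 1, d_in=(N_PAST + 1) * spec.artic_dim,
                                 n_out=spec.n_mel, input_scale=spec.target_scale_mm)
    items = []
    for i in range(spec.n_items):
        kind, tokens = _item_tokens(spec, rng)
        items.append(_build_item(f"item{i:04d}_{kind}", tokens, targets, spec, gmap, rng))
    return SyntheticCorpus(spec=spec, phone_targets=targets, items=items,
                           ground_truth=gmap)


def training_pairs(corpus: SyntheticCorpus) -> list[tuple[np.ndarray, np.ndarray]]:
    """(articulatory, mel) frame pairs per item with silence frames removed."""
    from .artic import remove_silence

    pairs = []
    for item in corpus.items:
        art, keep = remove_silence(item.traj100, item.seg, corpus.spec.rate)
        pairs.append((art, item.mel[keep]))
    return pairs


def generate_new_speaker(corpus: SyntheticCorpus, matrix: np.ndarray | None = None,
                         bias: np.ndarray | None = None, delay: int = 7,
                         noise_sd: float = 0.1, seed: int = 0):
    """Simulated calibration-session data from a new speaker.

    x_new(t) = A x_ref(t - delay) + b + eps applied per item at 100 Hz, with
    first-frame padding for the shifted-in edge.  Returns (new_items,
    ref_items, speech_masks) aligned in reference time.
    """
    spec = corpus.spec
    rng = np.random.default_rng(seed)
    d = spec.artic_dim
    if matrix is None:
        matrix = np.eye(d) + rng.normal(0.0, 0.15, size=(d, d))
    if bias is None:
        bias = rng.normal(0.0, 2.0, size=d)
    new_items, ref_items, masks = [], [], []
    for item in corpus.items:
        ref = item.traj100
        t = len(ref)
        shifted = np.empty_like(ref)
        if delay >= 0:
            shifted[delay:] = ref[:t - delay] if delay else ref
            shifted[:delay] = ref[0]
        else:
            shifted[:t + delay] = ref[-delay:]
            shifted[t + delay:] = ref[-1]
        new = shifted @ matrix.T + bias + rng.normal(0.0, noise_sd, size=ref.shape)
        centers = (np.arange(t) + 0.5) / spec.rate
        masks.append(~item.seg.silence_mask(centers))
        new_items.append(new)
        ref_items.append(ref)
    return new_items, ref_items, masks
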