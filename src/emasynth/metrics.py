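"""Intelligibility and objective evaluation metrics.

Recognition accuracy Acc = R/N over forced-choice responses, chance level
1/C for C categories, confusion matrices with automatic seriation (rows and
columns reordered to gather the large confusions near the diagonal), word
accuracy WAcc = (N - S - D - I)/N from a minimum-edit-distance alignment,
mel-cepstral distortion, and a nearest-centroid classifier standing in for
human listeners on synthetic stimuli.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np

from .vocoder import MelCepstrogram


# ---------------------------------------------------------------------------
# Accuracy and chance level
# ---------------------------------------------------------------------------


def accuracy(truth, response) -> float:
    """Fraction of exact matches, Acc = R/N."""
    truth, response = list(truth), list(response)
    if len(truth) != len(response):
        raise ValueError("truth/response length mismatch")
    if not truth:
        raise ValueError("cannot score an empty response set")
    return sum(t == r for t, r in zip(truth, response)) / len(truth)


def chance_level(n_categories: int) -> float:
    """Expected accuracy of uniform guessing over C categories, 1/C."""
    if n_categories < 1:
        raise ValueError("need at least one category")
    return 1.0 / n_categories


def simulate_uniform_guesser(labels, n_trials: int, seed: int = 0) -> float:
    """Empirical accuracy of a uniform random guesser (chance-level check)."""
    labels = list(labels)
    rng = np.random.default_rng(seed)
    truth = rng.integers(0, len(labels), n_trials)
    guess = rng.integers(0, len(labels), n_trials)
    return float(np.mean(truth == guess))


# ---------------------------------------------------------------------------
# Confusion matrices and seriation
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """Row = ground truth, column = response; proportions row-normalized."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts must be C x C")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def proportions(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(sums > 0, self.counts / sums, 0.0)
        return p

    @property
    def error_column(self) -> np.ndarray:
        """Per-row error rate, 1 - diagonal proportion."""
        return 1.0 - np.diag(self.proportions)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def permuted(self, order: np.ndarray) -> "ConfusionMatrix":
        order = np.asarray(order)
        return ConfusionMatrix(
            labels=[self.labels[i] for i in order],
            counts=self.counts[np.ix_(order, order)],
        )


def confusion_matrix(truth, response, labels) -> ConfusionMatrix:
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, r in zip(truth, response):
        if t not in index or r not in index:
            raise ValueError(f"unknown label in ({t!r}, {r!r})")
        counts[index[t], index[r]] += 1
    return ConfusionMatrix(labels=labels, counts=counts)


def _band_objective(p: np.ndarray, order: np.ndarray) -> float:
    """sum_ij p[order_i, order_j] * w(|i - j|) with decreasing w(d) = 1/(1+d)."""
    q = p[np.ix_(order, order)]
    c = len(order)
    w = 1.0 / (1.0 + np.abs(np.arange(c)[:, None] - np.arange(c)[None, :]))
    return float(np.sum(q * w))


def seriate(cm: ConfusionMatrix, exhaustive_limit: int = 8) -> ConfusionMatrix:
    """Reorder rows and columns to concentrate mass near the diagonal.

    Maximizes the band-diagonal objective sum p_ij / (1 + |i - j|) over joint
    row/column permutations: exhaustively for C <= exhaustive_limit, by
    greedy insertion plus 2-opt (pairwise swap) refinement for larger C.
    The counts themselves are only permuted, never changed.
    """
    c = len(cm.labels)
    if c < 2:
        return cm
    p = cm.proportions
    identity = np.arange(c)
    if c <= exhaustive_limit:
        best = max(itertools.permutations(range(c)),
                   key=lambda perm: _band_objective(p, np.array(perm)))
        order = np.array(best)
    else:
        # greedy insertion on symmetrized similarity, then 2-opt swaps
        sim = p + p.T
        remaining = list(range(c))
        start = int(np.argmax(sim.sum(axis=1)))
        order_list = [start]
        remaining.remove(start)
        while remaining:
            last = order_list[-1]
            nxt = max(remaining, key=lambda j: sim[last, j])
            order_list.append(nxt)
            remaining.remove(nxt)
        order = np.array(order_list)
        improved = True
        while improved:
            improved = False
            score = _band_objective(p, order)
            for i in range(c - 1):
                for j in range(i + 1, c):
                    cand = order.copy()
                    cand[i], cand[j] = cand[j], cand[i]
                    s = _band_objective(p, cand)
                    if s > score + 1e-15:
                        order, score, improved = cand, s, True
    if _band_objective(p, order) < _band_objective(p, identity):
        order = identity
    return cm.permuted(order)


# ---------------------------------------------------------------------------
# Word accuracy
# ---------------------------------------------------------------------------


def tokenize_words(text: str) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace."""
    text = re.sub(r"[^\w\s']", " ", text.lower())
    return text.split()


def word_accuracy(ref, hyp) -> tuple[float, dict]:
    """WAcc = (N - S - D - I) / N from a unit-cost minimum-edit alignment.

    ``ref``/``hyp`` may be token lists or raw strings (tokenized here).  Ties
    in the alignment are broken toward substitutions rather than
    insertion+deletion pairs.  Returns (WAcc, {"S","D","I","N"}).
    """
    if isinstance(ref, str):
        ref = tokenize_words(ref)
    if isinstance(hyp, str):
        hyp = tokenize_words(hyp)
    ref, hyp = list(ref), list(hyp)
    n, m = len(ref), len(hyp)
    if n == 0:
        raise ValueError("empty reference")
    dist = np.zeros((n + 1, m + 1), dtype=np.int64)
    dist[:, 0] = np.arange(n + 1)
    dist[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = dist[i - 1, j - 1] + (ref[i - 1] != hyp[j - 1])
            dele = dist[i - 1, j] + 1
            ins = dist[i, j - 1] + 1
            dist[i, j] = min(sub, dele, ins)
    # backtrace, preferring the diagonal (match/substitution) move on ties
    s = d = ins_count = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dist[i, j] == dist[i - 1, j - 1] + (ref[i - 1] != hyp[j - 1]):
            s += ref[i - 1] != hyp[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and dist[i, j] == dist[i - 1, j] + 1:
            d += 1
            i -= 1
        else:
            ins_count += 1
            j -= 1
    wacc = (n - s - d - ins_count) / n
    return wacc, {"S": s, "D": d, "I": ins_count, "N": n}


# ---------------------------------------------------------------------------
# Mel-cepstral distortion and the machine listener
# ---------------------------------------------------------------------------


def mel_cepstral_distortion_frames(a: np.ndarray, b: np.ndarray) -> float:
    """Frame-mean MCD in dB, (10/ln10) * sqrt(2 * sum_{m>=1} (a_m - b_m)^2).

    The zeroth coefficient (gain) is excluded, so the measure is loudness
    invariant.
    """
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    if a.shape != b.shape:
        raise ValueError("cepstrogram shape mismatch")
    diff = a[:, 1:] - b[:, 1:]
    per_frame = (10.0 / np.log(10.0)) * np.sqrt(2.0 * np.sum(diff**2, axis=1))
    return float(np.mean(per_frame))


def mel_cepstral_distortion(a: MelCepstrogram, b: MelCepstrogram) -> float:
    return mel_cepstral_distortion_frames(a.frames, b.frames)


def centroid_classify(stimuli, templates: dict) -> list[str]:
    """Nearest-class labels by MCD between mean cepstra.

    ``stimuli`` is a list of T x M cepstral matrices (steady-state frames of
    each stimulus); ``templates`` maps label -> list of T x M matrices.  Each
    class is represented by the mean frame of its templates; ties are broken
    by sorted label order.
    """
    if not templates or any(len(v) == 0 for v in templates.values()):
        raise ValueError("each class needs at least one template")
    labels = sorted(templates)
    centroids = {
        lab: np.mean(np.vstack([np.atleast_2d(t).mean(axis=0, keepdims=True)
                                for t in templates[lab]]), axis=0, keepdims=True)
        for lab in labels
    }
    out = []
    for stim in stimuli:
        mean_frame = np.atleast_2d(stim).mean(axis=0, keepdims=True)
        best = min(
            labels,
            key=lambda lab: (mel_cepstral_distortion_frames(mean_frame, centroids[lab]), lab),
        )
        out.append(best)
    return out


@dataclass
class ScoreReport:
    acc: float
    per_category: dict
    chance: float
    wacc: float | None = None
    edits: dict | None = None


def score_report(truth, response, labels, ref_words=None, hyp_words=None) -> ScoreReport:
    cm = confusion_matrix(truth, response, labels)
    acc = accuracy(truth, response)
    per_cat = {
        lab: float(cm.proportions[i, i]) if cm.counts[i].sum() else np.nan
        for i, lab in enumerate(cm.labels)
    }
    wacc = edits = None
    if ref_words is not None and hyp_words is not None:
        wacc, edits = word_accuracy(ref_words, hyp_words)
    return ScoreReport(acc=acc, per_category=per_cat,
                       chance=chance_level(len(labels)), wacc=wacc, edits=edits)
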