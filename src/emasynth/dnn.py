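"""Articulatory-to-acoustic mapping with a feed-forward DNN.

The network maps a stacked articulatory context vector (current frame plus
its 4 predecessors, z-scored) to 25 z-scored mel-cepstral coefficients
through 3 hidden layers of 200 leaky rectified linear units.  Training grows
the network one hidden layer at a time: each stage re-initializes the output
layer, keeps previously trained hidden layers, and fine-tunes everything by
Polak-Ribiere conjugate-gradient updates on 100 random blocks per epoch,
with patience-based early stopping on a validation item set.

Layer weights are initialized from a zero-mean Gaussian whose standard
deviation is 1/N, N being the previous layer's width; the error criterion is
the per-frame mean squared error over the 25 outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .artic import Normalizer, apply_normalizer, fit_normalizer, invert_normalizer, stack_context

DEFAULT_HIDDEN = 200
DEFAULT_N_OUT = 25
DEFAULT_SLOPE = 0.01
N_PAST = 4


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class DNNModel:
    """Feed-forward regression network with leaky-ReLU hidden layers."""

    weights: list[np.ndarray]  # layer l: (n_in, n_out)
    biases: list[np.ndarray]
    slope: float
    in_norm: Normalizer  # per-dim stats of the (unstacked) articulatory frames
    out_norm: Normalizer  # per-dim stats of the mel-cepstral frames
    n_past: int = N_PAST

    def __post_init__(self) -> None:
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape[1] != b.shape[0]:
                raise ValueError(f"layer {l}: weight/bias shape mismatch")
            if l > 0 and self.weights[l - 1].shape[1] != w.shape[0]:
                raise ValueError(f"layer {l}: inconsistent with previous layer")
            if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
                raise ValueError(f"layer {l}: non-finite parameters")

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    def forward(self, stacked: np.ndarray) -> np.ndarray:
        """Map stacked *z-scored* context rows to z-scored outputs."""
        stacked = np.atleast_2d(stacked)
        if stacked.shape[1] != self.weights[0].shape[0]:
            raise ValueError(
                f"input dim {stacked.shape[1]} != network input {self.weights[0].shape[0]}"
            )
        h = stacked
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = h @ w + b
            h = np.where(h > 0, h, self.slope * h)
        return h @ self.weights[-1] + self.biases[-1]

    def predict(self, frames: np.ndarray) -> np.ndarray:
        """Full mapping: raw articulatory frames -> de-normalized mel-cepstra."""
        z = apply_normalizer(self.in_norm, frames)
        out_z = self.forward(stack_context(z, self.n_past))
        return invert_normalizer(self.out_norm, out_z)

    def predict_frame(self, context: np.ndarray) -> np.ndarray:
        """Single stacked raw-context row -> one mel-cepstral frame.

        Used by the streaming path; numerically identical to `predict` on the
        corresponding row because the offline path also evaluates row-wise.
        """
        d = len(self.in_norm.mean)
        z = (context.reshape(self.n_past + 1, d) - self.in_norm.mean) / self.in_norm.sd
        out_z = self.forward(z.reshape(1, -1))
        return invert_normalizer(self.out_norm, out_z)[0]


def init_layer(n_in: int, n_out: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian(0, (1/n_in)^2) weights and zero biases."""
    if n_in < 1 or n_out < 1:
        raise ValueError("layer sizes must be positive")
    return rng.normal(0.0, 1.0 / n_in, size=(n_in, n_out)), np.zeros(n_out)


def mse_loss(predicted: np.ndarray, target: np.ndarray) -> float:
    """Mean squared error over output dimensions, sum (o_i - m_i)^2 / n_out.

    For 2-D inputs the per-frame MSE is averaged over frames.
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if predicted.shape != target.shape:
        raise ValueError("predicted/target shape mismatch")
    d = predicted.shape[-1]
    return float(np.mean(np.sum((predicted - target) ** 2, axis=-1) / d))


# ---------------------------------------------------------------------------
# Flattened-parameter plumbing for the conjugate-gradient optimizer
# ---------------------------------------------------------------------------


def _flatten(weights, biases):
    return np.concatenate([a.ravel() for a in weights + biases])


def _unflatten(theta, shapes_w, shapes_b):
    arrays, pos = [], 0
    for shp in shapes_w + shapes_b:
        n = int(np.prod(shp))
        arrays.append(theta[pos:pos + n].reshape(shp))
        pos += n
    k = len(shapes_w)
    return arrays[:k], arrays[k:]


def _loss_and_grad(theta, shapes_w, shapes_b, slope, x, y):
    """Block MSE and its gradient by backpropagation."""
    weights, biases = _unflatten(theta, shapes_w, shapes_b)
    n, d_out = y.shape
    acts = [x]
    h = x
    for w, b in zip(weights[:-1], biases[:-1]):
        pre = h @ w + b
        h = np.where(pre > 0, pre, slope * pre)
        acts.append(h)
    out = h @ weights[-1] + biases[-1]
    diff = out - y
    loss = float(np.mean(np.sum(diff**2, axis=1) / d_out))
    # d loss / d out
    delta = diff * (2.0 / (n * d_out))
    grads_w = [None] * len(weights)
    grads_b = [None] * len(biases)
    for l in range(len(weights) - 1, -1, -1):
        grads_w[l] = acts[l].T @ delta
        grads_b[l] = delta.sum(axis=0)
        if l > 0:
            delta = delta @ weights[l].T
            delta = np.where(acts[l] > 0, delta, slope * delta)
    return loss, _flatten(grads_w, grads_b)


def _cg_minimize(fun, theta0, n_line_searches=3, step0=None):
    """Short Polak-Ribiere CG run with interpolating line searches.

    Performs at most ``n_line_searches`` line searches along successive
    conjugate directions and returns the best parameters seen, so the
    objective never increases.
    """
    f0, g = fun(theta0)
    theta, f = theta0, f0
    best_theta, best_f = theta0, f0
    d = -g
    step = step0
    for _ in range(n_line_searches):
        slope = float(d @ g)
        if slope >= 0:  # not a descent direction: restart on the gradient
            d = -g
            slope = float(d @ g)
            if slope >= 0:  # zero gradient
                break
        t1 = step if step is not None else min(1.0, 1.0 / (1.0 + abs(slope)))
        f1, g1 = fun(theta + t1 * d)
        evals = [(t1, f1, g1)]
        # quadratic interpolation through f(0), f'(0), f(t1)
        denom = f1 - f - slope * t1
        if denom > 0:
            t2 = float(np.clip(-slope * t1 * t1 / (2.0 * denom), 0.1 * t1, 10.0 * t1))
        else:
            t2 = 3.0 * t1  # criterion still decreasing: extrapolate
        if not np.isclose(t2, t1):
            f2, g2 = fun(theta + t2 * d)
            evals.append((t2, f2, g2))
        # shrink while nothing improves
        shrink = 0
        while min(e[1] for e in evals) >= f and shrink < 3:
            t3 = 0.1 * min(e[0] for e in evals)
            f3, g3 = fun(theta + t3 * d)
            evals.append((t3, f3, g3))
            shrink += 1
        t_star, f_star, g_star = min(evals, key=lambda e: e[1])
        if f_star >= f:
            break  # converged (or direction useless): keep best
        theta = theta + t_star * d
        g_new = g_star
        beta = float(g_new @ (g_new - g)) / max(float(g @ g), 1e-300)
        d = -g_new + max(beta, 0.0) * d
        f, g = f_star, g_new
        step = t_star  # warm-start the next line search
        if f < best_f:
            best_theta, best_f = theta, f
    return best_theta, best_f


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    hidden: int = DEFAULT_HIDDEN
    n_hidden_layers: int = 3
    slope: float = DEFAULT_SLOPE
    train_frac: float = 0.90
    val_frac: float = 0.05
    test_frac: float = 0.05
    patience_epochs: int = 20
    blocks_per_epoch: int = 100
    line_searches: int = 3
    max_epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.patience_epochs < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainReport:
    layer_log: list[dict] = field(default_factory=list)
    train_items: list[int] = field(default_factory=list)
    val_items: list[int] = field(default_factory=list)
    test_items: list[int] = field(default_factory=list)
    final_val_mse: float = np.nan
    final_test_mse: float = np.nan


def split_items(n_items: int, cfg: TrainConfig, rng: np.random.Generator):
    """Random item-level 90/5/5 split; leftover-item ties go to validation."""
    if n_items < 3:
        raise ValueError("need at least 3 items for a train/val/test split")
    perm = rng.permutation(n_items)
    n_train = int(round(cfg.train_frac * n_items))
    n_train = min(max(n_train, 1), n_items - 2)
    rest = n_items - n_train
    n_val = int(np.ceil(rest / 2))  # ties resolved toward validation
    train = sorted(perm[:n_train].tolist())
    val = sorted(perm[n_train:n_train + n_val].tolist())
    test = sorted(perm[n_train + n_val:].tolist())
    return train, val, test


def cg_block_update(model_params, shapes_w, shapes_b, slope, block_x, block_y,
                    line_searches=3, step0=None):
    """One conjugate-gradient run on a frame block; block loss never increases."""
    if block_x.shape[0] == 0:
        raise ValueError("empty block")
    fun = lambda th: _loss_and_grad(th, shapes_w, shapes_b, slope, block_x, block_y)
    f_before, _ = fun(model_params)
    theta, f_after = _cg_minimize(fun, model_params, line_searches, step0)
    if not np.all(np.isfinite(theta)):
        raise FloatingPointError("non-finite parameters after CG update")
    assert f_after <= f_before + 1e-12, "CG block update increased the loss"
    return theta, f_after


def _epoch(theta, shapes_w, shapes_b, slope, x, y, cfg, rng):
    order = rng.permutation(x.shape[0])
    blocks = np.array_split(order, cfg.blocks_per_epoch)
    step = None
    for blk in blocks:
        if blk.size == 0:
            continue
        theta, _ = cg_block_update(theta, shapes_w, shapes_b, slope,
                                   x[blk], y[blk], cfg.line_searches, step)
    return theta


def train_layerwise(items: list[tuple[np.ndarray, np.ndarray]],
                    cfg: TrainConfig | None = None,
                    progress: bool = False) -> tuple[DNNModel, TrainReport]:
    """Train the mapping on (articulatory frames, mel frames) item pairs.

    Items are raw (not yet z-scored, not yet context-stacked) with silence
    frames already removed.  Normalization statistics are fit on the training
    items only; context stacking happens after z-scoring, per item.
    """
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    report = TrainReport()
    train_idx, val_idx, test_idx = split_items(len(items), cfg, rng)
    report.train_items, report.val_items, report.test_items = train_idx, val_idx, test_idx

    in_norm = fit_normalizer(np.vstack([items[i][0] for i in train_idx]))
    out_norm = fit_normalizer(np.vstack([items[i][1] for i in train_idx]))

    def prep(idx):
        xs = [stack_context(apply_normalizer(in_norm, items[i][0]), N_PAST) for i in idx]
        ys = [apply_normalizer(out_norm, items[i][1]) for i in idx]
        return np.vstack(xs), np.vstack(ys)

    x_tr, y_tr = prep(train_idx)
    x_val, y_val = prep(val_idx)
    x_te, y_te = prep(test_idx)
    d_in, d_out = x_tr.shape[1], y_tr.shape[1]

    hidden_w: list[np.ndarray] = []
    hidden_b: list[np.ndarray] = []
    theta = None
    for stage in range(1, cfg.n_hidden_layers + 1):
        n_prev = d_in if stage == 1 else cfg.hidden
        w_new, b_new = init_layer(n_prev, cfg.hidden, rng)
        w_out, b_out = init_layer(cfg.hidden, d_out, rng)
        weights = hidden_w + [w_new, w_out]
        biases = hidden_b + [b_new, b_out]
        shapes_w = [w.shape for w in weights]
        shapes_b = [b.shape for b in biases]
        theta = _flatten(weights, biases)

        def val_mse(th):
            w, b = _unflatten(th, shapes_w, shapes_b)
            m = DNNModel(w, b, cfg.slope, in_norm, out_norm)
            return mse_loss(m.forward(x_val), y_val)

        best_theta, best_val, best_epoch = theta.copy(), val_mse(theta), 0
        history = []
        for epoch in range(1, cfg.max_epochs + 1):
            theta = _epoch(theta, shapes_w, shapes_b, cfg.slope, x_tr, y_tr, cfg, rng)
            vm = val_mse(theta)
            history.append(vm)
            if vm < best_val:
                best_theta, best_val, best_epoch = theta.copy(), vm, epoch
            if progress:
                print(f"stage {stage} epoch {epoch}: val MSE {vm:.5f} (best {best_val:.5f})")
            if epoch - best_epoch >= cfg.patience_epochs:
                break
        theta = best_theta
        weights, biases = _unflatten(theta, shapes_w, shapes_b)
        hidden_w, hidden_b = list(weights[:-1]), list(biases[:-1])
        report.layer_log.append({
            "stage": stage,
            "epochs": len(history),
            "best_epoch": best_epoch,
            "best_val_mse": best_val,
            "val_history": history,
        })

    model = DNNModel(list(weights), list(biases), cfg.slope, in_norm, out_norm)
    report.final_val_mse = mse_loss(model.forward(x_val), y_val)
    report.final_test_mse = mse_loss(model.forward(x_te), y_te)
    return model, report


def evaluate_mapping(model: DNNModel, pairs: list[tuple[np.ndarray, np.ndarray]]) -> dict:
    """Frame-averaged z-scored MSE and mel-cepstral distortion on held-out pairs."""
    from .metrics import mel_cepstral_distortion_frames

    if not pairs:
        raise ValueError("no evaluation pairs")
    mses, mcds, n_frames = [], [], 0
    for art, mel in pairs:
        pred = model.predict(art)
        pred_z = apply_normalizer(model.out_norm, pred)
        mel_z = apply_normalizer(model.out_norm, mel)
        t = mel.shape[0]
        mses.append(mse_loss(pred_z, mel_z) * t)
        mcds.append(mel_cepstral_distortion_frames(pred, mel) * t)
        n_frames += t
    return {"mse": sum(mses) / n_frames, "mcd_db": sum(mcds) / n_frames}
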