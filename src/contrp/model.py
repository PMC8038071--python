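"""Three-branch multimodal CNN over (FGSR, HGSR, HR) Cont-RP images.

Each branch is a VGG-style stack of five convolution blocks — (2,2,3,3,3)
convolution layers of 3x3 kernels at stride 1 with ReLU, each block closed by
2x2 stride-2 max pooling — followed by a global max pool that yields one
feature vector of length ``block_filters[-1]`` (256 by default) regardless of
the input side.  The three branch vectors are concatenated into a 768-dim
representation and a single dense sigmoid unit outputs P(stressed); P(relaxed)
is its complement.

The network is implemented directly in numpy: im2col convolutions, explicit
reverse-mode gradients, and plain SGD.  Gradients are validated against
central finite differences in the test suite.  Arithmetic runs in float32 by
default (float64 available via ``dtype`` for gradient checking).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ArchConfig:
    block_filters: tuple[int, ...] = (32, 64, 128, 256, 256)
    convs_per_block: tuple[int, ...] = (2, 2, 3, 3, 3)
    kernel: int = 3
    pool: int = 2

    def __post_init__(self) -> None:
        if len(self.block_filters) != len(self.convs_per_block):
            raise ConfigError("block_filters and convs_per_block must have equal length")
        if any(f < 1 for f in self.block_filters) or any(c < 1 for c in self.convs_per_block):
            raise ConfigError("filter counts and convs per block must be positive")
        if self.kernel % 2 == 0:
            raise ConfigError("kernel must be odd (same padding)")

    @property
    def branch_feature_dim(self) -> int:
        return self.block_filters[-1]

    @property
    def concat_dim(self) -> int:
        return 3 * self.branch_feature_dim


#: scaled-down filter widths for CPU-budget experiments
SMALL_FILTERS = (8, 16, 32, 64, 64)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 4
    epochs: int = 15
    seed: int = 0
    momentum: float = 0.0  # plain SGD by default
    #: refit the scalar head bias to BCE-optimality on the training set after
    #: the SGD epochs (train-data only; no effect on ranking/AUC).  Off by
    #: default; used by short schedules where SGD ranks the samples long
    #: before the sigmoid offset settles.
    calibrate_bias: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ConfigError("epochs must be >= 0")
        if not (0 <= self.momentum < 1):
            raise ConfigError("momentum must lie in [0, 1)")


@dataclass
class SampleTriple:
    """One classifier sample: the three modality Cont-RP images plus label."""

    rp_fgsr: np.ndarray
    rp_hgsr: np.ndarray
    rp_hr: np.ndarray
    label: int
    recording_id: str
    start_s: float = 0.0

    def __post_init__(self) -> None:
        sides = {im.shape for im in (self.rp_fgsr, self.rp_hgsr, self.rp_hr)}
        if len(sides) != 1:
            raise DataError(f"modality images must share one side, got {sides}")
        if self.label not in (0, 1):
            raise DataError(f"label must be 0 (relaxed) or 1 (stressed), got {self.label}")


MODALITIES = ("rp_fgsr", "rp_hgsr", "rp_hr")

# ---------------------------------------------------------------------------
# layers (forward + reverse-mode gradients)


def _im2col(x, k):
    """Patch matrix (B, Cin*k*k, H*Wd) in channels-first layout.

    Built from k*k shifted slice copies of the padded input; every copy writes
    a contiguous (H, Wd) plane, which keeps the gather memory-bound rather
    than stride-bound.
    """
    B, Cin, H, Wd = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = np.empty((B, Cin, k, k, H, Wd), dtype=x.dtype)
    for ki in range(k):
        for kj in range(k):
            cols[:, :, ki, kj] = xp[:, :, ki:ki + H, kj:kj + Wd]
    return cols.reshape(B, Cin * k * k, H * Wd)


def _conv_forward(x, W, b, k):
    """Same-padding stride-1 convolution. x: (B,Cin,H,Wd); W: (Cout,Cin,k,k)."""
    B, Cin, H, Wd = x.shape
    Cout = W.shape[0]
    cols = _im2col(x, k)
    y = np.matmul(W.reshape(Cout, -1)[None], cols).reshape(B, Cout, H, Wd)
    return y + b[:, None, None], cols


def _conv_backward(dy, cols, x_shape, W, k):
    B, Cin, H, Wd = x_shape
    Cout = W.shape[0]
    p = k // 2
    dyf = dy.reshape(B, Cout, H * Wd)
    dW = np.matmul(dyf, cols.transpose(0, 2, 1)).sum(axis=0).reshape(W.shape)
    db = dy.sum(axis=(0, 2, 3))
    dcols = np.matmul(W.reshape(Cout, -1).T[None], dyf).reshape(B, Cin, k, k, H, Wd)
    dxp = np.zeros((B, Cin, H + 2 * p, Wd + 2 * p), dtype=dy.dtype)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki:ki + H, kj:kj + Wd] += dcols[:, :, ki, kj]
    return dxp[:, :, p:p + H, p:p + Wd], dW, db


def _pool_forward(x, s):
    """s x s max pooling at stride s; trailing rows/cols beyond a multiple of s drop."""
    B, C, H, Wd = x.shape
    H2, W2 = H // s, Wd // s
    xt = x[:, :, :H2 * s, :W2 * s].reshape(B, C, H2, s, W2, s)
    y = xt.max(axis=(3, 5))
    return y, xt


def _pool_backward(dy, xt, y, x_shape, s):
    B, C, H, Wd = x_shape
    H2, W2 = y.shape[2], y.shape[3]
    mask = xt == y[:, :, :, None, :, None]
    counts = mask.sum(axis=(3, 5), keepdims=True, dtype=dy.dtype)
    dxt = mask * (dy[:, :, :, None, :, None] / counts)
    dx = np.zeros(x_shape, dtype=dy.dtype)
    dx[:, :, :H2 * s, :W2 * s] = dxt.reshape(B, C, H2 * s, W2 * s)
    return dx


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# model


class MultimodalCNN:
    """Weight-independent FGSR/HGSR/HR branches, concatenation, sigmoid head."""

    def __init__(self, arch: ArchConfig = ArchConfig(), seed: int = 0,
                 dtype=np.float32) -> None:
        self.arch = arch
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.branches = {name: self._init_branch(rng) for name in MODALITIES}
        # zero-initialized readout: the initial output is exactly 0.5 and the
        # first gradient steps fit a logistic regression on the branch features
        self.head_w = np.zeros(arch.concat_dim, dtype=dtype)
        self.head_b = np.zeros((), dtype=dtype)

    def _init_branch(self, rng):
        k = self.arch.kernel
        layers = []
        cin = 1
        for cout, n_convs in zip(self.arch.block_filters, self.arch.convs_per_block):
            block = []
            for _ in range(n_convs):
                fan_in = k * k * cin
                W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                               size=(cout, cin, k, k)).astype(self.dtype)
                b = np.zeros(cout, dtype=self.dtype)
                block.append({"W": W, "b": b})
                cin = cout
            layers.append(block)
        return layers

    # -- introspection ------------------------------------------------------

    def num_params(self) -> int:
        n = 0
        for branch in self.branches.values():
            for block in branch:
                for layer in block:
                    n += layer["W"].size + layer["b"].size
        return n + self.head_w.size + 1

    def parameters(self):
        for branch in self.branches.values():
            for block in branch:
                for layer in block:
                    yield layer, "W"
                    yield layer, "b"
        yield self, "head_w"
        yield self, "head_b"

    # -- forward / backward -------------------------------------------------

    def _forward_branch(self, x, params, train):
        k, s = self.arch.kernel, self.arch.pool
        caches = []
        for block in params:
            for layer in block:
                y, _ = _conv_forward(x, layer["W"], layer["b"], k)
                relu_mask = y > 0
                y *= relu_mask
                # cache the layer input, not the patch matrix: ~9x less live
                # memory, and the backward pass rebuilds patches into warm,
                # recycled buffers instead of freshly faulted pages
                caches.append(("conv", layer, x if train else None,
                               x.shape, relu_mask if train else None))
                x = y
            y, xt = _pool_forward(x, s)
            caches.append(("pool", None, xt if train else None, x.shape, y))
            x = y
        feat = x.max(axis=(2, 3))  # global max pool -> (B, F)
        caches.append(("gmax", None, x if train else None, x.shape, feat))
        return feat, caches

    def _backward_branch(self, dfeat, caches):
        grads = []
        kind, _, x, x_shape, feat = caches[-1]
        mask = x == feat[:, :, None, None]
        counts = mask.sum(axis=(2, 3), keepdims=True, dtype=dfeat.dtype)
        dx = mask * (dfeat[:, :, None, None] / counts)
        k, s = self.arch.kernel, self.arch.pool
        for entry in reversed(caches[:-1]):
            kind, layer, cache, x_shape, aux = entry
            if kind == "pool":
                dx = _pool_backward(dx, cache, aux, x_shape, s)
            else:
                dx = dx * aux  # ReLU gate
                cols = _im2col(cache, k)
                dx, dW, db = _conv_backward(dx, cols, x_shape, layer["W"], k)
                grads.append((layer, dW, db))
        return grads

    def _stack_batch(self, samples):
        sides = {s.rp_fgsr.shape for s in samples}
        if len(sides) != 1:
            raise DataError(f"mismatched image sides within batch: {sides}")
        xs = {}
        for mod in MODALITIES:
            arr = np.stack([getattr(s, mod) for s in samples]).astype(self.dtype)
            xs[mod] = arr[:, None]  # (B, 1, H, W)
        return xs

    def _forward(self, samples, train=False):
        xs = self._stack_batch(samples)
        feats, caches = {}, {}
        for mod in MODALITIES:
            feats[mod], caches[mod] = self._forward_branch(xs[mod], self.branches[mod], train)
        reps = np.concatenate([feats[m] for m in MODALITIES], axis=1)
        z = reps @ self.head_w + self.head_b
        p = _sigmoid(z)
        return p, reps, caches

    # -- public API ---------------------------------------------------------

    def extract_representation(self, samples: list[SampleTriple]) -> np.ndarray:
        """Pre-head 768-dim vectors; columns [0:F) FGSR, [F:2F) HGSR, [2F:3F) HR."""
        _, reps, _ = self._forward(samples, train=False)
        return reps

    def predict_proba(self, samples: list[SampleTriple], batch_size: int = 16) -> np.ndarray:
        out = []
        for i in range(0, len(samples), batch_size):
            p, _, _ = self._forward(samples[i:i + batch_size], train=False)
            out.append(p)
        return np.concatenate(out)

    def calibrate_head_bias(self, samples: list[SampleTriple],
                            batch_size: int = 16) -> None:
        """Refit the head bias on the given (training) samples only.

        Candidate biases are the decision thresholds between consecutive
        sorted logits plus the bias-only BCE optimum (convex 1-D Newton);
        the candidate with the highest training accuracy wins, ties broken
        by lower cross-entropy (so with uninformative features the result is
        exactly the BCE optimum, the log-odds of the base rate).  Every logit
        shifts by one constant: ordering and AUC are untouched.
        """
        y = np.array([s.label for s in samples], dtype=np.float64)
        reps = np.concatenate([self._forward(samples[i:i + batch_size])[1]
                               for i in range(0, len(samples), batch_size)])
        z = (reps @ self.head_w).astype(np.float64)  # logits minus bias
        b = float(self.head_b)
        for _ in range(100):  # Newton on the convex bias-only BCE
            p = 1.0 / (1.0 + np.exp(-(z + b)))
            g = float((p - y).mean())
            h = float((p * (1.0 - p)).mean())
            if h < 1e-12 or abs(g) < 1e-10:
                break
            b -= float(np.clip(g / h, -10.0, 10.0))
        zs = np.unique(z)
        candidates = [b, float(-(zs[0] - 1.0)), float(-(zs[-1] + 1.0))]
        candidates += [float(-m) for m in (zs[:-1] + zs[1:]) / 2.0]
        best = None
        for cand in candidates:
            p = 1.0 / (1.0 + np.exp(-(z + cand)))
            acc = float(((p >= 0.5).astype(int) == y).mean())
            pc = np.clip(p, 1e-12, 1 - 1e-12)
            bce = float(-(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean())
            key = (-acc, bce)
            if best is None or key < best[0]:
                best = (key, cand)
        self.head_b = np.asarray(best[1], dtype=self.dtype)

    def predict(self, samples: list[SampleTriple], batch_size: int = 16):
        """Probabilities plus hard labels; p >= 0.5 classifies as stressed."""
        p = self.predict_proba(samples, batch_size)
        return p, (p >= 0.5).astype(int)

    def train(self, samples: list[SampleTriple], cfg: TrainConfig = TrainConfig()) -> list[float]:
        """SGD with binary cross-entropy; returns the per-epoch mean loss trace."""
        labels = np.array([s.label for s in samples])
        if len(set(labels.tolist())) < 2:
            raise DataError("training requires both classes present")
        rng = np.random.default_rng(cfg.seed)
        lr = self.dtype(cfg.learning_rate)
        mu = self.dtype(cfg.momentum)
        velocity: dict = {}

        def step(key, param, grad):
            if mu > 0:
                v = velocity.get(key)
                v = mu * v - lr * grad if v is not None else -lr * grad
                velocity[key] = v
                param += v
            else:
                param -= lr * grad

        trace = []
        for _ in range(cfg.epochs):
            order = rng.permutation(len(samples))
            losses = []
            for i in range(0, len(order), cfg.batch_size):
                batch = [samples[j] for j in order[i:i + cfg.batch_size]]
                y = np.array([s.label for s in batch], dtype=self.dtype)
                p, reps, caches = self._forward(batch, train=True)
                eps = 1e-7
                pc = np.clip(p, eps, 1 - eps)
                loss = -(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean()
                losses.append(float(loss))
                # backward
                B = len(batch)
                dz = ((p - y) / B).astype(self.dtype)
                dreps = np.outer(dz, self.head_w)
                F = self.arch.branch_feature_dim
                for mi, mod in enumerate(MODALITIES):
                    dfeat = dreps[:, mi * F:(mi + 1) * F]
                    for li, (layer, dW, dB) in enumerate(
                            self._backward_branch(dfeat, caches[mod])):
                        step((mod, li, "W"), layer["W"], dW)
                        step((mod, li, "b"), layer["b"], dB)
                step(("head", "w"), self.head_w, reps.T @ dz)
                step(("head", "b"), self.head_b, dz.sum())
            trace.append(float(np.mean(losses)))
        if cfg.calibrate_bias:
            self.calibrate_head_bias(samples)
        return trace


def build_model(arch: ArchConfig = ArchConfig(), seed: int = 0,
                dtype=np.float32) -> MultimodalCNN:
    """Construct the three-branch model with seeded weight initialization."""
    return MultimodalCNN(arch, seed=seed, dtype=dtype)


def save_checkpoint(model: MultimodalCNN, path) -> None:
    """Persist weights plus the architecture to one npz archive."""
    import json

    arrays = {"arch_json": np.array(json.dumps({
        "block_filters": list(model.arch.block_filters),
        "convs_per_block": list(model.arch.convs_per_block),
        "kernel": model.arch.kernel, "pool": model.arch.pool}))}
    for mod in MODALITIES:
        for bi, block in enumerate(model.branches[mod]):
            for li, layer in enumerate(block):
                arrays[f"{mod}_b{bi}_l{li}_W"] = layer["W"]
                arrays[f"{mod}_b{bi}_l{li}_b"] = layer["b"]
    arrays["head_w"] = model.head_w
    arrays["head_b"] = np.asarray(model.head_b)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path) -> MultimodalCNN:
    import json

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["arch_json"]))
        arch = ArchConfig(tuple(meta["block_filters"]), tuple(meta["convs_per_block"]),
                          meta["kernel"], meta["pool"])
        model = MultimodalCNN(arch, seed=0)
        for mod in MODALITIES:
            for bi, block in enumerate(model.branches[mod]):
                for li, layer in enumerate(block):
                    layer["W"] = z[f"{mod}_b{bi}_l{li}_W"]
                    layer["b"] = z[f"{mod}_b{bi}_l{li}_b"]
        model.head_w = z["head_w"]
        model.head_b = z["head_b"][()]
    return model
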