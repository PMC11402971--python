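"""Minimal feed-forward neural-network kernels (numpy, float32).

Implements exactly the layer types the viability models need — linear maps,
ReLU, batch normalization with running statistics, inverted dropout, and
feature-wise affine modulation — together with analytic backpropagation to
both parameters and inputs.  Input gradients are needed downstream for
integrated-gradients attribution, so every layer supports a backward pass in
inference mode as well as in training mode.

Shapes follow the (batch, features) convention throughout.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base class: a differentiable map with optional parameters."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 w_scale: float | None = None, bias_init: np.ndarray | None = None):
        # fan-in scaled (He) init unless an explicit scale is requested
        scale = w_scale if w_scale is not None else float(np.sqrt(2.0 / n_in))
        self.W = rng.normal(0.0, scale, size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        if bias_init is not None:
            self.b = np.asarray(bias_init, dtype=DTYPE).copy()
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, gout):
        self.dW[...] = self._x.T @ gout
        self.db[...] = gout.sum(axis=0)
        return gout @ self.W.T


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gout):
        return np.where(self._mask, gout, 0.0)


class BatchNorm(Layer):
    """Batch normalization; inference uses stored running statistics, so
    predictions are deterministic once training stops."""

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n, dtype=DTYPE)
        self.beta = np.zeros(n, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n, dtype=DTYPE)
        self.running_var = np.ones(n, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._training = True

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, training):
        self._training = training
        if training and x.shape[0] > 1:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            self._training = False
            mu = self.running_mean
            var = self.running_var
        self._istd = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        self._xhat = ((x - mu) * self._istd).astype(DTYPE)
        return self.gamma * self._xhat + self.beta

    def backward(self, gout):
        self.dgamma[...] = (gout * self._xhat).sum(axis=0)
        self.dbeta[...] = gout.sum(axis=0)
        if not self._training:
            return gout * self.gamma * self._istd
        n = gout.shape[0]
        gxhat = gout * self.gamma
        return (self._istd / n) * (n * gxhat - gxhat.sum(axis=0)
                                   - self._xhat * (gxhat * self._xhat).sum(axis=0))


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = float(rate)
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, gout):
        if self._mask is None:
            return gout
        return gout * self._mask


class DiagonalGate(Layer):
    """Elementwise multiplicative gate ``x -> g * x`` (initialised at 1).

    With proximal L1 shrinkage during optimisation the gate performs input
    feature selection: genes whose gate reaches exactly 0 are dropped from
    the model, concentrating both capacity and input gradients on the
    genes the network actually uses.
    """

    def __init__(self, n: int):
        self.g = np.ones(n, dtype=DTYPE)
        self.dg = np.zeros_like(self.g)

    def params(self):
        return [self.g]

    def grads(self):
        return [self.dg]

    def forward(self, x, training):
        self._x = x
        return x * self.g

    def backward(self, gout):
        self.dg[...] = (gout * self._x).sum(axis=0)
        return gout * self.g


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x, training):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, gout):
        for l in reversed(self.layers):
            gout = l.backward(gout)
        return gout


def linear_block(n_in: int, n_out: int, dropout: float,
                 rng: np.random.Generator) -> Sequential:
    """Linear -> ReLU -> BatchNorm -> Dropout, the repeating encoder unit."""
    return Sequential([Linear(n_in, n_out, rng), ReLU(),
                       BatchNorm(n_out), Dropout(dropout, rng)])


class Adam:
    """Adam with decoupled (AdamW-style) weight decay."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params, self.grad_refs = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, self.grad_refs, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            upd = lr_t * m / (np.sqrt(v) + self.eps)
            if self.weight_decay and p.ndim > 1:  # decay weight matrices only
                upd = upd + self.lr * self.weight_decay * p
            p -= upd.astype(p.dtype)


def film_modulate(hidden: np.ndarray, gamma: np.ndarray,
                  beta: np.ndarray) -> np.ndarray:
    """Feature-wise linear modulation: ``gamma * hidden + beta`` elementwise.

    ``hidden``, ``gamma`` and ``beta`` must share their trailing dimension.
    """
    hidden = np.asarray(hidden)
    gamma = np.asarray(gamma)
    beta = np.asarray(beta)
    if hidden.shape[-1] != gamma.shape[-1] or hidden.shape[-1] != beta.shape[-1]:
        raise ValueError(
            f"FiLM shape mismatch: hidden {hidden.shape[-1]}, "
            f"gamma {gamma.shape[-1]}, beta {beta.shape[-1]}")
    return gamma * hidden + beta


class FiLMNetwork:
    """Gene-expression encoder modulated per FiLM layer by parameters
    generated from a compound embedding.

    variant:
      * ``film``  — generator emits both scale (gamma) and shift (beta);
      * ``scale`` — beta clamped to 0, only gamma learned;
      * ``shift`` — gamma clamped to 1, only beta learned.
    The generator's final layer starts at gamma ~ 1, beta ~ 0 so the
    untrained network is approximately unconditioned.
    """

    def __init__(self, n_genes: int, n_compound: int, gene_widths, comp_widths,
                 embedding_dim: int, n_film_layers: int, dropout: float,
                 variant: str, rng: np.random.Generator,
                 gene_gate: bool = False):
        if variant not in ("film", "scale", "shift"):
            raise ValueError(f"unknown FiLM variant {variant!r}")
        self.variant = variant
        self.g = int(embedding_dim)
        self.n_film_layers = int(n_film_layers)
        if self.n_film_layers < 1:
            raise ValueError("conditioning variants need n_film_layers >= 1")

        blocks = []
        self.gate = DiagonalGate(n_genes) if gene_gate else None
        if self.gate is not None:
            blocks.append(self.gate)
        prev = n_genes
        for w in gene_widths:
            blocks.append(linear_block(prev, w, dropout, rng))
            prev = w
        blocks.append(Sequential([Linear(prev, self.g, rng), ReLU()]))
        self.gene_encoder = Sequential(blocks)

        cblocks = []
        prev = n_compound
        for w in comp_widths:
            cblocks.append(linear_block(prev, w, dropout, rng))
            prev = w
        self.c = prev if comp_widths else n_compound
        self.comp_encoder = Sequential(cblocks)

        self.generators: list[Linear] = []
        self.post_blocks: list[Sequential] = []
        n_out_gen = self.g if variant in ("scale", "shift") else 2 * self.g
        for _ in range(self.n_film_layers):
            bias = np.zeros(n_out_gen, dtype=DTYPE)
            if variant in ("film", "scale"):
                bias[: self.g] = 1.0  # gamma head starts at identity
            gen = Linear(self.c, n_out_gen, rng, w_scale=1e-3, bias_init=bias)
            self.generators.append(gen)
            self.post_blocks.append(linear_block(self.g, self.g, dropout, rng))
        self.head = Linear(self.g, 1, rng)

    # -- parameter plumbing ------------------------------------------------
    def _modules(self):
        return ([self.gene_encoder, self.comp_encoder]
                + self.generators + self.post_blocks + [self.head])

    def params(self):
        return [p for m in self._modules() for p in m.params()]

    def grads(self):
        return [g for m in self._modules() for g in m.grads()]

    def conditioning_params(self, comp: np.ndarray):
        """(gamma, beta) emitted for each FiLM layer, inference mode."""
        e = self.comp_encoder.forward(np.asarray(comp, dtype=DTYPE), False)
        out = []
        for gen in self.generators:
            raw = gen.forward(e, False)
            if self.variant == "scale":
                gamma, beta = raw, np.zeros_like(raw)
            elif self.variant == "shift":
                gamma, beta = np.ones_like(raw), raw
            else:
                gamma, beta = raw[:, : self.g], raw[:, self.g:]
            out.append((gamma, beta))
        return out

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, n: np.ndarray, training: bool) -> np.ndarray:
        h = self.gene_encoder.forward(x, training)
        e = self.comp_encoder.forward(n, training)
        self._film_cache = []
        for gen, post in zip(self.generators, self.post_blocks):
            raw = gen.forward(e, training)
            if self.variant == "scale":
                gamma, beta = raw, None
            elif self.variant == "shift":
                gamma, beta = None, raw
            else:
                gamma, beta = raw[:, : self.g], raw[:, self.g:]
            self._film_cache.append((h, gamma))
            if self.variant == "shift":
                h = h + beta
            elif self.variant == "scale":
                h = gamma * h
            else:
                h = gamma * h + beta
            h = post.forward(h, training)
        return self.head.forward(h, training)

    def backward(self, gout: np.ndarray):
        """Returns (d/d x, d/d n) of the scalar objective whose upstream
        gradient w.r.t. the network output is ``gout``."""
        g = self.head.backward(gout)
        de_total = None
        for gen, post, (h_in, gamma) in zip(reversed(self.generators),
                                            reversed(self.post_blocks),
                                            reversed(self._film_cache)):
            g = post.backward(g)
            if self.variant == "shift":
                draw = g
                dh = g
            elif self.variant == "scale":
                draw = g * h_in
                dh = g * gamma
            else:
                draw = np.concatenate([g * h_in, g], axis=1)
                dh = g * gamma
            de = gen.backward(draw)
            de_total = de if de_total is None else de_total + de
            g = dh
        dx = self.gene_encoder.backward(g)
        dn = self.comp_encoder.backward(de_total)
        return dx, dn


class ConcatNetwork:
    """Plain multilayer perceptron on the concatenated [expression, compound]
    vector — the unconditioned baseline."""

    def __init__(self, n_genes: int, n_compound: int, widths, dropout: float,
                 rng: np.random.Generator):
        self.n_genes = n_genes
        blocks = []
        prev = n_genes + n_compound
        for w in widths:
            blocks.append(linear_block(prev, w, dropout, rng))
            prev = w
        self.net = Sequential(blocks + [Sequential([Linear(prev, 1, rng)])])

    def params(self):
        return self.net.params()

    def grads(self):
        return self.net.grads()

    def forward(self, x, n, training):
        return self.net.forward(np.concatenate([x, n], axis=1), training)

    def backward(self, gout):
        g = self.net.backward(gout)
        return g[:, : self.n_genes], g[:, self.n_genes:]


def count_params(net) -> int:
    return int(sum(p.size for p in net.params()))


def get_weights(net) -> list[np.ndarray]:
    return [p.copy() for p in net.params()]


def set_weights(net, weights: list[np.ndarray]) -> None:
    for p, w in zip(net.params(), weights):
        p[...] = w


def get_bn_state(net) -> list[tuple[np.ndarray, np.ndarray]]:
    out = []
    for bn in _iter_batchnorms(net):
        out.append((bn.running_mean.copy(), bn.running_var.copy()))
    return out


def set_bn_state(net, state) -> None:
    for bn, (m, v) in zip(_iter_batchnorms(net), state):
        bn.running_mean[...] = m
        bn.running_var[...] = v


def _iter_batchnorms(obj):
    if isinstance(obj, BatchNorm):
        yield obj
    elif isinstance(obj, Sequential):
        for l in obj.layers:
            yield from _iter_batchnorms(l)
    elif isinstance(obj, (FiLMNetwork,)):
        for m in obj._modules():
            yield from _iter_batchnorms(m)
    elif isinstance(obj, ConcatNetwork):
        yield from _iter_batchnorms(obj.net)
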