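"""Conditional viability regression.

The core estimator predicts cellular viability ``y = f(x | n)`` from a
standardized expression vector ``x`` conditioned on a compound feature
vector ``n`` (fingerprint bits + concentration).  Conditioning is by
feature-wise linear modulation (FiLM): a generator network maps the compound
embedding to per-feature scale (gamma) and shift (beta) parameters that
affinely transform the expression embedding, repeated across FiLM layers.

Variants
--------
``film``          full conditioning (gamma and beta learned)
``scale``         beta held at 0
``shift``         gamma held at 1
``concatenation`` unconditioned MLP on [x, n], widened to a comparable
                  trainable-parameter count
``straw``         structural ablation: each compound's fingerprint replaced
                  by a fixed random binary code (concentration kept real)

Everything follows the scikit-learn estimator contract: ``fit(X, y)``,
``predict(X)``, ``get_params``/``set_params``, fitted attributes with a
trailing underscore.  ``X`` holds the expression block first and the
compound block (``n_compound_features`` columns) last.
"""

from __future__ import annotations

import hashlib
import io
import json

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.utils.validation import check_is_fitted

from . import _nn
from ._nn import film_modulate  # re-exported  # noqa: F401
from .featurization import make_cv_splits

VARIANTS = ("film", "scale", "shift", "concatenation", "straw")

__all__ = ["ViabilityRegressor", "ViabilityEnsemble", "film_modulate",
           "evaluate_r2", "cross_validate_ensemble", "save_model",
           "load_model", "matched_concat_widths"]


def matched_concat_widths(n_in: int, target_params: int,
                          ratios=(4, 2, 1), tol: float = 0.10) -> list[int]:
    """Hidden widths for the concatenation baseline so its trainable
    parameter count matches ``target_params`` within ``tol`` (10%)."""

    def n_params(u):
        widths = [max(1, int(round(r * u))) for r in ratios]
        total, prev = 0, n_in
        for w in widths:
            total += prev * w + w + 2 * w  # linear + batchnorm affine
            prev = w
        total += prev + 1  # head
        return widths, total

    lo, hi = 1, 1
    while n_params(hi)[1] < target_params:
        hi *= 2
    best_w, best_err = None, np.inf
    for u in range(max(1, lo), hi + 1):
        widths, total = n_params(u)
        err = abs(total - target_params) / target_params
        if err < best_err:
            best_w, best_err = widths, err
        if total > target_params * (1 + tol):
            break
    if best_err > tol:
        raise ValueError(
            f"cannot match parameter count within {tol:.0%} (best {best_err:.1%})")
    return best_w


class ViabilityRegressor(BaseEstimator, RegressorMixin):
    """FiLM-conditioned neural viability regressor (numpy backend).

    Parameters largely mirror the published architecture: expression encoder
    hidden widths, compound encoder hidden widths, a shared embedding width
    onto which both project, and ``n_film_layers`` modulation layers, trained
    by mean-squared error with Adam and early stopping on a held-out
    validation split (grouped by cell line when ``groups`` is passed to
    ``fit``).
    """

    def __init__(self, variant: str = "film",
                 gene_encoder_widths=(2048, 512, 256),
                 compound_encoder_widths=(256, 128),
                 embedding_dim: int = 128,
                 n_film_layers: int = 2,
                 dropout: float = 0.1,
                 n_compound_features: int = 513,
                 lr: float = 1e-3,
                 weight_decay: float = 0.0,
                 l1_gene_layer: float = 0.0,
                 gene_gate: bool = False,
                 l1_gene_gate: float = 0.0,
                 batch_size: int = 256,
                 max_epochs: int = 100,
                 patience: int = 10,
                 validation_fraction: float = 0.1,
                 max_grad_norm: float = 5.0,
                 random_state: int = 0):
        self.variant = variant
        self.gene_encoder_widths = gene_encoder_widths
        self.compound_encoder_widths = compound_encoder_widths
        self.embedding_dim = embedding_dim
        self.n_film_layers = n_film_layers
        self.dropout = dropout
        self.n_compound_features = n_compound_features
        self.lr = lr
        self.weight_decay = weight_decay
        self.l1_gene_layer = l1_gene_layer
        self.gene_gate = gene_gate
        self.l1_gene_gate = l1_gene_gate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.max_grad_norm = max_grad_norm
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _split_blocks(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-D [n_samples, n_genes + n_compound]")
        if hasattr(self, "n_genes_") and X.shape[1] != self.n_genes_ + self.n_compound_features:
            raise ValueError(
                f"X has {X.shape[1]} columns, expected "
                f"{self.n_genes_ + self.n_compound_features}")
        nc = self.n_compound_features
        return X[:, :-nc], X[:, -nc:]

    def _straw_codes(self, comp):
        """Replace fingerprint bits with a fixed random code per distinct
        bit pattern (i.e. per compound); the concentration column is kept."""
        bits = comp[:, :-1]
        out = bits.copy()
        patterns = {}
        for i in range(bits.shape[0]):
            key = bits[i].astype(np.int8).tobytes()
            if key not in patterns:
                digest = hashlib.blake2b(
                    f"straw:{self.random_state}:".encode() + key,
                    digest_size=8).digest()
                rng = np.random.default_rng(int.from_bytes(digest, "little"))
                patterns[key] = (rng.random(bits.shape[1]) < 0.5).astype(np.float64)
            out[i] = patterns[key]
        return np.concatenate([out, comp[:, -1:]], axis=1)

    def _prepare_comp(self, comp):
        return self._straw_codes(comp) if self.variant == "straw" else comp

    def _build_network(self, n_genes, rng):
        nc = self.n_compound_features
        gw = list(self.gene_encoder_widths)
        cw = list(self.compound_encoder_widths)
        if self.variant in ("film", "scale", "shift", "straw"):
            film_variant = "film" if self.variant == "straw" else self.variant
            return _nn.FiLMNetwork(
                n_genes, nc, gw, cw, self.embedding_dim,
                self.n_film_layers, self.dropout, film_variant, rng,
                gene_gate=self.gene_gate)
        if self.variant == "concatenation":
            ref = _nn.FiLMNetwork(
                n_genes, nc, gw, cw, self.embedding_dim,
                self.n_film_layers, self.dropout, "film",
                np.random.default_rng(0))
            widths = matched_concat_widths(n_genes + nc, _nn.count_params(ref))
            return _nn.ConcatNetwork(n_genes, nc, widths, self.dropout, rng)
        raise ValueError(f"unknown variant {self.variant!r}; "
                         f"choose from {VARIANTS}")

    @staticmethod
    def _first_gene_layer(net):
        if isinstance(net, _nn.FiLMNetwork):
            i = 1 if net.gate is not None else 0
            block = net.gene_encoder.layers[i]
        else:
            block = net.net.layers[0]
        return block.layers[0]

    def _validation_split(self, n, groups, rng):
        idx = np.arange(n)
        if groups is not None:
            groups = np.asarray(groups)
            uniq = np.array(sorted(set(groups.tolist())), dtype=object)
            n_val = max(1, int(round(self.validation_fraction * len(uniq))))
            if len(uniq) - n_val < 1:
                raise ValueError("not enough groups for a validation split")
            val_groups = set(rng.permutation(uniq)[:n_val].tolist())
            mask = np.array([g in val_groups for g in groups])
            return idx[~mask], idx[mask]
        n_val = max(1, int(round(self.validation_fraction * n)))
        perm = rng.permutation(n)
        return perm[n_val:], perm[:n_val]

    # ------------------------------------------------------------------
    def fit(self, X, y, groups=None):
        expr, comp = self._split_blocks(X)
        y = np.asarray(y, dtype=np.float64).ravel()
        if expr.shape[0] == 0:
            raise ValueError("empty training set")
        if expr.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        self.n_genes_ = expr.shape[1]
        self.n_features_in_ = X.shape[1]
        comp = self._prepare_comp(comp)

        rng = np.random.default_rng(self.random_state)
        net = self._build_network(self.n_genes_, rng)
        opt = _nn.Adam(net.params(), net.grads(), lr=self.lr,
                       weight_decay=self.weight_decay)

        tr, va = self._validation_split(len(y), groups, rng)
        Xe = expr.astype(_nn.DTYPE)
        Xc = comp.astype(_nn.DTYPE)
        yv = y.astype(_nn.DTYPE)

        best = (np.inf, None, None, -1)
        train_log, val_log = [], []
        bad = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(tr)
            losses = []
            for start in range(0, len(order), self.batch_size):
                b = order[start:start + self.batch_size]
                pred = net.forward(Xe[b], Xc[b], True).ravel()
                resid = pred - yv[b]
                loss = float(np.mean(resid ** 2))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        "reduce lr or check inputs")
                losses.append(loss)
                g = (2.0 * resid / len(b)).astype(_nn.DTYPE)[:, None]
                net.backward(g)
                # global gradient-norm clipping stabilizes the occasional
                # exploding batch without changing well-behaved steps
                total = float(np.sqrt(sum(float((gr ** 2).sum())
                                          for gr in net.grads())))
                if total > self.max_grad_norm:
                    scale = self.max_grad_norm / total
                    for gr in net.grads():
                        gr *= scale
                opt.step()
                if self.l1_gene_layer > 0:
                    # proximal soft-threshold on the first expression layer:
                    # encourages genuine gene selection so attributions
                    # concentrate on the genes the model actually uses
                    W = self._first_gene_layer(net).W
                    thr = self.lr * self.l1_gene_layer
                    W[...] = np.sign(W) * np.maximum(np.abs(W) - thr, 0.0)
                if self.l1_gene_gate > 0 and getattr(net, "gate", None):
                    gate = net.gate.g
                    thr = self.lr * self.l1_gene_gate
                    gate[...] = np.sign(gate) * np.maximum(
                        np.abs(gate) - thr, 0.0)
            train_log.append(float(np.mean(losses)))
            val_pred = self._forward_eval(net, Xe[va], Xc[va])
            val_loss = float(np.mean((val_pred - yv[va]) ** 2))
            val_log.append(val_loss)
            if val_loss < best[0] - 1e-6:
                best = (val_loss, _nn.get_weights(net), _nn.get_bn_state(net),
                        epoch)
                bad = 0
            else:
                bad += 1
                if bad >= self.patience:
                    break
        if best[1] is not None:
            _nn.set_weights(net, best[1])
            _nn.set_bn_state(net, best[2])
        self.network_ = net
        self.loss_curve_ = train_log
        self.validation_loss_curve_ = val_log
        self.best_epoch_ = best[3]
        return self

    # viability is physically bounded (0 = complete killing; a few-fold
    # growth at most); predictions far outside that range can only be
    # extrapolation failures, so inference clamps to a generous envelope
    PREDICTION_BOUNDS = (-2.0, 4.0)

    @classmethod
    def _forward_eval(cls, net, Xe, Xc, batch: int = 4096):
        out = np.empty(Xe.shape[0], dtype=np.float64)
        for s in range(0, Xe.shape[0], batch):
            out[s:s + batch] = net.forward(
                Xe[s:s + batch], Xc[s:s + batch], False).ravel()
        return np.clip(out, *cls.PREDICTION_BOUNDS)

    def predict(self, X):
        check_is_fitted(self, "network_")
        expr, comp = self._split_blocks(X)
        comp = self._prepare_comp(comp)
        return self._forward_eval(self.network_, expr.astype(_nn.DTYPE),
                                  comp.astype(_nn.DTYPE))

    def input_gradients(self, X):
        """d prediction / d input for each row, inference mode.

        Returns ``(d_expr, d_comp)``; rows are independent so the batched
        backward pass yields per-row gradients.
        """
        check_is_fitted(self, "network_")
        expr, comp = self._split_blocks(X)
        comp = self._prepare_comp(comp)
        dx_all = np.empty_like(expr)
        dn_all = np.empty_like(comp)
        batch = 4096
        lo, hi = self.PREDICTION_BOUNDS
        for s in range(0, expr.shape[0], batch):
            Xe = expr[s:s + batch].astype(_nn.DTYPE)
            Xc = comp[s:s + batch].astype(_nn.DTYPE)
            out = self.network_.forward(Xe, Xc, False)
            # the prediction clamp is part of the model: zero gradient
            # where it binds, so attributions match what predict() returns
            upstream = ((out > lo) & (out < hi)).astype(_nn.DTYPE)
            dx, dn = self.network_.backward(upstream)
            if not (np.isfinite(dx).all() and np.isfinite(dn).all()):
                raise FloatingPointError("non-finite input gradients")
            dx_all[s:s + batch] = dx
            dn_all[s:s + batch] = dn
        return dx_all, dn_all

    def film_parameters(self, compound_block):
        """Per-FiLM-layer (gamma, beta) generated for the given compound
        vectors.  Only defined for conditioning variants."""
        check_is_fitted(self, "network_")
        if not isinstance(self.network_, _nn.FiLMNetwork):
            raise ValueError("concatenation variant has no FiLM parameters")
        comp = self._prepare_comp(np.asarray(compound_block, dtype=np.float64))
        return self.network_.conditioning_params(comp.astype(_nn.DTYPE))


def evaluate_r2(model, X, y) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot on held-out data."""
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(y) < 2 or np.var(y) == 0:
        raise ValueError("R^2 undefined: need >= 2 labels with variance > 0")
    pred = model.predict(X)
    return float(1.0 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2))


class ViabilityEnsemble:
    """Mean aggregate of the k cross-validation fold models."""

    def __init__(self, members, fold_r2, fold_assignments):
        self.members_ = list(members)
        self.fold_r2_ = list(fold_r2)
        self.fold_assignments_ = dict(fold_assignments)

    @property
    def mean_r2_(self):
        return float(np.mean(self.fold_r2_))

    @property
    def se_r2_(self):
        r = np.asarray(self.fold_r2_, dtype=np.float64)
        return float(r.std(ddof=1) / np.sqrt(len(r)))

    def predict(self, X):
        return np.mean([m.predict(X) for m in self.members_], axis=0)

    def input_gradients(self, X):
        parts = [m.input_gradients(X) for m in self.members_]
        dx = np.mean([p[0] for p in parts], axis=0)
        dn = np.mean([p[1] for p in parts], axis=0)
        return dx, dn


def cross_validate_ensemble(estimator: ViabilityRegressor, X, y, sample_ids,
                            k: int = 5, seed: int = 0) -> ViabilityEnsemble:
    """Grouped k-fold cross-validation by cell line.

    Each member model never sees its test fold's cell lines; per-fold R^2 is
    measured on the held-out fold and the ensemble predicts with the
    arithmetic mean of the members.
    """
    sample_ids = np.asarray(sample_ids)
    folds = make_cv_splits(sample_ids.tolist(), k=k, seed=seed)
    assign = np.array([folds[s] for s in sample_ids])
    members, r2s = [], []
    for fold in range(k):
        test = assign == fold
        est = clone(estimator)
        est.set_params(random_state=estimator.random_state + fold)
        est.fit(np.asarray(X)[~test], np.asarray(y)[~test],
                groups=sample_ids[~test])
        members.append(est)
        r2s.append(evaluate_r2(est, np.asarray(X)[test], np.asarray(y)[test]))
    return ViabilityEnsemble(members, r2s, folds)


# ---------------------------------------------------------------------------
# Checkpointing: single-file npz archive with config JSON, weights, batchnorm
# state, frozen expression stats and the gene-id list.

def save_model(model: ViabilityRegressor, path,
               expression_stats=None, gene_ids=None) -> None:
    check_is_fitted(model, "network_")
    payload = {
        "config": json.dumps(model.get_params()),
        "n_genes": model.n_genes_,
        "gene_ids": json.dumps(list(gene_ids) if gene_ids is not None else None),
    }
    arrays = {f"w{i}": w for i, w in enumerate(_nn.get_weights(model.network_))}
    for i, (m, v) in enumerate(_nn.get_bn_state(model.network_)):
        arrays[f"bn_mean{i}"] = m
        arrays[f"bn_var{i}"] = v
    if expression_stats is not None:
        arrays["stats_mean"], arrays["stats_scale"] = expression_stats
    buf = io.BytesIO()
    np.savez(buf, meta=json.dumps(payload), **arrays)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_model(path):
    """Returns ``(model, expression_stats, gene_ids)``."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        config = json.loads(meta["config"])
        for key in ("gene_encoder_widths", "compound_encoder_widths"):
            config[key] = tuple(config[key])
        model = ViabilityRegressor(**config)
        n_genes = int(meta["n_genes"])
        model.n_genes_ = n_genes
        model.n_features_in_ = n_genes + model.n_compound_features
        net = model._build_network(
            n_genes, np.random.default_rng(model.random_state))
        weights = [data[f"w{i}"] for i in range(len(_nn.get_weights(net)))]
        _nn.set_weights(net, weights)
        n_bn = len(_nn.get_bn_state(net))
        _nn.set_bn_state(net, [(data[f"bn_mean{i}"], data[f"bn_var{i}"])
                               for i in range(n_bn)])
        model.network_ = net
        stats = None
        if "stats_mean" in data:
            stats = (data["stats_mean"].copy(), data["stats_scale"].copy())
        gene_ids = json.loads(meta["gene_ids"])
    return model, stats, gene_ids
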