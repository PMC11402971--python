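import numpy as np
import pytest

from condviab import _nn
from condviab.model import (ViabilityRegressor, cross_validate_ensemble,
                            evaluate_r2, film_modulate, load_model,
                            matched_concat_widths, save_model)


class TestFilmModulate:
    def test_identity_affine(self):
        h = np.array([0.3, -1.2, 4.0])
        out = film_modulate(h, np.ones(3), np.zeros(3))
        assert np.array_equal(out, h)

    def test_direct_arithmetic(self):
        out = film_modulate(np.array([1.0, 2.0]), np.array([3.0, 0.0]),
                            np.array([0.0, 5.0]))
        assert out.tolist() == [3.0, 5.0]

    def test_zero_gamma_annihilates(self):
        rng = np.random.default_rng(0)
        h = rng.normal(size=7)
        beta = rng.normal(size=7)
        out = film_modulate(h, np.zeros(7), beta)
        assert np.array_equal(out, beta)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            film_modulate(np.ones(3), np.ones(4), np.zeros(4))


class TestArchitecture:
    def test_concat_baseline_parameter_matching(self):
        widths = matched_concat_widths(813, 120_000)
        total, prev = 0, 813
        for w in widths:
            total += prev * w + 3 * w
            prev = w
        total += prev + 1
        assert abs(total - 120_000) / 120_000 < 0.10

    def test_scale_variant_beta_is_zero(self, tiny_training_set):
        d = tiny_training_set
        est = ViabilityRegressor(variant="scale", gene_encoder_widths=(16,),
                                 compound_encoder_widths=(8,),
                                 embedding_dim=8, dropout=0.0, max_epochs=2,
                                 random_state=0)
        est.fit(d.X[d.train_mask], d.y[d.train_mask])
        for gamma, beta in est.film_parameters(d.X[:3, -513:]):
            assert np.all(beta == 0)
            assert not np.all(gamma == 1)

    def test_shift_variant_gamma_is_one(self, tiny_training_set):
        d = tiny_training_set
        est = ViabilityRegressor(variant="shift", gene_encoder_widths=(16,),
                                 compound_encoder_widths=(8,),
                                 embedding_dim=8, dropout=0.0, max_epochs=2,
                                 random_state=0)
        est.fit(d.X[d.train_mask], d.y[d.train_mask])
        for gamma, beta in est.film_parameters(d.X[:3, -513:]):
            assert np.all(gamma == 1)

    def test_output_is_scalar_per_example(self, tiny_model, tiny_training_set):
        pred = tiny_model.predict(tiny_training_set.X[:5])
        assert pred.shape == (5,)

    def test_straw_codes_per_compound(self, tiny_training_set):
        d = tiny_training_set
        est = ViabilityRegressor(variant="straw", random_state=3)
        comp = d.X[:200, -513:]
        coded = est._straw_codes(comp)
        # concentration column untouched
        assert np.array_equal(coded[:, -1], comp[:, -1])
        ids = d.row_compounds[:200]
        by_comp = {}
        for i, c in enumerate(ids):
            key = coded[i, :-1].tobytes()
            by_comp.setdefault(c, set()).add(key)
        assert all(len(v) == 1 for v in by_comp.values())  # stable per compound
        assert len({next(iter(v)) for v in by_comp.values()}) == len(by_comp)

    def test_unknown_variant_rejected(self, tiny_training_set):
        d = tiny_training_set
        est = ViabilityRegressor(variant="nope")
        with pytest.raises(ValueError, match="variant"):
            est.fit(d.X[:10], d.y[:10])


class TestGradients:
    """Analytic backpropagation against float64 central finite differences;
    this underwrites both training and integrated-gradients attribution."""

    @pytest.mark.parametrize("variant,gate", [("film", False),
                                              ("film", True),
                                              ("scale", False),
                                              ("shift", False)])
    def test_film_network_gradients(self, variant, gate):
        rng = np.random.default_rng(0)
        net = _nn.FiLMNetwork(7, 5, [6], [4], 3, 2, 0.0, variant, rng,
                              gene_gate=gate)
        if gate:
            net.gate.g[...] = rng.uniform(0.5, 1.5, net.gate.g.shape)
        for gen in net.generators:
            # move the generators off their near-identity initialization so
            # finite differences are well-scaled in float32
            gen.W += rng.normal(0, 0.5, gen.W.shape).astype(np.float32)
            gen.b += rng.normal(0, 0.5, gen.b.shape).astype(np.float32)
        x = rng.standard_normal((4, 7)).astype(np.float32)
        n = rng.standard_normal((4, 5)).astype(np.float32)
        self._check(net, x, n)

    def test_concat_network_gradients(self):
        rng = np.random.default_rng(1)
        net = _nn.ConcatNetwork(7, 5, [8, 4], 0.0, rng)
        x = rng.standard_normal((4, 7)).astype(np.float32)
        n = rng.standard_normal((4, 5)).astype(np.float32)
        self._check(net, x, n)

    @staticmethod
    def _check(net, x, n):
        def loss():
            out = np.asarray(net.forward(x, n, False), dtype=np.float64)
            return float(np.sum(out ** 2) / 2)

        out = net.forward(x, n, False)
        dx, dn = net.backward(out.copy())
        scale = max(np.abs(dx).max(), np.abs(dn).max(),
                    *[np.abs(g).max() for g in net.grads()])
        eps = 1e-3
        rng = np.random.default_rng(9)
        for p, g in zip(net.params(), net.grads()):
            fp, fg = p.ravel(), g.ravel()
            for k in rng.choice(fp.size, size=min(5, fp.size), replace=False):
                orig = fp[k]
                fp[k] = orig + eps
                lp = loss()
                fp[k] = orig - eps
                lm = loss()
                fp[k] = orig
                assert abs((lp - lm) / (2 * eps) - fg[k]) / scale < 5e-3
        for arr, ganal in [(x, dx), (n, dn)]:
            fa, fg = arr.ravel(), ganal.ravel()
            for k in rng.choice(fa.size, size=6, replace=False):
                orig = fa[k]
                fa[k] = orig + eps
                lp = loss()
                fa[k] = orig - eps
                lm = loss()
                fa[k] = orig
                assert abs((lp - lm) / (2 * eps) - fg[k]) / scale < 5e-3


class TestTraining:
    def test_loss_decreases(self, tiny_model):
        assert tiny_model.loss_curve_[-1] <= tiny_model.loss_curve_[0]

    def test_seed_determinism(self, tiny_training_set):
        d = tiny_training_set

        def run():
            est = ViabilityRegressor(variant="film",
                                     gene_encoder_widths=(16,),
                                     compound_encoder_widths=(8,),
                                     embedding_dim=8, dropout=0.1,
                                     max_epochs=5, random_state=7)
            est.fit(d.X[d.train_mask], d.y[d.train_mask],
                    groups=d.row_cells[d.train_mask])
            return est

        a, b = run(), run()
        assert a.validation_loss_curve_ == b.validation_loss_curve_
        assert np.array_equal(a.predict(d.X[:50]), b.predict(d.X[:50]))

    def test_prediction_deterministic_and_batch_invariant(self, tiny_model,
                                                          tiny_training_set):
        X = tiny_training_set.X[:40]
        p1 = tiny_model.predict(X)
        p2 = tiny_model.predict(X)
        assert np.array_equal(p1, p2)
        shuffled = np.arange(40)[::-1]
        p3 = tiny_model.predict(X[shuffled])
        assert np.allclose(p3, p1[shuffled], atol=1e-6)

    def test_wrong_gene_dimension(self, tiny_model, tiny_training_set):
        with pytest.raises(ValueError, match="columns"):
            tiny_model.predict(tiny_training_set.X[:3, :-1])

    def test_empty_training_set(self):
        est = ViabilityRegressor()
        with pytest.raises(ValueError):
            est.fit(np.empty((0, 520)), np.empty(0))

    def test_identity_film_is_compound_invariant(self, tiny_training_set):
        """Freezing every FiLM generator at (gamma=1, beta=0) makes the
        prediction independent of the compound input."""
        d = tiny_training_set
        est = ViabilityRegressor(variant="film", gene_encoder_widths=(16,),
                                 compound_encoder_widths=(8,),
                                 embedding_dim=8, dropout=0.0, max_epochs=2,
                                 random_state=0)
        est.fit(d.X[d.train_mask], d.y[d.train_mask])
        for gen in est.network_.generators:
            gen.W[...] = 0.0
            gen.b[...] = 0.0
            gen.b[:est.network_.g] = 1.0
        Xa = d.X[:20].copy()
        Xb = Xa.copy()
        rng = np.random.default_rng(0)
        Xb[:, -513:] = rng.random(Xb[:, -513:].shape)
        assert np.allclose(est.predict(Xa), est.predict(Xb), atol=1e-6)


class TestEvaluation:
    class _Const:
        def __init__(self, vals):
            self.vals = np.asarray(vals, dtype=float)

        def predict(self, X):
            return self.vals

    def test_perfect_predictions(self):
        y = [0.0, 1.0, 2.0]
        assert evaluate_r2(self._Const(y), None, y) == pytest.approx(1.0)

    def test_mean_predictions(self):
        y = [0.0, 1.0, 2.0]
        assert evaluate_r2(self._Const([1, 1, 1]), None, y) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        assert evaluate_r2(self._Const([0, 1, 1]), None,
                           [0, 1, 2]) == pytest.approx(0.5)

    def test_zero_variance_labels(self):
        with pytest.raises(ValueError):
            evaluate_r2(self._Const([1, 1]), None, [3.0, 3.0])


@pytest.fixture(scope="module")
def ensemble(tiny_training_set):
    d = tiny_training_set
    est = ViabilityRegressor(variant="film", gene_encoder_widths=(16,),
                             compound_encoder_widths=(8,),
                             embedding_dim=8, dropout=0.0, max_epochs=4,
                             validation_fraction=0.2, random_state=0)
    return cross_validate_ensemble(est, d.X, d.y, d.row_cells, k=4, seed=3)


class TestCrossValidation:

    def test_one_model_per_fold(self, ensemble):
        assert len(ensemble.members_) == 4
        assert len(ensemble.fold_r2_) == 4

    def test_no_leakage(self, ensemble, tiny_training_set):
        # re-derive fold membership: every cell line sits in exactly one fold
        folds = ensemble.fold_assignments_
        assert set(folds.values()) == {0, 1, 2, 3}
        cells = set(tiny_training_set.row_cells)
        assert set(folds) == cells

    def test_ensemble_not_worse_than_weakest_member(self, ensemble,
                                                    tiny_training_set):
        d = tiny_training_set
        member_r2 = [evaluate_r2(m, d.X[d.test_mask], d.y[d.test_mask])
                     for m in ensemble.members_]
        ens_r2 = evaluate_r2(ensemble, d.X[d.test_mask], d.y[d.test_mask])
        assert ens_r2 >= min(member_r2)


class TestCheckpoint:
    def test_roundtrip(self, tiny_model, tiny_training_set, tmp_path):
        d = tiny_training_set
        path = tmp_path / "model.npz"
        stats = (np.arange(d.n_genes, dtype=float),
                 np.ones(d.n_genes))
        gene_ids = list(d.expression_z.columns)
        save_model(tiny_model, path, expression_stats=stats,
                   gene_ids=gene_ids)
        loaded, lstats, lgenes = load_model(path)
        assert loaded.get_params() == tiny_model.get_params()
        assert lgenes == gene_ids
        assert np.array_equal(lstats[0], stats[0])
        X = d.X[:30]
        assert np.allclose(loaded.predict(X), tiny_model.predict(X))
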