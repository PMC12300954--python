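"""Prediction head: input assembly, graph attention, dual-branch encoder,
FAN decoder, end-to-end predict."""

import numpy as np
import pytest

from wheatyield.autograd import Tensor
from wheatyield.dataset import CovariateEncoding, Preprocessor, stack_records
from wheatyield.fusion import FusedFeature
from wheatyield.model import (
    ConfigError, EncoderLayer, EncoderLayerSpec, FANLayer, FANLayerSpec,
    GraphAttention, YieldModel, build_adjacency, load_checkpoint,
    save_checkpoint,
)
from wheatyield.nn import sinusoidal_positions


def _layernorm_ref(x, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps)


class TestAdjacency:
    def test_window_radius2(self):
        adj = build_adjacency(6, "window_k", 2)
        assert adj.shape == (6, 6)
        np.testing.assert_array_equal(adj, adj.T)
        assert np.all(np.diag(adj) == 1)
        assert adj[0, 2] == 1 and adj[0, 3] == 0

    def test_full(self):
        np.testing.assert_array_equal(build_adjacency(4, "full"), np.ones((4, 4)))


class TestAssembleInput:
    @pytest.fixture
    def model(self, tiny_model_cfg):
        return YieldModel(tiny_model_cfg)

    def make_cov(self, b, n_regions=6):
        region = np.zeros((b, n_regions))
        region[:, 0] = 1.0
        return CovariateEncoding(time=np.zeros((b, 1)), region=region,
                                 area=np.zeros((b, 1)))

    def test_token_count_is_fused_plus_three(self, model, rng):
        fused = FusedFeature(Tensor(rng.standard_normal((2, 5, 8))), ())
        out = model.assemble_input(fused, self.make_cov(2))
        assert out.shape == (2, 8, 8)  # 5 + time + region + area

    def test_positional_encoding_closed_form(self):
        pos = sinusoidal_positions(4, 8)
        assert pos[0, 0] == 0.0           # sin(0)
        assert pos[0, 1] == 1.0           # cos(0)
        assert pos[1, 0] == pytest.approx(np.sin(1.0))

    def test_zero_covariate_projection_leaves_positional_encoding(self, model, rng):
        for proj in (model.time_proj, model.region_proj, model.area_proj):
            proj.weight.data[:] = 0
            proj.bias.data[:] = 0
        fused = FusedFeature(Tensor(rng.standard_normal((1, 5, 8))), ())
        out = model.assemble_input(fused, self.make_cov(1))
        pos = sinusoidal_positions(8, 8)
        np.testing.assert_allclose(out.data[0, :3], pos[:3], atol=1e-12)


class TestGraphAttention:
    def test_self_loop_only_returns_own_value_projection(self, rng):
        gat = GraphAttention(4, rng)
        x = rng.standard_normal((2, 3, 4))
        adj = np.eye(3)
        out = gat(Tensor(x), adj)
        np.testing.assert_allclose(out.data, (x @ gat.w.weight.data),
                                   atol=1e-10)

    def test_uniform_aggregation_with_equal_scores(self, rng):
        gat = GraphAttention(4, rng)
        row = rng.standard_normal(4)
        x = np.tile(row, (1, 5, 1))  # identical tokens -> identical scores
        out = gat(Tensor(x), np.ones((5, 5)))
        h = x @ gat.w.weight.data
        np.testing.assert_allclose(out.data, h.mean(axis=1, keepdims=True)
                                   * np.ones((1, 5, 1)), atol=1e-10)

    def test_chain_adjacency_matches_loop_oracle(self, rng):
        """4 nodes, radius-1 chain; per-node masked softmax by loop."""
        d = 3
        gat = GraphAttention(d, rng)
        x = rng.standard_normal((1, 4, d))
        adj = build_adjacency(4, "window_k", 1)
        out = gat(Tensor(x), adj).data[0]

        w = gat.w.weight.data
        a_src, a_dst = gat.a_src.data, gat.a_dst.data
        h = x[0] @ w
        expect = np.zeros_like(h)
        for i in range(4):
            neigh = [j for j in range(4) if adj[i, j] > 0]
            scores = []
            for j in neigh:
                e = a_src @ h[i] + a_dst @ h[j]
                scores.append(e if e > 0 else 0.2 * e)  # LeakyReLU
            m = max(scores)
            exps = [np.exp(s - m) for s in scores]
            alphas = [v / sum(exps) for v in exps]
            for alpha, j in zip(alphas, neigh):
                expect[i] += alpha * h[j]
        np.testing.assert_allclose(out, expect, atol=1e-6)

    def test_asymmetric_adjacency_rejected(self, rng):
        gat = GraphAttention(4, rng)
        adj = np.eye(3)
        adj[0, 1] = 1
        with pytest.raises(ValueError):
            gat(Tensor(rng.standard_normal((1, 3, 4))), adj)

    def test_missing_self_loop_rejected(self, rng):
        gat = GraphAttention(4, rng)
        adj = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError):
            gat(Tensor(rng.standard_normal((1, 3, 4))), adj)


class TestEncoder:
    def test_zero_weights_reduce_to_stacked_layernorm(self, rng):
        """Zero attention and FFN weights with residuals: each layer becomes
        LayerNorm(LayerNorm(x)); trace symbolically with eps = 1e-5."""
        spec = EncoderLayerSpec(d_model=8, n_heads=2)
        layer = EncoderLayer(spec, rng, use_gat=True)
        layer.eval()
        for p in layer.parameters():
            p.data = np.zeros_like(p.data)
        layer.norm1.gamma.data[:] = 1
        layer.norm2.gamma.data[:] = 1
        x = rng.standard_normal((2, 5, 8))
        out = layer(Tensor(x), build_adjacency(5)).data
        np.testing.assert_allclose(out, _layernorm_ref(_layernorm_ref(x)),
                                   atol=1e-10)

    def test_zero_graph_branch_equals_reference_transformer_layer(self, rng):
        """With the graph branch disabled the layer must equal an
        independently coded single-branch Transformer encoder layer."""
        spec = EncoderLayerSpec(d_model=8, n_heads=2, ffn_dim=16)
        layer = EncoderLayer(spec, rng, use_gat=False)
        layer.eval()
        x = rng.standard_normal((2, 5, 8))
        out = layer(Tensor(x), build_adjacency(5)).data

        # reference path in plain numpy, reading the same weights
        def linear(z, lin):
            return z @ lin.weight.data + lin.bias.data

        def mhsa_ref(z):
            b, t, d = z.shape
            h, dk = 2, 4
            def split(m):
                return m.reshape(b, t, h, dk).transpose(0, 2, 1, 3)
            q = split(linear(z, layer.mhsa.wq))
            k = split(linear(z, layer.mhsa.wk))
            v = split(linear(z, layer.mhsa.wv))
            s = q @ k.transpose(0, 1, 3, 2) / np.sqrt(dk)
            s = np.exp(s - s.max(axis=-1, keepdims=True))
            attn = s / s.sum(axis=-1, keepdims=True)
            o = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
            return linear(o, layer.mhsa.wo)

        def ln(z, norm):
            return _layernorm_ref(z) * norm.gamma.data + norm.beta.data

        h1 = ln(x + mhsa_ref(x), layer.norm1)
        f = np.maximum(linear(h1, layer.ffn1), 0.0)
        ref = ln(h1 + linear(f, layer.ffn2), layer.norm2)
        np.testing.assert_allclose(out, ref, atol=1e-10)

    @pytest.mark.parametrize("tokens", [1, 2, 5, 16])
    def test_shape_preserved(self, tokens, rng):
        spec = EncoderLayerSpec(d_model=8, n_heads=2)
        layer = EncoderLayer(spec, rng)
        layer.eval()
        x = Tensor(rng.standard_normal((2, tokens, 8)))
        assert layer(x, build_adjacency(tokens)).shape == (2, tokens, 8)

    def test_heads_must_divide_d_model(self):
        with pytest.raises(ConfigError):
            EncoderLayerSpec(d_model=8, n_heads=3)


class TestFAN:
    def test_zero_periodic_weights(self, rng):
        spec = FANLayerSpec(d_in=5, d_p=2, d_pbar=3)
        fan = FANLayer(spec, rng)
        fan.wp.weight.data[:] = 0
        out = fan(Tensor(rng.standard_normal((4, 5)))).data
        np.testing.assert_array_equal(out[:, :2], 1.0)  # cos block
        np.testing.assert_array_equal(out[:, 2:4], 0.0)  # sin block

    def test_output_width(self, rng):
        spec = FANLayerSpec(d_in=5, d_p=2, d_pbar=3)
        assert spec.d_out == 7
        fan = FANLayer(spec, rng)
        assert fan(Tensor(rng.standard_normal((4, 5)))).shape == (4, 7)

    def test_periodicity(self, rng):
        spec = FANLayerSpec(d_in=4, d_p=2, d_pbar=3)
        fan = FANLayer(spec, rng)
        x = rng.standard_normal((1, 4))
        # shift x so that Wp . delta is an exact multiple of 2*pi
        # (underdetermined system: 2 equations, 4 unknowns -> exact solution)
        wp = fan.wp.weight.data  # (4, 2)
        delta = np.linalg.lstsq(wp.T, 2 * np.pi * np.ones(2), rcond=None)[0]
        out1 = fan(Tensor(x)).data
        out2 = fan(Tensor(x + delta)).data
        np.testing.assert_allclose(out1[:, :4], out2[:, :4], atol=1e-8)

    def test_periodic_block_bounded(self, rng):
        spec = FANLayerSpec(d_in=4, d_p=3, d_pbar=2)
        fan = FANLayer(spec, rng)
        out = fan(Tensor(rng.standard_normal((10, 4)) * 100)).data
        assert np.all(np.abs(out[:, :6]) <= 1.0 + 1e-12)


class TestPredict:
    @pytest.fixture
    def fitted(self, tiny_sim, tiny_split, tiny_model_cfg):
        _, records, _ = tiny_sim
        model = YieldModel(tiny_model_cfg)
        arr = stack_records(records, tiny_split.train)
        prep = Preprocessor(6).fit(arr)
        return model, prep, records, arr

    def test_eval_deterministic(self, fitted, tiny_split):
        model, prep, records, _ = fitted
        arr = stack_records(records, tiny_split.test)
        a = model.predict(arr, prep)
        b = model.predict(arr, prep)
        np.testing.assert_array_equal(a, b)

    def test_bias_only_head_predicts_train_mean(self, fitted, tiny_split):
        model, prep, records, train_arr = fitted
        model.head.weight.data[:] = 0
        model.head.bias.data[:] = 0
        arr = stack_records(records, tiny_split.test)
        preds = model.predict(arr, prep)
        np.testing.assert_allclose(preds, train_arr["y"].mean(), rtol=1e-9)

    def test_gradient_wrt_ndvi_cell_matches_central_difference(self, fitted):
        model, prep, records, arr = fitted
        model.eval()
        series = prep.encode_series(arr)
        cov = prep.encode_covariates(arr)
        sub = {k: series[k][:2] for k in series}
        cov2 = CovariateEncoding(cov.time[:2], cov.region[:2], cov.area[:2])

        rs = Tensor(sub["rs"], requires_grad=True)
        batch = {"rs": rs, "cl": Tensor(sub["cl"]), "sd": Tensor(sub["sd"]),
                 "ss": Tensor(sub["ss"])}
        out = model(batch, cov2)
        out.sum().backward()
        auto = rs.grad[0, 4, 0]

        eps = 1e-5
        def value(delta):
            pert = sub["rs"].copy()
            pert[0, 4, 0] += delta
            b = {"rs": Tensor(pert), "cl": Tensor(sub["cl"]),
                 "sd": Tensor(sub["sd"]), "ss": Tensor(sub["ss"])}
            return float(model(b, cov2).sum().data)
        numeric = (value(eps) - value(-eps)) / (2 * eps)
        assert auto == pytest.approx(numeric, rel=1e-3)

    def test_checkpoint_round_trip(self, fitted, tiny_split, tmp_path):
        model, prep, records, _ = fitted
        save_checkpoint(model, tmp_path / "model.npz")
        back = load_checkpoint(tmp_path / "model.npz")
        arr = stack_records(records, tiny_split.test)
        np.testing.assert_allclose(model.predict(arr, prep),
                                   back.predict(arr, prep), rtol=1e-12)

    def test_single_source_ablation_model_runs(self, tiny_sim, tiny_split,
                                               tiny_model_cfg, rng):
        import dataclasses
        _, records, _ = tiny_sim
        cfg = dataclasses.replace(tiny_model_cfg, fusion="none",
                                  sources=("cl",))
        model = YieldModel(cfg)
        arr = stack_records(records, tiny_split.train)
        prep = Preprocessor(6).fit(arr)
        preds = model.predict(arr, prep)
        assert np.isfinite(preds).all()
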