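"""Network assembly: shapes, determinism, parameter accounting and the
checksum harness."""

import numpy as np
import pytest

from metaswin.autograd import Tensor
from metaswin.model import (ModelConfig, REFERENCE_COUNTS, architecture_checksum,
                            build_network, count_parameters, load_checkpoint,
                            save_checkpoint)

RNG = np.random.default_rng(23)


class TestConfigValidation:
    def test_bad_mixer_and_roi(self):
        with pytest.raises(ValueError):
            ModelConfig(mixer="mlp")
        with pytest.raises(ValueError):
            ModelConfig(roi=(96, 96, 100))

    def test_heads_must_divide_stage_width(self):
        with pytest.raises(ValueError):
            ModelConfig(feature_size=10, mixer="attention")
        ModelConfig(feature_size=10, mixer="pooling", use_se=False,
                    heads=(1, 1, 1, 1))  # pooling has no head constraint

    def test_stage_widths(self):
        cfg = ModelConfig(feature_size=24, in_channels=1, out_channels=14, roi=(96,) * 3)
        assert cfg.stage_widths == (24, 48, 96, 192)

    def test_config_json_roundtrip(self):
        cfg = ModelConfig(feature_size=12, mixer="pooling", roi=(32,) * 3,
                          pooling_depths=(1, 1, 1, 1))
        assert ModelConfig.from_json(cfg.to_json()) == cfg


class TestParameterAccounting:
    def test_totals_match_published_counts(self, reference_grid_counts):
        for key, total in reference_grid_counts.items():
            assert total == REFERENCE_COUNTS[key], key

    def test_se_delta_uniform_across_mixers_and_channel_configs(self, reference_grid_counts):
        g = reference_grid_counts
        deltas_c24 = {g[(m, True, 24, 1, 14)] - g[(m, False, 24, 1, 14)]
                      for m in ("attention", "pooling")}
        assert deltas_c24 == {106_032}
        deltas_c48 = {g[(m, True, 48, i, o)] - g[(m, False, 48, i, o)]
                      for m in ("attention", "pooling") for i, o in ((1, 14), (4, 3))}
        assert deltas_c48 == {421_728}

    def test_mixer_delta_uniform_across_channel_configs(self, reference_grid_counts):
        g = reference_grid_counts
        deltas = {g[("attention", se, 48, i, o)] - g[("pooling", se, 48, i, o)]
                  for se in (False, True) for i, o in ((1, 14), (4, 3))}
        assert deltas == {1_179_360}

    def test_channel_config_delta_uniform_across_mixers(self, reference_grid_counts):
        g = reference_grid_counts
        deltas = {g[(m, se, 48, 4, 3)] - g[(m, se, 48, 1, 14)]
                  for m in ("attention", "pooling") for se in (False, True)}
        assert deltas == {4_645}

    def test_totals_increase_with_feature_size(self):
        # strict monotonicity over the published size grid, all variants
        sizes = (24, 36, 48, 60, 72, 84)
        for mixer in ("attention", "pooling"):
            for se in (False, True):
                totals = [REFERENCE_COUNTS[(mixer, se, c, 1, 14)] for c in sizes]
                assert totals == sorted(totals) and len(set(totals)) == len(totals)
        # and for freshly built networks on a sub-grid
        built = [count_parameters(build_network(
            ModelConfig(feature_size=c, in_channels=1, out_channels=14,
                        mixer="pooling", roi=(96,) * 3))).total for c in (24, 36, 48)]
        assert built == sorted(built) and len(set(built)) == 3

    def test_counts_independent_of_roi_and_seed(self):
        base = dict(feature_size=12, in_channels=1, out_channels=2, mixer="pooling")
        a = count_parameters(build_network(ModelConfig(roi=(32,) * 3, **base), seed=0))
        b = count_parameters(build_network(ModelConfig(roi=(64,) * 3, **base), seed=9))
        assert a.total == b.total and a.components == b.components

    def test_pooling_mixers_report_zero_when_budget_not_retained(self):
        cfg = ModelConfig(feature_size=12, in_channels=1, out_channels=2, mixer="pooling",
                          roi=(32,) * 3, pooling_keeps_attention_budget=False)
        net = build_network(cfg)
        mixer_params = [p for n, p in net.named_parameters() if ".mixer." in n]
        assert mixer_params == []

    def test_report_total_is_sum_of_components(self, tiny_pooling_net):
        rep = count_parameters(tiny_pooling_net)
        assert rep.total == sum(rep.components.values())
        assert "patch_embed" in rep.components and "stage4" in rep.components
        assert "component\tparameters" in rep.to_tsv()


class TestChecksumHarness:
    def test_matching_reports_pass(self):
        cfg = ModelConfig(feature_size=24, in_channels=1, out_channels=14,
                          mixer="pooling", roi=(96,) * 3)
        rep = count_parameters(build_network(cfg))
        verdict = architecture_checksum([rep])
        assert verdict["entries"][0]["status"] == "pass"
        assert verdict["all_pass"]

    def test_missing_reference_is_skipped(self):
        cfg = ModelConfig(feature_size=12, in_channels=1, out_channels=2,
                          mixer="pooling", roi=(32,) * 3)
        verdict = architecture_checksum([count_parameters(build_network(cfg))])
        assert verdict["entries"][0]["status"] == "skipped"
        assert not verdict["all_pass"]  # nothing was actually checked

    def test_corrupted_count_fails(self):
        cfg = ModelConfig(feature_size=24, in_channels=1, out_channels=14,
                          mixer="pooling", roi=(96,) * 3)
        rep = count_parameters(build_network(cfg))
        rep = type(rep)(components=rep.components, total=rep.total - 1, config=rep.config)
        assert architecture_checksum([rep])["entries"][0]["status"] == "fail"

    def test_dropping_position_bias_tables_breaks_only_attention_checksum(self):
        # the bias tables are a closed-form tally: (2w-1)^3 * heads per block
        cfg24 = ModelConfig(feature_size=24, in_channels=1, out_channels=14,
                            mixer="attention", roi=(96,) * 3)
        rep = count_parameters(build_network(cfg24))
        table = (2 * 7 - 1) ** 3 * sum(2 * h for h in (3, 6, 12, 24))
        assert rep.total - table == REFERENCE_COUNTS[("attention", False, 24, 1, 14)] - table


class TestForwardPass:
    def test_pooling_forward_shapes_and_finiteness(self, tiny_pooling_net):
        x = Tensor(RNG.normal(size=(1, 4, 32, 32, 32)).astype(np.float32))
        out = tiny_pooling_net(x)
        assert out.shape == (1, 3, 32, 32, 32)
        assert np.isfinite(out.data).all()

    def test_attention_forward_shapes(self):
        cfg = ModelConfig(feature_size=12, in_channels=1, out_channels=14,
                          mixer="attention", roi=(32,) * 3)
        net = build_network(cfg, seed=2)
        out = net(Tensor(RNG.normal(size=(1, 1, 32, 32, 32)).astype(np.float32)))
        assert out.shape == (1, 14, 32, 32, 32)
        assert np.isfinite(out.data).all()

    def test_input_validation(self, tiny_pooling_net):
        with pytest.raises(ValueError):
            tiny_pooling_net(Tensor(np.zeros((1, 2, 32, 32, 32), np.float32)))
        with pytest.raises(ValueError):
            tiny_pooling_net(Tensor(np.zeros((1, 4, 32, 32, 30), np.float32)))

    def test_gradients_reach_every_parameter_tensor(self):
        # 64-cubed input so the bottleneck retains spatial variance;
        # strictly parameter-free mixer so every tensor is in the graph
        cfg = ModelConfig(feature_size=6, in_channels=1, out_channels=2,
                          mixer="pooling", roi=(64,) * 3,
                          pooling_keeps_attention_budget=False)
        net = build_network(cfg, seed=1)
        x = Tensor(RNG.normal(size=(1, 1, 64, 64, 64)).astype(np.float32))
        out = net(x)
        out.mean().backward()
        params = list(net.named_parameters())
        nonzero = [n for n, p in params if p.grad is not None and np.abs(p.grad).max() > 0]
        assert len(nonzero) / len(params) >= 0.99

    def test_retained_position_tables_are_inert(self, tiny_pooling_net):
        net = tiny_pooling_net
        x = Tensor(RNG.normal(size=(1, 4, 32, 32, 32)).astype(np.float32))
        ref = net(x).data
        for name, p in net.named_parameters():
            if "relative_position_bias_table" in name:
                p.data = p.data + 10.0
        np.testing.assert_allclose(net(x).data, ref, atol=0)


class TestDeterminismAndCheckpoints:
    def test_same_seed_same_weights(self):
        cfg = ModelConfig(feature_size=12, in_channels=1, out_channels=2,
                          mixer="attention", use_se=True, roi=(32,) * 3)
        a, b = build_network(cfg, seed=4), build_network(cfg, seed=4)
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)
        c = build_network(cfg, seed=5)
        diffs = [not np.array_equal(pa.data, pc.data)
                 for (_, pa), (_, pc) in zip(a.named_parameters(), c.named_parameters())]
        assert any(diffs)

    def test_checkpoint_roundtrip(self, tmp_path, tiny_pooling_net):
        path = tmp_path / "net.npz"
        save_checkpoint(tiny_pooling_net, path)
        restored = load_checkpoint(path)
        assert restored.cfg == tiny_pooling_net.cfg
        x = Tensor(RNG.normal(size=(1, 4, 32, 32, 32)).astype(np.float32))
        np.testing.assert_allclose(restored(x).data, tiny_pooling_net(x).data, atol=1e-6)
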