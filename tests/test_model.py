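"""Architecture construction and the parameter/FLOP accounting closures."""

from fractions import Fraction

import numpy as np
import pytest

from ltnet import nn
from ltnet.model import (LTBlockConfig, LTNetConfig, build_model, count_flops,
                         count_params_conv, count_params_dsc,
                         count_params_model, enumerate_model_params,
                         reference_config)


def _random_triples(rng, n=50):
    return [(int(k), int(ci), int(co))
            for k, ci, co in zip(rng.choice([1, 3, 5], n),
                                 rng.integers(1, 24, n),
                                 rng.integers(1, 24, n))]


class TestCountingClosures:
    def test_worked_standard(self):
        assert count_params_conv(3, 16, 32) == 4608
        assert count_params_conv(1, 7, 7) == 49

    def test_worked_dsc(self):
        assert count_params_dsc(3, 16, 32) == 656

    def test_param_ratio_identity_exact(self):
        # DP/CP = 1/C_out + 1/K^2 in exact rational arithmetic
        assert Fraction(656, 4608) == Fraction(1, 32) + Fraction(1, 9)

    def test_closures_match_constructed_layers(self, rng):
        """Brute-force enumeration of actually built conv layers."""
        for k, ci, co in _random_triples(rng):
            std = nn.Conv2d(ci, co, k, bias=False, rng=rng)
            assert count_params_conv(k, ci, co) == std.weight.size
            dw = nn.Conv2d(ci, ci, k, groups=ci, bias=False, rng=rng)
            pw = nn.Conv2d(ci, co, 1, bias=False, rng=rng)
            assert count_params_dsc(k, ci, co) == dw.weight.size + pw.weight.size

    def test_ratio_identity_for_random_triples(self, rng):
        for k, ci, co in _random_triples(rng):
            lhs = Fraction(count_params_dsc(k, ci, co), count_params_conv(k, ci, co))
            assert lhs == Fraction(1, co) + Fraction(1, k * k)

    def test_flops_unit_extent_reduces_to_params(self, rng):
        for k, ci, co in _random_triples(rng, 10):
            assert count_flops("standard", 1, 1, k, ci, co) == count_params_conv(k, ci, co)

    def test_flops_ratio_identity(self):
        for h, w in ((8, 8), (5, 7)):
            lhs = Fraction(count_flops("dsc", h, w, 3, 16, 32),
                           count_flops("standard", h, w, 3, 16, 32))
            assert lhs == Fraction(1, 32) + Fraction(1, 9)

    def test_flops_worked_arithmetic(self):
        assert count_flops("standard", 8, 8, 3, 16, 32) == 8 * 8 * 9 * 16 * 32
        assert count_flops("dsc", 8, 8, 3, 16, 32) == 8 * 8 * (9 * 16 + 16 * 32)

    def test_flops_counts_match_loop_enumeration(self, rng):
        """Independent oracle: count multiply-accumulates by iterating the
        nested loops of a naive convolution."""
        for k, ci, co in _random_triples(rng, 4):
            h = w = 4
            macs = 0
            for _ in range(h):
                for _ in range(w):
                    macs += k * k * ci * co
            assert count_flops("standard", h, w, k, ci, co) == macs


class TestModelConstruction:
    def test_logit_shape_and_finiteness(self, tiny_model_cfg, rng):
        m = build_model(tiny_model_cfg, seed=0)
        x = rng.uniform(0, 1, (2, 3, 16, 16)).astype(np.float32)
        logits = m.forward(x)
        assert logits.shape == (2, 3)
        assert np.all(np.isfinite(logits))

    def test_same_seed_same_logits(self, tiny_model_cfg, rng):
        x = rng.uniform(0, 1, (2, 3, 16, 16)).astype(np.float32)
        a = build_model(tiny_model_cfg, seed=5).forward(x)
        b = build_model(tiny_model_cfg, seed=5).forward(x)
        assert np.array_equal(a, b)
        c = build_model(tiny_model_cfg, seed=6).forward(x)
        assert not np.array_equal(a, c)

    def test_batch_permutation_equivariance(self, tiny_model_cfg, rng):
        m = build_model(tiny_model_cfg, seed=2)
        x = rng.uniform(0, 1, (6, 3, 16, 16)).astype(np.float32)
        perm = rng.permutation(6)
        assert np.allclose(m.forward(x)[perm], m.forward(x[perm]), atol=1e-5)

    def test_se_ratio_divisibility_enforced(self):
        with pytest.raises(ValueError):
            LTBlockConfig(channels=10, se_ratio=4)

    def test_state_roundtrip(self, tiny_model_cfg, rng, tmp_path):
        m = build_model(tiny_model_cfg, seed=3)
        x = rng.uniform(0, 1, (4, 3, 16, 16)).astype(np.float32)
        m.forward(x, train=True)  # move BN running stats off init
        path = tmp_path / "ckpt.npz"
        m.save(path)
        m2 = build_model(tiny_model_cfg, seed=99)
        m2.load(path)
        assert np.array_equal(m.forward(x), m2.forward(x))


class TestModelParamReport:
    def test_report_matches_enumeration_for_random_configs(self, rng):
        for i in range(20):
            n_blocks = int(rng.integers(1, 4))
            widths = [int(rng.choice([8, 12, 16, 24, 32])) for _ in range(n_blocks)]
            cfg = LTNetConfig(
                input_channels=int(rng.choice([1, 3])),
                stem_channels=int(rng.choice([4, 8, 16])),
                blocks=[LTBlockConfig(channels=c, n_convbn=int(rng.integers(1, 3)),
                                      se_ratio=4,
                                      stride=int(rng.choice([1, 2])))
                        for c in widths],
                n_classes=int(rng.integers(2, 5)),
                ablation_mode=str(rng.choice(["full", "original"])))
            assert count_params_model(cfg).total == \
                enumerate_model_params(build_model(cfg, seed=i))

    def test_total_invariant_to_input_size(self, tiny_model_cfg):
        import dataclasses
        a = count_params_model(tiny_model_cfg).total
        big = dataclasses.replace(tiny_model_cfg, input_size=(32, 32))
        assert count_params_model(big).total == a

    def test_original_mode_has_more_params(self, tiny_model_cfg):
        import dataclasses
        full = count_params_model(tiny_model_cfg).total
        orig = count_params_model(
            dataclasses.replace(tiny_model_cfg, ablation_mode="original")).total
        assert orig > full

    def test_head_removal_delta(self, tiny_model_cfg):
        rep = count_params_model(tiny_model_cfg)
        last = tiny_model_cfg.blocks[-1].channels
        n_cls = tiny_model_cfg.n_classes
        assert rep.per_layer["head.fc"] == (last + 1) * n_cls
        assert rep.total - sum(v for k, v in rep.per_layer.items()
                               if k != "head.fc") == (last + 1) * n_cls

    def test_per_layer_sums_to_total(self, tiny_model_cfg):
        rep = count_params_model(tiny_model_cfg)
        assert sum(rep.per_layer.values()) == rep.total
        assert all(v >= 0 for v in rep.per_layer.values())


class TestReferenceConfiguration:
    def test_reference_counts(self):
        cfg = reference_config()
        rep = count_params_model(cfg)
        assert rep.total == 32_614
        assert enumerate_model_params(build_model(cfg, seed=0)) == 32_614

    def test_reference_original_variant(self):
        assert count_params_model(reference_config("original")).total == 195_763

    def test_reference_forward(self, rng):
        m = build_model(reference_config(), seed=0)
        x = rng.uniform(0, 1, (2, 3, 16, 16)).astype(np.float32)
        logits = m.forward(x)
        assert logits.shape == (2, 3) and np.all(np.isfinite(logits))
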