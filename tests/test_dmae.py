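"""Edge-enhancement module checks: EFE identities, branch shapes, weight
generator properties, and full-module equivalence with a loop oracle."""

import numpy as np
import pytest

from pdayolo.dmae import (CWG, DMAE, EFE, BranchWeights, DMAEConfig, EdgeBranch,
                          cwg_forward, dmae_forward, edge_branch_forward,
                          efe_forward)
from pdayolo.nn import Tensor, init_scope
from pdayolo.nn import autograd as ag

from reference import dmae_ref, local_mean_ref


class TestEFE:
    def test_constant_input_has_zero_edge_map(self):
        efe = EFE(3)
        x = Tensor(np.full((1, 3, 9, 9), 4.25, dtype=np.float32))
        assert np.allclose(efe.edge_map(x).data, 0, atol=1e-7)

    def test_zero_dsconv_adds_exactly_half(self, rng):
        efe = EFE(3)
        for p in efe.parameters():
            p.data[:] = 0
        x = rng.standard_normal((1, 3, 7, 7)).astype(np.float32)
        out = efe_forward(x, module=efe)
        assert np.allclose(out.data, x + 0.5, atol=1e-6)

    def test_impulse_edge_map_arithmetic(self):
        """Single 5x5 channel, zero except centre = 9: the centre reads
        9 - 1 = 8, the 8 neighbours 0 - 1 = -1, everything further 0."""
        x = np.zeros((1, 1, 5, 5), dtype=np.float32)
        x[0, 0, 2, 2] = 9.0
        edge = EFE(1).edge_map(Tensor(x)).data[0, 0]
        assert edge[2, 2] == pytest.approx(8.0)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dy, dx) != (0, 0):
                    assert edge[2 + dy, 2 + dx] == pytest.approx(-1.0)
        assert np.allclose(edge[0, :], 0) and np.allclose(edge[:, 0], 0)

    def test_step_edge_response_is_local(self):
        """|F_edge| of a vertical step is maximal within one cell of the
        discontinuity and zero further away (high-pass behaviour)."""
        x = np.zeros((1, 1, 8, 8), dtype=np.float32)
        x[..., 4:] = 1.0
        edge = np.abs((Tensor(x) - ag.local_avg_pool(Tensor(x), 3)).data[0, 0])
        near = edge[:, 3:5].max()
        far = edge[:, [0, 1, 6, 7]].max()
        assert near > 0 and far == pytest.approx(0.0, abs=1e-7)
        assert near == pytest.approx(edge.max())


class TestEdgeBranch:
    def test_shape_contract(self, rng):
        cfg = DMAEConfig(16, feat_rls=[3, 6, 9, 12], reduction=4)
        x = rng.standard_normal((1, 16, 24, 24)).astype(np.float32)
        br = EdgeBranch(16, 4, 3)
        mid = ag.adaptive_avg_pool(br.reduce(Tensor(x)), (3, 3))
        assert mid.shape == (1, 4, 3, 3)
        out = edge_branch_forward(x, 3, cfg, module=br)
        assert out.shape == (1, 4, 24, 24)

    def test_exact_divisor_pooling_is_block_mean(self, rng):
        x = rng.standard_normal((1, 1, 6, 6)).astype(np.float64)
        pooled = ag.adaptive_avg_pool(Tensor(x), (3, 3)).data
        for i in range(3):
            for j in range(3):
                assert pooled[0, 0, i, j] == pytest.approx(
                    x[0, 0, 2 * i:2 * i + 2, 2 * j:2 * j + 2].mean())

    def test_constant_propagates_to_constant(self, rng):
        """Zero conv weights with nonzero biases: every stage (pool, conv,
        EFE, upsample) then maps a constant map to a constant map."""
        with init_scope(3):
            br = EdgeBranch(8, 4, 3)
        br.eval()
        br.reduce.conv.weight.data[:] = 0
        for conv, bias in ((br.extract.dw, 0.3), (br.extract.pw, -0.2),
                           (br.efe.ds.dw, 0.1), (br.efe.ds.pw, 0.4)):
            conv.weight.data[:] = 0
            conv.bias.data[:] = bias
        x = np.full((1, 8, 12, 12), 1.3, dtype=np.float32)
        out = br(Tensor(x)).data
        assert np.allclose(out, out[:, :, :1, :1], atol=1e-6)
        assert not np.allclose(out, 0)

    def test_oversized_resolution_rejected(self, rng):
        cfg = DMAEConfig(8, feat_rls=[3, 6, 9, 12], reduction=2)
        x = rng.standard_normal((1, 8, 5, 5)).astype(np.float32)
        with pytest.raises(ValueError):
            edge_branch_forward(x, 6, cfg)
        with pytest.raises(ValueError):
            edge_branch_forward(x, 7, cfg)  # not a configured resolution


class TestCWG:
    def test_zero_final_layer_gives_half_weights(self, rng):
        cfg = DMAEConfig(16)
        cwg = CWG(16, cfg.n + 1)
        cwg.fc2.weight.data[:] = 0
        cwg.fc2.bias.data[:] = 0
        w = cwg_forward(rng.standard_normal((2, 16, 8, 8)), cfg, module=cwg)
        assert isinstance(w, BranchWeights)
        assert np.allclose(w.w_local, 0.5) and np.allclose(w.w_edge, 0.5)

    def test_weights_strictly_inside_unit_interval(self, rng):
        cfg = DMAEConfig(16)
        w = cwg_forward(rng.standard_normal((3, 16, 8, 8)) * 5, cfg)
        allw = np.concatenate([w.w_local[:, None], w.w_edge], axis=1)
        assert np.all(allw > 0) and np.all(allw < 1)

    def test_spatial_permutation_invariance(self, rng):
        cfg = DMAEConfig(8)
        with init_scope(11):
            cwg = CWG(8, cfg.n + 1)
        x = rng.standard_normal((1, 8, 6, 6))
        perm = rng.permutation(36)
        xp = x.reshape(1, 8, 36)[:, :, perm].reshape(1, 8, 6, 6)
        w1 = cwg_forward(x, cfg, module=cwg)
        w2 = cwg_forward(xp, cfg, module=cwg)
        assert np.allclose(w1.w_local, w2.w_local, atol=1e-6)
        assert np.allclose(w1.w_edge, w2.w_edge, atol=1e-6)


class TestDMAE:
    def test_shape_preservation_default_config(self, rng):
        x = rng.standard_normal((1, 64, 24, 24)).astype(np.float32)
        out = dmae_forward(x, DMAEConfig(64))
        assert out.shape == (1, 64, 24, 24)

    def test_zero_weights_zero_bias_give_zero_output(self, rng):
        cfg = DMAEConfig(16)
        mod = DMAE(cfg)
        mod.eval()
        # force every branch gate to 0 and make fusion purely linear
        mod.cwg.fc2.weight.data[:] = 0
        mod.cwg.fc2.bias.data[:] = -40.0  # sigmoid underflows to ~0
        mod.fuse.bn.beta.data[:] = 0
        mod.fuse.bn.running_mean[:] = 0
        out = dmae_forward(rng.standard_normal((1, 16, 12, 12)), cfg, module=mod)
        assert np.allclose(out.data, 0, atol=1e-6)

    def test_matches_loop_oracle(self, rng):
        cfg = DMAEConfig(8, feat_rls=[2, 3, 4], reduction=2)
        with init_scope(5):
            mod = DMAE(cfg)
        mod.eval()
        x = rng.standard_normal((1, 8, 8, 8))
        out = dmae_forward(x.astype(np.float32), cfg, module=mod)
        assert np.allclose(out.data, dmae_ref(x, mod), atol=1e-5)

    def test_branch_weight_scaling_is_linear_before_fusion(self, rng):
        """Halving a branch gate halves that branch's concat entries."""
        cfg = DMAEConfig(8, feat_rls=[2, 4], reduction=2)
        with init_scope(9):
            mod = DMAE(cfg)
        mod.eval()
        x = Tensor(rng.standard_normal((1, 8, 8, 8)).astype(np.float32))
        w = mod.cwg(x).data
        branch0 = mod.local(x).data * w[:, 0:1]
        assert np.allclose(branch0 * 0.5, mod.local(x).data * (w[:, 0:1] * 0.5))

    def test_small_input_clamps_branch_resolutions(self, rng):
        cfg = DMAEConfig(8)  # feat_rls up to 12
        with init_scope(2):
            mod = DMAE(cfg)
        mod.eval()
        out = mod(Tensor(rng.standard_normal((1, 8, 5, 5)).astype(np.float32)))
        assert out.shape == (1, 8, 5, 5)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            dmae_forward(rng.standard_normal((1, 12, 8, 8)), DMAEConfig(16))


def test_config_validation():
    with pytest.raises(ValueError):
        DMAEConfig(16, feat_rls=[3, 3, 6])
    with pytest.raises(ValueError):
        DMAEConfig(16, feat_rls=[6, 3])
    with pytest.raises(ValueError):
        DMAEConfig(6, reduction=4)
    assert DMAEConfig(16).feat_rls == [3, 6, 9, 12]
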