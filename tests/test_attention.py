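"""Attention operators: pinned fixtures, sigmoid-range and shape invariants,
cascade composition, and analytic-vs-numeric gradients."""

import numpy as np
import pytest

from oxyflux._autodiff import Tensor
from oxyflux import attention as at

# 3×2 temporal-attention fixture with hand-set bottleneck weights (r=1).
F_TAM = np.array([[1.0, 2.0], [0.5, -1.0], [3.0, 0.25]])
W1_TAM = np.array([[0.2, -0.1, 0.3], [0.0, 0.4, -0.2], [0.5, 0.1, 0.1]])
W2_TAM = np.array([[0.3, -0.2, 0.1], [0.2, 0.0, -0.4], [-0.1, 0.5, 0.2]])
# Frozen values from an independent loop-based evaluation of the
# squeeze (mean over W), excitation (sigmoid∘W2∘relu∘W1) and rescale steps.
S_TAM_EXPECTED = np.array([0.582367540728, 0.452023062363, 0.524043940818])
F_TAM_EXPECTED = np.array([[0.582367540728, 1.164735081456],
                           [0.226011531182, -0.452023062363],
                           [1.572131822453, 0.131010985204]])

# 4×3 spatial-attention fixture: kernel rows act on (avg, max) pooled maps.
F_SAM = np.array([[1.0, -2.0, 0.5], [2.0, 0.0, 1.5],
                  [-1.0, 1.0, 2.5], [0.0, 3.0, -0.5]])
K_SAM = np.array([[0.2, 0.5, -0.3], [0.1, -0.4, 0.25]])
B_SAM = 0.15
M_SAM_EXPECTED = np.array([0.549833997312, 0.456361312763, 0.512497396484])
F_SAM_EXPECTED = np.array([[0.549833997312, -0.912722625526, 0.256248698242],
                           [1.099667994625, 0.0, 0.768746094726],
                           [-0.549833997312, 0.456361312763, 1.281243491211],
                           [0.0, 1.369083938289, -0.256248698242]])

# STAM on the SAM fixture, then SE with r=2 over C=4.
W1_STAM = np.array([[0.3, -0.2, 0.1, 0.4], [0.0, 0.25, -0.15, 0.2]])
W2_STAM = np.array([[0.2, -0.3], [0.4, 0.1], [-0.2, 0.5], [0.1, 0.3]])
S_STAM_EXPECTED = np.array([0.489851043416, 0.509535930799,
                            0.51866675345, 0.514102518815])
F_STAM_EXPECTED = np.array([[0.269336757289, -0.447098130463, 0.125523692208],
                            [0.560320355212, 0.0, 0.391703756925],
                            [-0.285180614322, 0.236699440491, 0.664538401965],
                            [0.0, 0.703849501143, -0.131738101209]])


class TestPinnedFixtures:
    def test_tam_matches_hand_computation(self):
        params = at.SEParams(W1=W1_TAM, W2=W2_TAM, r=1)
        out, weights = at.tam_apply(F_TAM, params)
        assert np.allclose(weights.values, S_TAM_EXPECTED, atol=1e-9)
        assert np.allclose(out, F_TAM_EXPECTED, atol=1e-9)

    def test_sam_matches_hand_computation(self):
        out, weights = at.sam_apply(F_SAM, K_SAM, bias=B_SAM)
        assert np.allclose(weights.values, M_SAM_EXPECTED, atol=1e-9)
        assert np.allclose(out, F_SAM_EXPECTED, atol=1e-9)

    def test_stam_matches_hand_computation(self):
        params = at.SEParams(W1=W1_STAM, W2=W2_STAM, r=2)
        out, m, s = at.stam_apply(F_SAM, K_SAM, params, bias=B_SAM)
        assert np.allclose(m.values, M_SAM_EXPECTED, atol=1e-9)
        assert np.allclose(s.values, S_STAM_EXPECTED, atol=1e-9)
        assert np.allclose(out, F_STAM_EXPECTED, atol=1e-9)


class TestZeroParameterBlocks:
    def test_tam_halves_input(self, rng):
        f = rng.normal(size=(6, 4))
        out, w = at.tam_apply(f, at.SEParams.zeros(6, r=2))
        assert np.allclose(w.values, 0.5)
        assert np.allclose(out, 0.5 * f)

    def test_sam_halves_input(self, rng):
        f = rng.normal(size=(5, 7))
        out, w = at.sam_apply(f, np.zeros((2, 3)), bias=0.0)
        assert np.allclose(w.values, 0.5)
        assert np.allclose(out, 0.5 * f)

    def test_stam_quarters_input(self, rng):
        f = rng.normal(size=(6, 4))
        out, _, _ = at.stam_apply(f, np.zeros((2, 3)), at.SEParams.zeros(6, r=2))
        assert np.allclose(out, 0.25 * f)


class TestInvariants:
    @pytest.mark.parametrize("c,w", [(10, 5), (10, 64)])
    def test_shape_preserved_and_weights_in_unit_interval(self, c, w, rng):
        f = rng.normal(size=(c, w)) * 3
        params = at.SEParams(W1=rng.normal(size=(c // 2, c)),
                             W2=rng.normal(size=(c, c // 2)), r=2)
        kernel = rng.normal(size=(2, 5))
        for out, weights in [at.tam_apply(f, params),
                             at.sam_apply(f, kernel, bias=0.3)]:
            assert out.shape == (c, w)
            assert np.all(weights.values > 0) and np.all(weights.values < 1)
        out, m, s = at.stam_apply(f, kernel, params)
        assert out.shape == (c, w)
        for v in (m.values, s.values):
            assert np.all(v > 0) and np.all(v < 1)

    def test_attention_shrinks_magnitudes(self, rng):
        f = rng.normal(size=(4, 6))
        params = at.SEParams(W1=rng.normal(size=(2, 4)),
                             W2=rng.normal(size=(4, 2)), r=2)
        out, _ = at.tam_apply(f, params)
        nz = f != 0
        assert np.all(np.abs(out[nz]) < np.abs(f[nz]))

    def test_constant_map_pooling_identity(self):
        f = np.full((5, 4), 2.5)
        _, w = at.sam_apply(f, np.array([[1.0], [1.0]]), bias=0.0)
        # avg and max pools both equal the constant; kernel k=1 sums them
        assert np.allclose(w.values, 1.0 / (1.0 + np.exp(-5.0)))

    def test_sam_permutation_equivariant_for_kernel_one(self, rng):
        f = rng.normal(size=(6, 8))
        kernel = np.array([[0.7], [-0.4]])
        perm = rng.permutation(8)
        out, m = at.sam_apply(f, kernel, bias=0.2)
        out_p, m_p = at.sam_apply(f[:, perm], kernel, bias=0.2)
        assert np.allclose(out_p, out[:, perm])
        assert np.allclose(m_p.values, m.values[perm])

    def test_stam_equals_manual_composition(self, rng):
        f = rng.normal(size=(6, 5))
        params = at.SEParams(W1=rng.normal(size=(3, 6)),
                             W2=rng.normal(size=(6, 3)), r=2)
        kernel = rng.normal(size=(2, 3))
        step1, m = at.sam_apply(f, kernel, bias=0.1)
        step2, s = at.tam_apply(step1, params)
        out, m2, s2 = at.stam_apply(f, kernel, params, bias=0.1)
        assert np.allclose(out, step2)
        assert np.allclose(m2.values, m.values)
        assert np.allclose(s2.values, s.values)


class TestValidation:
    def test_even_or_long_kernel_rejected(self):
        f = np.ones((4, 3))
        with pytest.raises(ValueError):
            at.sam_apply(f, np.ones((2, 4)))
        with pytest.raises(ValueError):
            at.sam_apply(f, np.ones((2, 5)))

    def test_ratio_must_divide_c(self):
        with pytest.raises(ValueError):
            at.SEParams(W1=np.zeros((2, 5)), W2=np.zeros((5, 2)), r=3)

    def test_map_must_be_matrix(self):
        with pytest.raises(ValueError):
            at.tam_apply(np.ones(5), at.SEParams.zeros(4))


class TestGradients:
    def _numeric(self, fn, x, eps=1e-6):
        g = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            x[i] += eps
            hi = fn()
            x[i] -= 2 * eps
            lo = fn()
            x[i] += eps
            g[i] = (hi - lo) / (2 * eps)
        return g

    def test_tam_gradients_match_finite_differences(self, rng):
        f = rng.normal(size=(1, 4, 3))
        w1 = rng.normal(size=(2, 4))
        w2 = rng.normal(size=(4, 2))

        def value():
            out, _ = at.tam_forward(Tensor(f), Tensor(w1), Tensor(w2))
            return float((out * out).sum().data)

        tf, t1, t2 = Tensor(f, True), Tensor(w1, True), Tensor(w2, True)
        out, _ = at.tam_forward(tf, t1, t2)
        (out * out).sum().backward()
        for t, arr in ((tf, f), (t1, w1), (t2, w2)):
            assert np.allclose(t.grad, self._numeric(value, arr), atol=1e-4)

    def test_sam_gradients_match_finite_differences(self, rng):
        f = rng.normal(size=(1, 4, 6))
        w = rng.normal(size=(1, 2, 3))
        b = rng.normal(size=1)

        def value():
            out, _ = at.sam_forward(Tensor(f), Tensor(w), Tensor(b))
            return float((out * out).sum().data)

        tf, tw, tb = Tensor(f, True), Tensor(w, True), Tensor(b, True)
        out, _ = at.sam_forward(tf, tw, tb)
        (out * out).sum().backward()
        for t, arr in ((tf, f), (tw, w), (tb, b)):
            assert np.allclose(t.grad, self._numeric(value, arr), atol=1e-4)
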