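import math

import numpy as np
import pytest

from medfuse.errors import ValidationError
from medfuse.metrics import (
    evaluate,
    normalized_fusion_mi,
    q_abf,
    q_w,
    spatial_frequency,
)
from medfuse.saliency import quantize

from _oracles import mi_by_counting

# Self-fusion value of the edge-transfer metric: every weighted pixel sits
# at strength ratio 1 and orientation agreement 1, so the score is exactly
# Qg(1) * Qalpha(1) of the standard sigmoids.
QABF_SELF = (0.9994 / (1 + math.exp(-7.5))) * (0.9879 / (1 + math.exp(-4.4)))


class TestSpatialFrequency:
    def test_constant_image_zero(self):
        assert spatial_frequency(np.full((8, 8), 0.3)) == 0.0

    def test_checkerboard_value(self):
        board = (np.indices((16, 16)).sum(axis=0) % 2).astype(float)
        assert spatial_frequency(board) == pytest.approx(255 * math.sqrt(2), abs=1e-9)

    def test_matches_definition_on_random(self, rng):
        img = rng.random((10, 12))
        arr = img * 255
        rf2 = np.mean((arr[:, 1:] - arr[:, :-1]) ** 2)
        cf2 = np.mean((arr[1:, :] - arr[:-1, :]) ** 2)
        assert spatial_frequency(img) == pytest.approx(math.sqrt(rf2 + cf2))


class TestFusionMI:
    def test_self_fusion_equals_two(self, rng):
        a = rng.random((32, 32))
        assert normalized_fusion_mi(a, a, a) == pytest.approx(2.0, abs=1e-9)

    def test_independent_noise_near_zero(self):
        # 64 bins at 256x256 keeps the finite-sample MI bias (~(bins-1)^2/2N
        # nats) well below the tolerance; at 256 bins the bias alone is ~0.2
        rng = np.random.default_rng(7)
        a, b, f = (rng.random((256, 256)) for _ in range(3))
        assert normalized_fusion_mi(a, b, f, bins=64) < 0.05

    def test_independent_noise_mi_shrinks_with_sample_size(self):
        # at fixed bins the estimate approaches 0 as the sample grows
        rng = np.random.default_rng(11)
        values = []
        for n in (64, 256):
            a, b, f = (rng.random((n, n)) for _ in range(3))
            values.append(normalized_fusion_mi(a, b, f))
        assert values[1] < values[0]

    def test_hand_countable_two_by_two(self):
        # 2x2 toy joint distributions, cross-checked by a dict-counting oracle
        a = np.array([[0.0, 0.0], [1.0, 1.0]])
        b = np.array([[0.0, 1.0], [0.0, 1.0]])
        f = np.array([[0.0, 0.0], [1.0, 0.0]])
        bins = 2
        qa, qb, qf = (quantize(x, bins) for x in (a, b, f))
        mi_fa, hf, ha = mi_by_counting(qf, qa, bins)
        mi_fb, _, hb = mi_by_counting(qf, qb, bins)
        expected = 2 * (mi_fa / (hf + ha) + mi_fb / (hf + hb))
        assert normalized_fusion_mi(a, b, f, bins=bins) == pytest.approx(
            expected, abs=1e-12
        )

    def test_symmetric_in_sources(self, rng):
        a, b, f = (rng.random((16, 16)) for _ in range(3))
        assert normalized_fusion_mi(a, b, f) == pytest.approx(
            normalized_fusion_mi(b, a, f), abs=1e-12
        )

    def test_constant_conventions(self):
        const = np.full((8, 8), 0.5)
        varied = np.linspace(0, 1, 64).reshape(8, 8)
        # identical constants: each ratio 0.5 -> MI = 2
        assert normalized_fusion_mi(const, const, const) == pytest.approx(2.0)
        # constant fused against varied sources: ratios 0 -> MI = 0
        assert normalized_fusion_mi(varied, varied, const) == 0.0

    def test_bad_bins_rejected(self):
        with pytest.raises(ValidationError):
            normalized_fusion_mi(np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((4, 4)), bins=1)


class TestQabf:
    def test_self_fusion_closed_form(self, rng):
        a = rng.random((32, 32))
        assert q_abf(a, a, a) == pytest.approx(QABF_SELF, abs=1e-12)

    def test_constant_fusion_transfers_no_edges(self, rng):
        a, b = rng.random((32, 32)), rng.random((32, 32))
        assert q_abf(a, b, np.full((32, 32), 0.5)) < 0.1

    def test_bounded_on_random_triples(self, rng):
        for _ in range(10):
            a, b, f = (rng.random((16, 16)) for _ in range(3))
            assert 0.0 <= q_abf(a, b, f) <= 1.0

    def test_constant_sources_yield_zero(self):
        c = np.full((16, 16), 0.5)
        assert q_abf(c, c, c) == 0.0


class TestQw:
    def test_self_fusion_is_one(self, rng):
        a = rng.random((32, 32))
        assert q_w(a, a, a) == pytest.approx(1.0, abs=1e-6)

    def test_uncorrelated_noise_near_zero(self, default_pair):
        ct, mr, _ = default_pair
        noise = np.random.default_rng(3).random(ct.shape)
        assert q_w(ct, mr, noise) <= 0.2

    def test_bounded_on_random_triples(self, rng):
        for _ in range(10):
            a, b, f = (rng.random((16, 16)) for _ in range(3))
            assert 0.0 <= q_w(a, b, f) <= 1.0

    def test_even_window_rejected(self, rng):
        a = rng.random((16, 16))
        with pytest.raises(ValidationError):
            q_w(a, a, a, window=6)

    def test_window_larger_than_image_rejected(self, rng):
        a = rng.random((5, 5))
        with pytest.raises(ValidationError):
            q_w(a, a, a, window=7)


class TestEvaluate:
    def test_self_fusion_report(self, rng):
        a = rng.random((32, 32))
        rep = evaluate(a, a, a)
        assert rep.sf == spatial_frequency(a)
        assert rep.mi == pytest.approx(2.0, abs=1e-9)
        assert rep.q_w == pytest.approx(1.0, abs=1e-6)
        assert rep.q_abf == pytest.approx(QABF_SELF, abs=1e-12)
        assert rep.viff is None

    def test_constant_triple_degenerates_gracefully(self):
        c = np.full((16, 16), 0.5)
        rep = evaluate(c, c, c)
        assert rep.sf == 0.0
        assert all(np.isfinite(v) for v in (rep.sf, rep.mi, rep.q_abf, rep.q_w))

    def test_finite_on_random_inputs(self, rng):
        a, b, f = (rng.random((16, 16)) for _ in range(3))
        rep = evaluate(a, b, f)
        assert all(np.isfinite(v) for v in (rep.sf, rep.mi, rep.q_abf, rep.q_w))

    def test_mirror_invariance(self, rng):
        a, b, f = (rng.random((16, 16)) for _ in range(3))
        rep = evaluate(a, b, f)
        rep_m = evaluate(a[:, ::-1], b[:, ::-1], f[:, ::-1])
        assert rep_m.sf == pytest.approx(rep.sf, abs=1e-9)
        assert rep_m.mi == pytest.approx(rep.mi, abs=1e-12)
        assert rep_m.q_w == pytest.approx(rep.q_w, abs=1e-9)
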