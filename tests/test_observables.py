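"""Segregation statistics: slice histograms, mu, rho/lambda, patterns."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleoidmc.interactions import NucleoidVolume
from nucleoidmc.observables import (
    canonical_pattern,
    classify_pattern,
    localization_lambda,
    pattern_frequencies,
    polar_fraction,
    slice_histogram,
    unmixing_mu,
)


def hist(xs, L=2000.0):
    return slice_histogram(np.asarray(xs, float), L)


class TestSliceHistogram:
    def test_all_in_one_slice(self):
        h = hist([-950.0, -980.0, -901.0])
        assert h.h[0] == pytest.approx(1.0)
        assert np.all(h.h[1:] == 0)

    def test_even_split(self):
        h = hist([-950.0, -750.0])
        assert h.h[0] == pytest.approx(0.5)
        assert h.h[1] == pytest.approx(0.5)

    def test_three_bin_weights(self):
        xs = [-950] * 3 + [-750] * 3 + [-550]
        h = hist(xs)
        np.testing.assert_allclose(h.h[:3], [3 / 7, 3 / 7, 1 / 7])

    def test_partial_final_slice_is_own_bin(self):
        h = slice_histogram(np.array([0.0]), 1900.0)
        assert h.n_bins == 10  # 9 x 200 nm + one 100-nm remainder
        assert h.edges[-1] - h.edges[-2] == pytest.approx(100.0)

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        h = hist(rng.uniform(-1000, 1000, size=137))
        assert h.h.sum() == pytest.approx(1.0)


class TestUnmixingMu:
    def test_identical_histograms_mixed(self):
        h = hist([-500.0, 0.0, 500.0])
        assert unmixing_mu(h, h) == pytest.approx(0.0)

    def test_disjoint_supports_unmixed(self):
        h1 = hist([-900.0, -700.0])
        h2 = hist([700.0, 900.0])
        assert unmixing_mu(h1, h2) == pytest.approx(1.0)

    def test_half_overlap(self):
        a = np.array([0.5, 0.5, 0.0])
        b = np.array([0.0, 0.5, 0.5])
        assert unmixing_mu(a, b) == pytest.approx(0.5)

    def test_mismatched_binning_rejected(self):
        with pytest.raises(ValueError):
            unmixing_mu(np.array([1.0]), np.array([0.5, 0.5]))

    @given(
        st.lists(st.floats(0, 1), min_size=4, max_size=4),
        st.lists(st.floats(0, 1), min_size=4, max_size=4),
        st.lists(st.floats(0, 1), min_size=4, max_size=4),
    )
    @settings(max_examples=200, deadline=None)
    def test_metric_axioms(self, a, b, c):
        def norm(v):
            v = np.asarray(v) + 1e-9
            return v / v.sum()

        a, b, c = norm(a), norm(b), norm(c)
        mab = unmixing_mu(a, b)
        assert 0.0 <= mab <= 1.0 + 1e-12
        assert mab == pytest.approx(unmixing_mu(b, a))
        assert unmixing_mu(a, a) == pytest.approx(0.0)
        # triangle inequality (total variation is a metric)
        assert mab <= unmixing_mu(a, c) + unmixing_mu(c, b) + 1e-12


class TestLocalization:
    def test_polar_fraction_counts(self):
        vol = NucleoidVolume(400, 2000)
        x = np.array([0.0, 100.0, 600.0, -700.0, 499.0, 501.0, 80.0, 0.0, 0.0, -502.0])
        assert polar_fraction(x, vol) == pytest.approx(0.4)

    def test_lambda_anchors(self):
        assert localization_lambda(0.5, 0.5) == pytest.approx(0.0)
        assert localization_lambda(1.0, 0.37) == pytest.approx(1.0)
        assert localization_lambda(0.75, 0.5) == pytest.approx(0.5)

    def test_lambda_monotone_in_rho(self):
        rho0 = 0.4
        lams = [localization_lambda(r, rho0) for r in np.linspace(0, 1, 11)]
        assert np.all(np.diff(lams) > 0)

    def test_lambda_undefined_at_rho0_one(self):
        with pytest.raises(ValueError):
            localization_lambda(0.9, 1.0)


class TestPatterns:
    def test_g1_ordering(self):
        pos = [("ter", -800.0), ("left", -300.0), ("ori", 200.0), ("right", 700.0)]
        got = classify_pattern(pos)
        assert got == canonical_pattern("ter-left-ori-right")

    def test_mirror_invariance_and_translation(self):
        pos = [("ter", -800.0), ("left", -300.0), ("ori", 200.0), ("right", 700.0)]
        mirrored = [(lbl, -x) for lbl, x in pos]
        shifted = [(lbl, x + 123.0) for lbl, x in pos]
        assert classify_pattern(pos) == classify_pattern(mirrored)
        assert classify_pattern(pos) == classify_pattern(shifted)

    def test_g2_eight_locus_pattern(self):
        seq = ["left", "ori", "right", "ter", "ter", "left", "ori", "right"]
        pos = [(lbl, -1750.0 + 500.0 * i) for i, lbl in enumerate(seq)]
        assert classify_pattern(pos) == canonical_pattern(
            "left-ori-right-ter-ter-left-ori-right"
        )

    def test_s_phase_copy_labels(self):
        seq = ["ori1", "left", "ter", "right", "ori2"]
        pos = [(lbl, -1000.0 + 500.0 * i) for i, lbl in enumerate(seq)]
        assert classify_pattern(pos) == canonical_pattern("ori1-left-ter-right-ori2")

    def test_coincident_positions_deterministic(self):
        pos = [("b", 0.0), ("a", 0.0), ("c", 10.0)]
        assert classify_pattern(pos) == classify_pattern(list(reversed(pos)))

    def test_frequencies_sum_to_one(self):
        from nucleoidmc.sampler import Trajectory
        from tests.conftest import ring_structure

        st_ = ring_structure(12)
        rng = np.random.default_rng(3)
        frames = rng.normal(scale=300, size=(25, st_.n_vertices, 3))
        traj = Trajectory(
            structure=st_,
            frames=frames,
            sweeps=np.arange(25),
            volume=NucleoidVolume(400, 2000),
            seed=0,
        )
        loci = [("a", 0), ("b", 4), ("c", 8)]
        freqs = pattern_frequencies(traj, loci)
        assert sum(freqs.values()) == pytest.approx(1.0)

    def test_two_state_stream_counts(self):
        from nucleoidmc.sampler import Trajectory
        from tests.conftest import ring_structure

        st_ = ring_structure(12)
        frames = np.zeros((10, st_.n_vertices, 3))
        # 6 frames a<b, 4 frames b<a
        for i in range(10):
            frames[i, 0, 0] = -100.0 if i < 6 else 100.0
            frames[i, 4, 0] = 100.0 if i < 6 else -100.0
            frames[i, 8, 0] = 500.0
        traj = Trajectory(
            structure=st_,
            frames=frames,
            sweeps=np.arange(10),
            volume=NucleoidVolume(400, 2000),
            seed=0,
        )
        freqs = pattern_frequencies(traj, [("a", 0), ("b", 4), ("c", 8)])
        assert freqs[canonical_pattern("a-b-c")] == pytest.approx(0.6)
        assert freqs[canonical_pattern("b-a-c")] == pytest.approx(0.4)
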