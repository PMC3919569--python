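"""Chain discretization, geometry and intrinsic-energy primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleoidmc.chain import (
    ChainPlacement,
    ChainSpec,
    ChainTooShortError,
    Conformation,
    Region,
    Structure,
    Topology,
    bending_energy,
    bending_energy_points,
    discretize_chromosome,
    has_overlap,
    kappa_for_persistence_length,
    min_segment_distance,
    radius_of_gyration,
)
from tests.conftest import ring_structure


@pytest.mark.parametrize(
    "bp,circular,expected",
    [
        (4_640_000, True, 1392),  # E. coli chromosome at 100 bp/nm, ls = 100/3
        (2_300_000, False, 690),
        (200_000, True, 60),
    ],
)
def test_discretization_counts(bp, circular, expected):
    spec = discretize_chromosome(ChainSpec(genome_length_bp=bp, circular=circular))
    assert spec.n_segments == expected


def test_discretization_scale_consistency():
    a = discretize_chromosome(ChainSpec(genome_length_bp=1_000_000))
    b = discretize_chromosome(ChainSpec(genome_length_bp=2_000_000))
    assert abs(b.n_segments - 2 * a.n_segments) <= 1


def test_too_short_circular_chain_rejected():
    with pytest.raises(ChainTooShortError):
        discretize_chromosome(ChainSpec(genome_length_bp=1_000))


def test_hard_core_diameter_range_enforced():
    with pytest.raises(ValueError):
        discretize_chromosome(
            ChainSpec(genome_length_bp=1_000_000, hard_core_diameter_nm=60.0)
        )


def test_calibrated_kappa_reproduces_persistence_length():
    # <cos theta> of the discrete chain must equal exp(-ls/lp)
    k = kappa_for_persistence_length(100.0, 100.0 / 3.0)
    mean_cos = 1.0 / np.tanh(k) - 1.0 / k
    assert mean_cos == pytest.approx(np.exp(-1.0 / 3.0), rel=1e-10)
    # and the naive constant would undershoot
    naive = 3.0
    lp_naive = -(100.0 / 3.0) / np.log(1.0 / np.tanh(naive) - 1.0 / naive)
    assert lp_naive < 90.0


class TestBendingEnergy:
    def test_straight_chain_is_zero(self):
        pts = np.zeros((5, 3))
        pts[:, 0] = np.arange(5.0)
        assert bending_energy_points(pts, 3.0, circular=False) == pytest.approx(0.0)

    def test_single_right_angle(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 1.0, 0]])
        assert bending_energy_points(pts, 3.0, circular=False) == pytest.approx(3.0)

    def test_regular_polygon_closed_form(self):
        # ring polygon: every joint bent by 2*pi/N, closure joint included
        st_ = ring_structure(100)
        from nucleoidmc.sampler import initialize_conformation

        conf = initialize_conformation(st_)
        kappa = st_.joint_kappa[0]
        expected = kappa * 100 * (1 - np.cos(2 * np.pi / 100))
        assert bending_energy(conf) == pytest.approx(expected, rel=1e-9)


class TestSegmentDistance:
    def test_parallel_offset(self):
        d = min_segment_distance([0, 0, 0], [1, 0, 0], [0, 40, 0], [1, 40, 0])
        assert d == pytest.approx(40.0)

    def test_crossing_perpendicular(self):
        d = min_segment_distance([-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0])
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_random_skew_pairs_match_dense_sampling(self, rng):
        # dense-point-sampling oracle: 300 points per segment
        t = np.linspace(0.0, 1.0, 300)
        for _ in range(25):
            a0, a1, b0, b1 = rng.normal(scale=3.0, size=(4, 3))
            pa = a0 + t[:, None] * (a1 - a0)
            pb = b0 + t[:, None] * (b1 - b0)
            brute = np.min(
                np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
            )
            exact = min_segment_distance(a0, a1, b0, b1)
            assert exact <= brute + 1e-9
            assert exact == pytest.approx(brute, abs=0.05)


class TestOverlap:
    def test_threshold_behaviour(self):
        # two straight 2-segment chains at controlled separation
        def two_chains(gap):
            spec = discretize_chromosome(
                ChainSpec(genome_length_bp=int(2 * 10000 / 3), circular=False)
            )
            topo = Topology(
                [ChainPlacement(spec, "a"), ChainPlacement(spec, "b")]
            )
            s = Structure(topo)
            pos = np.zeros((s.n_vertices, 3))
            ls = s.segment_length_nm
            for c in range(2):
                ids = s.chain_vertices(c)
                pos[ids, 0] = np.arange(len(ids)) * ls
                pos[ids, 1] = gap * c
            return Conformation(s, pos)

        assert has_overlap(two_chains(34.9)) is True
        assert has_overlap(two_chains(35.1)) is False

    def test_straight_chain_not_self_overlapping(self):
        # ls < hard-core diameter: next-nearest exclusion must allow a rod
        from tests.conftest import linear_structure
        from nucleoidmc.sampler import initialize_conformation

        st_ = linear_structure(20)
        conf = initialize_conformation(st_)
        assert has_overlap(conf) is False

    def test_symmetry_and_rigid_motion_invariance(self, rng):
        st_ = ring_structure(40)
        from nucleoidmc.sampler import initialize_conformation

        conf = initialize_conformation(st_)
        base = has_overlap(conf)
        # random rotation + translation
        q = rng.normal(size=(3, 3))
        u, _, vt = np.linalg.svd(q)
        R = u @ vt
        if np.linalg.det(R) < 0:
            R[:, 0] *= -1
        conf2 = Conformation(st_, conf.pos @ R.T + rng.normal(scale=500, size=3))
        assert has_overlap(conf2) == base


class TestRadiusOfGyration:
    def test_single_vertex_zero(self):
        st_ = ring_structure(10)
        conf = Conformation(st_, np.random.default_rng(0).normal(size=(10, 3)))
        assert radius_of_gyration(conf, subset=[3]) == pytest.approx(0.0)

    def test_two_vertices(self):
        st_ = ring_structure(10)
        pos = np.zeros((10, 3))
        pos[1, 0] = 2.0
        conf = Conformation(st_, pos)
        assert radius_of_gyration(conf, subset=[0, 1]) == pytest.approx(1.0)

    def test_square_corners(self):
        st_ = ring_structure(10)
        pos = np.zeros((10, 3))
        s = 7.0
        pos[:4, :2] = [[0, 0], [s, 0], [s, s], [0, s]]
        conf = Conformation(st_, pos)
        assert radius_of_gyration(conf, subset=range(4)) == pytest.approx(
            s / np.sqrt(2)
        )

    def test_empty_subset_rejected(self):
        st_ = ring_structure(10)
        conf = Conformation(st_, np.zeros((10, 3)))
        with pytest.raises(ValueError):
            radius_of_gyration(conf, subset=[])


class TestRegionsAndGenomicMap:
    def test_region_wrapping_contains(self):
        r = Region("NS", 4_300_000, 300_000)
        assert r.contains(4_500_000, 4_640_000)
        assert r.contains(100_000, 4_640_000)
        assert not r.contains(2_000_000, 4_640_000)

    def test_every_bp_maps_to_exactly_one_vertex_position(self):
        st_ = ring_structure(60)
        pl = st_.topology.chains[0]
        n = pl.spec.n_vertices
        positions = [pl.position_of_bp(bp) for bp in range(0, pl.spec.genome_length_bp, 1000)]
        assert set(positions) <= set(range(n))
        # monotone along the chain (up to the circular wrap)
        jumps = np.diff(positions)
        assert np.sum(jumps < 0) <= 1

    @given(st.integers(min_value=0, max_value=199_999))
    @settings(max_examples=50, deadline=None)
    def test_bp_vertex_roundtrip(self, bp):
        st_ = ring_structure(60)
        pl = st_.topology.chains[0]
        k = pl.position_of_bp(bp)
        assert abs((pl.bp_of_position(k) - bp + 100_000) % 200_000 - 100_000) <= (
            pl.spec.bp_per_segment / 2 + 1
        )


class TestJunctionTopologies:
    def test_g2_junction_merged_vertex(self):
        from nucleoidmc.scenarios import build_preset

        su = build_preset("g2-homogeneous", genome_length_bp=200_000)
        st_ = su.structure
        # two rings of 60 minus one merged terminus vertex
        assert st_.n_vertices == 2 * 60 - 1
        assert st_.n_segments == 120
        assert int(np.sum(st_.degree == 4)) == 1

    def test_s_phase_connectivity_and_bp_conservation(self):
        from nucleoidmc.scenarios import build_preset

        su = build_preset("s-homogeneous", genome_length_bp=200_000)
        st_ = su.structure
        juncs = np.where(st_.degree == 3)[0]
        assert len(juncs) == 2
        # total bp: unreplicated counted once, replicated twice
        n_u = len(st_.chain_vertices(0)) - 1
        n_r = len(st_.chain_vertices(1)) - 1
        N = 60
        assert n_u + n_r == N
        assert st_.n_segments == n_u + 2 * n_r
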