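"""Monte-Carlo engine: move validity, Boltzmann correctness, determinism."""

import numpy as np
import pytest

from nucleoidmc.chain import (
    ChainPlacement,
    ChainSpec,
    Conformation,
    Structure,
    Topology,
    has_overlap,
    radius_of_gyration,
)
from nucleoidmc.engine import Engine
from nucleoidmc.interactions import (
    EnergyModel,
    NucleoidVolume,
    PinConstraint,
    total_energy,
)
from nucleoidmc.sampler import (
    MCConfig,
    RunState,
    initialize_conformation,
    metropolis_accept,
    metropolis_step,
    propose_block_move,
    run_sampling,
)
from tests.conftest import linear_structure, ring_structure


def make_engine(st_, model=None, vol=None, seed=11, **kw):
    conf = initialize_conformation(st_)
    return Engine(st_, model or EnergyModel(confinement=False), vol, conf, seed, **kw)


class TestProposals:
    def test_zero_amplitude_is_identity(self, rng):
        st_ = ring_structure(30)
        conf = initialize_conformation(st_)
        cand = propose_block_move(conf, rng, amplitude=0.0)
        np.testing.assert_allclose(cand.pos, conf.pos, atol=1e-12)

    def test_anchors_unmoved(self, rng):
        st_ = ring_structure(30)
        conf = initialize_conformation(st_)
        for _ in range(20):
            cand = propose_block_move(conf, rng, amplitude=2.0)
            moved = np.any(np.abs(cand.pos - conf.pos) > 1e-12, axis=1)
            # crankshaft: a contiguous block moves, its two anchors do not
            assert not np.all(moved)
            conf = cand

    def test_bond_rigidity_after_many_kernel_moves(self):
        st_ = ring_structure(60)
        eng = make_engine(st_)
        eng.run(200_000)
        conf = eng.conformation()
        assert conf.max_bond_error() < 1e-9

    def test_junction_bond_rigidity_s_phase(self):
        from nucleoidmc.scenarios import build_preset

        su = build_preset("s-homogeneous", genome_length_bp=200_000)
        conf = initialize_conformation(su.structure)
        eng = Engine(su.structure, su.model, su.volume, conf, seed=4)
        eng.set_confinement(su.volume.radius_nm * 20, su.volume.half_length_nm * 20)
        eng.ensure_grid_covers(su.volume.radius_nm * 20, su.volume.half_length_nm * 20)
        eng.run(100_000)
        c = eng.conformation()
        assert c.max_bond_error() < 1e-9
        assert not has_overlap(c)


class TestMetropolis:
    def test_zero_delta_always_accepted(self, rng):
        assert all(metropolis_accept(0.0, rng) for _ in range(100))

    def test_hard_reject(self, rng):
        assert not metropolis_accept(np.inf, rng)

    def test_unit_delta_acceptance_rate(self, rng):
        n = 100_000
        acc = sum(metropolis_accept(1.0, rng) for _ in range(n))
        p = np.exp(-1.0)
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(acc / n - p) < 3 * sigma

    def test_reference_step_on_small_ring(self, rng):
        st_ = ring_structure(12)
        conf = initialize_conformation(st_)
        model = EnergyModel(confinement=False)
        for _ in range(30):
            conf, _ = metropolis_step(conf, model, None, rng, max_block_length=4)
        assert conf.max_bond_error() < 1e-9
        assert np.isfinite(total_energy(conf, model, None))


class TestBoltzmannCorrectness:
    def test_tethered_vertex_equipartition(self):
        # single vertex in a 3D harmonic well: var = 1/k per axis
        spec = ChainSpec(
            genome_length_bp=300, circular=False, n_segments=0
        )
        topo = Topology([ChainPlacement(spec, "pt")])
        st_ = Structure(topo)
        assert st_.n_vertices == 1
        k = 1.2e-3
        pin = PinConstraint(locus_bp=0, target=(0.0, 0.0, 0.0), spring_constant=k)
        pin.resolve(st_)
        model = EnergyModel(
            confinement=False, self_avoidance=False, pin_constraints=[pin]
        )
        vol = NucleoidVolume(400, 2000)
        eng = Engine(
            st_,
            model,
            vol,
            Conformation(st_, np.zeros((1, 3))),
            seed=5,
            translations=True,
            translation_amplitude_nm=40.0,
        )
        xs = np.empty((4000, 3))
        eng.run(20_000)
        for i in range(len(xs)):
            eng.run(60)
            xs[i] = eng.pos[0]
        var = xs.var(axis=0)
        se = np.sqrt(2.0 / len(xs)) * (1 / k)  # var estimator SE for Gaussian
        for ax in range(3):
            assert abs(var[ax] - 1 / k) < 4 * se
        # doubling the spring constant halves the variance
        pin2 = PinConstraint(locus_bp=0, target=(0.0, 0.0, 0.0), spring_constant=2 * k)
        pin2.resolve(st_)
        eng2 = Engine(
            st_,
            EnergyModel(confinement=False, self_avoidance=False, pin_constraints=[pin2]),
            vol,
            Conformation(st_, np.zeros((1, 3))),
            seed=6,
            translations=True,
            translation_amplitude_nm=30.0,
        )
        eng2.run(20_000)
        xs2 = np.empty((4000, 3))
        for i in range(len(xs2)):
            eng2.run(60)
            xs2[i] = eng2.pos[0]
        assert np.mean(xs2.var(axis=0)) == pytest.approx(
            0.5 * np.mean(var), rel=0.15
        )

    def test_tethered_vertex_gaussian_ks(self):
        from scipy.stats import kstest

        spec = ChainSpec(genome_length_bp=300, circular=False, n_segments=0)
        st_ = Structure(Topology([ChainPlacement(spec, "pt")]))
        k = 1.0e-3
        pin = PinConstraint(
            locus_bp=0, target=(0.0, 0.0, 0.0), spring_constant=k
        ).resolve(st_)
        eng = Engine(
            st_,
            EnergyModel(confinement=False, self_avoidance=False, pin_constraints=[pin]),
            NucleoidVolume(400, 2000),
            Conformation(st_, np.zeros((1, 3))),
            seed=17,
            translations=True,
            translation_amplitude_nm=40.0,
        )
        eng.run(20_000)
        xs = np.empty(10_000)
        for i in range(len(xs)):
            eng.run(25)
            xs[i] = eng.pos[0, 0]
        stat = kstest(xs, "norm", args=(0.0, np.sqrt(1 / k)))
        assert stat.pvalue > 0.01

    def test_phantom_ring_gyration_radius(self):
        # ideal (phantom, unbent) ring: <Rg^2> -> N ls^2 / 12
        N = 100
        st_ = ring_structure(N)
        model = EnergyModel(bending=False, self_avoidance=False, confinement=False)
        eng = make_engine(st_, model=model, seed=9, max_block_length=49)
        ls = st_.segment_length_nm
        eng.run(150_000)
        rg2 = []
        for _ in range(150):
            eng.run(3_000)
            rg2.append(radius_of_gyration(eng.conformation()) ** 2)
        rg2 = np.array(rg2)
        expected = N * ls**2 / 12.0
        r = np.corrcoef(rg2[:-1], rg2[1:])[0, 1]
        neff = len(rg2) * (1 - max(r, 0)) / (1 + max(r, 0))
        sem = rg2.std() / np.sqrt(max(neff, 2))
        assert abs(rg2.mean() - expected) < 3.5 * sem + 0.02 * expected

    def test_phantom_linear_gyration_radius(self):
        N = 100
        st_ = linear_structure(N)
        model = EnergyModel(bending=False, self_avoidance=False, confinement=False)
        eng = make_engine(st_, model=model, seed=10, max_block_length=50)
        ls = st_.segment_length_nm
        eng.run(150_000)
        rg2 = []
        for _ in range(150):
            eng.run(3_000)
            rg2.append(radius_of_gyration(eng.conformation()) ** 2)
        rg2 = np.array(rg2)
        expected = N * ls**2 / 6.0
        r = np.corrcoef(rg2[:-1], rg2[1:])[0, 1]
        neff = len(rg2) * (1 - max(r, 0)) / (1 + max(r, 0))
        sem = rg2.std() / np.sqrt(max(neff, 2))
        assert abs(rg2.mean() - expected) < 3.5 * sem + 0.03 * expected


class TestOverlapKernelAgainstBruteForce:
    def test_kernel_and_reference_agree_during_run(self):
        # the cell-list path must never accept a state the O(S^2) oracle
        # rejects
        st_ = ring_structure(60)
        eng = make_engine(st_, seed=13)
        for _ in range(10):
            eng.run(20_000)
            assert not has_overlap(eng.conformation())

    def test_dense_confined_run_stays_valid(self):
        from nucleoidmc.interactions import NucleoidVolume

        st_ = ring_structure(120)
        vol = NucleoidVolume(400, 800)
        conf = initialize_conformation(st_)
        eng = Engine(st_, EnergyModel(), vol, conf, seed=14)
        from nucleoidmc.sampler import AnnealSchedule, RunState, run_annealing

        state = RunState(eng, MCConfig(seed=14), vol)
        run_annealing(state, AnnealSchedule(sweeps_per_stage=4000))
        for _ in range(5):
            eng.run(20_000)
            eng.audit(check_overlap=True)


class TestLongitudinalPin:
    def test_radial_distribution_unaffected(self):
        """A longitudinal (class-target) pin penalizes x only; the pinned
        locus's radial distribution must match the unpinned case."""
        from scipy.stats import ks_2samp

        from nucleoidmc.sampler import AnnealSchedule, run_annealing

        radial = {}
        for pinned in (False, True):
            st_ = ring_structure(60)
            vol = NucleoidVolume(400, 1000)
            pins = []
            if pinned:
                pins = [
                    PinConstraint(locus_bp=0, target="mid-cell").resolve(st_)
                ]
            eng = Engine(
                st_,
                EnergyModel(pin_constraints=pins),
                vol,
                initialize_conformation(st_),
                seed=33,
            )
            state = RunState(eng, MCConfig(seed=33), vol)
            run_annealing(state, AnnealSchedule(sweeps_per_stage=4_000))
            eng.run(100_000)
            locus = st_.vertex_of_bp(0, 0)
            r = np.empty(600)
            for i in range(len(r)):
                eng.run(800)
                r[i] = np.hypot(eng.pos[locus, 1], eng.pos[locus, 2])
            radial[pinned] = r
        stat = ks_2samp(radial[False], radial[True])
        assert stat.pvalue > 0.01


class TestDeterminism:
    def test_same_seed_same_stream(self):
        st_ = ring_structure(40)
        res = []
        for rep in range(2):
            eng = make_engine(st_, seed=21)
            eng.run(50_000)
            res.append(eng.pos.copy())
        np.testing.assert_array_equal(res[0], res[1])

    def test_run_sampling_frames_reproducible(self):
        st_ = ring_structure(40)
        outs = []
        for rep in range(2):
            eng = make_engine(st_, seed=22)
            state = RunState(
                eng,
                MCConfig(seed=22, n_sweeps=30_000, sample_interval_sweeps=3_000),
                None,
            )
            traj = run_sampling(state)
            outs.append(traj.frames.copy())
        np.testing.assert_array_equal(outs[0], outs[1])
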