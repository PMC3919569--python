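"""Phase setups, macrodomain layout and the experiment grid."""

import numpy as np
import pytest

from nucleoidmc.chain import DEFAULT_GENOME_BP, DIF_BP, ORIC_BP
from nucleoidmc.scenarios import (
    MD_REGION_LABELS,
    PRESETS,
    build_phase_setup,
    build_preset,
    default_md_layout,
    experiment_grid,
)

SCALED = 1_546_667  # one-third genome used by the desk-scale runs


class TestMDLayout:
    def test_default_regions_tile_genome(self):
        layout = default_md_layout()
        total = sum(r.length_bp(DEFAULT_GENOME_BP) for r in layout.regions)
        assert total == DEFAULT_GENOME_BP
        assert {r.label for r in layout.regions} == {
            "Ori", "Right", "Ter", "Left", "NS-right", "NS-left",
        }
        assert layout.condensed == MD_REGION_LABELS

    def test_md_widths(self):
        layout = default_md_layout()
        for lbl in MD_REGION_LABELS:
            assert layout.region(lbl).length_bp(DEFAULT_GENOME_BP) == 800_000

    def test_anchors(self):
        layout = default_md_layout()
        assert layout.region("Ori").center_bp(DEFAULT_GENOME_BP) == ORIC_BP
        assert layout.region("Ter").center_bp(DEFAULT_GENOME_BP) == DIF_BP

    def test_reporter_tags(self):
        layout = default_md_layout()
        assert layout.reporter("left") == 2_616_013
        assert layout.reporter("right") == 738_100
        assert layout.reporter("ori") == 4_413_507

    def test_scaled_layout_preserves_fractions(self):
        layout = default_md_layout(SCALED)
        frac = layout.region("Ter").length_bp(SCALED) / SCALED
        assert frac == pytest.approx(800_000 / DEFAULT_GENOME_BP, rel=1e-4)


class TestPhaseSetups:
    def test_g1_full_scale_segment_count(self):
        su = build_phase_setup("G1", 2000)
        assert su.structure.n_segments == 1392
        assert not su.model.md_constraints
        assert not su.model.pin_constraints

    def test_g2_shared_terminus(self):
        su = build_phase_setup("G2", 3600, genome_length_bp=SCALED)
        st_ = su.structure
        assert st_.n_vertices == 2 * 464 - 1
        j = np.where(st_.degree == 4)[0]
        assert len(j) == 1
        # the shared vertex is the dif locus of both rings
        assert st_.vertex_of_bp(int(DIF_BP * SCALED / DEFAULT_GENOME_BP), 0) == j[0]
        assert st_.vertex_of_bp(int(DIF_BP * SCALED / DEFAULT_GENOME_BP), 1) == j[0]

    def test_g2_dissociated_termini_variant(self):
        su = build_phase_setup(
            "G2", 3600, genome_length_bp=SCALED, dissociated_termini=True
        )
        assert su.structure.n_vertices == 2 * 464
        assert int(np.max(su.structure.degree)) == 2

    def test_s_phase_genomic_conservation(self):
        su = build_phase_setup("S", 2600, genome_length_bp=SCALED)
        st_ = su.structure
        n_u = len(st_.chain_vertices(0)) - 1
        n_r = len(st_.chain_vertices(1)) - 1
        assert n_u + n_r == 464  # unreplicated once, replicated twice
        assert len(st_.chain_vertices(1)) == len(st_.chain_vertices(2))
        # replicated piece is ~2.24/4.64 of the genome (NS+Ori+NS)
        assert n_r / 464 == pytest.approx(2_240_000 / 4_640_000, abs=0.01)

    def test_s_phase_fork_positions(self):
        su = build_phase_setup("S", 2600, genome_length_bp=SCALED)
        st_ = su.structure
        layout = su.layout
        juncs = np.where(st_.degree == 3)[0]
        fork_bps = {
            int(round(st_.bp_of_vertex_position(0, 0))),
            int(round(st_.bp_of_vertex_position(0, len(st_.chain_vertices(0)) - 1))),
        }
        expected = {layout.region("Right").start_bp, layout.region("Left").end_bp}
        for bp in fork_bps:
            assert min(abs(bp - e) for e in expected) <= SCALED / 464 + 1
        assert len(juncs) == 2

    def test_s_phase_md_copies(self):
        su = build_phase_setup("S", 2600, condensed="all", genome_length_bp=SCALED)
        labels = [(m.region.label, m.chain) for m in su.model.md_constraints]
        assert ("Ori", 1) in labels and ("Ori", 2) in labels
        assert ("Ter", 0) in labels
        assert ("Ori", 0) not in labels

    def test_pins_assign_symmetric_quarters(self):
        su = build_phase_setup(
            "G2", 3600, pins={"ori": "quarter"}, genome_length_bp=SCALED
        )
        xs = sorted(p.target_x(su.volume) for p in su.model.pin_constraints)
        assert xs == [-900.0, 900.0]

    def test_bad_pin_locus_rejected(self):
        with pytest.raises(ValueError):
            build_phase_setup("G1", 2000, pins={"nonsense": "mid-cell"})

    def test_no_ns_control_condenses_everything(self):
        su = build_phase_setup(
            "G1", 2000, condensed="all+ns", genome_length_bp=SCALED
        )
        assert len(su.model.md_constraints) == 6

    def test_vertex_in_single_md(self):
        su = build_phase_setup("G2", 3600, condensed="all", genome_length_bp=SCALED)
        claimed = {}
        for i, md in enumerate(su.model.md_constraints):
            for v in md.vertices:
                assert v not in claimed
                claimed[v] = i


class TestGridAndPresets:
    def test_every_preset_builds(self):
        for name in PRESETS:
            su = build_preset(name, genome_length_bp=200_000)
            assert su.structure.n_vertices > 0

    def test_grid_contains_published_conditions(self):
        names = [n for n, _ in experiment_grid()]
        assert "g1-ori-midcell" in names  # forced ori at mid-cell
        assert "g2-mds-pinned" in names
        assert any(n.startswith("fig6-md400-fiber35") for n in names)
        # three fiber widths, two condensation protocols in the scan
        assert any("fiber30" in n and "after" in n for n in names)
        assert any("fiber40" in n and "before" in n for n in names)

    def test_mirror_symmetry_of_unpinned_g1(self):
        # without pins, locus statistics must be symmetric about mid-cell
        from nucleoidmc.sampler import AnnealSchedule, MCConfig, simulate
        from nucleoidmc.observables import locus_positions

        su = build_preset("g1-homogeneous", genome_length_bp=200_000)
        mc = MCConfig(
            seed=8, n_sweeps=400_000, sample_interval_sweeps=1_000,
            equilibration_sweeps=100_000,
        )
        traj = simulate(su, mc, AnnealSchedule(sweeps_per_stage=4_000))
        df = locus_positions(traj, su.loci)
        mean_frac = df.groupby("locus")["fraction"].mean()
        # sampling error at ~few hundred weakly correlated frames
        assert np.all(np.abs(mean_frac - 0.5) < 0.22)
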