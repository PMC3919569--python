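"""Phase setups: G1/S/G2 topologies, macrodomain layout, experiment grid.

The chromosome is divided into four ~800-kb regions that condense into
macrodomains (Ori, Right, Ter, Left) plus two non-structured (NS) regions
flanking Ori.  Default boundaries are 800-kb intervals anchored at oriC
(3,925,744 bp) and dif (1,588,800 bp) on the 4.64-Mb map; for reduced
genome lengths (desk-scale runs) every coordinate scales proportionally,
so region mass fractions are preserved.

Phases:

* G1 — one circular chromosome.
* S  — half-replicated: one linear unreplicated piece (Right+Ter+Left)
  and two linear replicated copies (NS-left+Ori+NS-right), all three
  bound together at the two replication forks, which sit at the upper
  (ori-proximal) borders of the Left and Right macrodomains.
* G2 — two circular chromosomes sharing their replication-terminus vertex
  (optionally dissociated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain import (
    DEFAULT_GENOME_BP,
    DIF_BP,
    ORIC_BP,
    ChainPlacement,
    ChainSpec,
    Conformation,
    Region,
    Structure,
    Topology,
    discretize_chromosome,
)
from .interactions import (
    DEFAULT_MD_SPRING,
    DEFAULT_PIN_SPRING,
    EnergyModel,
    MDConstraint,
    NucleoidVolume,
    PinConstraint,
)

MD_WIDTH_BP = 800_000
#: fluorescent-tag coordinates used in vivo (full-genome map)
TAG_BP = {"ori": 4_413_507, "right": 738_100, "left": 2_616_013, "ter": DIF_BP}
PHASE_LENGTHS_NM = {"G1": (1800.0, 2000.0), "S": (2600.0, 3000.0), "G2": (3600.0,)}
MD_REGION_LABELS = ("Ori", "Right", "Ter", "Left")


@dataclass
class MDLayout:
    """Six-region tiling of the circular genome."""

    genome_length_bp: int
    regions: list[Region]
    condensed: tuple[str, ...] = MD_REGION_LABELS

    def region(self, label: str) -> Region:
        for r in self.regions:
            if r.label.lower() == label.lower():
                return r
        raise KeyError(label)

    def reporter(self, label: str) -> int:
        """bp of the imaging tag associated with a region (scaled map)."""
        scale = self.genome_length_bp / DEFAULT_GENOME_BP
        return int(round(TAG_BP[label.lower().replace("-region", "")] * scale))

    def validate(self) -> None:
        total = sum(r.length_bp(self.genome_length_bp) for r in self.regions)
        if total != self.genome_length_bp:
            raise ValueError(
                f"regions cover {total} bp of {self.genome_length_bp}"
            )
        # pairwise disjoint: check every region start against the others
        for r in self.regions:
            hits = sum(
                other.contains(r.start_bp, self.genome_length_bp)
                for other in self.regions
            )
            if hits != 1:
                raise ValueError(f"overlapping regions at {r.start_bp}")


def default_md_layout(
    genome_length_bp: int = DEFAULT_GENOME_BP,
    condensed: tuple[str, ...] = MD_REGION_LABELS,
) -> MDLayout:
    """Ori/Right/Ter/Left (~800 kb each) + NS-right/NS-left tiling."""
    G = genome_length_bp
    s = G / DEFAULT_GENOME_BP

    def bp(x):
        return int(round(x * s)) % G

    w2 = MD_WIDTH_BP / 2
    ori = Region("Ori", bp(ORIC_BP - w2), bp(ORIC_BP + w2))
    ter = Region("Ter", bp(DIF_BP - w2), bp(DIF_BP + w2), reporter_bp=bp(DIF_BP))
    right = Region(
        "Right", bp(DIF_BP - w2 - MD_WIDTH_BP), bp(DIF_BP - w2), reporter_bp=bp(TAG_BP["right"])
    )
    left = Region(
        "Left", bp(DIF_BP + w2), bp(DIF_BP + w2 + MD_WIDTH_BP), reporter_bp=bp(TAG_BP["left"])
    )
    ns_right = Region("NS-right", ori.end_bp, right.start_bp)
    ns_left = Region("NS-left", left.end_bp, ori.start_bp)
    layout = MDLayout(G, [ori, ns_right, right, ter, left, ns_left], condensed)
    layout.validate()
    return layout


@dataclass
class PhaseSetup:
    """A complete, runnable system for one cell-cycle phase."""

    phase: str
    volume: NucleoidVolume
    topology: Topology
    structure: Structure
    model: EnergyModel
    layout: MDLayout
    loci: list[tuple[str, int]] = field(default_factory=list)  # (label, vertex)
    name: str = ""

    @property
    def vertex_region(self) -> np.ndarray:
        """Region label index per global vertex (first matching chain)."""
        st = self.structure
        out = np.full(st.n_vertices, -1, dtype=np.int32)
        for c in range(st.n_chains):
            pl = st.topology.chains[c]
            ids = st.chain_vertices(c)
            for k, v in enumerate(ids):
                if out[v] >= 0:
                    continue
                bp = int(round(pl.bp_of_position(k))) % self.layout.genome_length_bp
                for ri, r in enumerate(self.layout.regions):
                    if r.contains(bp, self.layout.genome_length_bp):
                        out[v] = ri
                        break
        return out

    def region_labels(self) -> list[str]:
        return [r.label for r in self.layout.regions]


def _ring_spec(genome_bp: int, fiber_diameter_nm: float) -> ChainSpec:
    return discretize_chromosome(
        ChainSpec(genome_length_bp=genome_bp, hard_core_diameter_nm=fiber_diameter_nm)
    )


def build_phase_setup(
    phase: str,
    nucleoid_length_nm: float | None = None,
    condensed: tuple[str, ...] | str = (),
    pins: dict[str, str] | None = None,
    genome_length_bp: int = DEFAULT_GENOME_BP,
    fiber_diameter_nm: float = 35.0,
    md_diameter_nm: float = 360.0,
    md_center_rule: str = "center-of-mass",
    md_spring: float = DEFAULT_MD_SPRING,
    pin_spring: float = DEFAULT_PIN_SPRING,
    dissociated_termini: bool = False,
    nucleoid_radius_nm: float = 400.0,
    single_md: str | None = None,
) -> PhaseSetup:
    """Assemble topology + constraints + tracked loci for one phase.

    ``condensed`` lists the regions folded into macrodomains ("all" = the
    four MD regions; "all+ns" adds the NS regions, the no-NS control).
    ``pins`` maps locus names ('ori', 'ter') to target classes ('mid-cell',
    'quarter', 'pole', 'septum'); quarter/pole signs are assigned per
    chromosome copy.  ``single_md`` condenses just one region at
    ``md_diameter_nm`` (the single-MD localization experiments).
    """
    phase = phase.upper()
    if phase not in PHASE_LENGTHS_NM:
        raise ValueError(f"unknown phase {phase!r}")
    if nucleoid_length_nm is None:
        nucleoid_length_nm = PHASE_LENGTHS_NM[phase][0]
    vol = NucleoidVolume(nucleoid_radius_nm, nucleoid_length_nm)
    layout = default_md_layout(genome_length_bp)
    G = genome_length_bp
    if condensed == "all":
        condensed = MD_REGION_LABELS
    elif condensed == "all+ns":
        condensed = tuple(r.label for r in layout.regions)
    if single_md is not None:
        condensed = (single_md,)
    pins = dict(pins or {})

    ring = _ring_spec(G, fiber_diameter_nm)
    N = ring.n_segments

    if phase == "G1":
        topo = Topology([ChainPlacement(ring, "chr", start_bp=0)])
        md_chains = {lbl: [0] for lbl in condensed}
    elif phase == "G2":
        dif = int(round(DIF_BP * G / DEFAULT_GENOME_BP))
        c1 = ChainPlacement(ring, "chr1", start_bp=dif)
        c2 = ChainPlacement(ring, "chr2", start_bp=dif)
        junctions = [] if dissociated_termini else [[(0, 0), (1, 0)]]
        topo = Topology([c1, c2], junctions)
        md_chains = {lbl: [0, 1] for lbl in condensed}
    else:  # S phase, half-replicated
        # forks at the ori-proximal borders of Right and Left
        fork_r_bp = layout.region("Right").start_bp
        fork_l_bp = layout.region("Left").end_bp
        kr = int(round(fork_r_bp * N / G))
        kl = int(round(fork_l_bp * N / G))
        n_unrep = kl - kr
        n_rep = N - n_unrep
        bp_per_seg = G / N

        def piece(n_seg, label):
            return ChainSpec(
                genome_length_bp=int(round(n_seg * bp_per_seg)),
                bp_per_nm=ring.bp_per_nm,
                persistence_length_nm=ring.persistence_length_nm,
                cylinders_per_persistence_length=ring.cylinders_per_persistence_length,
                hard_core_diameter_nm=fiber_diameter_nm,
                circular=False,
                n_segments=n_seg,
            )

        unrep = ChainPlacement(
            piece(n_unrep, "unrep"), "unrep", start_bp=int(round(kr * bp_per_seg)), genome_length_bp=G
        )
        rep_spec = piece(n_rep, "rep")
        rep1 = ChainPlacement(rep_spec, "rep1", start_bp=int(round(kl * bp_per_seg)), genome_length_bp=G)
        rep2 = ChainPlacement(rep_spec, "rep2", start_bp=int(round(kl * bp_per_seg)), genome_length_bp=G)
        topo = Topology(
            [unrep, rep1, rep2],
            junctions=[
                [(0, n_unrep), (1, 0), (2, 0)],  # fork at Left border
                [(0, 0), (1, n_rep), (2, n_rep)],  # fork at Right border
            ],
        )
        md_chains = {}
        for lbl in condensed:
            if lbl in ("Right", "Ter", "Left"):
                md_chains[lbl] = [0]
            else:  # Ori / NS copies: one MD per sister chromatid
                md_chains[lbl] = [1, 2]

    structure = Structure(topo)

    # --- constraints ----------------------------------------------------
    mds = []
    claimed: set[int] = set()
    for lbl, chains in md_chains.items():
        region = layout.region(lbl)
        for c in chains:
            md = MDConstraint(
                region=region,
                sphere_diameter_nm=md_diameter_nm,
                spring_constant=md_spring,
                center_rule=md_center_rule,
                chain=c,
            )
            md.resolve(structure)
            expected = region.length_bp(G) / (G / N)
            if len(md.vertices) < 0.7 * expected:
                raise ValueError(
                    f"region {lbl} only partially covered by chain {c}"
                )
            # junction vertices shared between chromosome copies (the G2
            # terminus) stay a member of the first copy's constraint only;
            # as the shared vertex is the center of both Ter spheres this
            # drops no actual restraint
            md.vertices = np.array(
                [v for v in md.vertices if int(v) not in claimed], dtype=np.int32
            )
            claimed.update(int(v) for v in md.vertices)
            mds.append(md)

    pin_list: list[PinConstraint] = []

    def add_pin(bp, chain, target):
        pin_list.append(
            PinConstraint(
                locus_bp=bp, target=target, spring_constant=pin_spring, chain=chain
            ).resolve(structure)
        )

    oric = int(round(ORIC_BP * G / DEFAULT_GENOME_BP))
    dif = int(round(DIF_BP * G / DEFAULT_GENOME_BP))
    for locus, target in pins.items():
        locus = locus.lower()
        if locus == "ori":
            if phase == "G1":
                add_pin(oric, 0, target)
            else:
                copies = [1, 2] if phase == "S" else [0, 1]
                signed = target in ("quarter", "pole")
                for c, sign in zip(copies, ("-", "+")):
                    add_pin(oric, c, f"{target}:{sign}" if signed else target)
        elif locus == "ter":
            add_pin(dif, 0, target)
        else:
            raise ValueError(f"no locus {locus!r} in this topology")

    model = EnergyModel(md_constraints=mds, pin_constraints=pin_list)

    # --- tracked loci (centers of the four regions, per copy) -----------
    loci: list[tuple[str, int]] = []
    if phase == "G1":
        for lbl in ("ter", "left", "ori", "right"):
            r = layout.region(lbl if lbl != "ori" else "Ori")
            loci.append((lbl, structure.region_center_vertex(r, 0)))
    elif phase == "S":
        loci.append(("ori1", structure.region_center_vertex(layout.region("Ori"), 1)))
        loci.append(("ori2", structure.region_center_vertex(layout.region("Ori"), 2)))
        for lbl in ("left", "right", "ter"):
            loci.append((lbl, structure.region_center_vertex(layout.region(lbl), 0)))
    else:
        for c in (0, 1):
            for lbl in ("ter", "left", "ori", "right"):
                loci.append((lbl, structure.region_center_vertex(layout.region(lbl), c)))

    return PhaseSetup(
        phase=phase,
        volume=vol,
        topology=topo,
        structure=structure,
        model=model,
        layout=layout,
        loci=loci,
        name=f"{phase.lower()}",
    )


# ---------------------------------------------------------------------------
# presets and the experiment grid
# ---------------------------------------------------------------------------

PRESETS: dict[str, dict] = {
    # homogeneous polymers, with/without forced ori/ter localization
    "g1-homogeneous": dict(phase="G1", nucleoid_length_nm=2000),
    "g1-ori-midcell": dict(phase="G1", nucleoid_length_nm=2000, pins={"ori": "mid-cell"}),
    "g1-ter-pole": dict(phase="G1", nucleoid_length_nm=2000, pins={"ter": "pole:+"}),
    "g1-ori-ter": dict(
        phase="G1", nucleoid_length_nm=2000, pins={"ori": "mid-cell", "ter": "pole:+"}
    ),
    "s-homogeneous": dict(phase="S", nucleoid_length_nm=2600),
    "s-ori-quarters": dict(phase="S", nucleoid_length_nm=2600, pins={"ori": "quarter"}),
    "s-ori-ter": dict(
        phase="S", nucleoid_length_nm=2600, pins={"ori": "quarter", "ter": "mid-cell"}
    ),
    "g2-homogeneous": dict(phase="G2", nucleoid_length_nm=3600),
    "g2-dissociated": dict(phase="G2", nucleoid_length_nm=3600, dissociated_termini=True),
    "g2-ori-quarters": dict(phase="G2", nucleoid_length_nm=3600, pins={"ori": "quarter"}),
    "g2-ori-ter": dict(
        phase="G2", nucleoid_length_nm=3600, pins={"ori": "quarter", "ter": "mid-cell"}
    ),
    # macrodomain experiments
    "g1-single-md": dict(
        phase="G1", nucleoid_length_nm=2000, single_md="Ori", md_diameter_nm=360
    ),
    "g1-mds": dict(phase="G1", nucleoid_length_nm=2000, condensed="all"),
    "g1-mds-pinned": dict(
        phase="G1",
        nucleoid_length_nm=2000,
        condensed="all",
        pins={"ori": "mid-cell", "ter": "pole:+"},
    ),
    "s-mds": dict(phase="S", nucleoid_length_nm=2600, condensed="all"),
    "s-mds-septum": dict(
        phase="S",
        nucleoid_length_nm=2600,
        condensed="all",
        pins={"ori": "quarter", "ter": "septum"},
    ),
    "s-mds-septum-3um": dict(
        phase="S",
        nucleoid_length_nm=3000,
        condensed="all",
        pins={"ori": "quarter", "ter": "septum"},
    ),
    "g2-mds": dict(phase="G2", nucleoid_length_nm=3600, condensed="all"),
    "g2-mds-pinned": dict(
        phase="G2",
        nucleoid_length_nm=3600,
        condensed="all",
        pins={"ori": "quarter", "ter": "mid-cell"},
    ),
    # no-NS control: the whole chromosome as a string of MDs
    "g1-all-md-no-ns": dict(phase="G1", nucleoid_length_nm=2000, condensed="all+ns"),
}


def build_preset(name: str, **overrides) -> PhaseSetup:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    setup = build_phase_setup(**kwargs)
    setup.name = name
    return setup


def experiment_grid(genome_length_bp: int = DEFAULT_GENOME_BP) -> list[tuple[str, dict]]:
    """The grid of published in-silico experiments.

    Homogeneous +/- pins, the single-MD diameter scan (100-500 nm at fiber
    widths 30/35/40 nm, both condensation schedules), multi-MD +/- pins per
    phase, and the all-MD/no-NS control.
    """
    grid: list[tuple[str, dict]] = []
    for name, kwargs in PRESETS.items():
        kw = dict(kwargs)
        kw["genome_length_bp"] = genome_length_bp
        grid.append((name, kw))
    for d_md in (100, 200, 250, 300, 350, 400, 450, 500):
        for d_fiber in (30, 35, 40):
            for protocol in ("before", "after"):
                grid.append(
                    (
                        f"fig6-md{d_md}-fiber{d_fiber}-{protocol}",
                        dict(
                            phase="G1",
                            nucleoid_length_nm=2000,
                            single_md="Ori",
                            md_diameter_nm=float(d_md),
                            fiber_diameter_nm=float(d_fiber),
                            genome_length_bp=genome_length_bp,
                        ),
                    )
                )
    return grid
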