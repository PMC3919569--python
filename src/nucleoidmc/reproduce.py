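"""Desk-scale reproductions of the published in-silico experiments.

The full-scale runs behind the published figures use N = 1392 cylinders
per chromosome and 1-2 x 10^9 sweeps; the experiments here reproduce the
same measurements at desk scale.  The unconfined gyration-radius and the
single-macrodomain localization experiments run at the full chromosome
size (their observables are not robust to dilution); the segregation
(unmixing) experiments scale the genome to one third (N = 464 per
chromosome copy) inside the full-size nucleoid, keeping the
discretization, fiber diameter, macrodomain mass fractions, pin targets
and slice thickness standard, and scaling macrodomain sphere diameters as
the cube root of the mass so the intra-MD volume fraction is preserved.
Sweep counts are scaled to the reduced chain lengths; every experiment is
deterministic per seed.

Each experiment returns a dict with at least ``value`` (the quantity on
the scale the reference prints) and ``n`` (the problem size used).
"""

from __future__ import annotations

import numpy as np

from .chain import (
    ChainPlacement,
    ChainSpec,
    Structure,
    Topology,
    discretize_chromosome,
    radius_of_gyration,
)
from .engine import Engine
from .interactions import EnergyModel
from .observables import localization_lambda, mu_series, mu_summary, polar_fraction
from .sampler import AnnealSchedule, MCConfig, RunState, initialize_conformation, run_annealing, run_sampling, simulate
from .scenarios import build_preset

#: one-third genome: N = 464 segments per chromosome copy
SCALED_GENOME_BP = 1_546_667
#: MD sphere diameter preserving the standard intra-MD volume fraction at
#: one-third the genomic content: 360 nm * (1/3)^(1/3)
SCALED_MD_DIAMETER_NM = 250.0
#: blocks must be able to carry a whole condensed macrodomain (~80
#: segments at this scale) for MDs to stay mobile
SCALED_MAX_BLOCK = 100

_MU_ANNEAL = dict(sweeps_per_stage=12_000, max_stage_retries=60)
#: replicate-consistency threshold on mean mu (the published rule flags
#: incompatible simulation pairs rather than silently averaging)
MU_CONSISTENCY = 0.15


def _mu_experiment(
    preset: str,
    seed: int,
    chain_pair: tuple[int, int],
    replicates: int = 2,
    n_sweeps: int = 2_500_000,
    equilibration_sweeps: int = 1_000_000,
    **overrides,
):
    """Pooled mean unmixing parameter over independent replicates.

    Replicates follow the published two-simulation protocol: each starts
    from its own seed; per-replicate means are reported alongside the
    pooled value, and pairs whose means disagree by more than
    ``MU_CONSISTENCY`` are flagged (metastable states).
    """
    setup = build_preset(
        preset,
        genome_length_bp=SCALED_GENOME_BP,
        md_diameter_nm=SCALED_MD_DIAMETER_NM,
        **overrides,
    )
    mc_kw = dict(
        n_sweeps=n_sweeps,
        sample_interval_sweeps=5_000,
        equilibration_sweeps=equilibration_sweeps,
        max_block_length=SCALED_MAX_BLOCK,
    )
    if not setup.model.md_constraints:
        # no macrodomains to carry: the standard block length samples
        # faster (large blocks trigger frequent whole-ring co-rotations)
        mc_kw["max_block_length"] = 50
    pooled = []
    rep_means = []
    for r in range(replicates):
        mc = MCConfig(seed=(seed + 101 * r) % (2**31), **mc_kw)
        traj = simulate(setup, mc, AnnealSchedule(**_MU_ANNEAL))
        mu = mu_series(traj, *chain_pair)
        pooled.append(mu)
        rep_means.append(float(np.mean(mu)))
    mu = np.concatenate(pooled)
    out = mu_summary(mu)
    out["value"] = out["mean"]
    out["n"] = setup.structure.n_segments
    out["replicate_means"] = rep_means
    out["replicates_consistent"] = bool(
        max(rep_means) - min(rep_means) <= MU_CONSISTENCY
    )
    return out


def rg_ratio_unconfined(seed: int, n_segments: int = 1392) -> dict:
    """Equilibrium gyration radius of the unconfined self-avoiding ring,
    as a multiple of the 400-nm nucleoid radius."""
    genome = int(round(n_segments * 10_000 / 3))  # 100 bp/nm, ls = 100/3 nm
    spec = discretize_chromosome(ChainSpec(genome_length_bp=genome))
    assert spec.n_segments == n_segments
    st = Structure(Topology([ChainPlacement(spec, "chr")]))
    conf = initialize_conformation(st)
    engine = Engine(
        st,
        EnergyModel(confinement=False),
        None,
        conf,
        seed=seed,
        max_block_length=max(n_segments // 2 - 1, 1),
    )
    state = RunState(engine, MCConfig(seed=seed), None)
    # equilibrate from the planar circle; large-block crankshafts relax the
    # global size quickly
    for _ in range(30):
        rate = engine.run(20_000)
        engine.adapt_amplitude(rate)
        engine.recenter()
    n_frames, interval = 120, 12_000
    rg = np.empty(n_frames)
    for i in range(n_frames):
        engine.run(interval)
        engine.recenter()
        rg[i] = radius_of_gyration(engine.conformation())
    engine.audit(check_overlap=False)
    return {
        "value": float(np.mean(rg) / 400.0),
        "n": n_segments,
        "rg_nm": float(np.mean(rg)),
        "sem_nm": float(np.std(rg) / np.sqrt(max(_effective_n(rg), 1))),
    }


def _effective_n(x: np.ndarray) -> float:
    """Effective sample size from the lag-1 autocorrelation."""
    x = np.asarray(x, float)
    if len(x) < 3 or np.std(x) == 0:
        return float(len(x))
    r = np.corrcoef(x[:-1], x[1:])[0, 1]
    r = min(max(r, 0.0), 0.999)
    return len(x) * (1 - r) / (1 + r)


def single_md_localization(seed: int, md_diameter_nm: float = 400.0) -> dict:
    """Localization parameter of a single condensed macrodomain in G1.

    rho: polar occupancy of the MD center; rho0: the same for the
    fiber-diameter control, i.e. the bare chromosome tracking the same
    locus (the smallest possible MD coincides with the fiber itself).

    This experiment runs at the full chromosome size (N = 1392, 2-um
    nucleoid): the polar push on a condensed MD is an osmotic effect of
    the surrounding chain and vanishes when the chain density is diluted,
    so a reduced chain in the full-size nucleoid cannot show it.  Blocks
    up to 350 segments let the 240-member sphere translate as a unit.
    """
    setup = build_preset("g1-single-md", md_diameter_nm=md_diameter_nm)
    center = setup.structure.region_center_vertex(setup.layout.region("Ori"), 0)
    mc = MCConfig(
        seed=seed, max_block_length=350, n_sweeps=1_800_000,
        sample_interval_sweeps=900, equilibration_sweeps=800_000,
    )
    traj = simulate(setup, mc, AnnealSchedule(**_MU_ANNEAL))
    rho = polar_fraction(traj.frames[:, center, 0], setup.volume)
    # control: the bare ring.  Every monomer of the homogeneous ring is
    # statistically equivalent to the tracked locus, so rho0 is averaged
    # over all monomers, which converges far faster than one tracked locus
    control = build_preset("g1-homogeneous")
    mc0 = MCConfig(
        seed=seed, max_block_length=50, n_sweeps=1_000_000,
        sample_interval_sweeps=2_500, equilibration_sweeps=600_000,
    )
    traj0 = simulate(control, mc0, AnnealSchedule(**_MU_ANNEAL))
    L = control.volume.length_nm
    rho0 = float(np.mean(np.abs(traj0.frames[:, :, 0]) > L / 4.0))
    lam = localization_lambda(rho, rho0)
    return {
        "value": float(lam),
        "n": 1392,
        "rho": float(rho),
        "rho0": float(rho0),
        "md_diameter_nm": md_diameter_nm,
    }


def g2_homogeneous_mu(seed: int) -> dict:
    """Mean unmixing of two terminus-linked bare chromosomes (G2).

    The bare pair is strongly metastable at desk scale (mixed and demixed
    arrangements both persist for whole runs), so this experiment pools
    three replicates with extended equilibration."""
    return _mu_experiment(
        "g2-homogeneous", seed, (0, 1), replicates=3,
        n_sweeps=3_000_000, equilibration_sweeps=2_000_000,
    )


def g2_ori_quarters_mu(seed: int) -> dict:
    """G2 bare chromosomes with each ori pinned at its cell quarter."""
    return _mu_experiment(
        "g2-ori-quarters", seed, (0, 1),
        n_sweeps=2_000_000, equilibration_sweeps=800_000,
    )


def g2_mds_pinned_mu(seed: int) -> dict:
    """G2 with all macrodomains condensed, ori at quarters, ter at
    mid-cell (the stable Left-Ori-Right-Ter-Ter-Left-Ori-Right state)."""
    return _mu_experiment("g2-mds-pinned", seed, (0, 1))


def s_mds_septum_mu(seed: int) -> dict:
    """S phase, macrodomains condensed, terminus bound at the septum,
    nucleoid 2.6 um; mu between the replicated chains."""
    return _mu_experiment("s-mds-septum", seed, (1, 2))


def s_mds_septum_3um_mu(seed: int) -> dict:
    """Same as :func:`s_mds_septum_mu` with a 3.0-um nucleoid."""
    return _mu_experiment("s-mds-septum-3um", seed, (1, 2))


EXPERIMENTS = {
    "rg-ratio-unconfined": rg_ratio_unconfined,
    "single-md-localization": single_md_localization,
    "g2-homogeneous-mu": g2_homogeneous_mu,
    "g2-ori-quarters-mu": g2_ori_quarters_mu,
    "g2-mds-pinned-mu": g2_mds_pinned_mu,
    "s-mds-septum-mu": s_mds_septum_mu,
    "s-mds-septum-3um-mu": s_mds_septum_3um_mu,
}


def run_experiment(name: str, seed: int) -> dict:
    if name not in EXPERIMENTS:
        raise KeyError(
            f"unknown experiment {name!r}; available: {sorted(EXPERIMENTS)}"
        )
    return EXPERIMENTS[name](seed)
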