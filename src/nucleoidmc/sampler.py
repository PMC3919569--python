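"""Metropolis Monte-Carlo driver: initialization, annealing, sampling.

The Monte-Carlo time unit is the *sweep*: one proposed update of a random
set of contiguous cylinders (one block-move attempt).  Initial states are
exact-bond-length layouts (regular polygons, tangent polygon pairs for the
terminus-joined G2 dimer, circle-arc triplets for the half-replicated S
topology).  Because those layouts are much more extended than the nucleoid,
every run starts in an enlarged embedding volume which is slowly shrunk to
the target nucleoid ("volume annealing"); a shrink stage is applied only
when the current conformation already fits the shrunken volume, so hard
constraints are never violated at any point of a run.  Macrodomain
condensation spheres are annealed the same way, either before confinement
(condense-then-confine, the default) or after (confine-then-condense).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import asin, ceil, cos, pi, sin, sqrt

import numpy as np
from scipy.optimize import brentq

from .chain import Conformation, Structure
from .engine import AnnealingStalledError, Engine
from .interactions import EnergyModel, NucleoidVolume, total_energy

__all__ = [
    "MCConfig",
    "AnnealSchedule",
    "RunState",
    "Trajectory",
    "initialize_conformation",
    "run_annealing",
    "run_sampling",
    "metropolis_accept",
    "propose_block_move",
    "metropolis_step",
    "AnnealingStalledError",
]


@dataclass
class MCConfig:
    seed: int = 0
    n_sweeps: int = 1_000_000
    sample_interval_sweeps: int = 100_000
    equilibration_sweeps: int = 0
    max_block_length: int = 50
    rotation_amplitude: float = 1.5  # initial; adapted during equilibration
    target_acceptance: tuple[float, float] = (0.3, 0.5)
    p_reflect: float | None = None  # None: auto (0.05 if forks present)
    translations: bool = False
    translation_amplitude_nm: float = 50.0

    def __post_init__(self):
        if self.sample_interval_sweeps < 1:
            raise ValueError("sample_interval_sweeps must be >= 1")
        if not (1 <= self.max_block_length):
            raise ValueError("max_block_length must be >= 1")


@dataclass
class AnnealSchedule:
    initial_volume_scale: float = 3.0
    shrink_factor_per_stage: float = 0.98
    sweeps_per_stage: int = 20_000
    max_stage_retries: int = 400
    md_condensation: str = "before"  # 'before' (condense-then-confine) | 'after'

    def __post_init__(self):
        if not (0 < self.shrink_factor_per_stage < 1):
            raise ValueError("shrink factor must be in (0, 1)")
        if self.initial_volume_scale < 1:
            raise ValueError("initial volume scale must be >= 1")
        if self.md_condensation not in ("before", "after"):
            raise ValueError("md_condensation must be 'before' or 'after'")


@dataclass
class RunState:
    """Everything needed to continue (or reproduce) a run."""

    engine: Engine
    mc: MCConfig
    volume: NucleoidVolume | None
    equilibrated: bool = False

    @property
    def structure(self) -> Structure:
        return self.engine.structure

    @property
    def conformation(self) -> Conformation:
        return self.engine.conformation()

    @property
    def sweep(self) -> int:
        return self.engine.sweep


@dataclass
class Trajectory:
    """Periodically saved conformations plus per-chunk logs."""

    structure: Structure
    frames: np.ndarray  # (F, V, 3)
    sweeps: np.ndarray  # (F,)
    volume: NucleoidVolume | None
    seed: int
    acceptance: np.ndarray = field(default_factory=lambda: np.zeros(0))
    energies: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame(self, i: int) -> Conformation:
        return Conformation(
            self.structure,
            self.frames[i].copy(),
            sweep=int(self.sweeps[i]),
            nucleoid_length_nm=self.volume.length_nm if self.volume else None,
        )


# ---------------------------------------------------------------------------
# initial conformations
# ---------------------------------------------------------------------------

def _polygon_ring(n: int, ls: float, center, plane_sign: float = 1.0) -> np.ndarray:
    """Regular n-gon with side exactly ls, in the z=0 plane."""
    R = ls / (2.0 * sin(pi / n))
    cx, cy, cz = center
    ang = 2.0 * pi * np.arange(n) / n
    pts = np.empty((n, 3))
    pts[:, 0] = cx + R * np.cos(ang)
    pts[:, 1] = cy + plane_sign * R * np.sin(ang)
    pts[:, 2] = cz
    return pts


def _arc_chain(n: int, ls: float, j1: np.ndarray, j2: np.ndarray, psi: float):
    """n equal chords of length ls from j1 to j2 along a major circle arc
    lying in the plane spanned by x and (0, cos psi, sin psi)."""
    d = float(np.linalg.norm(j2 - j1)) / 2.0
    rho0 = ls / (2.0 * sin(pi / n))  # full-polygon radius: chord -> 0

    def chord(rho):
        alpha = asin(ls / (2.0 * rho))
        return 2.0 * rho * sin(min(n * alpha, pi))

    lo = rho0 * (1.0 + 1e-12)
    hi = max(4.0 * rho0, 4.0 * d, n * ls)
    rho = brentq(lambda r: chord(r) - 2.0 * d, lo, hi, xtol=1e-10, rtol=1e-15)
    alpha = asin(ls / (2.0 * rho))
    h = sqrt(max(rho * rho - d * d, 0.0))
    e2 = np.array([0.0, cos(psi), sin(psi)])
    mid = 0.5 * (j1 + j2)
    c = mid + h * e2  # circle center; arc bulges toward -e2
    # angles of j1, j2 about c in the (x, e2) plane
    th1 = np.arctan2(-h, float((j1 - mid)[0]))
    pts = np.empty((n + 1, 3))
    for s in (1.0, -1.0):
        for k in range(n + 1):
            th = th1 + s * 2.0 * alpha * k
            pts[k] = c + rho * (cos(th) * np.array([1.0, 0, 0]) + sin(th) * e2)
        if np.linalg.norm(pts[-1] - j2) < 1e-6 * ls:
            break
    else:
        raise RuntimeError("arc construction failed to land on the junction")
    pts[0] = j1
    pts[-1] = j2
    return pts


def initialize_conformation(structure: Structure, seed: int = 0) -> Conformation:
    """Deterministic self-avoiding initial layout for the supported
    topologies (single ring, terminus-joined ring pair, three-chain
    replication bubble, free linear chains, point chains)."""
    st = structure
    ls = st.segment_length_nm
    V = st.n_vertices
    pos = np.zeros((V, 3))
    n_chains = st.n_chains
    circ = st.chain_circular
    n_junc = int(np.sum(st.degree > 2))

    if n_chains == 1 and circ[0]:
        ids = st.chain_vertices(0)
        pos[ids] = _polygon_ring(len(ids), ls, (0.0, 0.0, 0.0))
    elif n_chains == 2 and circ.all() and n_junc == 1:
        # two rings sharing one vertex: externally tangent polygons in the
        # z = 0 plane, joined at the origin, leaving it in opposite
        # directions
        # the two ring planes are kept perpendicular so the chain arcs near
        # the shared vertex do not wind around each other when condensing
        j = int(np.where(st.degree > 2)[0][0])
        for c, sign in ((0, 1.0), (1, -1.0)):
            ids = st.chain_vertices(c)
            n = len(ids)
            R = ls / (2.0 * sin(pi / n))
            kj = int(np.where(ids == j)[0][0])
            phi = 2.0 * pi * (np.arange(n) - kj) / n
            pts = np.zeros((n, 3))
            pts[:, 0] = sign * (R * np.cos(phi) - R)
            if c == 0:
                pts[:, 1] = R * np.sin(phi)
            else:
                pts[:, 2] = R * np.sin(phi)
            pos[ids] = pts
    elif n_chains == 3 and not circ.any() and n_junc == 2:
        juncs = np.where(st.degree > 2)[0]
        lens = [len(st.chain_vertices(c)) - 1 for c in range(3)]
        span = 0.35 * min(lens) * ls
        j1 = np.array([-span / 2.0, 0.0, 0.0])
        j2 = np.array([span / 2.0, 0.0, 0.0])
        for c, psi in enumerate((0.0, 2.0 * pi / 3.0, 4.0 * pi / 3.0)):
            ids = st.chain_vertices(c)
            n = len(ids) - 1
            ja, jb = int(ids[0]), int(ids[-1])
            a = j1 if ja == juncs[0] else j2
            b = j2 if jb == juncs[1] else j1
            pts = _arc_chain(n, ls, a, b, psi)
            pos[ids] = pts
    elif n_junc == 0:
        # independent chains: rings in stacked planes, linear chains as
        # straight rods, single vertices at lattice points
        z = 0.0
        gap = 2.0 * st.hard_core_diameter_nm + ls
        for c in range(n_chains):
            ids = st.chain_vertices(c)
            n = len(ids)
            if circ[c]:
                pos[ids] = _polygon_ring(n, ls, (0.0, 0.0, z))
            elif n == 1:
                pos[ids[0]] = (0.0, 0.0, z)
            else:
                xs = (np.arange(n) - (n - 1) / 2.0) * ls
                pos[ids, 0] = xs
                pos[ids, 2] = z
            z += gap
        # recenter stack
        pos[:, 2] -= pos[:, 2].mean()
    else:
        raise NotImplementedError("no initializer for this topology")
    conf = Conformation(st, pos)
    if conf.max_bond_error() > 1e-9:
        raise RuntimeError("initial layout violates bond lengths")
    return conf


# ---------------------------------------------------------------------------
# annealing and sampling
# ---------------------------------------------------------------------------

def _needed_scale(engine: Engine, vol: NucleoidVolume) -> float:
    p = engine.pos
    r = np.sqrt(np.max(p[:, 1] ** 2 + p[:, 2] ** 2))
    x = np.max(np.abs(p[:, 0]))
    return max(r / vol.radius_nm, x / vol.half_length_nm, 1.0) * 1.02


def _anneal_quantity(engine, mc, schedule, shrink_step, excess, adapt=True):
    """Generic stage loop: run sweeps, shrink the boundary one step, wait
    for feasibility.  ``shrink_step`` moves walls toward their targets and
    returns False once they are there; ``excess`` measures how far the
    conformation still protrudes beyond the (piston) walls.  Stalls are
    declared when the walls are at target but the excess stops shrinking."""
    retries = 0
    best = np.inf
    while True:
        walls_moving = shrink_step()
        rate = engine.run(schedule.sweeps_per_stage)
        if adapt:
            engine.adapt_amplitude(rate, *mc.target_acceptance)
        e = excess()
        if not walls_moving and e <= 0.0:
            return
        if e < best - max(1e-3 * best, 1e-6):
            best = e
            retries = 0
        elif not walls_moving:
            retries += 1
            if retries > schedule.max_stage_retries:
                raise AnnealingStalledError(
                    f"annealing stalled with boundary excess {e:.1f} nm "
                    f"(sweep {engine.sweep}, acceptance {rate:.3f})"
                )


def run_annealing(
    state: RunState, schedule: AnnealSchedule | None = None
) -> RunState:
    """Volume (and MD-sphere) annealing down to the target nucleoid."""
    schedule = schedule or AnnealSchedule()
    engine = state.engine
    mc = state.mc
    vol = state.volume
    f = schedule.shrink_factor_per_stage
    # replication-fork vertices move only by reflections; give them extra
    # mobility while the walls close in
    saved_p_reflect = engine.p_reflect
    if len(engine.refl_junc):
        engine.p_reflect = max(saved_p_reflect, 0.2)

    if engine.n_md and schedule.md_condensation == "after":
        saved_k = engine.md_k_active.copy()
        engine.md_k_active[:] = 0.0
        engine.md_r[:] = 1e12

    def md_anneal():
        # start radii at whatever the current conformation needs
        for i in range(engine.n_md):
            engine.md_r[i] = max(
                engine.md_r_target[i], engine.md_member_max_dist(i) * 1.001
            )
        # amplitude adaptation targets the bulk acceptance rate, which is
        # dominated by moves inside the shrinking (dense) spheres; letting
        # it run here freezes the large-scale folding, so condensation uses
        # a fixed moderate amplitude instead
        saved_amp = engine.amplitude
        engine.amplitude = max(saved_amp, 0.8)

        def shrink_step():
            moving = False
            for i in range(engine.n_md):
                tgt = engine.md_r_target[i]
                if engine.md_r[i] > tgt:
                    engine.md_r[i] = max(tgt, f * engine.md_r[i])
                    moving = True
            return moving

        def excess():
            return float(
                sum(
                    max(0.0, engine.md_member_max_dist(i) - engine.md_r[i])
                    for i in range(engine.n_md)
                )
            )

        # Soft sphere walls while shrinking: protruding loops may fluctuate
        # outward (at harmonic cost) and unthread while the walls close in.
        # Once the walls reach their target radii the wall stiffness is
        # ramped up, squeezing in the members that equilibrium pressure
        # holds just outside; trapped loops that survive the ramp trigger a
        # re-expansion restart.
        try:
            for cycle in range(4):
                engine.md_wall_k = 1e-3
                while shrink_step():
                    engine.run(schedule.sweeps_per_stage)
                # stiffness ramp: squeeze in the members that equilibrium
                # pressure holds just outside the target radius
                for wall_k in (1e-3, 3e-3, 1e-2, 3e-2, 1e-1, 3e-1, 1.0):
                    engine.md_wall_k = wall_k
                    for _ in range(12):
                        engine.run(schedule.sweeps_per_stage)
                        if excess() <= 1.0:
                            break
                    if excess() <= 1.0:
                        break
                if excess() <= 30.0:
                    break  # residual small enough for the hard-wall piston
                # a large surviving excess signals a trapped loop:
                # re-expand the stuck spheres and try again
                if cycle < 3:
                    for i in range(engine.n_md):
                        d = engine.md_member_max_dist(i)
                        if d > engine.md_r[i]:
                            engine.md_r[i] = max(engine.md_r[i], d) * 1.6
        finally:
            engine.md_wall_k = 0.0
        if np.any(engine.md_r > engine.md_r_target * (1 + 1e-9)):
            raise AnnealingStalledError(
                "condensation could not reach the target sphere radii"
            )
        # hard walls; the piston rule absorbs any residual excess
        _anneal_quantity(
            engine, mc, schedule, lambda: False, excess, adapt=False
        )
        engine.amplitude = saved_amp

    if vol is not None and engine.conf_on:
        s0 = max(schedule.initial_volume_scale, _needed_scale(engine, vol))
        engine.set_confinement(vol.radius_nm * s0, vol.half_length_nm * s0)
        engine.ensure_grid_covers(vol.radius_nm * s0, vol.half_length_nm * s0)
        if engine.n_md and schedule.md_condensation == "before":
            md_anneal()

        def shrink_step():
            moving = (
                engine.conf_r > vol.radius_nm
                or engine.conf_half > vol.half_length_nm
            )
            engine.set_confinement(
                max(vol.radius_nm, f * engine.conf_r),
                max(vol.half_length_nm, f * engine.conf_half),
            )
            return moving

        def excess():
            p = engine.pos
            rad = float(np.sqrt(np.max(p[:, 1] ** 2 + p[:, 2] ** 2)))
            xmax = float(np.max(np.abs(p[:, 0])))
            return max(0.0, rad - engine.conf_r) + max(
                0.0, xmax - engine.conf_half
            )

        # soft walls while shrinking, then a stiffness ramp (as for the MD
        # spheres: condensed balls wedged at a wall need a graded push, the
        # hard piston alone cannot move them inward)
        try:
            engine.conf_wall_k = 1e-3
            while shrink_step():
                rate = engine.run(schedule.sweeps_per_stage)
                engine.adapt_amplitude(rate, *mc.target_acceptance)
            for wall_k in (1e-3, 3e-3, 1e-2, 3e-2, 1e-1, 3e-1, 1.0):
                engine.conf_wall_k = wall_k
                for _ in range(12):
                    engine.run(schedule.sweeps_per_stage)
                    if excess() <= 1.0:
                        break
                if excess() <= 1.0:
                    break
        finally:
            engine.conf_wall_k = 0.0
        # hard walls; piston absorbs the residue
        _anneal_quantity(engine, mc, schedule, lambda: False, excess)
        engine.set_confinement(vol.radius_nm, vol.half_length_nm)
    elif engine.n_md and schedule.md_condensation == "before":
        md_anneal()

    if engine.n_md and schedule.md_condensation == "after":
        engine.md_k_active[:] = saved_k
        md_anneal()

    engine.p_reflect = saved_p_reflect
    return state


def run_sampling(state: RunState, mc: MCConfig | None = None) -> Trajectory:
    """Equilibrate (with amplitude adaptation), then sample one frame per
    ``sample_interval_sweeps``.  Adaptation is frozen during measurement so
    detailed balance holds over the sampled portion of the chain."""
    mc = mc or state.mc
    engine = state.engine
    interval = int(mc.sample_interval_sweeps)

    # equilibration with adaptation
    remaining = int(mc.equilibration_sweeps)
    chunk = max(min(interval, 50_000), 1000)
    while remaining > 0:
        n = min(chunk, remaining)
        rate = engine.run(n)
        engine.adapt_amplitude(rate, *mc.target_acceptance)
        remaining -= n
        if not engine.conf_on:
            engine.recenter()
    state.equilibrated = True

    n_frames = int(mc.n_sweeps) // interval
    V = engine.structure.n_vertices
    frames = np.empty((n_frames, V, 3))
    sweeps = np.empty(n_frames, dtype=np.int64)
    acc = np.empty(n_frames)
    energies = np.empty(n_frames)
    model, vol = engine.model, state.volume
    soft_model = EnergyModel(
        bending=model.bending,
        self_avoidance=False,  # hard terms hold by construction; audit-checked
        confinement=False,
        md_constraints=model.md_constraints,
        pin_constraints=model.pin_constraints,
    )
    for i in range(n_frames):
        acc[i] = engine.run(interval)
        if not engine.conf_on:
            engine.recenter()
        frames[i] = engine.pos
        sweeps[i] = engine.sweep
        energies[i] = total_energy(engine.conformation(), soft_model, vol)
    if engine.overflowed and engine.conf_on:
        # inside a confined run the box strictly contains the nucleoid, so
        # an overflow means a bookkeeping bug, not physics
        raise RuntimeError(
            f"{engine.overflowed} proposals left the simulation box"
        )
    return Trajectory(
        structure=engine.structure,
        frames=frames,
        sweeps=sweeps,
        volume=state.volume,
        seed=engine.seed,
        acceptance=acc,
        energies=energies,
    )


def simulate(
    setup,
    mc: MCConfig,
    schedule: AnnealSchedule | None = None,
    audit_final: bool = True,
    anneal_attempts: int = 3,
) -> Trajectory:
    """Initialize, anneal into the nucleoid, equilibrate and sample.

    ``setup`` is anything with ``structure``, ``model`` and ``volume``
    attributes (typically a :class:`~nucleoidmc.scenarios.PhaseSetup`).
    A stalled anneal (a mechanically locked initialization path) is
    retried from a seed derived deterministically from ``mc.seed``.
    """
    last_err: Exception | None = None
    for attempt in range(max(anneal_attempts, 1)):
        seed = (mc.seed + 7919 * attempt) % (2**31)
        conf = initialize_conformation(setup.structure, seed=seed)
        engine = Engine(
            setup.structure,
            setup.model,
            setup.volume,
            conf,
            seed=seed,
            max_block_length=mc.max_block_length,
            p_reflect=mc.p_reflect if mc.p_reflect is not None else None,
            translations=mc.translations,
            translation_amplitude_nm=mc.translation_amplitude_nm,
        )
        engine.amplitude = mc.rotation_amplitude
        state = RunState(engine, mc, setup.volume)
        try:
            run_annealing(state, schedule)
        except AnnealingStalledError as err:
            last_err = err
            continue
        traj = run_sampling(state, mc)
        if audit_final:
            engine.audit(check_overlap=engine.structure.n_segments <= 2000)
        return traj
    raise AnnealingStalledError(
        f"annealing stalled in {anneal_attempts} attempts: {last_err}"
    )


# ---------------------------------------------------------------------------
# pure-python reference sampler (small systems, tests)
# ---------------------------------------------------------------------------

def metropolis_accept(delta_e: float, rng: np.random.Generator) -> bool:
    """Standard Metropolis rule on an energy difference in kBT."""
    if not np.isfinite(delta_e):
        return False
    if delta_e <= 0.0:
        return True
    return rng.random() < np.exp(-delta_e)


def propose_block_move(
    conf: Conformation,
    rng: np.random.Generator,
    max_block_length: int = 50,
    amplitude: float = 1.5,
) -> Conformation:
    """Reference crankshaft proposal for a single junction-free chain."""
    st = conf.structure
    if st.n_chains != 1 or np.any(st.degree > 2):
        raise NotImplementedError("reference proposal supports one plain chain")
    ids = st.chain_vertices(0)
    n = len(ids)
    circ = bool(st.chain_circular[0])
    blk = int(rng.integers(1, max_block_length + 1))
    cand = conf.copy()
    if circ:
        i = int(rng.integers(0, n))
        blk = min(blk, n - 2)
        a1, a2 = ids[i], ids[(i + blk + 1) % n]
        interior = [ids[(i + k) % n] for k in range(1, blk + 1)]
    else:
        i = int(rng.integers(0, n - 1))
        blk = min(blk, n - 2 - i)
        if blk < 1:
            return cand
        a1, a2 = ids[i], ids[i + blk + 1]
        interior = list(ids[i + 1 : i + blk + 1])
    p0, p1 = conf.pos[a1], conf.pos[a2]
    axis = p1 - p0
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        return cand
    axis = axis / norm
    theta = amplitude * (2 * rng.random() - 1.0)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
    cand.pos[interior] = (conf.pos[interior] - p0) @ R.T + p0
    return cand


def metropolis_step(
    conf: Conformation,
    model: EnergyModel,
    vol: NucleoidVolume | None,
    rng: np.random.Generator,
    **propose_kw,
) -> tuple[Conformation, bool]:
    """One reference Metropolis step (propose, evaluate, accept/reject)."""
    e_old = total_energy(conf, model, vol)
    cand = propose_block_move(conf, rng, **propose_kw)
    e_new = total_energy(cand, model, vol)
    if metropolis_accept(e_new - e_old, rng):
        return cand, True
    return conf, False
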