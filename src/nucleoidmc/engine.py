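"""Array-packing layer between the domain objects and the numba kernels.

An :class:`Engine` owns the mutable Monte-Carlo state (vertex coordinates,
linked-cell grid, RNG stream) for one run.  It is built from a compiled
:class:`~nucleoidmc.chain.Structure`, an
:class:`~nucleoidmc.interactions.EnergyModel` with resolved constraints and
a target :class:`~nucleoidmc.interactions.NucleoidVolume`; the confinement
dimensions and macrodomain sphere radii can be changed between chunks,
which is how volume annealing and condensation schedules are driven.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .chain import Conformation, Structure, has_overlap
from .interactions import EnergyModel, NucleoidVolume


class AnnealingStalledError(RuntimeError):
    pass


def _csr(lists, dtype=np.int32):
    ptr = np.zeros(len(lists) + 1, dtype=np.int32)
    for i, l in enumerate(lists):
        ptr[i + 1] = ptr[i] + len(l)
    idx = (
        np.concatenate([np.asarray(l, dtype=dtype) for l in lists])
        if ptr[-1] > 0
        else np.zeros(0, dtype=dtype)
    )
    return ptr, idx


class Engine:
    """Mutable MC state + kernel dispatch for one simulation run."""

    def __init__(
        self,
        structure: Structure,
        model: EnergyModel,
        volume: NucleoidVolume | None,
        conformation: Conformation,
        seed: int,
        max_block_length: int = 50,
        p_reflect: float | None = None,
        translations: bool = False,
        translation_amplitude_nm: float = 50.0,
        grid_pad_nm: float | None = None,
    ):
        st = structure
        self.structure = st
        self.model = model
        self.volume = volume  # *target* volume; current dims may be larger
        self.seed = int(seed)
        self.max_block_length = int(max_block_length)
        self.translations = bool(translations)
        self.translation_amplitude_nm = float(translation_amplitude_nm)

        V = st.n_vertices
        S = st.n_segments
        self.pos = np.array(conformation.pos, dtype=np.float64, order="C")
        if self.pos.shape != (V, 3):
            raise ValueError("conformation does not match structure")
        self.segs = st.segments.astype(np.int32)
        self.seg_chain = st.seg_chain
        self.seg_pos = st.seg_pos
        self.chain_ptr = st.chain_ptr
        self.chain_verts = st.chain_verts
        self.chain_circ = st.chain_circular

        # bending joints, CSR by center vertex
        self.joint_tri = st.joints
        self.joint_kappa = st.joint_kappa
        by_center: list[list[int]] = [[] for _ in range(V)]
        for j, tri in enumerate(st.joints):
            by_center[tri[1]].append(j)
        self.jv_ptr, self.jv_idx = _csr(by_center)

        # macrodomains
        mds = model.md_constraints
        self.n_md = len(mds)
        self.vert_md = np.full(V, -1, dtype=np.int32)
        md_lists = []
        self.md_center = np.zeros(self.n_md, dtype=np.int32)
        self.md_k = np.zeros(self.n_md, dtype=np.float64)
        self.md_r = np.zeros(self.n_md, dtype=np.float64)  # current radii
        self.md_r_target = np.zeros(self.n_md, dtype=np.float64)
        for i, md in enumerate(mds):
            if md.vertices is None or md.center_vertex is None:
                raise ValueError("MD constraint not resolved")
            for v in md.vertices:
                if self.vert_md[v] != -1:
                    raise ValueError("vertex belongs to two MD constraints")
                self.vert_md[v] = i
            md_lists.append(md.vertices)
            self.md_center[i] = md.center_vertex
            self.md_k[i] = md.spring_constant
            self.md_r[i] = md.radius_nm
            self.md_r_target[i] = md.radius_nm
        self.md_is_com = np.array(
            [md.center_rule == "center-of-mass" for md in mds], dtype=np.bool_
        )
        self.md_ptr, self.md_verts = _csr(md_lists)
        self.md_k_active = self.md_k.copy()
        self.md_wall_k = 0.0  # >0: soft sphere wall (annealing only)
        self.md_sum = np.zeros((self.n_md, 3), dtype=np.float64)
        self.md_ub = np.zeros(self.n_md, dtype=np.float64)
        self.refresh_md_sums()

        # pins
        pins = model.pin_constraints
        P = len(pins)
        self.vert_pin = np.full(V, -1, dtype=np.int32)
        self.pin_tgt = np.zeros((P, 3), dtype=np.float64)
        self.pin_k = np.zeros(P, dtype=np.float64)
        self.pin_long = np.zeros(P, dtype=np.bool_)
        vol_for_targets = volume
        for i, pin in enumerate(pins):
            if pin.vertex is None:
                raise ValueError("pin constraint not resolved")
            if self.vert_pin[pin.vertex] != -1:
                raise ValueError("vertex carries two pins")
            self.vert_pin[pin.vertex] = i
            if pin.longitudinal:
                if vol_for_targets is None:
                    raise ValueError("class-target pin requires a nucleoid volume")
                self.pin_tgt[i, 0] = pin.target_x(vol_for_targets)
                self.pin_long[i] = True
            else:
                self.pin_tgt[i] = pin.target_point(vol_for_targets)
            self.pin_k[i] = pin.spring_constant

        # per-vertex incident segments, exclusions
        self.vs_ptr, self.vs_idx = _csr(st.segments_of_vertex)
        self.excl_ptr, self.excl_idx = _csr(st.exclusions)

        # junction bookkeeping
        self.is_junc = st.degree > 2
        self.free_end = st.degree == 1
        pend_junc, pend_chain, pend_lists = [], [], []
        refl_junc, refl_nb = [], []
        for v in np.where(self.is_junc)[0]:
            if st.degree[v] == 3:
                refl_junc.append(v)
                refl_nb.append(list(st.adjacency[v]))
            for c in range(st.n_chains):
                if not st.chain_circular[c]:
                    continue
                ids = st.chain_vertices(c)
                if v not in ids:
                    continue
                pend = self._pendant_set(v, c)
                if pend is not None:
                    pend_junc.append(v)
                    pend_chain.append(c)
                    pend_lists.append(pend)
        self.pend_junc = np.array(pend_junc, dtype=np.int32)
        self.pend_chain = np.array(pend_chain, dtype=np.int32)
        self.pend_ptr, self.pend_idx = _csr(pend_lists)
        self.refl_junc = np.array(refl_junc, dtype=np.int32)
        self.refl_nb = (
            np.array(refl_nb, dtype=np.int32)
            if refl_nb
            else np.zeros((0, 3), dtype=np.int32)
        )
        if p_reflect is None:
            p_reflect = 0.05 if len(self.refl_junc) else 0.0
        self.p_reflect = float(p_reflect)

        # connected components (for rigid translations)
        comp = np.full(V, -1, dtype=np.int32)
        nc = 0
        for v0 in range(V):
            if comp[v0] >= 0:
                continue
            stack = [v0]
            comp[v0] = nc
            while stack:
                v = stack.pop()
                for w in st.adjacency[v]:
                    if comp[w] < 0:
                        comp[w] = nc
                        stack.append(int(w))
            nc += 1
        comp_lists = [np.where(comp == i)[0].astype(np.int32) for i in range(nc)]
        self.comp_ptr, self.comp_verts = _csr(comp_lists)

        # flags
        self.bend_on = model.bending
        self.sa_on = model.self_avoidance
        self.conf_on = model.confinement and volume is not None
        self.conf_r = volume.radius_nm if volume is not None else 0.0
        self.conf_half = volume.half_length_nm if volume is not None else 0.0
        self.conf_wall_k = 0.0  # >0: soft confinement walls (annealing only)
        self.hard_d2 = st.hard_core_diameter_nm**2
        self.amplitude = 1.5  # radians; adapted during equilibration

        # scratch
        self.in_moved = np.zeros(V, dtype=np.bool_)
        self.moved_buf = np.zeros(V, dtype=np.int64)
        self.npos_buf = np.zeros((V, 3), dtype=np.float64)
        self.idx_of = np.zeros(V, dtype=np.int64)
        self.seg_mark = np.zeros(S, dtype=np.int8)
        self.aff_buf = np.zeros(max(S, 1), dtype=np.int64)
        self.aff_lvl = np.zeros(max(S, 1), dtype=np.int64)
        self.md_cnt = np.zeros(max(self.n_md, 1), dtype=np.int64)
        self.md_touch = np.zeros(max(self.n_md, 1), dtype=np.int64)
        self.md_cmoved = np.zeros(max(self.n_md, 1), dtype=np.bool_)
        self.md_pend_ub = np.zeros(max(self.n_md, 1), dtype=np.float64)

        self.sweep = 0
        self.accepted = 0
        self.overflowed = 0

        self._setup_grid(grid_pad_nm)
        _kernels.seed_rng(self.seed)

    # ------------------------------------------------------------------
    def _pendant_set(self, v: int, c: int) -> np.ndarray | None:
        """Vertices co-rotating with junction ``v`` when a block of chain
        ``c`` moves it: the component of ``v`` after removing chain-c bonds.
        Returns None if that component re-enters chain ``c`` (no valid
        pendant move exists)."""
        st = self.structure
        ids = set(int(x) for x in st.chain_vertices(c))
        chain_edges = set()
        segs = st.segments
        for s in np.where(st.seg_chain == c)[0]:
            a, b = int(segs[s, 0]), int(segs[s, 1])
            chain_edges.add((a, b))
            chain_edges.add((b, a))
        seen = {int(v)}
        stack = [int(v)]
        pend = []
        while stack:
            u = stack.pop()
            for w in st.adjacency[u]:
                w = int(w)
                if (u, w) in chain_edges or w in seen:
                    continue
                if w in ids:
                    return None  # component loops back into the moving chain
                seen.add(w)
                pend.append(w)
                stack.append(w)
        return np.array(sorted(pend), dtype=np.int32)

    def _setup_grid(
        self,
        pad: float | None,
        extra_lo: np.ndarray | None = None,
        extra_hi: np.ndarray | None = None,
    ) -> None:
        ls = self.structure.segment_length_nm
        d = self.structure.hard_core_diameter_nm
        self.cell_size = ls + d + 2.0
        lo = self.pos.min(axis=0).copy()
        hi = self.pos.max(axis=0).copy()
        if self.conf_on:
            lo = np.minimum(lo, [-self.conf_half, -self.conf_r, -self.conf_r])
            hi = np.maximum(hi, [self.conf_half, self.conf_r, self.conf_r])
        if extra_lo is not None:
            lo = np.minimum(lo, extra_lo)
        if extra_hi is not None:
            hi = np.maximum(hi, extra_hi)
        extent = float(np.max(hi - lo))
        if pad is None:
            # unconfined systems are recentered between chunks; the box is a
            # distant container wall that is touched only by rare excursions
            pad = max(1000.0, 0.25 * extent) if self.conf_on else max(
                2000.0, 0.5 * extent
            )
        lo -= pad
        hi += pad
        self._grid_pad = pad
        # 2 extra margin cells per side (the kernel treats the outermost
        # layer as out-of-bounds)
        self.glo = lo - 2 * self.cell_size
        dims = np.ceil((hi - self.glo) / self.cell_size).astype(np.int64) + 2
        self.gdim = dims.astype(np.int64)
        ncell = int(dims[0] * dims[1] * dims[2])
        if ncell > 120_000_000:
            raise MemoryError("cell grid too large; reduce system extent")
        self.head = np.zeros(ncell, dtype=np.int32)
        self.nxt = np.zeros(self.structure.n_segments, dtype=np.int32)
        self.seg_mid = np.zeros((self.structure.n_segments, 3), dtype=np.float64)
        self.seg_cell = np.zeros(self.structure.n_segments, dtype=np.int64)
        self.inv_cell = 1.0 / self.cell_size
        bad = _kernels.build_grid(
            self.pos,
            self.segs,
            self.glo,
            self.inv_cell,
            self.gdim,
            self.head,
            self.nxt,
            self.seg_mid,
            self.seg_cell,
        )
        if bad:
            raise RuntimeError("segments outside the cell grid at setup")

    # ------------------------------------------------------------------
    def set_confinement(self, radius_nm: float, half_length_nm: float) -> None:
        self.conf_r = float(radius_nm)
        self.conf_half = float(half_length_nm)

    def ensure_grid_covers(self, radius_nm: float, half_length_nm: float) -> None:
        """Enlarge the collision grid if a (bigger) confinement volume would
        reach into the grid's out-of-bounds margin."""
        need_lo = np.array([-half_length_nm, -radius_nm, -radius_nm]) - self.cell_size
        need_hi = -need_lo
        box_lo = self.glo + 2 * self.cell_size
        box_hi = self.glo + (self.gdim - 2) * self.cell_size
        if np.all(need_lo >= box_lo) and np.all(need_hi <= box_hi):
            return
        self._setup_grid(500.0, extra_lo=need_lo, extra_hi=need_hi)

    def fits_volume(self, radius_nm: float, half_length_nm: float) -> bool:
        p = self.pos
        r2 = p[:, 1] ** 2 + p[:, 2] ** 2
        return bool(
            np.all(r2 <= radius_nm**2) and np.all(np.abs(p[:, 0]) <= half_length_nm)
        )

    def md_constraint_center(self, i: int) -> np.ndarray:
        """Sphere center of MD ``i``: members' center of mass or the
        central monomer, per the constraint's center rule."""
        members = self.md_verts[self.md_ptr[i] : self.md_ptr[i + 1]]
        if self.md_is_com[i]:
            return self.pos[members].mean(axis=0)
        return self.pos[self.md_center[i]]

    def md_member_max_dist(self, i: int) -> float:
        members = self.md_verts[self.md_ptr[i] : self.md_ptr[i + 1]]
        c = self.md_constraint_center(i)
        return float(
            np.sqrt(np.max(np.sum((self.pos[members] - c) ** 2, axis=1)))
        )

    def refresh_md_sums(self) -> None:
        """Recompute member-position sums and extent bounds exactly
        (cancels the float drift of their incremental updates)."""
        for i in range(self.n_md):
            members = self.md_verts[self.md_ptr[i] : self.md_ptr[i + 1]]
            self.md_sum[i] = self.pos[members].sum(axis=0)
            if self.md_is_com[i]:
                c = self.md_sum[i] / len(members)
                self.md_ub[i] = float(
                    np.sqrt(np.max(np.sum((self.pos[members] - c) ** 2, axis=1)))
                ) + 1e-9

    # ------------------------------------------------------------------
    def run(self, n_moves: int) -> float:
        """Run ``n_moves`` sweeps; returns the acceptance rate of the chunk."""
        if self.n_md:
            self.refresh_md_sums()
        p_trans = 0.0
        if self.translations:
            p_trans = 0.2
        acc, ovf = _kernels.run_moves(
            int(n_moves),
            self.pos,
            self.segs,
            self.seg_chain,
            self.seg_pos,
            self.chain_ptr,
            self.chain_verts,
            self.chain_circ,
            self.joint_tri,
            self.joint_kappa,
            self.jv_ptr,
            self.jv_idx,
            self.vert_md,
            self.md_ptr,
            self.md_verts,
            self.md_center,
            self.md_k_active,
            self.md_r,
            self.md_wall_k,
            self.md_is_com,
            self.md_sum,
            self.md_ub,
            self.vert_pin,
            self.pin_tgt,
            self.pin_k,
            self.pin_long,
            self.vs_ptr,
            self.vs_idx,
            self.excl_ptr,
            self.excl_idx,
            self.is_junc,
            self.free_end,
            self.pend_junc,
            self.pend_chain,
            self.pend_ptr,
            self.pend_idx,
            self.refl_junc,
            self.refl_nb,
            self.comp_ptr,
            self.comp_verts,
            self.bend_on,
            self.sa_on,
            self.conf_on,
            self.conf_r,
            self.conf_half,
            self.conf_wall_k,
            self.hard_d2,
            self.max_block_length,
            self.amplitude,
            self.p_reflect,
            p_trans,
            self.translation_amplitude_nm,
            self.glo,
            self.inv_cell,
            self.gdim,
            self.head,
            self.nxt,
            self.seg_mid,
            self.seg_cell,
            self.in_moved,
            self.moved_buf,
            self.npos_buf,
            self.idx_of,
            self.seg_mark,
            self.aff_buf,
            self.aff_lvl,
            self.md_cnt,
            self.md_touch,
            self.md_cmoved,
            self.md_pend_ub,
        )
        self.sweep += int(n_moves)
        self.accepted += int(acc)
        self.overflowed += int(ovf)
        return acc / max(n_moves, 1)

    def adapt_amplitude(self, rate: float, lo: float = 0.3, hi: float = 0.5) -> None:
        if rate < lo:
            self.amplitude = max(self.amplitude * 0.8, 1e-3)
        elif rate > hi:
            self.amplitude = min(self.amplitude * 1.25, np.pi)

    # ------------------------------------------------------------------
    def recenter(self) -> None:
        """Translate the system's centroid back to the origin and rebuild
        the collision grid.  A pure symmetry operation for unconfined
        systems (used between sampling chunks to cancel center-of-mass
        drift); never called on confined runs."""
        self.pos -= self.pos.mean(axis=0)
        bad = _kernels.build_grid(
            self.pos,
            self.segs,
            self.glo,
            self.inv_cell,
            self.gdim,
            self.head,
            self.nxt,
            self.seg_mid,
            self.seg_cell,
        )
        if bad:
            self._setup_grid(None)

    def conformation(self) -> Conformation:
        return Conformation(
            self.structure,
            self.pos.copy(),
            sweep=self.sweep,
            nucleoid_length_nm=2 * self.conf_half if self.conf_on else None,
        )

    def audit(self, check_overlap: bool = True) -> None:
        """Assert every hard constraint on the current state (reference path)."""
        conf = self.conformation()
        err = conf.max_bond_error()
        if err > 1e-9:
            raise AssertionError(f"bond length drift {err:.2e} exceeds 1e-9")
        if self.conf_on and not self.fits_volume(self.conf_r, self.conf_half):
            raise AssertionError("vertex outside confinement volume")
        for i in range(self.n_md):
            if self.md_member_max_dist(i) > self.md_r[i] + 1e-6:
                raise AssertionError(f"MD sphere {i} breached")
        if self.sa_on and check_overlap and has_overlap(conf):
            raise AssertionError("self-avoidance violated")
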