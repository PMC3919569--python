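"""Segregation statistics computed from sampled trajectories.

* slice histograms — monomer occupancy of 200-nm-thick slices along the
  nucleoid long axis, normalized per chromosome;
* unmixing parameter mu — the total-variation distance between the slice
  histograms of two chromosomes (0 = completely mixed, 1 = unmixed);
* polar occupancy rho — fraction of frames in which a macrodomain center
  sits beyond the cell quarters, and the localization parameter
  lambda = (rho - rho0)/(1 - rho0) measured against the fiber-diameter
  control (lambda = 0: no positional preference; lambda = 1: always polar);
* longitudinal locus trajectories and mirror-canonicalized ordering
  patterns (e.g. "ter-left-ori-right").
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .interactions import NucleoidVolume
from .sampler import Trajectory

SLICE_THICKNESS_NM = 200.0


@dataclass
class SliceHistogram:
    edges: np.ndarray  # (n_bins + 1,)
    h: np.ndarray  # (n_bins,), sums to 1 for a non-empty chain

    @property
    def n_bins(self) -> int:
        return len(self.h)


def slice_edges(length_nm: float, thickness_nm: float = SLICE_THICKNESS_NM) -> np.ndarray:
    """Bin edges covering [-L/2, L/2]; a final partial slice is its own bin."""
    if length_nm < thickness_nm:
        raise ValueError("nucleoid shorter than one slice")
    n = int(ceil(length_nm / thickness_nm - 1e-9))
    edges = -length_nm / 2.0 + thickness_nm * np.arange(n + 1)
    edges[-1] = length_nm / 2.0
    return edges


def slice_histogram(
    x: np.ndarray,
    length_nm: float,
    thickness_nm: float = SLICE_THICKNESS_NM,
) -> SliceHistogram:
    """Normalized monomer occupancy of the longitudinal slices.

    ``x`` are longitudinal coordinates (nm) of one chromosome's monomers.
    """
    edges = slice_edges(length_nm, thickness_nm)
    counts, _ = np.histogram(np.asarray(x, dtype=float), bins=edges)
    total = counts.sum()
    h = counts / total if total > 0 else counts.astype(float)
    return SliceHistogram(edges=edges, h=h)


def unmixing_mu(h1: SliceHistogram | np.ndarray, h2: SliceHistogram | np.ndarray) -> float:
    """mu = 1/2 sum_i |h1(s_i) - h2(s_i)| (total-variation distance)."""
    a = h1.h if isinstance(h1, SliceHistogram) else np.asarray(h1, float)
    b = h2.h if isinstance(h2, SliceHistogram) else np.asarray(h2, float)
    if a.shape != b.shape:
        raise ValueError("histograms have different binnings")
    return float(0.5 * np.sum(np.abs(a - b)))


def mu_series(traj: Trajectory, chain_a: int, chain_b: int) -> np.ndarray:
    """Per-frame unmixing parameter between two chains of a trajectory."""
    st = traj.structure
    if traj.volume is None:
        raise ValueError("trajectory has no nucleoid volume")
    L = traj.volume.length_nm
    va = np.unique(st.chain_vertices(chain_a))
    vb = np.unique(st.chain_vertices(chain_b))
    # a vertex shared between the chains (junction) is counted once, for
    # the lower-numbered chain — consistent with label-based analysis of
    # stored trajectories
    if chain_a < chain_b:
        vb = np.setdiff1d(vb, va)
    else:
        va = np.setdiff1d(va, vb)
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        xa = traj.frames[i, va, 0]
        xb = traj.frames[i, vb, 0]
        out[i] = unmixing_mu(slice_histogram(xa, L), slice_histogram(xb, L))
    return out


def mu_summary(mu: np.ndarray) -> dict:
    """Mean and the 10-90% quantile band of a mu distribution."""
    return {
        "mean": float(np.mean(mu)),
        "q10": float(np.quantile(mu, 0.10)),
        "q90": float(np.quantile(mu, 0.90)),
        "n_frames": int(len(mu)),
    }


def polar_fraction(x_center: np.ndarray, vol: NucleoidVolume) -> float:
    """rho: fraction of frames with the MD center beyond the cell quarters
    (|x| > L/4)."""
    x = np.asarray(x_center, dtype=float)
    if x.size == 0:
        raise ValueError("empty trajectory")
    return float(np.mean(np.abs(x) > vol.length_nm / 4.0))


def localization_lambda(rho: float, rho0: float) -> float:
    """lambda = (rho - rho0) / (1 - rho0); the affine map with
    lambda(rho=rho0) = 0 and lambda(rho=1) = 1."""
    if rho0 >= 1.0:
        raise ValueError("rho0 = 1 leaves lambda undefined")
    return (rho - rho0) / (1.0 - rho0)


def locus_positions(
    traj: Trajectory, loci: list[tuple[str, int]]
) -> pd.DataFrame:
    """Longitudinal trajectories of tracked loci.

    Returns a tidy frame with columns (frame, sweep, locus, x_nm,
    fraction); ``fraction`` is the position as a fraction of the nucleoid
    length in [0, 1].
    """
    if traj.volume is None:
        raise ValueError("trajectory has no nucleoid volume")
    L = traj.volume.length_nm
    rows = []
    for label, v in loci:
        x = traj.frames[:, v, 0]
        for i in range(traj.n_frames):
            rows.append(
                (i, int(traj.sweeps[i]), label, float(x[i]), float((x[i] + L / 2) / L))
            )
    return pd.DataFrame(rows, columns=["frame", "sweep", "locus", "x_nm", "fraction"])


def locus_histogram(
    traj: Trajectory, vertex: int, n_bins: int = 40
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized position histogram of one locus (Fig-3-style)."""
    L = traj.volume.length_nm
    counts, edges = np.histogram(
        traj.frames[:, vertex, 0], bins=n_bins, range=(-L / 2, L / 2)
    )
    return counts / counts.sum(), edges


PATTERN_SEP = "-"


def canonical_pattern(labels) -> str:
    """Mirror-canonicalize an ordered label sequence: of the sequence and
    its reverse, return the lexicographically smaller, joined with '-'."""
    if isinstance(labels, str):
        seq = tuple(labels.replace("–", PATTERN_SEP).split(PATTERN_SEP))
    else:
        seq = tuple(labels)
    rev = tuple(reversed(seq))
    return PATTERN_SEP.join(min(seq, rev))


def classify_pattern(positions: list[tuple[str, float]]) -> str:
    """Longitudinal ordering pattern of tracked loci, mirror-canonicalized.

    ``positions`` is a list of (label, x) pairs; coincident x values are
    broken by label (stable, deterministic).
    """
    if len(positions) < 2:
        raise ValueError("need at least two loci to classify a pattern")
    ordered = sorted(positions, key=lambda t: (t[1], t[0]))
    return canonical_pattern([lbl for lbl, _ in ordered])


def pattern_frequencies(
    traj: Trajectory, loci: list[tuple[str, int]]
) -> dict[str, float]:
    """Frequency of each canonical ordering pattern over the trajectory."""
    counts: Counter[str] = Counter()
    for i in range(traj.n_frames):
        positions = [(lbl, float(traj.frames[i, v, 0])) for lbl, v in loci]
        counts[classify_pattern(positions)] += 1
    total = sum(counts.values())
    return {k: v / total for k, v in sorted(counts.items())}
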