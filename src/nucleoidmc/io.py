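"""Run configuration, trajectory persistence and run manifests.

Trajectories are stored as extended-XYZ text: per frame a vertex-count
line, a comment line with ``sweep=<n> length=<nm> radius=<nm>``, then one
record per vertex: ``<chain_label> <region_label> x y z`` in nm.  Genomic
region annotations can be exported as a BED-like 3-column table on the
circular, 0-based half-open coordinate system.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .interactions import NucleoidVolume
from .sampler import AnnealSchedule, MCConfig, Trajectory


class TrajectoryParseError(ValueError):
    pass


@dataclass
class RunConfig:
    """Serializable description of a run (preset + overrides + MC setup)."""

    preset: str = "g1-homogeneous"
    overrides: dict = field(default_factory=dict)
    mc: dict = field(default_factory=dict)
    anneal: dict = field(default_factory=dict)
    replicates: int = 2
    mu_consistency_threshold: float = 0.1

    def mc_config(self, seed: int | None = None) -> MCConfig:
        kw = dict(self.mc)
        if seed is not None:
            kw["seed"] = seed
        return MCConfig(**kw)

    def anneal_schedule(self) -> AnnealSchedule:
        return AnnealSchedule(**self.anneal)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ValueError(f"malformed config file {path}")
        return cls.from_dict(d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def vertex_labels(setup) -> tuple[list[str], list[str]]:
    """(chain_label, region_label) per global vertex for a PhaseSetup."""
    st = setup.structure
    chain_of = [""] * st.n_vertices
    for c in range(st.n_chains - 1, -1, -1):
        for v in st.chain_vertices(c):
            chain_of[v] = st.labels[c]
    reg_idx = setup.vertex_region
    names = setup.region_labels()
    region_of = [names[i] if i >= 0 else "none" for i in reg_idx]
    return chain_of, region_of


def write_trajectory(
    traj: Trajectory,
    path,
    chain_labels: list[str] | None = None,
    region_labels: list[str] | None = None,
) -> None:
    st = traj.structure
    V = st.n_vertices
    if chain_labels is None:
        chain_labels = [""] * V
        for c in range(st.n_chains - 1, -1, -1):
            for v in st.chain_vertices(c):
                chain_labels[v] = st.labels[c]
    if region_labels is None:
        region_labels = ["none"] * V
    L = traj.volume.length_nm if traj.volume else 0.0
    R = traj.volume.radius_nm if traj.volume else 0.0
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"{V}\n")
            fh.write(f"sweep={int(traj.sweeps[i])} length={L:g} radius={R:g}\n")
            fr = traj.frames[i]
            for v in range(V):
                fh.write(
                    f"{chain_labels[v]} {region_labels[v]} "
                    f"{fr[v, 0]:.6f} {fr[v, 1]:.6f} {fr[v, 2]:.6f}\n"
                )


def read_trajectory(path):
    """Parse an extended-XYZ trajectory.

    Returns (frames (F,V,3), sweeps (F,), chain_labels, region_labels,
    length_nm, radius_nm).  Raises :class:`TrajectoryParseError` naming the
    offending frame on malformed input.
    """
    frames, sweeps = [], []
    chain_labels = region_labels = None
    length = radius = 0.0
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            V = int(lines[i])
        except ValueError as e:
            raise TrajectoryParseError(
                f"frame {frame_no}: bad vertex count line {i + 1}"
            ) from e
        if i + 1 + V >= len(lines) + 1 and V > 0:
            pass
        if i + 1 + V > len(lines):
            raise TrajectoryParseError(f"frame {frame_no}: truncated at line {i + 1}")
        meta = dict(
            kv.split("=") for kv in lines[i + 1].split() if "=" in kv
        )
        sweeps.append(int(float(meta.get("sweep", 0))))
        length = float(meta.get("length", 0.0))
        radius = float(meta.get("radius", 0.0))
        pos = np.empty((V, 3))
        cl, rl = [], []
        for v in range(V):
            parts = lines[i + 2 + v].split()
            if len(parts) != 5:
                raise TrajectoryParseError(
                    f"frame {frame_no}: malformed vertex line {i + 3 + v}"
                )
            cl.append(parts[0])
            rl.append(parts[1])
            pos[v] = [float(parts[2]), float(parts[3]), float(parts[4])]
        frames.append(pos)
        chain_labels, region_labels = cl, rl
        i += 2 + V
        frame_no += 1
    if not frames:
        raise TrajectoryParseError("no frames in file")
    return (
        np.array(frames),
        np.array(sweeps, dtype=np.int64),
        chain_labels,
        region_labels,
        length,
        radius,
    )


def write_regions_bed(layout, path) -> None:
    """BED-like (label, start_bp, end_bp) table, circular 0-based half-open."""
    with open(path, "w") as fh:
        for r in layout.regions:
            fh.write(f"{r.label}\t{r.start_bp}\t{r.end_bp}\n")


@dataclass
class RunManifest:
    """Provenance of one run: enough to re-run bit-identically."""

    config_hash: str
    seeds: list[int]
    software_version: str
    frame_counts: list[int]
    wall_time_s: float
    summaries: list[dict]
    consistent: bool | None = None

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def replicate_consistency(mu_means: list[float], threshold: float) -> bool:
    """The published replicate rule: a pair of simulations is consistent when
    their mean unmixing parameters agree within ``threshold``; inconsistent
    pairs are flagged so extra replicates can be scheduled (never silently
    averaged)."""
    if len(mu_means) < 2:
        return True
    return (max(mu_means) - min(mu_means)) <= threshold
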