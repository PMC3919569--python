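"""Confinement, macrodomain condensation and locus-pinning energies.

The nucleoid is a right cylinder along x with flat caps (only its diameter,
800 nm, and phase-dependent length are constrained by imaging).  Macrodomain
(MD) condensation keeps a genomic region inside a hard sphere of diameter
360 nm centered on the region's genomically central vertex, with an optional
harmonic bias pulling member loci toward that center.  Pins tether single
loci to cellular target positions; pins expressed as a target *class*
(mid-cell, quarter, pole, septum) act on the longitudinal coordinate only,
because in vivo imaging constrains only longitudinal positions.

All energies are in kBT (T = 310 K); hard constraint breaches are returned
as ``inf`` and amount to Metropolis rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain import Conformation, Region, bending_energy, has_overlap

#: default harmonic constant for MD condensation, kBT/nm^2.  Chosen so the
#: unconstrained rms radius sqrt(3/k) ~ 120 nm sits just inside the 180-nm
#: hard sphere.
DEFAULT_MD_SPRING = 2.0e-4
#: default pin constant, kBT/nm^2: ~30 nm rms longitudinal fluctuation.
DEFAULT_PIN_SPRING = 1.2e-3

TARGET_CLASSES = ("mid-cell", "quarter", "pole", "septum")


@dataclass
class NucleoidVolume:
    """Right cylinder along x, flat caps, centered at the origin."""

    radius_nm: float = 400.0
    length_nm: float = 1800.0

    def __post_init__(self):
        if self.length_nm < 2 * self.radius_nm:
            raise ValueError("nucleoid length must be at least one diameter")

    @property
    def half_length_nm(self) -> float:
        return self.length_nm / 2.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        radial2 = p[:, 1] ** 2 + p[:, 2] ** 2
        return (radial2 <= self.radius_nm**2 + 1e-9) & (
            np.abs(p[:, 0]) <= self.half_length_nm + 1e-9
        )

    def scaled(self, factor: float) -> "NucleoidVolume":
        return NucleoidVolume(self.radius_nm * factor, self.length_nm * factor)


@dataclass
class MDConstraint:
    """Condense a genomic region into a sphere around its central monomer."""

    region: Region
    sphere_diameter_nm: float = 360.0
    spring_constant: float = DEFAULT_MD_SPRING  # kBT/nm^2; 0 = pure hard sphere
    center_rule: str = "central-monomer"
    chain: int = 0  # which chain copy carries this constraint
    # resolved against a Structure by scenarios.build_phase_setup:
    vertices: np.ndarray | None = None
    center_vertex: int | None = None

    def __post_init__(self):
        if self.sphere_diameter_nm <= 0:
            raise ValueError("sphere diameter must be positive")
        if self.center_rule not in ("central-monomer", "center-of-mass"):
            raise ValueError(f"unknown center rule {self.center_rule!r}")

    @property
    def radius_nm(self) -> float:
        return self.sphere_diameter_nm / 2.0

    def resolve(self, structure) -> "MDConstraint":
        self.vertices = structure.region_vertices(self.region, self.chain)
        if len(self.vertices) == 0:
            raise ValueError(f"region '{self.region.label}' maps to no vertices")
        self.center_vertex = structure.region_center_vertex(self.region, self.chain)
        if self.center_rule == "central-monomer" and self.center_vertex not in self.vertices:
            raise ValueError("central monomer not a member of its own region")
        return self

    def center_position(self, conf: Conformation) -> np.ndarray:
        if self.center_rule == "center-of-mass":
            return conf.pos[self.vertices].mean(axis=0)
        return conf.pos[self.center_vertex]


@dataclass
class PinConstraint:
    """Harmonic tether of one locus to a cellular position.

    ``target`` is either an explicit 3D point (full 3D tether) or a target
    class string — ``mid-cell``, ``septum``, ``quarter``, ``pole``, with an
    optional ``:+``/``:-`` sign choosing the cell half — in which case only
    the longitudinal (x) coordinate is penalized.
    """

    locus_bp: int
    target: str | tuple | np.ndarray = "mid-cell"
    spring_constant: float = DEFAULT_PIN_SPRING
    chain: int = 0
    vertex: int | None = None  # resolved against a Structure

    @property
    def longitudinal(self) -> bool:
        return isinstance(self.target, str)

    def resolve(self, structure) -> "PinConstraint":
        self.vertex = structure.vertex_of_bp(self.locus_bp, self.chain)
        return self

    def target_x(self, vol: NucleoidVolume) -> float:
        """Longitudinal target implied by a target class."""
        name, _, sign = str(self.target).partition(":")
        s = -1.0 if sign == "-" else 1.0
        if name in ("mid-cell", "septum"):
            return 0.0
        if name == "quarter":
            return s * vol.length_nm / 4.0
        if name == "pole":
            x = s * (vol.half_length_nm - vol.radius_nm)
            return x
        raise ValueError(f"unknown pin target class {self.target!r}")

    def target_point(self, vol: NucleoidVolume) -> np.ndarray:
        if self.longitudinal:
            return np.array([self.target_x(vol), 0.0, 0.0])
        t = np.asarray(self.target, dtype=float)
        if not vol.contains(t[None, :])[0]:
            raise ValueError(f"pin target {t} outside nucleoid volume")
        return t


@dataclass
class EnergyModel:
    """Sum of the enabled energy terms; hard terms reject moves outright."""

    bending: bool = True
    self_avoidance: bool = True
    confinement: bool = True
    md_constraints: list[MDConstraint] = field(default_factory=list)
    pin_constraints: list[PinConstraint] = field(default_factory=list)


# ---------------------------------------------------------------------------
# energy terms (pure reference implementations; the MC engine mirrors them)
# ---------------------------------------------------------------------------

def inside_volume(conf: Conformation, vol: NucleoidVolume) -> bool:
    return bool(np.all(vol.contains(conf.pos)))


def md_energy(conf: Conformation, md: MDConstraint) -> float:
    """Harmonic condensation energy; inf when the hard sphere is breached."""
    if md.vertices is None or md.center_vertex is None:
        raise ValueError("MD constraint not resolved against a structure")
    c = md.center_position(conf)
    d2 = np.sum((conf.pos[md.vertices] - c) ** 2, axis=1)
    if np.any(d2 > md.radius_nm**2 + 1e-9):
        return float("inf")
    return float(0.5 * md.spring_constant * np.sum(d2))


def pin_energy(conf: Conformation, pin: PinConstraint, vol: NucleoidVolume) -> float:
    if pin.vertex is None:
        raise ValueError("pin constraint not resolved against a structure")
    r = conf.pos[pin.vertex]
    if pin.longitudinal:
        dx = r[0] - pin.target_x(vol)
        return float(0.5 * pin.spring_constant * dx * dx)
    t = pin.target_point(vol)
    return float(0.5 * pin.spring_constant * np.sum((r - t) ** 2))


def total_energy(
    conf: Conformation, model: EnergyModel, vol: NucleoidVolume | None
) -> float:
    """Total energy in kBT; inf on overlap, confinement or MD-sphere breach."""
    if model.confinement and vol is not None and not inside_volume(conf, vol):
        return float("inf")
    if model.self_avoidance and has_overlap(conf):
        return float("inf")
    e = 0.0
    for md in model.md_constraints:
        e += md_energy(conf, md)
        if not np.isfinite(e):
            return float("inf")
    if vol is not None:
        for pin in model.pin_constraints:
            e += pin_energy(conf, pin, vol)
    if model.bending:
        e += bending_energy(conf)
    return e
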