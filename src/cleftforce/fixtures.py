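"""Seeded generators for synthetic structures with closed-form oracles.

Every generator builds a system whose downstream statistic is known exactly:
rigid two-domain trajectories with prescribed mass-center distance draws,
donor–H–acceptor triples at exact geometry, charged pairs on the x-axis,
single Born spheres, and presence/absence contact patterns across frames.
The atoms carry full parameter sets (mass, charge, radius, LJ) so every
analysis module runs without external tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import AtomTable, StructureFrame, Trajectory

__all__ = [
    "FixtureSpec",
    "make_two_domain_trajectory",
    "make_hbond_triple",
    "make_salt_bridge_pair",
    "make_point_charge_pair",
    "make_born_sphere",
    "make_occupancy_trajectory",
]

FIXTURE_KINDS = ("two_domain", "hbond_triple", "salt_bridge", "point_charges",
                 "born_sphere", "occupancy")


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a fixture family instance.

    The same spec + seed always reproduces byte-identical coordinates.
    """

    kind: str
    seed: int = 0
    n_frames: int = 1
    frame_interval_ns: float = 0.1
    params: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_interval_ns <= 0:
            raise ValueError("frame_interval must be positive")


def _atom_table(rows: list[tuple]) -> AtomTable:
    """rows: (serial, name, resname, chain, resnum, mass, q, r, eps, rmin2)."""
    cols = list(zip(*rows))
    return AtomTable(
        serial=np.array(cols[0], dtype=int),
        name=np.array(cols[1], dtype="U6"),
        residue_name=np.array(cols[2], dtype="U5"),
        chain=np.array(cols[3], dtype="U4"),
        residue_number=np.array(cols[4], dtype=int),
        mass=np.array(cols[5], dtype=float),
        charge=np.array(cols[6], dtype=float),
        radius=np.array(cols[7], dtype=float),
        lj_epsilon=np.array(cols[8], dtype=float),
        lj_rmin_half=np.array(cols[9], dtype=float),
    )


# Rigid tetrahedron-like template: 4 non-collinear beads, mass-center at 0.
_DOMAIN_TEMPLATE = np.array([
    [1.0, 1.0, 1.0],
    [-1.0, -1.0, 1.0],
    [-1.0, 1.0, -1.0],
    [1.0, -1.0, -1.0],
])


def _domain_atoms(chain: str, resnum: int, serial0: int) -> list[tuple]:
    return [(serial0 + k, f"C{k + 1}", "DOM", chain, resnum,
             12.011, 0.0, 1.7, 0.07, 2.0) for k in range(4)]


def make_two_domain_trajectory(n_frames: int, frame_interval_ns: float,
                               mean_distance: float, sd: float,
                               seed: int = 0) -> Trajectory:
    """Two rigid 4-bead pseudo-domains with a prescribed mass-center distance.

    Per-frame mass-center distances are drawn from Normal(mean, sd) truncated
    positive by resampling; with sd = 0 every frame sits exactly at
    ``mean_distance``.  Domain A is fixed at the origin; domain B translates
    along +x, so the recomputed mass-center distance equals the draw exactly.
    Frames are stamped ``frame_interval_ns, 2*frame_interval_ns, ...``.
    """
    if mean_distance <= 0:
        raise ValueError("mean_distance must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if frame_interval_ns <= 0:
        raise ValueError("frame_interval must be positive")
    rng = np.random.default_rng(seed)
    if sd == 0:
        draws = np.full(n_frames, float(mean_distance))
    else:
        draws = rng.normal(mean_distance, sd, size=n_frames)
        while np.any(draws <= 0):            # truncate by resampling
            bad = draws <= 0
            draws[bad] = rng.normal(mean_distance, sd, size=int(bad.sum()))
    atoms = _atom_table(_domain_atoms("A", 1, 1) + _domain_atoms("B", 2, 5))
    coords = np.empty((n_frames, 8, 3))
    coords[:, :4] = _DOMAIN_TEMPLATE
    coords[:, 4:] = _DOMAIN_TEMPLATE
    coords[:, 4:, 0] += draws[:, None]
    times = frame_interval_ns * np.arange(1, n_frames + 1)
    return Trajectory(atoms, coords, times)


def make_hbond_triple(d_DA: float, dev_angle: float,
                      time_ns: float | None = None) -> StructureFrame:
    """One donor N–H and one acceptor O at exact distance/angle geometry.

    The donor nitrogen sits at the origin, the acceptor oxygen at
    ``(d_DA, 0, 0)``; the hydrogen is bonded at 1.0 Å from the donor,
    rotated off the donor→acceptor axis by exactly ``dev_angle`` degrees
    (the deviation-from-collinearity convention used by the detector).
    """
    if d_DA <= 1.0:
        raise ValueError("donor-acceptor distance must exceed 1 Å")
    if not (0 <= dev_angle < 90):
        raise ValueError("deviation angle must be in [0, 90)")
    theta = np.deg2rad(dev_angle)
    h_pos = np.array([np.cos(theta), np.sin(theta), 0.0])   # |N–H| = 1.0
    atoms = _atom_table([
        (1, "NE2", "GLN", "A", 1, 14.007, -0.62, 1.55, 0.20, 1.85),
        (2, "HE21", "GLN", "A", 1, 1.008, 0.31, 1.0, 0.046, 0.2245),
        (3, "OG", "SER", "B", 2, 15.999, -0.65, 1.52, 0.1521, 1.77),
    ])
    coords = np.array([[0.0, 0.0, 0.0], h_pos, [d_DA, 0.0, 0.0]])
    return StructureFrame(atoms, coords, time_ns)


def make_salt_bridge_pair(d_NO: float) -> StructureFrame:
    """Lysine-like ammonium N (+1e) and glutamate-like carboxylate O (−1e)."""
    if d_NO <= 1.0:
        raise ValueError("N–O distance must exceed 1 Å")
    atoms = _atom_table([
        (1, "NZ", "LYS", "A", 830, 14.007, 1.0, 1.55, 0.20, 1.85),
        (2, "OE1", "GLU", "B", 1, 15.999, -1.0, 1.52, 0.12, 1.70),
    ])
    coords = np.array([[0.0, 0.0, 0.0], [d_NO, 0.0, 0.0]])
    return StructureFrame(atoms, coords)


def make_point_charge_pair(q1: float, q2: float,
                           separation: float) -> StructureFrame:
    """Two single-atom selections on the x-axis with the given charges."""
    if separation <= 0:
        raise ValueError("separation must be positive")
    atoms = _atom_table([
        (1, "Q1", "CHG", "A", 1, 22.99, q1, 1.5, 0.0, 1.5),
        (2, "Q2", "CHG", "B", 2, 35.45, q2, 1.5, 0.0, 1.5),
    ])
    coords = np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])
    return StructureFrame(atoms, coords)


def make_born_sphere(q: float, radius: float) -> StructureFrame:
    """A single charged sphere at the origin (polar-solvation oracle input)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    atoms = _atom_table([
        (1, "Q", "BRN", "A", 1, 22.99, q, radius, 0.0, radius),
    ])
    return StructureFrame(atoms, np.zeros((1, 3)))


def make_occupancy_trajectory(mask, frame_interval_ns: float = 0.1
                              ) -> Trajectory:
    """Donor–H–acceptor triple bonded (2.9 Å) where mask is true, 6.0 Å else.

    ``mask`` is a per-frame boolean sequence; the resulting occupancy of the
    single donor–acceptor pair is exactly ``100 * sum(mask) / len(mask)``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("mask must be non-empty")
    template = make_hbond_triple(2.9, 0.0)
    coords = np.repeat(template.coords[None, :, :], mask.size, axis=0)
    coords[~mask, 2, 0] = 6.0   # move acceptor out of range
    times = frame_interval_ns * np.arange(1, mask.size + 1)
    return Trajectory(template.atoms, coords, times)


def build(spec: FixtureSpec):
    """Build a fixture from a :class:`FixtureSpec` (CLI entry point)."""
    p = spec.params
    if spec.kind == "two_domain":
        mean, sd = p if p else (10.0, 0.5)
        return make_two_domain_trajectory(spec.n_frames, spec.frame_interval_ns,
                                          mean, sd, spec.seed)
    if spec.kind == "hbond_triple":
        d, ang = p if p else (3.0, 0.0)
        return make_hbond_triple(d, ang)
    if spec.kind == "salt_bridge":
        return make_salt_bridge_pair(p[0] if p else 3.9)
    if spec.kind == "point_charges":
        q1, q2, sep = p if p else (1.0, -1.0, 10.0)
        return make_point_charge_pair(q1, q2, sep)
    if spec.kind == "born_sphere":
        q, r = p if p else (1.0, 2.0)
        return make_born_sphere(q, r)
    if spec.kind == "occupancy":
        rng = np.random.default_rng(spec.seed)
        frac = p[0] if p else 0.166
        mask = rng.random(spec.n_frames) < frac
        return make_occupancy_trajectory(mask, spec.frame_interval_ns)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
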