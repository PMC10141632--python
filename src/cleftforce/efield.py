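"""Inter-domain electrostatics: screened Coulomb forces, binding/sliding
decomposition, frame-averaged force statistics, and a finite-difference
linearized Poisson–Boltzmann (LPB) solver.

Two routes coexist deliberately.  The production force path is the analytic
screened-Coulomb (Yukawa) sum in the solvent dielectric — exact against its
closed form, so every downstream statistic has an oracle.  The FD-LPB solver
provides the two-dielectric electrostatics that the analytic route cannot:
potential maps, surface-potential classification and the polar solvation
energies consumed by the MM/PBSA machinery; on homogeneous media the two
routes must agree, which is the solver's cross-check.

The binding/sliding decomposition projects the total force F_T onto the line
connecting the two selections' mass centers:

    F_binding = |F_T| cos α        F_sliding = |F_T| sin α

with α the angle between F_T and the center connection, oriented so that a
positive binding component means attraction (force on the target pointing
toward the source).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.stats import t as student_t

from .constants import K_COULOMB, N_AVOGADRO, kT
from .geomtop import mass_center
from .structio import Selection, StructureFrame, Trajectory, resolve_selection

__all__ = [
    "IonicMedium",
    "ForceRecord",
    "ForceStats",
    "GridSpec",
    "PotentialGrid",
    "pairwise_force",
    "decompose_force",
    "average_force",
    "solve_lpb",
    "surface_potential",
]


@dataclass(frozen=True)
class IonicMedium:
    """Solvent/solute dielectrics and a 1:1 electrolyte at a temperature.

    κ (the inverse Debye length) is always derived from the fields, never
    stored, so it can't go stale: κ² = 8π·l_B·n with l_B the Bjerrum length
    in the solvent dielectric and n the per-species number density.  At the
    defaults (ε=80, 150 mM, 310 K) the Debye length is ≈ 8.1 Å.
    """

    solvent_dielectric: float = 80.0
    solute_dielectric: float = 2.0
    ionic_strength_mM: float = 150.0
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if self.solvent_dielectric < 1 or self.solute_dielectric < 1:
            raise ValueError("dielectric constants must be >= 1")
        if self.ionic_strength_mM < 0:
            raise ValueError("ionic strength must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kT(self) -> float:
        """Thermal energy, kcal/mol."""
        return kT(self.temperature)

    @property
    def kappa(self) -> float:
        """Inverse Debye length, 1/Å (0 when the medium has no salt)."""
        if self.ionic_strength_mM == 0:
            return 0.0
        bjerrum = K_COULOMB / (self.solvent_dielectric * self.kT)   # Å
        n_per_A3 = self.ionic_strength_mM * 1e-3 * N_AVOGADRO / 1e27
        return float(np.sqrt(8.0 * np.pi * bjerrum * n_per_A3))

    @property
    def debye_length(self) -> float:
        """Debye screening length, Å (inf with no salt)."""
        k = self.kappa
        return float("inf") if k == 0 else 1.0 / k


@dataclass(frozen=True)
class ForceRecord:
    """Total force (kT/Å) plus its binding/sliding split and angle α."""

    total: np.ndarray            # 3-vector, kT/Å
    binding: float               # signed, kT/Å; > 0 = attraction
    sliding: float               # non-negative, kT/Å
    alpha_deg: float

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.total))


def pairwise_force(frame: StructureFrame, source: Selection,
                   target: Selection, medium: IonicMedium = IonicMedium(),
                   ) -> np.ndarray:
    """Screened-Coulomb force ON ``target`` FROM ``source``, kT/Å.

    Sum over inter-selection pairs of the Yukawa force
    ``k_e q_i q_j e^{−κr} (1+κr) / (ε r²)`` along the pair axis, in the
    solvent dielectric, converted to kT/Å at the medium temperature.
    Satisfies Newton's third law exactly and reduces to bare Coulomb as the
    ionic strength goes to zero.
    """
    si = resolve_selection(frame, source)
    ti = resolve_selection(frame, target)
    if np.intersect1d(si, ti).size:
        raise ValueError("source and target selections overlap")
    if not frame.atoms.has_charges:
        raise ValueError("charges not assigned")
    # canonical pair ordering so F(A→B) == −F(B→A) bit-exactly
    flip = si[0] > ti[0]
    lo, hi = (ti, si) if flip else (si, ti)
    q_lo = frame.atoms.charge[lo]
    q_hi = frame.atoms.charge[hi]
    rvec = frame.coords[hi][:, None, :] - frame.coords[lo][None, :, :]
    r = np.linalg.norm(rvec, axis=2)
    if np.any(r < 1e-9):
        raise ValueError("coincident atoms between source and target")
    kappa = medium.kappa
    eps = medium.solvent_dielectric
    scale = (K_COULOMB * (q_hi[:, None] * q_lo[None, :])
             * np.exp(-kappa * r) * (1.0 + kappa * r) / (eps * r ** 3))
    force = (scale[:, :, None] * rvec).sum(axis=(0, 1))   # on hi, kcal/mol/Å
    if flip:        # force on target == on lo == exact negation
        force = -force
    return force / medium.kT


def decompose_force(total: np.ndarray, center_source: np.ndarray,
                    center_target: np.ndarray) -> ForceRecord:
    """Split a total force into binding and sliding components.

    α is measured between the force and the unit vector from the target's
    center toward the source's center, so binding > 0 reads as attraction.
    ``binding² + sliding² = |F_T|²`` holds to rounding.
    """
    total = np.asarray(total, dtype=float)
    axis = np.asarray(center_source, float) - np.asarray(center_target, float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("mass centers coincide; axis undefined")
    u = axis / norm
    mag = float(np.linalg.norm(total))
    if mag == 0.0:
        return ForceRecord(total, 0.0, 0.0, 0.0)
    binding = float(np.dot(total, u))
    sliding = float(np.sqrt(max(mag * mag - binding * binding, 0.0)))
    alpha = float(np.degrees(np.arccos(np.clip(binding / mag, -1.0, 1.0))))
    return ForceRecord(total, binding, sliding, alpha)


@dataclass
class ForceStats:
    """Windowed mean force components with 95% Student-t intervals."""

    n_frames: int
    mean_total: np.ndarray
    mean_magnitude: float
    mean_binding: float
    mean_sliding: float
    mean_alpha_deg: float
    ci95_binding: float          # half-width, kT/Å
    ci95_sliding: float
    ci95_magnitude: float


def _t_halfwidth(values: np.ndarray, level: float = 0.95) -> float:
    n = len(values)
    sd = float(np.std(values, ddof=1))
    tcrit = float(student_t.ppf(0.5 + level / 2.0, n - 1))
    return tcrit * sd / np.sqrt(n)


def average_force(traj: Trajectory, source: Selection, target: Selection,
                  medium: IonicMedium = IonicMedium(),
                  window: tuple[float, float] | None = None) -> ForceStats:
    """Frame-averaged force decomposition over a (t_start, t_end] window.

    Per frame the total force and its binding/sliding split are computed,
    then each component is averaged and given a 95% confidence interval via
    the Student-t quantile on the per-frame sample.  At least two frames
    are required (a one-frame CI is undefined).
    """
    if window is None:
        in_win = np.ones(traj.n_frames, dtype=bool)
    else:
        in_win = (traj.times > window[0]) & (traj.times <= window[1])
    idx = np.flatnonzero(in_win)
    if idx.size == 0:
        raise ValueError("no frames in the requested window")
    if idx.size < 2:
        raise ValueError("confidence interval undefined for a single frame")
    si = resolve_selection(traj, source)
    ti = resolve_selection(traj, target)
    totals, bindings, slidings, alphas = [], [], [], []
    for i in idx:
        frame = traj.frame(i)
        f = pairwise_force(frame, source, target, medium)
        rec = decompose_force(f, mass_center(frame, si),
                              mass_center(frame, ti))
        totals.append(rec.total)
        bindings.append(rec.binding)
        slidings.append(rec.sliding)
        alphas.append(rec.alpha_deg)
    totals = np.array(totals)
    bindings = np.array(bindings)
    slidings = np.array(slidings)
    mags = np.linalg.norm(totals, axis=1)
    return ForceStats(
        n_frames=int(idx.size),
        mean_total=totals.mean(axis=0),
        mean_magnitude=float(mags.mean()),
        mean_binding=float(bindings.mean()),
        mean_sliding=float(slidings.mean()),
        mean_alpha_deg=float(np.mean(alphas)),
        ci95_binding=_t_halfwidth(bindings),
        ci95_sliding=_t_halfwidth(slidings),
        ci95_magnitude=_t_halfwidth(mags),
    )


# ---------------------------------------------------------------------------
# finite-difference linearized Poisson–Boltzmann
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """FD grid controls: resolution (grid/Å), solute filling ratio, extent.

    The box is sized so the solute's largest dimension (atom spheres
    included) spans ``filling_ratio`` of the box edge; ``min_extent`` can
    force a larger box when far-field values are needed.
    """

    resolution: float = 2.0       # grid points per Å
    filling_ratio: float = 0.70
    min_extent: float = 0.0       # Å, optional lower bound on box edge
    cg_rtol: float = 1e-8
    max_iter: int = 20000

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not (0 < self.filling_ratio < 1):
            raise ValueError("filling ratio must be in (0, 1)")


@dataclass
class PotentialGrid:
    """Solved potential (kT/e) on a regular grid with trilinear readout."""

    origin: np.ndarray          # Å, position of node (0,0,0)
    spacing: float              # Å
    values: np.ndarray          # (nx, ny, nz), kT/e

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at arbitrary points (must lie inside)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        f = (pts - self.origin) / self.spacing
        shape = np.array(self.values.shape)
        if np.any(f < 0) or np.any(f > shape - 1):
            raise ValueError("interpolation point outside the grid")
        i0 = np.minimum(f.astype(int), shape - 2)
        w = f - i0
        out = np.zeros(len(pts))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    weight = (np.where(dx, w[:, 0], 1 - w[:, 0])
                              * np.where(dy, w[:, 1], 1 - w[:, 1])
                              * np.where(dz, w[:, 2], 1 - w[:, 2]))
                    out += weight * self.values[i0[:, 0] + dx,
                                                i0[:, 1] + dy,
                                                i0[:, 2] + dz]
        return out if np.asarray(points).ndim > 1 else float(out[0])


def _grid_geometry(frame: StructureFrame, grid: GridSpec):
    coords = frame.coords
    radii = np.nan_to_num(frame.atoms.radius, nan=1.5)
    lo = (coords - radii[:, None]).min(axis=0)
    hi = (coords + radii[:, None]).max(axis=0)
    extent = float(max((hi - lo).max(), 1.0)) / grid.filling_ratio
    extent = max(extent, grid.min_extent)
    center = (lo + hi) / 2.0
    h = 1.0 / grid.resolution
    n = int(np.ceil(extent / h)) + 1
    origin = center - (n - 1) * h / 2.0
    return origin, h, n


def _edge_dielectric(origin, h, n, axis, coords, radii, eps_in, eps_out,
                     n_sub: int = 3):
    """Harmonic-mean dielectric on grid edges along one axis.

    Each edge is sub-sampled at ``n_sub`` interior points; a sample inside
    any atom sphere takes ε_in.  The harmonic mean reflects the series
    composition of the two media along the edge and markedly improves the
    Born-energy accuracy at coarse grids.
    """
    shape = [n, n, n]
    shape[axis] = n - 1
    ax = [np.arange(s) for s in shape]
    grid_idx = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).astype(float)
    inv_sum = np.zeros(shape)
    fractions = (np.arange(n_sub) + 0.5) / n_sub
    for frac in fractions:
        pos_idx = grid_idx.copy()
        pos_idx[..., axis] += frac
        pos = origin + h * pos_idx
        flat = pos.reshape(-1, 3)
        inside = np.zeros(flat.shape[0], dtype=bool)
        for c, r in zip(coords, radii):
            inside |= np.einsum("ij,ij->i", flat - c, flat - c) <= r * r
        eps = np.where(inside, eps_in, eps_out).reshape(shape)
        inv_sum += 1.0 / eps
    return n_sub / inv_sum


def solve_lpb(frame: StructureFrame, medium: IonicMedium = IonicMedium(),
              grid: GridSpec = GridSpec(),
              reference: bool = False) -> PotentialGrid:
    """7-point finite-difference solution of the linearized PB equation.

    Solves ``∇·(ε∇φ) − ε_out κ² λ(r) φ = −4π k_e ρ`` with ε = ε_in inside
    atom spheres and ε_out outside (edge dielectrics are sub-sampled
    harmonic means), λ = 1 in the solvent region, Dirichlet boundary from
    the analytic Debye–Hückel superposition, and charges spread to grid
    nodes trilinearly.  With ``reference=True`` the medium is homogeneous
    at ε_in with no salt — the vacuum-like reference state used by the
    reaction-field energy.  The potential is returned in kT/e.
    """
    if not (frame.atoms.has_charges and frame.atoms.has_radii):
        raise ValueError("charges and radii must be assigned")
    coords = frame.coords
    charges = frame.atoms.charge
    radii = frame.atoms.radius
    eps_in = medium.solute_dielectric
    eps_out = eps_in if reference else medium.solvent_dielectric
    kappa = 0.0 if reference else medium.kappa

    origin, h, n = _grid_geometry(frame, grid)
    if np.all(charges == 0):        # no sources: φ ≡ 0 exactly
        return PotentialGrid(origin, h, np.zeros((n, n, n)))
    axes = [origin[d] + h * np.arange(n) for d in range(3)]

    # trilinear charge spreading
    rho = np.zeros((n, n, n))
    f = (coords - origin) / h
    i0 = np.clip(f.astype(int), 0, n - 2)
    w = f - i0
    for a, q in enumerate(charges):
        if q == 0:
            continue
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    weight = ((w[a, 0] if dx else 1 - w[a, 0])
                              * (w[a, 1] if dy else 1 - w[a, 1])
                              * (w[a, 2] if dz else 1 - w[a, 2]))
                    rho[i0[a, 0] + dx, i0[a, 1] + dy, i0[a, 2] + dz] \
                        += q * weight

    # edge dielectrics and node-level ion accessibility
    if eps_in == eps_out:
        eps_x = np.full((n - 1, n, n), eps_out)
        eps_y = np.full((n, n - 1, n), eps_out)
        eps_z = np.full((n, n, n - 1), eps_out)
    else:
        eps_x = _edge_dielectric(origin, h, n, 0, coords, radii,
                                 eps_in, eps_out)
        eps_y = _edge_dielectric(origin, h, n, 1, coords, radii,
                                 eps_in, eps_out)
        eps_z = _edge_dielectric(origin, h, n, 2, coords, radii,
                                 eps_in, eps_out)
    if kappa > 0:
        nodes = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        flat = nodes.reshape(-1, 3)
        solvent = np.ones(flat.shape[0], dtype=bool)
        for c, r in zip(coords, radii):
            solvent &= np.einsum("ij,ij->i", flat - c, flat - c) > r * r
        lam = solvent.reshape(n, n, n).astype(float)
    else:
        lam = np.zeros((n, n, n))

    # Dirichlet boundary: Debye–Hückel superposition in the outer medium
    phi = np.zeros((n, n, n))
    boundary = np.zeros((n, n, n), dtype=bool)
    boundary[0, :, :] = boundary[-1, :, :] = True
    boundary[:, 0, :] = boundary[:, -1, :] = True
    boundary[:, :, 0] = boundary[:, :, -1] = True
    bpts = np.stack(np.meshgrid(*axes, indexing="ij"),
                    axis=-1)[boundary]
    bvals = np.zeros(len(bpts))
    for c, q in zip(coords, charges):
        if q == 0:
            continue
        r = np.linalg.norm(bpts - c, axis=1)
        r = np.maximum(r, 1e-6)
        bvals += K_COULOMB * q * np.exp(-kappa * r) / (eps_out * r)
    phi[boundary] = bvals

    # assemble the SPD system over interior nodes
    interior = ~boundary
    idx_map = -np.ones((n, n, n), dtype=int)
    idx_map[interior] = np.arange(interior.sum())
    ii, jj, kk = np.nonzero(interior)
    m = len(ii)
    diag = np.zeros(m)
    rows, cols, vals = [], [], []
    b = 4.0 * np.pi * K_COULOMB * rho[interior] / h

    neighbor_defs = [
        (eps_x, (-1, 0, 0)), (eps_x, (+1, 0, 0)),
        (eps_y, (0, -1, 0)), (eps_y, (0, +1, 0)),
        (eps_z, (0, 0, -1)), (eps_z, (0, 0, +1)),
    ]
    for eps_arr, (dx, dy, dz) in neighbor_defs:
        ni, nj, nk = ii + dx, jj + dy, kk + dz
        if dx != 0:
            e = eps_arr[np.minimum(ii, ni), jj, kk]
        elif dy != 0:
            e = eps_arr[ii, np.minimum(jj, nj), kk]
        else:
            e = eps_arr[ii, jj, np.minimum(kk, nk)]
        diag += e
        nbr_interior = interior[ni, nj, nk]
        rows.append(idx_map[ii, jj, kk][nbr_interior])
        cols.append(idx_map[ni, nj, nk][nbr_interior])
        vals.append(-e[nbr_interior])
        nbr_boundary = ~nbr_interior
        np.add.at(b, np.flatnonzero(nbr_boundary),
                  e[nbr_boundary] * phi[ni[nbr_boundary],
                                        nj[nbr_boundary],
                                        nk[nbr_boundary]])
    diag += (h * h * eps_out * kappa * kappa) * lam[interior]
    rows.append(np.arange(m))
    cols.append(np.arange(m))
    vals.append(diag)
    A = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(m, m))
    M = sp.diags(1.0 / diag)
    x, info = spla.cg(A, b, rtol=grid.cg_rtol, maxiter=grid.max_iter, M=M)
    if info != 0:
        raise RuntimeError(f"LPB conjugate-gradient failed (info={info})")
    phi[interior] = x
    return PotentialGrid(origin, h, phi / medium.kT)


def surface_potential(frame: StructureFrame, grid: PotentialGrid,
                      probe: float = 1.4, n_points: int = 500,
                      threshold: float = 1.0):
    """Mean potential (kT/e) on each solvent-exposed atom's surface points.

    Surface points are the accessible Shrake–Rupley samples at radius
    ``r_i + probe``; fully buried atoms are omitted.  Each value is
    classified against ±``threshold`` kT/e into "negative" / "neutral" /
    "positive" (the usual red/white/blue map).  Returns a list of
    ``(atom_index, value, classification)`` tuples.
    """
    from .surface import accessible_points
    if not frame.atoms.has_radii:
        raise ValueError("radii must be assigned")
    counts, points = accessible_points(frame.coords, frame.atoms.radius,
                                       probe, n_points)
    out = []
    for i, pts in enumerate(points):
        if counts[i] == 0:
            continue
        vals = grid.interpolate(pts)
        v = float(np.mean(vals))
        cls = ("negative" if v < -threshold
               else "positive" if v > threshold else "neutral")
        out.append((i, v, cls))
    return out
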