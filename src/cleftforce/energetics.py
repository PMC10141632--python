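"""MM/PBSA free-energy machinery.

The per-entity energy is the four-term sum

    E = E_c + E_v + E_p + E_np

with E_c the Coulombic energy, E_v the Lennard-Jones (van der Waals) energy,
E_p the polar solvation energy from the linearized-PB reaction field, and
E_np = α·SASA + β the nonpolar solvation term (α = 0.0054 kcal/mol/Å²,
β = 0.92 kcal/mol).  Binding free energy follows the single-trajectory
scheme: both parts are cut from the complex frame unchanged, so intra-part
Coulomb and LJ contributions cancel exactly in

    ΔE_bind = E_complex − E_partA − E_partB

leaving the inter-part MM terms plus the solvation differences.  Because
the affine E_np carries its intercept once per entity, ΔE_np includes a
constant −β offset on top of α·ΔSASA; this follows from composing the
four-term energy per entity literally, and is documented because some
MM/PBSA conventions drop β in differences.  No entropy term is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .constants import K_COULOMB
from .efield import GridSpec, IonicMedium, solve_lpb
from .structio import Selection, StructureFrame, Trajectory, resolve_selection
from .surface import accessible_points

__all__ = [
    "EnergyBreakdown",
    "NonpolarModel",
    "SasaResult",
    "BindingEnergyRecord",
    "coulomb_energy",
    "lj_energy",
    "sasa",
    "nonpolar_energy",
    "polar_solvation",
    "mmpbsa_binding",
]


@dataclass(frozen=True)
class EnergyBreakdown:
    """Four-term energy (kcal/mol); ``total`` is always their exact sum."""

    coulomb: float
    vdw: float
    polar: float
    nonpolar: float

    @property
    def total(self) -> float:
        return self.coulomb + self.vdw + self.polar + self.nonpolar


@dataclass(frozen=True)
class NonpolarModel:
    """Affine SASA model for the nonpolar solvation energy.

    ``slope_alpha`` (kcal/mol/Å²) and ``intercept_beta`` (kcal/mol) are the
    conventional surface-tension coefficients; note this α is a surface
    coefficient, unrelated to the force-decomposition angle α.
    """

    slope_alpha: float = 0.0054
    intercept_beta: float = 0.92

    def evaluate(self, sasa_total: float) -> float:
        return self.slope_alpha * sasa_total + self.intercept_beta


@dataclass
class SasaResult:
    """Per-atom and total solvent-accessible surface area (Å²)."""

    per_atom: np.ndarray
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


@dataclass
class BindingEnergyRecord:
    """Windowed single-trajectory ΔE_bind with per-term means and SDs."""

    n_frames: int
    delta_coulomb: float
    delta_vdw: float
    delta_polar: float
    delta_nonpolar: float
    delta_e: float
    sd_delta_e: float
    per_frame_delta_e: np.ndarray


def _pair_arrays(frame: StructureFrame, sel_a, sel_b):
    ia = sel_a if isinstance(sel_a, np.ndarray) \
        else resolve_selection(frame, sel_a)
    ib = sel_b if isinstance(sel_b, np.ndarray) \
        else resolve_selection(frame, sel_b)
    if np.intersect1d(ia, ib).size:
        raise ValueError("selections overlap")
    return ia, ib


def coulomb_energy(frame: StructureFrame, sel_a: Selection, sel_b: Selection,
                   dielectric: float = 1.0) -> float:
    """Inter-selection Coulomb energy Σ k_e q_i q_j / (ε r_ij), kcal/mol."""
    ia, ib = _pair_arrays(frame, sel_a, sel_b)
    if not frame.atoms.has_charges:
        raise ValueError("charges not assigned")
    r = cdist(frame.coords[ia], frame.coords[ib])
    if np.any(r < 1e-9):
        raise ValueError("coincident atoms between selections")
    q = np.outer(frame.atoms.charge[ia], frame.atoms.charge[ib])
    return float(K_COULOMB * np.sum(q / r) / dielectric)


def lj_energy(frame: StructureFrame, sel_a: Selection,
              sel_b: Selection) -> float:
    """Inter-selection Lennard-Jones energy, kcal/mol.

    CHARMM form ε_ij[(R_min,ij/r)¹² − 2(R_min,ij/r)⁶] with Lorentz–Berthelot
    combination: ε_ij geometric mean, R_min,ij the sum of the Rmin/2 halves.
    """
    ia, ib = _pair_arrays(frame, sel_a, sel_b)
    if not frame.atoms.has_lj:
        raise ValueError("LJ parameters not assigned")
    r = cdist(frame.coords[ia], frame.coords[ib])
    if np.any(r < 1e-9):
        raise ValueError("coincident atoms between selections")
    eps = np.sqrt(np.outer(frame.atoms.lj_epsilon[ia],
                           frame.atoms.lj_epsilon[ib]))
    rmin = (frame.atoms.lj_rmin_half[ia][:, None]
            + frame.atoms.lj_rmin_half[ib][None, :])
    s6 = (rmin / r) ** 6
    return float(np.sum(eps * (s6 * s6 - 2.0 * s6)))


def sasa(frame: StructureFrame, probe: float = 1.4,
         n_points: int = 1000) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom's expanded sphere (radius + probe) is sampled with a
    deterministic golden-spiral lattice; the accessible fraction times the
    expanded-sphere area gives the per-atom SASA.
    """
    if not frame.atoms.has_radii:
        raise ValueError("radii not assigned")
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    counts, _ = accessible_points(frame.coords, frame.atoms.radius, probe,
                                  n_points)
    expanded = frame.atoms.radius + probe
    per_atom = (counts / n_points) * 4.0 * np.pi * expanded ** 2
    return SasaResult(per_atom, probe, n_points)


def nonpolar_energy(sasa_total: float,
                    model: NonpolarModel = NonpolarModel()) -> float:
    """Nonpolar solvation energy α·SASA + β, kcal/mol."""
    if sasa_total < 0:
        raise ValueError("SASA must be non-negative")
    return model.evaluate(sasa_total)


def polar_solvation(frame: StructureFrame,
                    medium: IonicMedium = IonicMedium(),
                    grid: GridSpec = GridSpec()) -> float:
    """Polar (reaction-field) solvation energy from the FD-LPB solver.

    Two solves on the identical grid and charge discretization: the solvated
    state (ε_in inside the solute, ε_out and κ outside) minus the reference
    state (homogeneous ε_in, no salt).  The grid self-energy cancels in the
    difference; the result is ½ Σ q_i Δφ(r_i) in kcal/mol.
    """
    solvated = solve_lpb(frame, medium, grid, reference=False)
    ref = solve_lpb(frame, medium, grid, reference=True)
    dphi = (solvated.interpolate(frame.coords)
            - ref.interpolate(frame.coords))            # kT/e
    q = frame.atoms.charge
    return float(0.5 * np.sum(q * np.atleast_1d(dphi)) * medium.kT)


def energy_breakdown(frame: StructureFrame, sel_a: Selection,
                     sel_b: Selection,
                     medium: IonicMedium = IonicMedium(),
                     grid: GridSpec = GridSpec(),
                     nonpolar: NonpolarModel = NonpolarModel(),
                     coulomb_dielectric: float | None = None,
                     ) -> EnergyBreakdown:
    """Inter-selection four-term breakdown for one frame (kcal/mol)."""
    eps = (medium.solute_dielectric if coulomb_dielectric is None
           else coulomb_dielectric)
    return EnergyBreakdown(
        coulomb=coulomb_energy(frame, sel_a, sel_b, eps),
        vdw=lj_energy(frame, sel_a, sel_b),
        polar=polar_solvation(frame, medium, grid),
        nonpolar=nonpolar_energy(sasa(frame).total, nonpolar),
    )


def mmpbsa_binding(traj: Trajectory, complex_sel: Selection,
                   part_a: Selection, part_b: Selection,
                   window: tuple[float, float] | None = None,
                   medium: IonicMedium = IonicMedium(),
                   grid: GridSpec = GridSpec(),
                   nonpolar: NonpolarModel = NonpolarModel(),
                   coulomb_dielectric: float | None = None,
                   sasa_points: int = 1000) -> BindingEnergyRecord:
    """Single-trajectory MM/PBSA binding free energy over a time window.

    Per frame, parts A and B are extracted from the complex frame unchanged
    and  ΔE = E_c(inter) + E_v(inter)
            + [E_p(complex) − E_p(A) − E_p(B)]
            + [E_np(complex) − E_np(A) − E_np(B)]
    is accumulated; the record reports the mean and SD over the window.
    E_c(inter) uses the solute dielectric unless overridden.  The parts must
    partition the complex selection exactly.
    """
    ic = resolve_selection(traj, complex_sel)
    ia = resolve_selection(traj, part_a)
    ib = resolve_selection(traj, part_b)
    if np.intersect1d(ia, ib).size:
        raise ValueError("parts overlap")
    if not np.array_equal(np.union1d(ia, ib), ic):
        raise ValueError("parts must exactly partition the complex selection")
    if window is None:
        frames = np.arange(traj.n_frames)
    else:
        frames = np.flatnonzero((traj.times > window[0])
                                & (traj.times <= window[1]))
    if frames.size == 0:
        raise ValueError("no frames in the requested window")
    eps = (medium.solute_dielectric if coulomb_dielectric is None
           else coulomb_dielectric)

    d_c, d_v, d_p, d_np, d_tot = [], [], [], [], []
    for fi in frames:
        frame = traj.frame(fi)
        fc = frame.subset(ic)
        fa = frame.subset(ia)
        fb = frame.subset(ib)
        # inter-part MM terms == complex minus intra-part terms exactly
        la = np.flatnonzero(np.isin(ic, ia))
        lb = np.flatnonzero(np.isin(ic, ib))
        ec = coulomb_energy(fc, la, lb, eps)
        ev = lj_energy_idx(fc, la, lb)
        ep = (polar_solvation(fc, medium, grid)
              - polar_solvation(fa, medium, grid)
              - polar_solvation(fb, medium, grid))
        enp = (nonpolar_energy(sasa(fc, n_points=sasa_points).total, nonpolar)
               - nonpolar_energy(sasa(fa, n_points=sasa_points).total,
                                 nonpolar)
               - nonpolar_energy(sasa(fb, n_points=sasa_points).total,
                                 nonpolar))
        d_c.append(ec)
        d_v.append(ev)
        d_p.append(ep)
        d_np.append(enp)
        d_tot.append(ec + ev + ep + enp)
    d_tot = np.array(d_tot)
    sd = float(np.std(d_tot, ddof=1)) if len(d_tot) > 1 else 0.0
    return BindingEnergyRecord(
        n_frames=int(frames.size),
        delta_coulomb=float(np.mean(d_c)),
        delta_vdw=float(np.mean(d_v)),
        delta_polar=float(np.mean(d_p)),
        delta_nonpolar=float(np.mean(d_np)),
        delta_e=float(np.mean(d_tot)),
        sd_delta_e=sd,
        per_frame_delta_e=d_tot,
    )


def lj_energy_idx(frame: StructureFrame, ia: np.ndarray,
                  ib: np.ndarray) -> float:
    """LJ energy between two index arrays of the same frame."""
    return lj_energy(frame, np.asarray(ia), np.asarray(ib))
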