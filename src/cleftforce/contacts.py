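"""Salt-bridge and hydrogen-bond detection with per-pair occupancy.

Criteria follow the common trajectory-analysis conventions: a salt bridge is
a basic nitrogen (Lys NZ, Arg NE/NH1/NH2, ...) within 4 Å of an acidic
oxygen (Asp/Glu carboxylates, nucleotide phosphates); a hydrogen bond is a
donor–H ... acceptor triple with donor–acceptor distance ≤ 3.5 Å and the
D–H vector deviating ≤ 20° from the D→A direction.

Note the angle convention: 20° is the *deviation from collinearity* of D–H
against D→A (VMD's convention), not the D–H···A interior angle.  The two
give different answers; the interior-angle equivalent of this cutoff would
be ≥ 160°-ish and is NOT what is implemented here.

Cutoffs are boundary-inclusive (a pair at exactly 4.0 Å counts).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structio import Selection, StructureFrame, Trajectory, resolve_selection

__all__ = [
    "ContactCriteria",
    "SaltBridgeChemistry",
    "Contact",
    "OccupancyRecord",
    "detect_salt_bridges",
    "detect_hbonds",
    "occupancy",
    "filter_occupancy",
    "residue_occupancy",
]


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric cutoffs for contact detection (all boundary-inclusive)."""

    salt_bridge_cutoff: float = 4.0      # Å, N–O distance
    hbond_distance_cutoff: float = 3.5   # Å, donor–acceptor distance
    hbond_angle_cutoff: float = 20.0     # degrees, D–H deviation from D→A

    def __post_init__(self) -> None:
        if min(self.salt_bridge_cutoff, self.hbond_distance_cutoff,
               self.hbond_angle_cutoff) <= 0:
            raise ValueError("all cutoffs must be positive")
        if self.hbond_angle_cutoff >= 90:
            raise ValueError("angle cutoff must be < 90°")


#: Nucleotide phosphate oxygen names (ATP/ADP naming).
_PHOSPHATE_O = {"O1A", "O2A", "O3A", "O1B", "O2B", "O3B", "O1G", "O2G", "O3G"}


@dataclass(frozen=True)
class SaltBridgeChemistry:
    """Which atoms count as basic nitrogens / acidic oxygens.

    Defaults emulate the usual trajectory-analysis chemistry; both sets are
    plain mappings so ligand atoms or termini can be added in config.
    """

    basic: dict = field(default_factory=lambda: {
        "LYS": {"NZ"},
        "ARG": {"NE", "NH1", "NH2"},
    })
    acidic: dict = field(default_factory=lambda: {
        "ASP": {"OD1", "OD2"},
        "GLU": {"OE1", "OE2"},
        "ATP": set(_PHOSPHATE_O),
        "ADP": set(_PHOSPHATE_O),
        "PTR": {"O1P", "O2P", "O3P"},
    })

    def basic_mask(self, frame: StructureFrame) -> np.ndarray:
        return _chem_mask(frame, self.basic)

    def acidic_mask(self, frame: StructureFrame) -> np.ndarray:
        return _chem_mask(frame, self.acidic)


def _chem_mask(frame: StructureFrame, table: dict) -> np.ndarray:
    atoms = frame.atoms
    mask = np.zeros(atoms.n_atoms, dtype=bool)
    for i in range(atoms.n_atoms):
        names = table.get(atoms.residue_name[i])
        if names and atoms.name[i] in names:
            mask[i] = True
    return mask


@dataclass(frozen=True)
class Contact:
    """One detected interaction; ``key`` identifies it across frames."""

    kind: str            # "salt_bridge" | "hbond"
    partner_a: str       # residue label (salt bridge) or donor atom label
    partner_b: str       # residue label (salt bridge) or acceptor atom label
    distance: float      # Å (N–O min distance, or donor–acceptor)
    angle: float | None = None   # degrees, hbond only

    @property
    def key(self) -> tuple:
        return (self.kind, self.partner_a, self.partner_b)


@dataclass
class OccupancyRecord:
    """Fraction of frames (as a percent) in which one contact is present."""

    kind: str
    partner_a: str
    partner_b: str
    occupancy: float     # percent of frames
    count: int           # frames where the criterion held
    n_frames: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 100.0):
            raise ValueError("occupancy must be within [0, 100]")


def _element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def detect_salt_bridges(frame: StructureFrame,
                        criteria: ContactCriteria = ContactCriteria(),
                        chemistry: SaltBridgeChemistry = SaltBridgeChemistry(),
                        ) -> list[Contact]:
    """All basic-N / acidic-O residue pairs within the distance cutoff.

    Pairs are deduplicated to one record per residue pair, reporting the
    minimum N–O distance over the residues' atoms.
    """
    bi = np.flatnonzero(chemistry.basic_mask(frame))
    ai = np.flatnonzero(chemistry.acidic_mask(frame))
    if bi.size == 0 or ai.size == 0:
        return []
    d = cdist(frame.coords[bi], frame.coords[ai])
    best: dict[tuple, float] = {}
    for (r, c) in zip(*np.nonzero(d <= criteria.salt_bridge_cutoff)):
        pa = frame.atoms.residue_label(bi[r])
        pb = frame.atoms.residue_label(ai[c])
        key = (pa, pb)
        if key not in best or d[r, c] < best[key]:
            best[key] = float(d[r, c])
    return [Contact("salt_bridge", pa, pb, dist)
            for (pa, pb), dist in sorted(best.items())]


def _find_donors(frame: StructureFrame,
                 bond_cutoff: float = 1.25) -> list[tuple[int, int]]:
    """(heavy, hydrogen) donor pairs: H within bond_cutoff of an N or O."""
    elements = np.array([_element(n) for n in frame.atoms.name])
    h_idx = np.flatnonzero(elements == "H")
    heavy_idx = np.flatnonzero(np.isin(elements, ("N", "O")))
    donors = []
    for h in h_idx:
        if heavy_idx.size == 0:
            continue
        dist = np.linalg.norm(frame.coords[heavy_idx] - frame.coords[h],
                              axis=1)
        j = int(np.argmin(dist))
        if dist[j] <= bond_cutoff:
            donors.append((int(heavy_idx[j]), int(h)))
    return donors


def detect_hbonds(frame: StructureFrame,
                  criteria: ContactCriteria = ContactCriteria(),
                  ) -> list[Contact]:
    """Donor–H···acceptor triples passing the distance and angle cutoffs.

    Detected at atom-triple granularity: the donor heavy atom must carry a
    bound hydrogen, the acceptor is any other N/O, the donor–acceptor
    distance is ≤ the cutoff, and the D–H vector deviates from the D→A
    direction by no more than the angle cutoff.
    """
    elements = np.array([_element(n) for n in frame.atoms.name])
    acceptors = np.flatnonzero(np.isin(elements, ("N", "O")))
    out: list[Contact] = []
    for d_idx, h_idx in _find_donors(frame):
        dvec = frame.coords[h_idx] - frame.coords[d_idx]
        dvec = dvec / np.linalg.norm(dvec)
        for a_idx in acceptors:
            if a_idx == d_idx:
                continue
            avec = frame.coords[a_idx] - frame.coords[d_idx]
            r = np.linalg.norm(avec)
            if r < 1e-9 or r > criteria.hbond_distance_cutoff:
                continue
            cosang = float(np.clip(np.dot(dvec, avec / r), -1.0, 1.0))
            ang = float(np.degrees(np.arccos(cosang)))
            if ang <= criteria.hbond_angle_cutoff:
                out.append(Contact(
                    "hbond",
                    frame.atoms.atom_label(d_idx),
                    frame.atoms.atom_label(a_idx),
                    float(r), ang))
    return sorted(out, key=lambda c: (c.partner_a, c.partner_b))


def _contact_in_pair(frame_atoms, contact: Contact, labels_a: set,
                     labels_b: set) -> bool:
    """True if the contact spans the two selections (either direction)."""
    pa, pb = contact.partner_a, contact.partner_b
    return ((pa in labels_a and pb in labels_b)
            or (pa in labels_b and pb in labels_a))


def _selection_labels(traj: Trajectory, sel: Selection) -> set:
    idx = resolve_selection(traj, sel)
    labels = set()
    for i in idx:
        labels.add(traj.atoms.atom_label(i))
        labels.add(traj.atoms.residue_label(i))
    return labels


def occupancy(traj: Trajectory, detector, sel_a: Selection, sel_b: Selection,
              criteria: ContactCriteria = ContactCriteria(),
              ) -> list[OccupancyRecord]:
    """Per-pair occupancy over all frames, between two selections.

    ``detector`` is :func:`detect_salt_bridges` or :func:`detect_hbonds`
    (or any callable with the same (frame, criteria) signature).  A pair
    never observed is absent from the output; occupancy is
    ``100 * count / n_frames`` over *all* frames of the trajectory.
    """
    if traj.n_frames < 1:
        raise ValueError("trajectory must have at least one frame")
    labels_a = _selection_labels(traj, sel_a)
    labels_b = _selection_labels(traj, sel_b)
    counts: dict[tuple, int] = defaultdict(int)
    for frame in traj:
        seen = set()
        for contact in detector(frame, criteria):
            if contact.key in seen:
                continue
            if _contact_in_pair(traj.atoms, contact, labels_a, labels_b):
                seen.add(contact.key)
                counts[contact.key] += 1
    records = [
        OccupancyRecord(kind, pa, pb, 100.0 * c / traj.n_frames, c,
                        traj.n_frames)
        for (kind, pa, pb), c in counts.items()]
    return sorted(records, key=lambda r: -r.occupancy)


def filter_occupancy(records: list[OccupancyRecord],
                     threshold: float) -> list[OccupancyRecord]:
    """Records with occupancy strictly greater than threshold, sorted desc.

    The strict inequality follows the usual "high-occupancy (>10%)" reading;
    a record at exactly the threshold is excluded.
    """
    if not (0.0 <= threshold <= 100.0):
        raise ValueError("threshold must be within [0, 100]")
    keep = [r for r in records if r.occupancy > threshold]
    return sorted(keep, key=lambda r: -r.occupancy)


def _residue_of(partner: str) -> str:
    parts = partner.split(":")
    return ":".join(parts[:3])


def residue_occupancy(records: list[OccupancyRecord]) -> dict[str, float]:
    """Summed occupancy per residue across all of its pairs.

    A residue engaged in several bonds can exceed 100%; this is the
    "summed-occupancy" reading of per-residue hydrogen-bond contribution
    and is an interpretation, not a frame-wise union.
    """
    out: dict[str, float] = defaultdict(float)
    for r in records:
        out[_residue_of(r.partner_a)] += r.occupancy
        out[_residue_of(r.partner_b)] += r.occupancy
    return dict(out)
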