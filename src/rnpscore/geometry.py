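"""Geometric substrate: contacts, binning, superposition and ligand RMSD.

Conventions (fixed here, configurable via :class:`BinningScheme`):

* a protein bead and an RNA bead are in contact when their distance is
  strictly below the 9 A cutoff;
* distance bins are half-open ``[k*w, (k+1)*w)`` of width 1 A;
* the contact angle is measured between the RNA bead's reference axis and
  the vector from the RNA bead to the protein bead, binned in 20 degree
  half-open bins with 180 degrees closed into the last bin;
* base-face (edge) assignment splits the base plane into three 120 degree
  wedges anchored at the glycosidic direction: the Sugar face around the
  glycosidic bond, the Watson-Crick face opposite it, and the Hoogsteen
  face on the remaining side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .reduction import Bead, ReducedComplex

__all__ = [
    "BinningScheme",
    "Contact",
    "GeometryError",
    "EDGE_SECTORS",
    "find_contacts",
    "bin_distance",
    "contact_angle",
    "assign_edge",
    "superpose_receptors",
    "apply_transform",
    "ligand_rmsd",
    "ligand_rmsd_structures",
    "pairwise_ligand_rmsd",
]


class GeometryError(ValueError):
    """Degenerate or inconsistent geometry."""


#: in-plane wedge boundaries (degrees from the glycosidic direction,
#: measured about the oriented base normal); half-open [lo, hi)
EDGE_SECTORS: dict[str, tuple[float, float]] = {
    "Sugar": (0.0, 120.0),
    "WC": (120.0, 240.0),
    "Hoogsteen": (240.0, 360.0),
}

#: minimum in-space distance from the base centroid for edge assignment
EDGE_DEGENERACY_TOL = 0.1

BASE_EDGE_ROLES = ("PYR", "PUR6")


@dataclass(frozen=True)
class BinningScheme:
    distance_bin_width: float = 1.0      # A
    distance_cutoff: float = 9.0         # A, strict upper bound for contacts
    angle_bin_width: float = 20.0        # degrees
    edge_labels: tuple[str, ...] = ("WC", "Hoogsteen", "Sugar")

    def __post_init__(self) -> None:
        nd = self.distance_cutoff / self.distance_bin_width
        if abs(nd - round(nd)) > 1e-9:
            raise ValueError("distance_cutoff must be an integer multiple of distance_bin_width")
        na = 180.0 / self.angle_bin_width
        if abs(na - round(na)) > 1e-9:
            raise ValueError("angle_bin_width must divide 180")

    @property
    def n_distance_bins(self) -> int:
        return int(round(self.distance_cutoff / self.distance_bin_width))

    @property
    def n_angle_bins(self) -> int:
        return int(round(180.0 / self.angle_bin_width))

    @property
    def n_edge_bins(self) -> int:
        return len(self.edge_labels)


@dataclass
class Contact:
    protein_bead: Bead
    rna_bead: Bead
    distance: float          # A
    angle: float             # degrees in [0, 180]
    edge: str | None = None  # WC | Hoogsteen | Sugar, base-ring beads only


def bin_distance(r: float, scheme: BinningScheme) -> int:
    """Half-open distance bin index floor(r / width); r must be < cutoff."""
    if r < 0 or r >= scheme.distance_cutoff:
        raise GeometryError(f"distance {r} A outside [0, {scheme.distance_cutoff}) A")
    return int(r / scheme.distance_bin_width)


def bin_angle(theta: float, scheme: BinningScheme) -> int:
    """Angle bin, half-open, with 180 degrees closed into the last bin."""
    if theta < 0 or theta > 180:
        raise GeometryError(f"angle {theta} outside [0, 180]")
    return min(int(theta / scheme.angle_bin_width), scheme.n_angle_bins - 1)


def contact_angle(rna_bead: Bead, protein_bead: Bead) -> float:
    """Angle (degrees) between the RNA bead axis and the RNA->protein vector."""
    v = protein_bead.position - rna_bead.position
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise GeometryError("coincident bead positions: contact angle undefined")
    cosang = float(np.clip(np.dot(v / n, rna_bead.axis), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def assign_edge(base_bead: Bead, protein_bead: Bead) -> str:
    """Assign a contact to the WC, Hoogsteen or Sugar face of a base.

    The protein bead is projected into the base plane; the signed in-plane
    angle from the glycosidic direction selects one of the three wedges of
    :data:`EDGE_SECTORS`.
    """
    if base_bead.edge_frame is None:
        raise GeometryError(f"bead {base_bead.type} carries no edge frame")
    normal, glyco = base_bead.edge_frame
    v = protein_bead.position - base_bead.position
    if np.linalg.norm(v) < EDGE_DEGENERACY_TOL:
        raise GeometryError("protein bead coincides with base centroid: edge undefined")
    in_plane = v - np.dot(v, normal) * normal
    if np.linalg.norm(in_plane) < 1e-9:
        raise GeometryError("protein bead exactly on the base normal: edge undefined")
    in_plane /= np.linalg.norm(in_plane)
    phi = float(
        np.degrees(np.arctan2(np.dot(np.cross(glyco, in_plane), normal), np.dot(glyco, in_plane)))
        % 360.0
    )
    for label, (lo, hi) in EDGE_SECTORS.items():
        if lo <= phi < hi:
            return label
    return "Sugar"  # phi == 360 folds to 0; unreachable after the modulo


def find_contacts(complex_: ReducedComplex, scheme: BinningScheme | None = None) -> list[Contact]:
    """All protein-bead x RNA-bead pairs strictly within the distance cutoff."""
    scheme = scheme or BinningScheme()
    prot = complex_.protein_beads
    rna = complex_.rna_beads
    if not prot or not rna:
        return []
    d = cdist(
        np.array([b.position for b in prot]), np.array([b.position for b in rna])
    )
    contacts: list[Contact] = []
    for i, j in zip(*np.nonzero(d < scheme.distance_cutoff)):
        pb, rb = prot[i], rna[j]
        theta = contact_angle(rb, pb)
        edge = None
        if rb.type.role in BASE_EDGE_ROLES and rb.edge_frame is not None:
            edge = assign_edge(rb, pb)
        contacts.append(Contact(pb, rb, float(d[i, j]), theta, edge))
    return contacts


def superpose_receptors(
    ref_positions: np.ndarray, mov_positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) with R @ mov + t ~ ref (Kabsch).

    Returns a proper rotation (det +1).  Requires >= 3 non-collinear points.
    """
    ref = np.asarray(ref_positions, dtype=float)
    mov = np.asarray(mov_positions, dtype=float)
    if ref.shape != mov.shape:
        raise GeometryError(f"point sets differ in shape: {ref.shape} vs {mov.shape}")
    if ref.shape[0] < 3:
        raise GeometryError("superposition needs at least 3 points")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    ref0 = ref - ref_c
    if np.linalg.matrix_rank(ref0, tol=1e-8) < 2:
        raise GeometryError("reference points are collinear; rotation underdetermined")
    rot, _ = Rotation.align_vectors(ref0, mov - mov_c)
    R = rot.as_matrix()
    t = ref_c - R @ mov_c
    return R, t


def apply_transform(positions: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return positions @ R.T + t


def _side_positions(obj, side: str) -> np.ndarray:
    if isinstance(obj, ReducedComplex):
        beads = obj.receptor_beads if side == "receptor" else obj.ligand_beads
        return np.array([b.position for b in beads])
    raise TypeError(f"unsupported input type {type(obj).__name__}")


def _check_correspondence(native: ReducedComplex, model: ReducedComplex) -> None:
    for side in ("receptor_beads", "ligand_beads"):
        nb, mb = getattr(native, side), getattr(model, side)
        if len(nb) != len(mb):
            raise GeometryError(
                f"{side}: native has {len(nb)} beads, model has {len(mb)}"
            )
        for k, (a, b) in enumerate(zip(nb, mb)):
            if a.type != b.type:
                raise GeometryError(
                    f"{side}[{k}]: bead type mismatch {a.type} vs {b.type}"
                )


def ligand_rmsd(native: ReducedComplex, model: ReducedComplex) -> float:
    """Ligand RMSD after optimal superposition of the receptors.

    Native and model must share an exact bead correspondence (same types in
    the same order on both sides).  The model receptor is superposed onto
    the native receptor and the resulting transform applied to the model
    ligand before computing the RMSD over ligand beads.
    """
    _check_correspondence(native, model)
    R, t = superpose_receptors(
        _side_positions(native, "receptor"), _side_positions(model, "receptor")
    )
    lig_model = apply_transform(_side_positions(model, "ligand"), R, t)
    lig_native = _side_positions(native, "ligand")
    return float(np.sqrt(np.mean(np.sum((lig_model - lig_native) ** 2, axis=1))))


def _chain_atom_map(structure, chains: list[str]) -> dict[tuple, np.ndarray]:
    out: dict[tuple, np.ndarray] = {}
    for cid in chains:
        if cid not in structure.chains:
            raise GeometryError(f"chain {cid!r} not present in structure")
        for res in structure.chains[cid]:
            for a in res.atoms:
                if a.element in ("H", "D"):
                    continue
                out[(cid, a.residue_id[1], a.residue_id[2], a.name)] = a.position
    return out


def ligand_rmsd_structures(
    native, model, receptor_chains: list[str], ligand_chains: list[str]
) -> float:
    """All-heavy-atom ligand RMSD between parsed structures.

    Atoms are matched by (chain, residue number, insertion code, atom name);
    the model receptor is superposed onto the native receptor first.
    """
    pairs = []
    for side_chains in (receptor_chains, ligand_chains):
        nat = _chain_atom_map(native, side_chains)
        mod = _chain_atom_map(model, side_chains)
        common = [k for k in nat if k in mod]
        missing = [k for k in nat if k not in mod] + [k for k in mod if k not in nat]
        if missing:
            raise GeometryError(f"atom correspondence mismatch; first unmatched: {missing[0]}")
        pairs.append(
            (np.array([nat[k] for k in common]), np.array([mod[k] for k in common]))
        )
    (rec_nat, rec_mod), (lig_nat, lig_mod) = pairs
    R, t = superpose_receptors(rec_nat, rec_mod)
    lig = apply_transform(lig_mod, R, t)
    return float(np.sqrt(np.mean(np.sum((lig - lig_nat) ** 2, axis=1))))


def pairwise_ligand_rmsd(ligand_positions: list[np.ndarray]) -> np.ndarray:
    """Symmetric RMSD matrix between ligand poses sharing one fixed receptor.

    With a common receptor the superposition is the identity, so pose-pose
    distance is the plain coordinate RMSD.
    """
    n = len(ligand_positions)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = ligand_positions[i] - ligand_positions[j]
            mat[i, j] = mat[j, i] = np.sqrt(np.mean(np.sum(d * d, axis=1)))
    return mat
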