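"""Coarse-grained (united-atom) representation of protein-RNA complexes.

Amino acids are reduced to one to three beads depending on side-chain size:
a CA bead at the alpha carbon, a proximal side-chain bead (SC1, out to the
C-gamma layer) and, for large residues, a distal side-chain bead (SC2).
Nucleotides are reduced to a phosphate bead (P, centroid of P/OP1/OP2), a
ribose bead (RIB, centroid of the furanose ring) and base-ring centroids:
one bead for pyrimidines (PYR), two for purines (PUR6 for the six-membered
ring and PUR5 for the five-membered ring).

Every bead is typed by residue identity *and* role -- the CA bead of an
alanine and the CA bead of a lysine are distinct interaction types -- giving
52 protein types and 14 RNA types.  Base-ring beads additionally carry an
orthonormal edge frame (base-plane normal plus the in-plane glycosidic
direction) used to assign contacts to the Watson-Crick, Hoogsteen or Sugar
face of the base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structure_io import Residue, Structure, StructureWarning

__all__ = [
    "BeadType",
    "Bead",
    "ReducedComplex",
    "PROTEIN_BEAD_TYPES",
    "RNA_BEAD_TYPES",
    "SIDECHAIN_PARTITION",
    "reduce_protein_residue",
    "reduce_rna_residue",
    "reduce_complex",
    "reduce_structure_chains",
    "transform_beads",
    "beads_to_pdb",
]


#: side-chain heavy-atom membership of the SC1 (proximal, out to the C-gamma
#: layer) and SC2 (distal) beads.  GLY has no side chain; one tuple means a
#: two-bead residue, two tuples a three-bead residue.
SIDECHAIN_PARTITION: dict[str, tuple[tuple[str, ...], ...]] = {
    "GLY": (),
    "ALA": (("CB",),),
    "SER": (("CB", "OG"),),
    "CYS": (("CB", "SG"),),
    "THR": (("CB", "OG1", "CG2"),),
    "VAL": (("CB", "CG1", "CG2"),),
    "PRO": (("CB", "CG", "CD"),),
    "LEU": (("CB", "CG"), ("CD1", "CD2")),
    "ILE": (("CB", "CG1", "CG2"), ("CD1",)),
    "MET": (("CB", "CG"), ("SD", "CE")),
    "PHE": (("CB", "CG"), ("CD1", "CD2", "CE1", "CE2", "CZ")),
    "TYR": (("CB", "CG"), ("CD1", "CD2", "CE1", "CE2", "CZ", "OH")),
    "TRP": (("CB", "CG"), ("CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")),
    "ASP": (("CB", "CG"), ("OD1", "OD2")),
    "ASN": (("CB", "CG"), ("OD1", "ND2")),
    "GLU": (("CB", "CG"), ("CD", "OE1", "OE2")),
    "GLN": (("CB", "CG"), ("CD", "OE1", "NE2")),
    "HIS": (("CB", "CG"), ("ND1", "CD2", "CE1", "NE2")),
    "LYS": (("CB", "CG"), ("CD", "CE", "NZ")),
    "ARG": (("CB", "CG"), ("CD", "NE", "CZ", "NH1", "NH2")),
}

PHOSPHATE_ATOMS = ("P", "OP1", "OP2", "O1P", "O2P")
RIBOSE_RING = ("C1'", "C2'", "C3'", "C4'", "O4'")
PYR_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
PUR6_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
PUR5_RING = ("C4", "C5", "N7", "C8", "N9")

#: chirality reference ring atom used to orient the base-plane normal
_EDGE_REF_ATOM = {"PYR": "C5", "PUR6": "N7"}

_RNA_ROLES = {
    "A": ("P", "RIB", "PUR5", "PUR6"),
    "G": ("P", "RIB", "PUR5", "PUR6"),
    "C": ("P", "RIB", "PYR"),
    "U": ("P", "RIB", "PYR"),
}


@dataclass(frozen=True)
class BeadType:
    residue_code: str
    role: str

    def __str__(self) -> str:  # e.g. "ALA.CA", "A.PUR6"
        return f"{self.residue_code}.{self.role}"


def _protein_bead_types() -> list[BeadType]:
    types = []
    for code in sorted(SIDECHAIN_PARTITION):
        types.append(BeadType(code, "CA"))
        for k in range(len(SIDECHAIN_PARTITION[code])):
            types.append(BeadType(code, f"SC{k + 1}"))
    return types


def _rna_bead_types() -> list[BeadType]:
    return [BeadType(code, role) for code in sorted(_RNA_ROLES) for role in _RNA_ROLES[code]]


PROTEIN_BEAD_TYPES: list[BeadType] = _protein_bead_types()   # 52 types
RNA_BEAD_TYPES: list[BeadType] = _rna_bead_types()           # 14 types


@dataclass
class Bead:
    type: BeadType
    position: np.ndarray
    axis: np.ndarray
    # (unit plane normal, unit in-plane glycosidic direction); base-ring beads only
    edge_frame: tuple[np.ndarray, np.ndarray] | None = None
    constituent_atoms: tuple[str, ...] = ()
    residue_id: tuple[str, int, str] = ("", 0, "")


@dataclass
class ReducedComplex:
    receptor_beads: list[Bead]
    ligand_beads: list[Bead]
    receptor_kind: str
    ligand_kind: str
    source_id: str = ""
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        kinds = {self.receptor_kind, self.ligand_kind}
        if kinds != {"protein", "rna"}:
            raise ValueError(
                f"a reduced complex needs one protein and one rna side, got "
                f"receptor={self.receptor_kind!r} ligand={self.ligand_kind!r}"
            )

    @property
    def protein_beads(self) -> list[Bead]:
        return self.receptor_beads if self.receptor_kind == "protein" else self.ligand_beads

    @property
    def rna_beads(self) -> list[Bead]:
        return self.receptor_beads if self.receptor_kind == "rna" else self.ligand_beads

    def positions(self, side: str) -> np.ndarray:
        """(n, 3) coordinate array for 'receptor'/'ligand'/'protein'/'rna'."""
        beads = getattr(self, f"{side}_beads")
        return np.array([b.position for b in beads]) if beads else np.empty((0, 3))

    def swapped(self) -> "ReducedComplex":
        return ReducedComplex(
            receptor_beads=self.ligand_beads,
            ligand_beads=self.receptor_beads,
            receptor_kind=self.ligand_kind,
            ligand_kind=self.receptor_kind,
            source_id=self.source_id,
        )


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector cannot be normalized")
    return v / n


def _centroid(residue: Residue, names: tuple[str, ...]) -> tuple[np.ndarray | None, tuple[str, ...]]:
    found = [a for name in names for a in (residue.atom(name),) if a is not None]
    if not found:
        return None, ()
    pos = np.mean([a.position for a in found], axis=0)
    return pos, tuple(a.name for a in found)


def reduce_protein_residue(residue: Residue) -> list[Bead]:
    code = residue.code
    if code not in SIDECHAIN_PARTITION:
        warnings.warn(
            f"cannot reduce unknown amino acid {code!r}; residue skipped",
            StructureWarning, stacklevel=2,
        )
        return []
    ca = residue.atom("CA")
    if ca is None:
        warnings.warn(
            f"{code} {residue.residue_id}: missing CA, residue skipped",
            StructureWarning, stacklevel=2,
        )
        return []

    groups = SIDECHAIN_PARTITION[code]
    sc_beads: list[Bead] = []
    for k, names in enumerate(groups):
        pos, used = _centroid(residue, names)
        if pos is None:
            warnings.warn(
                f"{code} {residue.residue_id}: no atoms for SC{k + 1} bead; bead skipped",
                StructureWarning, stacklevel=2,
            )
            continue
        if len(used) < len(names):
            warnings.warn(
                f"{code} {residue.residue_id}: SC{k + 1} bead built from "
                f"{len(used)}/{len(names)} atoms",
                StructureWarning, stacklevel=2,
            )
        try:
            axis = _unit(pos - ca.position)
        except ValueError:
            axis = np.array([0.0, 0.0, 1.0])
        sc_beads.append(
            Bead(BeadType(code, f"SC{k + 1}"), pos, axis, None, used, residue.residue_id)
        )

    # CA axis: toward SC1, or the N->C backbone direction for glycine
    if sc_beads:
        ca_axis = _unit(sc_beads[0].position - ca.position)
    else:
        n_at, c_at = residue.atom("N"), residue.atom("C")
        if n_at is not None and c_at is not None and np.linalg.norm(c_at.position - n_at.position) > 1e-9:
            ca_axis = _unit(c_at.position - n_at.position)
        else:
            ca_axis = np.array([0.0, 0.0, 1.0])
    ca_bead = Bead(BeadType(code, "CA"), ca.position.copy(), ca_axis, None, ("CA",), residue.residue_id)
    return [ca_bead] + sc_beads


def _plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through `points` (SVD)."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def _project_in_plane(v: np.ndarray, normal: np.ndarray) -> np.ndarray:
    return v - np.dot(v, normal) * normal


def _signed_angle_deg(g: np.ndarray, x: np.ndarray, normal: np.ndarray) -> float:
    """In-plane angle from g to x about `normal`, in [0, 360)."""
    ang = np.degrees(np.arctan2(np.dot(np.cross(g, x), normal), np.dot(g, x)))
    return float(ang % 360.0)


def _base_edge_frame(
    residue: Residue, role: str, bead_pos: np.ndarray, ring_points: np.ndarray
) -> tuple[np.ndarray, np.ndarray] | None:
    glyco_n = residue.atom("N9") or residue.atom("N1")
    c1 = residue.atom("C1'")
    if glyco_n is None or c1 is None:
        return None
    normal = _plane_normal(ring_points)
    glyco = _project_in_plane(glyco_n.position - c1.position, normal)
    if np.linalg.norm(glyco) < 1e-9:
        return None
    glyco = _unit(glyco)
    # orient the normal by base chirality so that the Hoogsteen face always
    # falls on the same signed side of the glycosidic direction
    ref = residue.atom(_EDGE_REF_ATOM[role])
    if ref is not None:
        ref_dir = _project_in_plane(ref.position - bead_pos, normal)
        if np.linalg.norm(ref_dir) > 1e-9:
            if _signed_angle_deg(glyco, _unit(ref_dir), normal) < 180.0:
                normal = -normal
    return normal, glyco


def reduce_rna_residue(residue: Residue) -> list[Bead]:
    code = residue.code
    if code not in _RNA_ROLES:
        warnings.warn(
            f"cannot reduce nucleotide with unassigned code {code!r}; residue skipped",
            StructureWarning, stacklevel=2,
        )
        return []
    rid = residue.residue_id
    beads: list[Bead] = []

    rib_pos, rib_used = _centroid(residue, RIBOSE_RING)

    # base bead(s)
    base_beads: list[tuple[str, np.ndarray, tuple[str, ...], np.ndarray]] = []
    if code in ("C", "U"):
        pos, used = _centroid(residue, PYR_RING)
        if pos is not None:
            pts = np.array([residue.atom(n).position for n in PYR_RING if residue.atom(n)])
            base_beads.append(("PYR", pos, used, pts))
    else:
        all_ring = tuple(dict.fromkeys(PUR6_RING + PUR5_RING))
        pts_all = np.array([residue.atom(n).position for n in all_ring if residue.atom(n)])
        pos5, used5 = _centroid(residue, PUR5_RING)
        pos6, used6 = _centroid(residue, PUR6_RING)
        if pos5 is not None:
            base_beads.append(("PUR5", pos5, used5, pts_all))
        if pos6 is not None:
            base_beads.append(("PUR6", pos6, used6, pts_all))

    if rib_pos is None and not base_beads:
        warnings.warn(
            f"{code} {rid}: no ribose and no base-ring atoms; residue rejected",
            StructureWarning, stacklevel=2,
        )
        return []

    # anchor for inter-bead axes: the glycosidic-ring bead (PYR for
    # pyrimidines, PUR6 for purines)
    base_anchor = None
    for role, pos, _, _ in base_beads:
        if role in ("PYR", "PUR6"):
            base_anchor = pos

    p_atom = residue.atom("P")
    if p_atom is not None:
        p_pos, p_used = _centroid(residue, PHOSPHATE_ATOMS)
        target = rib_pos if rib_pos is not None else base_anchor
        axis = _unit(target - p_pos) if target is not None and np.linalg.norm(target - p_pos) > 1e-9 \
            else np.array([0.0, 0.0, 1.0])
        beads.append(Bead(BeadType(code, "P"), p_pos, axis, None, p_used, rid))
    else:
        warnings.warn(
            f"{code} {rid}: no phosphate (5'-terminal residue?); P bead omitted",
            StructureWarning, stacklevel=2,
        )

    if rib_pos is not None:
        target = base_anchor if base_anchor is not None else (
            p_atom.position if p_atom is not None else None
        )
        axis = _unit(target - rib_pos) if target is not None and np.linalg.norm(target - rib_pos) > 1e-9 \
            else np.array([0.0, 0.0, 1.0])
        beads.append(Bead(BeadType(code, "RIB"), rib_pos, axis, None, rib_used, rid))

    # one oriented base normal per residue: the edge frame of the
    # glycosidic-ring bead fixes the sign, and PUR5 shares it so that the
    # angle term stays invariant under rigid motions
    anchor_frame = None
    for role, pos, _, pts in base_beads:
        if role in ("PYR", "PUR6") and len(pts) >= 3:
            anchor_frame = _base_edge_frame(residue, role, pos, pts)
    for role, pos, used, pts in base_beads:
        frame = anchor_frame if role in ("PYR", "PUR6") else None
        if anchor_frame is not None:
            axis = anchor_frame[0]
        elif len(pts) >= 3:
            warnings.warn(
                f"{code} {rid}: base normal orientation undetermined (missing "
                f"glycosidic atoms); using an unoriented ring normal",
                StructureWarning, stacklevel=2,
            )
            axis = _plane_normal(pts)
        else:
            axis = np.array([0.0, 0.0, 1.0])
        beads.append(Bead(BeadType(code, role), pos, axis, frame, used, rid))

    return beads


def _reduce_residues(residues: list[Residue], kind: str) -> list[Bead]:
    out: list[Bead] = []
    for r in residues:
        if kind == "protein":
            out.extend(reduce_protein_residue(r))
        else:
            out.extend(reduce_rna_residue(r))
    return out


def reduce_structure_chains(structure: Structure, chain_ids: list[str]) -> tuple[list[Bead], str]:
    """Reduce the named chains; they must share a single polymer kind."""
    kinds = set()
    beads: list[Bead] = []
    for cid in chain_ids:
        if cid not in structure.chains:
            raise KeyError(f"chain {cid!r} not present in structure {structure.source_id!r}")
        from .structure_io import classify_chain

        kind = classify_chain(structure.chains[cid])
        if kind == "other":
            raise ValueError(f"chain {cid!r} is neither protein nor RNA (mixed or unusable)")
        kinds.add(kind)
        beads.extend(_reduce_residues(structure.chains[cid], kind))
    if len(kinds) != 1:
        raise ValueError(f"chains {chain_ids} mix polymer kinds {sorted(kinds)}")
    return beads, kinds.pop()


def reduce_complex(
    structure: Structure, receptor_chains: list[str], ligand_chains: list[str]
) -> ReducedComplex:
    """Reduce a parsed structure into receptor and ligand bead lists.

    Exactly one side must be protein and the other RNA; either may serve as
    receptor.  Bead order is deterministic: chains in the order given,
    residues in file order, roles in the fixed per-residue order.
    """
    rec_beads, rec_kind = reduce_structure_chains(structure, receptor_chains)
    lig_beads, lig_kind = reduce_structure_chains(structure, ligand_chains)
    if rec_kind == lig_kind:
        raise ValueError(
            f"receptor and ligand are both {rec_kind}; need one protein and one rna side"
        )
    return ReducedComplex(rec_beads, lig_beads, rec_kind, lig_kind, structure.source_id)


def transform_beads(beads: list[Bead], rotation: np.ndarray, translation: np.ndarray) -> list[Bead]:
    """Apply the rigid motion x -> R x + t to positions, axes and edge frames."""
    out = []
    for b in beads:
        frame = None
        if b.edge_frame is not None:
            frame = (rotation @ b.edge_frame[0], rotation @ b.edge_frame[1])
        out.append(
            Bead(
                type=b.type,
                position=rotation @ b.position + translation,
                axis=rotation @ b.axis,
                edge_frame=frame,
                constituent_atoms=b.constituent_atoms,
                residue_id=b.residue_id,
            )
        )
    return out


def beads_to_pdb(complex_: ReducedComplex) -> str:
    """Pseudo-PDB export of a reduced complex (one ATOM per bead).

    Non-standard: the bead role is written in the atom-name field and the
    residue code in the residue field; intended for visual inspection only.
    """
    lines = []
    serial = 1
    for chain_label, beads in (("R", complex_.receptor_beads), ("L", complex_.ligand_beads)):
        for b in beads:
            role = b.type.role[:4]
            res = b.type.residue_code[:3]
            lines.append(
                f"ATOM  {serial:>5d} {role:<4.4s} {res:>3.3s} {chain_label}"
                f"{b.residue_id[1] % 10000:>4d}    "
                f"{b.position[0]:8.3f}{b.position[1]:8.3f}{b.position[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
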