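"""Rigid-body pose sampling and synthetic training material.

The decoys-as-reference-state potential needs large sets of poses that are
geometrically plausible (the two molecules touch, without gross overlap)
but carry no interaction physics.  :func:`generate_decoys` produces such
sets by rejection sampling: rotations are drawn from a deterministic
Euler-angle grid (10 degree steps by default, emulating FFT-docking
rotational sampling), translations from a shell around the receptor, and a
pose is kept when at least one bead pair is within the contact cutoff while
at most a small fraction of ligand beads sits inside clash range.

The module also builds the package's synthetic study material: idealized
all-atom protein-RNA complexes (:func:`make_toy_complex`) and bead-level
training sets with a known enriched contact planted at one
(protein type, RNA type, distance bin) cell
(:func:`make_planted_training_set`), used to verify that training recovers
a signal deliberately placed in the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .geometry import BinningScheme
from .reduction import (
    PROTEIN_BEAD_TYPES,
    RNA_BEAD_TYPES,
    SIDECHAIN_PARTITION,
    Bead,
    BeadType,
    ReducedComplex,
    transform_beads,
)
from .structure_io import AtomRecord, Residue, Structure

__all__ = [
    "Pose",
    "DecoySet",
    "sample_pose",
    "generate_decoys",
    "perturbation_decoys",
    "AA_COMPOSITION_WEIGHTS",
    "make_toy_complex",
    "make_planted_training_set",
]


@dataclass
class Pose:
    """Rigid ligand pose: rotate about the native ligand centroid, then shift.

    The transform of a ligand point x is ``R (x - c) + c + t`` with c the
    native ligand centroid; the identity rotation with zero translation
    leaves the ligand unchanged.
    """

    rotation: np.ndarray      # unit quaternion, scalar-last (x, y, z, w)
    translation: np.ndarray   # centroid displacement, A
    seed_provenance: str = ""

    def matrix(self) -> np.ndarray:
        return Rotation.from_quat(self.rotation).as_matrix()

    def apply(self, positions: np.ndarray, center: np.ndarray) -> np.ndarray:
        R = self.matrix()
        return (positions - center) @ R.T + center + self.translation


@dataclass
class DecoySet:
    native: ReducedComplex
    poses: list[Pose]
    scheme: BinningScheme = field(default_factory=BinningScheme)
    _rmsds: np.ndarray | None = field(default=None, repr=False)

    def _ligand_center(self) -> np.ndarray:
        return self.native.positions("ligand").mean(axis=0)

    def ligand_positions(self, k: int) -> np.ndarray:
        return self.poses[k].apply(self.native.positions("ligand"), self._ligand_center())

    def complexes(self) -> list[ReducedComplex]:
        """Materialize each pose as a ReducedComplex sharing the receptor."""
        c = self._ligand_center()
        out = []
        for p in self.poses:
            R = p.matrix()
            t_eff = c + p.translation - R @ c
            out.append(
                ReducedComplex(
                    receptor_beads=self.native.receptor_beads,
                    ligand_beads=transform_beads(self.native.ligand_beads, R, t_eff),
                    receptor_kind=self.native.receptor_kind,
                    ligand_kind=self.native.ligand_kind,
                    source_id=f"{self.native.source_id}/decoy",
                )
            )
        return out

    def ligand_rmsds(self) -> np.ndarray:
        """RMSD of each pose's ligand from the native ligand (receptor fixed)."""
        if self._rmsds is None:
            lig = self.native.positions("ligand")
            c = self._ligand_center()
            vals = []
            for p in self.poses:
                d = p.apply(lig, c) - lig
                vals.append(np.sqrt(np.mean(np.sum(d * d, axis=1))))
            self._rmsds = np.array(vals)
        return self._rmsds


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_pose(
    seed,
    rotation_step: float = 10.0,
    receptor_center: np.ndarray | None = None,
    inner_radius: float = 0.0,
    shell_width: float = 15.0,
    ligand_center: np.ndarray | None = None,
) -> Pose:
    """Draw one pose: grid rotation plus a translation into a shell.

    The rotation is one of the ``(360/step)^3`` z-y-z Euler triples of the
    deterministic grid; the ligand centroid target is drawn uniformly (by
    volume) from the spherical shell ``[inner_radius, inner_radius +
    shell_width]`` around the receptor center.
    """
    n = 360.0 / rotation_step
    if abs(n - round(n)) > 1e-9 or rotation_step <= 0:
        raise ValueError("rotation_step must be a positive divisor of 360")
    n = int(round(n))
    rng = _rng(seed)
    receptor_center = np.zeros(3) if receptor_center is None else np.asarray(receptor_center)
    ligand_center = np.zeros(3) if ligand_center is None else np.asarray(ligand_center)
    angles = rng.integers(0, n, size=3) * rotation_step
    rot = Rotation.from_euler("ZYZ", angles, degrees=True)
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    lo, hi = inner_radius, inner_radius + shell_width
    r = (lo**3 + rng.random() * (hi**3 - lo**3)) ** (1.0 / 3.0)
    target = receptor_center + r * u
    return Pose(
        rotation=rot.as_quat(),
        translation=target - ligand_center,
        seed_provenance=f"grid{rotation_step:g}",
    )


def generate_decoys(
    native: ReducedComplex,
    n: int,
    max_clash_fraction: float = 0.2,
    seed: int = 0,
    scheme: BinningScheme | None = None,
    clash_distance: float = 3.0,
    rotation_step: float = 10.0,
    shell_width: float = 15.0,
    max_attempts_factor: int = 1000,
) -> DecoySet:
    """Geometry-only decoy set via rejection sampling.

    A pose is accepted when (a) at least one receptor-ligand bead pair is
    within the contact cutoff (the molecules touch) and (b) the fraction of
    ligand beads closer than ``clash_distance`` to any receptor bead does
    not exceed ``max_clash_fraction``.  No energies are consulted.
    """
    if n < 1:
        raise ValueError("need n >= 1 decoys")
    scheme = scheme or BinningScheme()
    rng = _rng(seed)
    rec = native.positions("receptor")
    lig = native.positions("ligand")
    rec_center = rec.mean(axis=0)
    lig_center = lig.mean(axis=0)
    inner = float(np.max(np.linalg.norm(rec - rec_center, axis=1)))
    poses: list[Pose] = []
    attempts = 0
    cap = max_attempts_factor * n
    while len(poses) < n:
        if attempts >= cap:
            raise RuntimeError(
                f"decoy generation exhausted {cap} attempts "
                f"(acceptance rate {len(poses) / attempts:.4f}); relax the filters "
                f"or increase the attempt cap"
            )
        attempts += 1
        pose = sample_pose(
            rng,
            rotation_step=rotation_step,
            receptor_center=rec_center,
            inner_radius=inner,
            shell_width=shell_width,
            ligand_center=lig_center,
        )
        moved = pose.apply(lig, lig_center)
        dmin = cdist(rec, moved).min(axis=0)
        if dmin.min() >= scheme.distance_cutoff:
            continue
        clash_frac = np.count_nonzero(dmin < clash_distance) / len(dmin)
        if clash_frac > max_clash_fraction:
            continue
        pose.seed_provenance = f"generate_decoys:seed={seed}:k={len(poses)}"
        poses.append(pose)
    return DecoySet(native=native, poses=poses, scheme=scheme)


def perturbation_decoys(
    native: ReducedComplex,
    n: int,
    seed: int = 0,
    max_rotation: float = 90.0,
    max_translation: float = 18.0,
    min_scale: float = 0.0,
) -> DecoySet:
    """Graded near-native decoy series by perturbing the native pose.

    Pose k draws a rotation angle and translation magnitude scaled by
    roughly ``(k+1)/n``, producing a set whose ligand RMSDs ramp from
    near-zero to tens of Angstroms -- the shape of bound-docking test sets
    built by perturbing a crystal structure.  ``min_scale`` lifts the lower
    end of the ramp.
    """
    if n < 1:
        raise ValueError("need n >= 1 decoys")
    rng = _rng(seed)
    poses = []
    for k in range(n):
        s = min_scale + (1.0 - min_scale) * (k + 1) / n
        ax = rng.normal(size=3)
        ax /= np.linalg.norm(ax)
        rot = Rotation.from_rotvec(np.radians(s * max_rotation * rng.random()) * ax)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        poses.append(
            Pose(rot.as_quat(), s * max_translation * rng.random() * u,
                 f"perturbation_decoys:seed={seed}:k={k}")
        )
    return DecoySet(native=native, poses=poses)


# ---------------------------------------------------------------------------
# idealized all-atom fixtures
# ---------------------------------------------------------------------------

_AA_CODES = sorted(SIDECHAIN_PARTITION)
_NT_CODES = ("A", "C", "G", "U")

#: sequence composition of the toy complexes.  Protein-RNA interfaces are
#: strongly enriched in basic and polar residues (arginine and lysine above
#: all, contacting the phosphate-ribose backbone), and a knowledge-based
#: potential exists to exploit exactly that recurring chemistry, so the
#: generator draws interface sequences from an RNA-binding-like composition
#: rather than uniformly over the twenty amino acids.
AA_COMPOSITION_WEIGHTS: dict[str, float] = {
    "ARG": 10.0, "LYS": 10.0, "SER": 4.0, "ASN": 4.0,
    "THR": 3.0, "GLN": 3.0, "HIS": 2.0, "TYR": 2.0,
}
_AA_DEFAULT_WEIGHT = 0.3


def _protein_helix_residue(code: str, i: int) -> list[tuple[str, np.ndarray]]:
    """Backbone + templated side chain for residue i of an ideal alpha helix."""

    def helix(s: float) -> np.ndarray:
        ang = np.radians(100.0 * s)
        return np.array([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * s])

    ca = helix(i)
    radial = np.array([ca[0], ca[1], 0.0])
    radial /= np.linalg.norm(radial)
    tang = np.array([-radial[1], radial[0], 0.0])
    atoms = [
        ("N", helix(i - 0.35)),
        ("CA", ca),
        ("C", helix(i + 0.35)),
        ("O", helix(i + 0.35) + 1.23 * radial),
    ]
    axial = np.array([0.0, 0.0, 1.0])
    k = 0
    for group in SIDECHAIN_PARTITION[code]:
        for name in group:
            # compact outward march: even large side chains stay within a
            # few Angstroms of CA, as rotamers do
            pos = (
                ca
                + radial * (1.4 + 0.5 * k)
                + tang * (0.45 * ((-1) ** k))
                + axial * (0.3 * ((k % 3) - 1))
            )
            atoms.append((name, pos))
            k += 1
    return atoms


def _hexagon(center: np.ndarray, first_vertex: np.ndarray, sign: float) -> list[np.ndarray]:
    """Vertices of a planar (z=0) regular hexagon starting at first_vertex."""
    v = first_vertex - center
    out = []
    for k in range(6):
        ang = np.radians(60.0 * k * sign)
        cz, sz = np.cos(ang), np.sin(ang)
        out.append(center + np.array([cz * v[0] - sz * v[1], sz * v[0] + cz * v[1], 0.0]))
    return out


def _base_template(code: str) -> list[tuple[str, np.ndarray]]:
    """Planar base-ring template in the local z=0 plane, glycosidic N at x=1."""
    bond = 1.4
    if code in ("C", "U"):
        c0 = np.array([1.0 + bond, 0.0, 0.0])
        n1 = np.array([1.0, 0.0, 0.0])
        verts = _hexagon(c0, n1, sign=1.0)
        return list(zip(("N1", "C2", "N3", "C4", "C5", "C6"), verts))
    # purine: pentagon carrying N9, fused hexagon sharing the C4-C5 edge
    r5 = bond / (2.0 * np.sin(np.radians(36.0)))
    c5c = np.array([1.0 + r5, 0.0, 0.0])
    pent_names = ("N9", "C8", "N7", "C5", "C4")
    pent = []
    for k, name in enumerate(pent_names):
        ang = np.radians(180.0 - 72.0 * k)
        pent.append((name, c5c + r5 * np.array([np.cos(ang), np.sin(ang), 0.0])))
    pos = dict(pent)
    mid = 0.5 * (pos["C4"] + pos["C5"])
    out_dir = mid - c5c
    out_dir /= np.linalg.norm(out_dir)
    hex_center = mid + out_dir * (bond * np.sqrt(3.0) / 2.0)
    for sign in (1.0, -1.0):
        verts = _hexagon(hex_center, pos["C4"], sign)
        if np.linalg.norm(verts[5] - pos["C5"]) < 1e-6:
            hex_names = ("C4", "N3", "C2", "N1", "C6", "C5")
            hexa = list(zip(hex_names, verts))
            break
    else:  # pragma: no cover - construction is exact
        raise RuntimeError("hexagon fusion failed")
    merged = dict(pent)
    merged.update(dict(hexa))
    return list(merged.items())


def _rna_helix_residue(code: str, m: int, has_phosphate: bool = True) -> list[tuple[str, np.ndarray]]:
    """One idealized nucleotide placed on a regular helix of radius 9 A."""
    atoms: list[tuple[str, np.ndarray]] = []
    # local template: C1' at origin, base extending along +x
    local: list[tuple[str, np.ndarray]] = [("C1'", np.zeros(3))]
    local.extend(_base_template(code))
    # ribose ring behind C1', tilted out of the base plane
    rib_center = np.array([-1.15, 0.0, 0.45])
    r_rib = 1.5 / (2.0 * np.sin(np.radians(36.0)))
    for k, name in enumerate(("C2'", "C3'", "C4'", "O4'")):
        ang = np.radians(144.0 + 72.0 * k)
        local.append(
            (name, rib_center + r_rib * np.array([np.cos(ang), 0.35 * np.sin(ang), np.sin(ang)]))
        )
    if has_phosphate:
        p = np.array([-2.6, 1.4, 1.1])
        local.extend(
            [("P", p), ("OP1", p + np.array([0.7, 0.9, 0.4])), ("OP2", p + np.array([0.7, -0.9, 0.4]))]
        )
    # place: rotate the template about z by the helical twist and translate
    ang = np.radians(32.7 * m)
    cz, sz = np.cos(ang), np.sin(ang)
    Rz = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]])
    origin = Rz @ np.array([9.0, 0.0, 0.0]) + np.array([0.0, 0.0, 2.8 * m])
    for name, p in local:
        atoms.append((name, Rz @ p + origin))
    return atoms


#: default x-offset of the RNA helix from the protein helix axis; placed so
#: that the closest heavy-atom approach is around 3.5 A (the van der Waals
#: contact distance typical of interfaces) for the templated geometries
INTERFACE_OFFSET_DEFAULT = 7.5


def make_toy_complex(
    n_protein_residues: int,
    n_rna_residues: int,
    seed: int = 0,
    interface_gap: float | None = None,
    interface_offset: float | None = None,
    uniform_composition: bool = False,
) -> Structure:
    """Idealized all-atom protein-RNA complex with a defined interface.

    The protein is an ideal alpha helix with templated side chains, the RNA
    a regular helix with exactly planar base rings; residue sequences are
    drawn from the seeded generator, amino acids with the RNA-binding-like
    bias of :data:`AA_COMPOSITION_WEIGHTS` unless ``uniform_composition``
    is set.

    By default the RNA sits at a fixed offset from the protein helix axis
    (``interface_offset``, default :data:`INTERFACE_OFFSET_DEFAULT`), so
    that a given residue-nucleotide contact recurs at its characteristic
    distance across complexes -- the recurring interface chemistry that
    knowledge-based potentials rely on; the closest heavy-atom gap then
    varies around ~3.5 A with the sequences.  Passing ``interface_gap``
    instead slides the RNA until the minimum heavy-atom gap equals that
    value exactly (sequence-adaptive placement).
    """
    if n_protein_residues < 1 or n_rna_residues < 1:
        raise ValueError("need at least one residue per side")
    rng = np.random.default_rng(seed)
    chains: dict[str, list[Residue]] = {"A": [], "B": []}
    if uniform_composition:
        aa_p = np.full(len(_AA_CODES), 1.0 / len(_AA_CODES))
    else:
        aa_p = np.array(
            [AA_COMPOSITION_WEIGHTS.get(c, _AA_DEFAULT_WEIGHT) for c in _AA_CODES]
        )
        aa_p /= aa_p.sum()

    prot_atoms_all = []
    for i in range(n_protein_residues):
        code = _AA_CODES[rng.choice(len(_AA_CODES), p=aa_p)]
        atom_list = _protein_helix_residue(code, i)
        recs = [
            AtomRecord(name, name.lstrip("0123456789")[0], pos.copy(), code, ("A", i + 1, ""))
            for name, pos in atom_list
        ]
        prot_atoms_all.extend(pos for _, pos in atom_list)
        chains["A"].append(Residue(code, code, recs, "protein", False, ("A", i + 1, "")))

    rna_residues_raw = []
    rna_atoms_all = []
    for m in range(n_rna_residues):
        code = _NT_CODES[rng.integers(0, len(_NT_CODES))]
        atom_list = _rna_helix_residue(code, m, has_phosphate=(m > 0))
        rna_residues_raw.append((code, atom_list))
        rna_atoms_all.extend(pos for _, pos in atom_list)

    prot = np.array(prot_atoms_all)
    rna = np.array(rna_atoms_all)
    if interface_gap is not None:
        # sequence-adaptive: slide until the closest pair sits at the gap
        shift = np.array([30.0, 0.0, 0.0])
        for _ in range(8):
            dmin = cdist(prot, rna + shift).min()
            if abs(dmin - interface_gap) < 0.2:
                break
            shift[0] -= dmin - interface_gap
    else:
        offset = INTERFACE_OFFSET_DEFAULT if interface_offset is None else interface_offset
        shift = np.array([offset, 0.0, 0.0])
        # safety floor: never let sequences interpenetrate
        dmin = cdist(prot, rna + shift).min()
        if dmin < 2.8:
            shift[0] += 2.8 - dmin
    for m, (code, atom_list) in enumerate(rna_residues_raw):
        recs = [
            AtomRecord(name, name.lstrip("0123456789")[0], pos + shift, code, ("B", m + 1, ""))
            for name, pos in atom_list
        ]
        chains["B"].append(Residue(code, code, recs, "rna", False, ("B", m + 1, "")))

    return Structure(chains=chains, source_id=f"toy(seed={seed})")


# ---------------------------------------------------------------------------
# planted-signal bead-level training sets
# ---------------------------------------------------------------------------

def _random_frame(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    R = Rotation.random(random_state=rng).as_matrix()
    return R[:, 2], R[:, 0]


def _make_bead(btype: BeadType, pos: np.ndarray, rng: np.random.Generator, rid) -> Bead:
    normal, glyco = _random_frame(rng)
    frame = (normal, glyco) if btype.role in ("PYR", "PUR6") else None
    return Bead(btype, pos, normal, frame, (), rid)


def make_planted_training_set(
    n_complexes: int,
    planted_pair: tuple[BeadType, BeadType],
    planted_bin: int,
    enrichment: float,
    seed: int = 0,
    scheme: BinningScheme | None = None,
    n_background_protein_types: int = 8,
    n_background_rna_types: int = 5,
    mean_contacts_per_cell: float = 2.0,
) -> list[ReducedComplex]:
    """Bead-level training complexes with one enriched contact cell.

    Background contacts are spread multinomially over a pool of
    (protein type, RNA type, distance bin) cells, uniformly across type
    pairs and in proportion to bin volume across distance bins (a uniform
    spatial density of non-specific contacts, which is also the profile a
    geometry-only decoy reference produces); the planted cell receives
    ``enrichment`` times the background mean of its own distance bin.
    Every contact is realized as an isolated protein-RNA bead pair on a
    widely spaced lattice, so the intended contact is the only pair within
    the cutoff and the realized histogram is exactly the constructed one up
    to in-bin placement.
    """
    if enrichment <= 1:
        raise ValueError("enrichment must exceed 1")
    scheme = scheme or BinningScheme()
    if not 0 <= planted_bin < scheme.n_distance_bins:
        raise ValueError(f"planted_bin {planted_bin} outside the distance bins")
    rng = np.random.default_rng(seed)
    p_star, r_star = planted_pair
    pool_p = [t for t in PROTEIN_BEAD_TYPES[:n_background_protein_types] if t != p_star]
    pool_p = ([p_star] + pool_p)[:n_background_protein_types]
    pool_r = [t for t in RNA_BEAD_TYPES[:n_background_rna_types] if t != r_star]
    pool_r = ([r_star] + pool_r)[:n_background_rna_types]
    if p_star not in pool_p or r_star not in pool_r:
        raise ValueError("planted types must be in the bead enumeration")
    # bin weights proportional to shell volume: uniform spatial density
    w = scheme.distance_bin_width
    bin_w = np.array(
        [((b + 1) * w) ** 3 - (b * w) ** 3 for b in range(scheme.n_distance_bins)]
    )
    bin_p = bin_w / bin_w.sum()
    cells = [
        (i, j, b)
        for i in pool_p
        for j in pool_r
        for b in range(scheme.n_distance_bins)
        if (i, j, b) != (p_star, r_star, planted_bin)
    ]
    n_bg = int(round(mean_contacts_per_cell * len(cells)))
    cell_p = np.array([bin_p[b] for (_, _, b) in cells])
    cell_p /= cell_p.sum()
    # per-cell background mean in the planted bin, per complex
    n_pairs = len(pool_p) * len(pool_r)
    mean_in_planted_bin = n_bg * bin_p[planted_bin] / n_pairs
    n_planted = max(1, int(round(enrichment * mean_in_planted_bin)))

    complexes = []
    for c in range(n_complexes):
        bg_counts = rng.multinomial(n_bg, cell_p)
        slots: list[tuple[BeadType, BeadType, int]] = [(p_star, r_star, planted_bin)] * n_planted
        for (i, j, b), cnt in zip(cells, bg_counts):
            slots.extend([(i, j, b)] * int(cnt))
        # lattice of well-separated slots
        n_slots = len(slots)
        side = int(np.ceil(n_slots ** (1.0 / 3.0)))
        spacing = 30.0
        prot_beads, rna_beads = [], []
        for k, (i, j, b) in enumerate(slots):
            g = spacing * np.array(
                [k % side, (k // side) % side, k // (side * side)], dtype=float
            )
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            lo = b * scheme.distance_bin_width
            hi = lo + scheme.distance_bin_width
            r = max(lo + (0.05 + 0.9 * rng.random()) * (hi - lo), 0.2)
            prot_beads.append(_make_bead(i, g, rng, ("P", k, "")))
            rna_beads.append(_make_bead(j, g + r * u, rng, ("R", k, "")))
        complexes.append(
            ReducedComplex(
                receptor_beads=prot_beads,
                ligand_beads=rna_beads,
                receptor_kind="protein",
                ligand_kind="rna",
                source_id=f"planted(seed={seed},c={c})",
            )
        )
    return complexes
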