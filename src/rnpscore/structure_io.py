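"""Tolerant PDB input for protein-RNA complexes.

Docking decoys frequently carry malformed bookkeeping columns (occupancy,
B-factor, altloc), so this reader keeps only what scoring needs: atom names,
coordinates, residue identity and chain membership.  Only the first MODEL of
a multi-model file is read, alternate locations other than blank/'A' are
dropped, hydrogens are discarded, and occupancy/B-factor columns are never
interpreted.  Posttranscriptionally modified nucleotides are mapped onto
their parent base (A, U, G or C) so that modified RNAs can be scored without
"demodification".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "Structure",
    "ParseError",
    "StructureWarning",
    "parse_pdb",
    "classify_chain",
    "map_modified_residue",
    "write_pdb",
]


class ParseError(ValueError):
    """Raised when PDB content cannot be interpreted as a polymer structure."""


class StructureWarning(UserWarning):
    """Non-fatal oddities met while reading or reducing a structure."""


AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: protein residue aliases (selenomethionine is ubiquitous in crystal structures)
PROTEIN_ALIASES = {"MSE": "MET"}

NUCLEOTIDE_CODES = {"A", "U", "G", "C"}

#: modified nucleotide -> parent base.  The PDB chemical component dictionary
#: holds >100 such variants; this table covers the common tRNA/rRNA ones and
#: unknown codes fall back to a ring-atom census (purine vs pyrimidine).
MODIFIED_NUCLEOTIDES = {
    "PSU": "U",   # pseudouridine
    "H2U": "U",   # dihydrouridine
    "5MU": "U",   # ribothymidine
    "4SU": "U",   # 4-thiouridine
    "OMU": "U",   # 2'-O-methyluridine
    "UR3": "U",   # 3-methyluridine
    "5MC": "C",   # 5-methylcytidine
    "OMC": "C",   # 2'-O-methylcytidine
    "1MA": "A",   # 1-methyladenosine
    "2MA": "A",   # 2-methyladenosine
    "MIA": "A",   # 2-methylthio-N6-isopentenyladenosine
    "6MZ": "A",   # N6-methyladenosine
    "I":   "G",   # inosine: pairs and stacks like a guanosine-type purine
    "7MG": "G",   # 7-methylguanosine
    "2MG": "G",   # N2-methylguanosine
    "M2G": "G",   # N2,N2-dimethylguanosine
    "1MG": "G",   # 1-methylguanosine
    "OMG": "G",   # 2'-O-methylguanosine
    "YG":  "G",   # wybutosine
}

WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}

RIBOSE_ATOMS = {"C1'", "C2'", "C3'", "C4'", "O4'"}
PURINE_RING = {"N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"}
PYRIMIDINE_RING = {"N1", "C2", "N3", "C4", "C5", "C6"}


@dataclass
class AtomRecord:
    """One heavy-atom coordinate record."""

    name: str
    element: str
    position: np.ndarray
    residue_name: str
    residue_id: tuple[str, int, str]  # (chain id, sequence number, insertion code)
    is_hetero: bool = False


@dataclass
class Residue:
    code: str                      # canonical code (3-letter amino acid, 1-letter base)
    raw_code: str                  # code as read from the file
    atoms: list[AtomRecord]
    kind: str = "other"            # protein | rna | other
    is_modified: bool = False
    residue_id: tuple[str, int, str] = ("", 0, "")

    def atom_names(self) -> set[str]:
        return {a.name for a in self.atoms}

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    source_id: str = ""

    @property
    def chain_kinds(self) -> dict[str, str]:
        return {cid: classify_chain(res) for cid, res in self.chains.items()}

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for res in self.chains.values() for r in res)

    def n_residues(self) -> int:
        return sum(len(res) for res in self.chains.values())


def _infer_element(atom_name: str) -> str:
    """Element from the atom-name column when columns 77-78 are absent.

    PDB convention right-justifies 1-letter elements in a 4-char field; a
    leading digit (as in ``1HB``) marks a hydrogen variant.
    """
    stripped = atom_name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit():
        stripped = stripped.lstrip("0123456789")
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if two in {"FE", "ZN", "MG", "MN", "CL", "BR", "SE", "NA"}:
        return two.capitalize()
    return stripped[0].upper()


def _parse_atom_line(line: str) -> AtomRecord | None:
    name = line[12:16].strip()
    altloc = line[16:17]
    resname = line[17:20].strip()
    chain_id = line[21:22]
    try:
        resseq = int(line[22:26])
    except ValueError:
        return None
    icode = line[26:27].strip()
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError:
        return None
    if altloc not in (" ", "", "A"):
        return None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _infer_element(name)
    element = element.capitalize()
    pos = np.array([x, y, z], dtype=float)
    if not np.all(np.isfinite(pos)):
        return None
    return AtomRecord(
        name=name,
        element=element,
        position=pos,
        residue_name=resname,
        residue_id=(chain_id, resseq, icode),
        is_hetero=line.startswith("HETATM"),
    )


def classify_chain(residues: list[Residue]) -> str:
    """Vote on a chain's polymer kind from an atom census.

    A chain is ``protein`` when >=90% of its residues carry a CA atom, ``rna``
    when >=90% carry a C1' (or a P together with ribose atoms), and ``other``
    otherwise -- mixed chains are rejected downstream.
    """
    if not residues:
        raise ValueError("cannot classify an empty chain")
    n = len(residues)
    n_ca = 0
    n_rna = 0
    for r in residues:
        names = r.atom_names()
        if "CA" in names and "C1'" not in names:
            n_ca += 1
        if "C1'" in names or ("P" in names and names & RIBOSE_ATOMS):
            n_rna += 1
    if n_ca / n >= 0.9:
        return "protein"
    if n_rna / n >= 0.9:
        return "rna"
    return "other"


def map_modified_residue(
    raw_code: str, atoms: list[AtomRecord], modres_hint: str | None = None
) -> tuple[str, bool]:
    """Map an RNA residue code to its canonical parent base.

    Returns ``(canonical_code, is_modified)``.  Known modified codes use the
    built-in lookup table; a MODRES record, when supplied, overrides the
    fallback for unknown codes.  Otherwise the parent is inferred from a
    ring-atom census: an N9 atom marks a purine (mapped to A with a warning),
    a pyrimidine ring maps to U with a warning.
    """
    code = raw_code.strip().upper()
    if code in NUCLEOTIDE_CODES:
        return code, False
    if code in MODIFIED_NUCLEOTIDES:
        return MODIFIED_NUCLEOTIDES[code], True
    if modres_hint and modres_hint.strip().upper() in NUCLEOTIDE_CODES:
        return modres_hint.strip().upper(), True
    names = {a.name for a in atoms}
    has_ring = bool(names & {"N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"})
    has_backbone = bool(names & (RIBOSE_ATOMS | {"P"}))
    if not has_ring and not has_backbone:
        raise ParseError(
            f"residue {raw_code!r}: no ring atoms and no backbone; cannot assign a parent base"
        )
    if not has_ring:
        warnings.warn(
            f"unknown nucleotide {raw_code!r} with backbone only; treating as U",
            StructureWarning,
            stacklevel=2,
        )
        return "U", True
    if "N9" in names:
        warnings.warn(
            f"unknown nucleotide {raw_code!r}: purine ring detected, defaulting to A",
            StructureWarning,
            stacklevel=2,
        )
        return "A", True
    warnings.warn(
        f"unknown nucleotide {raw_code!r}: pyrimidine ring detected, defaulting to U",
        StructureWarning,
        stacklevel=2,
    )
    return "U", True


def _residue_is_polymer(names: set[str], resname: str) -> bool:
    if resname in WATER_NAMES:
        return False
    amino_like = "CA" in names and "N" in names and "C" in names
    has_ring = bool(names & (PURINE_RING | PYRIMIDINE_RING))
    nucleo_like = bool(names & RIBOSE_ATOMS) or ("P" in names and has_ring)
    return amino_like or nucleo_like


def parse_pdb(text: str, source_id: str = "") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Only the first MODEL is kept; altloc blank/'A' records are used;
    occupancy and B-factor are ignored entirely; waters and non-polymer
    HETATM groups are excluded; hydrogens are dropped.
    """
    modres: dict[str, str] = {}
    atoms: list[AtomRecord] = []
    seen_any_record = False
    in_first_model = True
    model_seen = False
    for line in text.splitlines():
        rec = line[:6]
        if rec.startswith("MODRES") and len(line) >= 27:
            modres[line[12:15].strip()] = line[24:27].strip()
        elif rec.startswith("MODEL"):
            if model_seen:
                in_first_model = False
            model_seen = True
        elif rec.startswith("ENDMDL"):
            if model_seen:
                in_first_model = False
        elif rec.startswith(("ATOM  ", "HETATM", "ATOM")) and line[:6].strip() in ("ATOM", "HETATM"):
            seen_any_record = True
            if not in_first_model:
                continue
            atom = _parse_atom_line(line)
            if atom is None:
                continue
            if atom.element in ("H", "D"):
                continue
            atoms.append(atom)
    if not seen_any_record:
        raise ParseError("no ATOM or HETATM records found in input")
    if not atoms:
        raise ParseError("no usable coordinates found (all records malformed or non-first-model)")

    # group into residues preserving file order
    grouped: dict[tuple[str, int, str], list[AtomRecord]] = {}
    for a in atoms:
        grouped.setdefault(a.residue_id, []).append(a)

    chains: dict[str, list[Residue]] = {}
    for rid, recs in grouped.items():
        names = {a.name for a in recs}
        resname = recs[0].residue_name
        if not _residue_is_polymer(names, resname):
            continue
        res = Residue(
            code=resname, raw_code=resname, atoms=recs, residue_id=rid
        )
        chains.setdefault(rid[0], []).append(res)

    if not chains:
        raise ParseError("no polymer residues found (only waters/ligands/ions present)")

    # classify each chain, then canonicalize residue codes per kind
    structure = Structure(chains=chains, source_id=source_id)
    for cid, residues in chains.items():
        kind = classify_chain(residues)
        kept: list[Residue] = []
        for r in residues:
            r.kind = kind
            if kind == "protein":
                code = r.raw_code.upper()
                if code in PROTEIN_ALIASES:
                    r.code, r.is_modified = PROTEIN_ALIASES[code], True
                elif code in AMINO3:
                    r.code = code
                else:
                    warnings.warn(
                        f"non-standard amino acid {code!r} in chain {cid}; kept as-is",
                        StructureWarning,
                        stacklevel=2,
                    )
                kept.append(r)
            elif kind == "rna":
                try:
                    r.code, r.is_modified = map_modified_residue(
                        r.raw_code, r.atoms, modres.get(r.raw_code)
                    )
                except ParseError as exc:
                    warnings.warn(str(exc), StructureWarning, stacklevel=2)
                    continue
                kept.append(r)
            else:
                kept.append(r)
        chains[cid] = kept
    return structure


def write_pdb(structure: Structure) -> str:
    """Emit minimal valid PDB text (fixture writer; 3-decimal coordinates)."""
    lines = []
    serial = 1
    for cid, residues in structure.chains.items():
        for res in residues:
            for a in res.atoms:
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                rec = "HETATM" if a.is_hetero else "ATOM  "
                lines.append(
                    f"{rec}{serial:>5d} {name:<4.4s} {res.raw_code:>3.3s} {cid:1.1s}"
                    f"{a.residue_id[1]:>4d}{a.residue_id[2]:1.1s}   "
                    f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2.2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
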