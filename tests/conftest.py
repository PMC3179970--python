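import warnings

import numpy as np
import pytest

from rnpscore import (
    ReducedComplex,
    StructureWarning,
    make_toy_complex,
    parse_pdb,
    reduce_complex,
    write_pdb,
)
from rnpscore.reduction import Bead, BeadType


@pytest.fixture(autouse=True)
def _quiet_structure_warnings():
    # 5'-terminal phosphate omissions etc. are expected on fixtures
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", StructureWarning)
        yield


def pdb_atom_line(serial, name, res, chain, seq, x, y, z,
                  record="ATOM", occ="  1.00", element=None, altloc=" ", icode=" "):
    """Fixed-column PDB ATOM/HETATM record (independent of the package writer)."""
    el = element if element is not None else name.lstrip("0123456789'")[0]
    nm = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:>5d} {nm:<4.4s}{altloc}{res:>3s} {chain}{seq:>4d}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:>6s}  0.00          {el:>2s}"
    )


@pytest.fixture(scope="session")
def toy_structure():
    return make_toy_complex(10, 4, seed=7)


@pytest.fixture(scope="session")
def toy_complex(toy_structure):
    parsed = parse_pdb(write_pdb(toy_structure), source_id="toy7")
    return reduce_complex(parsed, ["A"], ["B"])


@pytest.fixture(scope="session")
def training_set():
    out = []
    for k in range(8):
        s = make_toy_complex(12, 4, seed=k)
        cx = reduce_complex(parse_pdb(write_pdb(s)), ["A"], ["B"])
        cx.source_id = f"train_{k}"
        out.append(cx)
    return out


def simple_bead(residue_code, role, position, axis=(0.0, 0.0, 1.0), edge_frame=None):
    return Bead(
        type=BeadType(residue_code, role),
        position=np.asarray(position, dtype=float),
        axis=np.asarray(axis, dtype=float),
        edge_frame=edge_frame,
    )


def pair_complex(protein_beads, rna_beads):
    return ReducedComplex(
        receptor_beads=list(protein_beads),
        ligand_beads=list(rna_beads),
        receptor_kind="protein",
        ligand_kind="rna",
        source_id="fixture",
    )
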