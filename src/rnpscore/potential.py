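"""Knowledge-based potentials for protein-RNA complexes.

Both potentials convert binned contact statistics into energies by reverse
Boltzmann statistics,

    eps(i, j, b) = -RT * ln( N_obs(i, j, b) / N_exp(i, j, b) ),

where ``i`` runs over the 52 protein united-atom types, ``j`` over the 14
RNA united-atom types and ``b`` over the bins of one of three statistical
terms: distance (1 A bins to a 9 A cutoff), angle (20 degree bins) and
base edge (Watson-Crick / Hoogsteen / Sugar).  They differ only in the
reference state N_exp:

* quasi-chemical (QUASI-RNP): ``N_exp(i,j,b) = X_i * X_j * N_obs(b)`` with
  mole fractions X of the two type alphabets -- contacts happen at random
  in proportion to how common the partners are;
* decoys-as-reference-state (DARS-RNP): N_exp is the (globally rescaled)
  contact count observed in geometry-only docking decoys of the same
  training complexes -- what sticking two shapes together produces without
  any physics.

The total score of a pose adds a distance term Ed, an angle term Ea, a base
edge (site) term Es and a steric clash penalty Ep with equal weights:
``E = Ed + Ea + Es + Ep``.  Lower is better.

:class:`RNPPotential` packages training and scoring as a scikit-learn style
estimator (``fit`` on native complexes, ``predict`` energies of poses); the
module-level functions expose the individual steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .geometry import BinningScheme, bin_angle, bin_distance, find_contacts
from .reduction import (
    PROTEIN_BEAD_TYPES,
    RNA_BEAD_TYPES,
    BeadType,
    ReducedComplex,
)

__all__ = [
    "PROTEIN_TYPE_INDEX",
    "RNA_TYPE_INDEX",
    "TERMS",
    "ContactCounts",
    "ReferenceCounts",
    "PotentialTable",
    "ScoreBreakdown",
    "count_contacts",
    "mole_fractions",
    "quasi_expected",
    "dars_expected",
    "energy_table",
    "loo_tables",
    "score_complex",
    "train_potential",
    "RNPPotential",
]

PROTEIN_TYPE_INDEX: dict[BeadType, int] = {t: k for k, t in enumerate(PROTEIN_BEAD_TYPES)}
RNA_TYPE_INDEX: dict[BeadType, int] = {t: k for k, t in enumerate(RNA_BEAD_TYPES)}

TERMS = ("dist", "angle", "edge")


def _empty_tables(scheme: BinningScheme) -> dict[str, np.ndarray]:
    P, R = len(PROTEIN_BEAD_TYPES), len(RNA_BEAD_TYPES)
    return {
        "dist": np.zeros((P, R, scheme.n_distance_bins)),
        "angle": np.zeros((P, R, scheme.n_angle_bins)),
        "edge": np.zeros((P, R, scheme.n_edge_bins)),
    }


@dataclass
class ComplexContribution:
    tables: dict[str, np.ndarray]
    protein_beads: np.ndarray    # per-type bead counts, shape (52,)
    rna_beads: np.ndarray        # shape (14,)


@dataclass
class ContactCounts:
    """Binned contact histograms N_obs plus per-complex contributions."""

    tables: dict[str, np.ndarray]
    protein_beads: np.ndarray
    rna_beads: np.ndarray
    scheme: BinningScheme
    per_complex: dict[str, ComplexContribution] = field(default_factory=dict)

    @property
    def n_complexes(self) -> int:
        return len(self.per_complex)

    def totals_per_bin(self, term: str) -> np.ndarray:
        """N_obs(b): contacts per bin summed over all type pairs."""
        return self.tables[term].sum(axis=(0, 1))

    def total(self, term: str) -> float:
        return float(self.tables[term].sum())

    def without(self, complex_id: str) -> "ContactCounts":
        """Counts with one complex's contribution removed (leave-one-out)."""
        if complex_id not in self.per_complex:
            raise KeyError(f"unknown complex id {complex_id!r}")
        sub = self.per_complex[complex_id]
        return ContactCounts(
            tables={t: self.tables[t] - sub.tables[t] for t in TERMS},
            protein_beads=self.protein_beads - sub.protein_beads,
            rna_beads=self.rna_beads - sub.rna_beads,
            scheme=self.scheme,
            per_complex={k: v for k, v in self.per_complex.items() if k != complex_id},
        )


@dataclass
class ReferenceCounts:
    """Expected contact counts N_exp under a reference state."""

    tables: dict[str, np.ndarray]
    kind: str                                   # "quasi" | "dars"
    mole_fractions_protein: np.ndarray | None = None
    mole_fractions_rna: np.ndarray | None = None


@dataclass
class ScoreBreakdown:
    Ed: float
    Ea: float
    Es: float
    Ep: float
    n_contacts: int
    n_clashes: int

    @property
    def E(self) -> float:
        return self.Ed + self.Ea + self.Es + self.Ep


def _type_indices(complex_: ReducedComplex) -> tuple[np.ndarray, np.ndarray]:
    try:
        pi = np.array([PROTEIN_TYPE_INDEX[b.type] for b in complex_.protein_beads], dtype=int)
    except KeyError as exc:
        raise KeyError(f"unknown protein bead type {exc.args[0]}") from None
    try:
        ri = np.array([RNA_TYPE_INDEX[b.type] for b in complex_.rna_beads], dtype=int)
    except KeyError as exc:
        raise KeyError(f"unknown RNA bead type {exc.args[0]}") from None
    return pi, ri


def _count_one(complex_: ReducedComplex, scheme: BinningScheme) -> ComplexContribution:
    tables = _empty_tables(scheme)
    edge_index = {label: k for k, label in enumerate(scheme.edge_labels)}
    pi, ri = _type_indices(complex_)
    contacts = find_contacts(complex_, scheme)
    prot_ids = {id(b): k for k, b in enumerate(complex_.protein_beads)}
    rna_ids = {id(b): k for k, b in enumerate(complex_.rna_beads)}
    for c in contacts:
        i = pi[prot_ids[id(c.protein_bead)]]
        j = ri[rna_ids[id(c.rna_bead)]]
        tables["dist"][i, j, bin_distance(c.distance, scheme)] += 1
        tables["angle"][i, j, bin_angle(c.angle, scheme)] += 1
        if c.edge is not None:
            tables["edge"][i, j, edge_index[c.edge]] += 1
    pcounts = np.bincount(pi, minlength=len(PROTEIN_BEAD_TYPES)).astype(float)
    rcounts = np.bincount(ri, minlength=len(RNA_BEAD_TYPES)).astype(float)
    return ComplexContribution(tables, pcounts, rcounts)


def count_contacts(
    complexes: list[ReducedComplex],
    scheme: BinningScheme | None = None,
    ids: list[str] | None = None,
) -> ContactCounts:
    """Accumulate binned contact statistics over training complexes.

    Every interface contact increments one cell of each applicable term's
    histogram; per-complex sub-counts are retained for leave-one-out use.
    """
    if not complexes:
        raise ValueError("need at least one complex to count contacts")
    scheme = scheme or BinningScheme()
    if ids is None:
        ids = [c.source_id or f"complex_{k}" for k, c in enumerate(complexes)]
    if len(set(ids)) != len(ids):
        raise ValueError("complex ids must be unique")
    totals = _empty_tables(scheme)
    pbeads = np.zeros(len(PROTEIN_BEAD_TYPES))
    rbeads = np.zeros(len(RNA_BEAD_TYPES))
    per_complex: dict[str, ComplexContribution] = {}
    for cid, cx in zip(ids, complexes):
        contrib = _count_one(cx, scheme)
        per_complex[cid] = contrib
        for t in TERMS:
            totals[t] += contrib.tables[t]
        pbeads += contrib.protein_beads
        rbeads += contrib.rna_beads
    return ContactCounts(totals, pbeads, rbeads, scheme, per_complex)


def mole_fractions(counts: ContactCounts) -> tuple[np.ndarray, np.ndarray]:
    """Type mole fractions X_i (protein) and X_j (RNA) over training beads."""
    pt, rt_ = counts.protein_beads.sum(), counts.rna_beads.sum()
    if pt == 0 or rt_ == 0:
        raise ValueError("training set has zero beads on one side")
    return counts.protein_beads / pt, counts.rna_beads / rt_


def quasi_expected(counts: ContactCounts) -> ReferenceCounts:
    """Quasi-chemical reference: N_exp(i,j,b) = X_i * X_j * N_obs(b).

    Because the mole fractions each sum to one, the expected counts conserve
    the per-bin totals of the observed histogram, term by term.
    """
    xi, xj = mole_fractions(counts)
    outer = np.outer(xi, xj)
    tables = {t: outer[:, :, None] * counts.totals_per_bin(t)[None, None, :] for t in TERMS}
    return ReferenceCounts(tables, "quasi", xi, xj)


def dars_expected(decoy_counts: ContactCounts, native_counts: ContactCounts) -> ReferenceCounts:
    """Decoys-as-reference-state: decoy histograms rescaled to native totals.

    Each term's decoy histogram is multiplied by a single scale factor so
    that its grand total matches the natives' grand total for that term.
    """
    tables = {}
    for t in TERMS:
        decoy_total = decoy_counts.total(t)
        if decoy_total == 0:
            raise ValueError(
                f"decoy counts for term {t!r} are all zero; generate larger decoy sets"
            )
        s = native_counts.total(t) / decoy_total
        tables[t] = decoy_counts.tables[t] * s
    return ReferenceCounts(tables, "dars")


@dataclass
class PotentialTable:
    """Energies eps(i, j, bin) for the three statistical terms.

    ``energies[term]`` has shape (52 protein types, 14 RNA types, n_bins).
    The observed/expected histograms used to build the table are retained
    for inspection and serialization.
    """

    energies: dict[str, np.ndarray]
    scheme: BinningScheme
    rt: float = 1.0
    pseudocount: float = 1.0
    clash_distance: float = 3.0     # A between bead centers
    clash_penalty: float = 1.0      # energy per clashing pair, in units of RT
    provenance: str = ""
    n_obs: dict[str, np.ndarray] | None = None
    n_exp: dict[str, np.ndarray] | None = None

    def to_tsv(self, path) -> None:
        write_table(self, path)

    @classmethod
    def from_tsv(cls, path) -> "PotentialTable":
        return read_table(path)


def energy_table(
    obs: ContactCounts,
    exp: ReferenceCounts,
    rt: float = 1.0,
    pseudocount: float = 1.0,
    clash_distance: float = 3.0,
    clash_penalty: float = 1.0,
    provenance: str = "",
) -> PotentialTable:
    """Reverse-Boltzmann energies eps = -RT ln((N_obs + a)/(N_exp + a)).

    The pseudocount ``a`` regularizes empty cells, which are unavoidable at
    any realistic training scale.  With ``a = 0``, a cell empty in both
    histograms carries no evidence and gets zero energy; a cell empty in
    exactly one of them would need an infinite energy and is an error.
    """
    if rt <= 0:
        raise ValueError("RT must be positive")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    energies = {}
    for t in TERMS:
        o, e = obs.tables[t], exp.tables[t]
        if pseudocount == 0:
            one_sided = (o == 0) != (e == 0)
            if np.any(one_sided):
                raise ValueError(
                    f"term {t!r} has cells observed on one side only; "
                    f"a positive pseudocount is required"
                )
            both = (o > 0) & (e > 0)
            eps = np.zeros_like(o)
            eps[both] = -rt * np.log(o[both] / e[both])
            energies[t] = eps
        else:
            energies[t] = -rt * np.log((o + pseudocount) / (e + pseudocount))
    return PotentialTable(
        energies=energies,
        scheme=obs.scheme,
        rt=rt,
        pseudocount=pseudocount,
        clash_distance=clash_distance,
        clash_penalty=clash_penalty,
        provenance=provenance,
        n_obs={t: obs.tables[t].copy() for t in TERMS},
        n_exp={t: exp.tables[t].copy() for t in TERMS},
    )


def score_complex(
    complex_: ReducedComplex,
    table: PotentialTable,
    scheme: BinningScheme | None = None,
) -> ScoreBreakdown:
    """Four-term score of one pose: E = Ed + Ea + Es + Ep, equal weights.

    Ed/Ea sum the distance/angle energies over all interface contacts; Es
    sums the edge energies over contacts made with base-ring beads; Ep adds
    ``clash_penalty`` for every bead pair closer than ``clash_distance``.
    """
    scheme = scheme or table.scheme
    if (
        scheme.n_distance_bins != table.energies["dist"].shape[2]
        or scheme.n_angle_bins != table.energies["angle"].shape[2]
    ):
        raise ValueError("binning scheme inconsistent with the potential table")
    edge_index = {label: k for k, label in enumerate(scheme.edge_labels)}
    pi, ri = _type_indices(complex_)
    prot_ids = {id(b): k for k, b in enumerate(complex_.protein_beads)}
    rna_ids = {id(b): k for k, b in enumerate(complex_.rna_beads)}
    contacts = find_contacts(complex_, scheme)
    ed = ea = es = 0.0
    for c in contacts:
        i = pi[prot_ids[id(c.protein_bead)]]
        j = ri[rna_ids[id(c.rna_bead)]]
        ed += table.energies["dist"][i, j, bin_distance(c.distance, scheme)]
        ea += table.energies["angle"][i, j, bin_angle(c.angle, scheme)]
        if c.edge is not None:
            es += table.energies["edge"][i, j, edge_index[c.edge]]
    ppos = complex_.positions("protein")
    rpos = complex_.positions("rna")
    n_clashes = 0
    if len(ppos) and len(rpos):
        n_clashes = int(np.count_nonzero(cdist(ppos, rpos) < table.clash_distance))
    ep = table.clash_penalty * table.rt * n_clashes
    return ScoreBreakdown(ed, ea, es, ep, len(contacts), n_clashes)


def loo_tables(
    native_counts: ContactCounts,
    decoy_counts: ContactCounts | None = None,
    kind: str = "quasi",
    **table_kwargs,
) -> dict[str, PotentialTable]:
    """Leave-one-out tables: for each training complex, a table built with
    that complex's contacts (and, for DARS, its decoys) removed."""
    if native_counts.n_complexes < 2:
        raise ValueError("leave-one-out needs at least two training complexes")
    if kind == "dars" and decoy_counts is None:
        raise ValueError("DARS leave-one-out needs decoy counts")
    tables = {}
    for cid in native_counts.per_complex:
        obs = native_counts.without(cid)
        if kind == "quasi":
            exp = quasi_expected(obs)
        else:
            exp = dars_expected(decoy_counts.without(cid), obs)
        tables[cid] = energy_table(
            obs, exp, provenance=f"loo:{cid}", **table_kwargs
        )
    return tables


def train_potential(
    complexes: list[ReducedComplex],
    reference: str = "dars",
    decoy_complexes: dict[str, list[ReducedComplex]] | None = None,
    scheme: BinningScheme | None = None,
    ids: list[str] | None = None,
    **table_kwargs,
) -> PotentialTable:
    """One-call training: count, build the reference state, take the log."""
    scheme = scheme or BinningScheme()
    counts = count_contacts(complexes, scheme, ids)
    if reference == "quasi":
        exp = quasi_expected(counts)
    elif reference == "dars":
        if decoy_complexes is None:
            raise ValueError("DARS training needs decoy complexes")
        flat, flat_ids = [], []
        for cid, dlist in decoy_complexes.items():
            for k, d in enumerate(dlist):
                flat.append(d)
                flat_ids.append(f"{cid}/decoy_{k}")
        dc = count_contacts(flat, scheme, flat_ids)
        exp = dars_expected(dc, counts)
    else:
        raise ValueError(f"unknown reference state {reference!r}")
    return energy_table(counts, exp, provenance=f"{reference}:{len(complexes)} complexes",
                        **table_kwargs)


# ---------------------------------------------------------------------------
# serialization: TSV body + JSON comment header, round-trips bit-exactly
# ---------------------------------------------------------------------------

def _bin_labels(scheme: BinningScheme, term: str) -> list[str]:
    if term == "dist":
        w = scheme.distance_bin_width
        return [f"{k * w:g}-{(k + 1) * w:g}" for k in range(scheme.n_distance_bins)]
    if term == "angle":
        w = scheme.angle_bin_width
        return [f"{k * w:g}-{(k + 1) * w:g}" for k in range(scheme.n_angle_bins)]
    return list(scheme.edge_labels)


def write_table(table: PotentialTable, path) -> None:
    header = {
        "format": "rnpscore-potential",
        "version": 1,
        "rt": table.rt,
        "pseudocount": table.pseudocount,
        "clash_distance": table.clash_distance,
        "clash_penalty": table.clash_penalty,
        "provenance": table.provenance,
        "scheme": {
            "distance_bin_width": table.scheme.distance_bin_width,
            "distance_cutoff": table.scheme.distance_cutoff,
            "angle_bin_width": table.scheme.angle_bin_width,
            "edge_labels": list(table.scheme.edge_labels),
        },
    }
    lines = [f"# {json.dumps(header)}"]
    lines.append("term\tprotein_type\trna_type\tbin_label\tn_obs\tn_exp\tenergy")
    for t in TERMS:
        labels = _bin_labels(table.scheme, t)
        arr = table.energies[t]
        obs = table.n_obs[t] if table.n_obs else np.zeros_like(arr)
        exp = table.n_exp[t] if table.n_exp else np.zeros_like(arr)
        for i, pt in enumerate(PROTEIN_BEAD_TYPES):
            for j, rt_ in enumerate(RNA_BEAD_TYPES):
                for b, lab in enumerate(labels):
                    lines.append(
                        f"{t}\t{pt}\t{rt_}\t{lab}\t{obs[i, j, b]:.17g}"
                        f"\t{exp[i, j, b]:.17g}\t{arr[i, j, b]:.17g}"
                    )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_table(path) -> PotentialTable:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise ValueError("missing JSON header line")
        header = json.loads(first[2:])
        if header.get("format") != "rnpscore-potential":
            raise ValueError("not a potential table file")
        scheme = BinningScheme(
            distance_bin_width=header["scheme"]["distance_bin_width"],
            distance_cutoff=header["scheme"]["distance_cutoff"],
            angle_bin_width=header["scheme"]["angle_bin_width"],
            edge_labels=tuple(header["scheme"]["edge_labels"]),
        )
        colnames = fh.readline().rstrip("\n").split("\t")
        if colnames[:4] != ["term", "protein_type", "rna_type", "bin_label"]:
            raise ValueError("unexpected column layout")
        energies = _empty_tables(scheme)
        n_obs = _empty_tables(scheme)
        n_exp = _empty_tables(scheme)
        pidx = {str(t): k for t, k in PROTEIN_TYPE_INDEX.items()}
        ridx = {str(t): k for t, k in RNA_TYPE_INDEX.items()}
        bidx = {t: {lab: k for k, lab in enumerate(_bin_labels(scheme, t))} for t in TERMS}
        for line in fh:
            term, pt, rt_, lab, o, e, en = line.rstrip("\n").split("\t")
            i, j, b = pidx[pt], ridx[rt_], bidx[term][lab]
            n_obs[term][i, j, b] = float(o)
            n_exp[term][i, j, b] = float(e)
            energies[term][i, j, b] = float(en)
    return PotentialTable(
        energies=energies,
        scheme=scheme,
        rt=header["rt"],
        pseudocount=header["pseudocount"],
        clash_distance=header["clash_distance"],
        clash_penalty=header["clash_penalty"],
        provenance=header.get("provenance", ""),
        n_obs=n_obs,
        n_exp=n_exp,
    )


# ---------------------------------------------------------------------------
# estimator interface
# ---------------------------------------------------------------------------

class RNPPotential(BaseEstimator):
    """Trainable protein-RNA scoring potential (scikit-learn estimator).

    Parameters
    ----------
    reference : {"dars", "quasi"}
        Reference state.  "dars" measures expected contacts on
        geometry-only docking decoys of the training complexes; "quasi"
        uses the quasi-chemical mole-fraction product.
    scheme : BinningScheme, optional
        Contact cutoff and bin widths (default: 9 A cutoff, 1 A distance
        bins, 20 degree angle bins, three base edges).
    rt : float
        Energy scale RT; scores are unitless multiples of it.
    pseudocount : float
        Additive regularizer for empty histogram cells.
    clash_distance, clash_penalty : float
        Steric term: every bead pair closer than ``clash_distance`` (A)
        adds ``clash_penalty * rt`` to the score.
    n_reference_decoys : int
        Decoys generated per training complex when ``reference="dars"`` and
        no decoy sets are supplied to :meth:`fit`.
    max_clash_fraction : float
        Clash filter used by the internal decoy generator.
    random_state : int
        Seed for internal decoy generation.

    Attributes
    ----------
    table_ : PotentialTable
        Trained energies for the three statistical terms.
    counts_ : ContactCounts
        Observed training histograms (with per-complex contributions).
    reference_counts_ : ReferenceCounts
        The expected histograms N_exp.
    decoy_counts_ : ContactCounts or None
        Decoy histograms (DARS only).
    """

    def __init__(
        self,
        reference: str = "dars",
        scheme: BinningScheme | None = None,
        rt: float = 1.0,
        pseudocount: float = 1.0,
        clash_distance: float = 3.0,
        clash_penalty: float = 1.0,
        n_reference_decoys: int = 200,
        max_clash_fraction: float = 0.2,
        random_state: int = 0,
    ) -> None:
        self.reference = reference
        self.scheme = scheme
        self.rt = rt
        self.pseudocount = pseudocount
        self.clash_distance = clash_distance
        self.clash_penalty = clash_penalty
        self.n_reference_decoys = n_reference_decoys
        self.max_clash_fraction = max_clash_fraction
        self.random_state = random_state

    def _scheme(self) -> BinningScheme:
        return self.scheme or BinningScheme()

    def fit(
        self,
        X: list[ReducedComplex],
        y=None,
        decoy_sets: dict[str, list[ReducedComplex]] | None = None,
        ids: list[str] | None = None,
    ) -> "RNPPotential":
        """Train on native complexes (and decoys for the DARS reference)."""
        if self.reference not in ("dars", "quasi"):
            raise ValueError(f"unknown reference state {self.reference!r}")
        scheme = self._scheme()
        if ids is None:
            ids = [c.source_id or f"complex_{k}" for k, c in enumerate(X)]
        self.counts_ = count_contacts(X, scheme, ids)
        self.decoy_counts_ = None
        if self.reference == "quasi":
            self.reference_counts_ = quasi_expected(self.counts_)
        else:
            if decoy_sets is None:
                from .decoys import generate_decoys

                decoy_sets = {}
                for k, (cid, cx) in enumerate(zip(ids, X)):
                    ds = generate_decoys(
                        cx,
                        n=self.n_reference_decoys,
                        max_clash_fraction=self.max_clash_fraction,
                        seed=(self.random_state + 7919 * k) % (2**31),
                        scheme=scheme,
                    )
                    decoy_sets[cid] = ds.complexes()
            flat, flat_ids = [], []
            for cid, dlist in decoy_sets.items():
                for k, d in enumerate(dlist):
                    flat.append(d)
                    flat_ids.append(f"{cid}/decoy_{k}")
            self.decoy_counts_ = count_contacts(flat, scheme, flat_ids)
            # regroup decoy contributions per parent complex for leave-one-out
            self._decoy_parent_ids_ = {
                cid: [f"{cid}/decoy_{k}" for k in range(len(dlist))]
                for cid, dlist in decoy_sets.items()
            }
            self.reference_counts_ = dars_expected(self.decoy_counts_, self.counts_)
        self.table_ = energy_table(
            self.counts_,
            self.reference_counts_,
            rt=self.rt,
            pseudocount=self.pseudocount,
            clash_distance=self.clash_distance,
            clash_penalty=self.clash_penalty,
            provenance=f"{self.reference}:{len(X)} complexes",
        )
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "table_"):
            raise AttributeError("estimator is not fitted; call fit() first")

    def score_breakdown(self, complex_: ReducedComplex) -> ScoreBreakdown:
        self._check_fitted()
        return score_complex(complex_, self.table_, self._scheme())

    def predict(self, X: list[ReducedComplex]) -> np.ndarray:
        """Total energy E for each pose (lower = better)."""
        self._check_fitted()
        return np.array([self.score_breakdown(c).E for c in X])

    def leave_one_out(self) -> dict[str, PotentialTable]:
        """Retrained table per training complex with that complex held out."""
        self._check_fitted()
        decoy_counts = None
        if self.reference == "dars":
            decoy_counts = self.decoy_counts_
            # collapse each parent's decoys into one removable contribution
            merged = ContactCounts(
                tables={t: decoy_counts.tables[t].copy() for t in TERMS},
                protein_beads=decoy_counts.protein_beads.copy(),
                rna_beads=decoy_counts.rna_beads.copy(),
                scheme=decoy_counts.scheme,
                per_complex={},
            )
            for cid, dec_ids in self._decoy_parent_ids_.items():
                tabs = _empty_tables(decoy_counts.scheme)
                pb = np.zeros(len(PROTEIN_BEAD_TYPES))
                rb = np.zeros(len(RNA_BEAD_TYPES))
                for did in dec_ids:
                    sub = decoy_counts.per_complex[did]
                    for t in TERMS:
                        tabs[t] += sub.tables[t]
                    pb += sub.protein_beads
                    rb += sub.rna_beads
                merged.per_complex[cid] = ComplexContribution(tabs, pb, rb)
            decoy_counts = merged
        return loo_tables(
            self.counts_,
            decoy_counts,
            kind=self.reference,
            rt=self.rt,
            pseudocount=self.pseudocount,
            clash_distance=self.clash_distance,
            clash_penalty=self.clash_penalty,
        )
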