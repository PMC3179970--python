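# Methods

## Coarse-grained representation

Each amino acid is reduced to one to three united atoms: a `CA` bead at the
alpha carbon, a proximal side-chain bead `SC1` (heavy atoms out to the
C-gamma layer) and, for the thirteen larger residues, a distal bead `SC2`.
Glycine has only `CA`; ALA, SER, CYS, THR, VAL and PRO have `CA`+`SC1`.
The exact atom→bead membership is one editable table
(`reduction.SIDECHAIN_PARTITION`); side-chain beads are unweighted
centroids of their member heavy atoms. Nucleotides contribute a phosphate
bead `P` (centroid of P/OP1/OP2; O5'/O3' are counted with the ribose side
to keep the bead local and stable for modified backbones), a ribose bead
`RIB` (furanose ring centroid) and base-ring centroids: `PYR` for
pyrimidines, `PUR6` and `PUR5` for the two purine rings. Because the CA
of an alanine and the CA of a lysine interact differently, every
(residue, role) combination is its own interaction type: 52 protein and 14
RNA types. Hydrogens are ignored throughout.

Each bead carries a reference axis for the angle term: base-ring beads use
the base-plane normal (least-squares plane of the ring atoms, oriented by
the base's own chirality so the sign is reproducible), `P` points at its
ribose, `RIB` at its base ring, `CA` at `SC1` (or along N→C for glycine),
and side-chain beads along CA→bead. `PYR`/`PUR6` beads additionally carry
an orthonormal edge frame — the oriented plane normal plus the in-plane
glycosidic direction (C1'→N1/N9) — used to decide which face of the base a
protein bead approaches.

Chains are classified by an atom census (≥90 % of residues with CA →
protein; ≥90 % with C1' or P+ribose → RNA; otherwise rejected as mixed).
Modified nucleotides are mapped to parent bases through a built-in lookup
(pseudouridine→U, 5MC→C, 1MA→A, 7MG→G, inosine→G, …); unknown codes fall
back to a MODRES record when present, else to a ring-atom census (N9 ⇒
purine, default A; pyrimidine ring ⇒ default U), with a warning either
way. The PDB reader deliberately ignores occupancy and B-factor columns,
keeps only altloc blank/'A' and the first MODEL, and drops waters and
non-polymer heteroatoms — docking decoys routinely carry malformed
bookkeeping columns and the scoring needs none of them.

## Contacts, bins and boundary conventions

A contact is any protein-bead/RNA-bead pair with distance strictly below
the 9 Å cutoff. Distance bins are half-open `[k, k+1)` Å; angle bins are
half-open 20° bins with θ=180° closed into the last bin; the contact angle
is measured between the RNA bead's axis and the vector from the RNA bead to
the protein bead (one angle per contact, always anchored on the RNA side).
Edge assignment projects the protein bead into the base plane and reads the
signed in-plane angle φ from the glycosidic direction: Sugar for
φ ∈ [0°, 120°), Watson–Crick for [120°, 240°) (the face opposite the
sugar), Hoogsteen for [240°, 360°). The wedge boundaries are module
constants (`geometry.EDGE_SECTORS`). A protein bead within 0.1 Å of the
base centroid, or exactly on the base normal, is a degenerate-geometry
error. All three statistical terms share the single 9 Å contact set.

## Reference states and energies

Energies are reverse-Boltzmann log-ratios
`ε = −RT·ln((N_obs+α)/(N_exp+α))` per (protein type, RNA type, bin) cell,
per term. Defaults: `RT = 1` (scores are unitless; only rankings and
correlations are consumed) and pseudocount `α = 1`, which keeps every cell
finite at any training scale. With `α = 0`, cells empty in both histograms
carry zero energy (no evidence), while one-sided zeros are an error.

*Quasi-chemical*: `N_exp(i,j,b) = X_i·X_j·N_obs(b)`, where the mole
fractions X are bead-type frequencies over all training complexes and
`N_obs(b)` is the per-bin total. The construction conserves per-bin totals
exactly, which the tests assert. The same form is applied to the angle and
edge terms using their own per-bin totals.

*DARS*: `N_exp` is the contact histogram of geometry-only docking decoys
of the same training complexes (200 per complex by default at fixture
scale), rescaled by one global factor per term so that its grand total
matches the natives' grand total. Per-bin rescaling variants would pin
every bin's total to the native profile and thereby erase the distance
profile differences DARS exists to capture, so the global variant is used.

The score of a pose is `E = Ed + Ea + Es + Ep` with equal, unoptimized
weights. `Ed` and `Ea` sum their terms over all contacts, `Es` over
base-ring contacts only. `Ep` adds `clash_penalty · RT` (default 1.0) for
every bead pair closer than `clash_distance` (default 3.0 Å between bead
centers) — defaults chosen so the clash term has the same order of
magnitude as the statistical terms on the packaged fixtures; both constants
are configurable. Leave-one-out tables subtract the held-out complex's
contact, bead and (for DARS) decoy contributions before rebuilding the
reference state, so a scored complex never informs its own table.

`RNPPotential` wraps training and scoring as a scikit-learn estimator
(`fit`/`predict`/`get_params`; fitted attributes `table_`, `counts_`,
`reference_counts_`), and the potential serializes to TSV with a JSON
header at 17 significant digits, which round-trips bit-exactly.

## Decoy generation

The rigid-body sampler draws rotations from the deterministic z-y-z
Euler grid at 10° steps (emulating the rotational sampling of FFT docking
programs) and ligand-centroid positions uniformly by volume from a
spherical shell around the receptor (inner radius = receptor bounding
radius, width 15 Å). A pose is accepted when the molecules touch (≥1 bead
pair inside the contact cutoff) and at most a fraction (default 0.2) of
ligand beads sits inside clash range — a pure shape filter, no energies.
Rejection sampling is capped at 1000·n attempts. Everything is
reproducible bitwise from the seed. A second generator,
`perturbation_decoys`, produces a graded near-native series by perturbing
the native pose with ramped rotations/translations, the shape of
bound-docking test sets made by perturbing a crystal structure.

## Synthetic study material

`make_toy_complex` builds an idealized complex: an ideal α-helix with
templated compact side chains against a regular RNA helix with exactly
planar base rings (ring-plane residuals < 1e-6 Å, so frame conventions are
analytically checkable). Two deliberate realism choices matter:

* **Composition.** Interface sequences are drawn from an
  RNA-binding-like amino-acid distribution (arginine/lysine-rich, then
  Ser/Asn/Gln/Thr/His/Tyr). Real protein–RNA interfaces are strongly
  enriched in these residues, and a knowledge-based potential works
  precisely by exploiting such recurring chemistry; uniformly random
  sequences would leave nothing to learn.
* **Placement.** The RNA sits at a fixed offset from the protein axis
  (default 7.5 Å, giving a ~3.2–4.6 Å closest heavy-atom gap across
  sequences, median 3.8 Å — the van der Waals contact regime). A fixed
  geometry means a given residue–nucleotide contact recurs at its
  characteristic distance across complexes, the way salt bridges and
  stacking contacts do in real structures. A sequence-adaptive placement
  (exact minimum gap; available via `interface_gap`) shifts all distances
  by the length of whichever side chain happens to be longest and destroys
  that recurrence.

What the toy complexes do **not** emulate: conformational variety (all
complexes share one backbone geometry), base-mediated specific recognition
(the interfaces are mostly backbone-facing), crystallographic noise,
modified residues in context, and any unbound-docking conformational
change. Passing tests on this material therefore demonstrate the
statistical machinery — counting, reference states, LOO hygiene,
invariances — and the potential's ability to recover planted or
construction-borne signal; they do not certify performance on real
complexes, which requires real training data.

`make_planted_training_set` builds bead-level complexes whose contacts are
isolated pairs on a widely spaced lattice: background contacts are
multinomial over a pool of (type, type, bin) cells — uniform over type
pairs, proportional to shell volume over distance bins (i.e. uniform
spatial density, which is also the profile geometry-only decoys produce,
so the background cancels in both reference states) — and one chosen cell
receives `enrichment`× the per-cell background mean of its bin. Training
on such a set must return that cell as the global distance-term minimum,
for both reference states; this is the package's parameter-recovery check.

## Clustering and evaluation

Clustering restricts to the `top_n` best-scored decoys (default 100) and
repeatedly extracts the row of the pairwise ligand-RMSD matrix with the
most off-diagonal entries under the cutoff (default 5 Å); that row plus its
neighbors form a cluster and leave the matrix. Ties go to the earlier
input position; iteration stops when no row has a neighbor inside the
cutoff; the seed row always joins its own cluster; clusters are reported
largest-first (size ties by representative score) with the lowest-energy
member as representative. When nothing clusters, a relaxed pass (top 200,
10 Å) runs and the result is flagged. Ligand RMSD superposes receptors by
Kabsch (via scipy's rotation alignment) and measures heavy-atom RMSD over
the ligand — all heavy atoms when all-atom models are supplied, bead
positions for reduced models; evaluation reports Pearson r between score
and RMSD over decoys below 5/10/20 Å with standard error
`sqrt((1−r²)/(n−2))`, reported as undefined below three points or at zero
variance.

## Problem sizes and variability

The packaged end-to-end checks run at desk scale: 20 training complexes of
18 protein + 4 RNA residues (~23 interface contacts each), 200 reference
and 200 evaluation decoys per complex, and the planted-signal sets use a
6×4-type pool at ~2 contacts per background cell. At this scale
leave-one-out native discrimination retains sequence-luck variance: across
independent populations the fraction of natives ranked in the top 5 % of
their decoy sets typically falls between ~0.6 and 0.95, and the
score–RMSD correlation among native-like decoys is small and positive
(pooled across complexes, since single complexes often have too few
native-like decoys for a defined coefficient). The packaged suite runs the
default population; `scripts/acceptance.py` recomputes every quantity at
whatever seed it is given and reports the measured values.

## Known limitations

* Bead memberships (`SC1`/`SC2` partition, phosphate membership, axis
  definitions) are this package's conventions, kept in editable tables;
  other coarse-graining choices are plausible.
* The edge wedges are symmetric 120° sectors anchored at the glycosidic
  bond — a geometric idealization of the base-edge classification, not a
  per-atom assignment.
* The clash term is a flat per-pair penalty at bead resolution; it cannot
  resolve partial overlaps below bead granularity.
* DNA chains, protein chemical modifications, mmCIF input and
  reconstruction of all-atom models from beads are out of scope.
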