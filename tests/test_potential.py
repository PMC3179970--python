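import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from sklearn.base import clone

from rnpscore import (
    BinningScheme,
    RNPPotential,
    count_contacts,
    dars_expected,
    energy_table,
    loo_tables,
    mole_fractions,
    quasi_expected,
    score_complex,
    train_potential,
)
from rnpscore.potential import (
    PROTEIN_TYPE_INDEX,
    RNA_TYPE_INDEX,
    TERMS,
    ContactCounts,
    PotentialTable,
)
from rnpscore.reduction import BeadType, transform_beads

from conftest import pair_complex, simple_bead

SCHEME = BinningScheme()


def one_contact_complex():
    """ALA.CA against A.PUR6 at 4.2 A, 30 degrees off the base normal, WC side."""
    frame = (np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))
    rna = simple_bead("A", "PUR6", (0, 0, 0), axis=(0, 0, 1), edge_frame=frame)
    direction = np.array([-np.sin(np.radians(30)), 0.0, np.cos(np.radians(30))])
    prot = simple_bead("ALA", "CA", 4.2 * direction)
    return pair_complex([prot], [rna])


def counts_from(tables, scheme=SCHEME, protein_beads=None, rna_beads=None):
    P, R = len(PROTEIN_TYPE_INDEX), len(RNA_TYPE_INDEX)
    return ContactCounts(
        tables=tables,
        protein_beads=protein_beads if protein_beads is not None else np.ones(P),
        rna_beads=rna_beads if rna_beads is not None else np.ones(R),
        scheme=scheme,
    )


class TestCountContacts:
    def test_single_contact_hand_binned(self):
        counts = count_contacts([one_contact_complex()], SCHEME, ids=["one"])
        i = PROTEIN_TYPE_INDEX[BeadType("ALA", "CA")]
        j = RNA_TYPE_INDEX[BeadType("A", "PUR6")]
        assert counts.tables["dist"][i, j, 4] == 1  # 4.2 A -> bin 4
        assert counts.tables["dist"].sum() == 1
        assert counts.tables["angle"][i, j, 1] == 1  # 30 deg -> bin 1
        wc = list(SCHEME.edge_labels).index("WC")
        assert counts.tables["edge"][i, j, wc] == 1

    def test_duplicating_training_set_doubles_counts(self, training_set):
        once = count_contacts(training_set, SCHEME)
        twice = count_contacts(
            training_set + training_set,
            SCHEME,
            ids=[f"a{k}" for k in range(len(training_set))]
            + [f"b{k}" for k in range(len(training_set))],
        )
        for t in TERMS:
            assert np.array_equal(twice.tables[t], 2 * once.tables[t])

    def test_distant_molecules_have_zero_counts(self):
        far = pair_complex(
            [simple_bead("ALA", "CA", (0, 0, 0))], [simple_bead("A", "P", (50, 0, 0))]
        )
        counts = count_contacts([far], SCHEME, ids=["far"])
        assert all(counts.tables[t].sum() == 0 for t in TERMS)

    def test_every_contact_feeds_each_term_once(self, training_set):
        counts = count_contacts(training_set, SCHEME)
        assert counts.tables["dist"].sum() == counts.tables["angle"].sum()
        assert counts.totals_per_bin("dist").sum() == counts.total("dist")


class TestMoleFractions:
    def test_direct_ratio(self):
        prot = [simple_bead("ALA", "CA", (k, 0, 0)) for k in range(3)] + [
            simple_bead("GLY", "CA", (k, 5, 0)) for k in range(7)
        ]
        rna = [simple_bead("A", "P", (k, 10, 0)) for k in range(4)]
        counts = count_contacts([pair_complex(prot, rna)], SCHEME, ids=["x"])
        xi, xj = mole_fractions(counts)
        assert xi[PROTEIN_TYPE_INDEX[BeadType("ALA", "CA")]] == pytest.approx(0.3)
        assert xi.sum() == pytest.approx(1.0, abs=1e-12)
        assert xj[RNA_TYPE_INDEX[BeadType("A", "P")]] == pytest.approx(1.0)

    def test_full_type_coverage_normalizes(self, training_set):
        xi, xj = mole_fractions(count_contacts(training_set, SCHEME))
        assert xi.sum() == pytest.approx(1.0, abs=1e-12)
        assert xj.sum() == pytest.approx(1.0, abs=1e-12)


class TestQuasiReference:
    def test_product_formula_on_a_single_cell(self):
        P, R = len(PROTEIN_TYPE_INDEX), len(RNA_TYPE_INDEX)
        tables = {t: np.zeros((P, R, SCHEME.n_distance_bins if t == "dist"
                               else SCHEME.n_angle_bins if t == "angle" else 3))
                  for t in TERMS}
        tables["dist"][0, 0, 2] = 100
        pb = np.zeros(P)
        pb[0] = pb[1] = 5  # X_0 = 0.5
        rb = np.zeros(R)
        rb[0] = rb[1] = 5
        exp = quasi_expected(counts_from(tables, protein_beads=pb, rna_beads=rb))
        assert exp.tables["dist"][0, 0, 2] == pytest.approx(25.0)

    def test_single_type_limit_is_identity(self):
        P, R = len(PROTEIN_TYPE_INDEX), len(RNA_TYPE_INDEX)
        tables = {t: np.zeros((P, R, 9 if t != "edge" else 3)) for t in TERMS}
        tables["dist"][3, 2, :] = np.arange(9)
        pb = np.zeros(P); pb[3] = 10
        rb = np.zeros(R); rb[2] = 4
        exp = quasi_expected(counts_from(tables, protein_beads=pb, rna_beads=rb))
        assert np.allclose(exp.tables["dist"][3, 2], np.arange(9))

    def test_conservation_for_random_counts(self, training_set):
        counts = count_contacts(training_set, SCHEME)
        exp = quasi_expected(counts)
        for t in TERMS:
            # summation identity: sum_ij Xi Xj Nobs(b) = Nobs(b)
            assert np.allclose(
                exp.tables[t].sum(axis=(0, 1)), counts.totals_per_bin(t), rtol=1e-9
            )


class TestDarsReference:
    def test_self_reference_limit(self, training_set):
        counts = count_contacts(training_set, SCHEME)
        exp = dars_expected(counts, counts)
        for t in TERMS:
            assert np.allclose(exp.tables[t], counts.tables[t])

    def test_global_rescaling(self):
        P, R = len(PROTEIN_TYPE_INDEX), len(RNA_TYPE_INDEX)
        nat = {t: np.zeros((P, R, 9 if t != "edge" else 3)) for t in TERMS}
        dec = {t: np.zeros((P, R, 9 if t != "edge" else 3)) for t in TERMS}
        for t in TERMS:
            nat[t][0, 0, 0] = 10
            dec[t][0, 0, 0] = 60
            dec[t][1, 1, 1] = 40
        exp = dars_expected(counts_from(dec), counts_from(nat))
        for t in TERMS:  # s = 10 / 100
            assert exp.tables[t][0, 0, 0] == pytest.approx(6.0)
            assert exp.tables[t][1, 1, 1] == pytest.approx(4.0)
            assert exp.tables[t].sum() == pytest.approx(nat[t].sum())

    def test_enriched_native_cell_beats_reference(self):
        # planted-signal arithmetic: native concentrated where decoys are flat
        P, R = len(PROTEIN_TYPE_INDEX), len(RNA_TYPE_INDEX)
        nat = {t: np.zeros((P, R, 9 if t != "edge" else 3)) for t in TERMS}
        dec = {t: np.zeros((P, R, 9 if t != "edge" else 3)) for t in TERMS}
        for t in TERMS:
            dec[t][:2, :2, :2] = 1.0       # flat decoy background, total 8
            nat[t][:2, :2, :2] = 1.0
            nat[t][0, 0, 0] = 5.0          # enrichment; total 12
        exp = dars_expected(counts_from(dec), counts_from(nat))
        # s = 12/8 -> exp = 1.5 < obs = 5 in the planted cell
        assert exp.tables["dist"][0, 0, 0] == pytest.approx(1.5)
        assert exp.tables["dist"][0, 0, 0] < nat["dist"][0, 0, 0]

    def test_zero_decoy_term_is_an_error(self, training_set):
        counts = count_contacts(training_set, SCHEME)
        empty = counts_from({t: np.zeros_like(counts.tables[t]) for t in TERMS})
        with pytest.raises(ValueError, match="decoy"):
            dars_expected(empty, counts)


class TestEnergyTable:
    def test_equal_counts_give_zero_energy(self, training_set):
        counts = count_contacts(training_set, SCHEME)
        table = energy_table(counts, dars_expected(counts, counts), pseudocount=1.0)
        for t in TERMS:
            assert np.allclose(table.energies[t], 0.0, atol=1e-12)

    def test_two_to_one_ratio_is_minus_log_two(self):
        P, R = len(PROTEIN_TYPE_INDEX), len(RNA_TYPE_INDEX)
        obs = {t: np.full((P, R, 9 if t != "edge" else 3), 2.0) for t in TERMS}
        exp = {t: np.full((P, R, 9 if t != "edge" else 3), 1.0) for t in TERMS}
        from rnpscore.potential import ReferenceCounts

        table = energy_table(
            counts_from(obs), ReferenceCounts(exp, "quasi"), rt=1.0, pseudocount=0.0
        )
        assert table.energies["dist"][0, 0, 0] == pytest.approx(-math.log(2.0), abs=1e-12)

    def test_formula_oracle_on_random_tuples(self):
        # independent scalar re-computation of -RT ln((o+a)/(e+a))
        rng = np.random.default_rng(12)
        from rnpscore.potential import ReferenceCounts

        P, R = len(PROTEIN_TYPE_INDEX), len(RNA_TYPE_INDEX)
        for _ in range(5):
            rt = float(rng.uniform(0.2, 3.0))
            alpha = float(rng.uniform(0.1, 2.0))
            obs = {t: rng.integers(0, 50, (P, R, 9 if t != "edge" else 3)).astype(float)
                   for t in TERMS}
            exp = {t: rng.uniform(0, 50, (P, R, 9 if t != "edge" else 3)) for t in TERMS}
            table = energy_table(
                counts_from(obs), ReferenceCounts(exp, "quasi"), rt=rt, pseudocount=alpha
            )
            for t in TERMS:
                flat_o = obs[t].ravel()
                flat_e = exp[t].ravel()
                sample = rng.integers(0, flat_o.size, 100)
                for k in sample:
                    expected = -rt * math.log((flat_o[k] + alpha) / (flat_e[k] + alpha))
                    assert table.energies[t].ravel()[k] == pytest.approx(expected, abs=1e-12)

    def test_one_sided_zero_with_no_pseudocount_errors(self):
        P, R = len(PROTEIN_TYPE_INDEX), len(RNA_TYPE_INDEX)
        obs = {t: np.zeros((P, R, 9 if t != "edge" else 3)) for t in TERMS}
        exp = {t: np.zeros((P, R, 9 if t != "edge" else 3)) for t in TERMS}
        obs["dist"][0, 0, 0] = 3.0
        from rnpscore.potential import ReferenceCounts

        with pytest.raises(ValueError):
            energy_table(counts_from(obs), ReferenceCounts(exp, "quasi"), pseudocount=0.0)

    def test_monotone_in_observed_count(self, training_set):
        counts = count_contacts(training_set, SCHEME)
        exp = quasi_expected(counts)
        t0 = energy_table(counts, exp)
        bumped = count_contacts(training_set, SCHEME)
        i, j, b = np.argwhere(bumped.tables["dist"] > 0)[0]
        bumped.tables["dist"][i, j, b] += 5
        t1 = energy_table(bumped, exp)
        assert t1.energies["dist"][i, j, b] < t0.energies["dist"][i, j, b]


class TestScoring:
    def test_zero_contacts_zero_energy(self):
        far = pair_complex(
            [simple_bead("ALA", "CA", (0, 0, 0))], [simple_bead("A", "P", (50, 0, 0))]
        )
        counts = count_contacts([one_contact_complex()], SCHEME, ids=["x"])
        table = energy_table(counts, quasi_expected(counts))
        b = score_complex(far, table, SCHEME)
        assert b.E == 0 and b.n_contacts == 0 and b.n_clashes == 0

    def test_single_contact_sums_known_cells(self):
        cx = one_contact_complex()
        counts = count_contacts([cx], SCHEME, ids=["x"])
        table = energy_table(counts, quasi_expected(counts))
        i = PROTEIN_TYPE_INDEX[BeadType("ALA", "CA")]
        j = RNA_TYPE_INDEX[BeadType("A", "PUR6")]
        table.energies["dist"][i, j, 4] = -0.5
        table.energies["angle"][i, j, 1] = -0.2
        wc = list(SCHEME.edge_labels).index("WC")
        table.energies["edge"][i, j, wc] = -0.1
        b = score_complex(cx, table, SCHEME)
        assert b.Ed == pytest.approx(-0.5)
        assert b.Ea == pytest.approx(-0.2)
        assert b.Es == pytest.approx(-0.1)
        assert b.Ep == 0.0
        assert b.E == pytest.approx(-0.8)

    def test_clash_penalty_counts_close_pairs(self):
        cx = pair_complex(
            [simple_bead("ALA", "CA", (0, 0, 0))], [simple_bead("A", "P", (2.5, 0, 0))]
        )
        counts = count_contacts([cx], SCHEME, ids=["x"])
        table = energy_table(counts, quasi_expected(counts))
        for t in TERMS:
            table.energies[t][:] = 0.0
        b = score_complex(cx, table, SCHEME)
        assert b.n_clashes == 1
        assert b.Ep == pytest.approx(1.0)

    def test_total_is_exact_sum(self, training_set, toy_complex):
        table = train_potential(training_set, reference="quasi")
        b = score_complex(toy_complex, table)
        assert b.E == b.Ed + b.Ea + b.Es + b.Ep

    def test_rigid_motion_invariance(self, training_set, toy_complex):
        table = train_potential(training_set, reference="quasi")
        base = score_complex(toy_complex, table).E
        rng = np.random.default_rng(8)
        for _ in range(10):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.uniform(-30, 30, 3)
            moved = pair_complex(
                transform_beads(toy_complex.protein_beads, R, t),
                transform_beads(toy_complex.rna_beads, R, t),
            )
            assert score_complex(moved, table).E == pytest.approx(base, abs=1e-9)


class TestLeaveOneOut:
    def test_two_complex_identity(self, training_set):
        pair = training_set[:2]
        counts = count_contacts(pair, SCHEME, ids=["a", "b"])
        tables = loo_tables(counts, kind="quasi")
        solo = train_potential([pair[1]], reference="quasi", ids=["b"])
        for t in TERMS:
            assert np.allclose(tables["a"].energies[t], solo.energies[t], atol=1e-12)

    def test_counts_are_conserved(self, training_set):
        counts = count_contacts(training_set, SCHEME)
        for cid in list(counts.per_complex)[:3]:
            rest = counts.without(cid)
            for t in TERMS:
                assert np.allclose(
                    rest.tables[t] + counts.per_complex[cid].tables[t], counts.tables[t]
                )

    def test_each_fold_differs_from_full_table(self, training_set):
        subset = training_set[:5]
        counts = count_contacts(subset, SCHEME)
        full = energy_table(counts, quasi_expected(counts))
        for cid, table in loo_tables(counts, kind="quasi").items():
            assert any(
                not np.allclose(table.energies[t], full.energies[t]) for t in TERMS
            ), f"fold {cid} identical to full table"

    def test_single_complex_is_an_error(self, training_set):
        counts = count_contacts(training_set[:1], SCHEME, ids=["only"])
        with pytest.raises(ValueError):
            loo_tables(counts, kind="quasi")


class TestSerialization:
    def test_tsv_roundtrip_is_bit_exact(self, training_set, tmp_path):
        table = train_potential(training_set, reference="quasi", rt=0.7, pseudocount=0.5)
        path = tmp_path / "table.tsv"
        table.to_tsv(path)
        back = PotentialTable.from_tsv(path)
        for t in TERMS:
            assert np.array_equal(back.energies[t], table.energies[t])
            assert np.array_equal(back.n_obs[t], table.n_obs[t])
            assert np.array_equal(back.n_exp[t], table.n_exp[t])
        assert back.rt == table.rt
        assert back.pseudocount == table.pseudocount
        assert back.scheme == table.scheme


class TestEstimator:
    def test_sklearn_params_protocol(self):
        est = RNPPotential(reference="quasi", rt=2.0)
        params = est.get_params()
        assert params["reference"] == "quasi" and params["rt"] == 2.0
        est2 = clone(est).set_params(pseudocount=0.5)
        assert est2.get_params()["pseudocount"] == 0.5

    def test_predict_matches_function_path(self, training_set, toy_complex):
        est = RNPPotential(reference="quasi").fit(training_set)
        direct = score_complex(toy_complex, est.table_).E
        assert est.predict([toy_complex])[0] == pytest.approx(direct, abs=1e-12)

    def test_unfitted_predict_raises(self, toy_complex):
        with pytest.raises(AttributeError):
            RNPPotential().predict([toy_complex])

    def test_unknown_reference_rejected(self, training_set):
        with pytest.raises(ValueError):
            RNPPotential(reference="bogus").fit(training_set)
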