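import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier

from phlastab import (
    ContactRecord,
    StablePeptideClassifier,
    allocate_contacts,
    decompose_prediction,
    explain_conformation,
    explain_phla,
    pair_index,
    summarize,
)
from phlastab.interpret import default_anchor_positions

from ._oracles import enumerate_tree_decomposition


def _contact(pep_pos, pep_aa, hla_aa, transformed, hla_pos=1, distance=3.0):
    return ContactRecord(
        peptide_pos=pep_pos, peptide_aa=pep_aa, hla_pos=hla_pos, hla_aa=hla_aa,
        distance=distance, transformed=transformed,
        feature_index=pair_index(pep_aa, hla_aa),
    )


class TestDecomposition:
    def test_single_stump_arithmetic(self):
        """One split: bias = root fraction, contrib = leaf - root, P = leaf."""
        X = np.array([[0.0], [1.0], [0.0], [1.0]] * 5)
        y = np.array([0, 1, 0, 1] * 5)
        forest = RandomForestClassifier(
            n_estimators=1, max_depth=1, bootstrap=False, random_state=0
        ).fit(X, y)
        bias, contribs, p = decompose_prediction(forest, np.array([1.0]))
        assert bias == pytest.approx(0.5)
        assert contribs[0] == pytest.approx(p - bias)
        assert p == pytest.approx(1.0)

    def test_root_only_tree_identity(self):
        X = np.random.default_rng(0).random((10, 3))
        y = np.arange(10) % 2
        forest = RandomForestClassifier(
            n_estimators=3, bootstrap=False, min_samples_split=100, random_state=0
        ).fit(X, y)
        bias, contribs, p = decompose_prediction(forest, X[0])
        assert np.all(contribs == 0)
        assert p == pytest.approx(bias)

    def test_matches_exhaustive_path_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.random((200, 8))
        y = (X[:, 0] + X[:, 3] > 1.0).astype(int)
        forest = RandomForestClassifier(
            n_estimators=10, max_depth=3, random_state=1
        ).fit(X, y)
        for x in rng.random((100, 8)):
            bias, contribs, p = decompose_prediction(forest, x)
            oracle_biases, oracle_contribs = zip(
                *(enumerate_tree_decomposition(t, x, 1) for t in forest.estimators_)
            )
            assert bias == pytest.approx(np.mean(oracle_biases), abs=1e-12)
            np.testing.assert_allclose(
                contribs, np.mean(oracle_contribs, axis=0), atol=1e-12
            )
            assert bias + contribs.sum() == pytest.approx(p, abs=1e-9)

    def test_conservation_on_trained_forest(self, small_forest, small_matrix):
        for x in small_matrix.X[:: max(1, len(small_matrix.X) // 25)]:
            bias, contribs, p = decompose_prediction(small_forest, x)
            assert bias + contribs.sum() == pytest.approx(p, abs=1e-9)

    def test_bias_exact_half_without_bootstrap(self, exact_forest, small_matrix):
        bias, _, _ = decompose_prediction(exact_forest, small_matrix.X[0])
        assert bias == pytest.approx(0.5, abs=1e-12)

    def test_bias_near_half_with_bootstrap(self, small_matrix):
        clf = StablePeptideClassifier(n_estimators=500, random_state=0).fit(
            small_matrix.X, small_matrix.y
        )
        bias, _, _ = decompose_prediction(clf, small_matrix.X[0])
        assert bias == pytest.approx(0.5, abs=0.02)

    def test_wrong_length_rejected(self, small_forest):
        with pytest.raises(ValueError, match="length"):
            decompose_prediction(small_forest, np.zeros(5))

    def test_non_forest_rejected(self, small_matrix):
        lr = StablePeptideClassifier(model="lr").fit(small_matrix.X, small_matrix.y)
        with pytest.raises(ValueError, match="random forest"):
            decompose_prediction(lr, small_matrix.X[0])


class TestContactAllocation:
    def test_proportional_split(self):
        contacts = [
            _contact(1, "R", "D", 0.5),
            _contact(2, "R", "D", 0.25, hla_pos=2),
        ]
        contribs = np.zeros(210)
        contribs[pair_index("R", "D")] = 0.06
        out = allocate_contacts(contribs, contacts)
        np.testing.assert_allclose(out, [0.04, 0.02])

    def test_single_contact_inherits_everything(self):
        contacts = [_contact(1, "A", "L", 0.7)]
        contribs = np.zeros(210)
        contribs[pair_index("A", "L")] = -0.11
        np.testing.assert_allclose(allocate_contacts(contribs, contacts), [-0.11])

    @pytest.mark.parametrize("seed", range(4))
    def test_conservation_per_feature(self, seed):
        rng = np.random.default_rng(seed)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        contacts = [
            _contact(
                int(rng.integers(1, 10)), rng.choice(aas), rng.choice(aas),
                float(rng.uniform(0.01, 1.0)), hla_pos=int(rng.integers(1, 20)),
            )
            for _ in range(40)
        ]
        contribs = np.zeros(210)
        present = {c.feature_index for c in contacts}
        for j in present:
            contribs[j] = rng.normal(0, 0.05)
        out = allocate_contacts(contribs, contacts)
        for j in present:
            total = sum(o for o, c in zip(out, contacts) if c.feature_index == j)
            assert total == pytest.approx(contribs[j], abs=1e-9)

    def test_orphan_contribution_is_hard_error(self):
        contacts = [_contact(1, "A", "L", 0.5)]
        contribs = np.zeros(210)
        contribs[pair_index("R", "D")] = 0.1  # no R-D contact exists
        with pytest.raises(ValueError, match="zero-valued"):
            allocate_contacts(contribs, contacts)

    def test_scale_consistency_of_fractional_shares(self):
        contacts = [
            _contact(1, "R", "D", 0.5),
            _contact(2, "R", "D", 0.25, hla_pos=2),
            _contact(3, "A", "L", 0.4, hla_pos=3),
        ]
        doubled = [
            ContactRecord(
                c.peptide_pos, c.peptide_aa, c.hla_pos, c.hla_aa,
                c.distance, 2 * c.transformed, c.feature_index,
            )
            for c in contacts
        ]
        contribs = np.zeros(210)
        contribs[pair_index("R", "D")] = 0.09
        contribs[pair_index("A", "L")] = -0.03
        a = allocate_contacts(contribs, contacts)
        b = allocate_contacts(contribs, doubled)
        np.testing.assert_allclose(a, b)  # shares within a feature unchanged


class TestSummaries:
    def test_all_positive_on_anchors_gives_share_one(self):
        contacts = [
            _contact(2, "A", "L", 0.5),
            _contact(9, "V", "F", 0.5, hla_pos=2),
            _contact(5, "G", "G", 0.5, hla_pos=3),
        ]
        cc = np.array([0.1, 0.2, -0.05])
        rep = summarize("x", "c", 0.75, 0.5, np.zeros(210), contacts, cc)
        assert rep.anchor_positions == frozenset({2, 9})
        assert rep.anchor_share == pytest.approx(1.0)
        assert rep.anchor_share_negative == pytest.approx(0.0)

    def test_constructed_shares(self):
        contacts = [
            _contact(2, "A", "L", 0.5),
            _contact(3, "D", "R", 0.5, hla_pos=2),
            _contact(5, "G", "G", 0.5, hla_pos=3),
        ]
        cc = np.array([0.26, 0.32, 0.42])
        rep = summarize("x", "c", 0.9, 0.5, np.zeros(210), contacts, cc,
                        anchor_positions=[2, 9])
        assert rep.anchor_share == pytest.approx(0.26)
        assert rep.position_summary[3]["positive_share"] == pytest.approx(0.32)

    def test_negation_swaps_positive_and_negative(self):
        contacts = [
            _contact(1, "A", "L", 0.5),
            _contact(2, "C", "F", 0.5, hla_pos=2),
            _contact(3, "G", "S", 0.5, hla_pos=3),
        ]
        cc = np.array([0.3, -0.1, 0.2])
        a = summarize("x", "c", 0.9, 0.5, np.zeros(210), contacts, cc)
        b = summarize("x", "c", 0.1, 0.5, np.zeros(210), contacts, -cc)
        assert a.anchor_share == pytest.approx(b.anchor_share_negative)
        for pos in a.position_summary:
            assert a.position_summary[pos]["positive"] == pytest.approx(
                b.position_summary[pos]["negative"]
            )

    def test_all_zero_contributions_flagged(self):
        contacts = [_contact(1, "A", "L", 0.5)]
        rep = summarize("x", "c", 0.5, 0.5, np.zeros(210), contacts, np.zeros(1))
        assert rep.degenerate
        assert np.isnan(rep.anchor_share)

    def test_default_anchors_are_two_and_cterm(self):
        assert default_anchor_positions(9) == frozenset({2, 9})
        assert default_anchor_positions(10) == frozenset({2, 10})


class TestEndToEndExplanation:
    def test_sole_destabilizing_feature_concentrates_negative_mass(self):
        """When one feature alone separates the classes, an unstable example's
        negative contributions concentrate (>50%) on it."""
        rng = np.random.default_rng(0)
        n = 400
        y = (np.arange(n) % 2).astype(int)
        X = rng.uniform(0, 1, (n, 210))
        signal_idx = 17
        X[:, signal_idx] = np.where(y == 1, rng.uniform(0.8, 1.0, n), rng.uniform(0.0, 0.2, n))
        # every tree may see all features, so the sole signal is always split on
        clf = StablePeptideClassifier(
            n_estimators=100, max_features=210, random_state=0
        ).fit(X, y)
        x = X[y == 0][0]
        bias, fc, p = decompose_prediction(clf, x)
        assert p < 0.5
        neg_total = -fc[fc < 0].sum()
        assert -fc[signal_idx] > 0.5 * neg_total

    def test_planted_destabilizer_tops_negative_contributions(
        self, small_planted, small_forest
    ):
        """On real structures, contacts of the displaced signal residue are all
        informative, so the planted pair leads the negative ranking (the sharp
        >50% concentration belongs to the sole-signal case above)."""
        spec, data = small_planted
        (signal_idx,) = data.manifest["signal_feature_indices"]
        unstable = [
            pid for pid, lab in data.manifest["true_labels"].items() if lab == 0
        ]
        for pid in unstable[:6]:
            rec = data.store.conformations(pid)[0][1]
            rep = explain_conformation(small_forest, rec, kind="sigmoid")
            fc = rep.feature_contribs
            assert rep.prediction < 0.5
            assert int(np.argmin(fc)) == signal_idx
            # and the planted contact itself leads the contact-level ranking
            assert rep.contacts[int(np.argmin(rep.contact_contribs))].feature_index == signal_idx

    def test_explain_phla_averages_consistently(self, small_planted, small_forest):
        _, data = small_planted
        phla_id = data.store.phla_ids()[0]
        recs = [rec for _, rec in data.store.conformations(phla_id)][:3]
        reports, averaged = explain_phla(small_forest, recs)
        assert averaged["n_conformations"] == len(recs)
        assert averaged["prediction"] == pytest.approx(
            np.mean([r.prediction for r in reports])
        )
        residual = (
            averaged["bias"] + np.sum(averaged["feature_contribs"])
            - averaged["prediction"]
        )
        assert abs(residual) < 1e-9
        # per-conformation conservation: allocated + absent-pair mass closes
        for r in reports:
            assert r.contact_contribs.sum() + r.absent_feature_contrib == pytest.approx(
                r.feature_contribs.sum(), abs=1e-9
            )

    def test_report_serialization(self, small_planted, small_forest):
        _, data = small_planted
        rec = data.store.conformations(data.store.phla_ids()[0])[0][1]
        rep = explain_conformation(small_forest, rec)
        d = rep.to_dict()
        assert abs(d["conservation_residual"]) < 1e-9
        assert len(d["top_features"]) == 10
        assert rep.to_json()
        assert "P(stable)" in rep.to_text()
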