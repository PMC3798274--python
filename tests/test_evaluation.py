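import numpy as np
import pandas as pd
import pytest

from taxadecon import evaluation as ev
from taxadecon.calling import PresenceCalls
from taxadecon.deconvolve import GenomicContent
from taxadecon.errors import ParameterError, UndefinedStatisticError
from taxadecon.io_tables import (
    ElementCounts,
    ReferenceLengths,
    ReferencePresence,
    TaxonProfile,
)


def _calls(matrix, taxa, elements):
    return PresenceCalls(
        calls=pd.DataFrame(matrix, index=taxa, columns=elements), threshold=0.5
    )


class TestAccuracyRecall:
    def test_perfect_predictions(self):
        truth = pd.DataFrame([[1, 0], [0, 2]], index=["t1", "t2"], columns=["a", "b"])
        report = ev.accuracy_recall(_calls([[True, False], [False, True]],
                                           ["t1", "t2"], ["a", "b"]), truth)
        assert report.accuracy == 1.0 and report.recall == 1.0

    def test_hand_confusion_counts(self):
        # truth: a,b present; c,d absent.  calls: a,c present.
        truth = pd.DataFrame([[1, 1, 0, 0]], index=["t"], columns=list("abcd"))
        report = ev.accuracy_recall(
            _calls([[True, False, True, False]], ["t"], list("abcd")), truth
        )
        assert (report.tp, report.fp, report.tn, report.fn) == (1, 1, 1, 1)
        assert report.accuracy == 0.5 and report.recall == 0.5

    def test_recall_undefined_without_positives(self):
        truth = pd.DataFrame([[0, 0]], index=["t"], columns=["a", "b"])
        report = ev.accuracy_recall(_calls([[False, True]], ["t"], ["a", "b"]), truth)
        with pytest.warns(UserWarning, match="recall undefined"):
            assert np.isnan(report.recall)

    def test_invariant_under_simultaneous_permutation(self, rng):
        taxa = [f"t{i}" for i in range(5)]
        elements = [f"e{j}" for j in range(7)]
        truth = pd.DataFrame(rng.integers(0, 3, (5, 7)), index=taxa, columns=elements)
        calls = _calls(rng.random((5, 7)) > 0.5, taxa, elements)
        base = ev.accuracy_recall(calls, truth)
        t_perm, e_perm = rng.permutation(taxa), rng.permutation(elements)
        permuted = ev.accuracy_recall(
            PresenceCalls(calls=calls.calls.loc[t_perm, e_perm], threshold=0.5),
            truth.loc[t_perm, e_perm],
        )
        assert base.to_dict() == permuted.to_dict()


def _brute_force_auc(scores, labels):
    pos = scores[labels]
    neg = scores[~labels]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def _setup(self, predicted, truth_row):
        elements = [f"e{j}" for j in range(len(predicted))]
        content = GenomicContent(pd.DataFrame([predicted], index=["t"], columns=elements))
        reference = ReferenceLengths(pd.Series(400.0, index=elements))
        truth = pd.DataFrame([truth_row], index=["t"], columns=elements)
        return content, reference, truth

    def test_perfect_separation(self):
        content, ref, truth = self._setup([390, 410, 10, 20], [1, 1, 0, 0])
        auc, _ = ev.roc_auc(content, ref, truth)
        assert auc == 1.0

    def test_all_ties_give_half(self):
        content, ref, truth = self._setup([100, 100, 100, 100], [1, 1, 0, 0])
        auc, _ = ev.roc_auc(content, ref, truth)
        assert auc == pytest.approx(0.5)

    def test_matches_pairwise_probability_on_toy_set(self):
        predicted = [380.0, 120.0, 120.0, 300.0, 80.0, 10.0]
        labels = [1, 1, 0, 0, 0, 1]
        content, ref, truth = self._setup(predicted, labels)
        auc, _ = ev.roc_auc(content, ref, truth)
        brute = _brute_force_auc(np.array(predicted) / 400.0,
                                 np.array(labels, dtype=bool))
        assert auc == pytest.approx(brute, abs=1e-12)

    def test_single_class_rejected(self):
        content, ref, truth = self._setup([100, 200], [1, 1])
        with pytest.raises(UndefinedStatisticError):
            ev.roc_auc(content, ref, truth)


class TestErrorVariationCorrelation:
    def _build(self, errors, cvs):
        elements = [f"e{j}" for j in range(len(errors))]
        truth = pd.DataFrame([[400.0] * len(errors)], index=["t"], columns=elements)
        content = GenomicContent(truth * (1 + np.asarray(errors)))
        base = np.outer(1 + np.linspace(-1, 1, 9), np.ones(len(errors)))
        counts = base * 100.0
        # give column j sd proportional to requested cv
        counts = 100.0 + (base - 1) * 100.0 * np.asarray(cvs) / np.std(
            np.linspace(-1, 1, 9), ddof=1
        )
        counts_df = pd.DataFrame(counts, columns=elements,
                                 index=[f"S{i}" for i in range(9)])
        return content, truth, ElementCounts(counts_df)

    def test_collinear_points_give_unit_correlation(self):
        content, truth, counts = self._build([0.1, 0.2, 0.3], [0.05, 0.10, 0.15])
        r, _ = ev.error_variation_correlation(content, truth, counts, axis="samples")
        assert r == pytest.approx(1.0)

    def test_anticollinear_points_give_minus_one(self):
        content, truth, counts = self._build([0.3, 0.2, 0.1], [0.05, 0.10, 0.15])
        r, _ = ev.error_variation_correlation(content, truth, counts, axis="samples")
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        content, truth, counts = self._build([0.1, 0.1, 0.1], [0.05, 0.10, 0.15])
        with pytest.raises(UndefinedStatisticError):
            ev.error_variation_correlation(content, truth, counts, axis="samples")

    def test_requires_three_elements(self):
        content, truth, counts = self._build([0.1, 0.2], [0.05, 0.10])
        with pytest.raises(UndefinedStatisticError):
            ev.error_variation_correlation(content, truth, counts, axis="samples")


class TestJaccard:
    def _references(self):
        elements = list("abcdef")
        copy = pd.DataFrame(
            [[1, 1, 1, 0, 0, 0],
             [0, 1, 1, 1, 0, 0],
             [0, 0, 0, 1, 1, 1]],
            index=["g1", "g2", "g3"], columns=elements, dtype=float,
        )
        genus = pd.Series({"g1": "X", "g2": "X", "g3": "Y"})
        return ReferencePresence(copy_numbers=copy, genus=genus)

    def _counts(self):
        elements = list("abcdef")
        rng = np.random.default_rng(0)
        return ElementCounts(pd.DataFrame(
            rng.uniform(1, 100, (6, 6)), columns=elements,
            index=[f"S{i}" for i in range(6)],
        ))

    def test_set_arithmetic(self):
        assert ev._jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
        assert ev._jaccard({"a"}, {"a"}) == 1.0
        assert ev._jaccard({"a"}, {"b"}) == 0.0
        assert np.isnan(ev._jaccard(set(), set()))

    def test_genus_similarity_matches_manual_means(self):
        refs = self._references()
        calls = _calls([[True, True, True, False, False, False]], ["r1"], list("abcdef"))
        sim = ev.jaccard_genus_similarity(calls, refs, self._counts(), top_k=6)
        # vs genus X: mean(J with g1 = 1.0, J with g2 = 2/4)
        assert sim.similarity.loc["r1", "X"] == pytest.approx((1.0 + 0.5) / 2)
        assert sim.best_match["r1"] == "X"


class TestGenusSpecificElements:
    def _refs(self, frac_in_g=1.0):
        elements = ["marker", "core", "other"]
        rows, genus = [], {}
        for i in range(100):  # genus G genomes
            rows.append([1.0 if i < round(100 * frac_in_g) else 0.0, 1.0, 0.0])
            genus[f"G{i}"] = "G"
        for i in range(10):  # out-group genomes
            rows.append([0.0, 1.0, 1.0])
            genus[f"H{i}"] = "H"
        copy = pd.DataFrame(rows, index=list(genus), columns=elements)
        return ReferencePresence(copy_numbers=copy, genus=pd.Series(genus))

    def test_extreme_case(self):
        specific = ev.genus_specific_elements(self._refs())
        assert specific["G"] == {"marker"}
        assert specific["H"] == {"other"}

    def test_in_fraction_boundary(self):
        specific = ev.genus_specific_elements(self._refs(frac_in_g=0.79), in_frac=0.8)
        assert "marker" not in specific["G"]

    def test_stringent_variant(self):
        specific = ev.genus_specific_elements(self._refs(), in_frac=0.9, out_frac=0.1)
        assert specific["G"] == {"marker"}

    def test_single_genus_rejected(self):
        refs = ReferencePresence(
            copy_numbers=pd.DataFrame({"e": [1.0]}, index=["g"]),
            genus=pd.Series({"g": "only"}),
        )
        with pytest.raises(ParameterError):
            ev.genus_specific_elements(refs)


class TestCorrelationBaseline:
    def test_proportional_counts_called_present(self):
        prof = TaxonProfile(pd.DataFrame(
            {"t1": [0.2, 0.5, 0.3, 0.6], "t2": [0.8, 0.5, 0.7, 0.4]},
            index=[f"S{i}" for i in range(4)],
        ))
        counts = ElementCounts(pd.DataFrame(
            {"e": (prof.data["t1"] * 1000).to_numpy()}, index=prof.sample_ids
        ))
        calls = ev.correlation_baseline(counts, prof, r_threshold=0.999)
        assert calls.calls.loc["t1", "e"]
        assert not calls.calls.loc["t2", "e"]

    def test_floor_threshold_calls_everything_defined(self, rng):
        prof = TaxonProfile(pd.DataFrame(
            rng.dirichlet(np.ones(3), 5), index=[f"S{i}" for i in range(5)],
            columns=["t1", "t2", "t3"],
        ))
        counts = ElementCounts(pd.DataFrame(
            rng.uniform(1, 10, (5, 4)), index=prof.sample_ids,
            columns=[f"e{j}" for j in range(4)],
        ))
        calls = ev.correlation_baseline(counts, prof, r_threshold=-1.0)
        assert calls.calls.all().all()

    def test_matches_textbook_formula_on_hand_example(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 6.0])
        prof = TaxonProfile(pd.DataFrame({"t": x / x.sum()},
                                         index=[f"S{i}" for i in range(4)]))
        counts = ElementCounts(pd.DataFrame({"e": y},
                                            index=[f"S{i}" for i in range(4)]))
        r_manual = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean())**2).sum() * ((y - y.mean())**2).sum()))
        present = ev.correlation_baseline(counts, prof, r_threshold=r_manual - 1e-12)
        absent = ev.correlation_baseline(counts, prof, r_threshold=r_manual + 1e-12)
        assert present.calls.loc["t", "e"]
        assert not absent.calls.loc["t", "e"]

    def test_constant_vector_warns_and_calls_absent(self):
        prof = TaxonProfile(pd.DataFrame(
            {"t": [0.5, 0.4, 0.6]}, index=["S0", "S1", "S2"]
        ))
        counts = ElementCounts(pd.DataFrame(
            {"flat": [3.0, 3.0, 3.0]}, index=["S0", "S1", "S2"]
        ))
        with pytest.warns(UserWarning, match="constant"):
            calls = ev.correlation_baseline(counts, prof, r_threshold=-1.0)
        assert not calls.calls.loc["t", "flat"]
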