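import numpy as np
import pytest

from ezloc import (
    GeneratorSpec,
    NormalizationResources,
    generate_corpus,
    preprocess_corpus,
)
from ezloc.corpus import ExperimentConfig
from ezloc.experiment import (
    BowRepresentation,
    LeakageError,
    ModelSpec,
    evaluate_holdout,
    run_nested_cv,
    select_task_subset,
    split_by_patient,
    summarize,
)
from tests.conftest import make_doc


@pytest.fixture(scope="module")
def labeled_corpus():
    spec = GeneratorSpec(n_patients=40, signal_strength=0.9, seed=5)
    corpus, _ = generate_corpus(spec)
    return corpus


@pytest.fixture(scope="module")
def labeled_tokens(labeled_corpus):
    return preprocess_corpus(labeled_corpus, NormalizationResources.default())


class TestSplit:
    def test_counts_and_no_straddle(self, labeled_corpus):
        n = len(labeled_corpus.patient_ids)
        split = split_by_patient(labeled_corpus, 15 / 122, seed=0)
        assert len(split.holdout_patient_ids) == round(15 / 122 * n)
        assert not split.learning_patient_ids & split.holdout_patient_ids
        assert split.learning_patient_ids | split.holdout_patient_ids == set(
            labeled_corpus.patient_ids
        )

    def test_zero_fraction(self, labeled_corpus):
        split = split_by_patient(labeled_corpus, 0.0, seed=0)
        assert not split.holdout_patient_ids

    def test_deterministic(self, labeled_corpus):
        a = split_by_patient(labeled_corpus, 0.2, seed=3)
        b = split_by_patient(labeled_corpus, 0.2, seed=3)
        assert a == b

    def test_both_classes_on_both_sides(self, labeled_corpus):
        split = split_by_patient(labeled_corpus, 0.2, seed=1)
        by_patient = {}
        for doc in labeled_corpus.seizure_documents():
            by_patient.setdefault(doc.patient_id, doc.labels)
        for task in ("side", "localization"):
            for side_set in (split.learning_patient_ids,
                             split.holdout_patient_ids):
                values = {by_patient[p].get(task) for p in side_set}
                values.discard(None)
                assert len(values) == 2


class TestTaskSubset:
    def test_sublocalization_restricted_to_extra_temporal(self, labeled_tokens):
        subset = select_task_subset(labeled_tokens, "sublocalization")
        assert subset
        assert all(d.labels["localization"] == "extra_temporal" for d in subset)

    def test_side_keeps_all_labeled_seizures(self, labeled_tokens):
        subset = select_task_subset(labeled_tokens, "side")
        assert len(subset) == len([d for d in labeled_tokens
                                   if d.doc_kind == "seizure"])

    def test_unlabeled_documents_excluded(self):
        docs = [make_doc(["a"], doc_id="d0", labels={"side": "left"}),
                make_doc(["b"], doc_id="d1", labels={"side": "right"}),
                make_doc(["c"], doc_id="d2")]
        assert len(select_task_subset(docs, "side")) == 2

    def test_empty_subset_is_an_error(self):
        with pytest.raises(ValueError):
            select_task_subset([make_doc(["a"])], "side")


def _separable_dataset(n_per_class=20):
    docs = []
    for i in range(n_per_class):
        docs.append(make_doc(["rosso", "fuoco", "fiamma", "lato"],
                             doc_id=f"L{i}", patient_id=f"pl{i}",
                             labels={"side": "left"}))
        docs.append(make_doc(["blu", "acqua", "onda", "lato"],
                             doc_id=f"R{i}", patient_id=f"pr{i}",
                             labels={"side": "right"}))
    return docs


SMALL_CFG = dict(task="side", n_features=20, k_outer=4, k_inner=3,
                 seeds=(0,), n_repeats=1)


class TestNestedCV:
    @pytest.mark.parametrize("family", ["logreg_l1", "svm_linear", "svm_rbf",
                                        "svm_poly3"])
    def test_separable_dataset_is_perfect(self, family):
        cfg = ExperimentConfig(representation="bw", model=family, **SMALL_CFG)
        result = run_nested_cv(_separable_dataset(), "bw", family, cfg)
        assert result.mean_f1() == pytest.approx(1.0, abs=1e-9)

    def test_bit_identical_reruns(self):
        cfg = ExperimentConfig(representation="bw", model="logreg_l1",
                               **SMALL_CFG)
        r1 = run_nested_cv(_separable_dataset(), "bw", "logreg_l1", cfg)
        r2 = run_nested_cv(_separable_dataset(), "bw", "logreg_l1", cfg)
        assert r1.fold_records == r2.fold_records
        assert r1.aggregate == r2.aggregate

    def test_stratification_within_one_document(self):
        docs = _separable_dataset(25)
        cfg = ExperimentConfig(representation="bw", model="svm_linear",
                               task="side", n_features=20, k_outer=10,
                               k_inner=3, seeds=(1,), n_repeats=1)
        result = run_nested_cv(docs, "bw", "svm_linear", cfg)
        global_left = 0.5
        for rec in result.fold_records:
            n_fold = sum(rec.confusion.values())
            n_left = rec.confusion["TP"] + rec.confusion["FN"]
            assert abs(n_left - global_left * n_fold) <= 1

    def test_confusion_sums_to_fold_size(self):
        cfg = ExperimentConfig(representation="bw", model="svm_linear",
                               **SMALL_CFG)
        docs = _separable_dataset(10)
        result = run_nested_cv(docs, "bw", "svm_linear", cfg)
        assert sum(sum(r.confusion.values()) for r in result.fold_records) == \
            len(docs)

    def test_aggregate_recomputable_from_fold_records(self):
        cfg = ExperimentConfig(representation="bw", model="svm_linear",
                               task="side", n_features=20, k_outer=4,
                               k_inner=3, seeds=(0, 1), n_repeats=2)
        result = run_nested_cv(_separable_dataset(12), "bw", "svm_linear", cfg)
        rebuilt = summarize(cfg, result.fold_records)
        assert rebuilt.aggregate == result.aggregate
        assert rebuilt.per_trial_medians == result.per_trial_medians
        assert rebuilt.pooled_confusion == result.pooled_confusion


class TestHoldout:
    def test_shape_and_leakage_guard(self):
        learn = _separable_dataset(15)
        hold = [make_doc(["rosso", "fuoco", "fiamma", "lato"], doc_id="h0",
                         patient_id="hp0", labels={"side": "left"}),
                make_doc(["blu", "acqua", "onda", "lato"], doc_id="h1",
                         patient_id="hp1", labels={"side": "right"})]
        combos = [("bw", family, {"C": 1.0})
                  for family in ("logreg_l1", "svm_linear", "svm_poly3")]
        rows = evaluate_holdout(learn, hold, "side", combos, n_features=20)
        assert len(rows) == 3
        assert all(set(("accuracy", "precision_w", "npv_w", "specificity_w",
                        "f1_w")) <= set(r) for r in rows)
        assert all(r["f1_w"] == pytest.approx(1.0) for r in rows)

    def test_fold_local_inventories_differ(self):
        docs = _separable_dataset(10)
        left = [d for d in docs if d.labels["side"] == "left"]
        right = [d for d in docs if d.labels["side"] == "right"]
        rep_a = BowRepresentation(20).fit(left)
        rep_b = BowRepresentation(20).fit(right)
        assert rep_a.digest() != rep_b.digest()

    def test_leakage_canary_fails_loudly(self):
        learn = _separable_dataset(15)
        hold = [make_doc(["rosso", "fiamma"], doc_id="h0", patient_id="hp0",
                         labels={"side": "left"}),
                make_doc(["blu", "onda"], doc_id="h1", patient_id="hp1",
                         labels={"side": "right"})]

        class RefittingBow(BowRepresentation):
            """Deliberately broken: refits its inventory on every transform."""

            def transform(self, docs):
                self.fit(docs)
                return super().transform(docs)

        import ezloc.experiment as exp

        original = exp.make_representation

        def patched(name, n_features=200, embedding_model=None):
            return RefittingBow(n_features)

        exp.make_representation = patched
        try:
            with pytest.raises(LeakageError):
                evaluate_holdout(learn, hold, "side",
                                 [("bw", "svm_linear", {"C": 1.0})],
                                 n_features=20)
        finally:
            exp.make_representation = original

    def test_empty_holdout_is_an_error(self):
        with pytest.raises(ValueError):
            evaluate_holdout(_separable_dataset(5), [], "side", [])


class TestModelSpec:
    def test_default_grids(self):
        assert len(ModelSpec("logreg_l1").hyper_grid) == 5
        assert len(ModelSpec("svm_rbf").hyper_grid) == 25

    def test_poly_degree_fixed(self):
        est = ModelSpec("svm_poly3").make_estimator({"C": 1.0})
        assert est.degree == 3

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            ModelSpec("random_forest")
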