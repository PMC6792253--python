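"""Annotation encoding, matrix assembly, and univariate selection."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.ensemble import RandomForestClassifier

from varprior.clinfilter import AnnotatedVariant
from varprior.features import (EncodingError, FeatureMatrix, FeatureSpec,
                               SelectionResult, SpecError,
                               assemble_feature_matrix, average_importances,
                               bin_count_encode, encode_numeric_single,
                               load_feature_specs, reduce_multi_value,
                               reference_specs, report_feature_importance,
                               select_top_k)

NUM = FeatureSpec(name="CADD Scaled", kind="numeric_single", default_value=-1.0,
                  expected_range=(0.0, 99.0))
FREQ = FeatureSpec(name="gnomAD AF", kind="numeric_single", is_allele_freq=True)
MULTI_MAX = FeatureSpec(name="polyphen", kind="numeric_multi",
                        worst_direction="max", default_value=-1.0)
MULTI_MIN = FeatureSpec(name="sift", kind="numeric_multi",
                        worst_direction="min", default_value=2.0)
CAT = FeatureSpec(name="clinvar", kind="categorical",
                  vocabulary=["Pathogenic", "LikelyPathogenic", "Benign"])


class TestEncoders:
    def test_numeric_passthrough(self):
        assert encode_numeric_single(23.1, NUM) == 23.1

    def test_missing_takes_extremal_default(self):
        assert encode_numeric_single(None, NUM) == -1.0

    def test_missing_allele_frequency_is_zero(self):
        assert encode_numeric_single(None, FREQ) == 0.0

    def test_non_numeric_payload_names_variant_and_feature(self):
        with pytest.raises(EncodingError, match=r"v-1.*CADD Scaled"):
            encode_numeric_single("high", NUM, variant_key="v-1")

    def test_reduce_worst_max(self):
        assert reduce_multi_value([2.1, 5.3], MULTI_MAX) == 5.3

    def test_reduce_worst_min(self):
        assert reduce_multi_value([0.4, 0.1], MULTI_MIN) == 0.1

    def test_reduce_empty_falls_back_to_default(self):
        assert reduce_multi_value([], MULTI_MAX) == -1.0
        assert reduce_multi_value(None, MULTI_MIN) == 2.0

    def test_bin_count_example(self):
        out = bin_count_encode(["Pathogenic", "Pathogenic", "Benign"], CAT)
        assert out.tolist() == [2, 0, 1, 0]

    def test_bin_count_empty_all_zero(self):
        assert bin_count_encode([], CAT).sum() == 0

    def test_bin_count_unknown_label_goes_to_other(self):
        out = bin_count_encode(["Mystery", " Benign "], CAT)
        assert out.tolist() == [0, 0, 1, 1]

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.sampled_from(
        ["Pathogenic", "LikelyPathogenic", "Benign", "junk", "other junk"])))
    def test_bin_count_conserves_label_count(self, labels):
        assert bin_count_encode(labels, CAT).sum() == len(labels)


def make_variant(key, annotations, reported=False, case_id="c1"):
    return AnnotatedVariant(
        key=key, case_id=case_id, genes=["G"], total_depth=30, alt_depth=15,
        transcript_effects=["Missense"], gene_disease_assocs=["OMIM"],
        annotations=annotations,
        label="reported" if reported else "not_reported",
        acmg_class="VUS" if reported else None,
    )


class TestAssembly:
    SPECS = [NUM, FREQ, MULTI_MAX, CAT]

    def test_single_cell_matrix(self):
        m = assemble_feature_matrix([make_variant("v1", {"CADD Scaled": 5.0})], [NUM])
        assert m.X.shape == (1, 1)
        assert m.X.iloc[0, 0] == 5.0

    def test_reference_specs_give_95_columns(self, small_cohort):
        _, _, _, cohort = small_cohort
        m = assemble_feature_matrix(cohort.variants[:50], reference_specs())
        assert m.X.shape[1] == 95

    def test_no_nan_survives_assembly(self, small_cohort):
        _, _, _, cohort = small_cohort
        m = assemble_feature_matrix(cohort.variants[:500], reference_specs())
        assert np.isfinite(m.X.to_numpy()).all()

    def test_reencoding_is_bit_identical(self):
        variants = [
            make_variant("v1", {"CADD Scaled": 5.0, "clinvar": ["Benign"]}),
            make_variant("v2", {"polyphen": [0.1, 0.9], "gnomAD AF": 0.004}),
        ]
        a = assemble_feature_matrix(variants, self.SPECS)
        b = assemble_feature_matrix(variants, self.SPECS)
        assert a.X.equals(b.X)

    def test_unknown_annotation_dropped(self, caplog):
        v = make_variant("v1", {"CADD Scaled": 5.0, "mystery": 1.0})
        with caplog.at_level("WARNING"):
            m = assemble_feature_matrix([v], [NUM])
        assert m.X.shape == (1, 1)
        assert "mystery" in caplog.text

    def test_duplicate_feature_names_rejected(self):
        with pytest.raises(SpecError):
            assemble_feature_matrix([], [NUM, NUM])

    def test_tsv_round_trip(self):
        variants = [make_variant("v1", {"CADD Scaled": 5.0}, reported=True),
                    make_variant("v2", {})]
        m = assemble_feature_matrix(variants, self.SPECS)
        mat, side = io.StringIO(), io.StringIO()
        m.to_tsv(mat, side)
        mat.seek(0), side.seek(0)
        m2 = FeatureMatrix.from_tsv(mat, side)
        assert m2.X.equals(m.X)
        assert m2.labels.tolist() == m.labels.tolist()
        assert m2.variant_keys == m.variant_keys


class TestSpecValidation:
    def test_default_inside_expected_range_rejected(self):
        with pytest.raises(SpecError, match="inside expected range"):
            FeatureSpec(name="bad", kind="numeric_single", default_value=0.5,
                        expected_range=(0.0, 1.0))

    def test_categorical_needs_vocabulary(self):
        with pytest.raises(SpecError):
            FeatureSpec(name="bad", kind="categorical")

    def test_duplicate_names_in_file_rejected(self):
        text = "- {name: A, kind: numeric_single, default_value: -1}\n" * 2
        with pytest.raises(SpecError, match="duplicate"):
            load_feature_specs(text)


def planted_matrix(seed=0, n=4000, n_cols=30, n_signal=6, shift=0.8):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.2).astype(np.int64)
    X = rng.normal(size=(n, n_cols))
    for j in range(n_signal):
        X[y == 1, j] += shift
    return FeatureMatrix(
        X=pd.DataFrame(X, columns=[f"f{j:02d}" for j in range(n_cols)]),
        labels=y,
        case_ids=[f"case_{i % 10}" for i in range(n)],
        variant_keys=[f"v{i}" for i in range(n)],
    )


class TestSelection:
    def test_recovers_planted_signal_columns(self):
        m = planted_matrix()
        sel = select_top_k(m, 6)
        assert set(sel.selected) == {f"f{j:02d}" for j in range(6)}

    def test_k_at_least_column_count_is_identity(self):
        m = planted_matrix(n=200, n_cols=5, n_signal=1)
        sel = select_top_k(m, 99)
        assert sel.selected == list(m.X.columns)

    def test_ties_break_by_column_order(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=300)
        y = (rng.random(300) < 0.3).astype(np.int64)
        X = pd.DataFrame({"a": col, "b": col, "c": col})
        m = FeatureMatrix(X=X, labels=y, case_ids=["c"] * 300,
                          variant_keys=[f"v{i}" for i in range(300)])
        sel = select_top_k(m, 2)
        assert sel.selected == ["a", "b"]

    def test_selection_uses_training_rows_only(self):
        # permuting (or deleting) rows outside the training cases never
        # changes the result, because selection sees the training matrix only
        m = planted_matrix(seed=1)
        train_cases = [f"case_{i}" for i in range(5)]
        sel_full = select_top_k(m.rows_for_cases(train_cases), 6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.n_rows)
        m_perm = FeatureMatrix(
            X=m.X.iloc[perm].reset_index(drop=True), labels=m.labels[perm],
            case_ids=[m.case_ids[i] for i in perm],
            variant_keys=[m.variant_keys[i] for i in perm],
        )
        sel_perm = select_top_k(m_perm.rows_for_cases(train_cases), 6)
        assert sel_full.selected == sel_perm.selected
        assert sel_full.fitted_on == sel_perm.fitted_on

    def test_chi2_method_on_count_columns(self):
        rng = np.random.default_rng(4)
        y = (rng.random(1000) < 0.3).astype(np.int64)
        X = pd.DataFrame({
            "signal": rng.poisson(1 + 2 * y),
            "noise": rng.poisson(1.5, size=1000),
        })
        m = FeatureMatrix(X=X.astype(float), labels=y, case_ids=["c"] * 1000,
                          variant_keys=[f"v{i}" for i in range(1000)])
        assert select_top_k(m, 1, method="chi2").selected == ["signal"]


class TestImportances:
    def fit_forest(self, m, cols):
        clf = RandomForestClassifier(n_estimators=20, random_state=0)
        clf.fit(m.X[cols].to_numpy(), m.labels)
        return clf

    def test_importances_sum_to_one_sorted_descending(self):
        m = planted_matrix(n=1000)
        sel = select_top_k(m, 6)
        clf = self.fit_forest(m, sel.selected)
        imp = report_feature_importance(clf, sel)
        vals = list(imp.values())
        assert sum(vals) == pytest.approx(1.0, abs=1e-6)
        assert vals == sorted(vals, reverse=True)

    def test_single_feature_model_gets_full_importance(self):
        m = planted_matrix(n=500)
        sel = SelectionResult(selected=["f00"], scores={})
        clf = self.fit_forest(m, ["f00"])
        assert report_feature_importance(clf, sel) == {"f00": pytest.approx(1.0)}

    def test_model_without_importances_rejected(self):
        from sklearn.linear_model import LogisticRegression
        sel = SelectionResult(selected=["f00"], scores={})
        with pytest.raises(TypeError):
            report_feature_importance(LogisticRegression(), sel)

    def test_averaging_two_forests_orders_by_mean(self):
        a = {"x": 0.8, "y": 0.2}
        b = {"x": 0.4, "y": 0.6}
        avg = average_importances([a, b])
        assert list(avg) == ["x", "y"]
        assert avg["x"] == pytest.approx(0.6)
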