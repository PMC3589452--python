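"""Length normalisation, log/Z transforms, imputation, and ΔZ calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import corequant as cq
from corequant.matrix import AbundanceMatrix, LevelError
from corequant.quantification import (
    ZPolicy,
    call_significance,
    impute_missing,
    log_transform,
    normalize_by_length,
    stage_aggregate,
    zscore_rows,
)


def matrix_from(values, level, samples=None):
    samples = samples or [f"s{i}" for i in range(np.asarray(values).shape[1])]
    frame = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=[f"p{i}" for i in range(np.asarray(values).shape[0])],
        columns=samples,
    )
    return AbundanceMatrix(frame, level=level)


class TestNormalizeAndLog:
    def test_hand_division_fixture(self, toy_catalog):
        counts = matrix_from([[10, np.nan], [40, 200], [5, 1]], "counts")
        counts.values.index = ["p1", "p2", "p3"]
        counts.missing_mask.index = ["p1", "p2", "p3"]
        norm = normalize_by_length(counts, toy_catalog)  # lengths 100, 200, 50
        expected = [[0.1, np.nan], [0.2, 1.0], [0.1, 0.02]]
        np.testing.assert_allclose(norm.values.to_numpy(), expected)
        assert norm.level == "normalized"
        assert bool(norm.missing_mask.loc["p1", "s1"]) is True

    def test_log10_known_values(self):
        m = matrix_from([[1.0, 0.1, 100.0]], "normalized")
        logged = log_transform(m)
        np.testing.assert_allclose(logged.values.to_numpy(), [[0.0, -1.0, 2.0]])

    def test_nonpositive_value_rejected(self):
        m = matrix_from([[0.0, 1.0]], "normalized")
        with pytest.raises(ValueError, match="positive"):
            log_transform(m)

    def test_level_order_is_enforced(self):
        counts = matrix_from([[1, 2]], "counts")
        with pytest.raises(LevelError):
            log_transform(counts)  # skipped normalisation
        with pytest.raises(LevelError):
            zscore_rows(counts)
        with pytest.raises(LevelError):
            impute_missing(matrix_from([[0.1, 0.2]], "log"))


class TestZScores:
    def test_1_2_3_row(self):
        z = zscore_rows(matrix_from([[1.0, 2.0, 3.0]], "log"))
        np.testing.assert_allclose(z.values.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_literal_sign_inverts(self):
        z = zscore_rows(matrix_from([[1.0, 2.0, 3.0]], "log"), ZPolicy(sign="literal"))
        np.testing.assert_allclose(z.values.to_numpy(), [[1.0, 0.0, -1.0]])

    def test_population_sd_mode(self):
        z = zscore_rows(matrix_from([[1.0, 2.0, 3.0]], "log"), ZPolicy(sd_mode="population"))
        sd = np.std([1, 2, 3])
        np.testing.assert_allclose(z.values.to_numpy(), [[-1 / sd, 0.0, 1 / sd]])

    def test_constant_row_maps_to_zero(self):
        z = zscore_rows(matrix_from([[2.0, 2.0, 2.0]], "log"))
        np.testing.assert_allclose(z.values.to_numpy(), 0.0)

    def test_fixture_matches_independent_computation(self):
        rng = np.random.default_rng(42)
        raw = rng.normal(size=(5, 9))
        z = zscore_rows(matrix_from(raw, "log"))
        for i in range(5):
            row = raw[i]
            expect = (row - row.mean()) / row.std(ddof=1)
            np.testing.assert_allclose(z.values.to_numpy()[i], expect, atol=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_fully_observed_rows_have_mean0_sd1(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.normal(size=(6, 7))
        raw[0] = raw[0, 0]  # one constant row allowed: maps to zeros
        z = zscore_rows(matrix_from(raw, "log")).values.to_numpy()
        for row in z[1:]:
            assert abs(row.mean()) < 1e-9
            assert abs(row.std(ddof=1) - 1.0) < 1e-9


class TestImputation:
    def test_quoted_rule_arithmetic(self):
        # global min -2.4 and max 2.1; the gapped row's missing cell becomes
        # -2.4/1.5 = -1.6 and its observed cells 2.1*1.5 = 3.15
        z = matrix_from([[-2.4, 0.0, 2.1], [0.5, np.nan, 1.0]], "zscore")
        imp = impute_missing(z)
        np.testing.assert_allclose(
            imp.values.to_numpy(), [[-2.4, 0.0, 2.1], [3.15, -1.6, 3.15]]
        )
        assert imp.level == "zscore_imputed"
        # the mask still records the original observation pattern
        assert bool(imp.missing_mask.loc["p1", "s1"]) is True

    def test_no_missing_is_identity(self):
        z = matrix_from([[-1.0, 0.0, 1.0], [0.3, -0.3, 0.0]], "zscore")
        np.testing.assert_allclose(impute_missing(z).values, z.values)

    def test_four_by_three_hand_fixture(self):
        z = matrix_from(
            [
                [-2.0, 0.0, 2.0],
                [np.nan, 0.5, -0.5],
                [1.0, np.nan, np.nan],
                [0.1, 0.2, -0.1],
            ],
            "zscore",
        )
        imp = impute_missing(z).values.to_numpy()
        low, high = -2.0 / 1.5, 2.0 * 1.5
        np.testing.assert_allclose(
            imp,
            [
                [-2.0, 0.0, 2.0],
                [low, high, high],
                [high, low, low],
                [0.1, 0.2, -0.1],
            ],
        )

    def test_literal_rule_shrinks_negative_minimum(self):
        # documented behaviour: with min < 0, |min/1.5| < |min|, so the
        # imputed-low value sits strictly inside the observed range
        z = matrix_from([[-3.0, 0.0, 3.0], [np.nan, 1.0, 1.5]], "zscore")
        imp = impute_missing(z)
        low = imp.values.loc["p1", "s0"]
        assert low == -2.0
        assert low > -3.0  # NOT pushed below the observed minimum

    def test_all_missing_matrix_rejected(self):
        z = matrix_from([[np.nan, np.nan]], "zscore")
        with pytest.raises(ValueError):
            impute_missing(z)

    def test_extremes_computed_before_any_assignment(self):
        # two gapped rows: both must use the pre-imputation extremes, not
        # values written while imputing the other row
        z = matrix_from([[np.nan, -1.0, 1.0], [2.0, np.nan, -2.0]], "zscore")
        imp = impute_missing(z).values.to_numpy()
        np.testing.assert_allclose(
            imp, [[-2.0 / 1.5, 3.0, 3.0], [3.0, -2.0 / 1.5, 3.0]]
        )


class TestStageAggregationAndCalls:
    def test_stage_means(self):
        z = matrix_from([[1.0, 2.0, 3.0, 5.0]], "zscore_imputed", ["a", "b", "c", "d"])
        stages = stage_aggregate(
            z, {"a": "early", "b": "early", "c": "early", "d": "late"}, ["early", "late"]
        )
        assert stages.loc["p0", "early"] == 2.0
        assert stages.loc["p0", "late"] == 5.0  # single-sample stage passes through

    def test_empty_stage_rejected(self):
        z = matrix_from([[1.0, 2.0]], "zscore_imputed", ["a", "b"])
        with pytest.raises(ValueError, match="middle"):
            stage_aggregate(z, {"a": "early", "b": "early"}, ["early", "middle"])

    def test_unassigned_sample_rejected(self):
        z = matrix_from([[1.0, 2.0]], "zscore_imputed", ["a", "b"])
        with pytest.raises(ValueError, match="without a stage"):
            stage_aggregate(z, {"a": "early"}, ["early"])

    def test_delta_threshold_rule(self):
        stage_matrix = pd.DataFrame(
            {
                "early": [1.2, 0.0, 0.0],
                "middle": [-0.9, 2.0, 0.5],
                "late": [-0.9, 2.0, 2.5],
            },
            index=["pA", "pB", "pC"],
        )
        calls = call_significance(stage_matrix).set_index(["protein_id", "stage_from"])
        a = calls.loc[("pA", "early")]
        assert a["delta_z"] == pytest.approx(-2.1)
        assert a["direction"] == "decreased" and bool(a["significant"])
        b = calls.loc[("pB", "early")]  # exactly 2.0 is inclusive
        assert b["delta_z"] == pytest.approx(2.0) and bool(b["significant"])
        c = calls.loc[("pC", "middle")]
        assert c["delta_z"] == pytest.approx(2.0) and c["direction"] == "increased"
        # adjacent pairs only: early->late never appears
        assert set(calls.reset_index()["stage_from"]) == {"early", "middle"}

    def test_ten_protein_fixture_matches_hand_rule(self):
        rng = np.random.default_rng(7)
        stage_matrix = pd.DataFrame(
            rng.uniform(-3, 3, size=(10, 3)),
            columns=["early", "middle", "late"],
            index=[f"p{i}" for i in range(10)],
        )
        calls = call_significance(stage_matrix)
        for r in calls.itertuples(index=False):
            expect = stage_matrix.loc[r.protein_id, r.stage_to] - stage_matrix.loc[
                r.protein_id, r.stage_from
            ]
            assert r.delta_z == pytest.approx(expect)
            assert r.significant == (abs(expect) >= 2.0)

    def test_heuristic_p_is_optional_and_monotone(self):
        stage_matrix = pd.DataFrame(
            {"early": [0.0, 0.0], "middle": [1.0, 3.0]}, index=["a", "b"]
        )
        calls = call_significance(stage_matrix, heuristic_p=True)
        assert "p_heuristic" in calls
        p = calls.set_index("protein_id")["p_heuristic"]
        assert p["b"] < p["a"]


def test_quantify_composes_in_sklearn_pipeline(toy_catalog):
    from sklearn.pipeline import Pipeline

    counts = matrix_from([[10, 20, np.nan], [40, 10, 30], [5, 5, 5]], "counts")
    counts.values.index = ["p1", "p2", "p3"]
    counts.missing_mask.index = ["p1", "p2", "p3"]
    pipe = Pipeline(
        [
            ("norm", cq.LengthNormalizer(toy_catalog)),
            ("log", cq.LogTransformer()),
            ("z", cq.RowZScorer()),
            ("impute", cq.ExtremeValueImputer()),
        ]
    )
    out = pipe.fit_transform(counts)
    direct = cq.quantify(counts, toy_catalog)
    np.testing.assert_allclose(out.values.to_numpy(), direct.values.to_numpy())
    assert out.level == "zscore_imputed"
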