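"""Predictor binarization, coverage, accuracy and aggregation."""

import numpy as np
import pandas as pd
import pytest

from curagap.classify import PathogenicityCall, RuleConfig
from curagap.predict import (
    ALGORITHMS,
    aggregate_accuracy,
    binarize_prediction,
    cadd_band_report,
    prediction_accuracy,
    prediction_coverage,
    round_half_up_pct,
)
from curagap.synth import GroundTruth, synth_predictor_scores


@pytest.mark.parametrize(
    "alg, value, expected",
    [
        ("sift", "deleterious", "pathogenic"),
        ("sift", "tolerated", "benign"),
        ("sift", None, "none"),
        ("polyphen2", "probably_damaging", "pathogenic"),
        ("polyphen2", "possibly_damaging", "pathogenic"),
        ("polyphen2", "benign", "benign"),
        ("mutation_taster2", "disease_causing", "pathogenic"),
        ("mutation_taster2", "polymorphism", "benign"),
        ("mutation_assessor", "high", "pathogenic"),
        ("mutation_assessor", "medium", "pathogenic"),
        ("mutation_assessor", "low", "benign"),
        ("mutation_assessor", "neutral", "benign"),
        ("provean", -2.5, "pathogenic"),
        ("provean", -2.4, "benign"),
        ("cadd", 25.0, "pathogenic"),
        ("cadd", 20.0, "pathogenic"),  # boundary tie-break: equal is pathogenic
        ("cadd", 19.99, "benign"),
        ("cadd", float("nan"), "none"),
    ],
)
def test_binarization(alg, value, expected):
    assert binarize_prediction(alg, value) == expected


def test_possibly_damaging_grouping_is_configurable():
    rules = RuleConfig(polyphen_possibly_is_pathogenic=False)
    assert binarize_prediction("polyphen2", "possibly_damaging", rules) == "benign"


def test_unknown_algorithm_rejected():
    with pytest.raises(ValueError):
        binarize_prediction("revel", 0.9)


def _scores(rows: dict) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index")
    for alg in ALGORITHMS:
        if alg not in df.columns:
            df[alg] = np.nan
    return df


def _calls(tiers: dict) -> dict:
    return {u: PathogenicityCall(t) for u, t in tiers.items()}


class TestCoverage:
    def test_three_of_ten(self):
        rows = {f"v{i}": {"sift": "deleterious"} for i in range(3)}
        rows.update({f"v{i}": {} for i in range(3, 10)})
        cov = prediction_coverage(_scores(rows), [f"v{i}" for i in range(10)])
        assert cov["sift"] == pytest.approx(0.30)
        assert cov["cadd"] == 0.0

    def test_empty_denominator_rejected(self):
        with pytest.raises(ValueError):
            prediction_coverage(_scores({"v": {}}), [])

    def test_coverage_dilutes_with_unscored_variants(self):
        rows = {f"v{i}": {"cadd": 30.0} for i in range(4)}
        small = prediction_coverage(_scores(rows), list(rows))
        bigger = prediction_coverage(_scores(rows), list(rows) + ["w1", "w2"])
        assert bigger["cadd"] < small["cadd"]


class TestAccuracy:
    def test_perfect_predictions(self):
        rows = {"a": {"sift": "deleterious"}, "b": {"sift": "tolerated"}}
        calls = _calls({"a": "Pathogenic", "b": "Benign"})
        acc = prediction_accuracy(_scores(rows), calls)
        assert acc.loc["sift", "accuracy_overall"] == 1.0
        assert acc.loc["sift", "accuracy_pathogenic"] == 1.0
        assert acc.loc["sift", "accuracy_benign"] == 1.0

    def test_vus_excluded_from_accuracy_but_not_coverage(self):
        rows = {"a": {"sift": "deleterious"}, "b": {"sift": "deleterious"}}
        calls = _calls({"a": "Pathogenic", "b": "VUS"})
        acc = prediction_accuracy(_scores(rows), calls)
        assert acc.loc["sift", "n_scored"] == 2
        assert acc.loc["sift", "n_evaluable"] == 1
        assert acc.loc["sift", "accuracy_overall"] == 1.0

    def test_planted_rates_recovered_at_scale(self):
        """Coverage 0.4 / accuracy 0.75 planted on 2000 variants come back."""
        n = 2000
        truth = GroundTruth(
            variants=pd.DataFrame({
                "tier": ["Pathogenic"] * (n // 2) + ["Benign"] * (n // 2),
                "super_class": ["pathogenic"] * (n // 2) + ["benign"] * (n // 2),
                "region": ["exonic"] * n,
                "width": ["SNV"] * n,
            }, index=[f"v{i}" for i in range(n)]),
            keys={}, mention_to_uid={}, alt_models=[],
        )
        cov = {a: 0.4 for a in ALGORITHMS}
        acc_in = {a: (0.75, 0.75) for a in ALGORITHMS}
        scores, planted = synth_predictor_scores(truth, coverage=cov,
                                                 accuracy=acc_in, seed=2)
        calls = _calls(dict(truth.variants["tier"]))
        cov_out = prediction_coverage(scores, list(truth.variants.index))
        acc_out = prediction_accuracy(scores, calls)
        for alg in ("sift", "provean", "cadd"):
            assert cov_out[alg] == pytest.approx(0.4, abs=3 * np.sqrt(0.4 * 0.6 / n))
            n_eval = acc_out.loc[alg, "n_evaluable"]
            assert acc_out.loc[alg, "accuracy_overall"] == pytest.approx(
                0.75, abs=3 * np.sqrt(0.75 * 0.25 / n_eval))
        # planted bookkeeping agrees with the evaluation path
        assert planted["sift_scored"].sum() == acc_out.loc["sift", "n_scored"]


class TestCaddBands:
    def test_counts_strictly_above_cutoffs(self):
        rows = {f"v{i}": {"cadd": s} for i, s in enumerate([5.0, 15.0, 25.0, 35.0])}
        calls = _calls({f"v{i}": "Pathogenic" for i in range(4)})
        rep = cadd_band_report(_scores(rows), calls, (10, 20, 30))
        assert list(rep["n_above"]) == [3, 2, 1]
        assert rep.loc[30, "pathogenic_fraction"] == 1.0

    def test_unsorted_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            cadd_band_report(_scores({"v": {"cadd": 5.0}}), _calls({"v": "Benign"}),
                             (30, 10))


class TestAggregate:
    def test_single_correct_algorithm_counts(self):
        rows = {"a": {"sift": "deleterious"}}
        agg = aggregate_accuracy(_scores(rows), _calls({"a": "Pathogenic"}))
        assert agg["n_any_accurate"] == 1
        assert agg["any_accurate"] + agg["no_accurate"] == pytest.approx(1.0)

    def test_solely_cadd_definition(self):
        rows = {
            "a": {"cadd": 30.0, "sift": "tolerated"},  # CADD right, SIFT wrong
            "b": {"cadd": 30.0, "sift": "deleterious"},  # both right
            "c": {"cadd": 5.0},  # CADD wrong, rest absent
        }
        calls = _calls({"a": "Pathogenic", "b": "Pathogenic", "c": "Pathogenic"})
        agg = aggregate_accuracy(_scores(rows), calls)
        assert agg["n_solely_cadd"] == 1
        assert agg["n_any_accurate"] == 2
        assert agg["no_accurate"] == pytest.approx(1 / 3)

    def test_perfect_accuracy_reduces_to_coverage_union(self):
        """With accuracy 1, any-accurate equals having >= 1 score (exact)."""
        n = 400
        truth = GroundTruth(
            variants=pd.DataFrame({
                "tier": ["Pathogenic", "Benign"] * (n // 2),
                "super_class": ["pathogenic", "benign"] * (n // 2),
                "region": ["exonic"] * n,
                "width": ["SNV"] * n,
            }, index=[f"v{i}" for i in range(n)]),
            keys={}, mention_to_uid={}, alt_models=[],
        )
        cov = {a: 0.3 for a in ALGORITHMS}
        acc = {a: (1.0, 1.0) for a in ALGORITHMS}
        scores, planted = synth_predictor_scores(truth, coverage=cov, accuracy=acc,
                                                 seed=3)
        calls = _calls(dict(truth.variants["tier"]))
        agg = aggregate_accuracy(scores, calls)
        union = planted[[f"{a}_scored" for a in ALGORITHMS]].any(axis=1).mean()
        assert agg["any_accurate"] == pytest.approx(float(union))

    def test_zero_coverage_means_no_accurate(self):
        truth = GroundTruth(
            variants=pd.DataFrame({
                "tier": ["Pathogenic"], "super_class": ["pathogenic"],
                "region": ["exonic"], "width": ["SNV"],
            }, index=["v0"]),
            keys={}, mention_to_uid={}, alt_models=[],
        )
        scores, _ = synth_predictor_scores(
            truth, coverage={a: 0.0 for a in ALGORITHMS},
            accuracy={a: (1.0, 1.0) for a in ALGORITHMS}, seed=1)
        agg = aggregate_accuracy(scores, _calls({"v0": "Pathogenic"}))
        assert agg["no_accurate"] == 1.0


@pytest.mark.parametrize("fraction, pct", [
    (0.757, 76), (0.755, 76), (0.754, 75), (0.005, 1), (0.0049, 0), (1.0, 100),
])
def test_round_half_up_matches_reporting_style(fraction, pct):
    assert round_half_up_pct(fraction) == pct
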