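"""Benchmarking in-silico impact predictors against curated tiers.

Scores are ingested, never computed: a table keyed by variant uid carries
categorical calls from SIFT, PolyPhen2, MutationTaster2, MutationAssessor,
a numeric PROVEAN score, and a CADD phred score.  Each is binarized to
pathogenic/benign/none; coverage, accuracy (split by curated super-class),
CADD cutoff banding and cross-algorithm aggregation follow.

Accuracy denominators exclude VUS/Unassigned variants (there is no truth to
match), while coverage denominators include every curated variant.
Percentages destined for integer-style reporting use round-half-up.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .classify import RuleConfig, super_class

__all__ = [
    "ALGORITHMS",
    "binarize_prediction",
    "binarize_table",
    "prediction_coverage",
    "prediction_accuracy",
    "cadd_band_report",
    "aggregate_accuracy",
    "round_half_up_pct",
]

ALGORITHMS = ("sift", "polyphen2", "mutation_taster2", "mutation_assessor",
              "provean", "cadd")

_CATEGORICAL = {
    "sift": {"deleterious": "pathogenic", "tolerated": "benign"},
    "mutation_taster2": {"disease_causing": "pathogenic", "polymorphism": "benign"},
    "mutation_assessor": {"high": "pathogenic", "medium": "pathogenic",
                          "low": "benign", "neutral": "benign"},
}

PROVEAN_DELETERIOUS_MAX = -2.5


def round_half_up_pct(fraction: float) -> int:
    """Integer percent, round-half-up (the reporting style of the source tables)."""
    if fraction is None or (isinstance(fraction, float) and math.isnan(fraction)):
        return 0
    return int(math.floor(fraction * 100 + 0.5))


def _is_absent(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and (not value.strip() or value.lower() in ("na", "nan", "none", ".")):
        return True
    return False


def binarize_prediction(algorithm: str, value, rules: RuleConfig = RuleConfig()) -> str:
    """Collapse one algorithm's raw output to pathogenic / benign / none."""
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if _is_absent(value):
        return "none"
    if algorithm in _CATEGORICAL:
        mapped = _CATEGORICAL[algorithm].get(str(value).strip().lower())
        if mapped is None:
            raise ValueError(f"unknown {algorithm} call {value!r}")
        return mapped
    if algorithm == "polyphen2":
        v = str(value).strip().lower()
        if v == "probably_damaging":
            return "pathogenic"
        if v == "possibly_damaging":
            return "pathogenic" if rules.polyphen_possibly_is_pathogenic else "benign"
        if v == "benign":
            return "benign"
        raise ValueError(f"unknown polyphen2 call {value!r}")
    if algorithm == "provean":
        return "pathogenic" if float(value) <= PROVEAN_DELETERIOUS_MAX else "benign"
    # cadd: score equal to the cutoff counts as pathogenic (boundary tie-break)
    return "pathogenic" if float(value) >= rules.cadd_cutoff else "benign"


def binarize_table(scores: pd.DataFrame, rules: RuleConfig = RuleConfig()) -> pd.DataFrame:
    """Binarized (pathogenic/benign/none) table, one column per algorithm."""
    out = {}
    for alg in ALGORITHMS:
        col = scores[alg] if alg in scores.columns else pd.Series(np.nan, index=scores.index)
        out[alg] = col.map(lambda v: binarize_prediction(alg, v, rules))
    return pd.DataFrame(out, index=scores.index)


def prediction_coverage(scores: pd.DataFrame, denominator_ids) -> pd.Series:
    """Fraction of the denominator set receiving any value, per algorithm."""
    denominator_ids = list(denominator_ids)
    if not denominator_ids:
        raise ValueError("empty denominator set")
    sub = scores.reindex(denominator_ids)
    cov = {}
    for alg in ALGORITHMS:
        col = sub[alg] if alg in sub.columns else pd.Series(np.nan, index=sub.index)
        cov[alg] = float((~col.map(_is_absent)).mean())
    return pd.Series(cov)


def _super_classes(calls) -> pd.Series:
    return pd.Series({u: super_class(c.tier) for u, c in calls.items()}, dtype=object)


def prediction_accuracy(scores: pd.DataFrame, calls, rules: RuleConfig = RuleConfig(),
                        denominator_ids=None) -> pd.DataFrame:
    """Per-algorithm coverage and accuracy, overall and by curated super-class."""
    ids = list(denominator_ids) if denominator_ids is not None else list(calls.keys())
    binary = binarize_table(scores.reindex(ids), rules)
    truth = _super_classes(calls).reindex(ids)
    rows = []
    for alg in ALGORITHMS:
        pred = binary[alg]
        scored = pred != "none"
        evaluable = scored & truth.notna()
        correct = evaluable & (pred == truth)
        path = truth == "pathogenic"
        ben = truth == "benign"
        n_eval = int(evaluable.sum())
        rows.append({
            "algorithm": alg,
            "n_scored": int(scored.sum()),
            "coverage": float(scored.mean()),
            "n_evaluable": n_eval,
            "accuracy_overall": float(correct.sum() / n_eval) if n_eval else math.nan,
            "accuracy_pathogenic": float(correct[path & evaluable].mean())
            if int((path & evaluable).sum()) else math.nan,
            "accuracy_benign": float(correct[ben & evaluable].mean())
            if int((ben & evaluable).sum()) else math.nan,
        })
    return pd.DataFrame(rows).set_index("algorithm")


def cadd_band_report(scores: pd.DataFrame, calls, cutoffs=(10.0, 20.0, 30.0),
                     denominator_ids=None) -> pd.DataFrame:
    """Counts strictly above each CADD cutoff and the pathogenic-evidence
    fraction among them."""
    if list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    ids = list(denominator_ids) if denominator_ids is not None else list(calls.keys())
    cadd = scores.reindex(ids)["cadd"].astype(float)
    truth = _super_classes(calls).reindex(ids)
    rows = []
    for c in cutoffs:
        above = cadd > c
        n_above = int(above.sum())
        n_path = int((above & (truth == "pathogenic")).sum())
        rows.append({
            "cutoff": float(c),
            "n_above": n_above,
            "n_pathogenic": n_path,
            "pathogenic_fraction": n_path / n_above if n_above else math.nan,
        })
    return pd.DataFrame(rows).set_index("cutoff")


def aggregate_accuracy(scores: pd.DataFrame, calls, rules: RuleConfig = RuleConfig(),
                       denominator_ids=None) -> dict:
    """Cross-algorithm aggregation over the full denominator set.

    A variant counts as accurately predicted if any algorithm's binarized
    call matches its curated super-class; solely-CADD means CADD is correct
    while every other algorithm is absent or incorrect.  Variants without a
    super-class (VUS/Unassigned) can never be accurately predicted and count
    in the denominator, so any-accurate + no-accurate = 1.
    """
    ids = list(denominator_ids) if denominator_ids is not None else list(calls.keys())
    binary = binarize_table(scores.reindex(ids), rules)
    truth = _super_classes(calls).reindex(ids)
    correct = binary.eq(truth, axis=0) & truth.notna().to_numpy()[:, None]
    any_correct = correct.any(axis=1)
    others = [a for a in ALGORITHMS if a != "cadd"]
    solely_cadd = correct["cadd"] & ~correct[others].any(axis=1)
    n = len(ids)
    n_any = int(any_correct.sum())
    # CADD accuracy under the three candidate denominators (the printed
    # number's denominator is ambiguous, so all three are emitted)
    cadd_scored = binary["cadd"] != "none"
    cadd_correct = correct["cadd"]
    n_scored = int(cadd_scored.sum())
    scored_classified = cadd_scored & truth.notna()
    n_sc = int(scored_classified.sum())
    return {
        "n": n,
        "n_any_accurate": n_any,
        "any_accurate": n_any / n if n else math.nan,
        "no_accurate": 1.0 - n_any / n if n else math.nan,
        "n_solely_cadd": int(solely_cadd.sum()),
        "solely_cadd_among_accurate": float(solely_cadd.sum() / n_any) if n_any else math.nan,
        "n_cadd_scored": n_scored,
        "cadd_accuracy_all": float(cadd_correct.sum() / n) if n else math.nan,
        "cadd_accuracy_scored": float(cadd_correct.sum() / n_scored) if n_scored else math.nan,
        "cadd_accuracy_scored_classified": float(cadd_correct[scored_classified].mean())
        if n_sc else math.nan,
    }
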