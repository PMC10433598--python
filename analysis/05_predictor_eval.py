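#!/usr/bin/env python
"""Benchmark the in-silico impact predictors against the curated tiers.

Per-algorithm coverage and accuracy (split by curated super-class), CADD
cutoff banding at 10/20/30, and the cross-algorithm aggregate: how many
variants get an accurate call from anything, and how often CADD is the only
algorithm that gets it right.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from common import INPUTS, RESULTS, load_corpus  # noqa: E402

from curagap.io import read_scores_tsv  # noqa: E402
from curagap.predict import (  # noqa: E402
    aggregate_accuracy,
    cadd_band_report,
    prediction_accuracy,
    prediction_coverage,
)


def main() -> int:
    model, variants, report, calls, classes = load_corpus()
    scores = read_scores_tsv(INPUTS / "scores.tsv")
    uids = [v.uid for v in variants]

    cov = prediction_coverage(scores, uids)
    acc = prediction_accuracy(scores, calls, denominator_ids=uids)
    for alg in acc.index:
        print(f"{alg:>18}: coverage {cov[alg]:.0%}; accuracy "
              f"{acc.loc[alg, 'accuracy_pathogenic']:.0%} pathogenic / "
              f"{acc.loc[alg, 'accuracy_benign']:.0%} benign "
              f"(n={acc.loc[alg, 'n_evaluable']:.0f} evaluable)")
    bands = cadd_band_report(scores, calls, denominator_ids=uids)
    for cut, row in bands.iterrows():
        print(f"CADD > {cut:.0f}: {row['n_above']:.0f} variants, "
              f"{row['pathogenic_fraction']:.0%} with pathogenic evidence")
    agg = aggregate_accuracy(scores, calls, denominator_ids=uids)
    print(f"any algorithm accurate for {agg['any_accurate']:.0%} of the "
          f"{agg['n']} variants; of those, {agg['solely_cadd_among_accurate']:.0%} "
          f"were solely CADD; {agg['no_accurate']:.0%} had no accurate call")
    print(f"CADD accuracy at cutoff 20 under the three denominators: "
          f"{agg['cadd_accuracy_all']:.0%} of all, "
          f"{agg['cadd_accuracy_scored']:.0%} of scored, "
          f"{agg['cadd_accuracy_scored_classified']:.0%} of scored+classified")

    acc.to_csv(RESULTS / "predictor_accuracy.tsv", sep="\t")
    bands.to_csv(RESULTS / "cadd_bands.tsv", sep="\t")
    with open(RESULTS / "predictor_summary.json", "w") as fh:
        json.dump({"coverage": cov.to_dict(), "aggregate": agg}, fh, indent=2,
                  default=float)
    print(f"wrote {RESULTS / 'predictor_accuracy.tsv'}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
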