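#!/usr/bin/env python
"""Assign pathogenicity tiers, variant classes, rescue calls and feature overlap.

Applies the evidence cascade (clinical CTD composite, creatine-uptake
thresholds, segregation, control observations) to every consolidated
variant, labels region and SNV/MNV class, calls chaperone rescue from the
published 4-PBA assay table, and intersects coding variants with annotated
protein feature sites.
"""

import sys
from collections import Counter
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd  # noqa: E402

from common import INPUTS, RESULTS, load_corpus  # noqa: E402

from curagap.classify import (  # noqa: E402
    classify_rescue,
    load_feature_map,
    map_protein_features,
    packaged_rescue_table,
    super_class,
)


def main() -> int:
    model, variants, report, calls, classes = load_corpus()
    point = [v.uid for v in variants if classes[v.uid].region != "large_deletion"]
    tiers = Counter(calls[u].tier for u in point)
    supers = Counter(super_class(calls[u].tier) or "uncertain/none" for u in point)
    print(f"tiers over {len(point)} point variants: {dict(tiers)}")
    print(f"super-classes: {dict(supers)}")
    regions = Counter(classes[v.uid].region for v in variants)
    widths = Counter(classes[v.uid].width for v in variants)
    print(f"regions: {dict(regions)}; widths: {dict(widths)}")

    table = packaged_rescue_table()
    table["call"] = [classify_rescue(r["uptake_before"], r["uptake_after"])
                     for _, r in table.iterrows()]
    n_resc = (table["call"] == "rescued").sum()
    print(f"4-PBA assay table: {n_resc} of {len(table)} variants rescued "
          f"(uptake gain >= 5 percentage points of WT)")
    table.to_csv(RESULTS / "rescue_calls.tsv", sep="\t", index=False)

    fmap = load_feature_map(INPUTS / "feature_map.tsv")
    tags = map_protein_features(variants, fmap)
    hits = {u: t for u, t in tags.items() if t}
    print(f"{len(hits)} variants fall on annotated protein feature sites")
    pd.DataFrame(
        [{"uid": u, "features": ",".join(sorted(t))} for u, t in sorted(hits.items())]
    ).to_csv(RESULTS / "feature_overlap.tsv", sep="\t", index=False)

    rows = [{"uid": u, "tier": calls[u].tier,
             "rules": ";".join(calls[u].fired_rules)} for u in sorted(calls)]
    pd.DataFrame(rows).to_csv(RESULTS / "tier_calls.tsv", sep="\t", index=False)
    print(f"wrote {RESULTS / 'tier_calls.tsv'}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
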