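#!/usr/bin/env python
"""Harmonize the raw mention table onto canonical genomic keys.

Parses every notation dialect, maps to genomic coordinates, 3'-shifts
indels, and consolidates duplicate names of the same alteration.  Reports
the dedup bookkeeping and writes the normalized variant table.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from common import RESULTS, load_corpus, load_model  # noqa: E402

from curagap.io import write_variants_tsv, write_vcf_like  # noqa: E402


def main() -> int:
    model, variants, report, calls, classes = load_corpus()
    print(f"{report.n_raw} raw mentions -> {report.n_unique} unique variants; "
          f"{report.n_duplicates} mentions ({report.duplicate_pct:.0%}) were "
          f"duplicate names of an already-seen alteration")
    if report.unresolved:
        print(f"{len(report.unresolved)} mentions could not be resolved:")
        for mid, reason in report.unresolved:
            print(f"  {mid}: {reason}")
    else:
        print("every mention resolved to a genomic key")
    multi = [v for v in variants if len(v.aliases) > 1]
    print(f"{len(multi)} variants were published under more than one notation; "
          "examples:")
    for v in multi[:3]:
        print(f"  {v.canonical_chgvs or v.uid}  <-  {sorted(v.aliases)}")
    write_variants_tsv(variants, calls, classes, RESULTS / "variants.tsv")
    write_vcf_like(variants, model, RESULTS / "variants_vcf_like.tsv")
    print(f"wrote {RESULTS / 'variants.tsv'}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
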