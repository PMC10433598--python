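#!/usr/bin/env python
"""Generate the synthetic study inputs with planted ground truth.

Writes under results/synth/: the gene model (TSV + FASTA), the 210-mention
corpus with 12% alias mentions, database exports (LOVD/ClinVar TSV,
dbSNP/gnomAD/1000G VCF) and the predictor score table, plus the ground-truth
table the later drivers can be checked against.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np  # noqa: E402

from curagap.classify import packaged_feature_map  # noqa: E402
from curagap.gene_model import write_gene_model  # noqa: E402
from curagap.io import write_mentions_tsv, write_scores_tsv  # noqa: E402
from curagap.synth import (  # noqa: E402
    CorpusSpec,
    synth_corpus,
    synth_db_exports,
    synth_gene_model,
    synth_predictor_scores,
)

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import INPUTS  # noqa: E402


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=4)]

    INPUTS.mkdir(parents=True, exist_ok=True)
    model = synth_gene_model(sub[0])
    print(f"gene model: {len(model.exons)} exons, cDNA {model.tx_length} bp, "
          f"CDS c.{model.cds_start_cdna}..c.{model.cds_end_cdna}")
    write_gene_model(model, INPUTS / "gene_model.tsv", INPUTS / "gene_model.fa")

    spec = CorpusSpec(seed=sub[1])
    mentions, truth = synth_corpus(model, spec)
    for i, am in enumerate(truth.alt_models):
        write_gene_model(am, INPUTS / f"gene_model_alt{i}.tsv")
    write_mentions_tsv(mentions, INPUTS / "mentions.tsv")
    truth.variants.to_csv(INPUTS / "ground_truth.tsv", sep="\t")
    n_alias = int(truth.variants["n_alias_mentions"].sum())
    print(f"corpus: {len(mentions)} mentions, {truth.n_unique} unique variants, "
          f"{n_alias} alias mentions planted "
          f"({n_alias / len(mentions):.0%} of the raw list)")

    synth_db_exports(truth, model, INPUTS / "db", seed=sub[2])
    scores, _ = synth_predictor_scores(truth, seed=sub[3])
    write_scores_tsv(scores, INPUTS / "scores.tsv")

    fmap = packaged_feature_map()
    with open(INPUTS / "feature_map.tsv", "w") as fh:
        fh.write("residue\tfeature\n")
        for r in sorted(fmap):
            fh.write(f"{r}\t{fmap[r]}\n")
    print(f"wrote database exports, predictor scores and a {len(fmap)}-site "
          f"protein feature map under {INPUTS}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
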