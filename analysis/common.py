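"""Shared plumbing for the numbered analysis drivers.

Each driver is re-runnable on its own: it reloads the synthetic inputs
written by ``01_simulate.py`` and recomputes the upstream stages it needs
(everything is fast enough that no intermediate pickles are worth the
staleness risk).
"""

from pathlib import Path

from curagap.classify import assign_pathogenicity, classify_variant_class
from curagap.gene_model import read_gene_model
from curagap.harmonize import consolidate_mentions
from curagap.io import read_mentions_tsv

RESULTS = Path(__file__).resolve().parents[1] / "results"
INPUTS = RESULTS / "synth"

DB_DIALECTS = {"LOVD": "tsv_lovd", "ClinVar": "tsv_lovd",
               "dbSNP": "vcf", "gnomAD": "vcf", "1000G": "vcf"}


def load_model():
    model = read_gene_model(INPUTS / "gene_model.tsv", INPUTS / "gene_model.fa")
    alts = [read_gene_model(p, INPUTS / "gene_model.fa")
            for p in sorted(INPUTS.glob("gene_model_alt*.tsv"))]
    return model, alts


def load_corpus():
    model, alts = load_model()
    mentions = read_mentions_tsv(INPUTS / "mentions.tsv")
    variants, report = consolidate_mentions(mentions, model, alts)
    calls = {v.uid: assign_pathogenicity(v.evidence) for v in variants}
    classes = {v.uid: classify_variant_class(v, model) for v in variants}
    return model, variants, report, calls, classes


def db_paths():
    return {name: (INPUTS / "db" / (name + (".tsv" if d.startswith("tsv") else ".vcf")), d)
            for name, d in DB_DIALECTS.items()}
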