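"""Synthetic corpora with planted ground truth.

Everything the pipeline consumes can be generated here with known truth:
a random single-transcript gene model, a mention corpus whose alias mentions
are rewritten in alternate notation dialects, tier-consistent evidence,
database exports with per-stratum presence probabilities, and predictor
score tables with per-algorithm coverage/accuracy.

The default parameters emulate the curated CTD/SLC6A8 corpus this package
analyzes: 210 raw mentions of which 12% are duplicate names (=> 185 unique
variants), 4 large deletions, a 116/63/2 exonic/intronic/UTR split and
147 SNVs, tier mix 92 pathogenic-or-likely / 68 benign-or-likely / 21
uncertain among the 181 point variants, database presence rates matching
the published per-database overlap figures, and the published per-algorithm
prediction coverage/accuracy rates.  All randomness flows from integer
seeds through numpy Generators; nothing depends on hash ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import EvidenceBundle, super_class
from .gene_model import CdnaPosition, GeneModel, build_gene_model, revcomp
from .harmonize import (
    GenomicKey,
    NormalizedVariant,
    RawVariantMention,
    normalize_variant,
    resolve_protein_notation,
)
from .notation import parse_notation

__all__ = [
    "CorpusSpec",
    "GroundTruth",
    "synth_gene_model",
    "synth_corpus",
    "synth_evidence",
    "synth_db_exports",
    "synth_predictor_scores",
    "DEFAULT_PRESENCE",
    "DEFAULT_COVERAGE",
    "DEFAULT_ACCURACY",
    "DEFAULT_CADD_BANDS",
]


# --------------------------------------------------------------- corpus spec
def _default_class_mix() -> dict:
    return {"exonic": 116 / 185, "intronic": 63 / 185, "utr": 2 / 185,
            "large_deletion": 4 / 185}


def _default_tier_mix() -> dict:
    return {"pathogenic": 92 / 181, "benign": 68 / 181, "vus": 21 / 181}


@dataclass
class CorpusSpec:
    n_mentions: int = 210
    alias_rate: float = 0.12
    class_mix: dict = field(default_factory=_default_class_mix)
    snv_fraction: float = 147 / 185
    tier_mix: dict = field(default_factory=_default_tier_mix)
    likely_pathogenic_fraction: float = 0.3
    likely_benign_fraction: float = 0.2
    alt_numbering_offset_aa: int = 115
    seed: int = 0

    def __post_init__(self) -> None:
        for mix in (self.class_mix, self.tier_mix):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("mix fractions must sum to 1")


@dataclass
class GroundTruth:
    variants: pd.DataFrame  # index uid: tier, super_class, region, width, kind...
    keys: dict
    mention_to_uid: dict
    alt_models: list

    @property
    def n_unique(self) -> int:
        return len(self.variants)


def _allocate(n: int, fracs: dict) -> dict:
    """Largest-remainder integer allocation of n among categories."""
    raw = {k: n * f for k, f in fracs.items()}
    out = {k: int(v) for k, v in raw.items()}
    short = n - sum(out.values())
    order = sorted(fracs, key=lambda k: (-(raw[k] - out[k]), k))
    for k in order[:short]:
        out[k] += 1
    return out


# ----------------------------------------------------------------- gene model
def synth_gene_model(seed: int, n_exons: int = 13,
                     exon_len_range=(120, 220), intron_len_range=(80, 300),
                     strand: str = "+", chromosome: str = "chrX",
                     build_label: str = "synthetic-1",
                     g_offset: int = 100_000) -> GeneModel:
    """Random but reproducible single-transcript gene model with sequence.

    Shaped loosely on the creatine transporter transcript: ~13 exons, a
    cDNA in the low kilobases, modest UTRs at either end.
    """
    if exon_len_range[0] < 1 or intron_len_range[0] < 1:
        raise ValueError("length ranges must be positive")
    rng = np.random.default_rng(seed)
    exon_lens = rng.integers(exon_len_range[0], exon_len_range[1] + 1, n_exons)
    intron_lens = (rng.integers(intron_len_range[0], intron_len_range[1] + 1,
                                n_exons - 1) if n_exons > 1 else np.array([], dtype=int))
    exons = []
    g = g_offset + 1
    for i, L in enumerate(exon_lens):
        exons.append((g, g + int(L) - 1))
        g += int(L)
        if i < n_exons - 1:
            g += int(intron_lens[i])
    span_len = exons[-1][1] - exons[0][0] + 1
    seq = "".join(rng.choice(list("ACGT"), span_len))
    tx_len = int(exon_lens.sum())
    cds_start = min(90, max(1, tx_len // 10))
    tail = min(60, max(0, tx_len - cds_start - 3))
    cds_len = 3 * ((tx_len - tail - cds_start + 1) // 3)
    cds_end = cds_start + cds_len - 1
    return build_gene_model(
        exons, strand=strand, cds_start_cdna=cds_start, cds_end_cdna=cds_end,
        sequence=seq, gene_symbol="SYNGENE", chromosome=chromosome,
        build_label=build_label,
    )


# ------------------------------------------------------------------ evidence
def synth_evidence(tier: str, rng) -> list:
    """Evidence bundles that the rule cascade maps back onto ``tier``.

    Pathogenic: strongly impaired uptake (<60% WT) plus the full clinical
    composite; LikelyPathogenic: uptake in the 60-70 band only; Benign:
    near-wild-type uptake or control-population observations; LikelyBenign:
    non-segregation; VUS: explicitly conflicting reports plus a benign-side
    functional bundle; Unassigned: nothing.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if tier == "Pathogenic":
        u = float(rng.uniform(0, 60))
        b = EvidenceBundle(phenotype="yes", mrs_creatine_absent=True,
                           elevated_cr_crn=True, uptake_pct_wt=u)
        if rng.random() < 0.25:
            before = min(u, 25.0)
            after = before + (float(rng.uniform(10, 40)) if rng.random() < 0.5 else 0.0)
            b = replace(b, pba_uptake_before=before, pba_uptake_after=after)
        return [b]
    if tier == "LikelyPathogenic":
        return [EvidenceBundle(uptake_pct_wt=float(rng.uniform(60, 69.9)))]
    if tier == "Benign":
        if rng.random() < 0.5:
            return [EvidenceBundle(uptake_pct_wt=float(rng.uniform(75, 110)))]
        if rng.random() < 0.5:
            return [EvidenceBundle(unaffected_males=int(rng.integers(1, 6)))]
        cohort = int(rng.integers(100, 500))
        return [EvidenceBundle(control_count=int(rng.integers(1, 31)),
                               control_cohort=cohort)]
    if tier == "LikelyBenign":
        return [EvidenceBundle(segregates="no")]
    if tier == "VUS":
        return [
            EvidenceBundle(phenotype="yes", mrs_creatine_absent=True,
                           elevated_cr_crn=True, conflicting_reports=True),
            EvidenceBundle(uptake_pct_wt=float(rng.uniform(75, 110))),
        ]
    if tier == "Unassigned":
        return []
    raise ValueError(f"unknown tier {tier!r}")


# --------------------------------------------------------- notation helpers
def _comp(b: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A"}[b]


def _tx_bases(model: GeneModel, s: int, e: int) -> str:
    seg = "".join(model.base_at(p) for p in range(s, e + 1))
    return seg if model.strand == "+" else revcomp(seg)


def _intron_info(model: GeneModel, gpos: int):
    """(intron index, donor offset, acceptor offset) for an intronic position."""
    pos = model.genomic_to_cdna(gpos)
    if pos.intron_offset == 0:
        raise ValueError("not intronic")
    # find which intron by scanning donors
    for i in range(1, model.n_introns + 1):
        donor_g = model.tx_to_genomic(model.tx_exon_bounds(i)[1])
        acceptor_g = model.tx_to_genomic(model.tx_exon_bounds(i + 1)[0])
        lo, hi = sorted((donor_g, acceptor_g))
        if lo < gpos < hi:
            d_up = abs(gpos - donor_g)
            d_down = abs(acceptor_g - gpos)
            return i, d_up, d_down
    raise ValueError("intron not found")


def _format_sub_cdna(model: GeneModel, g: int, alt_t: str, anchor: str = "nearest") -> str:
    """c. notation of a substitution at genomic g, choosing the intron anchor."""
    ref_t = model.tx_base_at(g)
    pos = model.genomic_to_cdna(g)
    if pos.intron_offset != 0 and anchor != "nearest":
        i, d_up, d_down = _intron_info(model, g)
        if anchor == "donor":
            base = model.tx_to_cdna(model.tx_exon_bounds(i)[1])
            pos = replace(base, intron_offset=d_up)
        else:
            base = model.tx_to_cdna(model.tx_exon_bounds(i + 1)[0])
            pos = replace(base, intron_offset=-d_down)
    return f"c.{pos}{ref_t}>{alt_t}"


def _format_sub_genomic(model: GeneModel, g: int, alt_t: str) -> str:
    ref_g = model.base_at(g)
    alt_g = alt_t if model.strand == "+" else _comp(alt_t)
    return f"{model.chromosome}:g.{g}{ref_g}>{alt_g}"


def _format_ivs(model: GeneModel, g: int, alt_t: str, rng) -> str:
    i, d_up, d_down = _intron_info(model, g)
    ref_t = model.tx_base_at(g)
    if rng.random() < 0.5:
        return f"IVS{i}+{d_up} {ref_t} > {alt_t}"
    return f"IVS{i}-{d_down} {ref_t} > {alt_t}"


# ------------------------------------------------------------------- corpus
class _VariantDraft:
    __slots__ = ("nv", "notation", "region", "width", "tier", "g_anchor", "alt_t",
                 "aliases_possible")

    def __init__(self, nv, notation, region, width, g_anchor=None, alt_t=None):
        self.nv = nv
        self.notation = notation
        self.region = region
        self.width = width
        self.g_anchor = g_anchor
        self.alt_t = alt_t
        self.tier = None
        self.aliases_possible = []


def _draw_snv(model: GeneModel, region: str, rng, used_keys: set) -> _VariantDraft:
    for _ in range(200):
        if region == "exonic":
            t = int(rng.integers(model.cds_start_cdna, model.cds_end_cdna + 1))
            g = model.tx_to_genomic(t)
        elif region == "utr":
            if rng.random() < 0.5 and model.cds_start_cdna > 1:
                t = int(rng.integers(1, model.cds_start_cdna))
            else:
                t = int(rng.integers(model.cds_end_cdna + 1, model.tx_length + 1))
            g = model.tx_to_genomic(t)
        else:  # intronic
            i = int(rng.integers(1, model.n_introns + 1))
            L = model.intron_length(i)
            d = int(rng.integers(1, L))
            donor_g = model.tx_to_genomic(model.tx_exon_bounds(i)[1])
            g = donor_g + d if model.strand == "+" else donor_g - d
        ref_t = model.tx_base_at(g)
        alt_t = str(rng.choice([b for b in "ACGT" if b != ref_t]))
        notation = _format_sub_cdna(model, g, alt_t)
        nv = normalize_variant(parse_notation(notation), model)
        if nv.uid in used_keys:
            continue
        return _VariantDraft(nv, notation, region, "SNV", g_anchor=g, alt_t=alt_t)
    raise RuntimeError("could not place a unique SNV; model too small for the corpus")


def _draw_mnv(model: GeneModel, region: str, rng, used_keys: set) -> _VariantDraft:
    for _ in range(200):
        k = int(rng.integers(2, 6))
        op = "dup" if rng.random() < 0.5 else "del"
        if region in ("exonic", "utr"):
            if region == "exonic":
                t1 = int(rng.integers(model.cds_start_cdna, model.cds_end_cdna - k + 2))
            else:
                t1 = int(rng.integers(1, max(2, model.cds_start_cdna - k)))
            # keep the segment inside one exon so the printed range is simple
            e1 = model._tx_exon_index_of(t1)
            if model.tx_exon_bounds(e1)[1] < t1 + k - 1:
                continue
            c1, c2 = model.tx_to_cdna(t1), model.tx_to_cdna(t1 + k - 1)
            g1, g2 = model.tx_to_genomic(t1), model.tx_to_genomic(t1 + k - 1)
            s, e = min(g1, g2), max(g1, g2)
            bases = _tx_bases(model, s, e)
            notation = f"c.{c1}_{c2}{op}{bases}"
        else:
            i = int(rng.integers(1, model.n_introns + 1))
            L = model.intron_length(i)
            if L <= k + 2:
                continue
            d = int(rng.integers(1, L - k))
            base = model.tx_to_cdna(model.tx_exon_bounds(i)[1])
            donor_g = model.tx_to_genomic(model.tx_exon_bounds(i)[1])
            step = 1 if model.strand == "+" else -1
            g1, g2 = donor_g + step * d, donor_g + step * (d + k - 1)
            s, e = min(g1, g2), max(g1, g2)
            bases = _tx_bases(model, s, e)
            notation = f"c.{base}+{d}_{base}+{d + k - 1}{op}{bases}"
        nv = normalize_variant(parse_notation(notation), model)
        if nv.uid in used_keys:
            continue
        return _VariantDraft(nv, notation, region, "MNV")
    raise RuntimeError("could not place a unique MNV")


def _draw_large_del(model: GeneModel, rng, used_keys: set) -> _VariantDraft:
    n = len(model.exons)
    for _ in range(200):
        if rng.random() < 0.25:
            notation = "whole gene deletion"
        else:
            a = int(rng.integers(1, n + 1))
            b = int(rng.integers(a, n + 1))
            notation = f"deletion of exons {a}-{b}" if a != b else f"deletion of exon {a}"
        nv = normalize_variant(parse_notation(notation), model)
        if nv.uid in used_keys:
            continue
        return _VariantDraft(nv, notation, "large_deletion", "MNV")
    raise RuntimeError("could not place a unique large deletion")


def _alias_options(draft: _VariantDraft, model: GeneModel, alt_models: list) -> list:
    """Alternate-dialect renderings of one variant, all mapping to its key."""
    opts: list[tuple[str, str]] = []  # (dialect name, notation)
    nv = draft.nv
    if draft.width == "SNV" and draft.region == "intronic":
        opts.append(("genomic", _format_sub_genomic(model, draft.g_anchor, draft.alt_t)))
        # the IVS form and the opposite-boundary c. form are built lazily
        opts.append(("ivs", ""))
        opts.append(("opposite-anchor", ""))
    elif draft.width == "SNV":
        opts.append(("genomic", _format_sub_genomic(model, draft.g_anchor, draft.alt_t)))
        if nv.canonical_phgvs and nv.canonical_phgvs[2] != nv.canonical_phgvs[-1]:
            for tag, m in [("protein", model)] + [("protein-alt", am) for am in alt_models]:
                residue = nv.protein_residue
                if tag == "protein-alt":
                    shift = (m.cds_start_cdna - model.cds_start_cdna) // 3
                    residue = residue - shift
                    if residue < 1:
                        continue
                p = f"p.{nv.canonical_phgvs[2]}{residue}{nv.canonical_phgvs[-1]}"
                try:
                    keys, ambiguous, _ = resolve_protein_notation(
                        parse_notation(p), [model] + alt_models)
                except Exception:
                    continue
                if not ambiguous and keys == [nv.key]:
                    opts.append((tag, p))
    elif nv.key.kind == "dup":
        opts.append(("sloppy-dup", ""))
        pos, ref, alt = nv.key.start, nv.key.ref, nv.key.alt
        opts.append(("genomic", f"{model.chromosome}:g.{pos}_{nv.key.end}dup{ref}"))
    elif nv.key.kind in ("del", "delins", "ins") :
        k = nv.key
        if k.kind == "del":
            opts.append(("genomic", f"{model.chromosome}:g.{k.start}_{k.end}del{k.ref}"))
    return opts


def _render_alias(dialect: str, notation: str, draft: _VariantDraft,
                  model: GeneModel, rng) -> str:
    if notation:
        return notation
    if dialect == "ivs":
        return _format_ivs(model, draft.g_anchor, draft.alt_t, rng)
    if dialect == "opposite-anchor":
        i, d_up, d_down = _intron_info(model, draft.g_anchor)
        primary = draft.notation
        use_donor = "+" not in primary.split(">")[0]
        return _format_sub_cdna(model, draft.g_anchor, draft.alt_t,
                                anchor="donor" if use_donor else "acceptor")
    if dialect == "sloppy-dup":
        # single-anchor form: c.<start>dupBASES (range implied by the bases)
        nvn = draft.notation  # c.A_BdupXXXX
        head = nvn.split("_")[0]
        bases = nvn.split("dup")[1]
        return f"{head}dup{bases}"
    raise ValueError(dialect)


def synth_corpus(model: GeneModel, spec: CorpusSpec):
    """Mention corpus with planted alias groups, classes, tiers and evidence.

    Returns ``(mentions, truth)``.  The number of alias mentions is
    ``round(alias_rate * n_mentions)``; each alias re-renders an existing
    variant in a different notation dialect, so exact consolidation
    recovers the planted unique count deterministically.
    """
    rng = np.random.default_rng(spec.seed)
    n_alias = int(round(spec.alias_rate * spec.n_mentions))
    n_unique = spec.n_mentions - n_alias
    counts = _allocate(n_unique, spec.class_mix)
    if counts.get("intronic", 0) > 0 and model.n_introns == 0:
        raise ValueError("intronic variants requested on a single-exon model")
    n_ld = counts.get("large_deletion", 0)
    n_point = n_unique - n_ld
    n_snv = int(round(spec.snv_fraction * n_unique))
    if n_snv > n_point:
        raise ValueError("snv_fraction infeasible: more SNVs than point variants")

    # region labels for point variants, then SNV/MNV widths among them
    regions: list[str] = []
    for r in ("exonic", "intronic", "utr"):
        regions.extend([r] * counts.get(r, 0))
    order = rng.permutation(len(regions))
    regions = [regions[i] for i in order]
    widths = ["SNV"] * n_snv + ["MNV"] * (n_point - n_snv)
    w_order = rng.permutation(len(widths))
    widths = [widths[i] for i in w_order]

    # alternate-numbering transcript twin (same genome, CDS starting later)
    alt_models = []
    shift_nt = 3 * spec.alt_numbering_offset_aa
    if model.cds_start_cdna + shift_nt < model.cds_end_cdna - 3:
        alt_models.append(replace(model, cds_start_cdna=model.cds_start_cdna + shift_nt))

    used_keys: set[str] = set()
    drafts: list[_VariantDraft] = []
    for region, width in zip(regions, widths):
        d = (_draw_snv(model, region, rng, used_keys) if width == "SNV"
             else _draw_mnv(model, region, rng, used_keys))
        used_keys.add(d.nv.uid)
        drafts.append(d)
    for _ in range(n_ld):
        d = _draw_large_del(model, rng, used_keys)
        used_keys.add(d.nv.uid)
        drafts.append(d)

    # tiers over point variants; large deletions are pathogenic events but are
    # excluded from the pathogenic* stratum by reporting convention
    tier_counts = _allocate(n_point, spec.tier_mix)
    tier_pool: list[str] = []
    for tier_name, c in (("pathogenic", tier_counts["pathogenic"]),
                         ("benign", tier_counts["benign"]),
                         ("vus", tier_counts["vus"])):
        tier_pool.extend([tier_name] * c)
    t_order = rng.permutation(len(tier_pool))
    tier_pool = [tier_pool[i] for i in t_order]
    for d, sup in zip(drafts[:n_point], tier_pool):
        if sup == "pathogenic":
            d.tier = ("LikelyPathogenic"
                      if rng.random() < spec.likely_pathogenic_fraction else "Pathogenic")
        elif sup == "benign":
            d.tier = ("LikelyBenign"
                      if rng.random() < spec.likely_benign_fraction else "Benign")
        else:
            d.tier = "VUS"
    for d in drafts[n_point:]:
        d.tier = "Pathogenic"

    # alias mention assignment: VUS variants first (their contradictory second
    # bundle rides on the alias mention), then random dialect-capable variants
    for d in drafts:
        d.aliases_possible = _alias_options(d, model, alt_models)
    capable = [i for i, d in enumerate(drafts) if d.aliases_possible]
    vus_capable = [i for i in capable if drafts[i].tier == "VUS"]
    other_capable = [i for i in capable if drafts[i].tier != "VUS"]
    if n_alias > len(capable):
        raise ValueError("alias_rate infeasible: not enough dialect-capable variants")
    chosen = vus_capable[:n_alias]
    if len(chosen) < n_alias:
        extra = rng.choice(len(other_capable), size=n_alias - len(chosen), replace=False)
        chosen = chosen + [other_capable[int(i)] for i in extra]

    mentions: list[RawVariantMention] = []
    mention_to_uid: dict[str, str] = {}
    records = []
    evidence_lists = [synth_evidence(d.tier, rng) for d in drafts]
    mid = 0
    for i, d in enumerate(drafts):
        mid += 1
        mention_id = f"M{mid:04d}"
        notations = [d.notation]
        # published style sometimes prints the protein name next to the cDNA
        if (d.width == "SNV" and d.nv.canonical_phgvs
                and rng.random() < 0.3):
            notations.append(d.nv.canonical_phgvs)
        bundles = evidence_lists[i]
        ev = bundles[0] if bundles else EvidenceBundle()
        mentions.append(RawVariantMention(
            mention_id=mention_id,
            source_id=f"SRC{int(rng.integers(10_000, 99_999))}",
            notations=notations, evidence=ev,
        ))
        mention_to_uid[mention_id] = d.nv.uid
    n_alias_per: dict[str, int] = {}
    for i in chosen:
        d = drafts[i]
        opt = d.aliases_possible[int(rng.integers(len(d.aliases_possible)))]
        alias_notation = _render_alias(opt[0], opt[1], d, model, rng)
        mid += 1
        mention_id = f"M{mid:04d}"
        bundles = evidence_lists[i]
        ev = bundles[1] if len(bundles) > 1 else EvidenceBundle()
        mentions.append(RawVariantMention(
            mention_id=mention_id,
            source_id=f"SRC{int(rng.integers(10_000, 99_999))}",
            notations=[alias_notation], evidence=ev,
        ))
        mention_to_uid[mention_id] = d.nv.uid
        n_alias_per[d.nv.uid] = n_alias_per.get(d.nv.uid, 0) + 1

    for d in drafts:
        records.append({
            "uid": d.nv.uid,
            "tier": d.tier,
            "super_class": super_class(d.tier) or ("vus" if d.tier == "VUS" else ""),
            "region": d.region,
            "width": d.width,
            "kind": d.nv.key.kind,
            "notation": d.notation,
            "n_alias_mentions": n_alias_per.get(d.nv.uid, 0),
        })
    truth = GroundTruth(
        variants=pd.DataFrame(records).set_index("uid"),
        keys={d.nv.uid: d.nv.key for d in drafts},
        mention_to_uid=mention_to_uid,
        alt_models=alt_models,
    )
    # shuffle mention order so consolidation cannot rely on generation order
    m_order = rng.permutation(len(mentions))
    mentions = [mentions[i] for i in m_order]
    return mentions, truth


# ------------------------------------------------------------- DB exports
DEFAULT_PRESENCE = {
    "LOVD":    {"pathogenic": 0.72, "benign": 0.88, "vus": 0.60, "large_deletion": 0.75},
    "ClinVar": {"pathogenic": 0.21, "benign": 0.45, "vus": 0.15, "large_deletion": 0.25},
    "dbSNP":   {"pathogenic": 0.27, "benign": 0.85, "vus": 0.50, "large_deletion": 0.0},
    "gnomAD":  {"pathogenic": 0.03, "benign": 0.60, "vus": 0.30, "large_deletion": 0.0},
    "1000G":   {"pathogenic": 0.01, "benign": 0.30, "vus": 0.15, "large_deletion": 0.0},
}

_CLINICAL_DBS = ("LOVD", "ClinVar")
_VCF_DBS = ("dbSNP", "gnomAD", "1000G")


def _write_vcf(path, model: GeneModel, rows) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.contigs.add(model.chromosome, length=model.span[1] + 10_000)
    header.add_line('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">')
    header.add_line('##INFO=<ID=CLNSIG,Number=1,Type=String,Description="Recorded classification">')
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for pos, ref, alt, af, clnsig in sorted(rows):
            rec = vf.new_record(contig=model.chromosome, start=pos - 1,
                                alleles=(ref, alt))
            if af is not None:
                rec.info["AF"] = af
            if clnsig:
                rec.info["CLNSIG"] = clnsig
            vf.write(rec)


def synth_db_exports(truth: GroundTruth, model: GeneModel, out_dir,
                     presence: dict | None = None,
                     misclassification_rate: float = 0.06,
                     mnv_presence_factor: float = 0.5,
                     seed: int = 0):
    """Database snapshot files with independently planted per-stratum presence.

    Writes LOVD and ClinVar as HGVS-column TSVs (some entries re-notated in
    alternate dialects to exercise representation-invariant matching) and
    dbSNP/gnomAD/1000G as plain VCFs.  Clinical catalogs carry the true
    super-class flipped with ``misclassification_rate``.  MNV presence in
    the population databases is damped by ``mnv_presence_factor``
    (multi-nucleotide variants translate to databases at a lower rate);
    the clinical archives keep their per-stratum rates as configured.

    Returns ``(paths, planted)`` where ``paths`` maps db name to
    ``(path, dialect)`` and ``planted`` is the boolean presence frame.
    """
    from pathlib import Path

    from .harmonize import key_to_allele_pair

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    presence = presence or DEFAULT_PRESENCE
    rng = np.random.default_rng(seed)
    df = truth.variants
    dbs = list(presence)
    planted = pd.DataFrame(False, index=df.index, columns=dbs)
    recorded_cls = pd.DataFrame("", index=df.index, columns=list(_CLINICAL_DBS))
    for uid, row in df.iterrows():
        stratum = "large_deletion" if row["region"] == "large_deletion" else (
            row["super_class"] or "vus")
        for db in dbs:
            p = presence[db].get(stratum, 0.0)
            if (row["width"] == "MNV" and row["region"] != "large_deletion"
                    and db in _VCF_DBS):
                p *= mnv_presence_factor
            if rng.random() < p:
                planted.loc[uid, db] = True
        for db in _CLINICAL_DBS:
            sc = row["super_class"] or "vus"
            if sc in ("pathogenic", "benign") and rng.random() < misclassification_rate:
                sc = "benign" if sc == "pathogenic" else "pathogenic"
            recorded_cls.loc[uid, db] = sc

    paths: dict[str, tuple] = {}
    for db in dbs:
        keys = [truth.keys[u] for u in df.index if planted.loc[u, db]]
        if db in _CLINICAL_DBS:
            rows = []
            for key in keys:
                uid = str(key)
                nv = NormalizedVariant(key=key)
                if key.kind == "large_del":
                    notation = f"deletion of exons {key.exons[0]}-{key.exons[-1]}"
                else:
                    from .harmonize import _annotate_canonical

                    _annotate_canonical(nv, model)
                    notation = nv.canonical_chgvs
                    if rng.random() < 0.3:
                        # re-notate in an alternate dialect
                        if key.kind == "sub":
                            notation = f"{model.chromosome}:g.{key.start}{key.ref}>{key.alt}"
                        elif key.kind == "dup":
                            notation = f"{model.chromosome}:g.{key.start}_{key.end}dup{key.ref}"
                rows.append({"cHGVS": notation,
                             "classification": recorded_cls.loc[uid, db]})
            path = out_dir / f"{db}.tsv"
            pd.DataFrame(rows, columns=["cHGVS", "classification"]).to_csv(
                path, sep="\t", index=False)
            paths[db] = (path, "tsv_lovd")
        else:
            rows = []
            for key in keys:
                if key.kind == "large_del":
                    continue
                pos, ref, alt = key_to_allele_pair(model, key)
                af = float(10 ** rng.uniform(-4, -1))
                rows.append((pos, ref, alt, af, None))
            path = out_dir / f"{db}.vcf"
            _write_vcf(path, model, rows)
            paths[db] = (path, "vcf")
    return paths, planted


# -------------------------------------------------------- predictor scores
DEFAULT_COVERAGE = {
    "sift": 0.32, "polyphen2": 0.32, "mutation_taster2": 0.37,
    "mutation_assessor": 0.32, "provean": 0.31, "cadd": 0.76,
}

# (accuracy on pathogenic, accuracy on benign) conditional on a score existing
DEFAULT_ACCURACY = {
    "sift": (0.73, 0.74),
    "polyphen2": (0.74, 0.73),
    "mutation_taster2": (0.86, 0.60),
    "mutation_assessor": (0.75, 0.75),
    "provean": (0.78, 0.80),
    "cadd": (0.75, 0.72),
}

# piecewise-uniform CADD phred bands conditional on truth and correctness
DEFAULT_CADD_BANDS = {
    "pathogenic_correct": (((20.0, 30.0), 0.625), ((30.0, 40.0), 0.375)),
    "pathogenic_wrong": (((0.0, 10.0), 0.87), ((10.0, 20.0), 0.13)),
    "benign_correct": (((0.0, 10.0), 1.0),),
    "benign_wrong": (((20.0, 30.0), 0.8), ((30.0, 36.0), 0.2)),
    "unclassified": (((0.0, 10.0), 0.25), ((10.0, 20.0), 0.25),
                     ((20.0, 30.0), 0.35), ((30.0, 36.0), 0.15)),
}


def _draw_banded(bands, rng) -> float:
    ws = np.array([w for _, w in bands])
    i = int(rng.choice(len(bands), p=ws / ws.sum()))
    lo, hi = bands[i][0]
    return float(rng.uniform(lo, hi))


def synth_predictor_scores(truth: GroundTruth,
                           coverage: dict | None = None,
                           accuracy: dict | None = None,
                           cadd_band_params: dict | None = None,
                           seed: int = 0):
    """Predictor score table with planted coverage and accuracy.

    Each algorithm scores each point variant independently with its coverage
    probability; conditional on scoring a classified variant, the binarized
    call matches the truth with the algorithm's accuracy for that
    super-class.  CADD numeric scores come from truth- and
    correctness-conditional piecewise-uniform bands so cutoff banding is
    controllable.  Large deletions receive no scores.

    Returns ``(scores, planted)``; ``planted`` holds the scored/correct
    booleans per algorithm for parameter-recovery tests.
    """
    coverage = coverage or DEFAULT_COVERAGE
    accuracy = accuracy or DEFAULT_ACCURACY
    bands = cadd_band_params or DEFAULT_CADD_BANDS
    rng = np.random.default_rng(seed)
    df = truth.variants
    algs = list(coverage)
    scores = pd.DataFrame(np.nan, index=df.index, columns=algs, dtype=object)
    planted = pd.DataFrame(False, index=df.index,
                           columns=[f"{a}_scored" for a in algs]
                           + [f"{a}_correct" for a in algs])
    for uid, row in df.iterrows():
        if row["region"] == "large_deletion":
            continue
        sc = row["super_class"] if row["super_class"] in ("pathogenic", "benign") else None
        for alg in algs:
            if rng.random() >= coverage[alg]:
                continue
            planted.loc[uid, f"{alg}_scored"] = True
            if sc is None:
                label = "pathogenic" if rng.random() < 0.5 else "benign"
                correct = False
            else:
                acc = accuracy[alg][0 if sc == "pathogenic" else 1]
                correct = bool(rng.random() < acc)
                label = sc if correct else ("benign" if sc == "pathogenic" else "pathogenic")
            planted.loc[uid, f"{alg}_correct"] = correct
            scores.loc[uid, alg] = _raw_value(alg, label, sc, correct, bands, rng)
    return scores, planted


def _raw_value(alg, label, sc, correct, bands, rng):
    if alg == "sift":
        return "deleterious" if label == "pathogenic" else "tolerated"
    if alg == "polyphen2":
        if label == "pathogenic":
            return "probably_damaging" if rng.random() < 0.7 else "possibly_damaging"
        return "benign"
    if alg == "mutation_taster2":
        return "disease_causing" if label == "pathogenic" else "polymorphism"
    if alg == "mutation_assessor":
        if label == "pathogenic":
            return "high" if rng.random() < 0.5 else "medium"
        return "low" if rng.random() < 0.5 else "neutral"
    if alg == "provean":
        return (float(rng.uniform(-8.0, -2.5)) if label == "pathogenic"
                else float(rng.uniform(-2.4, 4.0)))
    if alg == "cadd":
        if sc is None:
            return _draw_banded(bands["unclassified"], rng)
        band = f"{sc}_{'correct' if correct else 'wrong'}"
        return _draw_banded(bands[band], rng)
    raise ValueError(alg)
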