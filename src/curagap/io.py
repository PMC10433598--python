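"""Tabular I/O for mention tables, normalized variants and predictor scores.

The mention TSV is the pipeline's primary input: one row per published
mention, its notation strings pipe-separated, evidence fields as columns.
"""

from __future__ import annotations

import math

import pandas as pd

from .classify import EvidenceBundle
from .harmonize import RawVariantMention

__all__ = [
    "write_mentions_tsv",
    "read_mentions_tsv",
    "write_variants_tsv",
    "write_vcf_like",
    "read_scores_tsv",
    "write_scores_tsv",
]

_EVIDENCE_COLUMNS = [
    "phenotype", "mrs_creatine_absent", "elevated_cr_crn", "uptake_pct_wt",
    "segregates", "unaffected_males", "control_count", "control_cohort",
    "de_novo", "conflicting_reports", "pba_uptake_before", "pba_uptake_after",
]


def _num(v):
    if v is None:
        return ""
    return f"{v:g}"


def write_mentions_tsv(mentions, path) -> None:
    rows = []
    for m in mentions:
        ev = m.evidence if m.evidence is not None else EvidenceBundle()
        rows.append({
            "mention_id": m.mention_id,
            "source_id": m.source_id,
            "notations": "|".join(m.notations),
            "reported_transcript": m.reported_transcript or "",
            "phenotype": ev.phenotype,
            "mrs_creatine_absent": int(ev.mrs_creatine_absent),
            "elevated_cr_crn": int(ev.elevated_cr_crn),
            "uptake_pct_wt": _num(ev.uptake_pct_wt),
            "segregates": ev.segregates,
            "unaffected_males": _num(ev.unaffected_males),
            "control_count": _num(ev.control_count),
            "control_cohort": _num(ev.control_cohort),
            "de_novo": ev.de_novo,
            "conflicting_reports": int(ev.conflicting_reports),
            "pba_uptake_before": _num(ev.pba_uptake_before),
            "pba_uptake_after": _num(ev.pba_uptake_after),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _opt_float(v):
    if v is None or v == "" or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def _opt_int(v):
    f = _opt_float(v)
    return None if f is None else int(f)


def read_mentions_tsv(path) -> list[RawVariantMention]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mentions = []
    for _, row in df.iterrows():
        ev = EvidenceBundle(
            phenotype=row.get("phenotype") or "unknown",
            mrs_creatine_absent=bool(int(row.get("mrs_creatine_absent") or 0)),
            elevated_cr_crn=bool(int(row.get("elevated_cr_crn") or 0)),
            uptake_pct_wt=_opt_float(row.get("uptake_pct_wt")),
            segregates=row.get("segregates") or "unknown",
            unaffected_males=_opt_int(row.get("unaffected_males")),
            control_count=_opt_int(row.get("control_count")),
            control_cohort=_opt_int(row.get("control_cohort")),
            de_novo=row.get("de_novo") or "unknown",
            conflicting_reports=bool(int(row.get("conflicting_reports") or 0)),
            pba_uptake_before=_opt_float(row.get("pba_uptake_before")),
            pba_uptake_after=_opt_float(row.get("pba_uptake_after")),
            source_ids=(row["source_id"],),
        )
        mentions.append(RawVariantMention(
            mention_id=row["mention_id"],
            source_id=row["source_id"],
            notations=[s for s in row["notations"].split("|") if s],
            evidence=ev,
            reported_transcript=row.get("reported_transcript") or None,
        ))
    return mentions


def write_variants_tsv(variants, calls, classes, path) -> None:
    """Normalized-variant export: key, canonical notations, aliases, labels."""
    rows = []
    for v in variants:
        call = calls.get(v.uid) if calls else None
        cls = classes.get(v.uid) if classes else None
        rows.append({
            "uid": v.uid,
            "chrom": v.key.chrom,
            "start": v.key.start,
            "end": v.key.end,
            "kind": v.key.kind,
            "ref": v.key.ref,
            "alt": v.key.alt,
            "canonical_chgvs": v.canonical_chgvs or "",
            "canonical_phgvs": v.canonical_phgvs or "",
            "tier": call.tier if call else "",
            "region": cls.region if cls else "",
            "width": cls.width if cls else "",
            "flags": ",".join(sorted(v.flags)),
            "n_mentions": len(v.mention_ids),
            "aliases": "|".join(sorted(v.aliases)),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_vcf_like(variants, model, path) -> None:
    """Plain CHROM/POS/ID/REF/ALT table of the point variants, for DB matching."""
    from .harmonize import key_to_allele_pair

    rows = []
    for v in variants:
        if v.key.kind == "large_del":
            continue
        pos, ref, alt = key_to_allele_pair(model, v.key)
        rows.append({"CHROM": v.key.chrom, "POS": pos, "ID": v.uid,
                     "REF": ref, "ALT": alt})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_scores_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="uid")
    return df


def write_scores_tsv(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index_label="uid")
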