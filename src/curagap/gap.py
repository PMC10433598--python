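"""Cross-referencing curated variants against database exports.

Loads database snapshots (VCF or TSV), normalizes their entries through the
same canonical-key machinery as the curated corpus (so matching is
representation-independent), builds a presence matrix, and computes overlap,
classification concordance, uncaptured-anywhere and SNV/MNV inclusion
statistics.  The inclusion contrast uses a two-sided Mann-Whitney U test on
per-variant inclusion counts with an exact, tie-aware null distribution for
small samples; an unpaired t-test is reported alongside for transparency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classify import super_class
from .harmonize import (
    GenomicKey,
    NormalizationError,
    allele_pair_to_key,
    normalize_variant,
)
from .gene_model import CoordinateError
from .notation import parse_notation

__all__ = [
    "DatabaseCatalog",
    "PresenceMatrix",
    "MannWhitneyResult",
    "load_db_export",
    "mark_presence",
    "overlap_report",
    "inclusion_rank_test",
    "exact_mwu_tied",
    "POPULATION_AND_CLINVAR",
]

logger = logging.getLogger(__name__)

POPULATION_AND_CLINVAR = ("ClinVar", "dbSNP", "gnomAD", "1000G")

TIER_STRATA = ("pathogenic_star", "benign", "vus")
REGION_STRATA = ("exonic", "intronic", "utr", "large_deletion")
WIDTH_STRATA = ("SNV", "MNV")


@dataclass
class DatabaseCatalog:
    db_name: str
    entries: dict  # GenomicKey -> {"classification": str|None, "af": float|None}
    snapshot_label: str = ""
    build: str = ""
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def large_deletions(self):
        return [k for k in self.entries if k.kind == "large_del"]


@dataclass
class PresenceMatrix:
    presence: pd.DataFrame  # bool, index=variant uid, columns=db names
    concordance: pd.DataFrame  # 1.0 match / 0.0 mismatch / NaN not comparable

    @property
    def databases(self) -> list[str]:
        return list(self.presence.columns)


@dataclass
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    n_snv: int
    n_mnv: int
    method: str
    t_test_p: float
    counts_snv: list = field(default_factory=list)
    counts_mnv: list = field(default_factory=list)


# ------------------------------------------------------------------ loaders
def _classification_of(raw) -> str | None:
    if raw is None:
        return None
    s = str(raw).strip().lower().replace(" ", "_")
    if not s or s in ("na", "nan", "none", "."):
        return None
    if "conflict" in s or "uncertain" in s or s == "vus":
        return "vus"
    if "benign" in s:
        return "benign"
    if "pathogenic" in s:
        return "pathogenic"
    return None


def load_db_export(path, dialect: str, model, db_name: str = "",
                   snapshot_label: str = "") -> DatabaseCatalog:
    """Read a database export into a catalog of canonical keys.

    ``dialect``: ``vcf`` (ClinVar/dbSNP/gnomAD/1000G style), ``tsv_lovd``
    (one HGVS column, optional classification), ``tsv_generic``
    (chrom/pos/ref/alt columns).  Malformed records are skipped, logged and
    counted, never fatal.
    """
    entries: dict = {}
    skipped = 0
    if dialect == "vcf":
        import pysam

        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                try:
                    alts = rec.alts or ()
                    for alt in alts:
                        key = allele_pair_to_key(model, rec.pos, rec.ref, alt)
                        info = dict(rec.info)
                        cls = _classification_of(info.get("CLNSIG"))
                        af = info.get("AF")
                        if isinstance(af, (tuple, list)):
                            af = af[0] if af else None
                        entries[key] = {"classification": cls,
                                        "af": float(af) if af is not None else None}
                except (NormalizationError, CoordinateError, ValueError) as exc:
                    skipped += 1
                    logger.warning("%s: skipped VCF record at %s: %s", db_name, rec.pos, exc)
    elif dialect in ("tsv_lovd", "tsv_generic"):
        df = pd.read_csv(path, sep="\t", dtype=str)
        if dialect == "tsv_lovd":
            hgvs_col = next(
                (c for c in df.columns if c.lower() in ("chgvs", "hgvs", "variant", "dna")),
                df.columns[0],
            )
            for _, row in df.iterrows():
                raw = row[hgvs_col]
                try:
                    parsed = parse_notation(str(raw))
                    nv = normalize_variant(parsed, model)
                    entries[nv.key] = {
                        "classification": _classification_of(row.get("classification")),
                        "af": None,
                    }
                except (NormalizationError, CoordinateError, ValueError) as exc:
                    skipped += 1
                    logger.warning("%s: skipped row %r: %s", db_name, raw, exc)
        else:
            for _, row in df.iterrows():
                try:
                    key = allele_pair_to_key(model, int(row["pos"]), row["ref"], row["alt"])
                    af = row.get("af")
                    entries[key] = {
                        "classification": _classification_of(row.get("classification")),
                        "af": float(af) if af not in (None, "", "nan") else None,
                    }
                except (NormalizationError, CoordinateError, ValueError, KeyError) as exc:
                    skipped += 1
                    logger.warning("%s: skipped row: %s", db_name, exc)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not entries:
        logger.warning("%s: catalog from %s is empty", db_name, path)
    return DatabaseCatalog(
        db_name=db_name or str(path),
        entries=entries,
        snapshot_label=snapshot_label,
        build=model.build_label,
        n_skipped=skipped,
    )


# ----------------------------------------------------------------- matching
def _large_del_match(a: GenomicKey, b: GenomicKey, min_reciprocal: float = 0.5) -> bool:
    """Reciprocal exon-set overlap for large deletions."""
    sa, sb = set(a.exons), set(b.exons)
    if not sa or not sb:
        return bool(sa) == bool(sb)
    inter = len(sa & sb)
    return inter / len(sa) >= min_reciprocal and inter / len(sb) >= min_reciprocal


def mark_presence(variants, calls, catalogs) -> PresenceMatrix:
    """Presence and classification-concordance of each curated variant per catalog.

    Point variants match on exact canonical key; large deletions match by
    reciprocal exon-set overlap.  Concordance is recorded only where both
    sides carry a classification, with likely tiers collapsed.
    """
    catalogs = list(catalogs)
    for cat in catalogs:
        if cat.build and cat.build != variants[0].key.build:
            raise ValueError(
                f"build mismatch: corpus {variants[0].key.build} vs "
                f"{cat.db_name} {cat.build}"
            )
    uids = [v.uid for v in variants]
    pres = pd.DataFrame(False, index=uids, columns=[c.db_name for c in catalogs])
    conc = pd.DataFrame(np.nan, index=uids, columns=[c.db_name for c in catalogs])
    for v in variants:
        sc = super_class(calls[v.uid].tier) if v.uid in calls else None
        if calls.get(v.uid) is not None and calls[v.uid].tier == "VUS":
            sc = "vus"
        for cat in catalogs:
            entry = None
            if v.key.kind == "large_del":
                for k in cat.large_deletions():
                    if _large_del_match(v.key, k):
                        entry = cat.entries[k]
                        break
            else:
                entry = cat.entries.get(v.key)
            if entry is None:
                continue
            pres.loc[v.uid, cat.db_name] = True
            db_cls = entry.get("classification")
            if db_cls is not None and sc is not None:
                conc.loc[v.uid, cat.db_name] = float(db_cls == sc)
    return PresenceMatrix(presence=pres, concordance=conc)


# ------------------------------------------------------------------ report
def _strata_masks(variants, calls, classes) -> dict[str, pd.Series]:
    uids = [v.uid for v in variants]
    is_ld = pd.Series([classes[u].region == "large_deletion" for u in uids], index=uids)
    sc = pd.Series([super_class(calls[u].tier) if u in calls else None for u in uids],
                   index=uids, dtype=object)
    tier = pd.Series([calls[u].tier if u in calls else "Unassigned" for u in uids],
                     index=uids, dtype=object)
    region = pd.Series([classes[u].region for u in uids], index=uids)
    width = pd.Series([classes[u].width for u in uids], index=uids)
    masks = {
        "total": pd.Series(True, index=uids),
        # the pathogenic stratum excludes large deletions by reporting convention
        "pathogenic_star": (sc == "pathogenic") & ~is_ld,
        "benign": (sc == "benign") & ~is_ld,
        "vus": (sc.isna()) & ~is_ld,
        "exonic": region == "exonic",
        "intronic": region == "intronic",
        "utr": region == "utr",
        "large_deletion": is_ld,
        "SNV": width == "SNV",
        "MNV": width == "MNV",
    }
    masks["_tier"] = tier
    return masks


def overlap_report(matrix: PresenceMatrix, calls, classes, variants) -> dict:
    """Per-database per-stratum presence fractions, concordance, uncaptured tiers.

    Fractions are kept at full precision here; percentage rounding to the
    integer reporting style happens only at write-out.
    """
    masks = _strata_masks(variants, calls, classes)
    pres = matrix.presence
    out: dict = {"per_database": {}, "uncaptured": {}, "concordance": {}, "n": {}}
    for db in matrix.databases:
        col = pres[db]
        rows = {}
        for name in ("total", "pathogenic_star", "benign", "vus", "exonic",
                     "intronic", "utr", "large_deletion", "SNV", "MNV"):
            mask = masks[name]
            n = int(mask.sum())
            rows[name] = {
                "n": n,
                "n_present": int(col[mask].sum()),
                "fraction": float(col[mask].mean()) if n else math.nan,
            }
        out["per_database"][db] = rows
        conc = matrix.concordance[db].dropna()
        out["concordance"][db] = {
            "n_comparable": int(len(conc)),
            "fraction": float(conc.mean()) if len(conc) else math.nan,
        }
    absent_everywhere = ~pres.any(axis=1)
    for name in ("pathogenic_star", "benign", "vus", "total"):
        mask = masks[name]
        n = int(mask.sum())
        out["uncaptured"][name] = {
            "n": n,
            "n_uncaptured": int(absent_everywhere[mask].sum()),
            "fraction": float(absent_everywhere[mask].mean()) if n else math.nan,
        }
    out["n"]["variants"] = len(variants)
    return out


# ----------------------------------------------------- Mann-Whitney U test
def exact_mwu_tied(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U with ties, by dynamic programming.

    Enumerates the permutation null distribution of the rank-sum of the
    first group over all C(n1+n2, n1) assignments, grouping tied values so
    the computation stays polynomial.  Returns (U1, two-sided p), with the
    two-sided p defined as ``min(1, 2*min(P(U <= u), P(U >= u)))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)  # midranks; *2 makes them integers
    r2 = np.rint(ranks * 2).astype(int)
    obs2 = int(r2[:n1].sum())
    # group tied values: (doubled midrank, multiplicity)
    groups: dict[int, int] = {}
    for v in r2:
        groups[v] = groups.get(v, 0) + 1
    # DP over groups: ways[(k, s)] = #assignments choosing k items with doubled
    # rank-sum s for group 1
    from math import comb

    ways = {(0, 0): 1}
    for rank2, m in sorted(groups.items()):
        nxt: dict[tuple[int, int], int] = {}
        for (k, s), w in ways.items():
            for take in range(0, min(m, n1 - k) + 1):
                key = (k + take, s + take * rank2)
                nxt[key] = nxt.get(key, 0) + w * comb(m, take)
        ways = nxt
    dist: dict[int, int] = {}
    for (k, s), w in ways.items():
        if k == n1:
            dist[s] = dist.get(s, 0) + w
    total = sum(dist.values())
    le = sum(w for s, w in dist.items() if s <= obs2)
    ge = sum(w for s, w in dist.items() if s >= obs2)
    p = min(1.0, 2.0 * min(le, ge) / total)
    u1 = obs2 / 2.0 - n1 * (n1 + 1) / 2.0
    return u1, p


def inclusion_rank_test(matrix: PresenceMatrix, classes,
                        dbs=POPULATION_AND_CLINVAR,
                        exact_max_n: int = 25) -> MannWhitneyResult:
    """SNV vs MNV inclusion contrast over the named databases.

    The per-variant statistic is the number of those databases containing
    the variant (0..len(dbs)).  Exact tie-aware null distribution when the
    combined sample is small, normal approximation with tie correction
    otherwise; a Welch t-test p-value is carried along for transparency.
    """
    cols = [d for d in dbs if d in matrix.presence.columns]
    counts = matrix.presence[cols].sum(axis=1)
    width = pd.Series({u: classes[u].width for u in matrix.presence.index})
    snv = counts[width == "SNV"].to_numpy(dtype=float)
    mnv = counts[width == "MNV"].to_numpy(dtype=float)
    if len(snv) == 0 or len(mnv) == 0:
        raise ValueError("both SNV and MNV groups must be non-empty")
    if len(snv) + len(mnv) <= exact_max_n:
        u, p = exact_mwu_tied(snv, mnv)
        method = "exact"
    else:
        res = stats.mannwhitneyu(snv, mnv, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        method = "asymptotic"
    if np.ptp(np.concatenate([snv, mnv])) == 0:
        t_p = 1.0
    else:
        t_p = float(stats.ttest_ind(snv, mnv, equal_var=False).pvalue)
    return MannWhitneyResult(
        u_statistic=float(u), p_value=float(p),
        n_snv=len(snv), n_mnv=len(mnv), method=method, t_test_p=t_p,
        counts_snv=[int(c) for c in snv], counts_mnv=[int(c) for c in mnv],
    )
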