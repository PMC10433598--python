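"""Rule-based pathogenicity classification from curated evidence.

The classifier operationalizes an ACMG-style tier assignment for a creatine
transporter deficiency (CTD) corpus.  Evidence per mention is structured as
an :class:`EvidenceBundle`: the clinical CTD composite (developmental
phenotype, absent MRS cerebral creatine peak, elevated urinary
creatine:creatinine ratio), an in vitro creatine uptake measurement as a
percent of wild type, family segregation, and control-population
observations.  The operative thresholds: uptake below 70% of wild type is
pathogenic-level functional impairment; uptake within 25% of wild type
(>= 75%) is benign-level function; uptake in the 10-point band just under
the cutoff without independent clinical confirmation earns only a "likely"
call.  Conflicting reports across sources demote a variant to VUS.

Also here: variant class labels (region x SNV/MNV), chaperone-rescue calls
(4-phenylbutyrate uptake before/after), and protein feature-site overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

__all__ = [
    "EvidenceBundle",
    "RuleConfig",
    "PathogenicityCall",
    "VariantClass",
    "TIER_ORDER",
    "assign_pathogenicity",
    "super_class",
    "classify_variant_class",
    "classify_rescue",
    "map_protein_features",
    "load_feature_map",
    "packaged_feature_map",
]

TIERS = ("Pathogenic", "LikelyPathogenic", "VUS", "LikelyBenign", "Benign", "Unassigned")

# ordering used by the monotonicity property: toward benign is smaller
TIER_ORDER = {
    "Benign": 0,
    "LikelyBenign": 1,
    "VUS": 2,
    "Unassigned": 2,
    "LikelyPathogenic": 3,
    "Pathogenic": 4,
}


def super_class(tier: str) -> str | None:
    """Collapse likely tiers to the binary pathogenic/benign super-classes."""
    if tier in ("Pathogenic", "LikelyPathogenic"):
        return "pathogenic"
    if tier in ("Benign", "LikelyBenign"):
        return "benign"
    return None


@dataclass(frozen=True)
class RuleConfig:
    uptake_pathogenic_cutoff: float = 70.0
    uptake_benign_floor: float = 75.0
    likely_band_width: float = 10.0
    rescue_margin: float = 5.0
    cadd_cutoff: float = 20.0
    cadd_cutoffs: tuple[float, ...] = (10.0, 20.0, 30.0)
    control_af_threshold: float = 0.001
    uptake_conflict_span: float = 15.0
    polyphen_possibly_is_pathogenic: bool = True

    def __post_init__(self) -> None:
        if self.uptake_benign_floor <= self.uptake_pathogenic_cutoff:
            raise ValueError("benign floor must exceed the pathogenic cutoff")


@dataclass(frozen=True)
class EvidenceBundle:
    """Structured evidence from one mention of a variant."""

    phenotype: str = "unknown"  # clinical CTD phenotype: yes | no | unknown
    mrs_creatine_absent: bool = False
    elevated_cr_crn: bool = False
    uptake_pct_wt: float | None = None
    segregates: str = "unknown"  # yes | no | unknown
    unaffected_males: int | None = None
    control_count: int | None = None
    control_cohort: int | None = None
    de_novo: str = "unknown"
    conflicting_reports: bool = False
    pba_uptake_before: float | None = None
    pba_uptake_after: float | None = None
    source_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.uptake_pct_wt is not None and self.uptake_pct_wt < 0:
            raise ValueError("uptake_pct_wt must be >= 0")
        if (
            self.control_count is not None
            and self.control_cohort is not None
            and self.control_count > self.control_cohort
        ):
            raise ValueError("control_count cannot exceed cohort size")

    def is_empty(self) -> bool:
        return (
            self.phenotype == "unknown"
            and not self.mrs_creatine_absent
            and not self.elevated_cr_crn
            and self.uptake_pct_wt is None
            and self.segregates == "unknown"
            and self.unaffected_males is None
            and self.control_count is None
            and not self.conflicting_reports
        )

    @property
    def full_clinical_composite(self) -> bool:
        return (
            self.phenotype == "yes"
            and self.mrs_creatine_absent
            and self.elevated_cr_crn
        )


@dataclass
class PathogenicityCall:
    tier: str
    fired_rules: list[str] = field(default_factory=list)
    rationale: str = ""


@dataclass(frozen=True)
class VariantClass:
    region: str  # exonic | intronic | utr | large_deletion
    width: str  # SNV | MNV

    def __post_init__(self) -> None:
        if self.region == "large_deletion" and self.width != "MNV":
            raise ValueError("large deletions are MNV by convention")


# ------------------------------------------------------------- the cascade
def _benign_controls(b: EvidenceBundle, rules: RuleConfig) -> bool:
    if b.unaffected_males is not None and b.unaffected_males > 0:
        return True
    if b.control_count is not None and b.control_count > 0:
        if b.control_cohort:
            return b.control_count / b.control_cohort >= rules.control_af_threshold
        return True
    return False


def _cascade(b: EvidenceBundle, rules: RuleConfig) -> tuple[str, list[str]]:
    """Deterministic rule cascade over one (possibly merged) bundle."""
    fired: list[str] = []
    u = b.uptake_pct_wt
    clinical = b.phenotype == "yes"
    if u is not None:
        if u < rules.uptake_pathogenic_cutoff:
            if clinical:
                fired.append("uptake<cutoff+clinical")
                return "Pathogenic", fired
            if u >= rules.uptake_pathogenic_cutoff - rules.likely_band_width:
                fired.append("uptake-in-likely-band")
                return "LikelyPathogenic", fired
            fired.append("uptake<cutoff")
            return "Pathogenic", fired
        if u >= rules.uptake_benign_floor:
            fired.append("uptake-near-wildtype")
            return "Benign", fired
        # gray zone between cutoff and floor: fall through to other evidence
    if _benign_controls(b, rules):
        fired.append("observed-in-controls")
        return "Benign", fired
    if b.segregates == "no":
        fired.append("no-segregation")
        return "LikelyBenign", fired
    if clinical:
        if b.full_clinical_composite:
            fired.append("clinical-composite")
            return "Pathogenic", fired
        fired.append("clinical-partial")
        return "LikelyPathogenic", fired
    return "Unassigned", fired


def _merge(bundles: list[EvidenceBundle]) -> EvidenceBundle:
    uptakes = [b.uptake_pct_wt for b in bundles if b.uptake_pct_wt is not None]
    phen = "unknown"
    if any(b.phenotype == "yes" for b in bundles):
        phen = "yes"
    elif any(b.phenotype == "no" for b in bundles):
        phen = "no"
    seg = "unknown"
    if any(b.segregates == "no" for b in bundles):
        seg = "no"
    elif any(b.segregates == "yes" for b in bundles):
        seg = "yes"
    males = [b.unaffected_males for b in bundles if b.unaffected_males is not None]
    ctrl = [(b.control_count, b.control_cohort) for b in bundles if b.control_count is not None]
    sources: list[str] = []
    for b in bundles:
        sources.extend(b.source_ids)
    return EvidenceBundle(
        phenotype=phen,
        mrs_creatine_absent=any(b.mrs_creatine_absent for b in bundles),
        elevated_cr_crn=any(b.elevated_cr_crn for b in bundles),
        uptake_pct_wt=sum(uptakes) / len(uptakes) if uptakes else None,
        segregates=seg,
        unaffected_males=max(males) if males else None,
        control_count=ctrl[0][0] if ctrl else None,
        control_cohort=ctrl[0][1] if ctrl else None,
        source_ids=tuple(sorted(set(sources))),
    )


def assign_pathogenicity(evidence, rules: RuleConfig = RuleConfig()) -> PathogenicityCall:
    """Tier from the merged evidence of all mentions of one variant.

    Conflicts — an explicit conflicting-reports flag, uptake measurements
    disagreeing by more than the configured span, or bundles that
    individually land on opposite sides — demote to VUS before the merged
    cascade runs.  Empty evidence yields Unassigned, not an error.
    """
    bundles = [b for b in evidence if not b.is_empty()]
    if not bundles:
        return PathogenicityCall("Unassigned", [], "no usable evidence")
    if any(b.conflicting_reports for b in bundles):
        return PathogenicityCall("VUS", ["conflicting-reports"],
                                 "sources explicitly conflict")
    uptakes = [b.uptake_pct_wt for b in bundles if b.uptake_pct_wt is not None]
    if uptakes and max(uptakes) - min(uptakes) > rules.uptake_conflict_span:
        return PathogenicityCall(
            "VUS", ["conflicting-uptake"],
            f"uptake measurements span {min(uptakes):g}-{max(uptakes):g}% of WT",
        )
    sides = set()
    for b in bundles:
        tier, _ = _cascade(b, rules)
        sc = super_class(tier)
        if sc:
            sides.add(sc)
    if sides == {"pathogenic", "benign"}:
        return PathogenicityCall("VUS", ["contradictory-bundles"],
                                 "independent sources point in opposite directions")
    tier, fired = _cascade(_merge(bundles), rules)
    return PathogenicityCall(tier, fired, "; ".join(fired) or "no rule fired")


# -------------------------------------------------------- class & rescue
def classify_variant_class(variant, model) -> VariantClass:
    """Region and SNV/MNV width of a normalized variant."""
    key = variant.key
    if key.kind == "large_del":
        return VariantClass("large_deletion", "MNV")
    anchor = key.start if model.strand == "+" else key.end
    region = model.region_of(model.genomic_to_cdna(anchor))
    if region in ("utr5", "utr3"):
        region = "utr"
    width = "SNV" if key.kind == "sub" and len(key.ref) == 1 else "MNV"
    return VariantClass(region, width)


def classify_rescue(uptake_before: float, uptake_after: float | None,
                    rules: RuleConfig = RuleConfig()) -> str:
    """Chaperone (4-PBA) rescue call from uptake before/after treatment."""
    if uptake_before is None:
        raise ValueError("uptake_before is required")
    if uptake_before < 0 or (uptake_after is not None and uptake_after < 0):
        raise ValueError("uptake percentages must be >= 0")
    if uptake_after is None:
        return "not_measured"
    return "rescued" if uptake_after - uptake_before >= rules.rescue_margin else "not_rescued"


# ------------------------------------------------------- protein features
def load_feature_map(path) -> dict[int, str]:
    """Read a (residue, feature) TSV into a residue -> feature-tag map."""
    fmap: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("residue"):
                continue
            res, feat = line.split("\t")
            r = int(res)
            if r < 1:
                raise ValueError("residue indices must be >= 1")
            fmap[r] = feat
    return fmap


def packaged_feature_map() -> dict[int, str]:
    """Literature-annotated SLC6A8 protein feature sites shipped with the package."""
    ref = resources.files("curagap").joinpath("data/protein_features.tsv")
    with resources.as_file(ref) as path:
        return load_feature_map(path)


def packaged_rescue_table():
    """Published 4-PBA creatine-uptake measurements (percent of wild type).

    Columns: variant (protein notation), uptake_before, uptake_after.
    """
    import pandas as pd

    ref = resources.files("curagap").joinpath("data/fourpba_uptake.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def map_protein_features(variants, feature_map: dict[int, str]) -> dict[str, set[str]]:
    """Feature tags per variant uid; variants without a protein residue get an empty set."""
    out: dict[str, set[str]] = {}
    for v in variants:
        tags: set[str] = set()
        if v.protein_residue is not None and v.protein_residue in feature_map:
            tags.add(feature_map[v.protein_residue])
        out[v.uid] = tags
    return out
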