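"""Pathogenicity cascade, rescue calls, variant classes, feature overlap."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from curagap.classify import (
    TIER_ORDER,
    EvidenceBundle,
    RuleConfig,
    VariantClass,
    assign_pathogenicity,
    classify_rescue,
    classify_variant_class,
    map_protein_features,
    packaged_feature_map,
    packaged_rescue_table,
)
from curagap.harmonize import normalize_variant
from curagap.notation import parse_notation


# ---------------------------------------------------------- tier assignment
class TestWorkedExamples:
    """The published per-category examples the cascade must reproduce."""

    def test_low_uptake_with_clinical_picture_is_pathogenic(self):
        # p.R207W: mental disability, raised urine Cr:Crn, <10% WT uptake
        b = EvidenceBundle(phenotype="yes", elevated_cr_crn=True, uptake_pct_wt=9.0)
        assert assign_pathogenicity([b]).tier == "Pathogenic"

    def test_uptake_near_cutoff_alone_is_likely_pathogenic(self):
        # p.F314L: 65% of WT activity, close to the 70% cutoff, nothing else
        b = EvidenceBundle(uptake_pct_wt=65.0)
        assert assign_pathogenicity([b]).tier == "LikelyPathogenic"

    def test_uptake_within_25pct_of_wt_is_benign(self):
        # p.T481I: transport within 25% of wild type
        b = EvidenceBundle(uptake_pct_wt=80.0)
        assert assign_pathogenicity([b]).tier == "Benign"

    def test_non_segregation_is_likely_benign(self):
        # p.V182M: found in a patient but did not segregate with phenotype
        b = EvidenceBundle(segregates="no")
        assert assign_pathogenicity([b]).tier == "LikelyBenign"

    def test_control_population_observations_are_benign(self):
        # c.394+88G>C: detected in 21 of 166 non-CTD individuals
        b = EvidenceBundle(control_count=21, control_cohort=166)
        assert assign_pathogenicity([b]).tier == "Benign"

    def test_conflicting_sources_are_vus(self):
        # p.A388T: one source pathogenic, another non-pathogenic, no primary data
        b = EvidenceBundle(conflicting_reports=True)
        assert assign_pathogenicity([b]).tier == "VUS"

    def test_opposite_side_bundles_are_vus(self):
        bs = [
            EvidenceBundle(phenotype="yes", mrs_creatine_absent=True,
                           elevated_cr_crn=True),
            EvidenceBundle(uptake_pct_wt=95.0),
        ]
        assert assign_pathogenicity(bs).tier == "VUS"

    def test_discordant_uptake_measurements_are_vus(self):
        bs = [EvidenceBundle(uptake_pct_wt=20.0), EvidenceBundle(uptake_pct_wt=90.0)]
        assert assign_pathogenicity(bs).tier == "VUS"

    def test_no_evidence_is_unassigned(self):
        assert assign_pathogenicity([]).tier == "Unassigned"
        assert assign_pathogenicity([EvidenceBundle()]).tier == "Unassigned"

    def test_full_clinical_composite_without_assay_is_pathogenic(self):
        b = EvidenceBundle(phenotype="yes", mrs_creatine_absent=True,
                           elevated_cr_crn=True)
        assert assign_pathogenicity([b]).tier == "Pathogenic"

    def test_partial_clinical_picture_is_only_likely(self):
        b = EvidenceBundle(phenotype="yes")
        assert assign_pathogenicity([b]).tier == "LikelyPathogenic"


_seg = st.sampled_from(["yes", "no", "unknown"])
_bundle_base = st.fixed_dictionaries({
    "phenotype": _seg,
    "mrs_creatine_absent": st.booleans(),
    "elevated_cr_crn": st.booleans(),
    "segregates": _seg,
    "unaffected_males": st.one_of(st.none(), st.integers(0, 5)),
})


class TestProperties:
    @given(_bundle_base,
           st.floats(0, 120, allow_nan=False),
           st.floats(0, 120, allow_nan=False))
    def test_lower_uptake_never_moves_toward_benign(self, base, u1, u2):
        lo, hi = sorted((u1, u2))
        t_lo = assign_pathogenicity([EvidenceBundle(uptake_pct_wt=lo, **base)]).tier
        t_hi = assign_pathogenicity([EvidenceBundle(uptake_pct_wt=hi, **base)]).tier
        assert TIER_ORDER[t_lo] >= TIER_ORDER[t_hi]

    @given(st.lists(st.builds(
        EvidenceBundle,
        phenotype=_seg,
        uptake_pct_wt=st.one_of(st.none(), st.floats(0, 120, allow_nan=False)),
        segregates=_seg,
        conflicting_reports=st.booleans(),
    ), min_size=0, max_size=4), st.randoms(use_true_random=False))
    def test_deterministic_and_order_invariant(self, bundles, rnd):
        first = assign_pathogenicity(bundles).tier
        shuffled = list(bundles)
        rnd.shuffle(shuffled)
        assert assign_pathogenicity(shuffled).tier == first
        assert first in TIER_ORDER


# ------------------------------------------------------------------ rescue
RESCUE_EXPECTED = {
    "p.Y80H": "not_rescued", "p.G87R": "not_rescued", "p.G132V": "not_rescued",
    "p.G253R": "not_rescued", "p.G337W": "rescued", "p.G356V": "not_rescued",
    "p.P382L": "not_rescued", "p.P390L": "not_rescued", "p.R391W": "rescued",
    "p.A404P": "rescued", "p.G421R": "not_rescued", "p.G424D": "rescued",
    "p.A448D": "rescued", "p.C491W": "not_rescued", "p.V539I": "rescued",
    "p.P544L": "rescued", "p.P554L": "rescued",
}


class TestRescue:
    def test_published_rescue_table(self):
        """All 17 chaperone-assay rows: 8 rescued, 9 not rescued."""
        table = packaged_rescue_table()
        assert len(table) == 17
        calls = {
            row["variant"]: classify_rescue(row["uptake_before"], row["uptake_after"])
            for _, row in table.iterrows()
        }
        assert calls == RESCUE_EXPECTED
        assert sum(c == "rescued" for c in calls.values()) == 8
        assert sum(c == "not_rescued" for c in calls.values()) == 9

    def test_missing_after_measurement(self):
        assert classify_rescue(10.0, None) == "not_measured"

    def test_margin_boundary(self):
        rules = RuleConfig()
        assert classify_rescue(10.0, 10.0 + rules.rescue_margin, rules) == "rescued"
        assert classify_rescue(10.0, 10.0 + rules.rescue_margin - 0.1, rules) == "not_rescued"

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_rescue(-1.0, 10.0)


# ---------------------------------------------------------- variant classes
class TestVariantClass:
    def test_examples(self, seq_model):
        def cls(raw):
            return classify_variant_class(
                normalize_variant(parse_notation(raw), seq_model), seq_model)

        ref = seq_model.base_at(95)
        alt = "A" if ref != "A" else "G"
        assert cls(f"c.35{ref}>{alt}") == VariantClass("exonic", "SNV")
        iref = seq_model.base_at(70)
        ialt = "A" if iref != "A" else "G"
        assert cls(f"c.30+40{iref}>{ialt}") == VariantClass("intronic", "SNV")
        assert cls("c.2_4del") == VariantClass("exonic", "MNV")
        assert cls("whole gene deletion") == VariantClass("large_deletion", "MNV")

    def test_large_deletions_cannot_be_snv(self):
        with pytest.raises(ValueError):
            VariantClass("large_deletion", "SNV")


# --------------------------------------------------------- protein features
class TestFeatures:
    def test_packaged_feature_sites(self):
        fmap = packaged_feature_map()
        assert fmap[421] == "creatine_binding"
        assert fmap[181] == "disulfide"
        assert fmap[132] == "helix_stabilizing"
        assert fmap[625] == "phosphorylation"

    def test_lookup_and_empty_for_non_coding(self, seq_model):
        fmap = {2: "creatine_binding"}
        ref = seq_model.base_at(95)
        coding = normalize_variant(parse_notation(
            f"c.35{ref}>{'A' if ref != 'A' else 'G'}"), seq_model)
        iref = seq_model.base_at(70)
        intronic = normalize_variant(parse_notation(
            f"c.30+40{iref}>{'A' if iref != 'A' else 'G'}"), seq_model)
        tags = map_protein_features([coding, intronic], fmap)
        assert tags[intronic.uid] == set()
        if coding.protein_residue == 2:
            assert tags[coding.uid] == {"creatine_binding"}
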