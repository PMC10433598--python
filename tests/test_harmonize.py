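"""Normalization to genomic keys, 3'-shifting, aliases and consolidation."""

from dataclasses import replace

import numpy as np
import pytest

from curagap.gene_model import build_gene_model
from curagap.harmonize import (
    NormalizationError,
    RawVariantMention,
    consolidate_mentions,
    ivs_to_chgvs,
    normalize_variant,
    resolve_protein_notation,
)
from curagap.notation import parse_notation
from curagap.synth import CorpusSpec, synth_corpus


def norm(raw, model):
    return normalize_variant(parse_notation(raw), model)


class TestIvs:
    def test_ivs_maps_to_exon_boundaries(self, two_exon_model):
        p = ivs_to_chgvs(parse_notation("IVS1+5A>G"), two_exon_model)
        assert str(p.cdna_start) == "100+5"
        p = ivs_to_chgvs(parse_notation("IVS1-10A>G"), two_exon_model)
        assert str(p.cdna_start) == "101-10"

    def test_ivs12_with_exon12_ending_at_1767(self):
        # 13 exons; exons 1-11 of 147 bp (1617) + exon 12 of 150 bp -> c.1767
        exons, g = [], 1
        for length in [147] * 11 + [150, 100]:
            exons.append((g, g + length - 1))
            g += length + 200
        m = build_gene_model(exons)
        p = ivs_to_chgvs(parse_notation("IVS12 + 32 C > A"), m)
        assert str(p.cdna_start) == "1767+32"
        assert (p.ref, p.alt) == ("C", "A")

    def test_intron_index_out_of_range(self, two_exon_model):
        with pytest.raises(NormalizationError):
            ivs_to_chgvs(parse_notation("IVS2+5A>G"), two_exon_model)


class TestNormalization:
    def test_substitution_key(self, seq_model):
        ref = seq_model.base_at(95)
        alt = "A" if ref != "A" else "G"
        nv = norm(f"c.35{ref}>{alt}", seq_model)
        assert (nv.key.start, nv.key.ref, nv.key.alt) == (95, ref, alt)
        assert nv.key.kind == "sub"

    def test_cdna_and_genomic_agree(self, seq_model):
        ref = seq_model.base_at(95)
        alt = "A" if ref != "A" else "G"
        assert norm(f"c.35{ref}>{alt}", seq_model).key == \
            norm(f"chrX:g.95{ref}>{alt}", seq_model).key

    def test_three_prime_shift_of_dup(self, seq_model):
        # reference ...ATTTG... at g.10-14: a T duplication written at the
        # first T must canonicalize to the last T (HGVS 3' rule)
        first = norm("c.11dupT", seq_model)
        last = norm("c.13dupT", seq_model)
        assert first.key == last.key
        assert first.key.start == first.key.end == 13

    def test_sloppy_dup_pair_collapses(self, seq_model):
        # TGCCC planted at g.70-74 = c.30+40..30+44 (intron 1)
        full = norm("c.30+40_30+44dupTGCCC", seq_model)
        sloppy = norm("c.30+40dupTGCCC", seq_model)
        assert full.key == sloppy.key
        assert full.key.kind == "dup"
        assert full.key.ref == "TGCCC"

    def test_opposite_intron_anchors_collapse(self, seq_model):
        # intron 1 is g.31..90 (60 bp): g.70 is c.30+40 from the donor and
        # c.31-21 from the acceptor; both must land on one key
        g = 70
        ref = seq_model.base_at(g)
        alt = "A" if ref != "A" else "G"
        donor = norm(f"c.30+40{ref}>{alt}", seq_model)
        acceptor = norm(f"c.31-21{ref}>{alt}", seq_model)
        assert donor.key == acceptor.key
        assert donor.key.start == g

    def test_ref_mismatch_is_flagged_not_relocated(self, seq_model):
        ref = seq_model.base_at(95)
        wrong = "C" if ref != "C" else "G"
        alt = "T" if wrong != "T" and ref != "T" else "A"
        nv = norm(f"c.35{wrong}>{alt}", seq_model)
        assert "ref-mismatch" in nv.flags
        assert nv.key.start == 95  # stated coordinates kept

    def test_not_shifted_flag_without_sequence(self, two_exon_model):
        nv = norm("c.11dupT", two_exon_model)
        assert "not-shifted" in nv.flags

    def test_idempotent_canonical_form(self, seq_model):
        for raw in ("c.11dupT", "c.2_4del", "c.30+40dupTGCCC"):
            nv = norm(raw, seq_model)
            again = norm(nv.canonical_chgvs, seq_model)
            assert again.key == nv.key
            assert again.canonical_chgvs == nv.canonical_chgvs

    def test_unparseable_input_raises(self, seq_model):
        with pytest.raises(NormalizationError):
            normalize_variant(parse_notation("garbage"), seq_model)

    def test_whole_gene_deletion_equals_full_exon_range(self, seq_model):
        assert norm("whole gene deletion", seq_model).key == \
            norm("deletion of exons 1-2", seq_model).key


class TestProteinResolution:
    @pytest.fixture
    def coding_model(self):
        # single exon, CDS = ATG TTA CGA TAA (M L R *)
        return build_gene_model([(1, 12)], sequence="ATGTTACGATAA")

    def test_companion_cdna_pins_the_key(self, coding_model):
        keys, ambiguous, _ = resolve_protein_notation(
            parse_notation("p.L2F"), [coding_model], mention_context="c.6A>C")
        assert not ambiguous
        assert keys[0].start == 6

    def test_two_codon_changes_give_ambiguity(self, coding_model):
        # TTA -> Phe via c.6A>T or c.6A>C: same residue change, two keys
        keys, ambiguous, _ = resolve_protein_notation(
            parse_notation("p.L2F"), [coding_model])
        assert ambiguous and len(keys) == 2

    def test_nonsense_with_unique_codon_change(self, coding_model):
        keys, ambiguous, _ = resolve_protein_notation(
            parse_notation("p.R3X"), [coding_model])
        assert not ambiguous
        assert keys[0] == norm("c.7C>T", coding_model).key

    def test_residue_beyond_protein_raises(self, coding_model):
        with pytest.raises(NormalizationError):
            resolve_protein_notation(parse_notation("p.R99W"), [coding_model])

    def test_alternate_transcript_numbering(self, synth_model):
        m = synth_model
        alt_m = replace(m, cds_start_cdna=m.cds_start_cdna + 30)  # 10 codons later
        # find a coding substitution whose protein notation resolves uniquely
        for t in range(m.cds_start_cdna + 60, m.cds_start_cdna + 400, 3):
            g = m.tx_to_genomic(t)
            ref = m.tx_base_at(g)
            alt = "A" if ref != "A" else "G"
            nv = norm(f"c.{m.tx_to_cdna(t)}{ref}>{alt}", m)
            if not nv.canonical_phgvs or nv.canonical_phgvs[2] == nv.canonical_phgvs[-1]:
                continue
            keys, ambiguous, _ = resolve_protein_notation(
                parse_notation(nv.canonical_phgvs), [m, alt_m])
            if ambiguous or keys != [nv.key]:
                continue
            shifted = f"p.{nv.canonical_phgvs[2]}{nv.protein_residue - 10}{nv.canonical_phgvs[-1]}"
            keys2, amb2, flags = resolve_protein_notation(
                parse_notation(shifted), [m, alt_m])
            assert keys2 == [nv.key] and not amb2
            assert "transcript-mismatch" in flags
            return
        pytest.fail("no uniquely resolvable coding substitution found")


class TestConsolidation:
    def test_two_aliases_of_three_mentions(self, seq_model):
        ms = [
            RawVariantMention("m1", "s1", ["c.30+40dupTGCCC"]),
            RawVariantMention("m2", "s2", ["c.30+40_30+44dupTGCCC"]),
            RawVariantMention("m3", "s3", ["c.2_4del"]),
        ]
        variants, rep = consolidate_mentions(ms, seq_model)
        assert (rep.n_unique, rep.n_duplicates) == (2, 1)
        dup = next(v for v in variants if v.key.kind == "dup")
        assert dup.aliases == {"c.30+40dupTGCCC", "c.30+40_30+44dupTGCCC"}
        assert dup.mention_ids == {"m1", "m2"}

    def test_conservation_with_unresolvable_mentions(self, seq_model):
        ms = [
            RawVariantMention("m1", "s1", ["c.11dupT"]),
            RawVariantMention("m2", "s2", ["complete nonsense"]),
        ]
        variants, rep = consolidate_mentions(ms, seq_model)
        assert rep.n_unique + rep.n_duplicates + len(rep.unresolved) == rep.n_raw
        assert rep.unresolved[0][0] == "m2"

    def test_order_independence(self, synth_model, default_corpus):
        mentions, truth = default_corpus
        v1, r1 = consolidate_mentions(mentions, synth_model, truth.alt_models)
        rng = np.random.default_rng(99)
        shuffled = [mentions[i] for i in rng.permutation(len(mentions))]
        v2, r2 = consolidate_mentions(shuffled, synth_model, truth.alt_models)
        assert [v.uid for v in v1] == [v.uid for v in v2]
        assert (r1.n_unique, r1.n_duplicates) == (r2.n_unique, r2.n_duplicates)

    def test_planted_alias_groups_fully_recovered(self, synth_model):
        """Every alias group collapses to one key; no spurious merges (20 seeds)."""
        for seed in range(1, 21):
            mentions, truth = synth_corpus(synth_model, CorpusSpec(seed=seed))
            variants, rep = consolidate_mentions(mentions, synth_model, truth.alt_models)
            assert not rep.unresolved
            assert rep.n_unique == truth.n_unique
            got = {mid: v.uid for v in variants for mid in v.mention_ids}
            assert got == truth.mention_to_uid
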