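"""Database matching, overlap reporting and the inclusion rank test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from curagap.classify import PathogenicityCall, VariantClass, assign_pathogenicity
from curagap.gap import (
    POPULATION_AND_CLINVAR,
    DatabaseCatalog,
    exact_mwu_tied,
    inclusion_rank_test,
    load_db_export,
    mark_presence,
)
from curagap.harmonize import normalize_variant
from curagap.notation import parse_notation


# --------------------------------------------------------------- MWU oracle
def enumeration_mwu(x, y):
    """Brute-force permutation null of the rank-sum, same two-sided rule."""
    x, y = list(x), list(y)
    n1 = len(x)
    combined = np.array(x + y, dtype=float)
    ranks = stats.rankdata(combined)
    obs = ranks[:n1].sum()
    sums = [ranks[list(idx)].sum()
            for idx in itertools.combinations(range(len(combined)), n1)]
    sums = np.array(sums)
    le = np.sum(sums <= obs + 1e-9)
    ge = np.sum(sums >= obs - 1e-9)
    p = min(1.0, 2.0 * min(le, ge) / len(sums))
    u1 = obs - n1 * (n1 + 1) / 2.0
    return u1, p


class TestExactMannWhitney:
    def test_identical_groups_give_p_one(self):
        u, p = exact_mwu_tied([2, 2, 2, 2], [2, 2, 2])
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(12))
    def test_agrees_with_enumeration_for_small_samples(self, seed):
        """DP null distribution == brute-force enumeration, combined n <= 12."""
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(1, 7))
        n2 = int(rng.integers(1, 13 - n1))
        x = rng.integers(0, 5, n1)  # inclusion counts: heavy ties
        y = rng.integers(0, 5, n2)
        u_dp, p_dp = exact_mwu_tied(x, y)
        u_en, p_en = enumeration_mwu(x, y)
        assert u_dp == pytest.approx(u_en)
        assert p_dp == pytest.approx(p_en)

    def test_four_vs_four_case(self):
        x, y = [4, 3, 3, 2], [1, 0, 2, 0]
        u_dp, p_dp = exact_mwu_tied(x, y)
        u_en, p_en = enumeration_mwu(x, y)
        assert (u_dp, p_dp) == pytest.approx((u_en, p_en))

    def test_matches_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(5)
        x = rng.permutation(20)[:8].astype(float)
        y = rng.permutation(40)[20:29].astype(float) + 100.5  # disjoint, no ties
        x, y = list(x), list(y)
        u_dp, p_dp = exact_mwu_tied(x, y)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u_dp == pytest.approx(res.statistic)
        assert p_dp == pytest.approx(res.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            exact_mwu_tied([], [1, 2])


def _matrix(counts_snv, counts_mnv, dbs=POPULATION_AND_CLINVAR):
    """Presence matrix realizing the given per-variant inclusion counts."""
    rows, classes = {}, {}
    for i, c in enumerate(counts_snv):
        uid = f"s{i}"
        rows[uid] = [j < c for j in range(len(dbs))]
        classes[uid] = VariantClass("exonic", "SNV")
    for i, c in enumerate(counts_mnv):
        uid = f"m{i}"
        rows[uid] = [j < c for j in range(len(dbs))]
        classes[uid] = VariantClass("exonic", "MNV")
    pres = pd.DataFrame.from_dict(rows, orient="index", columns=list(dbs))
    from curagap.gap import PresenceMatrix

    return PresenceMatrix(presence=pres, concordance=pres.astype(float) * np.nan), classes


class TestInclusionTest:
    def test_identical_inclusion_profiles(self):
        m, cls = _matrix([2, 2, 2], [2, 2])
        res = inclusion_rank_test(m, cls)
        assert res.p_value == 1.0
        assert res.method == "exact"

    def test_power_at_large_planted_effect(self):
        rng = np.random.default_rng(11)
        snv = rng.binomial(4, 0.6, 80)
        mnv = rng.binomial(4, 0.15, 40)
        m, cls = _matrix(snv, mnv)
        res = inclusion_rank_test(m, cls)
        assert res.method == "asymptotic"
        assert res.p_value < 0.05
        assert res.t_test_p < 0.05

    def test_empty_group_is_an_error(self):
        m, cls = _matrix([1, 2], [])
        with pytest.raises(ValueError):
            inclusion_rank_test(m, cls)


# ----------------------------------------------------------------- loaders
class TestLoaders:
    def test_vcf_records_become_canonical_keys(self, seq_model, tmp_path):
        import pysam

        header = pysam.VariantHeader()
        header.contigs.add("chrX", length=2000)
        path = tmp_path / "db.vcf"
        refs = [seq_model.base_at(p) for p in (5, 95, 100)]
        with pysam.VariantFile(str(path), "w", header=header) as vf:
            for pos, ref in zip((5, 95, 100), refs):
                alt = "A" if ref != "A" else "G"
                rec = vf.new_record(contig="chrX", start=pos - 1, alleles=(ref, alt))
                vf.write(rec)
        cat = load_db_export(path, "vcf", seq_model, db_name="test")
        assert len(cat) == 3

    def test_tsv_hgvs_and_generic_agree(self, seq_model, tmp_path):
        """The same variants entered as cHGVS and as pos/ref/alt give equal keys."""
        ref = seq_model.base_at(95)
        alt = "A" if ref != "A" else "G"
        p1 = tmp_path / "lovd.tsv"
        p1.write_text(f"cHGVS\tclassification\nc.35{ref}>{alt}\tbenign\nc.11dupT\t\n")
        p2 = tmp_path / "generic.tsv"
        # the dup is entered VCF-style, left-anchored at the other end of the run
        p2.write_text(
            "pos\tref\talt\n"
            f"95\t{ref}\t{alt}\n"
            f"10\t{seq_model.base_at(10)}\t{seq_model.base_at(10)}T\n"
        )
        c1 = load_db_export(p1, "tsv_lovd", seq_model)
        c2 = load_db_export(p2, "tsv_generic", seq_model)
        assert set(c1.entries) == set(c2.entries)

    def test_empty_and_malformed_rows(self, seq_model, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("cHGVS\tclassification\nnot a variant\t\n")
        cat = load_db_export(p, "tsv_lovd", seq_model)
        assert len(cat) == 0
        assert cat.n_skipped == 1


# ------------------------------------------------------------------ matching
class TestPresence:
    def _variants(self, seq_model, raws):
        return [normalize_variant(parse_notation(r), seq_model) for r in raws]

    def test_three_of_four_present(self, seq_model):
        ref, iref = seq_model.base_at(95), seq_model.base_at(70)
        alt = "A" if ref != "A" else "G"
        ialt = "A" if iref != "A" else "G"
        raws = [f"c.35{ref}>{alt}", f"c.30+40{iref}>{ialt}", "c.11dupT", "c.2_4del"]
        vs = self._variants(seq_model, raws)
        calls = {v.uid: PathogenicityCall("Unassigned") for v in vs}
        cat = DatabaseCatalog(
            "db", {v.key: {"classification": None, "af": None} for v in vs[:3]},
            build=seq_model.build_label)
        m = mark_presence(vs, calls, [cat])
        assert m.presence["db"].sum() == 3
        assert float(m.presence["db"].mean()) == 0.75

    def test_recorded_vus_vs_curated_benign_is_discordant(self, seq_model):
        # mirrors the c.76G>A case: present in the archive but rated VUS there
        ref = seq_model.base_at(95)
        alt = "A" if ref != "A" else "G"
        v = self._variants(seq_model, [f"c.35{ref}>{alt}"])[0]
        calls = {v.uid: assign_pathogenicity(
            [__import__("curagap").EvidenceBundle(uptake_pct_wt=90.0)])}
        cat = DatabaseCatalog("db", {v.key: {"classification": "vus", "af": None}},
                              build=seq_model.build_label)
        m = mark_presence([v], calls, [cat])
        assert bool(m.presence.loc[v.uid, "db"])
        assert m.concordance.loc[v.uid, "db"] == 0.0

    def test_alias_written_entry_matches_canonical(self, seq_model):
        sloppy = normalize_variant(parse_notation("c.30+40dupTGCCC"), seq_model)
        canonical = normalize_variant(parse_notation("c.30+40_30+44dupTGCCC"), seq_model)
        cat = DatabaseCatalog("db", {sloppy.key: {"classification": None, "af": None}},
                              build=seq_model.build_label)
        calls = {canonical.uid: PathogenicityCall("Unassigned")}
        m = mark_presence([canonical], calls, [cat])
        assert bool(m.presence.iloc[0, 0])

    def test_build_mismatch_is_fatal(self, seq_model):
        ref = seq_model.base_at(95)
        v = self._variants(seq_model, [f"c.35{ref}>{'A' if ref != 'A' else 'G'}"])[0]
        cat = DatabaseCatalog("db", {}, build="GRCh37")
        with pytest.raises(ValueError):
            mark_presence([v], {v.uid: PathogenicityCall("Unassigned")}, [cat])

    def test_large_deletion_reciprocal_overlap(self, synth_model):
        a = normalize_variant(parse_notation("deletion of exons 2-6"), synth_model)
        b = normalize_variant(parse_notation("deletion of exons 2-5"), synth_model)
        c = normalize_variant(parse_notation("deletion of exons 10-11"), synth_model)
        cat = DatabaseCatalog("db", {a.key: {"classification": None, "af": None}},
                              build=synth_model.build_label)
        calls = {v.uid: PathogenicityCall("Pathogenic") for v in (b, c)}
        m = mark_presence([b, c], calls, [cat])
        assert bool(m.presence.loc[b.uid, "db"])  # 4/5 and 4/4 overlap
        assert not bool(m.presence.loc[c.uid, "db"])
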