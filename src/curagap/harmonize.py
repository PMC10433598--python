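"""Normalization of parsed notations to canonical genomic keys.

The harmonizer turns every parseable mention of a variant — whatever dialect
it was printed in — into the same :class:`GenomicKey`, so that duplicate
mentions of one genomic alteration consolidate to a single record.  Keys for
duplications, deletions and insertions are 3'-shifted (in transcript
orientation) to the most-3' equivalent position whenever the model carries
sequence, following the HGVS normalization rule; when no sequence is
available the stated position is kept and a ``not-shifted`` flag records the
degraded guarantee.  A stated reference base that contradicts the model
sequence is kept as written and flagged (``ref-mismatch``) — re-location of a
mis-annotated variant is never guessed automatically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .gene_model import CdnaPosition, CoordinateError, GeneModel, _COMPLEMENT
from .notation import ParsedNotation, parse_notation

__all__ = [
    "NormalizationError",
    "GenomicKey",
    "NormalizedVariant",
    "ConsolidationReport",
    "RawVariantMention",
    "ivs_to_chgvs",
    "normalize_variant",
    "resolve_protein_notation",
    "consolidate_mentions",
    "allele_pair_to_key",
]

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    """A notation could not be mapped to a genomic key."""


def _comp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def _rc(seq: str) -> str:
    return _comp(seq)[::-1]


@dataclass(frozen=True, order=True)
class GenomicKey:
    """Canonical genomic identity of a variant.

    ``kind`` is one of ``sub``, ``del``, ``dup``, ``ins``, ``delins``,
    ``large_del``.  ``start``/``end`` are 1-based closed genomic coordinates
    (for ``ins``: the two bases flanking the insertion point); ``ref``/``alt``
    are plus-strand bases.  Large deletions are identified by their exon set
    instead of base-level coordinates.
    """

    chrom: str
    start: int
    end: int
    kind: str
    ref: str
    alt: str
    build: str
    exons: tuple[int, ...] = ()

    def __str__(self) -> str:
        if self.kind == "large_del":
            ex = ",".join(map(str, self.exons)) if self.exons else "all"
            return f"{self.chrom}:exondel[{ex}]:{self.build}"
        core = f"{self.chrom}:{self.start}-{self.end}:{self.kind}"
        if self.kind == "sub":
            core += f":{self.ref}>{self.alt}"
        elif self.kind in ("del", "dup"):
            core += f":{self.ref}"
        elif self.kind == "ins":
            core += f":{self.alt}"
        else:
            core += f":{self.ref}>{self.alt}"
        return f"{core}:{self.build}"


@dataclass
class RawVariantMention:
    """One published mention: its printed notations plus evidence payload."""

    mention_id: str
    source_id: str
    notations: list[str]
    evidence: object | None = None  # EvidenceBundle; kept opaque here
    reported_transcript: str | None = None

    def __post_init__(self) -> None:
        if not self.notations:
            raise ValueError("a mention must carry at least one notation string")


@dataclass
class NormalizedVariant:
    key: GenomicKey
    canonical_chgvs: str | None = None
    canonical_phgvs: str | None = None
    protein_residue: int | None = None
    aliases: set = field(default_factory=set)
    mention_ids: set = field(default_factory=set)
    evidence: list = field(default_factory=list)
    flags: set = field(default_factory=set)
    class_labels: dict = field(default_factory=dict)

    @property
    def uid(self) -> str:
        return str(self.key)


@dataclass
class ConsolidationReport:
    n_raw: int
    n_unique: int
    n_duplicates: int
    unresolved: list  # (mention_id, reason)

    @property
    def duplicate_pct(self) -> float:
        normalized = self.n_unique + self.n_duplicates
        return self.n_duplicates / normalized if normalized else 0.0


# ------------------------------------------------------------------ IVS
def ivs_to_chgvs(parsed: ParsedNotation, model: GeneModel) -> ParsedNotation:
    """Rewrite legacy IVSn±k notation as the equivalent c. notation.

    ``IVSn+k`` is k bases past the last base of exon n; ``IVSn-k`` is k bases
    before the first base of exon n+1 (transcript orientation).
    """
    if parsed.system != "ivs":
        raise NormalizationError(f"not an IVS notation: {parsed.raw!r}")
    n = parsed.ivs_intron
    if n is None or not 1 <= n <= model.n_introns:
        raise NormalizationError(
            f"intron {n} out of range for a model with {model.n_introns} introns"
        )
    off = parsed.ivs_offset
    if off == 0:
        raise NormalizationError("IVS offset of 0 is meaningless")
    if abs(off) > model.intron_length(n):
        raise NormalizationError(f"IVS{n}{off:+d} spans past the intron")
    if off > 0:
        t = model.tx_exon_bounds(n)[1]
    else:
        t = model.tx_exon_bounds(n + 1)[0]
    anchor = replace(model.tx_to_cdna(t), intron_offset=off)
    return ParsedNotation(
        system="cdna", raw=parsed.raw, edit_kind=parsed.edit_kind or "substitution",
        cdna_start=anchor, ref=parsed.ref, alt=parsed.alt,
        rules_applied=parsed.rules_applied + ["ivs-to-cdna"],
    )


# ------------------------------------------------------------ 3' shifting
def _tx_direction(model: GeneModel) -> int:
    """Genomic step that moves one base toward the transcript 3' end."""
    return 1 if model.strand == "+" else -1


def _shift3_interval(model: GeneModel, s: int, e: int) -> tuple[int, int, bool]:
    """3'-shift a dup/del interval [s, e] (genomic, ascending) along the
    transcript direction while the flanking sequence permits.  Returns the
    shifted interval and whether any shift happened."""
    lo, hi = model.span
    d = _tx_direction(model)
    moved = False
    while True:
        if d > 0:
            if e + 1 <= hi and model.base_at(s) == model.base_at(e + 1):
                s, e = s + 1, e + 1
                moved = True
                continue
        else:
            if s - 1 >= lo and model.base_at(e) == model.base_at(s - 1):
                s, e = s - 1, e - 1
                moved = True
                continue
        return s, e, moved


def _shift3_insertion(model: GeneModel, pos: int, alt: str) -> tuple[int, str, bool]:
    """3'-shift an insertion (after plus-strand position ``pos``) along the
    transcript direction, rotating the inserted bases as it rolls."""
    lo, hi = model.span
    d = _tx_direction(model)
    moved = False
    while True:
        if d > 0:
            if pos + 1 <= hi and alt[0] == model.base_at(pos + 1):
                alt = alt[1:] + alt[0]
                pos += 1
                moved = True
                continue
        else:
            if pos >= lo and alt[-1] == model.base_at(pos):
                alt = alt[-1] + alt[:-1]
                pos -= 1
                moved = True
                continue
        return pos, alt, moved


def _ins_as_dup(model: GeneModel, pos: int, alt: str) -> tuple[int, int] | None:
    """If inserting ``alt`` after plus-strand ``pos`` duplicates the adjacent
    segment, return that segment's genomic interval."""
    k = len(alt)
    lo, hi = model.span
    if pos - k + 1 >= lo:
        seg = "".join(model.base_at(p) for p in range(pos - k + 1, pos + 1))
        if seg == alt:
            return pos - k + 1, pos
    if pos + k <= hi:
        seg = "".join(model.base_at(p) for p in range(pos + 1, pos + k + 1))
        if seg == alt:
            return pos + 1, pos + k
    return None


# ---------------------------------------------------------- normalization
def _genomic_interval_of(model: GeneModel, start: CdnaPosition, end: CdnaPosition | None,
                         length: int | None) -> tuple[int, int]:
    g1 = model.cdna_to_genomic(start)
    if end is not None:
        g2 = model.cdna_to_genomic(end)
    elif length is not None and length > 1:
        g2 = g1 + _tx_direction(model) * (length - 1)
    else:
        g2 = g1
    return (g1, g2) if g1 <= g2 else (g2, g1)


def _segment(model: GeneModel, s: int, e: int) -> str:
    return "".join(model.base_at(p) for p in range(s, e + 1))


def normalize_variant(parsed: ParsedNotation, model: GeneModel) -> NormalizedVariant:
    """Map a parsed cdna/ivs/genomic notation to its canonical genomic key."""
    if parsed.system == "ivs":
        parsed = ivs_to_chgvs(parsed, model)
    if parsed.system == "large_deletion":
        return _normalize_large_deletion(parsed, model)
    if parsed.system not in ("cdna", "genomic"):
        raise NormalizationError(
            f"cannot normalize a {parsed.system!r} notation directly: {parsed.raw!r}"
        )
    flags: set[str] = set()
    have_seq = model.sequence is not None
    kind = parsed.edit_kind
    chrom, build = model.chromosome, model.build_label

    if parsed.system == "cdna":
        if kind == "substitution":
            g = model.cdna_to_genomic(parsed.cdna_start)
            ref_t, alt_t = parsed.ref, parsed.alt
            if ref_t is None or alt_t is None:
                raise NormalizationError(f"substitution without alleles: {parsed.raw!r}")
            ref_g = ref_t if model.strand == "+" else _comp(ref_t)
            alt_g = alt_t if model.strand == "+" else _comp(alt_t)
            if have_seq and model.base_at(g) != ref_g:
                flags.add("ref-mismatch")
            key = GenomicKey(chrom, g, g, "sub", ref_g, alt_g, build)
        else:
            length = len(parsed.bases) if parsed.bases else None
            s, e = _genomic_interval_of(model, parsed.cdna_start, parsed.cdna_end, length)
            key, extra = _normalize_indel(model, kind, s, e, parsed.bases)
            flags |= extra
    else:  # genomic
        if parsed.chrom and parsed.chrom != chrom:
            raise NormalizationError(
                f"chromosome {parsed.chrom} does not match model {chrom}"
            )
        if kind == "substitution":
            g = parsed.g_start
            model.genomic_to_cdna(g)  # range check
            if have_seq and model.base_at(g) != parsed.ref:
                flags.add("ref-mismatch")
            key = GenomicKey(chrom, g, g, "sub", parsed.ref, parsed.alt, build)
        else:
            s = parsed.g_start
            e = parsed.g_end
            if e is None:
                e = s + (len(parsed.bases) - 1 if parsed.bases else 0)
            s, e = min(s, e), max(s, e)
            key, extra = _normalize_indel(model, kind, s, e, parsed.bases,
                                          bases_are_plus_strand=True)
            flags |= extra

    nv = NormalizedVariant(key=key, flags=flags)
    _annotate_canonical(nv, model)
    return nv


def _normalize_indel(model: GeneModel, kind: str, s: int, e: int,
                     bases: str | None, *, bases_are_plus_strand: bool = False
                     ) -> tuple[GenomicKey, set[str]]:
    flags: set[str] = set()
    have_seq = model.sequence is not None
    chrom, build = model.chromosome, model.build_label
    stated = None
    if bases:
        stated = bases if (bases_are_plus_strand or model.strand == "+") else _rc(bases)

    if kind in ("del", "dup"):
        if have_seq:
            seg = _segment(model, s, e)
            if stated is not None and stated != seg:
                flags.add("ref-mismatch")
            s, e, _ = _shift3_interval(model, s, e)
            seg = _segment(model, s, e)
        else:
            flags.add("not-shifted")
            seg = stated if stated is not None else "N" * (e - s + 1)
        if kind == "del":
            return GenomicKey(chrom, s, e, "del", seg, "", build), flags
        return GenomicKey(chrom, s, e, "dup", seg, seg * 2, build), flags

    if kind == "ins":
        if stated is None:
            raise NormalizationError("insertion without inserted bases")
        # anchor: insertion between s and e (HGVS flanking pair); the
        # plus-strand position the bases follow is min(s, e)
        pos = s
        alt = stated
        if have_seq:
            dup_iv = _ins_as_dup(model, pos, alt)
            if dup_iv is not None:
                ds, de = _shift3_interval(model, *dup_iv)[:2]
                seg = _segment(model, ds, de)
                return GenomicKey(chrom, ds, de, "dup", seg, seg * 2, build), flags
            pos, alt, _ = _shift3_insertion(model, pos, alt)
        else:
            flags.add("not-shifted")
        return GenomicKey(chrom, pos, pos + 1, "ins", "", alt, build), flags

    if kind == "delins":
        if have_seq:
            seg = _segment(model, s, e)
        else:
            seg = "N" * (e - s + 1)
            flags.add("not-shifted")
        return GenomicKey(chrom, s, e, "delins", seg, stated or "", build), flags

    raise NormalizationError(f"unsupported edit kind {kind!r}")


def _normalize_large_deletion(parsed: ParsedNotation, model: GeneModel) -> NormalizedVariant:
    if parsed.whole_gene:
        exons = tuple(range(1, len(model.exons) + 1))
    else:
        first = parsed.exon_first or 1
        last = parsed.exon_last or len(model.exons)
        if last > len(model.exons):
            raise NormalizationError(
                f"exon {last} out of range for {len(model.exons)}-exon model"
            )
        exons = tuple(range(first, last + 1))
    tx_lo = model.tx_exon_bounds(exons[0])[0]
    tx_hi = model.tx_exon_bounds(exons[-1])[1]
    g1, g2 = model.tx_to_genomic(tx_lo), model.tx_to_genomic(tx_hi)
    key = GenomicKey(model.chromosome, min(g1, g2), max(g1, g2), "large_del",
                     "", "", model.build_label, exons=exons)
    return NormalizedVariant(key=key)


def _annotate_canonical(nv: NormalizedVariant, model: GeneModel) -> None:
    """Fill canonical c./p. strings for a point-variant key."""
    key = nv.key
    if key.kind == "large_del":
        nv.canonical_chgvs = f"del(exons {key.exons[0]}-{key.exons[-1]})" if key.exons else None
        return
    c1 = model.genomic_to_cdna(key.start)
    c2 = model.genomic_to_cdna(key.end)
    if model.strand == "-":
        c1, c2 = c2, c1
    if key.kind == "sub":
        ref_t = key.ref if model.strand == "+" else _comp(key.ref)
        alt_t = key.alt if model.strand == "+" else _comp(key.alt)
        nv.canonical_chgvs = f"c.{c1}{ref_t}>{alt_t}"
        _protein_consequence(nv, model, key.start, ref_t, alt_t)
        return
    seg_t = key.ref if model.strand == "+" else _rc(key.ref)
    if key.kind == "del":
        rng = f"{c1}" if key.start == key.end else f"{c1}_{c2}"
        nv.canonical_chgvs = f"c.{rng}del{seg_t}"
    elif key.kind == "dup":
        rng = f"{c1}" if key.start == key.end else f"{c1}_{c2}"
        nv.canonical_chgvs = f"c.{rng}dup{seg_t}"
    elif key.kind == "ins":
        ins_t = key.alt if model.strand == "+" else _rc(key.alt)
        nv.canonical_chgvs = f"c.{c1}_{c2}ins{ins_t}"
    else:
        alt_t = key.alt if model.strand == "+" else _rc(key.alt)
        nv.canonical_chgvs = f"c.{c1}_{c2}delins{alt_t}"


def _protein_consequence(nv: NormalizedVariant, model: GeneModel,
                         gpos: int, ref_t: str, alt_t: str) -> None:
    """Annotate p. consequence of a coding substitution when sequence allows."""
    if model.sequence is None:
        return
    t = model.genomic_to_tx(gpos)
    if t is None or not model.cds_start_cdna <= t <= model.cds_end_cdna:
        return
    from Bio.Seq import Seq

    cds_off = t - model.cds_start_cdna
    residue = cds_off // 3 + 1
    frame = cds_off % 3
    cds = model.cds_sequence()
    codon = cds[cds_off - frame : cds_off - frame + 3]
    if len(codon) < 3:
        return
    aa_ref = str(Seq(codon).translate())
    mutated = codon[:frame] + alt_t + codon[frame + 1 :]
    aa_alt = str(Seq(mutated).translate())
    nv.protein_residue = residue
    if aa_alt == "*":
        aa_alt = "X"
    nv.canonical_phgvs = f"p.{aa_ref}{residue}{aa_alt}"


# ------------------------------------------------------- protein notation
def resolve_protein_notation(parsed: ParsedNotation, models,
                             mention_context: str | None = None):
    """Candidate genomic keys for a protein-level notation.

    If the same mention carries a cdna notation (``mention_context``), it
    pins the key.  Otherwise every single-nucleotide change of the actual
    codon (read from each candidate model's sequence) that produces the
    stated substitution is enumerated; more than one surviving key sets
    ``ambiguity``.  A residue that matches only a non-primary model (an
    alternate transcript numbering) is flagged ``transcript-mismatch``.

    Returns ``(keys, ambiguity, flags)``.
    """
    from Bio.Seq import Seq

    if parsed.system != "protein":
        raise NormalizationError(f"not a protein notation: {parsed.raw!r}")
    models = list(models)
    if mention_context is not None:
        ctx = parse_notation(mention_context)
        for model in models:
            try:
                nv = normalize_variant(ctx, model)
                return [nv.key], False, set()
            except (NormalizationError, CoordinateError):
                continue
        raise NormalizationError(f"context notation unusable: {mention_context!r}")

    if parsed.edit_kind == "frameshift":
        raise NormalizationError(
            f"frameshift protein notation is not resolvable to one key: {parsed.raw!r}"
        )
    keys: list[GenomicKey] = []
    flags: set[str] = set()
    matched_primary = False
    any_residue_ok = False
    for idx, model in enumerate(models):
        if model.sequence is None:
            continue
        cds = model.cds_sequence()
        r = parsed.aa_pos
        if r is None or r * 3 > len(cds):
            continue
        any_residue_ok = True
        codon = cds[(r - 1) * 3 : r * 3]
        if str(Seq(codon).translate()) != parsed.aa_ref:
            continue
        target = parsed.aa_alt if parsed.edit_kind != "nonsense" else "*"
        for frame in range(3):
            for b in "ACGT":
                if b == codon[frame]:
                    continue
                mutated = codon[:frame] + b + codon[frame + 1 :]
                if str(Seq(mutated).translate()) != target:
                    continue
                t = model.cds_start_cdna + (r - 1) * 3 + frame
                cpos = model.tx_to_cdna(t)
                nv = normalize_variant(
                    ParsedNotation(system="cdna", raw=parsed.raw,
                                   edit_kind="substitution", cdna_start=cpos,
                                   ref=codon[frame], alt=b),
                    model,
                )
                if nv.key not in keys:
                    keys.append(nv.key)
                    if idx == 0:
                        matched_primary = True
    if not any_residue_ok:
        raise NormalizationError(
            f"residue {parsed.aa_pos} beyond protein length for all models"
        )
    if keys and not matched_primary:
        flags.add("transcript-mismatch")
    return keys, len(keys) > 1, flags


# ---------------------------------------------------------- consolidation
_SYSTEM_PRIORITY = {"genomic": 0, "cdna": 1, "ivs": 2, "large_deletion": 3, "protein": 4}


def consolidate_mentions(mentions, model: GeneModel, alt_models=()):
    """Collapse raw mentions onto unique genomic keys.

    Every successfully normalized mention attaches to exactly one
    :class:`NormalizedVariant`; unresolvable mentions are listed with a
    reason, never dropped silently.  Output order (and the report counts)
    are invariant to the input permutation.
    """
    mentions = list(mentions)
    variants: dict[GenomicKey, NormalizedVariant] = {}
    unresolved: list[tuple[str, str]] = []
    models = [model] + list(alt_models)
    n_normalized = 0
    for m in mentions:
        parsed = sorted(
            (parse_notation(s) for s in m.notations),
            key=lambda p: _SYSTEM_PRIORITY.get(p.system, 9),
        )
        nv = None
        reason = "unparseable"
        for p in parsed:
            if p.system == "unparseable":
                continue
            try:
                if p.system == "protein":
                    keys, ambiguous, pflags = resolve_protein_notation(p, models)
                    if ambiguous:
                        reason = "protein-ambiguous"
                        continue
                    if not keys:
                        reason = "protein-unresolvable"
                        continue
                    nv = NormalizedVariant(key=keys[0], flags=set(pflags))
                    _annotate_canonical(nv, model)
                    if nv.protein_residue is None:
                        nv.protein_residue = p.aa_pos
                else:
                    nv = normalize_variant(p, model)
                break
            except (NormalizationError, CoordinateError) as exc:
                reason = str(exc)
                continue
        if nv is None:
            unresolved.append((m.mention_id, reason))
            logger.warning("mention %s unresolved: %s", m.mention_id, reason)
            continue
        n_normalized += 1
        tgt = variants.get(nv.key)
        if tgt is None:
            variants[nv.key] = nv
            tgt = nv
        else:
            tgt.flags |= nv.flags
            if tgt.protein_residue is None:
                tgt.protein_residue = nv.protein_residue
        tgt.aliases.update(m.notations)
        tgt.mention_ids.add(m.mention_id)
        ev = m.evidence
        if ev is not None and not getattr(ev, "is_empty", lambda: False)():
            tgt.evidence.append(ev)
    out = sorted(variants.values(), key=lambda v: v.uid)
    report = ConsolidationReport(
        n_raw=len(list(mentions)),
        n_unique=len(out),
        n_duplicates=n_normalized - len(out),
        unresolved=sorted(unresolved),
    )
    return out, report


# ------------------------------------------------- VCF-style allele pairs
def allele_pair_to_key(model: GeneModel, pos: int, ref: str, alt: str) -> GenomicKey:
    """Canonical key for a VCF-style (POS, REF, ALT) record.

    Trims shared prefix/suffix bases, classifies the edit, and 3'-shifts it
    through the same machinery as the notation path, so database exports and
    curated mentions land on identical keys regardless of representation.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    chrom, build = model.chromosome, model.build_label
    if len(ref) == 1 and len(alt) == 1:
        if model.sequence is not None and model.base_at(pos) != ref:
            raise NormalizationError(f"REF {ref} disagrees with sequence at {pos}")
        return GenomicKey(chrom, pos, pos, "sub", ref, alt, build)
    if len(ref) > len(alt) and ref.startswith(alt):
        s = pos + len(alt)
        e = pos + len(ref) - 1
        key, _ = _normalize_indel(model, "del", s, e, None)
        return key
    if len(alt) > len(ref) and alt.startswith(ref):
        anchor = pos + len(ref) - 1
        inserted = alt[len(ref):]
        key, _ = _normalize_indel(model, "ins", anchor, anchor + 1, inserted,
                                  bases_are_plus_strand=True)
        return key
    key, _ = _normalize_indel(model, "delins", pos, pos + len(ref) - 1, alt,
                              bases_are_plus_strand=True)
    return key


def key_to_allele_pair(model: GeneModel, key: GenomicKey) -> tuple[int, str, str]:
    """VCF-style (POS, REF, ALT) for a point-variant key (left-anchored)."""
    if key.kind == "sub":
        return key.start, key.ref, key.alt
    if key.kind == "del":
        anchor = key.start - 1
        base = model.base_at(anchor)
        return anchor, base + key.ref, base
    if key.kind == "dup":
        anchor = key.start - 1
        base = model.base_at(anchor)
        return anchor, base, base + key.ref
    if key.kind == "ins":
        base = model.base_at(key.start)
        return key.start, base, base + key.alt
    if key.kind == "delins":
        return key.start, key.ref, key.alt
    raise NormalizationError(f"no allele-pair form for kind {key.kind!r}")
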