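"""Parsing of published variant notation dialects.

Published variant mentions arrive in many shapes: standard coding-DNA HGVS
(``c.1540C>T``), legacy intron notation (``IVS12+32 C>A``), protein HGVS in
one- or three-letter code (``p.R514X`` / ``p.Arg514Ter``), raw genomic
coordinates (``chrX: NC_000023.11: 153,694,577 C > T``), free-text
multi-exon deletions, and several sloppy variants of each (extra spaces,
single-anchor duplications such as ``c.1016+41dupTGCCC``, offset-only range
ends such as ``c.1016+41_45dupTGCCC``).

:func:`parse_notation` is a *total* function over strings: anything it does
not recognize comes back with ``system="unparseable"`` instead of raising.
Every tolerated non-standard form is recorded by name in
``ParsedNotation.rules_applied`` so that dialect handling is auditable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .gene_model import CdnaPosition

__all__ = ["ParsedNotation", "parse_notation", "AA3_TO_1"]

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Ter": "*", "Sec": "U",
}


@dataclass
class ParsedNotation:
    system: str  # genomic | cdna | protein | ivs | large_deletion | unparseable
    raw: str
    edit_kind: str | None = None  # substitution|dup|del|ins|delins|frameshift|nonsense|large_del
    # cdna-system fields
    cdna_start: CdnaPosition | None = None
    cdna_end: CdnaPosition | None = None
    # genomic-system fields
    g_start: int | None = None
    g_end: int | None = None
    chrom: str | None = None
    accession: str | None = None
    # alleles / payload (transcript strand for c., plus strand for g.)
    ref: str | None = None
    alt: str | None = None
    bases: str | None = None  # dup/del/ins payload as printed
    # ivs-system fields
    ivs_intron: int | None = None
    ivs_offset: int | None = None
    # protein-system fields
    aa_ref: str | None = None
    aa_pos: int | None = None
    aa_alt: str | None = None
    # large-deletion fields
    exon_first: int | None = None
    exon_last: int | None = None
    whole_gene: bool = False
    rules_applied: list[str] = field(default_factory=list)


_CPOS = r"(?P<{p}sign>[-*]?)(?P<{p}base>\d+)(?P<{p}off>[+-]\d+)?"


def _cpos_re(prefix: str) -> str:
    return _CPOS.format(p=prefix)


def _make_cpos(sign: str, base: str, off: str | None) -> CdnaPosition:
    tag = {"": "none", "-": "5", "*": "3"}[sign]
    return CdnaPosition(int(base), int(off) if off else 0, utr_tag=tag)


_CDNA_SUB = re.compile(
    rf"^c\.{_cpos_re('a')}(?P<ref>[ACGTU])>(?P<alt>[ACGTU])$", re.I
)
_CDNA_RANGE_EDIT = re.compile(
    rf"^c\.{_cpos_re('a')}(?:_{_cpos_re('b')})?"
    r"(?P<op>delins|del|dup|ins)(?P<bases>[ACGTU]*)$",
    re.I,
)
_IVS = re.compile(
    r"^IVS(?P<intron>\d+)(?P<off>[+-]\d+)"
    r"(?:(?P<ref>[ACGTU])>(?P<alt>[ACGTU]))?$",
    re.I,
)
_PROT = re.compile(
    r"^p\.\(?(?P<ref>[A-Z][a-z]{2}|[A-Z*])(?P<pos>\d+)"
    r"(?P<alt>[A-Z][a-z]{2}|fs\*?\d*|fsX\d*|fs|[A-Z*])\)?$"
)
_GENOMIC = re.compile(
    r"^(?:(?P<chrom>chr[0-9XYM]+):)?(?:(?P<acc>N[CGMT]_\d+\.?\d*):?)?(?:g\.)?"
    r"(?P<start>[\d,]+)(?:_(?P<end>[\d,]+))?"
    r"(?:(?P<ref>[ACGTU]+)>(?P<alt>[ACGTU]+)"
    r"|(?P<op>delins|del|dup|ins)(?P<bases>[ACGTU]*))$",
    re.I,
)
_EXON_RANGE = re.compile(r"exons?\s*(\d+)(?:\s*(?:-|–|to|_)\s*(\d+))?", re.I)


def _squash(raw: str) -> tuple[str, list[str]]:
    rules = []
    s = raw.strip()
    if re.search(r"\s", s):
        rules.append("whitespace-tolerant")
        s = re.sub(r"\s+", "", s)
    return s, rules


def _parse_cdna(s: str, raw: str, rules: list[str]) -> ParsedNotation | None:
    m = _CDNA_SUB.match(s)
    if m:
        return ParsedNotation(
            system="cdna", raw=raw, edit_kind="substitution",
            cdna_start=_make_cpos(m["asign"], m["abase"], m["aoff"]),
            ref=m["ref"].upper().replace("U", "T"),
            alt=m["alt"].upper().replace("U", "T"),
            rules_applied=rules,
        )
    m = _CDNA_RANGE_EDIT.match(s)
    if m is None:
        return None
    op = m["op"].lower()
    bases = m["bases"].upper().replace("U", "T") or None
    start = _make_cpos(m["asign"], m["abase"], m["aoff"])
    end = None
    if m["bbase"] is not None:
        end = _make_cpos(m["bsign"], m["bbase"], m["boff"])
        # Sloppy dialect: the range end is only an intron offset, e.g.
        # c.1016+41_45dup  meaning  c.1016+41_1016+45dup
        if (
            start.intron_offset != 0
            and end.intron_offset == 0
            and end.utr_tag == "none"
            and int(m["bbase"]) < start.base
        ):
            end = CdnaPosition(start.base, int(m["bbase"]) * (1 if start.intron_offset > 0 else -1),
                               utr_tag=start.utr_tag)
            rules = rules + ["sloppy-offset-range-end"]
        # Sloppy dialect: c.1016_41dupTGCCC -> single anchor c.1016+41, the
        # "range end" is actually an intron offset on the start base.
        elif (
            start.intron_offset == 0
            and end.intron_offset == 0
            and start.utr_tag == "none"
            and end.utr_tag == "none"
            and end.base < start.base
        ):
            start = CdnaPosition(start.base, int(m["bbase"]))
            end = None
            rules = rules + ["sloppy-anchor-offset-pair"]
    return ParsedNotation(
        system="cdna", raw=raw, edit_kind=op,
        cdna_start=start, cdna_end=end, bases=bases,
        rules_applied=rules,
    )


def _aa1(code: str) -> str | None:
    if len(code) == 3:
        return AA3_TO_1.get(code)
    if code in "ACDEFGHIKLMNPQRSTVWY":
        return code
    if code in ("*", "X"):
        return "*"
    return None


def parse_notation(raw: str) -> ParsedNotation:
    """Parse one printed variant notation; never raises on bad input."""
    if not isinstance(raw, str) or not raw.strip():
        return ParsedNotation(system="unparseable", raw=str(raw))
    s, rules = _squash(raw)

    # free-text large deletions first (they contain spaces/words)
    low = raw.lower()
    if "deletion" in low or "deleted" in low or re.search(r"\bdel\b", low):
        if "whole gene" in low or "entire gene" in low or "whole-gene" in low:
            return ParsedNotation(
                system="large_deletion", raw=raw, edit_kind="large_del",
                whole_gene=True, rules_applied=rules + ["free-text-large-deletion"],
            )
        m = _EXON_RANGE.search(raw)
        if m:
            first = int(m.group(1))
            last = int(m.group(2)) if m.group(2) else first
            return ParsedNotation(
                system="large_deletion", raw=raw, edit_kind="large_del",
                exon_first=min(first, last), exon_last=max(first, last),
                rules_applied=rules + ["free-text-large-deletion"],
            )

    if s.lower().startswith("c."):
        p = _parse_cdna(s, raw, rules)
        if p is not None:
            return p
    m = _IVS.match(s)
    if m:
        p = ParsedNotation(
            system="ivs", raw=raw, edit_kind="substitution",
            ivs_intron=int(m["intron"]), ivs_offset=int(m["off"]),
            rules_applied=rules + ["legacy-ivs"],
        )
        if m["ref"]:
            p.ref = m["ref"].upper().replace("U", "T")
            p.alt = m["alt"].upper().replace("U", "T")
        return p
    if s.startswith("p."):
        m = _PROT.match(s)
        if m:
            ref1 = _aa1(m["ref"])
            alt_code = m["alt"]
            if alt_code.startswith("fs"):
                alt1, kind = None, "frameshift"
            else:
                alt1 = _aa1(alt_code)
                kind = "nonsense" if alt1 == "*" else "substitution"
            if ref1 is not None and (alt1 is not None or kind == "frameshift"):
                r = rules + (["one-letter-amino-acid"] if len(m["ref"]) == 1 else [])
                return ParsedNotation(
                    system="protein", raw=raw, edit_kind=kind,
                    aa_ref=ref1, aa_pos=int(m["pos"]), aa_alt=alt1,
                    rules_applied=r,
                )
    m = _GENOMIC.match(s)
    if m and (m["chrom"] or m["acc"] or "," in m["start"] or s.lower().find("g.") >= 0
              or len(m["start"]) >= 6):
        r = list(rules)
        if "," in m["start"] or (m["end"] and "," in m["end"]):
            r.append("digit-group-commas")
        start = int(m["start"].replace(",", ""))
        end = int(m["end"].replace(",", "")) if m["end"] else None
        if m["ref"]:
            return ParsedNotation(
                system="genomic", raw=raw, edit_kind="substitution",
                g_start=start, g_end=end or start,
                chrom=m["chrom"], accession=m["acc"],
                ref=m["ref"].upper(), alt=m["alt"].upper(), rules_applied=r,
            )
        op = m["op"].lower()
        return ParsedNotation(
            system="genomic", raw=raw, edit_kind=op,
            g_start=start, g_end=end,
            chrom=m["chrom"], accession=m["acc"],
            bases=(m["bases"].upper() or None), rules_applied=r,
        )
    return ParsedNotation(system="unparseable", raw=raw, rules_applied=rules)
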