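"""Single-transcript gene model: cDNA <-> genomic coordinate mapping.

A :class:`GeneModel` holds the exon structure of one transcript on one
chromosome, the cDNA offset of the first coding base, and (optionally) the
reference sequence of the genomic span.  All genomic coordinates are 1-based
and fully closed, matching the convention used when variants are printed as
e.g. ``chrX:153,694,577``.

cDNA ("c.") coordinates follow HGVS conventions:

* coding positions run ``c.1 .. c.<CDS length>``;
* 5' UTR positions are ``c.-k`` (k bases before the first coding base);
* 3' UTR positions are ``c.*k`` (k bases after the last coding base);
* intronic positions are written relative to the nearest exon boundary,
  ``c.<last exonic base>+k`` after a donor or ``c.<first exonic base>-k``
  before an acceptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "GeneModelError",
    "CoordinateError",
    "CdnaPosition",
    "GeneModel",
    "build_gene_model",
    "read_gene_model",
    "write_gene_model",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GeneModelError(ValueError):
    """Invalid gene model definition (overlapping exons, bad CDS offset...)."""


class CoordinateError(ValueError):
    """Position outside the transcript / gene span, or an invalid offset."""


@dataclass(frozen=True, order=True)
class CdnaPosition:
    """One c. coordinate, possibly with an intronic offset.

    ``base`` is interpreted according to ``utr_tag``:
    ``"none"`` -> coding position (1-based), ``"5"`` -> c.-base,
    ``"3"`` -> c.*base.  ``intron_offset`` is +k for positions k bases
    3' of an exon end and -k for positions k bases 5' of an exon start
    (both in transcript orientation); 0 for exonic positions.
    """

    base: int
    intron_offset: int = 0
    utr_tag: str = "none"  # "none" | "5" | "3"

    def __post_init__(self) -> None:
        if self.utr_tag not in ("none", "5", "3"):
            raise ValueError(f"bad utr_tag {self.utr_tag!r}")
        if self.base < 1:
            raise ValueError("CdnaPosition.base must be >= 1 (sign lives in utr_tag)")

    def __str__(self) -> str:
        if self.utr_tag == "5":
            s = f"-{self.base}"
        elif self.utr_tag == "3":
            s = f"*{self.base}"
        else:
            s = str(self.base)
        if self.intron_offset > 0:
            s += f"+{self.intron_offset}"
        elif self.intron_offset < 0:
            s += str(self.intron_offset)
        return s


@dataclass(frozen=True)
class GeneModel:
    gene_symbol: str
    chromosome: str
    build_label: str
    strand: str  # "+" or "-"
    exons: tuple[tuple[int, int], ...]  # genomic, 1-based closed, ascending start
    cds_start_cdna: int
    cds_end_cdna: int | None = None  # cDNA position of last coding base
    sequence: str | None = None  # genomic plus-strand bases over the span
    # derived, filled in __post_init__
    _tx_exons: tuple[tuple[int, int], ...] = field(default=(), repr=False, compare=False)
    _tx_starts: tuple[int, ...] = field(default=(), repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise GeneModelError("gene model needs at least one exon")
        prev_end = None
        for s, e in self.exons:
            if s > e or s < 1:
                raise GeneModelError(f"bad exon interval ({s}, {e})")
            if prev_end is not None and s <= prev_end:
                raise GeneModelError("exons overlap or are unsorted")
            prev_end = e
        # transcript order: 5'->3' of the mRNA
        tx = self.exons if self.strand == "+" else tuple(reversed(self.exons))
        starts = []
        t = 1
        for s, e in tx:
            starts.append(t)
            t += e - s + 1
        object.__setattr__(self, "_tx_exons", tx)
        object.__setattr__(self, "_tx_starts", tuple(starts))
        if not 1 <= self.cds_start_cdna <= self.tx_length:
            raise GeneModelError(
                f"cds_start_cdna {self.cds_start_cdna} outside transcript of "
                f"length {self.tx_length}"
            )
        cds_end = self.cds_end_cdna
        if cds_end is None:
            object.__setattr__(self, "cds_end_cdna", self.tx_length)
        elif not self.cds_start_cdna <= cds_end <= self.tx_length:
            raise GeneModelError(f"cds_end_cdna {cds_end} outside transcript")
        if self.sequence is not None and len(self.sequence) != self.span_length:
            raise GeneModelError(
                f"sequence length {len(self.sequence)} != gene span {self.span_length}"
            )

    # ------------------------------------------------------------------ span
    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def span_length(self) -> int:
        s, e = self.span
        return e - s + 1

    @property
    def tx_length(self) -> int:
        return self._tx_starts[-1] + (
            self._tx_exons[-1][1] - self._tx_exons[-1][0] + 1
        ) - 1

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def cds_length(self) -> int:
        return self.cds_end_cdna - self.cds_start_cdna + 1

    # ------------------------------------------------------------- sequence
    def base_at(self, gpos: int) -> str:
        """Plus-strand reference base at a genomic position."""
        if self.sequence is None:
            raise CoordinateError("gene model carries no sequence")
        lo, hi = self.span
        if not lo <= gpos <= hi:
            raise CoordinateError(f"genomic position {gpos} outside span {self.span}")
        return self.sequence[gpos - lo].upper()

    def tx_base_at(self, gpos: int) -> str:
        """Transcript-strand base at a genomic position."""
        b = self.base_at(gpos)
        return b if self.strand == "+" else b.translate(_COMPLEMENT)

    def transcript_sequence(self) -> str:
        """Spliced mRNA sequence (transcript strand)."""
        if self.sequence is None:
            raise CoordinateError("gene model carries no sequence")
        lo = self.span[0]
        parts = [self.sequence[s - lo : e - lo + 1] for s, e in self.exons]
        seq = "".join(parts).upper()
        return seq if self.strand == "+" else revcomp(seq)

    def cds_sequence(self) -> str:
        return self.transcript_sequence()[self.cds_start_cdna - 1 : self.cds_end_cdna]

    # ------------------------------------------------- transcript coordinate
    def tx_to_genomic(self, t: int) -> int:
        if not 1 <= t <= self.tx_length:
            raise CoordinateError(f"transcript position {t} outside 1..{self.tx_length}")
        for (s, e), ts in zip(self._tx_exons, self._tx_starts):
            if ts <= t <= ts + (e - s):
                return s + (t - ts) if self.strand == "+" else e - (t - ts)
        raise AssertionError("unreachable")

    def genomic_to_tx(self, gpos: int) -> int | None:
        """Transcript coordinate for an exonic genomic position, else None."""
        lo, hi = self.span
        if not lo <= gpos <= hi:
            raise CoordinateError(f"genomic position {gpos} outside span {self.span}")
        for (s, e), ts in zip(self._tx_exons, self._tx_starts):
            if s <= gpos <= e:
                return ts + (gpos - s if self.strand == "+" else e - gpos)
        return None

    def tx_exon_bounds(self, exon_index: int) -> tuple[int, int]:
        """(first, last) transcript coordinate of transcript-order exon (1-based)."""
        if not 1 <= exon_index <= len(self.exons):
            raise CoordinateError(f"exon index {exon_index} out of range")
        s, e = self._tx_exons[exon_index - 1]
        ts = self._tx_starts[exon_index - 1]
        return ts, ts + (e - s)

    def intron_length(self, intron_index: int) -> int:
        """Length of transcript-order intron ``intron_index`` (1-based)."""
        if not 1 <= intron_index <= self.n_introns:
            raise CoordinateError(f"intron index {intron_index} out of range")
        a = self._tx_exons[intron_index - 1]
        b = self._tx_exons[intron_index]
        if self.strand == "+":
            return b[0] - a[1] - 1
        return a[0] - b[1] - 1

    # -------------------------------------------------------- c. coordinate
    def cdna_to_tx(self, pos: CdnaPosition) -> int:
        if pos.utr_tag == "5":
            t = self.cds_start_cdna - pos.base
        elif pos.utr_tag == "3":
            t = self.cds_end_cdna + pos.base
        else:
            t = self.cds_start_cdna + pos.base - 1
            if pos.base > self.cds_length and pos.intron_offset == 0 and t > self.tx_length:
                raise CoordinateError(f"c.{pos} beyond transcript")
        if not 1 <= t <= self.tx_length:
            raise CoordinateError(f"c.{pos} outside transcript")
        return t

    def tx_to_cdna(self, t: int) -> CdnaPosition:
        if not 1 <= t <= self.tx_length:
            raise CoordinateError(f"transcript position {t} outside transcript")
        if t < self.cds_start_cdna:
            return CdnaPosition(self.cds_start_cdna - t, utr_tag="5")
        if t > self.cds_end_cdna:
            return CdnaPosition(t - self.cds_end_cdna, utr_tag="3")
        return CdnaPosition(t - self.cds_start_cdna + 1)

    # --------------------------------------------------------- main mapping
    def _tx_exon_index_of(self, t: int) -> int:
        for i in range(len(self._tx_exons)):
            a, b = self.tx_exon_bounds(i + 1)
            if a <= t <= b:
                return i + 1
        raise CoordinateError(f"transcript position {t} not exonic")

    def cdna_to_genomic(self, pos: CdnaPosition) -> int:
        """Genomic coordinate of a c. position (strand-aware).

        Intronic offsets must be anchored at the adjacent exon boundary, as
        HGVS requires: +k anchors at the last base of an exon, -k at the
        first base of the next exon.
        """
        t = self.cdna_to_tx(pos)
        g = self.tx_to_genomic(t)
        off = pos.intron_offset
        if off == 0:
            return g
        i = self._tx_exon_index_of(t)
        a, b = self.tx_exon_bounds(i)
        if off > 0:
            if t != b:
                raise CoordinateError(f"c.{pos}: +offset not anchored at an exon end")
            # a far-anchor form may reach the last intron base (offset == length)
            if i > self.n_introns or off > self.intron_length(i):
                raise CoordinateError(f"c.{pos}: offset spans past intron {i}")
        else:
            if t != a:
                raise CoordinateError(f"c.{pos}: -offset not anchored at an exon start")
            if i == 1 or -off > self.intron_length(i - 1):
                raise CoordinateError(f"c.{pos}: offset spans past intron {i - 1}")
        return g + off if self.strand == "+" else g - off

    def genomic_to_cdna(self, gpos: int) -> CdnaPosition:
        """Inverse of :meth:`cdna_to_genomic`.

        Intronic positions are reported relative to the *nearer* exon
        boundary; at the exact midpoint of an intron the upstream (+k)
        form is used, giving a deterministic canonical representation.
        """
        t = self.genomic_to_tx(gpos)
        if t is not None:
            return self.tx_to_cdna(t)
        # intronic: locate flanking transcript-order exons
        for i in range(1, len(self._tx_exons)):
            up = self._tx_exons[i - 1]
            down = self._tx_exons[i]
            if self.strand == "+":
                inside = up[1] < gpos < down[0]
                d_up = gpos - up[1]
                d_down = down[0] - gpos
            else:
                inside = down[1] < gpos < up[0]
                d_up = up[0] - gpos
                d_down = gpos - down[1]
            if inside:
                if d_up <= d_down:
                    base = self.tx_to_cdna(self.tx_exon_bounds(i)[1])
                    return replace(base, intron_offset=d_up)
                base = self.tx_to_cdna(self.tx_exon_bounds(i + 1)[0])
                return replace(base, intron_offset=-d_down)
        raise CoordinateError(f"genomic position {gpos} not in gene span")

    def region_of(self, pos: CdnaPosition) -> str:
        """One of ``exonic``, ``intronic``, ``utr5``, ``utr3``."""
        if pos.intron_offset != 0:
            return "intronic"
        self.cdna_to_tx(pos)  # range check
        if pos.utr_tag == "5":
            return "utr5"
        if pos.utr_tag == "3":
            return "utr3"
        return "exonic"

    def format_cdna(self, pos: CdnaPosition) -> str:
        return f"c.{pos}"


def build_gene_model(
    exons,
    strand: str = "+",
    cds_start_cdna: int = 1,
    sequence: str | None = None,
    *,
    cds_end_cdna: int | None = None,
    gene_symbol: str = "GENE",
    chromosome: str = "chrX",
    build_label: str = "synthetic-1",
) -> GeneModel:
    """Validate and construct a :class:`GeneModel`."""
    return GeneModel(
        gene_symbol=gene_symbol,
        chromosome=chromosome,
        build_label=build_label,
        strand=strand,
        exons=tuple(tuple(x) for x in exons),
        cds_start_cdna=cds_start_cdna,
        cds_end_cdna=cds_end_cdna,
        sequence=sequence,
    )


# --------------------------------------------------------------------- I/O
def write_gene_model(model: GeneModel, path, fasta_path=None) -> None:
    """TSV with a ``# key=value`` header block and (exon_index, g_start, g_end) rows."""
    with open(path, "w") as fh:
        fh.write(f"# gene={model.gene_symbol}\n")
        fh.write(f"# chrom={model.chromosome}\n")
        fh.write(f"# build={model.build_label}\n")
        fh.write(f"# strand={model.strand}\n")
        fh.write(f"# cds_start={model.cds_start_cdna}\n")
        fh.write(f"# cds_end={model.cds_end_cdna}\n")
        fh.write("exon_index\tg_start\tg_end\n")
        for i, (s, e) in enumerate(model.exons, 1):
            fh.write(f"{i}\t{s}\t{e}\n")
    if fasta_path is not None and model.sequence is not None:
        with open(fasta_path, "w") as fh:
            fh.write(f">{model.gene_symbol} {model.chromosome}:{model.span[0]}-{model.span[1]}\n")
            seq = model.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_gene_model(path, fasta_path=None) -> GeneModel:
    meta: dict[str, str] = {}
    exons: list[tuple[int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                k, _, v = line.lstrip("# ").partition("=")
                meta[k.strip()] = v.strip()
            elif not line.startswith("exon_index"):
                _, s, e = line.split("\t")
                exons.append((int(s), int(e)))
    sequence = None
    if fasta_path is not None:
        from Bio import SeqIO

        sequence = str(next(SeqIO.parse(str(fasta_path), "fasta")).seq)
    cds_end = meta.get("cds_end")
    return build_gene_model(
        exons,
        strand=meta.get("strand", "+"),
        cds_start_cdna=int(meta.get("cds_start", 1)),
        cds_end_cdna=None if cds_end in (None, "None", "") else int(cds_end),
        sequence=sequence,
        gene_symbol=meta.get("gene", "GENE"),
        chromosome=meta.get("chrom", "chrX"),
        build_label=meta.get("build", "synthetic-1"),
    )
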