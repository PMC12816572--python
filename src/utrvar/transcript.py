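"""Strand-aware coordinate system for a 5'UTR plus the first main-ORF codon.

Ties together three coordinate conventions:

* genomic positions (1-based, inclusive intervals, VCF-style, plus strand);
* 0-based transcript offsets from the 5' cap (internal representation);
* HGVS-like signed ``c.`` values, where ``c.-k`` indexes UTR bases counting
  back from the main AUG and ``c.1`` is the A of the main AUG (there is no
  ``c.0``).

The modelled region is the contiguous 5'UTR plus the first three CDS bases;
multi-exon UTRs are out of scope.  On the minus strand the cap base is the
maximum genomic coordinate of the UTR interval and the CDS start lies one
below its minimum; mirrored on the plus strand.
"""

from __future__ import annotations

from dataclasses import dataclass


class CoordinateError(ValueError):
    """A genomic or transcript position falls outside the modelled region."""


@dataclass(frozen=True)
class TranscriptModel:
    """Genomic anchoring of a single-exon 5'UTR and its main-ORF start.

    Parameters
    ----------
    chrom : chromosome name.
    strand : ``"+"`` or ``"-"``.
    utr5_start, utr5_end : 1-based inclusive genomic interval of the 5'UTR.
    cds_start_genomic : genomic position of the first base (the A) of the
        main-ORF AUG; must be adjacent to the UTR interval on the coding side.
    transcript_id : free-text label.
    """

    chrom: str
    strand: str
    utr5_start: int
    utr5_end: int
    cds_start_genomic: int
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.utr5_end < self.utr5_start:
            raise ValueError("utr5_end must be >= utr5_start")
        if self.strand == "-" and self.cds_start_genomic != self.utr5_start - 1:
            raise ValueError(
                "on the minus strand cds_start_genomic must be one below the "
                f"UTR minimum ({self.utr5_start - 1}), got {self.cds_start_genomic}"
            )
        if self.strand == "+" and self.cds_start_genomic != self.utr5_end + 1:
            raise ValueError(
                "on the plus strand cds_start_genomic must be one above the "
                f"UTR maximum ({self.utr5_end + 1}), got {self.cds_start_genomic}"
            )

    @property
    def utr_length(self) -> int:
        return self.utr5_end - self.utr5_start + 1

    @property
    def cap_genomic(self) -> int:
        """Genomic coordinate of the 5' cap base."""
        return self.utr5_end if self.strand == "-" else self.utr5_start

    @classmethod
    def from_config(cls, config: dict) -> "TranscriptModel":
        """Build from a key-value block (chrom, strand, utr5_start, utr5_end,
        cds_start, transcript_id)."""
        known = {"chrom", "strand", "utr5_start", "utr5_end", "cds_start", "transcript_id"}
        unknown = set(config) - known
        if unknown:
            raise ValueError(f"unknown transcript config keys: {sorted(unknown)}")
        return cls(
            chrom=str(config["chrom"]),
            strand=str(config["strand"]),
            utr5_start=int(config["utr5_start"]),
            utr5_end=int(config["utr5_end"]),
            cds_start_genomic=int(config["cds_start"]),
            transcript_id=str(config.get("transcript_id", "")),
        )

    @classmethod
    def from_bed_line(cls, line: str) -> "TranscriptModel":
        """Build from a 5-column BED-like line: chrom, start (0-based),
        end (exclusive), name, strand.  The CDS start is taken as the base
        adjacent to the interval on the coding side."""
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 5:
            raise ValueError("need 5 BED columns: chrom, start, end, name, strand")
        chrom, start0, end, name, strand = fields[:5]
        utr5_start = int(start0) + 1
        utr5_end = int(end)
        cds = utr5_start - 1 if strand == "-" else utr5_end + 1
        return cls(chrom, strand, utr5_start, utr5_end, cds, name)


@dataclass(frozen=True)
class TxPosition:
    """A transcript-relative position.

    ``c_value`` is the signed HGVS-like coordinate (negative = UTR, positive =
    CDS); ``offset_from_cap`` the 0-based distance from the cap base.  For UTR
    bases ``offset_from_cap = utr_length + c_value``.
    """

    c_value: int
    offset_from_cap: int

    def __post_init__(self) -> None:
        if self.c_value == 0:
            raise CoordinateError("there is no c.0")


def genomic_to_tx(model: TranscriptModel, gpos: int) -> TxPosition:
    """Map a genomic position to its transcript coordinate.

    Accepts positions within the 5'UTR or the first three CDS bases.  On the
    minus strand increasing genomic position maps to decreasing cap offset.
    """
    L = model.utr_length
    if model.strand == "-":
        in_utr = model.utr5_start <= gpos <= model.utr5_end
        in_cds = model.cds_start_genomic - 2 <= gpos <= model.cds_start_genomic
        if in_utr:
            offset = model.utr5_end - gpos
            return TxPosition(c_value=offset - L, offset_from_cap=offset)
        if in_cds:
            c = model.cds_start_genomic - gpos + 1
            return TxPosition(c_value=c, offset_from_cap=L + c - 1)
    else:
        in_utr = model.utr5_start <= gpos <= model.utr5_end
        in_cds = model.cds_start_genomic <= gpos <= model.cds_start_genomic + 2
        if in_utr:
            offset = gpos - model.utr5_start
            return TxPosition(c_value=offset - L, offset_from_cap=offset)
        if in_cds:
            c = gpos - model.cds_start_genomic + 1
            return TxPosition(c_value=c, offset_from_cap=L + c - 1)
    raise CoordinateError(
        f"g.{gpos} outside modelled region {model.chrom}:"
        f"{model.utr5_start}-{model.utr5_end} (+first CDS codon) on {model.strand}"
    )


def tx_to_genomic(model: TranscriptModel, pos: "TxPosition | int") -> int:
    """Exact inverse of :func:`genomic_to_tx`.

    ``pos`` may be a :class:`TxPosition` or a bare signed c. value in
    ``[-utr_length, 3]`` (excluding 0).
    """
    c = pos.c_value if isinstance(pos, TxPosition) else int(pos)
    L = model.utr_length
    if c == 0:
        raise CoordinateError("there is no c.0")
    if not (-L <= c <= 3):
        raise CoordinateError(f"c.{c} outside modelled range [-{L}, 3]")
    if model.strand == "-":
        if c < 0:
            return model.utr5_end - (L + c)
        return model.cds_start_genomic - (c - 1)
    if c < 0:
        return model.utr5_start + (L + c)
    return model.cds_start_genomic + (c - 1)


def c_to_offset(c_value: int, utr_length: int) -> int:
    """Signed c. value -> 0-based cap offset (UTR bases only)."""
    if c_value == 0:
        raise CoordinateError("there is no c.0")
    if c_value > 0:
        raise CoordinateError(f"c.{c_value} is not a UTR position")
    offset = utr_length + c_value
    if not 0 <= offset < utr_length:
        raise CoordinateError(f"c.{c_value} outside UTR of length {utr_length}")
    return offset


def offset_to_c(offset: int, utr_length: int) -> int:
    """0-based cap offset -> signed c. value (UTR bases only)."""
    if not 0 <= offset < utr_length:
        raise CoordinateError(f"offset {offset} outside UTR of length {utr_length}")
    return offset - utr_length


def pkd1_like_model() -> TranscriptModel:
    """The PKD1-like transcript anchoring used by the synthetic fixture.

    209-nt 5'UTR on the genomic minus strand of chr16, spanning
    2,135,690-2,135,898 (GRCh38 numbering), main-ORF A at 2,135,689.
    """
    return TranscriptModel(
        chrom="chr16",
        strand="-",
        utr5_start=2_135_690,
        utr5_end=2_135_898,
        cds_start_genomic=2_135_689,
        transcript_id="PKD1-like",
    )
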