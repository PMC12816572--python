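"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython, VCF via pysam (uncompressed text), conservation tracks
and variant tables as TSV, reports as TSV/JSON.  VCF records are plus-strand
genomic; conversion to/from transcript ``c.`` coordinates goes through the
transcript model, including the strand flip of REF/ALT alleles and the
anchor-base convention for insertions (a transcript duplication on a
minus-strand gene is written as a left-aligned plus-strand insertion).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scanner import ConservationTrack, UOrf, UtrSequence
from .transcript import TranscriptModel, genomic_to_tx, tx_to_genomic
from .variants import VariantError, VariantSpec, parse_hgvs_c

_COMP = str.maketrans("ACGT", "TGCA")


def _comp(s: str) -> str:
    return s.translate(_COMP)


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA


def write_utr_fasta(utr: UtrSequence, path: str, name: str = "utr5") -> None:
    records = [
        SeqRecord(Seq(utr.seq), id=name, description="5'UTR in mRNA orientation"),
        SeqRecord(Seq(utr.cds_prefix), id=f"{name}_cds_prefix", description="CDS prefix"),
    ]
    SeqIO.write(records, path, "fasta")


def read_utr_fasta(
    path: str,
    utr_id: Optional[str] = None,
    cds_prefix_id: Optional[str] = None,
    cds_offset: Optional[int] = None,
) -> UtrSequence:
    """Read a UTR either as two records (UTR + CDS-prefix) or as one record
    split at ``cds_offset`` (the 0-based position of the main AUG)."""
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    try:
        if cds_offset is not None:
            seq = str(records[0].seq).upper()
            return UtrSequence(seq=seq[:cds_offset], cds_prefix=seq[cds_offset:])
        if len(records) < 2:
            raise ParseError(f"{path}: need UTR and CDS-prefix records (or cds_offset)")
        by_id = {r.id: str(r.seq).upper() for r in records}
        utr_id = utr_id or records[0].id
        cds_prefix_id = cds_prefix_id or records[1].id
        return UtrSequence(seq=by_id[utr_id], cds_prefix=by_id[cds_prefix_id])
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# conservation tracks: 2-column TSV (cap_offset, score) per channel


def read_conservation_tsv(
    basewise_path: Optional[str] = None,
    elementwise_path: Optional[str] = None,
    basewise_min: float = 2.0,
    elementwise_min: float = 0.8,
) -> ConservationTrack:
    def _read(path: Optional[str]) -> dict[int, float]:
        if path is None:
            return {}
        df = pd.read_csv(path, sep="\t", header=None, names=["offset", "score"], comment="#")
        return {int(r.offset): float(r.score) for r in df.itertuples()}

    return ConservationTrack(
        basewise=_read(basewise_path),
        elementwise=_read(elementwise_path),
        basewise_min=basewise_min,
        elementwise_min=elementwise_min,
    )


def write_conservation_tsv(track: ConservationTrack, basewise_path: str, elementwise_path: str) -> None:
    for path, channel in ((basewise_path, track.basewise), (elementwise_path, track.elementwise)):
        pd.DataFrame(sorted(channel.items()), columns=["offset", "score"]).to_csv(
            path, sep="\t", index=False, header=False
        )


# ---------------------------------------------------------------------------
# variant tables


def read_variant_table(path: str) -> list[tuple[str, list[VariantSpec]]]:
    """TSV of HGVS-like c. strings with optional af / splice_score columns.

    Columns: ``hgvs`` (';'-separated for in-phase multi-edit constructs),
    optional ``construct`` label, optional ``af``, ``splice_score``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"hgvs": str}, comment="#")
    if "hgvs" not in df.columns:
        raise ParseError(f"{path}: missing required column 'hgvs'")
    out = []
    for i, row in df.iterrows():
        hgvs = str(row["hgvs"]).strip()
        if not hgvs or hgvs == "nan":
            specs: list[VariantSpec] = []
        else:
            try:
                specs = [parse_hgvs_c(tok) for tok in hgvs.split(";")]
            except VariantError as exc:
                raise ParseError(f"{path}: line {i + 2}: {exc}") from exc
        af = row.get("af")
        splice = row.get("splice_score")
        from dataclasses import replace as _replace

        specs = [
            _replace(
                s,
                af=None if pd.isna(af) else float(af),
                splice_score=None if pd.isna(splice) else float(splice),
            )
            for s in specs
        ]
        label = str(row["construct"]) if "construct" in df.columns else hgvs
        out.append((label, specs))
    return out


# ---------------------------------------------------------------------------
# VCF


def variant_to_vcf_record(
    spec: VariantSpec, utr: UtrSequence, model: TranscriptModel
) -> tuple[str, int, str, str]:
    """(chrom, pos, ref, alt) for one transcript variant, plus-strand style.

    Substitutions map directly (with complementing on the minus strand).  A
    duplication is first normalised to the 3'-most transcript position, then
    written as a plus-strand insertion after the anchor base preceding the
    duplicated run — on a minus-strand gene this is the base one below the
    run's minimum genomic coordinate.
    """
    from .variants import _resolve  # resolved against the concrete sequence

    edit = _resolve(utr, spec)
    minus = model.strand == "-"
    if spec.kind == "substitution":
        g = tx_to_genomic(model, spec.start_c)
        ref = _comp(spec.ref) if minus else spec.ref
        alt = _comp(spec.alt) if minus else spec.alt
        return model.chrom, g, ref, alt
    if spec.kind == "duplication":
        c_norm = edit.start - utr.utr_length
        g_dup = tx_to_genomic(model, c_norm)
        if minus:
            anchor = g_dup - 1
            anchor_tx_offset = edit.start + 1
            anchor_ref = (
                _comp(utr.seq[anchor_tx_offset])
                if anchor_tx_offset < utr.utr_length
                else _comp(utr.cds_prefix[0])
            )
            return model.chrom, anchor, anchor_ref, anchor_ref + _comp(spec.ref)
        anchor = g_dup
        return model.chrom, anchor, utr.seq[edit.start], utr.seq[edit.start] + spec.ref
    raise VariantError(f"VCF export not supported for kind {spec.kind!r}")


def write_vcf(
    variants: list[VariantSpec], utr: UtrSequence, model: TranscriptModel, path: str
) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={model.chrom}>")
    header.add_line('##INFO=<ID=HGVSC,Number=1,Type=String,Description="Transcript c. notation">')
    records = []
    for spec in variants:
        chrom, pos, ref, alt = variant_to_vcf_record(spec, utr, model)
        records.append((pos, ref, alt, spec.label))
    records.sort()
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for pos, ref, alt, label in records:
            rec = vcf.new_record(
                contig=model.chrom, start=pos - 1, stop=pos - 1 + len(ref), alleles=(ref, alt)
            )
            if label:
                rec.info["HGVSC"] = label.replace(" ", "_")
            vcf.write(rec)


def read_vcf(path: str, utr: UtrSequence, model: TranscriptModel) -> list[VariantSpec]:
    """Read plus-strand VCF records and convert each to a transcript variant.

    SNVs and simple insertions (anchor-base convention) are supported; an
    insertion whose inserted bases equal the adjacent transcript base becomes
    a duplication.
    """
    import pysam

    minus = model.strand == "-"
    out = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) == 1 and len(alt) == 1:
                tx = genomic_to_tx(model, rec.pos)
                tref = _comp(ref) if minus else ref
                talt = _comp(alt) if minus else alt
                out.append(
                    VariantSpec(
                        "substitution",
                        tx.c_value,
                        tx.c_value,
                        ref=tref,
                        alt=talt,
                        label=f"c.{tx.c_value}{tref}>{talt}",
                    )
                )
            elif len(alt) > len(ref) and alt.startswith(ref) and len(ref) == 1:
                inserted_plus = alt[1:]
                if minus:
                    # insertion after plus-strand pos == insertion after the
                    # transcript base at pos+len on the other side
                    g_first_after = rec.pos + 1
                    tx = genomic_to_tx(model, g_first_after)
                    inserted_tx = _revcomp(inserted_plus)
                    anchor_offset = tx.offset_from_cap
                    base_before = utr.seq[anchor_offset]
                    if inserted_tx == base_before * len(inserted_tx):
                        c = anchor_offset - utr.utr_length
                        out.append(
                            VariantSpec(
                                "duplication", c, c, ref=base_before,
                                label=f"c.{c}dup{base_before}",
                            )
                        )
                    else:
                        c1 = anchor_offset - utr.utr_length
                        out.append(
                            VariantSpec(
                                "insertion", c1, c1 + 1, alt=inserted_tx,
                                label=f"c.{c1}_{c1 + 1}ins{inserted_tx}",
                            )
                        )
                else:
                    tx = genomic_to_tx(model, rec.pos)
                    c1 = tx.c_value
                    if inserted_plus == utr.seq[tx.offset_from_cap] * len(inserted_plus):
                        out.append(
                            VariantSpec(
                                "duplication", c1, c1, ref=inserted_plus[0],
                                label=f"c.{c1}dup{inserted_plus[0]}",
                            )
                        )
                    else:
                        out.append(
                            VariantSpec(
                                "insertion", c1, c1 + 1, alt=inserted_plus,
                                label=f"c.{c1}_{c1 + 1}ins{inserted_plus}",
                            )
                        )
            else:
                raise ParseError(f"{path}: unsupported VCF record at pos {rec.pos}")
    return out


# ---------------------------------------------------------------------------
# reports


def uorf_report_frame(uorfs: list[UOrf]) -> pd.DataFrame:
    return pd.DataFrame([asdict(u) for u in uorfs])


def write_uorf_report(uorfs: list[UOrf], tsv_path: str, json_path: Optional[str] = None) -> None:
    df = uorf_report_frame(uorfs)
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path:
        with open(json_path, "w") as fh:
            json.dump([asdict(u) for u in uorfs], fh, indent=2)
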