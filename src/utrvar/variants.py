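"""5'UTR variant parsing, application and consequence classification.

Variants are expressed in transcript ``c.`` coordinates (a small HGVS-like
subset: substitution, single-base duplication, deletion, insertion).  A
variant's translational consequence is derived purely from the structural
diff of the upstream-ORF architecture before and after the edit, plus Kozak
class changes at surviving starts and at the main AUG.

Consequence codes, ranked by severity (most severe first):

``uStop_lost_oORF``       a uORF stop is lost and reading continues past the
                          main AUG (overlapping ORF; out-of-frame read-through
                          represses the main ORF).
``uAUG_created_oORF``     a new AUG opens an overlapping ORF.
``uStop_lost_extension``  a uORF stop is lost but a new in-frame stop still
                          terminates within the UTR.
``uAUG_created_uORF``     a new AUG opens a contained uORF.
``uAUG_created_NTE``      a new AUG in frame with the CDS extends the protein
                          N-terminus.
``uStart_lost``           an existing upstream AUG is destroyed.
``uFrameshift``           an indel shifts a uORF's frame (secondary whenever a
                          stop change is also called).
``uAA_substitution``      the uORF peptide changes (including truncating
                          stop-gains within the uORF).
``kozak_changed_uORF``    the Kozak strength class of a uORF start changes.
``kozak_changed_mORF``    the Kozak strength class of the main AUG changes.
``uSynonymous``           uORF nucleotides change, peptide unchanged.
``no_uorf_change``        nothing above applies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .scanner import (
    CONTAINED_UORF,
    N_TERMINAL_EXTENSION,
    OVERLAPPING_OORF,
    UtrSequence,
    _first_inframe_stop,
    kozak_class,
)
from .transcript import c_to_offset, offset_to_c

SEVERITY_ORDER = [
    "uStop_lost_oORF",
    "uAUG_created_oORF",
    "uStop_lost_extension",
    "uAUG_created_uORF",
    "uAUG_created_NTE",
    "uStart_lost",
    "uFrameshift",
    "uAA_substitution",
    "kozak_changed_uORF",
    "kozak_changed_mORF",
    "uSynonymous",
    "no_uorf_change",
]
_RANK = {code: i for i, code in enumerate(SEVERITY_ORDER)}

DEFAULT_SPLICE_THRESHOLD = 0.05


class VariantError(ValueError):
    """Malformed, out-of-range or reference-mismatching variant."""


@dataclass(frozen=True)
class VariantSpec:
    """One 5'UTR variant in transcript coordinates.

    ``start_c``/``end_c`` are signed c. values (UTR positions are negative).
    For substitutions and duplications ``end_c == start_c``.  ``af`` and
    ``splice_score`` are optional annotations consumed as inputs (population
    allele frequency; splice-prediction score).
    """

    kind: str  # substitution | duplication | insertion | deletion
    start_c: int
    end_c: int
    ref: str = ""  # substitution reference / duplicated base
    alt: str = ""  # substitution alt / inserted bases
    label: str = ""
    af: Optional[float] = None
    splice_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "duplication", "insertion", "deletion"):
            raise VariantError(f"unknown variant kind {self.kind!r}")
        if self.af is not None and self.af < 0:
            raise VariantError("allele frequency cannot be negative")


_MINUS = "[-−–]"  # ASCII hyphen, unicode minus, en dash
_POS = rf"{_MINUS}?\d+"


def _c(tok: str) -> int:
    v = int(re.sub(_MINUS, "-", tok))
    if v == 0:
        raise VariantError("invalid coordinate c.0 (there is no c.0)")
    return v


_SUB_RE = re.compile(rf"^c\.({_POS})([ACGT])>([ACGT])$")
_DUP_RE = re.compile(rf"^c\.({_POS})dup([ACGT])$")
_DEL_RE = re.compile(rf"^c\.({_POS})(?:_({_POS}))?del$")
_INS_RE = re.compile(rf"^c\.({_POS})_({_POS})ins([ACGT]+)$")


def parse_hgvs_c(text: str) -> VariantSpec:
    """Parse one HGVS-like ``c.`` string of the supported subset.

    Supported: ``c.<pos><ref>><alt>``, ``c.<pos>dup<base>``,
    ``c.<start>_<end>del``, ``c.<pos>_<pos+1>ins<bases>``.  Duplications are
    normalised to the 3'-most equivalent transcript position when applied to
    a sequence (the sequence is not available at parse time).
    """
    text = text.strip()
    m = _SUB_RE.match(text)
    if m:
        pos = _c(m.group(1))
        return VariantSpec("substitution", pos, pos, ref=m.group(2), alt=m.group(3), label=text)
    m = _DUP_RE.match(text)
    if m:
        pos = _c(m.group(1))
        return VariantSpec("duplication", pos, pos, ref=m.group(2), label=text)
    m = _DEL_RE.match(text)
    if m:
        start = _c(m.group(1))
        end = _c(m.group(2)) if m.group(2) else start
        if end < start:
            raise VariantError(f"deletion range reversed in {text!r}")
        return VariantSpec("deletion", start, end, label=text)
    m = _INS_RE.match(text)
    if m:
        start, end = _c(m.group(1)), _c(m.group(2))
        if end != start + 1 and not (start == -1 and end == 1):
            raise VariantError(f"insertion must be between adjacent positions in {text!r}")
        return VariantSpec("insertion", start, end, alt=m.group(3), label=text)
    raise VariantError(f"unsupported variant syntax: {text!r}")


@dataclass
class _Edit:
    """A variant resolved against a concrete sequence: 0-based cap offsets."""

    spec: VariantSpec
    start: int  # first affected/anchor offset
    end: int  # last affected offset (inclusive); for insertions end==start
    inserted: str = ""
    deleted: int = 0

    @property
    def shift(self) -> int:
        return len(self.inserted) - self.deleted


def _resolve(utr: UtrSequence, spec: VariantSpec) -> _Edit:
    L = utr.utr_length
    if spec.start_c > -1 or spec.end_c > -1:
        # insertions between c.-1 and c.1 would touch the CDS; out of scope
        raise VariantError(
            f"{spec.label or spec.kind}: affected positions must lie within the UTR"
        )
    start = c_to_offset(spec.start_c, L)
    end = c_to_offset(spec.end_c, L)
    if spec.kind == "substitution":
        found = utr.seq[start]
        if found != spec.ref:
            raise VariantError(
                f"{spec.label}: reference mismatch at c.{spec.start_c}: "
                f"expected {spec.ref}, found {found}"
            )
        return _Edit(spec, start, end, inserted=spec.alt, deleted=1)
    if spec.kind == "duplication":
        # normalise to the 3'-most equivalent position on the transcript strand
        if utr.seq[start] != spec.ref:
            raise VariantError(
                f"{spec.label}: duplicated base mismatch at c.{spec.start_c}: "
                f"expected {spec.ref}, found {utr.seq[start]}"
            )
        while start + 1 < L and utr.seq[start + 1] == spec.ref:
            start += 1
        return _Edit(spec, start, start, inserted=spec.ref, deleted=0)
    if spec.kind == "deletion":
        return _Edit(spec, start, end, inserted="", deleted=end - start + 1)
    # insertion after `start` (between start_c and end_c)
    return _Edit(spec, start, start, inserted=spec.alt, deleted=0)


def _apply_edits(seq: str, edits: list[_Edit]) -> str:
    """Apply non-overlapping edits, 3'-most first, so upstream coordinates
    stay valid."""
    out = seq
    for e in sorted(edits, key=lambda e: e.start, reverse=True):
        if e.spec.kind == "substitution":
            out = out[: e.start] + e.inserted + out[e.start + 1 :]
        elif e.spec.kind == "deletion":
            out = out[: e.start] + out[e.end + 1 :]
        else:  # insertion / duplication: insert after the anchor base
            out = out[: e.start + 1] + e.inserted + out[e.start + 1 :]
    return out


def _check_overlap(edits: list[_Edit]) -> None:
    spans = sorted((e.start, e.end, e.spec.label or e.spec.kind) for e in edits)
    for (s1, e1, l1), (s2, e2, l2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise VariantError(f"overlapping variants: {l1} and {l2}")


def apply_variant(utr: UtrSequence, variants: list[VariantSpec]) -> UtrSequence:
    """Apply one or more non-overlapping variants to the UTR sequence.

    Reference alleles are verified against the sequence; edits are applied
    3'->5' so that coordinate shifts from indels never invalidate the
    remaining (more 5') coordinates — "in phase" combinations are supported.
    """
    edits = [_resolve(utr, v) for v in variants]
    _check_overlap(edits)
    return UtrSequence(seq=_apply_edits(utr.seq, edits), cds_prefix=utr.cds_prefix)


def _map_offsets(utr_len: int, edits: list[_Edit]) -> dict[int, Optional[int]]:
    """Map each reference cap offset to its alt-sequence offset (None if the
    base was deleted)."""
    deleted: set[int] = set()
    ins_after: dict[int, int] = {}
    for e in edits:
        if e.spec.kind == "deletion":
            deleted.update(range(e.start, e.end + 1))
        elif e.spec.kind in ("insertion", "duplication"):
            ins_after[e.start] = ins_after.get(e.start, 0) + len(e.inserted)
    mapping: dict[int, Optional[int]] = {}
    shift = 0
    for pos in range(utr_len):
        if pos in deleted:
            mapping[pos] = None
            shift -= 1
        else:
            mapping[pos] = pos + shift
        shift += ins_after.get(pos, 0)
    return mapping


@dataclass
class _OrfRecord:
    start: int
    extent: str
    stop_end: Optional[int]  # cap offset of last stop base (contained/oORF in prefix)
    frame_in: bool  # in frame with the mORF
    coding: str  # nucleotides from ATG to last pre-stop base (contained only)
    kozak: str
    gap: Optional[int]  # stop_to_maug_gap, contained only


def _architecture(utr: UtrSequence) -> list[_OrfRecord]:
    """Every upstream ATG of the UTR with its extent class and stop."""
    L = utr.utr_length
    out = []
    for i in range(L - 2):
        if utr.seq[i : i + 3] != "ATG":
            continue
        stop = _first_inframe_stop(utr.mrna, i)
        if stop is not None and stop + 2 <= L - 1:
            extent, stop_end, gap = CONTAINED_UORF, stop + 2, L - 1 - (stop + 2)
            coding = utr.seq[i:stop]
        else:
            coding, gap = "", None
            if (L - i) % 3 == 0:
                extent, stop_end = N_TERMINAL_EXTENSION, None
            else:
                extent = OVERLAPPING_OORF
                stop_end = stop + 2 if stop is not None else None
        out.append(
            _OrfRecord(
                start=i,
                extent=extent,
                stop_end=stop_end,
                frame_in=(L - i) % 3 == 0,
                coding=coding,
                kozak=kozak_class(utr.mrna, i).strength,
                gap=gap,
            )
        )
    return out


def _translate(nt: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(nt).translate()) if nt else ""


@dataclass
class ConsequenceCall:
    """Structural diff of the upstream-ORF architecture across a variant."""

    code: str
    secondary_codes: list[str] = field(default_factory=list)
    affected_uorf: Optional[int] = None  # index into the ref contained-uORF list
    details: dict = field(default_factory=dict)
    splice_flagged: bool = False

    @property
    def all_codes(self) -> list[str]:
        return [self.code] + self.secondary_codes


def classify_consequence(
    ref_utr: UtrSequence,
    variants: list[VariantSpec],
    splice_threshold: float = DEFAULT_SPLICE_THRESHOLD,
) -> ConsequenceCall:
    """Classify the joint translational consequence of ``variants``.

    Scans the reference and edited sequences, matches upstream ORFs by their
    (coordinate-shift adjusted) start position, and emits the diff-derived
    code; ties are broken by the documented severity ranking, the most severe
    event becoming the primary code and the rest secondary.
    """
    edits = [_resolve(ref_utr, v) for v in variants]
    _check_overlap(edits)
    alt_utr = UtrSequence(seq=_apply_edits(ref_utr.seq, edits), cds_prefix=ref_utr.cds_prefix)
    mapping = _map_offsets(ref_utr.utr_length, edits)

    ref_orfs = _architecture(ref_utr)
    alt_orfs = {o.start: o for o in _architecture(alt_utr)}
    ref_contained = [o for o in ref_orfs if o.extent == CONTAINED_UORF]
    contained_index = {o.start: i for i, o in enumerate(ref_contained)}

    frameshifted = any(e.shift % 3 != 0 for e in edits)
    events: list[tuple[str, Optional[int], dict]] = []
    matched_alt_starts: set[int] = set()
    alt_L = alt_utr.utr_length

    for ref_orf in ref_orfs:
        mstart = mapping.get(ref_orf.start)
        idx = contained_index.get(ref_orf.start)
        detail: dict = {"ref_start_offset": ref_orf.start, "ref_extent": ref_orf.extent}
        alt_orf = alt_orfs.get(mstart) if mstart is not None else None
        if alt_orf is None:
            events.append(("uStart_lost", idx, detail))
            continue
        matched_alt_starts.add(alt_orf.start)
        fs_inside = any(
            e.shift % 3 != 0
            and ref_orf.start <= e.start <= (ref_orf.stop_end if ref_orf.stop_end is not None else ref_utr.utr_length)
            for e in edits
        )
        if ref_orf.extent == CONTAINED_UORF:
            if alt_orf.extent == CONTAINED_UORF:
                detail.update(
                    old_stop_offset=ref_orf.stop_end,
                    new_stop_offset=alt_orf.stop_end,
                    old_gap=ref_orf.gap,
                    new_gap=alt_orf.gap,
                )
                if alt_orf.gap == ref_orf.gap:
                    if alt_orf.coding != ref_orf.coding:
                        if fs_inside:
                            events.append(("uFrameshift", idx, detail))
                        elif _translate(alt_orf.coding) != _translate(ref_orf.coding):
                            events.append(("uAA_substitution", idx, detail))
                        else:
                            events.append(("uSynonymous", idx, detail))
                elif alt_orf.gap < ref_orf.gap:
                    # stop moved toward the mAUG: the old stop is lost, a new
                    # in-frame stop still terminates within the UTR
                    detail["new_stop_overlaps_uorf"] = _stops_within(
                        ref_contained, mapping, alt_orf.stop_end, ref_orf.start
                    )
                    events.append(("uStop_lost_extension", idx, detail))
                    if fs_inside:
                        events.append(("uFrameshift", idx, dict(detail)))
                else:
                    # stop moved away from the mAUG: a premature stop
                    # truncates the peptide (amino-acid-level change)
                    detail["premature_stop"] = True
                    events.append(("uAA_substitution", idx, detail))
                    if fs_inside:
                        events.append(("uFrameshift", idx, dict(detail)))
            else:
                # stop lost entirely: reading continues to/past the mAUG
                detail.update(
                    old_stop_offset=ref_orf.stop_end,
                    old_gap=ref_orf.gap,
                    new_extent=alt_orf.extent,
                    new_frame="in_frame" if alt_orf.frame_in else "out_of_frame",
                    terminates=(
                        "in_cds_prefix" if alt_orf.stop_end is not None else "beyond_cds_prefix"
                    ),
                )
                events.append(("uStop_lost_oORF", idx, detail))
                if fs_inside:
                    events.append(("uFrameshift", idx, dict(detail)))
        else:
            if alt_orf.extent == CONTAINED_UORF:
                detail.update(new_stop_offset=alt_orf.stop_end, new_gap=alt_orf.gap)
                events.append(("uAUG_created_uORF", idx, detail))
            elif alt_orf.extent != ref_orf.extent:
                events.append(("uFrameshift", idx, detail))
        koz_alt = alt_orf.kozak
        # only a *defined uORF*'s Kozak motif matters (plus the mAUG below)
        if koz_alt != ref_orf.kozak and (
            ref_orf.extent == CONTAINED_UORF or alt_orf.extent == CONTAINED_UORF
        ):
            events.append(
                (
                    "kozak_changed_uORF",
                    idx,
                    {**detail, "old_kozak": ref_orf.kozak, "new_kozak": koz_alt},
                )
            )

    for start, alt_orf in alt_orfs.items():
        if start in matched_alt_starts:
            continue
        code = {
            CONTAINED_UORF: "uAUG_created_uORF",
            OVERLAPPING_OORF: "uAUG_created_oORF",
            N_TERMINAL_EXTENSION: "uAUG_created_NTE",
        }[alt_orf.extent]
        events.append(
            (code, None, {"new_start_offset": start, "new_gap": alt_orf.gap})
        )

    # main-ORF Kozak: -3 from the UTR tail, +4 from the CDS prefix
    ref_m = kozak_class(ref_utr.mrna, ref_utr.utr_length).strength
    alt_m = kozak_class(alt_utr.mrna, alt_utr.utr_length).strength
    if ref_m != alt_m:
        events.append(
            ("kozak_changed_mORF", None, {"old_kozak": ref_m, "new_kozak": alt_m})
        )

    splice_flagged = any(
        v.splice_score is not None and v.splice_score >= splice_threshold for v in variants
    )
    if not events:
        return ConsequenceCall("no_uorf_change", splice_flagged=splice_flagged)
    events.sort(key=lambda ev: _RANK[ev[0]])
    primary = events[0]
    secondary = [e[0] for e in events[1:]]
    return ConsequenceCall(
        code=primary[0],
        secondary_codes=secondary,
        affected_uorf=primary[1],
        details=primary[2],
        splice_flagged=splice_flagged,
    )


def _stops_within(ref_contained, mapping, new_stop_end, exclude_start) -> list[int]:
    """Indices of other reference uORFs whose (mapped) span contains the new
    stop's last base — e.g. a rescued uORF1 stop landing inside uORF2."""
    hits = []
    for i, o in enumerate(ref_contained):
        if o.start == exclude_start:
            continue
        ms, me = mapping.get(o.start), mapping.get(o.stop_end)
        if ms is not None and me is not None and ms <= new_stop_end <= me:
            hits.append(i)
    return hits
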