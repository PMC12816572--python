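"""Upstream-ORF discovery and annotation in a 5'UTR.

Detects AUG-initiated upstream open reading frames (uORFs), translates their
peptides and attaches frame, cap/CDS distances, Kozak strength and optional
conservation calls.  Only ATG starts are scanned; near-cognate starts such as
CTG are deliberately not considered.  A uORF counts as *contained* when its
stop codon lies entirely within the UTR (a stop whose last base sits at c.-1
still counts; a stop overlapping the main AUG does not).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Optional

from Bio.Seq import Seq

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Orf extent classes
CONTAINED_UORF = "contained_uorf"
OVERLAPPING_OORF = "overlapping_oorf"
N_TERMINAL_EXTENSION = "n_terminal_extension"

#: Kozak strength classes
STRONG, MODERATE, WEAK = "strong", "moderate", "weak"


@dataclass(frozen=True)
class UtrSequence:
    """A 5'UTR in mRNA (5'->3') orientation plus a short CDS prefix.

    ``cds_prefix`` must begin with ATG (the main-ORF start) and supplies the
    +4 Kozak base of the mAUG and the read-through context for overlapping
    ORFs.  Degenerate bases are rejected: consequence calls must be
    deterministic.
    """

    seq: str
    cds_prefix: str

    def __post_init__(self) -> None:
        for name, s in (("seq", self.seq), ("cds_prefix", self.cds_prefix)):
            bad = set(s) - set("ACGT")
            if bad:
                raise ValueError(f"{name} contains non-ACGT characters: {sorted(bad)}")
        if not self.cds_prefix.startswith("ATG"):
            raise ValueError("cds_prefix must start with ATG")

    @property
    def utr_length(self) -> int:
        return len(self.seq)

    @property
    def mrna(self) -> str:
        """UTR + CDS prefix as one scanning template."""
        return self.seq + self.cds_prefix


@dataclass
class UOrf:
    """One AUG-initiated upstream ORF, fully contained in the UTR."""

    start_offset: int  # 0-based cap offset of the A of the uAUG
    end_offset: int  # 0-based cap offset of the last stop-codon base
    peptide: str  # amino acids, stop excluded
    frame_vs_morf: str  # "in_frame" | "out_of_frame"
    stop_to_maug_gap: int  # nt between last stop base and the mAUG A
    cap_to_uaug: int  # = start_offset
    kozak: str  # strong | moderate | weak
    kozak_incomplete: bool = False
    conserved_start: Optional[bool] = None
    conserved_stop: Optional[bool] = None
    functional_evidence: Optional[bool] = None  # external uORF-catalog flag

    @property
    def length_nt(self) -> int:
        return self.end_offset - self.start_offset + 1


@dataclass
class KozakCall:
    strength: str
    minus3: Optional[str]
    plus4: Optional[str]
    incomplete: bool


def kozak_class(sequence: str, atg_offset: int) -> KozakCall:
    """Score the Kozak context of the ATG at ``atg_offset`` in ``sequence``.

    Only the -3 and +4 positions of the core motif (A/G)XXATGG are scored:
    -3 matches the consensus if A or G, +4 if G.  Both matching -> strong,
    exactly one -> moderate, neither -> weak.  Missing context (ATG too close
    to either end) yields a call flagged ``incomplete`` with non-matching
    treatment of the absent base rather than an error.
    """
    if sequence[atg_offset : atg_offset + 3] != "ATG":
        raise ValueError(f"no ATG at offset {atg_offset}")
    minus3 = sequence[atg_offset - 3] if atg_offset >= 3 else None
    plus4_idx = atg_offset + 3
    plus4 = sequence[plus4_idx] if plus4_idx < len(sequence) else None
    n = (minus3 in ("A", "G")) + (plus4 == "G")
    strength = (WEAK, MODERATE, STRONG)[n]
    return KozakCall(strength, minus3, plus4, incomplete=minus3 is None or plus4 is None)


def _first_inframe_stop(template: str, start: int) -> Optional[int]:
    """Offset of the first base of the first in-frame stop codon at/after
    ``start`` in ``template``, or None."""
    for i in range(start, len(template) - 2, 3):
        if template[i : i + 3] in STOP_CODONS:
            return i
    return None


def classify_orf_extent(utr: UtrSequence, atg_offset: int) -> str:
    """Classify the reading frame opened by the ATG at ``atg_offset``.

    * ``contained_uorf`` — the first in-frame stop ends within the UTR;
    * ``n_terminal_extension`` — in frame with the main ORF with no stop
      before the mAUG;
    * ``overlapping_oorf`` — otherwise: reading continues past the mAUG out
      of frame, terminating wherever the UTR+CDS prefix provides a stop, or
      beyond the modelled sequence.
    """
    if utr.seq[atg_offset : atg_offset + 3] != "ATG":
        raise ValueError(f"no ATG at offset {atg_offset} of the UTR")
    L = utr.utr_length
    stop = _first_inframe_stop(utr.mrna, atg_offset)
    if stop is not None and stop + 2 <= L - 1:
        return CONTAINED_UORF
    if (L - atg_offset) % 3 == 0:
        return N_TERMINAL_EXTENSION
    return OVERLAPPING_OORF


def scan_uorfs(utr: UtrSequence) -> list[UOrf]:
    """All contained uORFs of the UTR, ordered 5'->3' by start offset.

    Every ATG in the UTR whose first in-frame stop lies entirely within the
    UTR yields one record; nested and overlapping starts each produce their
    own record.  ATGs reading through to or past the mAUG are not returned
    here (see :func:`classify_orf_extent`).
    """
    L = utr.utr_length
    out: list[UOrf] = []
    for i in range(L - 2):
        if utr.seq[i : i + 3] != "ATG":
            continue
        # searching seq alone restricts stops to codons fully inside the UTR
        stop = _first_inframe_stop(utr.seq, i)
        if stop is None or stop + 2 > L - 1:
            continue
        coding = utr.seq[i:stop]
        peptide = str(Seq(coding).translate()) if coding else ""
        koz = kozak_class(utr.mrna, i)
        out.append(
            UOrf(
                start_offset=i,
                end_offset=stop + 2,
                peptide=peptide,
                frame_vs_morf="in_frame" if (L - i) % 3 == 0 else "out_of_frame",
                stop_to_maug_gap=L - 1 - (stop + 2),
                cap_to_uaug=i,
                kozak=koz.strength,
                kozak_incomplete=koz.incomplete,
            )
        )
    return out


@dataclass
class ConservationTrack:
    """Per-base conservation scores keyed by cap offset.

    Two independent channels: ``basewise`` (PhyloP-like, threshold default
    2.0, indicating purifying selection) and ``elementwise`` (PhastCons-like,
    threshold default 0.8, indicating conserved elements).  Either channel
    may be absent.
    """

    basewise: dict[int, float] = field(default_factory=dict)
    elementwise: dict[int, float] = field(default_factory=dict)
    basewise_min: float = 2.0
    elementwise_min: float = 0.8


def _codon_conserved(track: ConservationTrack, first: int) -> Optional[bool]:
    """A codon is conserved if all three bases exceed the basewise threshold
    OR the elementwise score exceeds its threshold at all three bases.
    Returns None (flags absent) on partial coverage of both channels."""
    offs = (first, first + 1, first + 2)
    base_ok = elem_ok = None
    if all(o in track.basewise for o in offs):
        base_ok = all(track.basewise[o] > track.basewise_min for o in offs)
    if all(o in track.elementwise for o in offs):
        elem_ok = all(track.elementwise[o] > track.elementwise_min for o in offs)
    if base_ok is None and elem_ok is None:
        return None
    return bool(base_ok) or bool(elem_ok)


def conservation_gate(uorf: UOrf, track: Optional[ConservationTrack]) -> UOrf:
    """Return a copy of ``uorf`` with conserved_start / conserved_stop set
    from the track; an absent track (or partial coverage of a codon) leaves
    the corresponding flag absent."""
    if track is None:
        return replace(uorf, conserved_start=None, conserved_stop=None)
    return replace(
        uorf,
        conserved_start=_codon_conserved(track, uorf.start_offset),
        conserved_stop=_codon_conserved(track, uorf.end_offset - 2),
    )


def peptide_identity_class(aligned_peptides: list[str]) -> tuple[float, str]:
    """Mean pairwise percent identity of equal-length gapped peptides and
    its class: high (>=80%), moderate (>=50%), weak (<50%).

    Per unordered pair, identity = identical non-double-gap columns divided
    by columns where at least one sequence is non-gap.
    """
    if len(aligned_peptides) < 2:
        raise ValueError("need at least 2 aligned peptides")
    n = len(aligned_peptides[0])
    if any(len(p) != n for p in aligned_peptides):
        raise ValueError("aligned peptides must have equal length")
    pct = []
    for a, b in combinations(aligned_peptides, 2):
        denom = ident = 0
        for x, y in zip(a, b):
            if x == "-" and y == "-":
                continue
            denom += 1
            if x == y:
                ident += 1
        pct.append(100.0 * ident / denom if denom else 0.0)
    mean = sum(pct) / len(pct)
    klass = "high" if mean >= 80.0 else "moderate" if mean >= 50.0 else "weak"
    return mean, klass
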