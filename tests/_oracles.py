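"""Independent brute-force re-derivations used to cross-check the package.

These deliberately avoid the package's scanning/diffing code paths: ORF sets
are enumerated with naive loops and translated with Biopython, and the
consequence decision table is re-stated from its documentation rather than
imported.
"""

from __future__ import annotations

from Bio.Seq import Seq

_STOPS = {"TAA", "TAG", "TGA"}

SEVERITY = [
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


def brute_force_uorfs(seq: str) -> list[tuple[int, int, str]]:
    """All (start_offset, end_offset, peptide) for AUG-initiated ORFs whose
    first in-frame stop lies entirely within ``seq``."""
    out = []
    for i in range(len(seq)):
        if seq[i : i + 3] != "ATG":
            continue
        j = i
        while j + 3 <= len(seq):
            codon = seq[j : j + 3]
            if codon in _STOPS:
                out.append((i, j + 2, str(Seq(seq[i:j]).translate())))
                break
            j += 3
    return out


def brute_force_identity(peptides: list[str]) -> float:
    """Mean pairwise percent identity by explicit column counting."""
    vals = []
    for a_i in range(len(peptides)):
        for b_i in range(a_i + 1, len(peptides)):
            a, b = peptides[a_i], peptides[b_i]
            denom = same = 0
            for x, y in zip(a, b):
                if x == "-" and y == "-":
                    continue
                denom += 1
                same += x == y
            vals.append(100.0 * same / denom if denom else 0.0)
    return sum(vals) / len(vals)


def _extent(seq: str, prefix: str, i: int):
    """(extent, stop_end_or_None, gap_or_None, coding) re-derived naively."""
    L = len(seq)
    full = seq + prefix
    j = i
    stop_end = None
    while j + 3 <= len(full):
        if full[j : j + 3] in _STOPS:
            stop_end = j + 2
            break
        j += 3
    if stop_end is not None and stop_end <= L - 1:
        return "contained", stop_end, L - 1 - stop_end, seq[i:j]
    if (L - i) % 3 == 0:
        return "nte", None, None, ""
    return "oorf", stop_end, None, ""


def _kozak(full: str, i: int) -> str:
    m3 = full[i - 3] if i >= 3 else ""
    p4 = full[i + 3] if i + 3 < len(full) else ""
    n = (m3 in "AG") + (p4 == "G")
    return ("weak", "moderate", "strong")[n]


def slow_consequence(seq: str, prefix: str, pos: int, alt_base: str) -> list[str]:
    """Re-derive the full code set for a single-base substitution at cap
    offset ``pos``, most severe first."""
    alt_seq = seq[:pos] + alt_base + seq[pos + 1 :]
    L = len(seq)
    ref_atgs = {i for i in range(L - 2) if seq[i : i + 3] == "ATG"}
    alt_atgs = {i for i in range(L - 2) if alt_seq[i : i + 3] == "ATG"}
    events: list[str] = []
    for i in sorted(ref_atgs):
        if i not in alt_atgs:
            events.append("uStart_lost")
            continue
        r_ext, r_stop, r_gap, r_coding = _extent(seq, prefix, i)
        a_ext, a_stop, a_gap, a_coding = _extent(alt_seq, prefix, i)
        if r_ext == "contained":
            if a_ext == "contained":
                if a_gap == r_gap:
                    if a_coding != r_coding:
                        if str(Seq(a_coding).translate()) != str(Seq(r_coding).translate()):
                            events.append("uAA_substitution")
                        else:
                            events.append("uSynonymous")
                elif a_gap < r_gap:
                    events.append("uStop_lost_extension")
                else:
                    events.append("uAA_substitution")
            else:
                events.append("uStop_lost_oORF")
        else:
            if a_ext == "contained":
                events.append("uAUG_created_uORF")
            elif a_ext != r_ext:
                events.append("uFrameshift")
        if (r_ext == "contained" or a_ext == "contained") and _kozak(
            seq + prefix, i
        ) != _kozak(alt_seq + prefix, i):
            events.append("kozak_changed_uORF")
    for i in sorted(alt_atgs - ref_atgs):
        ext = _extent(alt_seq, prefix, i)[0]
        events.append(
            {"contained": "uAUG_created_uORF", "oorf": "uAUG_created_oORF", "nte": "uAUG_created_NTE"}[ext]
        )
    if _kozak(seq + prefix, L) != _kozak(alt_seq + prefix, L):
        events.append("kozak_changed_mORF")
    if not events:
        return ["no_uorf_change"]
    return sorted(events, key=SEVERITY.index)
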