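"""Synthetic data: fixture UTR, variant panels, conservation tracks, assays.

Everything needed to exercise the pipeline without downloads.  The central
piece is a constraint-satisfying "PKD1-like" 5'UTR: a 209-nt sequence on a
minus-strand transcript model that reproduces every structural fact of the
real PKD1 5'UTR relevant to the analysis — two AUG-initiated uORFs with fixed
peptides, positions, frames and Kozak contexts, and a panel of variants with
fixed architectural consequences (a uORF1 frameshift/stop-loss duplication,
two in-phase rescue stops, a benign substitution, a cap-proximal
substitution, and uORF start-loss knockouts).  The genomic anchoring reuses
the real coordinates (chr16:2,135,690-2,135,898, minus strand) so printed
genomic<->c. pairs are testable verbatim, while the sequence itself is
synthetic.

The generator places the uORFs codon-by-codon from synonymous choices, fills
the remaining bases by seeded randomised search, and accepts a candidate only
when an *independent* validator — built purely on the scanner and variant
classifier, never trusting the construction — passes every constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .scanner import ConservationTrack, UOrf, UtrSequence, scan_uorfs
from .transcript import TranscriptModel, offset_to_c, pkd1_like_model
from .variants import VariantSpec, classify_consequence, parse_hgvs_c

DEFAULT_SEED = 1

_CODONS = {
    "M": ["ATG"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "R": ["CGT", "CGC", "CGA", "CGG"],  # CGN only: +4 Kozak base must be C
    # L restricted so that a C>A edit at the first base of the next codon can
    # complete a TAA/TGA stop in the +1-shifted frame (the rescue-2 design)
    "L": ["CTA", "CTG", "TTA", "TTG"],
}
_STOPS = ["TAA", "TAG", "TGA"]


@dataclass(frozen=True)
class FixtureConstraints:
    """Structural facts the generated UTR must satisfy (all machine-checked).

    Offsets are 0-based from the 5' cap; the two uORFs are placed so that
    uAUG1 sits 122 nt and uAUG2 189 nt from the cap, terminating 63 and 2 nt
    upstream of the main AUG respectively.
    """

    utr_length: int = 209
    uorf1_start: int = 122
    uorf1_end: int = 145
    uorf1_peptide: str = "MPSAGPA"
    uorf2_start: int = 189
    uorf2_end: int = 206
    uorf2_peptide: str = "MRALP"
    cds_prefix_length: int = 30
    #: reference bases pinned by the variant panel, keyed by c. position
    pinned_ref: dict = field(
        default_factory=lambda: {-209: "G", -69: "G", -59: "C", -52: "C", -8: "C"}
    )


#: paper-style variant panel: construct label -> HGVS c. strings
PANEL_HGVS: dict[str, list[str]] = {
    "wildtype": [],
    "patient": ["c.-69dupG"],
    "rescue1": ["c.-69dupG", "c.-59C>A"],
    "rescue2": ["c.-69dupG", "c.-8C>A"],
    "benign": ["c.-52C>T"],
    "nhs1": ["c.-209G>A"],
    "uorf1_ko": ["c.-86T>C"],
    "uorf2_ko": ["c.-19T>C"],
    "double_ko": ["c.-86T>C", "c.-19T>C"],
}

#: optional per-variant annotations consumed as inputs (population allele
#: frequency; splice-prediction score).  The patient duplication is absent
#: from the population database (af None = unobserved); the benign control is
#: common; the splice scores sit below the 0.05 gate.
PANEL_ANNOTATIONS: dict[str, dict] = {
    "patient": {"af": None, "splice_score": 0.01},
    "benign": {"af": 0.01, "splice_score": 0.0},
    "nhs1": {"af": None, "splice_score": 0.01},
}

#: expected primary consequence code per construct (used by the validator)
PANEL_EXPECTED_CODE: dict[str, str] = {
    "patient": "uStop_lost_oORF",
    "rescue1": "uStop_lost_extension",
    "rescue2": "uStop_lost_extension",
    "benign": "no_uorf_change",
    "nhs1": "no_uorf_change",
    "uorf1_ko": "uStart_lost",
    "uorf2_ko": "uStart_lost",
    "double_ko": "uStart_lost",
}


def panel_variants(label: str) -> list[VariantSpec]:
    """The parsed variant list for one panel construct."""
    specs = [parse_hgvs_c(h) for h in PANEL_HGVS[label]]
    ann = PANEL_ANNOTATIONS.get(label)
    if ann:
        specs = [replace(s, af=ann["af"], splice_score=ann["splice_score"]) for s in specs]
    return specs


class FixtureError(RuntimeError):
    pass


def _place(seq: list, start: int, codons: list[str]) -> None:
    s = "".join(codons)
    for k, b in enumerate(s):
        seq[start + k] = b


def _fill_free(seq: list, rng: np.random.Generator) -> bool:
    """Fill unassigned positions left to right, rejecting bases that complete
    an ATG with already-assigned neighbours."""
    n = len(seq)
    for i in range(n):
        if seq[i] is not None:
            continue
        cands = list("ACGT")
        rng.shuffle(cands)
        ok_base = None
        for b in cands:
            seq[i] = b
            bad = False
            for w in (i - 2, i - 1, i):
                if 0 <= w and w + 2 < n:
                    tri = (seq[w], seq[w + 1], seq[w + 2])
                    if tri == ("A", "T", "G"):
                        bad = True
                        break
            if not bad:
                ok_base = b
                break
            seq[i] = None
        if ok_base is None:
            return False
    return True


def _attempt(constraints: FixtureConstraints, rng: np.random.Generator) -> Optional[UtrSequence]:
    c = constraints
    L = c.utr_length
    seq: list = [None] * L

    u1 = [rng.choice(_CODONS[a]) for a in c.uorf1_peptide] + [rng.choice(_STOPS)]
    u2 = [rng.choice(_CODONS[a]) for a in c.uorf2_peptide] + [rng.choice(_STOPS)]
    _place(seq, c.uorf1_start, u1)
    _place(seq, c.uorf2_start, u2)

    # Kozak -3 bases of the two uAUGs (the +4 bases fall inside the placed
    # codons and are C by codon choice)
    seq[c.uorf1_start - 3] = "G"
    seq[c.uorf2_start - 3] = "G"
    # reference bases required by the variant panel (those outside the uORFs)
    for cpos, base in c.pinned_ref.items():
        off = L + cpos
        if seq[off] is None:
            seq[off] = base
        elif seq[off] != base:
            return None
    # the rescue-1 design: a C>A at c.-59 must complete a stop (TAA/TGA) in
    # the +1-shifted reading frame of uORF1
    off59 = L - 59
    seq[off59 - 2] = "T"
    seq[off59 - 1] = rng.choice(["A", "G"])

    if not _fill_free(seq, rng):
        return None
    utr_seq = "".join(seq)

    # cheap pre-checks before the full validator: edits must not mint an ATG
    if utr_seq[1] == "T" and utr_seq[2] == "G":  # c.-209G>A would create AUG
        return None
    off52 = L - 52
    if utr_seq[off52 - 1] == "A" and utr_seq[off52 + 1] == "G":  # c.-52C>T
        return None
    if utr_seq[off59 + 1] == "T" and utr_seq[off59 + 2] == "G":  # c.-59C>A
        return None

    prefix = ["A", "T", "G"] + [rng.choice(list("ACGT")) for _ in range(c.cds_prefix_length - 3)]
    prefix[3] = rng.choice(["C", "T"])  # mAUG Kozak stays moderate; no shifted-frame TGA
    return UtrSequence(seq=utr_seq, cds_prefix="".join(prefix))


@dataclass
class FixtureReport:
    passed: bool
    checks: list  # (name, ok, detail)

    def failures(self) -> list:
        return [c for c in self.checks if not c[1]]


def validate_fixture(
    utr: UtrSequence, constraints: FixtureConstraints = FixtureConstraints()
) -> FixtureReport:
    """Re-check every constraint using only scanner/classifier primitives.

    The generator is never trusted: this validator derives the uORF
    architecture and the panel consequences from scratch.
    """
    c = constraints
    checks: list = []

    def check(name: str, ok: bool, detail: str = "") -> None:
        checks.append((name, bool(ok), detail))

    L = utr.utr_length
    check("utr_length", L == c.utr_length, f"{L} != {c.utr_length}" if L != c.utr_length else "")
    uorfs = scan_uorfs(utr)
    check("exactly_two_uorfs", len(uorfs) == 2, f"found {len(uorfs)}")
    if len(uorfs) == 2:
        u1, u2 = uorfs
        check(
            "uorf1_structure",
            u1.start_offset == c.uorf1_start
            and u1.end_offset == c.uorf1_end
            and u1.peptide == c.uorf1_peptide
            and u1.frame_vs_morf == "in_frame"
            and u1.stop_to_maug_gap == c.utr_length - 1 - c.uorf1_end,
            f"{u1}",
        )
        check(
            "uorf2_structure",
            u2.start_offset == c.uorf2_start
            and u2.end_offset == c.uorf2_end
            and u2.peptide == c.uorf2_peptide
            and u2.frame_vs_morf == "out_of_frame"
            and u2.stop_to_maug_gap == c.utr_length - 1 - c.uorf2_end,
            f"{u2}",
        )
        check(
            "uorf_kozak_moderate_G-3_C+4",
            all(u.kozak == "moderate" for u in (u1, u2))
            and utr.seq[c.uorf1_start - 3] == "G"
            and utr.seq[c.uorf1_start + 3] == "C"
            and utr.seq[c.uorf2_start - 3] == "G"
            and utr.seq[c.uorf2_start + 3] == "C",
        )
    for cpos, base in c.pinned_ref.items():
        found = utr.seq[L + cpos]
        check(f"ref_base_c{cpos}", found == base, f"expected {base}, found {found}")
    atgs = [i for i in range(len(utr.mrna) - 2) if utr.mrna[i : i + 3] == "ATG"]
    expected_atgs = sorted([c.uorf1_start, c.uorf2_start, L])
    check("atg_positions", atgs == expected_atgs, f"{atgs}")

    for label, expected in PANEL_EXPECTED_CODE.items():
        try:
            call = classify_consequence(utr, panel_variants(label))
        except Exception as exc:  # ref mismatch etc.
            check(f"panel_{label}", False, repr(exc))
            continue
        ok = call.code == expected
        detail = f"code={call.code}"
        if label == "rescue1" and ok:
            ok = call.details.get("new_gap") == 58
            detail += f" new_gap={call.details.get('new_gap')}"
        if label == "rescue2" and ok:
            ok = call.details.get("new_gap") == 7
            detail += f" new_gap={call.details.get('new_gap')}"
        check(f"panel_{label}", ok, detail)

    check(
        "cds_prefix",
        utr.cds_prefix.startswith("ATG")
        and len(utr.cds_prefix) >= 30
        and utr.cds_prefix[3] != "G",
        utr.cds_prefix,
    )
    return FixtureReport(passed=all(ok for _, ok, _ in checks), checks=checks)


def generate_fixture(
    seed: int = DEFAULT_SEED,
    constraints: FixtureConstraints = FixtureConstraints(),
    max_attempts: int = 10_000,
) -> tuple[UtrSequence, TranscriptModel]:
    """Generate a validator-passing fixture UTR plus its transcript model.

    Deterministic for a fixed seed.  Raises :class:`FixtureError` after
    ``max_attempts`` failed draws rather than silently relaxing constraints.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        utr = _attempt(constraints, rng)
        if utr is None:
            continue
        if validate_fixture(utr, constraints).passed:
            return utr, pkd1_like_model()
    raise FixtureError(
        f"no constraint-satisfying sequence after {max_attempts} attempts; "
        "try a different seed"
    )


# ---------------------------------------------------------------------------
# reporter-assay simulation


#: relative-activity truths implied by reported wildtype-minus-variant mean
#: differences (wildtype = 1 by construction)
TRUE_MEAN_DIFFERENCES: dict[str, float] = {
    "patient": 0.8678,
    "rescue1": -0.097,
    "rescue2": 0.4465,
    "benign": 0.008,
    "nhs1": 0.06369,
    "uorf1_ko": -0.09,
    "uorf2_ko": -0.34,
    "double_ko": -1.31,
}

#: the two assay families (each run and analysed as its own experiment set)
FAMILY_VARIANTS = ["wildtype", "patient", "rescue1", "rescue2", "benign", "nhs1"]
FAMILY_KNOCKOUTS = ["wildtype", "uorf1_ko", "uorf2_ko", "double_ko"]


def default_true_means(constructs: list[str]) -> dict[str, float]:
    return {
        lab: 1.0 - TRUE_MEAN_DIFFERENCES.get(lab, 0.0) for lab in constructs
    }


@dataclass
class AssaySimConfig:
    """Simulation of the dual-reporter measurement process.

    Per transfection replicate a lognormal transfection-efficiency factor
    multiplies both signals (and therefore cancels in the GLuc/SeAP ratio);
    additive measurement noise on the GLuc channel is scaled so that after
    technical-duplicate averaging the per-replicate relative activity has
    standard deviation ``noise_sd``; the SeAP channel carries a small
    independent relative noise.  12 transfections split over two independent
    experiments, two technical duplicates each, mirror the stated replicate
    structure.
    """

    true_means: dict[str, float] = field(
        default_factory=lambda: default_true_means(FAMILY_VARIANTS)
    )
    n_replicates: int = 12
    n_experiments: int = 2
    n_duplicates: int = 2
    efficiency_sigma: float = 0.3
    noise_sd: float = 0.1
    seap_cv: float = 0.02
    base_gluc: float = 1.0e6
    base_seap: float = 5.0e5
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.true_means.values()):
            raise ValueError("true mean relative activities must be positive")
        if self.n_replicates % self.n_experiments:
            raise ValueError("replicates must split evenly over experiments")


def simulate_assay(config: AssaySimConfig) -> pd.DataFrame:
    """Per-well GLuc/SeAP table for the configured constructs."""
    rng = np.random.default_rng(config.seed)
    per_exp = config.n_replicates // config.n_experiments
    well_sd = config.noise_sd * np.sqrt(config.n_duplicates)
    rows = []
    for construct, mu in config.true_means.items():
        for exp in range(1, config.n_experiments + 1):
            for rep in range(1, per_exp + 1):
                eff = rng.lognormal(0.0, config.efficiency_sigma) if config.efficiency_sigma else 1.0
                for dup in range(1, config.n_duplicates + 1):
                    g = mu + (rng.normal(0.0, well_sd) if well_sd else 0.0)
                    s = 1.0 + (
                        rng.normal(0.0, config.seap_cv * np.sqrt(config.n_duplicates))
                        if config.seap_cv
                        else 0.0
                    )
                    rows.append(
                        {
                            "construct": construct,
                            "experiment": exp,
                            "replicate": rep,
                            "duplicate": dup,
                            "gluc": config.base_gluc * eff * max(g, 1e-6),
                            "seap": config.base_seap * eff * max(s, 1e-6),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# conservation simulation


def simulate_conservation(
    uorfs: list[UOrf],
    utr_length: int,
    basewise_min: float = 2.0,
    elementwise_min: float = 0.8,
    seed: int = DEFAULT_SEED,
) -> ConservationTrack:
    """Per-base track with background below threshold and the start/stop
    codons of every given uORF planted above threshold on both channels."""
    rng = np.random.default_rng(seed)
    basewise = {
        i: float(rng.uniform(-1.0, min(1.5, basewise_min - 0.5))) for i in range(utr_length)
    }
    elementwise = {
        i: float(rng.uniform(0.0, max(0.0, elementwise_min - 0.3))) for i in range(utr_length)
    }
    for u in uorfs:
        for codon_start in (u.start_offset, u.end_offset - 2):
            for k in range(3):
                basewise[codon_start + k] = float(rng.uniform(basewise_min + 0.5, basewise_min + 3.0))
                elementwise[codon_start + k] = float(
                    rng.uniform(min(elementwise_min + 0.05, 0.99), 1.0)
                )
    return ConservationTrack(
        basewise=basewise,
        elementwise=elementwise,
        basewise_min=basewise_min,
        elementwise_min=elementwise_min,
    )


def write_variant_panel(
    utr: UtrSequence, model: TranscriptModel, tsv_path: str, vcf_path: str
) -> None:
    """Emit the construct panel as an HGVS TSV and the unique simple variants
    as a plus-strand VCF (strand conversion included)."""
    from . import io as _io

    rows = []
    for label in PANEL_HGVS:
        ann = PANEL_ANNOTATIONS.get(label, {})
        rows.append(
            {
                "construct": label,
                "hgvs": ";".join(PANEL_HGVS[label]),
                "af": "" if ann.get("af") is None else ann.get("af"),
                "splice_score": "" if ann.get("splice_score") is None else ann.get("splice_score"),
            }
        )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)

    seen = {}
    for label in PANEL_HGVS:
        for h in PANEL_HGVS[label]:
            seen.setdefault(h, parse_hgvs_c(h))
    _io.write_vcf(list(seen.values()), utr, model, vcf_path)
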