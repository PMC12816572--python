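"""End-to-end pipeline: scan -> classify -> prioritise -> (optional) assay.

Mechanises a manual curation protocol, so every output table records the
tool version and a hash of the configuration, and the per-variant report
carries the full decision trail (consequence codes, criteria met, thresholds
applied).  Deterministic given inputs and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import pandas as pd

from . import __version__
from .assay import anova_tukey, format_p, normalize, percent_change
from .io import write_uorf_report
from .prioritize import AfModel, assign_tier, max_credible_af, rarity_filter
from .scanner import ConservationTrack, UtrSequence, conservation_gate, scan_uorfs
from .transcript import TranscriptModel
from .variants import VariantSpec, classify_consequence

logger = logging.getLogger("utrvar")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline in one validated block."""

    transcript: Optional[dict] = None
    af_model: AfModel = field(default_factory=AfModel)
    rarity_threshold: float = 1e-3
    splice_threshold: float = 0.05
    basewise_min: float = 2.0
    elementwise_min: float = 0.8
    alpha: float = 0.05
    wildtype_label: str = "wildtype"
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("rarity_threshold", "splice_threshold", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("basewise_min",):
            pass

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "af_model" in d and isinstance(d["af_model"], dict):
            d["af_model"] = AfModel(**d["af_model"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = {k: (asdict(v) if isinstance(v, AfModel) else v) for k, v in asdict(self).items()}
        return hashlib.md5(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _header(config: PipelineConfig) -> str:
    return f"# utrvar {__version__} config_hash={config.config_hash()} seed={config.seed}\n"


def _write_table(df: pd.DataFrame, path: str, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(
    config: PipelineConfig,
    utr: UtrSequence,
    variants: list[tuple[str, list[VariantSpec]]],
    outdir: str,
    track: Optional[ConservationTrack] = None,
    assay_table: Optional[pd.DataFrame] = None,
    model: Optional[TranscriptModel] = None,
) -> dict:
    """Run all stages and write the report bundle into ``outdir``.

    ``variants`` is a list of (construct label, variant list) — an empty
    variant list is the wildtype no-op.  Returns the bundle as in-memory
    objects keyed like the files written.
    """
    os.makedirs(outdir, exist_ok=True)
    bundle: dict = {}

    uorfs = scan_uorfs(utr)
    if track is not None:
        uorfs = [conservation_gate(u, track) for u in uorfs]
    write_uorf_report(uorfs, os.path.join(outdir, "uorfs.tsv"), os.path.join(outdir, "uorfs.json"))
    bundle["uorfs"] = uorfs
    logger.info("scanned %d uORF(s)", len(uorfs))

    credible = max_credible_af(config.af_model)
    rows = []
    for label, specs in variants:
        if not specs:
            continue
        call = classify_consequence(utr, specs, splice_threshold=config.splice_threshold)
        af = next((s.af for s in specs if s.af is not None), None)
        lead = specs[0] if len(specs) == 1 else specs[0]
        from dataclasses import replace as _replace

        lead = _replace(lead, af=af)
        result = assign_tier(call, lead, config.af_model, config.rarity_threshold)
        logger.info(
            "%s: code=%s criteria=%s tier=%s (rarity<%g credible<%g splice>=%g)",
            label, call.code, result.criteria_met, result.tier,
            config.rarity_threshold, credible, config.splice_threshold,
        )
        rows.append(
            {
                "construct": label,
                "hgvs": ";".join(s.label for s in specs),
                "primary_code": call.code,
                "secondary_codes": ";".join(call.secondary_codes),
                "affected_uorf": "" if call.affected_uorf is None else call.affected_uorf,
                "tier": result.tier,
                "criteria_met": ";".join(result.criteria_met),
                "af": "" if af is None else af,
                "passed_rarity": result.passed_rarity,
                "passed_credible_af": result.passed_credible_af,
                "max_credible_af": credible,
                "splice_flagged": result.splice_flagged,
                "details": json.dumps(call.details, sort_keys=True),
            }
        )
    consequences = pd.DataFrame(
        rows,
        columns=[
            "construct", "hgvs", "primary_code", "secondary_codes", "affected_uorf",
            "tier", "criteria_met", "af", "passed_rarity", "passed_credible_af",
            "max_credible_af", "splice_flagged", "details",
        ],
    )
    _write_table(consequences, os.path.join(outdir, "consequences.tsv"), config)
    bundle["consequences"] = consequences

    if assay_table is not None:
        rel = normalize(assay_table, wildtype=config.wildtype_label)
        res = anova_tukey(rel, alpha=config.alpha)
        wt = config.wildtype_label
        tk_rows = []
        for construct in rel["construct"].unique():
            if construct == wt:
                continue
            md = res.tukey.mean_difference(wt, construct)
            p = res.tukey.adjusted_p(wt, construct)
            tk_rows.append(
                {
                    "pair": f"{wt} vs {construct}",
                    "mean_difference": round(md, 6),
                    "percent_change": round(percent_change(md), 2),
                    "adjusted_p": format_p(p),
                    "significant": res.tukey.significant(wt, construct),
                }
            )
        tukey_df = pd.DataFrame(tk_rows)
        _write_table(tukey_df, os.path.join(outdir, "assay_tukey.tsv"), config)
        summary = {
            "anova_F": round(res.f_statistic, 4),
            "anova_p": res.p_value,
            "n_constructs": int(rel["construct"].nunique()),
            "comparisons": tk_rows,
        }
        with open(os.path.join(outdir, "assay_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2)
        bundle["assay"] = res
        bundle["assay_tukey"] = tukey_df
    return bundle
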