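"""Rarity/credibility filters and prioritisation tiers for 5'UTR variants.

Two allele-frequency gates coexist: a fixed review threshold (default 0.001)
used to select rare variants for manual-style review, and a *maximum credible
population allele frequency* derived from the disease model — the highest
allele frequency a truly pathogenic variant could plausibly reach in a
population database given the disease prevalence, heterogeneity and
penetrance.  Variant consequence codes are then mapped to two tiers:
'potentially disease-causing' (AUG-creating and uORF-stop-disrupting
variants) and 'of uncertain significance' (everything else rare, via five
criteria of which the last is a catch-all for any rare 5'UTR variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .variants import ConsequenceCall, VariantSpec

DEFAULT_RARITY_THRESHOLD = 1e-3

#: codes prioritised as potentially disease-causing (AUG creation or
#: disruption of an existing uORF stop, including frameshifts that lose it)
_PDC_CODES = {
    "uAUG_created_uORF",
    "uAUG_created_oORF",
    "uStop_lost_extension",
    "uStop_lost_oORF",
}

_CRITERIA = {
    "uAUG_created_uORF": "AUG_creating",
    "uAUG_created_oORF": "AUG_creating",
    "uStop_lost_extension": "stop_disrupting",
    "uStop_lost_oORF": "stop_disrupting",
    "uAUG_created_NTE": "NTE",
    "uAA_substitution": "uorf_missense",
    "kozak_changed_uORF": "kozak_alteration",
    "kozak_changed_mORF": "kozak_alteration",
    "uStart_lost": "uorf_start_loss",
}


@dataclass(frozen=True)
class AfModel:
    """Disease model for the maximum credible allele frequency.

    All proportions in (0, 1]; inheritance is heterozygous (one pathogenic
    allele per affected individual).  Defaults reproduce a disease with
    prevalence 1 in 1000, allelic heterogeneity 0.1, genetic heterogeneity
    0.9 and penetrance 0.75 (reduced from full penetrance to account for age
    structure in population databases).
    """

    prevalence: float = 1e-3
    allelic_heterogeneity: float = 0.1
    genetic_heterogeneity: float = 0.9
    penetrance: float = 0.75
    inheritance: str = "heterozygous"

    def __post_init__(self) -> None:
        for name in ("prevalence", "allelic_heterogeneity", "genetic_heterogeneity", "penetrance"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.inheritance != "heterozygous":
            raise ValueError("only heterozygous inheritance is modelled")


def max_credible_af(model: AfModel) -> float:
    """Maximum credible population allele frequency under the disease model.

    prevalence x genetic_heterogeneity x allelic_heterogeneity / (2 x
    penetrance): the factor 1/2 converts the frequency of affected genotypes
    to an allele frequency for heterozygous inheritance.
    """
    return (
        model.prevalence
        * model.genetic_heterogeneity
        * model.allelic_heterogeneity
        / (2.0 * model.penetrance)
    )


def rarity_filter(
    variant: VariantSpec, threshold: float = DEFAULT_RARITY_THRESHOLD
) -> bool:
    """True if the variant is rare: allele frequency below ``threshold``, or
    absent from the annotation (unobserved in the population = rare)."""
    if variant.af is None:
        return True
    if variant.af < 0:
        raise ValueError("negative allele frequency")
    return variant.af < threshold


@dataclass
class PrioritizationResult:
    tier: str  # potentially_disease_causing | uncertain_significance | not_prioritised
    criteria_met: list[str] = field(default_factory=list)
    passed_rarity: bool = True
    passed_credible_af: bool = True
    splice_flagged: bool = False


def assign_tier(
    call: ConsequenceCall,
    variant: VariantSpec,
    af_model: Optional[AfModel] = None,
    rarity_threshold: float = DEFAULT_RARITY_THRESHOLD,
) -> PrioritizationResult:
    """Map a consequence call plus AF annotations to a prioritisation tier.

    A pure function of the code set and the AF gates: common variants are
    not prioritised; rare AUG-creating or stop-disrupting variants are
    potentially disease-causing; every other rare 5'UTR variant is at least
    of uncertain significance (catch-all criterion).
    """
    af_model = af_model or AfModel()
    passed_rarity = rarity_filter(variant, rarity_threshold)
    credible = max_credible_af(af_model)
    passed_credible = variant.af is None or variant.af < credible
    splice = call.splice_flagged

    if not passed_rarity:
        return PrioritizationResult(
            "not_prioritised", [], passed_rarity, passed_credible, splice
        )
    criteria = sorted({_CRITERIA[c] for c in call.all_codes if c in _CRITERIA})
    if any(c in _PDC_CODES for c in call.all_codes):
        tier = "potentially_disease_causing"
    else:
        tier = "uncertain_significance"
        criteria.append("other_rare_5utr")
    return PrioritizationResult(tier, criteria, passed_rarity, passed_credible, splice)
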