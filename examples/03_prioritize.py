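"""Filter variants by population-frequency credibility and assign tiers.

The maximum credible allele frequency is the highest population frequency a
truly pathogenic variant could plausibly reach given disease prevalence,
heterogeneity and penetrance; variants above the rarity threshold are not
prioritised at all, rare stop-disrupting/AUG-creating variants are
'potentially disease-causing', and every other rare 5'UTR variant is at
least 'of uncertain significance'.
"""

from utrvar import AfModel, assign_tier, classify_consequence, generate_fixture, max_credible_af
from utrvar.simulate import panel_variants

af_model = AfModel()  # prevalence 1/1000, het 0.1/0.9, penetrance 0.75
print(f"max credible allele frequency: {max_credible_af(af_model):.1e}")

utr, _ = generate_fixture(seed=1)
for label in ("patient", "benign", "nhs1"):
    specs = panel_variants(label)
    call = classify_consequence(utr, specs)
    res = assign_tier(call, specs[0], af_model)
    af = specs[0].af
    print(
        f"{label:8s} af={'absent' if af is None else af} code={call.code:18s} "
        f"-> {res.tier} (criteria: {', '.join(res.criteria_met) or '-'})"
    )
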