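"""Classify the translational consequence of each modelled 5'UTR variant.

Applies the construct panel to the fixture and reports the structural diff
of the upstream-ORF architecture: the patient duplication frameshifts uORF1
and loses its stop (out-of-frame read-through across the main AUG); the two
in-phase rescues restore an in-frame stop 58 and 7 nt upstream of the main
AUG; the benign and cap-proximal substitutions change nothing; the knockout
substitutions destroy uORF starts.
"""

from utrvar import classify_consequence, generate_fixture
from utrvar.simulate import PANEL_HGVS, panel_variants

utr, _ = generate_fixture(seed=1)
for label, hgvs in PANEL_HGVS.items():
    if not hgvs:
        continue
    call = classify_consequence(utr, panel_variants(label))
    extra = ""
    if "new_gap" in call.details:
        extra = f", new stop {call.details['new_gap']} nt before mAUG"
    if call.details.get("new_stop_overlaps_uorf"):
        extra += " (inside uORF2)"
    if call.details.get("new_frame"):
        extra += f", reads through {call.details['new_frame']}"
    print(f"{label:10s} {';'.join(hgvs):22s} -> {call.code}{extra}")
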