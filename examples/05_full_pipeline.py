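"""Run the whole pathway: scan -> classify -> prioritise -> assay stats.

Generates every input synthetically (fixture UTR, variant panel,
conservation track, assay table), drives the pipeline once, and lists the
report bundle it writes: a uORF report, a per-variant consequence+tier
table with the full decision trail, and the Tukey comparison table.
"""

import os
import tempfile

from utrvar import generate_fixture, scan_uorfs
from utrvar.pipeline import PipelineConfig, run_pipeline
from utrvar.simulate import (
    FAMILY_VARIANTS,
    AssaySimConfig,
    default_true_means,
    panel_variants,
    simulate_assay,
    simulate_conservation,
)

utr, model = generate_fixture(seed=1)
variants = [(lab, panel_variants(lab)) for lab in
            ("patient", "rescue1", "rescue2", "benign", "nhs1")]
track = simulate_conservation(scan_uorfs(utr), utr.utr_length, seed=1)
assay = simulate_assay(AssaySimConfig(true_means=default_true_means(FAMILY_VARIANTS), seed=1))

outdir = tempfile.mkdtemp(prefix="utrvar_")
bundle = run_pipeline(PipelineConfig(), utr, variants, outdir, track=track, assay_table=assay)

print("report bundle:")
for name in sorted(os.listdir(outdir)):
    print(f"  {outdir}/{name}")
print()
print(bundle["consequences"][["construct", "primary_code", "tier"]].to_string(index=False))
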