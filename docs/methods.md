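# Methods

This note documents the models, conventions and numerical choices behind
`utrvar`, in the order the pipeline applies them, and closes with what the
synthetic-data suite does and does not establish.

## Coordinate model

A transcript is modelled as a contiguous 5′UTR plus the first codon of the
main ORF (`transcript.TranscriptModel`). Internally every position is a
0-based offset from the 5′ cap; HGVS-like signed `c.` values (…, c.−2,
c.−1, c.1 — there is no c.0) and 1-based inclusive genomic intervals appear
only at API and report boundaries, which confines the two off-by-one-prone
conventions to the conversion helpers. On a minus-strand gene the cap is
the maximum genomic coordinate of the UTR interval and the main-AUG A sits
one below its minimum. Multi-exon (splice-aware) UTRs are out of scope: the
modelled gene's 5′UTR is a single genomic block.

Insertions and duplications are held in transcript orientation and
converted to plus-strand VCF form only on output: a duplication is first
normalised to its 3′-most equivalent transcript position, then written as a
left-aligned insertion after the plus-strand anchor base below the run —
which is how the same event acquires two superficially different printed
coordinates in transcript and genomic notation.

## uORF scanning and annotation

Only ATG starts are considered (near-cognate starts such as CTG initiate
far less efficiently and are deliberately excluded). Every ATG whose first
in-frame stop codon lies entirely within the UTR is a *contained uORF*; a
stop whose last base is at c.−1 still counts, a stop codon overlapping the
main AUG does not. An ATG without such a stop is either an *N-terminal
extension* (in frame with the main ORF, no intervening stop) or an
*overlapping ORF* (out of frame, reading through the main AUG). Nested and
overlapping ATGs each get their own record, because variant diffing needs
per-start identity. Degenerate bases are rejected at parse time so that
consequence calls are deterministic.

Kozak strength uses only the −3 and +4 positions of the core motif
(A/G)XXATGG: both matching → strong, one → moderate, none → weak. Missing
context (an ATG within 3 nt of the cap) yields a class with an
`incomplete` flag rather than an error.

Conservation is gated per codon on two independent, optional channels:
basewise scores (PhyloP-style; default threshold 2.0, i.e. purifying
selection) and elementwise scores (PhastCons-style; default 0.8, i.e. a
conserved element). A codon is conserved if all three bases clear the
basewise threshold or all three clear the elementwise one. Published
analyses of this locus also quote a basewise threshold of 0.6 in one
place; the thresholds are configurable and 2.0/0.8 are the defaults.
Peptide-level conservation classifies the mean pairwise percent identity
of aligned orthologous peptides (identical non-double-gap columns over
columns with at least one residue): ≥ 80% high, ≥ 50% moderate, otherwise
weak; boundary values take the higher class. Catalogue evidence that a
uORF is actually translated is consumed as a boolean input flag, never
computed.

## Variant consequence classification

Variants are applied 3′→5′ so that indel length changes never invalidate
the remaining, more 5′, coordinates; reference alleles are verified against
the sequence and overlapping variants rejected. Classification is a
structural diff: the ORF architecture (every ATG with its extent class and
stop) is derived for reference and edited sequence, starts are matched
through the indel-adjusted coordinate map, and events are read off the
comparison. A matched contained uORF whose stop moved toward the main AUG
is a stop-loss with extension (the new stop-to-mAUG gap is reported, along
with any other uORF the new stop lands inside — reported as a fact, with no
functional prediction attached, since the mechanism of such overlap is
open); one whose reading now crosses the main AUG is a stop-loss oORF, with
the termination point located in the CDS prefix or flagged as beyond it.
New ATGs absent from the adjusted reference are creation events coded by
their extent.

Two taxonomy projections were needed where the closed code set has no
exact label: a stop-*gain* that truncates an existing uORF is coded
`uAA_substitution` (it is an amino-acid-level change within a defined
uORF), and an extent flip of a non-contained upstream ATG is coded
`uFrameshift`. Kozak changes are reported only when the strength *class*
changes, and only for defined (contained) uORFs or the main AUG. When a
variant triggers several events the primary code is the most severe under
a fixed ranking (stop-loss oORF > AUG-created oORF > stop-loss extension >
AUG-created uORF > NTE > start-loss > frameshift > missense > Kozak >
synonymous), mirroring the prioritisation tiers; the rest become secondary
codes. A supplied splice-prediction score ≥ 0.05 (configurable) adds a
"possible splice effect" flag without changing the code.

## Prioritisation

The maximum credible population allele frequency for a heterozygous
disease is prevalence × genetic heterogeneity × allelic heterogeneity /
(2 × penetrance); the factor ½ converts affected-genotype frequency to
allele frequency. With the defaults (prevalence 10⁻³, allelic
heterogeneity 0.1, genetic heterogeneity 0.9, penetrance 0.75) this is
6 × 10⁻⁵. Penetrance stays a free parameter with default 0.75 even for a
disease that is fully penetrant by adulthood, because population databases
mix ages and carry no phenotype. Both gates — the 0.001 review threshold
and the credible-AF bound — are evaluated and reported per variant; an
absent AF annotation means unobserved and is treated as rare. One AF value
is used per variant; whether it is a global or population-maximum
frequency is the caller's choice of input column. Tiering is a pure
function of the code set and AF flags: stop-disrupting and AUG-creating
codes are potentially disease-causing; N-terminal extensions, uORF
missense, Kozak class changes and uORF start-losses are of uncertain
significance; a catch-all criterion keeps every other rare 5′UTR variant
in the uncertain tier, so no rare variant goes unprioritised.

## Assay statistics

Technical duplicates are averaged before any statistics, so n per
construct equals the number of transfections (12 by default) — the
alternative of treating duplicates as observations would be
pseudo-replication. The GLuc/SeAP ratio of each transfection is divided by
the mean wildtype ratio of the same experiment, cancelling batch effects;
analysis stays on the linear relative-activity scale, matching how mean
differences like 0.87 on a 0–1-like scale are conventionally reported.
Group comparison is one-way ANOVA followed by Tukey's HSD
(statsmodels/scipy studentized-range), significance fixed at 0.05,
p-values below 10⁻⁴ formatted as "<0.0001". The duplicate-average-then-
ratio order is a documented choice; its effect is below simulation noise
at the planted effect sizes.

## Synthetic-data generator

The fixture generator emulates the structure of a real disease-gene 5′UTR,
not its sequence: uORF codons are drawn from synonymous sets (with two
deliberate restrictions — the arginine codon after uAUG2 is CGN so the +4
Kozak base is C, and the leucine codon before the proximal pinned base is
one of CTA/CTG/TTA/TTG so a single C>A edit can complete a stop in the
+1-shifted frame), a handful of bases are pinned (Kozak −3 bases, the
reference bases the variant panel edits, the two bases that let the first
rescue edit complete a shifted-frame stop), and all remaining positions are
filled left-to-right by a seeded draw that refuses to complete an ATG.
Candidates then face an independent validator that re-derives everything —
uORF count, positions, peptides, frames, gaps, Kozak classes, panel
consequence codes including both rescue gaps — using only the scanner and
classifier; generation retries (bounded at 10,000 attempts, in practice a
few suffice) until the validator passes, and fails loudly rather than
relaxing a constraint. The CDS prefix is 30 nt with no stop in the
+1-shifted frame, so the patient duplication demonstrably reads through
the main AUG; the main-AUG Kozak context defaults to moderate (an
assumption — the real gene's context is not modelled).

The assay simulator draws, per transfection, a lognormal
transfection-efficiency factor (σ = 0.3) multiplying both reporter
signals — which therefore cancels exactly in the ratio, as the
normalisation model assumes — plus additive measurement noise on the GLuc
channel scaled so the per-replicate relative activity has standard
deviation `noise_sd`, and a small (2%) relative noise on SeAP. The default
`noise_sd` = 0.1 sits at the upper end of the plausible 0.05–0.1 band: a
power analysis of the planted truths shows that the smallest effects (a
0.064 difference expected non-significant, a 0.09 difference expected
significant) are borderline at n = 12, and only the upper end keeps the
false-significance rate of the near-null constructs low; even so, those
borderline calls flip in a non-negligible fraction of simulation runs —
an intrinsic property of the study design, not of the implementation. The
simulator does not model plate position effects, signal crosstalk,
heteroscedastic (intensity-dependent) measurement error or outliers;
passing parameter-recovery tests therefore show the statistics recover
planted truths under an idealised noise model, not that the wet-lab
numbers themselves are reproducible.

Conservation simulation plants above-threshold scores on both channels at
the start/stop codons of the requested uORFs over a sub-threshold
background, so the gate's recovery is a planted-truth test.

## Determinism and numerics

Every stochastic component takes an explicit seed (numpy `default_rng`);
identical seeds give byte-identical outputs, and pipeline tables carry the
tool version and a configuration hash. Tukey p-values from scipy's
studentized-range integration agree with R's `ptukey` to ~4 significant
figures at moderate p but only to a few percent below 10⁻⁶, where both are
tail approximations; tests freeze R values with tolerances chosen
accordingly. Problem sizes in the test suite — 1,000 random UTRs for
scanner/oracle equivalence, 1,000 random single-base edits for classifier
equivalence, 200 seeded runs for assay parameter recovery — were chosen so
the whole suite completes in about two minutes on one core.

## Known limitations

Single-exon UTR model only; no ribosome-profiling, RNA-structure or
translation-efficiency prediction; no general HGVS grammar (intronic
offsets, inversions, repeats); VCF export covers substitutions and
duplications (the panel's needs); no ACMG evidence combination beyond the
two tiers; assay analysis has no outlier-rejection rules because none are
defined for the protocol modelled.
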