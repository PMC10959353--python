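# Methods

This note documents the models, algorithms and defaults behind
`mobiloscope`, the assumptions they rest on, and what the synthetic-data
validation does and does not demonstrate about real data.

## Proxy copy numbers

pCN is defined as a ratio of mean depths,
`pCN_f = mean_depth(consensus_f) / mean_depth(genome)`, with both depths
computed from the same read set. The numerator uses *all-hits* alignments to
the family consensus library (every reported location contributes coverage);
the denominator uses one placement per read on the reference assembly and
includes zero-depth positions. The ratio form is invariant to read length
and sequencing depth and implicitly corrects for consensus length.

Two properties of this estimator are worth knowing:

* **LTR double counting.** A consensus carries its LTR twice, so a read from
  an LTR maps to both LTR positions under the all-hits convention. The
  resulting inflation factor is `(4L + m) / (2L + m)` for LTR length `L` and
  internal length `m` — about +6% for a 150 bp LTR on a 5 kb element,
  consistent with the ~+5–7% bias the validation observes at all true copy
  numbers. It is a property of the all-alignments counting convention and is
  documented, not corrected.
* **Sampling noise.** The per-family depth estimate is driven by the number
  of reads hitting the family, so its coefficient of variation is roughly
  `sqrt(read_len / (depth × copies × element_len))` — about 2.5% for a
  2-copy family at 15×. Depth-invariance of the estimator is therefore
  checked on the family-summed pCN (CV ≈ 0.6%), where sampling noise does
  not mask the systematic behavior, and by *superset doubling* (the 15×
  read set plus an independent second 15× batch), which removes the
  between-run resampling variance that two unrelated simulations would add.

## Random-intercept mixed model and marginal R²

Per (family, bioclimatic variable) pair the model is
`pcn ~ 1 + x + (1 | clade)`, fitted by REML. The criterion is profiled down
to the variance ratio `λ = σ²_clade / σ²_resid`: for fixed λ the GLS
estimates and the residual variance are closed-form (the random-intercept
structure makes `(I + λZZᵀ)⁻¹` a per-group shrinkage), so the fit is a 1-D
minimization over log λ (coarse grid + bounded Brent, with the λ = 0
boundary checked explicitly and variances floored at zero). The fit agrees
with an established mixed-model implementation to ~5 decimals on identical
data; p-values are two-sided Wald tests, stable at the panel sizes used
(n = 320, 5 clades). With a single clade the model is degenerate and the
code falls back to an ordinary linear model with a warning; the same OLS
path implements the no-population-structure variant, for which the marginal
R² formula reduces exactly to the classical R².

Marginal R² follows the variance-partition definition
`Var(Xβ̂) / (Var(Xβ̂) + σ̂²_clade + σ̂²_resid)`. With only 5 clades the
clade-variance estimate is noisy and the ratio is slightly biased upward
(Jensen); the validation shows mean recovery within ±0.03 of generating
values {0, 0.10, 0.40} over 200 replicate panels, and a type-I rate of the
p < 0.05 flag within 0.05 ± 0.02 under the null. Association scans apply no
multiplicity correction by default (per-test p < 0.05 convention); BH
adjustment is available but off.

## 2-LTR junction detection

For each annotated full-length copy the tail-to-head record is
`last min(flank, |3'LTR|) bp of the 3'LTR + first min(flank, |5'LTR|) bp of
the 5'LTR` (default flank 300 bp), extracted in element orientation so
minus-strand copies give the same record as their plus-strand equivalent. A
read supports a 2-LTR circle when a **single contiguous matched block**
crosses the junction with at least `min_overlap = 5` bp on both sides;
split alignments whose blocks merely abut the fusion do not count, because a
genuine circular template yields contiguous sequence across it.

Two deliberate hardening choices sit on top of that rule:

* **Exact-match verification window.** Any bounded-mismatch extension
  aligner (including this package's) can occasionally carry an alignment a
  few coincidentally matching bases past its true endpoint, letting a
  linear-template read appear to cross the fusion. `scan_junctions`
  therefore re-checks the read bases over ±10 bp of the junction against
  the record and requires an exact match. A genuine circle read without a
  sequencing error at the fusion always passes; the chance of a linear read
  passing is ~4⁻¹⁰ per eligible read.
* **X-drop extension.** Seed extension stops when the running score
  (+1 match / −3 mismatch) drops 12 below its running best, bounding
  end-overshoot to a few bases. This keeps clip boundaries, contig block
  ends and junction overlaps tight.

Per-copy raw signal is the summed per-base depth of junction-spanning reads,
ignoring coordinate-duplicate reads (rolling-circle amplification produces
genuine duplicates; deduplication by (reference, start, end, strand) is the
conservative choice). Normalization divides by the sample's total
genome-wide coverage and multiplies by 10⁶ (per million bases — the
constant is arbitrary and inert for the ratio comparisons the results use).
Reads cross-mapping among the near-identical junction records of one family
count at every location ("greedy-all" attribution); per-family signals are
the sums over copies and are exactly additive. The genomic control applies
the identical computation to whole-genome reads of the same genotype:
nonzero control signal flags genomic tail-to-head-like junctions (e.g.
tandem or nested element pairs) rather than eccDNA.

## Circle-forming regions

Per sample, the ten longest assembled contigs (ties broken by input order)
are split-aligned to the reference; each matched block becomes a labeled
interval; overlapping or book-ended intervals merge (distance 0), recording
contig count and the distinct contributing samples; regions seen in fewer
than 3 samples are dropped. Specificity on an axis (stress or genotype) is
the fraction of the region's contigs whose sample carries the modal
category: > 0.5 (strict) → SPECIFIC; otherwise ≥ 10 samples → RECURRENT,
else NONE. A modal tie can never reach a strict majority, so ties fall
through to RECURRENT/NONE by construction. Regions are annotated with the
concatenated names of overlapping gene/TE features and their sequences are
extracted when ≥ 2 kb (shorter regions are flagged, not extracted).

Since de novo assembly is out of scope, the validation "assembly" turns each
simulated circle into one contig (random rotation, light trimming) — the
idealized output of an assembler given deep rolling-circle coverage of a
circular template. Real assemblies add fragmentation and chimeras that this
stand-in does not model.

## TIP filtering and zygosity

Candidate insertion calls are clustered per (family, chromosome) by
single-linkage within 10 bp (absorbing TSD-induced breakpoint ambiguity);
clusters observed in ≥ 2 individuals spanning ≥ 2 genetic backgrounds are
background differences against the reference, not new insertions, and are
removed. Removal is monotone: adding an observation from a second background
can only remove a cluster, never rescue one.

At a retained site, reads overlapping the insertion point are classified as
*clipped* (soft-clipped with the clip boundary within 20 bp of the point —
the tolerance covers the TSD shift plus X-drop overshoot) or *spanning*
(a matched block covers the point with no nearby clip). The clipped
fraction is reported as missing (not 0) when no reads overlap. Interpretive
bands (< 0.35 somatic-like, > 0.65 homozygous-like, support-poor below 2
split reads) are reporting conventions, not biological thresholds. The
site-level simulator draws reads covering the insertion point from the
carrier/non-carrier haplotypes with symmetric start windows, so the clipped
fraction is exactly binomial in the carrier fraction; a whole-genome
simulation would instead expose two clip stacks (one per element end)
against one spanning window and center near 0.6 for a heterozygote — the
same caveat applies when interpreting the statistic on real alignments.

## GWAS post-processing

Site filters keep MAF ≥ 0.05 and missingness ≤ 0.05 (both boundaries
inclusive-keep). Significance thresholds are BH-FDR < 0.05 (step-up with
enforced monotonicity, delegated to a standard implementation and checked
against the textbook definition) or Bonferroni α/n. Candidate windows are
20 kb with 10 kb step, anchored at multiples of the step from position 0 of
each chromosome (documented so coordinates are reproducible), kept when
containing ≥ 2 significant SNPs. Genes overlap a window by ≥ 1 bp; the
±10 kb "linked" annotation and a user-supplied gene-list membership
annotation are provided for labeling. Cross-family gene-set intersections
are exclusive (UpSet-style). Both 20 kb and 50 kb window sizes are exposed;
the larger one suits candidate-gene searches around a single peak.

## Synthetic data: scope and defaults

The generator emulates the statistical structure the analysis assumes:
families as LTR + internal + LTR consensus (default 300 bp + 4 kb + 300 bp);
genomes with non-overlapping TSD-flanked copies (TSD 5 bp, typical of
Copia-like integrases; per-copy divergence default 1%; ≥ 100 bp separation
between insertions); eccDNA pools with 2-LTR (full element), 1-LTR (element
minus its 5'LTR) and fragment (internal-region substring) circles;
rolling-circle fragments sampled uniformly on the circle with wrap-around
(closure-crossing probability read_len/circle_len per read); uniform
substitution errors only (the downstream filters operate on alignment
intervals, not gap structure); and accession panels generated under the
exact random-intercept model the analysis fits (baseline 50 copies, clade
and residual variances 1, i.i.d. standard-normal covariates), truncated at
zero — the baseline keeps truncation inactive at the simulated effect
sizes. All randomness derives from one integer seed through a named
generator per sub-task, so adding a simulation does not perturb others.

Not modeled: PCR/ligation bias, rolling-circle chimeras, indels, long
reads, linear-DNA carryover beyond a uniform WGS admixture, nested or
tandem insertions (except when engineered explicitly for the
genomic-control checks), and assembly fragmentation. Passing tests
therefore demonstrate correctness of the computations and their specificity
and sensitivity under clean conditions, not robustness to every artifact of
real libraries.

## Problem sizes used in validation

The end-to-end study uses 4 families × 5 copies in a 500 kb genome with 12
samples over 20 seeds; junction specificity uses 1-LTR and fragment circles
at 50× plus 5× WGS; pCN recovery uses true copy numbers {2, 8, 32} (150 bp
LTRs, ~5 kb elements — the longer internal region keeps the LTR
double-counting inflation well inside the ±15% recovery band) at 15× in a
~510 kb genome; mixed-model recovery uses 200 replicate panels of 320
accessions per target R² and 1000 null panels for the type-I rate; exact
oracles (BH, merging, windows, TIP clustering) use 1000 random instances.
`scripts/acceptance.py` re-runs the same experiments with slightly fewer
replicates (8 end-to-end seeds, 150 panels per R² target, 500 null panels),
sized to complete in a few minutes on one CPU.

## Numerical and degenerate-input choices

Coordinates are 0-based half-open internally, converted only at SAM/GFF3
boundaries. Aligner defaults: 21 bp exact seeds (about 5 per 100 bp read),
mismatch budget 5% of read length, minimum accepted block 21 bp, X-drop 12.
Duplicate marking keys on (reference, start, end, strand). Empty read sets
are warnings with empty/zero results, not errors; a zero genome coverage
total or zero genome length is an error because the normalizations are
undefined. Families with no alignments get depth 0. Tie-breaks are stable
everywhere (stable sorts; first-encountered wins), so outputs are invariant
to input order where the contracts require it.
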