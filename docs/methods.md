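# Methods

## The DMR statistic

The unit of testing is a fixed 100-bp genomic window, per cytosine
context (CG, CHG, CHH).  Within a window, per-cytosine counts are pooled
per sample: A = Σ a_i (methylated reads), B = Σ b_i (unmethylated), and
the level is the coverage-weighted m = A / (A + B).  Pooling — rather
than per-cytosine testing — is used because the level definition pools,
and because a single per-window decision is what the difference cutoff
operates on.

Eligibility is decided on the wild-type sample only: a window is testable
when ≥ `min_cytosines` (4) cytosines of its context each carry
≥ `min_cov_per_cytosine` (4) wild-type reads.  No mutant coverage filter
is applied, with one necessary exception: a window whose pooled mutant
coverage is zero has no defined m_mut and is excluded (and logged).

Each testable window's 2×2 table [[A_wt, B_wt], [A_mut, B_mut]] gets a
two-sided Fisher exact test.  The two-sided p sums hypergeometric
probabilities of all tables with the observed margins whose probability
is ≤ that of the observed table; as in R's `fisher.test`, a relative
tolerance of 1e-7 on this comparison absorbs floating-point ties between
analytically equal tables.  The implementation enumerates the support
vectorised in log space (`gammaln`), which handles the ~10^5 tables of a
genome scan in seconds; it is verified against an exact-integer
enumeration oracle for every table with grand total ≤ 40 (≈1.4 × 10^5
tables, agreement ≤ 1e-10).

P-values are Benjamini–Hochberg adjusted.  The FDR family is all
testable windows of one (contrast, context); whether the family should
instead span contexts is not decided by any external constraint, so
per-context was chosen (the more common practice) and the family is
whatever frame is passed to `fdr_adjust`, making the alternative a
one-line change.

A window is a candidate when |m_wt − m_mut| ≥ the context cutoff
(CG 0.4, CHG 0.2, CHH 0.1; boundary inclusive) and q < 0.01.  Direction
is the sign of m_wt − m_mut (`hypo_in_mutant` when positive).
Same-direction candidates with inter-window gap ≤ 200 bp (inclusive)
merge into a DMR; opposite directions and different contexts never
merge.  DMR summary levels are recomputed from pooled member counts; the
score is −log10 of the best member q.

## The noise-reduction cascade

Per-replicate DMR sets then pass through, in this order:

1. **Replicate/allele intersection** — a DMR survives iff it overlaps
   (≥ 1 bp, same direction) a DMR of the other replicate.  Groups of
   mutually overlapping intervals are reported as their union span
   (keeping the evidence of both replicates); intersection-span and
   first-set-span variants are selectable.  No re-merge is performed
   after intersection.
2. **HV subtraction** — any DMR overlapping a hypervariable interval is
   removed whole, not trimmed: partial evidence from a volatile locus is
   still suspect.
3. **Annotation** — exclusive labels with priority TE > gene >
   intergenic (configurable); a region touching both a TE and a gene is
   a TE region, matching the emphasis on transposon methylation.

All coordinates are 0-based half-open internally; 1-based only where a
file format requires it (count tables, SNP tables, GFF3).  "Overlap"
always means ≥ 1 shared base.

## Small RNA

Reads arrive as BED of mapped positions (alignment is upstream).  Each
read belongs to exactly one 500-bp static window, by its strand-aware 5′
end, avoiding double counting of boundary-spanning reads; RPM = count ×
10^6 / library size.  DSR calling is this package's own procedure
(assembled from standard ingredients: the 10-RPM eligibility floor in
either sample, a pseudocounted fold change ≥ 2 with pseudocount 0.5 RPM,
and Fisher/BH q < 0.01 on window count vs rest of library); output
headers say so.  Whether eligibility should consider the wild type only
is exposed (`rpm_min_scope`).  The global comparison is a two-sided
Mann–Whitney U on the RPM vectors of windows reaching the floor in the
wild type; the exact null distribution is used up to pooled n = 50
without ties, the tie-corrected normal approximation beyond.

## The synthetic-data generator

The generator's job is to emulate the statistical structure this
analysis must survive, at desk scale, with known truth.  Defaults:

* **Genome**: two 1-Mb chromosomes at GC 0.36 plus a 100-kb unmethylated
  control chromosome (the chloroplast stand-in for conversion-efficiency
  estimation).  A 200-SNP substitution table consistent with the genome
  exercises pseudo-genome construction.
* **Latent methylome**: TE-like loci (10 % of the genome, 0.5–3 kb)
  methylated at CG/CHG/CHH = 0.85/0.35/0.10; gene-body loci (15 %,
  1–4 kb) CG-only; background unmethylated.  Reads flip to "methylated"
  at rate 1 − conversion_rate (0.995) regardless of latent state.
* **Replicate variability** is modelled at two levels, which is the load-
  bearing design choice.  Per (locus, sample), the latent level may shift
  by ±U(0.15, 0.4) ("epimutation") with probability 0.5 at designated
  hypervariable loci (30 TE loci, emitted as the HV BED) and 0.02
  elsewhere; per cytosine, levels are Beta-distributed around the locus
  level with dispersion rho = 0.05, and counts are binomial at
  Poisson(10) coverage — i.e. beta-binomial counts.  Epimutation shifts
  rarely clear the CG (0.4) or CHG (0.2) cutoffs but routinely clear the
  CHH cutoff (0.1), so identical-genotype comparisons produce hundreds of
  spurious CHH candidate windows but few CG/CHG ones — the variability
  pattern the cascade exists to absorb.  Because epimutation draws are
  independent per sample, replicate intersection removes nearly all of
  it, and what survives is concentrated at HV loci, which the HV
  subtraction then removes.
* **Planted DMRs**: 50 per context, 300–800 bp, each guaranteed ≥ 4
  context cytosines (re-drawn otherwise), 70 % placed inside non-HV TE
  loci and the rest in unannotated space, never overlapping HV regions
  or each other.  Inside a planted region of context c the wild-type
  level is min(baseline_c + Δm, 0.95) and the mutant level is Δm lower —
  i.e. the region is a methylated locus in the wild type that loses Δm
  in the mutant, consistently across replicates (epimutation never
  applies inside planted spans).  Δm defaults: CG 0.6, CHG 0.4, CHH 0.3,
  all above their calling cutoffs so sensitivity is meaningful; 20 % of
  planted regions instead get Δm = 0.05, below every cutoff, to exercise
  true-negative behaviour.
* **Small RNA**: 300 clusters (200–400 bp) with negative-binomial read
  counts (mean 400, dispersion size 100), read lengths with a 24-nt mode,
  reads contained within their cluster; 30,000 background reads uniform
  over the genome; 20 clusters planted at 10-fold reduction in
  mutant-role libraries.

Sample draws are seeded from (config seed, role, replicate), so a
configuration reproduces byte-identical outputs, and wild-type- and
mutant-role samples share everything except planted effects and their
own noise draws.

What the generator does **not** emulate: read-level artefacts
(sequencing error, PCR duplicates, mapping bias), indel polymorphism,
chromosome-scale methylation gradients (pericentromeric enrichment),
correlated epimutation between contexts' neighbouring loci, and
cluster-level small-RNA length/strand structure beyond the marginal
length distribution.  Passing recovery tests therefore demonstrates the
pipeline's statistical behaviour under the stated count model, not
robustness to alignment artefacts.

## Calibration and recovery (what the tests compute)

* Null calibration: two identical-genotype replicate pairs under the
  default model yield ~400 single-replicate CHH candidate windows each,
  7–11 intersected regions (mostly HV loci), and ≤ 2 — typically 0 —
  after HV subtraction.
* Recovery: with Δm = 0.3 CHH regions at 15× coverage, sensitivity is
  ≥ 0.8 and precision ≥ 0.9 against planted truth (in practice 1.0 at
  the tested seeds); sub-threshold (Δm = 0.05) regions are recovered at
  ≤ 0.1.  Recovery is overlap-based (≥ 1 bp against the final DMR set),
  so a merged call spanning two planted regions recovers both.
* DSRs: planted 10-fold reductions are recovered at ≥ 0.9 (a cluster
  straddling a window boundary yields two window calls); identical
  null library pairs produce zero DSRs across tested seeds.

Problem sizes were chosen so the full default study (simulation plus
all-context, two-replicate analysis) completes in well under a minute on
one CPU, and the complete test suite in a few minutes.

## Known limitations

* The Fisher test treats pooled window counts as binomial within a
  sample; biological overdispersion is handled by the replicate
  intersection, not by a dispersion-modelled test (e.g. beta-binomial
  regression), which is deliberately out of scope.
* Window fragments of small-RNA clusters cut by a 500-bp boundary have
  inflated relative variance and can occasionally produce a borderline
  DSR call in a real-effect contrast (library-composition shifts add to
  this); interpret single-window DSRs at cluster edges with care.
* SNP handling is substitution-only; indels in a polymorphism table are
  rejected rather than guessed at, since coordinate-preserving
  substitution is what keeps DMR sets comparable across accessions.
* `intersect_replicates` chains overlaps transitively within a group of
  mutually overlapping intervals; with the union-span option a chain of
  small overlaps can report a span longer than any single replicate's
  DMR.
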