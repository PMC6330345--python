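# Methods

`somaclone` implements a desk-scale version of a clone-discrimination
analysis for vegetatively propagated plants (the motivating system is
grapevine clones of a single cultivar differing in cluster compactness):
somatic polymorphisms and expression divergence are read out of a
replicated RNA-seq design — four clones (two compact-cluster, two
loose-cluster), three biological replicates, two phenological stages
(just before flowering, E-L 18–19, and end of flowering, E-L 26) — and
reproductive performance is scored from per-inflorescence counts. All
inputs can be simulated with known ground truth, which is how the test
suite and the acceptance script exercise the method.

## Genotype classification (strict rules)

Clones of one cultivar are genetically identical apart from somatic
mutations, so candidate somatic sites are sites where exactly the allele
pattern *one clone heterozygous, all others homozygous* appears. Because
RNA-seq allele counts are noisy and likelihood-based genotypers are tuned
for DNA, classification is deliberately rule-based:

* a replicate is assignable only at **depth ≥ 50** reads (`min_depth`);
* **heterozygous** when the minor allele carries **≥ 30%** of reads
  (`het_minor_fraction`, boundary inclusive — 15/50 qualifies);
* **homozygous** when the minor allele has **≤ 1 read** *and* **< 2%** of
  reads (both conditions; 2 reads in 100 is ambiguous);
* anything else is *not assigned*, with a reason code
  (`low_depth` / `ambiguous` / `inconsistent_replicates`).

The minor allele is defined per clone as the allele with fewer reads
summed across that clone's replicates; an exact 50/50 tie is heterozygous
(fraction 0.5 ≥ 0.30). The rules are applied per replicate and a clone
status requires unanimity across replicates — the strictest consistent
reading of "consistent across replicates". The per-replicate depth gate is
the default; a pooled-depth variant (`pooled_depth=True`) applies the gate
to the clone total instead. `classify_replicate` is symmetric in its two
read counts: the decision depends only on (minor reads, depth), never on
which allele is ref or alt.

A site **passes** detection when ≥ 1 clone is heterozygous, every other
clone is homozygous (one not-assigned clone disqualifies the site), and —
by default — at least one homozygous clone has **zero** minor-allele reads
summed over its replicates. More than one heterozygous clone is allowed
and reported; the canonical somatic pattern has exactly one.

These rules are conservative by construction. At a per-read error rate of
0.5% and depth 100, a homozygous replicate exceeds one minor-allele read
with probability ≈ 9%, so with nine homozygous replicates per site a
substantial fraction of truly somatic sites is deliberately discarded as
ambiguous (sensitivity ≈ 0.3) while the false-positive rate stays at zero
in all our simulations. The trade is intentional: the procedure is meant
to produce a small list of certain candidates, not an exhaustive one.
Recall 1.0 is reached only in the noiseless limit (error rate 0), which
the acceptance script reports alongside the noisy-regime value.

## Variant I/O

VCF 4.2 with per-sample `AD` (Number=R) and `DP`, sample names
`<clone>_<replicate>`. Multi-allelic sites are decomposed into one record
per alternate allele; missing `AD` drops the sample-genotype (absent data,
never zero depth) with a logged count. The quality filter keeps sites with
`QUAL > 40` (strict; exactly 40 is removed) and is applied per site, QUAL
being a site-level field. Indels are assumed VCF left-aligned; no
re-normalization is performed.

## Effect annotation

A minimal consequence caller sufficient for flagging protein-disrupting
variants on toy gene models (GFF3 gene/mRNA/exon/CDS + FASTA):

* coding SNVs are translated on the strand-corrected CDS with the standard
  genetic code and classified by protein comparison: `stop_gained`,
  `stop_lost`, `start_lost` (only the annotated first ATG counts as
  start), `missense_variant`, `synonymous_variant`;
* the first and last **2 intronic bases** are splice donor/acceptor sites
  (orientation follows the strand); introns shorter than 4 bp are skipped
  as ambiguous;
* coding indels with length change not divisible by 3 are
  `frameshift_variant`; in-frame coding indels are reported as
  `missense_variant` (protein altered, not truncated) rather than a
  category outside the fixed vocabulary;
* exonic-but-not-coding positions are `utr_variant`; everything inside a
  gene span but outside exons is `intron_variant`; no overlap is
  `intergenic_variant`.

Category → impact is a fixed one-to-one map; `HIGH` = {stop gain/loss,
splice donor/acceptor, start loss, frameshift}. All overlapping models are
annotated (no canonical-transcript selection). The high-impact report
joins passing candidate sites with HIGH effects, naming the heterozygous
clone as the affected one.

## Expression filters

Counts are CPM-normalised; logs use `log2(CPM + 1)` so zero-count genes
stay finite. Significance for every contrast follows one decision rule:
|fold change| > 2 and Benjamini–Hochberg adjusted p < 0.05, with BH applied
across genes within each contrast.

The internal DE test is a **moderated two-sample test on log2-CPM**:
per-gene pooled variances (4 residual df at n = 3 + 3) are shrunk toward a
scaled inverse-chi-square prior fitted across genes by the method of
moments on log variances (inverse-trigamma step), and the t statistic uses
residual + prior df. At three replicates per group an unmoderated t is
dominated by variance noise — the chi-square spread of a 4-df variance
estimate alone loses ~10% of genuinely 8-fold-changed genes per stage at
the relevant BH thresholds — whereas moderation is the field-standard
remedy and keeps the null p-value distribution uniform (verified on pure
null simulations: the pre-adjustment positive rate at α = 0.05 stays
within Monte-Carlo error of 0.05 at 50 × 1000 genes). Externally computed
p-values (e.g. from a count-model DE package) can be injected in place of
the internal test; the fold-change/α decision rule is unchanged.

Other filters:

* **Absent / only-expressed genes** (per stage): a gene is
  `absent_in_clone` when the focal clone's replicates total ≤ 3 reads,
  every replicate of every other clone reaches an expression floor
  (default 5 reads), and the CPM fold change (pseudo-count 1) is ≥ 8.
  `only_expressed_in_clone` is the mirror condition. The ≤ 3 threshold is
  inclusive and applied to the per-clone per-stage total; both choices are
  switchable. The fold-change pseudo-count keeps ratios finite where raw
  ratios would diverge on near-zero denominators.
* **Constant differential expression**: a gene is `constant_de` for a
  contrast when significant in the same direction at both stages.
* **Contrast summary**: significant-gene counts per contrast, direction
  and stage, plus the both-stages-same-sign overlap (each gene counted
  once).

## QT clustering

Quality-threshold clustering with distance `1 − Pearson correlation` of
mean per-clone-per-stage log2-CPM profiles and a diameter bound of 0.2:
from every seed gene a candidate cluster grows by repeatedly adding the
gene that least increases the diameter while all pairwise distances stay
≤ 0.2; the largest candidate is emitted and removed; iteration stops when
no candidate reaches the minimum size (default 2). Ties break toward the
lowest gene index, so output is deterministic. Every emitted cluster is
guaranteed to respect the diameter bound; on well-separated instances the
greedy result coincides with exhaustive maximum-subset extraction (checked
against a brute-force subset oracle for ≤ 10 genes). Hierarchical
post-refinement of QT clusters is a noted extension point, not
implemented.

## Enrichment

Hypergeometric tests of a gene list against a category map over the gene
universe: upper tail for over-representation and lower tail for
under-representation, each BH-adjusted across categories, significant at
adjusted p < 0.05. Categories with no universe genes are skipped with a
warning.

## Phenotype indices

Per inflorescence: fruitset = (seeded + seedless) / flowers; coulure
(0–10) defaults to `10 × (1 − fruitset)` — so fruitset + coulure/10 ≡ 1 —
and millerandage (0–10) defaults to
`10 × (seedless + LGOs) / (seeded + seedless + LGOs)`, undefined (NaN,
excluded from means with `n` reported) when no post-flowering organ
exists. The published index formulas are not reproduced verbatim here;
the defaults are reconstructions consistent with the verbal definitions
and the 0–10 scale, and both functions accept an injectable replacement.
Clone summaries average per-inflorescence indices (mean of ratios), which
differs from applying the formulas to clone-mean counts; the test suite
demonstrates the difference on a two-record counterexample. An externally
computed compactness index column can be carried through but is not
computed.

## Synthetic data: what it emulates and what it does not

* **Allele counts**: depth per site × sample is negative binomial
  (mean 100, dispersion 0.1 by default; dispersion 0 gives constant depth,
  the noiseless/controlled limit used in several checks), alternate reads
  binomial — `het_alt_fraction` (default 0.5, configurable for
  allele-specific expression) in the carrier clone, `error_rate`
  (default 0.005) elsewhere. Planted carrier clones rotate round-robin;
  background sites are all-homozygous.
* **Expression**: baseline gene means are log-normal (log2 mean ~
  N(7, 1.5)), emulating a count matrix pre-filtered to expressed genes;
  per-sample library factors uniform on (0.85, 1.15); counts negative
  binomial with dispersion 0.05. Planted classes: clone-silent genes
  (0–3 reads total in the silent clone per stage, every other clone
  floored at 10 reads per replicate so the ≥ 8 fold-change criterion is
  attainable), constant clone effects (identical log2 effect at both
  stages), and stage-specific effects. Planted sets must be disjoint.
* **Phenotypes**: flowers per inflorescence Poisson around clone means;
  each flower multinomially becomes a seeded berry, seedless berry, LGO,
  or abscises. Default clone settings emulate a compact/loose panel
  (~300 flowers and fruitset ~0.7 for compact clones; loose clones either
  drop fruitset at moderate flower number or combine many flowers with
  strong flower drop).

Not emulated: read-level artifacts (mapping bias, PCR duplicates,
positional error profiles), allele-specific expression coupling across
sites, genuine library-composition effects beyond a scalar factor,
between-season phenotype variance, and any hormone data. Passing tests
therefore show that the decision rules and their implementation behave as
specified under the stated stochastic model — not that the thresholds are
optimal for any particular real data set.

All generators draw from child streams derived deterministically from one
master seed (`numpy` `SeedSequence`), so identical parameters give
byte-identical outputs.

## Pipeline and problem sizes

`run_pipeline` executes simulate → classify → annotate → contrast →
gene-classes → cluster → enrich → phenotype from one YAML config, writes
TSV/VCF/FASTA/GFF3/JSON outputs under a run directory, and finishes with a
manifest (stage summaries, seeds, SHA-256 checksums); re-running a config
reproduces identical checksums. The demo configuration uses 20 planted
sites + 50 background sites, 500 genes, and 10 inflorescences per clone;
the acceptance script uses 100 planted + 500 background sites, 1000 genes
with 20 silent + 40 constant-effect genes, and 50 null-matrix replicates —
sizes chosen so every check is a few seconds on one CPU while keeping
Monte-Carlo error small relative to the tolerances tested.

## Known limitations

* The strict-rule sensitivity analysis above: at realistic error rates the
  pipeline trades recall for near-certain precision; users wanting higher
  recall should relax `hom_max_minor_reads` or drop
  `require_zero_minor_clone`, understanding the false-positive cost.
* The consequence caller is intentionally minimal (no HGVS, no regulatory
  features, no canonical-transcript logic, simplified indel handling).
* The internal DE test assumes approximately normal log2-CPM within
  groups; severely zero-inflated genes are better served by injecting
  p-values from a count-model package.
* Coulure/millerandage formulas are reconstructions (see above), suitable
  for comparing clones within a run rather than matching externally
  published index values exactly.
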