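# Methods

This note records the models, parameter choices and numerical decisions
behind `patapa`, and what the synthetic-data validation does and does not
demonstrate about real PAT-seq data.

## Coordinates and input conventions

All internal coordinates are 0-based half-open; conversions to and from
1-based closed GFF3 happen only at the file boundary, so interval
lengths are preserved by construction. A tag's cleavage coordinate is
the 3'-most reference-consuming base of its alignment in transcriptional
orientation (alignment end − 1 for `+`, alignment start for `−`);
soft-clipped bases are excluded because clipped oligo(dT)/adaptor
sequence is not genomic evidence. For BED6 input the record's start
coordinate is taken verbatim as the cleavage position. The mapping
quality cutoff (`min_mapq`, default 10, SAM/BAM only) is exposed as a
flag; no published value exists for this step, so the default is
deliberately permissive and configurable.

When a gene has several transcripts, the representative is the one with
the longest annotated 3' UTR, falling back to the longest transcript:
this maximizes the surface available for 3' UTR assignment, which is the
quantity of interest here.

## Internal-priming filter

Oligo(dT) primers can anneal to genomic A-rich tracts, creating false
cleavage signals. A tag is removed when the `ip_window` = 10 nt window
immediately downstream of its cleavage position (read in sense
orientation; truncated windows use only available bases) contains
≥ `ip_max_a` = 7 A, or begins with a run of ≥ `ip_run_a` = 6 A. The
published criteria in this field vary and are often embedded in
unpublished scripts; these defaults express the common intent
(A-fraction ≥ ~0.65, or a leading tract long enough to prime) and all
three numbers are configurable. The rule is a pure function of the
window string, which allows exhaustive verification over every possible
window at a reduced window length.

## PAC calling

Clustering is single-linkage over sorted positions per (chromosome,
strand): a new cluster starts when the gap to the previous tag exceeds
`cluster_window` = 24 nt. This reading of "tags within 24 nt form one
cluster" is deterministic, order-invariant and exactly equivalent to the
transitive closure of the pairwise |Δpos| ≤ 24 relation (verified against
an O(n²) oracle). The summit is the position with the most tags; ties
break toward the most distal position in transcriptional orientation,
which is conservative for 3' UTR lengthening calls (a distal-biased
summit can only shorten the measured CK→ST length increase of a distal
shift, never inflate it).

Assignment is by summit, not span: spans can straddle annotation
boundaries and the summit is the best single-nucleotide estimate of the
cleavage site. The candidate regions are the representative transcript's
3' UTR, CDS, introns, 5' UTR, and the downstream extension (200 nt past
the annotated 3' UTR end; 200 + 218 nt past the gene end when no 3' UTR
is annotated, the extra term standing in for an average 3' UTR length).
Exactly one (gene, region) hit assigns the PAC; several hits yield the
ambiguous label `AMB` (keeping the gene of a 3' UTR hit if there is
one); none yields `INTERGENIC`. Every PAC receives exactly one label, so
region tables are partitions.

The minimum-support filter (`min_pats` = 10) applies to the tag total
pooled over all samples; a per-condition variant would couple PAC
existence to the design, and the pooled reading matches how the
threshold is usually stated. A gene with more than one surviving PAC is
an APA gene; `AMB` PACs count toward their assigned gene when one was
resolved, intergenic PACs never count.

Pipeline order is fixed — filter, then cluster — and `run_all` enforces
it; `cluster_tags(require_filtered=True)` refuses tags that have not
passed the filter.

## Differential expression

Normalization is median-of-ratios: the per-unit reference is the
geometric mean across samples over units observed in every sample, and a
sample's size factor is the median ratio to that reference. If no unit
is everywhere-positive the geometric means fall back to each unit's
positive entries. Size factors encode relative depth only: rescaling all
counts by a constant leaves them unchanged (the reference rescales too)
and scales normalized counts accordingly.

The two-group test is a negative-binomial Wald test on normalized group
means. Per-unit NB dispersion is estimated by method of moments,
a = (s² − m)/m², pooled across the two conditions by residual df. At
3 + 3 replicates this estimator has 4 df and is far too noisy to use
raw — in simulation it cost nearly all power against 4-fold changes — so
per-unit estimates are squeezed toward the median positive estimate
across units with a prior weight of 10 pseudo-df, the moderation
strategy count-based DE tools rely on, and floored at 1e-8. The Wald
statistic log(m_ST/m_CK)/SE with SE² = (1/m + a)/n per group (a 0.5
pseudo-mean guards zeros) is referred to a t distribution with
residual + prior df (14 at 3 + 3), reflecting the information actually
behind the SE. Measured on NB simulations at dispersion 0.1, mean 100,
n = 3 + 3: null type-I error ≈ 0.04–0.06 at p < 0.05 across seeds, power
≈ 0.95–0.99 for 4-fold changes at padj < 0.05. Units whose squeezed
dispersion sits at the floor (effectively Poisson data) are tested
exactly instead: conditional on the total, the treatment sum is binomial
with probability given by the size-factor split. BH adjustment is
applied across all tested units; all-zero units are excluded first.
There is no fold-change shrinkage and no dispersion trend fitting;
numerical parity with full DE engines such as DESeq2 is explicitly a
non-goal, and the package's gene-level "expression" is simply the sum of
tag counts over the gene's PACs.

## 3' UTR length dynamics

The procedures in this area are usually cited to prior work without
formulas, so the operationalization here is explicit and isolated behind
small functions:

- Per-PAC 3' UTR length = genomic distance (nt, inclusive) from the
  stop-codon-adjacent 3' UTR start to the PAC summit, extension PACs
  included. Intronic gaps inside 3' UTRs are not subtracted.
- Weighted 3' UTR length (WUL) = Σ usageᵢ × lengthᵢ, with usage shares
  from pooled condition counts (per-sample counts for the per-sample
  WUL). WUL is invariant to count scaling and PAC permutation and always
  lies between the shortest and longest member length.
- Direction statistic r = Pearson correlation across samples between the
  condition indicator (CK = 0, ST = 1) and per-sample WUL; r > 0 means
  lengthening. Zero-variance cases return r = 0 with a degeneracy flag;
  samples with no tags for the gene are dropped. Swapping the condition
  labels negates r exactly.
- Significance: Pearson chi-square (no continuity correction) on the
  2 × k condition × PAC table of pooled counts. If any expected cell is
  below 5 the asymptotic p-value is replaced by a Monte-Carlo estimate
  (2000 tables resampled under independence with observed row totals and
  pooled column proportions, fixed internal seed, add-one p-value) — a
  hand-rolled fallback because the SciPy routine offers no Monte-Carlo
  option.

Genes need ≥ 2 PACs in the 3' UTR (including the extension) to enter;
the union of PACs is kept across conditions (zero counts where absent)
so the table stays well-formed, and genes with zero counts throughout
one condition are excluded as undefined. BH adjustment runs across all
eligible genes; LENGTHEN requires r > 0 and padj < alpha, SHORTEN r < 0
and padj < alpha, everything else is UNCHANGED. The classified table
joins the gene-level log2 fold change so lengthen-and-up versus
lengthen-and-down quadrant counts are reproducible.

## APA events

Switching: ≥ 1 PAC with padj < alpha and log2fc > 0 and ≥ 1 with
padj < alpha and log2fc < 0 in the same gene; all up/down pairs are
recorded. Condition-specific PACs use a strict-zero rule (any tag in the
other condition disqualifies; `max_other` relaxes it) plus a support
floor of `min_total` = 10 pooled tags in the named condition, mirroring
the PAC support filter since no published expression floor exists for
this call. Inducible APA: ≤ 1 expressed PAC in CK and ≥ 2 in ST, where
"expressed" means pooled count ≥ max(min_total, 1) — a zero-count PAC is
never expressed, so `min_total = 0` degrades to "any tag at all". Note
the call is not monotone in `min_total`: lowering the floor also adds
control-side expressed PACs and can remove a gene from the inducible
set. Homology is input data (a user-supplied many-to-many TSV), not
computed; overlap reports count genes with a homolog in the partner set
and homolog pairs present in both sets.

These event classes deliberately overlap: a gene that moves usage
between PACs at constant expression has one PAC up and one down and so
satisfies the switching definition; induced PACs are ST-only and so
satisfy the specific-PAC definition. The ground-truth scorer therefore
evaluates each class over the planted labels that can discriminate it
(UTR classes over LENGTHEN/SHORTEN/NULL genes, switching false calls
over SWITCH/NULL genes, specific-PAC precision against all planted
ST-only sites with recall over the dedicated specific sites).

## Synthetic data generator

The generator emulates the structure of a two-condition PAT-seq study
with three replicates per condition. Gene loci have a fixed architecture
(80 nt 5' UTR, two 300-nt CDS exons, 120-nt intron, 300-nt 3' UTR) laid
on chromosomes of 250 loci with 1300-nt spacers, so gene extensions
never collide. A configurable fraction (default 10%) of genes lack the
3' UTR annotation to exercise the 200 + 218 nt fallback. Cleavage sites
sit at fixed offsets (60/160/260/360/460 nt from the 3' UTR start;
40–400 nt past the gene end for unannotated genes), placing the distal
sites in the extension; a small fraction of multi-PAC null genes carry
one site in the CDS, intron or 5' UTR to populate region tables.

Defaults are the study conditions the validation runs under: 1000 genes,
50% APA genes (2–5 PACs at probabilities 0.4/0.3/0.2/0.1), mean tag
yield 200 per gene per library, NB dispersion 0.1, and planted events at
10% lengthening, 2% shortening, 3% switching, 3% ST-specific PACs and
1.6% inducible APA. Lengthening moves `usage_shift` = 0.2 of usage from
the proximal PAC (seeded at share ≈ 0.5 so the transfer is always
possible) to the distal PAC under ST; shortening mirrors it. Switching
multiplies one PAC's usage 4-fold up and another's 4-fold down at
constant gene total — the same effect size the DE power analysis uses.
Specific sites get share 0 in CK and 0.15 in ST; inducible genes express
one PAC in CK and spread 60% of ST usage over 1–4 induced sites.

Counts are hierarchical: a gene's library total is drawn
NB(gene mean, dispersion) and split multinomially across its PACs with
condition-specific shares. The per-PAC marginal then has exactly mean
μ = share × gene mean and variance μ + d·μ² — the NB moment structure at
the same dispersion — while usage conditional on the total is exactly
multinomial, which keeps the chi-square usage test calibrated under the
null. (Drawing per-PAC counts independently NB would make usage
proportions overdispersed relative to multinomial and invalidate the
chi-square null.) Tag positions jitter around the true site by a rounded
Normal(0, jitter_sd = 5 nt), well inside the 24-nt cluster window, so
sites ≥ 90 nt apart essentially never merge. Planted internal-priming
artifacts are 15-nt A-tracts in intergenic spacers with NB(25) tags per
sample at the tract boundary (jitter 2 nt); the background genome is
uniform over A/C/G/T, which bounds the false-removal rate of the
A-richness rule at ≈ 0.4% of tags analytically and < 1% by test.

What passing the synthetic validation does **not** show about real data:
no mappability, chimeric-read or alignment artifacts; no microhetero-
geneity in cleavage beyond Gaussian jitter; no overlapping or antisense
gene pairs except the constructed ambiguity tests; dispersion is
homogeneous across PACs; gene totals are condition-balanced except
through planted events. Recovery rates on real libraries will be lower,
and the event definitions (strict-zero specific calls in particular) are
sensitive to sequencing depth.

## Problem sizes and determinism

The shipped validation runs the full pipeline on the 1000-gene default
study (~1.2 M tags, ~2000 PACs, about 15 s), a 500-gene null study for
false-call safety, and a 120-gene study twice for byte-level determinism;
oracle checks use 200 random clustering instances, all 4⁸ downstream
8-mers, and 1000 random matrices/tables. All randomness flows through
`numpy.random.default_rng` seeds carried in the configs; reruns with the
same seed and config are byte-identical, including the Monte-Carlo
chi-square fallback (fixed internal seed) and file outputs (sorted,
index-free TSV writes).
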