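# patapa

Alternative polyadenylation (APA) analysis for poly(A)-tag 3'-end
sequencing (PAT-seq) data: from aligned poly(A) tags to poly(A) site
clusters (PACs), differential PAC and gene expression between two
conditions, usage-weighted 3' UTR length dynamics, and APA event calls.

Most plant and animal genes carry more than one cleavage/polyadenylation
site; which site a transcript uses changes the 3' UTR content and thereby
mRNA stability, localization and translation. PAT-seq reads mark single
cleavage events at nucleotide resolution, so a two-condition experiment
(e.g. control `CK` vs salt stress `ST`, three replicates each) can ask:
which poly(A) sites exist, which shift in usage under stress, and which
genes lengthen or shorten their 3' UTRs. `patapa` is for researchers who
have such tag libraries aligned to a genome (SAM/BAM, or pre-extracted
cleavage sites in BED6) and want a tested, deterministic pipeline for the
downstream statistics.

## Method

1. **Internal-priming filter.** A tag whose downstream genomic 10-mer
   (transcriptional orientation) contains ≥ 7 A, or starts with ≥ 6
   consecutive A, is treated as an oligo(dT) mispriming artifact and
   removed.
2. **PAC calling.** Tags within 24 nt of each other (single-linkage gap
   rule per chromosome and strand) form one PAC; its summit is the modal
   tag position (ties break distal). PACs are assigned to genes and
   regions (3' UTR, CDS, intron, 5' UTR, downstream extension,
   intergenic, ambiguous) by summit position. The annotated 3' UTR is
   extended 200 nt downstream to rescue sites past the annotation
   (200 + 218 nt for genes lacking a 3' UTR annotation). PACs with fewer
   than 10 tags pooled across samples are dropped. A gene with > 1 PAC is
   an APA gene.
3. **Differential expression.** Counts are normalized by median-of-ratios
   size factors; each PAC (and each gene, as the sum of its PACs) is
   tested for log2 fold change ST vs CK with a negative-binomial Wald
   test using empirically squeezed method-of-moments dispersions, and
   Benjamini–Hochberg adjustment (significant at padj < 0.05).
4. **3' UTR dynamics.** For genes with ≥ 2 PACs in the 3' UTR, the
   usage-weighted 3' UTR length is WUL = Σᵢ pᵢ·Lᵢ (pᵢ = usage share,
   Lᵢ = distance from 3' UTR start to summit). The direction statistic r
   is the Pearson correlation between the condition indicator and
   per-sample WUL (r > 0: lengthening); significance is a chi-square test
   on the condition × PAC count table, BH-adjusted across genes.
5. **APA events.** Switching genes (one PAC significantly up and another
   down), condition-specific PACs (zero tags in the other condition,
   ≥ 10 in this one), condition-inducible APA genes (≤ 1 expressed PAC in
   CK, ≥ 2 in ST), and homolog-map overlaps of event gene sets between
   two analyses.

A synthetic-data generator (`patapa.synthetic_data`) builds a toy genome,
GFF3 and tag libraries with planted APA events and internal-priming
tracts, so every stage can be validated against ground truth.

## Worked example

```python
from patapa import SimConfig, simulate, RunConfig, run_all, truth_compare

sim = simulate(SimConfig(n_genes=200, seed=7), "example/sim")
res = run_all(RunConfig(genome=sim.genome_fasta, gff3=sim.gff3,
                        samples=sim.sample_sheet, outdir="example/run"))
print(f"PACs called: {res.report['n_pacs']}")
print(f"APA gene fraction: {res.report['apa_gene_fraction']:.2f}")
print(f"PAC region distribution: {res.report['region_distribution']}")
print(f"DE PACs (padj < 0.05): {res.report['n_de_pacs']}")
print(f"3' UTR classes: lengthen={res.utr_summary['n_lengthen']} "
      f"shorten={res.utr_summary['n_shorten']} unchanged={res.utr_summary['n_unchanged']}")
print(f"events: {res.report['events']}")
scores = truth_compare(res, sim.truth)
print(f"PAC recall vs planted truth: {scores['pac']['recall']:.3f}")
```

prints

```
PACs called: 395
APA gene fraction: 0.50
PAC region distribution: {'CDS': 1, 'EXTENDED_UTR3': 60, 'INTRON': 1, 'UTR3': 333}
DE PACs (padj < 0.05): 40
3' UTR classes: lengthen=30 shorten=10 unchanged=59
events: {'switching_genes': 7, 'st_specific_pacs': 13, 'st_specific_pac_genes': 9, 'inducible_apa_genes': 3}
PAC recall vs planted truth: 1.000
```

Half of the 200 simulated genes were planted with more than one poly(A)
site and the pipeline recovers exactly that fraction; most PACs fall in
annotated 3' UTRs with a minority rescued from the 200-nt extension; the
class counts reflect the planted lengthening/shortening events plus the
usage shifts implied by switching and induction.

The same stages are available from the shell:

```bash
patapa simulate --out simdir --seed 7
patapa run --config run.yaml          # callpac -> de -> utr -> events -> report
patapa callpac --genome g.fa --gff3 ann.gff3 --samples sheet.tsv --out pacdir
patapa de --pacs pacdir/pacs.tsv --samples sheet.tsv --level gene --out de.tsv
```

`patapa run` writes `pacs.bed`/`pacs.tsv`, per-sample bedGraph coverage,
DE tables, the 3' UTR table, per-event TSVs, six summary tables and a
human-readable `summary.txt`, all byte-reproducible for a fixed seed and
config.

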