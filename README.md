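# editome

Temporal analysis of A-to-I RNA editing and its coupling to alternative
splicing and translation, in the style of a developmental bulk
transcriptome study (five time points, two replicates each, total RNA-seq
plus ribosome profiling).

A-to-I editing deaminates adenosine to inosine in double-stranded RNA;
ribosomes and aligners read inosine as guanosine, so edited positions
appear as A→G mismatches on the transcript strand. This package
implements, as a tested and reusable pipeline:

- **High-confidence site calling** from stranded read alignments: read-end
  trimming (12 nt from the start, 2 nt from the end), mismatch pileup, and
  a five-step filter cascade — presence in both replicates, exclusion of
  known SNPs and of positions within 4 nt on the intronic side of splice
  sites, removal of multiallelic positions, and support thresholds
  (editing level ≥ 0.02, ≥ 10 reads coverage, ≥ 3 edited reads) — plus
  region annotation (CDS synonymous/nonsynonymous, UTRs, intron, ncRNA)
  and the nucleotide-context summary around edited adenosines.
- **Differential editing** between adjacent time points with a
  beta-binomial likelihood-ratio test on per-replicate edited/non-edited
  counts: `LLR = 2[ℓ(g₁) + ℓ(g₂) − ℓ(pooled)]`, chi-square reference,
  p ≤ 0.05.
- **Temporal pattern discovery**: per-site editing-level trajectories are
  z-scored, the fuzzifier m is set from the matrix dimensions by the
  Schwämmle–Jensen estimate, fuzzy c-means with c = 6 finds soft clusters,
  and clusters are renumbered by peak time. Sites are also grouped by
  prevalence (f1–f5: detected at 1…5 of the 5 time points).
- **Splicing efficiency**: percent spliced in,
  `PSI = 100·inclusion/(inclusion+exclusion)`, per event
  (EX/IR/Alt3/Alt5/MIC), with type-specific coverage filters and the
  differential rule |ΔPSI| ≥ 15 with a range statistic ≥ 5.
- **Translational efficiency**: median-of-ratios size factors, CDS-length
  correction, TE = normalised Ribo / normalised RNA, and per-gene
  negative-binomial GLM Wald tests of the library-type × time interaction
  (|log2FC| ≥ 1, BH-adjusted p ≤ 0.05).
- **Integration**: Fisher's exact test of editing×splicing gene presence,
  pairing of each site with its nearest same-gene event, Pearson
  trajectory correlation with Strong/Moderate/Weak/None categories
  (|r| ≥ 0.7 / 0.5 / 0.3), distance and event-type contrasts of positively
  vs negatively correlated pairs, AS/ES gene classes with
  translatable-transcript and TE summaries, and ADAR-expression
  correlation with editing activity.
- **A synthetic-data generator** that emulates all of the above with
  planted ground truth — temporally patterned editing sites, labelled SNP /
  multiallelic / low-support / splice-proximal / read-end / single-replicate
  contaminants, PSI trajectories correlated with nearby editing, and
  negative-binomial counts with planted TE fold changes — so every stage
  can be scored against known answers.

Real sequencing data re-processing (alignment, duplicate marking, event
discovery, ORF calling) is out of scope; the pipeline consumes simplified
alignment/pileup tables, junction-count tables and count matrices.

## Worked example

```python
from editome.io_formats import RunConfig
from editome.pipeline import run_all
from editome import evaluation

result = run_all(RunConfig(outdir="editome_run", seed=1))

rec = evaluation.site_recovery(result.sites, result.dataset.truth)
print(f"high-confidence sites: {rec['n_called']}")
print(f"precision {rec['precision']:.3f}, recall {rec['recall']:.3f}, "
      f"contaminants leaked {rec['n_leaked']}")

clus = evaluation.clustering_recovery(result.clustering.labels,
                                      result.dataset.truth)
print(f"temporal clustering ARI vs planted families: {clus['ari']:.3f}")

de = result.diffedit_results
print(f"differentially edited sites (p<=0.05): "
      f"{de.loc[de.significant, 'site_id'].nunique()}")
```

prints (seed 1):

```
high-confidence sites: 1990
precision 1.000, recall 0.995, contaminants leaked 0
temporal clustering ARI vs planted families: 0.956
differentially edited sites (p<=0.05): 1005
```

Of 2,000 planted sites, 1,990 survive the cascade with no contaminant of
any class leaking through; the six planted trajectory families are
recovered almost exactly (adjusted Rand index 0.96); and about half the
sites change significantly between at least one pair of adjacent time
points, as expected since four of the six planted patterns are
time-point-specific.

The same pipeline is available from a shell:

```bash
editome all --seed 1 --outdir editome_run
```

which writes the site table, attrition counts, cluster assignments, PSI
and differential tables, TE results, site–event pairs and a JSON manifest
into the output directory.

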