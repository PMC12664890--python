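# diffloopkit

Differential chromatin loop calling from HiChIP loop tables, with
distance-decay-aware false-discovery control and a built-in evaluation
suite.

## The problem

HiChIP measures protein-centric 3D chromatin contacts. Comparing two
conditions (e.g. wild-type vs. perturbed cells) means asking, for every
pair of genomic bins (an *interaction*; a *loop* once it passes a
significance criterion), whether its contact count changed beyond
replicate noise. Two features make this harder than RNA-seq-style testing:
counts decay steeply with the genomic distance between the anchors, so
long-range loops have systematically less power; and the counts track the
underlying 1D ChIP signal, so an apparent 3D change can be a disguised 1D
change.

`diffloopkit` takes per-sample loop tables as produced by a caller such as
FitHiChIP (tab-delimited `chr1 start1 end1 chr2 start2 end2 count qvalue`
at a fixed bin size), builds the union count matrix over a complete (A) or
loop-filtered (F) background, and models the counts with a self-contained
negative-binomial engine:

* **exact test** — conditions on the two-group total count; works down to
  one replicate per condition (fixed dispersion, default φ = 0.16);
* **GLM likelihood-ratio and quasi-likelihood F tests** and a **Wald
  mode** — NB log-link regressions with Cox–Reid dispersion estimation
  and empirical-Bayes variance moderation (≥ 2 replicates per condition).

A loop is differential when `padj < f`, `|log2FC| > l` and it was
significant in at least one input sample (caller FDR `< t`); defaults
`f = 0.05`, `l = 1`, `t = 0.01`. For the distance confound the package
offers **IHW-style covariate weighting** (cross-fitted weighted BH on the
baseMean/logCPM covariate) or **equal-occupancy distance stratification**
(contiguous strata holding ≥ C/M of the total contact count, per-stratum
models, one pooled BH pass — never both, to avoid double correction).
Differential loops whose anchors show no 1D ChIP change are annotated as
genuine `3D-change`.

The evaluation suite implements KR matrix balancing, aggregate peak
analysis (APA) with differential APA scores `d_AB = S_AA − S_AB`,
slack-tolerant loop overlap, top-k recovery of reference differential
Hi-C loops (exact test, `|log2FC| > 2`), and a replicate-permutation
type-I harness. A synthetic-data module generates statistically matched
multi-replicate loop tables, contact maps and coverage tracks with planted
effects, so the whole stack is testable without any external download.

## Worked example

```bash
python examples/01_differential_calling.py
```

```
tested 162594 locus pairs across 6 samples
differential loops called at padj<0.05, |log2FC|>1: 26
planted loops recovered: 26 / 30
```

The script simulates a 3 + 3 replicate experiment (20 Mb chromosome, 5 kb
bins, 150 000 background contacts per replicate, NB dispersion 0.1) with
thirty 4-fold planted loops, and calls differential loops with the QL
F-test under IHW weighting. The caller recovers 26 of the 30 planted
loops and — just as important — calls nothing else: every call is a true
positive. The misses are the planted pairs closest to the intensity floor,
where a 4-fold change cannot clear the genome-wide FDR threshold.

Other examples: `02_apa_scoring.py` (APA/differential-APA on matched
contact maps), `03_type1_calibration.py` (null replicate permutations),
`04_equal_occupancy_stratification.py` (distance stratification). A thin
CLI wraps the same functions:

```bash
diffloopkit simulate --config sim.yaml --outdir simdata/
diffloopkit diff --config run.yaml --test glm_qlf --fdr-method ihw --out calls.tsv
diffloopkit eval-type1 --config null.yaml --n-iter 60 --out fdp.tsv
```

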