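# ighquant

Base-level quantification of immunoglobulin heavy-chain (IGH) class
expression from aligned bulk RNA-seq reads, with the downstream cohort
analyses used to study antibody-class expression as a prognostic marker in
breast cancer: correlation and immune-metagene analysis, gene-set
enrichment of top correlates, median-dichotomized Kaplan–Meier curves, and
stratified multivariable Cox proportional-hazards model batteries.

**Who it is for.** Transcriptomics and tumor-immunology groups who need
per-class antibody expression (IGHM, IGHG1–4, IGHA1–2, …, plus the J-chain
gene as an internal control) from existing BAM files. The IGH locus is
somatically rearranged in B cells, so transcript-model pipelines (FPKM/TPM)
quantify it unreliably; `ighquant` works directly from genome alignments and
exon intervals instead.

## The statistic

Reads with mapping quality above 10 are walked CIGAR operation by CIGAR
operation; bases aligned via M/=/X that fall inside a class's merged exon
intervals are allocated to that class (N and D advance the reference without
contributing; S/I/H/P contribute nothing). With *B_c* allocated bases, *L_c*
the merged exon length, and *N* the library's total mapped reads,

```
expr_c = log2(1 + 10^6 · B_c / (L_c · N))
```

— the log2 of counts per base per million mapped reads. Downstream, this
value is used like any log-scale expression value: dichotomized at the
cohort median for Kaplan–Meier analysis, or z-scored as a continuous
covariate in stratified Cox models (hazard ratio per SD).

## Worked example

Simulate a toy locus with spliced reads, quantify it, and check against the
generator's ground truth:

```python
from ighquant import (ReadSimConfig, simulate_locus, simulate_reads,
                      write_sam, quantify_sample)

cfg = ReadSimConfig(seed=1)                 # 3 classes x 3 exons of 300 bp
model, layouts = simulate_locus(cfg)
reads, truth = simulate_reads(model, layouts, cfg)
write_sam(reads, model, "toy.sam")

for cls, e in quantify_sample("toy.sam", model).items():
    print(cls, e.bases, e.length, e.library_reads, round(e.value, 4))
```

prints

```
IGHM 8973 900 857 13.5061
IGHG1 8941 900 857 13.501
IGHG2 8722 900 857 13.4652
```

i.e. for IGHM, 8973 read bases were allocated to its 900 exonic bases out of
a library of 857 mapped reads, giving log2(1 + 10^6·8973/(900·857)) ≈ 13.51
— and `truth` confirms the base counts exactly, since the generator computes
them per position during simulation. A cohort-scale run looks like:

```python
from ighquant import CohortSimConfig, simulate_cohort, run_model_battery

table, betas = simulate_cohort(CohortSimConfig(n=3000, seed=5))
res = run_model_battery(table, ["IGHA2"], "model1")[0]
print(res.table.loc["IGHA2"].round(3), res.n, res.events)
```

which reports the fitted hazard ratio per SD of IGHA2 expression with its
Wald 95% CI (here HR ≈ 0.85, matching the simulated protective effect) and
the complete-case n/events bookkeeping.

The same operations are available from the shell:

```
ighquant simulate --kind reads --seed 1 --out-prefix toy
ighquant quantify --bam toy.sam --locus-model toy.locus.json --out expr.tsv
ighquant simulate --kind cohort --n 3000 --seed 5 --out-prefix sim
ighquant survive --cohort sim.cohort.tsv --ig-var IGHA2 --battery model1 --out cox.tsv
ighquant run-all --cohort sim.cohort.tsv --expr matrix.tsv --gmt sets.gmt --out-dir results
```

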