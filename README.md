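# pipetarget

Pleiotropy-informed prioritization of therapeutic targets from
cross-disease GWAS summary data.

Many genetic loci influence two or more diseases at once. Such
pleiotropic association signals are unusually informative about
druggable biology: genes they implicate are enriched for targets of
drugs that succeed in the clinic. `pipetarget` turns a table of
pleiotropic lead SNPs — index variants significant across multiple
diseases of one disorder system — into a genome-wide ranking of
candidate therapeutic targets, a pathway-crosstalk subnetwork of
interconnected high-priority genes, and a suite of evaluation analyses
for benchmarking the ranking against clinical evidence. It is aimed at
statistical geneticists and translational bioinformaticians working
with GWAS summary-level data.

## Method

The prioritization runs in three steps.

**1. Pleiotropic and peripheral genes.** Lead SNPs (p < 5×10⁻⁸) are
expanded by LD (R² ≥ 0.8) and scored

```
S_SNP = R² · ( log₁₀((1−P)/P) − log₁₀((1−T)/T) ),   T = 5×10⁻⁸
```

so the score vanishes at the genome-wide threshold and grows with the
strength of the pleiotropic association, attenuated by LD. SNP scores
are transferred to genes through three kinds of genomic evidence:
proximity (*nGene*, any gene within ±20 kb), promoter-capture Hi-C
contacts (*cGene*) and eQTLs (*eGene*), the latter two attenuated by
the empirical CDF of the link strength within each tissue dataset,
with the maximum taken over supporting SNPs. Each evidence dataset's
gene scores then seed a random walk with restart (restart γ = 0.75) on
a high-confidence STRING-like protein-interaction network (combined
score ≥ 700), producing one *affinity predictor* per dataset that also
scores peripheral genes wired to the seeds.

**2. Gene-level credit scores.** A random forest separating clinical
proof-of-concept targets from simulated negatives filters the
predictors, keeping those at least as important as the proximity
baseline. Per retained predictor, affinities are converted to P-like
values by the gene-wise eCDF; per gene they are combined Fisher-style,
`x = −2 Σ ln P`, referred to the lower tail of χ²(2J), and the
−log₁₀ of the combined value is min–max rescaled to a **credit score**
in [0, 10] (10 = best).

**3. Pathway crosstalk.** On a network merged from pathway interaction
lists, the connected subnetwork concentrating the highest credits is
extracted with a threshold + Steiner-tree heuristic, and its
significance assessed by a degree-preserving node permutation test.

The evaluation suite implements benchmarking AUC against simulated
negative targets, leading prioritization analysis (LPA; a GSEA-style
enrichment of proof-of-concept targets at the top of the ranking,
reporting NES, p, FDR, coverage and the leading edge), the summary
metric `PICT = log₁₀(NES · Coverage / FDR)`, target-level disease
relationship trees, spin-glass module detection with Fisher-exact
enrichment, and a supra-hexagonal self-organizing map of credit
profiles with targetability overlays.

## Worked example

All inputs can be simulated: the bundled generator plants a set of
true target genes into every input layer (GWAS signals, regulatory
links, network community, drug records, a dedicated pathway).

```sh
pipe simulate --out bundle --seed 1
pipe run --bundle bundle --out run --seed 1
```

which prints, per simulated disease:

```
disease01: AUC=1.000 NES=1.99 coverage=1.00 PICT=4.30
disease02: AUC=1.000 NES=2.02 coverage=1.00 PICT=4.30
disease03: AUC=0.995 NES=1.85 coverage=1.00 PICT=4.27
run complete -> run
```

AUC is the probability that a clinical proof-of-concept target
outranks a simulated negative target under the credit ranking (1.0 =
perfect separation); NES and coverage describe how strongly and how
completely those targets concentrate in the leading edge of the
ranking; PICT summarizes enrichment, coverage and FDR in one number
(higher = pleiotropy more informative for that disease's
therapeutics). `run/prioritization.tsv` holds the per-gene credit
scores and ranks, `run/crosstalk.tsv` the detected crosstalk
subnetwork, `run/evaluation.json` the per-disease statistics, and
`run/hexmap.json` the trained hexagonal map.

Individual stages are available as subcommands (`pipe score-snps`,
`pipe prioritize`, `pipe crosstalk`, `pipe hexmap`, ...); run
`pipe --help` for the list.

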