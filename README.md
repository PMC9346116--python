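# cupcompass

Tumor-entity prediction, genomic biomarker scoring and clinical-benefit
analytics for cancer of unknown primary (CUP) cohorts.

CUP is metastatic cancer whose primary site cannot be identified by
conventional diagnostics. Molecular workups of such patients combine
several independent readouts: a tissue-of-origin prediction from the
tumor transcriptome and methylome, genomic biomarkers guiding therapy
(tumor mutational burden, homologous-recombination deficiency,
microsatellite instability, viral infection status, tumor purity and
ploidy), and — once a molecularly guided therapy is applied — a
clinical-benefit evaluation based on progression-free-survival ratios.
`cupcompass` implements that whole analysis layer as a tested, reusable
library with seeded synthetic cohorts, so every stage can be exercised
end-to-end without access to controlled patient data.

## Methods at a glance

**Pairwise-tournament expression classifier.** A query FPKM profile *q*
is compared against every unordered pair (*a*, *b*) of reference
samples. Reference *a* scores

  s_a = |{g : q_g > t_up ∧ a_g > t_up ∧ b_g < t_down}| / |G′|

with t_up = 13, t_down = 3 FPKM, and symmetrically for *b*; the higher
score takes the pair's win. References are ranked by total wins and the
top-ranked non-CUP reference's entity is the prediction. For liver
biopsies, genes upregulated in normal liver are masked from the gene
universe G′ to suppress contamination by surrounding tissue. The
thresholds can be re-tuned by stratified 10-fold cross-validation.

**Methylome nearest neighbour.** After removing SNP-overlapping probes
and restricting to CpGs shared by the 850k/450k/27k array platforms, the
top 5000 most variant CpGs across the reference are selected; the query
is assigned the entity of the reference sample with the highest Spearman
correlation over those CpGs. COAD and READ are reported as one
"COAD/READ" basket. k-nearest-probe imputation and a seeded t-SNE
embedding (perplexity 100) support visualization.

**Genomic biomarkers.** TMB = (non-silent SNVs + coding indels) /
coding-sequence length in Mb, with merged-CDS denominators (35.334619 Mb
for WGS; capture-intersected values for the exome kits); ≥ 10 mut/Mb is
flagged very high and ≥ 100 total mutations is hypermutation. The HRD
composite is the unweighted sum of LOH-HRD (sub-chromosomal
loss-of-heterozygosity runs > 15 Mb) and LST (copy-state transitions
with ≥ 10 Mb flanks after 3 Mb smoothing), classed low (≤ 10),
intermediate (11–20) or high (> 20). MSI is called at score > 3.5;
variants with a control alternative-allele fraction ≥ 1/30 are flagged
germline; 96-channel mutational catalogs are normalized by 2800 (WGS) or
30 (WES) Mb with a < 50-SNV exclusion; viruses are reported when at
least two of three detection methods pass their read and genome-coverage
thresholds.

**Purity/ploidy grid search.** Given segment coverage ratios and BAFs,
every (TCC ∈ [0.15, 1.0], ploidy ∈ [1.0, 6.5]) grid point implies
real-valued allele-specific copy numbers; the fit objective is their
length-weighted squared distance to the nearest nonnegative integers.
All local minima are returned ranked, solutions at 100% tumor cell
content are flagged unreliable, and near-tied minima are ordered by
parsimony (lowest ploidy first) to resolve the intrinsic whole-genome
+2-copy degeneracy.

**Clinical benefit.** PFS per therapy line (months of 30.4375 days),
PFSr = PFS2/PFS1 comparing the first molecularly guided therapy against
the last prior systemic therapy (defined only when the prior line ended
in progression or death; PFSr > 1.3 marks clinical benefit), a modified
ratio with configurable denominator floor and ratio cap, Kaplan–Meier
estimation and the log-rank test.

## Worked example

```python
from cupcompass import SyntheticConfig, gen_expression_cohort, tournament_rank

cfg = SyntheticConfig(seed=7, n_entities=4, samples_per_entity=5,
                      queries_per_entity=1, n_genes=500, noise_cv=0.3)
cohort = gen_expression_cohort(cfg)
query = cohort.queries[0]
result = tournament_rank(query, cohort.reference, cohort.liver_genes)
print(f"query {query.sample_id}: predicted {result.predicted_entity} "
      f"(true {cohort.truth[query.sample_id]})")
print(result.table.head(3)[["wins", "similarity_sum", "entity", "rank"]])
```

prints

```
query Q_PAAD_000: predicted PAAD (true PAAD)
              wins  similarity_sum entity  rank
sample_id
REF_PAAD_000  17.0            0.75   PAAD     1
REF_PAAD_001  17.0            0.75   PAAD     2
REF_PAAD_002  17.0            0.75   PAAD     3
```

The cohort has 20 reference samples, so each query's tournament plays
C(20, 2) = 190 duels; the five references from the query's true entity
collect the most wins (17 of their 19 pairs each), and the rank-1
sample's label is the prediction.

The same stages are available from the shell:

```
cup-compass simulate --seed 7 --out sim/
cup-compass fit-cna --segments sim/segments.seg
cup-compass clinical --lines sim/therapy_lines.csv --cutoff 2019-06-30
cup-compass run --config pipeline.yaml --out run/
```

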