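# Methods

This note documents the models and procedures implemented in
`cupcompass`, the assumptions they make, the tunable parameters that
matter, and the design choices taken where the underlying methodology
left the design open.

## Pairwise-tournament expression classifier

A query profile is compared against all C(n, 2) unordered pairs of
reference samples. Within a pair (a, b), reference a's similarity is
the fraction of gene-universe genes that are upregulated (FPKM > t_up)
in both the query and a while downregulated (FPKM < t_down) in b. The
higher-scoring reference takes the pair's win; the references are then
ranked by wins and the top-ranked non-CUP reference supplies the
predicted entity (references labelled CUP are skipped, recorded in the
`cup_skipped` flag).

Parameters: `t_up` = 13 FPKM, `t_down` = 3 FPKM (re-tunable by
stratified 10-fold cross-validation over a threshold grid, ties broken
toward the defaults), `tie_award` = 0.5.

Choices made where the method definition is open:

- **Score denominator.** The "fraction of genes" is taken over the full
  gene universe |G′|. The pairwise comparison is denominator-invariant
  (both scores in a pair share it), so this choice affects reported
  magnitudes but never a ranking.
- **Exact score ties** award 0.5 wins to each side, conserving the
  per-pair win total. Σ wins = C(n, 2) is enforced by a property test.
- **Ranking ties** are broken by each sample's summed similarity over
  all its pairs, then lexicographically by sample id, making the output
  deterministic and order-invariant.
- **Strict inequalities** exactly as specified: FPKM values in
  [t_down, t_up] are neutral and contribute to no score.
- The production path precomputes boolean up/down indicator matrices
  and evaluates all pair scores as one matrix product; tests pin it to
  a naive gene-by-gene, pair-by-pair loop.

Liver-biopsy masking removes a configurable liver gene set from the
gene universe only when the query's biopsy site is liver. The masking
exists because bulk biopsies taken from liver metastases carry normal
liver tissue whose transcripts attract liver-like reference samples.

## Methylome nearest-neighbour classifier

Probe selection applies three filters in order: (i) drop probes
overlapping known SNPs, (ii) keep only probes present in all platform
manifests (emulating the 850k ∩ 450k ∩ 27k intersection), (iii) rank by
beta-value variance across the reference and keep the top K (default
5000). Variance uses non-missing values with the sample (n−1)
denominator; variance ties break by probe id. Prediction computes
Spearman correlation (average ranks for ties) between query and every
reference over the selected probes, using pairwise-complete values, and
returns the entity of the best-correlated sample; COAD and READ are
merged into a single reporting basket, the only merged basket. The
query must cover ≥ 80% of selected probes (configurable).

Imputation (used for the t-SNE embedding, optional elsewhere) replaces
each missing cell by the mean of the k = 10 nearest probes, with
distance the mean squared difference over samples where both probes are
observed, restricted to donors observed in the target sample, clipped
to [0, 1]. The default prediction path deliberately works on
pairwise-complete data without imputation: imputation is a smoothing
choice that belongs to visualization, not to the nearest-neighbour
decision.

t-SNE is call-level only (scikit-learn), perplexity 100, auto-reduced
with a warning when the cohort is too small; it is a visualization aid
and carries no acceptance weight.

## Genomic biomarkers

- **Coding length**: merged union of CDS intervals (0-based half-open
  internally; GTF converted at the read boundary), optionally
  intersected with the merged capture target; reported in Mb. The
  platform denominators 35.334619 / 31.057260 / 30.894643 Mb ship as
  constants for WGS and the two exome kits.
- **TMB** = (non-silent SNVs + coding indels) / coding Mb; the
  very-high flag uses TMB ≥ 10 (inclusive; the boundary value counts).
  **Hypermutation**: total mutations ≥ 100.
- **LOH-HRD**: maximal runs of adjacent LOH segments (minor copy 0,
  major ≥ 1) are merged; runs > 15 Mb count unless they span their
  whole chromosome.
- **LST**: per chromosome, segments < 3 Mb are discarded, equal
  total-copy-number neighbours merged, and breakpoints with both flanks
  ≥ 10 Mb counted. Whether the 3-Mb smoothing is applied per chromosome
  or per arm is a known ambiguity; this implementation smooths per
  chromosome (no centromere model).
- **HRD class**: low ≤ 10, intermediate 11–20, high > 20 on the
  unweighted sum (exhaustively swept in tests).
- **MSI**: score > 3.5 (strict) ⇒ MSI, else MSS.
- **Germline flag**: control alt-allele fraction ≥ 1/30. The "1/30
  reads" rule is read as a fraction because a fixed count is undefined
  at arbitrary depths.
- **Catalog normalization**: 96-channel catalogs divided by 2800 Mb
  (WGS) or 30 Mb (WES); samples with < 50 SNVs are excluded rather than
  normalized. Signature decomposition itself is out of scope.
- **Viral consensus**: k-mer method passes at ≥ 1 read per 40 M mapped
  and ≥ 10% genome coverage; assembly method at ≥ 1 read per 1 M
  mapped; alignment method at coverage ≥ max(5% of genome, 100 bp). A
  virus is reported when ≥ 2 methods pass; the rule is monotone in
  evidence by construction.

## Purity/ploidy grid search

Forward model (diploid admixed normal):
r = (τC + 2(1−τ)) / (τψ + 2(1−τ)) and b = (τm + (1−τ)) / (τC + 2(1−τ)),
where τ is tumor cell content, ψ ploidy, C/m total/minor copy number
and b the folded BAF. The fit inverts this per segment at every grid
point (τ step 0.01 over [0.15, 1.0], ψ step 0.05 over [1.0, 6.5],
< 10k points) and scores the length-weighted mean squared distance of
implied copy numbers to their nearest nonnegative integers. Segments
with < 20 heterozygous SNPs are excluded. Strict 8-neighbourhood local
minima are reported ranked; the global minimum is always included so
flat plateaus (e.g. a fully balanced genome) still yield a solution.

Two deliberate choices:

- **Unreliability at τ = 1.0**: full-purity solutions are retained but
  flagged unreliable — in practice they indicate samples whose purity
  is too low for the model to anchor.
- **Parsimony ranking.** The objective carries an exact degeneracy:
  shifting every segment's copy number by +2 at τ′ = τ/(1−τ),
  ψ′ = ψ + 2 reproduces identical ratios and BAFs, so minima come in
  families whose objectives differ only by noise. Minima within 50% of
  the best objective are therefore treated as indistinguishable and
  ordered by ploidy (then τ), the standard lowest-ploidy prior of
  purity/ploidy callers; clearly separated minima remain ordered by
  objective. Without this rule the +2 family wins roughly half of
  low-purity noisy fits despite being biologically implausible, which
  is exactly the ambiguity that historically required manual review.

## Clinical-benefit analytics

PFS runs from therapy start to progression or death (events) or to the
earlier of last follow-up and the analysis cutoff (censored); months
are 30.4375 days. PFSr = PFS2/PFS1 is defined only when the prior line
ended in an event — patients without progression on the prior therapy
keep their PFS2 but have no ratio, and cohort summaries therefore carry
different n for ratio and PFS2 aggregates. Benefit is PFSr > 1.3
(strict). The modified ratio applies an optional floor to PFS1 and an
optional cap to the ratio; the defining publication's exact parameters
are not restated here, so the rule ships empty (mPFSr = PFSr) with
floor/cap as configuration, and a floor-2/cap-12 example appears in the
tests. Kaplan–Meier estimation and the log-rank test are delegated to
lifelines; the median is the smallest time where S(t) ≤ 0.5, undefined
when never reached.

## Synthetic cohorts

The generators produce inputs with exactly the structure the stages
assume, deterministically under (config, seed):

- **Expression**: each entity owns a disjoint block of marker genes at
  a lognormal mean of 50 FPKM (background 1 FPKM), with a configurable
  coefficient of variation (lognormal noise keeps FPKM positive;
  CV = 0 reproduces templates exactly). Queries are fresh entity draws,
  optionally mixed convexly with a liver profile; an optional
  liver-like reference entity whose markers are the liver genes
  reproduces the attraction effect that motivates masking.
- **Methylome**: entity CpG blocks at beta 0.8 against background 0.1
  with Beta-distributed noise, planted missingness, a disjoint
  SNP-probe list and three nested platform manifests.
- **Copy number**: integer allele-specific states from a fixed diverse
  palette, coverage ratio and BAF computed by the same forward model
  the fitter inverts (exact inversion at zero noise is a tested
  invariant), optional multiplicative coverage noise.
- **Clinical**: per patient a prior line with Exponential(hazard_pre)
  time-to-progression and a recommended line with
  Exponential(hazard_post), censored at a follow-up horizon (default
  72 months); overall survival Exponential(hazard_os). Default hazards
  correspond to median progression times of 2.9 and 7.8 months and a
  median OS of 22.1 months.

Defaults (6 entities × 20 reference samples, 2000 genes, 5000 probes,
40 segments, 20 patients) keep the full test suite and the acceptance
script in seconds. What the generators do **not** emulate: real entity
signatures, inter-gene and inter-probe correlation, batch effects,
array-specific artefacts, subclonal copy number, or informative
censoring. Perfect accuracy on these cohorts therefore demonstrates
correctness of the decision rules, not expected performance on real
tumors.

## Problem sizes in the acceptance script

The script measures classifier accuracy on 6-entity cohorts (8
references and 4 queries per entity; 1000 genes / 2000 probes),
purity/ploidy recovery on 2 × 50 random 30-segment cases (noiseless,
and 2% coverage noise), TMB on the printed WGS denominator, and
PFS-ratio/Kaplan–Meier statistics on 500 simulated patients — sizes at
which the stochastic quantities are stable to a few percent across
seeds.
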