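# Methods

## The problem

Histone proteins are encoded by families of redundant genes — up to 11
near-identical genes for a single protein, most of them clustered at a few
genomic loci. Per-gene mutation counts are therefore a misleading measure of
how mutable the *protein* is, and any burden analysis must pool the family.
This package implements that redundancy-aware analysis end to end: pooled
per-protein rates, rank-based group contrasts with FDR control, a
within-family homogeneity test that stays valid on sparse tables, SBS96
mutational-profile refitting against a signature catalog, and co-occurrence
and covariate statistics — together with a synthetic-cohort generator that
gives every stage a known ground truth.

## The rate statistic

For a protein encoded by genes *i = 1..n* with counted mutations *m_i* and
CDS lengths *c_i* (bp),

    r = (Σ m_i) / (Σ c_i)

in mutations per base pair. Nine consequence classes count toward *m_i*:
missense, silent, nonsense, nonstop, frameshift insertion, frameshift
deletion, splice site, splice region, and translation start site; anything
else (UTR, intronic, …) is retained in the data model as `other` but never
counted. Exact duplicate calls (same patient, chromosome, position, alternate
allele) are removed before counting, and the removal is logged. `r` is a
mediant of the per-gene rates, so it always lies between the least and most
mutable member gene — the property tests rely on this invariant.

Per-cancer-type rates are computed only for cancer types with at least 10
patients; smaller types contribute only to the pan-cancer pool. The sampling
unit for all rate contrasts is the protein (one `r` per protein per cancer
type), not the gene.

## Group comparisons

Histone vs non-histone (or histone vs driver-protein) contrasts use the
two-sided Mann–Whitney U test: exact enumeration when the product of group
sizes is ≤ 200 and there are no ties, otherwise the tie- and
continuity-corrected normal approximation. Effect size is the fold change
mean(r_histone)/mean(r_comparison), defined only when both means are
positive. When comparing against a driver list, histone genes are first
removed from the driver set so the contrast is histones vs *non-histone*
drivers.

Family-level comparisons (H1, H2A, H2B, H3, H4) use Kruskal–Wallis with tie
correction and a chi-squared reference on k−1 df; the degenerate all-equal
case is reported as H = 0, p = 1. A cancer type enters the family analysis
only if every family has ≥ 10 counted mutations there; exclusions are
returned with a machine-readable reason. When the omnibus test is
significant at 0.05, a hand-rolled Dunn post-hoc (pairwise z-tests on pooled
ranks with the tie-corrected variance) is attached, BH-adjusted.

Benjamini–Hochberg adjustment is applied per analysis family — across
cancer types within one question — via `statsmodels`. Calibration is
verified empirically: each test's type-I error at α = 0.05 lies in
[0.03, 0.07] over 1,000 null simulations, and BH keeps empirical FDR ≤ 0.07
on 80/20 null/alternative mixtures (see `tests/test_acceptance.py`).

## Within-family homogeneity

For each multi-gene protein, the patients-with-a-mutation count per gene is
tested against a null of counts proportional to CDS length
(`null="length"`, the default; `null="uniform"` is also exposed — for the
identical-length paralogs typical of histone families the two coincide).
The statistic is the Pearson goodness-of-fit chi-squared. When any expected
cell is below 5 the asymptotic reference is not trusted; instead 10,000
tables are redrawn multinomially from the null at the observed total and

    p = (1 + #{simulated χ² ≥ observed χ²}) / (n_sim + 1),

the add-one correction keeping p strictly positive. The Monte-Carlo p agrees
with the asymptotic p within ±0.02 on dense tables and with exact
enumeration on all two-gene tables of total ≤ 6 (verified in the test
suite). Groups with a single gene or zero total mutations are skipped with a
reason rather than tested.

## Profiles and signature refitting

Single-nucleotide variants are mapped to the 96 pyrimidine-centred
trinucleotide channels in COSMIC file order (substitution blocks C>A, C>G,
C>T, T>A, T>C, T>G; flanks lexicographic within each block).
Purine-reference variants are reverse-complemented at profile-construction
time; I/O always carries the reference-strand context. Indels and MNVs are
skipped with a logged count, so channel sums always equal the number of
contributing SNVs.

Patients are partitioned by histone-mutation status and their mutations into
three groups (histone calls of histone-mutated patients; their non-histone
calls; all calls of the remaining patients), each group getting its own
profile. Both silent and missense SNVs contribute to profiles; consequence
filtering applies only to rate counting.

Exposures w (fraction of mutations per signature) maximize the multinomial
log-likelihood Σ_c n_c log(Σ_k w_k S_ck) over the simplex, where S is the
catalog matrix, optionally extended with a flat 1/96 column that absorbs
context-free processes. The optimizer is EM with closed-form updates,
initialized uniformly; the objective is concave in w, EM is monotone, and
iteration stops at a relative log-likelihood change below 1e-10 (cap 10,000
iterations), so the fit is deterministic with no solver dependence. A
brute-force simplex-grid oracle (0.01 resolution, K ≤ 3) confirms the EM
optimum in tests. Exposures are reported as percentages summing to 100.

Robustness: 100 multinomial bootstrap resamples at the profile's own size,
each refit; the 2.5/97.5 percentiles form the 95% CI and the bootstrap mean
is reported alongside. A signature is called *active* when its
point-estimate exposure exceeds 5% (the threshold is applied to the point
estimate; the CI is reported, not thresholded). Percentile intervals of this
kind undercover mildly — measured coverage is ≈ 93–95% at 10,000 mutations —
which the coverage acceptance band (≥ 43 of 50 datasets) anticipates.
Signatures sharing an annotated etiology (UV: SBS7a–d; MMR: SBS6, 15, 21,
26, 44; POLE: SBS10a–b; POLD1: SBS10c–d; tobacco: SBS4, 92; APOBEC: SBS2,
13) can be merged by summing exposures; the grand total is preserved and
group members absent from the catalog contribute a warning, not an error.

## Co-occurrence and covariates

Patients are cross-classified by query-gene mutation (optionally restricted
to a supplied list of driver positions) and histone mutation; the one-sided
exact hypergeometric (Fisher) test in the enrichment direction gives the
p-value, and the odds ratio is ad/bc with the Haldane 0.5 correction applied
only when a zero cell occurs (and flagged). A zero margin makes the table
degenerate: p = 1, flagged rather than tested. The full patient universe
(clinical table) must be supplied so never-mutated patients populate the
table.

Covariate analysis operates at gene level (pan-cancer m_i/c_i per gene)
against expression, replication time (100 = very early to 1500 = very late)
and chromatin state (−50 closed to +50 open), with Pearson correlation and
its two-sided t-test; genes missing a covariate are dropped pairwise and
logged, and zero-variance inputs yield a flagged undefined result.

## The synthetic cohort generator

The generator defines the study conditions for every test. It emulates a
multi-cancer WES cohort over a histone-like registry: an 11-gene H4 family,
a 10-gene H3.1 family, smaller H2A/H2B/H1 families (including dispersed
variant histones), a POLE-like polymerase gene and 50 single-copy background
genes, placed at clustered per-chromosome loci. Defaults: 500 patients over
five cancer types; per-patient burdens negative-binomial with mean 50 and
dispersion 2 (heavy-tailed, as in real cohorts); CDS sequences i.i.d. at 50%
GC. A mutation draws its gene with probability ∝ CDS length × a per-gene
rate multiplier (the designed-effect dial), its SBS96 channel from the
configured signature mixture restricted to channels with at least one
matching site in that gene's sequence (either strand,
pyrimidine-collapsed) — implemented as masking + renormalization, which is
distributionally identical to rejection sampling — and its position
uniformly over the matching sites. Consequences are silent:missense = 1:3
on the SNV bulk with small fixed masses for the other seven counted classes
and for `other`; frameshift classes are emitted as indels.

Ground truth records the configured and the availability-corrected
(*effective*) channel mixtures, per-gene selection probabilities and realized
counts, per-patient burdens and hypermutator flags. At the default CDS
lengths (≥ 312 bp) every gene contains all 32 pyrimidine trinucleotides with
overwhelming probability, so the effective mixture equals the configured one
and recovery tests compare against the designed exposures directly. A
separate generator plants a patient-level 2×2 association with an exact
designed odds ratio (Plackett coupling of the two margins) for validating
the co-occurrence test.

What the generator does *not* emulate: indel sequence context, copy number,
clustered mutational processes (kataegis), transcription-strand bias, and
real per-site mutability beyond trinucleotide availability. Passing tests
therefore demonstrate correctness of the estimators under the stated
sampling model, not robustness to every artefact of real tumor data.

All randomness flows from a single integer seed; the pipeline fans it out to
per-stage seeds by hashing the stage name (always below 2^31), so stages are
independently reproducible and reruns are byte-identical.

## Numerical and design choices

- Coordinates are 1-based inclusive (MAF convention); unknown MAF
  classification strings are retained as `other`, never dropped.
- Signature catalog columns must sum to 1 within 1e-3 and are renormalized;
  rows may arrive in any order and are mapped onto the canonical channel
  ordering. 96 rows exactly; negative entries are a hard error.
- Multi-gene-spanning MAF rows count once per gene-annotation row,
  matching per-gene counting semantics.
- CI endpoints are clipped to bracket the bootstrap mean in the rare case a
  skewed resample distribution would place the mean outside the percentile
  interval, preserving the `ci_low ≤ mean ≤ ci_high` contract.
- Problem sizes used by the validation suite and `scripts/acceptance.py`
  were chosen as the smallest at which the statistical claims are sharp:
  ~50,000 SNVs for mixture recovery (sampling error well under the ±2
  percentage-point band), 50 datasets × 100 bootstrap resamples for
  coverage, 1,000 replicates for calibration, 2,000 patients for odds-ratio
  recovery.

## Known limitations

- The refit assumes the catalog spans the true processes; no de-novo
  signature extraction (NMF) is provided, by design.
- Exposure estimates on real data may differ in detail from other
  maximum-likelihood refitting tools whose regularization and initialization
  differ; the objective here is the plain multinomial likelihood.
- The covariate analysis is a straight Pearson correlation; it does not
  adjust for confounding between covariates.
- Driver-gene discovery (background-model-based significance of individual
  genes) is out of scope; the package consumes driver lists, it does not
  produce them.
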