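# Methods

This note documents the models, numerical conventions and design
decisions of `spmtrace`: what each stage computes, what the synthetic
patient generator emulates, which parameters matter and why the defaults
are what they are, and what passing the test suite does and does not show
about real data.

## Presence adjudication

A somatic SNV is identified by the tuple (chrom, pos, ref, alt); SNVs only,
no normalisation or left-alignment is performed. For each variant called
in any sample and each sample, the status is decided in order: CALLED
(in the sample's own call set), CANDIDATE_PRESENT (in its
candidate-mutation-site list — candidate membership is taken to mean
"present", recorded as its own status so the decision stays auditable),
else the read-level rule on the pileup: depth < 50 → EXCLUDED; depth ≥ 50
and VAF < 0.01 → ABSENT; depth ≥ 50 and VAF > 0.02 → RESCUED_PRESENT;
otherwise EXCLUDED. The VAF boundaries 0.01 and 0.02 themselves fall to
EXCLUDED because both inequalities are strict. An uncovered site (depth 0)
is EXCLUDED by the letter of the rule, though "absent" is arguably the
intent; the choice is conservative for overlap counts. A missing pileup
record yields EXCLUDED with a warning rather than an error, keeping the
pipeline total on sparse inputs.

Exclusion is global per variant: a variant with any EXCLUDED cell is
dropped from all overlap counts (not just the offending pair). The
per-cell statuses are retained so the pairwise alternative can be
recomputed.

## Overlap partition and origin inference

Non-excluded variants partition by the exact subset of samples in which
their status is one of {CALLED, CANDIDATE_PRESENT, RESCUED_PRESENT};
classes are disjoint and their counts sum to the non-excluded total (a
tested invariant). The origin call for recurrence R maximises
shared(p) = number of non-excluded variants jointly present in primary p
and R, *including* variants also present in other samples — joint
presence, not pairwise-exclusive classes; where no variant spans a
primary, the recurrence and a third sample, the two readings coincide.
The margin between the top two primaries is reported and a tie yields
AMBIGUOUS rather than an arbitrary winner.

## Copy-number profile similarity

Median tumour/normal ratio profiles (Control-FREEC `ratio.txt` dialect;
MedianRatio −1 encodes missing) are compared by Spearman rank correlation
over the bins present in both profiles after pairwise deletion; fewer
than 3 shared bins, or a constant profile, makes the correlation
undefined and it is reported missing. Profiles are clustered by
complete-linkage agglomeration on distance 1 − rho; an undefined pair is
assigned the maximal distance 2 with a warning. Complete linkage is used
for consistency with the expression clustering; the t-approximation
p-value for rho is available but informational — no pipeline decision
depends on it.

## Germline filter cascade

Each replicate library is filtered on its own, in order: exonic;
FILTER = PASS; depth ≥ 8; depth ≤ q99; QUAL ≥ 20, where q99 is the 99 %
quantile of the depth distribution of the records *entering that stage*
(computing it on raw depths is a config option), with linear interpolation
between order statistics by default and nearest-rank selectable — no
convention is canonical, so the stage is parameterised. Records strictly
above the cap are removed (a guard against collapsed paralogs); a
degenerate all-equal depth distribution removes nothing.

The replicates are then union-merged on (chrom, pos, ref, alt): a variant
seen in only one replicate is kept, a key present in both keeps the first
replicate's annotation (conflicts are logged), and multi-allelic sites —
records carrying more than one alternate allele, or positions where the
union contains more than one distinct alternate — are removed. Survivors
are restricted to exact upper-cased matches against the cancer-gene list
with impact in {MODERATE, HIGH} (impact strings are normalised
case-insensitively onto the four standard categories; anything else maps
to "unknown" and fails the filter). Finally, records with effective
population allele frequency ≥ 0.05 are removed, where the effective value
is the exome-cohort frequency when present and the genome-cohort value
otherwise; records with neither are retained — absence of evidence of
commonness — and logged. Annotations are consumed from input fields,
never computed: the contribution here is the cascade logic, not the
annotators.

Every stage is traced as (name, records in, records out); the trace is
monotone non-increasing by construction. The depth cap is a property of
the original library's depth distribution, so the fitted caps are recorded
in the trace, and re-applying the cascade *with the recorded caps* is a
no-op (the idempotence contract the tests check). Re-estimating the
quantile on the cascade's own output would keep trimming the upper tail —
a property of any within-sample quantile rule, not of this
implementation.

## Mutational signatures

Substitutions are classified into the 96 canonical channels (six
pyrimidine-strand substitution types × 16 flank combinations, substitution
type major, flanks alphabetical — the COSMIC v2 table layout, which the
signature-file reader validates). Purine-reference variants are
reverse-complemented; applying the map to an already-pyrimidine variant is
the identity. A variant whose context is absent or inconsistent with its
reference allele is skipped with a warning and tallied, so catalogue total
plus rejects equals the input count.

Exposures solve min ||S·e − c||₂ subject to e ≥ 0 via the Lawson–Hanson
active-set algorithm (scipy's `nnls`): deterministic, no random
initialisation; optimality is checkable through the KKT conditions
(gradient components ~0 on the active support, ≥ 0 off it), which the
tests verify numerically at 1e-8. Exposures are reported in absolute
mutation-count units, matching the catalogue scale; normalised proportions
are a derived view. A relative cutoff can zero minor signatures, by
default without re-fitting; with re-fitting enabled NNLS is re-run on the
surviving support and the residual can only grow. No cutoff is applied by
default because thresholding conventions vary between published
workflows; consequently which signatures "survive" in a given sample is
not treated as a reproducible quantity, only the decomposition itself is.

Two synthetic signature-matrix constructors ship with the package (both
generated, never copied from reference data): a 30-column sparse-Dirichlet
matrix with realistic collinearity, and a block-orthogonal matrix whose
Gram condition number is ~1. Decomposition-accuracy checks use the
orthogonal construction so that what is measured is the solver, not the
identifiability limit of a collinear basis; with collinear signatures the
per-signature uncertainty of *any* linear decomposition exceeds the
multinomial lower bound.

## Expression and immune summaries

RPKM = count / (length/10³) / (mapped_total/10⁶); gene lengths and mapped
totals are inputs, not computations (the exact length definition — exon
union vs transcript — is upstream's choice). A gene is overexpressed in a
tumour sample when its RPKM is strictly above 10 *and* at least 10× the
normal-cohort median ("above" strict, "at least" inclusive); the median
uses the standard even-n midpoint and no pseudo-count, and a zero median
with tumour RPKM above the floor qualifies (any fold over zero) and is
logged. Heatmap-style structure uses row Z-scores (population sd;
zero-variance rows are zeroed with a warning) and complete-linkage
agglomeration on Euclidean distances for genes and samples; the number of
expression clusters is a visual judgement in practice, so the package
exposes the dendrogram and an optional cut height rather than hard-coding
a count.

Immune summaries from a deconvolution fraction table: total immune
fraction excludes the "Other/uncharacterised" share; M1/M2 ratio is
undefined (reported missing) when M2 = 0, and the immunosuppressive
percentage 100·(Treg + M2)/total-immune is undefined when no immune
signal is present. The percentage is invariant to rescaling all immune
fractions jointly (a tested property).

## The synthetic patient generator

The generator emulates the *statistical structure* every stage assumes,
not sequencing reads. Somatic truth is a partition of variants into
lesion-membership classes given directly by the scenario: per-primary
private counts, a set inherited by the recurrence from one origin primary,
recurrence-private variants, and optional pairwise-shared sets between
primaries. Conservation (classes sum to the total) holds by construction,
and the error example "more inherited variants than the origin has" cannot
be expressed — the origin's total is private + inherited + its shared
pairs. Observed data follow a diploid heterozygous model: depth ~
Poisson(mean depth), alt reads ~ Binomial(depth, purity/2) at carried
sites and Binomial(depth, error rate) elsewhere. No copy-number/VAF
interaction is modelled, since the adjudication rule operates on raw VAF
only. A configurable fraction of truly carried calls is withheld from the
call tables (still present in pileups) and a fraction of those withheld
appear in the candidate lists, exercising both rescue paths. Variant
contexts are drawn from the per-lesion signature mixture S·w, with a
random strand flip so the reverse-complement path is exercised; a context
table accompanies each variant rather than a genome FASTA.

Default scenario values are the studied case where printed: samples
T1/T2/T3/R1 with 141/5/120 private, 120 inherited, 97 recurrence-private
and 2 T1∩T3-shared variants; purities 0.18/0.16/0.68/0.64; mean depth
295.72 (tumours) and 277.81 (normal); 42-sample normal expression cohort;
per-sample immune targets (total immune 32.4/35.2/12.5/17.8 %,
immunosuppressive 53.5/37.3/16.4/27 %, M1/M2 0.66/0.96/2.22, with 2.0 for
the recurrence where only a qualitative statement exists); signature
mixtures supported on the signatures attributed to each sample, dominated
by the alcohol-associated one. Values no source states were chosen once
as realistic and are plain parameters: per-site error rate 2×10⁻⁴ (so
ABSENT calls are exercised at non-zero alt counts), call dropout 0.10 with
candidate fraction 0.5, germline base cohort 20,000 records per replicate
— the cascade's logic is exercised by the funnel's proportions, not its
absolute head, and the full-scale record count is an input-data property,
not a model parameter — replicate dropout 0.15, CN bin noise sd 0.10 on
2,200 bins with 2 % missing, fraction-table Dirichlet concentration 5,000.
Randomness is split per component from the master seed
(`SeedSequence.spawn`), so regenerating one component never perturbs the
others, and outputs are byte-identical across runs at a fixed seed.

Germline truth (the planted survivors) is computed by the generator's own
single-pass restatement of the filter rule, independent of the cascade
implementation, so precision/recall against it is a genuine two-route
check. The expression generator plants overexpressed genes at 1.5–3×
their qualifying threshold with Poisson count noise; planted sets for the
origin primary and the recurrence overlap, which is what makes the two
samples cluster together in expression space.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: FFPE deamination artefacts and
strand-asymmetric damage, subclonal cancer-cell-fraction continua, indels
and structural variants, mapping artefacts correlated across samples,
annotation errors, batch effects in expression, and the biases of real
deconvolution. Results on the simulator bound the pipeline's correctness,
not a caller's sensitivity on degraded material.

## Problem sizes and numerical conventions

The test suite and the acceptance script run scaled-down scenarios — e.g.
25/10/20 private + 20 inherited variants at depth 200 for batch origin
recovery, 1,500–20,000 germline records, 300–2,000 genes, catalogues of
500 mutations over 5 signatures — sizes chosen so that the statistical
contracts under test (binomial tails, multinomial standard errors,
quantile behaviour) are already in their asymptotic regime while a full
run of everything stays in the seconds-to-minutes range. Tolerances:
NNLS exact-combination recovery 1e-6, KKT 1e-8, Spearman-vs-oracle and
closed-form RPKM 1e-12; ties in ranks are averaged; leaf order in
dendrograms follows scipy's deterministic index-order tie-break.

## Known limitations

* Global per-variant exclusion is one of two defensible readings of
  "excluded from the analysis"; the per-pair alternative can be derived
  from the stored matrix but is not the default.
* The germline endpoint count on real data depends on the versions of the
  external gene list and population-frequency databases; only the cascade
  logic, not any published endpoint count, is a testable quantity here.
* Origin inference is an argmax over shared counts with a margin — it is
  not a phylogeny; deeper clonal reconstruction is out of scope.
* The signature module fits a fixed reference matrix; de-novo extraction
  (NMF) and indel/doublet signatures are out of scope.
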