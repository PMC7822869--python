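# Methods

## Study design and data model

The pipeline analyses a paired-compartment bulk RNA-seq design: two
diagnosis groups (control, MDD), each subject contributing one
whole-homogenate ("total") and one purified-synaptosome ("synaptic")
FPKM profile. Inputs are a genes × samples FPKM matrix and a sample
sheet mapping samples to subject, group, fraction and covariates (age,
PMI, brain pH, sex, antidepressant exposure, alcohol). All statistics
operate on FPKM; no count-level modelling is attempted, and the pipeline
deliberately starts downstream of read processing.

Gene identity is the (version-suffixed) Ensembl ID, compared as an
opaque string; gene symbols are display metadata. Missing covariate
values are allowed — operations that need a covariate drop those samples
and log the count.

## Detection and differential expression

A gene is *detected* in a fraction when its mean FPKM is ≥ 0.5 in at
least one group (boundary inclusive). Detected genes are tested with a
two-sided pooled-variance Student's *t* on log2(FPKM + 1). The +1
pseudocount stabilises the log transform near zero and is configurable
(`AnalysisConfig.log_pseudocount`); it is distinct from the ratio
pseudocount below. Fold change is the ratio of linear-scale group means
(MDD/control), matching how published per-gene tables present values
like 0.758 for downregulation. Calls: *up* when *p* < α (default 0.05)
and FC ≥ 1.3; *down* when *p* < α and FC ≤ 1/1.3. BH *q*-values are
computed over the detected genes of the fraction and reported but never
used for selection: in this design nothing survives FDR control
(reference *q*-values sit near 1), and the operative selection rule is
the raw-*p*-plus-fold-change criterion. Summary percentages
(e.g. "1.51 % upregulated") are 100·count/detected rounded **half-up to
two decimals** using exact decimal arithmetic.

Two deliberate conventions: (i) zero variance in both groups with equal
means yields *p* = 1 (logged), and perfectly separated zero-variance
groups yield *p* = 0; (ii) a zero control mean makes the fold change
undefined — the gene is excluded from classification (class
`undefined`) but keeps its *p* and *q*.

A note on thresholds: a 1.3-fold change is |log2 FC| ≈ 0.379. The value
0.584 sometimes quoted alongside "1.3-fold" is actually log2(1.5); this
package treats the fold change itself (1.3) as the operative threshold.

## Enrichment-ratio shift

For gene *g* and subject *s*, ratio(g, s) = (synaptic FPKM + c) /
(total FPKM + c). The default pseudocount c = 0 with per-observation
exclusion of zero denominators (count logged); a small positive c is a
configurable alternative, and both behaviours are unit-tested. The
ratio gene universe is the **intersection** of the two fractions'
detected sets — the background of the ratio analysis should be genes
quantifiable in both compartments; the near-equality of detected counts
in the two fractions makes the intersection nearly complete in practice.

Group ratios are **arithmetic means** of subject-level ratios; the
MDD/Ct column is the quotient of the two group means; the shift test is
the two-sided pooled-variance *t* on subject-level ratios (control vs.
MDD). Shifted genes are selected at raw *p* < 0.05, mirroring the
selection used for the reference table; no FDR is applied at this stage.
Distribution summaries count ratios strictly above/below 1 (exactly 1.0
falls in neither bucket), the median, and tail percentages at >1.5×,
>2× (enrichment) and <1/1.5, <1/2 (depletion), all as half-up
two-decimal percentages of the universe; tail nesting
(2× ⊂ 1.5×) is asserted on every run. Top/bottom-*n* rankings break
ties lexicographically by gene id.

`validate_ratio_table` re-derives the MDD/Ct column of a published-style
table from its two ratio columns; the shipped 119-row reference table
passes at tolerance 1e-4 (accommodating its 6-decimal rounding; two rows
are printed at fewer decimals and are transcribed exactly as printed).
The reference table's own *p*-values are design-dependent and are *not*
re-derived — the declared subject-level *t* test is this package's
documented choice.

## qPCR cross-validation

Livak relative quantification: technical replicates are collapsed to
their mean Ct per (sample, gene); the per-sample reference is the
geometric mean of the housekeeping Cts (GAPDH, ACTB, 18S rRNA by
default); ΔCt = Ct_target − reference; ΔΔCt = mean ΔCt(MDD) − mean
ΔCt(control); FC = 2^−ΔΔCt with a *t* test on per-sample ΔCt. By
construction the result is invariant to adding a constant to every Ct,
and group swap inverts FC exactly. Amplification-efficiency correction
(Pfaffl) is out of scope. Cross-platform agreement is Pearson's *r* on
paired per-gene fold changes (≥3 genes required). Covariate screens use
Pearson's *r*, with binary covariates coded 0/1 (point-biserial);
demographics are compared at subject level with Student's *t*
(continuous) and two-sided Fisher's exact by the point-probability
method (2×2 categorical).

## Gene-set enrichment

Right-tailed hypergeometric *p* for the overlap of a query with each
set, set membership intersected with the universe, sets smaller than 2
after intersection skipped. The universe should be the detected genes
of the relevant fraction (or the ratio universe for shift queries), not
the genome, so the background matches the detection filter. Scores are
−log10 *p*; BH *q* across the tested sets; significance requires
*p* < α and *q* < the FDR ceiling. The packaged GMT
(`demo_gene_sets.synthetic.gmt`) is a small synthetic demonstration
collection, not a curated database.

## Synthetic-data generator

FPKM is log-normal with additive log2 effects:

log2 FPKM = b_g + e_g·[syn] + d_g^(f)·[MDD] + h_g·[MDD]·[syn] + ε

* b_g ~ N(4.0, 1.5²) log2 FPKM — a well-expressed bulk transcriptome,
  far above the 0.5-FPKM detection floor;
* e_g ~ N(log2 0.89, 0.5²) — synaptic enrichment with median ratio
  below 1, as observed for brain compartment ratios;
* d_g^(f) — planted group effect (default log2 ≈ 0.585, i.e. 1.5-fold)
  acting in the gene's designated fraction, for the first
  ⌊frac·n⌋ genes of a seeded shuffle (DE-total, DE-synaptic and shift
  slices disjoint by default);
* h_g — planted group-by-fraction interaction (default log2 = 1), the
  ground truth of the shift test;
* ε ~ N(0, 0.5²) per (gene, sample) — the noise level is a free choice
  (no variance estimates accompany published FPKM tables); 0.5 on the
  log2 scale is a realistic bulk-RNA-seq subject-to-subject spread;
* optional dropout replaces values with exact 0 to exercise
  pseudocount/exclusion handling (default off).

Default design: 15 subjects per group, 2,000 genes, one global seed
driving a single generator. Subject covariates (age, PMI, pH, sex,
antidepressant only in the MDD group, alcohol) are generated
group-matched so demographic comparisons are null by construction.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: library-size or length biases, correlated
noise between the paired fractions beyond the shared gene effects,
batch effects, heavy-tailed or gene-dependent dispersion,
count-level sampling noise, and the skew that makes *t* tests on raw
ratios only approximately calibrated at small n. Null calibration and
recovery results are statements about this generative model.

## Numerical choices and problem sizes

* Percent rounding: half-up, two decimals, exact Decimal arithmetic.
* BH: standard step-up with cumulative minimum (statsmodels backend),
  validated in tests against an independent step-up oracle.
* Hypergeometric right tails from scipy, validated exhaustively against
  exact-fraction enumeration for all universe sizes ≤ 30.
* Determinism: a run is reproducible bit-for-bit from config + seed;
  report bodies differ only in the provenance timestamp.
* Simulation sizes used by the tests and the acceptance script — 2,000
  genes × 30 subjects for calibration/recovery, a few hundred genes for
  unit-level checks — keep the full suite in the tens of seconds while
  leaving ≥100 planted genes per recovery scenario.

## Known limitations

* The shift test operates on raw subject ratios, not log ratios; it is
  the declared convention here, but log-scale testing would be more
  robust to ratio skew.
* No covariate-adjusted DE model; covariates are screened post hoc.
* FDR is reported, not enforced, at the DE and shift stages — by
  design, but users quantifying genome-wide error should rely on the
  *q* columns.
* Enrichment treats gene sets as flat lists; no ontology-graph
  propagation.
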