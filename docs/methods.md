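# Methods

## The quantification model

`gclfq` implements gene-centric label-free quantification for shotgun
proteomics of paired cohort samples. The unit of analysis is the *gene
protein product* (GP): all peptide evidence for a gene's isoforms is pooled
before any statistics are computed.

**Peptide capacity.** For each gene, every annotated isoform is digested in
silico and the digest peptides with at most one missed cleavage ("singly
miscut") passing the length filter are counted as positional spans; the
gene's peptide capacity is the arithmetic mean of these per-isoform counts.
Two identical peptide sequences at different positions of one isoform count
twice, because each position contributes an observable peptide. The default
cleavage rule is plain trypsin (cut after K or R unless followed by P; the
trypsin/Lys-C variant that also cuts K|P is selectable), and the default
observable-length window is 6–30 residues. These are declared conventions of
this package — the capacity definition itself fixes only the ≤1
missed-cleavage count; protease rule and length window are configurable
(`DigestionParams`).

**iBAQ.** A gene's iBAQ in one sample is the summed AUC of its uniquely
assigned peptides divided by its peptide capacity — an intensity per
theoretically observable peptide, comparable across genes of different
length and isoform count. Peptides whose sequence is digest-compatible with
more than one gene are dropped by default (counts are logged); an optional
razor mode assigns them to the matching gene with the most unique peptides.

**iFOT.** Within one LC-MS run ("one experiment" = one sample), each gene's
iBAQ is divided by the summed iBAQ of all quantified genes, giving the
intensity-based fraction of total. iFOT is stored as a plain fraction
(display scalings such as ×10⁵ are formatting only) and sums to 1 per sample
by construction; any per-sample global intensity factor cancels exactly.
Undetected gene/sample cells (zero AUC) stay missing through the log2
transform — no pseudo-count is ever added, so missingness propagates to the
pairing stage instead of being imputed.

## Paired differential expression

The design has each subject sampled at three timepoints: T0 (before the
intervention), T1 (end of the 4-week intervention), T2 (one week after).
For a comparison num-vs-den, the effect estimator is the **average paired
log2 fold change**: the mean over subjects of
log2 iFOT(num) − log2 iFOT(den), using only subjects where the gene is
detected at both timepoints (complete pairs). Significance is the classical
paired two-tailed t-test on the same per-subject differences
(t = mean(d)/(sd(d)/√n), df = n−1, n−1-denominator SD). A gene is *called*
differential when |log2fc| ≥ log2(1.5) ≈ 0.585 (inclusive), P < 0.05
(strict), and at least `min_pairs` (default 3) complete pairs exist; a gene
with no complete pair for a comparison is ND (not detected) and never
called. Raw P values are thresholded, matching the reporting convention this
reproduces; a Benjamini–Hochberg q-value column is emitted for information
only.

Degenerate cases: fewer than two pairs → P undefined; all differences zero →
P = 1 (no evidence of change); zero variance with nonzero mean → P undefined
and flagged. The t statistic is invariant to the logarithm base and to
positive rescaling of the differences, and antisymmetric pair swapping
negates every fold change while preserving every P value — both are enforced
as property tests.

**Fold reporting.** Printed linear folds are round(2^|log2fc|) to the
nearest integer (half away from zero) with the direction carried by the
sign. Averaging is done on per-pair log2 differences, not on the ratio of
means; this is what makes the estimator paired.

## Over-representation and biomarker correlation

Enrichment of the called genes against user-supplied GMT gene sets is a
transparent hypergeometric upper-tail test (k of the n called genes fall in
a set of size K within the N-gene background, default background = all
quantified genes), reported as the "k/K" ratio plus P. It is deliberately a
topology-blind ORA stand-in; results are labelled as such and P values from
topology-aware commercial tools are not comparable.

Clinical biomarker association uses per-subject log2 fold changes on both
sides (protein: paired log2 iFOT difference; biomarker: log2 ratio of
values, requiring positive measurements), Pearson's r per (gene, parameter)
with a two-tailed P from t = r·√((n−2)/(1−r²)), pairwise-complete subjects,
minimum 3. |r| = 1 is reported as P = 0 with a degeneracy flag.

## The synthetic-data generator

The generator emulates the statistical structure of the study the pipeline
was designed for, so the full pipeline can be exercised and validated with
no raw mass-spectrometry data:

- 14 subjects × 3 timepoints (42 runs), ~900 genes with 1–3 random isoforms
  of 80–600 residues drawn with human-like amino-acid frequencies
  (K+R ≈ 11%, giving realistic tryptic peptide counts);
- per-gene baseline abundance log-uniform on iFOT scale over
  10⁻⁷·⁵–10⁻¹. The half-decade beyond six orders exists because realized
  per-sample extremes do not reach the interval ends and dropout trims the
  low tail; with it, the realized per-sample max/min positive iFOT ratio
  exceeds 10⁶, the dynamic range the pipeline is meant to handle;
- log2-scale Gaussian per-cell noise (default SD 0.5), a per-(gene, subject)
  random effect (default SD 0.5) that pairing removes, and a per-sample
  global intensity factor that iFOT removes;
- spiked log2 effects (default ±1..3 on 10% of genes) applied at T1 and
  persisting at T2 scaled by `t2_carryover` (default 0.5, emulating partial
  relaxation one week after);
- detection dropout as a Bernoulli draw with logistic probability in log10
  abundance (midpoint 10⁻⁷·², slope 2.5 per decade), so low-abundance genes
  lose samples, pairs, and eventually become ND;
- gene abundance split across up to 5 of the gene's own digest peptides with
  Dirichlet(1) weights, so the signal is carried at the gene level and
  survives peptide-to-gene assignment.

**Compositional caveat.** iFOT values are fractions of a per-sample total,
so spiking a gene perturbs every gene's iFOT through the denominator by the
spiked gene's share of that total. For this reason spiked genes are drawn
only from baselines below 10⁻³·⁵ (`spike_max_baseline_log10`): the regulated
fraction of a real proteome is not its dominant structural mass, and keeping
the dominant mass stable keeps the denominator stable. Under this
configuration the distortion is ≲0.01 log2 units; with it disabled (spikes
uniform over abundance) recovery would be biased by the aggregate
denominator shift — a real property of fraction-of-total normalization, not
an artifact of the generator. Consequently "exact" recovery in the
noise-free limit is exact only up to the spiked gene's own mass fraction
(tested at |error| < 0.01).

**What passing tests do and do not show.** The generator encodes exactly the
assumptions of the paired t-test (log-scale additivity, Gaussian noise,
independent cells given the subject effect) plus abundance-dependent
missingness. Calibration and recovery results on it validate the pipeline's
arithmetic and its handling of missingness — they do not validate the
t-test's robustness to real-data features the generator omits: correlated
peptide-level noise, ionization competition, match-between-runs artifacts,
heavy-tailed intensity error, or informative (MNAR beyond
abundance-logistic) missingness.

## Validation problem sizes

Unit and property tests run on toy sequences and small simulations (tens of
genes). The statistical-calibration checks use one null dataset
(2 000 genes, 14 subjects, no spikes — type-I rate at α = 0.05 within 3 SE
of 0.05 over ~2 000 genes) and one spiked dataset (2 000 genes, 200 spiked,
noise SD 0.3 — |bias| < 0.05 and RMSE < 0.25 on recovered log2 effects);
both complete in seconds. The digestion engine is checked against an
independent brute-force substring oracle on 1 000 random sequences and
cross-checked against an external digestion library on tryptic peptide
sets.

## Known limitations

- Gene-centric only: isoform-level quantification is out of scope, and
  shared-peptide handling (drop, or razor) is coarser than full protein
  inference.
- No match-between-runs, retention alignment, or identification-FDR
  modelling; the pipeline starts from an identified peptide AUC table.
- The ORA stand-in ignores pathway topology.
- Calling uses raw P values by design (mirroring the reporting convention);
  users scanning many comparisons should read the BH column.
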