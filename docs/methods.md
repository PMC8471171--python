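# Methods

`mepact` implements a desk-scale, fully testable version of an integrative
epigenomics analysis: find genes whose promoter **hyper**methylation coincides
with transcriptional **up**-regulation, screen transcription factors for
preferential binding to methylated DNA, intersect knockdown responses to
nominate direct targets, and quantify the standard validation assays.
Because the underlying patient and array data are not redistributable, every
stage runs against a synthetic-data generator with planted ground truth; the
statistical machinery itself is generic.

## Differential testing

Both the methylation and the expression layer use an empirical-Bayes
moderated two-sample t-statistic. Per feature *g* with pooled variance
s²_g on d = n₁ + n₂ − 2 degrees of freedom, a scaled inverse-χ² prior
(d₀, s₀²) is fitted across features by moment-matching log s²: the excess of
var(log s²) over trigamma(d/2) identifies d₀ through a trigamma inversion
(Newton iteration), and the mean of log s² identifies s₀² through the
digamma identity. The posterior variance

    s²_post = (d₀·s₀² + d·s²) / (d₀ + d)

replaces s² in the pooled-variance t, which is referred to a t distribution
with d₀ + d degrees of freedom. Tests are two-sided; no Welch correction is
applied (the model assumes a common within-group variance per feature, as in
the standard limma-style formulation). When the log-variances are nearly
constant across features the trigamma inversion is infeasible and the code
falls back to d₀ = 0, i.e. the ordinary pooled t — in that regime shrinkage
is immaterial because s² ≈ s₀² anyway. A `prior_df` argument overrides the
fitted d₀ (0 gives the textbook t; ∞ gives a z-like test with one shared
variance), which is how the reduction properties are tested.

Promoter methylation is summarised **on the beta scale**: the arithmetic
mean beta over all probes inside the strand-oriented promoter window
[TSS−1500, TSS+500) (half-open; for minus-strand genes [TSS−500, TSS+1500)
in genome coordinates), and the reported effect is Δβ = mean(case) −
mean(control). M-value testing would have better variance behaviour at the
extremes, but the effect threshold the pipeline enforces (|Δβ| ≥ 0.1) is
defined on the beta scale, so testing the reported quantity directly keeps
effect and test coherent. Genes whose window contains no probe are dropped
and listed in a QC report rather than failing the run.

Significance defaults: methylation BH-adjusted p ≤ 0.05 AND |Δβ| ≥ 0.1;
expression BH-adjusted p ≤ 0.01 AND |log2FC| ≥ 0.5. Benjamini–Hochberg
adjustment delegates to `statsmodels` and is cross-checked against a
brute-force step-up implementation in the tests.

## Quadrant integration

Genes present in both differential tables (inner join — the scatter of Δβ
vs log2FC only makes sense for doubly measured genes) are assigned to
hyper_up / hyper_down / hypo_up / hypo_down when significant in **both**
layers, by the sign pair (sign Δβ, sign log2FC). A zero effect with a
significance flag (possible only under user-supplied thresholds) has no
defined sign and maps to `none`. Knockdown panels are intersected as
{significant AND log2FC < 0} per cell line; candidate direct targets are the
consistently-down genes whose promoters are significantly hypermethylated
(Δβ > 0).

## TF-microarray screen

Replicate spots are collapsed by median (robust; replicate handling is a
package choice). Per channel, the positivity threshold is the mean of the
negative-control spots plus four sample standard deviations (ddof = 1).
The methylated/unmethylated preference ratio floors each channel at its own
threshold before dividing, so a sub-background denominator cannot inflate
the ratio; flooring is conservative and keeps ratios finite. Classes:
`not_expressed` (both terminal-tag stains below the expression floor, default
1× the tag thresholds), `non_binder` (neither DNA channel positive),
`methyl_preferring` (methylated channel positive and floored ratio ≥ cutoff,
default 2 — the cutoff is a named config parameter, not a literature
constant), `unmethyl_preferring` (symmetric), else `non_discriminating`.
Methyl-preferring factors are ranked by descending ratio with ties broken by
descending methylated-channel MFI, then lexicographic id; the top 15 are
flagged by default. The classification is invariant to spot order and to a
common rescaling of all channels, and swapping the two DNA channels exactly
exchanges the two preferring classes — all property-tested.

## Methylation-aware motif scanning

Motifs are PWMs over {A, C, G, T, M}, M = 5-methylcytosine in CpG context.
A promoter carries a mask of methylated CpG cytosines; encoding rewrites
masked C→M on the plus strand and — since CpG methylation is treated as
symmetric (hemimethylation is not modelled) — the cytosine complementary to
each masked CpG's guanine becomes M on the minus strand. Masked positions
that are not CpG cytosines are rejected.

Every window on both strands is scored as Σ log2(emission/background)
(bits). Exact p-values come from dynamic programming: per-position
per-letter scores are rounded to integer multiples of the granularity
(default 10⁻³ bits), the position distributions are convolved under the
background model, and P(score ≥ s) is read off the tail. Scanned windows
are integerised with the same rounding, so lookups are exact with respect
to the DP — the only approximation is the granularity itself, and the DP is
verified against full 5^w word enumeration at small widths. Letters with
zero emission score −∞; windows containing them are reported with p = 1 and
can never be hits. q-values are BH over all windows tested in a scan. The
default reporting threshold is p ≤ 10⁻⁴ (the conventional scanning
default). A 4-column (A C G T) input motif is extended by splitting the C
mass equally between C and M in both emissions and background, which leaves
the C log-odds untouched and makes the motif methylation-indifferent.

## Enrichment

Overrepresentation uses one-sided Fisher's exact tests (via `scipy`) on the
2×2 study/set table over a user-supplied universe, BH-adjusted, significant
at adjusted p ≤ 0.05. GSEA is the weighted Kolmogorov–Smirnov running sum:
members increment by |score|^weight (normalised over members), non-members
decrement by 1/(N−N_h); ES is the extremum. The null permutes **gene
labels** (equivalently, random same-size member subsets) rather than
phenotype labels: phenotype permutation needs the per-sample matrix and many
samples to be exchangeable, while gene-label permutation is deterministic at
any size for a fixed seed — a documented divergence from the original
phenotype-permuting formulation. NES divides ES by the mean |null ES| of
the same sign; p uses the +1 correction (p ≥ 1/(n_perm+1)); q is the
standard NES-based FDR within the positive/negative pools. Significance
follows NES > 1, p ≤ 0.05, q ≤ 0.25.

## Validation assays

* **Bisulfite clones**: per-CpG percent = mean call over clones × 100;
  overall percent = mean over all calls. Conversion rate = converted /
  total non-CpG cytosines per clone; the pass threshold defaults to 95%
  with exclusion off (no published cutoff exists; the gate is explicit
  configuration).
* **ΔΔCt**: replicate Cts are combined by arithmetic mean (median available
  by config); ΔCt = Ct_target − Ct_housekeeping per condition; fold =
  2^(−ΔΔCt) against the reference condition. Invariant to a global Ct shift
  and to a housekeeping shift applied in both conditions.
* **ChIP percent input**: the input Ct is first adjusted for the dilution,
  adjusted = ct_input − log2(1/input_fraction), then percent =
  100 · 2^(adjusted − ct_ip), averaged over replicate rows. With
  input_fraction = 1 this reduces to 100 · 2^(ct_input − ct_ip).
* **Luciferase**: per-well activity = firefly/renilla; per condition, fold
  = mean promoter activity / mean empty-vector activity.

## Synthetic data: what it emulates and what it does not

The generator plants truth at the structure of the study data. Defaults are
the benchmark conditions used throughout: 200 genes, 8 CpGs per promoter,
20 samples per group, promoter Δβ effect 0.3, expression log2FC effect 1.5,
logit-scale beta noise SD 0.5, log2 expression noise SD 0.5, 10% of genes
planted hyper_up and 5% in each remaining quadrant. Betas are generated as
logistic(logit(group promoter mean) + per-probe offset + noise), clamped to
[10⁻⁴, 1−10⁻⁴]: noise on the logit scale keeps values in the open interval
with the mean-dependent variance real arrays show. Each gene has one TSS
(alternating strands) and all its probes inside the promoter window —
multi-TSS genes and inter-window probes add nothing testable here. The TF
array plants binders at 8× methylated/unmethylated preference over a
background of non-binders with 10% multiplicative spot noise; knockdown
panels (3 lines, 5 replicates/arm, noise SD 0.3) shift a consistent set and
disjoint per-line extras down by the effect size. Validation tables encode
user-specified true fractions/folds/activities with optional technical
noise.

Not emulated: Illumina probe chemistry and normalisation artefacts, batch
effects, copy-number confounding, correlated probes beyond a shared
promoter mean, cell-type mixture, or scanner-level image features. Passing
tests therefore demonstrate that the statistics recover planted effects
under idealised noise — they say nothing about preprocessing real arrays,
which is explicitly upstream of this package.

Problem sizes in the test suite and acceptance script (20 seeds × 200
genes for quadrant recovery, 20 TF-array seeds, 500 null features for
calibration, 1000 GSEA permutations) were chosen so that the whole suite
runs in seconds on one CPU while binomial sampling error stays well inside
the asserted bounds.

## Degenerate inputs and tie-breaks

Constant features get t = 0, p = 1 when the effect is also zero; an
all-zero-variance matrix falls back to the ordinary t with a warning.
Fewer than two samples per group, fewer than two negative-control spots
(SD undefined), out-of-range p-values, betas outside [0,1], non-CpG mask
positions, empty clone matrices and non-positive Renilla readings raise
errors. Screen ranking ties break deterministically (ratio, then MFI, then
id); GSEA sets with no member in the ranking are skipped with a warning;
motifs wider than the sequence return an empty result with a warning.

## Known limitations

The moderated-t prior fit assumes a common residual df across features
(complete matrices, no missingness). GSEA's gene-label permutation ignores
inter-gene correlation, so its p-values are anti-conservative on strongly
correlated real expression panels. The motif scanner's p-values condition
on the background model, not on the observed sequence composition. The
quadrant counts of the original tissue analysis are not reproducible
without the patient data; the package reproduces the procedure and its
desk-scale derivable numbers only.
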