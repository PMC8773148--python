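# Methods

## The quantity being estimated

Per-gene adaptation is the mean, along all branches of the gene's tree, of
the proportion of codons assigned to positively selected rate classes: for
each branch, aBSREL's maximum-likelihood rate distribution is a set of
(ω, weight) pairs, and the branch's proportion is the summed weight of
classes with ω > 1. Group adaptation is the unweighted mean over genes.
Genes enter the quantification when their gene-wide BUSTED p-value is at or
below a threshold 10⁻ˣ; sweeping x from weak (0.9) to strict (10⁻⁵) evidence
produces the excess curve over the default grid
{0.9, 0.5, 0.1, 0.05, 0.01, 1e-3, 1e-4, 1e-5}.

By default every branch contributes its ω>1 weight regardless of that
branch's own test significance, because the group statistic averages along
all branches; `parse_absrel_json(..., only_significant=True)` instead zeroes
branches whose corrected p exceeds a cutoff, for users who prefer the
conservative reading.

## The dN-matched permutation null

Raw substitution rate confounds the NEM/non-NEM contrast, so the reference
distribution is built from non-NEM sets whose mean dN is constrained to a
band around the NEM target. With dN_t the mean dN of included NEM genes and
a scheme (α, X, band 0.95–1.05, 5 free draws), a reference set of the NEM
sample size is drawn without replacement in stages:

1. five initial members are drawn unconditionally;
2. thereafter every X-th accepted member is drawn unconditionally (these
   draws keep the reference sets' variance from collapsing);
3. all other slots repeatedly draw candidates, accepting one only if the
   running mean dN lands inside [0.95·α·dN_t, 1.05·α·dN_t] or moves strictly
   closer to it;
4. if the final mean ends outside the band, the most-deviant unconditionally
   drawn member (then, if those are exhausted, any member) is swapped for
   fresh candidates until the mean re-enters. Each swap considers a small
   candidate batch and prefers the landing closest to the declared level
   α·dN_t — the band is a tolerance, not a destination, and re-entering at
   the approach-side edge would bias the reference's mean dN.

Every returned sample satisfies the band contract; infeasible pools (the
achievable sample-mean range misses the band) and exhausted try budgets
raise immediately rather than returning silently out-of-band samples.
Permutations use independent counter-derived substreams of one master seed,
and the pool is put in canonical gene-id order, so results depend on neither
evaluation order nor row order.

The estimate is `excess % = 100·(A_NEM − mean(A_ref))/mean(A_ref)`; the CI
is the 2.5th/97.5th percentile interval of the per-permutation excess; the
p-value is the add-one one-sided estimator (1 + #{A_ref ≥ A_NEM})/(n_perm+1),
whose floor 1/(n_perm+1) is the strongest claim a permutation test of that
size can make — smaller printed p-values require a different summary and are
not produced here.

## Scheme parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.95 | rescales the matching level to α·dN_NEM; < 1 keeps matching feasible when non-NEMs have systematically lower dN, at the cost of a small deliberate upward offset in the excess (adaptation scales with dN) |
| X | 3 | one fully random draw per X accepted members; controls reference-set variance |
| band | 0.95–1.05 | ±5% tolerance around α·dN_NEM |
| free draws | 5 | unconditional warm-up draws |
| max tries/slot | 10,000 | hard guard; exceeded ⇒ error |
| n_perm | 1,000 | permutations per estimate (100 is the enforced floor for CIs) |

`calibrate_matching` grids (α, X), runs n_cal matched samplings per
candidate (the study-scale choice is 10⁴; the default here is 10³), pools
the sampled non-NEM dN/dS values, and compares variance (two-sided
variance-ratio F test from summary moments) and mean (Welch's test) against
the NEM dN/dS values. The chosen candidate minimises |Δvariance| among those
with variance p > 0.05, falling back (flagged) to the global minimiser.
Genes with dS = 0 keep their place in the quantification (matching needs
only dN) but are excluded from these ω diagnostics. Pooled samplings
overlap, so the pooled degrees of freedom overstate independent information;
the diagnostics are treated as qualitative guidance, which is how they are
used.

## GO stratification, enrichment, set arithmetic, lag

GO-stratified excess restricts the NEM side to one category's genes
(recomputing the dN target and sample size from the restricted set — the
matched size always equals the NEM count being contrasted) while the
reference pool stays the full thresholded non-NEM set; the top-k categories
by NEM gene count (k = 10, minimum 20 NEM genes) are reported with raw
permutation p-values and Benjamini–Hochberg q-values.

Enrichment builds, at each significance level ℓ ∈ {0.05, 0.01, 0.001}, the
2×2 table of NEM status against BUSTED p ≤ ℓ over all records and applies
the two-sided Fisher's exact test (hypergeometric summation convention); the
reported odds ratio is the sample cross-product ratio with explicit ∞/NaN
handling for empty cells.

Ortholog families (per-species sets of ortholog-group ids) yield the core
set (intersection over all species) and an UpSet-style exclusive
intersection profile whose counts sum to the union size; pairwise
(Venn-style) overlaps are also emitted because prose "shared between A and
B" counts are ambiguous between the two conventions.

Chronogram lag consumes two dated Newick trees (branch lengths in My; leaf
ages 0 within a relative tolerance of 1e-6, checked with the worst offender
named). Clades are matched by shared leaf set by default (robust to label
drift between gene and species trees) or by internal-node label; a leaf set
that is not monophyletic is computed on its MRCA and flagged rather than
rejected, since gene trees are routinely incongruent with the species tree.
Lag > 0 means the first (nematocyst) tree's node is older.

## The synthetic generator

The generator emulates an eight-taxon ortholog selection scan (13 branches
per gene). Each gene gets: a label (counts realized exactly, order
shuffled); dN ~ Gamma(2, scale) with per-label scales (equal by default;
the `confounded_null` preset gives non-NEMs a 1.5× larger scale); dS ~
Gamma(8, 0.25), chosen so dN/dS has mean ≈ 0.05 and variance ≈ 1e-3, the
regime of codon-model fits on conserved orthologs; an evidence class (null
0.65 / moderate 0.30 / strong 0.05) with BUSTED p uniform on (0,1),
(0, 0.05) or (0, 1e-6) respectively; and mean adaptation
μ = κ·dN·effect·LogNormal(0, σ) for non-null classes (κ = 0.10, σ = 0.5),
zero for null genes. μ is spread over 1 + Poisson(1) branches (capped), so
the per-gene branch mean equals μ unless a branch saturates at 1 (logged as
a warning past 1% of genes). GO terms are drawn per gene (2 of 15
categories, popularity ∝ 1/(rank+1)).

Adaptation is *linear in dN by design*: this is precisely the confounding
structure that matching the sample's mean dN removes, mirroring the fact
that the matching procedure constrains only the mean. The class shares make
the included-gene effect mixture at p ≤ 0.5 equal
(0.30·1.5 + 0.05·1.6)/0.35 ≈ 1.51 under the `headline` preset (planted
ratios 1.5/1.6), and 1.6 at p ≤ 1e-5 where only strong-evidence genes
survive — hence the ~50%/~60% recovered excesses.

What the generator does **not** emulate: real BUSTED p-value distributions
(only threshold behaviour matters downstream), correlated selection across
genes, branch-specific rate structure (the downstream statistic uses only
the per-gene branch mean), GO-term correlation with function, or any
coupling between selection evidence and NEM status (an optional
`class_probs_nem` tilt exists for studying enrichment power, but no preset
uses it). Passing tests therefore validate the estimator's statistical
machinery, not the biology of any particular dataset.

Paired chronograms are built by random sequential coalescence (organismal
root age = root_age − lag), with every internal node of the nematocyst copy
aged +lag, optionally jittered (clamped to keep parents at least as old as
children) with the realized offsets recorded for verification.

## Statistical properties and limitations

* With α < 1 the reference is deliberately matched *below* the NEM dN level,
  which inflates the excess by roughly (1/α − 1) under dN-linear adaptation;
  this offset is part of the published scheme and is therefore retained in
  the headline estimates. Statistical-calibration studies (null rejection
  rate, confound removal) use the exact-match scheme α = 1, the only member
  of the family for which an unbiased matched excess is attainable by
  construction.
* The matched permutation test is mildly anticonservative: conditioning the
  reference sets on the dN band removes variance that the NEM group mean
  retains. In the package's null study (200 replicate datasets, 120/1,200
  genes, p ≤ 0.5, α = 1, X = 3, 499 permutations) the measured rejection
  rate at nominal 0.05 is 0.09 and the mean excess is +1.6% ± 1.2 (SE) —
  within three standard errors of nominal, but users should expect the test
  to run slightly hot at these sample sizes.
* Under the confounded null (no effect, 1.5× dN scale gap) the matched
  excess CI covers 0 in ~90% of replicates while the naive unmatched
  contrast covers 0 in ~43% — the matching does its job, imperfectly but
  decisively.
* Replicate-study problem sizes (200 replicates of 120/1,200 genes with 499
  permutations; 1,500/15,000 genes for the headline scenario) are the
  package's desk-scale study conditions; all are parameters, not constants.
* Ties in calibration are broken by grid order; thresholds must be listed
  descending; curve points that cannot be computed are emitted flagged (NaN
  values) rather than dropped, as are points with fewer than 10 NEM genes.
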