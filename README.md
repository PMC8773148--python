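# nemquant

Quantifying how much more adaptive evolution nematocyst proteins (NEMs)
experience than the rest of the proteome, across cnidarians.

Nematocysts — the stinging organelles of corals, jellyfish, *Hydra* and the
parasitic myxozoans — are a candidate driver of cnidarian adaptive success.
Testing that idea quantitatively requires comparing the amount of positive
selection carried by the proteins building the organelle against a fair
background, and "fair" is the hard part: NEMs and non-NEMs differ in raw
substitution rate, so any naive contrast confounds adaptation with dN.
`nemquant` implements the full quantification used for this question, for
people working with ortholog-level selection scans (HyPhy BUSTED/aBSREL
summaries plus PAML dN/dS):

* **Excess of adaptation.** Per gene, adaptation A is the mean over branches
  of the proportion of codons in positively selected (ω > 1) aBSREL rate
  classes. Genes enter at a BUSTED gene-wide threshold *p* ≤ 10⁻ˣ. The
  statistic is

  `excess % = 100 · (A_NEM − A_ref) / A_ref`

  where `A_ref` is the mean group adaptation of repeatedly sampled non-NEM
  reference sets of the same size whose **mean dN is constrained to
  [0.95·α·dN_NEM, 1.05·α·dN_NEM]** (defaults α = 0.95, with one fully random
  draw per X = 3 accepted members, five initial free draws). The permutation
  distribution gives a percentile 95% CI and a one-sided add-one p-value.
* **(α, X) calibration** by repeated samplings, comparing NEM vs pooled
  reference dN/dS variance (F test) and mean (Welch test).
* **GO-stratified excess** for the categories with the most NEM genes, with
  Benjamini–Hochberg q-values.
* **Fisher's exact enrichment** of positively selected genes among NEMs at
  significance levels 0.05 / 0.01 / 0.001.
* **Proteome set arithmetic**: core set (ortholog groups shared by all
  species) and UpSet-style exclusive intersection profiles.
* **Macroevolutionary lag**: per-clade age offsets between a dated
  nematocyst-protein tree and a dated organismal tree (My).
* **Synthetic data** with known ground truth (planted effect ratios, a
  dN–label confound, paired chronograms with a known lag) so the whole
  pipeline is testable without the multi-genome inputs.

## Worked example

Fit the excess-of-adaptation model on a synthetic dataset in the study's
regime (1,500 NEM / 15,000 non-NEM genes; planted NEM effect ratios 1.5 for
moderate-evidence and 1.6 for strong-evidence genes):

```python
from nemquant import ExcessOfAdaptation, generate_gene_stats, preset_config

records = generate_gene_stats(
    preset_config("headline", n_nem=1500, n_nonnem=15000, seed=42)
)
result = ExcessOfAdaptation(records).fit(threshold=0.5, n_perm=1000, seed=1)
print(result.summary())
```

```
Excess of adaptation (permutation contrast, dN-matched non-NEM reference)
--------------------------------------------------------------------
BUSTED inclusion threshold      p <= 0.5
NEM genes / reference pool      1006 / 10076
NEM group adaptation            0.008645
reference mean (sd)             0.005656 (0.000266)
excess of adaptation            +52.84%
95% CI                          [+40.09%, +69.05%]
one-sided permutation p         0.000999  (n_perm = 1000)
```

1,006 NEM genes survive the weak-evidence threshold; their mean
selected-codon proportion (0.0086) is about 53% above the mean of 1,000
dN-matched non-NEM reference sets (0.0057), recovering the planted ~50%
effect; the p-value sits at the permutation floor 1/1001. Tightening the
threshold to 1e-5 keeps only the 74 strong-evidence genes and raises the
excess to +57.7% (CI [+37.8%, +83.1%]), recovering the planted ~60% effect.

The same pipeline runs from the shell:

```bash
nemquant demo --out-dir demo_run --seed 5        # end-to-end on synthetic data
nemquant simulate --preset headline --out stats.tsv --seed 42
nemquant quantify --gene-stats stats.tsv --threshold 0.5 --out est.json
nemquant curve --gene-stats stats.tsv --out curve.tsv --plot curve.png
nemquant lag --tree-a nematocyst.nwk --tree-b organismal.nwk --out lag.tsv
```

Real HyPhy results are adapted with `parse_busted_json` / `parse_absrel_json`,
and r8s-style dated Newick trees with `read_dated_newick`.

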