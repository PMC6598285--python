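# plexquant

Spectrum-to-protein quantitation and differential expression for iTRAQ 4-plex
proteomics, with downstream expression-profile clustering, hypergeometric
pathway enrichment, and fermentation end-product stoichiometry. The package
re-implements, as a tested and reusable pipeline, the quantitation workflow
used to study how exogenous ethanol (0/50/100/200 mM) reshapes the proteome
and the end products of the H₂–ethanol-coproducing anaerobe *Ethanoligenens
harbinense* YUAN-3. Because raw spectra for such studies are rarely deposited,
the package ships a synthetic 4-plex data generator with known ground truth,
so every stage is testable end to end.

It is aimed at proteomics practitioners and method developers who need a
transparent, scriptable implementation of the classic reporter-ion
quantitation recipe — and a benchmark harness to measure how reliably that
recipe recovers planted fold changes under noise.

## The method

Each MS/MS spectrum (one peptide–spectrum match, PSM) carries four reporter-ion
intensities $I_{114},\dots,I_{117}$; channel 114 is the control condition.
The pipeline applies, in order:

1. **Isotope cross-over correction.** Observed intensities mix the true ones
   through the reagent purity matrix $P$ ($P_{rc}$ = fraction of channel $c$'s
   signal seen in channel $r$). True intensities are recovered by non-negative
   least squares, $\hat T = \arg\min_{T \ge 0}\lVert PT - I\rVert_2$, which
   equals $P^{-1}I$ on consistent data but never goes negative on noisy
   spectra.
2. **Qualification.** A spectrum contributes only if the peptide carries the
   4-plex label, maps to the target proteome, and has $\log_{10}(e) \le -2.0$.
3. **Normalization.** For each comparison $c/114$ the factor
   $\nu_c = \sum I_c / \sum I_{114}$ over all qualifying spectra rescales every
   ratio, enforcing the equal-loading assumption.
4. **Spectrum ratios with the "Divide 0" sentinel.** $r = (I_c/I_{114})/\nu_c$;
   a zero denominator with positive numerator is recorded as the fixed
   placeholder 10.
5. **Protein medians.** Per protein and comparison, the median ratio over
   spectra whose two-channel intensity sum exceeds 20,000.
6. **Significance gate.** A one-sample Wilcoxon signed-rank test of the log₂
   ratios against 0 (exact null for small n); a protein is accurately
   quantified when it has ≥ 3 contributing spectra and $p \le 0.01$.
7. **Fold-change calls.** Up-regulated at median ratio ≥ 1.2, down-regulated
   at ≤ 0.83.

Downstream, DE proteins are summarized as Venn regions and COG tallies,
assembled into a protein × condition log₂-ratio matrix, row-z-scored and
clustered hierarchically (Euclidean, average linkage, k = 6 by default), and
tested for pathway over-representation with the hypergeometric upper tail
$p = \sum_{i\ge k} \binom{K}{i}\binom{N-K}{n-i}/\binom{N}{n}$ (raw
$p \le 0.05$ = significant, BH-adjusted values reported alongside). The
fermentation module converts measured yields into endogenous ethanol
(deducting exogenous additions at 46.07 mg L⁻¹ per mM), ethanol:acetate molar
ratios, and the ethanol weight fraction of the liquid end-products.

## Worked example

Simulate a 100-protein 4-plex experiment (20 spectra per protein, 0.25
log₂-unit spectrum noise, 20% of proteins planted at |fold change| 1.6) and
run the full pipeline:

```bash
plexquant run --set synthetic.n_proteins=100 --set synthetic.seed=1 --outdir demo
```

```
run: 115/114 -> 20 DE proteins
run: 116/114 -> 20 DE proteins
run: 117/114 -> 20 DE proteins
run: artifacts written to demo
```

All 20 planted proteins are recovered in every stress condition
(`demo/truth.tsv` holds the ground truth for comparison). `demo/proteins.tsv`
lists one row per protein and comparison, e.g.

```
protein_acc  comparison  median_ratio        n_psm  p_value             status
P0001        115/114     1.0027070982562174  17     0.644134521484375   not_significant
```

— an unchanged protein: median ratio ≈ 1, an insignificant Wilcoxon p, so it
is never called. `demo/clusters.tsv` assigns each DE protein to one of six
profile clusters, and `demo/enrichment.tsv` reports per-pathway
hypergeometric p-values (with the default random annotation no pathway is
enriched; plant one with `plexquant.simulate.PlantedPathway` to see a hit).
`demo/run_report.json` records the counts at every filter stage — 2000
spectra in, 1752 qualifying, 28 proteins accurately quantified, 20 DE.

The stoichiometry stage works from a plain yield table:

```python
from plexquant.fermentation import reference_yield_table, summarize
for s in summarize(reference_yield_table()):
    print(s.condition_mM, s.molar_ratio, s.ethanol_weight_pct, s.fold_vs_control)
```

```
0.0   2.2843207836259087  63.66961862697788  1.0
50.0  None                None               None
100.0 None                None               None
200.0 32.03240450747554   96.08994207763794  14.022726027397262
```

At 200 mM exogenous ethanol the ethanol:acetate molar ratio rises from 2.28
to 32.0 — a 14-fold shift toward ethanol-type fermentation — and ethanol
reaches 96.1% (w/w) of the liquid end-products. (The 50/100 mM acetate yields
were reported graphically only, so no ratio is derived there.)

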