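# lipidflex

Quantitative analysis of factorial mouse-lipidome designs: QC filtering,
per-class feature condensation, lipid-class **plasticity**, organ
**flexibility**, and organ–blood partial-correlation clustering — with a
synthetic factorial generator so every stage is testable end to end.

## What it does and for whom

Shotgun lipidomics quantifies hundreds of lipid species (in pmol) across
organs, tissues and bodily fluids. In a factorial study design — e.g. 10
sample types × 2 diets × 2 sexes × 2 genotypes × 3 biological replicates —
two questions dominate: *how much latitude does each lipid class have in its
fatty-acid composition within an organ* (plasticity), and *how strongly do
the experimental conditions reshape each organ's lipidome* (flexibility)?
`lipidflex` is aimed at lipidomics analysts and methods developers who need
a reproducible implementation of that analysis chain:

1. **Nomenclature** — parse annotations of the form
   `class C:DB;OH` (species level, e.g. `PI 34:1;0`) and chain-resolved
   subspecies (`PI 18:1;0_16:0;0`, sn-resolved `PC O- 18:1;0/16:0;0`)
   against a closed 24-class vocabulary.
2. **QC** — blank/signal filtering per analytical batch (strict 5× over
   blank, S/N > 5 where supplied), occupancy filtering (> 1 pmol in ≥ 2 of
   3 replicates in at least one condition), reference-based batch
   correction, and RSD reproducibility summaries.
3. **Features** — normalise to mol% and condense each lipid class to three
   features per sample: abundance (mol%), amount-weighted mean double
   bonds, and amount-weighted mean carbons,

       q̄ = (1/n_c) · Σ_j  j · Σ_i n_ji

   where `n_c` is the class's total molar amount and `n_ji` the amount of
   species *i* with feature value *j* (total double bonds or carbons).
   24 detected classes ⇒ exactly 72 features. Fatty-acid profiles and
   centered/scaled PCA (with a storage-lipid-free variant) are included.
4. **Plasticity** — per (class, organ), the min–max ranges of the two chain
   indices are mapped affinely onto [1, 10] (widest range in the pool → 10,
   narrowest → 1) and multiplied: a score in [1, 100].
5. **Flexibility** — per organ, features are z-scored and fit by OLS,
   `z(feature) ~ sex + diet + genotype` (treatment coding; reference levels
   female / low-protein / inbred), optionally with `diet×genotype` or
   `diet×sex` interactions; flexibility per factor is `Σ|β|` over features
   with p < 0.01. A variance decomposition over all organs quantifies how
   much of the per-species variance each covariate explains.
6. **Blood correlation** — partial Spearman correlation (ranks
   residualised on sex and genotype) of each organ lipid with its blood
   counterpart across the paired animals; significant positive correlations
   feed complete-linkage Euclidean clustering of organs with plasma as the
   self-correlation reference.
7. **Synthetic data** — a deterministic generator emulating the full study
   design (240 study samples, blanks and references per batch, realistic
   RSD bands, organ-specific class profiles) with known injected effects,
   chain-index spreads and organ–blood coupling for recovery testing.

## Worked example

```python
import lipidflex as lf

sp = lf.parse_species("PC O- 18:1;0/16:0;0")
sp.total_carbons, sp.sn_resolved        # -> (34, True)

matrix, truth = lf.generate(lf.default_config(seed=1))
molpct   = lf.normalize_mol_percent(matrix.subset(roles=("study",)))
features = lf.condense(molpct)          # 72 features for 24 classes

flex = lf.flexibility_score(lf.fit_factor_model(features), alpha=0.01)
print(flex.sort_values("flexibility", ascending=False).head(5))
```

```
sample_type     term  flexibility  n_significant
      brain genotype    13.713081             10
 full_blood      sex     9.460497              7
      liver     diet     7.005378              5
     kidney      sex     6.447641              5
      liver      sex     5.951513              4
```

The flexibility table reads: in this simulated dataset the brain lipidome
responds to genotype (10 features significantly shifted, summed effect
size ≈ 13.7 within-organ standard deviations), full blood responds most to
sex, and the liver to diet — each score aggregating how far the condition
moves that organ's condensed features. Plasticity scores likewise pick out
the loosely controlled classes of the most variable organ (here e.g.
cardiolipin in spleen scores 91 of a possible 100, while the tightly
controlled brain and lung classes sit near the floor).

The same pipeline runs from the shell:

```bash
lipidflex simulate --seed 1 --out sim
lipidflex run-all --table sim_lipidome.tsv --metadata sim_metadata.tsv --out results
```

writing `features.tsv`, `plasticity.tsv`, `flexibility.tsv`,
`interactions.tsv`, `blood_correlations.tsv`, `cluster_order.txt` and a
reproducibility `manifest.json`.

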