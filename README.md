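# benthosom

Classification of benthic macroinvertebrate communities with a
self-organizing map (SOM), and the statistical battery that ecologists run
around such a classification: indicator-species analysis, diversity
indices, and environmental-association tests.  The package implements the
workflow used in lake biomonitoring surveys such as the Lianhuan Lake
(northern China) study system — 13 interconnected lakes sampled in three
seasons, yielding ~74 site visits, 44 macroinvertebrate taxa and 13 water
chemistry variables — and ships a synthetic-community generator that
reproduces that statistical structure with known ground truth.

## The method

Given a site × taxon density matrix **Y** (individuals/m²) and a site ×
variable environment matrix **X**:

1. **SOM classification.** A batch Kohonen map is trained on ln(Y+1).
   The output layer holds about 5·√n neurons (43 for n = 74), with the
   final near-square grid chosen by the smallest combined rank of
   quantization error (mean site→BMU distance) and topographic error
   (fraction of sites whose two best neurons are not lattice-adjacent).
2. **Group number.** K-means clusters the occupied codebook neurons for
   k = 2…10; the Simple Structure Index (SSI) — a feature-wise contrast ×
   cluster-size × center-deviation score — picks k; sites inherit their
   BMU neuron's cluster.
3. **Indicator species.** For species *i* and group *j*,
   A<sub>ij</sub> = μ<sub>ij</sub>/Σ<sub>g</sub>μ<sub>ig</sub> (specificity),
   B<sub>ij</sub> = occupancy of *i* in *j* (fidelity), and
   IndVal<sub>ij</sub> = A·B·100.  Significance by permuting whole-site
   group labels (add-one estimator, 999–1000 permutations); IndVal ≥ 50 %
   with p < .05 marks an indicator.
4. **Diversity.** Richness S, abundance N, biomass, Shannon
   H′ = −Σ p ln p, Pielou J = H′/ln S, summarised as mean ± SD by lake,
   season or group.
5. **Environment.** Correlation-matrix PCA of the log-transformed
   variables (pH exempt); a DCA gradient-length check (< 4 SD → linear
   methods); then RDA of the Hellinger-transformed community on
   VIF-screened, permutation-forward-selected predictors with per-axis
   permutation tests; Kruskal–Wallis (with Dunn/BH compact letters) of
   each variable across groups; and a BH-adjusted Spearman grid of the
   five indices against the 13 variables.

## Worked example

```sh
python examples/01_simulate_and_classify.py
```

```
SOM 7x7: quantization error 10.91, topographic error 0.014
SSI by k: {2: 0.38, 3: 0.73, 4: 1.09, 5: 2.03, 6: 1.73, 7: 1.17, 8: 0.88, 9: 0.9, 10: 0.95}
selected k = 5 (true number of planted groups: 5)
adjusted Rand index against the planted groups: 1.000
```

The SSI curve peaks at k = 5, matching the five planted community groups,
and the site partition agrees with the ground truth (ARI = 1.0).  The
other examples cover indicator species (`02`), diversity indices and the
Spearman screen (`03`), and the one-call pipeline (`04`), which writes
every report table (site groups, SSI curve, indicator table, diversity
summaries, PCA/RDA summaries, Kruskal–Wallis table, Spearman grid) as TSV
plus a JSON summary.

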