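# coexscreen

Discover a trait-associated gene co-expression module from bulk
transcriptomes, score its activity in bulk and single-cell data, and screen
approved drugs against the module by protein–protein interaction (PPI)
network proximity with a permutation-derived Gaussian null.

The package targets the common systems-biology workflow used in disease
transcriptomics (for example, identifying a neuroinflammation module in
case/control brain expression and repurposing drugs against it): WGCNA-style
module detection, single-sample module scoring, hub-gene classification, and
a network-proximity drug screen, all reimplemented as a tested, reusable
Python library with a synthetic-data module that plants known structure so
every stage can be validated against ground truth.

## Methods at a glance

**Module discovery.** Genes are filtered by standard deviation, outlier
samples removed by a static cut of the sample dendrogram, and a soft power
β chosen by the scale-free topology fit R² ≥ 0.9. The adjacency is
a_ij = |bicor(x_i, x_j)|^β (biweight midcorrelation; signed variant
available), converted to the topological overlap matrix

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

and modules come from average-linkage clustering of 1 − TOM with a static
height cut, followed by merging modules whose eigengenes correlate above
1 − mergeCutHeight (default merge height 0.1). Modules are characterized by
their eigengene (first principal component of the standardized module
submatrix), the eigengene–trait point-biserial correlation, kME
(gene–eigengene correlation) and top-kME hub genes.

**Module scoring.** `ssgsea_score` is the rank-weighted running-sum
single-sample enrichment score (exponent α = 0.25) for bulk or pseudo-bulk
matrices; `additive_module_score` is the expression-bin-controlled additive
score for single cells on library-size log-normalized counts.

**Discrimination.** Hub-gene expression feeds a standardized logistic
regression; modules are ranked by the median area under the
precision–recall curve (step-wise average-precision rule) over 3 replicates
of stratified 5-fold cross-validation.

**Drug screening.** On a score-thresholded STRING-dialect PPI graph
(combined score ≥ 600, largest connected component), a drug with effective
targets X (pChEMBL > 6) is scored against module hubs Y by

    D(X, Y) = Σ_{x∈X} Σ_{y∈Y} d(x, y) / (|X|·|Y|),
    Z = (D − μ) / σ,

where μ, σ come from 1,000 same-size uniform pseudo-target draws, and the
one-sided lower-tail p (small D = closer than chance) is BH-adjusted across
drugs.

## Worked example

```python
from coexscreen import synthetic, CoexpressionModules, ProximityScreen
from coexscreen.discrimination import repeated_cv_auprc

bulk = synthetic.generate_bulk_expression(
    synthetic.ModulePlantSpec(seed=1, loading_spread=0.15))
est = CoexpressionModules(power="auto", min_module_size=20)
est.fit(bulk.expression.T, bulk.trait)
print(est.trait_correlation_.round(4))
```

prints the per-module eigengene–trait correlations; the planted
trait-associated module stands out:

```
               r       p
module
module_1 -0.0394  0.5796
module_2  0.3889  0.0000
module_3  0.0107  0.8807
module_4 -0.0392  0.5820
```

`module_2` is the planted disease module (r = 0.39 at n = 200; the other
modules are null). Its hub genes discriminate cases from controls with a
median cross-validated AUPRC of 0.73 against a 0.5 prevalence baseline:

```python
target = est.trait_correlation_["r"].abs().idxmax()
cv = repeated_cv_auprc(bulk.expression.loc[est.hubs_[target]].T.to_numpy(),
                       bulk.trait.to_numpy(), seed=1)
print(round(cv.median_auprc, 3))   # 0.731
```

Screening 200 synthetic drugs (20 planted within one hop of a designated
hub cluster, 180 null) against those hubs ranks the planted drugs on top:

```
 rank drug_id       drug_name  n_targets  proximity         Z        p_adj
    1 DRUG195 planted_drug195          9   2.277778 -7.602553 2.903444e-12
    2 DRUG193 planted_drug193         10   2.400000 -7.138089 4.731865e-11
    3 DRUG199 planted_drug199          7   2.228571 -6.811642 2.794857e-10
```

with all 20 planted drugs inside the top-20 BH ranks on this seed.

The same workflow is available from the shell:

```
coexscreen run --seed 1 --out-dir run1
coexscreen proximity --edges edges.tsv --drugs drugs.tsv --hubs hubs.txt \
    --score-threshold 600 --pchembl-min 6 --n-background 1000 --seed 1 \
    --out ranked.tsv
```

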