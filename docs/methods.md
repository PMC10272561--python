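# Methods

This note documents the models, the synthetic-data conditions, the
numerical choices, and the known limits of `coexscreen`.

## Synthetic data model

**Bulk expression.** Genes of module *m* follow a single-factor Gaussian
model, x_g = λ_g f_m + σ ε_g, with f_m standard normal per sample,
independent across modules, and ε white noise. For the one designated
trait module, f is shifted by the trait effect (in SD units of the factor)
in case samples. Background genes are pure noise with the same σ. Defaults:
4 modules × 50 genes, 200 background genes, 100 cases / 100 controls,
loading 0.8, noise SD 0.6, trait effect 0.8 — chosen to mirror a
case/control brain microarray design (≈230 samples) at desk scale. Under
this model the within-module correlation is λ²/(λ² + σ²) = 0.64 at the
defaults, the module eigengene estimates f, and kME ≈ λ/√(λ² + σ²), so hub
recovery is analytically predictable. `loading_spread` draws per-gene
loadings uniformly around λ, giving modules an internal hub hierarchy;
the default chain tests use spread 0.15.

A consequence worth stating explicitly: all trait information in module
genes flows through the shared factor, whose case/control separation is
0.8 SD. The Bayes-optimal classifier on any set of module genes therefore
has AUROC ≤ Φ(0.8/√2) ≈ 0.71, i.e. AUPRC ≈ 0.70 at prevalence 0.5. The
measured hub-gene median CV AUPRC (≈ 0.63–0.73 across seeds) sits at this
information-theoretic ceiling; higher values would require a larger planted
effect, not a better classifier. Real case/control cohorts, where
discrimination can be much higher, carry trait signal through many partially
independent channels that the single-factor generator deliberately omits.

**PPI network.** Barabási–Albert preferential attachment (default 500
nodes, 3 edges per new node) with uniform synthetic combined scores in
[600, 999], sharing gene symbols with the expression universe. The degree
distribution is heavy-tailed like a real interactome; it has no edge-weight
structure or community structure beyond that.

**Module hub placement.** `choose_module_hubs` grows a connected cluster by
breadth-first search from a random node, visiting neighbors in ascending
degree order and skipping nodes above the 0.9 degree quantile unless growth
stalls. Rationale: genes of one functional module cluster together in real
interactomes and are usually not the global high-degree core; a cluster
grown through the core would have a 1-hop neighborhood covering half of a
scale-free graph, which makes "near the module" meaningless.

**Drugs.** Null drugs draw 3–10 distinct targets uniformly from all nodes;
planted drugs draw only from nodes within the planting radius (default 1
hop) of the hub cluster. Potencies are N(7, 1) on the pChEMBL scale, so the
strict > 6 filter keeps ≈ Φ(1) ≈ 84% of targets — planted drugs can lose
targets to the filter, as real ones would.

**Single-cell counts.** Negative-binomial counts (variance μ + αμ², single
global dispersion α = 0.5) with log-normal per-cell library-size factors,
4 subtypes × 50 cells per sample × 8 samples (first half "case"). Module
genes' means are multiplied by the module shift (default 4) in the one
designated active subtype and again in case-sample cells. The generator has
no dropout model beyond NB sampling, no batch effects, and no cell-cycle or
ambient-RNA structure; passing tests show the scoring and marker logic
recover a strong planted signal, not robustness to those artifacts.

## Module discovery

Biweight midcorrelation uses the canonical constant 9 in
u = (x − median)/(9·MAD) with weights (1 − u²)² 1[|u| < 1]; vectors with
MAD = 0, or whose weighted vector is numerically zero (all weight mass at
the median), fall back to Pearson centering. The scale-free fit uses 10
equal-width connectivity bins, log–log regression of frequency on mean
connectivity, and a signed R² (negated when the slope is positive); the
chosen power is the smallest with fit ≥ 0.9, else the argmax (flagged).
On planted-module data the scale-free target is typically not reached —
four equal-size modules are not scale-free — and the argmax fallback picks
a high power; module recovery is insensitive to this (exact recovery at
powers 6–20 in the chain tests).

The dendrogram is cut statically. When no explicit height is given, the cut
is placed at the midpoint of the largest gap among the upper half of the
merge heights: tight modules finish merging well below the plateau where
unrelated genes join (TOM dissimilarity saturates near 1), so the widest
high gap separates module structure from that plateau. A fixed quantile of
merge heights does not work here — almost all merge heights sit on the
plateau, so any quantile cut lands on it and collapses the partition.
Clusters below the minimum size (default 30) are labelled grey. Eigengenes
are the first right-singular vector of the gene-standardized submatrix,
unit variance, sign-aligned to the module mean; merging iterates over the
closest eigengene pair until no dissimilarity is below the merge height
(default 0.1). Modules larger than 1,000 genes and the grey bin are
excluded from downstream characterization. Ties anywhere (hub ordering,
module labels) break lexicographically by gene id for reproducibility.

## Scoring

ssGSEA walks genes in descending expression (ties broken by gene position
for determinism; tied ranks averaged in the weights), accumulating
P_in(i) = Σ_{g∈S, pos≤i} r_g^α / Σ_{g∈S} r_g^α against the non-set ECDF
P_out, and sums P_in − P_out; α = 0.25. Min–max normalization across
samples is on by default and exposed, since both conventions are in use.
Bulk matrices are scored as given; counts are log-normalized
(ln(1 + 10⁴·count/libsize)) first. The additive per-cell score bins genes
into 24 equal-occupancy average-expression bins and, per set gene, samples
100 control genes from its bin (never set genes; with replacement only when
the bin is too small), reporting mean(set) − mean(controls) per cell.

## Discrimination

Features are standardized inside the CV pipeline (train-fold statistics
only) and fitted by logistic regression with a tiny ridge (1e−6) so
separable data stay defined. AUPRC uses the step-wise average-precision
rule with tied scores grouped at one threshold — stated explicitly because
interpolation conventions change the number. Folds are stratified (both
classes in every fold); out-of-fold probabilities are pooled into one curve
per replicate and the median over 3 replicates is reported. Pooling was
chosen over per-fold averaging for stability at n of a few hundred; the
per-fold table is returned for inspection.

## Network proximity

Edges with combined score ≥ 600 are kept (the strict ">" is exposed), the
graph is simplified and by default restricted to its largest connected
component so every distance is finite. D(X, Y) is the mean BFS hop distance
over all mapped (target, hub) pairs. The null draws size-matched
pseudo-target sets uniformly from all nodes — not degree-matched; the
uniform null matches the pseudo-target permutation being emulated, and a
degree-binned matched sampler would be the natural extension if degree
confounding is a concern. Backgrounds are cached per target-set size and
seeded as (master seed, size), so results are independent of drug order and
identical between cached and per-drug sampling. μ and the unbiased σ are
fitted to 1,000 draws; a KS/QQ normality report is advisory and never
blocks. p is the one-sided lower tail of Z = (D − μ)/σ (small D
significant), BH-adjusted across all drugs with ≥ 1 mapped target; drugs
that fail mapping are excluded from the correction and listed with reason
codes.

## Pipeline

One master seed fans out to stage sub-seeds through stable stage labels,
so each stage is reproducible in isolation. Every output table is a TSV;
the manifest records parameters, sub-seeds and SHA-256 hashes of outputs,
and reruns with the same config are byte-identical. The default synthetic
run (400 genes × 200 samples, 500-node network, 200 drugs, 1,000
backgrounds) completes in a few seconds on one CPU; the problem sizes were
chosen so the full validation suite exercises every stage at desk scale.

## Limitations

- The generator's single-factor modules cannot emulate overlapping modules,
  module–module correlation, or microarray probe artifacts.
- The static cut replaces the dynamic hybrid tree cut; on real data with
  nested module structure the dynamic cut can split clusters the static cut
  keeps together. The cut height is exposed for that case.
- Pseudo-targets are degree-uniform; for drugs whose targets are
  systematically high-degree this null is liberal.
- Published absolute results from cohort accessions (module counts,
  module sizes, specific AUPRC values, drug rankings) depend on those
  cohorts and database snapshots and are out of scope; the validation here
  is property-based on planted ground truth.
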