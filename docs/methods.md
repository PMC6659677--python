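# Methods

This note documents the statistical models, the synthetic study the
package validates itself on, and the numerical and design choices that
were genuinely open.

## Gene-based association test

For a gene with SNP p-values p₁…p_k the observed statistic is
T = Σᵢ Q₁(1 − pᵢ), where Q₁ is the quantile function of the chi-square
distribution with one degree of freedom. Under the null the SNP z-scores
are correlated through LD, so T is distributed as Σ zᵢ² with
z ~ MVN(0, Σ), Σ the SNP correlation (LD) matrix. The null is simulated
(eigen-factorisation of Σ, which unlike Cholesky also handles the singular
perfect-LD case) and the empirical p-value is computed with the
permutation-test +1 correction, p = (1 + #{T* ≥ T})/(1 + n), so no gene
ever reports p = 0 and downstream −log p stays finite.

Simulation staging: 10³ draws for every gene, escalating to 10⁴ when
p ≤ 0.1 and to 10⁶ when p ≤ 0.001. These constants are config-exposed
(`sim_stages`): the staging idea is standard for this family of tests but
the exact constants are not asserted to match any external tool. The
pipeline default caps the last stage at 10⁵, which resolves p-values down
to ~10⁻⁵ — sufficient at the packaged problem size.

LD matrices estimated from small reference panels are routinely
indefinite; before factorisation negative eigenvalues are floored at zero
and the diagonal renormalised to 1 (`repair_psd`). Coordinates are 0-based
half-open (BED native); a SNP belongs to a gene iff
start − flank ≤ pos < end + flank, flank default 50,000 bp (regulatory
regions and LD spillover). SNP input p-values of exactly 0 are clamped to
the smallest positive float at read time with a warning.

Per-gene child seeds are spawned from one root `SeedSequence`, so results
are independent of gene iteration order and bit-reproducible.

## Background network and permutation null

Background edges need ≥ 2 independent publications (config `min_pubs`);
(A,B)/(B,A) duplicates collapse keeping the maximum publication count, and
self-loops are dropped. The significant subnetwork is the induced subgraph
on genes with p strictly < alpha (0.05). Only the largest component (by
nodes, then edges) seeds the next stage, to limit false-positive carry-over.

The permutation null shuffles the observed p-values across *all*
background nodes that have one (not only significant ones), re-induces the
subnetwork and records the largest component's node and edge counts. The
observed percentile is 100 × #{null strictly below observed}/n_perm: ties
count against significance. Note this estimator applied to a heavily
discrete statistic (e.g. at alpha = 0.05, where the induced subgraph is
nearly empty and component sizes concentrate on {0, 1, 2}) is *not*
uniformly distributed under the null — its calibration test is therefore
run at alpha = 0.3 on a 300-node preferential-attachment background, the
percolation regime in which the largest-component size takes many values
and the percentile is approximately continuous. At analysis settings the
percentile remains a valid, conservative tail measure.

## Evidence scoring and core extraction

QC keeps records with both taxids 9606, exactly one PubMed id and a
non-empty detection method. Pairs are scored additively,
score = #distinct publications + #distinct methods, and score ≤ 2 —
i.e. exactly one publication with one method — is discarded. The additive
form is the simplest combiner under which that cutoff does precisely what
it is meant to (remove single-evidence pairs); it is config-exposed
(`min_score`).

A seed's interactome is the seed plus its surviving first-layer
interactors. A node's connection degree is the fraction of seeds whose
interactome contains it; nodes strictly above 15% are inter-interactome
hubs. Exclusion-listed promiscuous binders (ubiquitin-C-like proteins)
stay in the graph but can never be hubs and are dropped from the adjusted
average-neighbor statistic; both the raw 2E/V and the exclusion-adjusted
value are reported, since the two definitions differ in published uses.
The core is the IIHs plus their direct interactors with *induced* edges
(including interactor–interactor edges); its density 2E/(V(V−1)) is ranked
against uniformly sampled same-size node subsets.

## Over-representation and block retention

Fold enrichment (k/n)/(K/N) is computed in exact rational arithmetic and
rounded only for display. The enrichment p is the hypergeometric upper
tail P(X ≥ k), identical to the one-tailed Fisher test; Bonferroni is the
default adjustment for pathway analysis, BH for expression. Candidate
genes outside an explicit annotation universe are dropped from n (logged),
mirroring annotation-coverage behaviour of public enrichment services.
The default universe size 20,650 is the annotated-gene domain under which
the package's reference fold-enrichment values are exactly recomputable.
The set-counts-and-sizes correction used by some web services is not
implemented.

Block retention first removes terms in negligible semantic classes
(default drop list: general, metabolism, enzymes, protein modification,
physiology), then reports per functional block the percentage of
full-network enriched terms that recur in the core enrichment, flagging
blocks strictly above 12%. Terms (not semantic classes) are counted;
blocks with no full-network terms are reported undefined rather than 0.

## Differential expression

Per probe, ordinary least squares of expression on status + sex + age +
post-mortem interval; two-sided t-test on the status coefficient with
residual degrees of freedom. The fit is a vectorised shared-design OLS
(one matrix factorisation for all genes); tests cross-check it against
statsmodels on single genes. Probes collapse to genes by minimum raw p
(ties: smaller SE, then probe id), and BH-FDR is applied across collapsed
genes only — the network gene set, not the whole array. Expression values
are taken as provided (assumed already log-scale); no normalisation is
performed.

## The synthetic study

The generators emulate the structure, not the content, of the restricted
inputs a real analysis of this kind uses.

* **GWAS**: genes laid out on 22 chromosomes with spacing large enough
  that flanked windows never overlap; 1–10 SNPs per gene; z-scores
  MVN(0, Σ) with AR(1) LD Σᵢⱼ = ρ^|i−j| (default ρ = 0.5) — chosen as the
  minimal one-parameter, closed-form-PSD stand-in for panel-estimated LD.
  Risk genes receive a per-SNP mean shift (non-centrality), default 4.0:
  at the 0.05 gene-level threshold this gives per-SNP two-sided power
  ≈ 0.98, the weakest regime in which a 24-gene planted module is reliably
  (≥ 80% of members) recovered inside the largest significant component —
  i.e. the defaults encode a study of robustly associated risk genes.
  With shift 2.5, for comparison, a single-SNP risk gene clears the
  threshold only ~71% of the time and module recovery fails by design.
* **Background network**: preferential attachment (m = 2) over 500
  proteins for realistic degree heterogeneity without fitting; the
  24-gene module is wired connected via a random spanning tree, and
  module edges always carry ≥ 2 publications; 70% of other edges do.
* **Evidence**: per pair, 1 + Poisson extra publications/methods; records
  cycle through the distinct ids so aggregated counts are exact.
  Contamination (non-human taxid, zero/two PubMed ids, missing method) is
  injected per record — never per pair — at 5% each, and contaminated
  record indices are emitted so QC recovery is exactly testable.
* **Pathways**: universe 20,650 containing the gene ids plus fillers;
  one planted 23-gene pathway overlapping 8 planted-module genes (module
  genes preferred so the pathway overlaps the *recoverable* subnetwork);
  199 uniform random pathways of 10–200 genes.
* **Expression**: 10 cases / 11 controls; per-gene baseline N(8, 2),
  planted status effect −1.5 on 15 risk genes, covariate effects
  (sex 0.3, age 0.02/yr, PMI 0.05/hr) and N(0, 0.5) noise; ~5% of genes
  get a second probe to exercise collapsing.

All generators are pure functions of the scenario; independent RNG streams
per stage mean adding one generator never perturbs another's output.
Planted truths are written to a JSON manifest so recovery tests never
re-derive them.

What passing tests do **not** show about real data: the generators have no
allele-frequency structure, no gene-density or window-overlap complexity,
Poisson rather than empirical evidence multiplicity, uniform rather than
ontology-structured pathways, and Gaussian homoscedastic expression noise.
Results on real inputs depend on properties (LD panel quality, database
redundancy, batch effects) the synthetic study deliberately omits.

## Statistical conventions in the tests

Monte-Carlo agreement checks that span many genes ("within 3 binomial
standard errors") are applied jointly: with m ≈ 600 simultaneous 3-SE
(0.27%) bands, ~2 boundary crossings are expected for a *correct*
implementation, so up to max(1, 1% of m) crossings are tolerated and every
deviation must stay below 6 SE. KS calibration tests use α = 0.01 with
fixed seeds. Problem sizes in the suite (600-gene calibration runs, 10³
simulations per gene, 100-seed recovery loops, 999-permutation planted
test) were chosen so the whole analysis remains a desk-scale computation.

## Known limitations

* Association blocks (aggregation of adjacent significant genes) are not
  implemented; filtering is gene-level only.
* LD is an input (or synthetic); estimation from genotype panels is out
  of scope.
* The permutation null shuffles node labels only; degree-preserving
  network rewiring is not offered.
* The score combiner and the staging constants of the gene test are
  reasonable defaults, config-exposed, not claims about external tools'
  internals.
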