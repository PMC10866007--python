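# Methods notes

This note records the models, conventions, numerical choices and known
limitations behind `crustpipe`, in the order the pipeline runs.

## Fluorometric enzyme activities

The activity chain is the standard quench-corrected microplate scheme:
q = (f_q − f_b)/f_r, e = f_r/(c·V2), F = (f − f_b)/q − f_s and
Ab = F·V/(e·V1·t·m). Conventions worth stating:

* **Parenthesization of F.** The correction is implemented as
  (f − f_b)/q − f_s. The alternative grouping (f − f_b)/(q − f_s) is
  dimensionally incoherent — f_s is a fluorescence, q a dimensionless
  coefficient — and does not correspond to any published correction
  scheme, so it is not offered.
* **Units.** c (μM) × V2 (μL) is converted to nmol inside the emission
  coefficient (10 μM × 50 μL = 0.5 nmol), so e is fluorescence per nmol
  and Ab comes out in nmol g⁻¹ dry soil h⁻¹ without further conversion.
* **Dry mass.** m is the dry weight of the 2 g wet aliquot,
  m = 2 g × (1 − gravimetric moisture). Moisture is supplied per sample;
  the synthetic default is 0.10, giving m = 1.8 g.
* **Replicate aggregation** is the arithmetic mean over the eight wells
  per role (median available for plates with suspected outlier wells);
  no automatic outlier rejection.
* **Negative corrected fluorescence** is reported as-is with a
  `negative_F` QC flag rather than clipped: clipping would silently bias
  low activities toward zero. Flagged samples are excluded from
  stoichiometry, which needs strictly positive activities. Replicate CV
  above 15 % in any formula-relevant role is also flagged. The quench
  coefficient is validated to (0, 1.5]: q ≤ 0 means a fully quenched
  plate (error), q slightly above 1 can occur by noise, and values far
  above 1 indicate a pipetting problem (flag).

## Stoichiometry and the limitation vector

* Stoichiometric ratios are quotients of natural logarithms
  (ln BG / ln(LAP+NAG) etc.), not logs of quotients. A denominator
  activity of exactly 1 makes the quotient undefined; such samples are
  flagged and the ratio omitted. Unlike the vector angle these ratios
  are not invariant to rescaling the activity units; activities enter on
  the raw nmol g⁻¹ h⁻¹ scale.
* The angle is degrees(arctan(y/x)) with x = BG/(BG+AP),
  y = BG/(BG+LAP+NAG), so that high P-enzyme investment (large AP,
  small x) yields large angles and a P-limitation call. Both coordinates
  are positive, so the angle always lies in (0°, 90°); it is invariant
  under uniform rescaling of all four activities and strictly monotone:
  increasing AP raises it, increasing LAP+NAG lowers it.
* The 45° boundary is called `balanced` within an absolute tolerance of
  1e−9 degrees; below is `N-limited`, above `P-limited`.
* Vectors are computed per sample and then summarized per group
  (mean ± sd), not computed from group-mean activities — the group sd is
  a genuine between-replicate spread, and the group summary is ordered
  by mean length so the most C-limited fraction is first.

## Synthetic data

The generator emulates a six-fraction, five-replicate biocrust design
and always emits ground truth beside the data; every generator is a pure
function of its seed.

* **Plates** are produced by inverting the activity chain from a chosen
  true activity with nominal controls (f_r = 1000, q* = 0.8, f_b = 100,
  f_s = 50), then adding independent multiplicative Gaussian noise
  (CV 5 % by default) per well. At CV 0 the processing module recovers
  the true activity to machine precision — an exact round-trip identity
  used heavily in the tests. Default true activities give rhizoid soil
  the highest BG and lowest AP, so its limitation vector is the longest
  and all six fractions are N-limited, matching the qualitative field
  pattern the package targets.
* **ASV tables** use a lognormal–multinomial compositional model:
  per-feature baseline log means ~ N(0, 1.5); 30 % of features receive
  group-specific log-mean shifts ~ N(0, 0.5); planted correlation blocks
  share a per-sample latent factor with loadings ±0.9 (two default
  blocks of six features, one all-positive and one mixed-sign), a
  construction that guarantees a positive-semidefinite dependence
  structure; residual log noise sd 0.3; per-sample relative abundances
  are the softmax of the log means and counts are one multinomial draw
  at a uniform random depth in [10 000, 60 000]. Block members get a
  fixed log mean of 2.0 so they stay above the 0.1 % rare-feature filter,
  and group shifts never land on block members — the blocks are the
  controlled correlation ground truth, and mixing group-level mean
  shifts into them would confound the planted pairwise signal. Depths
  and sparsity are chosen to look like a rarefaction-scale amplicon
  dataset; the model does not emulate sequencing error, chimeras or
  taxonomy.
* **Chemistry** (TOC, TN, TP, NH4, NO3) is lognormal around per-variable
  baselines with multiplicative group shifts; defaults enrich rhizoid
  soil 2×, sifted layer soils 1.4–1.5× over sublayer soils, mirroring
  the field ordering BRS > BSS > BS.

What passing tests on this generator does **not** show: robustness to
real-data features it omits — uneven library preparation, taxon-specific
amplification bias, true zero-inflation beyond multinomial sampling, or
compositional effects stronger than the planted blocks induce.

## Diversity

* Rarefaction is a single multivariate-hypergeometric draw per sample
  (subsampling without replacement) to the minimum sample depth by
  default; it is not averaged over repeated draws, matching the
  standardize-to-minimum convention of amplicon workflows.
* Chao1 uses the bias-corrected form S_obs + F1(F1−1)/(2(F2+1))
  (the common mothur/QIIME default); the classic form is a flag away.
  Shannon uses natural log by default with a base switch.
* PCoA is classical scaling: Gower double-centering of −d²/2 followed by
  a symmetric eigendecomposition. Negative eigenvalues (expected for
  Bray–Curtis) are reported unchanged and excluded from the
  proportion-explained denominator; no Cailliez or Lingoes correction is
  applied by default. On Euclidean input the coordinates reproduce the
  input distances to 1e−8 (verified against scikit-bio's implementation
  in the tests).
* The group-separation permutation test is one-way PERMANOVA with
  unrestricted label permutations, pseudo-F from among/within sums of
  squared distances, and p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm);
  default n_perm = 999 with an explicit seed. Fewer than 99 permutations
  triggers a warning.

## Group statistics

* Chemistry, EEAs and alpha diversity use classical one-way ANOVA +
  Tukey HSD (Welch correction off by default, available by flag). A
  degenerate complete separation (zero within-group variance, differing
  means) is reported as F = ∞, p = 0 rather than an error.
* Taxon-abundance comparisons default to Kruskal–Wallis with pairwise
  two-sided rank-sum tests and BH-FDR over the pairs — a nonparametric
  default chosen because relative abundances are bounded, skewed and
  tie-heavy; a parametric route is available through the ANOVA surface.
* Compact letter displays use the insert-and-absorb algorithm; letters
  are assigned in order of descending group mean, so 'a' always marks
  the highest group. Significant pairs never share a letter and
  non-significant pairs always share at least one (property-tested).
* BH-FDR is the step-up procedure (via statsmodels), monotone and capped
  at 1.

## Co-occurrence networks

* Features below 0.1 % overall mean relative abundance are **combined**
  into an OTHER bin (not discarded — column sums are preserved); the bin
  is excluded from node candidacy.
* Correlations are tie-corrected Spearman on **relative abundances**:
  raw counts track sequencing depth, which varies several-fold between
  samples and would correlate every feature with every other. Two-sided
  p values use the t approximation with n − 2 degrees of freedom.
* BH-FDR runs over all candidate pairs before any rho thresholding;
  edges then require |ρ| ≥ 0.6 and adjusted p < 0.05. The numeric
  cutoffs are a common co-occurrence convention and fully configurable.
  The "Jaccard" criterion seen in some workflows is implemented as an
  optional presence/absence filter (minimum co-presence count and/or
  maximum Jaccard distance), off by default.
* Isolated features are not nodes: node counts reflect the connected
  part of the graph, which is how network tables in this literature
  count "nodes" (far fewer than candidate features).
* The clustering coefficient is the unweighted local clustering averaged
  over nodes, degree-1 nodes contributing 0 (the Gephi convention).
  Edge sets are monotone in the thresholds: raising the rho cutoff or
  lowering the FDR level never adds an edge.
* Calibration caveat: with ~2×10⁴ candidate pairs and n = 30 samples the
  t-approximate Spearman p values are slightly anti-conservative in the
  far tail, and compositional coupling adds weak dependence between
  pairs, so the realized false-discovery proportion among discovered
  edges can run somewhat above the nominal FDR level even though the
  per-null-pair false-edge rate stays orders of magnitude below it.
  Exact permutation p values would remove the approximation at
  considerable cost; they are not implemented.

## Problem sizes and determinism

Default simulated studies are 6 groups × 5 replicates, 500 ASVs, depths
10–60 k. The statistical-calibration checks in the test suite use 1 000
null replicates for ANOVA, PERMANOVA (199 permutations each, 15 samples)
and BH-FDR (100 p values), and 100 simulation seeds for planted-edge
recovery; these sizes give Monte-Carlo standard errors well under the
tolerances asserted. The end-to-end pipeline test runs a reduced study
(120 ASVs, depths 2–4 k) — large enough to exercise every stage,
including per-group networks. All randomness flows through explicit
`numpy.random.Generator` seeds; the pipeline writes its seeds and
thresholds to `run_log.txt`, and identical seeds reproduce every output
byte for byte.

## Known limitations

* No compositionality-aware network inference (SparCC/SPIEC-EASI); the
  Spearman-on-proportions route inherits compositional artifacts.
* No UniFrac or other phylogeny-aware diversity (no tree input), no
  rarefaction curves, no mixed models or repeated-measures structure.
* The fluorometry module is endpoint-only: no kinetic (multi-timepoint)
  assays or substrate-saturation modeling.
* The plate file layout (tidy CSV with explicit roles) is this package's
  own convention; plate readers exporting 8×12 grids need a one-off
  conversion because grid layouts do not carry role annotations.
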