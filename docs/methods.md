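# Methods

This note records the models implemented in `gwescan`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not demonstrate.

## Ordination

**RDA.** The response is the accession × SNP dosage matrix, centered but
not standardized (dosage columns share units; a `scale` flag exposes the
correlation-scale variant). Predictors are centered; with a `condition`
block both response and predictors are first residualized on it (partial
RDA). Fitted values come from projection onto an orthonormal basis of the
predictor span; their SVD gives constrained axes. Inertia is reported as
raw sums of squares — the constrained/total ratio (R²) is identical to the
variance convention. SNP loadings are the unit-norm right singular
vectors; biplot scores are predictor–site-score correlations. Predictor
collinearity is an error, with the offending columns named via
rank-revealing QR.

**Adjusted R².** Ezekiel's correction, `1 − (1 − R²)(n − 1)/(n − p − 1)`,
used everywhere a model's explained fraction is compared across different
predictor counts.

**Permutation tests.** Rows of the (residualized) response are permuted;
`p = (1 + #{F* ≥ F}) / (1 + n_perm)`, so p can never be 0. The default
`n_perm = 999` trades runtime against resolution; the stepwise routine is
commonly run at 10 000 in published analyses and the knob goes that high.
A wide response (p ≫ n) is first collapsed to `U·S` from its thin SVD —
row permutations interact with the response only through Frobenius norms
of projections, which the right-orthogonal factor cannot change, so all
R², pseudo-F and p-values are exactly preserved at ~n/p the cost.

**Forward selection.** At each step the candidate with the largest
adjusted-R² gain is tested by a permutation test conditioned on the
already-selected variables, and enters only if p ≤ α **and** the new
cumulative adjusted R² stays at or below the full-model adjusted R² (the
double stopping rule that controls stepwise type-1 error). The adjusted
R² uses the nominal count of selected variables; conditioning degrees of
freedom are not charged to the candidate set (documented simplification —
it only matters for reporting, not for ordering or stopping).

**Variance partitioning.** Two-block inclusion–exclusion on the adjusted-
R² scale: `a = adjR²(full) − adjR²(block2)`, etc., so `a+b+c+d = 1` by
construction. The geography block is, by default, the principal
coordinates of the pairwise Vincenty (WGS-84) distance matrix, keeping
positive-eigenvalue axes covering ≥ 95 % of the positive inertia; raw
lon/lat can be used instead. Vincenty's inverse iteration is implemented
directly with a spherical fallback for the (never encountered in tests)
non-convergent near-antipodal case.

## CAA detection

**Loading outliers.** Per constrained axis, loadings are standardized
across SNPs and any SNP with |z| > 3 on any of the first three axes is
flagged (the union is invariant to axis sign flips); a zero-variance axis
is skipped with a warning. A pooled-z variant of the same idea reads the
maximum |z| per SNP, available via the returned z map.

**Scan model.** The pipeline scans the common-variant universe
(MAF ≥ 0.1 by default): rare, near-fixed variants carry almost no usable
climate signal at n = 150 and their leptokurtic dosages produce unstable
loadings. The scan RDA constrains on climate variables chosen by forward
selection *conditioned on lineage structure* (PCA + k-means labels as
indicator covariates — a deliberately light-weight substitute for spatial
ancestry estimation), topped up by conditional-R² ranking if fewer than
three variables survive. Conditioning on discrete lineage indicators
removes between-lineage allele-frequency differences exactly, which is
what lets a 3-SD rule operate at a usable false-discovery rate.

**Variable assignment.** Each flagged SNP is assigned to the single
variable maximizing |Pearson r| with its dosages (pairwise-complete);
ties break to the earlier column; constant variables are excluded and a
monomorphic SNP is an error.

**Mixed-model GEA.** EMMAX/P3D: variance components are REML-estimated
once under the null through the spectral decomposition of the VanRaden
kinship, then every SNP is tested by generalized least squares with
genotype PCs (default 3) as fixed covariates, Wald t-tests, and per-
phenotype Benjamini–Hochberg adjustment (q ≤ 0.05). Kinship-group
"compression" is deliberately not reproduced — it is a speed heuristic,
not part of the test's definition. The multi-locus variant (MLMM-style)
repeatedly adds the most significant SNP as a fixed cofactor until no SNP
passes the q threshold or a step cap is hit.

## Introgression evaluation

**Tail selection.** Per trait column, lines in the lower/upper
`percentile` (default 5) tails; a line qualifies if it falls in the same
tail for at least `min_traits` (default 2) columns, with boundary ties
broken by stable line-id order. A line qualifying for both tails is
dropped from both.

**Spectra and KS.** Frequency spectra use 9 equal right-closed bins on
(0, 1]; a SNP with zero frequency in a group contributes no allele there
and is excluded from that group's spectrum. The KS statistic D is the
classical two-sample statistic on the frequency vectors restricted to
SNPs segregating in both groups. Its *significance*, however, is
calibrated by permutation: a 17-line tail's frequency vector is a noisier
reading of the same loci, so the classical two-sample p-value rejects
even for random subsets; `tail_spectrum_test` compares the observed D to
D from random equal-sized line subsets, which is exact under
exchangeability. The spectra count donor **alleles** (donor-origin
segment × the allele the line's donor parent actually transmitted, one
donor gamete per line), giving the wide per-SNP frequency spread real
populations show.

**Fold change.** `FC = (f_tail + ε)/(f_WP + ε)` with ε = 1/(2N) by
default (N = tail size); FC ≥ 2 is "strongly differentiated", a two-sided
option takes max(FC, 1/FC), and when no SNP reaches the threshold it
falls back to the 95th FC percentile.

**Arm bins.** Each arm is split into three equal-length bins measured
from the centromere (boundary SNPs go to the nearer-centromere bin; the
chromosome end is distal). The input set is LD-deduplicated first
(`prune_ld`, r² < 0.5 in 50-kb windows) — against the *panel* genotypes
when historical-recombination redundancy is the target.

**CT–yield.** Ordinary least squares of yield on canopy temperature; r is
signed and R² = r².

## Phenotype tools

NDVI uses the band-calibrated form `(1.236·NIR − 0.188·R)/(NIR +
0.044·R)` on plot-mean pixel values (scale-invariant; a zero denominator
is an error). DDTH is control-mean DTH minus the line value (positive =
earlier than checks). BLUPs come from `y = Xb + Zu + e` with one random
line effect: fixed trial dummies, a check indicator and degree-2 row/range
polynomials (a deliberately simple stand-in for spline-based spatial
correction); REML is a bounded one-dimensional profile of
λ = σg²/σe² through the spectral decomposition of ZZ′ (tolerance 1e-8),
robust at the σg² → 0 boundary, cross-checked against statsmodels
MixedLM. `h² = varG/(varG + varE)` on a per-plot basis; a helper drops
trials whose within-trial h² is below 0.2 before across-environment fits.

## Synthetic landscape generator

Defaults define the study conditions used throughout the tests: 150
accessions in 4 lineages, 5000 SNPs, 50 adaptive loci with logistic slope
3, lineage Fst 0.15, inbreeding F = 0.98.

* **Geography.** Lineage centers drawn in a 60° × 15° extent; accessions
  scatter around their center. Lineages are therefore spatially clustered
  but the climate fields are not lineage-locked.
* **Environment.** Four latent Gaussian-process fields with exponential
  covariance (`spatial_range` 1.5°, i.e. fine-grained, mountain-terrain
  variation) combine into 58 named variables — lon/lat/alt, 19 bioclim
  summaries, 36 monthly tmin/tmax/prec sharing seasonal latents — plus
  i.i.d. site noise (0.6 monthly, 0.8 bioclim in latent units), so the
  table is as collinear as real extractions and varies within lineages.
* **Neutral SNPs.** Ancestral frequencies from a U-shaped Beta(0.5, 0.5)
  spectrum (a drifted panel), Balding–Nichols per-lineage drift, dosages
  near-homozygous (F = 0.98), concentrating mass on 0/2 as in a selfer.
* **Adaptive loci.** Frequency at a site is `logistic(slope · z)` of the
  standardized driving variable — a cline centered at 0.5, the maximally
  informative adaptive polymorphism. Drivers are 3 mutually weakly
  correlated climate variables (greedy decorrelation), mirroring the
  observation that detected climate signals concentrate on a few
  gradients.
* **Linked mode.** For LD-dependent experiments, haplotypes are mosaics
  of founder haplotypes related by a random genealogy (each derived
  allele arises once, on one branch), with founder switching per
  adjacent-SNP interval `1 − exp(−d_cM/ld_decay_cm)` on a pericentromeric
  map `cM(u) ∝ 1 + sign(2u−1)|2u−1|^γ`. Panel LD then mirrors historical
  recombination: long-range in the pericentromere, decaying distally.
* **Introgression lines.** donor × recurrent F1 → one backcross →
  `selfing_generations` (default 3) selfings; gametes carry Poisson
  crossovers on the cM map without interference. Expected donor genome
  fraction 0.25; residual heterozygosity halves per selfing. Donor-allele
  dosages are origin × the single donor gamete drawn per line.
* **Phenotypes.** trait = Σ effect·donor-allele dosage + polygenic line
  effect (CT and yield drawn with genetic correlation −0.5 by default) +
  trial effect + quadratic row/range trend + residual scaled so the
  per-plot h² equals `h2_target` (1.0 ⇒ no residual).

## What the experiments show — and what they do not

* The outlier-scan operating point (recall 1.0, empirical FDR ≈ 0.05–0.15
  at seed-to-seed variation) holds under the generator's conditions:
  discrete, cleanly separable lineages, climate-independent lineage
  geography, three concentrated drivers, and no linkage between scan
  SNPs. Real panels have admixture, isolation-by-distance continua and
  LD, all of which blur the scan; the numbers above are a verification of
  the machinery, not a field-performance claim.
* The chromosome-arm gradient experiment demonstrates the *mechanism* —
  historical-recombination LD redundancy plus gene-dense distal QTL
  placement plus truncation selection produce rising independent
  differentiated-CAA counts toward the telomeres — at a scaled-down
  genome (7 × 9 Mb, 6300 SNPs) where 50-kb windows are meaningful. It
  does not reproduce any field count.
* The tail-spectrum null uniformity holds for the permutation-calibrated
  p-value only; classical two-sample KS p-values on tail-vs-WP frequency
  vectors are degenerate under the null by construction and should not be
  interpreted as significance.
* Scaled problem sizes used by the checks (chosen once, as the package's
  study conditions): default panel 150 × 5000; null calibration panel
  2000 SNPs; spectrum population 351 lines × 800 CAAs with 100 null
  replicates; arm-bin genome as above over 10 seeds; BLUP design 300
  lines × 3 trials.

## Numerical conventions

Missing dosage is `NaN`, never 0; frequencies exclude missing calls from
the denominator. LD is pairwise-complete; PCA/kinship mean-impute per
SNP. Positions are 1-based (VCF); windows are half-open
`[start, start + window)` and pruning comparability is pairwise distance
< window within a chromosome, scanning left to right and removing the
later SNP of a violating pair. Kinship is VanRaden with denominator
2Σp(1−p) and an unforced diagonal. All randomness flows from
`numpy.random.default_rng` seeded per stage by a SHA-256 derivation from
the global seed, so every stage is independently re-runnable and full
reruns are byte-identical.

## Known limitations

No coalescent realism, no selection during line development, no genotype
imputation or phasing, no multi-allelic support. The augmented-design
BLUP uses polynomial spatial covariates rather than splines, and
generalized heritability definitions used with spline models will not
match the simple variance ratio reported here. GWAS "compression" and
Bayesian multi-locus models are out of scope.
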