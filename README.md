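# gwescan

Genome-wide environmental scans (GWES) for landscape genomics, and the
downstream evaluation of climate-associated alleles (CAAs) in a crop
introgression population — with a synthetic landscape-genomics generator so
that every stage of the pipeline can be verified against planted ground
truth.

## The problem

Wild crop relatives such as *Aegilops tauschii* (the diploid D-genome
ancestor of bread wheat) harbour alleles that track climatic gradients
across their native range. Identifying those climate-associated alleles,
and asking whether they improve the performance of introgression lines
(ILs) carrying wild chromosome segments in an adapted cultivar background,
requires a chain of methods:

1. **Genotype panel preparation** — VCF input, LD pruning (r² < 0.5 in
   50-kb windows, 5-kb step), allele frequencies, VanRaden kinship,
   genotype PCA, PCA + k-means lineage assignment.
2. **Variance partitioning** — how much SNP variation do climate and
   geography (Vincenty geodesic distances → principal coordinates)
   explain, uniquely and jointly? Partitions on the adjusted-R² scale:
   `a + b + c + d = 1` with `adjR² = 1 − (1 − R²)(n − 1)/(n − p − 1)`.
3. **Redundancy analysis (RDA)** — constrained ordination of the SNP
   matrix on ecogeographic predictors; forward selection with the double
   stopping rule (permutation α and the full-model adjusted-R² ceiling).
4. **CAA detection** — SNPs whose loadings on the first three constrained
   axes lie more than 3 SD from the mean (per axis, unioned), each
   assigned to its best-correlated variable; plus a kinship mixed-model
   scan (EMMAX/P3D) with ecogeographic variables as phenotypes and
   Benjamini–Hochberg FDR ≤ 0.05; the two sets are combined.
5. **Introgression evaluation** — lines in the lower/upper 5th percentile
   of trait distributions, 9-bin CAA allele-frequency spectra, tail-vs-
   whole-population contrasts, fold-change ≥ 2 differentiation,
   differentiated-CAA counts in three equal chromosome-arm bins from the
   centromere, multi-locus mixed-model trait GWAS, and the yield ~ canopy
   temperature (CT) regression.
6. **Phenotype tools** — the band-calibrated vegetation index
   `NDVI = (1.236·NIR − 0.188·R)/(NIR + 0.044·R)`, deviation in days to
   heading (control mean − line), one-random-effect REML BLUPs for
   augmented trial designs, and `h² = varG/(varG + varE)`.

The synthetic module generates geo-referenced panels with four spatially
clustered lineages, smooth climate surfaces, logistic allele-frequency
clines at planted adaptive loci, BC₁F₃-style introgression populations
(Poisson crossovers on a cM map, optional pericentromeric suppression),
and plot-level phenotypes with planted QTL — so recall, false-discovery
rate, calibration and trend claims are all testable.

## Worked example

Run the full environmental scan on a synthetic panel (150 accessions,
5000 SNPs, 50 planted clinal loci) and print the stage log:

```
$ gwescan -v gwes --seed 1 -o out/
INFO gwescan.pipeline: stage=simulate accessions=150 snps=5000 adaptive=50
INFO gwescan.pipeline: stage=prune before=5000 after=5000
INFO gwescan.pipeline: stage=varpart climate=0.0188 geo=0.01
INFO gwescan.pipeline: stage=forward_select selected=7 reason=adj_r2_ceiling
INFO gwescan.pipeline: stage=rda_scan scan_snps=2831 outliers=57
INFO gwescan.pipeline: stage=mlm_gea snps=57
INFO gwescan.pipeline: stage=combine n_rda=57 n_gwas=57 n_both=50 n_union=64
{
  "n_rda": 57,
  "n_gwas": 57,
  "n_both": 50,
  "n_union": 64
}
```

Reading the output: of 5000 SNPs, 2831 common variants enter the outlier
scan; the RDA loading scan flags 57 candidate CAAs and the mixed-model GEA
flags 57, with 50 SNPs found by **both** methods — exactly the 50 planted
adaptive loci (the union of 64 contains every planted locus plus a handful
of false positives). `out/varpart.json` holds the climate/geography
variance partition, `out/forward_selection.csv` the stepwise selection
table (variable, cumulative adjusted R², pseudo-F, permutation p), and
`out/caa.tsv` the combined CAA table (snp, chrom, pos, method, assigned
variable, correlation, |z|, q).

`gwescan introgression` continues into the IL evaluation (tail selection,
spectra, fold-change sets, arm-bin counts, trait GWAS, CT–yield
regression); `gwescan report` pretty-prints the JSON summaries. Every
output carries the config hash and seed, and a rerun with the same config
is byte-identical.

The same machinery is available as a library: `gwescan.ordination.RDA`,
`ForwardSelector`, `gwescan.gea.EmmaxGWAS` and `gwescan.pheno.BlupModel`
are scikit-learn-style estimators (`fit`, fitted `_` attributes,
`get_params`/`set_params`), and every pipeline operation is a plain
function over them.

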