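"""Synthetic landscape-genomics data with known ground truth.

The generator emulates a geo-referenced panel of a selfing wild grass:
spatially clustered lineages, smooth climate surfaces, neutral SNPs drifted
per lineage (Balding-Nichols), a configurable set of adaptive loci whose
allele frequency follows a logistic cline in one climate variable, and a
backcross-derived introgression population with planted trait QTL.  Every
downstream stage (ordination, outlier scan, mixed-model GWAS, tail-spectrum
analysis) can therefore be checked against the planted truth.

All randomness flows from a single ``numpy.random.Generator`` seeded from
the config, so identical configs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, Variant

__all__ = [
    "LandscapeConfig",
    "SimTruth",
    "IntrogressionPopulation",
    "simulate_panel",
    "uniform_genetic_map",
    "pericentromeric_genetic_map",
    "simulate_introgression_population",
    "simulate_phenotypes",
]

CLIMATE_PREFIXES = ("bio", "tmin_", "tmax_", "prec_")


def env_variable_names(n: int = 58) -> list[str]:
    names = (
        ["lon", "lat", "alt"]
        + [f"bio{k}" for k in range(1, 20)]
        + [f"tmin_{m}" for m in range(1, 13)]
        + [f"tmax_{m}" for m in range(1, 13)]
        + [f"prec_{m}" for m in range(1, 13)]
    )
    if not 3 < n <= len(names):
        raise ValueError(f"n_env_vars must be in (3, {len(names)}]")
    return names[:n]


def is_climate_variable(name: str) -> bool:
    return name.startswith(CLIMATE_PREFIXES)


@dataclass
class LandscapeConfig:
    """Knobs of the synthetic geo-referenced panel.

    Defaults emulate the study conditions used throughout the test suite:
    150 accessions in 4 spatial lineages, 5000 SNPs of which 50 are
    climate-adaptive with logistic slope 3 on the standardized driving
    variable, near-complete selfing (F = 0.98) and lineage Fst 0.15.
    """

    n_accessions: int = 150
    n_snps: int = 5000
    n_adaptive: int = 50
    adaptive_slope: float = 3.0
    n_driver_variables: int = 3
    lon_extent: tuple = (30.0, 90.0)
    lat_extent: tuple = (30.0, 45.0)
    n_env_vars: int = 58
    spatial_range: float = 1.5
    env_noise_monthly: float = 0.6
    env_noise_bio: float = 0.8
    sfs_beta: float = 0.5
    n_lineages: int = 4
    fst: float = 0.15
    inbreeding: float = 0.98
    missing_rate: float = 0.0
    n_chromosomes: int = 7
    chrom_length: int = 600_000_000
    ld_decay_cm: float | None = None
    n_founders: int = 3
    cm_per_chrom: float = 150.0
    map_suppression: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_accessions < 10:
            raise ValueError("n_accessions must be >= 10")
        if self.spatial_range <= 0:
            raise ValueError("spatial_range must be positive")
        if self.n_adaptive > self.n_snps:
            raise ValueError("more adaptive loci than SNPs")
        if self.n_lineages < 1:
            raise ValueError("n_lineages must be >= 1")
        if not 0 <= self.inbreeding <= 1:
            raise ValueError("inbreeding must be in [0, 1]")
        if self.n_driver_variables < 1:
            raise ValueError("need at least one driving variable")


@dataclass
class SimTruth:
    """Planted ground truth: adaptive loci, QTL and lineage labels."""

    adaptive_loci: list  # (snp_index, driving_variable, logistic_slope)
    lineage_labels: np.ndarray
    qtl: list = field(default_factory=list)  # (snp_index, trait, effect)

    @property
    def adaptive_indices(self) -> list[int]:
        return [i for i, _, _ in self.adaptive_loci]


def _spatial_fields(coords: np.ndarray, n_fields: int, spatial_range: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Gaussian-process draws with exponential covariance at the sites."""
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    C = np.exp(-d / spatial_range) + 1e-6 * np.eye(len(coords))
    L = np.linalg.cholesky(C)
    return L @ rng.standard_normal((len(coords), n_fields))


def _map_cm(pos: np.ndarray, length: float, cm_total: float, gamma: float) -> np.ndarray:
    """Cumulative cM position with pericentromeric suppression.

    cM(u) = C/2 * (1 + sign(2u-1)|2u-1|^gamma): flat at the (mid-chromosome)
    centromere, steep toward the telomeres; gamma = 1 gives a uniform map.
    """
    u = np.asarray(pos, dtype=float) / length
    t = 2.0 * u - 1.0
    return cm_total / 2.0 * (1.0 + np.sign(t) * np.abs(t) ** gamma)


def _genealogical_founders(n_founders: int, n_snps: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Founder haplotypes related by a random genealogy.

    A random binary tree joins the founders; each SNP's derived allele
    arises once, on a random branch, and is carried by the clade below it.
    Carrier sets of linked SNPs are therefore nested or disjoint (complete
    gametic association), as on a real non-recombining genealogy, and the
    clade-size distribution gives a drifted, low-frequency-heavy spectrum.
    """
    clades = [{i} for i in range(n_founders)]
    active = [{i} for i in range(n_founders)]
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        merged = active[i] | active[j]
        active = [c for k, c in enumerate(active) if k not in (i, j)]
        active.append(merged)
        if len(merged) < n_founders:
            clades.append(merged)
    member = np.zeros((len(clades), n_founders), dtype=np.int8)
    for ci, clade in enumerate(clades):
        member[ci, list(clade)] = 1
    return member[rng.integers(len(clades), size=n_snps)].T


def _linked_dosage(p0: np.ndarray, lineage: np.ndarray, variants,
                   config, rng: np.random.Generator) -> np.ndarray:
    """Haplotype-mosaic dosages with LD shaped by the recombination map.

    ``n_founders`` ancestral founder haplotypes are drawn from the
    ancestral frequencies; lineages drift by diverging in founder-usage
    weights (Dirichlet mixtures), and each accession haplotype copies a
    founder mosaic whose switch probability between adjacent SNPs is
    1 - exp(-d_cM / ld_decay_cm).  Local LD therefore mirrors historical
    recombination: near-complete through the pericentromere, decaying over
    ~ld_decay_cm distally, with consistent phase across lineages because
    the haplotype pool is shared.  Inbreeding duplicates the first
    haplotype.
    """
    n = len(lineage)
    n_snps = len(p0)
    chroms = np.array([v.chrom for v in variants])
    pos = np.array([v.pos for v in variants], dtype=float)
    founders = _genealogical_founders(config.n_founders, n_snps, rng)
    # founder-usage drift per lineage; smaller Fst -> flatter weights
    alpha = max((1.0 - config.fst) / max(config.fst, 1e-6), 1e-3) / config.n_founders
    weights = rng.dirichlet(np.full(config.n_founders, alpha), size=config.n_lineages)
    dosage = np.zeros((n, n_snps))
    chrom_blocks = []
    for c in dict.fromkeys(chroms.tolist()):
        idx = np.nonzero(chroms == c)[0]
        cm = _map_cm(pos[idx], config.chrom_length, config.cm_per_chrom,
                     config.map_suppression)
        switch_p = 1.0 - np.exp(-np.diff(cm) / config.ld_decay_cm)
        chrom_blocks.append((idx, switch_p))

    def mosaic_hap(lin: int) -> np.ndarray:
        hap = np.empty(n_snps, dtype=np.int8)
        for idx, switch_p in chrom_blocks:
            seg = np.zeros(len(idx), dtype=np.int64)
            seg[1:] = np.cumsum(rng.random(len(idx) - 1) < switch_p)
            founder_ids = rng.choice(
                config.n_founders, size=seg[-1] + 1, p=weights[lin]
            )
            hap[idx] = founders[founder_ids[seg], idx]
        return hap

    for i in range(n):
        h1 = mosaic_hap(lineage[i])
        h2 = h1 if rng.random() < config.inbreeding else mosaic_hap(lineage[i])
        dosage[i] = h1 + h2
    return dosage


def _pick_driver_variables(env: pd.DataFrame, candidates: list[str], k: int,
                           rng: np.random.Generator) -> list[str]:
    """Choose k mutually weakly correlated climate variables.

    Starting from a random candidate, greedily add the variable whose worst
    absolute correlation with the chosen set is smallest, so each driver
    represents a distinct climatic gradient.
    """
    E = env[candidates].to_numpy(dtype=float)
    E = (E - E.mean(axis=0)) / E.std(axis=0)
    C = np.abs(np.corrcoef(E.T))
    chosen = [int(rng.integers(len(candidates)))]
    while len(chosen) < k:
        remaining = [j for j in range(len(candidates)) if j not in chosen]
        chosen.append(min(remaining, key=lambda j: max(C[j, c] for c in chosen)))
    return [candidates[j] for j in chosen]


def simulate_panel(config: LandscapeConfig):
    """Generate (coordinates, env table, genotypes, truth) for one panel.

    * Accessions cluster around ``n_lineages`` spatial centers.
    * Environmental variables are smooth spatial fields plus noise; the
      monthly temperature families share latent fields, so the table is as
      collinear as real bioclim extractions.
    * Neutral SNP frequencies drift per lineage (Balding-Nichols with the
      configured Fst); adaptive SNP frequency at a site is
      logistic(a + slope * standardized driving variable).
    * Dosages are binomial(2, p) with probability ``inbreeding`` collapsed
      to a homozygote, matching a selfer's genotype spectrum.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_accessions

    # --- coordinates: lineage clusters within the extent
    lon0, lon1 = config.lon_extent
    lat0, lat1 = config.lat_extent
    centers = np.column_stack(
        [
            rng.uniform(lon0 + 0.1 * (lon1 - lon0), lon1 - 0.1 * (lon1 - lon0),
                        config.n_lineages),
            rng.uniform(lat0 + 0.1 * (lat1 - lat0), lat1 - 0.1 * (lat1 - lat0),
                        config.n_lineages),
        ]
    )
    lineage = rng.integers(0, config.n_lineages, size=n)
    spread = np.array([(lon1 - lon0) / 12.0, (lat1 - lat0) / 12.0])
    coords = centers[lineage] + rng.standard_normal((n, 2)) * spread
    coords[:, 0] = np.clip(coords[:, 0], lon0, lon1)
    coords[:, 1] = np.clip(coords[:, 1], lat0, lat1)

    # --- environment: latent spatial fields combined into named variables
    latents = _spatial_fields(coords, 4, config.spatial_range, rng)
    f_temp, f_prec, f_season, f_alt = latents.T
    names = env_variable_names(config.n_env_vars)
    cols: dict[str, np.ndarray] = {
        "lon": coords[:, 0],
        "lat": coords[:, 1],
        "alt": 1200.0 + 600.0 * f_alt + 60.0 * rng.standard_normal(n),
    }
    for name in names[3:]:
        noise = rng.standard_normal(n)
        if name.startswith("bio"):
            w = rng.normal(0, 1, size=3)
            v = (w[0] * f_temp + w[1] * f_prec + w[2] * f_season
                 + config.env_noise_bio * noise)
        elif name.startswith(("tmin_", "tmax_")):
            m = int(name.split("_")[1])
            season = np.cos(2 * np.pi * (m - 1) / 12.0)
            base = 1.0 if name.startswith("tmax_") else 0.8
            v = (base * f_temp + 0.6 * season * f_season
                 + config.env_noise_monthly * noise)
        else:  # prec_m
            m = int(name.split("_")[1])
            season = np.sin(2 * np.pi * (m - 1) / 12.0)
            v = (f_prec + 0.5 * season * f_season
                 + config.env_noise_monthly * noise)
        cols[name] = 10.0 * v
    env = pd.DataFrame(cols, columns=names)
    samples = [f"acc{i:03d}" for i in range(n)]
    env.index = pd.Index(samples, name="sample")

    # --- variants: sorted positions on n_chromosomes
    per_chrom = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per_chrom[: config.n_snps % config.n_chromosomes] += 1
    variants: list[Variant] = []
    for c, m in enumerate(per_chrom, start=1):
        pos = np.sort(rng.choice(config.chrom_length, size=m, replace=False)) + 1
        chrom = f"{c}D"
        variants.extend(Variant(chrom=chrom, pos=int(p), id=f"{chrom}_{p}") for p in pos)

    # --- allele frequencies: drifted (U-shaped) ancestral spectrum
    p0 = np.clip(rng.beta(config.sfs_beta, config.sfs_beta, size=config.n_snps),
                 0.01, 0.99)
    site_freq = np.empty((n, config.n_snps))
    if config.fst > 0:
        a = p0 * (1 - config.fst) / config.fst
        b = (1 - p0) * (1 - config.fst) / config.fst
        lineage_freq = rng.beta(
            np.broadcast_to(a, (config.n_lineages, config.n_snps)),
            np.broadcast_to(b, (config.n_lineages, config.n_snps)),
        )
    else:
        lineage_freq = np.broadcast_to(p0, (config.n_lineages, config.n_snps)).copy()
    site_freq[:] = lineage_freq[lineage]

    climate_cols = [c for c in names if is_climate_variable(c)]
    drivers = _pick_driver_variables(
        env, climate_cols, min(config.n_driver_variables, len(climate_cols)), rng
    )
    adaptive_idx = rng.choice(config.n_snps, size=config.n_adaptive, replace=False)
    adaptive_idx.sort()
    truth_records = []
    for k, i in enumerate(adaptive_idx):
        var = drivers[k % len(drivers)]
        z = env[var].to_numpy()
        z = (z - z.mean()) / z.std()
        # cline centered at frequency 0.5: the maximally informative
        # adaptive polymorphism
        site_freq[:, i] = 1.0 / (1.0 + np.exp(-config.adaptive_slope * z))
        truth_records.append((int(i), var, float(config.adaptive_slope)))

    # --- dosages: linked founder mosaics or independent inbred draws
    if config.ld_decay_cm is not None:
        dosage = _linked_dosage(p0, lineage, variants, config, rng)
        adaptive_cols = np.asarray(adaptive_idx, dtype=int)
    else:
        adaptive_cols = None
    u_inbred = rng.random((n, config.n_snps)) < config.inbreeding
    hom = 2.0 * (rng.random((n, config.n_snps)) < site_freq)
    het = rng.binomial(2, site_freq).astype(float)
    independent = np.where(u_inbred, hom, het)
    if config.ld_decay_cm is None:
        dosage = independent
    elif adaptive_cols is not None and adaptive_cols.size:
        # adaptive clines are site-specific; they override the mosaic draw
        dosage[:, adaptive_cols] = independent[:, adaptive_cols]
    if config.missing_rate > 0:
        miss = rng.random((n, config.n_snps)) < config.missing_rate
        dosage[miss] = np.nan

    G = GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)
    coords_df = pd.DataFrame(
        {"lon": coords[:, 0], "lat": coords[:, 1], "lineage": lineage},
        index=env.index,
    )
    truth = SimTruth(adaptive_loci=truth_records, lineage_labels=lineage)
    return coords_df, env, G, truth


# ---------------------------------------------------------------------------
# Introgression population


def uniform_genetic_map(G: GenotypeMatrix, cm_per_chrom: float = 150.0) -> pd.DataFrame:
    """Linear bp -> cM map, ``cm_per_chrom`` per chromosome."""
    rows = []
    chroms = G.chroms()
    pos = G.positions()
    for c in dict.fromkeys(chroms.tolist()):
        m = chroms == c
        p = pos[m].astype(float)
        span = p.max() - p.min() or 1.0
        cm = (p - p.min()) / span * cm_per_chrom
        for vid, cmv, pv in zip(np.array(G.variant_ids)[m], cm, p):
            rows.append((vid, c, int(pv), float(cmv)))
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "cM"])


def pericentromeric_genetic_map(
    G: GenotypeMatrix,
    chrom_lengths: dict,
    cm_per_chrom: float = 150.0,
    suppression: float = 3.0,
) -> pd.DataFrame:
    """bp -> cM map with recombination suppressed around the centromere.

    The centromere sits at the chromosome midpoint; the cumulative map is
    cM(u) = C/2 * (1 + sign(2u-1)|2u-1|^gamma) with gamma = ``suppression``,
    so the map is flat (no recombination) at the center and steep at the
    telomeres — the gradient wheat chromosomes show.
    """
    rows = []
    chroms = G.chroms()
    pos = G.positions()
    for c in dict.fromkeys(chroms.tolist()):
        m = chroms == c
        L = float(chrom_lengths[c])
        u = pos[m].astype(float) / L
        t = 2 * u - 1
        cm = cm_per_chrom / 2.0 * (1 + np.sign(t) * np.abs(t) ** suppression)
        for vid, cmv, pv in zip(np.array(G.variant_ids)[m], cm, pos[m]):
            rows.append((vid, c, int(pv), float(cmv)))
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "cM"])


@dataclass
class IntrogressionPopulation:
    """Donor-origin matrix and traits of a backcross introgression panel.

    ``genotypes.dosage`` counts donor-origin alleles per SNP: 0 = recurrent
    parent, 1 = heterozygous, 2 = homozygous donor segment.
    """

    genotypes: GenotypeMatrix
    donor_of_line: dict
    recurrent_of_line: dict
    allele_genotypes: GenotypeMatrix | None = None
    traits: pd.DataFrame | None = None
    truth: SimTruth | None = None

    @property
    def line_ids(self) -> list[str]:
        return list(self.genotypes.samples)

    def line_means(self, trait: str) -> np.ndarray:
        if self.traits is None:
            raise ValueError("population has no trait table")
        means = self.traits.groupby("line", observed=True)[trait].mean()
        return means.reindex(self.line_ids).to_numpy()

    def donor_fraction(self) -> np.ndarray:
        """Per-line donor genome fraction (mean donor dosage / 2)."""
        return np.nanmean(self.genotypes.dosage, axis=1) / 2.0

    @property
    def marker_genotypes(self) -> GenotypeMatrix:
        """Donor-allele matrix when available, else the origin matrix."""
        return self.allele_genotypes if self.allele_genotypes is not None else self.genotypes

    def het_fraction(self) -> np.ndarray:
        return np.nanmean(self.genotypes.dosage == 1, axis=1)


def _meiosis(h1: np.ndarray, h2: np.ndarray, cm: np.ndarray,
             total_cm: float, rng: np.random.Generator) -> np.ndarray:
    """One gamete: Poisson crossovers on the cM map, no interference."""
    n_xo = rng.poisson(total_cm / 100.0)
    start = int(rng.integers(2))
    if n_xo == 0:
        return (h1 if start == 0 else h2).copy()
    xo = np.sort(rng.uniform(0.0, total_cm, size=n_xo))
    seg = np.searchsorted(xo, cm, side="right")
    pick = (start + seg) % 2
    return np.where(pick == 0, h1, h2)


def simulate_introgression_population(
    donor_ids,
    recurrent_ids,
    n_lines: int,
    genetic_map: pd.DataFrame,
    G: GenotypeMatrix | None = None,
    selfing_generations: int = 3,
    seed: int = 0,
) -> IntrogressionPopulation:
    """Simulate BC1-then-selfed introgression lines as donor/recurrent mosaics.

    Each line: donor x recurrent F1 -> one backcross to the recurrent
    parent -> ``selfing_generations`` rounds of selfing.  Gametes carry
    Poisson crossovers on the cM map (no interference).  ``genetic_map``
    must map every SNP (columns snp, chrom, pos, cM); ``G`` only supplies
    the variant metadata when given.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    gm = genetic_map.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    if G is not None:
        missing = set(G.variant_ids) - set(gm["snp"])
        if missing:
            raise ValueError(f"unmapped SNPs: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    donor_ids = list(donor_ids)
    recurrent_ids = list(recurrent_ids)
    chrom_groups = [
        (c, grp.index.to_numpy(), grp["cM"].to_numpy())
        for c, grp in gm.groupby("chrom", sort=True)
    ]
    p = len(gm)
    dosage = np.zeros((n_lines, p))
    donor_of, recurrent_of = {}, {}
    line_ids = [f"IL{i + 1:03d}" for i in range(n_lines)]
    for li, lid in enumerate(line_ids):
        donor_of[lid] = donor_ids[int(rng.integers(len(donor_ids)))]
        recurrent_of[lid] = recurrent_ids[int(rng.integers(len(recurrent_ids)))]
        h1 = np.zeros(p)  # recurrent gamete
        h2 = np.zeros(p)
        for c, idx, cm in chrom_groups:
            total = float(cm.max() - cm.min()) if len(cm) else 0.0
            f1_donor = np.ones(len(idx))
            f1_rec = np.zeros(len(idx))
            # BC1: gamete from the F1, other haplotype recurrent
            bc1 = _meiosis(f1_donor, f1_rec, cm, total, rng)
            a, b = bc1, np.zeros(len(idx))
            for _ in range(selfing_generations):
                a, b = (
                    _meiosis(a, b, cm, total, rng),
                    _meiosis(a, b, cm, total, rng),
                )
            h1[idx], h2[idx] = a, b
        dosage[li] = h1 + h2
    variants = [
        Variant(chrom=str(r.chrom), pos=int(r.pos), id=str(r.snp))
        for r in gm.itertuples()
    ]
    geno = GenotypeMatrix(samples=line_ids, variants=variants, dosage=dosage)
    allele_geno = None
    if G is not None:
        # count the donor ALLELE each line can transmit: every donor segment
        # of a line descends from the single donor gamete in its F1, so one
        # gamete is drawn per line from the donor's genotype
        donor_row = {s: i for i, s in enumerate(G.samples)}
        col_of = {vid: j for j, vid in enumerate(G.variant_ids)}
        order = np.array([col_of[s] for s in gm["snp"]])
        donor_dos = G.imputed()[:, order]
        allele = np.zeros_like(dosage)
        for li, lid in enumerate(line_ids):
            d = donor_dos[donor_row[donor_of[lid]]]
            gamete = (rng.random(p) < d / 2.0).astype(float)
            allele[li] = dosage[li] * gamete
        allele_geno = GenotypeMatrix(
            samples=line_ids, variants=list(variants), dosage=allele
        )
    return IntrogressionPopulation(
        genotypes=geno,
        donor_of_line=donor_of,
        recurrent_of_line=recurrent_of,
        allele_genotypes=allele_geno,
    )


DEFAULT_TRAITS = ("yield", "sns", "tgw", "gw", "gl", "ct", "ndvi", "ddth")


def simulate_phenotypes(
    pop: IntrogressionPopulation,
    qtl=(),
    h2_target: float = 0.5,
    n_trials: int = 2,
    seed: int = 0,
    traits=DEFAULT_TRAITS,
    polygenic_sd: float = 1.0,
    ct_yield_genetic_corr: float = -0.5,
    trial_effect_sd: float = 0.5,
    spatial_sd: float = 0.3,
) -> pd.DataFrame:
    """Plot-level phenotypes with planted QTL and a controllable h^2.

    trait = sum(effect * donor dosage) + polygenic line effect + trial
    effect + quadratic row/range trend + residual; the residual is scaled
    so the per-plot heritability var(g)/(var(g) + var(e)) equals
    ``h2_target`` (1.0 gives a zero residual).  The CT and yield polygenic
    effects are drawn with genetic correlation ``ct_yield_genetic_corr``.
    ``qtl`` is a list of (snp_id or index, trait, effect).
    """
    if not 0 < h2_target <= 1:
        raise ValueError("h2_target must be in (0, 1]")
    rng = np.random.default_rng(seed)
    G = pop.marker_genotypes  # QTL effects act through the donor allele
    n = G.n_samples
    idx = {v.id: j for j, v in enumerate(G.variants)}
    genetic = {t: np.zeros(n) for t in traits}
    for snp, trait, effect in qtl:
        if isinstance(snp, str):
            if snp not in idx:
                raise KeyError(f"QTL SNP {snp} absent from population")
            j = idx[snp]
        else:
            j = int(snp)
        if not 0 <= j < G.n_variants:
            raise KeyError(f"QTL SNP index {j} out of range")
        if trait not in genetic:
            raise KeyError(f"QTL trait {trait} not simulated")
        genetic[trait] += float(effect) * np.nan_to_num(G.dosage[:, j])
    if polygenic_sd > 0:
        rho = ct_yield_genetic_corr
        cov = polygenic_sd**2 * np.array([[1.0, rho], [rho, 1.0]])
        cy = rng.multivariate_normal(np.zeros(2), cov, size=n)
        for t in traits:
            if t == "ct":
                genetic[t] = genetic[t] + cy[:, 0]
            elif t == "yield":
                genetic[t] = genetic[t] + cy[:, 1]
            else:
                genetic[t] = genetic[t] + polygenic_sd * rng.standard_normal(n)
    n_cols = int(np.ceil(np.sqrt(n)))
    rows_list = []
    for t in range(n_trials):
        order = rng.permutation(n)
        trial_fx = {tr: trial_effect_sd * rng.standard_normal() for tr in traits}
        coef = {tr: spatial_sd * rng.standard_normal(3) for tr in traits}
        for plot_i, line_i in enumerate(order):
            row = plot_i // n_cols
            rng_i = plot_i % n_cols
            rec = {
                "line": G.samples[line_i],
                "trial": f"trial{t + 1}",
                "row": row,
                "range": rng_i,
                "is_check": 0,
            }
            rows_list.append((rec, line_i, trial_fx, coef, row, rng_i))
    # residual scale per trait from realized genetic variance
    resid_sd = {}
    for tr in traits:
        vg = float(np.var(genetic[tr]))
        resid_sd[tr] = (
            0.0 if h2_target == 1.0 else np.sqrt(vg * (1 - h2_target) / h2_target)
        )
    records = []
    for rec, line_i, trial_fx, coef, row, rng_i in rows_list:
        out = dict(rec)
        for tr in traits:
            c = coef[tr]
            spatial = c[0] * (row / n_cols) + c[1] * (rng_i / n_cols) + c[2] * (
                row * rng_i / n_cols**2
            )
            out[tr] = (
                genetic[tr][line_i]
                + trial_fx[tr]
                + spatial
                + resid_sd[tr] * rng.standard_normal()
            )
        records.append(out)
    table = pd.DataFrame(records)
    pop.traits = table
    if pop.truth is None:
        pop.truth = SimTruth(adaptive_loci=[], lineage_labels=np.array([]), qtl=list(qtl))
    else:
        pop.truth.qtl = list(qtl)
    return table
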