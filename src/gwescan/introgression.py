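"""Evaluating climate-associated alleles in an introgression population.

Lines in the phenotype tails (lower/upper 5th percentile, required in at
least ``min_traits`` trait columns) are compared with the whole population
(WP): allele-frequency spectra in 9 bins, two-sample Kolmogorov-Smirnov on
the per-SNP frequency vectors, fold-change differentiation (FC >= 2 with an
adaptive fallback threshold), counts of differentiated SNPs in three
equal-length chromosome-arm bins measured from the centromere, trait GWAS
on the donor-origin matrix, and the yield-on-canopy-temperature regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, KinshipMatrix, kinship, prune_ld
from . import gea

__all__ = [
    "TailSelection",
    "SpectrumResult",
    "select_tail_lines",
    "frequency_spectrum",
    "tail_spectrum_test",
    "fc_differentiation",
    "arm_bin_counts",
    "caa_trait_gwas",
    "regress_trait_on_ct",
]


@dataclass
class TailSelection:
    traits: list[str]
    percentile: float
    min_traits: int
    lower: list[str]
    upper: list[str]


def select_tail_lines(
    trait_table: pd.DataFrame,
    traits: list[str],
    percentile: float = 5.0,
    min_traits: int = 2,
    line_col: str = "line",
) -> TailSelection:
    """Lines in the lower/upper ``percentile`` tail of >= ``min_traits`` traits.

    ``trait_table`` holds one row per line (pass line means across trials,
    or per-trial columns as separate trait names).  A line can only belong
    to one tail per trait; boundary ties resolve by stable line-id order.
    """
    if min_traits > len(traits):
        raise ValueError("min_traits cannot exceed the number of traits")
    lower_hits: dict[str, int] = {}
    upper_hits: dict[str, int] = {}
    for trait in traits:
        sub = trait_table[[line_col, trait]].dropna()
        if len(sub) < 20:
            raise ValueError(f"trait {trait} has fewer than 20 scored lines")
        if sub[trait].std() == 0:
            raise ValueError(f"trait {trait} has no variance")
        sub = sub.sort_values([trait, line_col], kind="stable")
        k = int(np.floor(len(sub) * percentile / 100.0))
        for lid in sub[line_col].iloc[:k]:
            lower_hits[lid] = lower_hits.get(lid, 0) + 1
        for lid in sub[line_col].iloc[len(sub) - k:]:
            upper_hits[lid] = upper_hits.get(lid, 0) + 1
    lower = sorted(l for l, c in lower_hits.items() if c >= min_traits)
    upper = sorted(l for l, c in upper_hits.items() if c >= min_traits)
    # a line qualifying for both tails (possible with discordant traits) is
    # dropped from both, keeping the tails disjoint
    overlap = set(lower) & set(upper)
    lower = [l for l in lower if l not in overlap]
    upper = [l for l in upper if l not in overlap]
    return TailSelection(
        traits=list(traits),
        percentile=percentile,
        min_traits=min_traits,
        lower=lower,
        upper=upper,
    )


@dataclass
class SpectrumResult:
    bin_edges: np.ndarray
    wp_proportions: np.ndarray
    tail_proportions: np.ndarray
    ks_d: float
    ks_p: float


def frequency_spectrum(
    freqs_wp: np.ndarray, freqs_tail: np.ndarray, n_bins: int = 9
) -> SpectrumResult:
    """Allele-frequency spectra and two-sample KS of tail vs WP.

    Bins are equal width on (0, 1]; SNPs with zero frequency in a group
    carry no allele to count there and are excluded from that group's
    spectrum.  The KS statistic is computed on the raw frequency vectors
    restricted to SNPs segregating in both groups (the (0, 1] domain of the
    spectra), not on the binned counts.
    """
    fw = np.asarray(freqs_wp, dtype=float)
    ft = np.asarray(freqs_tail, dtype=float)
    if fw.shape != ft.shape:
        raise ValueError("frequency vectors must cover the same SNP set")
    if ft[~np.isnan(ft)].size == 0:
        raise ValueError("tail frequency vector is empty")
    edges = np.linspace(0.0, 1.0, n_bins + 1)

    def props(f: np.ndarray) -> np.ndarray:
        f = f[~np.isnan(f) & (f > 0)]
        if f.size == 0:
            return np.zeros(n_bins)
        # (0,1] bins: right-closed
        counts, _ = np.histogram(-f, bins=-edges[::-1])
        counts = counts[::-1]
        return counts / counts.sum()

    ok = ~np.isnan(fw) & ~np.isnan(ft) & (fw > 0) & (ft > 0)
    if ok.sum() >= 2:
        ks = stats.ks_2samp(ft[ok], fw[ok], method="asymp")
        d, p = float(ks.statistic), float(ks.pvalue)
    else:
        d, p = 0.0, 1.0
    return SpectrumResult(
        bin_edges=edges,
        wp_proportions=props(fw),
        tail_proportions=props(ft),
        ks_d=d,
        ks_p=p,
    )


def _ks_d(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample KS statistic on the (0,1] domain (zeros dropped)."""
    ok = (x > 0) & (y > 0)
    if ok.sum() < 2:
        return 0.0
    return float(stats.ks_2samp(x[ok], y[ok], method="asymp").statistic)


def tail_spectrum_test(
    dosage: np.ndarray,
    tail_rows,
    n_perm: int = 199,
    n_bins: int = 9,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SpectrumResult, float]:
    """Tail-vs-WP spectrum with a subset-permutation calibrated p-value.

    The classical two-sample KS treats the tail and WP frequency vectors as
    independent samples, but the tail frequencies are computed from far
    fewer lines and are a noisier reading of the same loci, so the
    asymptotic p-value rejects even when the tail is a random subset.  Here
    the observed D is compared against D from ``n_perm`` random line
    subsets of the same size: p = (1 + #{D_perm >= D_obs}) / (1 + n_perm),
    exact under exchangeability of lines.

    ``dosage`` is the per-line donor-allele matrix (lines x SNPs);
    ``tail_rows`` are row indices of the tail lines.  Returns the
    :class:`SpectrumResult` (with the classical KS fields) and the
    permutation p-value.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    tail_rows = np.asarray(list(tail_rows), dtype=int)
    if tail_rows.size == 0:
        raise ValueError("tail is empty")
    n = dosage.shape[0]
    freq_wp = dosage.mean(axis=0) / 2.0
    freq_tail = dosage[tail_rows].mean(axis=0) / 2.0
    spec = frequency_spectrum(freq_wp, freq_tail, n_bins=n_bins)
    d_obs = _ks_d(freq_wp, freq_tail)
    n_ge = 0
    for _ in range(n_perm):
        rows = rng.choice(n, size=tail_rows.size, replace=False)
        if _ks_d(freq_wp, dosage[rows].mean(axis=0) / 2.0) >= d_obs:
            n_ge += 1
    return spec, (1 + n_ge) / (1 + n_perm)


def fc_differentiation(
    freq_tail: np.ndarray,
    freq_wp: np.ndarray,
    fc_min: float = 2.0,
    pseudo: float | None = None,
    n_lines: int | None = None,
    two_sided: bool = False,
    snp_ids=None,
) -> pd.DataFrame:
    """Fold-change differentiated SNPs between a tail group and the WP.

    FC = (freq_tail + pseudo) / (freq_wp + pseudo); ``pseudo`` defaults to
    1/(2N) with N = ``n_lines`` (or 1/(2*100) if neither is given).  With
    ``two_sided`` the larger of the ratio and its inverse is used.  If no
    SNP reaches ``fc_min`` the threshold is lowered to the 95th percentile
    of the FC distribution, mirroring the adjusted-threshold rule.
    Returns a DataFrame with columns snp, fc, differentiated (sorted by the
    input SNP order).
    """
    ft = np.asarray(freq_tail, dtype=float)
    fw = np.asarray(freq_wp, dtype=float)
    if ft.shape != fw.shape:
        raise ValueError("frequency vectors must match")
    if np.nanmin(ft) < 0 or np.nanmin(fw) < 0:
        raise ValueError("frequencies must be non-negative")
    if pseudo is None:
        pseudo = 1.0 / (2 * (n_lines if n_lines else 100))
    fc = (ft + pseudo) / (fw + pseudo)
    if two_sided:
        fc = np.maximum(fc, 1.0 / fc)
    thresh = fc_min
    finite = fc[np.isfinite(fc)]
    if finite.size and np.nanmax(finite) < fc_min:
        thresh = float(np.nanpercentile(finite, 95))
    ids = list(snp_ids) if snp_ids is not None else list(range(len(fc)))
    return pd.DataFrame(
        {"snp": ids, "fc": fc, "differentiated": fc >= thresh}
    )


@dataclass
class ArmBinCounts:
    """Differentiated-SNP counts in three equal arm bins from the centromere.

    ``per_chrom`` maps chromosome -> (short-arm counts, long-arm counts),
    each proximal -> distal; ``totals`` aggregates both arms of all
    chromosomes, index 0 = proximal third, 2 = distal third.
    """

    per_chrom: dict = field(default_factory=dict)
    totals: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=int))


def arm_bin_counts(
    snp_table: pd.DataFrame,
    chromosome_table: pd.DataFrame,
    G: GenotypeMatrix | None = None,
    dedup_r2: float | None = 0.5,
    window_bp: int = 50_000,
    step_bp: int = 5_000,
) -> ArmBinCounts:
    """Count SNPs in three equal-length bins per arm from the centromere.

    ``snp_table`` needs columns chrom, pos (and snp if deduplicating);
    ``chromosome_table`` needs chrom, length, centromere_pos.  When ``G``
    and ``dedup_r2`` are given the SNP set is LD-deduplicated first (one
    representative per correlated cluster).  Bin boundaries sit at 33.3%
    and 66.7% of arm length measured from the centromere; a SNP outside the
    chromosome bounds raises.
    """
    snp_table = snp_table.copy()
    if dedup_r2 is not None and G is not None and len(snp_table):
        sub = G.subset_variants(snp_table["snp"].tolist())
        keep = set(prune_ld(sub, window_bp=window_bp, step_bp=step_bp, r2_max=dedup_r2))
        snp_table = snp_table[snp_table["snp"].isin(keep)]
    chrom_info = chromosome_table.set_index("chrom")
    result = ArmBinCounts()
    for chrom, grp in snp_table.groupby("chrom", sort=True):
        if chrom not in chrom_info.index:
            raise ValueError(f"chromosome {chrom} missing from centromere table")
        length = float(chrom_info.loc[chrom, "length"])
        cent = float(chrom_info.loc[chrom, "centromere_pos"])
        if not (0 < cent < length):
            raise ValueError(f"centromere of {chrom} outside chromosome bounds")
        short_counts = np.zeros(3, dtype=int)
        long_counts = np.zeros(3, dtype=int)
        for snp, pos in zip(grp.get("snp", grp.index), grp["pos"]):
            if pos < 1 or pos > length:
                raise ValueError(f"SNP {snp} at {pos} beyond chromosome {chrom} end")
            if pos <= cent:  # short arm: distance toward position 1
                d = (cent - pos) / cent
                short_counts[min(int(d * 3), 2)] += 1
            else:  # long arm
                d = (pos - cent) / (length - cent)
                long_counts[min(int(d * 3), 2)] += 1
        result.per_chrom[chrom] = (short_counts, long_counts)
        result.totals += short_counts + long_counts
    return result


def caa_trait_gwas(
    pop,
    trait: str,
    caa_set,
    n_pcs: int = 3,
    K: KinshipMatrix | None = None,
    multi_locus: bool = False,
    q: float = 0.05,
):
    """Mixed-model GWAS of an introgression-population trait over CAA SNPs.

    ``pop`` must expose ``genotypes`` (donor-origin :class:`GenotypeMatrix`)
    and ``line_means(trait)``.  Kinship is computed from the full
    donor-origin matrix unless supplied.  Delegates to the EMMAX scan (or
    the multi-locus forward scan when ``multi_locus``).
    """
    caa_set = list(caa_set)
    have = set(pop.genotypes.variant_ids)
    missing = [s for s in caa_set if s not in have]
    if missing:
        raise ValueError(f"CAA SNPs absent from population: {missing[:5]}")
    y = pop.line_means(trait)
    if np.std(y) == 0:
        raise ValueError(f"trait {trait} is constant")
    if K is None:
        K = kinship(pop.genotypes)
    markers = getattr(pop, "marker_genotypes", pop.genotypes)
    sub = markers.subset_variants(caa_set)
    if multi_locus:
        scan, cof = gea.mlmm_scan(y, sub, K, n_pcs=n_pcs, q=q)
        return scan, cof
    return gea.mlm_gwas(y, sub, K, n_pcs=n_pcs)


def regress_trait_on_ct(yield_values, ct_values):
    """Least-squares regression of a performance trait on canopy temperature.

    Returns (slope, intercept, r, R^2); r keeps its sign, R^2 = r^2.
    """
    y = np.asarray(yield_values, dtype=float)
    x = np.asarray(ct_values, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0:
        raise ValueError("canopy temperature has no variance")
    res = stats.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue),
        float(res.rvalue**2),
    )
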