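"""Genotype containers and population-genetics primitives.

Dosage matrices are stored as ``float64`` with ``np.nan`` marking missing
calls, so that a missing genotype is always distinct from homozygous
reference (dosage 0).  Coordinates are 1-based (VCF convention) and windows
are half-open ``[start, start + window_bp)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Variant",
    "GenotypeMatrix",
    "KinshipMatrix",
    "read_vcf",
    "write_vcf",
    "allele_frequency",
    "ld_r2",
    "prune_ld",
    "kinship",
    "pca",
    "infer_lineages",
    "lineage_dummies",
]


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP.  ``pos`` is 1-based."""

    chrom: str
    pos: int
    id: str
    ref: str = "A"
    alt: str = "T"

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs alt-allele dosage matrix with variant metadata.

    ``dosage[i, j]`` is the number of alternate alleles (0, 1, 2) carried by
    sample ``i`` at variant ``j``; missing calls are ``np.nan``.
    """

    samples: list[str]
    variants: list[Variant]
    dosage: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, p = self.dosage.shape
        if n != len(self.samples):
            raise ValueError(
                f"dosage has {n} rows but {len(self.samples)} samples given"
            )
        if p != len(self.variants):
            raise ValueError(
                f"dosage has {p} columns but {len(self.variants)} variants given"
            )
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("variant ids must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    def subset_variants(self, keep_ids) -> "GenotypeMatrix":
        keep = set(keep_ids)
        idx = [j for j, v in enumerate(self.variants) if v.id in keep]
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[j] for j in idx],
            dosage=self.dosage[:, idx].copy(),
        )

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        rows = [index[s] for s in sample_ids]
        return GenotypeMatrix(
            samples=list(sample_ids),
            variants=list(self.variants),
            dosage=self.dosage[rows, :].copy(),
        )

    def imputed(self) -> np.ndarray:
        """Dosage with missing values replaced by the per-SNP mean."""
        X = self.dosage.copy()
        col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        nan_r, nan_c = np.nonzero(np.isnan(X))
        X[nan_r, nan_c] = col_mean[nan_c]
        return X


@dataclass
class KinshipMatrix:
    """Realized-relationship matrix; sample order matches the source matrix."""

    samples: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.samples)):
            raise ValueError("kinship must be square and match samples")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")


# ---------------------------------------------------------------------------
# VCF input/output


_GT_DOSAGE = {0: 0.0, 1: 1.0, 3: 2.0, 2: np.nan}  # cyvcf2 gt_types codes


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF (v4.x, GT field) into a :class:`GenotypeMatrix`.

    Multi-allelic records are skipped (a count is logged); ``./.`` becomes a
    missing dosage, never 0.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for rec in vcf:
        if rec.ALT is None or len(rec.ALT) != 1:
            n_multi += 1
            continue
        variants.append(
            Variant(
                chrom=rec.CHROM,
                pos=rec.POS,
                id=rec.ID or f"{rec.CHROM}_{rec.POS}",
                ref=rec.REF,
                alt=rec.ALT[0],
            )
        )
        rows.append(np.array([_GT_DOSAGE[t] for t in rec.gt_types], dtype=float))
    vcf.close()
    if n_multi:
        logger.info("read_vcf: skipped %d multi-allelic records", n_multi)
    dosage = (
        np.column_stack(rows) if rows else np.empty((len(samples), 0), dtype=float)
    )
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write ``G`` as an uncompressed VCF v4.2 with GT fields."""
    gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in G.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples)
            + "\n"
        )
        for j, v in enumerate(G.variants):
            calls = [
                "./." if np.isnan(d) else gt_codes[float(d)] for d in G.dosage[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_dosage_csv(path) -> GenotypeMatrix:
    """CSV fallback: samples x SNPs, header row of ids ``chrom_pos``."""
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    variants = []
    for col in df.columns:
        chrom, pos = col.rsplit("_", 1)
        variants.append(Variant(chrom=chrom, pos=int(pos), id=col))
    return GenotypeMatrix(
        samples=[str(s) for s in df.index],
        variants=variants,
        dosage=df.to_numpy(dtype=float),
    )


def write_dosage_csv(G: GenotypeMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(G.dosage, index=G.samples, columns=G.variant_ids).to_csv(path)


# ---------------------------------------------------------------------------
# Frequencies, LD, pruning


def allele_frequency(G: GenotypeMatrix, sample_subset=None) -> np.ndarray:
    """Per-SNP alternate-allele frequency, missing calls excluded.

    freq = sum(dosage) / (2 * n_called); an all-missing SNP yields ``nan``.
    """
    X = G.dosage
    if sample_subset is not None:
        sample_subset = list(sample_subset)
        if not sample_subset:
            raise ValueError("sample_subset must be non-empty")
        index = {s: i for i, s in enumerate(G.samples)}
        X = X[[index[s] for s in sample_subset], :]
    called = np.sum(~np.isnan(X), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.nansum(X, axis=0) / (2.0 * called)
    freq[called == 0] = np.nan
    return freq


def ld_r2(g_i: np.ndarray, g_j: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Pairwise-complete: only jointly called samples enter.  Returns ``nan``
    when fewer than two joint calls remain or either vector is constant.
    """
    g_i = np.asarray(g_i, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    ok = ~(np.isnan(g_i) | np.isnan(g_j))
    if ok.sum() < 2:
        return float("nan")
    x, y = g_i[ok], g_j[ok]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
    return float(r * r)


def _ld_r2_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise r^2 over columns of X (mean-imputed, constant-safe)."""
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = Xc / sd_safe
    R = Z.T @ Z / X.shape[0]
    R2 = R * R
    R2[sd == 0, :] = np.nan
    R2[:, sd == 0] = np.nan
    return R2


def prune_ld(
    G: GenotypeMatrix,
    window_bp: int = 50_000,
    step_bp: int = 5_000,
    r2_max: float = 0.5,
) -> list[str]:
    """Greedy LD pruning; returns the retained variant ids.

    Scanning left to right within each chromosome, a SNP is kept iff its
    r^2 with every already-kept SNP less than ``window_bp`` upstream is
    below ``r2_max``.  Of a violating pair the higher-index (later) SNP is
    removed, so the kept set is deterministic and stable under re-runs.
    ``step_bp`` controls how far the scan window advances; comparability is
    decided by pairwise distance within ``window_bp``.
    """
    chroms = G.chroms()
    pos = G.positions()
    order = np.lexsort((pos, chroms))
    if not np.array_equal(order, np.arange(len(order))):
        # require sorted input: positions must be non-decreasing per chrom
        for c in np.unique(chroms):
            p = pos[chroms == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"variants on {c} are not position-sorted")
    kept: list[int] = []
    X = G.dosage
    for c in dict.fromkeys(chroms.tolist()):
        idx = np.nonzero(chroms == c)[0]
        kept_c: list[int] = []
        for j in idx:
            ok = True
            for i in reversed(kept_c):
                if pos[j] - pos[i] >= window_bp:
                    break
                r2 = ld_r2(X[:, i], X[:, j])
                if not np.isnan(r2) and r2 >= r2_max:
                    ok = False
                    break
            if ok:
                kept_c.append(j)
        kept.extend(kept_c)
    ids = G.variant_ids
    return [ids[j] for j in kept]


# ---------------------------------------------------------------------------
# Kinship and PCA


def kinship(G: GenotypeMatrix, method: str = "vanraden") -> KinshipMatrix:
    """VanRaden realized-relationship matrix.

    Z = dosage - 2p (mean-imputed, monomorphic SNPs dropped from the
    denominator), K = Z Z' / (2 * sum p(1-p)).  The diagonal is not forced
    to 1.
    """
    if method != "vanraden":
        raise ValueError(f"unknown kinship method: {method}")
    if G.n_samples < 2:
        raise ValueError("kinship needs at least 2 samples")
    X = G.imputed()
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    Xp = X[:, poly]
    pp = p[poly]
    Z = Xp - 2.0 * pp
    denom = 2.0 * np.sum(pp * (1.0 - pp))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic; kinship undefined")
    K = Z @ Z.T / denom
    return KinshipMatrix(samples=list(G.samples), values=K)


def infer_lineages(G: GenotypeMatrix, n_lineages: int, n_pcs: int = 3) -> np.ndarray:
    """Assign samples to lineages by k-means on the leading genotype PCs.

    A light-weight stand-in for spatial ancestry estimation: with discrete,
    well-differentiated lineages the k-means partition of PC space recovers
    the same groups.  Returns integer labels (deterministic)."""
    from sklearn.cluster import KMeans

    scores, _ = pca(G, min(n_pcs, G.n_samples - 1))
    km = KMeans(n_clusters=n_lineages, n_init=10, random_state=0).fit(scores)
    return km.labels_


def lineage_dummies(labels: np.ndarray) -> np.ndarray:
    """0/1 indicator columns for all but the first lineage level."""
    levels = np.unique(labels)
    return (labels[:, None] == levels[None, 1:]).astype(float)


def pca(G: GenotypeMatrix, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the centered (mean-imputed) dosage matrix.

    Returns (scores, explained-variance fractions).  Scores are U * S from
    the thin SVD of the centered matrix; fractions sum to at most 1 and are
    non-increasing.
    """
    X = G.imputed()
    Xc = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    scores = U[:, :n_components] * S[:n_components]
    var = S**2
    frac = var[:n_components] / var.sum()
    return scores, frac
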