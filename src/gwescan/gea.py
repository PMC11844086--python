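"""Climate-associated allele (CAA) detection.

Two complementary scans are combined:

* an ordination outlier scan — SNP loadings on the leading constrained RDA
  axes are standardized per axis and SNPs beyond ``z_thresh`` standard
  deviations on any axis are flagged;
* a kinship mixed-model association scan (EMMAX / P3D approximation): the
  two variance components are estimated once by REML under the null model,
  then every SNP is tested by generalized least squares with principal
  components as fixed covariates, and p-values are Benjamini-Hochberg
  adjusted.

Each RDA-flagged SNP is assigned to the single ecogeographic variable with
the strongest Pearson correlation to its dosages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .genotypes import GenotypeMatrix, KinshipMatrix
from .ordination import RDA

__all__ = [
    "CAARecord",
    "rda_outliers",
    "assign_variable",
    "EmmaxGWAS",
    "mlm_gwas",
    "mlmm_scan",
    "bh_fdr",
    "combine_caa",
]


@dataclass
class CAARecord:
    snp_id: str
    method: str  # "RDA", "GWAS" or "both"
    assigned_variable: str | None = None
    pearson_r: float | None = None
    max_abs_z: float | None = None
    fdr_q: float | None = None


def rda_outliers(
    rda: RDA, n_axes: int = 3, z_thresh: float = 3.0, snp_ids=None,
    return_z: bool = False,
):
    """SNPs whose loading is > ``z_thresh`` SD from the mean on any axis.

    Loadings are standardized per axis; an axis with zero loading variance
    is skipped.  The union over axes is returned (duplicates removed), so
    the set is invariant to axis sign flips.
    """
    L = np.asarray(rda.loadings_)
    if L.shape[1] < n_axes:
        raise ValueError(
            f"RDA has {L.shape[1]} constrained axes, need {n_axes}"
        )
    p = L.shape[0]
    ids = list(snp_ids) if snp_ids is not None else list(range(p))
    flagged: set = set()
    max_z = np.zeros(p)
    for a in range(n_axes):
        col = L[:, a]
        sd = col.std()
        if sd == 0:
            import warnings

            warnings.warn(f"axis {a} has zero loading variance; skipped", stacklevel=2)
            continue
        z = np.abs(col - col.mean()) / sd
        max_z = np.maximum(max_z, z)
        flagged.update(np.nonzero(z > z_thresh)[0].tolist())
    out = {ids[j] for j in flagged}
    if return_z:
        return out, dict(zip(ids, max_z))
    return out


def assign_variable(
    outliers, G: GenotypeMatrix, E: pd.DataFrame, max_abs_z: dict | None = None
) -> list[CAARecord]:
    """Assign each outlier SNP to the single best-correlated variable.

    The variable maximizing |Pearson r(dosage, variable)| wins; ties go to
    the earlier column.  Constant variables are excluded; a monomorphic SNP
    has no defined correlation and raises.
    """
    idx = {v.id: j for j, v in enumerate(G.variants)}
    missing = [s for s in outliers if s not in idx]
    if missing:
        raise ValueError(f"outliers not in genotype matrix: {missing[:5]}")
    Evals = E.to_numpy(dtype=float)
    keep = Evals.std(axis=0) > 0
    cols = [c for c, k in zip(E.columns, keep) if k]
    Ez = Evals[:, keep]
    Ez = (Ez - Ez.mean(axis=0)) / Ez.std(axis=0)
    records = []
    for snp in sorted(outliers, key=lambda s: idx[s]):
        g = G.dosage[:, idx[snp]]
        ok = ~np.isnan(g)
        gv = g[ok]
        if gv.std() == 0:
            raise ValueError(f"SNP {snp} is monomorphic; correlation undefined")
        gz = (gv - gv.mean()) / gv.std()
        r = gz @ Ez[ok] / ok.sum()
        best = int(np.argmax(np.abs(np.round(r, 12))))  # ties -> earlier column
        records.append(
            CAARecord(
                snp_id=snp,
                method="RDA",
                assigned_variable=cols[best],
                pearson_r=float(r[best]),
                max_abs_z=(max_abs_z or {}).get(snp),
            )
        )
    return records


class EmmaxGWAS(BaseEstimator):
    """Kinship mixed-model association scan (EMMAX / P3D).

    The model is y = X b + g beta + u + e with u ~ N(0, sigma_g^2 K) and
    e ~ N(0, sigma_e^2 I).  The variance ratio delta = sigma_e^2/sigma_g^2
    is estimated once by REML under the null (no SNP), via the spectral
    decomposition of K; every SNP is then tested by generalized least
    squares with the variance components held fixed, which is the standard
    population-parameters-previously-determined (P3D) approximation.

    Parameters
    ----------
    n_pcs : number of genotype principal components used as fixed
        covariates (0 disables).
    per_variable_fdr : kept for symmetry with the pipeline; BH adjustment
        is applied to the p-values of this scan.
    """

    def __init__(self, n_pcs: int = 3):
        self.n_pcs = n_pcs

    def fit(self, G: GenotypeMatrix, y, K: KinshipMatrix | None = None,
            pcs: np.ndarray | None = None):
        y = np.asarray(y, dtype=float)
        n = G.n_samples
        if y.shape != (n,):
            raise ValueError("y must be one value per sample")
        if np.std(y) == 0:
            raise ValueError("phenotype is constant")
        if K is not None and list(K.samples) != list(G.samples):
            raise ValueError("kinship sample order does not match genotypes")
        X = np.ones((n, 1))
        if self.n_pcs > 0:
            if pcs is None:
                from .genotypes import pca

                pcs, _ = pca(G, self.n_pcs)
            X = np.column_stack([X, pcs[:, : self.n_pcs]])
        Kv = K.values if K is not None else np.eye(n)
        vals, U = np.linalg.eigh((Kv + Kv.T) / 2.0)
        if vals.min() < -1e-8:
            import warnings

            warnings.warn("kinship not PSD; clipping negative eigenvalues", stacklevel=2)
        vals = np.clip(vals, 0.0, None)
        yt = U.T @ y
        Xt = U.T @ X
        Gt = U.T @ G.imputed()

        def neg_reml(log_delta: float) -> float:
            delta = np.exp(log_delta)
            w = 1.0 / (vals + delta)
            Xw = Xt * w[:, None]
            XtX = Xt.T @ Xw
            beta = np.linalg.solve(XtX, Xw.T @ yt)
            r = yt - Xt @ beta
            rss = float(r @ (w * r))
            df = n - X.shape[1]
            s2 = rss / df
            # restricted log-likelihood up to constants
            ll = -0.5 * (
                df * np.log(s2)
                + np.sum(np.log(vals + delta))
                + np.linalg.slogdet(XtX)[1]
                + df
            )
            return -ll

        res = optimize.minimize_scalar(
            neg_reml, bounds=(np.log(1e-6), np.log(1e6)), method="bounded",
            options={"xatol": 1e-8},
        )
        delta = float(np.exp(res.x))
        w = 1.0 / (vals + delta)
        sw = np.sqrt(w)
        yw = yt * sw
        Xw = Xt * sw[:, None]
        Gw = Gt * sw[:, None]
        # residualize phenotype and SNPs on the fixed covariates
        Qx, _ = np.linalg.qr(Xw)
        yr = yw - Qx @ (Qx.T @ yw)
        Gr = Gw - Qx @ (Qx.T @ Gw)
        gg = np.sum(Gr * Gr, axis=0)
        gy = Gr.T @ yr
        df = n - X.shape[1] - 1
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = gy / gg
            rss = float(yr @ yr) - beta * gy
            sigma2 = rss / df
            se = np.sqrt(sigma2 / gg)
            tstat = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
        mono = gg <= 1e-12
        pvals = np.where(mono, 1.0, pvals)
        beta = np.where(mono, 0.0, beta)
        se = np.where(mono, np.nan, se)
        qvals = bh_fdr(np.clip(pvals, np.nextafter(0, 1), 1.0))[0]
        self.delta_ = delta
        self.sigma_g2_ = float(yr @ yr) / (n - X.shape[1])
        self.sigma_e2_ = delta * self.sigma_g2_
        self.results_ = pd.DataFrame(
            {
                "snp": G.variant_ids,
                "chrom": G.chroms(),
                "pos": G.positions(),
                "effect": beta,
                "se": se,
                "p_value": pvals,
                "q_value": qvals,
            }
        )
        return self


def mlm_gwas(
    y, G: GenotypeMatrix, K: KinshipMatrix | None = None, n_pcs: int = 3,
    pcs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP mixed-model association scan; see :class:`EmmaxGWAS`."""
    return EmmaxGWAS(n_pcs=n_pcs).fit(G, y, K=K, pcs=pcs).results_


def mlmm_scan(
    y,
    G: GenotypeMatrix,
    K: KinshipMatrix | None = None,
    n_pcs: int = 3,
    max_steps: int = 10,
    q: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Multi-locus mixed model: forward inclusion of SNP cofactors.

    Repeatedly runs the single-SNP scan with previously selected SNPs as
    fixed cofactors (their columns residualized out), adding the most
    significant SNP while its BH q-value is <= ``q``, up to ``max_steps``.
    Returns the final scan table and the ordered cofactor list.
    """
    cofactors: list[str] = []
    y_work = np.asarray(y, dtype=float).copy()
    idx = {v.id: j for j, v in enumerate(G.variants)}
    scan = mlm_gwas(y_work, G, K, n_pcs=n_pcs)
    for _ in range(max_steps):
        open_rows = scan[~scan["snp"].isin(cofactors)]
        best = open_rows.loc[open_rows["p_value"].idxmin()]
        if best["q_value"] > q:
            break
        cofactors.append(str(best["snp"]))
        # residualize phenotype on the cofactor dosages (fixed effects)
        C = np.column_stack(
            [np.ones(G.n_samples)]
            + [np.nan_to_num(G.dosage[:, idx[c]], nan=np.nanmean(G.dosage[:, idx[c]]))
               for c in cofactors]
        )
        beta, *_ = np.linalg.lstsq(C, np.asarray(y, dtype=float), rcond=None)
        y_work = np.asarray(y, dtype=float) - C @ beta + beta[0]
        scan = mlm_gwas(y_work, G, K, n_pcs=n_pcs)
    return scan, cofactors


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted q-values, boolean significance at level ``q``).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    sig, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, sig


def combine_caa(rda_records: list[CAARecord], gwas_table: pd.DataFrame | list,
                universe=None) -> tuple[list[CAARecord], dict]:
    """Union of the RDA and GWAS CAA sets with method labels.

    ``gwas_table`` may be a DataFrame of significant scan rows (columns
    ``snp``/``q_value``, optionally ``variable``) or a plain iterable of SNP
    ids.  Returns the merged records and the tally
    (n_rda, n_gwas, n_both, n_union).
    """
    rda_map = {r.snp_id: r for r in rda_records}
    if isinstance(gwas_table, pd.DataFrame):
        gwas_ids = list(dict.fromkeys(gwas_table["snp"].astype(str)))
        qmap = dict(zip(gwas_table["snp"].astype(str), gwas_table.get("q_value", np.nan)))
        vmap = (
            dict(zip(gwas_table["snp"].astype(str), gwas_table["variable"]))
            if "variable" in gwas_table
            else {}
        )
    else:
        gwas_ids = list(dict.fromkeys(str(s) for s in gwas_table))
        qmap, vmap = {}, {}
    if universe is not None:
        universe = set(universe)
        stray = (set(rda_map) | set(gwas_ids)) - universe
        if stray:
            raise ValueError(f"CAA ids outside the variant universe: {sorted(stray)[:5]}")
    merged: list[CAARecord] = []
    both = set(rda_map) & set(gwas_ids)
    for snp, rec in rda_map.items():
        rec.method = "both" if snp in both else "RDA"
        if snp in qmap:
            rec.fdr_q = float(qmap[snp])
        merged.append(rec)
    for snp in gwas_ids:
        if snp in rda_map:
            continue
        merged.append(
            CAARecord(
                snp_id=snp,
                method="GWAS",
                assigned_variable=vmap.get(snp),
                fdr_q=float(qmap[snp]) if snp in qmap else None,
            )
        )
    tally = {
        "n_rda": len(rda_map),
        "n_gwas": len(gwas_ids),
        "n_both": len(both),
        "n_union": len(merged),
    }
    return merged, tally
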