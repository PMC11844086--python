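"""Phenotype derivations: calibrated NDVI, heading-date deviation,
augmented-design BLUPs and heritability.

The vegetation index uses the band-calibrated form
NDVI = (1.236*NIR - 0.188*R) / (NIR + 0.044*R) on plot-mean pixel values.
DDTH is the control-mean days-to-heading minus the line value, so positive
values mean earlier heading than the checks.

BLUPs come from a one-random-effect linear mixed model
y = X b + Z u + e, u ~ N(0, sigma_g^2 I) over lines, with trial, check
status and low-order row/range polynomials as fixed effects.  REML is a
one-dimensional profile over the variance ratio lambda = sigma_g^2 /
sigma_e^2 through the spectral decomposition of Z Z', which is robust at
the sigma_g^2 -> 0 boundary.  h^2 = varG / (varG + varE) on a per-plot
basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["ndvi", "ddth", "BlupResult", "BlupModel", "fit_blup", "heritability",
           "exclude_low_h2_trials"]


def ndvi(nir_mean: float, red_mean: float) -> float:
    """Band-calibrated NDVI from plot-mean NIR and red pixel values."""
    denom = nir_mean + 0.044 * red_mean
    if denom == 0:
        raise ValueError("NIR + 0.044*R is zero; NDVI undefined")
    return (1.236 * nir_mean - 0.188 * red_mean) / denom


def ddth(dth_line: float, dth_controls) -> float:
    """Deviation in days to heading: mean(control DTH) - line DTH."""
    controls = np.asarray(dth_controls, dtype=float)
    if controls.size == 0:
        raise ValueError("need at least one control DTH value")
    return float(np.mean(controls) - dth_line)


def heritability(var_g: float, var_e: float) -> float:
    """h^2 = varG / (varG + varE)."""
    if var_g < 0 or var_e < 0:
        raise ValueError("variance components must be non-negative")
    if var_g + var_e == 0:
        raise ValueError("both variance components are zero")
    return var_g / (var_g + var_e)


@dataclass
class BlupResult:
    var_g: float
    var_e: float
    h2: float
    effects: pd.Series  # per-line predicted genetic effects (BLUPs)


class BlupModel:
    """One-random-effect REML / BLUP for augmented trial designs.

    Parameters
    ----------
    fixed : fixed-effect columns; "trial" expands to dummies, "is_check" to
        a 0/1 indicator, any other column is used as numeric.
    spatial_degree : degree of the row/range polynomial covariates
        (0 disables spatial adjustment).
    """

    def __init__(self, fixed=("trial", "is_check"), spatial_degree: int = 2):
        self.fixed = tuple(fixed)
        self.spatial_degree = spatial_degree

    def _design(self, plots: pd.DataFrame) -> np.ndarray:
        n = len(plots)
        cols = [np.ones(n)]
        for f in self.fixed:
            if f not in plots.columns:
                continue
            if f == "trial":
                for lvl in sorted(plots["trial"].astype(str).unique())[1:]:
                    cols.append((plots["trial"].astype(str) == lvl).to_numpy(float))
            else:
                v = plots[f].to_numpy(float)
                if np.std(v) > 0:
                    cols.append(v)
        if self.spatial_degree > 0:
            for axis in ("row", "range"):
                if axis not in plots.columns:
                    continue
                v = plots[axis].to_numpy(float)
                if np.std(v) == 0:
                    continue
                v = (v - v.mean()) / v.std()
                for deg in range(1, self.spatial_degree + 1):
                    cols.append(v**deg)
        X = np.column_stack(cols)
        # drop linearly dependent columns
        q, r = np.linalg.qr(X)
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r[0, 0]))
        return X[:, keep]

    def fit(self, plots: pd.DataFrame, trait: str, line_col: str = "line"):
        plots = plots.dropna(subset=[trait]).reset_index(drop=True)
        y = plots[trait].to_numpy(float)
        n = len(y)
        lines = plots[line_col].astype(str)
        levels = sorted(lines.unique())
        counts = lines.value_counts()
        if "trial" in plots.columns:
            replicated = (
                plots.groupby(line_col, observed=True)["trial"].nunique().max() > 1
            ) or counts.max() > 1
        else:
            replicated = counts.max() > 1
        if not replicated:
            raise ValueError(
                "no line is replicated anywhere; genetic variance unidentifiable"
            )
        Z = (lines.to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)
        X = self._design(plots)
        p = X.shape[1]
        # spectral decomposition of Z Z' drives the 1-D REML profile
        ZZt = Z @ Z.T
        d, U = np.linalg.eigh((ZZt + ZZt.T) / 2.0)
        d = np.clip(d, 0.0, None)
        yt = U.T @ y
        Xt = U.T @ X

        def neg_reml(log_lam: float) -> float:
            lam = np.exp(log_lam)
            w = 1.0 / (1.0 + lam * d)
            Xw = Xt * w[:, None]
            XtX = Xt.T @ Xw
            beta = np.linalg.solve(XtX, Xw.T @ yt)
            r = yt - Xt @ beta
            rss = float(r @ (w * r))
            s2 = rss / (n - p)
            return 0.5 * (
                (n - p) * np.log(s2)
                - np.sum(np.log(w))
                + np.linalg.slogdet(XtX)[1]
            )

        res = optimize.minimize_scalar(
            neg_reml, bounds=(np.log(1e-8), np.log(1e8)), method="bounded",
            options={"xatol": 1e-8},
        )
        lam = float(np.exp(res.x))
        # treat a boundary solution as varG = 0
        if lam <= 2e-8:
            lam = 0.0
        w = 1.0 / (1.0 + lam * d)
        Xw = Xt * w[:, None]
        beta = np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)
        r = yt - Xt @ beta
        var_e = float(r @ (w * r)) / (n - p)
        var_g = lam * var_e
        # BLUP: u = lam * Z' H^{-1} (y - X beta)
        hinv_r = U @ (w * r)
        u = lam * (Z.T @ hinv_r)
        self.var_g_ = var_g
        self.var_e_ = var_e
        self.h2_ = heritability(var_g, var_e) if var_g + var_e > 0 else 0.0
        self.effects_ = pd.Series(u, index=levels, name=trait)
        self.fixed_effects_ = beta
        return self

    def get_params(self, deep: bool = True) -> dict:
        return {"fixed": self.fixed, "spatial_degree": self.spatial_degree}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self


def fit_blup(
    plots: pd.DataFrame,
    trait: str,
    fixed=("trial", "is_check"),
    spatial_degree: int = 2,
    line_col: str = "line",
) -> BlupResult:
    """Fit the augmented-design mixed model and return variance components,
    heritability and per-line BLUPs."""
    m = BlupModel(fixed=fixed, spatial_degree=spatial_degree).fit(
        plots, trait, line_col=line_col
    )
    return BlupResult(var_g=m.var_g_, var_e=m.var_e_, h2=m.h2_, effects=m.effects_)


def exclude_low_h2_trials(
    plots: pd.DataFrame,
    trait: str,
    threshold: float = 0.2,
    line_col: str = "line",
) -> pd.DataFrame:
    """Drop trials whose within-trial heritability is below ``threshold``.

    Mirrors the practice of excluding low-heritability flights/blocks
    before estimating across-environment BLUPs.  Trials where the model
    cannot be fitted (no replication) are kept untouched.
    """
    kept = []
    for trial, grp in plots.groupby("trial", observed=True):
        try:
            res = fit_blup(grp, trait, fixed=("is_check",), spatial_degree=0,
                           line_col=line_col)
            if res.h2 >= threshold:
                kept.append(grp)
        except ValueError:
            kept.append(grp)
    if not kept:
        return plots.iloc[0:0]
    return pd.concat(kept, axis=0).reset_index(drop=True)
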