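"""End-to-end orchestration: simulate -> GWES -> introgression evaluation.

Each stage draws its randomness from a child seed derived deterministically
from the global seed and the stage name, so stages can be re-run in
isolation and a full re-run is byte-identical.  Every output file carries a
header with the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gea, introgression as intro, synthetic
from .genotypes import GenotypeMatrix, kinship, pca, prune_ld, read_vcf, write_vcf
from .ordination import fit_rda, forward_select, geography_predictors, varpart

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "derive_seed", "run_simulate", "run_gwes",
           "run_introgression_eval"]


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed (< 2^31)."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).hexdigest()
    return int(h, 16) % (2**31)


@dataclass
class PipelineConfig:
    # synthetic panel
    n_accessions: int = 150
    n_snps: int = 5000
    n_adaptive: int = 50
    adaptive_slope: float = 3.0
    spatial_range: float = 10.0
    n_lineages: int = 4
    fst: float = 0.15
    inbreeding: float = 0.98
    # pruning / scan universe
    window_bp: int = 50_000
    step_bp: int = 5_000
    r2_max: float = 0.5
    maf_min: float = 0.1
    # ordination / scan
    n_perm: int = 999
    alpha: float = 0.05
    n_axes: int = 3
    z_thresh: float = 3.0
    n_pcs: int = 3
    fdr_q: float = 0.05
    geo_mode: str = "pcoa"  # or "lonlat"
    # introgression population
    n_lines: int = 351
    n_donors: int = 21
    selfing_generations: int = 3
    n_trials: int = 2
    h2: float = 0.5
    n_qtl: int = 10
    qtl_effect: float = 1.0
    cm_per_chrom: float = 150.0
    percentile: float = 5.0
    min_traits: int = 2
    n_bins: int = 9
    fc_min: float = 2.0
    tail_traits: tuple = ("yield", "sns", "tgw", "ct")
    gwas_traits: tuple = ("yield", "ct")
    # input paths (optional; synthetic data is generated when absent)
    vcf: str | None = None
    env_table: str | None = None
    centromeres: str | None = None
    trait_table: str | None = None
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("tail_traits", "gwas_traits"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(cfg: PipelineConfig) -> str:
    return f"# gwescan config_hash={cfg.config_hash()} seed={cfg.seed}\n"


def _write_table(df: pd.DataFrame, path: Path, cfg: PipelineConfig, sep=",") -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep=sep, index=False, lineterminator="\n")


def _write_json(obj: dict, path: Path, cfg: PipelineConfig) -> None:
    obj = {"config_hash": cfg.config_hash(), "seed": cfg.seed, **obj}
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def _log_stage(stage: str, **counts) -> None:
    logger.info("stage=%s %s", stage, " ".join(f"{k}={v}" for k, v in counts.items()))


def _rank_conditional_r2(Y: np.ndarray, candidates: pd.DataFrame, condition) -> list:
    """Candidate variables ranked by partial R^2 given the condition."""
    from .ordination import _as_2d, _orthonormal_basis, _residualize

    Yc = Y - Y.mean(axis=0)
    Z = _as_2d(condition)
    Qz = _orthonormal_basis(Z - Z.mean(axis=0))
    Yr = _residualize(Yc, Qz)
    gains = {}
    for col in candidates.columns:
        x = _residualize(
            _as_2d(candidates[col].to_numpy(float) - candidates[col].mean()), Qz
        )
        nrm = np.linalg.norm(x)
        if nrm == 0:
            continue
        q = x / nrm
        gains[col] = float(np.sum((q.T @ Yr) ** 2))
    return sorted(gains, key=gains.get, reverse=True)


def run_simulate(cfg: PipelineConfig, outdir):
    """Generate the synthetic panel and write VCF + CSV artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lc = synthetic.LandscapeConfig(
        n_accessions=cfg.n_accessions,
        n_snps=cfg.n_snps,
        n_adaptive=cfg.n_adaptive,
        adaptive_slope=cfg.adaptive_slope,
        spatial_range=cfg.spatial_range,
        n_lineages=cfg.n_lineages,
        fst=cfg.fst,
        inbreeding=cfg.inbreeding,
        seed=derive_seed(cfg.seed, "panel"),
    )
    coords, env, G, truth = synthetic.simulate_panel(lc)
    write_vcf(G, outdir / "panel.vcf")
    _write_table(env.reset_index(), outdir / "env.csv", cfg)
    _write_table(coords.reset_index(), outdir / "coords.csv", cfg)
    ids = G.variant_ids
    truth_df = pd.DataFrame(
        [(ids[i], var, slope) for i, var, slope in truth.adaptive_loci],
        columns=["snp", "driving_variable", "slope"],
    )
    _write_table(truth_df, outdir / "truth.csv", cfg)
    _log_stage("simulate", accessions=G.n_samples, snps=G.n_variants,
               adaptive=len(truth.adaptive_loci))
    return coords, env, G, truth


def run_gwes(cfg: PipelineConfig, outdir, panel=None):
    """Prune -> varpart -> forward selection -> RDA scan -> MLM GEA -> combine.

    ``panel`` may be the (coords, env, G, truth) tuple from
    :func:`run_simulate`; otherwise inputs are read from the configured
    paths (or simulated afresh when none are given).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if panel is not None:
        coords, env, G, _ = panel
    elif cfg.vcf and cfg.env_table:
        G = read_vcf(cfg.vcf)
        env = pd.read_csv(cfg.env_table, comment="#").set_index("sample")
        coords = env[["lon", "lat"]].copy()
    else:
        coords, env, G, _ = run_simulate(cfg, outdir)
    if list(env.index) != list(G.samples):
        missing = sorted(set(G.samples) ^ set(env.index))
        raise ValueError(f"sample ids of genotypes and env table differ: {missing[:10]}")

    kept = prune_ld(G, window_bp=cfg.window_bp, step_bp=cfg.step_bp, r2_max=cfg.r2_max)
    Gp = G.subset_variants(kept)
    _log_stage("prune", before=G.n_variants, after=Gp.n_variants)

    Y = Gp.imputed()
    Y = Y - Y.mean(axis=0)
    climate_cols = [c for c in env.columns if synthetic.is_climate_variable(c)]
    X_clim = env[climate_cols].to_numpy(float)
    if cfg.geo_mode == "pcoa":
        X_geo = geography_predictors(coords["lon"].to_numpy(), coords["lat"].to_numpy())
    else:
        X_geo = coords[["lon", "lat"]].to_numpy(float)
    vp = varpart(Y, X_clim, X_geo)
    _write_json(
        {
            "climate_unique": vp.a,
            "shared": vp.b,
            "geography_unique": vp.c,
            "residual": vp.d,
            "adj_r2_full": vp.adj_r2_full,
            "adj_r2_climate": vp.adj_r2_block1,
            "adj_r2_geography": vp.adj_r2_block2,
        },
        outdir / "varpart.json",
        cfg,
    )
    _log_stage("varpart", climate=round(vp.a, 4), geo=round(vp.c, 4))

    fs = forward_select(
        Y,
        env,
        alpha=cfg.alpha,
        n_perm=cfg.n_perm,
        seed=derive_seed(cfg.seed, "forward"),
    )
    _write_table(fs.to_frame(), outdir / "forward_selection.csv", cfg)
    _log_stage("forward_select", selected=len(fs.selected), reason=fs.stopping_reason)

    # scan universe: common variants only (rare, near-fixed SNPs carry no
    # usable climate signal and have heavy-tailed loadings)
    from .genotypes import allele_frequency, infer_lineages, lineage_dummies

    freq = allele_frequency(Gp)
    maf = np.minimum(freq, 1.0 - freq)
    scan_ids = [v for v, m in zip(Gp.variant_ids, maf) if m >= cfg.maf_min]
    Gs = Gp.subset_variants(scan_ids)
    Ys = Gs.imputed()
    Ys = Ys - Ys.mean(axis=0)
    labels = infer_lineages(Gp, cfg.n_lineages, n_pcs=cfg.n_pcs)
    D = lineage_dummies(labels)
    # scan model: climate predictors chosen by forward selection conditioned
    # on lineage structure (partial RDA), topped up to n_axes if needed
    scan_fs = forward_select(
        Ys,
        env[climate_cols],
        alpha=cfg.alpha,
        n_perm=cfg.n_perm,
        seed=derive_seed(cfg.seed, "scan_forward"),
        condition=D,
    )
    scan_vars = list(scan_fs.selected)
    if len(scan_vars) < cfg.n_axes:
        ranked = _rank_conditional_r2(Ys, env[climate_cols], D)
        for var in ranked:
            if var not in scan_vars:
                scan_vars.append(var)
            if len(scan_vars) >= cfg.n_axes:
                break
    rda = fit_rda(Ys, env[scan_vars], condition=D)
    outliers, zmap = gea.rda_outliers(
        rda, n_axes=cfg.n_axes, z_thresh=cfg.z_thresh,
        snp_ids=Gs.variant_ids, return_z=True,
    )
    rda_records = gea.assign_variable(outliers, Gs, env, max_abs_z=zmap)
    _log_stage("rda_scan", scan_snps=Gs.n_variants, outliers=len(outliers))

    K = kinship(Gp)
    pcs, _ = pca(Gp, cfg.n_pcs)
    gwas_rows = []
    for var in env.columns:
        y = env[var].to_numpy(float)
        if np.std(y) == 0:
            continue
        res = gea.mlm_gwas(y, Gs, K, n_pcs=cfg.n_pcs, pcs=pcs)
        sig = res[res["q_value"] <= cfg.fdr_q].copy()
        sig["variable"] = var
        gwas_rows.append(sig)
    gwas_sig = (
        pd.concat(gwas_rows, ignore_index=True)
        if gwas_rows
        else pd.DataFrame(columns=["snp", "variable", "q_value"])
    )
    # keep each GWAS SNP once, at its most significant variable
    if len(gwas_sig):
        gwas_sig = gwas_sig.sort_values(["q_value", "snp"], kind="stable")
        gwas_sig = gwas_sig.drop_duplicates("snp", keep="first")
        gwas_sig = gwas_sig.sort_values(["snp"], kind="stable")
    _log_stage("mlm_gea", snps=len(gwas_sig))

    records, tally = gea.combine_caa(rda_records, gwas_sig, universe=Gs.variant_ids)
    meta = {v.id: v for v in Gs.variants}
    caa = pd.DataFrame(
        [
            {
                "snp": r.snp_id,
                "chrom": meta[r.snp_id].chrom,
                "pos": meta[r.snp_id].pos,
                "method": r.method,
                "variable": r.assigned_variable,
                "r": r.pearson_r,
                "z": r.max_abs_z,
                "q": r.fdr_q,
            }
            for r in records
        ]
    ).sort_values(["chrom", "pos"], kind="stable")
    _write_table(caa, outdir / "caa.tsv", cfg, sep="\t")
    _write_json(tally, outdir / "caa_tally.json", cfg)
    _log_stage("combine", **tally)
    return {
        "caa": caa,
        "tally": tally,
        "varpart": vp,
        "forward_selection": fs,
        "pruned": Gp,
        "rda": rda,
        "env": env,
        "coords": coords,
    }


def run_introgression_eval(cfg: PipelineConfig, outdir, gwes_result=None, caa_table=None):
    """Tail selection -> spectra/KS -> FC sets -> arm bins -> trait GWAS -> CT regression."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if caa_table is None:
        if gwes_result is not None:
            caa_table = gwes_result["caa"]
        else:
            caa_path = Path(outdir) / "caa.tsv"
            if not caa_path.exists():
                raise FileNotFoundError("no CAA table: run the gwes stage first")
            caa_table = pd.read_csv(caa_path, sep="\t", comment="#")
    if gwes_result is not None:
        Gp = gwes_result["pruned"]
    elif cfg.vcf:
        Gp = read_vcf(cfg.vcf)
    else:
        raise ValueError("need genotypes (gwes result or vcf path)")

    caa_ids = [s for s in caa_table["snp"].astype(str) if s in set(Gp.variant_ids)]
    if not caa_ids:
        raise ValueError(
            f"CAA/introgression SNP universes disjoint: {len(caa_table)} CAAs, "
            f"{Gp.n_variants} population SNPs, intersection 0"
        )

    # simulate the introgression population on the panel SNP universe
    donors = list(Gp.samples[: cfg.n_donors])
    recurrents = [f"cultivar{i + 1}" for i in range(6)]
    gmap = synthetic.uniform_genetic_map(Gp, cm_per_chrom=cfg.cm_per_chrom)
    pop = synthetic.simulate_introgression_population(
        donors,
        recurrents,
        cfg.n_lines,
        gmap,
        G=Gp,
        selfing_generations=cfg.selfing_generations,
        seed=derive_seed(cfg.seed, "introgression"),
    )
    qtl_rng = np.random.default_rng(derive_seed(cfg.seed, "qtl"))
    n_qtl = min(cfg.n_qtl, len(caa_ids))
    qtl_snps = list(qtl_rng.choice(caa_ids, size=n_qtl, replace=False))
    qtl = [(s, "yield", cfg.qtl_effect) for s in qtl_snps]
    qtl += [(s, "ct", -0.5 * cfg.qtl_effect) for s in qtl_snps[: n_qtl // 2]]
    traits = synthetic.simulate_phenotypes(
        pop,
        qtl=qtl,
        h2_target=cfg.h2,
        n_trials=cfg.n_trials,
        seed=derive_seed(cfg.seed, "phenotypes"),
    )
    _write_table(traits, outdir / "plot_traits.csv", cfg)
    _log_stage("introgression_sim", lines=cfg.n_lines, qtl=len(qtl))

    line_means = traits.groupby("line", observed=True)[
        list(synthetic.DEFAULT_TRAITS)
    ].mean().reset_index()
    tails = intro.select_tail_lines(
        line_means,
        traits=list(cfg.tail_traits),
        percentile=cfg.percentile,
        min_traits=cfg.min_traits,
    )
    _write_json(
        {"lower": tails.lower, "upper": tails.upper, "traits": list(cfg.tail_traits)},
        outdir / "tails.json",
        cfg,
    )
    _log_stage("tails", lower=len(tails.lower), upper=len(tails.upper))

    Gi = pop.marker_genotypes.subset_variants(caa_ids)
    freq_wp = Gi.dosage.mean(axis=0) / 2.0
    row_of = {l: i for i, l in enumerate(Gi.samples)}
    spec_rng = np.random.default_rng(derive_seed(cfg.seed, "spectrum"))
    summary: dict = {}
    spectra_rows = []
    fc_frames = {}
    for name, lines in (("lower", tails.lower), ("upper", tails.upper)):
        if not lines:
            continue
        freq_tail = Gi.dosage[[row_of[l] for l in lines]].mean(axis=0) / 2.0
        spec, perm_p = intro.tail_spectrum_test(
            Gi.dosage, [row_of[l] for l in lines], n_bins=cfg.n_bins,
            rng=spec_rng,
        )
        summary[f"ks_d_{name}"] = spec.ks_d
        summary[f"ks_p_{name}"] = perm_p
        for b in range(cfg.n_bins):
            spectra_rows.append(
                {
                    "tail": name,
                    "bin_low": spec.bin_edges[b],
                    "bin_high": spec.bin_edges[b + 1],
                    "wp": spec.wp_proportions[b],
                    "tail_prop": spec.tail_proportions[b],
                }
            )
        fc = intro.fc_differentiation(
            freq_tail, freq_wp, fc_min=cfg.fc_min, n_lines=len(lines),
            snp_ids=Gi.variant_ids,
        )
        fc_frames[name] = fc
        _write_table(fc, outdir / f"fc_{name}.tsv", cfg, sep="\t")
    _write_table(pd.DataFrame(spectra_rows), outdir / "spectra.csv", cfg)

    # arm bins of differentiated CAAs (both tails pooled)
    diff_ids = sorted(
        set().union(
            *[set(fc[fc["differentiated"]]["snp"]) for fc in fc_frames.values()]
        )
    ) if fc_frames else []
    meta = {v.id: v for v in Gi.variants}
    if diff_ids:
        snp_tab = pd.DataFrame(
            {
                "snp": diff_ids,
                "chrom": [meta[s].chrom for s in diff_ids],
                "pos": [meta[s].pos for s in diff_ids],
            }
        )
        if cfg.centromeres:
            chrom_tab = pd.read_csv(cfg.centromeres, sep="\t", comment="#")
        else:
            chrom_tab = pd.DataFrame(
                [
                    {
                        "chrom": c,
                        "length": int(Gp.positions()[Gp.chroms() == c].max()),
                        "centromere_pos": int(Gp.positions()[Gp.chroms() == c].max() // 2),
                    }
                    for c in dict.fromkeys(Gp.chroms().tolist())
                ]
            )
        bins = intro.arm_bin_counts(snp_tab, chrom_tab, G=Gi, dedup_r2=cfg.r2_max,
                                    window_bp=cfg.window_bp, step_bp=cfg.step_bp)
        summary["arm_bin_counts"] = bins.totals.tolist()
    _log_stage("fc_bins", differentiated=len(diff_ids))

    K = kinship(pop.genotypes)
    gwas_out = {}
    for trait in cfg.gwas_traits:
        scan = intro.caa_trait_gwas(pop, trait, caa_ids, n_pcs=cfg.n_pcs, K=K)
        _write_table(scan, outdir / f"gwas_{trait}.tsv", cfg, sep="\t")
        gwas_out[trait] = scan
        summary[f"gwas_{trait}_sig"] = int((scan["q_value"] <= cfg.fdr_q).sum())
    slope, icept, r, r2 = intro.regress_trait_on_ct(
        line_means["yield"].to_numpy(), line_means["ct"].to_numpy()
    )
    summary.update(
        {"ct_yield_slope": slope, "ct_yield_r": r, "ct_yield_r2": r2,
         "mean_donor_fraction": float(pop.donor_fraction().mean())}
    )
    _write_json(summary, outdir / "introgression_summary.json", cfg)
    _log_stage("introgression_eval", **{k: round(v, 3) for k, v in summary.items()
                                        if isinstance(v, float)})
    return {"pop": pop, "tails": tails, "summary": summary, "gwas": gwas_out,
            "fc": fc_frames, "qtl": qtl}
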