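"""End-to-end pipeline driver: inputs -> calibration -> fits -> stats -> progression.

The pipeline mirrors the study design the package emulates: synthetic (or
user-supplied) structural connectome, atrophy map and cohort; baseline FIC
calibration; per-YWD-stratum sigma fits against FC targets; regression /
ANCOVA / Levene / FDR statistics on the fitted values; and the model-based
FC-vs-YWD progression map with RSN overlap scores. Every stage derives its
seed from the master seed and the stage name, so reruns with the same
config produce byte-identical outputs. A manifest lists every file written
plus all parameters and seeds.
"""

from __future__ import annotations

import os
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seeds import derive_seed
from .dmf import DMFParameters, calibrate_fic
from .errors import ConfigError
from .fitting import FitConfig, fit_sigma
from .hemodynamics import BWParameters
from .io import read_matrix, read_table, write_matrix, write_table, write_vector
from .progression import default_rsn_masks, fc_vs_ywd, node_scores, read_rsn_masks, rsn_overlap, threshold_edges
from .similarity import SSIMConfig
from .stats import ancova, cohens_d, levene, regress, ttests_fdr
from .synthetic import SyntheticConfig, gen_atrophy_map, gen_cohort, gen_connectome, gen_empirical_fc, write_manifest

__all__ = ["load_config", "run_pipeline"]

_BLOCKS = ("dmf", "bw", "ssim", "fit", "synthetic", "progression", "paths")


def load_config(source) -> dict:
    """Load a pipeline config from a YAML path or pass a dict through."""
    if isinstance(source, dict):
        cfg = dict(source)
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise ConfigError(f"{source}: config must be a mapping")
    unknown = set(cfg) - set(_BLOCKS) - {"seed", "out_dir"}
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def _build(cls, block: dict | None, **overrides):
    block = dict(block or {})
    block.update(overrides)
    valid = {f for f in cls.__dataclass_fields__}
    unknown = set(block) - valid
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**block)


def run_pipeline(config, out_dir: str | os.PathLike | None = None) -> dict:
    """Execute the full pipeline and write all declared outputs.

    Returns a dict with the in-memory results (calibration, per-stratum
    fits, statistics tables, progression map, RSN overlaps) and the list of
    files written.
    """
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", "dmfit_out"))

    paths = cfg.get("paths") or {}
    synth_block = cfg.get("synthetic")
    if synth_block is None and not paths:
        raise ConfigError("config needs either a 'synthetic' block or input 'paths'")
    # fail on missing inputs before any computation
    for key in ("connectome", "atrophy", "cohort", "target_fc", "rsn_masks"):
        p = paths.get(key)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"input file for '{key}' does not exist: {p}")

    params = _build(DMFParameters, cfg.get("dmf"))
    params.validate()
    bw = _build(BWParameters, cfg.get("bw"))
    ssim_cfg = _build(SSIMConfig, cfg.get("ssim"))
    fit_cfg = _build(FitConfig, cfg.get("fit"), seed=derive_seed(seed, "fit"))
    prog_block = dict(cfg.get("progression") or {})
    n_runs = int(prog_block.get("n_runs", 10))

    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def _write(writer, obj, name, **kw):
        path = out / name
        writer(obj, path, **kw)
        files.append(name)
        return path

    # ------------------------------------------------------------------ inputs
    if synth_block is not None:
        synth_block = dict(synth_block)
        group = synth_block.pop("group", "AD")
        n_per_cell = synth_block.pop("n_per_cell", 10)
        n_strata = int(synth_block.pop("n_strata", 4))
        scfg = _build(SyntheticConfig, synth_block, seed=derive_seed(seed, "synth"))
        connectome = gen_connectome(scfg)
        atrophy = gen_atrophy_map(scfg, group)
        cohort = gen_cohort(scfg, n_per_cell)
        _write(write_matrix, connectome.C, "connectome.csv",
               header="synthetic structural connectome; max entry 0.2")
        _write(write_vector, atrophy.alpha, "atrophy.csv",
               header=f"synthetic atrophy map, group {group}; positive-is-atrophy")
        _write(write_table, cohort, "cohort.csv")
    else:
        for key in ("connectome", "atrophy", "cohort"):
            if key not in paths:
                raise ConfigError(f"paths block must name '{key}' when no synthetic block is given")
        from .dmf import AtrophyMap, StructuralConnectome

        connectome = StructuralConnectome(C=read_matrix(paths["connectome"]))
        connectome.validate()
        atrophy = AtrophyMap(alpha=read_matrix(paths["atrophy"]).ravel())
        cohort = read_table(paths["cohort"])
        group = synth_block["group"] if synth_block else str(cfg.get("group", "AD"))
        scfg = None
        n_strata = int(prog_block.get("n_strata", 4))

    if paths.get("rsn_masks"):
        masks = read_rsn_masks(paths["rsn_masks"])
    else:
        masks = {k: [i for i in v if i < connectome.n_regions] for k, v in default_rsn_masks().items()}
        masks = {k: v for k, v in masks.items() if v}

    # -------------------------------------------------------------- calibration
    J0 = calibrate_fic(params, connectome, seed=derive_seed(seed, "calibrate"))
    _write(write_vector, J0.J0, "fic_baseline.csv", header="calibrated baseline FIC J0, nA")

    # -------------------------------------------------------- per-stratum fits
    patients = cohort[cohort["group"] != "HC"]
    if synth_block is not None:
        patients = patients[patients["group"] == group]
    if len(patients) < n_strata:
        raise ConfigError(f"only {len(patients)} patients for {n_strata} YWD strata")
    bins = pd.qcut(patients["ywd"], q=n_strata, duplicates="drop")
    fit_rows = []
    sigma_by_ywd = {}
    for k, (interval, sub) in enumerate(patients.groupby(bins, observed=True)):
        ywd_c = float(sub["ywd"].mean())
        if synth_block is not None:
            target = gen_empirical_fc(
                connectome, atrophy, float(sub["sigma_true"].mean()), params,
                seed=derive_seed(seed, "target", k), noise_sd=scfg.noise_sd, J0=J0, bw=bw,
            )
        else:
            if "target_fc" not in paths:
                raise ConfigError("paths block must name 'target_fc' when no synthetic block is given")
            from .similarity import FCMatrix

            target = FCMatrix(values=read_matrix(paths["target_fc"]))
        stratum_cfg = _build(
            FitConfig, asdict(fit_cfg), seed=derive_seed(seed, "fit", k)
        )
        res = fit_sigma(target, connectome, atrophy, J0, params, stratum_cfg, bw=bw, ssim_cfg=ssim_cfg)
        fit_rows.append({
            "stratum": k, "ywd": ywd_c, "n_subjects": len(sub),
            "sigma_hat": res.sigma_hat, "objective": res.objective_mean,
        })
        sigma_by_ywd[ywd_c] = res.sigma_hat
    fits = pd.DataFrame(fit_rows)
    _write(write_table, fits, "fitted_sigma.csv")

    # -------------------------------------------------------------- statistics
    stat_rows = []
    if len(fits) >= 3 and fits["ywd"].nunique() >= 3:
        reg = regress(fits["sigma_hat"], fits["ywd"])
        stat_rows.append({"analysis": "regress_sigma_vs_ywd", "term": "ywd",
                          "statistic": reg.R, "p_raw": reg.p, "p_adjusted": reg.p,
                          "effect_size": reg.eta_p2})
    pat = cohort[cohort["group"] != "HC"]
    if pat["gender"].nunique() == 2 and (pat["gender"].value_counts() >= 2).all():
        anc = ancova(pat["sigma_true"], pat["gender"], pat["ywd"])
        for _, row in anc.iterrows():
            stat_rows.append({"analysis": "ancova_gender_ywd", "term": row["term"],
                              "statistic": row["F"], "p_raw": row["p"],
                              "p_adjusted": row["p"], "effect_size": row["eta_p2"]})
    site_groups = [g["sigma_true"].to_numpy() for _, g in pat.groupby("site") if len(g) >= 2]
    if len(site_groups) >= 2:
        lev = levene(*site_groups)
        stat_rows.append({"analysis": "levene_site_spread", "term": "site",
                          "statistic": lev.statistic, "p_raw": lev.p_raw,
                          "p_adjusted": lev.p_adjusted, "effect_size": np.nan})
    by_group = {g: d["sigma_true"].to_numpy() for g, d in cohort.groupby("group") if len(d) >= 2}
    pairs = [(a, b) for i, a in enumerate(sorted(by_group)) for b in sorted(by_group)[i + 1:]]
    if pairs:
        tt = ttests_fdr(by_group, pairs)
        for _, row in tt.iterrows():
            stat_rows.append({"analysis": "ttest_groups", "term": f"{row['a']}_vs_{row['b']}",
                              "statistic": row["statistic"], "p_raw": row["p_raw"],
                              "p_adjusted": row["p_adjusted"],
                              "effect_size": cohens_d(by_group[row["a"]], by_group[row["b"]])})
    stats_df = pd.DataFrame(stat_rows)
    _write(write_table, stats_df, "stats.csv")

    # -------------------------------------------------------------- progression
    prog = None
    overlaps = {}
    if len(sigma_by_ywd) >= 3:
        prog = fc_vs_ywd(sigma_by_ywd, connectome, atrophy, J0, params,
                         n_runs=n_runs, seed=derive_seed(seed, "progression"), bw=bw)
        _write(write_matrix, prog.rho, "progression_rho.csv",
               header="mean Spearman correlation of FC entries vs YWD")
        edges = threshold_edges(prog, 0.05, sign="negative")
        edge_df = pd.DataFrame({
            "i": edges[:, 0], "j": edges[:, 1],
            "rho": prog.rho[edges[:, 0], edges[:, 1]],
        })
        _write(write_table, edge_df, "top_negative_edges.csv")
        neg = node_scores(prog, "negative")
        pos = node_scores(prog, "positive")
        _write(write_matrix, np.column_stack([neg, pos]), "node_scores.csv",
               header="columns: negative_score, positive_score")
        ov_neg = rsn_overlap(neg, masks, select="smallest")
        ov_pos = rsn_overlap(pos, masks, select="largest")
        overlaps = {"negative": ov_neg, "positive": ov_pos}
        radar = pd.DataFrame(
            [{"network": k, "sign": s, "jaccard": v}
             for s, d in overlaps.items() for k, v in d.items()]
        )
        _write(write_table, radar, "rsn_jaccard.csv")

    # ----------------------------------------------------------------- manifest
    manifest = {"seed": seed}
    for block_name, obj in (("dmf", params), ("bw", bw), ("ssim", ssim_cfg), ("fit", fit_cfg)):
        for key, val in asdict(obj).items():
            manifest[f"{block_name}.{key}"] = val
    if synth_block is not None:
        for key, val in asdict(scfg).items():
            manifest[f"synthetic.{key}"] = val
        manifest["synthetic.group"] = group
        manifest["synthetic.n_strata"] = n_strata
    manifest["progression.n_runs"] = n_runs
    for k, name in enumerate(sorted(files)):
        manifest[f"output.{k}"] = name
    write_manifest(out / "manifest.txt", manifest)
    files.append("manifest.txt")

    return {
        "out_dir": str(out),
        "files": files,
        "J0": J0,
        "fits": fits,
        "stats": stats_df,
        "progression": prog,
        "rsn_overlap": overlaps,
    }
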