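"""End-to-end pipeline: simulate -> estimate -> prep -> analyses -> report.

Stages communicate via files in the output directory so any stage can be
re-run and inspected; the report aggregates discovery counts, the admixture
threshold, heritability estimates, and mito-nuclear results. Identical
configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import admixture, assoc, copynumber, heritability, io, mitonuclear, pheno, simulate
from ._util import ConfigError, substreams

logger = logging.getLogger(__name__)

DEFAULTS = {
    "outdir": "mtcnkit_out",
    "seed": 0,
    "n_individuals": 2000,
    "stages": {
        "simulate": True,
        "estimate": True,
        "pheno": True,
        "phewas": True,
        "admixmap": True,
        "heritability": True,
        "mitonuclear": True,
    },
    "simulate": {
        "haplogroup_freq_african": 0.8,
        "ancestry_mean": 0.8,
        "ancestry_sd": 0.1,
        "generations_since_admixture": 8,
        "n_chromosomes": 3,
        "markers_per_chromosome": 150,
        "n_depth_sites": 16569,
        "autosomal_mean_depth": 2.8,
        "spike_multiplier": 3.0,
        "h2_target": 0.3,
        "n_binary_traits": 20,
        "n_quant_traits": 5,
        "prevalence": 0.1,
    },
    "thresholds": {
        "min_cases": 20,
        "trim_sd": 7.0,
        "fdr": [0.005, 0.05],
        "posterior_min": 0.9,
        "clump_p": 0.05,
        "clump_window": 1000000,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for k, v in override.items():
        if k not in base:
            raise ConfigError(f"unknown configuration key {path + k!r}")
        if isinstance(base[k], dict):
            if not isinstance(v, dict):
                raise ConfigError(f"key {path + k!r} must be a mapping")
            out[k] = _merge(base[k], v, path + k + ".")
        else:
            out[k] = v
    return out


def validate_config(config: dict | str | Path | None = None) -> dict:
    """Fill defaults, reject unknown keys, resolve paths.

    ``config`` may be a mapping, a path to a YAML file, or None (all
    defaults). Relative output paths are resolved against the config file's
    directory when one is given.
    """
    base_dir = Path.cwd()
    if config is None:
        config = {}
    elif isinstance(config, (str, Path)):
        p = Path(config)
        base_dir = p.parent.resolve()
        with open(p) as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ConfigError("configuration must be a mapping")
    merged = _merge(DEFAULTS, config)
    outdir = Path(merged["outdir"])
    if not outdir.is_absolute():
        outdir = base_dir / outdir
    merged["outdir"] = str(outdir)
    return merged


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: dict | str | Path | None = None) -> dict:
    """Execute the enabled stages in dependency order; returns the report."""
    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    th = cfg["thresholds"]
    sc = cfg["simulate"]
    rngs = substreams(cfg["seed"], 8)
    report: dict = {"config_hash": config_hash(cfg), "seed": cfg["seed"],
                    "n_individuals": cfg["n_individuals"], "stages_run": []}

    def stage(name):
        enabled = stages[name]
        if enabled:
            report["stages_run"].append(name)
            logger.info("stage %s starting", name)
        return enabled

    t0 = time.time()
    if not stage("simulate"):
        return report

    sim_cfg = simulate.SimulationConfig(
        n_individuals=cfg["n_individuals"], seed=cfg["seed"],
        haplogroup_freq_african=sc["haplogroup_freq_african"],
        ancestry_distribution=(sc["ancestry_mean"], sc["ancestry_sd"]),
        generations_since_admixture=sc["generations_since_admixture"],
    )
    cohort = simulate.simulate_cohort(sim_cfg)
    io.write_table(cohort, outdir / "cohort.tsv")

    marker_map = simulate.uniform_marker_map(sc["n_chromosomes"],
                                             sc["markers_per_chromosome"])
    local = simulate.simulate_local_ancestry(cohort, marker_map, sim_cfg,
                                             seed=int(rngs[0].integers(2**31)))
    io.write_local_ancestry(local, outdir / "local_ancestry.tsv")

    freqs = np.column_stack([
        rngs[1].uniform(0.05, 0.95, local.n_markers),
        rngs[1].uniform(0.05, 0.95, local.n_markers),
    ])
    genotypes = simulate.simulate_genotypes(local, freqs,
                                            seed=int(rngs[2].integers(2**31)))
    io.write_genotypes_tsv(genotypes, outdir / "genotypes.tsv")

    true_lrmtcn = simulate.simulate_copy_number(
        cohort, h2_target=sc["h2_target"], genotypes=genotypes,
        seed=int(rngs[3].integers(2**31)))
    coverage = simulate.CoverageConfig(
        autosomal_mean_depth=sc["autosomal_mean_depth"],
        spike_multiplier=sc["spike_multiplier"], n_sites=sc["n_depth_sites"])
    profiles = simulate.simulate_depth(true_lrmtcn, coverage,
                                       seed=int(rngs[4].integers(2**31)),
                                       individual_ids=cohort["individual_id"].to_numpy())

    if not stage("estimate"):
        return report
    spike = (copynumber.SPIKE_REGION if sc["n_depth_sites"] >= copynumber.SPIKE_REGION[1]
             else None)
    records = copynumber.estimate_cohort(profiles, spike_region=spike)
    records = copynumber.residualize(records, cohort, model="full")
    records = copynumber.standardize(records)
    io.write_table(records, outdir / "copy_number.tsv")
    rl = records["rlrmtcn"].to_numpy()
    report["mean_rmtcn"] = float(records["rmtcn"].mean())

    specs = ([simulate.TraitSpec(f"phecode_{i:03d}", "binary",
                                 prevalence=sc["prevalence"])
              for i in range(sc["n_binary_traits"])]
             + [simulate.TraitSpec(f"lab_{i:02d}", "quantitative")
                for i in range(sc["n_quant_traits"])])
    # plant one copy-number-dependent trait of each kind
    specs[0].beta_rlrmtcn = 0.4
    specs[sc["n_binary_traits"]].beta_rlrmtcn = 0.4
    counts, labs = simulate.simulate_phenotypes(cohort, rl, specs,
                                                seed=int(rngs[5].integers(2**31)))
    io.write_table(counts, outdir / "phecode_counts.tsv", index=True)
    io.write_table(labs, outdir / "labs.tsv")

    if not stage("pheno"):
        return report
    status = pheno.assign_case_control(counts)
    kept = pheno.filter_phecodes(status, min_cases=th["min_cases"])
    status = status[kept]
    prepared = pheno.prepare_labs(labs, cohort, trim_sd=th["trim_sd"])
    lab_wide = prepared.pivot_table(index="individual_id", columns="lab",
                                    values="transformed").reindex(
        cohort["individual_id"])
    report["n_phecodes_retained"] = len(kept)

    covars = np.column_stack(
        [cohort["sex"], cohort["age"], cohort["age"] ** 2]
        + [cohort[f"pc{k}"] for k in range(1, 21)])

    if stage("phewas"):
        scan = assoc.run_phewas(rl, status, lab_wide, covariates=covars,
                                min_cases=th["min_cases"], fdr_levels=tuple(th["fdr"]))
        io.write_table(scan, outdir / "phewas.tsv")
        for q in th["fdr"]:
            report[f"phewas_discoveries_fdr_{q}"] = int(scan[f"fdr_{q}"].sum())

    if stage("admixmap"):
        gfrac = admixture.global_ancestry(local, th["posterior_min"])
        amap = admixture.local_ancestry_assoc(
            rl, local, gfrac, cohort["duffy_genotype"].to_numpy(),
            posterior_min=th["posterior_min"])
        eff = admixture.effective_tests(local, posterior_min=th["posterior_min"])
        io.write_table(amap, outdir / "admixture_mapping.tsv")
        pd.DataFrame([{"n_eff": eff["n_eff"], "threshold": eff["threshold"]}]).to_csv(
            outdir / "admixture_threshold.tsv", sep="\t", index=False)
        report["admixture_n_eff"] = eff["n_eff"]
        report["admixture_threshold"] = eff["threshold"]
        clumped = assoc.clump_hits(amap.dropna(subset=["p"]),
                                   p_thresh=th["clump_p"], window=th["clump_window"])
        report["admixture_clumped_loci"] = int(len(clumped))

    if stage("heritability"):
        grm = heritability.build_grm(genotypes)
        est = heritability.estimate_h2_he(rl, grm, covariates=covars,
                                          covariate_set="sex+age+age2+20PCs")
        report["h2_he"] = est.h2
        report["h2_he_se"] = est.se

    if stage("mitonuclear"):
        ok = cohort["mt_origin"].isin(["African", "European"]).to_numpy()
        z = cohort.loc[ok, "african_ancestry"].to_numpy()
        x = mitonuclear.haplogroup_code(cohort.loc[ok, "mt_origin"].to_numpy())
        cov3 = np.column_stack([cohort.loc[ok, "sex"], cohort.loc[ok, "age"],
                                cohort.loc[ok, "age"] ** 2])
        mn = mitonuclear.run_mitonuclear_phewas(
            status[ok].reset_index(drop=True) if len(status.columns) else None,
            lab_wide[ok].reset_index(drop=True),
            z, x, covariates=cov3, min_cases=th["min_cases"],
            fdr_levels=tuple(th["fdr"]))
        io.write_table(mn, outdir / "mitonuclear_phewas.tsv")
        if not mn.empty:
            inter = mn[mn["term"] == "z_x"]
            report["mitonuclear_interaction_discoveries"] = int(
                inter[f"fdr_{th['fdr'][1]}"].sum())

    report["runtime_s"] = round(time.time() - t0, 2)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
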