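"""End-to-end orchestration: QC -> association -> meta -> shrinkage ->
risk scores -> discrimination -> adiposity strata, with a run manifest.

A run is configured either with input paths (genotype/phenotype tables) or
with a simulation block; one seed drives every random draw so identical
configs give byte-identical numeric outputs. Every file written is listed
in the manifest with its SHA-256 checksum, and each stage logs record
counts in and out of its filters.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import panel
from .association import association_scan, adjust_pvalues, build_covariates
from .core import GenotypeMatrix
from .discrimination import c_statistic, delong_test
from .grs import (GrsDefinition, WeightScheme, compute_grs,
                  impute_missing_by_centre_mean, quartile_association)
from .meta import pool_summary_frame
from .qc import sample_qc, snp_qc
from .shrinkage import EffectPair, through_origin_wls
from .simulate import SimConfig, simulate_cohort
from .strata import StratumScheme, define_strata, interaction_table


@dataclass
class PipelineConfig:
    outdir: str
    simulation: SimConfig | None = None
    genotype_path: str | None = None
    genotype_format: str = "tsv"
    cohort_path: str | None = None
    external_summary: pd.DataFrame | None = None  # snp_id, beta, se
    snp_call_threshold: float = 0.95
    hwe_threshold: float = 1.3e-4
    sample_call_threshold: float = 0.98
    f_zscore_threshold: float = 5.0
    multiplicity_method: str = "holm"
    adiposity_variables: tuple = ("bmi", "wc", "whr", "pbf")
    seed: int = 0

    def __post_init__(self):
        sim = self.simulation is not None
        paths = self.genotype_path is not None and self.cohort_path is not None
        if sim == paths:
            raise ValueError("exactly one of simulation / input paths must be given")


@dataclass
class RunManifest:
    seed: int
    stages: list = field(default_factory=list)
    files: dict = field(default_factory=dict)

    def log_stage(self, name: str, n_in: int, n_out: int, note: str = ""):
        self.stages.append(dict(stage=name, n_in=n_in, n_out=n_out, note=note,
                                wallclock=time.time()))

    def register(self, path: Path):
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.files[str(path)] = digest

    def write(self, path: Path):
        Path(path).write_text(json.dumps(
            dict(seed=self.seed, stages=self.stages, files=self.files), indent=2))


def _write(df: pd.DataFrame, path: Path, manifest: RunManifest):
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest.register(path)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed)

    # --- inputs -----------------------------------------------------------
    if config.simulation is not None:
        cohort = simulate_cohort(config.simulation)
        G, table = cohort.genotypes, cohort.table
    else:
        from .io import read_genotypes

        G = read_genotypes(config.genotype_path, config.genotype_format)
        table = pd.read_csv(config.cohort_path, sep="\t")
        if len(table) != G.n_individuals:
            raise ValueError("cohort table and genotype rows do not align")
    y = table["y"].to_numpy()
    manifest.log_stage("input", G.n_individuals, G.n_individuals,
                       f"{G.n_snps} SNPs")

    # --- QC ---------------------------------------------------------------
    srep = snp_qc(G, config.snp_call_threshold, config.hwe_threshold)
    keep_snps = np.flatnonzero(srep.kept.to_numpy())
    prep = sample_qc(G, config.sample_call_threshold, config.f_zscore_threshold)
    keep_rows = np.flatnonzero(prep.kept.to_numpy())
    G = G.subset(rows=keep_rows, cols=keep_snps)
    table = table.iloc[keep_rows].reset_index(drop=True)
    y = y[keep_rows]
    _write(srep, outdir / "snp_qc.tsv", manifest)
    _write(prep, outdir / "sample_qc.tsv", manifest)
    manifest.log_stage("qc", len(prep), len(keep_rows),
                       f"SNPs kept {len(keep_snps)}/{len(srep)}")

    # --- association ------------------------------------------------------
    covariates = build_covariates(age=table["age"], is_female=table["is_female"],
                                  centre=table["centre"])
    imputed = impute_missing_by_centre_mean(G, table["centre"].to_numpy())
    assoc = association_scan(imputed, y, covariates)
    assoc["p_adj"] = adjust_pvalues(assoc["p"].fillna(1.0),
                                    config.multiplicity_method)
    _write(assoc, outdir / "association.tsv", manifest)
    n_sig = int((assoc["p_adj"] < 0.05).sum())
    manifest.log_stage("association", G.n_snps, n_sig,
                       f"{config.multiplicity_method}-significant")

    # --- meta-analysis with external estimates ----------------------------
    external = config.external_summary
    if external is None:
        ext = panel.study_estimates("agen")
        ext = ext[ext.snp_id.isin(G.snps)]
        from .meta import se_from_ci

        pairs = [se_from_ci(r.or_, r.ci_low, r.ci_high) for r in ext.itertuples()]
        external = pd.DataFrame(dict(snp_id=ext.snp_id.to_numpy(),
                                     beta=[b for b, _ in pairs],
                                     se=[s for _, s in pairs]))
    meta_df = pool_summary_frame({
        "cohort": assoc[["snp_id", "beta", "se"]].dropna(),
        "external": external[external.snp_id.isin(G.snps)],
    })
    _write(meta_df, outdir / "meta_analysis.tsv", manifest)
    manifest.log_stage("meta", len(assoc), len(meta_df))

    # --- shrinkage --------------------------------------------------------
    ext_map = external.set_index("snp_id")
    pairs = [EffectPair(snp_id=r.snp_id, x=float(ext_map.at[r.snp_id, "beta"]),
                        y=float(r.beta), y_se=float(r.se))
             for r in assoc.dropna(subset=["beta", "se"]).itertuples()
             if r.snp_id in ext_map.index and np.isfinite(r.se)]
    if len(pairs) >= 3:
        shr = through_origin_wls(pairs)
        shr_df = pd.DataFrame([dict(slope=shr.slope, slope_se=shr.slope_se,
                                    reduction=shr.reduction,
                                    ci_low=shr.reduction_ci_low,
                                    ci_high=shr.reduction_ci_high,
                                    p_vs_unity=shr.p_vs_unity, r=shr.r,
                                    n_pairs=shr.n_pairs)])
        _write(shr_df, outdir / "shrinkage.tsv", manifest)
        manifest.log_stage("shrinkage", len(pairs), 1)

    # --- risk scores ------------------------------------------------------
    weights = {r.snp_id: float(r.beta) for r in external.itertuples()
               if r.snp_id in G.snps}
    scored_snps = list(weights) if weights else list(G.snps)
    w_scheme = (WeightScheme("external-meta", weights) if weights
                else WeightScheme.unweighted_for(scored_snps))
    u_scheme = WeightScheme.unweighted_for(scored_snps)
    defs = [GrsDefinition("overall-weighted", scored_snps, w_scheme),
            GrsDefinition("overall-unweighted", scored_snps, u_scheme)]
    truth_mech = None
    if config.simulation is not None:
        truth_mech = {s.snp_id: s.mechanism for s in config.simulation.snps}
        for mech, name in (("BC", "beta-cell"), ("IR", "insulin-resistance")):
            subset = [s for s in scored_snps if truth_mech.get(s) == mech]
            if subset:
                defs.append(GrsDefinition(name, subset, w_scheme))
    profiles = {d.name: compute_grs(imputed, d) for d in defs}
    score_df = pd.DataFrame({"iid": table["iid"] if "iid" in table else
                             imputed.individuals})
    for name, prof in profiles.items():
        score_df[name] = prof.rescaled
    _write(score_df, outdir / "grs_scores.tsv", manifest)
    quart = quartile_association(profiles["overall-weighted"].rescaled, y, covariates)
    _write(quart, outdir / "grs_quartiles.tsv", manifest)
    manifest.log_stage("grs", G.n_individuals, len(defs))

    # --- discrimination ---------------------------------------------------
    roc_w = c_statistic(profiles["overall-weighted"].rescaled, y)
    roc_u = c_statistic(profiles["overall-unweighted"].rescaled, y)
    cmp_ = delong_test(profiles["overall-weighted"].rescaled,
                       profiles["overall-unweighted"].rescaled, y)
    disc = pd.DataFrame([
        dict(score="overall-weighted", c=roc_w.c_statistic, ci_low=roc_w.ci_low,
             ci_high=roc_w.ci_high),
        dict(score="overall-unweighted", c=roc_u.c_statistic, ci_low=roc_u.ci_low,
             ci_high=roc_u.ci_high),
        dict(score="weighted-vs-unweighted", c=cmp_.delta_c, ci_low=np.nan,
             ci_high=np.nan, p=cmp_.p),
    ])
    _write(disc, outdir / "discrimination.tsv", manifest)
    manifest.log_stage("discrimination", G.n_individuals, 2)

    # --- adiposity strata and interaction ---------------------------------
    strata_labels, variables = {}, {}
    for var in config.adiposity_variables:
        if var not in table.columns:
            continue
        scheme = (StratumScheme(variable="bmi", mode="fixed_cutpoints")
                  if var == "bmi" else StratumScheme(variable=var))
        strata_labels[var] = define_strata(table[var].to_numpy(),
                                           sex=table["is_female"].to_numpy(),
                                           scheme=scheme)
        variables[var] = table[var].to_numpy()
    if strata_labels:
        inter = interaction_table(
            {k: v.rescaled for k, v in profiles.items()}, y, covariates,
            strata_labels, variables)
        _write(inter, outdir / "strata_interaction.tsv", manifest)
        manifest.log_stage("strata", len(strata_labels), len(inter))

    manifest.write(outdir / "manifest.json")
    return manifest
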