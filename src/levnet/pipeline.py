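"""End-to-end orchestration: synthetic cohorts through exposure-response.

The pipeline composes the stages in study order: PK simulation and
population fitting -> per-animal exposure prediction -> SUVr processing and
consensus region selection -> per-group covariance networks, thresholding,
nodal metrics and KS comparisons -> MRCC on the reference (WT male) group,
partition imposition and community ANOVA -> expression simulation and the
gene / network-metric exposure models.

Every artifact is comma-delimited text (full float precision) plus a JSON
manifest recording parameters, per-stage seeds and the artifact list.  All
randomness flows from the single config seed through named
``numpy.random.SeedSequence`` spawns, so a fixed config is byte-identical
across runs; in resume mode a stage whose artifacts already exist is loaded
from disk instead of recomputed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as comm
from . import expression as expr_mod
from . import network as net_mod
from . import pk as pk_mod
from . import suvr as suvr_mod
from . import synthetic as syn
from .regions import REFERENCE_REGION

__all__ = ["RunConfig", "run_full_pipeline"]

log = logging.getLogger("levnet.pipeline")

#: genes carried by the default synthetic expression panel, with effect
#: sizes on the scale of the exposure-response table of the source domain
DEFAULT_GENES = ("Amer3", "Lamp2", "Lrtm2", "Psma5", "Stat3",
                 "Gene06", "Gene07", "Gene08", "Gene09", "Gene10")


@dataclass
class RunConfig:
    """Every knob of a full pipeline run; round-trips through YAML."""

    seed: int = 0
    # synthetic cohort
    n_per_group: int = 12
    within_block_r: float = 0.8
    between_block_r: float = 0.0
    n_blocks: int = 3
    scale_sd: float = 0.1
    noise_sd: float = 0.0
    dose_shift_per_unit: float = 0.002  # mean SUVr shift per mg/kg
    sex_shift: float = 0.03             # additive female SUVr shift
    # PK
    pk_n_per_dose_per_sex: int = 3
    pk_bsv_sd: float = 0.2
    pk_prop_error_sd: float = 0.15
    pk_covariate_selection: str = "select"
    # network / community
    alpha: float = 0.05
    variance_fraction: float = 0.80
    gamma_range: tuple[float, float] = (0.5, 3.0)
    n_samples: int = 200
    n_null: int = 10000
    reference_sex: str = "male"
    reference_genotype: str = "WT"
    # expression
    genes: tuple[str, ...] = DEFAULT_GENES
    beta_auc: float = 0.00075
    beta_sex: float = -0.069
    expr_noise_sd: float = 0.12
    n_effect_genes: int = 5

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["gamma_range"] = list(self.gamma_range)
        d["genes"] = list(self.genes)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["gamma_range"] = tuple(d["gamma_range"])
        d["genes"] = tuple(d["genes"])
        return cls(**d)


def _stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (independent of stage execution order)."""
    ss = np.random.SeedSequence(
        [root_seed, int.from_bytes(stage.encode()[:8].ljust(8, b"\0"), "big")])
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index)


def _read_csv(path: Path, **kwargs) -> pd.DataFrame:
    # round_trip parsing so resumed stages see bit-identical floats
    return pd.read_csv(path, float_precision="round_trip", **kwargs)


def _cohort_spec(cfg: RunConfig, genotype: str, treatments: tuple[str, ...],
                 seed: int) -> syn.CohortSpec:
    shifts = {}
    for sex in syn.SEXES:
        for trt in treatments:
            dose = syn.TREATMENT_DOSES.get(trt, 0.0)
            shifts[(sex, trt)] = (cfg.dose_shift_per_unit * dose
                                  + (cfg.sex_shift if sex == "female" else 0.0))
    return syn.CohortSpec(
        n_per_group=cfg.n_per_group,
        planted_partition=syn.default_planted_partition(
            syn.DEFAULT_REGIONS, cfg.n_blocks),
        within_block_r=cfg.within_block_r,
        between_block_r=cfg.between_block_r,
        group_mean_shifts=shifts, scale_sd=cfg.scale_sd,
        noise_sd=cfg.noise_sd, genotype=genotype,
        treatments=treatments, seed=seed)


def run_full_pipeline(config: RunConfig, outdir, resume: bool = False) -> dict:
    """Execute every stage; return the manifest (also written to disk)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(json.dumps(dataclasses.asdict(config))),
                      "stages": {}, "artifacts": []}

    def artifact(name: str) -> Path:
        p = out / name
        manifest["artifacts"].append(name)
        return p

    def have(*names: str) -> bool:
        return resume and all((out / n).exists() for n in names)

    # ---- stage 1: synthetic cohort (raw uptake incl. cerebellum) ----------
    seed_cohort = _stage_seed(config.seed, "cohort")
    cohort_path = artifact("cohort_uptake.csv")
    if have("cohort_uptake.csv"):
        cohort = _read_csv(cohort_path)
        log.info("stage cohort: loaded from disk")
    else:
        fad = syn.generate_suvr_cohort(
            _cohort_spec(config, "5XFAD", syn.TREATMENTS, seed_cohort))
        wt = syn.generate_suvr_cohort(
            _cohort_spec(config, "WT", ("none",), seed_cohort + 1))
        cohort = pd.concat([wt, fad], ignore_index=True)
        _write_csv(cohort, cohort_path)
    manifest["stages"]["cohort"] = {"seed": seed_cohort, "n_animals": len(cohort)}

    # ---- stage 2: PK simulate + fit + exposures ---------------------------
    seed_pk = _stage_seed(config.seed, "pk")
    pk_obs_path = artifact("pk_observations.csv")
    pk_fit_path = artifact("pk_fit.json")
    exposures_path = artifact("exposures.csv")
    if have("pk_observations.csv", "pk_fit.json", "exposures.csv"):
        pk_obs = _read_csv(pk_obs_path)
        fit_dict = json.loads(pk_fit_path.read_text())
        params = pk_mod.PKParameterSet(**fit_dict["params"])
        exposures = _read_csv(exposures_path)
        log.info("stage pk: loaded from disk")
    else:
        spec = syn.PKSimSpec(structural=syn.DEFAULT_PK_PARAMS,
                             n_per_dose_per_sex=config.pk_n_per_dose_per_sex,
                             bsv_sd=config.pk_bsv_sd,
                             prop_error_sd=config.pk_prop_error_sd,
                             seed=seed_pk)
        sim = syn.generate_pk_profiles(spec)
        pk_obs = sim.observations
        _write_csv(pk_obs, pk_obs_path)
        model = pk_mod.PopulationPKModel(pk_obs)
        results = model.fit(covariate_selection=config.pk_covariate_selection)
        pk_fit_path.write_text(results.to_json())
        params = results.params
        # chronic exposure for every treated study animal (BID daily AUC)
        rng_w = np.random.default_rng(seed_pk + 10_000)
        rows = []
        for _, a in cohort.iterrows():
            dose_mg_per_kg = syn.TREATMENT_DOSES.get(a["treatment"], 0.0)
            w = float(np.maximum(0.0125, 0.025 + 0.002 * rng_w.standard_normal()))
            if dose_mg_per_kg > 0:
                est = pk_mod.predict_individual_auc(
                    params, a["animal_id"], dose_mg_per_kg * w, w,
                    dose_mg_per_kg=dose_mg_per_kg)
                auc, auc_bid, cl = est.auc, est.auc_daily_bid, est.cl_f_ind
            else:
                auc = auc_bid = 0.0
                cl = pk_mod.apply_allometry(params, w)[0]
            rows.append(dict(animal_id=a["animal_id"], sex=a["sex"],
                             genotype=a["genotype"], treatment=a["treatment"],
                             weight_kg=w, dose_mg_per_kg=dose_mg_per_kg,
                             cl_f_ind=cl, auc=auc, auc_daily_bid=auc_bid))
        exposures = pd.DataFrame(rows)
        _write_csv(exposures, exposures_path)
        fit_dict = json.loads(results.to_json())
    # exposure vs 0.5 h concentration on the simulated PK animals
    c05 = pk_obs[pk_obs["time_h"] == 0.5].set_index("animal_id")["conc_ng_per_ml"]
    pk_auc = {}
    for aid, g in pk_obs.groupby("animal_id"):
        first = g.iloc[0]
        pk_auc[aid] = pk_mod.predict_individual_auc(
            params, aid, first["dose_mg"], first["weight_kg"],
            dose_mg_per_kg=first["dose_mg_per_kg"]).auc
    shared = [a for a in pk_auc if a in c05.index]
    reg = pk_mod.exposure_concentration_regression(
        [pk_auc[a] for a in shared], c05.loc[shared].to_numpy())
    manifest["stages"]["pk"] = {
        "seed": seed_pk, "n_obs": len(pk_obs),
        "covariate_decisions": fit_dict.get("covariate_decisions", {}),
        "exposure_c05_r_squared": reg.r_squared,
        "exposure_c05_p": reg.p_value}

    # ---- stage 3: SUVr + consensus regions --------------------------------
    suvr_path = artifact("cohort_suvr.csv")
    consensus_path = artifact("consensus_regions.csv")
    if have("cohort_suvr.csv", "consensus_regions.csv"):
        suvr = _read_csv(suvr_path)
        consensus = _read_csv(consensus_path)["region"].tolist()
        log.info("stage suvr: loaded from disk")
    else:
        suvr = suvr_mod.compute_suvr(cohort, reference=REFERENCE_REGION)
        _write_csv(suvr, suvr_path)
        cohorts = {f"{g}_{t}": df for (g, t), df in
                   suvr.groupby(["genotype", "treatment"]) if len(df) >= 3}
        report = suvr_mod.select_consensus_regions(
            cohorts, variance_fraction=config.variance_fraction)
        consensus = report.consensus
        pd.DataFrame({"region": consensus}).to_csv(consensus_path, index=False)
    manifest["stages"]["suvr"] = {"n_consensus_regions": len(consensus)}

    # ---- stage 4: covariance networks, metrics, KS ------------------------
    metrics_path = artifact("nodal_metrics.csv")
    ks_path = artifact("ks_comparisons.csv")
    groups = {(g, s, t): df for (g, s, t), df
              in suvr.groupby(["genotype", "sex", "treatment"])}
    tnets: dict[tuple[str, str, str], net_mod.ThresholdedNetwork] = {}
    for key, df in groups.items():
        label = "_".join(key)
        net = net_mod.covariance_matrix(df, group_label=label)
        tnet = net_mod.threshold_network(net, alpha=config.alpha)
        tnets[key] = tnet
    if have("nodal_metrics.csv", "ks_comparisons.csv"):
        metrics_tidy = _read_csv(metrics_path)
        log.info("stage network: loaded from disk")
    else:
        tidy_rows = []
        for key, tnet in tnets.items():
            rmat = artifact(f"network_r_{'_'.join(key)}.csv")
            net_mod.covariance_matrix(groups[key],
                                      group_label=tnet.group).r_frame().to_csv(rmat)
            adj = artifact(f"adjacency_{'_'.join(key)}.csv")
            tnet.adjacency_frame().to_csv(adj)
            m = net_mod.nodal_metrics(tnet)
            for region, row in m.iterrows():
                for metric in net_mod.METRIC_NAMES:
                    tidy_rows.append(dict(genotype=key[0], sex=key[1],
                                          treatment=key[2], region=region,
                                          metric=metric, value=row[metric]))
        metrics_tidy = pd.DataFrame(tidy_rows)
        _write_csv(metrics_tidy, metrics_path)
        # KS: across treatments within sex, and across sex within treatment
        ks_rows = []
        fad_keys = [k for k in tnets if k[0] == "5XFAD"]
        for metric in net_mod.METRIC_NAMES:
            by_key = {k: net_mod.nodal_metrics(tnets[k])[metric].to_numpy()
                      for k in fad_keys}
            for sex in syn.SEXES:
                trts = [k for k in fad_keys if k[1] == sex]
                for i, ka in enumerate(trts):
                    for kb in trts[i + 1:]:
                        c = net_mod.compare_metric_distributions(
                            by_key[ka], by_key[kb], metric=metric,
                            group_a="_".join(ka), group_b="_".join(kb))
                        ks_rows.append(dataclasses.asdict(c))
            for trt in syn.TREATMENTS:
                pair = [k for k in fad_keys if k[2] == trt]
                if len(pair) == 2:
                    c = net_mod.compare_metric_distributions(
                        by_key[pair[0]], by_key[pair[1]], metric=metric,
                        group_a="_".join(pair[0]), group_b="_".join(pair[1]))
                    ks_rows.append(dataclasses.asdict(c))
        _write_csv(pd.DataFrame(ks_rows), ks_path)
    manifest["stages"]["network"] = {
        "alpha": config.alpha,
        "densities": {"_".join(k): t.density for k, t in sorted(tnets.items())}}

    # ---- stage 5: MRCC on reference group, imposition, ANOVA --------------
    seed_mrcc = _stage_seed(config.seed, "mrcc")
    partition_path = artifact("reference_partition.csv")
    coclass_path = artifact("coclassification.csv")
    anova_path = artifact("community_anova.csv")
    ref_key = (config.reference_genotype, config.reference_sex,
               "none" if config.reference_genotype == "WT" else "vehicle")
    if ref_key not in tnets:
        raise RuntimeError(f"reference group {ref_key} absent from cohort")
    if have("reference_partition.csv", "coclassification.csv",
            "community_anova.csv"):
        partition = comm.Partition.from_frame(_read_csv(partition_path))
        log.info("stage community: loaded from disk")
    else:
        res = comm.mrcc(tnets[ref_key], gamma_range=config.gamma_range,
                        n_samples=config.n_samples, n_null=config.n_null,
                        seed=seed_mrcc)
        partition = res.partition
        partition.to_frame().to_csv(partition_path, index=False)
        res.coclassification.to_csv(coclass_path)
        anova_rows = []
        for trt in syn.TREATMENTS:
            km = ("5XFAD", "male", trt)
            kf = ("5XFAD", "female", trt)
            if km not in groups or kf not in groups:
                continue
            a = comm.impose_partition(partition, groups[km])
            b = comm.impose_partition(partition, groups[kf])
            for c in comm.community_anova(a, b, partition):
                anova_rows.append(dict(treatment=trt, community=c.community,
                                       members=";".join(c.members),
                                       f_statistic=c.f_statistic,
                                       p_raw=c.p_raw,
                                       p_bonferroni=c.p_bonferroni,
                                       estimable=c.estimable))
        _write_csv(pd.DataFrame(anova_rows), anova_path)
    manifest["stages"]["community"] = {"seed": seed_mrcc,
                                       "k_reference": partition.k}

    # ---- stage 6: expression simulation + models --------------------------
    seed_expr = _stage_seed(config.seed, "expression")
    expr_path = artifact("expression_log2.csv")
    expr_meta_path = artifact("expression_metadata.csv")
    de_path = artifact("de_linear_model.csv")
    delta_path = artifact("delta_from_vehicle.csv")
    pkpd_path = artifact("gene_exposure_model.csv")
    netpkpd_path = artifact("network_metric_exposure_model.csv")
    fad = exposures[exposures["genotype"] == "5XFAD"].set_index("animal_id")
    if have("expression_log2.csv", "expression_metadata.csv"):
        values = _read_csv(expr_path, index_col=0)
        meta = _read_csv(expr_meta_path, index_col=0)
        etable = expr_mod.ExpressionTable(values=values, metadata=meta)
        log.info("stage expression: loaded from disk")
    else:
        g = len(config.genes)
        beta_auc = np.zeros(g)
        beta_sex = np.zeros(g)
        beta_auc[:config.n_effect_genes] = config.beta_auc
        beta_sex[:config.n_effect_genes] = config.beta_sex
        espec = syn.ExpressionSimSpec(
            genes=config.genes, beta_auc=beta_auc, beta_sex=beta_sex,
            intercept=8.0, noise_sd=config.expr_noise_sd, seed=seed_expr)
        values = syn.generate_expression(
            espec, fad["auc_daily_bid"].to_numpy(), fad["sex"].tolist(),
            animal_ids=list(fad.index))
        values.to_csv(expr_path)
        meta = fad[["sex", "genotype", "treatment"]].copy()
        meta["auc"] = fad["auc_daily_bid"]
        meta.to_csv(expr_meta_path)
        etable = expr_mod.ExpressionTable(values=values, metadata=meta)
    de = expr_mod.de_linear_model(
        expr_mod.ExpressionTable(values=etable.values,
                                 metadata=etable.metadata),
        factors=("sex", "treatment"))
    de.to_csv(de_path)
    deltas = expr_mod.delta_from_vehicle(etable)
    deltas.to_csv(delta_path)
    pkpd = expr_mod.GeneExposureModel(etable).fit()
    pkpd.table.to_csv(pkpd_path)
    # network summaries per (sex, treatment) group vs group-mean exposure
    rows = []
    for key, tnet in tnets.items():
        if key[0] != "5XFAD":
            continue
        gm = net_mod.global_metrics(tnet)
        grp = fad[(fad["sex"] == key[1]) & (fad["treatment"] == key[2])]
        rows.append(dict(sex=key[1], treatment=key[2],
                         auc=float(grp["auc_daily_bid"].mean()), **gm))
    netdf = pd.DataFrame(rows)
    netpkpd = expr_mod.network_metric_exposure_model(
        netdf.drop(columns=["treatment"]))
    netpkpd.to_csv(netpkpd_path)
    manifest["stages"]["expression"] = {
        "seed": seed_expr, "n_genes": len(etable.genes),
        "n_significant_de": int(de["significant"].sum())}

    # ---- manifest ---------------------------------------------------------
    from . import __version__
    manifest["version"] = __version__
    manifest["seed"] = config.seed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
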