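"""End-to-end orchestration: simulate -> discover -> MHL -> DMR -> survival
-> nomogram.

`run_pipeline` executes the stages in order on a cohort (in-memory or loaded
from disk), writes per-stage artifacts plus a manifest with the stage funnel
(discovered blocks -> CpG/read-filtered -> control-labelled -> missingness-
filtered -> stratified -> DMRs -> intersection -> panel -> scores ->
nomogram), and is fully deterministic: identical config and inputs produce
byte-identical outputs. `simulate_then_run` additionally generates a
synthetic cohort and compares the pipeline's calls against the planted
ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import blocks as blk
from . import dmr as dmrmod
from . import mhl as mhlmod
from . import nomogram as nom
from . import survival as surv
from .io import SampleHaplotypeSet, TargetRegion, read_haplotypes, read_regions
from .simulate import Cohort, CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "simulate_then_run", "load_cohort"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Every analysis threshold, defaulting to its published value."""

    out_dir: str | None = None
    # inputs (unused when an in-memory cohort is supplied)
    haplotype_dir: str | None = None
    region_bed: str | None = None
    cpg_map: str | None = None
    clinical_table: str | None = None
    # block discovery
    r2_cutoff: float = 0.3
    core_window: int = 3
    p_cutoff: float = 0.05
    min_pair_reads: int = 10
    # block filtering
    min_cpgs: int = 3
    min_median_reads: int = 50
    # MHL matrix
    max_missing_frac: float = 0.8
    k_neighbors: int = 5
    # differential screen
    localized_threshold: float = 0.05
    alpha: float = 0.05
    # panel / risk
    top_k: int = 20
    rank_comparison: str = "mhspc_vs_mcrpc"
    # ctDNA correlation screen
    min_fraction: float = 0.01
    min_nonmissing: float = 0.5
    r_cutoff: float = 0.5
    # nomogram
    horizons: tuple[float, ...] = (6.0, 12.0, 24.0)
    stepwise_direction: str = "backward"
    seed: int = 0

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["horizons"] = list(self.horizons)
        d["out_dir"] = None if d["out_dir"] is None else str(d["out_dir"])
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["horizons"] = tuple(d["horizons"])
        return cls(**d)


@dataclass
class PipelineResult:
    """In-memory bundle of every stage's output plus the manifest."""

    blocks: list[blk.MHB]
    filtered_blocks: list[blk.MHB]
    matrix_raw: mhlmod.MHLMatrix            # target blocks, pre-imputation
    matrix: mhlmod.MHLMatrix                # after missingness filter + KNN
    strata: dmrmod.StratifiedMHBSets
    screen: dmrmod.DMRScreen
    cox_fits: dict[str, surv.CoxFit]
    panel: list[str]
    composite: pd.Series
    risk: surv.RiskScore | None
    km: dict | None
    correlation: pd.DataFrame | None
    nomogram_fit: surv.CoxFit | None
    nomogram: nom.NomogramSpec | None
    auc: pd.DataFrame
    control_report: pd.DataFrame
    manifest: dict


def load_cohort(config: PipelineConfig) -> tuple[list[TargetRegion],
                                                 list[SampleHaplotypeSet],
                                                 pd.DataFrame]:
    """Load regions, per-sample haplotype files and the clinical table."""
    for name in ("region_bed", "cpg_map", "haplotype_dir", "clinical_table"):
        value = getattr(config, name)
        if value is None or not Path(value).exists():
            raise FileNotFoundError(f"pipeline input {name!r} missing: {value}")
    regions = read_regions(config.region_bed, config.cpg_map)
    clinical = pd.read_csv(config.clinical_table, index_col=0)
    samples = []
    for sid in clinical.index:
        path = Path(config.haplotype_dir) / f"{sid}.mhap.tsv"
        if not path.exists():
            raise FileNotFoundError(f"haplotype file for sample {sid} missing: {path}")
        samples.append(read_haplotypes(path, regions, sample_id=str(sid)))
    return regions, samples, clinical


def _pool_by_region(samples: Sequence[SampleHaplotypeSet]) -> dict[str, list]:
    pooled: dict[str, list] = {}
    for s in samples:
        for region_name, recs in s.records.items():
            pooled.setdefault(region_name, []).extend(recs)
    return pooled


def _mcrpc_survival(clinical: pd.DataFrame) -> pd.DataFrame:
    sub = clinical[clinical["state"] == "mcrpc"][["time", "event"]].dropna()
    return sub.astype({"event": int})


def run_pipeline(config: PipelineConfig,
                 cohort: Cohort | None = None) -> PipelineResult:
    """Execute every analysis stage in order; see the module docstring.

    Either supply an in-memory ``cohort`` (e.g. from
    :func:`mhlkit.simulate.generate_cohort`) or set the input paths in the
    config. Partial results are written as each stage completes, so a
    failure leaves the earlier artifacts on disk.
    """
    if cohort is not None:
        regions, samples, clinical = cohort.regions, cohort.samples, cohort.clinical
    else:
        regions, samples, clinical = load_cohort(config)
    region_map = {r.name: r for r in regions}
    out = Path(config.out_dir) if config.out_dir else None
    # the echoed config nulls out_dir so identical analyses written to
    # different directories still produce byte-identical artifacts
    echo = dataclasses.replace(config, out_dir=None)
    if out:
        out.mkdir(parents=True, exist_ok=True)
        echo.to_json(out / "config.json")
    manifest: dict = {"funnel": {}, "config": dataclasses.asdict(echo)}
    funnel = manifest["funnel"]
    funnel["n_samples"] = len(samples)
    funnel["n_regions"] = len(regions)

    # --- stage: cohort-wide block discovery --------------------------------
    pooled = _pool_by_region(samples)
    discovered: list[blk.MHB] = []
    for region in regions:
        recs = pooled.get(region.name)
        if not recs:
            continue
        discovered.extend(blk.discover_mhbs(
            recs, region, r2_cutoff=config.r2_cutoff,
            core_window=config.core_window, p_cutoff=config.p_cutoff,
            min_pair_reads=config.min_pair_reads))
    funnel["discovered_mhbs"] = len(discovered)
    logger.info("stage=discover n_blocks=%d", len(discovered))

    # --- stage: MHL matrix over all discovered blocks ----------------------
    matrix_all = mhlmod.build_matrix(samples, discovered, region_map)
    filtered = blk.filter_mhbs(discovered, matrix_all.support,
                               min_cpgs=config.min_cpgs,
                               min_median_reads=config.min_median_reads)
    funnel["filtered_mhbs"] = len(filtered)

    control_blocks = [b for b in filtered if b.region_class != "target"]
    target_blocks = [b for b in filtered if b.region_class == "target"]
    funnel["control_mhbs"] = len(control_blocks)
    funnel["target_mhbs"] = len(target_blocks)
    logger.info("stage=filter kept=%d target=%d control=%d",
                len(filtered), len(target_blocks), len(control_blocks))

    # control reporting: median MHL per control class (tracks panel quality)
    control_report = _control_report(matrix_all, control_blocks)
    if out:
        blk.blocks_to_bed(discovered, out / "blocks_discovered.bed")
        blk.blocks_to_bed(filtered, out / "blocks_filtered.bed",
                          out / "blocks_filtered.tsv")
        control_report.to_csv(out / "control_report.tsv", sep="\t")

    matrix_raw = matrix_all.subset([b.name for b in target_blocks])
    matrix_kept, removed = mhlmod.drop_high_missingness(
        matrix_raw, max_missing_frac=config.max_missing_frac)
    funnel["missingness_removed"] = len(removed)
    funnel["after_missingness"] = len(matrix_kept.mhb_ids)
    matrix = mhlmod.knn_impute(matrix_kept, k=config.k_neighbors)
    if out:
        matrix_raw.to_tsv(out / "mhl_matrix_raw.tsv", out / "mhl_support.tsv")
        matrix.to_tsv(out / "mhl_matrix_imputed.tsv")

    # --- stage: stratification + differential screen -----------------------
    states = clinical["state"]
    strata = dmrmod.stratify_by_localized(matrix.values, states,
                                          threshold=config.localized_threshold)
    funnel["low_localized"] = len(strata.low_localized)
    funnel["high_localized"] = len(strata.high_localized)
    screen = dmrmod.run_dmr_screen(matrix.values, states, strata,
                                   alpha=config.alpha)
    for (stratum, comp), ids in screen.significant.items():
        funnel[f"dmrs_{stratum}_{comp}"] = len(ids)
    funnel["intersection_low"] = len(screen.intersection["low_localized"])
    funnel["intersection_high"] = len(screen.intersection["high_localized"])
    if out:
        screen.table.to_csv(out / "dmr_table.tsv", sep="\t", index=False,
                            float_format="%.10g")
        for stratum, ids in screen.intersection.items():
            (out / f"dmr_intersection_{stratum}.txt").write_text(
                "".join(f"{i}\n" for i in ids))

    # --- stage: survival modelling (mCRPC) ---------------------------------
    survival = _mcrpc_survival(clinical)
    block_map = {b.name: b for b in target_blocks}
    candidates = screen.intersection["low_localized"]
    cox_fits: dict[str, surv.CoxFit] = {}
    panel: list[str] = []
    composite = pd.Series(dtype=float)
    risk = None
    km = None
    if len(survival) >= 3 and int(survival["event"].sum()) >= 2 and candidates:
        for c in candidates:
            cox_fits[c] = surv.cox_univariate(
                matrix.values[c].reindex(survival.index), survival)
        rank_tbl = screen.table[
            (screen.table["comparison"] == config.rank_comparison)
            & (screen.table["stratum"] == "low_localized")]
        ranking = dict(zip(rank_tbl["mhb_id"], rank_tbl["p_value"]))
        panel = surv.select_panel(candidates, cox_fits, block_map, ranking,
                                  top_k=config.top_k, alpha=config.alpha)
    funnel["cox_candidates"] = len(candidates)
    funnel["panel_size"] = len(panel)
    if panel:
        composite = surv.composite_score(panel, cox_fits, matrix.values)
        comp_mc = composite.reindex(survival.index).rename("composite_score")
        components = pd.concat(
            [comp_mc,
             clinical.loc[survival.index, "ctdna_fraction"],
             surv.log2_clinical(clinical.loc[survival.index],
                                columns=("psa", "ldh", "alp"))],
            axis=1)
        risk = surv.risk_score(components, survival)
        km = surv.km_logrank(risk.labels, survival)
        funnel["n_mcrpc"] = len(survival)
        funnel["n_events"] = int(survival["event"].sum())
        if out:
            _write_fit_table(cox_fits, block_map, out / "cox_univariate.tsv")
            pd.DataFrame({"mhb_id": panel}).to_csv(out / "panel.tsv", sep="\t",
                                                   index=False)
            pd.DataFrame({"composite_score": composite}).to_csv(
                out / "composite_score.csv", float_format="%.10g")
            pd.concat([risk.scores, risk.labels], axis=1).to_csv(
                out / "risk_groups.csv", float_format="%.10g")
            _write_km(km, out / "km_curves.tsv")

    # --- stage: ctDNA-fraction correlation screen --------------------------
    correlation = None
    try:
        mc_idx = clinical.index[clinical["state"] == "mcrpc"]
        correlation = surv.ctdna_correlation_screen(
            matrix_raw.values.loc[matrix_raw.values.index.intersection(mc_idx)],
            clinical["ctdna_fraction"],
            min_fraction=config.min_fraction,
            min_nonmissing=config.min_nonmissing,
            r_cutoff=config.r_cutoff, alpha=config.alpha)
        funnel["correlation_screened"] = correlation.attrs["n_screened"]
        funnel["correlation_flagged"] = correlation.attrs["n_flagged"]
        if out:
            correlation.to_csv(out / "ctdna_correlation.tsv", sep="\t",
                               index=False, float_format="%.10g")
    except surv.CorrelationScreenError as exc:
        logger.warning("correlation screen aborted: %s", exc)

    # --- stage: nomogram + time-dependent AUC ------------------------------
    nomogram_fit = None
    nomogram_spec = None
    auc_rows = []
    if risk is not None:
        mc = clinical.loc[survival.index]
        clin2 = surv.log2_clinical(mc, columns=("psa", "ldh", "alp",
                                                "albumin", "hemoglobin"))
        # univariate gate on clinical biomarkers before stepwise selection
        uni_sig = []
        for c in clin2.columns:
            fit = surv.cox_univariate(clin2[c], survival)
            if fit.converged and float(fit.summary["p"].iloc[0]) < config.alpha:
                uni_sig.append(c)
        X = pd.concat(
            [composite.reindex(survival.index).rename("composite_score"),
             mc["ctdna_fraction"], clin2[uni_sig]], axis=1)
        nomogram_fit = nom.stepwise_select(X, survival,
                                           alpha_enter=config.alpha,
                                           direction=config.stepwise_direction)
        if nomogram_fit.converged and nomogram_fit.covariates:
            nomogram_spec = nom.build_nomogram(nomogram_fit, X,
                                               horizons=config.horizons)
            lp = nomogram_fit.linear_predictor(X)
            for t in config.horizons:
                roc = nom.time_dependent_auc(lp, survival, t)
                auc_rows.append({"horizon_months": roc.horizon, "auc": roc.auc,
                                 "n_cases": roc.n_cases,
                                 "n_controls": roc.n_controls})
            funnel["nomogram_predictors"] = len(nomogram_fit.covariates)
            if out:
                nomogram_spec.to_json(out / "nomogram.json")
    auc = pd.DataFrame(auc_rows, columns=["horizon_months", "auc",
                                          "n_cases", "n_controls"])
    if out:
        auc.to_csv(out / "auc.tsv", sep="\t", index=False, float_format="%.10g")

    result = PipelineResult(
        blocks=discovered, filtered_blocks=filtered, matrix_raw=matrix_raw,
        matrix=matrix, strata=strata, screen=screen, cox_fits=cox_fits,
        panel=panel, composite=composite, risk=risk, km=km,
        correlation=correlation, nomogram_fit=nomogram_fit,
        nomogram=nomogram_spec, auc=auc, control_report=control_report,
        manifest=manifest)
    if out:
        manifest["inputs"] = _input_hashes(config)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return result


def _control_report(matrix: mhlmod.MHLMatrix,
                    control_blocks: Sequence[blk.MHB]) -> pd.DataFrame:
    rows = []
    for cls in ("positive_control", "negative_control"):
        names = [b.name for b in control_blocks if b.region_class == cls]
        if names:
            vals = matrix.values[names].to_numpy().ravel()
            vals = vals[~np.isnan(vals)]
            rows.append({"region_class": cls, "n_blocks": len(names),
                         "median_mhl": float(np.median(vals)) if len(vals) else np.nan})
        else:
            rows.append({"region_class": cls, "n_blocks": 0, "median_mhl": np.nan})
    return pd.DataFrame(rows).set_index("region_class")


def _write_fit_table(fits: Mapping[str, surv.CoxFit],
                     block_map: Mapping[str, blk.MHB], path) -> None:
    rows = []
    for name, fit in fits.items():
        s = fit.summary.iloc[0]
        b = block_map[name]
        rows.append({"gene": b.region_name,
                     "mhb": f"{b.chrom}:{b.start}-{b.end}",
                     "mhb_id": name, "p_value": s["p"], "hr": s["hr"],
                     "ci_low": s["ci_low"], "ci_high": s["ci_high"],
                     "converged": fit.converged})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _write_km(km: dict, path) -> None:
    rows = []
    for g, curve in km["curves"].items():
        for t, s in curve.items():
            rows.append({"group": g, "time": t, "survival": s})
    df = pd.DataFrame(rows)
    header = (f"# logrank_stat={km['logrank_stat']:.10g}\t"
              f"logrank_p={km['logrank_p']:.10g}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _input_hashes(config: PipelineConfig) -> dict:
    hashes = {}
    for name in ("region_bed", "cpg_map", "clinical_table"):
        value = getattr(config, name)
        if value and Path(value).exists():
            hashes[name] = hashlib.sha256(Path(value).read_bytes()).hexdigest()
    return hashes


def simulate_then_run(cohort_config: CohortConfig | None = None,
                      pipeline_config: PipelineConfig | None = None
                      ) -> tuple[PipelineResult, dict]:
    """Generate a synthetic cohort, run the pipeline, and score recovery.

    The recovery report compares pipeline calls against the planted ground
    truth: region-level precision/recall of the DMR intersection, the share
    of flagged correlation-screen blocks lying in planted DMR regions, the
    Cox coefficient on the true planted risk (should be near 1 under the
    proportional-hazards construction), and the achieved risk-group
    separation (KM medians and log-rank p).
    """
    cohort = generate_cohort(cohort_config)
    pcfg = pipeline_config or PipelineConfig()
    result = run_pipeline(pcfg, cohort=cohort)
    gt = cohort.ground_truth
    true_dmr = set(gt.regions.index[gt.regions["is_dmr"]])

    called = {c.rsplit(":", 1)[0] for c in result.screen.intersection["low_localized"]}
    tested = {c.rsplit(":", 1)[0] for c in result.matrix.mhb_ids}
    tp = len(called & true_dmr)
    precision = tp / len(called) if called else float("nan")
    recall = tp / len(true_dmr & tested) if (true_dmr & tested) else float("nan")

    corr_recovery = float("nan")
    if result.correlation is not None and len(result.correlation):
        flagged = result.correlation[result.correlation["flagged"]]["mhb_id"]
        in_dmr = [f.rsplit(":", 1)[0] in true_dmr for f in flagged]
        corr_recovery = float(np.mean(in_dmr)) if len(in_dmr) else float("nan")

    survival = _mcrpc_survival(cohort.clinical)
    true_risk = gt.patients.loc[survival.index, "true_risk"]
    gt_fit = surv.cox_univariate(true_risk.rename("true_risk"), survival)
    beta_true_risk = float(gt_fit.summary["beta"].iloc[0])

    report = {
        "dmr_precision": precision,
        "dmr_recall": recall,
        "n_called_dmr_regions": len(called),
        "n_planted_dmr_regions": len(true_dmr),
        "correlation_flagged_in_planted": corr_recovery,
        "beta_on_true_risk": beta_true_risk,
        "km_median_high": result.km["median_survival"]["high"] if result.km else float("nan"),
        "km_median_low": result.km["median_survival"]["low"] if result.km else float("nan"),
        "logrank_p": result.km["logrank_p"] if result.km else float("nan"),
        "auc": {float(row["horizon_months"]): float(row["auc"])
                for _, row in result.auc.iterrows()},
    }
    return result, report
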