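"""End-to-end pipeline orchestration.

One validated configuration drives simulate -> QC -> burden -> mucin ->
signatures -> CNA -> survival and emits per-stage TSV/JSON outputs plus a
single versioned summary JSON with every headline statistic.  Outputs are
pure functions of (inputs, config, seed); re-running an identical
configuration produces identical bytes.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import (
    arm_frequency_comparison, array_qc, burden_comparison, carrier_status,
    catalogs_from_records, cna_summary, exposures_to_frame, gene_frequency_table,
    hotspot_detect, load_arms, load_reference_signatures, mann_whitney,
    mc_known_db_overlap_test, mc_serine_test, msh2_region, mucin_family, mucsig,
    qc_gate, read_clinical_table, read_expression_matrix, read_mutation_table,
    read_probe_table, read_segment_table, refit_exposures, serine_gain_fraction,
    sig20_association_suite, survival_analysis,
)
from .mutations import classify_non_silent
from .signatures import MMR_SIGNATURE, MutationalSpectrum
from .simulate import CohortParams, simulate_cohort

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1
STAGE_ORDER = ("qc", "burden", "mucin", "signatures", "cna", "survival")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


class Thresholds(BaseModel):
    signature_cutoff: float = 0.06
    mapd: float = 0.30
    autocorr: float = 0.5
    min_ccf: float = 0.30
    neutral_band: float = 0.2
    del_threshold: float = -0.3
    min_gene_freq: float = 0.05
    n_draws: int = 9999
    exclude_mucins: list[str] = Field(default_factory=lambda: ["MUC4", "MUC16"])


class InputPaths(BaseModel):
    clinical: str
    mutations: str | None = None
    spectra: str | None = None
    segments: str | None = None
    probes: str | None = None
    expression: str | None = None
    known_sites: str | None = None
    ccf: str | None = None  # TSV sample_id\tccf when not simulated


class RunConfig(BaseModel):
    """Validated pipeline configuration (YAML-loadable)."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    simulate: dict | None = None
    inputs: InputPaths | None = None
    stages: list[str] = Field(default_factory=lambda: list(STAGE_ORDER))
    thresholds: Thresholds = Field(default_factory=Thresholds)

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v):
        unknown = set(v) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        return [s for s in STAGE_ORDER if s in v]

    def model_post_init(self, _ctx):
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulate' or 'inputs' must be given")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits) if np.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (np.floating,)) and not np.isfinite(obj):
        return None
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns (and writes) the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "stages": config.stages,
    }
    manifest = {"complete": False, "stages_done": []}
    t_start = time.time()

    # ---- data acquisition ----------------------------------------------
    stage = "input"
    try:
        if config.simulate is not None:
            params = CohortParams(seed=config.seed, **config.simulate)
            cohort = simulate_cohort(params)
            cohort.write(out / "simulated")
            clinical = cohort.clinical
            catalogs = cohort.catalogs
            spectra = cohort.spectra
            segments = cohort.segments
            probes = cohort.probes
            expression = cohort.expression
            known_sites = cohort.known_sites
            ccf = cohort.truth["ccf"].to_dict()
            groups = cohort.groups()
        else:
            ip = config.inputs
            clinical = read_clinical_table(ip.clinical)
            groups = {r.patient_id: r.group for r in clinical}
            catalogs = (
                catalogs_from_records(read_mutation_table(ip.mutations))
                if ip.mutations else {}
            )
            spectra = {}
            if ip.spectra:
                sp = pd.read_csv(ip.spectra, sep="\t", index_col=0)
                spectra = {c: MutationalSpectrum(c, sp[c].to_numpy()) for c in sp.columns}
            segments = {}
            if ip.segments:
                for rec in read_segment_table(ip.segments):
                    segments.setdefault(rec.sample_id, []).append(rec)
            probes = read_probe_table(ip.probes) if ip.probes else {}
            expression = read_expression_matrix(ip.expression) if ip.expression else None
            known_sites = set()
            if ip.known_sites:
                ks = pd.read_csv(ip.known_sites, sep="\t", dtype={"chrom": str})
                known_sites = set(zip(ks["chrom"], ks["pos"].astype(int), ks["alt"]))
            ccf = {}
            if ip.ccf:
                cc = pd.read_csv(ip.ccf, sep="\t")
                ccf = dict(zip(cc["sample_id"], cc["ccf"].astype(float)))
    except Exception as e:
        _write_manifest(out, manifest)
        raise PipelineError(stage, e) from e

    fam = mucin_family()
    clin_frame = _clinical_frame(clinical)

    for stage in config.stages:
        t0 = time.time()
        try:
            if stage == "qc" and probes:
                qcs = [array_qc(p) for p in probes.values()]
                gate = qc_gate(qcs, ccf, th.mapd, th.autocorr, th.min_ccf)
                gate.to_csv(out / "qc.tsv", sep="\t", index=False)
                summary["qc"] = {
                    "n_samples": len(gate),
                    "n_passed": int(gate["passed"].sum()),
                    "retained": sorted(gate.loc[gate["passed"], "sample_id"]),
                }
            elif stage == "burden" and catalogs:
                block = {}
                for metric in ("n_nonsilent", "n_snv", "n_known_db", "math_score"):
                    res = burden_comparison(catalogs, clinical, metric)
                    block[metric] = {
                        "median_bcp": res.group_summaries["median_bcp"],
                        "median_control": res.group_summaries["median_control"],
                        "p": res.p,
                        "adjusted_p": res.adjusted_p,
                    }
                block["median_nonsilent_overall"] = float(
                    np.median([c.n_nonsilent for c in catalogs.values()])
                )
                freq = gene_frequency_table(catalogs, groups, th.min_gene_freq)
                freq.to_csv(out / "gene_frequency.tsv", sep="\t", index=False)
                metrics = pd.DataFrame(
                    {
                        "patient_id": list(catalogs),
                        "n_snv": [c.n_snv for c in catalogs.values()],
                        "n_indel": [c.n_indel for c in catalogs.values()],
                        "n_nonsilent": [c.n_nonsilent for c in catalogs.values()],
                        "n_known_db": [c.n_known_db for c in catalogs.values()],
                        "math_score": [c.math_score for c in catalogs.values()],
                    }
                )
                metrics.to_csv(out / "burden_metrics.tsv", sep="\t", index=False)
                summary["burden"] = block
            elif stage == "mucin" and catalogs:
                block = {}
                for tag, exclude in (("all", set()), ("excl_artifact", set(th.exclude_mucins))):
                    cs = carrier_status(catalogs, fam, exclude)
                    bcp = [p for p, g in groups.items() if g == "BCP" and p in cs.index]
                    ctl = [p for p, g in groups.items() if g == "control" and p in cs.index]
                    block[f"carrier_frac_bcp_{tag}"] = float(cs[bcp].mean())
                    block[f"carrier_frac_control_{tag}"] = float(cs[ctl].mean())
                fam_set = set(fam.members)
                muc_mis = [
                    r for c in catalogs.values() for r in c.records
                    if r.gene in fam_set and r.consequence == "missense"
                ]
                if muc_mis:
                    block["serine_gain_fraction"] = serine_gain_fraction(muc_mis)
                    mc = mc_serine_test(muc_mis, fam, th.n_draws, config.seed)
                    block["mc_serine_p"] = mc.p
                    if known_sites:
                        mk = mc_known_db_overlap_test(
                            muc_mis, known_sites, fam, th.n_draws, config.seed
                        )
                        block["mc_known_db_p"] = mk.p
                        block["known_db_overlap"] = mk.observed
                muc_records = [
                    r for c in catalogs.values() for r in c.records
                    if r.gene in fam_set and classify_non_silent(r)
                ]
                hot = hotspot_detect(muc_records)
                hot.assign(patients=hot["patients"].str.join(",")).to_csv(
                    out / "hotspots.tsv", sep="\t", index=False
                )
                block["n_hotspots"] = int(len(hot))
                if expression is not None:
                    ms = mucsig(expression, fam)
                    ms.to_csv(out / "mucsig.tsv", sep="\t")
                    bcp = [p for p, g in groups.items() if g == "BCP" and p in ms.index]
                    ctl = [p for p, g in groups.items() if g == "control" and p in ms.index]
                    mw = mann_whitney(ms[bcp], ms[ctl])
                    block["mucsig_mean_bcp"] = float(ms[bcp].mean())
                    block["mucsig_mean_control"] = float(ms[ctl].mean())
                    block["mucsig_p"] = mw.p
                summary["mucin"] = block
            elif stage == "signatures" and spectra:
                ref = load_reference_signatures()
                exps = [
                    refit_exposures(s, ref, th.signature_cutoff) for s in spectra.values()
                ]
                exposures_to_frame(exps).to_csv(out / "exposures.tsv", sep="\t")
                present = {e.sample_id: bool(e.proportion(MMR_SIGNATURE) > 0) for e in exps}
                bcp = [p for p, g in groups.items() if g == "BCP" and p in present]
                ctl = [p for p, g in groups.items() if g == "control" and p in present]
                block = {
                    "sig20_frac_bcp": float(np.mean([present[p] for p in bcp])) if bcp else None,
                    "sig20_frac_control": float(np.mean([present[p] for p in ctl])) if ctl else None,
                }
                if catalogs:
                    seg_list = [s for segs in segments.values() for s in segs]
                    suite = sig20_association_suite(
                        exps, catalogs, expression, seg_list if segments else None,
                        msh2_region() if segments else None,
                    )
                    suite.to_csv(out / "sig20_associations.tsv", sep="\t", index=False)
                    block["associations"] = {
                        row.analysis: {"statistic": row.statistic, "p": row.p, "fdr": row.fdr}
                        for row in suite.itertuples()
                        if not np.isnan(row.p)
                    }
                summary["signatures"] = block
            elif stage == "cna" and segments:
                summ = cna_summary(segments, ccf, msh2_region=msh2_region(),
                                   neutral_band=th.neutral_band)
                summ.to_csv(out / "cna_summary.tsv", sep="\t", index=False)
                arm_cmp = arm_frequency_comparison(segments, groups, load_arms(),
                                                   th.neutral_band)
                arm_cmp.to_csv(out / "arm_comparison.tsv", sep="\t", index=False)
                bcp_m = summ["sample_id"].map(groups) == "BCP"
                summary["cna"] = {
                    "fga_median_bcp": float(summ.loc[bcp_m, "fga"].median()),
                    "fga_median_control": float(summ.loc[~bcp_m, "fga"].median()),
                    "fga_p": mann_whitney(
                        summ.loc[bcp_m, "fga"], summ.loc[~bcp_m, "fga"]
                    ).p,
                    "n_msh2_deleted": int((summ["msh2_call"] == "deleted").sum()),
                    "min_arm_fdr": float(arm_cmp["fdr"].min()) if len(arm_cmp) else None,
                }
            elif stage == "survival":
                block = {}
                for endpoint in ("dfs", "os"):
                    fit = survival_analysis(clin_frame, endpoint)
                    hr = fit.cox_summary.loc["group_bcp"]
                    block[endpoint] = {
                        "km_median": fit.median_survival,
                        "logrank_p": fit.logrank_p,
                        "cox_hr": float(hr["hr"]),
                        "cox_ci": [float(hr["hr_ci_low"]), float(hr["hr_ci_high"])],
                        "cox_p": float(hr["p"]),
                    }
                    for g, curve in fit.km_curves.items():
                        curve.to_csv(out / f"km_{endpoint}_{g}.tsv", sep="\t")
                summary["survival"] = block
        except Exception as e:
            _write_manifest(out, manifest)
            raise PipelineError(stage, e) from e
        manifest["stages_done"].append(stage)
        logger.info("stage %s done in %.2fs", stage, time.time() - t0)

    summary["runtime_s"] = round(time.time() - t_start, 2)
    summary = _round_floats(summary)
    # runtime varies between runs; keep it out of the determinism contract
    payload = {k: v for k, v in summary.items() if k != "runtime_s"}
    (out / "summary.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    manifest["complete"] = True
    _write_manifest(out, manifest)
    return summary


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _clinical_frame(clinical) -> pd.DataFrame:
    from .io import clinical_to_frame

    df = clinical_to_frame(clinical)
    for col in ("age_at_diagnosis", "dfs_time", "os_time"):
        df[col] = df[col].astype(float)
    for col in ("pathological_stage", "dfs_event", "os_event"):
        df[col] = df[col].astype(int)
    return df
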