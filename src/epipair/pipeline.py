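"""End-to-end pipeline: simulate → cohort → DMP → DMR → 5hmC → DGE →
integration, with one JSON run report.

All stages are driven by a :class:`~epipair.config.PipelineConfig`; every
source of randomness flows from the simulation seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import __version__, cohort, dge, dmp, dmr, hydroxy, integrate
from .config import PipelineConfig, SimulationConfig
from .simulate import SimulatedStudy, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """All per-stage tables plus the aggregated JSON-ready report."""

    study: SimulatedStudy
    cohort_summary: dict
    dmps: pd.DataFrame
    dmrs: pd.DataFrame
    dmp_context: dict
    calls_hcc: pd.DataFrame
    calls_ntl: pd.DataFrame
    transitions: pd.DataFrame
    hydroxy_context: dict
    degs: pd.DataFrame
    dyads: pd.DataFrame
    enrichment: pd.DataFrame
    report: dict


def run_all(pipe_cfg: PipelineConfig,
            sim_cfg: SimulationConfig | None = None,
            study: SimulatedStudy | None = None) -> PipelineResult:
    """Run every stage on a simulated (or supplied) study.

    Either ``study`` (pre-loaded inputs) or ``sim_cfg`` (simulate first)
    must be given.  Any stage failure propagates with the stage named.
    """
    if study is None:
        if sim_cfg is None:
            sim_cfg = SimulationConfig(seed=pipe_cfg.seed)
        study = _stage("simulate", simulate_study, sim_cfg)

    cohort_summary = _stage("cohort", cohort.summarize_cohort, study.sheet,
                            pipe_cfg.age_cutoff)

    def dmp_stage():
        tested = dmp.test_dmps(study.beta_bs_hcc, study.beta_bs_ntl,
                               pairing=study.sheet)
        called = dmp.call_dmps(tested, pipe_cfg.q_threshold,
                               pipe_cfg.delta_beta_threshold)
        flagged = dmp.apply_stringent_filters(
            called, study.beta_bs_hcc, study.beta_bs_ntl,
            delta=pipe_cfg.stringent_delta,
            fraction=pipe_cfg.stringent_fraction,
            n_sd=pipe_cfg.stringent_n_sd,
            ntl_hyper=pipe_cfg.stringent_ntl_hyper,
            ntl_hypo=pipe_cfg.stringent_ntl_hypo,
            sd_floor=pipe_cfg.stringent_sd_floor,
        )
        return dmp.exclude_age_related(flagged, study.exclusion)

    dmps = _stage("dmp", dmp_stage)
    dmp_context = _stage("dmp-context", dmp.summarize_context, dmps,
                         study.manifest)

    def dmr_stage():
        sig = dmr.significant_probes(dmps, study.manifest,
                                     pipe_cfg.q_threshold,
                                     pipe_cfg.dmr_use_stringent)
        return dmr.call_dmrs(sig, pipe_cfg.dmr_max_gap,
                             pipe_cfg.dmr_min_probes, pipe_cfg.dmr_min_delta,
                             pipe_cfg.dmr_mode)

    dmrs = _stage("dmr", dmr_stage)

    def hydroxy_stage():
        scores_hcc = hydroxy.compute_scores(study.beta_bs_hcc,
                                            study.beta_oxbs_hcc)
        scores_ntl = hydroxy.compute_scores(study.beta_bs_ntl,
                                            study.beta_oxbs_ntl)
        kw = dict(score_threshold=pipe_cfg.hmc_score_threshold,
                  min_samples=pipe_cfg.hmc_min_samples,
                  density_quantile=pipe_cfg.hmc_density_quantile)
        calls_hcc = hydroxy.call_5hmc(scores_hcc, **kw)
        calls_ntl = hydroxy.call_5hmc(scores_ntl, **kw)
        st_hcc = hydroxy.assign_states(calls_hcc["definite"],
                                       study.beta_oxbs_hcc,
                                       pipe_cfg.methylated_threshold)
        st_ntl = hydroxy.assign_states(calls_ntl["definite"],
                                       study.beta_oxbs_ntl,
                                       pipe_cfg.methylated_threshold)
        transitions = hydroxy.classify_transitions(st_ntl, st_hcc)
        context = hydroxy.summarize_hydroxy_context(calls_hcc, calls_ntl,
                                                    study.manifest)
        return calls_hcc, calls_ntl, transitions, context, scores_hcc

    calls_hcc, calls_ntl, transitions, hydroxy_context, scores_hcc = _stage(
        "hydroxy", hydroxy_stage
    )

    def dge_stage():
        expr_hcc, expr_ntl = dge.split_by_tissue(study.expression,
                                                 study.sheet)
        return dge.test_dge(expr_hcc, expr_ntl,
                            q_threshold=pipe_cfg.q_threshold,
                            fc_gates=pipe_cfg.fc_gates)

    degs = _stage("dge", dge_stage)

    def integrate_stage():
        dyads = integrate.merge_layers(degs, dmps, transitions,
                                       study.manifest)
        pooled_beta = pd.concat([study.beta_bs_hcc, study.beta_bs_ntl],
                                axis=1)
        pooled_scores = pd.concat(
            [study.beta_bs_hcc - study.beta_oxbs_hcc,
             study.beta_bs_ntl - study.beta_oxbs_ntl], axis=1)
        dyads = integrate.correlate_dyads(dyads, study.expression,
                                          pooled_beta, pooled_scores)
        dyads = integrate.select_dyads(dyads, degs, dmps,
                                       pipe_cfg.rho_threshold)
        universe = study.expression.index
        selected = dyads.loc[dyads["selected"], "gene_symbol"].unique()
        enrichment = integrate.enrich(selected, universe, study.gene_sets,
                                      pipe_cfg.enrichment_correction)
        return dyads, enrichment

    dyads, enrichment = _stage("integrate", integrate_stage)

    overlap = integrate.summary_report(degs, dmps, transitions,
                                       study.manifest)
    report = {
        "version": __version__,
        "seed": pipe_cfg.seed,
        "thresholds": {
            "q": pipe_cfg.q_threshold,
            "delta_beta": pipe_cfg.delta_beta_threshold,
            "dmr_max_gap": pipe_cfg.dmr_max_gap,
            "hmc_score": pipe_cfg.hmc_score_threshold,
            "rho": pipe_cfg.rho_threshold,
        },
        "cohort": {"n": cohort_summary["n"],
                   "aya_pct": cohort_summary["aya_pct"],
                   "moa_pct": cohort_summary["moa_pct"]},
        "dmp": {
            "n_tested": len(dmps),
            "n_called": int(dmps["is_dmp"].sum()),
            "n_stringent": int(dmp.passing(dmps).shape[0]),
            "hyper_fraction": dmp_context["hyper_fraction"],
        },
        "dmr": {"n_dmrs": len(dmrs)},
        "hydroxy": {
            "category_counts": hydroxy.category_counts(transitions),
            "n_gain": hydroxy_context["n_gain"],
            "n_loss": hydroxy_context["n_loss"],
        },
        "dge": {"n_degs": int(degs["is_deg"].sum())},
        "integration": {
            "n_dyads": len(dyads),
            "n_selected": int(dyads["selected"].sum()),
            "hyper_down_fraction": integrate.hyper_down_fraction(dyads),
            "overlaps": overlap,
            "enrichment": enrichment.to_dict(orient="records"),
        },
    }
    return PipelineResult(study, cohort_summary, dmps, dmrs, dmp_context,
                          calls_hcc, calls_ntl, transitions, hydroxy_context,
                          degs, dyads, enrichment, report)


def _stage(name, fn, *args, **kwargs):
    logger.info("stage %s: starting", name)
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
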