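"""Configuration objects for the simulator and the analysis pipeline.

Both configs are plain dataclasses that round-trip losslessly through YAML.
Simulator defaults reflect the cohort the package models: 70 matched
tumour/non-tumour liver pairs, roughly half of them adolescents and young
adults, overwhelmingly hypermethylated differential positions with an
effect of Δβ = 0.3, and a minor hydroxymethylated probe subset whose
transition mix leans toward 5hmC loss in the young stratum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


def _check_proportion(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic paired methylome/transcriptome study.

    ``transition_mix`` gives the proportions of planted hydroxymethylation
    transitions over the four categories (I: non-5mC→5hmC, II: 5mC→5hmC,
    III: 5hmC→non-5mC, IV: 5hmC→5mC).  ``beta_dispersion`` is the precision
    of the beta-distributed measurement noise on β values; ``None`` disables
    noise entirely (useful for exactness checks).
    """

    n_pairs: int = 70
    aya_fraction: float = 36 / 70
    n_probes: int = 20000
    n_genes: int = 2000
    dmp_fraction: float = 0.02
    hyper_fraction_among_dmps: float = 0.99
    delta_beta_effect: float = 0.3
    hmc_fraction: float = 0.01
    transition_mix: tuple[float, float, float, float] = (
        0.372, 0.056, 0.366, 0.206)
    deg_fraction: float = 0.10
    log_fc_effect: float = 1.5
    corr_dyad_fraction: float = 0.05
    rho_effect: float = 0.9
    beta_dispersion: float | None = 50.0
    seed: int = 0

    def __post_init__(self):
        for name in ("aya_fraction", "dmp_fraction",
                     "hyper_fraction_among_dmps", "hmc_fraction",
                     "deg_fraction", "corr_dyad_fraction"):
            _check_proportion(name, getattr(self, name))
        if not 0.0 <= self.rho_effect <= 1.0:
            raise ValueError("rho_effect must lie in [0, 1]")
        self.transition_mix = tuple(float(v) for v in self.transition_mix)
        if len(self.transition_mix) != 4:
            raise ValueError("transition_mix needs four proportions")
        if any(v < 0 for v in self.transition_mix):
            raise ValueError("transition_mix proportions must be >= 0")
        if abs(sum(self.transition_mix) - 1.0) > 1e-9:
            raise ValueError("transition_mix must sum to 1")
        for name in ("n_pairs", "n_probes", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineConfig:
    """Thresholds and paths for the end-to-end analysis run.

    Threshold defaults equal the published values where one exists
    (q < 0.05, |Δβ| ≥ 0.2, the three stringent criteria, the 250 bp
    neighbouring-CpG rule, the 5hmC-score ≥ 0.3 / ≥ 3 samples rule with the
    upper-75% density cut, Spearman |ρ| > 0.5, age cutoff 44); the remainder
    are labelled artifact decisions in the docs.
    """

    # multiple testing / effect thresholds
    q_threshold: float = 0.05
    delta_beta_threshold: float = 0.2
    # stringent DMP criteria
    stringent_delta: float = 0.20
    stringent_fraction: float = 0.70
    stringent_n_sd: float = 2.0
    stringent_ntl_hyper: float = 0.25
    stringent_ntl_hypo: float = 0.25
    stringent_sd_floor: float = 0.01
    # DMR rule
    dmr_max_gap: int = 250
    dmr_min_probes: int = 2
    dmr_min_delta: float = 0.2
    dmr_mode: str = "gap"          # "gap" (chain rule) or "span"
    dmr_use_stringent: bool = False
    # 5hmC calling
    hmc_score_threshold: float = 0.3
    hmc_min_samples: int = 3
    hmc_density_quantile: float = 0.75
    methylated_threshold: float = 0.3
    # expression / integration
    fc_gates: bool = False
    rho_threshold: float = 0.5
    enrichment_correction: str = "bonferroni"
    # cohort
    age_cutoff: int = 44
    seed: int = 0
    # paths (all optional; the library API never requires them)
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dmr_mode not in ("gap", "span"):
            raise ValueError("dmr_mode must be 'gap' or 'span'")
        if self.enrichment_correction not in ("bonferroni", "bh"):
            raise ValueError("enrichment_correction must be bonferroni or bh")
        _check_proportion("hmc_density_quantile", self.hmc_density_quantile)


def _to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    if "transition_mix" in d:
        d["transition_mix"] = list(d["transition_mix"])
    return d


def save_config(cfg, path) -> None:
    """Serialize a config dataclass to YAML."""
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))


def load_simulation_config(path) -> SimulationConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return SimulationConfig(**data)


def load_pipeline_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**data)
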