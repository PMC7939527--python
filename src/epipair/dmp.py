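"""Differential methylation position (DMP) calling with stringent filters.

Testing runs on M-values (logit-transformed β) through the shared paired
empirical-Bayes moderated t machinery; effect sizes (Δβ = mean β tumour −
mean β normal) stay on the β scale.  A probe is a DMP when q < 0.05 and
|Δβ| ≥ 0.2; stringent filtering then keeps the most extreme calls:

  c1  |mean Δβ| ≥ 0.20;
  c2  more than 70% of tumour samples lie beyond the normal mean ± 2 SD
      bound at that probe (above for hyper-, below for hypomethylated);
  c3  mean normal β ≤ 0.25 for hypermethylated probes, ≥ 0.25 for
      hypomethylated probes.

Thresholds are all configurable; an age-related probe exclusion list can be
applied before downstream summaries.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import PairedModeratedTTest, beta_to_m

logger = logging.getLogger(__name__)


def _align_pairs(beta_hcc: pd.DataFrame, beta_ntl: pd.DataFrame,
                 pairing: pd.DataFrame | None):
    """Align tumour and normal columns one-to-one.

    ``pairing`` is a sample sheet mapping sample ids to pair ids; without
    one, columns are paired by position.
    """
    if not beta_hcc.index.equals(beta_ntl.index):
        raise ValueError("tumour and normal matrices must share probe index")
    if pairing is not None:
        hcc = pairing[pairing["tissue"] == "HCC"].set_index("pair_id")
        ntl = pairing[pairing["tissue"] == "NTL"].set_index("pair_id")
        common = sorted(set(hcc.index) & set(ntl.index))
        hcc_cols = [hcc.loc[p, "sample_id"] for p in common]
        ntl_cols = [ntl.loc[p, "sample_id"] for p in common]
        beta_hcc = beta_hcc[hcc_cols]
        beta_ntl = beta_ntl[ntl_cols]
    elif beta_hcc.shape[1] != beta_ntl.shape[1]:
        raise ValueError("matrices have different sample counts and no "
                         "pairing was given")
    return beta_hcc, beta_ntl


def test_dmps(beta_hcc: pd.DataFrame, beta_ntl: pd.DataFrame,
              pairing: pd.DataFrame | None = None,
              epsilon: float = 1e-3, prior_df=None) -> pd.DataFrame:
    """Per-probe paired moderated t-test on M-values.

    Returns a DataFrame indexed by probe with ``delta_beta`` (β scale),
    ``statistic``, ``p`` and BH-adjusted ``q``.
    """
    beta_hcc, beta_ntl = _align_pairs(beta_hcc, beta_ntl, pairing)
    if beta_hcc.shape[1] < 3:
        raise ValueError("at least 3 pairs are required")
    m_hcc = beta_to_m(beta_hcc.to_numpy(), epsilon)
    m_ntl = beta_to_m(beta_ntl.to_numpy(), epsilon)
    res = PairedModeratedTTest(m_hcc, m_ntl,
                               feature_ids=beta_hcc.index).fit(
        prior_df=prior_df)
    out = res.to_frame().drop(columns="effect")
    out.insert(0, "delta_beta",
               beta_hcc.mean(axis=1) - beta_ntl.mean(axis=1))
    out.index.name = "probe_id"
    return out


def call_dmps(tested: pd.DataFrame, q_threshold: float = 0.05,
              delta_threshold: float = 0.2) -> pd.DataFrame:
    """Flag DMPs (q < threshold and |Δβ| ≥ threshold) and assign direction."""
    out = tested.copy()
    out["direction"] = np.where(out["delta_beta"] > 0, "hyper", "hypo")
    out["is_dmp"] = (out["q"] < q_threshold) & (
        out["delta_beta"].abs() >= delta_threshold
    )
    return out


def apply_stringent_filters(dmps: pd.DataFrame, beta_hcc: pd.DataFrame,
                            beta_ntl: pd.DataFrame,
                            delta: float = 0.20, fraction: float = 0.70,
                            n_sd: float = 2.0, ntl_hyper: float = 0.25,
                            ntl_hypo: float = 0.25,
                            sd_floor: float = 0.01) -> pd.DataFrame:
    """Evaluate the three stringent criteria per probe.

    The 2-SD bound (c2) uses the mean and SD of β across *all* normal
    samples at the probe, with an SD floor guarding degenerate
    zero-variance probes; the bound is mirrored below the mean for
    hypomethylated probes.  ``passes_stringent`` requires the probe to be a
    called DMP and all of c1-c3.
    """
    beta_hcc = beta_hcc.loc[dmps.index]
    beta_ntl = beta_ntl.loc[dmps.index]
    ntl_mean = beta_ntl.mean(axis=1)
    ntl_sd = beta_ntl.std(axis=1, ddof=1).clip(lower=sd_floor)
    hyper = dmps["direction"] == "hyper"

    out = dmps.copy()
    out["c1"] = out["delta_beta"].abs() >= delta

    upper = ntl_mean + n_sd * ntl_sd
    lower = ntl_mean - n_sd * ntl_sd
    frac_above = beta_hcc.gt(upper, axis=0).mean(axis=1)
    frac_below = beta_hcc.lt(lower, axis=0).mean(axis=1)
    out["c2"] = np.where(hyper, frac_above > fraction, frac_below > fraction)

    out["c3"] = np.where(hyper, ntl_mean <= ntl_hyper, ntl_mean >= ntl_hypo)

    is_dmp = out["is_dmp"] if "is_dmp" in out else True
    out["passes_stringent"] = is_dmp & out["c1"] & out["c2"] & out["c3"]
    return out


def exclude_age_related(dmps: pd.DataFrame, exclusion) -> pd.DataFrame:
    """Flag probes on an age-related exclusion list.

    ``exclusion`` is an iterable of probe ids; ids absent from the result
    table are warned about and ignored.  Flagged probes keep their rows but
    are dropped from downstream summaries.
    """
    exclusion = set(exclusion)
    unknown = exclusion - set(dmps.index)
    if unknown:
        logger.warning(
            "%d exclusion-list probe id(s) not present in results; ignored",
            len(unknown),
        )
    out = dmps.copy()
    out["age_excluded"] = out.index.isin(exclusion - unknown)
    return out


def passing(dmps: pd.DataFrame) -> pd.DataFrame:
    """Rows that pass the stringent filters and any age exclusion."""
    mask = dmps["passes_stringent"]
    if "age_excluded" in dmps:
        mask = mask & ~dmps["age_excluded"]
    return dmps[mask]


def summarize_context(dmps: pd.DataFrame, manifest: pd.DataFrame) -> dict:
    """Cross-tabulate passing DMPs by direction x island relation x feature.

    Also reports the hypermethylated fraction among all passing DMPs.
    Raises if any passing probe is missing from the manifest.
    """
    keep = passing(dmps)
    ann = manifest.set_index("probe_id")
    missing = keep.index.difference(ann.index)
    if len(missing):
        raise KeyError(f"probe(s) missing from manifest: {list(missing)[:5]}")
    ann = ann.loc[keep.index]
    n = len(keep)
    tab = (
        pd.crosstab(
            [keep["direction"], ann["island_relation"]], ann["feature"]
        )
        if n
        else pd.DataFrame()
    )
    n_hyper = int((keep["direction"] == "hyper").sum())
    return {
        "n_dmps": n,
        "n_hyper": n_hyper,
        "n_hypo": n - n_hyper,
        "hyper_fraction": (n_hyper / n) if n else float("nan"),
        "crosstab": tab,
    }
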