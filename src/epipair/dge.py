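"""Paired differential gene expression between tumour and normal profiles.

A simplified gene-level analysis: expression is assumed already normalised
and log2-scaled, and per-gene paired differences are tested with the same
empirical-Bayes moderated t machinery used for methylation, with BH
adjustment across genes.  Optional linear-scale fold-change gates
(< 0.7 or > 1.5) can be enabled on top of the q < 0.05 call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dmp import _align_pairs
from .stats import PairedModeratedTTest

FC_LOW, FC_HIGH = 0.7, 1.5


def test_dge(expr_hcc: pd.DataFrame, expr_ntl: pd.DataFrame,
             pairing: pd.DataFrame | None = None,
             q_threshold: float = 0.05, fc_gates: bool = False,
             prior_df=None) -> pd.DataFrame:
    """Per-gene paired moderated t-test on log2 expression.

    Returns a DataFrame indexed by gene with ``log_fc`` (mean paired log2
    difference tumour − normal), ``statistic``, ``p``, ``q``, ``direction``
    and the significance flag ``is_deg``.  With ``fc_gates`` the call also
    requires a linear fold change above 1.5 or below 0.7.
    """
    expr_hcc, expr_ntl = _align_pairs(expr_hcc, expr_ntl, pairing)
    if expr_hcc.shape[1] < 3:
        raise ValueError("at least 3 pairs are required")
    res = PairedModeratedTTest(expr_hcc.to_numpy(), expr_ntl.to_numpy(),
                               feature_ids=expr_hcc.index).fit(
        prior_df=prior_df)
    out = res.to_frame().rename(columns={"effect": "log_fc"})
    out.index.name = "gene_symbol"
    out["direction"] = np.where(out["log_fc"] > 0, "up", "down")
    out["is_deg"] = out["q"] < q_threshold
    if fc_gates:
        fc = 2.0 ** out["log_fc"]
        out["is_deg"] &= (fc > FC_HIGH) | (fc < FC_LOW)
    return out


def split_by_tissue(expr: pd.DataFrame, sheet: pd.DataFrame):
    """Split a pooled genes x samples matrix into paired HCC/NTL matrices."""
    hcc = sheet[sheet["tissue"] == "HCC"].sort_values("pair_id")
    ntl = sheet[sheet["tissue"] == "NTL"].sort_values("pair_id")
    return expr[list(hcc["sample_id"])], expr[list(ntl["sample_id"])]
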