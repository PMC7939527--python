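"""5-hydroxymethylcytosine (5hmC) calling and transition classification.

A BS array reads 5mC + 5hmC jointly while an oxBS array reads 5mC only, so
the per-sample 5hmC-score is the BS − oxBS β difference.  A probe is a
5hmC candidate in a tissue when its score is ≥ 0.3 in at least three
samples of that tissue; definite calls are candidates whose mean score
survives a density cut keeping the upper 75% of candidate mean scores.
Calls are made independently in tumour and normal tissue, each CpG is
assigned a state (non-5mC / 5mC / 5hmC) per tissue, and state changes are
classified into four categories:

  I   non-5mC → 5hmC (de novo hydroxymethylation)
  II  5mC → 5hmC
  III 5hmC → non-5mC
  IV  5hmC → 5mC
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STATES = ("non5mC", "fivemC", "fivehmC")
_CATEGORY = {
    ("non5mC", "fivehmC"): "I",
    ("fivemC", "fivehmC"): "II",
    ("fivehmC", "non5mC"): "III",
    ("fivehmC", "fivemC"): "IV",
}


def compute_scores(beta_bs: pd.DataFrame,
                   beta_oxbs: pd.DataFrame) -> pd.DataFrame:
    """Per-probe, per-sample 5hmC-score (β_BS − β_oxBS).

    Negative scores are retained (useful for QC) but never produce calls.
    """
    if not (beta_bs.index.equals(beta_oxbs.index)
            and list(beta_bs.columns) == list(beta_oxbs.columns)):
        raise ValueError("BS and oxBS matrices must share probes and samples")
    return beta_bs - beta_oxbs


def call_5hmc(scores: pd.DataFrame, score_threshold: float = 0.3,
              min_samples: int = 3,
              density_quantile: float = 0.75) -> pd.DataFrame:
    """Call 5hmC probes in one tissue from its score matrix.

    Returns a DataFrame indexed by probe with ``n_above`` (samples with
    score ≥ threshold), ``mean_score``, ``candidate`` and ``definite``
    flags.  The density filter keeps candidates whose mean score is at or
    above the (1 − density_quantile) quantile of candidate mean scores;
    ``density_quantile=1`` disables the cut.
    """
    if scores.shape[1] < min_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {scores.shape[1]} "
            "available samples"
        )
    n_above = (scores >= score_threshold).sum(axis=1)
    mean_score = scores.mean(axis=1)
    candidate = n_above >= min_samples
    definite = candidate.copy()
    if candidate.any() and density_quantile < 1.0:
        cut = float(np.quantile(mean_score[candidate],
                                1.0 - density_quantile))
        definite = candidate & (mean_score >= cut)
    return pd.DataFrame(
        {
            "n_above": n_above,
            "mean_score": mean_score,
            "candidate": candidate,
            "definite": definite,
        }
    )


def assign_states(called: pd.Series, beta_oxbs: pd.DataFrame,
                  methylated_threshold: float = 0.3) -> pd.Series:
    """Assign a methylation state to every probe in one tissue.

    A probe called 5hmC is ``fivehmC`` regardless of its oxBS level;
    otherwise it is ``fivemC`` when its mean β_oxBS is at or above the
    methylated threshold and ``non5mC`` below it.  The threshold is an
    artifact decision: the underlying array protocol defines no numeric
    boundary between methylated and unmethylated.
    """
    mean_ox = beta_oxbs.mean(axis=1)
    called = called.reindex(mean_ox.index, fill_value=False).astype(bool)
    state = np.where(
        called, "fivehmC",
        np.where(mean_ox >= methylated_threshold, "fivemC", "non5mC"),
    )
    return pd.Series(state, index=mean_ox.index, name="state")


def classify_transitions(states_ntl: pd.Series,
                         states_hcc: pd.Series) -> pd.DataFrame:
    """Classify per-CpG state changes from normal to tumour tissue.

    Returns one row per probe with both states and the category
    (I/II/III/IV, or ``none`` for any other state pair).  A pure function
    of the two state vectors.
    """
    if not states_ntl.index.equals(states_hcc.index):
        raise ValueError("state vectors must share the probe index")
    cats = [
        _CATEGORY.get((n, h), "none")
        for n, h in zip(states_ntl, states_hcc)
    ]
    return pd.DataFrame(
        {
            "ntl_state": states_ntl.to_numpy(),
            "hcc_state": states_hcc.to_numpy(),
            "category": cats,
        },
        index=states_ntl.index,
    )


def category_counts(transitions: pd.DataFrame) -> dict:
    """Counts per transition category (I-IV)."""
    counts = transitions["category"].value_counts()
    return {c: int(counts.get(c, 0)) for c in ("I", "II", "III", "IV")}


def summarize_hydroxy_context(calls_hcc: pd.DataFrame,
                              calls_ntl: pd.DataFrame,
                              manifest: pd.DataFrame) -> dict:
    """Gain/loss of 5hmC by genomic context.

    Gain = probes definite in tumour only, loss = definite in normal only;
    probes called in both tissues are shared.  Counts are reported per
    island relation and per gene-feature region.
    """
    hcc = set(calls_hcc.index[calls_hcc["definite"]])
    ntl = set(calls_ntl.index[calls_ntl["definite"]])
    gain, loss, shared = hcc - ntl, ntl - hcc, hcc & ntl
    ann = manifest.set_index("probe_id")
    missing = (hcc | ntl) - set(ann.index)
    if missing:
        raise KeyError(
            f"called probe(s) missing from manifest: {sorted(missing)[:5]}"
        )

    def count_by(probes, col):
        if not probes:
            return {}
        vc = ann.loc[sorted(probes), col].value_counts()
        return {str(k): int(v) for k, v in vc.items()}

    return {
        "n_gain": len(gain),
        "n_loss": len(loss),
        "n_shared": len(shared),
        "gain_by_island_relation": count_by(gain, "island_relation"),
        "loss_by_island_relation": count_by(loss, "island_relation"),
        "gain_by_feature": count_by(gain, "feature"),
        "loss_by_feature": count_by(loss, "feature"),
    }
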