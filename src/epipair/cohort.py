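"""Cohort description: age stratification, Table-style summaries, AFP.

Patients are stratified into adolescents and young adults (AYA, age <= 44
years) and middle/old age (MOA, age > 44).  Categorical variables are
compared between strata by chi-square (Fisher's exact for 2x2 tables with
any expected cell < 5), continuous variables by Welch's t-test.  AFP is
additionally reported normalised by tumour diameter (ng/mL per tumour-cm).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

AYA, MOA = "AYA", "MOA"
DEFAULT_AGE_CUTOFF = 44


def percent(count: float, total: float, decimals: int = 1) -> float:
    """Percentage of ``count`` in ``total`` rounded to ``decimals``."""
    if total == 0:
        raise ValueError("total must be non-zero")
    return round(100.0 * count / total, decimals)


def stratify_by_age(sheet: pd.DataFrame,
                    cutoff: int = DEFAULT_AGE_CUTOFF) -> pd.Series:
    """Label every pair AYA (age <= cutoff) or MOA (age > cutoff).

    Returns a Series indexed by ``pair_id``.  Missing ages raise with the
    offending pair named.
    """
    pairs = sheet.drop_duplicates("pair_id").set_index("pair_id")
    missing = pairs.index[pairs["age"].isna()]
    if len(missing):
        raise ValueError(f"missing age for pair(s): {', '.join(missing)}")
    return pairs["age"].le(cutoff).map({True: AYA, False: MOA})


def normalize_afp(afp, tumor_size):
    """AFP per tumour centimetre (ng/mL/tumour-cm).

    Element-wise ``afp / tumor_size``; non-positive or missing sizes yield
    NaN (flagged missing) rather than an error.
    """
    afp = np.asarray(afp, dtype=float)
    size = np.asarray(tumor_size, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(size > 0, afp / size, np.nan)
    return out if out.ndim else float(out)


def _describe(values: np.ndarray) -> dict:
    values = values[~np.isnan(values)]
    if values.size == 0:
        return {"n": 0}
    q1, q3 = np.percentile(values, [25, 75])  # linear interpolation
    return {
        "n": int(values.size),
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
        "median": float(np.median(values)),
        "range": [float(values.min()), float(values.max())],
        "iqr": float(q3 - q1),
    }


def _categorical_block(series_by_stratum: dict) -> dict:
    levels = sorted(
        {lv for s in series_by_stratum.values() for lv in s.dropna().unique()},
        key=str,
    )
    block = {}
    for name, s in series_by_stratum.items():
        s = s.dropna()
        block[name] = {
            str(lv): {
                "count": int((s == lv).sum()),
                "pct": percent((s == lv).sum(), len(s)) if len(s) else None,
            }
            for lv in levels
        }
    return block


def _categorical_test(aya: pd.Series, moa: pd.Series) -> dict:
    aya, moa = aya.dropna(), moa.dropna()
    if len(aya) == 0 or len(moa) == 0:
        return {"available": False}
    levels = sorted(set(aya.unique()) | set(moa.unique()), key=str)
    if len(levels) < 2:
        return {"available": False}
    table = np.array(
        [[(s == lv).sum() for lv in levels] for s in (aya, moa)], dtype=int
    )
    expected = stats.contingency.expected_freq(table)
    if table.shape == (2, 2) and (expected < 5).any():
        _, p = stats.fisher_exact(table)
        name = "fisher_exact"
    else:
        _, p, _, _ = stats.chi2_contingency(table)
        name = "chi_square"
    return {"available": True, "test": name, "p": float(p)}


def _continuous_test(aya: np.ndarray, moa: np.ndarray) -> dict:
    aya, moa = aya[~np.isnan(aya)], moa[~np.isnan(moa)]
    if len(aya) < 2 or len(moa) < 2:
        return {"available": False}
    t, p = stats.ttest_ind(aya, moa, equal_var=False)
    return {"available": True, "test": "welch_t", "statistic": float(t),
            "p": float(p)}


def summarize_cohort(sheet: pd.DataFrame,
                     cutoff: int = DEFAULT_AGE_CUTOFF) -> dict:
    """Descriptive and comparative cohort summary over pairs.

    Returns a nested dict with per-variable blocks (counts/percentages for
    categorical variables, mean/SD/median/range/IQR for continuous ones)
    stratified overall / AYA / MOA, plus the between-stratum test for each
    variable.  With an empty stratum, descriptive output is still produced
    and every test is flagged unavailable.
    """
    pairs = sheet.drop_duplicates("pair_id").copy()
    strat = stratify_by_age(sheet, cutoff)
    pairs["stratum"] = pairs["pair_id"].map(strat)
    aya = pairs[pairs["stratum"] == AYA]
    moa = pairs[pairs["stratum"] == MOA]
    strata = {"overall": pairs, AYA: aya, MOA: moa}

    n_aya, n_moa, n_all = len(aya), len(moa), len(pairs)
    summary: dict = {
        "n": {"overall": n_all, AYA: n_aya, MOA: n_moa},
        "aya_pct": percent(n_aya, n_all),
        "moa_pct": percent(n_moa, n_all),
        "age_cutoff": cutoff,
        "variables": {},
    }

    pairs = pairs.assign(
        afp_per_cm=normalize_afp(pairs.get("afp", np.nan),
                                 pairs.get("tumor_size", np.nan))
    )
    strata = {k: pairs.loc[v.index] for k, v in strata.items()}

    categorical = [c for c in ("sex", "hbv_positive", "cirrhosis")
                   if c in pairs.columns]
    continuous = [c for c in ("age", "tumor_size", "afp", "afp_per_cm")
                  if c in pairs.columns]

    for var in categorical:
        block = _categorical_block({k: v[var] for k, v in strata.items()})
        block["comparison"] = (
            _categorical_test(strata[AYA][var], strata[MOA][var])
            if n_aya and n_moa else {"available": False}
        )
        summary["variables"][var] = block
    for var in continuous:
        block = {k: _describe(v[var].to_numpy(dtype=float))
                 for k, v in strata.items()}
        block["comparison"] = (
            _continuous_test(strata[AYA][var].to_numpy(dtype=float),
                             strata[MOA][var].to_numpy(dtype=float))
            if n_aya and n_moa else {"available": False}
        )
        summary["variables"][var] = block
    return summary
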