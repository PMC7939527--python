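"""Shared statistical machinery for paired differential testing.

The central object is :class:`PairedModeratedTTest`, a small model class in
the statsmodels idiom: it is constructed from two feature x sample matrices
whose columns are paired one-to-one, and its :meth:`~PairedModeratedTTest.fit`
returns a :class:`ModeratedTTestResults` carrying effects, moderated
statistics, p-values and Benjamini-Hochberg q-values.

Variance moderation follows the empirical-Bayes scheme standard for
microarray-scale designs: per-feature sample variances of the paired
differences are shrunk toward a common prior variance, with the prior
variance and prior degrees of freedom estimated across features by the
method of moments on log-variances (a scaled inverse-chi-square prior).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "beta_to_m",
    "bh_adjust",
    "trigamma_inverse",
    "fit_variance_prior",
    "PairedModeratedTTest",
    "ModeratedTTestResults",
    "spearman",
    "hypergeometric_enrichment_p",
]

_S2_FLOOR = 1e-12


def beta_to_m(beta, epsilon: float = 1e-3):
    """Logit-transform methylation fractions to M-values.

    M = log2((beta + eps) / (1 - beta + eps)).  The offset ``epsilon`` guards
    the boundaries beta = 0 and beta = 1; the transform is strictly
    increasing in beta for any epsilon >= 0.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any((beta < 0) | (beta > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    return np.log2((beta + epsilon) / (1.0 - beta + epsilon))


def bh_adjust(p):
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 64) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Used to back out the prior degrees of freedom from the excess spread of
    log sample variances.
    """
    if not np.isfinite(x) or x <= 0:
        return np.inf
    # trigamma(y) ~ 1/y + 1/(2 y^2); invert the leading term for a start
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if y <= 0:
            y = 1e-8
        if abs(dif) < tol * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled inverse-chi-square variance prior.

    Given per-feature sample variances ``s2`` on ``df`` residual degrees of
    freedom each, returns ``(df_prior, s2_prior)``.  When the observed
    log-variances are no more dispersed than sampling alone predicts, the
    prior df is infinite and all variances shrink to the common value.
    """
    s2 = np.asarray(s2, dtype=float)
    z = np.log(np.maximum(s2, _S2_FLOOR))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    if e.size < 2:
        return np.inf, float(np.exp(e_mean))
    e_var = e.var(ddof=1)
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    df_prior = 2.0 * trigamma_inverse(excess)
    if not np.isfinite(df_prior):
        return np.inf, float(np.exp(e_mean))
    s2_prior = np.exp(
        e_mean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0)
    )
    return float(df_prior), float(s2_prior)


class PairedModeratedTTest:
    """Paired two-condition differential test with moderated variances.

    Parameters
    ----------
    endog_a, endog_b : array-like or DataFrame, features x samples
        Measurements under the two conditions; column ``j`` of ``endog_a``
        is paired with column ``j`` of ``endog_b``.
    feature_ids : sequence of str, optional
        Row labels; taken from ``endog_a``'s index when it is a DataFrame.
    """

    def __init__(self, endog_a, endog_b, feature_ids=None):
        a = np.asarray(endog_a, dtype=float)
        b = np.asarray(endog_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError(
                f"paired matrices must share shape, got {a.shape} vs {b.shape}"
            )
        if a.ndim != 2:
            raise ValueError("expected 2-d feature x sample matrices")
        if a.shape[1] < 3:
            raise ValueError("paired testing requires at least 3 pairs")
        if feature_ids is None and isinstance(endog_a, pd.DataFrame):
            feature_ids = endog_a.index
        self.diff = a - b
        self.n_pairs = a.shape[1]
        self.feature_ids = (
            pd.Index(feature_ids)
            if feature_ids is not None
            else pd.RangeIndex(a.shape[0])
        )

    def fit(self, prior_df=None, prior_var=None) -> "ModeratedTTestResults":
        """Estimate effects and moderated statistics.

        ``prior_df``/``prior_var`` override the method-of-moments estimates;
        ``prior_df=0`` recovers the ordinary paired t-test.
        """
        d = self.diff
        n = self.n_pairs
        df_resid = n - 1
        effect = d.mean(axis=1)
        s2 = d.var(axis=1, ddof=1)

        if prior_df is None or prior_var is None:
            est_df, est_var = fit_variance_prior(s2, df_resid)
            d0 = est_df if prior_df is None else float(prior_df)
            s02 = est_var if prior_var is None else float(prior_var)
        else:
            d0, s02 = float(prior_df), float(prior_var)

        if np.isinf(d0):
            s2_post = np.full_like(s2, s02)
        elif d0 == 0:
            s2_post = s2
        else:
            s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        s2_post = np.maximum(s2_post, _S2_FLOOR)

        tvalues = effect / np.sqrt(s2_post / n)
        df_total = df_resid + (0.0 if np.isinf(d0) else d0)
        if np.isinf(d0):
            pvalues = 2.0 * stats.norm.sf(np.abs(tvalues))
        else:
            pvalues = 2.0 * stats.t.sf(np.abs(tvalues), df_total)
        qvalues = bh_adjust(pvalues)
        return ModeratedTTestResults(
            model=self,
            effect=effect,
            s2=s2,
            s2_post=s2_post,
            tvalues=tvalues,
            pvalues=pvalues,
            qvalues=qvalues,
            df_resid=df_resid,
            df_prior=d0,
            var_prior=s02,
        )


class ModeratedTTestResults:
    """Results of :class:`PairedModeratedTTest`.

    Attributes mirror the statsmodels results convention: ``effect`` (mean
    paired difference), ``tvalues``, ``pvalues``, ``qvalues``, plus the
    moderation diagnostics ``df_prior`` and ``var_prior``.
    """

    def __init__(self, model, effect, s2, s2_post, tvalues, pvalues, qvalues,
                 df_resid, df_prior, var_prior):
        self.model = model
        self.effect = effect
        self.s2 = s2
        self.s2_post = s2_post
        self.tvalues = tvalues
        self.pvalues = pvalues
        self.qvalues = qvalues
        self.df_resid = df_resid
        self.df_prior = df_prior
        self.var_prior = var_prior
        self.n_pairs = model.n_pairs

    @property
    def df_total(self):
        d0 = self.df_prior
        return self.df_resid + (0.0 if np.isinf(d0) else d0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effect": self.effect,
                "statistic": self.tvalues,
                "p": self.pvalues,
                "q": self.qvalues,
            },
            index=self.model.feature_ids,
        )

    def summary(self, alpha: float = 0.05, top: int = 10) -> str:
        frame = self.to_frame().sort_values("p")
        n_sig = int((self.qvalues < alpha).sum())
        lines = [
            "Paired moderated t-test",
            f"  features: {len(self.effect)}   pairs: {self.n_pairs}",
            f"  prior df: {self.df_prior:.4g}   prior variance: "
            f"{self.var_prior:.4g}",
            f"  q < {alpha:g}: {n_sig}",
            "",
            frame.head(top).to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Average ranks are used for ties.  Constant input yields (nan, nan),
    flagging the correlation as undefined rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman expects two equal-length 1-d vectors")
    if x.size < 4:
        raise ValueError("spearman requires at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def hypergeometric_enrichment_p(overlap: int, universe: int, set_size: int,
                                list_size: int) -> float:
    """Upper-tail hypergeometric probability of an overlap at least as large.

    ``universe`` genes total, ``set_size`` in the gene set, ``list_size``
    selected; returns P(X >= overlap).
    """
    if universe <= 0:
        raise ValueError("universe must be non-empty")
    if overlap > min(set_size, list_size):
        raise ValueError("overlap exceeds set or list size")
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, list_size))
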