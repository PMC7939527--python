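"""Expression-methylation integration and gene-set enrichment.

Differentially expressed genes are merged, by gene symbol, with (a) probes
passing the stringent DMP filters and (b) probes undergoing de novo
hydroxymethylation (category I transitions), yielding gene-probe dyads.
Spearman's ρ is then computed between each gene's expression and the
probe's β value (or 5hmC-score for the de novo layer) across samples —
pooling both tissues by default, which maximises dynamic range — and dyads
with |ρ| above a threshold (default 0.5, strict) are selected and labelled
by concordance (e.g. hypermethylated & downregulated).  Selected genes are
finally tested for gene-set enrichment with an upper-tail hypergeometric
test, Bonferroni-corrected across sets by default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .dmp import passing
from .stats import bh_adjust, hypergeometric_enrichment_p, spearman

logger = logging.getLogger(__name__)

LAYER_DMP = "dmp"
LAYER_5HMC = "de_novo_5hmC"


def merge_layers(degs: pd.DataFrame, dmps: pd.DataFrame,
                 transitions: pd.DataFrame,
                 manifest: pd.DataFrame) -> pd.DataFrame:
    """Merge significant DEGs with DMP and de novo 5hmC probes by gene.

    One dyad per (DEG gene x matching probe): probes passing the stringent
    DMP filters form the ``dmp`` layer, category-I transition probes the
    ``de_novo_5hmC`` layer.  Only category I (non-5mC → 5hmC) is merged.
    DEG genes with no probe in either layer are dropped (count logged).
    """
    deg_genes = set(degs.index[degs["is_deg"]])
    probe_gene = manifest.set_index("probe_id")["gene_symbol"]

    rows = []
    dmp_probes = passing(dmps).index
    for probe in dmp_probes:
        g = probe_gene.get(probe, "")
        if g in deg_genes:
            rows.append({"gene_symbol": g, "probe_id": probe,
                         "layer": LAYER_DMP})
    cat1 = transitions.index[transitions["category"] == "I"]
    for probe in cat1:
        g = probe_gene.get(probe, "")
        if g in deg_genes:
            rows.append({"gene_symbol": g, "probe_id": probe,
                         "layer": LAYER_5HMC})
    dyads = pd.DataFrame(rows, columns=["gene_symbol", "probe_id", "layer"])
    n_dropped = len(deg_genes - set(dyads["gene_symbol"]))
    if n_dropped:
        logger.info("%d DEG gene(s) had no matching probe and were dropped",
                    n_dropped)
    return dyads


def correlate_dyads(dyads: pd.DataFrame, expr: pd.DataFrame,
                    beta: pd.DataFrame,
                    hmc_scores: pd.DataFrame | None = None,
                    samples: list | None = None) -> pd.DataFrame:
    """Compute Spearman ρ per dyad between expression and methylation.

    ``expr`` is genes x samples, ``beta`` probes x samples (pooled BS β);
    ``hmc_scores`` supplies the probe signal for the de novo 5hmC layer
    (falls back to β when absent).  ``samples`` restricts the columns used
    (e.g. tumour-only mode); by default the columns shared by both matrices
    are used, pooling the two tissues.
    """
    if expr.index.duplicated().any():
        raise ValueError("duplicate gene symbols in expression matrix")
    if samples is None:
        samples = [c for c in expr.columns if c in set(beta.columns)]
    if len(samples) < 4:
        raise ValueError("need at least 4 shared samples for correlation")
    out = dyads.copy()
    rhos, ps = [], []
    for _, row in out.iterrows():
        src = beta
        if row["layer"] == LAYER_5HMC and hmc_scores is not None:
            src = hmc_scores
        x = src.loc[row["probe_id"], samples].to_numpy(dtype=float)
        y = expr.loc[row["gene_symbol"], samples].to_numpy(dtype=float)
        rho, p = spearman(x, y)
        rhos.append(rho)
        ps.append(p)
    out["rho"] = rhos
    out["rho_p"] = ps
    return out


def select_dyads(dyads: pd.DataFrame, degs: pd.DataFrame,
                 dmps: pd.DataFrame,
                 rho_threshold: float = 0.5) -> pd.DataFrame:
    """Select dyads with |ρ| strictly above the threshold and label them.

    Concordance crosses the probe's methylation direction with the gene's
    expression direction (``hyper_down`` etc.); de novo 5hmC dyads get
    ``na``.  Also attaches the selection flag used downstream.
    """
    out = dyads.copy()
    out["selected"] = out["rho"].abs() > rho_threshold
    out.loc[out["rho"].isna(), "selected"] = False
    deg_dir = degs["direction"]
    dmp_dir = dmps["direction"]
    labels = []
    for _, row in out.iterrows():
        if row["layer"] != LAYER_DMP:
            labels.append("na")
            continue
        labels.append(
            f"{dmp_dir.get(row['probe_id'], 'na')}_"
            f"{deg_dir.get(row['gene_symbol'], 'na')}"
        )
    out["concordance"] = labels
    return out


def hyper_down_fraction(selected: pd.DataFrame) -> float:
    """Fraction of selected dmp-layer genes concomitantly hypermethylated
    and downregulated."""
    sel = selected[selected["selected"] & (selected["layer"] == LAYER_DMP)]
    genes = sel.groupby("gene_symbol")["concordance"].agg(
        lambda s: (s == "hyper_down").any()
    )
    return float(genes.mean()) if len(genes) else float("nan")


def enrich(selected_genes, universe, gene_sets: dict,
           correction: str = "bonferroni") -> pd.DataFrame:
    """Hypergeometric gene-set enrichment of a selected gene list.

    Gene sets are intersected with the universe before testing; the
    upper-tail hypergeometric p of the observed overlap is corrected across
    all tested sets (Bonferroni by default, BH available).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected_genes) & universe
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        overlap = len(selected & members)
        p = hypergeometric_enrichment_p(
            overlap, len(universe), len(members), len(selected)
        )
        rows.append({"gene_set": name, "overlap": overlap,
                     "set_size": len(members), "list_size": len(selected),
                     "universe_size": len(universe), "p": p})
    out = pd.DataFrame(rows)
    if correction == "bonferroni":
        out["p_adj"] = np.minimum(out["p"] * len(out), 1.0)
    elif correction == "bh":
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    else:
        raise ValueError("correction must be 'bonferroni' or 'bh'")
    return out


def summary_report(degs: pd.DataFrame, dmps: pd.DataFrame,
                   transitions: pd.DataFrame,
                   manifest: pd.DataFrame) -> dict:
    """Gene counts per layer and every pairwise/triple overlap.

    Layers follow the circular-plot convention: downregulated DEGs,
    stringent DMP genes, de novo (category I) 5hmC genes.
    """
    probe_gene = manifest.set_index("probe_id")["gene_symbol"]
    down = set(degs.index[degs["is_deg"] & (degs["direction"] == "down")])
    dmp_genes = {probe_gene.get(p, "") for p in passing(dmps).index} - {""}
    hmc_genes = {
        probe_gene.get(p, "")
        for p in transitions.index[transitions["category"] == "I"]
    } - {""}
    return {
        "n_down_degs": len(down),
        "n_dmp_genes": len(dmp_genes),
        "n_de_novo_5hmc_genes": len(hmc_genes),
        "deg_dmp": len(down & dmp_genes),
        "deg_5hmc": len(down & hmc_genes),
        "dmp_5hmc": len(dmp_genes & hmc_genes),
        "triple": len(down & dmp_genes & hmc_genes),
    }
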