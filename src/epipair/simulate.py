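"""Synthetic paired tumour/non-tumour methylome and transcriptome studies.

Generates probe manifests, sample sheets, paired bisulfite (BS) and
oxidative-bisulfite (oxBS) β-value matrices, expression matrices, probe
exclusion lists and gene sets — all with planted, parameterised effects and
a machine-readable truth table for recovery testing.

The measurement model mirrors paired BS/oxBS arrays: a BS β value reads
5mC + 5hmC jointly, an oxBS β value reads 5mC alone, so their difference
estimates the hydroxymethylated fraction.  Planted hypermethylated
positions fall preferentially on CpG-island promoter probes and
hypomethylated positions on open-sea gene-body probes; hydroxymethylation
transitions between tissues follow a configurable four-category mix.
Measurement noise is beta-distributed around the true fraction with a
common precision, so all observed values stay in [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimulationConfig

ISLAND_RELATIONS = ("island", "shore", "shelf", "open_sea")
FEATURES = ("TSS200", "TSS1500", "UTR5", "body", "UTR3", "intergenic")
CATEGORIES = ("I", "II", "III", "IV")

# marginal island-relation frequencies and feature mix conditional on the
# relation (islands sit in promoters, open sea in gene bodies)
_RELATION_P = {"island": 0.31, "shore": 0.23, "shelf": 0.10, "open_sea": 0.36}
_FEATURE_P = {
    "island": (0.30, 0.25, 0.10, 0.20, 0.05, 0.10),
    "shore": (0.15, 0.20, 0.10, 0.30, 0.05, 0.20),
    "shelf": (0.05, 0.10, 0.10, 0.40, 0.10, 0.25),
    "open_sea": (0.03, 0.07, 0.05, 0.45, 0.10, 0.30),
}
# unmethylated islands, mostly methylated open sea in normal tissue
_BASELINE_5MC = {"island": 0.12, "shore": 0.35, "shelf": 0.50, "open_sea": 0.65}

_PLACEMENT_BIAS = 0.8   # chance a planted DMP lands in its preferred context
_CLUSTER_P = 0.3        # chance a planted DMP recruits its genomic neighbour


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


@dataclass
class TruthTable:
    """Planted ground truth emitted by the simulator."""

    dmp_probes: list = field(default_factory=list)       # (probe_id, dir)
    dmr_intervals: list = field(default_factory=list)    # (chrom, s, e, dir)
    hmc_transitions: dict = field(default_factory=dict)  # probe_id -> cat
    deg_genes: list = field(default_factory=list)        # (gene, dir)
    corr_dyads: list = field(default_factory=list)       # (gene, probe, sign)

    def dmp_set(self) -> set:
        return {p for p, _ in self.dmp_probes}

    def deg_set(self) -> set:
        return {g for g, _ in self.deg_genes}

    def to_json(self, path) -> None:
        payload = {
            "dmp_probes": [list(t) for t in self.dmp_probes],
            "dmr_intervals": [list(t) for t in self.dmr_intervals],
            "hmc_transitions": self.hmc_transitions,
            "deg_genes": [list(t) for t in self.deg_genes],
            "corr_dyads": [list(t) for t in self.corr_dyads],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        d = json.loads(Path(path).read_text())
        return cls(
            dmp_probes=[tuple(t) for t in d["dmp_probes"]],
            dmr_intervals=[tuple(t) for t in d["dmr_intervals"]],
            hmc_transitions=dict(d["hmc_transitions"]),
            deg_genes=[tuple(t) for t in d["deg_genes"]],
            corr_dyads=[tuple(t) for t in d["corr_dyads"]],
        )


def validate_sheet(sheet: pd.DataFrame) -> None:
    """Check the one-HCC/one-NTL-per-pair structure and equal pair ages."""
    for pair_id, grp in sheet.groupby("pair_id"):
        tissues = sorted(grp["tissue"])
        if tissues != ["HCC", "NTL"]:
            raise ValueError(
                f"pair {pair_id} must have exactly one HCC and one NTL row"
            )
        if grp["age"].nunique() != 1:
            raise ValueError(f"pair {pair_id} has inconsistent ages")


def generate_manifest(config: SimulationConfig) -> pd.DataFrame:
    """Generate a CpG probe manifest with genomic context annotation.

    Probes are laid out along autosomes with roughly exponential inter-probe
    gaps; island relation and gene-feature region are drawn jointly so that
    islands concentrate in promoter windows and open sea in gene bodies.
    Every one of the ``n_genes`` gene symbols is guaranteed at least one
    probe; intergenic probes carry an empty symbol.
    """
    n, n_genes = config.n_probes, config.n_genes
    if n < 10:
        raise ValueError(f"n_probes must be >= 10, got {n}")
    rng = _rng(config, 1)

    n_chroms = int(min(22, max(1, n // 50 + 1)))
    chrom_idx = np.sort(rng.integers(0, n_chroms, size=n))
    gaps = 10 + rng.exponential(scale=400, size=n).astype(int)
    pos = np.empty(n, dtype=int)
    for c in range(n_chroms):
        mask = chrom_idx == c
        pos[mask] = 1000 + np.cumsum(gaps[mask])

    relations = rng.choice(
        ISLAND_RELATIONS, size=n, p=[_RELATION_P[r] for r in ISLAND_RELATIONS]
    )
    features = np.empty(n, dtype=object)
    for rel in ISLAND_RELATIONS:
        mask = relations == rel
        features[mask] = rng.choice(FEATURES, size=mask.sum(), p=_FEATURE_P[rel])

    genes = np.array([f"GENE{i + 1:05d}" for i in range(n_genes)])
    gene_col = np.full(n, "", dtype=object)
    genic = np.flatnonzero(features != "intergenic")
    if genic.size < n_genes:
        raise ValueError(
            f"only {genic.size} genic probes for {n_genes} genes; "
            "increase n_probes or decrease n_genes"
        )
    order = rng.permutation(genic)
    gene_col[order[:n_genes]] = genes                      # coverage
    gene_col[order[n_genes:]] = rng.choice(genes, size=genic.size - n_genes)

    manifest = pd.DataFrame(
        {
            "probe_id": [f"cg{i + 1:08d}" for i in range(n)],
            "chrom": [f"chr{c + 1}" for c in chrom_idx],
            "pos": pos,
            "island_relation": relations,
            "gene_symbol": gene_col,
            "feature": features,
        }
    )
    manifest = manifest.sort_values(
        ["chrom", "pos"],
        key=lambda s: s.str.removeprefix("chr").astype(int) if s.name == "chrom" else s,
    ).reset_index(drop=True)
    return manifest


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a paired HCC/NTL sample sheet with a bimodal age structure.

    Ages come from a two-component truncated-normal mixture — a young mode
    near 27 years on [13, 44] and an old mode near 67 on [45, 94] — with
    mixture weight ``aya_fraction`` on the young component, emulating the
    bimodal age distribution of the modelled cohort.  AFP is lognormal with
    stratum-specific scale so that tumour-size-normalised AFP is several-fold
    higher in the young stratum.
    """
    if config.n_pairs < 2:
        raise ValueError(f"n_pairs must be >= 2, got {config.n_pairs}")
    rng = _rng(config, 2)
    n = config.n_pairs

    young = rng.random(n) < config.aya_fraction
    ages = np.where(
        young,
        np.round(_truncnorm(rng, 27, 9, 13, 44, n)),
        np.round(_truncnorm(rng, 67, 11.3, 45, 94, n)),
    ).astype(int)
    male = rng.random(n) < 0.69
    hbv = rng.random(n) < np.where(young, 0.923, 0.80)
    cirrhosis = rng.random(n) < np.where(young, 0.0, 0.114)
    tumor_size = np.round(_truncnorm(rng, 14.4, 7.5, 5, 30, n), 1)
    # lognormal AFP per tumour-cm: young mean/SD 9273/14613, old 3305/7737
    sig_y = np.sqrt(np.log(1 + (14613 / 9273) ** 2))
    sig_o = np.sqrt(np.log(1 + (7737 / 3305) ** 2))
    mu = np.where(young, np.log(9273) - sig_y**2 / 2,
                  np.log(3305) - sig_o**2 / 2)
    sig = np.where(young, sig_y, sig_o)
    afp = np.round(tumor_size * rng.lognormal(mu, sig), 1)

    rows = []
    for i in range(n):
        pair = f"P{i + 1:04d}"
        base = {
            "pair_id": pair,
            "age": int(ages[i]),
            "sex": "M" if male[i] else "F",
            "hbv_positive": bool(hbv[i]),
            "cirrhosis": bool(cirrhosis[i]),
            "afp": float(afp[i]),
            "tumor_size": float(tumor_size[i]),
        }
        for tissue in ("HCC", "NTL"):
            rows.append({"sample_id": f"{pair}_{tissue}",
                         "tissue": tissue, **base})
    sheet = pd.DataFrame(rows)[
        ["sample_id", "pair_id", "tissue", "age", "sex", "hbv_positive",
         "cirrhosis", "afp", "tumor_size"]
    ]
    validate_sheet(sheet)
    return sheet


def _scan_planted_dmrs(manifest, planted: dict, max_gap: int = 250,
                       min_probes: int = 2) -> list:
    """Derive truth DMR intervals from planted DMPs (chain rule)."""
    sub = manifest[manifest["probe_id"].isin(planted)].copy()
    sub["direction"] = sub["probe_id"].map(planted)
    out = []
    for chrom, grp in sub.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        run = []
        prev_pos, prev_dir = None, None
        for _, row in grp.iterrows():
            if (run and row["direction"] == prev_dir
                    and row["pos"] - prev_pos <= max_gap):
                run.append(row)
            else:
                if len(run) >= min_probes:
                    out.append((chrom, int(run[0]["pos"]),
                                int(run[-1]["pos"]), prev_dir))
                run = [row]
            prev_pos, prev_dir = row["pos"], row["direction"]
        if len(run) >= min_probes:
            out.append((chrom, int(run[0]["pos"]), int(run[-1]["pos"]),
                        prev_dir))
    return out


def _pick_biased(rng, n_pick, preferred, available):
    """Pick ``n_pick`` indices, each preferring the ``preferred`` pool."""
    preferred = [i for i in preferred if i in available]
    chosen = []
    pref = list(preferred)
    rng.shuffle(pref)
    for _ in range(n_pick):
        if pref and rng.random() < _PLACEMENT_BIAS:
            idx = pref.pop()
        else:
            idx = int(rng.choice(list(available)))
            if idx in pref:
                pref.remove(idx)
        chosen.append(idx)
        available.discard(idx)
    return chosen


def simulate_methylome(manifest: pd.DataFrame, sheet: pd.DataFrame,
                       config: SimulationConfig):
    """Simulate paired BS/oxBS β matrices with planted DMPs and 5hmC.

    Returns ``(beta_bs_hcc, beta_bs_ntl, beta_oxbs_hcc, beta_oxbs_ntl,
    truth)``.  Observed values are β_BS = clamp(5mC + 5hmC) + noise and
    β_oxBS = clamp(5mC) + noise, the noise beta-distributed with precision
    ``beta_dispersion`` (``None``/inf ⇒ noise-free).
    """
    validate_sheet(sheet)
    if not set(manifest.columns) >= {"probe_id", "chrom", "pos",
                                     "island_relation", "feature"}:
        raise ValueError("manifest is missing required columns")
    rng = _rng(config, 3)
    n = len(manifest)
    probes = manifest["probe_id"].to_numpy()
    relations = manifest["island_relation"].to_numpy()
    features = manifest["feature"].to_numpy()

    base_mu = np.array([_BASELINE_5MC[r] for r in relations])
    baseline = rng.beta(base_mu * 10, (1 - base_mu) * 10)
    baseline = np.clip(baseline, 0.03, 0.95)

    truth = TruthTable()
    mc_ntl = baseline.copy()
    mc_hcc = baseline.copy()
    hmc_ntl = np.zeros(n)
    hmc_hcc = np.zeros(n)

    available = set(range(n))
    if config.delta_beta_effect > 0 and config.dmp_fraction > 0:
        n_dmp = int(round(config.dmp_fraction * n))
        n_hyper = int(round(config.hyper_fraction_among_dmps * n_dmp))
        island_tss = np.flatnonzero(
            (relations == "island") & np.isin(features, ["TSS200", "TSS1500"])
        )
        opensea_body = np.flatnonzero(
            (relations == "open_sea") & (features == "body")
        )
        planted = {}
        for direction, n_dir, pool in (
            ("hyper", n_hyper, island_tss),
            ("hypo", n_dmp - n_hyper, opensea_body),
        ):
            picks = _pick_biased(rng, n_dir, pool, available)
            # occasionally recruit the genomic neighbour so that planted
            # DMPs form >= 2-probe regions
            extra = []
            for i in picks:
                j = i + 1
                if (j < n and j in available and rng.random() < _CLUSTER_P
                        and manifest["chrom"].iat[j] == manifest["chrom"].iat[i]
                        and manifest["pos"].iat[j] - manifest["pos"].iat[i]
                        <= 250):
                    extra.append(j)
                    available.discard(j)
            for i in picks + extra:
                planted[probes[i]] = direction
                shift = (config.delta_beta_effect if direction == "hyper"
                         else -config.delta_beta_effect)
                target = baseline[i] + shift
                if not 0.02 <= target <= 0.98:
                    warnings.warn(
                        f"planted effect at {probes[i]} clamped into (0,1)",
                        stacklevel=2,
                    )
                    target = float(np.clip(target, 0.02, 0.98))
                mc_hcc[i] = target
        truth.dmp_probes = sorted(planted.items())
        truth.dmr_intervals = _scan_planted_dmrs(manifest, planted)

    if config.hmc_fraction > 0:
        n_hmc = min(int(round(config.hmc_fraction * n)), len(available))
        picks = rng.choice(sorted(available), size=n_hmc, replace=False)
        available -= set(int(i) for i in picks)
        cats = rng.choice(CATEGORIES, size=n_hmc, p=list(config.transition_mix))
        low = rng.uniform(0.05, 0.12, size=n_hmc)
        low2 = rng.uniform(0.05, 0.15, size=n_hmc)
        high = rng.uniform(0.50, 0.70, size=n_hmc)
        level = rng.uniform(0.35, 0.55, size=n_hmc)
        for k, i in enumerate(picks):
            cat = cats[k]
            if cat == "I":        # unmethylated NTL -> de novo 5hmC in HCC
                mc_ntl[i], mc_hcc[i] = low[k], low[k]
                hmc_hcc[i] = level[k]
            elif cat == "II":     # methylated NTL -> 5hmC in HCC
                mc_ntl[i], mc_hcc[i] = high[k], low2[k]
                hmc_hcc[i] = level[k]
            elif cat == "III":    # 5hmC in NTL -> unmethylated HCC
                mc_ntl[i], mc_hcc[i] = low[k], low[k]
                hmc_ntl[i] = level[k]
            else:                 # IV: 5hmC in NTL -> methylated HCC
                mc_ntl[i], mc_hcc[i] = low2[k], high[k]
                hmc_ntl[i] = level[k]
            truth.hmc_transitions[probes[i]] = str(cat)

    hcc_ids = sheet.loc[sheet["tissue"] == "HCC"].sort_values("pair_id")
    ntl_ids = sheet.loc[sheet["tissue"] == "NTL"].sort_values("pair_id")

    def observe(mu, sample_ids):
        mu = np.clip(mu, 0.0, 1.0)
        m = len(sample_ids)
        if config.beta_dispersion is None or np.isinf(config.beta_dispersion):
            vals = np.tile(mu[:, None], (1, m))
        else:
            phi = float(config.beta_dispersion)
            mu_c = np.clip(mu, 1e-3, 1 - 1e-3)[:, None]
            vals = rng.beta(mu_c * phi, (1 - mu_c) * phi, size=(len(mu), m))
        return pd.DataFrame(vals, index=probes, columns=list(sample_ids))

    beta_bs_hcc = observe(mc_hcc + hmc_hcc, hcc_ids["sample_id"])
    beta_bs_ntl = observe(mc_ntl + hmc_ntl, ntl_ids["sample_id"])
    beta_oxbs_hcc = observe(mc_hcc, hcc_ids["sample_id"])
    beta_oxbs_ntl = observe(mc_ntl, ntl_ids["sample_id"])
    return beta_bs_hcc, beta_bs_ntl, beta_oxbs_hcc, beta_oxbs_ntl, truth


def simulate_expression(manifest: pd.DataFrame, sheet: pd.DataFrame,
                        truth: TruthTable, config: SimulationConfig,
                        beta_bs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Simulate a log2 expression matrix with planted DEGs and dyads.

    Planted DEG genes are shifted by ±``log_fc_effect`` in tumour columns.
    Correlated dyads couple a gene's expression to the observed β of one of
    its planted DMP probes through a Gaussian copula on ranks, so the
    population Spearman ρ magnitude equals ``rho_effect``; coupling a gene
    to a differentially methylated probe induces a tumour/normal expression
    shift, so dyad genes are genuinely differentially expressed and are
    recorded in the truth table as DEGs too.  ``beta_bs`` (pooled BS β over
    all samples) is required whenever dyads are planted.

    The truth table is updated in place with ``deg_genes`` and
    ``corr_dyads``.
    """
    validate_sheet(sheet)
    rng = _rng(config, 4)
    genes = sorted(set(manifest["gene_symbol"]) - {""})
    samples = list(sheet["sample_id"])
    is_hcc = (sheet["tissue"] == "HCC").to_numpy()
    n_genes, n_samples = len(genes), len(samples)

    baseline = rng.normal(8.0, 2.0, size=n_genes)
    expr = baseline[:, None] + rng.normal(0.0, 0.8, size=(n_genes, n_samples))
    expr = pd.DataFrame(expr, index=genes, columns=samples)

    gene_pos = {g: i for i, g in enumerate(genes)}
    dmp_probe_by_gene: dict[str, list] = {}
    probe_gene = dict(zip(manifest["probe_id"], manifest["gene_symbol"]))
    dmp_dir = dict(truth.dmp_probes)
    for probe, _ in truth.dmp_probes:
        g = probe_gene.get(probe, "")
        if g:
            dmp_probe_by_gene.setdefault(g, []).append(probe)

    n_deg = int(round(config.deg_fraction * n_genes))
    deg_genes = []
    if n_deg > 0 and config.log_fc_effect != 0:
        chosen = rng.choice(genes, size=n_deg, replace=False)
        dirs = rng.choice(["up", "down"], size=n_deg)
        for g, d in zip(chosen, dirs):
            shift = config.log_fc_effect if d == "up" else -config.log_fc_effect
            expr.iloc[gene_pos[g], is_hcc] += shift
            deg_genes.append((str(g), str(d)))

    n_dyads = int(round(config.corr_dyad_fraction * n_genes))
    dyads = []
    if n_dyads > 0:
        eligible = sorted(set(dmp_probe_by_gene) - {g for g, _ in deg_genes})
        if not eligible:
            raise ValueError(
                "cannot plant correlated dyads: no non-DEG gene has a "
                "planted DMP probe"
            )
        if beta_bs is None:
            raise ValueError("beta_bs is required to plant correlated dyads")
        n_dyads = min(n_dyads, len(eligible))
        chosen = rng.choice(eligible, size=n_dyads, replace=False)
        rho_z = 2.0 * np.sin(np.pi * config.rho_effect / 6.0)
        for g in chosen:
            probe = str(rng.choice(dmp_probe_by_gene[g]))
            sign = -1 if rng.random() < 0.8 else 1
            x = beta_bs.loc[probe, samples].to_numpy(dtype=float)
            ranks = stats.rankdata(x)
            z = stats.norm.ppf((ranks - 0.5) / n_samples)
            eps = rng.normal(size=n_samples)
            zy = rho_z * sign * z + np.sqrt(max(0.0, 1 - rho_z**2)) * eps
            expr.iloc[gene_pos[g], :] = baseline[gene_pos[g]] + 1.5 * zy
            dyads.append((str(g), probe, int(sign)))
            dirsign = 1 if dmp_dir[probe] == "hyper" else -1
            deg_genes.append((str(g), "up" if sign * dirsign > 0 else "down"))

    truth.deg_genes = sorted(deg_genes)
    truth.corr_dyads = sorted(dyads)
    return expr


def generate_ancillary(manifest: pd.DataFrame, truth: TruthTable,
                       config: SimulationConfig,
                       n_decoy_sets: int = 3) -> tuple[list, dict]:
    """Emit an age-related probe exclusion list and gene sets.

    The exclusion list samples probes carrying no planted effect.  The
    ``PRC2_TARGETS`` set contains every planted dyad gene padded with random
    genes (emulating a Polycomb target list enriched among
    methylation-driven genes); decoy sets are random draws of the same size.
    """
    rng = _rng(config, 5)
    effected = truth.dmp_set() | set(truth.hmc_transitions)
    clean = [p for p in manifest["probe_id"] if p not in effected]
    n_excl = min(len(clean), max(5, int(round(0.01 * len(manifest)))))
    exclusion = sorted(rng.choice(clean, size=n_excl, replace=False))

    genes = sorted(set(manifest["gene_symbol"]) - {""})
    dyad_genes = sorted({g for g, _, _ in truth.corr_dyads})
    size = max(20, 2 * len(dyad_genes))
    others = [g for g in genes if g not in dyad_genes]
    pad = list(rng.choice(others, size=min(size - len(dyad_genes),
                                           len(others)), replace=False))
    gene_sets = {"PRC2_TARGETS": sorted(dyad_genes + pad)}
    for k in range(n_decoy_sets):
        gene_sets[f"DECOY_SET_{k + 1}"] = sorted(
            rng.choice(genes, size=min(size, len(genes)), replace=False)
        )
    return [str(p) for p in exclusion], gene_sets


@dataclass
class SimulatedStudy:
    """Bundle of all simulator outputs for one configuration."""

    manifest: pd.DataFrame
    sheet: pd.DataFrame
    beta_bs_hcc: pd.DataFrame
    beta_bs_ntl: pd.DataFrame
    beta_oxbs_hcc: pd.DataFrame
    beta_oxbs_ntl: pd.DataFrame
    expression: pd.DataFrame
    truth: TruthTable
    exclusion: list
    gene_sets: dict


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run every generator stage on one config and bundle the outputs."""
    manifest = generate_manifest(config)
    sheet = generate_cohort(config)
    bs_hcc, bs_ntl, ox_hcc, ox_ntl, truth = simulate_methylome(
        manifest, sheet, config
    )
    pooled = pd.concat([bs_hcc, bs_ntl], axis=1)
    expr = simulate_expression(manifest, sheet, truth, config, beta_bs=pooled)
    exclusion, gene_sets = generate_ancillary(manifest, truth, config)
    return SimulatedStudy(manifest, sheet, bs_hcc, bs_ntl, ox_hcc, ox_ntl,
                          expr, truth, exclusion, gene_sets)
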