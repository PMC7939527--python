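"""Tests of the synthetic-study generator: structure, determinism,
the BS/oxBS measurement model, and planted-effect bookkeeping."""

import warnings

import numpy as np
import pandas as pd
import pytest

from epipair import (SimulationConfig, generate_cohort, generate_manifest,
                     simulate_expression, simulate_methylome, simulate_study,
                     spearman)
from epipair.simulate import validate_sheet


def quiet_study(cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_study(cfg)


class TestManifest:
    def test_counts_and_uniqueness(self):
        cfg = SimulationConfig(n_probes=100, n_genes=20, seed=1)
        m = generate_manifest(cfg)
        assert len(m) == 100
        assert m["probe_id"].is_unique
        assert set(m.loc[m["gene_symbol"] != "", "gene_symbol"]) == {
            f"GENE{i + 1:05d}" for i in range(20)
        }

    def test_sorted_by_position_within_chromosome(self):
        m = generate_manifest(SimulationConfig(n_probes=500, n_genes=50,
                                               seed=4))
        for _, grp in m.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing
        assert (m["pos"] >= 1).all()

    def test_deterministic(self):
        cfg = SimulationConfig(n_probes=200, n_genes=30, seed=9)
        assert generate_manifest(cfg).equals(generate_manifest(cfg))

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_probes=0)
        with pytest.raises(ValueError, match="n_probes"):
            generate_manifest(SimulationConfig(n_probes=5, n_genes=2))

    def test_intergenic_probes_have_no_gene(self):
        m = generate_manifest(SimulationConfig(n_probes=400, n_genes=40,
                                               seed=2))
        assert (m.loc[m["feature"] == "intergenic", "gene_symbol"] == "").all()


class TestCohort:
    def test_structure(self):
        sheet = generate_cohort(SimulationConfig(n_pairs=10,
                                                 aya_fraction=0.5, seed=7))
        assert len(sheet) == 20
        assert sheet["pair_id"].nunique() == 10
        validate_sheet(sheet)

    def test_all_young_when_fraction_is_one(self):
        sheet = generate_cohort(SimulationConfig(n_pairs=25,
                                                 aya_fraction=1.0, seed=3))
        assert (sheet["age"] <= 44).all()
        assert (sheet["age"] >= 13).all()

    def test_observed_young_fraction_converges(self):
        sheet = generate_cohort(SimulationConfig(n_pairs=500,
                                                 aya_fraction=0.5, seed=13))
        pairs = sheet.drop_duplicates("pair_id")
        assert abs((pairs["age"] <= 44).mean() - 0.5) <= 0.05

    def test_rejects_bad_fraction(self):
        with pytest.raises(ValueError):
            SimulationConfig(aya_fraction=1.5)

    def test_bimodal_age_range(self):
        sheet = generate_cohort(SimulationConfig(n_pairs=300, seed=1))
        assert sheet["age"].between(13, 94).all()
        # no ages in the inter-modal gap is not required, but both modes are
        assert (sheet["age"] <= 44).any() and (sheet["age"] > 44).any()


class TestMethylome:
    def null_config(self, **kw):
        base = dict(n_pairs=8, n_probes=300, n_genes=40,
                    delta_beta_effect=0.0, dmp_fraction=0.0,
                    hmc_fraction=0.0, deg_fraction=0.0,
                    corr_dyad_fraction=0.0, seed=5)
        base.update(kw)
        return SimulationConfig(**base)

    def test_null_simulation_is_empty_and_flat(self):
        st = quiet_study(self.null_config())
        assert st.truth.dmp_probes == []
        assert st.truth.hmc_transitions == {}
        diff = (st.beta_bs_hcc.mean(axis=1)
                - st.beta_bs_ntl.mean(axis=1)).abs()
        assert diff.mean() < 0.05

    def test_beta_values_in_unit_interval(self, small_study):
        for mat in (small_study.beta_bs_hcc, small_study.beta_bs_ntl,
                    small_study.beta_oxbs_hcc, small_study.beta_oxbs_ntl):
            vals = mat.to_numpy()
            assert vals.min() >= 0 and vals.max() <= 1

    def test_noise_free_additivity_and_truth_exhaustiveness(self):
        """Without noise, BS − oxBS equals the planted 5hmC level exactly,
        oxBS never exceeds BS, and tissues differ only at truth probes."""
        cfg = self.null_config(hmc_fraction=0.05, dmp_fraction=0.05,
                               delta_beta_effect=0.3, beta_dispersion=None,
                               n_probes=600, seed=8)
        st = quiet_study(cfg)
        score_hcc = st.beta_bs_hcc - st.beta_oxbs_hcc
        assert (score_hcc.to_numpy() >= -1e-12).all()
        # per-probe score is constant across samples and either 0 or the
        # planted level in [0.35, 0.55]
        s = score_hcc.iloc[:, 0]
        assert np.allclose(score_hcc.sub(s, axis=0), 0)
        planted_gain = {
            p for p, c in st.truth.hmc_transitions.items() if c in ("I", "II")
        }
        assert set(s.index[s > 1e-9]) == planted_gain
        assert s[s > 1e-9].between(0.35, 0.55).all()
        # BS methylation differs between tissues only at planted probes
        diff = (st.beta_bs_hcc.iloc[:, 0]
                - st.beta_bs_ntl.iloc[:, 0]).abs()
        effected = st.truth.dmp_set() | set(st.truth.hmc_transitions)
        assert set(diff.index[diff > 1e-9]) <= effected

    def test_hyper_fraction_matches_configuration(self):
        cfg = SimulationConfig(n_pairs=6, n_probes=8000, n_genes=400,
                               dmp_fraction=0.05,
                               hyper_fraction_among_dmps=0.99,
                               hmc_fraction=0.0, seed=17)
        st = quiet_study(cfg)
        dirs = [d for _, d in st.truth.dmp_probes]
        frac = dirs.count("hyper") / len(dirs)
        assert frac == pytest.approx(0.99, abs=0.03)

    def test_planted_direction_consistent_with_shift(self):
        st = quiet_study(self.null_config(dmp_fraction=0.1,
                                          delta_beta_effect=0.3,
                                          beta_dispersion=None))
        delta = st.beta_bs_hcc.iloc[:, 0] - st.beta_bs_ntl.iloc[:, 0]
        for probe, direction in st.truth.dmp_probes:
            assert (delta[probe] > 0) == (direction == "hyper")

    def test_truth_dmrs_are_planted_probe_runs(self, small_study):
        planted = dict(small_study.truth.dmp_probes)
        pos = small_study.manifest.set_index("probe_id")
        for chrom, start, end, direction in small_study.truth.dmr_intervals:
            members = pos[(pos["chrom"] == chrom)
                          & pos["pos"].between(start, end)
                          & pos.index.isin(planted)]
            assert len(members) >= 2
            assert all(planted[p] == direction for p in members.index)


class TestExpression:
    def test_null_log_fc_near_zero(self):
        cfg = SimulationConfig(n_pairs=30, n_probes=300, n_genes=60,
                               deg_fraction=0.0, corr_dyad_fraction=0.0,
                               dmp_fraction=0.0, hmc_fraction=0.0, seed=6)
        st = quiet_study(cfg)
        hcc = st.expression[[c for c in st.expression if c.endswith("HCC")]]
        ntl = st.expression[[c for c in st.expression if c.endswith("NTL")]]
        log_fc = hcc.mean(axis=1) - ntl.mean(axis=1)
        assert st.truth.deg_genes == []
        assert log_fc.abs().max() < 0.6

    def test_planted_dyad_hits_target_rho(self):
        cfg = SimulationConfig(n_pairs=200, n_probes=1000, n_genes=100,
                               dmp_fraction=0.05, hmc_fraction=0.0,
                               deg_fraction=0.0, corr_dyad_fraction=0.05,
                               rho_effect=0.9, seed=10)
        st = quiet_study(cfg)
        assert st.truth.corr_dyads
        pooled = pd.concat([st.beta_bs_hcc, st.beta_bs_ntl], axis=1)
        cols = list(st.expression.columns)
        for gene, probe, sign in st.truth.corr_dyads:
            rho, _ = spearman(pooled.loc[probe, cols],
                              st.expression.loc[gene, cols])
            assert np.sign(rho) == sign
            assert abs(rho) == pytest.approx(0.9, abs=0.1)

    def test_dyads_require_beta_matrix(self):
        cfg = SimulationConfig(n_pairs=8, n_probes=300, n_genes=40,
                               dmp_fraction=0.05, corr_dyad_fraction=0.1,
                               seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            manifest = generate_manifest(cfg)
            sheet = generate_cohort(cfg)
            *_, truth = simulate_methylome(manifest, sheet, cfg)
            with pytest.raises(ValueError, match="beta_bs"):
                simulate_expression(manifest, sheet, truth, cfg)

    def test_same_seed_identical_outputs(self):
        cfg = SimulationConfig(n_pairs=6, n_probes=300, n_genes=40, seed=42)
        s1, s2 = quiet_study(cfg), quiet_study(cfg)
        assert s1.expression.equals(s2.expression)
        assert s1.truth.corr_dyads == s2.truth.corr_dyads
        assert s1.gene_sets == s2.gene_sets
        assert s1.exclusion == s2.exclusion


class TestAncillary:
    def test_exclusion_list_avoids_planted_probes(self, small_study):
        effected = (small_study.truth.dmp_set()
                    | set(small_study.truth.hmc_transitions))
        assert not (set(small_study.exclusion) & effected)

    def test_prc2_set_contains_all_dyad_genes(self, small_study):
        dyad_genes = {g for g, _, _ in small_study.truth.corr_dyads}
        assert dyad_genes <= set(small_study.gene_sets["PRC2_TARGETS"])
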