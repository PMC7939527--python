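"""Layer merging, correlation, dyad selection, enrichment and overlaps."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import overlap_counts_bruteforce, spearman_bruteforce
from epipair import dge, dmp, integrate
from epipair.stats import spearman


def manifest_frame():
    return pd.DataFrame({
        "probe_id": ["p1", "p2", "p3", "p4"],
        "chrom": "chr1",
        "pos": [100, 200, 300, 400],
        "island_relation": "island",
        "gene_symbol": ["G1", "G1", "G2", "G3"],
        "feature": "TSS200",
    })


def degs_frame(genes, is_deg=True, direction="down"):
    return pd.DataFrame(
        {"log_fc": -1.0, "statistic": -5.0, "p": 1e-4, "q": 1e-3,
         "direction": direction, "is_deg": is_deg},
        index=pd.Index(genes, name="gene_symbol"),
    )


def dmps_frame(probes, passes=True, direction="hyper"):
    return pd.DataFrame(
        {"delta_beta": 0.3 if direction == "hyper" else -0.3,
         "q": 1e-3, "direction": direction, "is_dmp": True,
         "passes_stringent": passes},
        index=pd.Index(probes, name="probe_id"),
    )


def transitions_frame(probes, category):
    return pd.DataFrame(
        {"ntl_state": "non5mC", "hcc_state": "fivehmC",
         "category": category},
        index=pd.Index(probes, name="probe_id"),
    )


class TestMergeLayers:
    def test_gene_with_two_probes_gives_two_dyads(self):
        dyads = integrate.merge_layers(
            degs_frame(["G1"]), dmps_frame(["p1", "p2"]),
            transitions_frame([], []), manifest_frame(),
        )
        assert len(dyads) == 2
        assert set(dyads["probe_id"]) == {"p1", "p2"}
        assert (dyads["layer"] == "dmp").all()

    def test_gene_without_probe_dropped(self, caplog):
        import logging
        with caplog.at_level(logging.INFO, logger="epipair.integrate"):
            dyads = integrate.merge_layers(
                degs_frame(["G9"]), dmps_frame(["p1"]),
                transitions_frame([], []), manifest_frame(),
            )
        assert dyads.empty
        assert "dropped" in caplog.text

    def test_only_category_one_transitions_merge(self):
        trans = transitions_frame(["p3", "p4"], ["I", "II"])
        dyads = integrate.merge_layers(
            degs_frame(["G2", "G3"]), dmps_frame([]), trans,
            manifest_frame(),
        )
        assert list(dyads["probe_id"]) == ["p3"]
        assert list(dyads["layer"]) == ["de_novo_5hmC"]

    def test_non_stringent_probe_not_merged(self):
        dyads = integrate.merge_layers(
            degs_frame(["G1"]), dmps_frame(["p1"], passes=False),
            transitions_frame([], []), manifest_frame(),
        )
        assert dyads.empty


class TestSpearmanOracle:
    def test_perfect_antitone(self):
        rho, _ = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_identity(self):
        rho, _ = spearman([1, 2, 3, 4], [1, 2, 3, 4])
        assert rho == pytest.approx(1.0)

    def test_ties_equal_rank_pearson(self):
        rho, _ = spearman([1, 1, 2, 3], [2, 1, 4, 3])
        assert rho == pytest.approx(
            spearman_bruteforce([1, 1, 2, 3], [2, 1, 4, 3])
        )

    def test_exhaustive_small_alphabet(self):
        """Every pair of length-4 vectors over {0,1,2}: full ties coverage."""
        vectors = [v for v in itertools.product((0, 1, 2), repeat=4)
                   if len(set(v)) > 1]
        for x in vectors[::7]:
            for y in vectors[::5]:
                rho, _ = spearman(x, y)
                assert rho == pytest.approx(spearman_bruteforce(x, y),
                                            abs=1e-12), (x, y)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.integers(5, 8), st.data())
    def test_random_lengths_with_ties(self, n, data):
        alphabet = st.integers(0, 3)
        x = data.draw(st.lists(alphabet, min_size=n, max_size=n))
        y = data.draw(st.lists(alphabet, min_size=n, max_size=n))
        if len(set(x)) == 1 or len(set(y)) == 1:
            rho, p = spearman(x, y)
            assert np.isnan(rho)
        else:
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(spearman_bruteforce(x, y))

    def test_constant_vector_flagged(self):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)


class TestSelectDyads:
    def dyads(self, rho):
        return pd.DataFrame({
            "gene_symbol": ["G1"], "probe_id": ["p1"], "layer": ["dmp"],
            "rho": [rho], "rho_p": [0.01],
        })

    def test_selection_is_strict_at_threshold(self):
        degs, dmps = degs_frame(["G1"]), dmps_frame(["p1"])
        at = integrate.select_dyads(self.dyads(0.5), degs, dmps)
        above = integrate.select_dyads(self.dyads(0.51), degs, dmps)
        assert not bool(at["selected"].iloc[0])
        assert bool(above["selected"].iloc[0])
        assert above["concordance"].iloc[0] == "hyper_down"

    def test_negative_rho_selected_by_magnitude(self):
        out = integrate.select_dyads(self.dyads(-0.7), degs_frame(["G1"]),
                                     dmps_frame(["p1"]))
        assert bool(out["selected"].iloc[0])

    def test_hyper_down_fraction(self):
        dyads = pd.DataFrame({
            "gene_symbol": ["G1", "G2"], "probe_id": ["p1", "p3"],
            "layer": ["dmp", "dmp"], "rho": [-0.8, 0.8],
            "rho_p": [0.01, 0.01],
        })
        degs = degs_frame(["G1", "G2"], direction="down")
        degs.loc["G2", "direction"] = "up"
        dmps = dmps_frame(["p1", "p3"])
        out = integrate.select_dyads(dyads, degs, dmps)
        assert integrate.hyper_down_fraction(out) == pytest.approx(0.5)


class TestEnrichment:
    def test_exact_small_universe(self):
        universe = [f"G{i}" for i in range(10)]
        out = integrate.enrich(universe[:5], universe,
                               {"S": universe[:5]})
        assert out["p"].iloc[0] == pytest.approx(1 / 252)

    def test_empty_selection_p_one(self):
        universe = [f"G{i}" for i in range(10)]
        out = integrate.enrich([], universe, {"S": universe[:5]})
        assert out["overlap"].iloc[0] == 0
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_bonferroni_scales_by_set_count(self):
        universe = [f"G{i}" for i in range(20)]
        sets = {f"S{k}": universe[k:k + 5] for k in range(4)}
        out = integrate.enrich(universe[:5], universe, sets)
        assert np.allclose(out["p_adj"], np.minimum(out["p"] * 4, 1.0))

    def test_bh_correction_available(self):
        universe = [f"G{i}" for i in range(20)]
        sets = {"A": universe[:5], "B": universe[5:10]}
        out = integrate.enrich(universe[:5], universe, sets, correction="bh")
        assert (out["p_adj"] >= out["p"] - 1e-12).all()

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            integrate.enrich([], [], {"S": []})


class TestSummaryReport:
    def test_disjoint_layers_zero_overlaps(self):
        report = integrate.summary_report(
            degs_frame(["G1"]), dmps_frame(["p3"]),
            transitions_frame(["p4"], ["I"]), manifest_frame(),
        )
        assert report["deg_dmp"] == report["deg_5hmc"] == 0
        assert report["triple"] == 0

    def test_triple_overlap_counted(self):
        report = integrate.summary_report(
            degs_frame(["G1"]), dmps_frame(["p1"]),
            transitions_frame(["p2"], ["I"]), manifest_frame(),
        )
        assert report["triple"] == 1

    @pytest.mark.parametrize("seed", [0, 4, 9])
    def test_counts_match_set_algebra(self, seed):
        rng = np.random.default_rng(seed)
        man = manifest_frame()
        genes = ["G1", "G2", "G3"]
        deg_pick = list(rng.choice(genes, rng.integers(0, 4), replace=False))
        dmp_pick = list(rng.choice(man["probe_id"], rng.integers(0, 5),
                                   replace=False))
        t_pick = list(rng.choice(man["probe_id"], rng.integers(0, 5),
                                 replace=False))
        report = integrate.summary_report(
            degs_frame(deg_pick), dmps_frame(dmp_pick),
            transitions_frame(t_pick, ["I"] * len(t_pick)), man,
        )
        gene_of = man.set_index("probe_id")["gene_symbol"]
        expected = overlap_counts_bruteforce([
            deg_pick, [gene_of[p] for p in dmp_pick],
            [gene_of[p] for p in t_pick],
        ])
        assert report["deg_dmp"] == expected["ab"]
        assert report["deg_5hmc"] == expected["ac"]
        assert report["dmp_5hmc"] == expected["bc"]
        assert report["triple"] == expected["abc"]


class TestEndToEndRecovery:
    def test_planted_dyads_recovered(self, dyad_recovery_study):
        st = dyad_recovery_study
        tested = dmp.test_dmps(st.beta_bs_hcc, st.beta_bs_ntl,
                               pairing=st.sheet)
        flagged = dmp.apply_stringent_filters(
            dmp.call_dmps(tested), st.beta_bs_hcc, st.beta_bs_ntl)
        e_hcc, e_ntl = dge.split_by_tissue(st.expression, st.sheet)
        degs = dge.test_dge(e_hcc, e_ntl)
        trans = transitions_frame([], [])
        dyads = integrate.merge_layers(degs, flagged, trans, st.manifest)
        pooled = pd.concat([st.beta_bs_hcc, st.beta_bs_ntl], axis=1)
        dyads = integrate.correlate_dyads(dyads, st.expression, pooled)
        dyads = integrate.select_dyads(dyads, degs, flagged)

        planted = {(g, p) for g, p, _ in st.truth.corr_dyads}
        selected = set(zip(dyads.loc[dyads["selected"], "gene_symbol"],
                           dyads.loc[dyads["selected"], "probe_id"]))
        assert len(planted & selected) / len(planted) >= 0.85

        # correlation-threshold step alone recovers >= 90% of planted dyads
        direct = pd.DataFrame(
            [(g, p, "dmp") for g, p, _ in st.truth.corr_dyads],
            columns=["gene_symbol", "probe_id", "layer"],
        )
        direct = integrate.correlate_dyads(direct, st.expression, pooled)
        assert (direct["rho"].abs() > 0.5).mean() >= 0.9

        # planted enrichment is recovered
        genes_sel = dyads.loc[dyads["selected"], "gene_symbol"].unique()
        enr = integrate.enrich(genes_sel, st.expression.index, st.gene_sets)
        prc2 = enr.set_index("gene_set").loc["PRC2_TARGETS"]
        assert prc2["p_adj"] < 0.05

    def test_duplicate_expression_genes_rejected(self, small_study):
        expr = pd.concat([small_study.expression,
                          small_study.expression.iloc[:1]])
        dyads = pd.DataFrame({"gene_symbol": [], "probe_id": [],
                              "layer": []})
        with pytest.raises(ValueError, match="duplicate"):
            integrate.correlate_dyads(dyads, expr, small_study.beta_bs_hcc)
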