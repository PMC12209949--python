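import numpy as np
import pytest

from tests.oracles import brute_betweenness, random_tiered_dag
from tiernet.stability_centrality import (
    CentralityResult,
    EdgeStabilityReport,
    alpha_sensitivity,
    betweenness,
    bootstrap_stability,
    nominate_mediators,
    read_stability_report,
    render_frequency,
    stable_edges,
)
from tiernet.synthetic_cohort import nesda_like_truth, sample_cohort
from tiernet.tiered_pc import TieredPDAG


def _pdag(edges, tiers=None, undirected=()):
    nodes = sorted({v for e in edges for v in e} | {v for e in undirected for v in e})
    tiers = tiers or {v: 0 for v in nodes}
    return TieredPDAG(
        nodes=nodes,
        tiers=tiers,
        directed=set(edges),
        undirected={frozenset(e) for e in undirected},
    )


class TestBetweenness:
    def test_path_scores_by_hand(self):
        g = _pdag([("A", "B"), ("B", "C"), ("C", "D")])
        res = betweenness(g)
        assert res.scores == {"A": 0.0, "B": 2.0, "C": 2.0, "D": 0.0}
        assert res.above_mean == {"B", "C"}

    def test_shortcut_bypasses_mediator(self):
        g = _pdag([("A", "M"), ("M", "B"), ("A", "B")])
        res = betweenness(g)
        assert res.scores["M"] == 0.0

    def test_matches_bruteforce_on_random_dags(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            nodes, tiers, edges = random_tiered_dag(rng, int(rng.integers(4, 9)))
            pdag = TieredPDAG(nodes=nodes, tiers=tiers, directed=set(edges))
            res = betweenness(pdag)
            want = brute_betweenness(nodes, edges)
            for v in nodes:
                assert res.scores[v] == pytest.approx(want[v], abs=1e-9)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            betweenness(TieredPDAG(nodes=[], tiers={}))


class TestNominateMediators:
    def test_single_chain_nominates_the_mediator(self):
        g = _pdag([("E", "M"), ("M", "O")], tiers={"E": 0, "M": 1, "O": 2})
        g.nodes.extend(["iso1", "iso2"])
        g.tiers.update({"iso1": 1, "iso2": 1})
        res = betweenness(g)
        assert nominate_mediators(g, res, "E", "O") == ["M"]

    def test_no_path_means_no_nominations(self):
        g = _pdag([("E", "M"), ("O", "X")], tiers={"E": 0, "M": 1, "O": 0, "X": 1})
        res = betweenness(g)
        assert nominate_mediators(g, res, "E", "O") == []

    def test_exposure_equal_outcome_rejected(self):
        g = _pdag([("E", "M")], tiers={"E": 0, "M": 1})
        with pytest.raises(ValueError):
            nominate_mediators(g, betweenness(g), "E", "E")


class TestStabilityReport:
    def test_frequency_rendering_matches_published_style(self):
        # rendering fixture: 1.0 -> "100%", 0.997 -> "99.7%"
        report = EdgeStabilityReport(
            frequencies={("MDD", "AGP"): 1.0, ("Acetate", "CVD"): 0.997},
            n_graphs=300,
            drop_rates=[0.0, 0.1, 0.2],
            alpha=0.05,
            seed=0,
            alpha_flags={("MDD", "AGP"): (True, True, True), ("Acetate", "CVD"): (True, True, True)},
            alphas=[0.01, 0.05, 0.075],
        )
        frame = report.to_frame().set_index("cause")
        assert frame.loc["MDD", "frequency_pct"] == "100%"
        assert frame.loc["Acetate", "frequency_pct"] == "99.7%"
        assert render_frequency(0.88) == "88%"

    def test_flag_vector_for_edge_entering_at_middle_alpha(self):
        report = EdgeStabilityReport(
            frequencies={("LDL_tg", "CVD"): 0.87},
            n_graphs=300,
            drop_rates=[0.0],
            alpha=0.05,
            seed=0,
            alpha_flags={("LDL_tg", "CVD"): (False, True, True)},
            alphas=[0.01, 0.05, 0.075],
        )
        row = report.to_frame().iloc[0]
        assert (row["alpha_0.01"], row["alpha_0.05"], row["alpha_0.075"]) == ("–", "✔", "✔")

    def test_tsv_roundtrip_reconstructs_report(self, tmp_path):
        report = EdgeStabilityReport(
            frequencies={("a", "b"): 0.5, ("b", "c"): 1.0},
            n_graphs=30,
            drop_rates=[0.0, 0.1],
            alpha=0.05,
            seed=7,
            alpha_flags={("a", "b"): (False, True, True), ("b", "c"): (True, True, True)},
            alphas=[0.01, 0.05, 0.075],
        )
        path = str(tmp_path / "stab.tsv")
        report.to_tsv(path)
        back = read_stability_report(path, 30, [0.0, 0.1], 0.05, 7)
        assert back.frequencies == report.frequencies
        assert back.alpha_flags == report.alpha_flags

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(ValueError):
            EdgeStabilityReport({("a", "b"): 1.2}, 1, [0.0], 0.05, 0)


@pytest.fixture(scope="module")
def cohort():
    truth = nesda_like_truth(1, n_biomarkers=5)
    return truth, sample_cohort(truth, 1500, seed=4)


class TestBootstrapStability:
    def test_single_graph_frequencies_are_indicator_valued(self, cohort):
        _, tab = cohort
        rep = bootstrap_stability(
            tab, n_boot=1, drop_rates=[0.0], seed=0, undirected_policy="skip"
        )
        assert rep.n_graphs == 1
        assert set(rep.frequencies.values()) <= {1.0}

    def test_frequencies_are_fractions_of_graph_count(self, cohort):
        _, tab = cohort
        rep = bootstrap_stability(tab, n_boot=5, drop_rates=[0.0, 0.2], seed=1)
        assert rep.n_graphs == 10
        assert all(0 <= f <= 1 for f in rep.frequencies.values())
        # strong designed edges are stable
        assert rep.frequencies.get(("MDD", "bm01"), 0) >= 0.8
        assert stable_edges(rep)  # nonempty at the default 0.8 threshold

    def test_undersampled_bootstrap_rejected(self, cohort):
        _, tab = cohort
        small = tab.df.iloc[:10]
        from tiernet.cohort import CohortTable

        tiny = CohortTable(small.reset_index(drop=True), list(tab.specs))
        with pytest.raises(ValueError, match="too few rows"):
            bootstrap_stability(tiny, n_boot=1, drop_rates=[0.0], seed=0)

    def test_invalid_configs_rejected(self, cohort):
        _, tab = cohort
        with pytest.raises(ValueError):
            bootstrap_stability(tab, n_boot=0)
        with pytest.raises(ValueError):
            bootstrap_stability(tab, drop_rates=[1.0])


class TestAlphaSensitivity:
    def test_presence_flags_are_monotone_with_shared_cache(self):
        truth = nesda_like_truth(2, n_biomarkers=5)
        tab = sample_cohort(truth, 1200, seed=5)
        graphs, flags = alpha_sensitivity(tab)
        for vec in flags.values():
            # skeleton presence never turns off as alpha grows
            assert not (vec[0] and not vec[2])
        sk = [graphs[a].skeleton_edges() for a in (0.01, 0.05, 0.075)]
        assert sk[0] <= sk[1] <= sk[2]

    def test_single_alpha_degenerates_gracefully(self):
        truth = nesda_like_truth(2, n_biomarkers=4)
        tab = sample_cohort(truth, 800, seed=6)
        graphs, flags = alpha_sensitivity(tab, alphas=[0.05])
        assert list(graphs) == [0.05]
        assert all(len(v) == 1 for v in flags.values())

    def test_non_increasing_alphas_rejected(self):
        truth = nesda_like_truth(2, n_biomarkers=4)
        tab = sample_cohort(truth, 300, seed=7)
        with pytest.raises(ValueError):
            alpha_sensitivity(tab, alphas=[0.05, 0.01])


def test_centrality_result_validates_above_mean_consistency():
    with pytest.raises(ValueError):
        CentralityResult({"a": 1.0, "b": 0.0}, 0.5, {"b"})
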