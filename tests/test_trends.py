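"""Decade trends, receiver pairing, sex splits and edge-set overlap."""

import itertools

import numpy as np
import pandas as pd
import pytest

import usem
from usem.model import build_usem
from usem.simulate import SimConfig
from usem.trends import edge_overlap_probability, pair_by_receiver, trend_from_coefficients


def _table(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"c{k}" for k in range(1, 7)])


class TestTrendFromCoefficients:
    def test_published_rising_row(self):
        t = trend_from_coefficients(_table({"MPFG->LMFG": [0.24, 0.27, 0.30, 0.36, 0.37, 0.41]}))
        assert round(t.loc["MPFG->LMFG", "r"], 2) == 0.99
        assert t.loc["MPFG->LMFG", "class"] == "rising"

    def test_published_falling_row(self):
        t = trend_from_coefficients(_table({"LIPL->RIPL": [0.49, 0.37, 0.27, 0.30, 0.16, 0.08]}))
        assert round(t.loc["LIPL->RIPL", "r"], 2) == -0.97
        assert t.loc["LIPL->RIPL", "class"] == "falling"

    def test_constant_vector_is_flat_with_undefined_r(self):
        t = trend_from_coefficients(_table({"A->B": [0.3] * 6}))
        assert t.loc["A->B", "class"] == "flat"
        assert np.isnan(t.loc["A->B", "r"])

    def test_affine_axis_invariance(self):
        """Index axis 1..6 and mean-age axis 24.5..74.5 give identical r."""
        rows = _table({"e": [0.2, 0.25, 0.33, 0.31, 0.4, 0.45]})
        r_index = trend_from_coefficients(rows)["r"].iloc[0]
        r_age = trend_from_coefficients(rows, cohort_axis=np.arange(24.5, 75, 10))["r"].iloc[0]
        assert r_index == pytest.approx(r_age, abs=1e-12)

    def test_needs_three_cohorts(self):
        with pytest.raises(ValueError, match="3 cohorts"):
            trend_from_coefficients(pd.DataFrame([[1.0, 2.0]], index=["e"]))

    def test_sign_recovery_at_generator_effect_sizes(self, dmn_edge_spec):
        """With coefficient noise at the sampling scale of the packaged
        scenario's per-cohort fits (SE ~ 0.01 at 20 subjects x 600 time
        points), the trend classifier recovers the sign of every
        drifting published slope in >= 95% of replicates."""
        rng = np.random.default_rng(77)
        sig_rows = [e for e in dmn_edge_spec["edges"] if abs(e["reported_r"]) >= 0.89]
        hits = total = 0
        for e in sig_rows:
            truth = np.array(e["coefficients"])
            slope_sign = np.sign(np.polyfit(np.arange(6), truth, 1)[0])
            want = "rising" if slope_sign > 0 else "falling"
            for _ in range(100):
                noisy = truth + rng.normal(0, 0.01, 6)
                t = trend_from_coefficients(_table({"e": list(noisy)}))
                hits += t.loc["e", "class"] == want
                total += 1
        assert hits / total >= 0.95


@pytest.fixture(scope="module")
def published_trends(dmn_edge_spec):
    coeffs = _table({
        f"{e['source']}->{e['target']}": e["coefficients"]
        for e in dmn_edge_spec["edges"]
    })
    return trend_from_coefficients(coeffs)


class TestPublishedTableClassification:
    def test_eight_of_thirteen_significant(self, published_trends):
        assert int(published_trends["significant"].sum()) == 8

    def test_paired_receivers(self, published_trends, dmn_nodes, dmn_edges):
        model = build_usem(dmn_nodes, dmn_edges)
        out = pair_by_receiver(published_trends, model)
        assert set(out["paired"]) == {"LMFG", "RIPL", "LMTG", "RMTG"}
        for node, d in out["paired"].items():
            assert len(d["rising"]) == 1 and len(d["falling"]) == 1
        assert out["unpaired"] == {}


class TestPairByReceiver:
    def test_all_flat_gives_empty_report(self):
        model = build_usem(["A", "B"], [("A", "B")])
        t = trend_from_coefficients(_table({"A->B": [0.3] * 6}))
        out = pair_by_receiver(t, model)
        assert out == {"paired": {}, "unpaired": {}}

    def test_single_rising_edge_unpaired(self):
        model = build_usem(["A", "B"], [("A", "B")])
        t = trend_from_coefficients(_table({"A->B": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]}))
        out = pair_by_receiver(t, model)
        assert out["paired"] == {}
        assert list(out["unpaired"]) == ["B"]


class TestDecadeTrends:
    def test_scenario_fit_recovers_rising_and_falling(self, scenario_covs, dmn_nodes, dmn_edges):
        model = build_usem(dmn_nodes, dmn_edges)
        res = usem.fit_ml(model, scenario_covs)
        table = usem.decade_trends(res)
        classes = set(table["class"])
        assert "rising" in classes and "falling" in classes
        # strongest published trends survive the generate-fit roundtrip
        assert table.loc["MPFG->LMFG", "class"] == "rising"
        assert table.loc["LIPL->RIPL", "class"] == "falling"


class TestSexSplitTrends:
    def test_published_female_vector_r(self):
        t = trend_from_coefficients(_table({"MPFG->LMFG": [0.11, 0.24, 0.30, 0.34, 0.36, 0.47]}))
        assert round(t.loc["MPFG->LMFG", "r"], 2) == 0.97

    def test_identical_sex_data_identical_tables(self):
        rng = np.random.default_rng(5)
        subjects = []
        for g in range(1, 7):
            data = rng.standard_normal((80, 2))
            for sex in ("M", "F"):  # same matrix for both sexes
                for k in range(2):
                    subjects.append(usem.Subject(f"c{g}{sex}{k}", f"c{g}", sex, data.copy()))
        panel = usem.standardize(usem.TimeSeriesPanel(["A", "B"], subjects))
        out = usem.sex_split_trends(panel, build_usem(["A", "B"], [("A", "B")]))
        pd.testing.assert_frame_equal(out["M"], out["F"])
        assert out["divergent"] == []

    def test_sex_by_cohort_interaction_flagged(self):
        """Females drift 0.1 -> 0.6 on A->B while males stay level: only
        that edge is flagged divergent."""
        G = 6
        CF = np.zeros((G, 2, 2))
        CM = np.zeros((G, 2, 2))
        for g in range(G):
            CF[g, 1, 0] = 0.1 + 0.1 * g
            CM[g, 1, 0] = 0.35
        cfg = SimConfig(
            node_names=["A", "B"], contemporaneous=CM,
            contemporaneous_by_sex={"F": CF, "M": CM},
            auto=[0.4, 0.4], n_cohorts=G, subjects_per_cohort=6,
            timepoints_per_subject=400, seed=55,
        )
        panel = usem.standardize(usem.simulate_panel(cfg))
        out = usem.sex_split_trends(panel, build_usem(["A", "B"], [("A", "B")]))
        assert out["divergent"] == ["A->B"]
        assert out["F"].loc["A->B", "class"] == "rising"
        assert out["M"].loc["A->B", "class"] == "flat"

    def test_missing_sex_level_raises(self):
        rng = np.random.default_rng(6)
        subjects = [usem.Subject(f"s{g}{k}", f"c{g}", "F" if g > 1 or k else "M",
                                 rng.standard_normal((50, 1)))
                    for g in range(1, 4) for k in range(2)]
        panel = usem.TimeSeriesPanel(["A"], subjects)
        with pytest.raises(ValueError, match="missing sex"):
            usem.sex_split_trends(panel, build_usem(["A"], []))


class TestEdgeOverlap:
    def test_published_network_agreement(self):
        """13-edge vs 13-edge sets on 9 nodes sharing 10 undirected edges:
        chance probability 0.023% (2 sf)."""
        nodes = [f"n{k}" for k in range(9)]
        pairs = list(itertools.combinations(nodes, 2))
        set_a = pairs[:13]
        set_b = pairs[3:16]  # shares exactly 10 pairs with set_a
        res = edge_overlap_probability(set_a, set_b, n_nodes=9)
        assert res.n_possible == 36
        assert res.overlap == 10
        assert res.probability * 100 == pytest.approx(0.023, abs=5e-4)

    def test_zero_overlap_probability_one(self):
        res = edge_overlap_probability([("a", "b")], [("c", "d")], n_nodes=4)
        assert res.probability == 1.0

    @pytest.mark.parametrize("n_nodes,ka,kb", [(4, 3, 2), (5, 4, 4), (4, 5, 3)])
    def test_matches_exhaustive_enumeration(self, n_nodes, ka, kb):
        """Tail equals the fraction of all C(N, kb) draws with at least the
        observed overlap (brute-force oracle on small populations)."""
        nodes = [f"n{k}" for k in range(n_nodes)]
        pairs = list(itertools.combinations(nodes, 2))
        set_a = pairs[:ka]
        set_b = pairs[1 : 1 + kb]
        res = edge_overlap_probability(set_a, set_b, n_nodes)
        a = set(map(frozenset, set_a))
        count = total = 0
        for draw in itertools.combinations(pairs, kb):
            total += 1
            count += len(a & set(map(frozenset, draw))) >= res.overlap
        assert res.probability == pytest.approx(count / total, abs=1e-12)

    def test_tail_monotone_decreasing_in_overlap(self):
        nodes = [f"n{k}" for k in range(9)]
        pairs = list(itertools.combinations(nodes, 2))
        set_a = pairs[:13]
        probs = []
        for j in range(14):  # set_b shares exactly j pairs with set_a
            set_b = pairs[13 - j : 26 - j]
            res = edge_overlap_probability(set_a, set_b, 9)
            assert res.overlap == j
            probs.append(res.probability)
        assert all(p_next <= p for p, p_next in zip(probs, probs[1:]))

    def test_oversized_set_rejected(self):
        pairs = [(f"n{k}", f"n{k+1}") for k in range(7)]
        with pytest.raises(ValueError, match="possible undirected"):
            edge_overlap_probability(pairs, pairs, n_nodes=3)
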