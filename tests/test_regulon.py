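"""Regulon network construction, edge weighting, and activity scoring."""

import numpy as np
import pandas as pd
import pytest

from tumorkit import regulon, simulate


@pytest.fixture
def sif_df():
    return regulon.parse_sif(
        [
            "TF1 controls-expression-of G1 1",
            "TF1 controls-expression-of G2 -1",
            "TF2 controls-expression-of G3 1",
            "TF1 binds-to G9",
            "# comment",
            "TF3 controls-expression-of G9 1",
        ]
    )


class TestNetworkConstruction:
    def test_relation_and_expression_restriction(self, sif_df):
        net = regulon.build_regulon_network(
            sif_df, ["TF1", "TF2", "G1", "G2", "G3"]
        )
        # binds-to dropped; TF3->G9 dropped (unexpressed); 3 edges remain
        assert len(net.edges) == 3
        assert set(net.regulators) == {"TF1", "TF2"}
        assert net.targets_of("TF1")["sign"].tolist() == [1, -1]

    def test_empty_after_filtering_errors(self, sif_df):
        with pytest.raises(ValueError, match="no expression-control edges"):
            regulon.build_regulon_network(sif_df, ["ZZZ"])

    def test_missing_sign_defaults_positive(self):
        sif = regulon.parse_sif(["TF1 controls-expression-of G1"])
        with pytest.warns(UserWarning, match="defaulting to \\+1"):
            net = regulon.build_regulon_network(sif, ["TF1", "G1"])
        assert net.edges["sign"].tolist() == [1]

    def test_malformed_line_reports_number(self):
        with pytest.raises(ValueError, match="line 2"):
            regulon.parse_sif(["a controls-expression-of b", "bad line"])

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loops"):
            regulon.RegulonNetwork(
                edges=pd.DataFrame(
                    {"regulator": ["a"], "target": ["a"], "sign": [1]}
                )
            )

    def test_secondary_expansion_sign_product(self):
        net = regulon.RegulonNetwork(
            edges=pd.DataFrame(
                {
                    "regulator": ["A", "B"],
                    "target": ["B", "C"],
                    "sign": [-1, -1],
                }
            )
        )
        expanded = regulon.expand_secondary(net)
        composite = expanded.edges.set_index(["regulator", "target"])["sign"]
        assert composite[("A", "C")] == 1  # (-1) * (-1)


class TestEdgeWeights:
    def test_perfect_monotone_dependency(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        expr = pd.DataFrame({"R": x, "T": np.exp(x)}).T
        expr.columns = [f"s{i}" for i in range(50)]
        net = regulon.RegulonNetwork(
            edges=pd.DataFrame({"regulator": ["R"], "target": ["T"], "sign": [1]})
        )
        w = regulon.assign_edge_weights(net, expr)
        assert w["rho"].iloc[0] == pytest.approx(1.0)
        assert w["weight"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_constant_target_weight_zero(self):
        expr = pd.DataFrame(
            {"s%d" % i: [float(i), 1.0] for i in range(10)}, index=["R", "T"]
        )
        net = regulon.RegulonNetwork(
            edges=pd.DataFrame({"regulator": ["R"], "target": ["T"], "sign": [1]})
        )
        w = regulon.assign_edge_weights(net, expr)
        assert w["weight"].iloc[0] == 0.0

    def test_null_weights_center_on_zero(self):
        rng = np.random.default_rng(1)
        n_edges, n = 400, 200
        genes = [f"R{i}" for i in range(n_edges)] + [f"T{i}" for i in range(n_edges)]
        expr = pd.DataFrame(
            rng.normal(size=(2 * n_edges, n)),
            index=genes,
            columns=[f"s{i}" for i in range(n)],
        )
        net = regulon.RegulonNetwork(
            edges=pd.DataFrame(
                {
                    "regulator": [f"R{i}" for i in range(n_edges)],
                    "target": [f"T{i}" for i in range(n_edges)],
                    "sign": 1,
                }
            )
        )
        w = regulon.assign_edge_weights(net, expr)
        assert abs(w["weight"].mean()) < 0.02

    def test_missing_gene_dropped_with_warning(self):
        expr = pd.DataFrame(
            np.arange(8.0).reshape(2, 4), index=["R", "T"], columns=list("abcd")
        )
        net = regulon.RegulonNetwork(
            edges=pd.DataFrame(
                {"regulator": ["R", "R"], "target": ["T", "MISSING"], "sign": [1, 1]}
            )
        )
        with pytest.warns(UserWarning, match="dropped"):
            w = regulon.assign_edge_weights(net, expr)
        assert len(w) == 1


class TestSignature:
    def test_median_sample_gives_zero_signature(self):
        expr = pd.DataFrame(
            {"a": [1.0, 5.0], "b": [2.0, 6.0], "c": [3.0, 7.0]}, index=["g1", "g2"]
        )
        sig = regulon.compute_signature(expr, "b")
        assert np.allclose(sig["score"], 0.0)

    def test_doubled_gene_is_top_ranked(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.normal(size=(20, 5)),
            index=[f"g{i}" for i in range(20)],
            columns=list("abcde"),
        )
        expr.loc["g7", "a"] = expr.loc["g7"].median() + 50
        sig = regulon.compute_signature(expr, "a")
        assert sig.loc["g7", "rank"] == 1

    def test_matches_brute_force(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(30, 6)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(6)],
        )
        sig = regulon.compute_signature(expr, "s2")
        for g in expr.index:
            assert sig.loc[g, "score"] == pytest.approx(
                expr.loc[g, "s2"] - np.median(expr.loc[g])
            )


def _toy_weights(signs, weights=None):
    n = len(signs)
    return pd.DataFrame(
        {
            "regulator": ["R"] * n,
            "target": [f"t{i}" for i in range(n)],
            "sign": signs,
            "weight": weights if weights is not None else [1.0] * n,
        }
    )


class TestComponents:
    def test_delta_concordance_alignment(self):
        # weights perfectly aligned with ascending-score order -> +1
        w = _toy_weights([1] * 6, weights=[0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        sig = pd.DataFrame(
            {"score": np.arange(6.0)}, index=[f"t{i}" for i in range(6)]
        )
        assert regulon.local_delta_concordance(w, sig, "R") == pytest.approx(1.0)
        sig_anti = pd.DataFrame(
            {"score": -np.arange(6.0)}, index=[f"t{i}" for i in range(6)]
        )
        assert regulon.local_delta_concordance(w, sig_anti, "R") == pytest.approx(-1.0)

    def test_delta_concordance_single_sign_group(self):
        # a one-sign regulon is scored from that group alone (no averaging)
        w = _toy_weights([-1] * 5, weights=[0.5, 0.4, 0.3, 0.2, 0.1])
        sig = pd.DataFrame(
            {"score": np.arange(5.0)}, index=[f"t{i}" for i in range(5)]
        )
        # negative edges ranked descending by score: weights align with it
        assert regulon.local_delta_concordance(w, sig, "R") == pytest.approx(1.0)

    def test_local_enrichment_extremes(self):
        # targets at the top of the local (network-covered) ranking -> near +1
        other = pd.DataFrame(
            {
                "regulator": ["Q"] * 45,
                "target": [f"u{i}" for i in range(45)],
                "sign": 1,
                "weight": 1.0,
            }
        )
        w = pd.concat([_toy_weights([1] * 5), other], ignore_index=True)
        scores = pd.Series(
            np.concatenate([np.arange(45.0), 100 + np.arange(5.0)]),
            index=[f"u{i}" for i in range(45)] + [f"t{i}" for i in range(5)],
        )
        sig = pd.DataFrame({"score": scores})
        val = regulon.local_enrichment(w, sig, "R")
        assert val > 0.85
        # repressed targets at the top score symmetric negative
        w_neg = pd.concat([_toy_weights([-1] * 5), other], ignore_index=True)
        assert regulon.local_enrichment(w_neg, sig, "R") == pytest.approx(-val)

    def test_local_enrichment_uniform_spread_near_zero(self):
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(300):
            w = _toy_weights([1] * 10)
            scores = pd.Series(
                rng.normal(size=50), index=[f"t{i}" for i in range(10)] + [f"u{i}" for i in range(40)]
            )
            full = pd.DataFrame(
                {
                    "regulator": ["R"] * 10 + ["Q"] * 40,
                    "target": list(scores.index),
                    "sign": 1,
                    "weight": 1.0,
                }
            )
            vals.append(regulon.local_enrichment(full, pd.DataFrame({"score": scores}), "R"))
        assert abs(np.mean(vals)) < 0.05

    def test_global_enrichment_extremes_and_symmetry(self):
        genes = [f"g{i}" for i in range(100)]
        sig = pd.DataFrame({"score": np.arange(100.0)}, index=genes)
        w = pd.DataFrame(
            {
                "regulator": ["R"] * 5,
                "target": genes[-5:],  # global extremes, activation-consistent
                "sign": 1,
                "weight": 1.0,
            }
        )
        up = regulon.global_enrichment(w, sig, "R")
        assert up > 0.85
        w_neg = w.assign(sign=-1)
        assert regulon.global_enrichment(w_neg, sig, "R") == pytest.approx(-up)

    def test_all_targets_missing_is_nan(self):
        w = _toy_weights([1] * 3)
        sig = pd.DataFrame({"score": [1.0, 2.0]}, index=["x", "y"])
        assert np.isnan(regulon.local_delta_concordance(w, sig, "R"))
        assert np.isnan(regulon.global_enrichment(w, sig, "R"))


class TestIntegration:
    def test_equal_components_integrate_to_zero(self):
        comp = pd.DataFrame(
            {
                "local_delta_concordance": [0.3, 0.3],
                "local_enrichment": [0.1, 0.1],
                "global_enrichment": [0.2, 0.2],
            },
            index=["R1", "R2"],
        )
        out = regulon.integrate_scores(comp)
        assert np.allclose(out["integrated"], 0.0)

    def test_planted_regulator_recovery(self):
        hits = 0
        for seed in range(5):
            net = simulate.make_regulon(20, 10, seed=seed)
            params = simulate.SimParams(seed=seed, effect_size=3.0, noise_sd=1.0)
            expr = simulate.simulate_regulator_expression(net, {"R003"}, params)
            sample = simulate.active_sample_ids(params)[0]
            scored = regulon.score_regulators(net, expr, sample)
            hits += scored.index[0] == "R003"
        assert hits >= 4

    def test_sign_flip_negates_integrated_scores(self):
        net = simulate.make_regulon(10, 8, seed=2)
        params = simulate.SimParams(seed=2, effect_size=2.0)
        expr = simulate.simulate_regulator_expression(net, {"R001"}, params)
        sample = simulate.active_sample_ids(params)[0]
        w = regulon.assign_edge_weights(net, expr)
        sig = regulon.compute_signature(expr, sample)
        flipped = sig.copy()
        flipped["score"] = -flipped["score"]
        g1 = regulon.global_enrichment(w, sig, "R001")
        g2 = regulon.global_enrichment(w, flipped, "R001")
        assert g1 == pytest.approx(-g2, abs=1e-9)

    def test_rank_invariance_under_monotone_transform(self):
        net = simulate.make_regulon(8, 6, seed=4)
        params = simulate.SimParams(seed=4, effect_size=2.0, n_samples=12)
        expr = simulate.simulate_regulator_expression(net, {"R002"}, params)
        sample = simulate.active_sample_ids(params)[0]
        w = regulon.assign_edge_weights(net, expr)
        sig = regulon.compute_signature(expr, sample)
        # strictly monotone per-gene transform of the signature scores
        # preserves every rank-based component
        sig2 = sig.copy()
        sig2["score"] = np.arcsinh(sig2["score"] * 3.0)
        for reg in net.regulators:
            assert regulon.global_enrichment(w, sig, reg) == pytest.approx(
                regulon.global_enrichment(w, sig2, reg), abs=0.02
            )

    def test_locality_with_shared_feature_space(self):
        # two regulons over identical target genes: dropping one leaves the
        # other's components untouched
        edges = pd.DataFrame(
            {
                "regulator": ["A"] * 6 + ["B"] * 6,
                "target": [f"t{i}" for i in range(6)] * 2,
                "sign": [1, 1, 1, -1, -1, 1] * 2,
            }
        )
        net = regulon.RegulonNetwork(edges=edges)
        rng = np.random.default_rng(0)
        genes = sorted(set(edges["regulator"]) | set(edges["target"]))
        expr = pd.DataFrame(
            rng.normal(size=(len(genes), 10)),
            index=genes,
            columns=[f"s{i}" for i in range(10)],
        )
        w_full = regulon.assign_edge_weights(net, expr)
        sig = regulon.compute_signature(expr, "s0")
        before = (
            regulon.local_delta_concordance(w_full, sig, "B"),
            regulon.local_enrichment(w_full, sig, "B"),
            regulon.global_enrichment(w_full, sig, "B"),
        )
        w_dropped = w_full.loc[w_full["regulator"] != "A"]
        after = (
            regulon.local_delta_concordance(w_dropped, sig, "B"),
            regulon.local_enrichment(w_dropped, sig, "B"),
            regulon.global_enrichment(w_dropped, sig, "B"),
        )
        assert before == pytest.approx(after)

    def test_activity_delta(self):
        comp = pd.DataFrame(
            {
                "local_delta_concordance": [0.5, -0.2, 0.1],
                "local_enrichment": [0.4, -0.1, 0.0],
                "global_enrichment": [0.6, -0.3, 0.1],
            },
            index=["R1", "R2", "R3"],
        )
        s1 = regulon.integrate_scores(comp)
        s2 = regulon.integrate_scores(comp * 0.5)
        delta = regulon.activity_delta(s1, s2)
        for r in ["R1", "R2", "R3"]:
            assert delta.loc[r, "difference"] == pytest.approx(
                s2.loc[r, "integrated"] - s1.loc[r, "integrated"]
            )
        same = regulon.activity_delta(s1, s1)
        assert np.allclose(same["difference"], 0.0)

    def test_disjoint_regulators_error(self):
        a = pd.DataFrame({"integrated": [1.0]}, index=["R1"])
        b = pd.DataFrame({"integrated": [1.0]}, index=["R2"])
        with pytest.raises(ValueError, match="disjoint"):
            regulon.activity_delta(a, b)
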