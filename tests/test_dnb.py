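"""DNB statistics against brute-force oracles, module search, tipping-point
selection and neighborhood expansion."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chondrotime import diffexpr, dnb
from chondrotime.core import InteractionNetwork, ValidationError
from chondrotime.simulate import DnbSpec, SimulationConfig, simulate_timecourse
from conftest import make_design


def brute_force_stats(module, logm, design, timepoint, epsilon=0.05):
    """Straight-line recomputation of SDin / PCCin / PCCout / CI."""
    samples = design.samples_at(timepoint)
    members = list(module)
    others = [g for g in logm.index if g not in set(members)]

    def pearson(a, b):
        va = logm.loc[a, samples].to_numpy(dtype=float)
        vb = logm.loc[b, samples].to_numpy(dtype=float)
        if va.std(ddof=1) == 0 or vb.std(ddof=1) == 0:
            return 0.0
        return float(np.corrcoef(va, vb)[0, 1])

    sd_in = float(
        np.mean([logm.loc[g, samples].to_numpy(dtype=float).std(ddof=1) for g in members])
    )
    pairs = [(a, b) for i, a in enumerate(members) for b in members[i + 1 :]]
    pcc_in = float(np.mean([abs(pearson(a, b)) for a, b in pairs]))
    pcc_out = (
        float(np.mean([abs(pearson(a, b)) for a in members for b in others]))
        if others
        else 0.0
    )
    return sd_in, pcc_in, pcc_out, sd_in * pcc_in / max(pcc_out, epsilon)


@pytest.fixture
def one_tp_design():
    return make_design({"D0": 3})


class TestModuleStats:
    def test_hand_arithmetic_two_genes(self, one_tp_design):
        # replicate vectors (1,2,3) and (2,4,6): r = 1, sds 1 and 2
        logm = pd.DataFrame(
            [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 1.0, 2.0]],
            index=["g1", "g2", "g3"],
            columns=one_tp_design.sample_ids,
        )
        s = dnb.module_stats(("g1", "g2"), logm, one_tp_design, "D0")
        assert s.pcc_in == pytest.approx(1.0, abs=1e-12)
        assert s.sd_in == pytest.approx(1.5, abs=1e-12)
        # CI with the brute-force PCCout
        _, _, pcc_out, ci = brute_force_stats(("g1", "g2"), logm, one_tp_design, "D0")
        assert s.pcc_out == pytest.approx(pcc_out, abs=1e-12)
        assert s.ci == pytest.approx(ci, abs=1e-12)

    def test_six_gene_brute_force_oracle(self, one_tp_design):
        rng = np.random.default_rng(0)
        logm = pd.DataFrame(
            rng.standard_normal((6, 3)),
            index=[f"g{i}" for i in range(6)],
            columns=one_tp_design.sample_ids,
        )
        from itertools import combinations

        for size in (2, 3, 4):
            for module in combinations(logm.index, size):
                s = dnb.module_stats(module, logm, one_tp_design, "D0")
                sd_in, pcc_in, pcc_out, ci = brute_force_stats(module, logm, one_tp_design, "D0")
                assert s.sd_in == pytest.approx(sd_in, abs=1e-12)
                assert s.pcc_in == pytest.approx(pcc_in, abs=1e-12)
                assert s.pcc_out == pytest.approx(pcc_out, abs=1e-12)
                assert s.ci == pytest.approx(ci, abs=1e-12)

    def test_ci_monotonicity_in_components(self):
        # finite differences through the CI formula above the floor
        base = dict(sd_in=1.2, pcc_in=0.6, pcc_out=0.3, eps=0.05)

        def ci(sd_in, pcc_in, pcc_out, eps):
            return sd_in * pcc_in / max(pcc_out, eps)

        c0 = ci(**{k: v for k, v in base.items()})
        assert ci(base["sd_in"] + 0.1, base["pcc_in"], base["pcc_out"], 0.05) > c0
        assert ci(base["sd_in"], base["pcc_in"] + 0.1, base["pcc_out"], 0.05) > c0
        assert ci(base["sd_in"], base["pcc_in"], base["pcc_out"] + 0.1, 0.05) < c0

    def test_zero_variance_member_correlations_are_zero(self, one_tp_design):
        logm = pd.DataFrame(
            [[1.0, 1.0, 1.0], [2.0, 4.0, 6.0], [1.0, 3.0, 2.0]],
            index=["flat", "g2", "g3"],
            columns=one_tp_design.sample_ids,
        )
        s = dnb.module_stats(("flat", "g2"), logm, one_tp_design, "D0")
        assert s.pcc_in == 0.0


class TestCandidateModules:
    def test_planted_pair_found(self):
        design = make_design({"D0": 30})
        rng = np.random.default_rng(1)
        data = rng.standard_normal((12, 30))
        data[1] = data[0] * 2  # perfectly correlated pair
        logm = pd.DataFrame(data, index=[f"g{i}" for i in range(12)], columns=design.sample_ids)
        modules = dnb.candidate_modules(logm, design, "D0", min_size=2, max_size=4)
        assert ("g0", "g1") in modules

    def test_null_data_has_no_tight_module(self):
        design = make_design({"D0": 50})
        found_tight = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            logm = pd.DataFrame(
                rng.standard_normal((100, 50)),
                index=[f"g{i}" for i in range(100)],
                columns=design.sample_ids,
            )
            modules = dnb.candidate_modules(logm, design, "D0", min_size=5, max_size=100)
            for m in modules:
                s = dnb.module_stats(m, logm, design, "D0")
                if s.pcc_in > 0.8:
                    found_tight += 1
                    break
        assert found_tight <= 0.05 * n_seeds + 1

    def test_deterministic(self, small_matrix):
        logm = diffexpr.log_transform(small_matrix)
        a = dnb.candidate_modules(logm, small_matrix.design, "D0", min_size=2, max_size=20)
        b = dnb.candidate_modules(logm, small_matrix.design, "D0", min_size=2, max_size=20)
        assert a == b

    def test_too_few_genes_rejected(self, one_tp_design):
        logm = pd.DataFrame(
            np.ones((2, 3)), index=["g1", "g2"], columns=one_tp_design.sample_ids
        )
        with pytest.raises(ValidationError, match="min module size"):
            dnb.candidate_modules(logm, one_tp_design, "D0", min_size=5)


class TestCriticalityCurve:
    def test_planted_tip_recovered(self):
        cfg = SimulationConfig(
            seed=11, n_replicates=10, cluster_spec=(), n_null_genes=100,
            dnb_spec=DnbSpec(module_size=15, tipping_index=2),
        )
        matrix, _, members = simulate_timecourse(cfg)
        logm = diffexpr.log_transform(matrix)
        res = dnb.criticality_curve(logm, matrix.design)
        assert res.tipping_timepoint == "D8"
        assert len(set(res.members) & set(members)) >= 10

    def test_argmax_semantics(self):
        # CI values (1,5,2,2) -> second timepoint; verified through a tiny
        # synthetic where D4 carries a perfectly correlated volatile block
        cfg = SimulationConfig(
            seed=12, n_replicates=8, cluster_spec=(), n_null_genes=40,
            dnb_spec=DnbSpec(module_size=8, tipping_index=1, rho_in_at_tip=0.95,
                             sd_multiplier_at_tip=4.0),
        )
        matrix, _, _ = simulate_timecourse(cfg)
        logm = diffexpr.log_transform(matrix)
        res = dnb.criticality_curve(logm, matrix.design)
        assert res.tipping_timepoint == str(res.ci_curve.idxmax())
        assert res.ci_curve.max() == res.ci_curve[res.tipping_timepoint]

    def test_single_timepoint_returned(self):
        design = make_design({"D0": 10})
        rng = np.random.default_rng(13)
        logm = pd.DataFrame(
            rng.standard_normal((30, 10)),
            index=[f"g{i}" for i in range(30)],
            columns=design.sample_ids,
        )
        res = dnb.criticality_curve(logm, design)
        assert res.tipping_timepoint == "D0"

    def test_null_tip_distribution_approximately_uniform(self):
        """With no planted module, every timepoint is an equally likely tip."""
        design = make_design({"D0": 5, "D4": 5, "D8": 5, "D12": 5})
        tips = []
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            logm = pd.DataFrame(
                rng.standard_normal((40, 20)),
                index=[f"g{i}" for i in range(40)],
                columns=design.sample_ids,
            )
            tips.append(dnb.criticality_curve(logm, design).tipping_timepoint)
        counts = [tips.count(tp) for tp in design.timepoints]
        p = stats.chisquare(counts).pvalue
        assert p > 0.01


class TestNeighborhood:
    def test_empty_network_keeps_members_isolated(self):
        net = InteractionNetwork.from_edges([])
        nodes, edges = dnb.dnb_neighborhood(["a", "b"], net, {"x"})
        assert nodes == ["a", "b"] and edges == []

    def test_star_network_keeps_only_deg_neighbors(self):
        net = InteractionNetwork.from_edges(
            [("hub", x) for x in ["d1", "d2", "d3", "n1", "n2"]]
        )
        nodes, edges = dnb.dnb_neighborhood(["hub"], net, {"d1", "d2", "d3"})
        assert set(nodes) == {"hub", "d1", "d2", "d3"}
        assert len(edges) == 3

    def test_monotone_in_deg_set(self):
        net = InteractionNetwork.from_edges(
            [("m", "a"), ("m", "b"), ("a", "b"), ("b", "c")]
        )
        nodes1, edges1 = dnb.dnb_neighborhood(["m"], net, {"a"})
        nodes2, edges2 = dnb.dnb_neighborhood(["m"], net, {"a", "b"})
        assert set(nodes1) <= set(nodes2)
        assert set(edges1) <= set(edges2)
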