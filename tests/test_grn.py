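"""TF-family enrichment, PWM scanning against enumeration oracles, and the
direction rule for regulatory edges."""

from itertools import combinations, product

import numpy as np
import pytest
from scipy import stats

from chondrotime import grn
from chondrotime.core import PromoterSet, PwmLibrary, TfAnnotation
from chondrotime.grn import (
    MotifHit,
    TranscriptionalState,
    build_state_network,
    count_pairs,
    pwm_scan,
    tf_family_enrichment,
)

BASES = "ACGT"


def hypergeom_by_enumeration(N, K, n, k):
    """P(X >= k) by enumerating every n-subset of an N-universe."""
    universe = list(range(N))
    family = set(range(K))
    total = hits = 0
    for draw in combinations(universe, n):
        total += 1
        if len(family & set(draw)) >= k:
            hits += 1
    return hits / total


class TestFamilyEnrichment:
    def _setup(self, family_sizes, subset):
        family_of = {}
        i = 0
        for fam, size in family_sizes.items():
            for _ in range(size):
                family_of[f"tf{i}"] = fam
                i += 1
        return TfAnnotation(family_of), set(family_of), subset

    def test_matches_exhaustive_enumeration(self):
        # N=10 TFs, family F1 of 5; subset of 4 drawn entirely from F1
        annot, universe, _ = self._setup({"F1": 5, "F2": 5}, None)
        subset = {f"tf{i}" for i in range(4)}  # all in F1
        res = tf_family_enrichment(subset, annot, universe)
        expected = hypergeom_by_enumeration(10, 5, 4, 4)
        assert res.loc["F1", "p_hyper"] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(5 / 210, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        annot, universe, _ = self._setup({"F1": 5, "F2": 5}, None)
        subset = {f"tf{i}" for i in range(5, 9)}  # all F2
        res = tf_family_enrichment(subset, annot, universe)
        assert res.loc["F1", "p_hyper"] == pytest.approx(1.0, abs=1e-12)

    def test_subset_equal_to_universe_is_degenerate(self):
        annot, universe, _ = self._setup({"F1": 4, "F2": 6}, None)
        res = tf_family_enrichment(universe, annot, universe)
        # drawing everything makes k = K surely: P(X >= K) = 1
        for fam in ("F1", "F2"):
            assert res.loc[fam, "p_hyper"] == pytest.approx(1.0, abs=1e-12)

    def test_hypergeometric_equals_one_sided_fisher(self):
        annot, universe, _ = self._setup({"F1": 7, "F2": 8, "F3": 5}, None)
        rng = np.random.default_rng(0)
        subset = set(rng.choice(sorted(universe), size=6, replace=False))
        res = tf_family_enrichment(subset, annot, universe)
        n, N = len(subset), len(universe)
        for fam in res.index:
            K, k = int(res.loc[fam, "family_size"]), int(res.loc[fam, "count"])
            table = [[k, n - k], [K - k, N - K - (n - k)]]
            fisher = stats.fisher_exact(table, alternative="greater")[1]
            assert res.loc[fam, "p_hyper"] == pytest.approx(fisher, abs=1e-12)


def consensus_pwm(consensus: str) -> np.ndarray:
    mat = np.full((4, len(consensus)), 0.0)
    for j, ch in enumerate(consensus):
        mat[BASES.index(ch), j] = 1.0
    return mat


class TestPwmScan:
    def test_consensus_trimer_p_matches_enumeration(self):
        lib = PwmLibrary({"M": consensus_pwm("ACG")})
        promoters = PromoterSet({"g1": "ACG"})
        hits = pwm_scan(promoters, lib, p_threshold=0.05, both_strands=False)
        assert len(hits) == 1
        h = hits[0]
        # uniform background: only the consensus trimer reaches the top score
        assert h.p_value == pytest.approx((1 / 4) ** 3, abs=1e-12)
        assert h.score == pytest.approx(3 * np.log2(1 / 0.25), abs=0.01)

    @pytest.mark.parametrize("width", [3, 4, 5, 6])
    def test_p_values_match_kmer_enumeration(self, width):
        """Exact DP null tail equals brute force over all 4^w words."""
        rng = np.random.default_rng(width)
        pwm = rng.dirichlet(np.full(4, 0.6), size=width).T
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        lib = PwmLibrary({"M": pwm}, bg)
        # score every word with the same floored, column-discretized matrix
        from chondrotime.grn import _SCORE_BIN, _floored_logodds

        mat_int = np.round(_floored_logodds(pwm, bg)[:4] / _SCORE_BIN).astype(int)
        word_scores = {}
        for word in product(range(4), repeat=width):
            s = sum(mat_int[b, j] for j, b in enumerate(word))
            p = np.prod([bg[b] for b in word])
            word_scores[word] = (s, p)
        for probe in list(product(range(4), repeat=width))[:: max(1, 4**width // 32)]:
            seq = "".join(BASES[b] for b in probe)
            hits = pwm_scan(PromoterSet({"g": seq}), lib, p_threshold=1.0, both_strands=False)
            assert len(hits) == 1
            s_probe = word_scores[probe][0]
            p_enum = sum(p for s, p in word_scores.values() if s >= s_probe)
            assert hits[0].p_value == pytest.approx(p_enum, abs=1e-12)

    def test_uniform_pwm_yields_no_hits(self):
        lib = PwmLibrary({"M": np.full((4, 4), 0.25)})
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list(BASES), size=100))
        hits = pwm_scan(PromoterSet({"g": seq}), lib, p_threshold=0.99)
        assert hits == []

    def test_planted_consensus_found_at_offset(self):
        rng = np.random.default_rng(2)
        cons = "ACGTAC"
        seq = list(rng.choice(list(BASES), size=300))
        seq[137 : 137 + 6] = list(cons)
        lib = PwmLibrary({"M": consensus_pwm(cons)})
        hits = pwm_scan(PromoterSet({"g": "".join(seq)}), lib, p_threshold=1e-3)
        assert any(h.offset == 137 and h.strand == "+" for h in hits)

    def test_strand_symmetry(self):
        """Scanning a sequence and its reverse complement mirrors hits."""
        rng = np.random.default_rng(3)
        cons = "ACGGTA"
        seq = list(rng.choice(list(BASES), size=200))
        seq[50:56] = list(cons)
        fwd = "".join(seq)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rev = "".join(comp[c] for c in reversed(fwd))
        lib = PwmLibrary({"M": consensus_pwm(cons)})
        h_fwd = pwm_scan(PromoterSet({"g": fwd}), lib, p_threshold=1e-3)
        h_rev = pwm_scan(PromoterSet({"g": rev}), lib, p_threshold=1e-3)
        mirrored = {
            (len(fwd) - h.offset - 6, {"+": "-", "-": "+"}[h.strand]) for h in h_fwd
        }
        assert {(h.offset, h.strand) for h in h_rev} == mirrored

    def test_n_bases_contribute_background(self):
        lib = PwmLibrary({"M": consensus_pwm("ACG")})
        hits = pwm_scan(PromoterSet({"g": "NNN"}), lib, p_threshold=1.0, both_strands=False)
        assert len(hits) == 1
        assert hits[0].score == pytest.approx(0.0, abs=1e-9)

    def test_motif_wider_than_promoter_warns(self):
        lib = PwmLibrary({"M": consensus_pwm("ACGTAC")})
        with pytest.warns(UserWarning, match="wider"):
            hits = pwm_scan(PromoterSet({"g": "ACG"}), lib)
        assert hits == []


def _hit(motif, gene):
    return MotifHit(motif, gene, 0, "+", 5.0, 1e-5)


class TestStateNetwork:
    def test_direction_rule(self):
        state = TranscriptionalState(
            label="state1",
            comparison="D4_vs_D0",
            direction={"TF1": "up", "T_up": "up", "T_down": "down", "T_nohit": "up"},
            tfs=frozenset({"TF1"}),
        )
        hits = [_hit("M1", "T_up"), _hit("M1", "T_down")]
        edges = build_state_network(state, hits, {"TF1": ["M1"]})
        signs = {(e.tf_gene_id, e.target_gene_id): e.sign for e in edges}
        assert signs[("TF1", "T_up")] == "activation"  # same direction
        assert signs[("TF1", "T_down")] == "inhibition"  # opposite direction
        assert ("TF1", "T_nohit") not in signs  # no motif hit -> no edge

    def test_tf_without_motif_contributes_nothing(self):
        state = TranscriptionalState(
            "state1", "D4_vs_D0", {"TF1": "up", "T1": "up"}, frozenset({"TF1"})
        )
        assert build_state_network(state, [_hit("M9", "T1")], {}) == []

    def test_count_pairs_manual_fixture(self):
        def edge(tf, tgt, state, sign):
            return grn.RegulatoryEdge(tf, tgt, state, sign, _hit("M", tgt))

        edges = [
            edge("TF1", "A", "state1", "activation"),
            edge("TF1", "B", "state1", "inhibition"),
            edge("TF2", "C", "state1", "activation"),
            edge("TF1", "D", "state2", "activation"),
            edge("TF3", "E", "state2", "inhibition"),
        ]
        counts, multi = count_pairs(edges)
        assert counts.loc["state1", "activation"] == 2
        assert counts.loc["state1", "inhibition"] == 1
        assert counts.loc["state2", "activation"] == 1
        assert counts.loc["state2", "inhibition"] == 1
        assert multi == ["TF1"]  # active in two states

    def test_empty_edge_list(self):
        counts, multi = count_pairs([])
        assert counts.empty and multi == []
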