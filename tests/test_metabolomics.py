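"""OPLS-DA fitting, VIP identities, and DRM screening semantics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chondrotime import metabolomics as mb
from chondrotime.core import MetaboliteTable, SampleDesign
from chondrotime.simulate import MetSpec, SimulationConfig, simulate_metabolome
from conftest import make_design


def table_from_array(x: np.ndarray, design: SampleDesign, prefix="m") -> MetaboliteTable:
    df = pd.DataFrame(
        x, index=[f"{prefix}{i}" for i in range(x.shape[0])], columns=design.sample_ids
    )
    return MetaboliteTable(df, design)


@pytest.fixture
def two_groups_20():
    return make_design({"A": 20, "B": 20})


class TestOplsFit:
    def test_class_carrying_variable_dominates_weights(self, two_groups_20):
        rng = np.random.default_rng(0)
        n = 40
        y = np.array([0.0] * 20 + [1.0] * 20)
        x = np.vstack([y * 4 + 10, *(rng.normal(10, 1, (3, n)))])  # x1 = class exactly
        table = table_from_array(np.abs(x), two_groups_20)
        model = mb.fit_oplsda(table, two_groups_20, "A", "B", n_orth=2)
        assert abs(model.weights[0]) > 0.95

    def test_orthogonal_scores_orthogonal_to_predictive(self, two_groups_20):
        rng = np.random.default_rng(1)
        x = rng.lognormal(2, 0.5, (12, 40))
        table = table_from_array(x, two_groups_20)
        for n_orth in (1, 2):
            model = mb.fit_oplsda(table, two_groups_20, "A", "B", n_orth=n_orth)
            for k in range(model.orth_scores.shape[1]):
                assert abs(model.orth_scores[:, k] @ model.scores) < 1e-8

    def test_permuted_labels_have_no_predictive_power(self):
        # scramble metabolite-class association: average CV Q2 must be <= 0
        rng = np.random.default_rng(2)
        q2s = []
        for rep in range(20):
            design = make_design({"A": 10, "B": 10})
            x = rng.lognormal(2, 0.4, (15, 20))  # pure noise, no class signal
            table = table_from_array(x, design)
            q2s.append(mb.cross_val_q2(table, design, "A", "B", seed=rep))
        assert np.mean(q2s) <= 0


class TestVip:
    def test_equal_weights_give_unit_vip(self, two_groups_20):
        # symmetric data: every variable identically informative
        y = np.array([0.0] * 20 + [1.0] * 20)
        x = np.vstack([y + 1, y + 2, y + 3]) + 0.0
        rng = np.random.default_rng(3)
        x = x + rng.normal(0, 1e-9, x.shape)  # break exact degeneracy
        table = table_from_array(x, two_groups_20)
        model = mb.fit_oplsda(table, two_groups_20, "A", "B", n_orth=0)
        vip = mb.vip_scores(model)
        np.testing.assert_allclose(vip, 1.0, atol=1e-3)

    @settings(derandomize=True, deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_mean_squared_vip_is_one(self, seed):
        rng = np.random.default_rng(seed)
        design = make_design({"A": 5, "B": 5})
        x = rng.lognormal(1, 0.6, (rng.integers(4, 20), 10))
        table = table_from_array(x, design)
        model = mb.fit_oplsda(table, design, "A", "B", n_orth=int(seed % 3))
        vip = mb.vip_scores(model)
        assert (vip**2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_hand_computed_three_variable_fixture(self):
        design = make_design({"A": 3, "B": 3})
        x = np.array(
            [
                [1.0, 2.0, 1.5, 5.0, 6.0, 5.5],
                [3.0, 3.1, 2.9, 3.0, 3.2, 2.8],
                [2.0, 1.0, 1.5, 4.0, 5.0, 4.5],
            ]
        )
        table = table_from_array(x, design)
        model = mb.fit_oplsda(table, design, "A", "B", n_orth=0)
        # single component: VIP_j = sqrt(p) * |w_j| with unit-norm w
        expected = np.sqrt(3) * np.abs(model.weights)
        np.testing.assert_allclose(mb.vip_scores(model), expected, atol=1e-10)


class TestPairwiseScreen:
    def _screen_with(self, fc_vip_pairs, design):
        """Build a table whose group-mean FCs are exact, then screen it."""
        a_mean = np.array([10.0] * len(fc_vip_pairs))
        b_mean = a_mean * np.array([fc for fc, _ in fc_vip_pairs])
        n = len(design.samples_at("A"))
        x = np.hstack(
            [np.tile(a_mean[:, None], (1, n)), np.tile(b_mean[:, None], (1, n))]
        )
        rng = np.random.default_rng(4)
        x = x * rng.normal(1, 1e-4, x.shape)
        return table_from_array(x, design)

    def test_boundary_semantics_and_brute_force_refilter(self):
        design = make_design({"A": 5, "B": 5})
        rng = np.random.default_rng(5)
        x = rng.lognormal(2, 0.6, (15, 10))
        table = table_from_array(x, design)
        screen = mb.pairwise_drm(table, design, "A", "B")
        t = screen.table
        for met in t.index:
            fc, vip = t.loc[met, "fold_change"], t.loc[met, "vip"]
            expected = bool((fc >= 2.0 or fc <= 0.5) and vip > 1.0)
            assert bool(t.loc[met, "drm_flag"]) == expected
        # explicit boundary rows: FC exactly 2 with VIP just above 1 is a DRM
        row = pd.Series({"fold_change": 2.0, "vip": 1.01})
        assert (row["fold_change"] >= 2.0 or row["fold_change"] <= 0.5) and row["vip"] > 1.0
        row2 = pd.Series({"fold_change": 1.9, "vip": 5.0})
        assert not (row2["fold_change"] >= 2.0 or row2["fold_change"] <= 0.5)

    def test_label_swap_inverts_fold_change_keeps_calls(self):
        design = make_design({"A": 5, "B": 5})
        rng = np.random.default_rng(6)
        x = rng.lognormal(2, 0.8, (12, 10))
        table = table_from_array(x, design)
        ab = mb.pairwise_drm(table, design, "A", "B")
        ba = mb.pairwise_drm(table, design, "B", "A")
        np.testing.assert_allclose(
            ab.table["fold_change"], 1.0 / ba.table["fold_change"], rtol=1e-10
        )
        assert ab.drms == ba.drms


class TestMultigroupScreen:
    def test_flat_means_not_called(self):
        design = make_design({"D0": 5, "D4": 5, "D8": 5, "D12": 5})
        rng = np.random.default_rng(7)
        x = rng.normal(50, 1, (10, 20))
        table = table_from_array(np.abs(x), design)
        screen = mb.multigroup_drm(table, design)
        assert screen.table["drm_flag"].sum() <= 1  # chance-level at most

    def test_planted_trend_called_reliably(self):
        design = make_design({"D0": 5, "D4": 5, "D8": 5, "D12": 5})
        called = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(20, 2, (10, 20))
            trend = np.repeat([1.0, 2.0, 3.0, 4.0], 5) * 10
            x[0] = trend * rng.normal(1, 0.1, 20)  # means 10,20,30,40 at CV 0.1
            table = table_from_array(np.abs(x), design)
            screen = mb.multigroup_drm(table, design)
            called += bool(screen.table.loc["m0", "drm_flag"])
        assert called >= 0.95 * n_seeds

    def test_anova_matches_textbook_f(self):
        design = make_design({"D0": 3, "D4": 3, "D8": 3, "D12": 3})
        x = np.array([[4.0, 5, 6, 7, 8, 9, 1, 2, 3, 10, 11, 12]] * 3)
        rng = np.random.default_rng(8)
        x = x + rng.normal(0, 0.3, x.shape)
        table = table_from_array(np.abs(x), design)
        screen = mb.multigroup_drm(table, design)
        for i, met in enumerate(table.metabolite_ids):
            groups = [x[i, j * 3 : (j + 1) * 3] for j in range(4)]
            expected = stats.f_oneway(*groups).pvalue
            assert screen.table.loc[met, "anova_p"] == pytest.approx(expected, abs=1e-10)


class TestDrmSets:
    def _screen(self, drm_up, drm_down, comparison):
        mets = sorted(set(drm_up) | set(drm_down) | {"null1"})
        t = pd.DataFrame(
            {
                "fold_change": [3.0 if m in drm_up else 0.3 if m in drm_down else 1.0 for m in mets],
                "vip": [2.0] * len(mets),
                "drm_flag": [m in set(drm_up) | set(drm_down) for m in mets],
                "direction": ["increased" if m in drm_up else "decreased" for m in mets],
            },
            index=mets,
        )
        return mb.MetaboliteScreen(t, comparison, 0.5, 2.0)

    def test_exclusive_regions_hand_tally(self):
        screens = {
            "D4_vs_D0": self._screen({"a", "b"}, set(), "D4_vs_D0"),
            "D8_vs_D0": self._screen({"b", "c"}, set(), "D8_vs_D0"),
            "D12_vs_D0": self._screen({"b"}, set(), "D12_vs_D0"),
        }
        out = mb.drm_sets(screens)
        regions = out["exclusive_regions"]
        assert regions["D4_vs_D0"] == 1  # a only
        assert regions["D8_vs_D0"] == 1  # c only
        assert regions["D4_vs_D0 & D8_vs_D0 & D12_vs_D0"] == 1  # b everywhere
        assert out["consistent_increased"]["D0"] == ["b"]

    def test_all_increased_fraction_is_one(self):
        screens = {"D4_vs_D0": self._screen({"a", "b", "c"}, set(), "D4_vs_D0")}
        assert mb.drm_sets(screens)["fraction_increased"] == 1.0


def test_planted_metabolome_screen_recovers_truth():
    """Sensitivity and null false-call rate on the planted panel."""
    sens, false_rate = [], []
    for seed in range(10):
        cfg = SimulationConfig(
            seed=seed, met_spec=MetSpec(cv=0.1, n_per_group=5)
        )
        table, truth = simulate_metabolome(cfg)
        screen = mb.pairwise_drm(table, table.design, "D0", "D4")
        called = screen.drms
        planted = truth["D4_vs_D0"]
        nulls = set(table.metabolite_ids) - planted
        sens.append(len(called & planted) / len(planted))
        false_rate.append(len(called & nulls) / len(nulls))
    assert np.mean(sens) >= 0.9
    assert np.mean(false_rate) <= 0.1
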