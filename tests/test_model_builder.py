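import numpy as np
import pytest

from conftest import make_hmm, sample_observations
from ehmm.model_builder import (CompositionConfig, StateSelection,
                                build_foreground_module, compose, entry_rates,
                                fit_background, fit_foreground_5state,
                                load_model, refine_foreground, save_model,
                                select_states)
from ehmm.signal_io import CANONICAL_FEATURES


def model5_from_means(means, sigma=1e-3):
    """A 5-state model with prescribed count-scale emission means; sigma is
    tiny so exp(mu + sigma^2/2) ~ the requested means."""
    mu = np.log(np.asarray(means, float))
    return make_hmm(np.full(5, 0.2), np.full((5, 5), 0.2), np.ones((5, 5), bool),
                    mu, np.full((5, 4), sigma), roles=["FG5"] * 5,
                    features=CANONICAL_FEATURES)


# features: accessibility, H3K27ac, H3K4me1, H3K4me3
HAND_MEANS = [
    [100, 10, 1, 1],    # state 0: acc/K27 = 10   (A)
    [80, 10, 1, 1],     # state 1: acc/K27 = 8    (A)
    [5, 5, 50, 10],     # state 2: me1/me3 = 5
    [5, 5, 40, 10],     # state 3: me1/me3 = 4
    [5, 5, 1, 10],      # state 4: me1/me3 = 0.1
]


class TestEntryRates:
    def test_enhancer_rate_from_genome_statistics(self):
        e, _ = entry_rates(CompositionConfig())
        assert round(100 * e, 2) == 1.33

    def test_promoter_rate_from_genome_statistics(self):
        _, p = entry_rates(CompositionConfig())
        assert round(100 * p, 2) == 0.23

    def test_zero_elements_zero_rate(self):
        e, p = entry_rates(CompositionConfig(n_enhancers_genome=0))
        assert e == 0.0 and p > 0

    def test_rate_at_least_one_rejected(self):
        with pytest.raises(ValueError):
            entry_rates(CompositionConfig(n_enhancers_genome=4 * 10**7))


class TestSelectStates:
    def test_enhancer_selection_by_hand(self):
        sel = select_states(model5_from_means(HAND_MEANS), "enhancer")
        assert set(sel.a_states) == {0, 1}
        assert set(sel.n_states) == {2, 3}
        assert sel.discarded == 4

    def test_promoter_selection_reverses_n_ranking(self):
        sel = select_states(model5_from_means(HAND_MEANS), "promoter")
        assert set(sel.a_states) == {0, 1}
        assert set(sel.n_states) == {4, 3}
        assert sel.discarded == 2

    def test_scale_invariance(self):
        scaled = [[10 * v for v in row] for row in HAND_MEANS]
        assert select_states(model5_from_means(scaled), "enhancer") == \
            select_states(model5_from_means(HAND_MEANS), "enhancer")

    def test_selection_partitions_states(self):
        with pytest.raises(ValueError):
            StateSelection((0, 1), (1, 2), 3)


class TestBuildForegroundModule:
    def module(self):
        m5 = model5_from_means(HAND_MEANS, sigma=0.4)
        return m5, build_foreground_module(m5, select_states(m5, "enhancer"),
                                           "enhancer")

    def test_directionality_forbidden_transitions(self):
        _, mod = self.module()
        n1, a, n2 = [0, 1], [2, 3], [4, 5]
        assert not mod.mask[np.ix_(a, n1)].any()      # no A -> N1
        assert not mod.mask[np.ix_(n2, a)].any()      # no N2 back to A
        assert not mod.mask[np.ix_(n1, n2)].any()     # no skipping A

    def test_n2_emissions_copy_n1(self):
        _, mod = self.module()
        assert np.array_equal(mod.emissions.mu[4:6], mod.emissions.mu[0:2])
        assert np.array_equal(mod.emissions.sigma[4:6], mod.emissions.sigma[0:2])

    def test_rows_stochastic(self):
        _, mod = self.module()
        assert np.allclose(mod.transmat.sum(axis=1), 1.0, atol=1e-9)

    def test_roles_ordered_n1_a_n2(self):
        _, mod = self.module()
        assert mod.roles == ["E_N1", "E_N1", "E_A", "E_A", "E_N2", "E_N2"]


class TestFits:
    def test_five_states_always_returned(self, rng):
        obs = [np.exp(rng.normal(1.5, 0.6, size=(30, 4))).clip(1.0) for _ in range(4)]
        model = fit_foreground_5state(obs, seed=0, max_iter=5)
        assert model.n_states == 5 and model.roles == ["FG5"] * 5

    def test_background_returns_ten_states(self, rng):
        obs = [np.exp(rng.normal(1.0, 0.6, size=(25, 4))).clip(1.0) for _ in range(4)]
        model = fit_background(obs, seed=0, max_iter=5)
        assert model.n_states == 10 and set(model.roles) == {"BG"}

    def test_five_state_recovery_up_to_relabelling(self):
        rng = np.random.default_rng(3)
        mu = np.array([[1.0, 1.0], [3.0, 1.0], [1.0, 3.0], [3.0, 3.0], [5.0, 5.0]])
        trans = np.full((5, 5), 0.05) + np.eye(5) * 0.75
        truth = make_hmm(np.full(5, 0.2), trans, np.ones((5, 5), bool),
                         mu, np.full((5, 2), 0.35), roles=["FG5"] * 5,
                         features=("fa", "fb"))
        _, obs = sample_observations(rng, truth, 60_000)
        fitted = fit_foreground_5state([obs], features=("fa", "fb"), seed=0)
        # match states by nearest emission mean vector
        order = [int(np.argmin(np.abs(fitted.emissions.mu - m).sum(axis=1)))
                 for m in mu]
        assert sorted(order) == list(range(5))
        assert np.abs(fitted.emissions.mu[order] - mu).max() < 0.1
        perm = fitted.transmat[np.ix_(order, order)]
        assert np.abs(perm - trans).max() < 0.03

    def test_short_region_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_foreground_5state([np.full((3, 4), 2.0)])


class TestRefineForeground:
    def test_emissions_unchanged_and_paths_end_in_n2(self, rng):
        m5 = model5_from_means(HAND_MEANS, sigma=0.4)
        mod = build_foreground_module(m5, select_states(m5, "enhancer"), "enhancer")
        regions = []
        for _ in range(6):
            states = [0] * 3 + [2] * 5 + [4] * 3  # N1 A N2 blocks
            mu = mod.emissions.mu[states]
            regions.append(np.exp(mu + 0.3 * rng.standard_normal(mu.shape)).clip(1.0))
        before = mod.emissions.mu.copy()
        refined = refine_foreground(mod, regions)
        assert np.array_equal(refined.emissions.mu, before)
        from ehmm.hmm_core import viterbi
        p = viterbi(refined, regions[0],
                    start_states=refined.role_indices("E_N1"),
                    end_states=refined.role_indices("E_N2"))
        assert refined.roles[p.states[-1]] == "E_N2"

    def test_long_accessible_stretch_raises_a_self_transition(self, rng):
        m5 = model5_from_means(HAND_MEANS, sigma=0.4)
        mod = build_foreground_module(m5, select_states(m5, "enhancer"), "enhancer")
        a_group = np.ix_([2, 3], [2, 3])
        init_self = mod.transmat[a_group].sum() / 2
        regions = []
        for _ in range(8):
            states = [0] * 2 + [2] * 16 + [4] * 2  # dominant central A stretch
            mu = mod.emissions.mu[states]
            regions.append(np.exp(mu + 0.2 * rng.standard_normal(mu.shape)).clip(1.0))
        refined = refine_foreground(mod, regions)
        # hand count: A occupies 16 of 20 bins, 15/16 A->A transitions
        assert refined.transmat[a_group].sum() / 2 > init_self


class TestCompose:
    def build(self):
        rngless = np.linspace(0.5, 1.5, 10)
        bg = make_hmm(np.full(10, 0.1),
                      np.full((10, 10), 0.01) + np.eye(10) * 0.90,
                      np.ones((10, 10), bool),
                      np.tile(rngless[:, None], (1, 4)), np.full((10, 4), 0.5),
                      roles=["BG"] * 10, features=CANONICAL_FEATURES)
        m5 = model5_from_means(HAND_MEANS, sigma=0.4)
        enh = build_foreground_module(m5, select_states(m5, "enhancer"), "enhancer")
        pro = build_foreground_module(m5, select_states(m5, "promoter"), "promoter")
        return bg, enh, pro, compose(bg, enh, pro)

    def test_rows_stochastic(self):
        *_, full = self.build()
        assert np.allclose(full.transmat.sum(axis=1), 1.0, atol=1e-9)

    def test_entry_rates_from_bg_rows(self):
        *_, full = self.build()
        e_n1 = full.role_indices("E_N1")
        p_n1 = full.role_indices("P_N1")
        for row in range(10):
            assert full.transmat[row, e_n1].sum() == pytest.approx(0.0133, abs=5e-5)
            assert full.transmat[row, p_n1].sum() == pytest.approx(0.00234, abs=5e-5)

    def test_no_cross_module_transitions(self):
        *_, full = self.build()
        e_idx = full.role_indices({"E_N1", "E_A", "E_N2"})
        p_idx = full.role_indices({"P_N1", "P_A", "P_N2"})
        assert (full.transmat[np.ix_(e_idx, p_idx)] == 0).all()
        assert (full.transmat[np.ix_(p_idx, e_idx)] == 0).all()

    def test_emissions_of_submodels_unaltered(self):
        bg, enh, pro, full = self.build()
        assert np.array_equal(full.emissions.mu[:10], bg.emissions.mu)
        assert np.array_equal(full.emissions.mu[10:16], enh.emissions.mu)
        assert np.array_equal(full.emissions.mu[16:], pro.emissions.mu)

    def test_n2_exit_mass_equals_n1_to_a_mass(self):
        bg, enh, _, full = self.build()
        n1_to_a = enh.transmat[0, [2, 3]].sum()
        exit_mass = full.transmat[14, :10].sum()  # first E_N2 row into BG
        assert exit_mass == pytest.approx(n1_to_a, abs=1e-9)


class TestSerialization:
    def test_save_load_save_identical_bytes(self, tmp_path):
        bg_trans = np.full((3, 3), 0.1) + np.eye(3) * 0.7
        model = make_hmm([0.2, 0.3, 0.5], bg_trans, np.ones((3, 3), bool),
                         np.array([[1.0, 2.0], [0.5, 0.1], [3.0, 0.7]]),
                         np.full((3, 2), 0.5))
        model.metadata["bin_width"] = 100
        model.metadata["reference_quantiles_f0"] = np.array([0.0, 1.0, 5.0])
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        save_model(model, p1)
        loaded = load_model(p1)
        save_model(loaded, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert loaded.roles == model.roles
        assert np.array_equal(loaded.transmat, model.transmat)
        assert np.array_equal(loaded.emissions.mu, model.emissions.mu)
        loaded.validate()

    def test_missing_features_rejected(self, tmp_path):
        import json

        model = make_hmm([1.0], [[1.0]], [[True]], [0.5], [0.5])
        path = tmp_path / "m.json"
        save_model(model, path)
        payload = json.loads(path.read_text())
        del payload["features"]
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="features"):
            load_model(path)

    def test_version_mismatch_rejected(self, tmp_path):
        import json

        model = make_hmm([1.0], [[1.0]], [[True]], [0.5], [0.5])
        path = tmp_path / "m.json"
        save_model(model, path)
        payload = json.loads(path.read_text())
        payload["format_version"] = 999
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="version"):
            load_model(path)
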