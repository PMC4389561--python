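import numpy as np
import pandas as pd
import pytest
import scipy.stats

from conftest import simulate_surviving
from geoshift._sse import _A, _B4, _B5, _integrate
from geoshift.markov import mk_loglik
from geoshift.musse import (MusseModel, MusseParams, compare_regions,
                            fit_musse, musse_loglik, normalize_rates)


class TestLikelihood:
    def test_pure_birth_equals_yule_closed_form(self, yule10):
        tree, states = yule10
        for lam in (0.1, 0.23, 0.5):
            ll = musse_loglik(tree, states,
                              MusseParams([lam], [0.0], np.zeros((1, 1))))
            yule = (tree.n_tips - 1) * np.log(lam) - lam * tree.total_length
            assert ll == pytest.approx(yule, abs=1e-8)

    def test_extinction_probability_zero_without_extinction(self):
        # mu = 0, rho = 1: E stays exactly 0 along any branch
        lam = np.array([0.3])
        mu = np.array([0.0])
        q = np.zeros((1, 1))
        y = np.array([0.0, 1.0])   # E, D at a tip with rho=1
        ok = _integrate(y, 25.0, lam, mu, q, _A, _B5, _B4, 1e-10, 1e-12)
        assert ok == 1
        assert y[0] == 0.0

    def test_extinction_probability_monotone_when_mu_positive(self):
        lam = np.array([0.2])
        mu = np.array([0.1])
        q = np.zeros((1, 1))
        y = np.array([0.0, 1.0])
        es = [0.0]
        for _ in range(30):
            ok = _integrate(y, 1.0, lam, mu, q, _A, _B5, _B4, 1e-10, 1e-12)
            assert ok == 1
            es.append(y[0])
        assert all(b >= a for a, b in zip(es, es[1:]))
        assert 0.0 < es[-1] < 1.0

    def test_state_independence_factorizes_into_tree_and_character(self):
        """With equal rates across states the MuSSE likelihood equals the
        single-state likelihood plus the Mk likelihood of the character
        (FitzJohn root weighting on both)."""
        tree, _, states, _ = simulate_surviving(
            2, [0.2, 0.2], 0.05, 0.03, seed=11, max_taxa=60,
            require_both_states=True)
        p2 = MusseParams([0.2, 0.2], [0.06, 0.06],
                         [[0, 0.03], [0.03, 0]])
        ll2 = musse_loglik(tree, states, p2, state_names=[0, 1])
        p1 = MusseParams([0.2], [0.06], np.zeros((1, 1)))
        ll1 = musse_loglik(tree, pd.Series(0, index=tree.tip_labels), p1)
        qmk = np.array([[-0.03, 0.03], [0.03, -0.03]])
        llmk = mk_loglik(tree, states, qmk, root_prior="fitzjohn")
        assert ll2 == pytest.approx(ll1 + llmk, abs=1e-6)

    def test_isolated_states_without_transitions_are_impossible(self):
        # q = 0 and both states observed: no history can produce the data
        tree, _, states, _ = simulate_surviving(
            2, [0.2, 0.2], 0.0, 0.05, seed=33, max_taxa=30,
            require_both_states=True)
        p = MusseParams([0.2, 0.2], [0.0, 0.0], np.zeros((2, 2)))
        assert musse_loglik(tree, states, p, state_names=[0, 1]) == -np.inf

    def test_sampling_fraction_tip_conditions(self, yule10):
        # k=1 with rho < 1 changes the likelihood, rho = 1 recovers it
        tree, states = yule10
        full = musse_loglik(tree, states,
                            MusseParams([0.2], [0.05], np.zeros((1, 1)),
                                        rho=[1.0]))
        half = musse_loglik(tree, states,
                            MusseParams([0.2], [0.05], np.zeros((1, 1)),
                                        rho=[0.5]))
        assert half != pytest.approx(full)

    def test_rho_zero_for_observed_state_rejected(self, yule10):
        tree, states = yule10
        with pytest.raises(ValueError, match="rho"):
            MusseModel(tree, states, rho=[0.0])

    def test_loglik_smooth_in_parameters(self):
        # central finite differences agree across step sizes (relative
        # 1e-4) on a 30-tip fixture: no integration-noise kinks
        tree, _, states, _ = simulate_surviving(
            2, [0.25, 0.25], 0.05, 0.05, seed=71, max_taxa=30,
            require_both_states=True)
        model = MusseModel(tree, states, state_names=[0, 1])

        def ll(lam0):
            return model.loglike(MusseParams([lam0, 0.2], [0.05, 0.05],
                                             [[0, 0.05], [0.05, 0]]))

        for x0 in (0.15, 0.3):
            g1 = (ll(x0 + 1e-4) - ll(x0 - 1e-4)) / 2e-4
            g2 = (ll(x0 + 1e-5) - ll(x0 - 1e-5)) / 2e-5
            assert g1 == pytest.approx(g2, rel=1e-4)

    def test_reported_loglik_reproducible_at_reported_params(self):
        tree, _, states, _ = simulate_surviving(
            2, [0.2, 0.2], 0.05, 0.03, seed=81, max_taxa=80,
            require_both_states=True)
        res = fit_musse(tree, states, constraints={"q": "equal"},
                        state_names=[0, 1])
        assert res.model.loglike(res.params) == pytest.approx(res.llf,
                                                              abs=1e-6)


class TestFitting:
    def test_deterministic_given_seed(self):
        tree, _, states, _ = simulate_surviving(
            2, [0.2, 0.2], 0.05, 0.03, seed=91, max_taxa=80,
            require_both_states=True)
        r1 = fit_musse(tree, states, constraints={"q": "equal"}, seed=4,
                       state_names=[0, 1])
        r2 = fit_musse(tree, states, constraints={"q": "equal"}, seed=4,
                       state_names=[0, 1])
        assert r1.llf == r2.llf
        np.testing.assert_array_equal(r1.params.lam, r2.params.lam)

    def test_wilks_property_on_state_independent_data(self):
        # constrained (lambda, mu equal across states) vs free fit:
        # 2*delta-lnL under chi2(2) 95% threshold in nearly all replicates
        crit = scipy.stats.chi2.ppf(0.95, df=2)
        ok = 0
        n_rep = 20
        seed = 500
        for rep in range(n_rep):
            tree, _, states, seed = simulate_surviving(
                2, [0.2, 0.2], 0.05, 0.03, seed=seed + 1, max_taxa=100,
                require_both_states=True)
            free = fit_musse(tree, states, constraints={"q": "equal"},
                             state_names=[0, 1])
            constrained = fit_musse(
                tree, states,
                constraints={"lambda": "equal", "mu": "equal",
                             "q": "equal"}, state_names=[0, 1])
            if 2 * (free.llf - constrained.llf) <= crit:
                ok += 1
        assert ok >= 16

    def test_misspecified_rho_biases_lambda_upward(self):
        seed = 100
        for rep in range(3):
            tree, _, states, seed = simulate_surviving(
                2, [0.2, 0.2], [0.05, 0.05], 0.02, seed=seed + 1,
                max_taxa=150, require_both_states=True)
            r_true = fit_musse(tree, states, rho=1.0,
                               constraints={"q": "equal"},
                               state_names=[0, 1])
            r_half = fit_musse(tree, states, rho=0.5,
                               constraints={"q": "equal"},
                               state_names=[0, 1])
            assert r_half.params.lam.mean() > r_true.params.lam.mean()

    def test_small_tree_warns(self):
        tree, _, states, _ = simulate_surviving(
            2, [0.3, 0.3], 0.0, 0.2, seed=2, max_taxa=8,
            require_both_states=True)
        with pytest.warns(UserWarning, match="tips"):
            fit_musse(tree, states, constraints={"q": "equal"},
                      state_names=[0, 1])

    def test_summary_reports_fit(self):
        tree, _, states, _ = simulate_surviving(
            2, [0.2, 0.2], 0.0, 0.05, seed=131, max_taxa=40,
            require_both_states=True)
        res = fit_musse(tree, states, constraints={"q": "equal"},
                        state_names=[0, 1])
        s = res.summary()
        assert "log-likelihood" in s and "lambda" in s


class TestNormalizationAndComparison:
    @staticmethod
    def rate_table():
        rows = []
        vals = {
            "c1": [(0.20, 0.05), (0.10, 0.02), (0.10, 0.03)],
            "c2": [(0.30, 0.08), (0.12, 0.05), (0.15, 0.04)],
            "c3": [(0.25, 0.06), (0.14, 0.03), (0.11, 0.05)],
            "c4": [(0.18, 0.04), (0.09, 0.02), (0.12, 0.03)],
            "c5": [(0.22, 0.07), (0.11, 0.04), (0.10, 0.02)],
        }
        for clade, triple in vals.items():
            for region, (lam, mu) in zip(["R1", "R2", "R3"], triple):
                rows.append({"clade": clade, "state": region,
                             "lambda": lam, "mu": mu, "fitted": True})
        return pd.DataFrame(rows)

    def test_normalization_arithmetic(self):
        df = pd.DataFrame({"clade": ["c"] * 3, "state": list("ABC"),
                           "lambda": [0.2, 0.1, 0.1],
                           "mu": [0.0, 0.0, 0.0]})
        out = normalize_rates(df, rate_cols=("lambda",))
        assert out["lambda_norm"].tolist() == pytest.approx(
            [0.5, 0.25, 0.25])

    def test_normalized_rows_sum_to_one_and_scale_invariance(self):
        df = self.rate_table()
        out = normalize_rates(df)
        sums = out.groupby("clade")["lambda_norm"].sum()
        assert np.allclose(sums, 1.0)
        scaled = df.copy()
        scaled.loc[scaled["clade"] == "c1", ["lambda", "mu"]] *= 7.0
        out2 = normalize_rates(scaled)
        pd.testing.assert_series_equal(out["lambda_norm"],
                                       out2["lambda_norm"])

    def test_zero_sum_clade_flagged_and_excluded(self):
        df = pd.DataFrame({"clade": ["z"] * 2 + ["c"] * 2,
                           "state": ["A", "B", "A", "B"],
                           "lambda": [0.0, 0.0, 0.1, 0.2],
                           "mu": [0.1, 0.1, 0.1, 0.1]})
        out = normalize_rates(df, rate_cols=("lambda",))
        assert out.loc[out["clade"] == "z", "excluded"].all()

    def test_identical_regions_give_f_zero(self):
        # identical per-region vectors (varying across clades): no
        # between-region variance, so F = 0 and p = 1.  Compared on the
        # raw values: normalizing two identical two-region vectors is
        # degenerate (every value becomes 1/2).
        df = pd.DataFrame({
            "clade": ["c1", "c1", "c2", "c2", "c3", "c3"],
            "state": ["A", "B"] * 3,
            "lambda": [0.2, 0.2, 0.4, 0.4, 0.3, 0.3],
            "mu": [0.1, 0.1, 0.2, 0.2, 0.15, 0.15]})
        comp = compare_regions(df)
        row = comp.anova[comp.anova["rate"] == "lambda"].iloc[0]
        assert row["F"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)

    def test_anova_matches_textbook_formula(self):
        comp = compare_regions(normalize_rates(self.rate_table()))
        df = normalize_rates(self.rate_table())
        for rate in ("lambda", "mu"):
            groups = [df.loc[df["state"] == r, f"{rate}_norm"].to_numpy()
                      for r in ("R1", "R2", "R3")]
            all_vals = np.concatenate(groups)
            grand = all_vals.mean()
            ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
            dfb = len(groups) - 1
            dfw = len(all_vals) - len(groups)
            f_oracle = (ssb / dfb) / (ssw / dfw)
            p_oracle = scipy.stats.f.sf(f_oracle, dfb, dfw)
            row = comp.anova[comp.anova["rate"] == rate].iloc[0]
            assert row["F"] == pytest.approx(f_oracle, abs=1e-10)
            assert row["p"] == pytest.approx(p_oracle, abs=1e-10)

    def test_tukey_at_least_as_conservative_as_pooled_t_tests(self):
        # the studentized-range adjustment can only inflate the pairwise
        # p-value computed from the same pooled within-group variance
        df = normalize_rates(self.rate_table())
        comp = compare_regions(df)
        for rate in ("lambda", "mu"):
            groups = [df.loc[df["state"] == r, f"{rate}_norm"].to_numpy()
                      for r in ("R1", "R2", "R3")]
            n_tot = sum(len(g) for g in groups)
            dfw = n_tot - len(groups)
            msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / dfw
            sub = comp.tukey[comp.tukey["rate"] == rate]
            names = ["R1", "R2", "R3"]
            for _, row in sub.iterrows():
                a = groups[names.index(row["group1"])]
                b = groups[names.index(row["group2"])]
                se = np.sqrt(msw * (1 / len(a) + 1 / len(b)))
                t = abs(a.mean() - b.mean()) / se
                p_pooled = 2 * scipy.stats.t.sf(t, dfw)
                assert row["p_adj"] >= p_pooled - 1e-9

    def test_too_few_regions_or_clades_rejected(self):
        df = pd.DataFrame({"clade": ["c1", "c2"], "state": ["A", "A"],
                           "lambda": [0.1, 0.2], "mu": [0.1, 0.1]})
        with pytest.raises(ValueError, match="regions"):
            compare_regions(normalize_rates(df))
        df2 = pd.DataFrame({"clade": ["c1", "c1"], "state": ["A", "B"],
                            "lambda": [0.1, 0.2], "mu": [0.1, 0.1]})
        with pytest.raises(ValueError, match="clades"):
            compare_regions(normalize_rates(df2))
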