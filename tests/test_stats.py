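"""Model ladder, Type III ANOVA, contrasts, and permutation fallback."""

import numpy as np
import pandas as pd
import pytest

from courtmetrics.errors import ContractError
from courtmetrics.stats import (
    anova_type3,
    bonferroni,
    cell_row,
    fit_ladder,
    fit_optimal,
    pairwise_contrasts,
    partial_eta_squared,
    permutation_contrast,
)
from courtmetrics.synthetic import cell_means_from_coefs, generate_entropy_table


def _flat_means(mu=3.0, conditions=None, roles=("O1", "O2", "O3")):
    conditions = conditions or ("low_before_tips", "low_after_tips",
                                "high_expertise", "random_walk")
    return {(c, r): mu for c in conditions for r in roles}


class TestLadder:
    def test_identical_tables_identical_aics(self):
        tab = generate_entropy_table(seed=12)
        a = fit_ladder(tab, "H_bits", "role").table
        b = fit_ladder(tab, "H_bits", "role").table
        pd.testing.assert_frame_equal(a, b)

    def test_first_comparison_flagged_non_nested(self):
        tab = generate_entropy_table(seed=12)
        comp = fit_ladder(tab, "H_bits", "role").table
        assert bool(comp.loc[comp.model == "rand_sess", "non_nested"].iloc[0])
        assert comp.loc[comp.model == "rand_sess", "chi2"].iloc[0] >= 0.0

    def test_interaction_data_selects_interactive(self):
        """Strong condition x role structure: interactive model wins by AIC."""
        wins = 0
        for seed in range(40):
            tab = generate_entropy_table(seed=1000 + seed)
            wins += fit_ladder(tab, "H_bits", "role").selected == "interactive"
        assert wins >= 36

    def test_null_role_data_prefers_session_trial_random(self):
        """No role effects, no interaction: the leaner random structure is the
        modal AIC choice.

        Under the null, AIC still picks `basic` whenever the spurious one-df
        likelihood gain exceeds the penalty of 2 (P(chi2_1 > 2) ~ 0.157) and
        `interactive` when the eight-df gain exceeds 16 (P ~ 0.04), so the
        expected selection rate for `rand_sess` is ~0.81; we assert at three
        binomial SEs below that.
        """
        counts = {}
        for seed in range(40):
            tab = generate_entropy_table(
                cell_means={k: 3.0 + (0.6 if k[0] == "random_walk" else 0.0)
                            for k in _flat_means()},
                seed=2000 + seed,
            )
            sel = fit_ladder(tab, "H_bits", "role").selected
            counts[sel] = counts.get(sel, 0) + 1
        assert max(counts, key=counts.get) == "rand_sess"
        assert counts["rand_sess"] >= 25  # 0.81 - 3 * sqrt(0.81*0.19/40) ~ 0.62

    def test_single_condition_rejected(self):
        tab = generate_entropy_table(seed=1)
        with pytest.raises(ContractError):
            fit_ladder(tab[tab.condition == "random_walk"], "H_bits", "role")


class TestOptimalFit:
    def test_zero_variance_recovers_cell_mean_differences_exactly(self):
        tab = generate_entropy_table(var_session=0, var_trial=0, var_resid=0, seed=2)
        fit = fit_optimal(tab, "H_bits", "role")
        mus = cell_means_from_coefs()
        fe = fit.fixed_effects().set_index("term")
        assert fe.loc["(Intercept)", "estimate"] == pytest.approx(
            mus[("low_before_tips", "O1")], abs=1e-6
        )
        assert fe.loc["condition[random_walk]", "estimate"] == pytest.approx(
            mus[("random_walk", "O1")] - mus[("low_before_tips", "O1")], abs=1e-6
        )

    def test_baselines_absent_from_table(self):
        tab = generate_entropy_table(seed=2)
        fe = fit_optimal(tab, "H_bits", "role").fixed_effects()
        assert not fe["term"].str.contains("low_before_tips").any()
        assert not fe["term"].str.contains(r"role\[O1\]").any()

    def test_random_effect_variances_nonnegative(self):
        fit = fit_optimal(generate_entropy_table(seed=2), "H_bits", "role")
        assert all(v >= 0 for v in fit.random_effects().values())

    def test_invalid_baseline_rejected(self):
        tab = generate_entropy_table(seed=2)
        with pytest.raises(ContractError):
            fit_optimal(tab, "H_bits", "role", cond_base="nonexistent")


class TestAnova3:
    def test_single_condition_contract_error(self):
        tab = generate_entropy_table(seed=3)
        with pytest.raises(ContractError):
            anova_type3(tab[tab.condition == "random_walk"], "H_bits", "role")

    def test_effects_detected_on_structured_data(self):
        an = anova_type3(generate_entropy_table(seed=3), "H_bits", "role")
        an = an.set_index("effect")
        assert an.loc["condition", "p"] < 1e-6
        assert an.loc["interaction", "p"] < 0.05
        assert ((an["partial_eta2"] >= 0) & (an["partial_eta2"] <= 1)).all()

    def test_partial_eta_squared_closed_form(self):
        assert partial_eta_squared(90.195, 3, 220) == pytest.approx(0.55, abs=0.005)
        assert partial_eta_squared(1.378, 8, 280) == pytest.approx(0.04, abs=0.005)


class TestBonferroni:
    def test_known_adjustment(self):
        assert bonferroni(0.0027, 6) == pytest.approx(0.016, abs=5e-4)

    def test_cap_at_one(self):
        assert bonferroni(0.5, 6) == 1.0
        assert np.all(bonferroni([0.2, 0.001], 6) == [1.0, 0.006])


class TestPairwiseContrasts:
    def test_estimates_equal_cell_prediction_differences(self):
        tab = generate_entropy_table(seed=4)
        fit = fit_optimal(tab, "H_bits", "role")
        contr = pairwise_contrasts(fit)
        for _, row in contr.iterrows():
            a, b = row["comparison"].split(" vs ")
            want = float(
                (cell_row(fit.info, a, row["role"]) - cell_row(fit.info, b, row["role"]))
                @ fit.result.beta
            )
            assert row["estimate"] == pytest.approx(want, abs=1e-10)

    def test_family_size_six_for_four_conditions(self):
        tab = generate_entropy_table(seed=4)
        contr = pairwise_contrasts(fit_optimal(tab, "H_bits", "role"))
        assert len(contr) == 18  # 3 roles x C(4,2)
        assert np.all(contr["p_adj"] <= 1.0)
        assert np.allclose(contr["p_adj"], np.minimum(1.0, contr["p_raw"] * 6))

    def test_identical_conditions_give_null_contrast(self):
        """Two conditions with identical generating means: their contrast is
        near zero and the Bonferroni-adjusted p saturates near 1."""
        mus = cell_means_from_coefs()
        for role in ("O1", "O2", "O3"):  # make low_after a clone of low_before
            mus[("low_after_tips", role)] = mus[("low_before_tips", role)]
        tab = generate_entropy_table(cell_means=mus, seed=5)
        contr = pairwise_contrasts(fit_optimal(tab, "H_bits", "role"))
        same = contr[contr["comparison"] == "low_before_tips vs low_after_tips"]
        assert np.abs(same["estimate"]).max() < 0.6
        # raw p is uniform under the null, so the x6 adjustment saturates at 1
        # for the typical contrast
        assert same["p_adj"].median() == 1.0

    def test_non_interactive_model_warns_and_returns_marginal(self):
        tab = generate_entropy_table(seed=4)
        fit = fit_optimal(tab, "H_bits", "role", model="basic")
        with pytest.warns(UserWarning, match="marginal"):
            contr = pairwise_contrasts(fit)
        assert set(contr["role"]) == {"(marginal)"}

    def test_dominant_random_walk_detected(self):
        tab = generate_entropy_table(seed=6)
        contr = pairwise_contrasts(fit_optimal(tab, "H_bits", "role"))
        rw = contr[contr["comparison"].str.contains("random_walk")]
        assert (rw["p_adj"] < 0.001).all()
        assert (rw["estimate"] < 0).all()  # other condition minus random walk


class TestPermutation:
    def _toy(self, shift=0.0, n=3):
        rows = []
        rng = np.random.default_rng(0)
        for cond, delta in (("high_expertise", shift), ("low_before_tips", 0.0)):
            for s in (1, 2):
                for t in range(1, n + 1):
                    rows.append({"condition": cond, "session": s, "trial": t,
                                 "role": "O3",
                                 "H_bits": delta + rng.normal(3.0, 0.3)})
        return pd.DataFrame(rows)

    def test_identical_groups_p_near_one(self):
        tab = self._toy(shift=0.0)
        tab.loc[tab.condition == "high_expertise", "H_bits"] = \
            tab.loc[tab.condition == "low_before_tips", "H_bits"].to_numpy()
        out = permutation_contrast(tab, "H_bits", "high_expertise",
                                   "low_before_tips", unit_level="O3")
        assert out["p"] == 1.0

    def test_exhaustive_matches_monte_carlo(self):
        tab = self._toy(shift=0.8)
        ex = permutation_contrast(tab, "H_bits", "high_expertise", "low_before_tips",
                                  unit_level="O3")
        assert ex["method"] == "exhaustive"
        mc = permutation_contrast(tab, "H_bits", "high_expertise", "low_before_tips",
                                  unit_level="O3", exhaustive_limit=1, n_perm=4000,
                                  seed=2)
        se = np.sqrt(ex["p"] * (1 - ex["p"]) / 4000)
        assert mc["p"] == pytest.approx(ex["p"], abs=max(4 * se, 0.01))

    def test_fixed_seed_reproducible(self):
        tab = self._toy(shift=0.4)
        a = permutation_contrast(tab, "H_bits", "high_expertise", "low_before_tips",
                                 exhaustive_limit=1, n_perm=500, seed=9)
        b = permutation_contrast(tab, "H_bits", "high_expertise", "low_before_tips",
                                 exhaustive_limit=1, n_perm=500, seed=9)
        assert a == b

    def test_too_few_trials_rejected(self):
        tab = self._toy().iloc[:7]
        with pytest.raises(ContractError):
            permutation_contrast(tab, "H_bits", "high_expertise", "low_before_tips")

    def test_low_n_perm_warns(self):
        tab = self._toy(shift=0.4)
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_contrast(tab, "H_bits", "high_expertise", "low_before_tips",
                                 exhaustive_limit=1, n_perm=50, seed=1)


class TestFamilywiseError:
    def test_bonferroni_contrasts_control_type_one_error(self):
        """On null data (no condition differences) the per-family error rate
        of Bonferroni-adjusted pairwise contrasts stays at or below alpha."""
        alpha = 0.05
        families = 0
        false_hits = 0
        for seed in range(60):
            tab = generate_entropy_table(
                cell_means={k: 3.0 + (0.4 if k[1] == "O3" else 0.0)
                            for k in _flat_means()},
                seed=3000 + seed,
            )
            contr = pairwise_contrasts(fit_optimal(tab, "H_bits", "role"))
            for _, fam in contr.groupby("role"):
                families += 1
                false_hits += int((fam["p_adj"] < alpha).any())
        rate = false_hits / families
        # 180 families; allow 2.5 binomial SEs above nominal
        assert rate <= alpha + 2.5 * np.sqrt(alpha * (1 - alpha) / families)
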