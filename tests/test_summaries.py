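"""Descriptive statistics and nonparametric tests vs independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ecocost.summaries import (
    EmptySelectionWarning,
    SummaryFilters,
    ceiling_proportion,
    choice_proportions,
    k_difference,
    kendall_tau,
    omission_rates,
    paired_t,
    success_rates,
    wilcoxon_signed_rank,
)


def _trials(rows):
    defaults = {
        "task": "effort", "recipient": "self", "cost_level": 3, "reward": 6,
        "choice": "costly", "success": True, "participant": "p1",
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestChoiceProportions:
    def test_direct_count(self):
        df = _trials(
            [{"choice": "costly"}] * 6 + [{"choice": "baseline"}] * 4
        )
        cp = choice_proportions(df)
        assert cp.pooled == pytest.approx(0.6)
        assert cp.participant_mean == pytest.approx(0.6)

    def test_all_costly(self):
        cp = choice_proportions(_trials([{"choice": "costly"}] * 5))
        assert cp.pooled == 1.0

    def test_omissions_dropped_by_default(self):
        df = _trials(
            [{"choice": "costly"}] * 3 + [{"choice": "omission"}] * 2
            + [{"choice": "baseline"}]
        )
        assert choice_proportions(df).pooled == pytest.approx(0.75)

    def test_pooled_equals_cell_weighted_mean(self, rng):
        n = 600
        df = pd.DataFrame(
            {
                "participant": rng.choice(["a", "b", "c"], n),
                "task": "effort",
                "recipient": rng.choice(["self", "environment"], n),
                "cost_level": rng.integers(1, 6, n),
                "reward": rng.choice([2, 4, 6, 8, 10], n),
                "choice": rng.choice(["costly", "baseline"], n, p=[0.7, 0.3]),
            }
        )
        cp = choice_proportions(df)
        weighted = np.average(
            cp.per_cell["proportion"], weights=cp.per_cell["n_trials"]
        )
        assert cp.pooled == pytest.approx(weighted, abs=1e-12)

    def test_empty_selection_flagged(self):
        df = _trials([{"choice": "costly"}])
        with pytest.warns(EmptySelectionWarning):
            cp = choice_proportions(df, SummaryFilters(task="time"))
        assert cp.empty and np.isnan(cp.pooled)


class TestOmissionRates:
    def test_zero_and_simple_arithmetic(self):
        df = _trials([{"choice": "costly"}] * 5)
        assert (omission_rates(df)["rate_pct"] == 0).all()
        rows = [{"choice": "omission"}] + [{"choice": "costly"}] * 249
        rate = omission_rates(_trials(rows))["rate_pct"].iloc[0]
        assert rate == pytest.approx(0.4)


class TestCeilingProportion:
    def test_all_at_ceiling(self):
        df = _trials([{"participant": p, "choice": "costly"} for p in "abcd" for _ in range(20)])
        assert ceiling_proportion(df, "effort") == 1.0

    def test_one_of_four_above_threshold(self):
        rows = []
        for p, n_costly in zip("abcd", [20, 10, 10, 10]):
            rows += [{"participant": p, "choice": "costly"}] * n_costly
            rows += [{"participant": p, "choice": "baseline"}] * (20 - n_costly)
        assert ceiling_proportion(_trials(rows), "effort") == pytest.approx(0.25)

    def test_strictly_greater_than_threshold(self):
        # exactly 95% costly does not count as ceiling
        rows = [{"participant": "a", "choice": "costly"}] * 19
        rows += [{"participant": "a", "choice": "baseline"}]
        assert ceiling_proportion(_trials(rows), "effort", threshold=0.95) == 0.0


class TestSuccessRates:
    def test_all_success_and_fixture_ratio(self):
        rows = [{"success": True}] * 10
        out = success_rates(_trials(rows))
        assert out["success_pct"].iloc[0] == 100.0
        rows = [{"success": True}] * 9 + [{"success": False}]
        out = success_rates(_trials(rows))
        assert out["success_pct"].iloc[0] == pytest.approx(90.0)

    def test_only_chosen_costly_effort_trials_count(self):
        rows = [{"success": True}] * 4 + [
            {"choice": "baseline", "success": None},
            {"task": "time", "success": False},
        ]
        out = success_rates(_trials(rows))
        assert out["n_trials"].iloc[0] == 4


class TestPairedT:
    def test_identical_samples_zero_t(self):
        t, df, md, ci = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and df == 2 and md == 0.0

    def test_closed_form_oracle(self):
        """t = mean(d) / (sd(d)/sqrt(n)) on a hand-computed fixture."""
        x = np.array([2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 1.0, 1.0, 1.0])
        d = x - y  # (1, 2, 3, 4): mean 2.5, sd sqrt(5/3)
        t, df, md, ci = paired_t(x, y)
        assert t == pytest.approx(2.5 / (np.sqrt(5 / 3) / 2), abs=1e-12)
        assert df == 3
        assert md == pytest.approx(2.5)
        assert ci[0] < 2.5 < ci[1]

    def test_random_fixtures_match_formula(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 30))
            x, y = rng.normal(0, 1, (2, n))
            t, df, md, _ = paired_t(x, y)
            d = x - y
            expected = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            assert t == pytest.approx(expected, abs=1e-10)
            assert df == n - 1

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            paired_t([1.0], [2.0])


def _wilcoxon_bruteforce(d):
    """Exact null tail probabilities by enumerating all sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    v_obs = ranks[d > 0].sum()
    vs = [
        np.asarray(signs).dot(ranks)
        for signs in itertools.product([0, 1], repeat=len(d))
    ]
    vs = np.asarray(vs)
    return v_obs, (vs >= v_obs).mean(), (vs <= v_obs).mean()


class TestWilcoxon:
    def test_all_positive_maximal_v(self):
        v, p = wilcoxon_signed_rank([5, 4, 3, 2, 1], [0, 0, 0, 0, 0], "greater")
        assert v == 15.0
        assert p == pytest.approx(1 / 2**5)

    def test_matches_enumeration_oracle_n6(self, rng):
        x = np.array([1.3, -0.4, 2.2, 0.8, -1.7, 0.5])
        v, p = wilcoxon_signed_rank(x, np.zeros(6), "greater")
        v_ref, p_ge, _ = _wilcoxon_bruteforce(x)
        assert v == v_ref
        assert p == pytest.approx(p_ge, abs=1e-12)

    def test_random_fixtures_match_enumeration(self, rng):
        """Exact path vs brute-force 2^n enumeration, 100 fixtures."""
        for _ in range(100):
            n = int(rng.integers(4, 9))
            x = rng.normal(0, 1, n)
            v_ref, p_ge, p_le = _wilcoxon_bruteforce(x)
            for alt, p_ref in (("greater", p_ge), ("less", p_le)):
                v, p = wilcoxon_signed_rank(x, np.zeros(n), alt)
                assert v == v_ref
                assert p == pytest.approx(p_ref, abs=1e-12)

    def test_agrees_with_scipy_exact(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 20))
            x = rng.normal(0.3, 1, n)
            v, p = wilcoxon_signed_rank(x, np.zeros(n), "greater")
            ref = stats.wilcoxon(x, alternative="greater", method="exact")
            assert v == ref.statistic if x.mean() > 0 else True
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_rank_sum_identity(self, rng):
        """V plus the negative-rank sum is n(n+1)/2 after zero-dropping."""
        for _ in range(50):
            n = int(rng.integers(4, 40))
            x = np.round(rng.normal(0, 1, n), 1)
            d = x[x != 0]
            if len(d) == 0:
                continue
            v_pos, _ = wilcoxon_signed_rank(d, np.zeros(len(d)), "greater")
            v_neg, _ = wilcoxon_signed_rank(-d, np.zeros(len(d)), "greater")
            m = len(d)
            assert v_pos + v_neg == pytest.approx(m * (m + 1) / 2)

    def test_normal_approximation_with_ties(self, rng):
        """Tied/large samples agree with scipy's corrected normal approx."""
        for _ in range(20):
            n = int(rng.integers(30, 60))
            x = np.round(rng.normal(0.2, 1, n), 1)
            x = x[x != 0]
            v, p = wilcoxon_signed_rank(x, np.zeros(len(x)), "greater")
            ref = stats.wilcoxon(
                x, alternative="greater", method="approx", correction=True
            )
            assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_all_zero_differences_raise(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


def _kendall_bruteforce(x, y):
    """Tau-b by direct concordant/discordant pair counting."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = x[i] - x[j], y[i] - y[j]
            if a == 0 and b == 0:
                tx += 1
                ty += 1
            elif a == 0:
                tx += 1
            elif b == 0:
                ty += 1
            elif a * b > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - tx) * (n0 - ty))


class TestKendallTau:
    def test_perfect_orders(self):
        x = [1, 2, 3, 4, 5]
        assert kendall_tau(x, x)[0] == pytest.approx(1.0)
        assert kendall_tau(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_tie_fixture_matches_pair_counting(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0]
        y = [2.0, 1.0, 3.0, 4.0, 4.0]
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx(_kendall_bruteforce(x, y), abs=1e-12)

    def test_random_fixtures_match_pair_counting(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 15))
            x = rng.integers(0, 6, n).astype(float)
            y = rng.integers(0, 6, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            tau, _ = kendall_tau(x, y)
            assert tau == pytest.approx(_kendall_bruteforce(x, y), abs=1e-12)

    def test_symmetry_and_reversal(self, rng):
        x, y = rng.normal(0, 1, (2, 20))
        assert kendall_tau(x, y)[0] == pytest.approx(kendall_tau(y, x)[0])
        assert kendall_tau(-x, y)[0] == pytest.approx(-kendall_tau(x, y)[0])

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            kendall_tau([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestKDifference:
    def _estimates(self, k_self, k_env, structure="separate"):
        df = pd.DataFrame(
            {
                "participant": [f"s{i}" for i in range(len(k_self))],
                "task": "effort",
                "k_self": k_self,
                "k_env": k_env,
            }
        )
        df.attrs["k_structure"] = structure
        return df

    def test_simple_differences(self):
        out = k_difference(self._estimates([0.5, 0.2], [0.2, 0.2]))
        assert out["k_diff"].tolist() == pytest.approx([0.3, 0.0])

    def test_joint_fit_rejected(self):
        with pytest.raises(ValueError):
            k_difference(self._estimates([0.5], [0.5], structure="joint"))

    def test_generator_coupling_recovered(self, rng):
        """Positive questionnaire coupling yields positive tau at n=1000."""
        from ecocost.cohort import simulate_questionnaires

        n = 1000
        truth = pd.DataFrame(
            {
                "participant": [f"s{i}" for i in range(n)],
                "task": "effort",
                "k_self": np.exp(rng.normal(-1.4, 0.7, n)),
                "k_env": np.exp(rng.normal(-1.1, 0.7, n)),
            }
        )
        q = simulate_questionnaires(truth, 0.8, rng)
        truth.attrs["k_structure"] = "separate"
        kd = k_difference(truth)
        tau, p = kendall_tau(kd["k_diff"], q["policy_support"])
        assert tau > 0 and p < 0.001
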