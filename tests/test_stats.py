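"""ANOVA, Tukey pairwise tests, compact letter displays, depth GLMs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cichlidhab.stats import (
    PairwiseResult,
    compact_letters,
    fit_depth_glms,
    letters_consistent,
    one_way_anova,
    species_letter_analysis,
    tukey_pairwise,
)


class TestAnova:
    def test_textbook_arithmetic(self):
        groups = {"a": [1, 2, 3], "b": [2, 3, 4], "c": [10, 11, 12]}
        res = one_way_anova(groups)
        # independent hand arithmetic: SSB = 3*sum((group mean - grand)^2),
        # SSW = sum squared deviations within = 2 per group
        grand = np.mean([1, 2, 3, 2, 3, 4, 10, 11, 12])
        ssb = 3 * sum((np.mean(v) - grand) ** 2 for v in groups.values())
        ssw = sum(np.sum((np.array(v) - np.mean(v)) ** 2) for v in groups.values())
        f_hand = (ssb / 2) / (ssw / 6)
        assert res["F"] == pytest.approx(f_hand)
        assert res["df_between"] == 2 and res["df_within"] == 6
        assert res["p"] < 0.01

    def test_identical_groups_f_zero(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res["F"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_shift_and_scale_invariance_of_f(self):
        rng = np.random.default_rng(4)
        groups = {k: rng.normal(i, 1, 12) for i, k in enumerate("abc")}
        f0 = one_way_anova(groups)["F"]
        shifted = {k: v + 100.0 for k, v in groups.items()}
        scaled = {k: v * 3.5 for k, v in groups.items()}
        assert one_way_anova(shifted)["F"] == pytest.approx(f0)
        assert one_way_anova(scaled)["F"] == pytest.approx(f0)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError, match="two groups"):
            one_way_anova({"a": [1, 2, 3]})
        with pytest.raises(ValueError, match="fewer than 2"):
            one_way_anova({"a": [1.0], "b": [1, 2]})
        with pytest.raises(ValueError, match="variance"):
            one_way_anova({"a": [1.0, 1.0], "b": [1.0, 1.0]})

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            groups = {k: rng.normal(0, 1, 10) for k in "abc"}
            hits += one_way_anova(groups)["p"] < 0.05
        assert 0.03 <= hits / n_rep <= 0.07


class TestTukey:
    def test_separated_groups_all_significant(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(8 * i, 1, 15) for i, k in enumerate("abc")}
        res = tukey_pairwise(groups)
        assert len(res) == 3
        assert all(r.significant for r in res)

    def test_identical_groups_none_significant(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 20)
        res = tukey_pairwise({"a": base, "b": base + 0.001, "c": base - 0.001})
        assert not any(r.significant for r in res)

    def test_invariant_to_group_ordering(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(i, 1, 10) for i, k in enumerate("abc")}
        res1 = {frozenset(r.pair): r.p_adjusted for r in tukey_pairwise(groups)}
        reordered = {k: groups[k] for k in reversed(list(groups))}
        res2 = {frozenset(r.pair): r.p_adjusted for r in tukey_pairwise(reordered)}
        for key in res1:
            assert res1[key] == pytest.approx(res2[key], rel=1e-9)

    def test_familywise_type_i_error_controlled(self):
        """Familywise rejection rate of the Tukey decision stays at ~alpha.

        For a balanced one-way layout, 'some pair significant' is exactly
        'max studentized range > critical value'.  That equivalence is
        asserted against tukey_pairwise on a first batch of replicates;
        the equivalent fast rule is then simulated at 2000 replicates so
        the Monte Carlo SE (~0.005) sits well inside the margin between
        the nominal 0.05 rate and the 0.06 bound.
        """
        from scipy.stats import studentized_range

        rng = np.random.default_rng(7)
        k, n = 4, 10
        q_crit = studentized_range.ppf(0.95, k, k * (n - 1))

        def q_max(groups):
            means = np.array([v.mean() for v in groups.values()])
            mse = np.mean([v.var(ddof=1) for v in groups.values()])
            return (means.max() - means.min()) / np.sqrt(mse / n)

        for _ in range(20):
            groups = {c: rng.normal(0, 1, n) for c in "abcd"}
            by_pairs = any(r.significant for r in tukey_pairwise(groups))
            assert by_pairs == (q_max(groups) > q_crit)

        n_rep = 2000
        any_sig = sum(
            q_max({c: rng.normal(0, 1, n) for c in "abcd"}) > q_crit
            for _ in range(n_rep)
        )
        assert any_sig / n_rep <= 0.06


def _pairwise_from_pattern(labels, sig_pairs):
    out = []
    for a, b in itertools.combinations(labels, 2):
        out.append(PairwiseResult((a, b), 0.0, 0.01 if {a, b} in sig_pairs else 0.5,
                                  {a, b} in sig_pairs))
    return out


class TestCompactLetters:
    def test_all_pairs_significant_distinct_letters(self):
        labels = ["A", "B", "C"]
        sig = [{"A", "B"}, {"A", "C"}, {"B", "C"}]
        letters = compact_letters(_pairwise_from_pattern(labels, sig))
        assert sorted(letters.values()) == ["a", "b", "c"]

    def test_no_pairs_significant_single_letter(self):
        letters = compact_letters(_pairwise_from_pattern(["A", "B", "C"], []))
        assert set(letters.values()) == {"a"}

    def test_chain_pattern_intermediate_shares_both(self):
        # only A-C significant: A 'a', B 'ab', C 'b'
        letters = compact_letters(
            _pairwise_from_pattern(["A", "B", "C"], [{"A", "C"}]),
            means={"A": 1.0, "B": 2.0, "C": 3.0},
        )
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    def test_letters_ordered_by_group_means(self):
        sig = [{"A", "B"}, {"A", "C"}, {"B", "C"}]
        letters = compact_letters(
            _pairwise_from_pattern(["A", "B", "C"], sig),
            means={"A": 9.0, "B": 1.0, "C": 5.0},
        )
        assert letters["B"] == "a" and letters["C"] == "b" and letters["A"] == "c"

    def test_incomplete_pair_cover_errors(self):
        pw = _pairwise_from_pattern(["A", "B", "C"], [])[:2]
        with pytest.raises(ValueError, match="every unordered pair"):
            compact_letters(pw)

    def test_inconsistent_duplicate_pair_errors(self):
        pw = _pairwise_from_pattern(["A", "B"], [])
        pw.append(PairwiseResult(("B", "A"), 0.0, 0.01, True))
        with pytest.raises(ValueError, match="inconsistent"):
            compact_letters(pw)


class TestDepthGlms:
    @pytest.fixture
    def sorted_cells(self):
        rng = np.random.default_rng(5)
        n = 200
        depth = rng.uniform(2, 13, n)
        # gravel shallow, sand deep by construction; others everywhere
        sub = np.where(
            (depth < 5) & (rng.random(n) < 0.5),
            "gravel",
            np.where((depth > 10) & (rng.random(n) < 0.5), "sand",
                     rng.choice(["rock", "stone", "rubble"], n)),
        )
        return pd.DataFrame(
            {
                "row": np.arange(n) // 10,
                "col": np.arange(n) % 10,
                "mean_depth_m": depth,
                "inclination_deg": rng.uniform(0, 45, n),
                "substratum": sub,
            }
        )

    def test_sorted_substrata_detected(self, sorted_cells):
        res = fit_depth_glms(sorted_cells)
        means = res["substratum"]["class_means"]
        assert means["gravel"] < means["sand"]
        gs = [c for c in res["substratum"]["contrasts"]
              if set(c.pair) == {"gravel", "sand"}]
        assert gs and gs[0].significant

    def test_independent_inclination_null_uniform_p(self):
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            df = pd.DataFrame(
                {
                    "mean_depth_m": rng.uniform(2, 13, 80),
                    "inclination_deg": rng.uniform(0, 45, 80),
                }
            )
            hits += fit_depth_glms(df)["inclination"]["p"] < 0.05
        assert 0.01 <= hits / n_rep <= 0.11

    def test_constant_depth_contrasts_zero(self):
        df = pd.DataFrame(
            {
                "mean_depth_m": np.full(30, 5.0),
                "inclination_deg": np.linspace(0, 30, 30),
                "substratum": ["rock"] * 15 + ["sand"] * 15,
            }
        )
        res = fit_depth_glms(df)
        for c in res["substratum"]["contrasts"]:
            assert c.mean_difference == pytest.approx(0.0)
            assert not c.significant

    def test_single_class_skips_contrasts_with_notice(self):
        df = pd.DataFrame(
            {
                "mean_depth_m": np.linspace(2, 13, 20),
                "inclination_deg": np.linspace(0, 30, 20),
                "substratum": ["rock"] * 20,
            }
        )
        res = fit_depth_glms(df)
        assert "notice" in res["substratum"]


class TestSpeciesLetterAnalysis:
    def test_letters_match_pairwise_relation(self):
        rng = np.random.default_rng(21)
        obs = pd.DataFrame(
            {
                "species": np.repeat(["s1", "s2", "s3", "s4"], 25),
                "value": np.concatenate(
                    [rng.normal(m, 1.0, 25) for m in (3.0, 3.3, 7.0, 12.0)]
                ),
            }
        )
        res = species_letter_analysis(obs)
        assert letters_consistent(res["pairwise"], res["letters"])
        # clearly separated extremes never share a letter
        assert not set(res["letters"]["s1"]) & set(res["letters"]["s4"])
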