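"""Physiology formulas and group-comparison statistics."""

import numpy as np
import pytest

from saltscreen import (
    anova_oneway,
    compare_physio,
    generate_physio_series,
    rel,
    rwc,
    tukey_cld,
    two_sample_t,
)

from oracles import permutation_t_pvalue


class TestIndexFormulas:
    @pytest.mark.parametrize(
        "fw, tw, dw, expected",
        [(0.8, 1.0, 0.2, 75.0), (1.0, 1.0, 0.2, 100.0), (0.2, 1.0, 0.2, 0.0)],
    )
    def test_rwc(self, fw, tw, dw, expected):
        assert rwc(fw, tw, dw) == pytest.approx(expected)

    def test_rwc_guards(self):
        with pytest.raises(ValueError):
            rwc(0.5, 0.2, 0.2)

    def test_rwc_unit_invariance(self):
        assert rwc(0.8, 1.0, 0.2) == pytest.approx(rwc(800.0, 1000.0, 200.0))

    @pytest.mark.parametrize(
        "c1, c2, expected", [(20.0, 80.0, 25.0), (80.0, 80.0, 100.0), (0.0, 80.0, 0.0)]
    )
    def test_rel(self, c1, c2, expected):
        assert rel(c1, c2) == pytest.approx(expected)

    def test_rel_guards(self):
        with pytest.raises(ValueError):
            rel(10.0, 0.0)
        with pytest.raises(ValueError):
            rel(90.0, 80.0)


class TestAnovaAndT:
    def test_hand_anova(self):
        # SSB = 13.5, SSW = 4, df (1, 4) -> F = 13.5
        f, p = anova_oneway([np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])])
        assert f == pytest.approx(13.5)
        assert 0 < p < 1

    def test_constant_groups_convention(self):
        f, p = anova_oneway([np.array([2.0, 2.0]), np.array([2.0, 2.0])])
        assert (f, p) == (0.0, 1.0)

    def test_f_equals_t_squared_two_groups(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=6), rng.normal(1.0, 1.0, size=6)
        f, _ = anova_oneway([x, y])
        t, _ = two_sample_t(x, y, welch=False)
        assert f == pytest.approx(t**2)

    def test_t_identity_and_antisymmetry(self):
        x = np.array([1.0, 2.0, 3.0])
        t, p = two_sample_t(x, x.copy())
        assert t == 0.0 and p == pytest.approx(1.0)
        y = np.array([2.0, 4.0, 5.0])
        t_xy, p_xy = two_sample_t(x, y)
        t_yx, p_yx = two_sample_t(y, x)
        assert t_xy == pytest.approx(-t_yx)
        assert p_xy == pytest.approx(p_yx)

    def test_welch_p_against_permutation_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0.0, 1.0, size=12)
        y = rng.normal(1.0, 1.5, size=12)
        _, p_welch = two_sample_t(x, y, welch=True)
        p_perm = permutation_t_pvalue(x, y, n_perm=20_000, rng=rng)
        assert p_welch == pytest.approx(p_perm, abs=0.02)


class TestTukeyCld:
    def test_constant_groups_share_a(self):
        comp = tukey_cld({"g1": [2.0, 2.0, 2.0], "g2": [2.0, 2.0, 2.0]})
        assert comp.letters == {"g1": "a", "g2": "a"}

    def test_forced_separation(self):
        rng = np.random.default_rng(1)
        lo = rng.normal(0.0, 1.0, size=5)
        hi = rng.normal(100.0, 1.0, size=5)
        comp = tukey_cld({"low": lo, "high": hi})
        assert comp.letters["high"] == "a"  # letters start at the largest mean
        assert comp.letters["low"] == "b"

    def test_middle_group_shares_both_letters(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 1.0, size=10)
        b = rng.normal(3.0, 1.0, size=10)  # indistinguishable from both extremes? no:
        groups = {
            "low": a,
            "mid": a + 2.1,  # separated from neither extreme decisively
            "high": a + 4.2,
        }
        comp = tukey_cld(groups, alpha=0.05)
        # letters are consistent with pairwise decisions
        distinct = comp.pairwise_p < comp.alpha
        for g1 in groups:
            for g2 in groups:
                if g1 == g2:
                    continue
                share = bool(set(comp.letters[g1]) & set(comp.letters[g2]))
                assert share != bool(distinct.loc[g1, g2])

    def test_letters_invariant_to_input_order(self):
        rng = np.random.default_rng(3)
        groups = {f"g{i}": rng.normal(i, 1.0, size=6) for i in range(4)}
        comp1 = tukey_cld(groups)
        comp2 = tukey_cld(dict(reversed(list(groups.items()))))
        assert comp1.letters == comp2.letters

    def test_null_familywise_separation_rate(self):
        """Under the global null, any-separation happens ~ alpha of the time."""
        rng = np.random.default_rng(4)
        n_sims, hits = 400, 0
        for _ in range(n_sims):
            groups = [rng.normal(0.0, 1.0, size=5) for _ in range(3)]
            comp = tukey_cld(groups, alpha=0.05)
            hits += len(set(comp.letters.values())) > 1
        rate = hits / n_sims
        assert 0.02 <= rate <= 0.09  # 5% +/- Monte-Carlo slack at 400 reps


class TestComparePhysio:
    def test_series_cardinality_and_noise_off_trend(self):
        series = generate_physio_series(noise_sd=0.0, seed=0)
        assert len(series) == 336  # 7 vars x 2 genotypes x 2 treatments x 4 days x 3 reps
        mda = series[(series["variable"] == "MDA") & (series["treatment"] == "T")]
        st = mda[mda["genotype"] == "ST"].groupby("day")["value"].mean()
        ss = mda[mda["genotype"] == "SS"].groupby("day")["value"].mean()
        assert (st.diff().dropna() > 0).all()  # damage rises under salt
        assert (ss - st).loc[13] > 0  # faster in the sensitive genotype

    def test_zero_slope_means_flat_series(self):
        trends = {"MDA": (8.0, 0.0)}
        series = generate_physio_series(noise_sd=0.0, seed=0, trends=trends)
        mda = series[(series["variable"] == "MDA") & (series["treatment"] == "T")]
        by_day = mda.groupby("day")["value"].mean()
        assert by_day.loc[1] == pytest.approx(by_day.loc[13])

    def test_comparison_table_shape_and_letters(self):
        series = generate_physio_series(noise_sd=0.3, seed=5)
        table = compare_physio(series, alpha=0.05)
        # 7 variables x 4 days x 4 groups
        assert len(table) == 112
        assert (table["letters"].str.len() >= 1).all()
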