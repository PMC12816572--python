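"""Dual-reporter normalisation and ANOVA + Tukey HSD statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from utrvar.assay import (
    AssayError,
    anova_tukey,
    format_p,
    normalize,
    percent_change,
)
from utrvar.simulate import AssaySimConfig, simulate_assay


def make_table(signals: dict[str, float], gluc_base=1e6, seap_base=5e5) -> pd.DataFrame:
    rows = []
    for construct, mu in signals.items():
        for exp in (1, 2):
            for rep in (1, 2, 3):
                for dup in (1, 2):
                    rows.append(
                        {
                            "construct": construct,
                            "experiment": exp,
                            "replicate": rep,
                            "duplicate": dup,
                            "gluc": gluc_base * mu,
                            "seap": seap_base,
                        }
                    )
    return pd.DataFrame(rows)


class TestNormalize:
    def test_identical_wells_give_unit_activity(self):
        rel = normalize(make_table({"wildtype": 1.0, "v": 1.0}))
        assert np.allclose(rel["relative_activity"], 1.0)

    def test_halved_gluc_gives_half_activity(self):
        rel = normalize(make_table({"wildtype": 1.0, "v": 0.5}))
        assert np.allclose(
            rel.loc[rel.construct == "v", "relative_activity"], 0.5
        )

    def test_invariant_to_per_experiment_rescaling(self):
        """Multiplying every signal of one experiment by a constant (the
        transfection-efficiency model) changes nothing."""
        t = make_table({"wildtype": 1.0, "v": 0.4})
        t2 = t.copy()
        mask = t2.experiment == 2
        t2.loc[mask, ["gluc", "seap"]] *= 37.5
        pd.testing.assert_frame_equal(normalize(t), normalize(t2))

    def test_missing_wildtype_errors(self):
        with pytest.raises(AssayError, match="wildtype"):
            normalize(make_table({"a": 1.0, "b": 2.0}))

    def test_nonpositive_signal_rejected(self):
        t = make_table({"wildtype": 1.0})
        t.loc[0, "gluc"] = 0.0
        with pytest.raises(AssayError, match="positive"):
            normalize(t)

    def test_recovers_planted_means_from_noisy_simulation(self):
        config = AssaySimConfig(
            true_means={"wildtype": 1.0, "v": 0.25}, noise_sd=0.05, seed=3
        )
        rel = normalize(simulate_assay(config))
        est = rel.loc[rel.construct == "v", "relative_activity"].mean()
        assert est == pytest.approx(0.25, abs=3 * 0.05 / np.sqrt(12))

    def test_zero_noise_recovery_is_exact(self):
        config = AssaySimConfig(
            true_means={"wildtype": 1.0, "v": 0.3},
            noise_sd=0.0,
            seap_cv=0.0,
            efficiency_sigma=0.25,
            seed=0,
        )
        rel = normalize(simulate_assay(config))
        assert np.allclose(rel.loc[rel.construct == "v", "relative_activity"], 0.3)


def rel_frame(groups: dict[str, list[float]]) -> pd.DataFrame:
    rows = []
    for construct, values in groups.items():
        for i, v in enumerate(values):
            rows.append(
                {"construct": construct, "experiment": 1, "replicate": i, "relative_activity": v}
            )
    return pd.DataFrame(rows)


# Frozen from R: aov + TukeyHSD on these three groups (see comments)
R_GROUPS = {
    "a": [1.10, 1.20, 1.30, 1.15],
    "b": [2.00, 2.10, 1.90, 2.05],
    "c": [1.50, 1.60, 1.55, 1.45],
}
# R: diff(b-a)=0.8250 p=3.585e-07; diff(c-a)=0.3375 p=5.0727e-04;
#    diff(c-b)=-0.4875 p=2.94256e-05; ANOVA F=110.1, p=4.71e-07
R_EXPECTED = {
    ("b", "a"): (0.8250, 3.585e-07),
    ("c", "a"): (0.3375, 5.0727e-04),
    ("c", "b"): (-0.4875, 2.94256e-05),
}


class TestAnovaTukey:
    def test_matches_r_tukeyhsd(self):
        res = anova_tukey(rel_frame(R_GROUPS))
        assert res.f_statistic == pytest.approx(110.1, rel=1e-3)
        assert res.p_value == pytest.approx(4.71e-07, rel=1e-2)
        for (g1, g2), (diff, p) in R_EXPECTED.items():
            assert res.tukey.mean_difference(g1, g2) == pytest.approx(diff, abs=1e-9)
            # R's ptukey and scipy's studentized-range integral are two
            # independent tail approximations; agreement loosens below 1e-6
            tol = 0.05 if p < 1e-6 else 1e-3
            assert res.tukey.adjusted_p(g1, g2) == pytest.approx(p, rel=tol)

    def test_pair_at_tabulated_critical_q_has_p_05(self):
        """Groups built so one pair's studentized range statistic equals the
        tabulated 5% critical value q(3, 9) = 3.9485: its adjusted p must be
        exactly 0.05 (frozen against R's ptukey)."""
        m = 1.6119651915
        groups = {
            "a": [0.0, 0.0, 1.0, -1.0],
            "b": [m, m, m + 1, m - 1],
            "c": [m / 2, m / 2, m / 2 + 1, m / 2 - 1],
        }
        res = anova_tukey(rel_frame(groups))
        assert res.tukey.adjusted_p("b", "a") == pytest.approx(0.05, abs=1e-6)
        assert res.tukey.adjusted_p("c", "a") == pytest.approx(0.3828589769, rel=1e-6)

    def test_identical_groups_not_significant(self):
        groups = {"a": [1.0, 1.1, 0.9, 1.05], "b": [1.0, 1.1, 0.9, 1.05]}
        res = anova_tukey(rel_frame(groups))
        assert res.tukey.mean_difference("a", "b") == pytest.approx(0.0)
        assert not res.tukey.significant("a", "b")

    def test_sign_convention_is_a_minus_b(self):
        res = anova_tukey(rel_frame(R_GROUPS))
        assert res.tukey.mean_difference("a", "b") == pytest.approx(-0.8250)

    def test_adjusted_p_at_least_pooled_t_p(self):
        """Tukey adjustment can only raise the pairwise p-value."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            groups = {
                name: list(rng.normal(loc, 0.1, size=6))
                for name, loc in (("a", 1.0), ("b", 1.05), ("c", 0.9), ("d", 1.2))
            }
            res = anova_tukey(rel_frame(groups))
            arrs = {k: np.array(v) for k, v in groups.items()}
            n = 6
            df = sum(len(v) - 1 for v in arrs.values())
            mse = sum((len(v) - 1) * v.var(ddof=1) for v in arrs.values()) / df
            for g1, g2 in (("a", "b"), ("c", "d"), ("a", "d")):
                t = abs(arrs[g1].mean() - arrs[g2].mean()) / np.sqrt(mse * 2 / n)
                p_t = 2 * stats.t.sf(t, df)
                assert res.tukey.adjusted_p(g1, g2) >= p_t - 1e-12

    def test_degenerate_zero_variance_errors(self):
        groups = {"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]}
        with pytest.raises(AssayError, match="degenerate"):
            anova_tukey(rel_frame(groups))

    def test_needs_two_groups(self):
        with pytest.raises(AssayError):
            anova_tukey(rel_frame({"a": [1.0, 1.2]}))


class TestPercentChange:
    @pytest.mark.parametrize(
        "md, pct",
        [(0.8678, -86.78), (-1.31, 131.0), (0.0, 0.0), (0.4465, -44.65)],
    )
    def test_examples(self, md, pct):
        assert percent_change(md) == pytest.approx(pct)


class TestFormatP:
    def test_small_p_formatted_as_inequality(self):
        assert format_p(3e-7) == "<0.0001"
        assert format_p(0.0034) == "0.0034"
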