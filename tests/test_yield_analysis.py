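import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mockbench.datasets import load_yield_means
from mockbench.yield_analysis import (
    LetterDisplay,
    YieldTable,
    YieldTableError,
    compact_letter_display,
    log_transform_yields,
    splitplot_anova,
    tukey_hsd_per_sample,
    yield_summary,
)


def balanced_table(
    n_methods=3,
    n_samples=4,
    n_rep_per_block=2,
    method_effects=None,
    seed=0,
    residual_sd=0.2,
    block_sd=0.1,
):
    rng = np.random.default_rng(seed)
    method_effects = method_effects or {}
    blocks = {"E1": rng.normal(0, block_sd), "E2": rng.normal(0, block_sd)}
    records = []
    for m in range(n_methods):
        method = f"m{m + 1}"
        for s in range(n_samples):
            rep = 0
            for experimenter, b in blocks.items():
                for _ in range(n_rep_per_block):
                    rep += 1
                    log_y = (
                        1.0
                        + method_effects.get(method, 0.0)
                        + 0.1 * s
                        + b
                        + rng.normal(0, residual_sd)
                    )
                    records.append(
                        {
                            "method": method,
                            "sample": f"s{s + 1}",
                            "replicate": rep,
                            "experimenter": experimenter,
                            "day": "D1" if rep <= n_rep_per_block else "D2",
                            "concentration": float(np.exp(log_y)),
                        }
                    )
    return YieldTable(pd.DataFrame(records))


class TestLogTransform:
    def test_unit_maps_to_zero(self):
        t = balanced_table(seed=3)
        df = t.data.copy()
        df.loc[0, "concentration"] = 1.0
        logged = log_transform_yields(YieldTable(df))
        assert logged.data.loc[0, "concentration"] == 0.0
        assert logged.log_scale

    def test_e_maps_to_one(self):
        t = balanced_table(seed=3)
        df = t.data.copy()
        df.loc[1, "concentration"] = np.e
        logged = log_transform_yields(YieldTable(df))
        assert logged.data.loc[1, "concentration"] == pytest.approx(1.0)

    def test_round_trip(self):
        t = balanced_table(seed=4)
        logged = log_transform_yields(t)
        np.testing.assert_allclose(
            np.exp(logged.data["concentration"]),
            t.data["concentration"],
            rtol=1e-12,
        )

    def test_zero_concentration_named(self):
        t = balanced_table(seed=5)
        df = t.data.copy()
        df.loc[2, "concentration"] = 0.0
        with pytest.raises(YieldTableError, match="detection limit"):
            log_transform_yields(YieldTable(df))


class TestSplitPlotAnova:
    def test_df_bookkeeping(self):
        # 6 methods x 12 samples x 2 blocks x 4 reps per cell
        t = balanced_table(n_methods=6, n_samples=12, n_rep_per_block=4, seed=6)
        anova = splitplot_anova(t).set_index("source")
        assert anova.loc["method", "df"] == 5
        assert anova.loc["whole_plot_error", "df"] == 5
        assert anova.loc["sample", "df"] == 11
        assert anova.loc["method:sample", "df"] == 55
        n_total = len(t.data)
        assert anova["df"].sum() == n_total - 1

    def test_ss_decomposition(self):
        t = balanced_table(n_methods=4, n_samples=3, seed=7)
        logged = log_transform_yields(t)
        anova = splitplot_anova(logged)
        y = logged.data["concentration"].to_numpy()
        ss_total = ((y - y.mean()) ** 2).sum()
        assert (anova["sum_sq"] >= 0).all()
        assert anova["sum_sq"].sum() == pytest.approx(ss_total, abs=1e-8)

    def test_error_strata(self):
        t = balanced_table(seed=8)
        anova = splitplot_anova(t).set_index("source")
        assert anova.loc["method", "error_stratum"] == "whole_plot_error"
        assert anova.loc["sample", "error_stratum"] == "residual"

    def test_power_large_method_effect(self):
        # 2x on the log scale: detected at p < 0.01 in at least 95% of sims
        hits = 0
        n_sims = 100
        for i in range(n_sims):
            t = balanced_table(
                n_methods=6,
                n_samples=4,
                method_effects={"m1": np.log(2) * 2},
                seed=9000 + i,
            )
            p = splitplot_anova(t).set_index("source").loc["method", "p"]
            hits += p < 0.01
        assert hits / n_sims >= 0.95

    def test_unbalanced_rejected(self):
        t = balanced_table(seed=10)
        df = t.data.iloc[:-1]
        with pytest.raises(YieldTableError, match="unbalanced"):
            splitplot_anova(YieldTable(df))


class TestTukeyHsd:
    def test_identical_data_not_significant(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(size=6)
        records = [
            {
                "method": m,
                "sample": "s",
                "replicate": i,
                "experimenter": "E1",
                "day": "D1",
                "concentration": v,
            }
            for m in ("a", "b")
            for i, v in enumerate(vals)
        ]
        res = tukey_hsd_per_sample(YieldTable(pd.DataFrame(records)), "s")
        assert not res["significant"].loc["a", "b"]

    def test_k2_matches_t_test(self):
        # q(alpha, 2, df) = sqrt(2) * t(alpha/2, df), so the HSD decision for
        # two groups coincides with the two-sample t test
        rng = np.random.default_rng(1)
        alpha = 0.05
        for shift in (0.0, 0.5, 1.0, 2.0):
            a = rng.normal(0, 1, size=8)
            b = rng.normal(shift, 1, size=8)
            records = [
                {
                    "method": lbl,
                    "sample": "s",
                    "replicate": i,
                    "experimenter": "E1",
                    "day": "D1",
                    "concentration": float(np.exp(v)),
                }
                for lbl, vals in (("a", a), ("b", b))
                for i, v in enumerate(vals)
            ]
            res = tukey_hsd_per_sample(
                YieldTable(pd.DataFrame(records)), "s", alpha=alpha
            )
            t_p = stats.ttest_ind(a, b).pvalue
            assert res["significant"].loc["a", "b"] == (t_p < alpha)
            q = np.sqrt(2) * stats.t.ppf(1 - alpha / 2, 14)
            assert res["q_critical"] == pytest.approx(q, rel=1e-6)

    def test_two_clusters(self):
        rng = np.random.default_rng(2)
        records = []
        for m in range(6):
            center = 0.0 if m < 3 else 4.0
            for i in range(6):
                records.append(
                    {
                        "method": f"m{m + 1}",
                        "sample": "s",
                        "replicate": i,
                        "experimenter": "E1",
                        "day": "D1",
                        "concentration": float(np.exp(center + rng.normal(0, 0.2))),
                    }
                )
        res = tukey_hsd_per_sample(YieldTable(pd.DataFrame(records)), "s")
        sig = res["significant"]
        low = [f"m{i}" for i in (1, 2, 3)]
        high = [f"m{i}" for i in (4, 5, 6)]
        for a in low:
            for b in high:
                assert sig.loc[a, b]
        for grp in (low, high):
            for a in grp:
                for b in grp:
                    if a != b:
                        assert not sig.loc[a, b]

    def test_monotone_in_separation(self):
        # widening the gap never flips significant -> non-significant
        rng = np.random.default_rng(3)
        noise_a = rng.normal(0, 0.3, size=6)
        noise_b = rng.normal(0, 0.3, size=6)
        previous = False
        for shift in np.linspace(0, 3, 13):
            records = [
                {
                    "method": lbl,
                    "sample": "s",
                    "replicate": i,
                    "experimenter": "E1",
                    "day": "D1",
                    "concentration": float(np.exp(v)),
                }
                for lbl, vals in (("a", noise_a), ("b", noise_b + shift))
                for i, v in enumerate(vals)
            ]
            sig = tukey_hsd_per_sample(YieldTable(pd.DataFrame(records)), "s")[
                "significant"
            ].loc["a", "b"]
            assert sig or not previous
            previous = sig

    def test_single_replicate_rejected(self):
        records = [
            {
                "method": m,
                "sample": "s",
                "replicate": 1,
                "experimenter": "E1",
                "day": "D1",
                "concentration": 1.0 + i,
            }
            for i, m in enumerate(("a", "b"))
        ]
        with pytest.raises(YieldTableError, match="replicates"):
            tukey_hsd_per_sample(YieldTable(pd.DataFrame(records)), "s")


def sig_from_threshold(means: dict[str, float], threshold: float) -> pd.DataFrame:
    labels = list(means)
    sig = pd.DataFrame(False, index=labels, columns=labels)
    for a in labels:
        for b in labels:
            if a != b and abs(means[a] - means[b]) > threshold:
                sig.loc[a, b] = True
    return sig


class TestCompactLetterDisplay:
    def test_no_pair_significant(self):
        means = {"a": 3.0, "b": 2.0, "c": 1.0}
        cld = compact_letter_display(sig_from_threshold(means, 10.0), means)
        assert set(cld.letters.values()) == {"A"}

    def test_all_pairs_significant(self):
        means = {"a": 40.0, "b": 30.0, "c": 20.0, "d": 10.0}
        cld = compact_letter_display(sig_from_threshold(means, 5.0), means)
        assert cld.letters == {"a": "A", "b": "B", "c": "C", "d": "D"}

    def test_chain_pattern(self):
        # 1~2 and 2~3 not significant, but 1 vs 3 significant
        means = {"x1": 2.0, "x2": 1.0, "x3": 0.0}
        cld = compact_letter_display(sig_from_threshold(means, 1.5), means)
        assert cld.letters == {"x1": "A", "x2": "AB", "x3": "B"}

    def test_asymmetric_matrix_rejected(self):
        sig = pd.DataFrame(
            [[False, True], [False, False]], index=["a", "b"], columns=["a", "b"]
        )
        with pytest.raises(ValueError, match="symmetric"):
            compact_letter_display(sig, {"a": 1.0, "b": 2.0})

    @given(
        st.lists(
            st.floats(min_value=0, max_value=10, allow_nan=False),
            min_size=2,
            max_size=7,
            unique=True,
        ),
        st.floats(min_value=0.1, max_value=12),
    )
    @settings(max_examples=200, deadline=None)
    def test_iff_invariant_on_realizable_matrices(self, mean_vals, threshold):
        means = {f"g{i}": m for i, m in enumerate(mean_vals)}
        sig = sig_from_threshold(means, threshold)
        cld = compact_letter_display(sig, means)
        labels = list(means)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                assert cld.share_letter(a, b) == (not sig.loc[a, b])

    def test_share_letter(self):
        cld = LetterDisplay(
            letters={"a": "A", "b": "AB"},
            significant=pd.DataFrame(
                [[False, False], [False, False]],
                index=["a", "b"],
                columns=["a", "b"],
            ),
        )
        assert cld.share_letter("a", "b")


class TestYieldSummary:
    def test_published_fold_ratios(self):
        means = load_yield_means()
        summary = yield_summary(means)
        per = summary["per_sample"]
        assert per["Staphylococcus aureus ATCC 12600"]["fold_ratio_1dp"] == 5.7
        assert per["Propionibacterium acnes ATCC 6919"]["fold_ratio_1dp"] == 5.4
        assert (
            per["Corynebacterium tuberculostearicum ATCC 35692"]["fold_ratio_1dp"]
            == 3.3
        )
        assert per["Staphylococcus aureus ATCC 12600"]["top_method"] == "4"

    def test_published_lowest_counts(self):
        summary = yield_summary(load_yield_means())
        assert summary["lowest_mean_counts"]["3"] == 7
        assert sum(summary["lowest_mean_counts"].values()) == 12

    def test_equal_means_tie(self):
        means = pd.DataFrame({"a": [2.0], "b": [2.0]}, index=["s"])
        per = yield_summary(means)["per_sample"]["s"]
        assert per["fold_ratio"] == pytest.approx(1.0)
        assert set(per["top_ties"]) == {"a", "b"}

    def test_missing_cell_rejected(self):
        means = pd.DataFrame({"a": [2.0, 1.0], "b": [2.0, np.nan]}, index=["s", "t"])
        with pytest.raises(YieldTableError, match="missing"):
            yield_summary(means)

    def test_from_yield_table(self):
        t = balanced_table(seed=12)
        summary = yield_summary(t)
        assert set(summary["per_sample"]) == set(t.samples)
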