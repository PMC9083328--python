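"""Imputation, ANOVA/Tukey machinery and optimal-protocol selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from extractbench._tukey import studentized_range_sf
from extractbench.detectability import compute_detectability
from extractbench.model import ConfigError
from extractbench.protocol_stats import (
    ComparisonConfig,
    ImputationError,
    anova_tukey,
    compare_protocols,
    count_optimal_by_class,
    impute,
    log2_transform,
    optimal_protocols,
)

from conftest import build_table, make_panel


# ---------------------------------------------------------------------------
# imputation and transform


def test_impute_fills_zero_and_missing_with_fifth_of_min_positive():
    out = impute([0.0, 5.0, 10.0, np.nan])
    assert out.tolist() == [1.0, 5.0, 10.0, 1.0]


def test_impute_leaves_positive_vectors_alone():
    assert impute([3.0, 4.0, 5.0]).tolist() == [3.0, 4.0, 5.0]


def test_impute_requires_a_positive_entry():
    with pytest.raises(ImputationError):
        impute([0.0, np.nan, 0.0])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.one_of(
            st.just(0.0),
            st.just(float("nan")),
            st.floats(1e-6, 1e6, allow_nan=False),
        ),
        min_size=1,
        max_size=20,
    ).filter(lambda v: any(np.isfinite(x) and x > 0 for x in v))
)
def test_impute_properties(values):
    out = impute(values)
    pos = [v for v in values if np.isfinite(v) and v > 0]
    assert np.all(np.isfinite(out)) and np.all(out > 0)
    imputed_any = len(pos) < len(values)
    expected_min = 0.2 * min(pos) if imputed_any else min(pos)
    assert out.min() == pytest.approx(expected_min)
    assert out.min() <= min(pos)
    for orig, new in zip(values, out):
        if np.isfinite(orig) and orig > 0:
            assert new == orig


def test_log2_transform_powers_of_two():
    assert log2_transform([1.0, 2.0, 8.0]).tolist() == [0.0, 1.0, 3.0]
    assert log2_transform([1.0]).tolist() == [0.0]


def test_log2_transform_rejects_nonpositive():
    with pytest.raises(ValueError):
        log2_transform([1.0, 0.0])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(1e-6, 1e6, allow_nan=False), min_size=1, max_size=10))
def test_log2_round_trip(values):
    back = np.exp2(log2_transform(values))
    assert np.allclose(back, values, rtol=1e-12)


# ---------------------------------------------------------------------------
# ANOVA + Tukey


def _random_groups(rng, k, nmin=3, nmax=6, spread=1.0):
    return {
        f"P{i}": rng.normal(rng.uniform(-spread, spread), 1.0,
                            rng.integers(nmin, nmax + 1))
        for i in range(k)
    }


def test_identical_constant_groups_use_degenerate_convention():
    groups = {"A": [2.0, 2.0, 2.0], "B": [2.0, 2.0, 2.0]}
    with pytest.warns(UserWarning, match="identical"):
        p, padj = anova_tukey(groups)
    assert p == 1.0
    assert (padj.to_numpy() == 1.0).all()


def test_zero_variance_unequal_means_convention():
    groups = {"A": [1.0, 1.0], "B": [2.0, 2.0], "C": [1.0, 1.0]}
    with pytest.warns(UserWarning, match="zero within-group variance"):
        p, padj = anova_tukey(groups)
    assert p == 0.0
    assert padj.loc["A", "B"] == 0.0
    assert padj.loc["A", "C"] == 1.0


def test_group_with_single_value_is_rejected():
    with pytest.raises(ConfigError, match="fewer than 2"):
        anova_tukey({"A": [1.0], "B": [1.0, 2.0]})
    with pytest.raises(ConfigError, match="two protocol groups"):
        anova_tukey({"A": [1.0, 2.0]})


def test_anova_p_matches_scipy_f_oneway():
    rng = np.random.default_rng(5)
    for _ in range(10):
        groups = _random_groups(rng, int(rng.integers(2, 6)))
        p, _ = anova_tukey(groups)
        ref = stats.f_oneway(*groups.values()).pvalue
        assert p == pytest.approx(ref, rel=1e-10)


def test_two_group_tukey_equals_pooled_t_test():
    """With k = 2 the studentized range is sqrt(2)·|t|, so the Tukey
    adjusted p must equal the two-sided pooled-variance t-test p."""
    rng = np.random.default_rng(7)
    for _ in range(25):
        a = rng.normal(0.0, 1.0, int(rng.integers(2, 8)))
        b = rng.normal(rng.uniform(-2, 2), 1.0, int(rng.integers(2, 8)))
        _, padj = anova_tukey({"A": a, "B": b})
        t_p = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert padj.loc["A", "B"] == pytest.approx(t_p, abs=1e-9)


def test_tukey_matches_scipy_tukey_hsd():
    """Independent route: scipy's Tukey HSD on the same fixtures."""
    rng = np.random.default_rng(11)
    for _ in range(3):
        groups = _random_groups(rng, 3, nmin=3, nmax=5)
        _, padj = anova_tukey(groups)
        ref = stats.tukey_hsd(*groups.values())
        names = list(groups)
        for i in range(3):
            for j in range(3):
                assert padj.loc[names[i], names[j]] == pytest.approx(
                    ref.pvalue[i, j], abs=1e-7
                )


def test_tukey_adjustment_is_conservative():
    """Adjusted p >= the unadjusted pairwise p from the same pooled variance."""
    rng = np.random.default_rng(13)
    for _ in range(20):
        groups = _random_groups(rng, int(rng.integers(3, 7)))
        data = list(groups.values())
        k = len(data)
        df = sum(len(d) for d in data) - k
        s2 = sum(((d - d.mean()) ** 2).sum() for d in data) / df
        _, padj = anova_tukey(groups)
        names = list(groups)
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(s2 * (1 / len(data[i]) + 1 / len(data[j])))
                t = abs(data[i].mean() - data[j].mean()) / se
                p_unadj = 2 * stats.t.sf(t, df)
                assert padj.loc[names[i], names[j]] >= p_unadj - 1e-12


def test_studentized_range_sf_is_a_survival_function():
    qs = np.linspace(0.0, 12.0, 50)
    sf = studentized_range_sf(qs, 5, 10)
    assert (np.diff(sf) <= 1e-12).all()
    assert sf[0] == pytest.approx(1.0)
    assert sf[-1] < 1e-4


# ---------------------------------------------------------------------------
# optimal-protocol selection


def _comparison(groups, alpha=0.05):
    medians = pd.Series({g: float(np.median(v)) for g, v in groups.items()})
    _, padj = anova_tukey(groups)
    return optimal_protocols(medians, padj, alpha)


def test_clear_winner_gives_singleton_set():
    rng = np.random.default_rng(17)
    groups = {
        "best": rng.normal(10.0, 0.1, 3),
        "low1": rng.normal(0.0, 0.1, 3),
        "low2": rng.normal(0.0, 0.1, 3),
    }
    assert _comparison(groups) == {"best"}


def test_identical_groups_select_everything():
    rng = np.random.default_rng(19)
    base = rng.normal(0.0, 1.0, 3)
    groups = {p: base.copy() for p in ("A", "B", "C")}
    assert _comparison(groups) == {"A", "B", "C"}


def test_median_ties_union_all_tied_tops():
    medians = pd.Series({"A": 1.0, "B": 1.0, "C": 0.0})
    padj = pd.DataFrame(
        [[1.0, 1.0, 0.01], [1.0, 1.0, 0.8], [0.01, 0.8, 1.0]],
        index=["A", "B", "C"],
        columns=["A", "B", "C"],
    )
    # C is significantly below A but not below B: the tie means C stays in
    assert optimal_protocols(medians, padj) == {"A", "B", "C"}


def test_scale_equivariance_of_comparison():
    """Multiplying raw concentrations by c > 0 shifts log2 values by a
    constant, leaving p-values and the optimal set unchanged."""
    panel = make_panel([("M1", "amino acids", "LC")])
    rng = np.random.default_rng(23)
    raw = rng.lognormal(2.0, 0.4, 9)

    def run(scale):
        cells = {}
        for g, prot in enumerate(("P1", "P2", "P3")):
            for r in range(3):
                cells[("mouse", "kidney", prot, r + 1)] = {
                    "M1": (scale * raw[3 * g + r], "valid")
                }
        comps = compare_protocols(build_table(panel, cells))
        return comps[("mouse", "kidney")]["M1"]

    base = run(1.0)
    scaled = run(137.5)
    assert scaled.optimal_set == base.optimal_set
    assert scaled.anova_p == pytest.approx(base.anova_p, rel=1e-8)
    assert np.allclose(
        scaled.tukey_adj_p.to_numpy(), base.tukey_adj_p.to_numpy(), atol=1e-9
    )


def test_three_protocol_planted_recovery_rate():
    """One high, one tied-high and one 4-sigma-deficient protocol: the
    {high, tied} optimal set is recovered at the rate an independent
    Monte-Carlo oracle predicts for triplicates (~94%, not higher)."""
    rng = np.random.default_rng(29)
    hits = 0
    reps = 400
    for _ in range(reps):
        groups = {
            "high": rng.normal(4.0, 1.0, 3),
            "tied": rng.normal(4.0, 1.0, 3),
            "low": rng.normal(0.0, 1.0, 3),
        }
        if _comparison(groups) == {"high", "tied"}:
            hits += 1
    # oracle estimate 0.938 (SE 0.004 at 4k reps); bound is oracle - 5 SE at n=400
    assert hits / reps >= 0.90


def test_undetectable_groups_enter_comparison_with_floor_values():
    """A metabolite detectable under one protocol is still compared across
    all protocols; the failing protocol's imputed floor loses."""
    panel = make_panel([("M1", "amino acids", "LC")])
    cells = {}
    for r in (1, 2, 3):
        cells[("mouse", "kidney", "good", r)] = {"M1": (100.0 + r, "valid")}
        cells[("mouse", "kidney", "bad", r)] = {"M1": (None, "below_lod")}
    comps = compare_protocols(build_table(panel, cells))
    comp = comps[("mouse", "kidney")]["M1"]
    assert comp.optimal_set == {"good"}
    assert comp.unique_best == "good"
    # floor = 0.2 * 101 -> log2 median of the bad group
    assert comp.protocol_medians["bad"] == pytest.approx(np.log2(0.2 * 101.0))


def test_count_optimal_by_class_totals(small_table):
    det = compute_detectability(small_table)
    comps = compare_protocols(small_table, detectability=det)
    for matrix, per_met in comps.items():
        counts = count_optimal_by_class(per_met, small_table.panel, det[matrix])
        classes = small_table.panel.classes
        assert (counts.optimal[classes].sum(axis=1) == counts.optimal["total"]).all()
        # every compared metabolite contributes to >= 1 protocol
        assert counts.optimal["total"].max() <= len(per_met)
        assert counts.unique_best["total"].sum() <= len(per_met)
        assert counts.detectable_total == len(per_met)


def test_config_validation():
    with pytest.raises(ConfigError):
        ComparisonConfig(alpha=0.0)
    with pytest.raises(ConfigError):
        ComparisonConfig(impute_fraction=0.0)
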