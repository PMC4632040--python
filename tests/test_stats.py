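"""t-test, KS and ANOVA implementations against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

import spinedyn as sd


# ---------------------------------------------------------------------------
# unpaired pooled-variance t-test


def test_ttest_identical_samples():
    r = sd.ttest_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.statistic == 0.0 and r.p_value == 1.0


def test_ttest_closed_form_example():
    """x={1,2,3}, y={2,3,4}: pooled variance 1, t = -1/sqrt(2/3)."""
    r = sd.ttest_unpaired([1, 2, 3], [2, 3, 4])
    assert r.statistic == pytest.approx(-1.224744871, abs=1e-8)
    assert r.df == 4
    assert r.p_value == pytest.approx(0.2878641347, abs=1e-8)


def test_ttest_degenerate_variance():
    equal = sd.ttest_unpaired([2.0, 2.0], [2.0, 2.0])
    assert equal.statistic == 0.0 and equal.p_value == 1.0
    unequal = sd.ttest_unpaired([1.0, 1.0], [2.0, 2.0])
    assert unequal.p_value == 0.0 and unequal.degenerate


@given(
    x=st_.lists(st_.floats(-5, 5), min_size=3, max_size=8),
    y=st_.lists(st_.floats(-5, 5), min_size=3, max_size=8),
)
@settings(max_examples=100, derandomize=True)
def test_ttest_symmetry(x, y):
    """Swapping samples negates t and preserves p."""
    a = sd.ttest_unpaired(x, y)
    b = sd.ttest_unpaired(y, x)
    assert a.statistic == pytest.approx(-b.statistic, abs=1e-10)
    assert a.p_value == pytest.approx(b.p_value, abs=1e-10)


@pytest.mark.parametrize("seed", [1, 2, 4, 5, 9])
def test_ttest_agrees_with_exhaustive_permutation(seed):
    """Two-tailed t p-value tracks the exhaustive permutation p (4 vs 4)."""
    rng = np.random.default_rng(seed)
    x = np.round(rng.normal(0, 1, 4), 3)
    y = np.round(rng.normal(0.6, 1, 4), 3)
    obs = sd.ttest_unpaired(x, y)
    pooled = np.concatenate([x, y])
    hits = total = 0
    for idx in itertools.combinations(range(8), 4):
        xs = pooled[list(idx)]
        ys = pooled[[i for i in range(8) if i not in idx]]
        total += 1
        if abs(sd.ttest_unpaired(xs, ys).statistic) >= abs(obs.statistic) - 1e-12:
            hits += 1
    assert obs.p_value == pytest.approx(hits / total, abs=0.02)


def test_welch_option():
    r = sd.ttest_unpaired([1, 2, 3, 4], [2, 4, 6, 8, 10], welch=True)
    assert r.name == "welch_t"
    assert 0 <= r.p_value <= 1


# ---------------------------------------------------------------------------
# two-sample Kolmogorov–Smirnov


def brute_force_ks_d(x, y):
    """sup |ECDF_x - ECDF_y| over every pooled evaluation point."""
    best = 0.0
    for t in list(x) + list(y):
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        best = max(best, abs(fx - fy))
    return best


def test_ks_trivial_cases():
    same = sd.ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert same.statistic == 0.0
    disjoint = sd.ks_two_sample([1.0, 2.0], [3.0, 4.0])
    assert disjoint.statistic == 1.0


def test_ks_equals_brute_force(rng):
    for _ in range(50):
        x = rng.normal(0, 1, rng.integers(2, 12))
        y = rng.normal(0.4, 1.3, rng.integers(2, 12))
        r = sd.ks_two_sample(x, y)
        assert r.statistic == pytest.approx(brute_force_ks_d(x, y), abs=1e-12)
        assert 0.0 <= r.p_value <= 1.0


def test_ks_invariant_under_monotone_transform(rng):
    x = rng.normal(0, 1, 25)
    y = rng.normal(0.5, 1, 30)
    base = sd.ks_two_sample(x, y)
    for transform in (np.exp, lambda v: v**3, lambda v: 2 * v + 7):
        r = sd.ks_two_sample(transform(x), transform(y))
        assert r.statistic == pytest.approx(base.statistic, abs=1e-12)


def test_ks_matches_scipy_d(rng):
    import scipy.stats

    x = rng.normal(0, 1, 40)
    y = rng.normal(0.3, 1, 55)
    mine = sd.ks_two_sample(x, y)
    ref = scipy.stats.ks_2samp(x, y)
    assert mine.statistic == pytest.approx(ref.statistic, abs=1e-12)


# ---------------------------------------------------------------------------
# two-way ANOVA and Bonferroni contrasts


def _balanced_2x2(reps=3):
    # cell means: control/young 10, control/old 12, mutant/young 14, mutant/old 20
    values, geno, age = [], [], []
    offsets = [-1.0, 0.0, 1.0][:reps]
    for g, a, mu in [
        ("control", "young", 10.0),
        ("control", "old", 12.0),
        ("mutant", "young", 14.0),
        ("mutant", "old", 20.0),
    ]:
        for off in offsets:
            values.append(mu + off)
            geno.append(g)
            age.append(a)
    return values, geno, age


def manual_balanced_ss(values, geno, age):
    """Hand-computed sums of squares for a balanced two-factor design."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(geno)
    a = np.asarray(age)
    grand = v.mean()
    ss_a = sum(
        (v[g == lev].mean() - grand) ** 2 * (g == lev).sum() for lev in set(geno)
    )
    ss_b = sum(
        (v[a == lev].mean() - grand) ** 2 * (a == lev).sum() for lev in set(age)
    )
    ss_cells = sum(
        (v[(g == gl) & (a == al)].mean() - grand) ** 2 * ((g == gl) & (a == al)).sum()
        for gl in set(geno)
        for al in set(age)
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_total = ((v - grand) ** 2).sum()
    ss_err = ss_total - ss_cells
    return ss_a, ss_b, ss_ab, ss_err, ss_total


def test_two_way_anova_matches_manual_sums_of_squares():
    values, geno, age = _balanced_2x2(reps=3)
    res = sd.two_way_anova(values, geno, age)
    ss_a, ss_b, ss_ab, ss_err, ss_total = manual_balanced_ss(values, geno, age)
    table = res.anova_table
    assert table.loc["C(genotype)", "sum_sq"] == pytest.approx(ss_a)
    assert table.loc["C(age)", "sum_sq"] == pytest.approx(ss_b)
    assert table.loc["C(genotype):C(age)", "sum_sq"] == pytest.approx(ss_ab)
    assert table.loc["Residual", "sum_sq"] == pytest.approx(ss_err)
    # decomposition closes
    assert table["sum_sq"].sum() == pytest.approx(ss_total)
    assert res.balanced


def test_anova_interaction_null_under_additive_means(rng):
    """With additive cell means, E[interaction SS] = MSE x its df: the
    mean interaction F across replicates is near 1."""
    fs = []
    for _ in range(300):
        values, geno, age = [], [], []
        for gi, g in enumerate(("control", "mutant")):
            for ai, a in enumerate(("young", "old")):
                for _r in range(4):
                    values.append(gi * 2.0 + ai * 3.0 + rng.normal(0, 1))
                    geno.append(g)
                    age.append(a)
        fs.append(sd.two_way_anova(values, geno, age).effects["interaction"].statistic)
    # F(1, 12) has mean df2/(df2-2) = 1.2
    assert np.mean(fs) == pytest.approx(1.2, abs=0.25)


def test_anova_degenerate_and_empty_cell():
    values, geno, age = _balanced_2x2(reps=2)
    res = sd.two_way_anova([1.0] * len(values), geno, age)
    assert res.effects["genotype"].degenerate
    with pytest.raises(ValueError, match="empty cell"):
        sd.two_way_anova(
            [1.0, 2.0, 3.0, 4.0],
            ["control", "control", "mutant", "control"],
            ["young", "old", "young", "old"],
        )


def test_bonferroni_adjustment_caps_at_one():
    values, geno, age = _balanced_2x2(reps=3)
    res = sd.bonferroni_pairwise(values, geno, age, m=3)
    assert len(res) == 2  # one contrast per age level
    for r in res:
        assert r.p_adjusted == pytest.approx(min(1.0, r.p_value * 3))
        assert r.p_adjusted >= r.p_value
        assert r.p_adjusted <= 1.0


def test_bonferroni_family_wise_error_under_null(rng):
    """With all cell means equal, the family-wise rejection rate of the
    Bonferroni-corrected per-age contrasts stays near or below 0.05."""
    n_reject = 0
    reps = 400
    for _ in range(reps):
        values, geno, age = [], [], []
        for g in ("control", "mutant"):
            for a in ("w4", "w6", "w8"):
                for _r in range(5):
                    values.append(rng.normal(0, 1))
                    geno.append(g)
                    age.append(a)
        contrasts = sd.bonferroni_pairwise(values, geno, age)
        if any(r.p_adjusted < 0.05 for r in contrasts):
            n_reject += 1
    fwer = n_reject / reps
    se = np.sqrt(0.05 * 0.95 / reps)
    assert fwer <= 0.05 + 3 * se


def test_one_way_anova_and_tukey():
    groups = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [8.0, 9.0, 10.0]]
    r = sd.one_way_anova(groups)
    assert r.df == (2, 6)
    assert r.p_value < 0.01
    values = [v for g in groups for v in g]
    labels = [f"g{i}" for i, g in enumerate(groups) for _ in g]
    tukey = sd.tukey_pairwise(values, labels)
    assert len(tukey) == 3


def test_results_table_and_stars():
    from spinedyn.stats import results_table

    r1 = sd.ttest_unpaired([1, 2, 3], [10, 11, 12])
    r2 = sd.ks_two_sample([1.0, 2.0], [1.0, 2.0])
    table = results_table([r1, r2])
    assert list(table["comparison"]) == ["student_t", "ks_two_sample"]
    assert table.iloc[0]["significance"] in {"*", "**", "***"}
    assert table.iloc[1]["significance"] == "ns"
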