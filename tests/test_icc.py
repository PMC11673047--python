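"""ICC correctness: hand-worked ANOVA, a brute-force oracle, an external
cross-check (pingouin), and the algebraic properties of the two forms."""

import numpy as np
import pandas as pd
import pytest

from ctharmony import reproducibility as rep


def oracle_icc(x, model):
    """Independent ANOVA from explicit sums over cells."""
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sse = sum(
        (x[i][j] - row[i] - col[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    if model == rep.CONSISTENCY:
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def test_worked_example_three_subjects_two_raters():
    # constant rater offset: perfect consistency, imperfect agreement
    x = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
    assert rep.icc(x, rep.CONSISTENCY).icc == pytest.approx(1.0)
    assert rep.icc(x, rep.AGREEMENT).icc == pytest.approx(8.0 / 9.0)


def test_degenerate_zero_variance_is_reproducible_sentinel():
    res = rep.icc(np.full((3, 2), 5.0))
    assert res.degenerate
    assert res.icc == rep.DEGENERATE_ICC == 1.0


def test_icc_matches_brute_force_oracle_on_random_matrices():
    rng = np.random.default_rng(77)
    for _ in range(100):
        n = int(rng.integers(3, 12))
        k = int(rng.integers(2, 6))
        x = rng.normal(size=(n, k)) + rng.normal(size=(1, k))
        for model in (rep.AGREEMENT, rep.CONSISTENCY):
            assert rep.icc(x, model).icc == pytest.approx(
                oracle_icc(x, model), abs=1e-10
            )


def test_icc_matches_pingouin_point_estimates():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    for _ in range(10):
        n, k = int(rng.integers(4, 10)), int(rng.integers(2, 5))
        x = rng.normal(size=(n, k))
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "scores": x.ravel(),
            }
        )
        res = pg.intraclass_corr(df, "targets", "raters", "scores")
        ref_a = res.loc[res.Type == "ICC(A,1)", "ICC"].values[0]
        ref_c = res.loc[res.Type == "ICC(C,1)", "ICC"].values[0]
        assert rep.icc(x, rep.AGREEMENT).icc == pytest.approx(ref_a, abs=1e-10)
        assert rep.icc(x, rep.CONSISTENCY).icc == pytest.approx(ref_c, abs=1e-10)


def test_agreement_bounded_by_consistency_when_rater_bias_present():
    """Agreement <= consistency whenever the rater mean-square is at least
    the residual mean-square (the extra denominator term is then
    nonnegative); with MSC < MSE and negative numerators the order can
    legitimately flip, so the assertion is conditional."""
    rng = np.random.default_rng(9)
    checked = 0
    for _ in range(100):
        x = rng.normal(size=(6, 4)) + rng.normal(scale=2.0, size=(1, 4))
        msr, msc, mse = rep._anova_mean_squares(x)
        if msc >= mse and msr >= mse:
            a = rep.icc(x, rep.AGREEMENT).icc
            c = rep.icc(x, rep.CONSISTENCY).icc
            assert a <= c + 1e-12
            checked += 1
    assert checked >= 30


def test_permutation_invariance():
    rng = np.random.default_rng(11)
    x = rng.normal(size=(7, 4))
    rows = rng.permutation(7)
    cols = rng.permutation(4)
    for model in (rep.AGREEMENT, rep.CONSISTENCY):
        assert rep.icc(x[rows], model).icc == pytest.approx(rep.icc(x, model).icc)
    # column permutation preserves consistency (and agreement: the ANOVA is
    # symmetric in rater labels)
    assert rep.icc(x[:, cols], rep.CONSISTENCY).icc == pytest.approx(
        rep.icc(x, rep.CONSISTENCY).icc
    )


def test_confidence_interval_brackets_estimate():
    rng = np.random.default_rng(21)
    for _ in range(20):
        x = rng.normal(size=(8, 4)) + 3 * rng.normal(size=(8, 1))
        for model in (rep.AGREEMENT, rep.CONSISTENCY):
            r = rep.icc(x, model)
            assert r.ci_low <= r.icc <= r.ci_high


def test_sample_size_and_finite_guards():
    with pytest.raises(rep.SampleSizeError):
        rep.icc(np.ones((2, 3)))
    with pytest.raises(ValueError):
        rep.icc(np.array([[1.0, np.nan], [2, 3], [4, 5]]))


def test_vectorized_table_path_matches_scalar_icc():
    rng = np.random.default_rng(17)
    subjects = [f"s{i}" for i in range(6)]
    protocols = ["A", "B", "C"]
    features = [f"f{i}" for i in range(5)]
    rows = [
        (s, "roi1", p, f, rng.normal())
        for s in subjects
        for p in protocols
        for f in features
    ]
    table = pd.DataFrame(rows, columns=["subject", "roi", "protocol", "feature", "value"])
    out = rep.icc_by_roi(table)
    assert len(out) == len(features)
    for _, row in out.iterrows():
        sub = table[table.feature == row.feature]
        m = sub.pivot_table(index="subject", columns="protocol", values="value")
        ref = rep.icc(m[protocols].to_numpy(), rep.AGREEMENT)
        assert row.icc == pytest.approx(ref.icc)
        assert row.ci_low == pytest.approx(ref.ci_low)
        assert row.ci_high == pytest.approx(ref.ci_high)
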