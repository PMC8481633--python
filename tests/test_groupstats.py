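import numpy as np
import pytest
from scipy import stats

import fmridyn as fd
from fmridyn.simulate import _box, _ellipsoid_mask, simulate_variability_maps


@pytest.fixture(scope="module")
def mask():
    return _ellipsoid_mask((16, 16, 10))


# ------------------------------------------------------------- glm_tmap

def test_glm_tmap_matches_two_sample_t(mask, rng):
    maps = simulate_variability_maps(16, mask, seed=1)
    groups = np.array([1] * 8 + [0] * 8)
    sm = fd.glm_tmap(maps, groups, mask)
    assert sm.df == 14
    t_scipy = stats.ttest_ind(maps[:8, mask], maps[8:, mask], axis=0).statistic
    np.testing.assert_allclose(sm.tmap[mask], t_scipy, atol=1e-10)
    # and the voxel-wise summary route agrees to machine precision
    v = maps[:, mask][:, 100]
    a = fd.GroupSummary(8, v[:8].mean(), v[:8].std(ddof=1))
    b = fd.GroupSummary(8, v[8:].mean(), v[8:].std(ddof=1))
    t_sum, _ = fd.summary_t_pooled(a, b)
    assert sm.tmap[mask][100] == pytest.approx(t_sum, abs=1e-10)


def test_glm_tmap_null_calibration(mask):
    """Under the null the supra-threshold fraction at p<0.001 is ~0.001."""
    rates = []
    for i in range(20):
        maps = simulate_variability_maps(24, mask, seed=100 + i)
        groups = np.array([1] * 12 + [0] * 12)
        sm = fd.glm_tmap(maps, groups, mask)
        thr = stats.t.ppf(1 - 0.0005, sm.df)
        rates.append(np.mean(np.abs(sm.tmap[mask]) > thr))
    assert np.mean(rates) < 0.005  # smoothing leaves it near nominal


def test_glm_tmap_planted_shift_peaks_in_region(mask):
    region = _box(6, 8, 6, 8, 4, 6, mask.shape) & mask
    assert region.sum() == 8
    maps = np.concatenate(
        [
            simulate_variability_maps(
                20, mask, effect_region=region, effect_size=1.5, seed=7
            ),
            simulate_variability_maps(20, mask, seed=8),
        ]
    )
    groups = np.array([1] * 20 + [0] * 20)
    sm = fd.glm_tmap(maps, groups, mask)
    thr = stats.t.ppf(1 - 0.0005, sm.df)
    assert np.nanmax(np.abs(sm.tmap[region])) > thr


def test_glm_tmap_covariate_adjustment(mask, rng):
    maps = simulate_variability_maps(20, mask, seed=3)
    groups = np.array([1] * 10 + [0] * 10)
    age = rng.normal(9, 2, 20)
    maps[:, mask] += 0.5 * age[:, None]  # confound affecting every voxel
    sm = fd.glm_tmap(maps, groups, mask, covariates=age)
    assert sm.df == 17  # N=20 minus intercept, group, age
    assert np.nanmax(np.abs(sm.tmap)) < 6  # no runaway effects


def test_glm_tmap_errors(mask):
    maps = simulate_variability_maps(4, mask, seed=0)
    with pytest.raises(ValueError, match="two groups"):
        fd.glm_tmap(maps, np.array([1, 1, 1, 1]), mask)
    with pytest.raises(ValueError, match="collinear"):
        fd.glm_tmap(
            maps,
            np.array([1, 1, 0, 0]),
            mask,
            covariates=np.array([1.0, 1.0, 0.0, 0.0]),
        )


# ---------------------------------------------- permutation correction

def test_permutation_p_floor(mask):
    region = _box(5, 9, 5, 9, 3, 7, mask.shape) & mask
    maps = np.concatenate(
        [
            simulate_variability_maps(
                10, mask, effect_region=region, effect_size=4.0, seed=21
            ),
            simulate_variability_maps(10, mask, seed=22),
        ]
    )
    groups = np.array([1] * 10 + [0] * 10)
    sm = fd.glm_tmap(maps, groups, mask)
    sm = fd.permutation_cluster_correct(sm, maps, groups, n_perm=100, seed=1)
    assert sm.clusters, "massive planted effect must produce a cluster"
    assert min(c["p"] for c in sm.clusters) == pytest.approx(1 / 101)


def test_permutation_warns_on_exhausted_labelings(mask, caplog):
    maps = simulate_variability_maps(6, mask, seed=2)
    groups = np.array([1, 1, 1, 0, 0, 0])
    sm = fd.glm_tmap(maps, groups, mask)
    with caplog.at_level("WARNING", logger="fmridyn"):
        fd.permutation_cluster_correct(sm, maps, groups, n_perm=100, seed=0)
    assert any("distinct labelings" in r.message for r in caplog.records)


def test_permutation_requires_min_permutations(mask):
    maps = simulate_variability_maps(8, mask, seed=2)
    groups = np.array([1] * 4 + [0] * 4)
    sm = fd.glm_tmap(maps, groups, mask)
    with pytest.raises(ValueError):
        fd.permutation_cluster_correct(sm, maps, groups, n_perm=10)


# ------------------------------------------------- summary statistics

@pytest.mark.parametrize(
    "a,b,expected",
    [
        ((50, 8.26, 1.93), (28, 8.93, 1.46), -1.596),
        ((50, 116.94, 17.45), (28, 122.43, 13.84), -1.430),
        ((50, 13.62, 6.30), (28, 14.75, 4.96), -0.818),
        ((50, 0.105, 0.069), (28, 0.093, 0.054), 0.791),
    ],
)
def test_summary_t_pooled_demographics(a, b, expected):
    t, df = fd.summary_t_pooled(fd.GroupSummary(*a), fd.GroupSummary(*b))
    assert t == pytest.approx(expected, abs=0.01)
    assert df == a[0] + b[0] - 2


def test_summary_t_identical_groups_zero():
    g = fd.GroupSummary(10, 5.0, 1.0)
    assert fd.summary_t_pooled(g, g)[0] == 0.0
    assert fd.summary_t_welch(g, g)[0] == 0.0


def test_summary_t_welch_perseverative_errors():
    t, _ = fd.summary_t_welch(
        fd.GroupSummary(50, 16.20, 9.24), fd.GroupSummary(28, 12.00, 5.55)
    )
    assert t == pytest.approx(2.506, abs=0.01)


def test_welch_equals_pooled_for_equal_variance_and_n():
    a = fd.GroupSummary(20, 3.0, 1.5)
    b = fd.GroupSummary(20, 2.0, 1.5)
    tw, dfw = fd.summary_t_welch(a, b)
    tp, dfp = fd.summary_t_pooled(a, b)
    assert tw == pytest.approx(tp, abs=1e-12)
    assert dfw == pytest.approx(dfp, abs=1e-9)


def test_chi2_gender_table_and_oracle():
    chi2, df = fd.pearson_chi2_2x2(np.array([[43, 7], [20, 8]]))
    assert chi2 == pytest.approx(2.454, abs=0.002) and df == 1
    oracle = stats.chi2_contingency(
        np.array([[43, 7], [20, 8]]), correction=False
    ).statistic
    assert chi2 == pytest.approx(oracle, abs=1e-10)


def test_chi2_special_cases():
    assert fd.pearson_chi2_2x2([[10, 10], [10, 10]])[0] == 0.0
    assert fd.pearson_chi2_2x2([[20, 0], [0, 20]])[0] == pytest.approx(40.0)
    t = np.array([[43, 7], [20, 8]])
    assert fd.pearson_chi2_2x2(t)[0] == pytest.approx(
        fd.pearson_chi2_2x2(t.T)[0], abs=1e-12
    )
    with pytest.raises(ValueError, match="marginal"):
        fd.pearson_chi2_2x2([[0, 0], [5, 5]])


# ------------------------------------------------------------- ANCOVA

def test_ancova_reduces_to_pooled_t(rng):
    vals = rng.standard_normal(30)
    groups = np.array([1] * 15 + [0] * 15)
    res = fd.ancova_scalar(vals, groups)
    a = fd.GroupSummary(15, vals[:15].mean(), vals[:15].std(ddof=1))
    b = fd.GroupSummary(15, vals[15:].mean(), vals[15:].std(ddof=1))
    t, _ = fd.summary_t_pooled(a, b)
    assert res["t"] == pytest.approx(t, abs=1e-10)
    assert res["F"] == pytest.approx(t**2, abs=1e-9)


def test_ancova_null_p_uniform():
    rng = np.random.default_rng(11)
    groups = np.array([1] * 20 + [0] * 20)
    ps = []
    for _ in range(200):
        vals = rng.standard_normal(40)
        cov = rng.standard_normal((40, 2))
        ps.append(fd.ancova_scalar(vals, groups, cov)["p"])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_ancova_power_one_sd_shift():
    rng = np.random.default_rng(13)
    groups = np.array([1] * 39 + [0] * 39)
    hits = 0
    for _ in range(200):
        vals = rng.standard_normal(78) + groups * 1.0
        hits += fd.ancova_scalar(vals, groups)["p"] < 0.05
    assert hits / 200 >= 0.8


# ------------------------------------------------- partial correlation

def test_partial_correlation_perfect(rng):
    x = rng.standard_normal(30)
    cov = rng.standard_normal((30, 2))
    r, p = fd.partial_correlation(x, x.copy(), cov)
    assert r == pytest.approx(1.0) and p == 0.0


def test_partial_correlation_confound_removed():
    rng = np.random.default_rng(5)
    rs = []
    for _ in range(50):
        c = rng.standard_normal(60)
        x = 2 * c + 0.3 * rng.standard_normal(60)
        y = -1.5 * c + 0.3 * rng.standard_normal(60)
        r, _ = fd.partial_correlation(x, y, c)
        rs.append(r)
    assert abs(np.mean(rs)) < 0.05  # raw correlation would be ~ -1


def test_partial_correlation_matches_pingouin(rng):
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    x, y = rng.standard_normal((2, 40))
    cov = rng.standard_normal((40, 3))
    df = pd.DataFrame(
        {"x": x, "y": y, "c0": cov[:, 0], "c1": cov[:, 1], "c2": cov[:, 2]}
    )
    for method in ("pearson", "spearman"):
        r, p = fd.partial_correlation(x, y, cov, method=method)
        ref = pingouin.partial_corr(
            df, x="x", y="y", covar=["c0", "c1", "c2"], method=method
        )
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-6)


def test_partial_correlation_insufficient_df(rng):
    with pytest.raises(ValueError, match="n > k"):
        fd.partial_correlation(
            rng.standard_normal(5), rng.standard_normal(5), rng.standard_normal((5, 3))
        )
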