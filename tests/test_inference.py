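"""Group inference: edge GLM, permutation null, NBS, demographics tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from wmfnet import inference as inf
from wmfnet.cohort import CohortSpec, latent_correlations, simulate_fc_cohort


def _random_z(rng, n, k):
    z = rng.normal(0, 0.3, size=(n, k, k))
    z = (z + z.transpose(0, 2, 1)) / 2
    for i in range(n):
        np.fill_diagonal(z[i], np.nan)
    return z


# ---------------------------------------------------------------------------
# edge GLM


def test_edge_glm_equals_pooled_t_without_covariates(rng):
    z = _random_z(rng, 12, 5)
    groups = ["a"] * 5 + ["b"] * 7
    stats = inf.edge_glm(z, groups)
    iu, ju = np.triu_indices(5, 1)
    for e in range(len(iu)):
        y = z[:, iu[e], ju[e]]
        expected = sps.ttest_ind(y[:5], y[5:], equal_var=True).statistic
        assert stats.t[e] == pytest.approx(expected, abs=1e-10)
    assert stats.df == 10


def test_edge_glm_group_collinear_covariate_fails(rng):
    z = _random_z(rng, 10, 4)
    groups = ["a"] * 5 + ["b"] * 5
    covs = pd.DataFrame({"dup_group": [1.0] * 5 + [0.0] * 5})
    with pytest.raises(ValueError, match="collinear"):
        inf.edge_glm(z, groups, covs)


def test_edge_glm_redundant_covariate_warns(rng):
    z = _random_z(rng, 12, 4)
    groups = ["a"] * 6 + ["b"] * 6
    age = rng.normal(45, 10, 12)
    covs = pd.DataFrame({"age": age, "age2": 2 * age + 1})
    with pytest.warns(UserWarning, match="collinear"):
        stats = inf.edge_glm(z, groups, covs)
    assert np.isfinite(stats.t).all()


def test_edge_glm_categorical_covariate_and_adjustment(rng):
    z = _random_z(rng, 16, 4)
    groups = ["a"] * 8 + ["b"] * 8
    covs = pd.DataFrame(
        {"age": rng.normal(45, 8, 16), "sex": rng.choice(["M", "F"], 16)}
    )
    stats = inf.edge_glm(z, groups, covs)
    assert stats.covariate_names == ["age", "sex"]
    assert stats.df == 16 - 4  # intercept, group, age, sex


def test_planted_effect_raises_t_on_planted_edges():
    spec = CohortSpec(effect_z=0.5)
    j1, j2, c1, c2 = latent_correlations(spec)
    z, groups, covs = simulate_fc_cohort(c1, c2, 16, 18, 200, seed=11)
    stats = inf.edge_glm(z, groups, covs[["age", "education", "sex", "mean_fd"]])
    planted = {tuple(sorted(e)) for e in spec.effect_edges}
    flags = np.array([tuple(e) in planted for e in stats.edges.tolist()])
    assert stats.t[flags].mean() > stats.t[~flags].mean() + 1.0


# ---------------------------------------------------------------------------
# permutation null


def _bruteforce_label_p(z, n1, covs=None):
    """Exhaustive two-group permutation p per edge via independent OLS fits."""
    n, k, _ = z.shape
    iu, ju = np.triu_indices(k, 1)
    y = z[:, iu, ju]

    def tstats(g):
        x = np.column_stack([np.ones(n), g] if covs is None else [np.ones(n), g, covs])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        df = n - x.shape[1]
        sigma2 = (resid**2).sum(axis=0) / df
        xtx_inv = np.linalg.inv(x.T @ x)
        return beta[1] / np.sqrt(sigma2 * xtx_inv[1, 1])

    g_obs = np.array([1.0] * n1 + [0.0] * (n - n1))
    t_obs = tstats(g_obs)
    count = np.zeros(len(iu))
    total = 0
    for members in itertools.combinations(range(n), n1):
        g = np.zeros(n)
        g[list(members)] = 1.0
        count += np.abs(tstats(g)) >= np.abs(t_obs) - 1e-12
        total += 1
    return count / total


def test_permutation_p_matches_exhaustive_enumeration(rng):
    z = _random_z(rng, 7, 4)
    groups = ["a"] * 4 + ["b"] * 3
    stats = inf.permutation_null(z, groups, scheme="labels", exact=True, seed=0)
    assert stats.n_permutations == 35  # C(7, 4) distinct splits
    expected = _bruteforce_label_p(z, 4)
    np.testing.assert_allclose(stats.p, expected, atol=1e-12)


def test_permutation_deterministic_and_never_zero(rng):
    z = _random_z(rng, 12, 4)
    groups = ["a"] * 6 + ["b"] * 6
    a = inf.permutation_null(z, groups, n_permutations=300, seed=9)
    b = inf.permutation_null(z, groups, n_permutations=300, seed=9)
    np.testing.assert_array_equal(a.p, b.p)
    np.testing.assert_array_equal(a.t_perm, b.t_perm)
    assert (a.p >= 1.0 / 301).all() and (a.p <= 1.0).all()


def test_zero_observed_t_gives_p_one(rng):
    z = _random_z(rng, 10, 3)
    z[5:] = z[:5]  # group 2 mirrors group 1 -> t = 0 on every edge
    groups = ["a"] * 5 + ["b"] * 5
    stats = inf.permutation_null(z, groups, n_permutations=200, seed=3)
    np.testing.assert_allclose(stats.t, 0.0, atol=1e-12)
    np.testing.assert_allclose(stats.p, 1.0)


def test_freedman_lane_matches_labels_scheme_without_covariates(rng):
    # with only an intercept as nuisance the two schemes draw from the same null
    z = _random_z(rng, 14, 4)
    groups = ["a"] * 7 + ["b"] * 7
    fl = inf.permutation_null(z, groups, n_permutations=800, seed=4, scheme="freedman_lane")
    lb = inf.permutation_null(z, groups, n_permutations=800, seed=4, scheme="labels")
    np.testing.assert_allclose(fl.p, lb.p, atol=0.1)


def test_small_permutation_count_warns(rng):
    z = _random_z(rng, 8, 3)
    groups = ["a"] * 4 + ["b"] * 4
    with pytest.warns(UserWarning, match="resolution"):
        inf.permutation_null(z, groups, n_permutations=50, seed=0)


def test_nbs_power_at_large_planted_effect():
    """A 0.5 Fisher-z group offset on connected edges is detected in most
    cohorts (smoke check of sensitivity, complementing the null FWER check)."""
    spec = CohortSpec(effect_z=0.5)
    _, _, c1, c2 = latent_correlations(spec)
    hits = 0
    for i in range(10):
        z, groups, covs = simulate_fc_cohort(c1, c2, 16, 18, 200, seed=500 + i)
        stats = inf.permutation_null(
            z, groups, covs[["age", "education", "sex", "mean_fd"]],
            n_permutations=500, seed=600 + i,
        )
        # a strict primary threshold suits concentrated strong effects: the
        # size-based statistic at p<0.05 rewards only spatially extended ones
        hits += inf.nbs_correct(stats, 0.005, 0.05).any_significant()
    assert hits >= 8


# ---------------------------------------------------------------------------
# NBS


def _stats_with_planted_suprathreshold(rng, k, strong_edges, p=500):
    iu, ju = np.triu_indices(k, 1)
    edges = np.column_stack([iu, ju])
    n_e = len(iu)
    t = rng.normal(0, 0.5, n_e)
    for i, j in strong_edges:
        e = np.nonzero((iu == i) & (ju == j))[0][0]
        t[e] = 10.0
    t_perm = rng.normal(0, 1.0, (p, n_e))
    return inf.EdgeStats(
        edges=edges, t=t, df=30, k=k, p=None, t_perm=t_perm, n_permutations=p
    )


def test_nbs_components_from_suprathreshold_edges(rng):
    stats = _stats_with_planted_suprathreshold(rng, 7, [(0, 1), (1, 2), (2, 3), (4, 5)])
    res = inf.nbs_correct(stats, primary_threshold_p=0.05, alpha=0.05)
    assert sorted(res.component_size) == [1, 3]
    chain = res.components[res.component_size.index(3)]
    assert sorted(chain) == [(0, 1), (1, 2), (2, 3)]
    assert all(s == 1 for s in res.component_sign)
    assert all(0 < p <= 1 for p in res.corrected_p)
    # a 3-edge chain is far larger than null maxima at this threshold
    assert res.corrected_p[res.component_size.index(3)] < 0.05


def test_nbs_empty_when_nothing_suprathreshold(rng):
    stats = _stats_with_planted_suprathreshold(rng, 6, [])
    stats.t = np.zeros_like(stats.t)
    res = inf.nbs_correct(stats, 0.05, 0.05)
    assert res.components == [] and not res.any_significant()


def test_nbs_requires_permutation_stream(rng):
    stats = inf.EdgeStats(
        edges=np.array([[0, 1]]), t=np.array([1.0]), df=10, k=2
    )
    with pytest.raises(ValueError, match="permutation"):
        inf.nbs_correct(stats)


def test_nbs_two_sided_separates_signs(rng):
    stats = _stats_with_planted_suprathreshold(rng, 6, [(0, 1), (1, 2)])
    e_neg = np.nonzero((stats.edges[:, 0] == 3) & (stats.edges[:, 1] == 4))[0][0]
    stats.t[e_neg] = -10.0
    res = inf.nbs_correct(stats, 0.05, 0.05, direction="two-sided")
    assert sorted(res.component_sign) == [-1, 1]


# ---------------------------------------------------------------------------
# demographics from summary statistics


@pytest.mark.parametrize(
    "summary, printed_p",
    [
        ((48.00, 14.14, 16, 41.00, 10.65, 18), 0.11),  # age
        ((13.00, 3.16, 16, 14.55, 2.52, 18), 0.12),  # education, years
        ((0.21, 0.11, 16, 0.34, 0.24, 18), 0.06),  # mean RMS motion
    ],
)
def test_t_from_summary_reproduces_printed_demographics(summary, printed_p):
    t, df, p = inf.t_test_from_summary(*summary)
    assert df == 32
    assert round(p, 2) == printed_p


def test_t_from_summary_degenerate_cases():
    t, df, p = inf.t_test_from_summary(5.0, 1.0, 10, 5.0, 1.0, 12)
    assert t == 0.0 and p == pytest.approx(1.0)
    t, df, p = inf.t_test_from_summary(3.0, 0.0, 5, 3.0, 0.0, 5)
    assert (t, p) == (0.0, 1.0)
    with pytest.raises(ValueError):
        inf.t_test_from_summary(1.0, 1.0, 1, 2.0, 1.0, 5)


def test_chi_square_2x2_hand_computed():
    stat, p = inf.chi_square_2x2(10, 6, 9, 9)
    assert stat == pytest.approx(0.537, abs=1e-3)  # 34*36^2/(16*18*19*15)
    stat0, p0 = inf.chi_square_2x2(5, 5, 5, 5)
    assert stat0 == 0.0 and p0 == pytest.approx(1.0)
    double, _ = inf.chi_square_2x2(20, 12, 18, 18)
    assert double == pytest.approx(2 * 0.5368, abs=2e-3)  # scale property
    yates, _ = inf.chi_square_2x2(10, 6, 9, 9, yates=True)
    assert yates < 0.537
    with pytest.raises(ValueError):
        inf.chi_square_2x2(0, 0, 9, 9)
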