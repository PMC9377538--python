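"""Clustering: node subsampling, profiles, correlation k-means, Dice stability."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wmfnet import clustering as cl
from wmfnet.mask import GroupMask, group_mask, subject_tissue_label

from conftest import full_mask


# ---------------------------------------------------------------------------
# interchanging-grid subsampling


def test_grid_subsample_full_cuboid_convention():
    mask = full_mask((4, 4, 2))
    nodes = cl.interchanging_grid_subsample(mask)
    assert len(nodes) == 8  # 4 per slice
    coords = {tuple(c) for c in mask.voxel_index[nodes]}
    even = {(x, y, 0) for x in (0, 2) for y in (0, 2)}
    odd = {(x, y, 1) for x in (1, 3) for y in (1, 3)}
    assert coords == even | odd


def test_grid_subsample_empty_mask_fails():
    empty = np.zeros((4, 4, 2), dtype=bool)
    gm = GroupMask(mask=empty, fraction_map=empty.astype(float), threshold=0.5)
    with pytest.raises(ValueError):
        cl.interchanging_grid_subsample(gm)


def test_grid_subsample_quarter_ratio(rng):
    blob = rng.random((12, 12, 8)) > 0.3
    gm = GroupMask(mask=blob, fraction_map=blob.astype(float), threshold=0.5)
    nodes = cl.interchanging_grid_subsample(gm)
    ratio = len(nodes) / gm.n_voxels
    assert 0.15 < ratio < 0.35  # ~1 in 4


# ---------------------------------------------------------------------------
# correlation profiles


def test_profile_matches_naive_pearson_oracle(rng):
    mask = full_mask((5, 4, 1))  # 20 voxels
    bold = rng.normal(size=(5, 4, 1, 30))
    nodes = np.array([0, 3, 7, 12, 19])
    prof = cl.correlation_profile(bold, mask, nodes)
    x = mask.extract_series(bold)
    for i in range(20):
        for jn, j in enumerate(nodes):
            expected = np.corrcoef(x[i], x[j])[0, 1]
            assert prof.values[i, jn] == pytest.approx(expected, abs=1e-12)


def test_profile_identical_and_negated_series(rng):
    mask = full_mask((3, 1, 1))
    base = rng.normal(size=10)
    bold = np.zeros((3, 1, 1, 10))
    bold[0, 0, 0] = base
    bold[1, 0, 0] = -base
    bold[2, 0, 0] = rng.normal(size=10)
    prof = cl.correlation_profile(bold, mask, np.array([0]))
    assert prof.values[0, 0] == pytest.approx(1.0)
    assert prof.values[1, 0] == pytest.approx(-1.0)


def test_profile_zero_variance_policy(rng):
    mask = full_mask((3, 1, 1))
    bold = rng.normal(size=(3, 1, 1, 12))
    bold[1, 0, 0] = 4.2  # constant series
    prof = cl.correlation_profile(bold, mask, np.array([0, 2]))
    assert list(prof.invalid_voxels) == [1]
    np.testing.assert_array_equal(prof.values[1], 0.0)


def test_profile_random_series_have_small_r(rng):
    mask = full_mask((4, 4, 1))
    bold = rng.normal(size=(4, 4, 1, 200))
    nodes = np.arange(0, 16, 4)
    prof = cl.correlation_profile(bold, mask, nodes)
    off_diag = prof.values[prof.values < 0.999]
    assert np.abs(off_diag).mean() < 0.2


def _profile(values):
    v = np.asarray(values, dtype=float)
    idx = np.zeros((v.shape[0], 3), dtype=int)
    nidx = np.zeros((v.shape[1], 3), dtype=int)
    return cl.CorrelationProfile(values=v, voxel_index=idx, node_index=nidx)


def test_average_profiles_two_stage_mean():
    mats = [np.full((2, 2), v) for v in (1.0, 3.0, 5.0, 9.0)]
    profs = [_profile(m) for m in mats]
    equal = cl.average_profiles(profs, ["a", "a", "b", "b"])
    np.testing.assert_allclose(equal.values, np.mean(mats, axis=0))  # balanced

    unequal = cl.average_profiles(profs, ["a", "b", "b", "b"])
    expected = (mats[0] + np.mean(mats[1:], axis=0)) / 2  # 0.5*1 + 0.5*mean(3,5,9)
    np.testing.assert_allclose(unequal.values, expected)
    assert not np.allclose(unequal.values, np.mean(mats, axis=0))

    same = cl.average_profiles([profs[0], profs[0]], ["a", "b"])
    np.testing.assert_allclose(same.values, mats[0])

    with pytest.raises(ValueError):
        cl.average_profiles(profs, ["a", "a", "a", "a"])


# ---------------------------------------------------------------------------
# correlation-distance k-means


def _two_block_rows(rng, n_per_block=4, dim=12, noise=0.02):
    v = rng.normal(size=dim)
    rows = [v + rng.normal(0, noise, dim) for _ in range(n_per_block)]
    rows += [-v + rng.normal(0, noise, dim) for _ in range(n_per_block)]
    return np.array(rows)


def _sse(x, labels):
    return sum(
        ((x[labels == lab] - x[labels == lab].mean(axis=0)) ** 2).sum()
        for lab in np.unique(labels)
    )


def test_kmeans_matches_bruteforce_optimum_on_8_rows(rng):
    rows = _two_block_rows(rng)
    labels = cl.kmeans_correlation(rows, k=2, n_replicates=10, seed=0)
    x = cl._standardize_rows(rows)
    best_sse, best_part = np.inf, None
    for size in range(1, 8):
        for members in itertools.combinations(range(8), size):
            part = np.ones(8, dtype=int)
            part[list(members)] = 0
            sse = _sse(x, part)
            if sse < best_sse:
                best_sse, best_part = sse, part
    # same bipartition as the exhaustive optimum
    assert (
        np.array_equal(labels, best_part + 1) or np.array_equal(labels, 2 - best_part)
    )
    assert _sse(x, labels) == pytest.approx(best_sse, rel=1e-9)


def test_kmeans_invariant_to_positive_affine_row_transforms(rng):
    rows = _two_block_rows(rng, n_per_block=6)
    scales = rng.uniform(0.2, 5.0, size=rows.shape[0])[:, None]
    shifts = rng.uniform(-10, 10, size=rows.shape[0])[:, None]
    a = cl.kmeans_correlation(rows, 2, seed=3)
    b = cl.kmeans_correlation(rows * scales + shifts, 2, seed=3)
    np.testing.assert_array_equal(a, b)


def test_kmeans_canonical_labels_by_size(rng):
    v = rng.normal(size=12)
    rows = np.array(
        [v + rng.normal(0, 0.02, 12) for _ in range(3)]
        + [-v + rng.normal(0, 0.02, 12) for _ in range(7)]
    )
    labels = cl.kmeans_correlation(rows, 2, seed=0)
    np.testing.assert_array_equal(labels, [2] * 3 + [1] * 7)  # largest gets label 1


def test_kmeans_preconditions(rng):
    rows = rng.normal(size=(5, 8))
    with pytest.raises(ValueError):
        cl.kmeans_correlation(rows, 5)
    with pytest.raises(ValueError):
        cl.kmeans_correlation(rows, 1)
    rows[2] = 3.14  # constant row
    with pytest.raises(ValueError):
        cl.kmeans_correlation(rows, 2)


# ---------------------------------------------------------------------------
# Dice co-assignment


def _dice_bruteforce(a, b):
    n = len(a)
    both = pa = pb = 0
    for i in range(n):
        for j in range(i + 1, n):
            ca, cb = a[i] == a[j], b[i] == b[j]
            pa += ca
            pb += cb
            both += ca and cb
    if pa + pb == 0:
        return 1.0
    return 2 * both / (pa + pb)


def test_dice_matches_bruteforce_pair_enumeration(rng):
    for _ in range(5):
        a = rng.integers(0, 4, 30)
        b = rng.integers(0, 4, 30)
        assert cl.dice_coassignment(a, b) == pytest.approx(_dice_bruteforce(a, b))


def test_dice_identity_symmetry_and_label_invariance(rng):
    a = rng.integers(0, 5, 40)
    b = rng.integers(0, 5, 40)
    assert cl.dice_coassignment(a, a) == 1.0
    assert cl.dice_coassignment(a, b) == pytest.approx(cl.dice_coassignment(b, a))
    permuted = (a + 2) % 5  # pure relabeling
    assert cl.dice_coassignment(a, permuted) == 1.0


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 10_000))
def test_dice_bounded_and_symmetric(seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 6, 25)
    b = rng.integers(0, 6, 25)
    d = cl.dice_coassignment(a, b)
    assert 0.0 <= d <= 1.0
    assert d == pytest.approx(cl.dice_coassignment(b, a))


def test_dice_of_random_equal_partitions_is_one_over_k(rng):
    k, v = 4, 800
    vals = [
        cl.dice_coassignment(rng.permutation(np.arange(v) % k), rng.permutation(np.arange(v) % k))
        for _ in range(20)
    ]
    assert np.mean(vals) == pytest.approx(1.0 / k, abs=0.02)


# ---------------------------------------------------------------------------
# stability and K selection


def test_stability_perfect_structure_gives_dice_one(rng):
    rows = _two_block_rows(rng, n_per_block=15, dim=60, noise=0.01)
    prof = _profile(rows)
    curve = cl.stability_analysis(prof, k_range=[2], n_folds=4, n_replicates=5, seed=0)
    assert curve.mean_dice[0] == pytest.approx(1.0)
    assert len(curve.per_pair_dice[0]) == 6  # all fold pairs
    assert curve.mean_dice[0] == pytest.approx(np.mean(curve.per_pair_dice[0]))


def _curve(d):
    ks = sorted(d)
    return cl.StabilityCurve(
        k_values=np.array(ks),
        mean_dice=np.array([d[k] for k in ks]),
        per_pair_dice=[[d[k]] * 6 for k in ks],
    )


def test_select_k_rule():
    assert cl.select_k(_curve({2: 0.95, 3: 0.90, 4: 0.80})) == 3
    assert cl.select_k(_curve({k: 0.99 for k in range(2, 23)})) == 22
    assert cl.select_k(_curve({2: 0.5, 3: 0.5})) is None  # explicit no-stable-K
    with pytest.raises(ValueError):
        cl.select_k(cl.StabilityCurve(np.array([]), np.array([]), []))


# ---------------------------------------------------------------------------
# layer assignment


def _parcellation_at_planes(x_planes, shape=(10, 5, 5)):
    coords, labels = [], []
    for lab, x in enumerate(x_planes, start=1):
        for y in range(shape[1]):
            for z in range(shape[2]):
                coords.append((x, y, z))
                labels.append(lab)
    order = np.lexsort(np.array(coords).T[::-1])
    return cl.Parcellation(
        labels=np.array(labels)[order],
        k=len(x_planes),
        voxel_index=np.array(coords)[order],
    )


def test_layers_by_distance_to_gm():
    shape = (10, 5, 5)
    gm = np.zeros(shape, dtype=bool)
    gm[0] = True  # gray matter at the x=0 face
    parc = _parcellation_at_planes([1, 4, 9], shape)
    parc = cl.assign_layers(parc, gm, voxel_size_mm=3.0)
    assert parc.layer == {1: "superficial", 2: "middle", 3: "deep"}
    assert parc.mean_gm_distance[1] == pytest.approx(3.0)
    assert parc.mean_gm_distance[3] == pytest.approx(27.0)


def test_layers_all_adjacent_degenerate_case():
    shape = (10, 5, 5)
    gm = np.zeros(shape, dtype=bool)
    gm[0] = True
    # three networks, all of whose voxels sit at the same distance from GM
    parc = _parcellation_at_planes([1], shape)
    parc.labels = (np.arange(len(parc.labels)) % 3) + 1
    parc.k = 3
    parc = cl.assign_layers(parc, gm, voxel_size_mm=3.0)
    assert set(parc.layer.values()) == {"superficial"}


def test_layers_explicit_override():
    shape = (10, 5, 5)
    gm = np.zeros(shape, dtype=bool)
    gm[0] = True
    parc = _parcellation_at_planes([1, 4, 9], shape)
    override = {1: "superficial", 2: "superficial", 3: "deep"}
    parc = cl.assign_layers(parc, gm, 3.0, layer_map=override)
    assert parc.layer == override
    with pytest.raises(ValueError):
        cl.assign_layers(parc, gm, 3.0, layer_map={1: "outer", 2: "middle", 3: "deep"})


# ---------------------------------------------------------------------------
# planted-parcel recovery on the synthetic cohort


def test_planted_parcel_recovery(tiny_spec, tiny_cohort):
    from sklearn.metrics import adjusted_rand_score

    subjects, truth = tiny_cohort
    labels = [subject_tissue_label(s.tissue_probs) for s in subjects]
    gmask = group_mask(labels, "WM", 0.6)
    nodes = cl.interchanging_grid_subsample(gmask)
    profiles = [cl.correlation_profile(s.bold, gmask, nodes) for s in subjects]
    avg = cl.average_profiles(profiles, [s.group for s in subjects])
    vi = gmask.voxel_index
    gt = truth.wm_parcel_labels[vi[:, 0], vi[:, 1], vi[:, 2]]
    keep = gt > 0
    pred = cl.kmeans_correlation(avg.values[keep], tiny_spec.k_true, 10, seed=0)
    assert adjusted_rand_score(gt[keep], pred) > 0.9
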