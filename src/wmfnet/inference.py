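"""Group inference on network FC: covariate-adjusted edge GLM, permutation
null, and network-based-statistic (NBS) correction.

Per edge, a linear model ``z ~ intercept + group + covariates`` gives the
group t-statistic.  The null distribution comes from label permutations —
by default the Freedman–Lane scheme (covariates are regressed out once and
the residuals' rows are permuted), which preserves nuisance structure; raw
label permutation is available as an option.  Edges whose permutation p
falls below a primary threshold form a graph on the networks; the size of
each connected component is compared with the permutation distribution of
the maximal component size, giving family-wise-error-corrected component
p-values (the NBS).

Also holds the summary-statistic demographics tests (pooled two-sample t
from printed means/SDs, 2x2 chi-square).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EdgeStats",
    "NBSResult",
    "encode_covariates",
    "edge_glm",
    "permutation_null",
    "nbs_correct",
    "t_test_from_summary",
    "chi_square_2x2",
]

_TIE_TOL = 1e-12


@dataclass
class EdgeStats:
    """Edge-wise group statistics on the K(K-1)/2 network pairs."""

    edges: np.ndarray  # (E, 2) upper-triangle network index pairs
    t: np.ndarray  # (E,) observed group t-statistics
    df: int
    k: int
    covariate_names: list = field(default_factory=list)
    p: np.ndarray | None = None  # (E,) two-sided permutation p-values
    t_perm: np.ndarray | None = None  # (P, E) permuted t-statistics
    n_permutations: int = 0
    scheme: str = ""


@dataclass
class NBSResult:
    """Suprathreshold components and their permutation-corrected p-values."""

    components: list  # list of lists of (i, j) network pairs
    component_size: list  # edge count per component
    component_sign: list  # +1 (group1 > group2) or -1 per component
    corrected_p: list
    primary_threshold: float
    alpha: float
    n_permutations: int
    direction: str
    null_max_size: np.ndarray

    @property
    def significant(self) -> list:
        return [p < self.alpha for p in self.corrected_p]

    def any_significant(self) -> bool:
        return any(self.significant)


# ---------------------------------------------------------------------------
# design handling


def _stack_z(z_matrices) -> np.ndarray:
    """(n, K, K) array from an array or a list of FCMatrix-like objects."""
    if isinstance(z_matrices, np.ndarray):
        z = z_matrices
    else:
        z = np.stack([m.z if hasattr(m, "z") else np.asarray(m) for m in z_matrices])
    if z.ndim != 3 or z.shape[1] != z.shape[2]:
        raise ValueError("expected per-subject square z matrices")
    return np.asarray(z, dtype=np.float64)


def encode_covariates(covariates: pd.DataFrame | None) -> tuple[np.ndarray, list]:
    """Numeric covariate matrix; categorical columns become 0/1 indicators."""
    if covariates is None or covariates.shape[1] == 0:
        return np.empty((0, 0)), []
    cols, names = [], []
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype.kind in "OUSb":
            codes, levels = pd.factorize(col)
            if len(levels) > 2:
                raise ValueError(f"covariate {name!r} has >2 categorical levels")
            cols.append(codes.astype(np.float64))
        else:
            cols.append(col.to_numpy(dtype=np.float64))
        names.append(str(name))
    return np.column_stack(cols), names


def _group_indicator(groups) -> np.ndarray:
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    # positive t means the lexicographically first group (the patient-like
    # group in generated cohorts) has higher connectivity
    return np.asarray([1.0 if g == labels[0] else 0.0 for g in groups])


def _nuisance_basis(c_cols: np.ndarray, names: list, g: np.ndarray) -> tuple[np.ndarray, list]:
    """Orthonormal basis of [intercept | covariates], pruning collinearity."""
    n = len(g)
    full = np.column_stack([np.ones(n)] + ([c_cols] if c_cols.size else []))
    full_names = ["intercept"] + names
    rank = np.linalg.matrix_rank(full)
    if rank < full.shape[1]:
        q, r, piv = _pivoted_qr(full)
        keep = np.sort(piv[:rank])
        dropped = [full_names[j] for j in range(full.shape[1]) if j not in set(keep.tolist())]
        warnings.warn(f"collinear covariates dropped: {dropped}", stacklevel=3)
        full = full[:, keep]
        full_names = [full_names[j] for j in keep]
    if np.linalg.matrix_rank(np.column_stack([g, full])) <= full.shape[1]:
        raise ValueError("group indicator is collinear with the covariates")
    qc, _ = np.linalg.qr(full)
    return qc, full_names


def _pivoted_qr(x):
    from scipy.linalg import qr

    q, r, piv = qr(x, mode="economic", pivoting=True)
    return q, r, piv


def _edge_t(ytil: np.ndarray, gtil: np.ndarray, df: int) -> np.ndarray:
    """t for the group coefficient given residualised data and regressor."""
    gg = gtil @ gtil
    b = (gtil @ ytil) / gg
    rss = (ytil**2).sum(axis=0) - b**2 * gg
    sigma2 = np.clip(rss, 0, None) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        return b / np.sqrt(sigma2 / gg)


def edge_glm(
    z_matrices,
    groups,
    covariates: pd.DataFrame | None = None,
) -> EdgeStats:
    """Observed covariate-adjusted two-sample t per edge.

    With no covariates the statistic equals the classic pooled-variance
    two-sample t.  WM-mean/global signals never enter; gender (or any
    categorical covariate) is coded as a 0/1 indicator.
    """
    z = _stack_z(z_matrices)
    n, k = z.shape[0], z.shape[1]
    if len(groups) != n:
        raise ValueError("group labels do not match number of subjects")
    g = _group_indicator(groups)
    if min((g == 1).sum(), (g == 0).sum()) < 3:
        raise ValueError("need at least 3 subjects per group")
    c_cols, names = encode_covariates(covariates)
    qc, used_names = _nuisance_basis(c_cols, names, g)

    iu, ju = np.triu_indices(k, 1)
    y = z[:, iu, ju]  # (n, E)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite z values on off-diagonal edges")
    df = n - 1 - qc.shape[1]
    if df < 1:
        raise ValueError("not enough degrees of freedom")
    ytil = y - qc @ (qc.T @ y)
    gtil = g - qc @ (qc.T @ g)
    t = _edge_t(ytil, gtil, df)
    return EdgeStats(
        edges=np.column_stack([iu, ju]),
        t=t,
        df=df,
        k=k,
        covariate_names=used_names[1:],
    )


def _all_label_permutations(g: np.ndarray) -> np.ndarray:
    """Every distinct assignment of the group labels (exact enumeration)."""
    n = len(g)
    n1 = int(g.sum())
    combos = list(itertools.combinations(range(n), n1))
    if len(combos) > 500_000:
        raise ValueError("exact enumeration infeasible; use random permutations")
    out = np.zeros((len(combos), n))
    for row, members in enumerate(combos):
        out[row, list(members)] = 1.0
    return out


def permutation_null(
    z_matrices,
    groups,
    covariates: pd.DataFrame | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    scheme: str = "freedman_lane",
    exact: bool = False,
) -> EdgeStats:
    """Permutation p-values per edge plus the permuted-t stream for NBS.

    ``scheme='freedman_lane'`` permutes the rows of the covariate-adjusted
    residuals (nuisance structure preserved); ``scheme='labels'`` permutes
    the raw group labels.  ``exact=True`` (labels scheme) enumerates every
    distinct group assignment instead of sampling.  p-values use the
    add-one estimator (1 + #{|t*| >= |t|}) / (1 + P) and never return 0.
    """
    if scheme not in ("freedman_lane", "labels"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if n_permutations < 100 and not exact:
        warnings.warn("fewer than 100 permutations: poor p-value resolution", stacklevel=2)
    base = edge_glm(z_matrices, groups, covariates)
    z = _stack_z(z_matrices)
    n, k = z.shape[0], z.shape[1]
    g = _group_indicator(groups)
    c_cols, names = encode_covariates(covariates)
    qc, _ = _nuisance_basis(c_cols, names, g)
    iu, ju = np.triu_indices(k, 1)
    y = z[:, iu, ju]
    df = base.df
    ytil = y - qc @ (qc.T @ y)
    gtil = g - qc @ (qc.T @ g)
    gg = gtil @ gtil
    s_col = (ytil**2).sum(axis=0)

    rng = np.random.default_rng(seed)
    if exact:
        if scheme != "labels":
            raise ValueError("exact enumeration requires scheme='labels'")
        g_perm = _all_label_permutations(g)
    elif scheme == "labels":
        g_perm = np.stack([g[rng.permutation(n)] for _ in range(n_permutations)])
    else:
        perms = np.stack([rng.permutation(n) for _ in range(n_permutations)])

    if scheme == "labels":
        gt = g_perm - (g_perm @ qc) @ qc.T  # residualised permuted indicators
        gg_p = (gt**2).sum(axis=1)
        b = (gt @ ytil) / gg_p[:, None]
        rss = np.clip(s_col[None, :] - b**2 * gg_p[:, None], 0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = b / np.sqrt(rss / df / gg_p[:, None])
    else:
        # Freedman–Lane: y* = fitted nuisance + permuted residuals; the
        # group regressor stays fixed, so only the data rows move.
        gt_rows = gtil[perms]  # (P, n)
        b = (gt_rows @ ytil) / gg
        qproj = np.einsum("pnq,ne->pqe", qc[perms], ytil)
        rss = np.clip(s_col[None, :] - (qproj**2).sum(axis=1) - b**2 * gg, 0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = b / np.sqrt(rss / df / gg)

    n_perm = t_perm.shape[0]
    exceed = (np.abs(t_perm) >= np.abs(base.t)[None, :] - _TIE_TOL).sum(axis=0)
    if exact:
        p = exceed / n_perm  # identity assignment is one of the enumerated
    else:
        p = (1.0 + exceed) / (1.0 + n_perm)
    base.p = p
    base.t_perm = t_perm
    base.n_permutations = n_perm
    base.scheme = "exact" if exact else scheme
    return base


# ---------------------------------------------------------------------------
# NBS


def _components_from_edges(active: np.ndarray, iu, ju, k) -> list:
    """Connected components (lists of edge positions) of the active-edge graph."""
    parent = list(range(k))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    idx = np.nonzero(active)[0]
    for e in idx:
        ra, rb = find(int(iu[e])), find(int(ju[e]))
        if ra != rb:
            parent[ra] = rb
    comps: dict = {}
    for e in idx:
        comps.setdefault(find(int(iu[e])), []).append(int(e))
    return list(comps.values())


def _max_component_size(active: np.ndarray, iu, ju, k) -> int:
    comps = _components_from_edges(active, iu, ju, k)
    return max((len(c) for c in comps), default=0)


def nbs_correct(
    stats: EdgeStats,
    primary_threshold_p: float = 0.05,
    alpha: float = 0.05,
    direction: str = "two-sided",
) -> NBSResult:
    """Network-based-statistic component correction.

    Edges with permutation p below ``primary_threshold_p`` form a graph on
    the networks (split by effect sign under two-sided testing, so
    increases and decreases form separate components).  Each observed
    component's edge count is compared with the permutation distribution
    of the maximal suprathreshold component size; corrected p-values use
    the add-one estimator.  No suprathreshold edge yields a valid empty
    result.
    """
    if stats.t_perm is None:
        raise ValueError("run permutation_null first: no permutation stream")
    if direction not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown direction {direction!r}")
    t_obs, t_perm = stats.t, stats.t_perm
    if direction == "two-sided":
        s_obs, s_perm = np.abs(t_obs), np.abs(t_perm)
    elif direction == "greater":
        s_obs, s_perm = t_obs, t_perm
    else:
        s_obs, s_perm = -t_obs, -t_perm

    n_perm, n_edges = s_perm.shape
    k = stats.k
    iu, ju = stats.edges[:, 0], stats.edges[:, 1]

    # per-edge exceedance counts against the shared permutation null
    sorted_perm = np.sort(s_perm, axis=0)
    supra_obs = np.empty(n_edges, dtype=bool)
    supra_perm = np.empty((n_perm, n_edges), dtype=bool)
    for e in range(n_edges):
        col = sorted_perm[:, e]
        c_obs = n_perm - np.searchsorted(col, s_obs[e] - _TIE_TOL, side="left")
        supra_obs[e] = (1.0 + c_obs) / (1.0 + n_perm) < primary_threshold_p
        c_perm = n_perm - np.searchsorted(col, s_perm[:, e] - _TIE_TOL, side="left")
        supra_perm[:, e] = c_perm / n_perm < primary_threshold_p

    def split_by_sign(active, tvals):
        if direction == "two-sided":
            return [active & (tvals > 0), active & (tvals < 0)]
        return [active]

    null_max = np.empty(n_perm, dtype=int)
    for p_i in range(n_perm):
        null_max[p_i] = max(
            _max_component_size(a, iu, ju, k)
            for a in split_by_sign(supra_perm[p_i], t_perm[p_i])
        )

    components, sizes, signs, corrected = [], [], [], []
    sign_values = (1, -1) if direction == "two-sided" else ((1,) if direction == "greater" else (-1,))
    for active, sgn in zip(split_by_sign(supra_obs, t_obs), sign_values):
        for comp in _components_from_edges(active, iu, ju, k):
            size = len(comp)
            p_corr = (1.0 + (null_max >= size).sum()) / (1.0 + n_perm)
            components.append([(int(iu[e]), int(ju[e])) for e in comp])
            sizes.append(size)
            signs.append(sgn)
            corrected.append(float(p_corr))
    return NBSResult(
        components=components,
        component_size=sizes,
        component_sign=signs,
        corrected_p=corrected,
        primary_threshold=primary_threshold_p,
        alpha=alpha,
        n_permutations=n_perm,
        direction=direction,
        null_max_size=null_max,
    )


# ---------------------------------------------------------------------------
# demographics from summary statistics


def t_test_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample Student t from printed summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("negative SD")
    df = n1 + n2 - 2
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, df, 1.0  # degenerate: identical constants
        return float(np.inf) * np.sign(mean1 - mean2), df, 0.0
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.statistic), df, float(res.pvalue)


def chi_square_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table (continuity correction optional)."""
    table = np.array([[a, b], [c, d]], dtype=np.float64)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in 2x2 table")
    res = sps.chi2_contingency(table, correction=yates)
    return float(res.statistic), float(res.pvalue)
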