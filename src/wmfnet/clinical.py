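"""Association between altered FC edges and clinical scores.

Patient-group partial correlations (controlling age, gender, education and
mean FD) between each tested edge's Fisher-z connectivity and each clinical
score, with Benjamini–Hochberg FDR control pooled across all tested
(edge, score) pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["partial_correlation", "fdr_bh", "associate"]


def _residualize(v: np.ndarray, design: np.ndarray, name: str) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    res = v - design @ beta
    if np.allclose(res, 0) or res.std() == 0:
        raise ValueError(f"zero-variance residual for {name!r}")
    return res


def partial_correlation(
    x, y, covariates: pd.DataFrame | np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson correlation of x and y after removing shared covariates.

    Both variables are residualised on [intercept | covariates]; the
    p-value uses t = r sqrt(df / (1 - r^2)) with df = n - q - 2 where q is
    the covariate count.  With no covariates this reduces to the plain
    Pearson correlation and its p-value.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y lengths differ")
    n = len(x)
    if covariates is None:
        c = np.empty((n, 0))
    else:
        c = np.asarray(covariates, dtype=np.float64)
        c = c.reshape(n, -1)
    q = c.shape[1]
    if n <= q + 2:
        raise ValueError(f"need n > q + 2 (n={n}, q={q})")
    design = np.column_stack([np.ones(n), c])
    rx = _residualize(x, design, "x")
    ry = _residualize(y, design, "y")
    r = float(np.clip(np.corrcoef(rx, ry)[0, 1], -1.0, 1.0))
    df = n - q - 2
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


def fdr_bh(p_values, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: adjusted q-values and rejection flags."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    reject, q, *_ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, reject


def associate(
    edge_values: pd.DataFrame,
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    q_level: float = 0.05,
) -> pd.DataFrame:
    """Partial correlation of every edge column with every score column.

    ``edge_values`` columns are edge names (one row per patient), ``scores``
    the clinical outcome columns, ``covariates`` the numeric control
    variables.  FDR is pooled across all (edge, score) pairs.  Returns a
    tidy frame: edge, score, partial_r, p, q, significant.
    """
    if not (len(edge_values) == len(scores) == len(covariates)):
        raise ValueError("row counts of edges, scores and covariates differ")
    rows = []
    for edge in edge_values.columns:
        for score in scores.columns:
            r, p = partial_correlation(
                edge_values[edge].to_numpy(),
                scores[score].to_numpy(),
                covariates.to_numpy(dtype=np.float64),
            )
            rows.append({"edge": edge, "score": score, "partial_r": r, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        q, flags = fdr_bh(out["p"].to_numpy(), q_level)
        out["q"] = q
        out["significant"] = flags
    return out
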