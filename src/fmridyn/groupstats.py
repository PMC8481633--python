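"""Group statistics: voxel-wise GLM contrasts with permutation cluster
correction, scalar ANCOVA, summary-statistic tests, partial correlations.

Voxel-wise group differences are tested with an OLS GLM (intercept +
group indicator + optional covariates); multiple comparisons are handled
by a max-cluster-extent permutation test: supra-threshold voxels (|t|
above the two-tailed cluster-forming threshold) are grouped into
26-connected clusters and each observed cluster's extent is compared to
the permutation distribution of the largest |t|-cluster extent. With
covariates present the Freedman-Lane scheme permutes reduced-model
residuals so the covariate effects are held fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import ndimage, stats
from scipy.stats import rankdata

logger = logging.getLogger("fmridyn")

CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class GroupSummary:
    """n, mean, sd for one group (as printed in a demographics table)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class StatMap:
    """Voxel-wise t map plus cluster-level inference results."""

    tmap: np.ndarray  # 3D, NaN outside mask
    df: int
    mask: np.ndarray
    cluster_labels: np.ndarray | None = None  # 3D int, 0 = background
    clusters: list = field(default_factory=list)  # dicts per cluster
    threshold: float | None = None


def _design(groups: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    groups = np.asarray(groups, dtype=float).reshape(-1)
    cols = [np.ones_like(groups), groups]
    if covariates is not None:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != groups.size:
            Z = Z.T
        cols.extend(Z.T)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates in group design")
    return X


def _group_t(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, int]:
    """t statistic for the group column (index 1) of X, vectorized over
    the columns of Y (N x V)."""
    N, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    beta = H @ Y
    resid = Y - X @ beta
    df = N - p
    sigma2 = (resid**2).sum(axis=0) / df
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[1] / np.sqrt(XtX_inv[1, 1] * sigma2)
    return t, df


def glm_tmap(
    maps: np.ndarray,
    groups: np.ndarray,
    mask: np.ndarray,
    covariates: np.ndarray | None = None,
) -> StatMap:
    """Voxel-wise group-difference t map from stacked subject maps.

    maps: (N, x, y, z) per-subject 3D maps; groups: length-N 0/1 indicator
    (1 = patient); covariates: optional (N, k). Voxels with any NaN across
    subjects are NaN in the output.
    """
    maps = np.asarray(maps, dtype=float)
    groups = np.asarray(groups)
    if maps.shape[0] != groups.size:
        raise ValueError("number of maps does not match number of group labels")
    if len(np.unique(groups)) != 2:
        raise ValueError("need exactly two groups")
    if min(np.bincount(groups.astype(int))) < 2:
        raise ValueError("both groups need at least 2 subjects")
    X = _design(groups, covariates)
    Y = maps[:, mask]
    good = np.isfinite(Y).all(axis=0)
    t = np.full(Y.shape[1], np.nan)
    t[good], df = _group_t(X, Y[:, good])
    tmap = np.full(mask.shape, np.nan)
    tmap[mask] = t
    return StatMap(tmap=tmap, df=df, mask=mask)


def _cluster_stats(
    abs_t: np.ndarray, thr: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label 26-connected |t|-supra-threshold voxels.

    Returns (labels, sizes, stat) where stat is the cluster extent with
    ties broken by supra-threshold mass: size + m/(1+m), m = sum(|t|-thr).
    Extent remains the primary ordering (the tie-break term is < 1); the
    continuous refinement removes the heavy ties an integer extent
    produces on small grids, keeping the permutation test exact rather
    than conservative.
    """
    supra = abs_t > thr
    labels, n = ndimage.label(supra, structure=CONNECTIVITY_26)
    if n == 0:
        z = np.zeros(0)
        return labels, z.astype(int), z
    sizes = np.bincount(labels.ravel())[1:]
    mass = np.bincount(labels.ravel(), weights=np.where(supra, abs_t - thr, 0.0).ravel())[1:]
    stat = sizes + mass / (1.0 + mass)
    return labels, sizes, stat


def permutation_cluster_correct(
    statmap: StatMap,
    maps: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    cluster_forming_p: float = 0.001,
    n_perm: int = 1000,
    seed: int = 0,
) -> StatMap:
    """Max-cluster-extent permutation correction of a voxel-wise t map.

    Two-tailed: the cluster-forming threshold is |t| > t_{df}(1 - p/2) and
    positive/negative clusters are pooled against a single null of the
    largest |t|-cluster extent per permutation. Cluster p-values use the
    add-one estimator (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    groups = np.asarray(groups).astype(int)
    mask = statmap.mask
    thr = stats.t.ppf(1.0 - cluster_forming_p / 2.0, statmap.df)
    n1 = int(groups.sum())
    n_distinct = comb(groups.size, n1)
    if n_perm >= n_distinct:
        logger.warning(
            "requested %d permutations but only %d distinct labelings exist",
            n_perm,
            n_distinct,
        )

    abs_t = np.abs(np.nan_to_num(statmap.tmap, nan=0.0))
    abs_t[~mask] = 0.0
    labels, sizes, stat_obs = _cluster_stats(abs_t, thr)

    # Freedman-Lane: permute residuals of the reduced (no-group) model
    X = _design(groups, covariates)
    Y = maps[:, mask]
    good = np.isfinite(Y).all(axis=0)
    Yg = Y[:, good]
    Z = np.delete(X, 1, axis=1)
    gamma = np.linalg.lstsq(Z, Yg, rcond=None)[0]
    fitted = Z @ gamma
    resid = Yg - fitted
    N = groups.size

    flat_mask_good = np.zeros(mask.shape, dtype=bool)
    mm = np.zeros(int(mask.sum()), dtype=bool)
    mm[good] = True
    flat_mask_good[mask] = mm

    null_max = np.empty(n_perm)
    tvol = np.zeros(mask.shape)
    for b in range(n_perm):
        perm = rng.permutation(N)
        t_b, _ = _group_t(X, fitted + resid[perm])
        tvol[:] = 0.0
        tvol[flat_mask_good] = np.nan_to_num(t_b, nan=0.0)
        _, _, st = _cluster_stats(np.abs(tvol), thr)
        null_max[b] = st.max() if st.size else 0.0
    clusters = []
    for lab, size in enumerate(sizes, start=1):
        in_cluster = labels == lab
        tv = statmap.tmap[in_cluster]
        peak = tv[np.nanargmax(np.abs(tv))]
        p = (1.0 + (null_max >= stat_obs[lab - 1]).sum()) / (1.0 + n_perm)
        peak_idx = np.argwhere(in_cluster)[np.nanargmax(np.abs(tv))]
        clusters.append(
            {
                "label": lab,
                "size": int(size),
                "peak_t": float(peak),
                "peak_index": tuple(int(i) for i in peak_idx),
                "sign": int(np.sign(peak)),
                "p": float(p),
            }
        )
    return StatMap(
        tmap=statmap.tmap,
        df=statmap.df,
        mask=mask,
        cluster_labels=labels,
        clusters=clusters,
        threshold=float(thr),
    )


def summary_t_pooled(a: GroupSummary, b: GroupSummary) -> tuple[float, int]:
    """Equal-variance two-sample t from printed group summaries."""
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if sp2 == 0:
        return 0.0, df
    se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    return float((a.mean - b.mean) / se), df


def summary_t_welch(a: GroupSummary, b: GroupSummary) -> tuple[float, float]:
    """Unequal-variance (Welch) t with Satterthwaite df."""
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    se2 = va + vb
    if se2 == 0:
        return 0.0, float(a.n + b.n - 2)
    t = (a.mean - b.mean) / np.sqrt(se2)
    df = se2**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(t), float(df)


def pearson_chi2_2x2(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square (no continuity correction) for a 2x2 table."""
    O = np.asarray(table, dtype=float)
    if O.shape != (2, 2) or (O < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    rows, cols, N = O.sum(axis=1), O.sum(axis=0), O.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero marginal in contingency table")
    E = np.outer(rows, cols) / N
    return float(((O - E) ** 2 / E).sum()), 1


def ancova_scalar(
    values: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
) -> dict:
    """Group-effect test on a per-subject scalar, adjusting for covariates.

    Same GLM as the voxel-wise map test applied to a single 'voxel';
    returns t, F = t^2, df and the two-tailed p for the group term.
    """
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    X = _design(groups, covariates)
    if min(np.bincount(np.asarray(groups).astype(int))) < 2:
        raise ValueError("both groups need at least 2 subjects")
    t, df = _group_t(X, values)
    t = float(t[0])
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": t, "F": t**2, "df": df, "p": float(p)}


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    method: str = "pearson",
) -> tuple[float, float]:
    """Partial correlation of x and y controlling for covariates.

    Both variables are residualized on the covariates (plus intercept);
    for Spearman, values are rank-transformed first. p comes from
    t = r sqrt((n - 2 - k) / (1 - r^2)) on n - 2 - k df.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if covariates is None:
        Z = np.ones((n, 1))
        k = 0
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        k = C.shape[1]
        Z = np.column_stack([np.ones(n), C])
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    if method == "spearman":
        x, y = rankdata(x), rankdata(y)
        Z = np.column_stack([Z[:, :1]] + [rankdata(Z[:, j]) for j in range(1, Z.shape[1])])
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom == 0:
        raise ValueError("zero residual variance; correlation undefined")
    r = float(np.clip(rx @ ry / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)
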