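"""Permutation-ecology statistics for chronosequence analysis.

Implements the battery applied to the forefield datasets: Shannon and
inverse-Simpson diversity, LOWESS trend fitting, Bray-Curtis/Euclidean
distance matrices, one-way PERMANOVA, the Mantel test, permutation Spearman
correlation, ordinary least squares for same-unit variable pairs, PCA, the
11 ice-edge distance bins, and the GO-category correlation screen.

Conventions shared by every permutation test:

* p-values use the add-one rule, p = (1 + #extreme) / (1 + n_perm), so
  p >= 1/(n_perm + 1) always;
* significance is strict, p < 0.05;
* a seed fixes the permutation stream bit-for-bit.

Shannon entropy is in nats.  PERMANOVA partitions squared inter-point
distances: with SS_total = sum_{i<j} d_ij^2 / n and SS_within summed over
groups, R^2 = 1 - SS_within/SS_total and
pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

ALPHA = 0.05
DEFAULT_N_PERM = 9999

# Ice-edge distance bins as printed in the study design.  Intervals are
# half-open [lo, hi); the printed scheme leaves no samples between 4,000 and
# 10,000 m, so the "2,000-4,000" bin absorbs that range to keep the bins a
# partition of [0, inf).
DISTANCE_BINS: List[Tuple[str, float, float]] = [
    ("0-50", 0.0, 50.0),
    ("50-150", 50.0, 150.0),
    ("150-250", 150.0, 250.0),
    ("250-350", 250.0, 350.0),
    ("350-500", 350.0, 500.0),
    ("500-750", 500.0, 750.0),
    ("750-1,000", 750.0, 1000.0),
    ("1,000-1,250", 1000.0, 1250.0),
    ("1,250-2,000", 1250.0, 2000.0),
    ("2,000-4,000", 2000.0, 10000.0),
    (">10,000", 10000.0, float("inf")),
]

BIN_LABELS = [b[0] for b in DISTANCE_BINS]


@dataclass(frozen=True)
class PermanovaResult:
    r2: float
    pseudo_f: float
    p: float
    n_perm: int
    seed: Optional[int]


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str
    seed: Optional[int]


@dataclass(frozen=True)
class CorrelationResult:
    rs: float
    p: float
    n_perm: int
    seed: Optional[int]


@dataclass(frozen=True)
class LinearModelResult:
    slope: float
    intercept: float
    r2: float
    p: float


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def _normalize(row: Sequence[float]) -> np.ndarray:
    x = np.asarray(row, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundance vector has negative entries")
    total = x.sum()
    if total <= 0:
        raise ValueError("abundance vector sums to zero")
    return x / total


def shannon(row: Sequence[float]) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats)."""
    p = _normalize(row)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def inverse_simpson(row: Sequence[float]) -> float:
    """Inverse Simpson 1/D = 1 / sum p_i^2 (effective number of taxa)."""
    p = _normalize(row)
    return float(1.0 / (p**2).sum())


def diversity_table(abundance: pd.DataFrame) -> pd.DataFrame:
    """Per-sample H and 1/D for a sample x taxon abundance matrix."""
    rows = {}
    for sample, row in abundance.iterrows():
        rows[sample] = {"shannon": shannon(row.values), "inv_simpson": inverse_simpson(row.values)}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Trend fitting
# ---------------------------------------------------------------------------

def lowess_trend(
    x: Sequence[float], y: Sequence[float], span: float = 2.0 / 3.0, iters: int = 1
) -> np.ndarray:
    """Tricube-weighted local linear fit evaluated at the input x.

    ``span`` is the fraction of points in each local window; ``iters``
    robustness iterations.  Deterministic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("lowess needs at least 3 points")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    fitted = _sm_lowess(y, x, frac=span, it=iters, return_sorted=False)
    return np.asarray(fitted, dtype=float)


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

def bray_curtis(matrix: Union[pd.DataFrame, np.ndarray]) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity (samples as rows).

    BC(i,j) = sum|x_ik - x_jk| / sum(x_ik + x_jk); a pair of all-zero rows
    has dissimilarity 0 by convention.
    """
    x = np.asarray(matrix, dtype=float)
    if np.any(x < 0):
        raise ValueError("Bray-Curtis requires non-negative entries")
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    return np.nan_to_num(d, nan=0.0)


def euclidean(matrix: Union[pd.DataFrame, np.ndarray]) -> np.ndarray:
    return squareform(pdist(np.asarray(matrix, dtype=float), metric="euclidean"))


def _check_square(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """SS_within for integer group codes on the squared-distance matrix."""
    ss_w = 0.0
    for g in range(n_groups):
        m = codes == g
        n_g = int(m.sum())
        if n_g > 1:
            ss_w += d2[np.ix_(m, m)].sum() / (2.0 * n_g)
    return ss_w


def permanova(
    dist: np.ndarray,
    groups: Sequence,
    n_perm: int = DEFAULT_N_PERM,
    seed: Optional[int] = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix with label permutation.

    ``groups`` is a factor with >= 2 levels; the test statistic is the
    pseudo-F ratio, and the p-value counts permuted F >= observed with the
    add-one rule.
    """
    d = _check_square(dist)
    labels = np.asarray(groups)
    n = d.shape[0]
    if len(labels) != n:
        raise ValueError("groups length must match distance matrix size")
    levels, codes = np.unique(labels, return_inverse=True)
    a = len(levels)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 group levels")
    d2 = d**2
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _permanova_ss(d2, codes, a)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        pseudo_f = np.inf
        r2 = 1.0
    else:
        pseudo_f = (ss_between / (a - 1)) / (ss_within / (n - a))
        r2 = 1.0 - ss_within / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm_codes = rng.permutation(codes)
        ss_w_p = _permanova_ss(d2, perm_codes, a)
        if ss_w_p <= 0:
            f_p = np.inf
        else:
            f_p = ((ss_total - ss_w_p) / (a - 1)) / (ss_w_p / (n - a))
        if f_p >= pseudo_f:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(float(r2), float(pseudo_f), float(p), n_perm, seed)


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def _offdiag_lower(d: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(d.shape[0], k=-1)
    return d[i, j]


def mantel(
    d1: np.ndarray,
    d2: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    method: str = "pearson",
    seed: Optional[int] = None,
    exact: bool = False,
) -> MantelResult:
    """Mantel test: correlation of two distance matrices' lower triangles.

    The p-value permutes rows/columns of ``d2`` simultaneously and is
    one-sided greater (the vegan convention).  ``method`` is "pearson"
    (default) or "spearman".  ``exact=True`` enumerates all n! permutations
    (small n only); the identity permutation is then included in the count,
    so p = #{r_perm >= r_obs} / n!.
    """
    a = _check_square(d1)
    b = _check_square(d2)
    if a.shape != b.shape:
        raise ValueError("distance matrices differ in size")
    n = a.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    v1 = _offdiag_lower(a)
    v2 = _offdiag_lower(b)
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("constant lower triangle: correlation undefined")

    if method == "pearson":
        def corr(x, y):
            return float(np.corrcoef(x, y)[0, 1])
    elif method == "spearman":
        def corr(x, y):
            return float(stats.spearmanr(x, y).statistic)
    else:
        raise ValueError(f"unknown correlation method {method!r}")

    r_obs = corr(v1, v2)
    if exact:
        from itertools import permutations

        count = 0
        total = 0
        for perm in permutations(range(n)):
            bp = b[np.ix_(perm, perm)]
            if corr(v1, _offdiag_lower(bp)) >= r_obs - 1e-12:
                count += 1
            total += 1
        return MantelResult(float(r_obs), count / total, total, method, seed)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)]
        if corr(v1, _offdiag_lower(bp)) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(float(r_obs), float(p), n_perm, method, seed)


# ---------------------------------------------------------------------------
# Permutation Spearman
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_perm(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = DEFAULT_N_PERM,
    seed: Optional[int] = None,
    exact: bool = False,
) -> CorrelationResult:
    """Spearman rank correlation with a two-sided permutation p-value.

    rs is Pearson correlation of midranks (average ranks on ties); the
    permutation p compares |rs| of y-permutations against |rs_obs|.
    ``exact=True`` enumerates all n! permutations (identity included):
    p = #{|rs_perm| >= |rs_obs|} / n!.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman undefined")
    rx = _midranks(x)
    ry = _midranks(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    rs_obs = float((rxc * ryc).sum() / denom)

    if exact:
        from itertools import permutations

        count = 0
        total = 0
        for perm in permutations(range(len(ryc))):
            rp = float((ryc[list(perm)] * rxc).sum() / denom)
            if abs(rp) >= abs(rs_obs) - 1e-12:
                count += 1
            total += 1
        return CorrelationResult(rs_obs, count / total, total, seed)

    rng = np.random.default_rng(seed)
    # vectorized: permute the centered y-ranks, correlate against x-ranks
    count = 0
    block = 2000
    done = 0
    while done < n_perm:
        k = min(block, n_perm - done)
        perms = np.array([rng.permutation(len(ryc)) for _ in range(k)])
        rp = (ryc[perms] @ rxc) / denom
        count += int((np.abs(rp) >= abs(rs_obs) - 1e-12).sum())
        done += k
    p = (1 + count) / (1 + n_perm)
    return CorrelationResult(rs_obs, float(p), n_perm, seed)


# ---------------------------------------------------------------------------
# Linear model, PCA
# ---------------------------------------------------------------------------

def linear_fit(x: Sequence[float], y: Sequence[float]) -> LinearModelResult:
    """Ordinary least squares of y on x, with slope t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant x: slope undefined")
    res = stats.linregress(x, y)
    return LinearModelResult(
        float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)
    )


def pca(matrix: Union[pd.DataFrame, np.ndarray]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-centered PCA via eigendecomposition of the covariance matrix.

    Returns (scores, loadings, variance_explained); components are ordered by
    decreasing eigenvalue and signed so the largest-magnitude loading of each
    component is positive.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    xc = x - x.mean(axis=0)
    cov = np.cov(xc, rowvar=False)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    for k in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] *= -1
    scores = xc @ evecs
    total = evals.sum()
    varexp = evals / total if total > 0 else np.zeros_like(evals)
    return scores, evecs, varexp


# ---------------------------------------------------------------------------
# Distance bins
# ---------------------------------------------------------------------------

def bin_distance(distance_m: float) -> str:
    """Label of the ice-edge distance bin containing ``distance_m``."""
    if distance_m < 0:
        raise ValueError("distance must be >= 0")
    for label, lo, hi in DISTANCE_BINS:
        if lo <= distance_m < hi:
            return label
    return BIN_LABELS[-1]  # unreachable: bins tile [0, inf)


def bin_midpoint(label: str) -> float:
    """Representative midpoint for ordering bins along the succession."""
    for lab, lo, hi in DISTANCE_BINS:
        if lab == label:
            return lo + 1000.0 if hi == float("inf") else (lo + hi) / 2.0
    raise KeyError(f"unknown bin label {label!r}")


# ---------------------------------------------------------------------------
# GO screening
# ---------------------------------------------------------------------------

def screen_go_correlations(
    go_matrix: pd.DataFrame,
    covariate: Sequence[float],
    r_threshold: float = 0.4,
    alpha: float = ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Spearman-screen every GO category against one covariate.

    Keeps categories with p < alpha and |rs| strictly greater than
    ``r_threshold``; returns a table (go_id, rs, p, sign) sorted by |rs|
    descending.  Constant columns are skipped (logged), not errors.
    """
    import logging

    logger = logging.getLogger(__name__)
    cov = np.asarray(covariate, dtype=float)
    if len(cov) != go_matrix.shape[0]:
        raise ValueError("covariate length must match number of samples")
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    child_seeds = ss.spawn(go_matrix.shape[1])
    rows = []
    for j, go_id in enumerate(go_matrix.columns):
        col = go_matrix.iloc[:, j].values
        if np.ptp(col) == 0:
            logger.info("GO column %s constant; skipped", go_id)
            continue
        res = spearman_perm(
            cov, col, n_perm=n_perm, seed=int(child_seeds[j].generate_state(1)[0] % (2**31))
        )
        if res.p < alpha and abs(res.rs) > r_threshold:
            rows.append(
                {"go_id": go_id, "rs": res.rs, "p": res.p, "sign": "+" if res.rs > 0 else "-"}
            )
    df = pd.DataFrame(rows, columns=["go_id", "rs", "p", "sign"])
    if len(df):
        df = df.reindex(df["rs"].abs().sort_values(ascending=False).index).reset_index(drop=True)
    return df
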