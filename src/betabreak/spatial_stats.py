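"""Correlation and rank tests for spatially structured regional data.

Regional summaries along a geographic gradient violate the independence
assumption behind the textbook test of a Pearson correlation: positive
spatial autocorrelation makes n observations carry fewer than n independent
pieces of information, so the naive test is anticonservative.  The modified
t-test implemented here keeps the correlation coefficient untouched and
replaces n by an *effective sample size* M̂ estimated from the spatial
autocorrelation of both variables:

1. great-circle (haversine) distances between region centroids;
2. equal-frequency distance classes (10 by default);
3. a Moran-type autocorrelation estimate per class and per variable;
4. autocorrelation matrices A and B filled with the class estimates
   (diagonal 1) and, with the centering projector H = I − 11ᵀ/n,

       v  = tr(HAHB) / (tr(HA) · tr(HB)),      M̂ = 1 + 1/v;

5. t = r·sqrt((M̂ − 2)/(1 − r²)) referred to a t distribution with
   (possibly non-integer) M̂ − 2 degrees of freedom.

In the i.i.d. limit the class estimates vanish, A ≈ B ≈ I and M̂ → n, so the
test reduces to the classical one.  Spearman and Mann-Whitney helpers wrap
scipy with the mid-rank / exact-enumeration conventions stated in their
docstrings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationResult",
    "haversine_matrix",
    "dutilleul_correlation",
    "spearman",
    "mann_whitney",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    m_hat: float        # effective sample size
    t: float
    p_value: float
    n: int
    n_classes: int
    p_naive: float      # classical test with n-2 df, for comparison
    valid: bool = True  # False when m_hat <= 2 leaves the test undefined


def haversine_matrix(coords) -> np.ndarray:
    """Pairwise great-circle distances (km) between (lat, lon) points in degrees."""
    coords = np.asarray(coords, dtype=float)
    lat = np.radians(coords[:, 0])[:, None]
    lon = np.radians(coords[:, 1])[:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def distance_class_matrix(dist: np.ndarray, n_classes: int = 10) -> np.ndarray:
    """Assign each off-diagonal pair to one of ``n_classes`` equal-frequency
    distance classes; returns an integer matrix (diagonal = -1)."""
    n = dist.shape[0]
    iu = np.triu_indices(n, k=1)
    pair_d = dist[iu]
    edges = np.quantile(pair_d, np.linspace(0.0, 1.0, n_classes + 1)[1:-1])
    labels = np.searchsorted(edges, pair_d, side="left")
    cls = np.full((n, n), -1, dtype=int)
    cls[iu] = labels
    cls.T[iu] = labels
    return cls


def _moran_by_class(z: np.ndarray, cls: np.ndarray, n_classes: int) -> np.ndarray:
    """Moran's I of centred variable ``z`` for each distance class."""
    n = z.size
    zc = z - z.mean()
    denom = float(zc @ zc)
    out = np.zeros(n_classes)
    for k in range(n_classes):
        w = cls == k
        s0 = w.sum()  # both orientations counted
        if s0 == 0 or denom == 0.0:
            out[k] = 0.0
            continue
        out[k] = (n / s0) * float(zc @ (w @ zc)) / denom
    return out


def _autocorr_matrix(corr_by_class: np.ndarray, cls: np.ndarray) -> np.ndarray:
    a = np.where(cls >= 0, corr_by_class[np.clip(cls, 0, None)], 0.0)
    np.fill_diagonal(a, 1.0)
    return a


def dutilleul_correlation(x, y, coords, n_classes: int = 10) -> CorrelationResult:
    """Pearson correlation with a modified t-test for spatial autocorrelation.

    Parameters
    ----------
    x, y : 1-d arrays of equal length (n >= 10)
    coords : (n, 2) array of (lat, lon) centroids in degrees
    n_classes : number of equal-frequency distance classes

    The correlation coefficient is the ordinary Pearson r; only its test
    changes.  ``valid`` is False when the estimated effective sample size
    drops to M̂ <= 2, in which case no p-value is defined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = x.size
    if y.size != n or coords.shape != (n, 2):
        raise ValueError("x, y and coords must agree in length")
    if n < 10:
        raise ValueError("need at least 10 observations")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("constant variable has no defined correlation")

    r = float(np.corrcoef(x, y)[0, 1])
    t_naive = r * np.sqrt((n - 2) / max(1e-300, 1.0 - r * r))
    p_naive = float(2.0 * stats.t.sf(abs(t_naive), n - 2))

    dist = haversine_matrix(coords)
    cls = distance_class_matrix(dist, n_classes)
    a = _autocorr_matrix(_moran_by_class(x, cls, n_classes), cls)
    b = _autocorr_matrix(_moran_by_class(y, cls, n_classes), cls)

    h = np.eye(n) - np.full((n, n), 1.0 / n)
    ha = h @ a
    hb = h @ b
    v = float(np.trace(ha @ h @ hb)) / (float(np.trace(ha)) * float(np.trace(hb)))
    m_hat = 1.0 + 1.0 / v
    if m_hat <= 2.0:
        return CorrelationResult(r, m_hat, np.nan, np.nan, n, n_classes, p_naive, valid=False)
    if abs(r) >= 1.0:
        return CorrelationResult(r, m_hat, np.inf, 0.0, n, n_classes, p_naive)
    t_stat = r * np.sqrt((m_hat - 2.0) / (1.0 - r * r))
    p_value = float(2.0 * stats.t.sf(abs(t_stat), m_hat - 2.0))
    return CorrelationResult(r, m_hat, float(t_stat), p_value, n, n_classes, p_naive)


def spearman(x, y):
    """Spearman rank correlation with mid-ranks for ties.

    The p-value uses the t approximation with n − 2 degrees of freedom
    (two-sided).  Requires n >= 4 and non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need two aligned samples with n >= 4")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("constant input: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def mann_whitney(a, b):
    """Two-sided Mann-Whitney U test, reporting U = min(U_a, U_b).

    Mid-ranks are used for ties, so U may be half-integer.  The p-value is
    the exact enumeration when n1·n2 <= 400 and the pooled data has no ties,
    and otherwise the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    u_a = float(res.statistic)
    u = min(u_a, a.size * b.size - u_a)
    return u, float(res.pvalue)
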