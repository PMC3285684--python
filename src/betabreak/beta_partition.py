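"""Sørensen-family partition of beta diversity into turnover and nestedness.

Presence/absence dissimilarity between sites can arise from two antithetical
phenomena: *spatial turnover* (species replace each other between sites) and
*nestedness* (poorer sites hold subsets of the species of richer sites).
Because Simpson dissimilarity is insensitive to richness differences, the
difference between Sørensen and Simpson dissimilarity isolates the
nestedness-resultant component:

    beta_SOR = beta_SIM + beta_NES

Both pairwise and multiple-site versions are provided.  The multiple-site
formulas operate on a binary sites × species matrix with

    P      = sum_i S_i − S_T           (richness surplus over the pooled pool)
    Σmin   = sum_{i<j} min(b_ij, b_ji)
    Σmax   = sum_{i<j} max(b_ij, b_ji)

where ``S_i`` is the richness of site i, ``S_T`` the pooled richness and
``b_ij`` the number of species present in site i but not in site j.  Then

    beta_SIM = Σmin / (P + Σmin)
    beta_SOR = (Σmin + Σmax) / (2·P + Σmin + Σmax)
    beta_NES = beta_SOR − beta_SIM

``resampled_beta`` standardizes for unequal site numbers by averaging the
multiple-site triple over repeated subsamples of a fixed number of sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BetaTriple", "pairwise_beta", "multisite_beta", "resampled_beta"]


@dataclass(frozen=True)
class BetaTriple:
    """Additive partition of Sørensen dissimilarity (all in [0, 1])."""

    beta_sor: float
    beta_sim: float
    beta_nes: float

    def __iter__(self):
        return iter((self.beta_sor, self.beta_sim, self.beta_nes))


def _as_binary_matrix(matrix) -> np.ndarray:
    mat = np.asarray(matrix)
    if mat.ndim != 2:
        raise ValueError("site matrix must be 2-dimensional (sites x species)")
    if mat.dtype != bool:
        vals = np.unique(mat)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("site matrix must be binary (0/1 presence/absence)")
        mat = mat.astype(bool)
    return mat


def pairwise_beta(site_a, site_b) -> BetaTriple:
    """Partition the Sørensen dissimilarity between two sites.

    Parameters
    ----------
    site_a, site_b : array-like of 0/1
        Presence/absence vectors over the same species list.  Both sites must
        be non-empty; an empty site leaves the Simpson denominator undefined.
    """
    a_vec = _as_binary_matrix(np.atleast_2d(site_a))[0]
    b_vec = _as_binary_matrix(np.atleast_2d(site_b))[0]
    if a_vec.shape != b_vec.shape:
        raise ValueError("sites must share one species list")
    if not a_vec.any() or not b_vec.any():
        raise ValueError("pairwise_beta requires two non-empty sites")
    shared = int(np.count_nonzero(a_vec & b_vec))
    only_a = int(np.count_nonzero(a_vec & ~b_vec))
    only_b = int(np.count_nonzero(b_vec & ~a_vec))
    if only_a == 0 and only_b == 0:
        return BetaTriple(0.0, 0.0, 0.0)
    m = min(only_a, only_b)
    beta_sor = (only_a + only_b) / (2 * shared + only_a + only_b)
    beta_sim = m / (shared + m)
    return BetaTriple(beta_sor, beta_sim, beta_sor - beta_sim)


def multisite_beta(matrix) -> BetaTriple:
    """Multiple-site Sørensen dissimilarity and its partition.

    Parameters
    ----------
    matrix : array-like, shape (n_sites, n_species)
        Binary presence/absence matrix; needs at least two sites, none of
        them empty.

    Notes
    -----
    Reduces exactly to :func:`pairwise_beta` at ``n_sites == 2``.  When all
    sites are identical every dissimilarity is 0 by convention (the defining
    ratios are 0/0 in that limit).
    """
    mat = _as_binary_matrix(matrix)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("multisite_beta needs at least two sites")
    richness = mat.sum(axis=1)
    if (richness == 0).any():
        empty = np.flatnonzero(richness == 0)
        raise ValueError(f"empty sites not allowed (row indices {empty.tolist()}); drop them first")
    pooled = int((mat.any(axis=0)).sum())
    surplus = int(richness.sum()) - pooled  # P

    shared = (mat.astype(np.int64) @ mat.astype(np.int64).T)
    excl = richness[:, None] - shared  # b_ij: in i, not in j
    iu = np.triu_indices(n, k=1)
    bmin = np.minimum(excl, excl.T)[iu].sum()
    bmax = np.maximum(excl, excl.T)[iu].sum()

    sim_den = surplus + bmin
    sor_den = 2 * surplus + bmin + bmax
    beta_sim = float(bmin / sim_den) if sim_den else 0.0
    beta_sor = float((bmin + bmax) / sor_den) if sor_den else 0.0
    return BetaTriple(beta_sor, beta_sim, beta_sor - beta_sim)


def resampled_beta(matrix, k: int = 15, reps: int = 10, seed=None) -> BetaTriple:
    """Average multiple-site partition over subsamples of ``k`` sites.

    Differences in the number of available sites are controlled for by
    drawing ``k`` sites without replacement ``reps`` times and averaging the
    resulting triples; additivity survives the averaging.  Species absent
    from every drawn site simply do not contribute.

    ``seed`` accepts anything :func:`numpy.random.default_rng` does,
    including an existing Generator (used by the pipeline to give each
    region its own stream).
    """
    mat = _as_binary_matrix(matrix)
    n = mat.shape[0]
    if k < 2:
        raise ValueError("k must be at least 2 sites")
    if n < k:
        raise ValueError(
            f"region has {n} usable sites but k={k}; filter regions to >= k non-empty sites first"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    triples = np.empty((reps, 3))
    for r in range(reps):
        idx = rng.choice(n, size=k, replace=False)
        triples[r] = tuple(multisite_beta(mat[idx]))
    sor, sim, nes = triples.mean(axis=0)
    return BetaTriple(float(sor), float(sim), float(nes))
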