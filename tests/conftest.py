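import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


def random_binary_matrix(rng, n_sites, n_species):
    """Random 0/1 matrix with no empty site and no never-seen species."""
    while True:
        mat = (rng.random((n_sites, n_species)) < 0.45).astype(np.uint8)
        if mat.any(axis=1).all() and mat.any(axis=0).all():
            return mat


def brute_force_multisite(mat):
    """Independent oracle: multiple-site Sørensen partition via explicit
    python set arithmetic (no shared code with the implementation)."""
    sites = [frozenset(np.flatnonzero(row)) for row in np.asarray(mat)]
    pool = frozenset().union(*sites)
    surplus = sum(len(s) for s in sites) - len(pool)
    sum_min = sum_max = 0
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            b_ij = len(sites[i] - sites[j])
            b_ji = len(sites[j] - sites[i])
            sum_min += min(b_ij, b_ji)
            sum_max += max(b_ij, b_ji)
    sim = sum_min / (surplus + sum_min) if surplus + sum_min else 0.0
    sor_den = 2 * surplus + sum_min + sum_max
    sor = (sum_min + sum_max) / sor_den if sor_den else 0.0
    return sor, sim, sor - sim
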