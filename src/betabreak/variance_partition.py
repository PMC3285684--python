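"""Partial-regression partition of explained variation between predictor groups.

The total variation in a response explained jointly by two groups of
predictors A and B decomposes, via three OLS fits, into the fraction each
group explains uniquely and the fraction they share:

    unique_A = R²_{A∪B} − R²_B
    unique_B = R²_{A∪B} − R²_A
    shared   = R²_A + R²_B − R²_{A∪B}

so that unique_A + unique_B + shared = R²_{A∪B} identically.  A shared
fraction can be negative (a suppression effect); it is reported as-is and
flagged, never clamped.  A three-group inclusion–exclusion extension is
provided for Venn-style displays.  All fractions are in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["VariancePartition", "ols_r2", "partition_variation", "partition_variation3"]


@dataclass(frozen=True)
class VariancePartition:
    labels: tuple
    full_r2: float                 # % of variance, joint model
    total_r2: dict                 # % per group, marginal model
    unique: dict                   # % per group, after controlling the rest
    shared: float                  # % jointly explained (may be < 0)
    residual: float                # 100 − full_r2
    negative_shared: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [("Complete model", self.full_r2)]
        for g in self.labels:
            rows.append((g, self.total_r2[g]))
            rows.append((f"{g} Single", self.unique[g]))
        rows.append(("Shared", self.shared))
        rows.append(("Residual", self.residual))
        return pd.DataFrame(rows, columns=["fraction", "pct_var"])


def ols_r2(y, X):
    """Coefficient of determination and coefficients of an OLS fit with intercept.

    Returns ``(r2, coef)`` where ``coef`` starts with the intercept.  Raises
    on rank deficiency, naming the offending columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more observations ({n}) than parameters ({p + 1})")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = []
        for j in range(p):
            sub = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(j)
        raise ValueError(f"rank-deficient design; collinear predictor columns: {bad}")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0.0:
        raise ValueError("constant response")
    r2 = 1.0 - float(resid @ resid) / tss
    return r2, coef


def _projection_r2(y, X) -> float:
    """R² of the least-squares projection of y onto span{1, X}.

    Unlike :func:`ols_r2` this tolerates a rank-deficient design — the fitted
    values are still unique even when the coefficients are not, which is
    exactly the situation when predictor groups overlap."""
    n = y.size
    design = np.column_stack([np.ones(n), X])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0.0:
        raise ValueError("constant response")
    return 1.0 - float(resid @ resid) / tss


def partition_variation(y, X_a, X_b, labels=("A", "B")) -> VariancePartition:
    """Two-group partial-regression variance partition (percent scale).

    Each group must be full rank on its own (``ols_r2`` raises otherwise),
    but the groups may overlap or even duplicate each other — the joint
    R² only needs fitted values, which stay well defined.
    """
    X_a = np.atleast_2d(np.asarray(X_a, dtype=float))
    X_b = np.atleast_2d(np.asarray(X_b, dtype=float))
    y = np.asarray(y, dtype=float)
    if X_a.shape[0] != y.size:
        X_a = X_a.T
    if X_b.shape[0] != y.size:
        X_b = X_b.T
    r2_a, _ = ols_r2(y, X_a)
    r2_b, _ = ols_r2(y, X_b)
    r2_ab = _projection_r2(y, np.column_stack([X_a, X_b]))
    la, lb = labels
    unique_a = r2_ab - r2_b
    unique_b = r2_ab - r2_a
    shared = r2_a + r2_b - r2_ab
    return VariancePartition(
        labels=tuple(labels),
        full_r2=100.0 * r2_ab,
        total_r2={la: 100.0 * r2_a, lb: 100.0 * r2_b},
        unique={la: 100.0 * unique_a, lb: 100.0 * unique_b},
        shared=100.0 * shared,
        residual=100.0 * (1.0 - r2_ab),
        negative_shared=shared < 0.0,
    )


def partition_variation3(y, X_a, X_b, X_c, labels=("A", "B", "C")) -> dict:
    """Three-group inclusion–exclusion partition for Venn-style displays.

    Returns a dict of the seven elementary fractions (percent): the three
    unique fractions, the three pairwise overlaps and the triple overlap,
    plus ``full`` and ``residual``.  Overlap fractions can be negative.
    """
    blocks = []
    y = np.asarray(y, dtype=float)
    for X in (X_a, X_b, X_c):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != y.size:
            X = X.T
        blocks.append(X)
    a, b, c = blocks

    def r2(*mats):
        return _projection_r2(y, np.column_stack(mats))

    r_a, r_b, r_c = ols_r2(y, a)[0], ols_r2(y, b)[0], ols_r2(y, c)[0]
    r_ab, r_ac, r_bc = r2(a, b), r2(a, c), r2(b, c)
    r_abc = r2(a, b, c)
    la, lb, lc = labels
    # pairwise-only overlaps by inclusion-exclusion, e.g. AB-only =
    # R²_AC + R²_BC − R²_C − R²_ABC; the triple overlap is the remainder.
    ab = r_ac + r_bc - r_c - r_abc
    ac = r_ab + r_bc - r_b - r_abc
    bc = r_ab + r_ac - r_a - r_abc
    abc = r_abc - (r_abc - r_bc) - (r_abc - r_ac) - (r_abc - r_ab) - ab - ac - bc
    out = {
        f"{la} unique": 100.0 * (r_abc - r_bc),
        f"{lb} unique": 100.0 * (r_abc - r_ac),
        f"{lc} unique": 100.0 * (r_abc - r_ab),
        f"{la}&{lb}": 100.0 * ab,
        f"{la}&{lc}": 100.0 * ac,
        f"{lb}&{lc}": 100.0 * bc,
        f"{la}&{lb}&{lc}": 100.0 * abc,
        "full": 100.0 * r_abc,
        "residual": 100.0 * (1.0 - r_abc),
    }
    return out
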