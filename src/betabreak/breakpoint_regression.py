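"""Two-segment (broken-stick) regression with exhaustive breakpoint search.

A response observed along absolute latitude is modelled as a line whose slope
changes at an unknown breakpoint.  The breakpoint is found by brute force:
every candidate latitude (1° spacing by default) is fitted and the candidate
with the smallest residual standard error wins, ties going to the smallest
candidate.  The piecewise fit is then compared with the simple linear fit by
an F test in which the broken stick spends 4 parameters (two slopes, one
intercept, and the breakpoint itself costs one degree of freedom), so the
comparison uses F(2, n − 4).

Two flavours of segment fit are available:

``continuous`` (default)
    y ~ 1 + x + (x − bp)·[x > bp] — the segments join at the breakpoint.
``discontinuous``
    an independent line per segment (4 regression coefficients).

In both modes the residual standard error uses n − 4 denominator degrees of
freedom so model comparison is consistent across modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PiecewiseFit",
    "ModelComparison",
    "SegmentSummary",
    "fit_piecewise",
    "search_breakpoint",
    "compare_to_linear",
    "segment_summary",
]


@dataclass(frozen=True)
class PiecewiseFit:
    breakpoint: float
    slope_below: float
    slope_above: float
    intercept_below: float
    intercept_above: float
    rss: float
    residual_se: float
    r2: float
    n: int
    mode: str

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        below = self.intercept_below + self.slope_below * x
        above = self.intercept_above + self.slope_above * x
        return np.where(x <= self.breakpoint, below, above)


@dataclass(frozen=True)
class ModelComparison:
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    r2_linear: float
    r2_piecewise: float
    exact_fit: bool = False  # piecewise RSS was 0; F reported as +inf


@dataclass(frozen=True)
class SegmentSummary:
    """Mean ± t-based 95% half-width and count for one latitude segment."""

    mean: float
    ci_half_width: float
    n: int
    degenerate: bool = False  # single observation: CI undefined


def _validate_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in x or y")
    return x, y


def fit_piecewise(x, y, breakpoint: float, mode: str = "continuous") -> PiecewiseFit:
    """Least-squares broken-stick fit at a fixed breakpoint.

    Requires n >= 5 and at least two points on each side of the breakpoint
    (x <= bp vs x > bp).
    """
    x, y = _validate_xy(x, y)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations for a piecewise fit")
    below = x <= breakpoint
    n_below = int(below.sum())
    if n_below < 2 or n - n_below < 2:
        raise ValueError(
            f"breakpoint {breakpoint} leaves a segment with fewer than 2 points"
        )
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0.0:
        raise ValueError("response is constant; piecewise fit is degenerate")

    if mode == "continuous":
        design = np.column_stack([np.ones(n), x, np.clip(x - breakpoint, 0.0, None)])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("degenerate (collinear) design at this breakpoint")
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        b0, b1, b2 = coef
        slope_below, slope_above = float(b1), float(b1 + b2)
        intercept_below = float(b0)
        # the above-segment line rewritten as intercept + slope*x
        intercept_above = float(b0 - b2 * breakpoint)
    elif mode == "discontinuous":
        resid = np.empty_like(y)
        params = []
        for mask in (below, ~below):
            design = np.column_stack([np.ones(mask.sum()), x[mask]])
            if np.linalg.matrix_rank(design) < 2:
                raise ValueError("degenerate segment (constant x) at this breakpoint")
            coef, _, _, _ = np.linalg.lstsq(design, y[mask], rcond=None)
            resid[mask] = y[mask] - design @ coef
            params.append(coef)
        (i_lo, s_lo), (i_hi, s_hi) = params
        slope_below, slope_above = float(s_lo), float(s_hi)
        intercept_below, intercept_above = float(i_lo), float(i_hi)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rss = float(resid @ resid)
    df = n - 4  # 3 regression coefficients + the breakpoint itself
    residual_se = float(np.sqrt(max(rss, 0.0) / df)) if df > 0 else np.nan
    return PiecewiseFit(
        breakpoint=float(breakpoint),
        slope_below=slope_below,
        slope_above=slope_above,
        intercept_below=intercept_below,
        intercept_above=intercept_above,
        rss=rss,
        residual_se=residual_se,
        r2=1.0 - rss / tss,
        n=n,
        mode=mode,
    )


def candidate_breakpoints(x, min_seg: int = 5) -> list:
    """Integer candidates strictly inside the observed range with at least
    ``min_seg`` points on each side."""
    x = np.asarray(x, dtype=float)
    lo, hi = np.floor(x.min()), np.ceil(x.max())
    cands = []
    for bp in range(int(lo) + 1, int(hi)):
        n_below = int((x <= bp).sum())
        if n_below >= min_seg and x.size - n_below >= min_seg:
            cands.append(bp)
    return cands


def search_breakpoint(x, y, candidates=None, mode: str = "continuous", min_seg: int = 5) -> PiecewiseFit:
    """Exhaustive 1°-interval grid search for the breakpoint.

    Fits every candidate and returns the fit with the lowest residual
    standard error; exact ties resolve to the smallest breakpoint.
    """
    x, y = _validate_xy(x, y)
    if candidates is None:
        candidates = candidate_breakpoints(x, min_seg=min_seg)
    else:
        candidates = [
            bp
            for bp in candidates
            if min_seg <= int((x <= bp).sum()) <= x.size - min_seg
        ]
    if not candidates:
        raise ValueError("no admissible breakpoint candidate (check min_seg and x range)")
    best = None
    tie_tol = 1e-9 * float(np.std(y))  # float fuzz counts as a tie
    for bp in sorted(candidates):
        fit = fit_piecewise(x, y, bp, mode=mode)
        if best is None or fit.residual_se < best.residual_se - tie_tol:
            best = fit
    return best


def compare_to_linear(x, y, pw: PiecewiseFit) -> ModelComparison:
    """ANOVA of the broken stick against the simple linear regression.

    F = ((RSS_lin − RSS_pw)/2) / (RSS_pw/(n−4)) on (2, n−4) degrees of
    freedom; n = 321 thus gives (2, 317).  A perfect piecewise fit
    (RSS_pw = 0) reports F = +inf with p = 0 and ``exact_fit`` set.
    """
    x, y = _validate_xy(x, y)
    n = x.size
    if n != pw.n:
        raise ValueError("comparison data does not match the piecewise fit")
    design = np.column_stack([np.ones(n), x])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rss_lin = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2_lin = 1.0 - rss_lin / tss
    df_den = n - 4
    # an RSS below float fuzz relative to the data scale is an exact fit
    tol = 1e-10 * tss
    if pw.rss <= tol:
        if rss_lin <= tol:
            # both models interpolate: the broken stick adds nothing
            return ModelComparison(0.0, 2, df_den, 1.0, r2_lin, pw.r2)
        return ModelComparison(np.inf, 2, df_den, 0.0, r2_lin, pw.r2, exact_fit=True)
    f_stat = max(0.0, (rss_lin - pw.rss) / 2.0 / (pw.rss / df_den))
    p_value = float(stats.f.sf(f_stat, 2, df_den))
    return ModelComparison(float(f_stat), 2, df_den, p_value, r2_lin, pw.r2)


def segment_summary(values, x, breakpoint: float) -> dict:
    """Per-segment mean ± 95% CI (t-based) below vs above a breakpoint."""
    x = np.asarray(x, dtype=float)
    values = np.asarray(values, dtype=float)
    if x.shape != values.shape:
        raise ValueError("values and x must align")
    out = {}
    for name, mask in (("below", x <= breakpoint), ("above", x > breakpoint)):
        seg = values[mask]
        if seg.size == 0:
            raise ValueError(f"no observations {name} breakpoint {breakpoint}")
        if seg.size == 1:
            out[name] = SegmentSummary(float(seg[0]), np.nan, 1, degenerate=True)
            continue
        se = seg.std(ddof=1) / np.sqrt(seg.size)
        half = float(stats.t.ppf(0.975, seg.size - 1) * se)
        out[name] = SegmentSummary(float(seg.mean()), half, int(seg.size))
    return out
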