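"""Nutrient conservation versus expression level.

Transcript abundance in each tissue is bimodal on the log2 scale: a
low-expression cluster of silent or rarely expressed genes and a
high-expression cluster.  A piecewise (segmented) regression of elemental
content on log2 abundance, broken at a fixed abundance, separates the two
clusters and asks whether highly expressed proteins are poorer in a
nutrient (negative above-breakpoint slope).  The default breakpoint of
5.5 log2 units can be re-derived on any dataset by AIC search.

The default piecewise model is a continuous hinge
``y = b0 + b1*x + b2*(x - c)+`` whose below-slope is b1 and above-slope
b1 + b2; a disjoint mode (independent segments with separate intercepts)
is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: significance stars at the conventional thresholds
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for cut, mark in STAR_LEVELS:
        if p < cut:
            return mark
    return ""


def join_expression_composition(
    expression: pd.DataFrame,
    composition: pd.DataFrame,
    id_column: str = "protein_id",
    value_column: str = "N",
) -> pd.DataFrame:
    """Inner-join expression values to a composition column per tissue.

    ``expression`` is long format (protein_id, tissue, log2_abundance).
    Duplicate (id, tissue) pairs violate the one-value-per-cell invariant
    and raise; unmatched ids on either side are counted and logged.
    """
    required = {id_column, "tissue", "log2_abundance"}
    if not required.issubset(expression.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")
    if expression.duplicated([id_column, "tissue"]).any():
        dup = expression[expression.duplicated([id_column, "tissue"])].iloc[0]
        raise ValueError(
            f"duplicate expression entry for ({dup[id_column]!r}, {dup['tissue']!r})"
        )
    comp = composition[[id_column, value_column]].drop_duplicates(id_column)
    joined = expression.merge(comp, on=id_column, how="inner")
    n_expr = expression[id_column].nunique()
    n_join = joined[id_column].nunique()
    if joined.empty:
        raise ValueError("no shared ids between expression and composition tables")
    if n_join < n_expr:
        logger.info("expression join: %d of %d ids matched", n_join, n_expr)
    return joined


@dataclass
class LinearFit:
    slope: float
    slope_se: float
    intercept: float
    rss: float
    n: int
    n_params: int = 2

    @property
    def aic(self) -> float:
        return gaussian_aic(self.rss, self.n, self.n_params)


def gaussian_aic(rss: float, n: int, n_params: int) -> float:
    """AIC of a Gaussian regression: n*log(RSS/n) + 2k, k counting sigma."""
    return n * np.log(rss / n) + 2 * (n_params + 1)


def fit_linear(y: Sequence[float], x: Sequence[float]) -> LinearFit:
    """Ordinary least squares of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    design = np.column_stack([np.ones_like(x), x])
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    df = len(x) - 2
    s2 = rss / df if df > 0 else np.nan
    sxx = float(((x - x.mean()) ** 2).sum())
    return LinearFit(
        slope=float(beta[1]), slope_se=float(np.sqrt(s2 / sxx)),
        intercept=float(beta[0]), rss=rss, n=len(x),
    )


@dataclass
class PiecewiseResults:
    """Fitted segmented regression around one breakpoint."""

    breakpoint: float
    slope_below: float
    se_below: float
    slope_above: float
    se_above: float
    intercept: float
    rss: float
    n: int
    n_params: int
    df_resid: int
    disjoint: bool = False
    degenerate: bool = False  # breakpoint outside data; collapsed to linear

    @property
    def aic(self) -> float:
        return gaussian_aic(self.rss, self.n, self.n_params)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": [self.slope_below, self.slope_above],
                "se": [self.se_below, self.se_above],
            },
            index=[f"slope (< {self.breakpoint:g})", f"slope (> {self.breakpoint:g})"],
        )


class PiecewiseRegression:
    """Segmented model of y on x with a known breakpoint.

    ``min_per_side`` guards estimability: with fewer (but more than zero)
    points on a side the fit raises, naming the side.  When one side is
    empty — the breakpoint lies outside the data range — the hinge term is
    unidentifiable and the model collapses to the ordinary linear fit, with
    both reported slopes equal.
    """

    def __init__(
        self,
        y: Sequence[float],
        x: Sequence[float],
        breakpoint: float = 5.5,
        disjoint: bool = False,
        min_per_side: int = 3,
    ):
        self.y = np.asarray(y, dtype=float)
        self.x = np.asarray(x, dtype=float)
        if self.y.shape != self.x.shape:
            raise ValueError("x and y must have equal length")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("non-finite values in input")
        self.breakpoint = float(breakpoint)
        self.disjoint = disjoint
        self.min_per_side = min_per_side

    def fit(self) -> PiecewiseResults:
        c = self.breakpoint
        below = self.x <= c
        above = ~below
        n_below, n_above = int(below.sum()), int(above.sum())
        for side, count in (("below", n_below), ("above", n_above)):
            if 0 < count < self.min_per_side:
                raise ValueError(
                    f"only {count} points {side} breakpoint {c:g}; "
                    f"need >= {self.min_per_side}"
                )
        if n_below == 0 or n_above == 0:
            lin = fit_linear(self.y, self.x)
            return PiecewiseResults(
                breakpoint=c, slope_below=lin.slope, se_below=lin.slope_se,
                slope_above=lin.slope, se_above=lin.slope_se,
                intercept=lin.intercept, rss=lin.rss, n=lin.n,
                n_params=2, df_resid=lin.n - 2, disjoint=self.disjoint,
                degenerate=True,
            )
        if self.disjoint:
            return self._fit_disjoint(below, above)
        return self._fit_hinge(c)

    def _fit_hinge(self, c: float) -> PiecewiseResults:
        hinge = np.clip(self.x - c, 0.0, None)
        design = np.column_stack([np.ones_like(self.x), self.x, hinge])
        beta, _, rank, _ = np.linalg.lstsq(design, self.y, rcond=None)
        if rank < 3:
            raise ValueError("degenerate hinge design (collinear columns)")
        resid = self.y - design @ beta
        rss = float(resid @ resid)
        n = len(self.x)
        df = n - 3
        s2 = rss / df
        cov = s2 * np.linalg.inv(design.T @ design)
        se_below = float(np.sqrt(cov[1, 1]))
        var_above = cov[1, 1] + cov[2, 2] + 2 * cov[1, 2]
        return PiecewiseResults(
            breakpoint=c, slope_below=float(beta[1]), se_below=se_below,
            slope_above=float(beta[1] + beta[2]),
            se_above=float(np.sqrt(max(var_above, 0.0))),
            intercept=float(beta[0]), rss=rss, n=n, n_params=3, df_resid=df,
        )

    def _fit_disjoint(self, below: np.ndarray, above: np.ndarray) -> PiecewiseResults:
        lo = fit_linear(self.y[below], self.x[below])
        hi = fit_linear(self.y[above], self.x[above])
        rss = lo.rss + hi.rss
        n = len(self.x)
        return PiecewiseResults(
            breakpoint=self.breakpoint,
            slope_below=lo.slope, se_below=lo.slope_se,
            slope_above=hi.slope, se_above=hi.slope_se,
            intercept=lo.intercept, rss=rss, n=n, n_params=4,
            df_resid=n - 4, disjoint=True,
        )


def fit_piecewise(
    y: Sequence[float],
    x: Sequence[float],
    breakpoint: float = 5.5,
    disjoint: bool = False,
) -> PiecewiseResults:
    """Fit a segmented regression at a fixed breakpoint."""
    return PiecewiseRegression(y, x, breakpoint, disjoint=disjoint).fit()


def select_breakpoint(
    y: Sequence[float],
    x: Sequence[float],
    candidate_grid: Optional[Sequence[float]] = None,
    disjoint: bool = False,
    flat_profile_delta: float = 2.0,
) -> Tuple[float, pd.DataFrame]:
    """Choose the breakpoint minimizing AIC over a candidate grid.

    The default grid spans 3.0-8.0 in steps of 0.25.  AIC ties are broken
    toward the grid median (then the smaller value).  If no candidate
    improves AIC over the straight-line fit by at least
    ``flat_profile_delta``, the data carry little evidence of any
    breakpoint and a warning is emitted.  Returns the selected breakpoint
    and the (breakpoint, aic) profile.
    """
    if candidate_grid is None:
        candidate_grid = np.arange(3.0, 8.0 + 1e-9, 0.25)
    grid = np.asarray(list(candidate_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty candidate grid")
    records = []
    for c in grid:
        try:
            fit = fit_piecewise(y, x, breakpoint=c, disjoint=disjoint)
        except ValueError:
            continue
        records.append({"breakpoint": float(c), "aic": fit.aic})
    if not records:
        raise ValueError("piecewise fit failed at every candidate breakpoint")
    profile = pd.DataFrame(records)
    best_aic = profile["aic"].min()
    ties = profile.loc[np.isclose(profile["aic"], best_aic, atol=1e-9), "breakpoint"]
    median = float(np.median(grid))
    best = float(ties.iloc[np.lexsort((ties, np.abs(ties - median)))[0]])
    if best_aic > fit_linear(y, x).aic - flat_profile_delta:
        warnings.warn(
            "flat AIC profile: no candidate breakpoint improves on the "
            "straight-line fit; data show little evidence of a breakpoint",
            stacklevel=2,
        )
    return best, profile


def linear_vs_piecewise_ftest(
    linear_fit: LinearFit, piecewise_fit: PiecewiseResults
) -> Tuple[float, float]:
    """Nested F test of the segmented model against the straight line.

    F = ((RSS_lin - RSS_pw)/ddf) / (RSS_pw/df_pw).  The fits must be on the
    same data (equal n) and the piecewise model must nest the linear one.
    """
    if linear_fit.n != piecewise_fit.n:
        raise ValueError("fits are not on the same data (different n)")
    ddf = piecewise_fit.n_params - linear_fit.n_params
    if ddf <= 0:
        raise ValueError("piecewise model does not nest the linear model")
    rss_gain = linear_fit.rss - piecewise_fit.rss
    # nestedness guarantees non-negative gain up to round-off
    assert rss_gain > -1e-8 * max(linear_fit.rss, 1.0), "non-nested fits"
    rss_gain = max(rss_gain, 0.0)
    f = (rss_gain / ddf) / (piecewise_fit.rss / piecewise_fit.df_resid)
    p = float(stats.f.sf(f, ddf, piecewise_fit.df_resid))
    return float(f), p


def tissue_sweep(
    joined: pd.DataFrame,
    value_column: str = "N",
    breakpoint: float = 5.5,
    disjoint: bool = False,
) -> pd.DataFrame:
    """Per-tissue linear and piecewise fits, ranked by above-breakpoint slope.

    Rows are sorted ascending by the high-expression slope, so the tissues
    with the strongest nutrient conservation (steepest negative slope) come
    first; ties are broken by tissue name.  Requires at least two tissues.
    """
    tissues = sorted(joined["tissue"].unique())
    if len(tissues) < 2:
        raise ValueError("tissue sweep needs at least 2 tissues")
    rows = []
    for tissue in tissues:
        sub = joined[joined["tissue"] == tissue]
        y = sub[value_column].to_numpy(dtype=float)
        x = sub["log2_abundance"].to_numpy(dtype=float)
        lin = fit_linear(y, x)
        pw = fit_piecewise(y, x, breakpoint=breakpoint, disjoint=disjoint)
        f, p = linear_vs_piecewise_ftest(lin, pw)
        rows.append({
            "tissue": tissue,
            "lin_estimate": lin.slope, "lin_se": lin.slope_se,
            "pw_estimate_below": pw.slope_below, "pw_se_below": pw.se_below,
            "pw_estimate_above": pw.slope_above, "pw_se_above": pw.se_above,
            "F": f, "p": p, "stars": significance_stars(p),
        })
    out = pd.DataFrame(rows)
    out = out.sort_values(["pw_estimate_above", "tissue"], kind="mergesort")
    return out.reset_index(drop=True)
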