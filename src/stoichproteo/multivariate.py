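"""Standing-variation multivariate analysis.

PCA over the composition variables pooled across species, followed by a
two-way MANOVA (species x functional category, with interaction) on the
leading principal components, using Pillai's trace.  PCA is computed on
z-scored variables (the correlation matrix) because the composition
variables are on incommensurate scales: atoms per residue, percent, and
residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class Standardization:
    """Column means and standard deviations used for z-scoring."""

    variables: List[str]
    center: np.ndarray
    scale: np.ndarray

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        x = frame[self.variables].to_numpy(dtype=float)
        return (x - self.center) / self.scale

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return z * self.scale + self.center


def standardize(
    table: pd.DataFrame, variables: Sequence[str], ddof: int = 1
) -> Tuple[np.ndarray, Standardization]:
    """Z-score the chosen columns (sample sd by default).

    Raises on missing values or a zero-variance column (named in the error).
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to standardize")
    x = table[list(variables)].to_numpy(dtype=float)
    if np.isnan(x).any():
        bad = [v for v in variables if table[v].isna().any()]
        raise ValueError(f"missing values in variables {bad}")
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=ddof)
    zero = [v for v, s in zip(variables, scale) if s == 0]
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    z = (x - center) / scale
    return z, Standardization(list(variables), center, scale)


@dataclass
class PcaModel:
    """Fitted principal components.

    ``loadings`` has orthonormal columns (variables x components); scores
    are the projections of the input rows; ``variance_fractions`` covers the
    retained components while ``all_variance_fractions`` sums to 1 over the
    full rank.  Component signs are fixed so the largest-magnitude loading
    in each column is positive, which makes the fit bit-reproducible.
    """

    variables: List[str]
    loadings: np.ndarray
    scores: np.ndarray
    variance_fractions: np.ndarray
    all_variance_fractions: np.ndarray
    centered: bool = True

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def component_names(self, prefix: str = "PC") -> List[str]:
        return [f"{prefix}{i + 1}" for i in range(self.n_components)]

    def loadings_frame(self, prefix: str = "PC") -> pd.DataFrame:
        return pd.DataFrame(self.loadings, index=self.variables,
                            columns=self.component_names(prefix))

    def scores_frame(self, index=None, prefix: str = "PC") -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=index, columns=self.component_names(prefix))

    def summary(self, prefix: str = "PC") -> pd.DataFrame:
        """Variance explained per retained component."""
        frac = self.variance_fractions
        return pd.DataFrame(
            {
                "component": self.component_names(prefix),
                "variance_fraction": frac,
                "cumulative_fraction": np.cumsum(frac),
            }
        )


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0


def fit_pca(
    matrix: np.ndarray,
    n_components: Optional[int] = None,
    variables: Optional[Sequence[str]] = None,
    center: bool = True,
) -> PcaModel:
    """PCA by singular value decomposition.

    ``matrix`` should already be standardized when a correlation-matrix PCA
    is intended.  With ``center=False`` the decomposition is through the
    origin (used for contrasts, whose expectation is zero by construction).
    Rank-deficient inputs retain only the non-degenerate components, with a
    warning.
    """
    x = np.asarray(matrix, dtype=float)
    n, p = x.shape
    if variables is None:
        variables = [f"x{i + 1}" for i in range(p)]
    if n_components is None:
        n_components = p
    if n_components > p:
        raise ValueError(f"n_components={n_components} exceeds {p} variables")
    if center:
        x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = s[0] * max(n, p) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if rank < n_components:
        warnings.warn(
            f"input rank {rank} < requested {n_components} components; "
            f"retaining {rank}", stacklevel=2,
        )
        n_components = rank
    var = s**2
    all_frac = var / var.sum()
    loadings = vt.T[:, :n_components].copy()
    scores = (u[:, :n_components] * s[:n_components]).copy()
    _fix_signs(loadings, scores)
    return PcaModel(
        variables=list(variables),
        loadings=loadings,
        scores=scores,
        variance_fractions=all_frac[:n_components].copy(),
        all_variance_fractions=all_frac,
        centered=center,
    )


def _dummy(values: pd.Series) -> np.ndarray:
    """Reference-coded dummy matrix (levels - 1 columns, sorted levels)."""
    levels = sorted(pd.unique(values))
    cols = [np.asarray(values == lv, dtype=float) for lv in levels[1:]]
    return np.column_stack(cols) if cols else np.empty((len(values), 0))


def _sscp_resid(y: np.ndarray, x: np.ndarray) -> Tuple[np.ndarray, int]:
    """Residual SSCP matrix of the multivariate OLS of y on x, and its rank."""
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return r.T @ r, rank


def _pillai_f(h: np.ndarray, e: np.ndarray, q: int, ve: int) -> Tuple[float, float, float, float, float]:
    """Pillai's trace and its standard F approximation.

    ``q`` is the hypothesis degrees of freedom, ``ve`` the error df.
    """
    p = h.shape[0]
    eigvals = np.linalg.eigvals(np.linalg.solve(h + e, h))
    v = float(np.real(eigvals).sum())
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (ve - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    if df2 <= 0 or v >= s:
        return v, np.inf, df1, max(df2, 0.0), 0.0
    f = (df2 / df1) * (v / s) / (1 - v / s)
    pval = float(stats.f.sf(f, df1, df2))
    return v, float(f), float(df1), float(df2), pval


def manova_pillai(
    scores: np.ndarray,
    group_factors: pd.DataFrame,
) -> pd.DataFrame:
    """Two-way crossed MANOVA with interaction, Pillai's trace per term.

    ``group_factors`` must hold exactly two categorical columns; each factor
    needs at least two levels.  Sums of squares are type II: each main
    effect is tested adjusted for the other main effect (not the
    interaction), and the interaction is tested against the additive model.
    With one factor column, a one-way MANOVA is returned.
    """
    y = np.asarray(scores, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    factors = list(group_factors.columns)
    for f in factors:
        if group_factors[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    n = len(y)
    ones = np.ones((n, 1))
    if len(factors) == 1:
        a = _dummy(group_factors[factors[0]])
        e_full, rank_full = _sscp_resid(y, np.hstack([ones, a]))
        e_null, _ = _sscp_resid(y, ones)
        ve = n - rank_full
        v, f, df1, df2, p = _pillai_f(e_null - e_full, e_full, a.shape[1], ve)
        return pd.DataFrame(
            [{"effect": factors[0], "pillai": v, "F": f,
              "df1": df1, "df2": df2, "p": p}]
        )
    if len(factors) != 2:
        raise ValueError("manova_pillai supports one or two factors")
    fa, fb = factors
    a = _dummy(group_factors[fa])
    b = _dummy(group_factors[fb])
    ab = np.einsum("ij,ik->ijk", a, b).reshape(n, -1)
    x_full = np.hstack([ones, a, b, ab])
    x_add = np.hstack([ones, a, b])
    e_full, rank_full = _sscp_resid(y, x_full)
    ve = n - rank_full
    e_add, _ = _sscp_resid(y, x_add)
    e_a_only, _ = _sscp_resid(y, np.hstack([ones, a]))
    e_b_only, _ = _sscp_resid(y, np.hstack([ones, b]))
    rows = []
    for name, h, q in (
        (fa, e_b_only - e_add, a.shape[1]),
        (fb, e_a_only - e_add, b.shape[1]),
        (f"{fa}:{fb}", e_add - e_full, ab.shape[1]),
    ):
        v, f, df1, df2, p = _pillai_f(h, e_full, q, ve)
        rows.append({"effect": name, "pillai": v, "F": f,
                     "df1": df1, "df2": df2, "p": p})
    return pd.DataFrame(rows)


def group_summaries(
    scores: pd.DataFrame,
    grouping: pd.Series,
) -> pd.DataFrame:
    """Per-group median, IQR and 95% CI of the median for each column.

    The CI uses the boxplot-notch convention: median +/- 1.58 * IQR / sqrt(n).
    """
    rows = []
    for group, idx in scores.groupby(np.asarray(grouping)).groups.items():
        sub = scores.loc[idx]
        n = len(sub)
        for col in scores.columns:
            x = sub[col].to_numpy(dtype=float)
            med = float(np.median(x))
            q1, q3 = np.percentile(x, [25, 75])
            iqr = float(q3 - q1)
            half = 1.58 * iqr / np.sqrt(n)
            rows.append(
                {"group": group, "axis": col, "n": n, "median": med,
                 "iqr": iqr, "ci_low": med - half, "ci_high": med + half}
            )
    return pd.DataFrame(rows)
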