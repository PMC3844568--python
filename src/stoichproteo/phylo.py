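"""Phylogenetic comparative methods on a fixed, rooted tree.

Implements the evolutionary side of the analysis: maximum-likelihood
ancestral states under Brownian motion (BM), per-tip divergence since the
most recent ancestor, phylogenetically independent contrasts (PIC) by
Felsenstein pruning, PCA on pooled contrasts ("evolutionary" principal
components), and phylogenetic generalized least squares (PGLS) with a pure
Brownian covariance — plus the per-protein PGLS sweep with its counting
and bias tests.

All algorithms treat the tree as known and error-free; branch lengths are
in arbitrary time units and need not be ultrametric.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .multivariate import PcaModel, fit_pca

logger = logging.getLogger(__name__)

ArrayLike = Union[np.ndarray, pd.Series, Mapping[str, float]]


class Phylogeny:
    """Rooted tree with strictly positive branch lengths and unique tips.

    Internal nodes are assigned deterministic labels ``N1..Nk`` in postorder
    when the source tree leaves them unlabelled, so ancestral states and
    contrasts can be reported against stable identifiers.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._validate_and_label()

    # -- construction ------------------------------------------------------

    @classmethod
    def read_newick(cls, path) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(path=str(path), schema="newick",
                                     preserve_underscores=True)
        except dendropy.utility.error.DataParseError as exc:
            raise ValueError(f"invalid Newick file {path}: {exc}") from None
        return cls(tree)

    @classmethod
    def from_string(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True)
        except dendropy.utility.error.DataParseError as exc:
            raise ValueError(f"invalid Newick string: {exc}") from None
        return cls(tree)

    def _validate_and_label(self) -> None:
        seen = set()
        k = 0
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                if node.taxon is None:
                    raise ValueError("leaf without a taxon label")
                label = node.taxon.label
                if label in seen:
                    raise ValueError(f"duplicate tip label {label!r}")
                seen.add(label)
            else:
                k += 1
                if node.label is None:
                    node.label = f"N{k}"
            if node.parent_node is not None:
                bl = node.edge.length
                if bl is None:
                    raise ValueError(
                        f"missing branch length above node "
                        f"{node.taxon.label if node.is_leaf() else node.label!r}"
                    )
                if bl <= 0:
                    raise ValueError(
                        f"non-positive branch length ({bl}) above node "
                        f"{node.taxon.label if node.is_leaf() else node.label!r}"
                    )
        self.tip_labels: List[str] = [
            lf.taxon.label for lf in self.tree.leaf_node_iter()
        ]
        self.internal_labels: List[str] = [
            nd.label for nd in self.tree.postorder_internal_node_iter()
        ]

    # -- basic structure ---------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def is_bifurcating(self) -> bool:
        return all(
            len(nd.child_nodes()) == 2
            for nd in self.tree.preorder_internal_node_iter()
        )

    def resolve_polytomies(self, eps_fraction: float = 1e-8) -> "Phylogeny":
        """Return a bifurcating copy; new branches get eps x tree depth."""
        tree = self.tree.clone(depth=1)
        tree.resolve_polytomies()
        depth = max(self.depths().values())
        eps = eps_fraction * depth
        for node in tree.postorder_node_iter():
            if node.parent_node is not None and not node.edge.length:
                node.edge.length = eps
        return Phylogeny(tree)

    def depths(self) -> Dict[str, float]:
        """Root-to-node path length for every node, keyed by label."""
        out: Dict[str, float] = {}
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            d = 0.0 if parent is None else out[_label(parent)] + node.edge.length
            out[_label(node)] = d
        return out

    def vcv(self, order: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """Brownian covariance matrix: shared root-to-MRCA branch length."""
        order = list(order) if order is not None else self.tip_labels
        idx = {lab: i for i, lab in enumerate(order)}
        n = len(order)
        v = np.zeros((n, n))
        # accumulate each edge's length onto all tip pairs below it
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            below = [
                lf.taxon.label for lf in node.leaf_iter() if lf.taxon.label in idx
            ]
            ids = [idx[lab] for lab in below]
            v[np.ix_(ids, ids)] += node.edge.length
        return pd.DataFrame(v, index=order, columns=order)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips})"


def _label(node: dendropy.Node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


def read_newick(path) -> Phylogeny:
    """Read and validate a Newick tree file."""
    return Phylogeny.read_newick(path)


def _as_tip_vector(tree: Phylogeny, tip_values: ArrayLike) -> np.ndarray:
    if isinstance(tip_values, (pd.Series, dict)):
        try:
            x = np.array([float(tip_values[t]) for t in tree.tip_labels])
        except KeyError as exc:
            raise ValueError(f"missing tip value for {exc.args[0]!r}") from None
    else:
        x = np.asarray(tip_values, dtype=float)
        if x.shape[0] != tree.n_tips:
            raise ValueError(
                f"expected {tree.n_tips} tip values, got {x.shape[0]}"
            )
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite tip values")
    return x


# -- ancestral states ------------------------------------------------------


def bm_ancestral_states(tree: Phylogeny, tip_values: ArrayLike) -> pd.Series:
    """Maximum-likelihood ancestral states under Brownian motion.

    The BM log-likelihood of a full set of node states is, up to constants,
    ``-1/2 * sum over edges of (x_child - x_parent)^2 / b``; its maximizer
    over the internal states is the solution of the tree-Laplacian linear
    system with tips as boundary values.  The root state equals the GLS
    phylogenetic mean of the tips.
    """
    x = _as_tip_vector(tree, tip_values)
    tip_idx = {lab: i for i, lab in enumerate(tree.tip_labels)}
    internals = list(tree.tree.postorder_internal_node_iter())
    int_idx = {_label(nd): i for i, nd in enumerate(internals)}
    m = len(internals)
    a = np.zeros((m, m))
    c = np.zeros(m)
    for nd in internals:
        i = int_idx[_label(nd)]
        neighbors = list(nd.child_nodes())
        edges = [(ch, ch.edge.length) for ch in neighbors]
        if nd.parent_node is not None:
            edges.append((nd.parent_node, nd.edge.length))
        for other, bl in edges:
            w = 1.0 / bl
            a[i, i] += w
            if other.is_leaf():
                c[i] += w * x[tip_idx[other.taxon.label]]
            else:
                a[i, int_idx[_label(other)]] -= w
    states = np.linalg.solve(a, c)
    return pd.Series(states, index=[_label(nd) for nd in internals],
                     name="ancestral_state")


def divergence_since_ancestor(tree: Phylogeny, tip_values: ArrayLike) -> pd.Series:
    """Signed tip divergence: tip value minus the ML state of its parent.

    Reporting differences from the reconstructed ancestor standardizes all
    ancestral values at the origin, isolating lineage-specific change.
    """
    x = _as_tip_vector(tree, tip_values)
    anc = bm_ancestral_states(tree, x)
    out = {}
    for i, lf in enumerate(tree.tree.leaf_node_iter()):
        out[lf.taxon.label] = x[i] - anc[_label(lf.parent_node)]
    return pd.Series(out, name="divergence")


# -- independent contrasts -------------------------------------------------


@dataclass
class ContrastSet:
    """Standardized independent contrasts with their node identifiers."""

    node_ids: List[str]
    contrasts: np.ndarray
    node_values: np.ndarray = field(default=None)

    def __len__(self) -> int:
        return len(self.node_ids)

    def to_series(self) -> pd.Series:
        return pd.Series(self.contrasts, index=self.node_ids, name="contrast")


def _contrast_transform(tree: Phylogeny) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Linear maps from tip values to contrasts and to nodal values.

    Felsenstein pruning is linear in the tip data, so the (n-1) contrasts
    are ``C @ x`` for a fixed matrix ``C``; similarly nodal estimates are
    ``A @ x``.  Computing the maps once lets whole matrices of per-family
    values be contrasted in a single product.
    """
    n = tree.n_tips
    tip_idx = {lab: i for i, lab in enumerate(tree.tip_labels)}
    coeff: Dict[int, np.ndarray] = {}
    blen: Dict[int, float] = {}
    contrast_rows, node_rows, node_ids = [], [], []
    for nd in tree.tree.postorder_node_iter():
        key = id(nd)
        if nd.is_leaf():
            row = np.zeros(n)
            row[tip_idx[nd.taxon.label]] = 1.0
            coeff[key] = row
            blen[key] = nd.edge.length
            continue
        children = nd.child_nodes()
        if len(children) != 2:
            raise ValueError(
                "independent contrasts require a bifurcating tree; "
                "call Phylogeny.resolve_polytomies() first"
            )
        k1, k2 = id(children[0]), id(children[1])
        b1, b2 = blen.pop(k1), blen.pop(k2)
        w1, w2 = coeff.pop(k1), coeff.pop(k2)
        contrast_rows.append((w1 - w2) / np.sqrt(b1 + b2))
        node_ids.append(_label(nd))
        node_row = (b2 * w1 + b1 * w2) / (b1 + b2)
        node_rows.append(node_row)
        coeff[key] = node_row
        augment = b1 * b2 / (b1 + b2)
        blen[key] = (nd.edge.length or 0.0) + augment if nd.parent_node else augment
    return np.array(contrast_rows), np.array(node_rows), node_ids


def independent_contrasts(tree: Phylogeny, tip_values: ArrayLike) -> ContrastSet:
    """Phylogenetically independent contrasts by pruning.

    Each contrast is ``(x_left - x_right) / sqrt(b_left + b_right)`` at an
    internal node, with the node taking the branch-length-weighted average
    of its children and its parent branch augmented by
    ``b_left*b_right/(b_left+b_right)``.  A bifurcating tree yields exactly
    ``n_tips - 1`` contrasts, each with expectation 0 and variance equal to
    the BM rate under Brownian evolution.
    """
    x = _as_tip_vector(tree, tip_values)
    cmat, amat, node_ids = _contrast_transform(tree)
    return ContrastSet(node_ids=node_ids, contrasts=cmat @ x, node_values=amat @ x)


def contrasts_matrix(tree: Phylogeny, tip_matrix: pd.DataFrame) -> pd.DataFrame:
    """Contrasts of every column of a (tips x variables) frame at once."""
    cmat, _, node_ids = _contrast_transform(tree)
    x = tip_matrix.loc[tree.tip_labels].to_numpy(dtype=float)
    return pd.DataFrame(cmat @ x, index=node_ids, columns=tip_matrix.columns)


def evolutionary_pca(
    contrast_matrix: Union[np.ndarray, pd.DataFrame],
    n_components: Optional[int] = None,
) -> PcaModel:
    """PCA of pooled independent contrasts through the origin.

    Contrasts have expectation zero by construction, so no centering is
    applied; columns are scaled to unit root-mean-square so the axes
    reflect the correlation structure of evolutionary change rather than
    raw scales.
    """
    if isinstance(contrast_matrix, pd.DataFrame):
        variables = list(contrast_matrix.columns)
        x = contrast_matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(contrast_matrix, dtype=float)
        variables = [f"x{i + 1}" for i in range(x.shape[1])]
    if x.shape[0] < x.shape[1]:
        warnings.warn(
            f"fewer contrast rows ({x.shape[0]}) than variables ({x.shape[1]}); "
            "fitting reduced rank", stacklevel=2,
        )
    rms = np.sqrt(np.mean(x**2, axis=0))
    if np.any(rms == 0):
        raise ValueError("a contrast column is identically zero")
    return fit_pca(x / rms, n_components=n_components, variables=variables,
                   center=False)


# -- PGLS ------------------------------------------------------------------


@dataclass
class PGLSResults:
    """GLS fit of y on x with Brownian phylogenetic covariance."""

    intercept: float
    slope: float
    slope_se: float
    tvalue: float
    pvalue: float
    df_resid: int
    sigma2: float

    @property
    def sign(self) -> int:
        return int(np.sign(self.slope))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": [self.intercept, self.slope],
                "se": [np.nan, self.slope_se],
                "t": [np.nan, self.tvalue],
                "p": [np.nan, self.pvalue],
            },
            index=["intercept", "slope"],
        )


class PGLS:
    """Phylogenetic generalized least squares with one predictor.

    The response is modelled on raw species values with error covariance
    proportional to the Brownian matrix V implied by the tree (shared
    branch length from root to each pair's most recent common ancestor).
    No additional transformation of V (e.g. Pagel's lambda) is estimated.
    """

    def __init__(self, tree: Phylogeny, y: ArrayLike, x: ArrayLike):
        self.tree = tree
        self.y = _as_tip_vector(tree, y)
        self.x = _as_tip_vector(tree, x)
        v = tree.vcv().to_numpy()
        try:
            self._chol = np.linalg.cholesky(v)
        except np.linalg.LinAlgError:
            raise ValueError("singular Brownian covariance matrix") from None

    def fit(self) -> PGLSResults:
        n = self.tree.n_tips
        design = np.column_stack([np.ones(n), self.x])
        lw = self._chol
        xw = np.linalg.solve(lw, design)
        yw = np.linalg.solve(lw, self.y)
        xtx = xw.T @ xw
        try:
            xtx_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError:
            raise ValueError("predictor has zero variance across species") from None
        beta = xtx_inv @ xw.T @ yw
        resid = yw - xw @ beta
        df = n - 2
        sigma2 = float(resid @ resid / df) if df > 0 else np.nan
        se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
        if se == 0.0:
            t = np.inf if beta[1] != 0 else 0.0
            p = 0.0 if beta[1] != 0 else 1.0
        else:
            t = float(beta[1] / se)
            p = float(2 * stats.t.sf(abs(t), df))
        return PGLSResults(
            intercept=float(beta[0]), slope=float(beta[1]), slope_se=se,
            tvalue=t, pvalue=p, df_resid=df, sigma2=sigma2,
        )


def pgls_fit(tree: Phylogeny, y: ArrayLike, x: ArrayLike) -> PGLSResults:
    """Convenience wrapper: fit ``y ~ x`` by PGLS on the given tree."""
    return PGLS(tree, y, x).fit()


def _gls_batch(
    lw: np.ndarray, x: np.ndarray, ymat: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized GLS of many responses on one predictor.

    ``lw`` is the Cholesky factor of V, ``x`` the predictor (n,), ``ymat``
    the responses (n, m).  Returns slopes, standard errors and two-sided
    p-values, one triple per column.
    """
    n, m = ymat.shape
    design = np.column_stack([np.ones(n), x])
    xw = np.linalg.solve(lw, design)
    yw = np.linalg.solve(lw, ymat)
    xtx = xw.T @ xw
    if abs(np.linalg.det(xtx)) < 1e-300:
        raise ValueError("predictor has zero variance across species")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (xw.T @ yw)  # (2, m)
    resid = yw - xw @ beta
    df = n - 2
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, np.where(beta[1] != 0, np.inf, 0.0))
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta[1], se, p


@dataclass
class TraitSweepResult:
    """Outcome of a per-family PGLS sweep against one trait."""

    trait: str
    detail: pd.DataFrame          # family, axis, slope, se, p, sign
    counts: pd.DataFrame          # axis, n_tests, n_significant
    alpha: float
    n_tests_per_axis: int
    expected_null_count: int
    conservative_threshold: int
    skipped_families: List[str]

    def summary(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.insert(0, "trait", self.trait)
        out["expected_null"] = self.expected_null_count
        out["threshold"] = self.conservative_threshold
        out["exceeds_threshold"] = out["n_significant"] >= self.conservative_threshold
        return out

    def significant(self) -> pd.DataFrame:
        return self.detail[self.detail["p"] < self.alpha]


def trait_sweep(
    tree: Phylogeny,
    scores: pd.DataFrame,
    trait: pd.Series,
    axes: Optional[Sequence[str]] = None,
    alpha: float = 0.01,
    threshold_multiplier: float = 4.0,
    p_adjust: Optional[str] = None,
) -> TraitSweepResult:
    """PGLS of every family's PC scores against a species-level trait.

    ``scores`` must carry columns ``species``, ``family_id`` and one column
    per axis; each family contributes one value per species per axis, so a
    sweep over N families performs N fits of size n_species per axis.  The
    observed count of fits with p below ``alpha`` is reported against the
    analytic null expectation ``alpha * N`` (rounded) and against the
    deliberately conservative threshold ``threshold_multiplier`` times that
    expectation, which guards against mild miscalibration of the many
    non-independent tests.  ``p_adjust="bh"`` switches significance calls
    to Benjamini-Hochberg adjusted p-values instead.
    """
    if trait.nunique() <= 1:
        raise ValueError(f"trait {trait.name!r} has zero variance across species")
    if axes is None:
        axes = [c for c in scores.columns if c not in ("species", "family_id")]
    species = tree.tip_labels
    x = _as_tip_vector(tree, trait)
    lw = np.linalg.cholesky(tree.vcv().to_numpy())

    wide = scores.pivot_table(index="species", columns="family_id",
                              values=list(axes), aggfunc="first")
    complete_fams, skipped = [], []
    for fam in scores["family_id"].unique():
        ok = all(
            fam in wide[ax].columns
            and not wide[ax][fam].reindex(species).isna().any()
            for ax in axes
        )
        (complete_fams if ok else skipped).append(fam)
    if skipped:
        logger.warning("trait sweep: skipped %d families with missing species",
                       len(skipped))
    if not complete_fams:
        raise ValueError("no family has complete species coverage")

    detail_rows = []
    count_rows = []
    for ax in axes:
        ymat = wide[ax][complete_fams].reindex(species).to_numpy(dtype=float)
        slope, se, p = _gls_batch(lw, x, ymat)
        if p_adjust == "bh":
            from statsmodels.stats.multitest import multipletests
            p_used = multipletests(p, method="fdr_bh")[1]
        else:
            p_used = p
        detail_rows.append(pd.DataFrame({
            "family_id": complete_fams, "axis": ax,
            "slope": slope, "se": se, "p": p, "p_used": p_used,
            "sign": np.sign(slope).astype(int),
        }))
        count_rows.append({"axis": ax, "n_tests": len(complete_fams),
                           "n_significant": int((p_used < alpha).sum())})
    detail = pd.concat(detail_rows, ignore_index=True)
    n_tests = len(complete_fams)
    expected = int(round(alpha * n_tests))
    return TraitSweepResult(
        trait=str(trait.name), detail=detail,
        counts=pd.DataFrame(count_rows), alpha=alpha,
        n_tests_per_axis=n_tests, expected_null_count=expected,
        conservative_threshold=int(round(threshold_multiplier * alpha * n_tests)),
        skipped_families=[str(f) for f in skipped],
    )


def sign_bias_test(significant_fits: pd.DataFrame) -> float:
    """Exact two-sided binomial test for an excess of one slope sign.

    Fits with a slope of exactly zero are uninformative and excluded.
    """
    if len(significant_fits) < 1:
        raise ValueError("no significant fits supplied")
    n_pos = int((significant_fits["slope"] > 0).sum())
    n_neg = int((significant_fits["slope"] < 0).sum())
    total = n_pos + n_neg
    if total == 0:
        return 1.0
    return float(stats.binomtest(n_pos, total, 0.5).pvalue)


def category_bias_test(
    significant_fits: pd.DataFrame,
    categories: Optional[pd.Series] = None,
    min_expected: float = 1.0,
) -> Tuple[float, float, pd.DataFrame]:
    """Pearson chi-square of slope sign against protein category.

    Builds the category x sign contingency table of the significant fits;
    categories whose smallest expected count falls below ``min_expected``
    are pooled into ``"other"`` before the test.  Returns (chi2, p, table).
    """
    df = significant_fits.copy()
    if categories is not None:
        df["category"] = df["family_id"].map(categories)
    if "category" not in df.columns:
        raise ValueError("significant fits need a 'category' column or a mapping")
    df = df[df["sign"] != 0] if "sign" in df.columns else df
    sign = np.sign(df["slope"]).astype(int) if "slope" in df.columns else df["sign"]
    table = pd.crosstab(df["category"], sign.replace({1: "positive", -1: "negative"}))
    if table.shape[0] < 2:
        raise ValueError("need at least 2 categories for a bias test")
    # single-pass pooling of sparse categories into "other"
    expected = (
        np.outer(table.sum(axis=1), table.sum(axis=0)) / table.values.sum()
    )
    sparse = table.index[expected.min(axis=1) < min_expected]
    if 0 < len(sparse) < table.shape[0]:
        pooled = table.loc[sparse].sum()
        table = table.drop(index=sparse)
        if "other" in table.index:
            table.loc["other"] += pooled
        else:
            table.loc["other"] = pooled
    if table.shape[0] < 2:
        raise ValueError("need at least 2 categories after pooling")
    chi2, p, _, _ = stats.chi2_contingency(table.values, correction=False)
    return float(chi2), float(p), table
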