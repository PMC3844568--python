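"""Ancestral states, contrasts, PGLS and the trait sweep."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stoichproteo.phylo import (
    Phylogeny,
    bm_ancestral_states,
    category_bias_test,
    contrasts_matrix,
    divergence_since_ancestor,
    evolutionary_pca,
    independent_contrasts,
    pgls_fit,
    read_newick,
    sign_bias_test,
    trait_sweep,
)
from stoichproteo.simulate import random_join_tree


# -- tree reading and validation -------------------------------------------


def test_read_newick_basic(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((A:1,B:1):1,C:2);\n")
    tree = read_newick(p)
    assert sorted(tree.tip_labels) == ["A", "B", "C"]
    assert len(tree.internal_labels) == 2
    assert tree.is_bifurcating()


def test_tree_validation_errors():
    with pytest.raises(ValueError, match="branch length"):
        Phylogeny.from_string("((A:1,B:0):1,C:2);")
    with pytest.raises(ValueError, match="branch length"):
        Phylogeny.from_string("((A:1,B):1,C:2);")
    with pytest.raises(ValueError, match="duplicate"):
        Phylogeny.from_string("((A:1,A:1):1,C:2);")


def test_default_tree_fixture(default_tree):
    assert default_tree.n_tips == 12
    assert default_tree.is_bifurcating()
    depths = default_tree.depths()
    assert depths["Dmel"] == pytest.approx(63.0)
    assert depths["Dgri"] == pytest.approx(63.0)


def test_vcv_shared_path_lengths():
    tree = Phylogeny.from_string("((A:1,B:1):1,C:2);")
    v = tree.vcv()
    assert v.loc["A", "A"] == pytest.approx(2.0)
    assert v.loc["A", "B"] == pytest.approx(1.0)
    assert v.loc["A", "C"] == pytest.approx(0.0)


def test_resolve_polytomies(star3):
    assert not star3.is_bifurcating()
    resolved = star3.resolve_polytomies()
    assert resolved.is_bifurcating()
    assert resolved.n_tips == 3


# -- ancestral states ------------------------------------------------------


def test_ancestral_star_tree_is_mean(star3):
    anc = bm_ancestral_states(star3, {"A": 1.0, "B": 2.0, "C": 3.0})
    assert anc.iloc[0] == pytest.approx(2.0)


def test_ancestral_constant_tips(default_tree):
    anc = bm_ancestral_states(default_tree,
                              {t: 7.5 for t in default_tree.tip_labels})
    np.testing.assert_allclose(anc.to_numpy(), 7.5, atol=1e-10)


def _bm_neg_loglik(states, tree, tips):
    """Brute-force BM log-likelihood over all node states (up to constants)."""
    labels = {**tips, **states}
    total = 0.0
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        lab = node.taxon.label if node.is_leaf() else node.label
        parent = node.parent_node
        plab = parent.taxon.label if parent.is_leaf() else parent.label
        total += (labels[lab] - labels[plab]) ** 2 / node.edge.length
    return total


def test_ancestral_matches_grid_search_oracle():
    """3-taxon tree with unequal branches: ML states by nested grid search."""
    tree = Phylogeny.from_string("((A:0.5,B:2.0):1.0,C:3.0);")
    tips = {"A": 1.0, "B": -0.5, "C": 2.0}
    anc = bm_ancestral_states(tree, tips)
    root_lab, inner_lab = anc.index[-1], anc.index[0]
    # nested grid refinement over the two internal states
    lo = np.array([-2.0, -2.0])
    hi = np.array([3.0, 3.0])
    best = None
    for _ in range(7):
        g1 = np.linspace(lo[0], hi[0], 41)
        g2 = np.linspace(lo[1], hi[1], 41)
        vals = np.array([
            [_bm_neg_loglik({inner_lab: a, root_lab: b}, tree, tips)
             for b in g2] for a in g1
        ])
        i, j = np.unravel_index(vals.argmin(), vals.shape)
        best = (g1[i], g2[j])
        span1, span2 = (hi - lo) / 8
        lo = np.array([g1[i] - span1, g2[j] - span2])
        hi = np.array([g1[i] + span1, g2[j] + span2])
    assert anc[inner_lab] == pytest.approx(best[0], abs=1e-4)
    assert anc[root_lab] == pytest.approx(best[1], abs=1e-4)


def test_ancestral_missing_tip_value(default_tree):
    values = {t: 1.0 for t in default_tree.tip_labels}
    values.pop("Dmel")
    with pytest.raises(ValueError, match="Dmel"):
        bm_ancestral_states(default_tree, values)


# -- divergence ------------------------------------------------------------


def test_divergence_star_tree(star3):
    div = divergence_since_ancestor(star3, {"A": 0.0, "B": 0.0, "C": 3.0})
    assert div["A"] == pytest.approx(-1.0)
    assert div["B"] == pytest.approx(-1.0)
    assert div["C"] == pytest.approx(2.0)


def test_divergence_linearity(default_tree):
    rng = np.random.default_rng(0)
    vals = pd.Series(rng.normal(size=12), index=default_tree.tip_labels)
    d1 = divergence_since_ancestor(default_tree, vals)
    d2 = divergence_since_ancestor(default_tree, -vals)
    np.testing.assert_allclose(d1.to_numpy(), -d2[d1.index].to_numpy(),
                               atol=1e-10)
    zero = divergence_since_ancestor(default_tree,
                                     pd.Series(2.0, index=default_tree.tip_labels))
    np.testing.assert_allclose(zero.to_numpy(), 0.0, atol=1e-10)


# -- independent contrasts -------------------------------------------------


def test_contrast_two_tip_closed_form():
    tree = Phylogeny.from_string("(A:1,B:1);")
    cs = independent_contrasts(tree, {"A": 3.0, "B": 1.0})
    assert len(cs) == 1
    assert abs(cs.contrasts[0]) == pytest.approx(np.sqrt(2.0))


def test_contrasts_count_and_zero(default_tree):
    cs = independent_contrasts(default_tree,
                               {t: 4.2 for t in default_tree.tip_labels})
    assert len(cs) == default_tree.n_tips - 1
    np.testing.assert_allclose(cs.contrasts, 0.0, atol=1e-12)


def test_contrasts_match_dendropy(default_tree):
    """Independent oracle: dendropy's PIC on the same tree and data."""
    import dendropy
    from dendropy.model.continuous import PhylogeneticIndependentContrasts

    rng = np.random.default_rng(1)
    values = dict(zip(default_tree.tip_labels, rng.normal(size=12)))
    ours = np.sort(np.abs(independent_contrasts(default_tree, values).contrasts))

    newick = default_tree.tree.as_string(schema="newick")
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=taxa,
                             preserve_underscores=True)
    cm = dendropy.ContinuousCharacterMatrix.from_dict(
        {lab: [v] for lab, v in values.items()}, taxon_namespace=taxa)
    pic = PhylogeneticIndependentContrasts(tree, cm)
    ctree = pic.contrasts_tree(character_index=0)
    theirs = np.sort(np.abs([
        nd.pic[0]["pic_contrast_standardized"]
        for nd in ctree.postorder_internal_node_iter()
    ]))
    np.testing.assert_allclose(ours, theirs, atol=1e-10)


def test_contrast_variance_under_bm(default_tree):
    """Standardized contrasts of BM data have variance equal to the BM rate."""
    rng = np.random.default_rng(2)
    lw = np.linalg.cholesky(default_tree.vcv().to_numpy())
    tips = pd.DataFrame(lw @ rng.standard_normal((12, 10_000)),
                        index=default_tree.tip_labels)
    cs = contrasts_matrix(default_tree, tips).to_numpy()
    var = cs.var()
    se = np.sqrt(2.0 / cs.size)  # variance-of-variance for standard normals
    assert abs(var - 1.0) < 3 * se


def test_contrasts_invariant_to_tip_order(default_tree):
    rng = np.random.default_rng(3)
    values = pd.Series(rng.normal(size=12), index=default_tree.tip_labels)
    shuffled = values.sample(frac=1, random_state=0)
    c1 = independent_contrasts(default_tree, values).contrasts
    c2 = independent_contrasts(default_tree, shuffled).contrasts
    np.testing.assert_allclose(c1, c2, atol=1e-12)
    a1 = bm_ancestral_states(default_tree, values)
    a2 = bm_ancestral_states(default_tree, shuffled)
    np.testing.assert_allclose(a1.to_numpy(), a2[a1.index].to_numpy(),
                               atol=1e-12)


def test_contrasts_require_bifurcating(star3):
    with pytest.raises(ValueError, match="bifurcating"):
        independent_contrasts(star3, {"A": 1.0, "B": 2.0, "C": 3.0})


# -- evolutionary PCA ------------------------------------------------------


def test_evolutionary_pca_coevolving_pair():
    rng = np.random.default_rng(4)
    c = rng.normal(size=(200, 1))
    mat = np.hstack([c, 2 * c])
    model = evolutionary_pca(mat)
    assert model.all_variance_fractions[0] == pytest.approx(1.0, abs=1e-10)
    assert abs(model.loadings[0, 0]) == pytest.approx(abs(model.loadings[1, 0]),
                                                      abs=1e-10)


def test_evolutionary_pca_independent_variables():
    rng = np.random.default_rng(5)
    model = evolutionary_pca(rng.normal(size=(20_000, 4)))
    np.testing.assert_allclose(model.all_variance_fractions, 0.25, atol=0.02)


def test_evolutionary_pca_deterministic_and_warns():
    rng = np.random.default_rng(6)
    mat = rng.normal(size=(100, 3))
    m1, m2 = evolutionary_pca(mat), evolutionary_pca(mat)
    np.testing.assert_array_equal(m1.loadings, m2.loadings)
    with pytest.warns(UserWarning, match="fewer"):
        evolutionary_pca(rng.normal(size=(2, 5)))


# -- PGLS ------------------------------------------------------------------


def test_pgls_star_tree_equals_ols():
    tree = Phylogeny.from_string("(A:1,B:1,C:1,D:1,E:1);")
    rng = np.random.default_rng(7)
    x = rng.normal(size=5)
    y = rng.normal(size=5)
    res = pgls_fit(tree, dict(zip(tree.tip_labels, y)),
                   dict(zip(tree.tip_labels, x)))
    ols = stats.linregress(x, y)
    assert res.slope == pytest.approx(ols.slope, abs=1e-10)
    assert res.pvalue == pytest.approx(ols.pvalue, abs=1e-10)


def test_pgls_exact_linear_relation(default_tree):
    rng = np.random.default_rng(8)
    x = pd.Series(rng.normal(size=12), index=default_tree.tip_labels)
    res = pgls_fit(default_tree, 2.0 * x, x)
    assert res.slope == pytest.approx(2.0, abs=1e-10)
    assert res.sigma2 == pytest.approx(0.0, abs=1e-18)


def test_pgls_zero_variance_predictor(default_tree):
    x = pd.Series(1.0, index=default_tree.tip_labels)
    y = pd.Series(np.arange(12.0), index=default_tree.tip_labels)
    with pytest.raises(ValueError):
        pgls_fit(default_tree, y, x)


def test_pic_pgls_slope_equivalence():
    """Classical identity: OLS-through-origin on contrasts = PGLS slope."""
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        tree = random_join_tree(12, rng)
        x = np.linalg.cholesky(tree.vcv().to_numpy()) @ rng.standard_normal(12)
        y = np.linalg.cholesky(tree.vcv().to_numpy()) @ rng.standard_normal(12)
        res = pgls_fit(tree, dict(zip(tree.tip_labels, y)),
                       dict(zip(tree.tip_labels, x)))
        cx = independent_contrasts(tree, dict(zip(tree.tip_labels, x))).contrasts
        cy = independent_contrasts(tree, dict(zip(tree.tip_labels, y))).contrasts
        assert res.slope == pytest.approx((cx @ cy) / (cx @ cx), abs=1e-8)


# -- trait sweep and bias tests --------------------------------------------


def _null_scores(tree, n_families, rng, axes=("PC1",)):
    lw = np.linalg.cholesky(tree.vcv().to_numpy())
    frames = []
    for fam in range(n_families):
        vals = {ax: lw @ rng.standard_normal(tree.n_tips) for ax in axes}
        frames.append(pd.DataFrame({
            "species": tree.tip_labels, "family_id": f"F{fam:04d}",
            **vals,
        }))
    return pd.concat(frames, ignore_index=True)


def test_trait_sweep_null_counts(default_tree):
    rng = np.random.default_rng(9)
    scores = _null_scores(default_tree, 400, rng)
    trait = pd.Series(
        np.linalg.cholesky(default_tree.vcv().to_numpy())
        @ rng.standard_normal(12),
        index=default_tree.tip_labels, name="genome_size_mb")
    sweep = trait_sweep(default_tree, scores, trait, axes=["PC1"])
    assert sweep.expected_null_count == 4  # round(0.01 * 400)
    assert sweep.conservative_threshold == 16
    lo, hi = stats.binom.ppf([0.005, 0.995], 400, 0.01)
    assert lo <= sweep.counts["n_significant"].item() <= hi


def test_trait_sweep_planted_association_recall(default_tree):
    """Families with a planted slope are recovered at high rate."""
    rng = np.random.default_rng(10)
    v = default_tree.vcv().to_numpy()
    # scale so BM tip values have unit variance on average
    lw = np.linalg.cholesky(v) / np.sqrt(np.diag(v).mean())
    trait_vals = lw @ rng.standard_normal(12)
    trait_vals /= trait_vals.std()
    frames = []
    n_fam, n_planted = 300, 30
    for fam in range(n_fam):
        noise = lw @ rng.standard_normal(12)
        y = noise if fam >= n_planted else trait_vals + 0.5 * noise
        frames.append(pd.DataFrame({"species": default_tree.tip_labels,
                                    "family_id": f"F{fam:04d}", "PC1": y}))
    scores = pd.concat(frames, ignore_index=True)
    trait = pd.Series(trait_vals, index=default_tree.tip_labels, name="t")
    sweep = trait_sweep(default_tree, scores, trait, axes=["PC1"])
    sig = set(sweep.significant()["family_id"])
    planted = {f"F{fam:04d}" for fam in range(n_planted)}
    recall = len(sig & planted) / n_planted
    assert recall >= 0.8
    assert sweep.counts["n_significant"].item() > sweep.conservative_threshold


def test_trait_sweep_errors(default_tree):
    rng = np.random.default_rng(11)
    scores = _null_scores(default_tree, 5, rng)
    flat = pd.Series(1.0, index=default_tree.tip_labels, name="t")
    with pytest.raises(ValueError, match="zero variance"):
        trait_sweep(default_tree, scores, flat)
    # family missing a species is skipped, not fatal
    trait = pd.Series(np.arange(12.0), index=default_tree.tip_labels, name="t")
    broken = scores[~((scores.family_id == "F0000")
                      & (scores.species == "Dmel"))]
    sweep = trait_sweep(default_tree, broken, trait, axes=["PC1"])
    assert sweep.skipped_families == ["F0000"]
    assert sweep.n_tests_per_axis == 4


def test_sign_bias_test_exact_values():
    balanced = pd.DataFrame({"slope": [1.0] * 10 + [-1.0] * 10})
    assert sign_bias_test(balanced) == pytest.approx(1.0)
    one_sided = pd.DataFrame({"slope": [0.5] * 20})
    assert sign_bias_test(one_sided) == pytest.approx(2 * 0.5**20)
    single = pd.DataFrame({"slope": [0.5]})
    assert sign_bias_test(single) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        sign_bias_test(pd.DataFrame({"slope": []}))


def test_category_bias_test_closed_form():
    fits = pd.DataFrame({
        "slope": [1.0] * 10 + [-1.0] * 10,
        "category": ["a"] * 10 + ["b"] * 10,
    })
    chi2, p, table = category_bias_test(fits)
    assert chi2 == pytest.approx(20.0)
    assert p < 0.001


def test_category_bias_test_no_association():
    fits = pd.DataFrame({
        "slope": [1.0, -1.0] * 20,
        "category": ["a"] * 20 + ["b"] * 20,
    })
    chi2, p, _ = category_bias_test(fits)
    assert chi2 == pytest.approx(0.0, abs=1e-10)
    assert p == pytest.approx(1.0)


def test_category_bias_test_pooling_and_errors():
    fits = pd.DataFrame({
        "slope": [1.0] * 12 + [-1.0] * 12 + [1.0],
        "category": ["a"] * 12 + ["b"] * 12 + ["rare"],
    })
    _, _, table = category_bias_test(fits)
    assert "other" in table.index and "rare" not in table.index
    with pytest.raises(ValueError, match="2 categories"):
        category_bias_test(pd.DataFrame({"slope": [1.0, -1.0],
                                         "category": ["a", "a"]}))
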