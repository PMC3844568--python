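"""End-to-end analysis stages over the standard file formats.

Each function binds the lower-level modules into one analysis stage of the
pipeline: composition assembly from per-species FASTA, standing-variation
multivariate analysis, phylogenetic comparative analysis with the
per-family PGLS trait sweep, and the expression piecewise analysis.  The
command-line interface is a thin wrapper over these functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import composition as comp_mod
from . import expression as expr_mod
from .multivariate import PcaModel, fit_pca, group_summaries, manova_pillai, standardize
from .phylo import (
    Phylogeny,
    TraitSweepResult,
    category_bias_test,
    contrasts_matrix,
    divergence_since_ancestor,
    evolutionary_pca,
    sign_bias_test,
    trait_sweep,
)

logger = logging.getLogger(__name__)

DEFAULT_N_COMPONENTS = 8


def compose_scenario_dir(
    scenario_dir,
    drop_initial_met: bool = False,
    ambiguity_policy: str = "drop_protein",
    scale: str = "per_residue",
    universal_only: bool = True,
) -> pd.DataFrame:
    """Build the composition table from a scenario directory.

    Expects ``proteins_<species>.fasta`` / ``cds_<species>.fasta`` per
    species plus ``orthologs.tsv`` and ``categories.tsv`` (the layout the
    scenario writer produces).  With ``universal_only`` the table is
    restricted to families present in every species.
    """
    scenario_dir = Path(scenario_dir)
    ortho = comp_mod.read_ortholog_map(scenario_dir / "orthologs.tsv")
    cats = comp_mod.read_category_map(scenario_dir / "categories.tsv")
    species = sorted(ortho["species"].unique())
    records = []
    for sp in species:
        recs = comp_mod.read_protein_fasta(
            scenario_dir / f"proteins_{sp}.fasta", sp,
            ambiguity_policy=ambiguity_policy,
        )
        cds_path = scenario_dir / f"cds_{sp}.fasta"
        if cds_path.exists():
            recs = comp_mod.attach_cds(recs, cds_path)
        records.extend(recs)
    records = comp_mod.annotate_records(records, ortho, cats)
    table = comp_mod.build_composition_table(
        records, drop_initial_met=drop_initial_met, scale=scale
    )
    if universal_only:
        table = comp_mod.filter_universal_orthologs(table, species)
    return table


@dataclass
class StandingResult:
    """Standing-variation PCA and MANOVA over the pooled composition table."""

    pca: PcaModel
    scores: pd.DataFrame            # species, family_id, category + PC columns
    manova: pd.DataFrame
    species_summaries: pd.DataFrame
    category_summaries: pd.DataFrame
    variables: List[str]

    def variance_table(self) -> pd.DataFrame:
        return self.pca.summary()


def standing_analysis(
    table: pd.DataFrame,
    variables: Optional[Sequence[str]] = None,
    n_components: int = DEFAULT_N_COMPONENTS,
) -> StandingResult:
    """Correlation-matrix PCA of the composition variables plus MANOVA.

    The MANOVA tests species and functional category (crossed, with
    interaction) on the retained principal components, using Pillai's
    trace.
    """
    variables = list(variables or comp_mod.PCA_VARIABLES)
    z, _ = standardize(table, variables)
    pca = fit_pca(z, n_components=n_components, variables=variables)
    axes = pca.component_names()
    scores = pd.concat(
        [
            table[["protein_id", "species", "family_id", "category"]].reset_index(drop=True),
            pca.scores_frame().reset_index(drop=True),
        ],
        axis=1,
    )
    manova = manova_pillai(pca.scores, table[["species", "category"]])
    return StandingResult(
        pca=pca,
        scores=scores,
        manova=manova,
        species_summaries=group_summaries(scores[axes], scores["species"]),
        category_summaries=group_summaries(scores[axes], scores["category"]),
        variables=variables,
    )


@dataclass
class EvolutionResult:
    """Comparative analysis: divergence, EPC axes and the trait sweep."""

    epc: PcaModel
    mean_divergence: pd.DataFrame        # species x axis mean divergence
    sweeps: Dict[str, TraitSweepResult]
    table2: pd.DataFrame                 # traits x PC axes significant counts
    bias_tests: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        return self.table2


def _family_axis_frame(scores: pd.DataFrame, axes: Sequence[str]) -> pd.DataFrame:
    return scores[["species", "family_id", *axes]]


def evolutionary_analysis(
    scores: pd.DataFrame,
    tree: Phylogeny,
    traits: pd.DataFrame,
    table: Optional[pd.DataFrame] = None,
    variables: Optional[Sequence[str]] = None,
    alpha: float = 0.01,
    threshold_multiplier: float = 4.0,
    trait_columns: Optional[Sequence[str]] = None,
) -> EvolutionResult:
    """Run the evolutionary stage on per-protein PC scores.

    - per-species mean divergence since the most recent ancestor, per axis;
    - evolutionary PCA on contrasts pooled over families (of the raw
      composition variables when ``table`` is given, otherwise of the PC
      scores);
    - the per-family PGLS sweep of every axis against every trait column,
      with significant-count, sign-bias and category-bias summaries.

    Diet breadth, an ordinal 0/1/2 code, is treated as numeric in the
    sweep, the minimal assumption for a single ordered trait.
    """
    axes = [c for c in scores.columns if c.startswith("PC")]
    species = tree.tip_labels

    # mean divergence per species per axis (ancestral values at the origin)
    div_rows = {}
    for ax in axes:
        per_species = np.zeros(len(species))
        fam_means = scores.pivot_table(index="species", columns="family_id",
                                       values=ax, aggfunc="first")
        fam_means = fam_means.reindex(species).dropna(axis=1)
        for fam in fam_means.columns:
            per_species += divergence_since_ancestor(
                tree, fam_means[fam]
            ).reindex(species).to_numpy()
        div_rows[ax] = per_species / fam_means.shape[1]
    mean_divergence = pd.DataFrame(div_rows, index=species)

    # pooled contrasts -> evolutionary principal components
    if table is not None:
        variables = list(variables or comp_mod.PCA_VARIABLES)
        pooled = []
        for fam, sub in table.groupby("family_id"):
            tipframe = sub.set_index("species")[variables]
            if set(species) - set(tipframe.index):
                continue
            pooled.append(contrasts_matrix(tree, tipframe))
        contrast_frame = pd.concat(pooled, ignore_index=True)
    else:
        pooled = []
        for fam, sub in scores.groupby("family_id"):
            tipframe = sub.set_index("species")[axes]
            if set(species) - set(tipframe.index):
                continue
            pooled.append(contrasts_matrix(tree, tipframe))
        contrast_frame = pd.concat(pooled, ignore_index=True)
    epc = evolutionary_pca(contrast_frame, n_components=min(
        DEFAULT_N_COMPONENTS, contrast_frame.shape[1]))

    # per-trait PGLS sweep with counting and bias tests
    if trait_columns is None:
        trait_columns = [c for c in traits.columns]
    fam_scores = _family_axis_frame(scores, axes)
    categories = (
        scores.drop_duplicates("family_id").set_index("family_id")["category"]
    )
    sweeps: Dict[str, TraitSweepResult] = {}
    table2_rows = []
    bias_rows = []
    for trait_name in trait_columns:
        trait = traits[trait_name].astype(float)
        trait.name = trait_name
        sweep = trait_sweep(tree, fam_scores, trait, axes=axes, alpha=alpha,
                            threshold_multiplier=threshold_multiplier)
        sweeps[trait_name] = sweep
        counts = dict(zip(sweep.counts["axis"], sweep.counts["n_significant"]))
        table2_rows.append({"trait": trait_name, **counts})
        for ax in axes:
            sig = sweep.significant()
            sig = sig[sig["axis"] == ax]
            if len(sig) == 0:
                continue
            row = {"trait": trait_name, "axis": ax, "n_significant": len(sig),
                   "sign_bias_p": sign_bias_test(sig)}
            try:
                chi2, p, _ = category_bias_test(sig, categories=categories)
                row["category_bias_chi2"] = chi2
                row["category_bias_p"] = p
            except ValueError:
                row["category_bias_chi2"] = np.nan
                row["category_bias_p"] = np.nan
            bias_rows.append(row)
    table2 = pd.DataFrame(table2_rows).set_index("trait")
    bias = pd.DataFrame(bias_rows)
    return EvolutionResult(epc=epc, mean_divergence=mean_divergence,
                           sweeps=sweeps, table2=table2, bias_tests=bias)


def expression_analysis(
    expression: pd.DataFrame,
    composition: pd.DataFrame,
    element: str = "N",
    breakpoint: float = 5.5,
    disjoint: bool = False,
) -> pd.DataFrame:
    """Per-tissue piecewise regression of elemental content on expression.

    Returns the ranked per-tissue table (steepest-negative high-expression
    slope first) with linear and segmented estimates, the nested F test
    and significance stars.
    """
    joined = expr_mod.join_expression_composition(
        expression, composition, value_column=element
    )
    return expr_mod.tissue_sweep(joined, value_column=element,
                                 breakpoint=breakpoint, disjoint=disjoint)
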