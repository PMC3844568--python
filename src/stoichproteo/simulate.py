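"""Synthetic proteome scenarios with known, planted structure.

Generates every input the analysis pipeline reads — ortholog families
whose amino-acid composition evolves on a phylogeny, species trait tables
with optional planted associations, and bimodal tissue expression with
planted high-expression slopes — so that each stage of the pipeline can be
validated against a ground truth.

Compositional drift uses Brownian motion on elementwise logit-transformed
amino-acid frequencies (back-transformed and renormalized at the tips).
This keeps frequencies in the simplex while giving tip values the
covariance structure (proportional to shared branch length) that the
comparative methods assume, so their calibration can be tested
meaningfully.  Sequences are realized by i.i.d. draws from each tip's
frequency vector; codons are sampled with a per-species GC bias so that
realized coding-sequence GC tracks a planted species GC level.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.special import expit, logit

from .atoms import AMINO_ACIDS, SIDECHAIN_ATOMS, ELEMENTS
from .composition import COMPOSITION_COLUMNS, DEFAULT_RESIDUE_CLASSES
from .phylo import Phylogeny

logger = logging.getLogger(__name__)

#: 12-taxon fruit-fly phylogeny used as the default fixture: the standard
#: whole-genome topology with round-number branch lengths in My, total
#: depth 63.  Any Newick tree may be substituted.
DEFAULT_TREE_NEWICK = (
    "((((((Dmel:5.4,(Dsim:2.3,Dsec:2.3):3.1):6.1,(Dyak:6.5,Dere:6.5):5.0)"
    ":21.4,Dana:32.9):11.1,(Dpse:14.5,Dper:14.5):29.5):18.6,Dwil:62.6):0.4,"
    "((Dmoj:32.7,Dvir:32.7):13.1,Dgri:45.8):17.2);"
)

#: baseline amino-acid frequencies (typical eukaryote proteome averages)
DEFAULT_BASE_FREQUENCIES: Dict[str, float] = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0965, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0694,
}

#: functional categories with their proteome fractions and logit-space
#: composition offsets.  Nucleic-acid-binding-like proteins get elevated
#: lysine/arginine (hence elevated N content, the positive charge needed to
#: bind DNA); membrane-associated categories get hydrophobic offsets.
DEFAULT_CATEGORIES: Dict[str, Tuple[float, Dict[str, float]]] = {
    "nucleic_acid_binding": (0.15, {"K": 0.5, "R": 0.5}),
    "transcription_factor": (0.10, {"K": 0.3, "R": 0.3, "Q": 0.2}),
    "transporter": (0.15, {"L": 0.4, "I": 0.3, "F": 0.2}),
    "receptor": (0.10, {"L": 0.3, "V": 0.3}),
    "oxidoreductase": (0.10, {"G": 0.2}),
    "other": (0.40, {}),
}

#: planted high-expression slopes per synthetic tissue (N atoms/residue per
#: log2 unit): a strongly conserving gut-like tissue, a weakly conserving
#: neural tissue, a germline tissue with no slope, and a testis-like tissue
#: where the slope is positive.
DEFAULT_TISSUE_SLOPES: Dict[str, float] = {
    "larval_midgut_like": -0.007,
    "adult_brain_like": -0.002,
    "ovary_like": 0.0,
    "testis_like": 0.0036,
}

#: trait ranges used for realism when simulating the species table
TRAIT_RANGES: Dict[str, Tuple[float, float]] = {
    "genome_size_mb": (130.0, 364.0),
    "intron_percent": (19.6, 24.0),
    "thorax_male_mm": (0.64, 1.78),
    "thorax_female_mm": (0.80, 1.89),
    "dimorphism_mm": (0.00, 0.18),
    "development_time_d": (10.0, 27.0),
    "ovariole_number": (16.0, 43.0),
}

DIET_LEVELS = {0: "specialist", 1: "oligophagous", 2: "generalist"}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic scenario, with realistic defaults.

    ``bm_sigma2`` is the Brownian step variance of the logit-frequency
    drift per unit branch length; with the bundled 63-unit-deep tree the
    default gives tip-level logit standard deviations near 0.25, i.e.
    moderate but clearly detectable compositional divergence.
    """

    seed: int = 20130904
    n_species: int = 12
    tree_newick: Optional[str] = None          # None -> bundled default tree
    random_tree: bool = False
    n_families: int = 500
    mean_length: float = 400.0
    length_dispersion: float = 4.0             # gamma shape; larger = tighter
    base_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_FREQUENCIES))
    root_logit_sd: float = 0.30                # between-family spread at root
    bm_sigma2: float = 1e-3
    gc_base: float = 52.0                      # percent
    gc_bm_sd: float = 3.0                      # species-level GC spread
    gc_range: Tuple[float, float] = (40.0, 62.0)
    gc_coupling: float = 0.8                   # codon-sampling GC bias strength
    length_bm_sigma2: float = 2e-4             # BM variance of log length
    categories: Mapping[str, Tuple[float, Mapping[str, float]]] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORIES))
    trait_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    trait_noise_sd: float = 1.0
    tissue_slopes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_SLOPES))
    expr_low_mean: float = 2.5
    expr_high_mean: float = 7.5
    expr_low_sd: float = 1.0
    expr_high_sd: float = 1.0
    expr_weight_low: float = 0.5
    breakpoint: float = 5.5
    include_stop: bool = True

    def __post_init__(self) -> None:
        total = sum(self.base_frequencies.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"base frequencies sum to {total}, not 1")
        if not (0.0 < self.expr_weight_low < 1.0) and self.expr_weight_low != 1.0:
            # weight 1.0 is allowed as an explicit degenerate case
            raise ValueError("mixing weight must lie in (0, 1]")
        if self.bm_sigma2 < 0:
            raise ValueError("bm_sigma2 must be non-negative")
        for name, value in (("expr_low_sd", self.expr_low_sd),
                            ("expr_high_sd", self.expr_high_sd)):
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        frac = sum(f for f, _ in self.categories.values())
        if abs(frac - 1.0) > 1e-6:
            raise ValueError(f"category fractions sum to {frac}, not 1")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["categories"] = {k: [v[0], dict(v[1])] for k, v in self.categories.items()}
        return json.dumps(d, sort_keys=True, indent=1)


def load_tree(config: SimulationConfig,
              rng: Optional[np.random.Generator] = None) -> Phylogeny:
    if config.random_tree:
        rng = np.random.default_rng(config.seed) if rng is None else rng
        return random_join_tree(config.n_species, rng)
    return Phylogeny.from_string(config.tree_newick or DEFAULT_TREE_NEWICK)


def random_join_tree(n_tips: int, rng: np.random.Generator,
                     prefix: str = "sp") -> Phylogeny:
    """Random bifurcating tree by sequential pairwise joins.

    Tips start at height 0; each join happens an Exp(1) interval above the
    taller of the two joined subtrees, so all branch lengths are strictly
    positive (but the tree is generally not ultrametric).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    nodes = [(f"{prefix}{i + 1}", 0.0) for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (nwk_j, h_j) = nodes.pop(j)
        (nwk_i, h_i) = nodes.pop(i)
        h = max(h_i, h_j) + rng.exponential(1.0) + 1e-6
        nodes.append((f"({nwk_i}:{h - h_i:.8f},{nwk_j}:{h - h_j:.8f})", h))
    return Phylogeny.from_string(nodes[0][0] + ";")


# -- compositional evolution ----------------------------------------------


@dataclass
class FamilySet:
    """Per-family, per-species amino-acid frequency vectors and labels."""

    species: List[str]
    family_ids: List[str]
    categories: np.ndarray           # (F,) strings
    lengths: np.ndarray              # (F, n_species) planted protein lengths
    freqs: np.ndarray                # (F, n_species, 20)
    species_gc: pd.Series            # percent per species

    @property
    def n_families(self) -> int:
        return len(self.family_ids)


def _bm_on_tree(tree: Phylogeny, root: np.ndarray, sigma2: float,
                rng: np.random.Generator) -> np.ndarray:
    """Evolve an array-valued state by BM along the tree; returns tip states.

    ``root`` may have any trailing shape; one independent BM per entry.
    """
    states = {id(tree.tree.seed_node): root}
    tips = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent = states[id(node.parent_node)]
        step = rng.normal(0.0, np.sqrt(sigma2 * node.edge.length), size=root.shape)
        value = parent + step
        if node.is_leaf():
            tips[node.taxon.label] = value
        else:
            states[id(node)] = value
    return np.stack([tips[t] for t in tree.tip_labels], axis=0)


def simulate_family_compositions(
    config: SimulationConfig,
    tree: Phylogeny,
    rng: Optional[np.random.Generator] = None,
) -> FamilySet:
    """Evolve per-family amino-acid frequencies on the tree.

    Each family draws a root logit-frequency vector around the baseline
    (plus its category's offsets), evolves it by BM along every branch,
    and back-transforms at the tips with a 1e-6 floor and renormalization.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    f = config.n_families
    aas = list(AMINO_ACIDS)
    base = np.array([config.base_frequencies[a] for a in aas])
    base = base / base.sum()
    base_logit = logit(base)

    cat_names = list(config.categories)
    cat_fracs = np.array([config.categories[c][0] for c in cat_names])
    counts = np.floor(cat_fracs * f).astype(int)
    counts[-1] += f - counts.sum()
    categories = np.repeat(cat_names, counts)

    offsets = np.zeros((f, len(aas)))
    for name in cat_names:
        _, off = config.categories[name]
        for aa, delta in off.items():
            offsets[categories == name, aas.index(aa)] += delta

    root = base_logit + offsets + rng.normal(0.0, config.root_logit_sd,
                                             size=(f, len(aas)))
    tip_logits = _bm_on_tree(tree, root, config.bm_sigma2, rng)  # (T, F, 20)
    freqs = expit(np.transpose(tip_logits, (1, 0, 2)))           # (F, T, 20)
    floored = freqs < 1e-6
    if floored.any():
        logger.info("floored %d degenerate frequencies", int(floored.sum()))
    freqs = np.clip(freqs, 1e-6, None)
    freqs = freqs / freqs.sum(axis=2, keepdims=True)

    # per-family root length (gamma) with lognormal BM drift across species
    root_len = np.maximum(
        rng.gamma(config.length_dispersion,
                  config.mean_length / config.length_dispersion, size=f),
        30.0,
    )
    log_len_tips = _bm_on_tree(tree, np.log(root_len), config.length_bm_sigma2,
                               rng)                          # (T, F)
    lengths = np.maximum(np.exp(log_len_tips.T), 30.0).astype(int)  # (F, T)

    depth = max(tree.depths()[t] for t in tree.tip_labels)
    gc_tip = _bm_on_tree(tree, np.zeros(()), config.gc_bm_sd**2 / depth, rng)
    gc = np.clip(config.gc_base + np.asarray(gc_tip, dtype=float),
                 *config.gc_range)
    species_gc = pd.Series(gc, index=tree.tip_labels, name="gc_percent")

    fam_ids = [f"F{i:05d}" for i in range(f)]
    return FamilySet(species=list(tree.tip_labels), family_ids=fam_ids,
                     categories=categories, lengths=lengths, freqs=freqs,
                     species_gc=species_gc)


_W_MATRIX = np.array([SIDECHAIN_ATOMS[a] for a in AMINO_ACIDS], dtype=float)
_CLASS_MATRIX = np.array(
    [[1.0 if a in DEFAULT_RESIDUE_CLASSES[c] else 0.0 for a in AMINO_ACIDS]
     for c in ("hydrophobic", "polar", "positive", "negative", "aromatic")]
)


def analytic_composition(familyset: FamilySet) -> pd.DataFrame:
    """Composition table computed exactly from the frequency vectors.

    This is the infinite-length limit of sequence realization: elemental
    contents are the frequency-weighted side-chain atom counts, class
    fractions the summed class frequencies.  Used for calibration studies
    where multinomial sampling noise from finite sequences would sit on
    top of the Brownian signal and is not wanted.
    """
    f, t = familyset.freqs.shape[:2]
    contents = (familyset.freqs @ _W_MATRIX).reshape(f * t, 4)
    classes = (familyset.freqs @ _CLASS_MATRIX.T).reshape(f * t, 5)
    fams = np.repeat(familyset.family_ids, t)
    sps = np.tile(familyset.species, f)
    df = pd.DataFrame({
        "protein_id": [f"{fam}_{sp}" for fam, sp in zip(fams, sps)],
        "species": sps,
        "family_id": fams,
        "category": np.repeat(familyset.categories, t),
        "length": familyset.lengths.reshape(-1),
        "C": contents[:, 0], "N": contents[:, 1],
        "O": contents[:, 2], "S": contents[:, 3],
        "f_hydrophobic": classes[:, 0], "f_polar": classes[:, 1],
        "f_positive": classes[:, 2], "f_negative": classes[:, 3],
        "f_aromatic": classes[:, 4],
        "gc_percent": familyset.species_gc.reindex(sps).to_numpy(),
    })
    return df[COMPOSITION_COLUMNS]


# -- sequence realization --------------------------------------------------


def _codon_map() -> Dict[str, List[str]]:
    table = CodonTable.unambiguous_dna_by_id[1]
    by_aa: Dict[str, List[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        by_aa.setdefault(aa, []).append(codon)
    return by_aa


_CODONS_BY_AA = _codon_map()


def _codon_weights(gc_target: float, coupling: float) -> Dict[str, np.ndarray]:
    """Per-amino-acid codon probabilities biased toward a GC fraction."""
    g = 0.5 + coupling * (gc_target - 0.5)
    g = min(max(g, 0.01), 0.99)
    out = {}
    for aa, codons in _CODONS_BY_AA.items():
        w = np.array([
            np.prod([g if b in "GC" else 1.0 - g for b in codon])
            for codon in codons
        ])
        out[aa] = w / w.sum()
    return out


def realize_sequences(
    familyset: FamilySet,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, List[Tuple[str, str, str]]]:
    """Draw protein and coding sequences from the tip frequency vectors.

    Residues are i.i.d. from each (family, species) frequency vector with
    an initiator methionine prepended; codons are sampled per residue with
    a GC bias pulling realized GC toward the species' planted level.
    Returns ``{species: [(protein_id, protein_seq, cds_seq), ...]}``.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    aas = np.array(list(AMINO_ACIDS))
    out: Dict[str, List[Tuple[str, str, str]]] = {}
    for j, sp in enumerate(familyset.species):
        lengths = familyset.lengths[:, j].astype(int)
        bounds = np.concatenate([[0], np.cumsum(lengths - 1)])
        cw = _codon_weights(familyset.species_gc[sp] / 100.0, config.gc_coupling)
        bodies = np.concatenate([
            rng.choice(aas, size=lengths[i] - 1, p=familyset.freqs[i, j])
            for i in range(familyset.n_families)
        ])
        # sample all codons for one amino acid at a time (vectorized)
        codons = np.empty(len(bodies), dtype="<U3")
        for aa in AMINO_ACIDS:
            mask = bodies == aa
            n_aa = int(mask.sum())
            if n_aa == 0:
                continue
            opts = np.array(_CODONS_BY_AA[aa], dtype="<U3")
            codons[mask] = opts[rng.choice(len(opts), size=n_aa, p=cw[aa])]
        entries = []
        for i, fam in enumerate(familyset.family_ids):
            lo, hi = bounds[i], bounds[i + 1]
            protein = "M" + "".join(bodies[lo:hi])
            cds = "ATG" + "".join(codons[lo:hi])
            if config.include_stop:
                cds += "TAA"
            entries.append((f"{fam}_{sp}", protein, cds))
        out[sp] = entries
    return out


# -- traits ----------------------------------------------------------------


def simulate_traits(
    config: SimulationConfig,
    tree: Phylogeny,
    rng: Optional[np.random.Generator] = None,
    planted_effects: Optional[Mapping[str, Tuple[float, pd.Series]]] = None,
) -> pd.DataFrame:
    """Species trait table evolved by BM on the tree, clipped to realistic ranges.

    ``planted_effects`` maps a trait name to ``(slope, species_signal)``;
    the trait is then built as slope x signal plus BM noise instead of
    pure BM, planting a phylogenetically structured association that the
    PGLS sweep should recover.  Diet breadth is an ordinal 0/1/2 code cut
    from a latent BM character.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    planted_effects = planted_effects or {}
    depth = max(tree.depths()[t] for t in tree.tip_labels)
    traits = {}
    for name, (lo, hi) in TRAIT_RANGES.items():
        z = np.asarray(_bm_on_tree(tree, np.zeros(()), 1.0 / depth, rng), float)
        z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
        mid, width = (lo + hi) / 2.0, hi - lo
        traits[name] = np.clip(mid + z * width / 5.0, lo, hi)
    table = pd.DataFrame(traits, index=tree.tip_labels)
    table["specific_development_time"] = (
        table["development_time_d"] / table["thorax_female_mm"]
    )
    latent = np.asarray(_bm_on_tree(tree, np.zeros(()), 1.0 / depth, rng), float)
    cuts = np.quantile(latent, [1 / 3, 2 / 3])
    table["diet_breadth"] = np.digitize(latent, cuts)
    for name, (slope, signal) in planted_effects.items():
        noise = np.asarray(
            _bm_on_tree(tree, np.zeros(()), config.trait_noise_sd**2 / depth, rng),
            float,
        )
        table[name] = slope * signal.reindex(tree.tip_labels).to_numpy() + noise
    table.index.name = "species"
    return table


# -- expression ------------------------------------------------------------


def simulate_expression(
    config: SimulationConfig,
    composition: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
    focal_species: Optional[str] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Bimodal expression per tissue with planted above-breakpoint slopes.

    For every gene of the focal species and every tissue, log2 abundance is
    drawn from a two-component Gaussian mixture.  The gene's N content is
    then tilted by ``sum over tissues of slope_t * (abundance_t - c)+``,
    which plants, within each tissue, a continuous-hinge conditional mean
    with below-breakpoint slope 0 and above-breakpoint slope exactly
    ``slope_t`` (tissues are independent, so cross-tissue terms only add
    residual noise).  Returns the expression table and a copy of the
    composition table with the tilted N column.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    species = focal_species or composition["species"].iloc[0]
    comp = composition.copy()
    mask = comp["species"] == species
    genes = comp.loc[mask, "protein_id"].to_numpy()
    n_genes = len(genes)
    if n_genes == 0:
        raise ValueError(f"no composition rows for focal species {species!r}")
    tissues = list(config.tissue_slopes)
    slopes = np.array([config.tissue_slopes[t] for t in tissues])

    low = rng.random((n_genes, len(tissues))) < config.expr_weight_low
    abundance = np.where(
        low,
        rng.normal(config.expr_low_mean, config.expr_low_sd,
                   (n_genes, len(tissues))),
        rng.normal(config.expr_high_mean, config.expr_high_sd,
                   (n_genes, len(tissues))),
    )
    tilt = (np.clip(abundance - config.breakpoint, 0.0, None) * slopes).sum(axis=1)
    comp.loc[mask, "N"] = np.clip(comp.loc[mask, "N"].to_numpy() + tilt, 0.0, 3.0)

    expression = pd.DataFrame({
        "protein_id": np.repeat(genes, len(tissues)),
        "tissue": np.tile(tissues, n_genes),
        "log2_abundance": abundance.reshape(-1),
    })
    return expression, comp


# -- scenario writer -------------------------------------------------------


def _write_fasta(path: Path, entries: Sequence[Tuple[str, str]],
                 width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k:k + width] + "\n")


def write_scenario(config: SimulationConfig, outdir,
                   realize: bool = True) -> Dict[str, object]:
    """Generate a full scenario and write every pipeline input format.

    Writes per-species protein and CDS FASTA, the Newick tree, ortholog and
    category TSVs, the trait table, the expression table and a manifest
    JSON echoing the configuration.  Identical configurations produce
    byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    tree = load_tree(config, rng)
    fams = simulate_family_compositions(config, tree, rng)
    comp = analytic_composition(fams)

    files: Dict[str, str] = {}
    tree_path = outdir / "tree.nwk"
    tree_path.write_text(
        tree.tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"
    )
    files["tree"] = tree_path.name

    if realize:
        seqs = realize_sequences(fams, config, rng)
        for sp in fams.species:
            _write_fasta(outdir / f"proteins_{sp}.fasta",
                         [(pid, prot) for pid, prot, _ in seqs[sp]])
            _write_fasta(outdir / f"cds_{sp}.fasta",
                         [(pid, cds) for pid, _, cds in seqs[sp]])
        files["proteins"] = "proteins_<species>.fasta"
        files["cds"] = "cds_<species>.fasta"

    ortho = pd.DataFrame({
        "family_id": np.repeat(fams.family_ids, len(fams.species)),
        "species": np.tile(fams.species, fams.n_families),
    })
    ortho["protein_id"] = ortho["family_id"] + "_" + ortho["species"]
    ortho.to_csv(outdir / "orthologs.tsv", sep="\t", index=False)
    files["orthologs"] = "orthologs.tsv"

    cats = ortho[["protein_id"]].copy()
    cats["category"] = np.repeat(fams.categories, len(fams.species))
    cats.to_csv(outdir / "categories.tsv", sep="\t", index=False)
    files["categories"] = "categories.tsv"

    traits = simulate_traits(config, tree, rng)
    traits.to_csv(outdir / "traits.tsv", sep="\t", float_format="%.6g")
    files["traits"] = "traits.tsv"

    expression, comp_tilted = simulate_expression(config, comp, rng)
    expression.to_csv(outdir / "expression.tsv", sep="\t", index=False,
                      float_format="%.6f")
    files["expression"] = "expression.tsv"
    comp_tilted.to_csv(outdir / "composition_analytic.tsv", sep="\t",
                       index=False, float_format="%.6g")
    files["composition_analytic"] = "composition_analytic.tsv"

    manifest = {
        "config": json.loads(config.to_json()),
        "files": files,
        "config_sha1": hashlib.sha1(config.to_json().encode()).hexdigest(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True) + "\n")
    return manifest
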