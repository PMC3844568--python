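"""Per-protein composition variables.

Computes, from raw protein and coding sequences, the ten variables the
downstream multivariate and comparative analyses run on: elemental content
of C, N, O and S (mean side-chain atoms per residue), protein length,
fractions of hydrophobic / polar / positively charged / negatively charged /
aromatic residues, and coding-sequence GC content.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from Bio import SeqIO

from .atoms import AMINO_ACIDS, DEFAULT_ATOM_TABLE, ELEMENTS, AminoAcidAtomTable

logger = logging.getLogger(__name__)

#: residue-class membership used for the five sequence-property fractions.
#: Charge classes are kept separate from the hydropathy classes and the
#: aromatic class overlaps the others, so the five fractions need not sum
#: to one.  All sets are configurable per call.
DEFAULT_RESIDUE_CLASSES: Dict[str, frozenset] = {
    "hydrophobic": frozenset("ACFILMVW"),
    "polar": frozenset("GNQSTY"),
    "positive": frozenset("HKR"),
    "negative": frozenset("DE"),
    "aromatic": frozenset("FWY"),
}

#: canonical column order of the composition table
COMPOSITION_COLUMNS: List[str] = [
    "protein_id",
    "species",
    "family_id",
    "category",
    "length",
    "C",
    "N",
    "O",
    "S",
    "f_hydrophobic",
    "f_polar",
    "f_positive",
    "f_negative",
    "f_aromatic",
    "gc_percent",
]

#: the ten analysis variables, in the order used throughout
ANALYSIS_VARIABLES: List[str] = [
    "C",
    "N",
    "O",
    "S",
    "gc_percent",
    "length",
    "f_hydrophobic",
    "f_polar",
    "f_positive",
    "f_negative",
    "f_aromatic",
]
# note: 11 columns are carried; the classic 10-variable set drops one of the
# redundant class fractions.  The default analysis set matches the ten
# variables entered into the exploratory PCA:
PCA_VARIABLES: List[str] = [
    "C",
    "O",
    "N",
    "S",
    "gc_percent",
    "length",
    "f_hydrophobic",
    "f_polar",
    "f_positive",
    "f_negative",
]

_VALID_AA = set(AMINO_ACIDS)


@dataclass
class ProteinRecord:
    """One protein sequence with its analysis labels."""

    protein_id: str
    species: str
    sequence: str
    family_id: str = ""
    category: str = ""
    cds: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")


def read_protein_fasta(
    path,
    species_label: str,
    ambiguity_policy: str = "drop_protein",
) -> List[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    The protein id is the first whitespace-delimited token of each header.
    Sequences are upper-cased; trailing ``*`` (stop) is stripped.  Records
    containing residues outside the 20 standard codes are handled per
    ``ambiguity_policy``:

    - ``"drop_protein"`` (default): exclude the whole record, log a warning;
    - ``"mask"``: keep the record; ambiguous residues are excluded from both
      numerator and denominator of every downstream statistic.

    Raises ``ValueError`` on an empty file or a duplicated protein id.
    """
    if ambiguity_policy not in ("drop_protein", "mask"):
        raise ValueError(f"unknown ambiguity policy {ambiguity_policy!r}")
    records: List[ProteinRecord] = []
    seen: Set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"duplicate protein id {pid!r} in {path}")
        seen.add(pid)
        seq = str(rec.seq).upper().rstrip("*")
        bad = set(seq) - _VALID_AA
        if bad:
            if ambiguity_policy == "drop_protein":
                logger.warning(
                    "dropping protein %s (%s): ambiguous residues %s",
                    pid, species_label, "".join(sorted(bad)),
                )
                continue
            # mask: strip the offending residues entirely
            seq = "".join(c for c in seq if c in _VALID_AA)
            if not seq:
                logger.warning("protein %s is entirely ambiguous; dropped", pid)
                continue
        records.append(ProteinRecord(protein_id=pid, species=species_label, sequence=seq))
    if not seen:
        raise ValueError(f"no FASTA records found in {path}")
    logger.info("read %d proteins for %s (%d kept)", len(seen), species_label, len(records))
    return records


def attach_cds(
    records: Sequence[ProteinRecord],
    cds_path,
    includes_stop: bool = True,
    strict_length: bool = False,
) -> List[ProteinRecord]:
    """Attach coding sequences from a nucleotide FASTA, matched by id.

    ``includes_stop`` declares the CDS dialect: with a stop codon the CDS is
    3*(L+1) nucleotides for an L-residue protein, otherwise 3*L.  Length
    mismatches raise only when ``strict_length`` is set; GC content is
    computed over the full given CDS either way.
    """
    cds_by_id = {}
    for rec in SeqIO.parse(str(cds_path), "fasta"):
        if rec.id in cds_by_id:
            raise ValueError(f"duplicate CDS id {rec.id!r} in {cds_path}")
        cds_by_id[rec.id] = str(rec.seq).upper()
    out = []
    for r in records:
        cds = cds_by_id.get(r.protein_id)
        if cds is not None and strict_length:
            expected = 3 * (len(r.sequence) + 1) if includes_stop else 3 * len(r.sequence)
            if len(cds) != expected:
                raise ValueError(
                    f"CDS length {len(cds)} for {r.protein_id!r} does not match "
                    f"expected {expected}"
                )
        out.append(replace(r, cds=cds))
    return out


def elemental_content(
    sequence: str,
    element: str,
    scale: str = "per_residue",
    atom_table: AminoAcidAtomTable = DEFAULT_ATOM_TABLE,
) -> float:
    """Mean number of side-chain atoms of ``element`` per residue.

    With ``scale="per_100_residues"`` the value is multiplied by exactly
    100, i.e. 100/L * sum(w_i * n_i) with n_i the residue counts.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if scale not in ("per_residue", "per_100_residues"):
        raise ValueError(f"unknown scale {scale!r}")
    w = atom_table.weights(element)
    try:
        total = sum(w[c] for c in sequence)
    except KeyError as exc:
        raise ValueError(f"invalid residue {exc.args[0]!r} in sequence") from None
    value = total / len(sequence)
    return 100.0 * value if scale == "per_100_residues" else value


def residue_class_fractions(
    sequence: str,
    classes: Mapping[str, frozenset] = None,
) -> Dict[str, float]:
    """Fractions of residues in each configurable class (values in [0, 1])."""
    if not sequence:
        raise ValueError("empty sequence")
    classes = DEFAULT_RESIDUE_CLASSES if classes is None else classes
    n = len(sequence)
    return {
        name: sum(1 for c in sequence if c in members) / n
        for name, members in classes.items()
    }


def gc_content(cds: str) -> float:
    """GC percentage of a nucleotide sequence, over unambiguous bases only.

    N and other ambiguity codes are excluded from both numerator and
    denominator.  Raises if no unambiguous A/C/G/T base is present.
    """
    if not cds:
        raise ValueError("empty nucleotide sequence")
    s = cds.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous A/C/G/T bases in sequence")
    return 100.0 * gc / (gc + at)


def build_composition_table(
    records: Iterable[ProteinRecord],
    atom_table: AminoAcidAtomTable = DEFAULT_ATOM_TABLE,
    drop_initial_met: bool = False,
    scale: str = "per_residue",
    classes: Mapping[str, frozenset] = None,
) -> pd.DataFrame:
    """Assemble the per-protein composition table.

    One row per record with the canonical :data:`COMPOSITION_COLUMNS`.
    ``drop_initial_met`` removes a leading methionine before all sequence
    statistics (a robustness variant: every protein starts with the
    initiator Met, which otherwise contributes a constant S atom).
    """
    if classes is None:
        classes = DEFAULT_RESIDUE_CLASSES
    factor = 100.0 if scale == "per_100_residues" else 1.0
    rows = []
    for r in records:
        seq = r.sequence
        if drop_initial_met and seq.startswith("M"):
            seq = seq[1:]
        if not seq:
            logger.warning("protein %s empty after Met removal; skipped", r.protein_id)
            continue
        # one pass over the sequence; per-element sums over <= 20 residue types
        counts = Counter(seq)
        n = len(seq)
        row = {
            "protein_id": r.protein_id,
            "species": r.species,
            "family_id": r.family_id,
            "category": r.category,
            "length": n,
        }
        for e in ELEMENTS:
            w = atom_table.weights(e)
            row[e] = factor * sum(w[aa] * k for aa, k in counts.items()) / n
        for name, members in classes.items():
            row[f"f_{name}"] = sum(k for aa, k in counts.items() if aa in members) / n
        row["gc_percent"] = gc_content(r.cds) if r.cds else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=COMPOSITION_COLUMNS)


def read_ortholog_map(path) -> pd.DataFrame:
    """TSV with columns family_id, species, protein_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family_id", "species", "protein_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"ortholog map must have columns {sorted(required)}")
    return df


def read_category_map(path) -> pd.DataFrame:
    """TSV with columns protein_id, category."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"protein_id", "category"}.issubset(df.columns):
        raise ValueError("category map must have columns protein_id, category")
    return df


def annotate_records(
    records: Sequence[ProteinRecord],
    ortholog_map: Optional[pd.DataFrame] = None,
    category_map: Optional[pd.DataFrame] = None,
) -> List[ProteinRecord]:
    """Fill family and functional-category labels from the mapping tables."""
    fam = {}
    if ortholog_map is not None:
        fam = dict(zip(ortholog_map["protein_id"], ortholog_map["family_id"]))
    cat = {}
    if category_map is not None:
        cat = dict(zip(category_map["protein_id"], category_map["category"]))
    return [
        replace(
            r,
            family_id=fam.get(r.protein_id, r.family_id),
            category=cat.get(r.protein_id, r.category),
        )
        for r in records
    ]


def filter_universal_orthologs(
    profiles: pd.DataFrame,
    species_set: Iterable[str],
    tie_break: str = "longest",
) -> pd.DataFrame:
    """Restrict a composition table to families present in every species.

    Keeps exactly the families with at least one member in each species of
    ``species_set``; within a family one protein is retained per species.
    Paralog ties are broken by longest protein, then lexicographically
    smallest protein id, which makes the selection deterministic.
    """
    species_set = set(species_set)
    if not species_set:
        raise ValueError("species_set is empty")
    if tie_break != "longest":
        raise ValueError(f"unknown tie_break {tie_break!r}")
    df = profiles[profiles["species"].isin(species_set)]
    df = df[df["family_id"] != ""]
    coverage = df.groupby("family_id")["species"].nunique()
    universal = coverage[coverage == len(species_set)].index
    df = df[df["family_id"].isin(universal)]
    # one protein per (family, species): longest, then smallest id
    df = df.sort_values(
        ["family_id", "species", "length", "protein_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    out = df.drop_duplicates(["family_id", "species"], keep="first")
    logger.info(
        "universal-ortholog filter: %d of %d families retained",
        out["family_id"].nunique(), profiles["family_id"].nunique(),
    )
    return out.reset_index(drop=True)


def write_composition_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_composition_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={c: str for c in
                                              ("protein_id", "species", "family_id", "category")})
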