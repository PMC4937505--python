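"""Cleavage-site mapping, digest validation, known-site overlap and motifs.

Caspases cleave C-terminal to aspartate, so every captured neo-C-terminal
peptide ends in D (the P1 residue).  Peptides are produced by trypsin or
chymotrypsin digestion combined with the caspase cleavage, i.e. the peptide
N-terminal boundary must follow the protease rule (or be the protein
N-terminus) and the C-terminus is the P1 Asp; internal uncut K/R/D residues
count as missed cleavages, at most four in total.

Site coordinates are 1-based on the FASTA sequence; motif windows span
P5..P1 plus P1'..P6' (11 positions) in Schechter-Berger nomenclature, padded
with '-' where the window runs past a protein terminus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "-"

#: Residues after which each protease cleaves (P1 of the protease rule).
PROTEASE_P1 = {
    "trypsin": set("KR"),
    "chymotrypsin": set("FWYL"),
}

#: Residues counting toward missed cleavages in the combined digest:
#: the protease residues plus the caspase P1 aspartate.
def _cut_residues(protease: str) -> set[str]:
    try:
        return PROTEASE_P1[protease] | {"D"}
    except KeyError:
        raise ValueError(f"unknown protease: {protease!r}") from None


WINDOW_P = 5   # P5..P1
WINDOW_PPRIME = 6  # P1'..P6'
WINDOW_POSITIONS = [f"P{i}" for i in range(WINDOW_P, 0, -1)] + [
    f"P{i}'" for i in range(1, WINDOW_PPRIME + 1)
]


@dataclass
class CleavageSite:
    """One caspase cleavage site: P1 Asp coordinate plus its context."""

    accession: str
    p1_position: int  # 1-based; protein[p1_position-1] == 'D'
    window: str  # 11 residues P5..P6', '-'-padded at termini
    peptides: list[str] = field(default_factory=list)
    proteases: set[str] = field(default_factory=set)
    ambiguous: bool = False


class PeptideNotFoundError(ValueError):
    """Peptide does not occur in the given protein sequence."""


def validate_digest(
    peptide: str,
    protein: str,
    protease: str = "trypsin",
    max_missed: int = 4,
    start: int | None = None,
) -> tuple[bool, dict]:
    """Check that a peptide is a plausible protease+caspase digest product.

    Valid iff the peptide ends in D (caspase P1), its N-terminal boundary
    follows the protease rule (preceding residue in the protease's cut set,
    or protein N-terminus), and the number of internal uncut K/R/D residues
    is at most ``max_missed``.  ``start`` (0-based) disambiguates peptides
    occurring at several positions; by default the first occurrence is used.

    Returns (valid, details) where details records the failure reason, the
    0-based start and the missed-cleavage count.

    Raises
    ------
    PeptideNotFoundError
        if the peptide does not occur in the protein (distinct from an
        invalid-digest False).
    """
    if start is None:
        start = protein.find(peptide)
        if start < 0:
            raise PeptideNotFoundError(f"peptide {peptide!r} not in protein")
    elif protein[start : start + len(peptide)] != peptide:
        raise PeptideNotFoundError(f"peptide {peptide!r} not at position {start}")
    cut = _cut_residues(protease)
    details: dict = {"start": start, "p1_position": start + len(peptide)}
    if not peptide.endswith("D"):
        details["reason"] = "no C-terminal Asp"
        return False, details
    if start > 0 and protein[start - 1] not in PROTEASE_P1[protease]:
        details["reason"] = "N-terminal boundary violates protease rule"
        return False, details
    missed = sum(1 for aa in peptide[:-1] if aa in cut)
    details["missed_cleavages"] = missed
    if missed > max_missed:
        details["reason"] = f"{missed} missed cleavages > {max_missed}"
        return False, details
    details["reason"] = "ok"
    return True, details


def extract_window(protein: str, p1_position: int) -> str:
    """P5..P6' residue window around a 1-based P1 position, '-'-padded."""
    i = p1_position - 1  # 0-based index of P1
    left = protein[max(0, i - WINDOW_P + 1) : i + 1]
    left = PAD * (WINDOW_P - len(left)) + left
    right = protein[i + 1 : i + 1 + WINDOW_PPRIME]
    right = right + PAD * (WINDOW_PPRIME - len(right))
    return left + right


def map_sites(
    peptides: pd.DataFrame,
    db: dict[str, str],
    max_missed: int = 4,
) -> list[CleavageSite]:
    """Map digest-valid neo-C-terminal peptides to cleavage-site coordinates.

    ``peptides`` needs columns peptide, proteins (;-separated accessions) and
    protease.  Peptides sharing a P1 coordinate collapse into one site with
    multiple supporters; sites found under different proteases are unioned.
    A peptide matching several positions within one protein emits all of
    them, flagged ambiguous.  Unmapped peptide/protein pairs are skipped.
    """
    sites: dict[tuple[str, int], CleavageSite] = {}
    for _, row in peptides.iterrows():
        pep = row["peptide"]
        protease = row.get("protease", "trypsin")
        for acc in str(row["proteins"]).split(";"):
            protein = db.get(acc)
            if protein is None:
                continue
            starts = _occurrences(protein, pep)
            valid_starts = []
            for st in starts:
                ok, _ = validate_digest(pep, protein, protease, max_missed, start=st)
                if ok:
                    valid_starts.append(st)
            for st in valid_starts:
                p1 = st + len(pep)
                key = (acc, p1)
                site = sites.get(key)
                if site is None:
                    site = CleavageSite(acc, p1, extract_window(protein, p1))
                    sites[key] = site
                if pep not in site.peptides:
                    site.peptides.append(pep)
                site.proteases.add(protease)
                if len(valid_starts) > 1:
                    site.ambiguous = True
    return [sites[k] for k in sorted(sites)]


def _occurrences(protein: str, peptide: str) -> list[int]:
    out, i = [], protein.find(peptide)
    while i >= 0:
        out.append(i)
        i = protein.find(peptide, i + 1)
    return out


def sites_table(sites: list[CleavageSite]) -> pd.DataFrame:
    """Flatten CleavageSite objects to the sites TSV layout."""
    return pd.DataFrame(
        {
            "accession": [s.accession for s in sites],
            "p1_position": [s.p1_position for s in sites],
            "window": [s.window for s in sites],
            "n_peptides": [len(s.peptides) for s in sites],
            "peptides": [";".join(sorted(s.peptides)) for s in sites],
            "proteases": [";".join(sorted(s.proteases)) for s in sites],
            "ambiguous": [s.ambiguous for s in sites],
        }
    )


def overlap_known(
    sites: list[CleavageSite] | pd.DataFrame,
    references: dict[str, pd.DataFrame],
    by: str = "site",
) -> pd.DataFrame:
    """Venn-style overlap of study sites with known-site repositories.

    References are tables with accession and p1_position columns.  Matching
    is exact-coordinate by default (``by='site'``); ``by='protein'`` matches
    at accession granularity for legacy repositories without coordinates.
    Returns one row per reference plus a 'union' row with shared,
    unique-to-study and unique-to-reference counts.
    """
    if isinstance(sites, list):
        study = {(s.accession, s.p1_position) for s in sites}
    else:
        study = set(zip(sites["accession"], sites["p1_position"]))
    if by == "protein":
        study = {acc for acc, _ in study}
    study_accs = {k if by == "protein" else k[0] for k in study}
    rows = []
    union: set = set()
    for name, ref in references.items():
        if by == "protein":
            ref_keys = set(ref["accession"])
        else:
            ref_keys = set(zip(ref["accession"], ref["p1_position"].astype(int)))
        ref_accs = {k if by == "protein" else k[0] for k in ref_keys}
        unmatched = len(ref_accs - study_accs)
        if unmatched:
            warnings.warn(
                f"{name}: {unmatched} reference accessions absent from study "
                "accession space (counted as non-overlapping)"
            )
        union |= ref_keys
        rows.append((name, len(study & ref_keys), len(study - ref_keys), len(ref_keys - study)))
    rows.append(("union", len(study & union), len(study - union), len(union - study)))
    return pd.DataFrame(rows, columns=["reference", "shared", "unique_study", "unique_reference"])


def motif_matrix(sites: list[CleavageSite]) -> pd.DataFrame:
    """Positional residue-probability matrix over the P5..P6' windows.

    Rows are the 20 canonical residues, columns the window positions.  Pad
    symbols from terminus-truncated windows are excluded from the column
    denominators; every column with at least one non-pad residue sums to 1.
    A ``count`` row records the non-padded count per column.
    """
    if not sites:
        raise ValueError("at least one site is required")
    n_pos = len(WINDOW_POSITIONS)
    counts = np.zeros((len(AMINO_ACIDS), n_pos))
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for s in sites:
        for j, aa in enumerate(s.window):
            if aa in aa_index:
                counts[aa_index[aa], j] += 1
    col_totals = counts.sum(axis=0)
    probs = np.divide(counts, col_totals, out=np.zeros_like(counts), where=col_totals > 0)
    mat = pd.DataFrame(probs, index=list(AMINO_ACIDS), columns=WINDOW_POSITIONS)
    mat.loc["count"] = col_totals
    return mat


def render_logo(matrix: pd.DataFrame, path: str) -> None:
    """Minimal probability-unit sequence logo (stacked letters per column)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    probs = matrix.drop(index="count", errors="ignore")
    fig, ax = plt.subplots(figsize=(0.6 * probs.shape[1], 2.5))
    for j, pos in enumerate(probs.columns):
        y = 0.0
        col = probs[pos].sort_values()
        for aa, p in col.items():
            if p <= 0:
                continue
            ax.text(j, y + p / 2, aa, ha="center", va="center",
                    fontsize=4 + 16 * p, family="monospace")
            y += p
    ax.set_xticks(range(probs.shape[1]), probs.columns, fontsize=7)
    ax.set_ylim(0, 1.02)
    ax.set_ylabel("probability")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
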