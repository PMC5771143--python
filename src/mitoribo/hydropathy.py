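"""Leader-peptide hydropathy (GRAVY) of the first residues of each ORF.

GRAVY is the grand average of hydropathy: the arithmetic mean of
Kyte-Doolittle per-residue values over a peptide; positive scores are
hydrophobic.  Applied here to the first 10 residues of each reading
frame, with initiator recoding (AUA/AUU -> Met) applied before scoring so
the scored peptide matches the mature protein sequence.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .reference import GeneticCode, GenomeReference, OrfAnnotation, ReferenceError, translate_prefix

#: Kyte & Doolittle (1982) hydropathy values, one per amino acid.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8,
    "R": -4.5,
    "N": -3.5,
    "D": -3.5,
    "C": 2.5,
    "Q": -3.5,
    "E": -3.5,
    "G": -0.4,
    "H": -3.2,
    "I": 4.5,
    "L": 3.8,
    "K": -3.9,
    "M": 1.9,
    "F": 2.8,
    "P": -1.6,
    "S": -0.8,
    "T": -0.7,
    "W": -0.9,
    "Y": -1.3,
    "V": 4.2,
}

DEFAULT_PREFIX_RESIDUES = 10


def load_scale_tsv(path: str | Path) -> dict[str, float]:
    """Load an override hydropathy scale from a 2-column TSV (aa, value)."""
    scale: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, value = line.split("\t")[:2]
        scale[aa] = float(value)
    if len(scale) != 20:
        raise ValueError(f"{path}: hydropathy scale must have 20 entries, got {len(scale)}")
    return scale


def gravy(peptide: str, scale: dict[str, float] | None = None) -> float:
    """Arithmetic mean of per-residue hydropathy values."""
    if not peptide:
        raise ValueError("empty peptide")
    if scale is None:
        scale = KYTE_DOOLITTLE
    try:
        return sum(scale[aa] for aa in peptide) / len(peptide)
    except KeyError as exc:
        raise ValueError(f"unknown amino acid letter {exc.args[0]!r}") from exc


def leader_hydropathy_table(
    ref: GenomeReference,
    orfs: list[OrfAnnotation],
    n_residues: int = DEFAULT_PREFIX_RESIDUES,
    code: GeneticCode | None = None,
    scale: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-gene table of the first-``n_residues`` peptide and its GRAVY.

    Reading frames too short for ``n_residues``, or with a premature stop
    inside the prefix, are flagged in the ``note`` column and carry NaN.
    """
    rows = []
    for orf in orfs:
        peptide = None
        score = float("nan")
        note = ""
        try:
            peptide = translate_prefix(ref, orf, n_residues, code=code)
            score = gravy(peptide, scale=scale)
        except ReferenceError as exc:
            note = str(exc)
        rows.append(
            {"gene_id": orf.gene_id, "peptide": peptide, "gravy": score, "note": note}
        )
    return pd.DataFrame(rows, columns=["gene_id", "peptide", "gravy", "note"])
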