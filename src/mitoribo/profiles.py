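"""Per-ORF positional footprint distributions.

Each gene's codon-resolution count vector is expressed as a proportion of
the footprints found over all the annotated reading frames in the
library, so the traces of all genes share one fractional scale and sum to
1 across the library (when every counted footprint maps inside a CDS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .footprints import CodonCountMatrix


@dataclass
class OrfDistribution:
    """Fractional footprint distribution across one gene's codons."""

    gene_id: str
    values: np.ndarray
    normalization: str = "per_all_orfs"

    @property
    def gene_share(self) -> float:
        return float(self.values.sum())


def orf_fractional_distribution(matrix: CodonCountMatrix) -> list[OrfDistribution]:
    """Divide every (gene, codon) count by the grand total over all genes.

    Expects single-assignment (``asite_offset``) counts so the proportions
    are interpretable as read shares.
    """
    total = matrix.total()
    if total == 0:
        raise ValueError("all-zero count matrix: no footprints mapped to any ORF")
    return [
        OrfDistribution(gene_id=gene_id, values=vec / total)
        for gene_id, vec in matrix.counts.items()
    ]


def distributions_to_frame(dists: list[OrfDistribution]) -> pd.DataFrame:
    rows = []
    for d in dists:
        for i, v in enumerate(d.values):
            rows.append({"gene_id": d.gene_id, "codon_index": i, "fraction": v})
    return pd.DataFrame(rows)
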