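"""5'-terminus footprint block analysis.

Mature mt-mRNAs begin at or within a few nucleotides of the start codon,
and initiating mitoribosomes leave footprints whose 5' ends pile up at
the transcript terminus.  This module reproduces that analysis: select
the initiation-proximal footprints (5' end from the transcript terminus
through 5 nt downstream of the start codon's first nucleotide), group
them by identical 5' start position into "blocks" whose depth is the
within-population fraction, and summarise how many cover the start codon
or the non-coding leader.

For reading frames that initiate internally on a bicistronic transcript
(large leaders), the window's upstream bound is anchored ``leader_context``
nt (default 40) upstream of the start codon instead of at the transcript
terminus.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .footprints import FootprintLibrary
from .reference import OrfAnnotation

logger = logging.getLogger(__name__)

DEFAULT_LEADER_CONTEXT = 40
#: nt downstream of the start codon's first nucleotide still admitted.
WINDOW_DOWNSTREAM_NT = 5


@dataclass(frozen=True)
class TerminusWindow:
    """Admissible footprint 5'-end genome positions, inclusive on both ends.

    ``lo``/``hi`` are forward-genome coordinates; in transcript orientation
    the window runs from the (possibly context-clipped) upstream bound to
    ``start_first_nt + 5``.
    """

    gene_id: str
    lo: int
    hi: int
    strand: str

    def contains(self, positions: np.ndarray) -> np.ndarray:
        return (positions >= self.lo) & (positions <= self.hi)


def terminus_window(
    orf: OrfAnnotation, leader_context: int = DEFAULT_LEADER_CONTEXT
) -> TerminusWindow:
    start = orf.start_first_nt
    if orf.strand == "+":
        upstream = max(orf.transcript_5p, start - leader_context)
        lo, hi = upstream, start + WINDOW_DOWNSTREAM_NT
    else:
        upstream = min(orf.transcript_5p, start + leader_context)
        lo, hi = start - WINDOW_DOWNSTREAM_NT, upstream
    return TerminusWindow(gene_id=orf.gene_id, lo=lo, hi=hi, strand=orf.strand)


def select_terminal_footprints(
    lib: FootprintLibrary,
    orf: OrfAnnotation,
    leader_context: int = DEFAULT_LEADER_CONTEXT,
) -> FootprintLibrary:
    """Footprints whose 5' end lies in the terminus window, strand-matched."""
    window = terminus_window(orf, leader_context)
    mask = (lib.strand == orf.strand) & window.contains(lib.five_prime)
    n = int(mask.sum())
    return lib.subset(mask, total_reads=max(n, 1) if n else 1)


@dataclass
class BlockGroup:
    """All footprints sharing one 5' start position."""

    position: int
    count: int
    fraction: float
    length_histogram: Counter

    @property
    def modal_length(self) -> int:
        return self.length_histogram.most_common(1)[0][0]


@dataclass
class BlockSet:
    """5'-start groups of the terminus population; fractions sum to 1."""

    gene_id: str
    groups: dict[int, BlockGroup] = field(default_factory=dict)

    @property
    def n_footprints(self) -> int:
        return sum(g.count for g in self.groups.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "position": g.position,
                "count": g.count,
                "fraction": g.fraction,
                "modal_length": g.modal_length,
            }
            for g in sorted(self.groups.values(), key=lambda g: g.position)
        ]
        return pd.DataFrame(rows, columns=["position", "count", "fraction", "modal_length"])


def block_fractions(subset: FootprintLibrary, gene_id: str = "") -> BlockSet:
    """Group terminus footprints by identical 5' start.

    The depth (fraction) of each block is its share of the terminus
    population; footprints of different lengths at one start form a
    single block carrying a length histogram.
    """
    if len(subset) == 0:
        logger.warning("block_fractions: empty footprint subset for %s", gene_id)
        return BlockSet(gene_id=gene_id)
    total = len(subset)
    groups: dict[int, BlockGroup] = {}
    positions = subset.five_prime
    for pos in np.unique(positions):
        sel = positions == pos
        hist = Counter(int(l) for l in subset.length[sel])
        count = int(sel.sum())
        groups[int(pos)] = BlockGroup(
            position=int(pos), count=count, fraction=count / total, length_histogram=hist
        )
    return BlockSet(gene_id=gene_id, groups=groups)


def start_coverage_fraction(
    subset: FootprintLibrary,
    orf: OrfAnnotation,
    metric: str = "includes_start_first_nt",
) -> float:
    """Fraction of the terminus population covering the initiation region.

    ``includes_start_first_nt``: footprints whose aligned span contains the
    first nucleotide of the start codon and whose 5' end lies at or
    upstream of it (transcript orientation).  ``covers_leader``:
    footprints whose 5' end lies strictly upstream of the start codon;
    requires a non-zero leader.
    """
    if metric not in ("includes_start_first_nt", "covers_leader"):
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "covers_leader" and orf.leader_length == 0:
        raise ValueError(
            f"{orf.gene_id}: covers_leader undefined for a leaderless transcript"
        )
    if len(subset) == 0:
        return 0.0
    start = orf.start_first_nt
    p = subset.five_prime
    if orf.strand == "+":
        at_or_before = p <= start
        strictly_before = p < start
        contains = at_or_before & (p + subset.length > start)
    else:
        at_or_before = p >= start
        strictly_before = p > start
        contains = at_or_before & (p - subset.length < start)
    hits = contains if metric == "includes_start_first_nt" else strictly_before
    return float(hits.sum()) / len(subset)


def region_pileup(
    lib: FootprintLibrary, start: int, end: int, strand: str
) -> np.ndarray:
    """Per-nucleotide coverage over [start, end) from strand-matching spans."""
    if end <= start:
        raise ValueError("empty interval")
    span_start, span_end = lib.intervals()
    sel = lib.strand == strand
    s = np.clip(span_start[sel], start, end) - start
    e = np.clip(span_end[sel], start, end) - start
    diff = np.zeros(end - start + 1, dtype=np.int64)
    np.add.at(diff, s, 1)
    np.add.at(diff, e, -1)
    return np.cumsum(diff[:-1])


def pileup_to_frame(coverage: np.ndarray, start: int) -> pd.DataFrame:
    return pd.DataFrame(
        {"position": np.arange(start, start + len(coverage)), "coverage": coverage}
    )
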