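"""Aligned footprint libraries: parsing, length filtering, codon counting.

Footprints are ribosome-protected fragments; in mitochondrial profiling
libraries they span 24-37 nt.  Each footprint is reduced to its 5'-most
aligned nucleotide in transcript orientation, its aligned length and its
strand.  Libraries are stored column-wise in numpy arrays so that
million-read simulated libraries stay cheap to process.

Read-to-codon assignment supports two modes:

``asite_offset``
    each footprint increments exactly one codon, the codon containing the
    position ``five_prime + offset`` in transcript orientation (the
    conventional fixed-offset A-site proxy; default offset 14 nt,
    mid-footprint for 24-37 nt fragments);
``coverage``
    each footprint increments every codon whose three nucleotides all lie
    inside its aligned span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .reference import CODON_INDEX, GenomeReference, OrfAnnotation, extract_orf_codons

logger = logging.getLogger(__name__)

#: Hard sanity bounds applied at parse time; anything outside is malformed.
PARSE_MIN_LENGTH = 15
PARSE_MAX_LENGTH = 50

#: The footprint length window supported by the mitoribosome data.
DEFAULT_MIN_LENGTH = 24
DEFAULT_MAX_LENGTH = 37

#: Default 5'-end to A-site offset in nt.
DEFAULT_ASITE_OFFSET = 14


class FootprintParseError(ValueError):
    """Raised for malformed footprint records."""


class Footprint(NamedTuple):
    five_prime_pos: int
    length: int
    strand: str


@dataclass
class FootprintLibrary:
    """One replicate's footprints, column-wise.

    ``total_reads`` is the denominator for fractional profiles.  It is
    fixed at parse time to the number of retained primary alignments and,
    by default, is NOT recomputed after length filtering ("total number of
    reads per replicate" read literally).
    """

    replicate_id: str
    condition: str
    five_prime: np.ndarray
    length: np.ndarray
    strand: np.ndarray
    total_reads: int

    def __post_init__(self) -> None:
        self.five_prime = np.asarray(self.five_prime, dtype=np.int64)
        self.length = np.asarray(self.length, dtype=np.int64)
        self.strand = np.asarray(self.strand, dtype="<U1")
        if not (len(self.five_prime) == len(self.length) == len(self.strand)):
            raise ValueError("footprint columns have unequal lengths")
        if self.total_reads < len(self.five_prime):
            raise ValueError(
                f"{self.replicate_id}: total_reads={self.total_reads} smaller than "
                f"stored footprint count {len(self.five_prime)}"
            )

    def __len__(self) -> int:
        return len(self.five_prime)

    def __iter__(self) -> Iterator[Footprint]:
        for p, l, s in zip(self.five_prime, self.length, self.strand):
            yield Footprint(int(p), int(l), str(s))

    @classmethod
    def from_records(
        cls,
        records: Sequence[Footprint],
        replicate_id: str = "rep1",
        condition: str = "control",
        total_reads: int | None = None,
    ) -> "FootprintLibrary":
        records = list(records)
        return cls(
            replicate_id=replicate_id,
            condition=condition,
            five_prime=np.array([r.five_prime_pos for r in records], dtype=np.int64),
            length=np.array([r.length for r in records], dtype=np.int64),
            strand=np.array([r.strand for r in records], dtype="<U1"),
            total_reads=len(records) if total_reads is None else total_reads,
        )

    def subset(self, mask: np.ndarray, total_reads: int | None = None) -> "FootprintLibrary":
        return FootprintLibrary(
            replicate_id=self.replicate_id,
            condition=self.condition,
            five_prime=self.five_prime[mask],
            length=self.length[mask],
            strand=self.strand[mask],
            total_reads=self.total_reads if total_reads is None else total_reads,
        )

    def intervals(self) -> tuple[np.ndarray, np.ndarray]:
        """Half-open genome intervals [start, end) of the aligned spans."""
        fwd = self.strand == "+"
        start = np.where(fwd, self.five_prime, self.five_prime - self.length + 1)
        end = np.where(fwd, self.five_prime + self.length, self.five_prime + 1)
        return start, end


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _check_parse_length(length: int, where: str) -> None:
    if not PARSE_MIN_LENGTH <= length <= PARSE_MAX_LENGTH:
        raise FootprintParseError(
            f"{where}: footprint length {length} outside sanity bounds "
            f"[{PARSE_MIN_LENGTH},{PARSE_MAX_LENGTH}]"
        )


def _read_bed(path: str | Path, genome_id: str | None) -> tuple[list[Footprint], int]:
    records: list[Footprint] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FootprintParseError(
                    f"{path}:{lineno}: BED6 record has {len(parts)} fields, need 6"
                )
            chrom, start_s, end_s, _name, _score, strand = parts[:6]
            if genome_id is not None and chrom != genome_id:
                raise FootprintParseError(
                    f"{path}:{lineno}: unknown contig {chrom!r} (expected {genome_id!r})"
                )
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FootprintParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if strand not in ("+", "-") or end <= start:
                raise FootprintParseError(f"{path}:{lineno}: malformed BED record")
            length = end - start
            _check_parse_length(length, f"{path}:{lineno}")
            five_prime = start if strand == "+" else end - 1
            records.append(Footprint(five_prime, length, strand))
    return records, len(records)


def _read_sam(path: str | Path, genome_id: str | None) -> tuple[list[Footprint], int]:
    import pysam

    records: list[Footprint] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                skipped += 1
                continue
            if genome_id is not None and read.reference_name != genome_id:
                raise FootprintParseError(
                    f"{path}: unknown contig {read.reference_name!r} "
                    f"(expected {genome_id!r})"
                )
            length = read.reference_length
            _check_parse_length(length, f"{path}:{read.query_name}")
            if read.is_reverse:
                records.append(Footprint(read.reference_end - 1, length, "-"))
            else:
                records.append(Footprint(read.reference_start, length, "+"))
    if skipped:
        logger.info("%s: skipped %d unmapped/secondary records", path, skipped)
    return records, len(records)


def read_footprints(
    path: str | Path,
    format: str | None = None,
    replicate_id: str = "rep1",
    condition: str = "control",
    genome_id: str | None = None,
) -> FootprintLibrary:
    """Read an aligned footprint library from BED6 or SAM/BAM.

    For minus-strand records the 5'-most nucleotide in transcript
    orientation is the rightmost aligned base.  ``total_reads`` is set to
    the number of retained primary alignments, before length filtering.
    """
    if format is None:
        suffix = Path(path).suffix.lower()
        format = "bed" if suffix == ".bed" else "sam"
    format = format.lower()
    if format == "bed":
        records, total = _read_bed(path, genome_id)
    elif format in ("sam", "bam"):
        records, total = _read_sam(path, genome_id)
    else:
        raise ValueError(f"unknown footprint format {format!r}")
    return FootprintLibrary.from_records(
        records, replicate_id=replicate_id, condition=condition, total_reads=total
    )


def filter_by_length(
    lib: FootprintLibrary,
    min_len: int = DEFAULT_MIN_LENGTH,
    max_len: int = DEFAULT_MAX_LENGTH,
    denominator: str = "parsed",
) -> FootprintLibrary:
    """Keep footprints with ``min_len <= length <= max_len``.

    ``denominator='parsed'`` (default) keeps the parse-time ``total_reads``;
    ``'filtered'`` resets it to the retained count.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    if denominator not in ("parsed", "filtered"):
        raise ValueError(f"unknown denominator policy {denominator!r}")
    mask = (lib.length >= min_len) & (lib.length <= max_len)
    total = lib.total_reads if denominator == "parsed" else int(mask.sum())
    return lib.subset(mask, total_reads=total)


# ---------------------------------------------------------------------------
# Codon counting
# ---------------------------------------------------------------------------

@dataclass
class CodonCountMatrix:
    """Per-(gene, codon) footprint counts plus the codon identities.

    ``counts[gene_id]`` is an int vector over the gene's complete codons;
    ``codons[gene_id]`` the matching RNA codon strings.  ``skipped_short``
    counts footprints dropped in ``asite_offset`` mode because the offset
    reached past their 3' end.
    """

    counts: dict[str, np.ndarray]
    codons: dict[str, list[str]]
    mode: str
    offset: int
    skipped_short: int = 0

    def total(self) -> int:
        return int(sum(v.sum() for v in self.counts.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene_id, vec in self.counts.items():
            cods = self.codons[gene_id]
            for i, (codon, count) in enumerate(zip(cods, vec)):
                rows.append(
                    {
                        "gene_id": gene_id,
                        "codon_index": i,
                        "codon": codon,
                        "count": int(count),
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _transcript_codon_index(
    orf: OrfAnnotation, positions: np.ndarray
) -> np.ndarray:
    """Codon index of genome positions, in transcript orientation (may be
    negative / past-the-end for positions outside the CDS)."""
    if orf.strand == "+":
        rel = positions - orf.cds_start
    else:
        rel = (orf.cds_end - 1) - positions
    return np.floor_divide(rel, 3)


def codon_counts(
    lib: FootprintLibrary,
    ref: GenomeReference,
    orfs: Sequence[OrfAnnotation],
    mode: str = "asite_offset",
    offset: int = DEFAULT_ASITE_OFFSET,
) -> CodonCountMatrix:
    """Assign footprints to codons of the annotated reading frames.

    Footprints are assigned to a reading frame only when strands match; a
    footprint over the overlap of a bicistronic pair contributes to each
    frame it satisfies the rule for.  In ``asite_offset`` mode footprints
    shorter than ``offset + 1`` are skipped (counted in ``skipped_short``).
    """
    if mode not in ("asite_offset", "coverage"):
        raise ValueError(f"unknown counting mode {mode!r}")
    counts: dict[str, np.ndarray] = {}
    codons: dict[str, list[str]] = {}
    skipped_short = 0

    fwd = lib.strand == "+"
    if mode == "asite_offset":
        long_enough = lib.length > offset
        skipped_short = int((~long_enough).sum())
        asite = np.where(fwd, lib.five_prime + offset, lib.five_prime - offset)
    span_start, span_end = lib.intervals()

    for orf in orfs:
        cods = extract_orf_codons(ref, orf)
        n = len(cods)
        vec = np.zeros(n, dtype=np.int64)
        strand_mask = lib.strand == orf.strand
        if mode == "asite_offset":
            sel = strand_mask & long_enough
            idx = _transcript_codon_index(orf, asite[sel])
            # positions in a trailing incomplete codon fall at index n; drop
            valid = (idx >= 0) & (idx < n)
            # the A-site must lie inside the CDS on the genome axis too
            pos = asite[sel]
            inside = (pos >= orf.cds_start) & (pos < orf.cds_end)
            np.add.at(vec, idx[valid & inside], 1)
        else:  # coverage
            s = span_start[strand_mask]
            e = span_end[strand_mask]
            if orf.strand == "+":
                j_lo = np.ceil((s - orf.cds_start) / 3).astype(np.int64)
                j_hi = np.floor_divide(e - 3 - orf.cds_start, 3)
            else:
                # codon j spans genome [cds_end-3(j+1), cds_end-3j)
                j_lo = np.ceil((orf.cds_end - e) / 3).astype(np.int64)
                j_hi = np.floor_divide(orf.cds_end - 3 - s, 3)
            j_lo = np.maximum(j_lo, 0)
            j_hi = np.minimum(j_hi, n - 1)
            ok = j_lo <= j_hi
            diff = np.zeros(n + 1, dtype=np.int64)
            np.add.at(diff, j_lo[ok], 1)
            np.add.at(diff, j_hi[ok] + 1, -1)
            vec = np.cumsum(diff[:-1])
        counts[orf.gene_id] = vec
        codons[orf.gene_id] = cods
    return CodonCountMatrix(
        counts=counts, codons=codons, mode=mode, offset=offset, skipped_short=skipped_short
    )
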