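"""Reference genome, ORF annotations, codon extraction and codon usage.

The mitochondrial genome is a single circular contig carrying 13
protein-coding reading frames.  Several features distinguish it from a
nuclear annotation and are modelled explicitly here:

* most mt-mRNAs have no 5' UTR at all; a few have leaders of 1 or 3 nt;
* two transcription units are bicistronic, with the downstream reading
  frame overlapping (out of frame) the upstream one and initiating
  internally;
* several reading frames end in an incomplete stop codon (U or UA on the
  genome) that is only completed to UAA by polyadenylation of the mRNA;
* the vertebrate mitochondrial genetic code reassigns UGA to Trp and
  AGA/AGG to stop, and initiates at AUA and AUU in addition to AUG.

Coordinates are 0-based, half-open on the forward genome axis throughout
the package; the GFF3 reader/writer converts from/to the 1-based inclusive
convention at the file boundary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

#: The 64 RNA codons in lexicographic (A<C<G<U) order; the fixed axis for
#: every 64-vector in the package.
CODONS: tuple[str, ...] = tuple(
    "".join(t) for t in itertools.product("ACGU", repeat=3)
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

_VALID_GENOME_ALPHABET = frozenset("ACGT")


class ReferenceError(ValueError):
    """Raised for malformed genomes or annotations."""


# ---------------------------------------------------------------------------
# Genetic code
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon translation table plus the set of initiator codons.

    ``table`` maps RNA codons to one-letter amino acids, with ``'*'`` for
    stop.  ``start_codons`` are rendered as initiator Met when they occur
    in first position of a reading frame, whatever their elongation
    meaning (AUU is Ile mid-frame but fMet at initiation).
    """

    table: dict[str, str]
    start_codons: frozenset[str]

    def __post_init__(self) -> None:
        if set(self.table) != set(CODONS):
            raise ReferenceError(
                f"genetic code must have exactly 64 RNA codon entries, got {len(self.table)}"
            )

    @classmethod
    def vertebrate_mitochondrial(cls) -> "GeneticCode":
        """The vertebrate mitochondrial code (NCBI transl_table 2).

        UGA->Trp, AUA->Met, AGA/AGG->stop; initiators include AUG, AUA,
        AUU.  Backed by Biopython's codon table.
        """
        tbl = CodonTable.unambiguous_rna_by_id[2]
        mapping = dict(tbl.forward_table)
        for stop in tbl.stop_codons:
            mapping[stop] = "*"
        return cls(table=mapping, start_codons=frozenset(tbl.start_codons))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneticCode":
        """Load an override code from a 2/3-column TSV: codon, aa[, start].

        ``aa`` is a one-letter amino acid or ``*``; a third column equal to
        ``start`` marks initiator codons.
        """
        table: dict[str, str] = {}
        starts: set[str] = set()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            codon = parts[0].upper().replace("T", "U")
            table[codon] = parts[1]
            if len(parts) > 2 and parts[2] == "start":
                starts.add(codon)
        return cls(table=table, start_codons=frozenset(starts))

    def is_stop(self, codon: str) -> bool:
        return self.table[codon] == "*"

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.table.items() if aa == "*")


# ---------------------------------------------------------------------------
# Genome and annotation containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeReference:
    """A single circular (or linear) DNA contig over the strict ACGT alphabet."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ReferenceError("genome sequence is empty")
        bad = set(self.sequence) - _VALID_GENOME_ALPHABET
        if bad:
            raise ReferenceError(
                f"genome {self.id!r} contains characters outside ACGT: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfAnnotation:
    """One reading frame on the genome.

    ``cds_start``/``cds_end`` are 0-based half-open on the forward genome
    axis regardless of strand.  ``leader_length`` is the 5' UTR length in
    transcript orientation; ``transcript_5p`` the genome coordinate of the
    transcript's first nucleotide.  ``incomplete_stop_nt`` counts the stop
    codon nucleotides missing from the genomic CDS (completed by
    polyadenylation on the real transcript).  Both reading frames of a
    bicistronic unit share a ``transcript_id``.
    """

    gene_id: str
    transcript_id: str
    strand: str
    cds_start: int
    cds_end: int
    leader_length: int = 0
    incomplete_stop_nt: int = 0
    transcript_5p: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ReferenceError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.cds_start < self.cds_end:
            raise ReferenceError(f"{self.gene_id}: cds_start must be < cds_end")
        if self.incomplete_stop_nt not in (0, 1, 2):
            raise ReferenceError(
                f"{self.gene_id}: incomplete_stop_nt must be 0, 1 or 2"
            )
        if (self.cds_end - self.cds_start + self.incomplete_stop_nt) % 3 != 0:
            raise ReferenceError(
                f"{self.gene_id}: CDS length {self.cds_end - self.cds_start} plus "
                f"{self.incomplete_stop_nt} incomplete-stop nt is not a multiple of 3"
            )
        if self.leader_length < 0:
            raise ReferenceError(f"{self.gene_id}: negative leader_length")
        expected_5p = (
            self.cds_start - self.leader_length
            if self.strand == "+"
            else self.cds_end - 1 + self.leader_length
        )
        if self.transcript_5p is None:
            object.__setattr__(self, "transcript_5p", expected_5p)
        elif self.transcript_5p != expected_5p:
            raise ReferenceError(
                f"{self.gene_id}: transcript_5p={self.transcript_5p} inconsistent "
                f"with leader_length={self.leader_length} (expected {expected_5p})"
            )

    @property
    def n_codons(self) -> int:
        """Number of complete codons in the genomic CDS (incomplete stop excluded)."""
        return (self.cds_end - self.cds_start) // 3

    @property
    def start_first_nt(self) -> int:
        """Genome coordinate of the first nucleotide of the start codon."""
        return self.cds_start if self.strand == "+" else self.cds_end - 1

    def validate_against(self, genome: GenomeReference) -> None:
        if self.cds_start < 0 or self.cds_end > len(genome):
            raise ReferenceError(
                f"{self.gene_id}: CDS [{self.cds_start},{self.cds_end}) outside "
                f"genome of length {len(genome)}"
            )
        if not 0 <= self.transcript_5p < len(genome):
            raise ReferenceError(
                f"{self.gene_id}: transcript_5p={self.transcript_5p} outside genome"
            )


# ---------------------------------------------------------------------------
# Codon usage
# ---------------------------------------------------------------------------

@dataclass
class CodonUsageProfile:
    """Genomic codon tally and the fractional abundance profile (sums to 1)."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        missing = set(CODONS) - set(self.counts)
        for c in missing:
            self.counts[c] = 0
        if any(v < 0 for v in self.counts.values()):
            raise ReferenceError("negative codon count")
        if self.total == 0:
            raise ReferenceError("no coding codons")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        tot = self.total
        return {c: self.counts[c] / tot for c in CODONS}

    def fraction_vector(self) -> "np.ndarray":
        import numpy as np

        tot = self.total
        return np.array([self.counts[c] / tot for c in CODONS], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        tot = self.total
        return pd.DataFrame(
            {
                "codon": CODONS,
                "count": [self.counts[c] for c in CODONS],
                "fraction": [self.counts[c] / tot for c in CODONS],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def read_genome_fasta(path: str | Path, circular: bool = True) -> GenomeReference:
    """Read a single-contig FASTA into a :class:`GenomeReference`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ReferenceError(
            f"{path}: expected exactly one contig, found {len(records)}"
        )
    rec = records[0]
    return GenomeReference(id=rec.id, sequence=str(rec.seq).upper(), circular=circular)


_TSV_COLUMNS = [
    "gene_id",
    "transcript_id",
    "strand",
    "cds_start",
    "cds_end",
    "leader_length",
    "incomplete_stop_nt",
    "transcript_5p",
]


def _orfs_from_gff3(path: str | Path) -> list[OrfAnnotation]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    orfs = []
    for feat in db.features_of_type("CDS"):
        def attr(name: str, default=None):
            vals = feat.attributes.get(name)
            if vals is None:
                if default is None:
                    raise ReferenceError(
                        f"{path}: CDS record {feat.id!r} missing attribute {name!r}"
                    )
                return default
            return vals[0]

        orfs.append(
            OrfAnnotation(
                gene_id=attr("gene_id"),
                transcript_id=attr("transcript_id"),
                strand=feat.strand,
                cds_start=feat.start - 1,  # GFF3 1-based inclusive -> 0-based half-open
                cds_end=feat.end,
                leader_length=int(attr("leader_length", "0")),
                incomplete_stop_nt=int(attr("incomplete_stop_nt", "0")),
                transcript_5p=int(attr("transcript_5p")) - 1
                if "transcript_5p" in feat.attributes
                else None,
            )
        )
    return orfs


def _orfs_from_tsv(path: str | Path) -> list[OrfAnnotation]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ReferenceError(f"{path}: annotation TSV missing columns {sorted(missing)}")
    orfs = []
    for _, row in df.iterrows():
        orfs.append(
            OrfAnnotation(
                gene_id=str(row.gene_id),
                transcript_id=str(row.transcript_id),
                strand=str(row.strand),
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
                leader_length=int(row.leader_length),
                incomplete_stop_nt=int(row.incomplete_stop_nt),
                transcript_5p=int(row.transcript_5p),
            )
        )
    return orfs


def read_annotations(path: str | Path) -> list[OrfAnnotation]:
    """Read ORF annotations from GFF3 (``.gff``/``.gff3``) or 8-column TSV."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return _orfs_from_gff3(path)
    return _orfs_from_tsv(path)


def load_reference(
    fasta_path: str | Path, annotation_path: str | Path, circular: bool = True
) -> tuple[GenomeReference, list[OrfAnnotation]]:
    """Load genome and annotations, validating every ORF against the genome.

    Overlapping reading frames of a bicistronic unit are both retained.
    """
    genome = read_genome_fasta(fasta_path, circular=circular)
    orfs = read_annotations(annotation_path)
    if not orfs:
        raise ReferenceError(f"{annotation_path}: no ORF records found")
    for orf in orfs:
        orf.validate_against(genome)
    return genome, orfs


def write_annotations_gff3(
    orfs: list[OrfAnnotation], path: str | Path, genome: GenomeReference
) -> None:
    """Write ORFs as GFF3 CDS features (1-based inclusive at the boundary)."""
    lines = ["##gff-version 3", f"##sequence-region {genome.id} 1 {len(genome)}"]
    for orf in orfs:
        attrs = ";".join(
            [
                f"ID={orf.gene_id}",
                f"gene_id={orf.gene_id}",
                f"transcript_id={orf.transcript_id}",
                f"leader_length={orf.leader_length}",
                f"incomplete_stop_nt={orf.incomplete_stop_nt}",
                f"transcript_5p={orf.transcript_5p + 1}",
            ]
        )
        lines.append(
            "\t".join(
                [
                    genome.id,
                    "mitoribo",
                    "CDS",
                    str(orf.cds_start + 1),
                    str(orf.cds_end),
                    ".",
                    orf.strand,
                    "0",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_annotations_tsv(orfs: list[OrfAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_id": o.gene_id,
                "transcript_id": o.transcript_id,
                "strand": o.strand,
                "cds_start": o.cds_start,
                "cds_end": o.cds_end,
                "leader_length": o.leader_length,
                "incomplete_stop_nt": o.incomplete_stop_nt,
                "transcript_5p": o.transcript_5p,
            }
            for o in orfs
        ]
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Codon extraction / usage / translation
# ---------------------------------------------------------------------------

def extract_orf_codons(ref: GenomeReference, orf: OrfAnnotation) -> list[str]:
    """Ordered RNA codons of one reading frame.

    Minus-strand frames are reverse-complemented first; a trailing
    incomplete stop codon is excluded (the genome does not contain the
    polyadenylation-completed codon).
    """
    orf.validate_against(ref)
    seq = ref.sequence[orf.cds_start : orf.cds_end]
    if orf.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    rna = seq.replace("T", "U")
    n = len(rna) // 3
    return [rna[3 * i : 3 * i + 3] for i in range(n)]


def codon_usage_profile(
    orfs_codons: list[list[str]],
    include_stops: bool = True,
    code: GeneticCode | None = None,
) -> CodonUsageProfile:
    """Tally codons over all reading frames into a fractional abundance profile.

    Overlapping codons of a bicistronic unit are counted once per reading
    frame (each frame is independently translated).  ``include_stops=False``
    drops stop codons from the tally (requires a genetic code).
    """
    counts = {c: 0 for c in CODONS}
    for codons in orfs_codons:
        for c in codons:
            counts[c] += 1
    if not include_stops:
        if code is None:
            code = GeneticCode.vertebrate_mitochondrial()
        for c in code.stop_codons:
            counts[c] = 0
    return CodonUsageProfile(counts=counts)


def genome_codon_usage(
    ref: GenomeReference,
    orfs: list[OrfAnnotation],
    include_stops: bool = True,
    code: GeneticCode | None = None,
) -> CodonUsageProfile:
    """Codon usage of the whole annotated coding region."""
    return codon_usage_profile(
        [extract_orf_codons(ref, o) for o in orfs], include_stops=include_stops, code=code
    )


def translate_prefix(
    ref: GenomeReference,
    orf: OrfAnnotation,
    n_residues: int,
    code: GeneticCode | None = None,
) -> str:
    """Translate the first ``n_residues`` codons of a reading frame.

    The first codon is rendered as initiator Met whenever it belongs to
    the code's start-codon set (AUA/AUU initiation in mitochondria), even
    though its elongation meaning differs.  A stop codon before
    ``n_residues`` is an error.
    """
    if code is None:
        code = GeneticCode.vertebrate_mitochondrial()
    codons = extract_orf_codons(ref, orf)
    if len(codons) < n_residues:
        raise ReferenceError(
            f"{orf.gene_id}: only {len(codons)} codons, need {n_residues}"
        )
    residues = []
    for i in range(n_residues):
        codon = codons[i]
        if i == 0 and codon in code.start_codons:
            residues.append("M")
            continue
        aa = code.table[codon]
        if aa == "*":
            raise ReferenceError(
                f"{orf.gene_id}: premature stop codon {codon} at codon position {i}"
            )
        residues.append(aa)
    return "".join(residues)
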