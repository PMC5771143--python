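"""Ground-truth synthetic data: genome, annotation and footprint libraries.

The generator emulates the statistical structure the analysis assumes of a
mitochondrial profiling experiment: a single circular contig carrying a
handful of reading frames with 0/1/3-nt leaders, at least one minus-strand
frame, optionally one bicistronic pair whose downstream frame starts
internally (its start codon displaced 40 nt upstream of the upstream
frame's stop, out of frame); footprint libraries of 24-37 nt reads drawn
per replicate with codon-identity dwell factors, an initiation-proximal
sampling boost, and multinomial (or Dirichlet-multinomial, for
overdispersion) replicate noise.  The seed fully determines every output.

Sampling model, per read: a gene is chosen with probability proportional
to ``expression x length`` (expression acts as a per-codon read-density
multiplier, so with uniform expression and unit dwell every coding codon
is equally likely and the expected fractional profile equals the genomic
abundance profile); a codon position within the gene proportional to the
dwell factor of its codon identity, multiplied by ``1 + initiation_weight``
for positions whose footprint covers the start codon; a length from the
configured distribution; the 5' end is then placed so the sampled codon
sits ``asite_offset`` nt from it, clamped at the transcript 5' terminus.
Clamped reads keep their drawn length measured from the terminus - this is
what creates the stacked 5'-terminus blocks over start codons.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .footprints import FootprintLibrary
from .reference import (
    CODON_INDEX,
    CODONS,
    GenomeReference,
    OrfAnnotation,
    extract_orf_codons,
    write_annotations_gff3,
)

_DNA_STOPS = ("TAA", "TAG", "AGA", "AGG")
_DNA_STARTS = ("ATG", "ATA", "ATT")
_DNA_SENSE = tuple(
    c.replace("U", "T") for c in CODONS if c.replace("U", "T") not in _DNA_STOPS
)


class SimulationError(ValueError):
    """Raised for infeasible simulation layouts."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror the real design: three biological replicates per
    condition, footprint lengths 24-37 nt (uniform by default), a 14-nt
    5'-end-to-A-site offset, unit dwell factors (no pausing), and one
    bicistronic unit with a 40-nt internal-start displacement.
    """

    seed: int = 0
    genome_length: int = 6000
    n_orfs: int = 6
    leader_lengths: tuple[int, ...] = (0, 1, 3)
    include_bicistronic: bool = True
    internal_start_displacement: int = 40
    dwell_factors: np.ndarray | None = None
    mutant_dwell_factors: np.ndarray | None = None
    initiation_weight: float = 1.0
    reads_per_replicate: int = 100_000
    replicates_per_condition: int = 3
    length_distribution: np.ndarray | None = None
    min_length: int = 24
    max_length: int = 37
    asite_offset: int = 14
    gene_expression: np.ndarray | None = None
    dispersion: float = math.inf

    def __post_init__(self) -> None:
        if self.dwell_factors is not None:
            self.dwell_factors = np.asarray(self.dwell_factors, dtype=float)
            if self.dwell_factors.shape != (64,) or np.any(self.dwell_factors <= 0):
                raise SimulationError("dwell_factors must be 64 positive reals")
        if self.mutant_dwell_factors is not None:
            self.mutant_dwell_factors = np.asarray(self.mutant_dwell_factors, dtype=float)
            if self.mutant_dwell_factors.shape != (64,) or np.any(
                self.mutant_dwell_factors <= 0
            ):
                raise SimulationError("mutant_dwell_factors must be 64 positive reals")
        if self.length_distribution is not None:
            ld = np.asarray(self.length_distribution, dtype=float)
            n_support = self.max_length - self.min_length + 1
            if ld.shape != (n_support,) or np.any(ld < 0):
                raise SimulationError(
                    f"length_distribution must be {n_support} non-negative probabilities"
                )
            self.length_distribution = ld / ld.sum()
        if self.initiation_weight < 0:
            raise SimulationError("initiation_weight must be >= 0")

    def control_dwell(self) -> np.ndarray:
        return (
            np.ones(64) if self.dwell_factors is None else self.dwell_factors
        )

    def conditions(self) -> dict[str, np.ndarray]:
        conds = {"control": self.control_dwell()}
        if self.mutant_dwell_factors is not None:
            conds["mutant"] = self.mutant_dwell_factors
        return conds

    def length_probs(self) -> np.ndarray:
        n = self.max_length - self.min_length + 1
        if self.length_distribution is None:
            return np.full(n, 1.0 / n)
        return self.length_distribution

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in (
            "dwell_factors",
            "mutant_dwell_factors",
            "length_distribution",
            "gene_expression",
        ):
            if d[key] is not None:
                d[key] = [float(x) for x in d[key]]
        d["leader_lengths"] = list(d["leader_lengths"])
        d["dispersion"] = "inf" if math.isinf(d["dispersion"]) else d["dispersion"]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if d.get("dispersion") in ("inf", None):
            d["dispersion"] = math.inf
        if "leader_lengths" in d:
            d["leader_lengths"] = tuple(d["leader_lengths"])
        for key in (
            "dwell_factors",
            "mutant_dwell_factors",
            "length_distribution",
            "gene_expression",
        ):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


@dataclass
class SimulationTruth:
    """Everything needed to recount the libraries from first principles."""

    gene_ids: list[str]
    dwell_factors: dict[str, np.ndarray]
    gene_expression: np.ndarray
    #: (condition, replicate_id) -> per-read arrays gene_index/codon_index/length
    records: dict[tuple[str, str], dict[str, np.ndarray]]

    def n_reads(self) -> int:
        return sum(len(r["length"]) for r in self.records.values())

    def records_frame(self) -> pd.DataFrame:
        frames = []
        for (cond, rep), rec in self.records.items():
            frames.append(
                pd.DataFrame(
                    {
                        "condition": cond,
                        "replicate_id": rep,
                        "gene_id": np.asarray(self.gene_ids)[rec["gene_index"]],
                        "codon_index": rec["codon_index"],
                        "length": rec["length"],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

def _random_cds(
    rng: np.random.Generator, n_codons: int, incomplete_stop_nt: int
) -> str:
    """A sense-strand CDS: start codon, stop-free body, (possibly clipped) stop.

    With an incomplete stop the genomic suffix must complete to a stop by
    polyadenylation, which restricts the choice to TA|A and T|AA (and AG|A).
    """
    start = str(rng.choice(_DNA_STARTS))
    body = "".join(rng.choice(_DNA_SENSE, size=n_codons - 2))
    if incomplete_stop_nt == 0:
        stop = str(rng.choice(_DNA_STOPS))
    elif incomplete_stop_nt == 1:
        stop = str(rng.choice(("TAA", "AGA")))
    else:
        stop = "TAA"
    full = start + body + stop
    return full[: len(full) - incomplete_stop_nt]


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeReference, list[OrfAnnotation]]:
    """Generate the reference contig and its ORF annotations.

    ``n_orfs`` monocistronic frames (every third on the minus strand,
    leaders cycling through ``leader_lengths``) plus, when configured, one
    plus-strand bicistronic pair sharing a transcript, the downstream
    frame starting out-of-frame inside the upstream one.
    """
    rng = np.random.default_rng([config.seed, 0])
    L = config.genome_length
    seq = rng.choice(np.array(list("ACGT")), size=L)
    orfs: list[OrfAnnotation] = []
    cursor = 80

    def place(sense: str, start_pos: int, strand: str) -> None:
        cds = sense if strand == "+" else str(Seq(sense).reverse_complement())
        if start_pos + len(cds) > L - 80:
            raise SimulationError(
                f"infeasible layout: genome_length={L} too short for requested ORFs"
            )
        seq[start_pos : start_pos + len(cds)] = list(cds)

    for i in range(config.n_orfs):
        n_cod = int(rng.integers(60, 121))
        strand = "-" if i % 3 == 2 else "+"
        incomplete = 1 if i == 1 else (2 if i == 3 else 0)
        leader = config.leader_lengths[i % len(config.leader_lengths)]
        sense = _random_cds(rng, n_cod, incomplete)
        place(sense, cursor, strand)
        orfs.append(
            OrfAnnotation(
                gene_id=f"orf{i + 1:02d}",
                transcript_id=f"rna{i + 1:02d}",
                strand=strand,
                cds_start=cursor,
                cds_end=cursor + len(sense),
                leader_length=leader,
                incomplete_stop_nt=incomplete,
            )
        )
        cursor += len(sense) + int(rng.integers(60, 100))

    if config.include_bicistronic:
        d = config.internal_start_displacement
        if d % 3 == 0:
            raise SimulationError(
                "internal_start_displacement must not be a multiple of 3 "
                "(the overlapping frames would be in frame)"
            )
        n_a = int(rng.integers(60, 100))
        a0, a1 = cursor, cursor + 3 * n_a
        b0 = a1 - (d + 3)
        k, r = divmod(b0 - a0, 3)
        for _attempt in range(200):
            sense_a = _random_cds(rng, n_a, 0)
            place(sense_a, a0, "+")
            seq[b0 : b0 + 3] = list("ATG")
            # repair upstream-frame codons clobbered by the internal ATG
            for kk in (k, k + 1):
                cod = "".join(seq[a0 + 3 * kk : a0 + 3 * kk + 3])
                if cod in _DNA_STOPS:
                    # mutate a base of this codon outside the ATG triplet
                    for pos in range(a0 + 3 * kk, a0 + 3 * kk + 3):
                        if not b0 <= pos < b0 + 3:
                            seq[pos] = "C"
                            break
            # downstream frame must be stop-free across the overlap
            overlap_ok = all(
                "".join(seq[b0 + 3 * j : b0 + 3 * j + 3]) not in _DNA_STOPS
                for j in range(1, (a1 - b0 - 3) // 3 + 1)
            )
            if overlap_ok:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise SimulationError("could not construct a stop-free bicistronic overlap")

        # complete the codon of the downstream frame that straddles the
        # upstream stop, then append its remaining body and stop
        jb = (a1 - b0) // 3  # first downstream codon not fully inside the overlap
        boundary_start = b0 + 3 * jb
        n_fill = boundary_start + 3 - a1
        while True:
            fill = "".join(rng.choice(np.array(list("ACGT")), size=n_fill))
            prefix = "".join(seq[boundary_start:a1])
            if prefix + fill not in _DNA_STOPS:
                break
        seq[a1 : a1 + n_fill] = list(fill)
        n_b = jb + 1 + int(rng.integers(40, 70))
        b_end = b0 + 3 * n_b
        tail = (
            "".join(rng.choice(_DNA_SENSE, size=n_b - jb - 2))
            + str(rng.choice(_DNA_STOPS))
        )
        if a1 + n_fill + len(tail) != b_end:  # pragma: no cover - arithmetic guard
            raise SimulationError("bicistronic layout arithmetic error")
        place(tail, a1 + n_fill, "+")
        orfs.append(
            OrfAnnotation(
                gene_id="bicA",
                transcript_id="rna_bic",
                strand="+",
                cds_start=a0,
                cds_end=a1,
                leader_length=0,
            )
        )
        orfs.append(
            OrfAnnotation(
                gene_id="bicB",
                transcript_id="rna_bic",
                strand="+",
                cds_start=b0,
                cds_end=b_end,
                leader_length=b0 - a0,
            )
        )
        cursor = b_end + 80

    if cursor > L - 80:
        raise SimulationError(
            f"infeasible layout: genome_length={L} too short for requested ORFs"
        )
    genome = GenomeReference(id="chrM_sim", sequence="".join(seq), circular=True)
    for orf in orfs:
        orf.validate_against(genome)
    return genome, orfs


# ---------------------------------------------------------------------------
# Footprint simulation
# ---------------------------------------------------------------------------

def _flatten_orfs(ref: GenomeReference, orfs: list[OrfAnnotation], offset: int):
    """Per-codon flattened arrays across all genes (sampling support)."""
    gene_of, codon_of, codon_id, e5_t, t5p_genome, is_fwd, boosted = (
        [], [], [], [], [], [], []
    )
    for g, orf in enumerate(orfs):
        cods = extract_orf_codons(ref, orf)
        n = len(cods)
        idx = np.array([CODON_INDEX[c] for c in cods], dtype=np.int64)
        tpos = orf.leader_length + 3 * np.arange(n)
        e5 = np.maximum(tpos - offset, 0)
        gene_of.append(np.full(n, g, dtype=np.int64))
        codon_of.append(np.arange(n, dtype=np.int64))
        codon_id.append(idx)
        e5_t.append(e5)
        t5p_genome.append(np.full(n, orf.transcript_5p, dtype=np.int64))
        is_fwd.append(np.full(n, orf.strand == "+"))
        # footprints whose clamped 5' end sits at/upstream of the start codon
        boosted.append(e5 <= orf.leader_length)
    return tuple(np.concatenate(a) for a in (gene_of, codon_of, codon_id, e5_t, t5p_genome, is_fwd, boosted))


def simulate_footprints(
    config: SimulationConfig,
    ref: GenomeReference,
    orfs: list[OrfAnnotation],
) -> tuple[list[FootprintLibrary], SimulationTruth]:
    """Draw replicate footprint libraries for every configured condition."""
    rng = np.random.default_rng([config.seed, 1])
    gene_of, codon_of, codon_id, e5_t, t5p_g, is_fwd, boosted = _flatten_orfs(
        ref, orfs, config.asite_offset
    )
    n_cells = gene_of.size
    expr = (
        np.ones(len(orfs))
        if config.gene_expression is None
        else np.asarray(config.gene_expression, dtype=float)
    )
    if expr.shape != (len(orfs),) or np.any(expr <= 0):
        raise SimulationError("gene_expression must be one positive weight per ORF")
    lengths_support = np.arange(config.min_length, config.max_length + 1)
    length_probs = config.length_probs()
    reads = config.reads_per_replicate

    libraries: list[FootprintLibrary] = []
    records: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for cond, dwell in config.conditions().items():
        w = expr[gene_of] * dwell[codon_id] * (1.0 + config.initiation_weight * boosted)
        p = w / w.sum()
        for r in range(config.replicates_per_condition):
            if math.isinf(config.dispersion):
                p_rep = p
            else:
                p_rep = np.zeros(n_cells)
                nz = p > 0
                p_rep[nz] = rng.dirichlet(config.dispersion * p[nz])
            counts = rng.multinomial(reads, p_rep)
            flat = np.repeat(np.arange(n_cells), counts)
            lens = rng.choice(lengths_support, size=reads, p=length_probs)
            e5 = e5_t[flat]
            five_prime = np.where(is_fwd[flat], t5p_g[flat] + e5, t5p_g[flat] - e5)
            strand = np.where(is_fwd[flat], "+", "-")
            rep_id = f"{cond}{r + 1}"
            libraries.append(
                FootprintLibrary(
                    replicate_id=rep_id,
                    condition=cond,
                    five_prime=five_prime,
                    length=lens,
                    strand=strand,
                    total_reads=reads,
                )
            )
            records[(cond, rep_id)] = {
                "gene_index": gene_of[flat],
                "codon_index": codon_of[flat],
                "length": lens,
            }
    truth = SimulationTruth(
        gene_ids=[o.gene_id for o in orfs],
        dwell_factors=config.conditions(),
        gene_expression=expr,
        records=records,
    )
    return libraries, truth


# ---------------------------------------------------------------------------
# Fixture output
# ---------------------------------------------------------------------------

def write_fixture(
    ref: GenomeReference,
    orfs: list[OrfAnnotation],
    libraries: list[FootprintLibrary],
    truth: SimulationTruth,
    out_dir: str | Path,
    config: SimulationConfig | None = None,
) -> dict[str, Path]:
    """Write FASTA + GFF3 + per-replicate BED6 + truth TSV (+ config YAML).

    The file set reloads cleanly through :func:`mitoribo.reference.load_reference`
    and :func:`mitoribo.footprints.read_footprints`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = out / "genome.fa"
    SeqIO.write(
        [SeqRecord(Seq(ref.sequence), id=ref.id, description="synthetic mitochondrial-like contig")],
        str(fasta),
        "fasta",
    )
    paths["fasta"] = fasta

    gff = out / "annotation.gff3"
    write_annotations_gff3(orfs, gff, ref)
    paths["annotation"] = gff

    for lib in libraries:
        bed = out / f"{lib.replicate_id}.bed"
        start, end = lib.intervals()
        pd.DataFrame(
            {
                "chrom": ref.id,
                "start": start,
                "end": end,
                "name": ".",
                "score": 0,
                "strand": lib.strand,
            }
        ).to_csv(bed, sep="\t", header=False, index=False)
        paths[f"bed:{lib.replicate_id}"] = bed

    truth_path = out / "truth.tsv"
    truth.records_frame().to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path

    if config is not None:
        cfg_path = out / "config.yaml"
        cfg_path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
        paths["config"] = cfg_path
    return paths
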