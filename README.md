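# mitoribo

Codon-level analysis of mitochondrial ribosome (mitoribosome) profiling
data: from aligned footprint libraries and an annotated mtDNA-like
reference to per-codon occupancy statistics, initiation-proximal
footprint structure, replicate clustering and leader-peptide hydropathy —
with a seeded synthetic-data generator so every stage can be verified
against known ground truth without any downloads.

## Who this is for

Mitoribosome profiling sequences the ~24–37 nt mRNA fragments protected
by translating 55S mitoribosomes. The 13 mtDNA-encoded reading frames
have unusual features — most mt-mRNAs start at or within 3 nt of the
start codon, AUA and AUU serve as initiators alongside AUG, UGA is Trp
and AGA/AGG are stops, two transcripts are bicistronic with overlapping
out-of-frame ORFs, and several ORFs end in incomplete stop codons
completed by polyadenylation. `mitoribo` implements the downstream
analysis of such libraries (adapter trimming and alignment are upstream
and out of scope).

## The statistics at the core

For each replicate library, reads are assigned to codons (fixed-offset
A-site proxy, default 14 nt from the 5′ end, or full-coverage counting)
and reduced to a **fractional footprint profile**: the 64-vector
*x* with *x_c* = (reads attributed to codon identity *c*) / (total reads).
The genomic comparison level is the **fractional abundance profile**
*a_c* = (occurrences of *c* in the coding region) / (total codons),
normalised so Σ*a_c* = 1.

* **Pausing (one-sample):** per codon, a two-tailed one-sample t test of
  the *n* replicate values of *x_c* against μ₀ = *a_c*,
  *t = (x̄_c − a_c)/(s_c/√n)* on *n*−1 df.
* **Condition comparison (two-sample):** per codon, a two-tailed Welch
  t test between control and mutant replicate profiles.
* Both families (64 codons) are Benjamini–Hochberg corrected;
  codons with *q* < 0.05 are called significant.
* **Terminus blocks:** footprints whose 5′ ends fall between the
  transcript 5′ terminus and 5 nt downstream of the start codon are
  grouped by identical 5′ start; each block's depth is its fraction of
  that population, and summary metrics report the fraction covering the
  start codon or the non-coding leader.
* **Clustering:** replicate profiles (plus the abundance profile) are
  compared by *D_ij* = 1 − Pearson *r_ij* and clustered agglomeratively
  (complete linkage by default, deterministic tie-breaking).
* **Hydropathy:** GRAVY (mean Kyte–Doolittle value) of the first 10
  residues of each ORF, with initiator recoding applied before scoring.

## Worked example

Simulate three replicate libraries in which glutamine CAG dwell is slowed
threefold, then run the one-sample pause test:

```python
import numpy as np
from mitoribo import (CODONS, codon_counts, fractional_footprint_profile,
                      genome_codon_usage, one_sample_codon_tests)
from mitoribo.simulate import SimulationConfig, simulate_genome, simulate_footprints

dwell = np.ones(64)
dwell[CODONS.index("CAG")] = 3.0          # slow glutamine codon threefold
cfg = SimulationConfig(seed=1, reads_per_replicate=200_000,
                       dwell_factors=dwell, include_bicistronic=False,
                       initiation_weight=0.0, asite_offset=0)
ref, orfs = simulate_genome(cfg)
libs, _ = simulate_footprints(cfg, ref, orfs)

usage = genome_codon_usage(ref, orfs)
profiles = [
    fractional_footprint_profile(codon_counts(lib, ref, orfs, offset=0),
                                 lib.total_reads, lib.replicate_id)
    for lib in libs
]
res = one_sample_codon_tests(profiles, usage)
print(res[res.significant][["codon", "amino_acid", "abundance_fraction",
                            "mean_fraction", "t", "q", "direction"]]
      .to_string(index=False))
```

Output:

```
codon amino_acid  abundance_fraction  mean_fraction          t        q direction
  ACG          T            0.024952       0.024192 -16.019672 0.049588  depleted
  AUA          M            0.017274       0.017052 -16.710413 0.049588  depleted
  CAC          H            0.024952       0.024312 -16.996415 0.049588  depleted
  CAG          Q            0.009597       0.028167 104.610171 0.005848  enriched
  UUC          F            0.017274       0.016822 -17.286794 0.049588  depleted
```

The slowed codon CAG is recovered as strongly enriched (its occupancy,
0.028, is about 2.9× its genomic abundance, 0.0096 — the small shortfall
from 3× is the renormalisation of a finite codon pool). The marginal
depletions at *q* ≈ 0.05 are the flip side of the same renormalisation:
extra ribosome residency on CAG slightly dilutes every other codon.

## Command line

The same stages are available as a CLI over a YAML config (see
`mitoribo --help`): `simulate`, `codon-usage`, `occupancy`, `pauses`,
`compare`, `terminus`, `profiles`, `cluster`, `hydropathy`, `all`.
Each run writes TSV tables, figures and a `run_log_<stage>.json` with
the version, seed and parameters.

## Layout

| module | contents |
| --- | --- |
| `mitoribo.reference` | genome/ORF containers, genetic code, codon extraction, usage profile |
| `mitoribo.footprints` | BED6/SAM/BAM readers, length filter, read→codon assignment |
| `mitoribo.occupancy` | fractional profiles, one-/two-sample t tests, BH-FDR |
| `mitoribo.terminus` | 5′-terminus windows, block fractions, start coverage, pileups |
| `mitoribo.profiles` | per-ORF positional distributions |
| `mitoribo.clustering` | 1−Pearson distances, agglomerative clustering, Newick export |
| `mitoribo.hydropathy` | Kyte–Doolittle GRAVY of leader peptides |
| `mitoribo.simulate` | ground-truth genome + footprint simulator, fixture writer |
| `mitoribo.validation` | end-to-end calibration/recovery experiments |
| `mitoribo.cli` | `mitoribo` command-line pipeline |

See `docs/methods.md` for the model, parameter and design details.
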