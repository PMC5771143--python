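# Methods

## Data model

A mitochondrial profiling experiment is reduced to three objects:

* **GenomeReference** — one circular DNA contig over strict ACGT
  (ambiguity codes are rejected at load). Coordinates are 0-based,
  half-open on the forward axis everywhere inside the package; the GFF3
  reader/writer converts from/to 1-based inclusive at the file boundary.
* **OrfAnnotation** — one reading frame with strand, CDS interval,
  5′-leader length (0/1/3 nt in the real system; large for internally
  initiating frames of bicistronic units), the transcript's 5′-terminus
  coordinate, and the number of stop-codon nucleotides missing from the
  genomic CDS (incomplete stops completed to UAA by polyadenylation).
  The frame invariant is (CDS length + missing stop nt) ≡ 0 mod 3.
  Both frames of a bicistronic unit share a transcript id and are both
  retained; frames wrapping the origin are rejected (none of the 13 real
  ORFs wrap, and the container still records circularity).
* **FootprintLibrary** — one replicate's protected fragments as
  (5′-most aligned base in transcript orientation, aligned length,
  strand), stored column-wise in numpy arrays so simulated libraries of
  10⁵–10⁶ reads stay cheap. Parse-time sanity bounds on length are
  15–50 nt; the analysis filter keeps 24–37 nt, the fragment range the
  mitoribosome protects.

The genetic code defaults to the vertebrate mitochondrial table
(NCBI transl_table 2, via Biopython): UGA→Trp, AGA/AGG→stop, AUA→Met,
initiators {AUU, AUC, AUA, AUG, GUG}. An override TSV is accepted for
testing.

## Read→codon assignment

The field's convention, and this package's default, assigns each read to
the codon containing the position `five_prime + offset` in transcript
orientation (`asite_offset` mode, offset 14 nt — mid-footprint for
24–37 nt fragments). A `coverage` mode (each codon whose three
nucleotides lie inside the aligned span) is retained for sensitivity
analysis. Reads shorter than offset+1 are skipped and counted. A read
over a bicistronic overlap contributes to each frame it satisfies the
rule for, so out-of-frame identities in the overlap receive counts from
both frames — a property of the measurement, discussed under
*Calibration* below.

Two denominator policies for fractional profiles read "total number of
reads per replicate" differently: `parsed` (all retained primary
alignments, before length filtering — the default, most literal
reading), `filtered` (after length filtering), and `cds` (reads assigned
to any codon). The choice rescales all 64 fractions identically, so
Pearson-based clustering is unaffected; the t tests are affected only
through μ₀ consistency, and the one-sample test is calibrated under the
`parsed`/`cds` choice used throughout the validation experiments.

## Statistical tests

Per codon, with n replicates: one-sample t = (x̄ − μ₀)/(s/√n) on n−1 df
against the genomic fractional abundance μ₀; two-sample Welch t with
Welch–Satterthwaite df between conditions (pooled-variance variant by
flag). Two-tailed p-values come from scipy's t distribution. Each
64-codon family is Benjamini–Hochberg corrected by the step-up rule
q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ (p₍ⱼ₎·m/j) capped at 1; significance is q < 0.05.

Degenerate inputs (possible with low-count synthetic data) are resolved
explicitly: replicate spread ≤ 1e-13 (fractions live on [0,1], so this
is numerically zero) with mean equal to the null value gives p = 1;
zero spread with unequal mean gives p = NaN, is flagged, and is excluded
from the BH family (m reduced). Codons absent from the coding region
(μ₀ = 0, observed 0) therefore land in the p = 1 branch rather than NaN.

## Terminus blocks

The initiation-proximal population of a gene is every strand-matched
footprint whose 5′ end lies between the transcript 5′ terminus and 5 nt
downstream of the start codon's **first** nucleotide (both ends
inclusive). The "+5" is anchored at the first nucleotide of the start
codon; the stacked-block figures this reproduces show five staggered
blocks immediately following the start-anchored one. For internally
initiating frames (large leaders), the upstream bound is
`start − leader_context` (default 40 nt, configurable) instead of the
transcript terminus; the unified rule is
upstream_bound = max(terminus, start − leader_context), which leaves
0/1/3-nt-leader genes untouched. Footprints sharing a 5′ start form one
block with a length histogram; block depth is the within-population
fraction. Start-coverage metrics: `includes_start_first_nt` (span
contains the start codon's first nucleotide and the 5′ end is at or
upstream of it) and `covers_leader` (5′ end strictly upstream of the
start codon; an error for leaderless transcripts, where it is
undefined). Both are emitted because published percentages of this kind
can be read either way.

## Clustering

Profiles are compared by D = 1 − Pearson r (computed on fractional
profiles; Pearson is invariant to each profile's affine scale, so counts
would cluster identically). Agglomeration is implemented directly —
complete (default), UPGMA-average and single linkage — with
deterministic tie-breaking towards the smallest cluster index, and is
cross-checked against `scipy.cluster.hierarchy.linkage` on tie-free
inputs in the tests. The abundance profile is clustered alongside the
six replicate profiles as a seventh leaf in the CLI's `cluster` stage.

## Hydropathy

GRAVY is the arithmetic mean of Kyte–Doolittle values (the published
20-entry scale is bundled and cross-checked against Biopython's copy;
an override TSV is accepted). The table scores the first 10 residues of
each frame, including the initiator, with AUA/AUU recoded to Met before
scoring so the peptide matches the mature protein. Frames shorter than
10 codons, or with a premature stop inside the prefix, are flagged and
carry NaN rather than aborting the table.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not the sequencing process (no adapter/error/contamination simulation —
alignment is upstream of this package).

**Genome.** `n_orfs` monocistronic frames of 60–120 codons with leaders
cycling through {0, 1, 3} nt, every third frame on the minus strand, one
frame with each incomplete-stop class, plus (by default) one plus-strand
bicistronic pair: the downstream frame starts at an internal ATG
displaced 40 nt upstream of the upstream frame's stop, out of frame
(a displacement divisible by 3 is rejected), with the overlap
constructed stop-free in both frames. Defaults: 6 monocistronic ORFs on
a 6 kb contig — a desk-scale genome with the same structural features as
the 16.6 kb, 13-ORF real system.

**Reads.** Per read: a codon position is drawn with probability
∝ expression(gene) × dwell(codon identity) × (1 + w·[initiation]),
where expression acts as a per-codon read-density multiplier (so with
uniform expression and unit dwell every coding position is equally
likely and the expected fractional profile equals the abundance
profile); the length is drawn from the configured 24–37 nt distribution
(uniform by default); the 5′ end is placed so the sampled codon sits at
the A-site offset, clamped at the transcript 5′ terminus. Clamped reads
keep their drawn length measured from the terminus: shortening them
instead (and resampling below 24 nt) would make every A-site in the
first ~5 codons of a leaderless frame unrepresentable and delete exactly
the initiation pileups the generator must emulate. The initiation
indicator marks positions whose clamped 5′ end lies at or upstream of
the start codon's first nucleotide — i.e. footprints that cover the
start — so the within-window composition shifts towards the terminus as
w grows, which is what makes start-coverage strictly monotone in w.
Replicate counts are multinomial, or Dirichlet-multinomial with
concentration `dispersion` for overdispersion (∞ = multinomial).
Defaults mirror the study design: 3 replicates per condition, 100k reads
per replicate, one control condition plus an optional mutant with its
own dwell vector. A single integer seed determines every output
byte-for-byte.

**What it does not model.** Sequencing error, rRNA/tRNA contamination,
nuclease sequence bias, UTR-length variation beyond the leader classes,
and any mechanistic initiation kinetics (the terminus pileup is a
sampling boost, not a kinetic model). Passing tests therefore show that
the pipeline recovers the truth of this generative model, not that real
libraries satisfy it.

## Calibration and the measurement's blind spot

Two properties of fixed-offset A-site assignment matter for validation
design. First, with a 14-nt offset, reads whose nominal 5′ end would lie
upstream of the transcript terminus clamp to it, so every A-site in
roughly the first five codons of a leaderless frame is re-assigned to
codon ~4: positions 0–3 are unmeasurable and position ~4 receives their
pile-up. Second, reads over a bicistronic overlap are counted once per
frame, inflating out-of-frame codon identities. Both effects bias the
plug-in null "expected fractional profile = abundance profile" by
several multinomial standard errors at 100k reads even with unit dwell —
they are properties of the measurement geometry, not of the statistics.
The null-calibration experiment therefore isolates the inferential
procedure: a monocistronic genome and a zero assignment offset, under
which the expected profile equals the abundance profile exactly and
every significant call is a false discovery. The power and
effect-recovery experiments keep the default 14-nt offset and instead
choose target codons whose every genomic occurrence is measurable
(no occurrence within the clamped region). Experiment sizes — 200 null
runs at 3×100k reads, 50 recovery runs at 3×500k, 50 clustering runs at
6×100k — keep the whole validation under a minute while leaving the
Monte-Carlo error well inside the margins being tested.

## Numerical choices

* Zero-variance tolerance 1e-13 absolute (fractions are on [0,1]).
* Pearson distances are symmetrised and clipped to [0,2] against
  rounding; a zero-variance profile is an error naming the profile.
* Clustering ties break towards the smallest cluster index; UPGMA
  average linkage weights merge distances by cluster size.
* BH-FDR restores input order and propagates NaN (excluded from m).
* The codon axis is the 64 RNA codons in lexicographic A<C<G<U order
  throughout.

## Known limitations

* The A-site offset is a single fixed value, not length-stratified;
  coverage mode is the only alternative assignment.
* The first codons of each frame are invisible to fixed-offset counting
  (see above); per-codon results there reflect the pile-up artifact.
* No deduplication or UMI handling (pileups at pause sites are signal in
  this assay); no soft-clip interpretation beyond the aligned span.
* Frames spanning the circular origin are rejected.
* The two-sample stage compares exactly two conditions; no multi-group
  ANOVA.
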