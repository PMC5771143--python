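"""End-to-end statistical validation experiments on synthetic data.

Each function runs the full pipeline (simulate genome -> simulate
footprint libraries -> codon counting -> fractional profiles -> tests /
clustering / terminus metrics) repeatedly and summarises how well the
procedures behave under known ground truth:

* false-discovery calibration under the complete null,
* power / direction recovery for a single slowed codon,
* recovery of a configured dwell factor as an occupancy/abundance ratio,
* separation of conditions by profile clustering,
* monotonicity of start-codon coverage in the initiation weight.

These are the quantities reported by ``scripts/acceptance.py``.

Two measurement artifacts of A-site profiling are deliberately removed
where an exact null is required (see docs/methods.md): with a nonzero
5'-end offset the first few codons of every frame are unmeasurable (their
reads clamp at the terminus and are re-assigned downstream), and reads
over a bicistronic overlap are counted once per frame, inflating
out-of-frame codon identities.  Both bias the plug-in null even with unit
dwell factors, so the calibration runs use a monocistronic genome and a
zero offset; the power/recovery runs keep the default 14-nt offset but
flag or measure only codons whose every occurrence is measurable.
"""

from __future__ import annotations

import numpy as np

from .clustering import hierarchical_cluster, pearson_distance_matrix
from .footprints import codon_counts
from .occupancy import (
    fractional_footprint_profile,
    one_sample_codon_tests,
    two_sample_codon_tests,
)
from .reference import CODON_INDEX, CODONS, extract_orf_codons, genome_codon_usage
from .simulate import SimulationConfig, simulate_footprints, simulate_genome
from .terminus import select_terminal_footprints, start_coverage_fraction


def _profiles_for(config, ref, orfs):
    libs, _ = simulate_footprints(config, ref, orfs)
    profiles = []
    for lib in libs:
        matrix = codon_counts(
            lib, ref, orfs, mode="asite_offset", offset=config.asite_offset
        )
        profiles.append(
            fractional_footprint_profile(
                matrix, lib.total_reads, replicate_id=lib.replicate_id,
                condition=lib.condition,
            )
        )
    return profiles


def _clean_codon_indices(ref, orfs, offset: int) -> np.ndarray:
    """Codon identities whose every genomic occurrence is A-site measurable.

    A position whose nominal 5' end would clamp at the transcript terminus
    (transcript offset < A-site offset) is either unmeasurable or receives
    the clamped pile-up, so identities occurring there are excluded.
    """
    edge = np.zeros(64, dtype=bool)
    seen = np.zeros(64, dtype=bool)
    for orf in orfs:
        cods = extract_orf_codons(ref, orf)
        for i, c in enumerate(cods):
            ci = CODON_INDEX[c]
            seen[ci] = True
            tpos = orf.leader_length + 3 * i
            if tpos - offset < 3:  # clamped, or A-site lands next to the pile-up
                edge[ci] = True
    return np.where(seen & ~edge)[0]


def null_calibration(
    seed: int,
    n_runs: int = 200,
    reads: int = 100_000,
    replicates: int = 3,
    alpha: float = 0.05,
) -> dict:
    """Complete-null calibration of the per-codon test procedures.

    All dwell factors are 1, the initiation boost is off, the genome is
    monocistronic and the assignment offset zero, so the expected
    fractional profile equals the genomic abundance profile exactly and
    every significant call is a false discovery.  Reports the empirical
    FDR of the one-sample procedure (mean of V/max(R,1) over runs, with
    its Monte-Carlo standard error) and the fraction of runs in which the
    two-sample comparison of two identically-distributed groups makes any
    call.
    """
    base = SimulationConfig(
        seed=seed, initiation_weight=0.0, include_bicistronic=False, asite_offset=0
    )
    ref, orfs = simulate_genome(base)
    abundance = genome_codon_usage(ref, orfs)
    fdp_one = np.zeros(n_runs)
    any_two = np.zeros(n_runs, dtype=bool)
    for run in range(n_runs):
        config = SimulationConfig(
            seed=seed + 1 + run,
            initiation_weight=0.0,
            include_bicistronic=False,
            asite_offset=0,
            reads_per_replicate=reads,
            replicates_per_condition=replicates,
            mutant_dwell_factors=np.ones(64),  # second, identically-distributed group
        )
        profiles = _profiles_for(config, ref, orfs)
        ctrl = [p for p in profiles if p.condition == "control"]
        mut = [p for p in profiles if p.condition == "mutant"]
        one = one_sample_codon_tests(ctrl, abundance, alpha=alpha)
        n_sig = int(one["significant"].sum())
        fdp_one[run] = n_sig / max(n_sig, 1)
        two = two_sample_codon_tests(ctrl, mut, alpha=alpha)
        any_two[run] = bool(two["significant"].any())
    return {
        "one_sample_empirical_fdr": float(fdp_one.mean()),
        "one_sample_fdr_mc_se": float(fdp_one.std(ddof=1) / np.sqrt(n_runs)),
        "two_sample_false_positive_run_fraction": float(any_two.mean()),
        "n_runs": n_runs,
    }


def pause_recovery(
    seed: int,
    n_runs: int = 50,
    reads: int = 500_000,
    factor: float = 3.0,
    codon: str | None = None,
    alpha: float = 0.05,
) -> dict:
    """Power to flag one slowed codon with the correct direction.

    The chosen codon's dwell factor is raised to ``factor`` in every run;
    success means the one-sample test calls it significant (q < alpha) and
    enriched.  By default the codon is the most frequent fully-measurable
    sense codon of the synthetic genome.
    """
    base = SimulationConfig(seed=seed, initiation_weight=0.0, include_bicistronic=False)
    ref, orfs = simulate_genome(base)
    abundance = genome_codon_usage(ref, orfs)
    frac = abundance.fraction_vector()
    if codon is None:
        clean = _clean_codon_indices(ref, orfs, base.asite_offset)
        ci = int(clean[np.argmax(frac[clean])])
    else:
        ci = CODON_INDEX[codon]
    if frac[ci] == 0:
        raise ValueError(f"codon {CODONS[ci]} absent from the synthetic coding region")
    dwell = np.ones(64)
    dwell[ci] = factor
    hits = 0
    for run in range(n_runs):
        config = SimulationConfig(
            seed=seed + 1 + run,
            initiation_weight=0.0,
            include_bicistronic=False,
            reads_per_replicate=reads,
            dwell_factors=dwell,
        )
        profiles = _profiles_for(config, ref, orfs)
        res = one_sample_codon_tests(profiles, abundance, alpha=alpha)
        row = res.iloc[ci]
        if bool(row["significant"]) and row["direction"] == "enriched":
            hits += 1
    return {"recovery_rate": hits / n_runs, "n_runs": n_runs, "codon": CODONS[ci]}


def dwell_ratio_recovery(
    seed: int,
    reads: int = 500_000,
    factor: float = 5.0,
    codon: str | None = None,
) -> dict:
    """Recover a configured dwell factor from empirical occupancy/abundance.

    With one codon slowed by ``factor``, the ratio of its fractional
    occupancy to its fractional abundance estimates
    ``factor / (1 + (factor-1) * a)`` with ``a`` the codon's abundance
    share; choosing the rarest fully-measurable codon keeps the
    renormalisation correction small.  Replicate profiles are averaged.
    """
    base = SimulationConfig(seed=seed, initiation_weight=0.0, include_bicistronic=False)
    ref, orfs = simulate_genome(base)
    abundance = genome_codon_usage(ref, orfs)
    frac = abundance.fraction_vector()
    if codon is None:
        clean = _clean_codon_indices(ref, orfs, base.asite_offset)
        ci = int(clean[np.argmin(frac[clean])])
    else:
        ci = CODON_INDEX[codon]
    dwell = np.ones(64)
    dwell[ci] = factor
    config = SimulationConfig(
        seed=seed + 1,
        initiation_weight=0.0,
        include_bicistronic=False,
        reads_per_replicate=reads,
        dwell_factors=dwell,
    )
    profiles = _profiles_for(config, ref, orfs)
    occ = float(np.mean([p.fractions[ci] for p in profiles]))
    return {
        "dwell_ratio": occ / float(frac[ci]),
        "configured_factor": factor,
        "codon": CODONS[ci],
        "n_reads": reads,
    }


def clustering_recovery(
    seed: int,
    n_runs: int = 50,
    reads: int = 100_000,
    effect: float = 2.0,
    n_affected: int = 5,
) -> dict:
    """Condition separation by the top dendrogram split.

    Control and mutant dwell vectors differ by ``effect`` on
    ``n_affected`` codons; success means the root merge of the
    complete-linkage dendrogram over the six replicate profiles puts the
    three control replicates on one side and the three mutant replicates
    on the other.
    """
    base = SimulationConfig(seed=seed, initiation_weight=0.0)
    ref, orfs = simulate_genome(base)
    frac = genome_codon_usage(ref, orfs).fraction_vector()
    affected = np.argsort(frac)[::-1][:n_affected]  # most frequent codons
    mutant = np.ones(64)
    mutant[affected] = effect
    hits = 0
    for run in range(n_runs):
        config = SimulationConfig(
            seed=seed + 1 + run,
            initiation_weight=0.0,
            reads_per_replicate=reads,
            mutant_dwell_factors=mutant,
        )
        profiles = _profiles_for(config, ref, orfs)
        dm = pearson_distance_matrix(profiles)
        dend = hierarchical_cluster(dm, linkage="complete")
        left, right = dend.top_split()
        by_cond = {
            frozenset(l for l in dm.labels if l.startswith("control")),
            frozenset(l for l in dm.labels if l.startswith("mutant")),
        }
        if {left, right} == by_cond:
            hits += 1
    return {"separation_rate": hits / n_runs, "n_runs": n_runs}


def terminus_monotonicity(
    seed: int,
    weights: tuple[float, ...] = (0.0, 1.0, 5.0),
    reads: int = 50_000,
) -> dict:
    """Start-codon coverage at the terminus as the initiation weight grows.

    Reports ``start_coverage_fraction`` (includes_start_first_nt) for the
    first leaderless gene, averaged over replicates, at each weight.
    """
    base = SimulationConfig(seed=seed)
    ref, orfs = simulate_genome(base)
    gene = next(o for o in orfs if o.leader_length == 0)
    fractions = []
    for w in weights:
        config = SimulationConfig(
            seed=seed + 1,  # same seed across weights: paired comparison
            initiation_weight=w,
            reads_per_replicate=reads,
        )
        libs, _ = simulate_footprints(config, ref, orfs)
        per_rep = [
            start_coverage_fraction(select_terminal_footprints(lib, gene), gene)
            for lib in libs
        ]
        fractions.append(float(np.mean(per_rep)))
    return {
        "weights": list(weights),
        "start_coverage_fractions": fractions,
        "strictly_increasing": all(a < b for a, b in zip(fractions, fractions[1:])),
        "gene_id": gene.gene_id,
    }
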