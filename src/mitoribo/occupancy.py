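"""Per-codon occupancy statistics.

Each replicate library is reduced to a fractional footprint profile: the
64-vector of footprint counts attributed to each codon identity, divided
by the replicate's total read count.  Dwell-time anomalies (pausing) are
then detected per codon by

* a one-sample two-tailed t test of the replicate fractions against the
  genomic fractional abundance of that codon, and
* a two-sample two-tailed Welch t test between conditions
  (control vs. mutant),

each followed by Benjamini-Hochberg FDR correction over the 64-codon
family, calling codons with q < 0.05 significant.

Zero-variance edge cases (possible with low-count synthetic data) are
resolved as: identical replicates equal to the null value give p = 1;
identical replicates different from the null give p = NaN and are
excluded from the FDR family (m reduced) with a ``degenerate`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .footprints import CodonCountMatrix
from .reference import CODON_INDEX, CODONS, CodonUsageProfile, GeneticCode

DEFAULT_FDR_THRESHOLD = 0.05

#: fractions live on [0, 1], so spreads below this are numerically zero
_ZERO_TOL = 1e-13


@dataclass
class FractionalCodonProfile:
    """64-vector of per-codon-identity footprint fractions for one replicate."""

    replicate_id: str
    fractions: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (64,):
            raise ValueError("fractional profile must have exactly 64 entries")
        if not np.all(np.isfinite(self.fractions)) or np.any(self.fractions < 0):
            raise ValueError("fractions must be finite and non-negative")

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions, index=list(CODONS), name=self.replicate_id)


def fractional_footprint_profile(
    matrix: CodonCountMatrix,
    total_reads: int,
    replicate_id: str = "",
    condition: str = "",
) -> FractionalCodonProfile:
    """Sum codon-identity counts over all ORF positions and divide by reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    sums = np.zeros(64, dtype=float)
    for gene_id, vec in matrix.counts.items():
        idx = np.array([CODON_INDEX[c] for c in matrix.codons[gene_id]], dtype=np.int64)
        np.add.at(sums, idx, vec)
    return FractionalCodonProfile(
        replicate_id=replicate_id, fractions=sums / total_reads, condition=condition
    )


# ---------------------------------------------------------------------------
# Multiple-testing correction
# ---------------------------------------------------------------------------

def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j>=i}(p_(j) * m / j)`` capped at 1, with the input order
    restored.  NaN entries are excluded from the family (m reduced) and
    returned as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    pv = p[finite]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(ranked, 1.0)
    q[finite] = qv
    return q


# ---------------------------------------------------------------------------
# Per-codon tests
# ---------------------------------------------------------------------------

def _stack(profiles: Sequence[FractionalCodonProfile]) -> np.ndarray:
    return np.stack([p.fractions for p in profiles], axis=0)


def _assemble(
    t: np.ndarray,
    p: np.ndarray,
    degenerate: np.ndarray,
    extra: dict[str, np.ndarray],
    effect: np.ndarray,
    alpha: float,
    code: GeneticCode | None,
) -> pd.DataFrame:
    q = bh_fdr(p)
    significant = np.where(np.isnan(q), False, q < alpha)
    direction = np.where(
        significant, np.where(effect > 0, "enriched", "depleted"), "none"
    )
    if code is None:
        code = GeneticCode.vertebrate_mitochondrial()
    df = pd.DataFrame(
        {
            "codon": list(CODONS),
            "amino_acid": [code.table[c] for c in CODONS],
            **extra,
            "t": t,
            "p": p,
            "q": q,
            "significant": significant.astype(bool),
            "direction": direction,
            "degenerate": degenerate.astype(bool),
        }
    )
    return df


def one_sample_codon_tests(
    profiles: Sequence[FractionalCodonProfile],
    abundance: CodonUsageProfile,
    alpha: float = DEFAULT_FDR_THRESHOLD,
    code: GeneticCode | None = None,
) -> pd.DataFrame:
    """Per-codon one-sample two-tailed t tests vs. the genomic abundance.

    ``t = (xbar - mu0) / (s / sqrt(n))`` with ``mu0`` the fractional
    abundance of the codon, two-tailed p on n-1 df, then BH-FDR over the
    64-codon family.
    """
    if len(profiles) < 2:
        raise ValueError("insufficient replicates: need at least 2 profiles")
    X = _stack(profiles)
    n = X.shape[0]
    mu0 = abundance.fraction_vector()
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    diff = mean - mu0

    t = np.zeros(64)
    p = np.ones(64)
    degenerate = np.zeros(64, dtype=bool)
    zero_var = sd <= _ZERO_TOL
    null_diff = np.abs(diff) <= _ZERO_TOL
    ok = ~zero_var
    t[ok] = diff[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    # zero variance, mean == mu0 (includes codons absent everywhere): p = 1
    t[zero_var & null_diff] = 0.0
    # zero variance, mean != mu0: undefined; exclude from the FDR family
    bad = zero_var & ~null_diff
    t[bad] = np.sign(diff[bad]) * np.inf
    p[bad] = np.nan
    degenerate[bad] = True

    return _assemble(
        t,
        p,
        degenerate,
        {"abundance_fraction": mu0, "mean_fraction": mean},
        effect=diff,
        alpha=alpha,
        code=code,
    )


def two_sample_codon_tests(
    control: Sequence[FractionalCodonProfile],
    treatment: Sequence[FractionalCodonProfile],
    alpha: float = DEFAULT_FDR_THRESHOLD,
    equal_var: bool = False,
    code: GeneticCode | None = None,
) -> pd.DataFrame:
    """Per-codon two-sample two-tailed t tests, control vs. treatment.

    Default is the unequal-variance (Welch) test with Welch-Satterthwaite
    df; ``equal_var=True`` selects the pooled-variance test.  ``t`` is
    signed as control minus treatment; ``direction`` reports the treatment
    relative to control.
    """
    if len(control) < 2 or len(treatment) < 2:
        raise ValueError("insufficient replicates: each group needs at least 2")
    X1, X2 = _stack(control), _stack(treatment)
    n1, n2 = X1.shape[0], X2.shape[0]
    m1, m2 = X1.mean(axis=0), X2.mean(axis=0)
    v1, v2 = X1.var(axis=0, ddof=1), X2.var(axis=0, ddof=1)
    diff = m1 - m2

    t = np.zeros(64)
    p = np.ones(64)
    degenerate = np.zeros(64, dtype=bool)
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = np.full(64, float(n1 + n2 - 2))
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
    ok = se > _ZERO_TOL
    t[ok] = diff[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=df[ok])
    bad = ~ok & (np.abs(diff) > _ZERO_TOL)
    t[bad] = np.sign(diff[bad]) * np.inf
    p[bad] = np.nan
    degenerate[bad] = True
    # zero spread in both groups with equal means keeps t = 0, p = 1

    return _assemble(
        t,
        p,
        degenerate,
        {"mean_control": m1, "mean_treatment": m2},
        effect=m2 - m1,
        alpha=alpha,
        code=code,
    )
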