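"""Multiple-testing accounting for metabolite and metabolite-ratio GWAS.

The prioritization strategy reduces the multiple-testing burden by testing
only the SNPs mapped to each metabolite's candidate genes.  The number of
tests is then

* for a single metabolite: the size of its unique SNP set;
* for an aggregated class measured as ``m`` species: unique SNP set × m
  (every species is tested against the same class-level SNP set);
* for a cross-class ratio A/B: |SNP(A) ∪ SNP(B)| × multiplicity, counting
  the unordered pair once (A/B and B/A give near-identical association
  p-values under the linear model, so they are one test);
* for within-class ratios of an m-species class: unique SNP set × m(m−1)/2.

Significance thresholds are Bonferroni (alpha / total tests).  For a
replication panel of correlated phenotypes the burden is instead
alpha / (independent SNPs × effective number of independent phenotypes),
with the effective number estimated from the eigenvalues of the phenotype
correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np


@dataclass(frozen=True)
class TestEntry:
    label: str
    unique_snp_count: int
    multiplicity: int = 1

    @property
    def n_tests(self) -> int:
        return self.unique_snp_count * self.multiplicity


@dataclass(frozen=True)
class TestAccount:
    """Per-metabolite test counts with the Bonferroni threshold."""

    entries: tuple[TestEntry, ...]
    alpha: float = 0.05

    @property
    def total_tests(self) -> int:
        return sum(e.n_tests for e in self.entries)

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.total_tests)

    def to_rows(self) -> list[tuple[str, int, int, int]]:
        return [
            (e.label, e.unique_snp_count, e.multiplicity, e.n_tests)
            for e in self.entries
        ]


@dataclass(frozen=True)
class RatioPair:
    """Unordered cross-class ratio A/B; the reciprocal is the same test."""

    label_a: str
    label_b: str
    union_snp_count: int
    multiplicity: int = 1

    @property
    def n_tests(self) -> int:
        return self.union_snp_count * self.multiplicity


@dataclass(frozen=True)
class WithinClassRatios:
    """All pairwise ratios among the m species of one aggregated class."""

    class_label: str
    unique_snp_count: int
    n_members: int

    @property
    def n_combinations(self) -> int:
        return self.n_members * (self.n_members - 1) // 2

    @property
    def n_tests(self) -> int:
        return self.unique_snp_count * self.n_combinations


@dataclass(frozen=True)
class RatioAccount:
    pairs: tuple[RatioPair, ...]
    within_class: tuple[WithinClassRatios, ...]
    alpha: float = 0.05

    @property
    def total_tests(self) -> int:
        return sum(p.n_tests for p in self.pairs) + sum(
            w.n_tests for w in self.within_class
        )

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.total_tests)


@dataclass(frozen=True)
class EffectiveTests:
    n_variables: int
    m_eff: float

    def __post_init__(self):
        if not (1.0 - 1e-9 <= self.m_eff <= self.n_variables + 1e-9):
            raise ValueError(
                f"m_eff {self.m_eff} outside [1, n_variables={self.n_variables}]"
            )


def count_tests(
    entries: Sequence[tuple[str, int, int]], alpha: float = 0.05
) -> TestAccount:
    """Build a :class:`TestAccount` from (label, unique_snp_count, multiplicity).

    Example: carnitine with a unique SNP set of 11,239 measured as 41
    species contributes 11,239 × 41 = 460,799 tests.
    """
    out = []
    for label, count, mult in entries:
        if count < 0:
            raise ValueError(f"negative SNP count for {label!r}: {count}")
        if mult < 1:
            raise ValueError(f"multiplicity must be >= 1 for {label!r}, got {mult}")
        out.append(TestEntry(label=label, unique_snp_count=count, multiplicity=mult))
    return TestAccount(entries=tuple(out), alpha=alpha)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


def count_ratio_tests(
    cross_pairs: Sequence[tuple[str, str, int, int]],
    within_classes: Sequence[tuple[str, int, int]] = (),
    alpha: float = 0.05,
) -> RatioAccount:
    """Account for ratio phenotypes.

    ``cross_pairs`` rows are (label_A, label_B, union_snp_count,
    multiplicity); pairs are unordered and each unordered pair may appear
    once.  ``within_classes`` rows are (class_label, unique_snp_count,
    n_members) and contribute n(n−1)/2 combinations each.
    """
    seen: set[frozenset[str]] = set()
    pairs = []
    for a, b, union, mult in cross_pairs:
        if a == b:
            raise ValueError(
                f"self-pair {a!r}/{b!r}; within-class ratios go in within_classes"
            )
        key = frozenset((a, b))
        if key in seen:
            raise ValueError(f"duplicate unordered pair {a!r}/{b!r}")
        seen.add(key)
        pairs.append(
            RatioPair(label_a=a, label_b=b, union_snp_count=union, multiplicity=mult)
        )
    within = []
    for label, count, n_members in within_classes:
        if n_members < 2:
            raise ValueError(
                f"within-class entry {label!r} needs n_members >= 2, got {n_members}"
            )
        within.append(
            WithinClassRatios(
                class_label=label, unique_snp_count=count, n_members=n_members
            )
        )
    return RatioAccount(pairs=tuple(pairs), within_class=tuple(within), alpha=alpha)


# ---------------------------------------------------------------------------
# effective number of independent tests


def _f_li_ji(lam: np.ndarray) -> float:
    # f(λ) = I(λ >= 1) + (λ - floor(λ))
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def _f_cheverud_nyholt(lam: np.ndarray) -> float:
    n = lam.size
    var = float(np.var(lam, ddof=1)) if n > 1 else 0.0
    return 1 + (n - 1) * (1 - var / n)

_M_EFF_ESTIMATORS: dict[str, Callable[[np.ndarray], float]] = {
    "li_ji": _f_li_ji,
    "cheverud_nyholt": _f_cheverud_nyholt,
}


def m_eff_li(correlation: np.ndarray, estimator: str = "li_ji") -> float:
    """Effective number of independent variables from a correlation matrix.

    The default estimator sums, over eigenvalues λ of the correlation
    matrix, ``I(λ >= 1) + (λ - floor(λ))`` (Li & Ji).  An eigenvalue above 1
    contributes one whole independent variable plus its fractional excess;
    the spectrum of an identity matrix gives back n, a rank-one matrix gives
    1.  The ``cheverud_nyholt`` variance-based estimator is available as an
    alternative.  Estimates are clipped into [1, n].
    """
    corr = np.asarray(correlation, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError(f"correlation must be a square matrix, got {corr.shape}")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have a unit diagonal")
    try:
        f = _M_EFF_ESTIMATORS[estimator]
    except KeyError:
        raise ValueError(
            f"unknown estimator {estimator!r}; choose from {sorted(_M_EFF_ESTIMATORS)}"
        ) from None
    lam = np.linalg.eigvalsh(corr)
    # f(lam) is discontinuous at integers; snap eigenvalues to 9 decimals so
    # roundoff (e.g. 1.999999999 for an exact 2) cannot flip a term by ~1
    lam = np.round(np.clip(lam, 0.0, None), 9)
    return float(np.clip(f(lam), 1.0, corr.shape[0]))


def replication_threshold(
    alpha: float, n_independent_snps: int, m_eff: float
) -> float:
    """alpha / (independent SNPs × effective number of phenotypes)."""
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if n_independent_snps < 1:
        raise ValueError(f"n_independent_snps must be >= 1, got {n_independent_snps}")
    if m_eff < 1:
        raise ValueError(f"m_eff must be >= 1, got {m_eff}")
    return alpha / (n_independent_snps * m_eff)
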