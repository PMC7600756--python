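"""Chi-square goodness-of-fit of hybrid genome content.

Tests whether the observed per-parent allele counts across one or more
hybrid strains depart from the counts expected under each strain's ploidy
model (e.g. a roughly triploid hybrid with two sub-genome copies from one
parent and one from the other expects a 2:1 split; a balanced tetraploid
expects 1:1).

The statistic is the usual Σ (O−E)²/E over all strain × parent cells with
E = strain total × expected fraction.  Degrees of freedom follow the
one-sample goodness-of-fit convention, *cells − 1* (not the contingency
(rows−1)(cols−1) rule): with four strains and two parents there are eight
cells and df = 7, for which the 1% critical value is 18.48.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

from scipy.stats import chi2

__all__ = [
    "ContentTable",
    "GofResult",
    "chi_square_gof",
    "chi_square_critical",
    "upper_tail_p",
]


@dataclass
class ContentTable:
    """Observed per-parent allele counts and expected fractions per strain."""

    strains: List[str]
    observed: Dict[str, Dict[str, float]]
    expected_fractions: Dict[str, Dict[str, float]]

    def __post_init__(self) -> None:
        for strain in self.strains:
            obs = self.observed[strain]
            frac = self.expected_fractions[strain]
            if set(obs) != set(frac):
                raise ValueError(f"strain {strain!r}: parent labels differ")
            if any(v < 0 for v in obs.values()):
                raise ValueError(f"strain {strain!r}: negative observed count")
            total_frac = sum(frac.values())
            if abs(total_frac - 1.0) > 1e-9:
                raise ValueError(
                    f"strain {strain!r}: expected fractions sum to {total_frac}"
                )

    @classmethod
    def balanced(cls, strains: Sequence[str], parents: Sequence[str],
                 observed: Dict[str, Dict[str, float]]) -> "ContentTable":
        """1:1 expectation per strain (balanced, tetraploid-like content)."""
        frac = {s: {p: 1.0 / len(parents) for p in parents} for s in strains}
        return cls(list(strains), observed, frac)

    @classmethod
    def two_to_one(cls, strains: Sequence[str], major_parent: str,
                   minor_parent: str,
                   observed: Dict[str, Dict[str, float]]) -> "ContentTable":
        """2:1 expectation per strain (triploid-like content)."""
        frac = {
            s: {major_parent: 2.0 / 3.0, minor_parent: 1.0 / 3.0}
            for s in strains
        }
        return cls(list(strains), observed, frac)


@dataclass
class GofResult:
    statistic: float
    df: int
    p_value: float
    critical_value: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def chi_square_critical(alpha: float, df: int) -> float:
    """(1−alpha) quantile of the chi-square distribution."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(chi2.ppf(1.0 - alpha, df))


def upper_tail_p(statistic: float, df: int) -> float:
    """Upper-tail (survival) probability of chi-square at ``df``.

    Evaluated through the regularized incomplete gamma survival function,
    which stays accurate for extreme statistics (p-values down to the
    smallest normal double, ~1e-308) rather than underflowing via the CDF.
    """
    if statistic < 0:
        raise ValueError("statistic must be >= 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(chi2.sf(statistic, df))


def chi_square_gof(table: ContentTable, alpha: float = 0.01) -> GofResult:
    """Goodness-of-fit of observed allele counts to ploidy expectations."""
    statistic = 0.0
    cells = 0
    for strain in table.strains:
        obs = table.observed[strain]
        frac = table.expected_fractions[strain]
        total = sum(obs.values())
        for parent in sorted(obs):
            expected = total * frac[parent]
            if expected <= 0:
                raise ValueError(
                    f"strain {strain!r}, parent {parent!r}: zero expected count"
                )
            statistic += (obs[parent] - expected) ** 2 / expected
            cells += 1
    df = cells - 1
    if df < 1:
        raise ValueError("need at least two cells")
    return GofResult(
        statistic=statistic,
        df=df,
        p_value=upper_tail_p(statistic, df),
        critical_value=chi_square_critical(alpha, df),
        alpha=alpha,
    )
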