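"""Mendelian segregation expectations and distortion tests.

Expected genotype counts under a cross ratio (1:2:1 intercross, 1:1
backcross, ...), a goodness-of-fit chi-square, and the exact binomial
probability of observing at most k individuals of a class — the
depletion signal used to flag recessive lethality.

Rounding of expected counts uses round-half-to-even: applied to the
quarter-integer expectations of a 1:2:1 cross it is the unique simple
rule consistent with 22.5 -> 22, 4.5 -> 4, 18.5 -> 18, 3.5 -> 4 and
15.5 -> 16 simultaneously.  Unrounded expectations always sum exactly
to the observed total (exact rational arithmetic).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from scipy.stats import chi2

from .errors import StatsError

__all__ = [
    "SegregationModel",
    "SegregationResult",
    "INTERCROSS_1_2_1",
    "BACKCROSS_1_1",
    "expected_counts",
    "gof_chisq",
    "absence_probability",
    "segregation_test",
]


@dataclass(frozen=True)
class SegregationModel:
    """Ordered genotype classes with their expected ratio."""

    classes: tuple[str, ...]
    ratios: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.ratios):
            raise ValueError("classes and ratios differ in length")
        if any(r <= 0 for r in self.ratios):
            raise ValueError("ratios must be positive")

    @property
    def proportions(self) -> tuple[Fraction, ...]:
        total = sum(self.ratios)
        return tuple(Fraction(r, total) for r in self.ratios)


INTERCROSS_1_2_1 = SegregationModel(("hom_wt", "het", "hom_mut"), (1, 2, 1))
BACKCROSS_1_1 = SegregationModel(("het", "hom"), (1, 1))


@dataclass(frozen=True)
class SegregationResult:
    observed: tuple[int, ...]
    expected: tuple[float, ...]
    expected_rounded: tuple[int, ...]
    statistic: float
    df: int
    p: float
    absence_p: tuple[float, ...]


def expected_counts(
    total: int, model: SegregationModel
) -> tuple[tuple[float, ...], tuple[int, ...]]:
    """Expected class counts for ``total`` offspring: exact real values
    and their half-to-even roundings."""
    if total < 0:
        raise ValueError("total must be >= 0")
    exact = [total * p for p in model.proportions]
    return tuple(float(e) for e in exact), tuple(round(e) for e in exact)


def gof_chisq(
    observed: Sequence[int], model: SegregationModel
) -> tuple[float, int, float]:
    """Pearson goodness-of-fit: sum (O-E)^2/E, df = classes - 1, upper
    tail of the chi-square distribution."""
    if len(observed) != len(model.classes):
        raise ValueError("observed length does not match model classes")
    total = sum(observed)
    if total <= 0:
        raise StatsError("no observations")
    expected = [float(total * p) for p in model.proportions]
    if any(e == 0 for e in expected):
        raise StatsError("zero expected count")
    stat = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    df = len(observed) - 1
    return stat, df, float(chi2.sf(stat, df))


def absence_probability(k: int, n: int, p0: float) -> float:
    """Exact lower binomial tail P(X <= k) under Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("need 0 < p0 < 1")
    q = Fraction(p0).limit_denominator(10**12)
    total = Fraction(0)
    term = (1 - q) ** n  # i = 0
    binom = 1
    for i in range(0, k + 1):
        if i > 0:
            binom = binom * (n - i + 1) // i
            term = q**i * (1 - q) ** (n - i)
        total += binom * term
    return float(min(total, Fraction(1)))


def segregation_test(
    observed: Sequence[int], model: SegregationModel
) -> SegregationResult:
    """Fit, rounding and per-class exact absence probabilities in one
    result object."""
    total = sum(observed)
    expected, rounded = expected_counts(total, model)
    stat, df, p = gof_chisq(observed, model)
    absence = tuple(
        absence_probability(o, total, float(prop))
        for o, prop in zip(observed, model.proportions)
    )
    return SegregationResult(
        observed=tuple(int(o) for o in observed),
        expected=expected,
        expected_rounded=rounded,
        statistic=stat,
        df=df,
        p=p,
        absence_p=absence,
    )
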